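"""Binary-classification evaluation: confusion matrix, sensitivity, PPV, accuracy.

Metrics are computed at full precision and rounded half-up only at
presentation, with the decimal count a report option — published comparison
tables in this domain mix one- and two-decimal formatting, and half-up
rounding at one decimal reconciles e.g. a 195/197 PPV (98.98) printed as 99.0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion_matrix",
    "sensitivity",
    "specificity",
    "ppv",
    "npv",
    "accuracy",
    "round_half_up",
    "evaluate",
    "compare_models",
]


def round_half_up(value: float, decimals: int = 2) -> float:
    value = float(value)
    if not np.isfinite(value):
        return value
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int
    positive_label: int = 1

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion matrix counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def as_table(self) -> pd.DataFrame:
        """Rows = true class, columns = predicted class."""
        return pd.DataFrame(
            [[self.tn, self.fp], [self.fn, self.tp]],
            index=pd.Index(["negative", "positive"], name="true"),
            columns=pd.Index(["negative", "positive"], name="predicted"),
        )


def confusion_matrix(y_true, y_pred, positive_label: int = 1) -> ConfusionMatrix:
    t = np.asarray(y_true)
    p = np.asarray(y_pred)
    if t.size == 0:
        raise ValueError("cannot build a confusion matrix from empty label vectors")
    if t.shape != p.shape:
        raise ValueError(f"label vectors differ in length: {t.shape} vs {p.shape}")
    values = set(np.unique(t)) | set(np.unique(p))
    if not values <= {0, 1}:
        raise ValueError(f"labels must be binary (0/1); found values {sorted(values)}")
    pos, neg = positive_label, 1 - positive_label
    return ConfusionMatrix(
        tp=int(((t == pos) & (p == pos)).sum()),
        fp=int(((t == neg) & (p == pos)).sum()),
        tn=int(((t == neg) & (p == neg)).sum()),
        fn=int(((t == pos) & (p == neg)).sum()),
        positive_label=positive_label,
    )


def sensitivity(cm: ConfusionMatrix) -> float:
    """Recall of the positive class, percent: 100*TP/(TP+FN)."""
    if cm.tp + cm.fn == 0:
        raise ZeroDivisionError("sensitivity undefined: no positive ground-truth samples")
    return 100.0 * cm.tp / (cm.tp + cm.fn)


def specificity(cm: ConfusionMatrix) -> float:
    if cm.tn + cm.fp == 0:
        raise ZeroDivisionError("specificity undefined: no negative ground-truth samples")
    return 100.0 * cm.tn / (cm.tn + cm.fp)


def ppv(cm: ConfusionMatrix) -> float:
    """Positive predictive value, percent: 100*TP/(TP+FP)."""
    if cm.tp + cm.fp == 0:
        raise ZeroDivisionError("PPV undefined: no positive predictions")
    return 100.0 * cm.tp / (cm.tp + cm.fp)


def npv(cm: ConfusionMatrix) -> float:
    if cm.tn + cm.fn == 0:
        raise ZeroDivisionError("NPV undefined: no negative predictions")
    return 100.0 * cm.tn / (cm.tn + cm.fn)


def accuracy(cm: ConfusionMatrix) -> float:
    if cm.n == 0:
        raise ZeroDivisionError("accuracy undefined on zero samples")
    return 100.0 * (cm.tp + cm.tn) / cm.n


@dataclass
class MetricsReport:
    sensitivity: float
    ppv: float
    accuracy: float
    cm: ConfusionMatrix
    n: int
    dataset_id: str = ""
    model_id: str = ""
    ablation_mode: str = "full"

    @classmethod
    def from_cm(cls, cm: ConfusionMatrix, **meta) -> "MetricsReport":
        # a report survives degenerate prediction vectors (e.g. no positive
        # calls): undefined metrics become NaN instead of aborting a run
        def safe(f):
            try:
                return f(cm)
            except ZeroDivisionError:
                return float("nan")

        return cls(
            sensitivity=safe(sensitivity), ppv=safe(ppv), accuracy=safe(accuracy),
            cm=cm, n=cm.n, **meta,
        )

    def rounded(self, decimals: int = 2) -> dict:
        return {
            "sensitivity": round_half_up(self.sensitivity, decimals),
            "ppv": round_half_up(self.ppv, decimals),
            "accuracy": round_half_up(self.accuracy, decimals),
        }

    def to_json(self, path=None, decimals: int = 2) -> dict:
        payload = {
            **self.rounded(decimals),
            "confusion_matrix": asdict(self.cm),
            "n": self.n,
            "dataset_id": self.dataset_id,
            "model_id": self.model_id,
            "ablation_mode": self.ablation_mode,
        }
        if path is not None:
            Path(path).parent.mkdir(parents=True, exist_ok=True)
            Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
        return payload


def evaluate(model, dataset, *, batch_size: int = 32, dataset_id: str = "", model_id: str = "") -> MetricsReport:
    """Run the model over a dataset (argmax decision rule) and report metrics."""
    if len(dataset) == 0:
        raise ValueError("cannot evaluate on an empty dataset")
    preds = []
    for start in range(0, len(dataset), batch_size):
        sl = slice(start, start + batch_size)
        masks = None if dataset.masks is None else dataset.masks[sl]
        preds.append(model.forward(dataset.images[sl], masks=masks).predictions)
    cm = confusion_matrix(dataset.labels, np.concatenate(preds))
    return MetricsReport.from_cm(
        cm, dataset_id=dataset_id, model_id=model_id, ablation_mode=model.ablation_mode
    )


def compare_models(reports: list, decimals: int = 2) -> pd.DataFrame:
    """One row per report plus pairwise accuracy margins (row minus column)."""
    if not reports:
        raise ValueError("need at least one report to compare")
    ids = [r.model_id or f"model{i}" for i, r in enumerate(reports)]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate model ids in comparison: {ids}")
    rows = []
    for mid, r in zip(ids, reports):
        row = {"model": mid, **r.rounded(decimals), "n": r.n}
        for other_id, other in zip(ids, reports):
            if other_id != mid:
                row[f"margin_vs_{other_id}"] = round_half_up(r.accuracy - other.accuracy, decimals)
        rows.append(row)
    return pd.DataFrame(rows)
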