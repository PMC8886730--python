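"""Training procedures: segmentation pretraining and alternating optimization.

Two training devices are central here:

* **Transfer learning** — the attention encoder-decoder is first trained as a
  lung-field segmenter (sigmoid of its raw map against binary lung masks,
  equally weighted binary cross-entropy + soft Dice). The resulting weights
  initialize the attention body of the classifier, steering global attention
  toward the lung fields from the start.

* **Alternating training** — the classifier's two components (the "main"
  backbone+classifier-head side and the "attention" encoder-decoder+projection
  side) are trained in alternation: in any given epoch exactly one side's
  parameters are updated while the other side is frozen. Freezing is enforced
  by excluding the frozen side from the optimizer step; optimizer moments are
  keyed by parameter name so each side resumes its own state when it thaws.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np

from . import nn
from .io import RunConfig, load_and_resize, load_mask
from .model import MultiScaleAttentionClassifier
from .phantom import PhantomSpec, generate_sample
from .unet import EncoderDecoder

__all__ = [
    "AlternatingSchedule",
    "component_for_epoch",
    "pretrain_encoder_decoder",
    "train_alternating",
    "ArrayDataset",
    "phantom_dataset",
    "dataset_from_manifest",
    "dice_score",
]


@dataclass
class ArrayDataset:
    """In-memory dataset: images (N,h,w,1), labels (N,), optional masks (N,h,w)."""

    images: np.ndarray
    labels: np.ndarray
    masks: np.ndarray | None = None

    def __len__(self):
        return len(self.images)

    def subset(self, idx) -> "ArrayDataset":
        return ArrayDataset(
            self.images[idx],
            self.labels[idx],
            None if self.masks is None else self.masks[idx],
        )


def phantom_dataset(n: int, spec: PhantomSpec, seed: int, pos_fraction: float = 0.5) -> ArrayDataset:
    """Render n phantoms directly to arrays (no disk round-trip)."""
    n_pos = int(round(n * pos_fraction))
    labels = np.array([1] * n_pos + [0] * (n - n_pos))
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xD5]))
    rng.shuffle(labels)
    images, masks = [], []
    for i in range(n):
        s = generate_sample(spec, seed=seed * 100003 + i, label=int(labels[i]))
        images.append(s.image)
        masks.append(s.lung_mask)
    return ArrayDataset(np.stack(images), labels.astype(int), np.stack(masks))


def dataset_from_manifest(manifest, size: int, split: str | None = None) -> ArrayDataset:
    """Load an ArrayDataset from a manifest DataFrame (paths already resolved)."""
    df = manifest
    if split is not None:
        df = df[df["split"] == split]
        if len(df) == 0:
            raise ValueError(f"manifest has no rows with split={split!r}")
    images = np.stack([load_and_resize(p, size) for p in df["path"]])
    labels = df["label"].to_numpy(dtype=int)
    masks = None
    if "mask_path" in df.columns and all(isinstance(p, str) and p for p in df["mask_path"]):
        masks = np.stack([load_mask(p, size) for p in df["mask_path"]])
    return ArrayDataset(images, labels, masks)


# ---------------------------------------------------------------------------
# alternation schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlternatingSchedule:
    period_epochs: int = 1
    first_component: str = "attention"
    total_epochs: int = 10

    def __post_init__(self):
        if self.period_epochs < 1:
            raise ValueError("period_epochs must be >= 1")
        if self.first_component not in ("attention", "main"):
            raise ValueError("first_component must be 'attention' or 'main'")
        if self.total_epochs < 0:
            raise ValueError("total_epochs must be >= 0")


def component_for_epoch(epoch: int, schedule: AlternatingSchedule) -> str:
    """Which component trains in a given epoch: pure function of the schedule."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    other = "main" if schedule.first_component == "attention" else "attention"
    return schedule.first_component if (epoch // schedule.period_epochs) % 2 == 0 else other


# ---------------------------------------------------------------------------
# segmentation pretraining
# ---------------------------------------------------------------------------

def dice_score(encdec: EncoderDecoder, images: np.ndarray, masks: np.ndarray, threshold: float = 0.5) -> float:
    """Hard Dice of thresholded sigma(A_G) against binary masks, pooled over samples."""
    raw = encdec.forward_array(images)
    prob = nn._sigmoid_np(raw[..., 0])
    pred = (prob >= threshold).astype(np.float64)
    m = np.asarray(masks, dtype=np.float64)
    inter = (pred * m).sum()
    denom = pred.sum() + m.sum()
    return float(2.0 * inter / denom) if denom > 0 else 1.0


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def pretrain_encoder_decoder(
    encdec: EncoderDecoder,
    dataset: ArrayDataset,
    *,
    epochs: int = 30,
    batch_size: int = 8,
    learning_rate: float = 3e-3,
    seed: int = 0,
) -> list[dict]:
    """Train sigma(A_G) toward the lung masks; mutates encdec in place.

    Loss is 0.5 * BCE + 0.5 * (1 - soft Dice). Returns the per-epoch history.
    With ``epochs=0`` the parameters are returned untouched.
    """
    if dataset.masks is None:
        raise ValueError("segmentation pretraining requires a dataset with lung masks")
    params = encdec.params()
    opt = nn.Adam(lr=learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([0x9E6, int(seed)]))
    history = []
    for epoch in range(epochs):
        t0 = time.perf_counter()
        losses = []
        for idx in _batches(len(dataset), batch_size, rng):
            nn.Adam.zero_grad(params)
            raw = encdec.forward(dataset.images[idx])
            loss = nn.seg_bce_dice_loss(raw, dataset.masks[idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"non-finite segmentation loss at epoch {epoch}")
            loss.backward()
            opt.step(params)
            losses.append(float(loss.data))
        history.append(
            {
                "epoch": epoch,
                "component": "attention",
                "mean_loss": float(np.mean(losses)),
                "seconds": time.perf_counter() - t0,
                "seed": seed,
            }
        )
    return history


# ---------------------------------------------------------------------------
# alternating classifier training
# ---------------------------------------------------------------------------

def _accuracy(model: MultiScaleAttentionClassifier, ds: ArrayDataset, batch_size: int = 32) -> float:
    correct = 0
    for start in range(0, len(ds), batch_size):
        sl = slice(start, start + batch_size)
        masks = None if ds.masks is None else ds.masks[sl]
        bundle = model.forward(ds.images[sl], masks=masks)
        correct += int((bundle.predictions == ds.labels[sl]).sum())
    return correct / len(ds)


def train_alternating(
    model: MultiScaleAttentionClassifier,
    train_ds: ArrayDataset,
    val_ds: ArrayDataset | None,
    schedule: AlternatingSchedule,
    *,
    learning_rate: float | None = None,
    attention_learning_rate: float | None = None,
    batch_size: int | None = None,
    seed: int = 0,
    stop_at_train_accuracy: float | None = None,
) -> tuple[list[dict], dict[str, np.ndarray]]:
    """Alternating freeze/train loop with cross-entropy classification loss.

    Per epoch exactly one component ('attention' = encoder-decoder + scale
    projections, 'main' = backbone + classifier head) receives optimizer steps;
    the other side's parameters are untouched. The attention side may use its
    own (typically smaller) learning rate so that a segmentation-pretrained
    global map is refined rather than overwritten. Training stops early once
    ``stop_at_train_accuracy`` is reached, when given. Returns (history, best
    state dict by validation accuracy — or final state when no validation set).
    """
    cfg: RunConfig = model.config
    lr = learning_rate if learning_rate is not None else cfg.learning_rate
    attn_lr = attention_learning_rate if attention_learning_rate is not None else lr
    bs = batch_size if batch_size is not None else cfg.batch_size
    sides = {"main": model.backbone_params(), "attention": model.attention_params()}
    opts = {"main": nn.Adam(lr=lr), "attention": nn.Adam(lr=attn_lr)}
    rng = np.random.default_rng(np.random.SeedSequence([0xA17, int(seed)]))
    history: list[dict] = []
    best_acc, best_state = -1.0, model.state_dict()
    for epoch in range(schedule.total_epochs):
        t0 = time.perf_counter()
        component = component_for_epoch(epoch, schedule)
        active = sides[component]
        opt = opts[component]
        losses = []
        for bi, idx in enumerate(_batches(len(train_ds), bs, rng)):
            nn.Adam.zero_grad(model.params())
            masks = None if train_ds.masks is None else train_ds.masks[idx]
            logits, _, _, _ = model.forward_graph(train_ds.images[idx], masks=masks)
            loss = nn.softmax_cross_entropy(logits, train_ds.labels[idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}, batch {bi}")
            loss.backward()
            opt.step(active)
            losses.append(float(loss.data))
        record = {
            "epoch": epoch,
            "component": component,
            "mean_loss": float(np.mean(losses)),
            "train_accuracy": _accuracy(model, train_ds),
            "seed": seed,
            "seconds": time.perf_counter() - t0,
        }
        if val_ds is not None and len(val_ds):
            record["val_accuracy"] = _accuracy(model, val_ds)
            if record["val_accuracy"] > best_acc:
                best_acc = record["val_accuracy"]
                best_state = model.state_dict()
        history.append(record)
        if (
            stop_at_train_accuracy is not None
            and record["train_accuracy"] >= stop_at_train_accuracy
        ):
            break
    if val_ds is None or not len(val_ds):
        best_state = model.state_dict()
    return history, best_state
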