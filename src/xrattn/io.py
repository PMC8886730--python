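"""Image loading, manifests, and run configuration.

All images enter the pipeline through :func:`load_and_resize`, which decodes
PNG/JPEG, converts to single-channel luminance, scales 8-bit values by 1/255,
and resamples to the configured square size with the package-wide half-pixel
bilinear convention (the same resampling used for the attention priors).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .nn import bilinear_matrix

__all__ = ["RunConfig", "load_and_resize", "read_manifest", "load_config", "resize_image"]


@dataclass
class RunConfig:
    """Run hyperparameters. Defaults follow the reference training recipe:
    480x480 inputs, adaptive-moment optimization with learning rate 8e-5 and
    batch size 16; the alternating schedule switches component every epoch."""

    image_size: int = 480
    learning_rate: float = 0.00008
    batch_size: int = 16
    optimizer: str = "adam"
    alternation_period_epochs: int = 1
    attachment_stages: list[int] = field(default_factory=lambda: [0, 1, 2])
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.alternation_period_epochs < 1:
            raise ValueError("alternation_period_epochs must be >= 1")
        if self.image_size < 8:
            raise ValueError("image_size must be >= 8")

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path=None, **overrides) -> RunConfig:
    """Build a RunConfig from a YAML file and/or keyword overrides.

    Unknown keys raise (no silent ignoring); unspecified keys take defaults.
    """
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a key-value mapping")
        values.update(loaded)
    values.update(overrides)
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(values) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}; known keys: {sorted(known)}")
    return RunConfig(**values)


def resize_image(arr: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Channelwise bilinear resize of an (h, w) or (h, w, c) array."""
    squeeze = arr.ndim == 2
    a = arr[..., None] if squeeze else arr
    h, w, _ = a.shape
    if (h, w) == (out_h, out_w):
        out = a.astype(np.float64)
    else:
        Rh = bilinear_matrix(out_h, h)
        Rw = bilinear_matrix(out_w, w)
        out = np.einsum("oh,hwc->owc", Rh, a.astype(np.float64))
        out = np.einsum("pw,owc->opc", Rw, out)
    return out[..., 0] if squeeze else out


def load_and_resize(path, size: int = 480) -> np.ndarray:
    """Decode an image file to a (size, size, 1) float array in [0, 1].

    RGB sources are luminance-converted; 8-bit values are divided by 255
    (fixed scale, so train and test preprocessing are identical).
    """
    p = Path(path)
    try:
        with Image.open(p) as im:
            im = im.convert("L")
            arr = np.asarray(im, dtype=np.float64) / 255.0
    except FileNotFoundError:
        raise IOError(f"image file not found: {p}")
    except OSError as exc:
        raise IOError(f"cannot decode image file {p}: {exc}")
    out = resize_image(arr, size, size)
    return np.clip(out, 0.0, 1.0)[..., None]


def load_mask(path, size: int | None = None) -> np.ndarray:
    """Load a binary mask PNG (stored as 0/255); threshold at 128."""
    p = Path(path)
    try:
        with Image.open(p) as im:
            arr = np.asarray(im.convert("L"), dtype=np.float64)
    except FileNotFoundError:
        raise IOError(f"mask file not found: {p}")
    if size is not None and arr.shape != (size, size):
        arr = resize_image(arr, size, size)
    return (arr >= 128).astype(np.uint8)


def read_manifest(csv_path) -> pd.DataFrame:
    """Read a dataset manifest CSV; validates labels and resolves paths.

    Required columns: ``path``, ``label``; optional: ``mask_path``, ``split``.
    Image paths are interpreted relative to the manifest's directory.
    """
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    if "path" not in df.columns or "label" not in df.columns:
        raise ValueError(f"manifest {csv_path} must have 'path' and 'label' columns")
    bad = df.index[~df["label"].isin([0, 1])]
    if len(bad):
        raise ValueError(
            f"manifest {csv_path}: label outside {{0,1}} at row(s) {list(bad[:5])}"
        )
    df = df.copy()
    df["label"] = df["label"].astype(int)
    root = csv_path.parent
    df["path"] = [str(root / p) for p in df["path"]]
    if "mask_path" in df.columns:
        df["mask_path"] = [
            str(root / p) if isinstance(p, str) and p else "" for p in df["mask_path"]
        ]
    if "split" not in df.columns:
        df["split"] = "train"
    return df


def save_checkpoint(path, state: dict[str, np.ndarray], meta: dict | None = None) -> None:
    """Write a parameter checkpoint (.npz) with a JSON provenance sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **state)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(meta or {}, indent=2, sort_keys=True, default=str))


def load_checkpoint(path) -> dict[str, np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise IOError(f"checkpoint not found: {path}")
    with np.load(path) as data:
        return {k: data[k] for k in data.files}


def write_run_log(path, record: dict) -> None:
    """Append one JSON-lines record (config echo, seed, artifacts) to a run log."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "a") as fh:
        fh.write(json.dumps(record, sort_keys=True, default=str) + "\n")
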