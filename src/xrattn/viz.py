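"""Attention visualization: global heat-map overlays and per-block panels.

The global map sigma(A_G) is rendered with a blue-to-red colormap and
alpha-blended over the grayscale input (red = high attention, blue = low).
Per-block attention-enforced activations are channel-mean-reduced and min-max
normalized to [0,1] (white = high attention-enforced activation).
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib
import numpy as np
from PIL import Image

from .io import resize_image

__all__ = ["global_heatmap_overlay", "normalize_activation", "attention_panel"]


def global_heatmap_overlay(
    image: np.ndarray,
    bounded_map: np.ndarray,
    alpha: float = 0.5,
    colormap: str = "jet",
) -> np.ndarray:
    """Alpha-blend a colormapped attention map over a grayscale image.

    ``image``: (h,w) or (h,w,1) in [0,1]; ``bounded_map``: sigma(A_G), resized
    to the image dims if needed. Returns an (h,w,3) RGB array in [0,1].
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 3:
        img = img[..., 0]
    m = np.asarray(bounded_map, dtype=np.float64)
    if m.ndim == 3:
        m = m[..., 0]
    if m.shape != img.shape:
        m = resize_image(m, *img.shape)
    if m.shape != img.shape:
        raise ValueError(f"map shape {m.shape} does not match image shape {img.shape}")
    cmap = matplotlib.colormaps[colormap]
    colored = np.asarray(cmap(m))[..., :3]
    base = np.repeat(img[..., None], 3, axis=-1)
    out = (1.0 - alpha) * base + alpha * colored
    return np.clip(out, 0.0, 1.0)


def normalize_activation(feature_map: np.ndarray, reduce: str = "mean") -> np.ndarray:
    """Reduce (h,w,c) over channels, then min-max normalize to [0,1].

    A spatially constant map normalizes to all zeros (defined fallback).
    """
    f = np.asarray(feature_map, dtype=np.float64)
    if f.ndim == 4:
        if f.shape[0] != 1:
            raise ValueError("pass one sample at a time")
        f = f[0]
    if f.ndim == 3:
        if reduce == "mean":
            f = f.mean(axis=-1)
        elif reduce == "max":
            f = f.max(axis=-1)
        else:
            raise ValueError(f"unknown reduction {reduce!r}; expected 'mean' or 'max'")
    lo, hi = f.min(), f.max()
    if hi - lo <= 0:
        return np.zeros_like(f)
    return (f - lo) / (hi - lo)


def _save_png(arr01: np.ndarray, path: Path) -> None:
    data = np.clip(np.round(arr01 * 255.0), 0, 255).astype(np.uint8)
    mode = "RGB" if data.ndim == 3 else "L"
    Image.fromarray(data, mode=mode).save(path)


def attention_panel(
    model,
    image: np.ndarray,
    out_dir,
    *,
    alpha: float = 0.5,
    colormap: str = "jet",
    reduce: str = "mean",
    source: str = "attended",
) -> list[str]:
    """Write the global overlay + one normalized per-block map.

    ``source='attended'`` panels show the attention-enforced activations
    F_j_attended (the default); ``source='attention'`` shows the raw local
    attention maps A_j instead. Produces J+1 PNGs with deterministic names and
    an ``index.json`` listing them; per-block images keep the block's native
    spatial dims.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    x = np.asarray(image, dtype=np.float64)
    if x.ndim == 2:
        x = x[..., None]
    bundle = model.forward(x[None])
    if bundle.global_map is None:
        raise ValueError("attention is disabled in the current ablation mode; nothing to visualize")
    if source not in ("attended", "attention"):
        raise ValueError(f"unknown panel source {source!r}")
    maps = bundle.attended_maps if source == "attended" else bundle.local_maps
    files = []
    overlay = global_heatmap_overlay(x, bundle.global_map[0], alpha=alpha, colormap=colormap)
    p = out / "global_overlay.png"
    _save_png(overlay, p)
    files.append(p.name)
    for k, block_map in enumerate(maps):
        panel = normalize_activation(block_map[0], reduce=reduce)
        p = out / f"block_{k}_{source}.png"
        _save_png(panel, p)
        files.append(p.name)
    index = {
        "files": files,
        "alpha": alpha,
        "colormap": colormap,
        "reduce": reduce,
        "source": source,
        "n_heads": len(maps),
    }
    (out / "index.json").write_text(json.dumps(index, indent=2, sort_keys=True))
    return files
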