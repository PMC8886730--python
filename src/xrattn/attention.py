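"""Shared-global-attention primitives: one attention body, per-scale heads.

A single encoder-decoder produces a raw global attention map ``A_G`` with the
input image's spatial dimensions. Each backbone stage ``j`` derives its local
attention tensor from the *same* bounded map through a three-step head:

    1. ``sigmoid_map``      —  sigma(A_G), elementwise logistic, shared by all heads
    2. ``resize_bilinear``  —  resample to the stage's spatial dims (h_j, w_j)
    3. ``scale_projection`` —  one convolution adapting channels to c_j

giving the local attention map ``A_j`` with exactly the feature map's shape.
The gate is residual:

    F_j_attended = A_j (*) F_j + F_j        ((*) = elementwise product)

so a zero attention map leaves the feature map bit-exactly unchanged, and the
head can only *modulate* — never erase — the backbone's signal.

All functions accept either plain numpy arrays (returning arrays) or autodiff
:class:`~xrattn.nn.Tensor` nodes (returning nodes), so the same code path
serves analysis and training.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import Parameter, Tensor

__all__ = [
    "sigmoid_map",
    "resize_bilinear",
    "scale_projection",
    "local_attention",
    "apply_attention",
    "ScaleHead",
]


def _wrap(x):
    """-> (tensor, was_array, had_batch_dim)"""
    if isinstance(x, Tensor):
        t = x
        arr = False
    else:
        t = Tensor(np.asarray(x, dtype=np.float64))
        arr = True
    if t.data.ndim == 3:  # (h, w, c) -> add batch axis
        t = _expand0(t)
        return t, arr, False
    if t.data.ndim != 4:
        raise ValueError(f"expected (h,w,c) or (N,h,w,c) input, got shape {t.data.shape}")
    return t, arr, True


def _expand0(t: Tensor) -> Tensor:
    out = Tensor(t.data[None])
    if t.requires_grad or t._parents:
        out._parents = (t,)
        out._backward = lambda g: [(t, g[0])]
    return out


def _squeeze0(t: Tensor) -> Tensor:
    out = Tensor(t.data[0])
    if t.requires_grad or t._parents:
        out._parents = (t,)
        out._backward = lambda g: [(t, g[None])]
    return out


def _unwrap(t: Tensor, arr: bool, batched: bool):
    if not batched:
        t = _squeeze0(t)
    return t.data if arr else t


def sigmoid_map(raw):
    """Elementwise logistic sigma(A_G); bounds the raw decoder output into (0,1)."""
    t, arr, batched = _wrap(raw)
    if np.isnan(t.data).any():
        raise FloatingPointError("NaN in raw attention map")
    return _unwrap(nn.sigmoid(t), arr, batched)


def resize_bilinear(x, target: tuple[int, int]):
    """Channelwise bilinear resample to ``target=(h_j, w_j)``, half-pixel centers.

    Interpolation is convex, so output values never leave the input's range;
    in particular a resampled sigmoid map stays strictly inside (0, 1).
    """
    h, w = int(target[0]), int(target[1])
    if h < 1 or w < 1:
        raise ValueError(f"target dims must be >= 1, got {target}")
    t, arr, batched = _wrap(x)
    return _unwrap(nn.bilinear_resize(t, h, w), arr, batched)


def scale_projection(prior, weight, bias=None):
    """Per-scale convolution C_j adapting the resized prior to c_j channels.

    ``weight`` is (kh, kw, c_g, c_j) — default heads use 1x1 kernels (pure
    channel adaptation); same-padding preserves (h_j, w_j).
    """
    t, arr, batched = _wrap(prior)
    w = weight if isinstance(weight, Tensor) else Tensor(np.asarray(weight, dtype=np.float64))
    if w.data.ndim != 4:
        raise ValueError("projection weight must be (kh, kw, c_in, c_out)")
    if w.data.shape[2] != t.data.shape[-1]:
        raise ValueError(
            f"projection expects {w.data.shape[2]} input channels, prior has {t.data.shape[-1]}"
        )
    b = bias if (bias is None or isinstance(bias, Tensor)) else Tensor(np.asarray(bias, dtype=np.float64))
    return _unwrap(nn.conv2d(t, w, b), arr, batched)


def local_attention(feature_shape, a_g, weight, bias=None):
    """Full head: sigma -> bilinear to the stage dims -> per-scale convolution.

    ``feature_shape`` is the (h_j, w_j, c_j) of the stage feature map; only its
    shape enters — the head is a function of the global map alone. The returned
    local attention map has exactly ``feature_shape``.
    """
    if hasattr(feature_shape, "shape"):
        feature_shape = feature_shape.shape
    if len(feature_shape) == 4:
        feature_shape = feature_shape[1:]
    h_j, w_j, c_j = feature_shape
    out = scale_projection(resize_bilinear(sigmoid_map(a_g), (h_j, w_j)), weight, bias)
    out_shape = out.shape if isinstance(out, Tensor) else np.asarray(out).shape
    if out_shape[-3:] != (h_j, w_j, c_j):
        raise ValueError(
            f"head produced shape {out_shape[-3:]}, feature map needs {(h_j, w_j, c_j)}"
        )
    return out


def apply_attention(feature, attn):
    """Residual gate: F_attended = attn (*) F + F, elementwise."""
    f, arr_f, batched_f = _wrap(feature)
    a, _, _ = _wrap(attn)
    if f.data.shape != a.data.shape:
        raise ValueError(
            f"feature map shape {f.data.shape} != attention map shape {a.data.shape}"
        )
    return _unwrap(nn.add(nn.mul(a, f), f), arr_f, batched_f)


class ScaleHead:
    """Trainable per-scale head: holds the C_j convolution parameters.

    Parameters
    ----------
    c_g, c_j : input (global-map) and output (stage) channel counts.
    kernel : spatial kernel extent of C_j (1 = channel adaptation, default).
    """

    def __init__(self, c_g: int, c_j: int, kernel: int = 1, *, name: str, rng: np.random.Generator):
        self.c_g, self.c_j, self.kernel = c_g, c_j, kernel
        fan_in = kernel * kernel * c_g
        self.weight = Parameter(nn.he_init(rng, (kernel, kernel, c_g, c_j), fan_in), f"{name}.weight")
        self.bias = Parameter(np.zeros(c_j), f"{name}.bias")

    def params(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def __call__(self, feature, a_g):
        return local_attention(
            feature.shape if hasattr(feature, "shape") else feature, a_g, self.weight, self.bias
        )
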