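"""Minimal reverse-mode automatic differentiation engine on numpy arrays.

This is the package's numerical substrate: a small set of differentiable
operations (dense and 2-D convolution layers, 2x2 max pooling, nearest
upsampling, bilinear resizing, elementwise nonlinearities, classification and
segmentation losses) plus an Adam optimizer, enough to express and train the
encoder-decoder attention network and the convolutional backbones.

Conventions
-----------
* Image tensors are channels-last: ``(N, H, W, C)``.
* Convolution weights are ``(kh, kw, C_in, C_out)``; padding is "same"
  (symmetric, ceil-mode for strided convolutions).
* Bilinear resampling uses half-pixel centers with edge clamping — the single
  interpolation convention used everywhere in the package.
* All floating point work is float64 for reproducibility across BLAS builds.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "add",
    "mul",
    "matmul",
    "relu",
    "sigmoid",
    "conv2d",
    "maxpool2x2",
    "upsample_nearest2x",
    "bilinear_resize",
    "concat_channels",
    "global_avg_pool",
    "softmax",
    "softmax_cross_entropy",
    "seg_bce_dice_loss",
    "bilinear_matrix",
    "Adam",
    "he_init",
]


class Tensor:
    """A node in the computation graph wrapping a numpy array."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple = ()

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def backward(self, grad=None):
        """Reverse-mode sweep from this node; accumulates into ``.grad``."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a seed requires a scalar output")
            grad = np.ones_like(self.data)
        # iterative DFS post-order (parents before children in `order`)
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is not None:
                for parent, pg in node._backward(g):
                    if id(parent) in grads:
                        grads[id(parent)] += pg
                    else:
                        grads[id(parent)] = pg

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())


class Parameter(Tensor):
    """A trainable tensor with a stable name for checkpointing/freezing."""

    __slots__ = ("name",)

    def __init__(self, data, name: str):
        super().__init__(data, requires_grad=True)
        self.name = name

    def __repr__(self):  # pragma: no cover
        return f"Parameter({self.name}, shape={self.data.shape})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    track = any(p.requires_grad or p._parents for p in parents)
    if track:
        out._parents = tuple(parents)
        out._backward = backward
    return out


# ---------------------------------------------------------------------------
# elementwise / linear algebra
# ---------------------------------------------------------------------------

def add(a, b):
    """Elementwise a + b; b may broadcast (bias over trailing channel axis)."""
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data + b.data

    def backward(g):
        ga = g
        if ga.shape != a.data.shape:
            ga = _unbroadcast(ga, a.data.shape)
        gb = g
        if gb.shape != b.data.shape:
            gb = _unbroadcast(gb, b.data.shape)
        return [(a, ga), (b, gb)]

    return _make(data, [a, b], backward)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.reshape(shape)


def mul(a, b):
    """Elementwise product (Hadamard); shapes must broadcast."""
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data * b.data

    def backward(g):
        return [
            (a, _unbroadcast(g * b.data, a.data.shape)),
            (b, _unbroadcast(g * a.data, b.data.shape)),
        ]

    return _make(data, [a, b], backward)


def matmul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data @ b.data

    def backward(g):
        return [(a, g @ b.data.T), (b, a.data.T @ g)]

    return _make(data, [a, b], backward)


def relu(x):
    x = _as_tensor(x)
    mask = x.data > 0
    return _make(x.data * mask, [x], lambda g: [(x, g * mask)])


def sigmoid(x):
    x = _as_tensor(x)
    s = _sigmoid_np(x.data)
    return _make(s, [x], lambda g: [(x, g * s * (1.0 - s))])


def _sigmoid_np(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


# ---------------------------------------------------------------------------
# convolution and spatial ops
# ---------------------------------------------------------------------------

def _same_pad(n: int, k: int, s: int) -> tuple[int, int]:
    out = -(-n // s)  # ceil
    total = max((out - 1) * s + k - n, 0)
    return total // 2, total - total // 2


def conv2d(x, w, b=None, stride: int = 1):
    """2-D convolution (cross-correlation), same padding.

    x: (N,H,W,Cin), w: (kh,kw,Cin,Cout), b: (Cout,) or None.
    """
    x, w = _as_tensor(x), _as_tensor(w)
    N, H, W, Cin = x.data.shape
    kh, kw, wc_in, Cout = w.data.shape
    if wc_in != Cin:
        raise ValueError(f"channel mismatch: input has {Cin} channels, kernel expects {wc_in}")
    pt, pb = _same_pad(H, kh, stride)
    pl, pr = _same_pad(W, kw, stride)
    xp = np.pad(x.data, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
    Hp, Wp = xp.shape[1], xp.shape[2]
    Ho, Wo = -(-H // stride), -(-W // stride)

    def _slice(i, j):
        return xp[:, i : i + (Ho - 1) * stride + 1 : stride, j : j + (Wo - 1) * stride + 1 : stride, :]

    # shift-and-matmul: one (N*Ho*Wo, Cin) x (Cin, Cout) product per kernel
    # offset, avoiding a full im2col copy of the kh*kw-expanded input
    out = np.zeros((N * Ho * Wo, Cout))
    for i in range(kh):
        for j in range(kw):
            out += _slice(i, j).reshape(-1, Cin) @ w.data[i, j]
    if b is not None:
        b = _as_tensor(b)
        out = out + b.data
    data = out.reshape(N, Ho, Wo, Cout)

    def backward(g):
        gm = g.reshape(N * Ho * Wo, Cout)
        gw = np.empty((kh, kw, Cin, Cout))
        gxp = np.zeros((N, Hp, Wp, Cin))
        for i in range(kh):
            for j in range(kw):
                gw[i, j] = _slice(i, j).reshape(-1, Cin).T @ gm
                gxp[:, i : i + (Ho - 1) * stride + 1 : stride, j : j + (Wo - 1) * stride + 1 : stride, :] += (
                    gm @ w.data[i, j].T
                ).reshape(N, Ho, Wo, Cin)
        gx = gxp[:, pt : pt + H, pl : pl + W, :]
        grads = [(x, gx), (w, gw)]
        if b is not None:
            grads.append((b, gm.sum(axis=0)))
        return grads

    parents = [x, w] if b is None else [x, w, b]
    return _make(data, parents, backward)


def maxpool2x2(x):
    x = _as_tensor(x)
    N, H, W, C = x.data.shape
    if H % 2 or W % 2:
        raise ValueError(f"maxpool2x2 requires even spatial dims, got {H}x{W}")
    v = x.data.reshape(N, H // 2, 2, W // 2, 2, C).transpose(0, 1, 3, 5, 2, 4).reshape(N, H // 2, W // 2, C, 4)
    idx = v.argmax(axis=-1)
    data = np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gv = np.zeros((N, H // 2, W // 2, C, 4))
        np.put_along_axis(gv, idx[..., None], g[..., None], axis=-1)
        gx = gv.reshape(N, H // 2, W // 2, C, 2, 2).transpose(0, 1, 4, 2, 5, 3).reshape(N, H, W, C)
        return [(x, gx)]

    return _make(data, [x], backward)


def upsample_nearest2x(x):
    x = _as_tensor(x)
    data = np.repeat(np.repeat(x.data, 2, axis=1), 2, axis=2)

    def backward(g):
        N, H2, W2, C = g.shape
        gx = g.reshape(N, H2 // 2, 2, W2 // 2, 2, C).sum(axis=(2, 4))
        return [(x, gx)]

    return _make(data, [x], backward)


def bilinear_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Row-stochastic (n_out, n_in) interpolation matrix, half-pixel centers.

    Sample location for output index i is ``(i + 0.5) * n_in / n_out - 0.5``,
    clamped to the valid range (edge replication outside it).
    """
    if n_out < 1 or n_in < 1:
        raise ValueError("interpolation sizes must be >= 1")
    R = np.zeros((n_out, n_in))
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    frac = src - i0
    R[np.arange(n_out), i0] += 1.0 - frac
    R[np.arange(n_out), i1] += frac
    return R


def bilinear_resize(x, out_h: int, out_w: int):
    """Channelwise separable bilinear resampling to (out_h, out_w)."""
    x = _as_tensor(x)
    if x.data.ndim != 4:
        raise ValueError("bilinear_resize expects (N,H,W,C)")
    N, H, W, C = x.data.shape
    if out_h < 1 or out_w < 1:
        raise ValueError("target dims must be >= 1")
    Rh = bilinear_matrix(out_h, H)
    Rw = bilinear_matrix(out_w, W)
    data = np.einsum("oh,nhwc->nowc", Rh, x.data)
    data = np.einsum("pw,nowc->nopc", Rw, data)

    def backward(g):
        # adjoints of the separable interpolation: transposed matrices
        gx = np.einsum("wp,nopc->nowc", Rw.T, g)
        gx = np.einsum("ho,nowc->nhwc", Rh.T, gx)
        return [(x, gx)]

    return _make(data, [x], backward)


def concat_channels(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    ca = a.data.shape[-1]
    data = np.concatenate([a.data, b.data], axis=-1)

    def backward(g):
        return [(a, g[..., :ca]), (b, g[..., ca:])]

    return _make(data, [a, b], backward)


def global_avg_pool(x):
    """(N,H,W,C) -> (N,C) spatial mean."""
    x = _as_tensor(x)
    N, H, W, C = x.data.shape
    data = x.data.mean(axis=(1, 2))

    def backward(g):
        gx = np.broadcast_to(g[:, None, None, :] / (H * W), (N, H, W, C)).copy()
        return [(x, gx)]

    return _make(data, [x], backward)


def global_max_pool(x):
    """(N,H,W,C) -> (N,C) spatial maximum (gradient to the argmax site)."""
    x = _as_tensor(x)
    N, H, W, C = x.data.shape
    flat = x.data.reshape(N, H * W, C)
    idx = flat.argmax(axis=1)
    data = np.take_along_axis(flat, idx[:, None, :], axis=1)[:, 0, :]

    def backward(g):
        gf = np.zeros((N, H * W, C))
        np.put_along_axis(gf, idx[:, None, :], g[:, None, :], axis=1)
        return [(x, gf.reshape(N, H, W, C))]

    return _make(data, [x], backward)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits, labels):
    """Mean cross-entropy between softmax(logits) (N,K) and int labels (N,)."""
    logits = _as_tensor(logits)
    labels = np.asarray(labels, dtype=int)
    N = logits.data.shape[0]
    p = softmax(logits.data)
    eps = 1e-12
    data = -np.log(p[np.arange(N), labels] + eps).mean()

    def backward(g):
        gl = p.copy()
        gl[np.arange(N), labels] -= 1.0
        return [(logits, g * gl / N)]

    return _make(data, [logits], backward)


def seg_bce_dice_loss(raw, mask, bce_weight: float = 0.5):
    """Equally weighted binary cross-entropy + soft Dice on sigmoid(raw).

    raw: (N,H,W,1) pre-sigmoid map; mask: (N,H,W) or (N,H,W,1) in {0,1}.
    Returns scalar loss = w*BCE + (1-w)*(1 - Dice), Dice pooled over the batch.
    """
    raw = _as_tensor(raw)
    m = np.asarray(mask, dtype=np.float64)
    if m.ndim == raw.data.ndim - 1:
        m = m[..., None]
    if m.shape != raw.data.shape:
        raise ValueError(f"mask shape {m.shape} does not match map shape {raw.data.shape}")
    z = raw.data
    s = _sigmoid_np(z)
    n = z.size
    # numerically stable BCE with logits
    bce = (np.maximum(z, 0) - z * m + np.log1p(np.exp(-np.abs(z)))).mean()
    eps = 1.0
    inter = float((s * m).sum())
    denom = float(s.sum() + m.sum())
    dice = (2.0 * inter + eps) / (denom + eps)
    data = bce_weight * bce + (1.0 - bce_weight) * (1.0 - dice)

    def backward(g):
        g_bce = (s - m) / n
        # d(1-dice)/ds_i = -(2*m_i*(denom+eps) - (2*inter+eps)) / (denom+eps)^2
        g_dice = -(2.0 * m * (denom + eps) - (2.0 * inter + eps)) / (denom + eps) ** 2
        gz = g * (bce_weight * g_bce + (1.0 - bce_weight) * g_dice * s * (1.0 - s))
        return [(raw, gz)]

    return _make(data, [raw], backward)


def soft_dice(prob: np.ndarray, mask: np.ndarray, eps: float = 1.0) -> float:
    """Soft Dice coefficient between a probability map and a binary mask."""
    prob = np.asarray(prob, dtype=np.float64)
    mask = np.asarray(mask, dtype=np.float64)
    if prob.shape != mask.shape:
        prob = prob.reshape(mask.shape)
    return float((2.0 * (prob * mask).sum() + eps) / (prob.sum() + mask.sum() + eps))


# ---------------------------------------------------------------------------
# initialization and optimization
# ---------------------------------------------------------------------------

def he_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Adam:
    """Adaptive-moment optimizer over a list of named Parameters.

    Moment state is keyed by parameter name, so parameters can be frozen for
    some epochs (excluded from ``step``) and later resume with their state.
    """

    def __init__(self, lr: float = 8e-5, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}
        self._t: dict[str, int] = {}

    def step(self, params: list[Parameter]) -> None:
        for p in params:
            if p.grad is None:
                continue
            m = self._m.setdefault(p.name, np.zeros_like(p.data))
            v = self._v.setdefault(p.name, np.zeros_like(p.data))
            t = self._t.get(p.name, 0) + 1
            self._t[p.name] = t
            m[:] = self.beta1 * m + (1 - self.beta1) * p.grad
            v[:] = self.beta2 * v + (1 - self.beta2) * p.grad**2
            mhat = m / (1 - self.beta1**t)
            vhat = v / (1 - self.beta2**t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    @staticmethod
    def zero_grad(params: list[Parameter]) -> None:
        for p in params:
            p.grad = None
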