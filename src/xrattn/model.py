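"""Classifier assembly: convolutional backbone + shared-attention heads.

The classifier wires one encoder-decoder attention body (``xrattn.unet``) into
a convolutional backbone at J attachment stages. At each attached stage j the
stage's output feature map F_j is residually gated by the local attention map
derived from the shared global map (``xrattn.attention``), and the gated map
feeds the next stage. A global-average-pool + dense layer gives 2-class logits.

Ablation modes reproduce the disable/segment protocols used to isolate the
attention block's contribution:

* ``full``               — normal operation.
* ``attention_disabled`` — every residual gate is bypassed (F_j passes through
  unchanged); the forward pass is then bit-identical to the backbone alone.
* ``seg_input_only``     — the input is replaced by image * lung_mask and the
  attention block is bypassed (segmentation instead of attention).
* ``seg_input_additive`` — the input is replaced by clip(image + image * mask)
  with the attention block bypassed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .attention import ScaleHead, apply_attention
from .io import RunConfig
from .nn import Parameter, Tensor
from .unet import EncoderDecoder, EncoderDecoderConfig

__all__ = ["MultiScaleAttentionClassifier", "ForwardBundle", "build_model", "ABLATION_MODES"]

ABLATION_MODES = ("full", "attention_disabled", "seg_input_only", "seg_input_additive")


@dataclass
class ForwardBundle:
    logits: np.ndarray  # (N, 2)
    probabilities: np.ndarray  # (N, 2), rows sum to 1
    global_map: np.ndarray | None  # sigma(A_G), (N, h, w, c_g)
    local_maps: list  # J attention maps A_j, local_maps[j].shape == F_j.shape
    attended_maps: list = field(default_factory=list)  # J gated maps F_j_attended
    predictions: np.ndarray = field(default=None)  # argmax over classes

    def __post_init__(self):
        if self.predictions is None:
            self.predictions = self.logits.argmax(axis=1)


class _ConvStage:
    """conv3x3 -> relu -> 2x2 maxpool; one backbone stage of the small CNN."""

    def __init__(self, c_in, c_out, name, rng):
        self.conv = nn.Parameter(nn.he_init(rng, (3, 3, c_in, c_out), 9 * c_in), f"{name}.w")
        self.bias = nn.Parameter(np.zeros(c_out), f"{name}.b")
        self.c_out = c_out

    def __call__(self, x):
        return nn.maxpool2x2(nn.relu(nn.conv2d(x, self.conv, self.bias)))

    def params(self):
        return [self.conv, self.bias]


class _Bottleneck:
    """Norm-free residual bottleneck (1x1 -> 3x3 -> 1x1, x4 expansion).

    The final 1x1 convolution is zero-initialized so each block is the identity
    at initialization, which keeps very deep norm-free stacks stable.
    """

    def __init__(self, c_in, c_mid, stride, name, rng):
        c_out = 4 * c_mid
        self.stride = stride
        self.w1 = Parameter(nn.he_init(rng, (1, 1, c_in, c_mid), c_in), f"{name}.w1")
        self.b1 = Parameter(np.zeros(c_mid), f"{name}.b1")
        self.w2 = Parameter(nn.he_init(rng, (3, 3, c_mid, c_mid), 9 * c_mid), f"{name}.w2")
        self.b2 = Parameter(np.zeros(c_mid), f"{name}.b2")
        self.w3 = Parameter(np.zeros((1, 1, c_mid, c_out)), f"{name}.w3")
        self.b3 = Parameter(np.zeros(c_out), f"{name}.b3")
        self.proj = None
        if stride != 1 or c_in != c_out:
            self.pw = Parameter(nn.he_init(rng, (1, 1, c_in, c_out), c_in), f"{name}.pw")
            self.pb = Parameter(np.zeros(c_out), f"{name}.pb")
            self.proj = (self.pw, self.pb)
        self.c_out = c_out

    def __call__(self, x):
        h = nn.relu(nn.conv2d(x, self.w1, self.b1, stride=self.stride))
        h = nn.relu(nn.conv2d(h, self.w2, self.b2))
        h = nn.conv2d(h, self.w3, self.b3)
        shortcut = x if self.proj is None else nn.conv2d(x, self.pw, self.pb, stride=self.stride)
        return nn.relu(nn.add(h, shortcut))

    def params(self):
        out = [self.w1, self.b1, self.w2, self.b2, self.w3, self.b3]
        if self.proj is not None:
            out.extend(self.proj)
        return out


class _ResNetStage:
    def __init__(self, blocks):
        self.blocks = blocks
        self.c_out = blocks[-1].c_out

    def __call__(self, x):
        for b in self.blocks:
            x = b(x)
        return x

    def params(self):
        return [p for b in self.blocks for p in b.params()]


def _small_cnn_stages(rng, in_channels=1, widths=(8, 16, 32)):
    stages, c = [], in_channels
    for j, w in enumerate(widths):
        stages.append(_ConvStage(c, w, f"backbone.stage{j}", rng))
        c = w
    return stages, []


def _resnet50_stages(rng, in_channels=1, width_multiplier=1.0):
    """Standard 50-layer residual layout: stem + stages of (3,4,6,3) bottlenecks."""
    wm = width_multiplier

    def ch(n):
        return max(4, int(round(n * wm)))

    stem_w = Parameter(nn.he_init(rng, (7, 7, in_channels, ch(64)), 49 * in_channels), "backbone.stem.w")
    stem_b = Parameter(np.zeros(ch(64)), "backbone.stem.b")

    def stem(x):
        return nn.maxpool2x2(nn.relu(nn.conv2d(x, stem_w, stem_b, stride=2)))

    stages = []
    c_in = ch(64)
    for s, (n_blocks, c_mid) in enumerate(zip((3, 4, 6, 3), (64, 128, 256, 512))):
        blocks = []
        for b in range(n_blocks):
            stride = 2 if (b == 0 and s > 0) else 1
            blk = _Bottleneck(c_in, ch(c_mid), stride, f"backbone.s{s}b{b}", rng)
            blocks.append(blk)
            c_in = blk.c_out
        stages.append(_ResNetStage(blocks))
    return stages, [(stem, [stem_w, stem_b])]


class MultiScaleAttentionClassifier:
    """Backbone + shared global attention with J scale-specific heads.

    Parameters
    ----------
    config : RunConfig — image size, seed, and attachment stages.
    backbone : "small_cnn" (3 stages, desk scale) or "resnet50".
    encdec_config : architecture of the attention encoder-decoder.
    head_kernel : spatial kernel of the per-scale projection C_j (default 1).
    """

    def __init__(
        self,
        config: RunConfig,
        backbone: str = "small_cnn",
        encdec_config: EncoderDecoderConfig | None = None,
        head_kernel: int = 1,
        backbone_width: float = 1.0,
    ):
        rng = np.random.default_rng(np.random.SeedSequence([0xBACB, int(config.seed)]))
        self.config = config
        self.backbone_name = backbone
        self.ablation_mode = "full"
        if backbone == "small_cnn":
            self.stages, self.prelude = _small_cnn_stages(rng)
        elif backbone == "resnet50":
            self.stages, self.prelude = _resnet50_stages(rng, width_multiplier=backbone_width)
        else:
            raise ValueError(f"unknown backbone {backbone!r}; expected small_cnn or resnet50")

        n_stages = len(self.stages)
        self.attachment_stages = list(config.attachment_stages)
        bad = [j for j in self.attachment_stages if not 0 <= j < n_stages]
        if bad:
            raise ValueError(
                f"attachment stage(s) {bad} out of range; valid stages are 0..{n_stages - 1}"
            )

        ed_cfg = encdec_config or EncoderDecoderConfig()
        ed_cfg.validate_size(config.image_size)
        self.encdec = EncoderDecoder(ed_cfg, seed=config.seed)
        self.c_g = ed_cfg.out_channels

        # one head per attached stage, sized from the stage's channel count
        head_rng = np.random.default_rng(np.random.SeedSequence([0x6EAD, int(config.seed)]))
        self.heads: dict[int, ScaleHead] = {}
        for j in self.attachment_stages:
            self.heads[j] = ScaleHead(
                self.c_g, self.stages[j].c_out, head_kernel, name=f"head{j}", rng=head_rng
            )

        # mean+max pooled head: focal opacities are localized, so the spatial
        # maximum carries class signal that a plain average would dilute
        c_last = 2 * self.stages[-1].c_out
        self.fc_w = Parameter(
            head_rng.normal(0.0, 1.0 / np.sqrt(c_last), (c_last, 2)), "classifier.fc.w"
        )
        self.fc_b = Parameter(np.zeros(2), "classifier.fc.b")

    # -- parameter plumbing ---------------------------------------------
    @property
    def n_heads(self) -> int:
        return len(self.heads)

    def backbone_params(self) -> list[Parameter]:
        out = [p for _, ps in self.prelude for p in ps]
        for s in self.stages:
            out.extend(s.params())
        out.extend([self.fc_w, self.fc_b])
        return out

    def attention_params(self) -> list[Parameter]:
        out = list(self.encdec.params())
        for j in sorted(self.heads):
            out.extend(self.heads[j].params())
        return out

    def params(self) -> list[Parameter]:
        return self.backbone_params() + self.attention_params()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {p.name: p.data.copy() for p in self.params()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.params():
            p.data[...] = state[p.name]

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params())

    # -- ablation -------------------------------------------------------
    def set_ablation(self, mode: str) -> "MultiScaleAttentionClassifier":
        if mode not in ABLATION_MODES:
            raise ValueError(f"unknown ablation mode {mode!r}; expected one of {ABLATION_MODES}")
        self.ablation_mode = mode
        return self

    def _transform_input(self, x: np.ndarray, masks: np.ndarray | None) -> np.ndarray:
        if self.ablation_mode in ("seg_input_only", "seg_input_additive"):
            if masks is None:
                raise ValueError(
                    f"ablation mode {self.ablation_mode!r} requires lung masks for the batch"
                )
            m = np.asarray(masks, dtype=np.float64)
            if m.ndim == x.ndim - 1:
                m = m[..., None]
            if self.ablation_mode == "seg_input_only":
                return x * m
            return np.clip(x + x * m, 0.0, 1.0)
        return x

    # -- forward --------------------------------------------------------
    def forward_graph(self, batch: np.ndarray, masks: np.ndarray | None = None):
        """Differentiable forward pass.

        Returns (logits Tensor, raw A_G Tensor or None, list of local-map Tensors).
        The global map is computed once per batch and shared by all heads.
        """
        x = np.asarray(batch, dtype=np.float64)
        if x.ndim == 3:
            x = x[None]
        n = self.config.image_size
        if x.shape[1] != n or x.shape[2] != n:
            raise ValueError(f"expected {n}x{n} inputs, got {x.shape[1]}x{x.shape[2]}")
        x = self._transform_input(x, masks)

        use_attention = self.ablation_mode == "full"
        raw_ag = self.encdec.forward(x) if use_attention else None

        # the backbone sees zero-centered intensities (better conditioned for
        # relu stacks); the attention body keeps the raw [0,1] image so the
        # segmentation-pretrained weights remain valid
        h = Tensor(2.0 * x - 1.0)
        for fn, _ in self.prelude:
            h = fn(h)
        local_maps, attended_maps = [], []
        for j, stage in enumerate(self.stages):
            h = stage(h)
            if use_attention and j in self.heads:
                attn = self.heads[j](h, raw_ag)
                local_maps.append(attn)
                h = apply_attention(h, attn)
                attended_maps.append(h)
        pooled = nn.concat_channels(nn.global_avg_pool(h), nn.global_max_pool(h))
        logits = nn.add(nn.matmul(pooled, self.fc_w), self.fc_b)
        return logits, raw_ag, local_maps, attended_maps

    def forward(self, batch: np.ndarray, masks: np.ndarray | None = None) -> ForwardBundle:
        """Inference forward pass returning numpy arrays."""
        logits, raw_ag, local_maps, attended = self.forward_graph(batch, masks)
        probs = nn.softmax(logits.data)
        return ForwardBundle(
            logits=logits.data.copy(),
            probabilities=probs,
            global_map=None if raw_ag is None else nn._sigmoid_np(raw_ag.data),
            local_maps=[m.data.copy() for m in local_maps],
            attended_maps=[m.data.copy() for m in attended],
        )


def build_model(
    config: RunConfig,
    backbone: str = "small_cnn",
    encdec_config: EncoderDecoderConfig | None = None,
    **kwargs,
) -> MultiScaleAttentionClassifier:
    """Factory mirroring the CLI surface; validates attachment stages."""
    return MultiScaleAttentionClassifier(config, backbone, encdec_config, **kwargs)
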