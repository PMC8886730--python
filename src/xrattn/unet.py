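"""Encoder-decoder network G(.) producing the raw global attention map.

A U-Net-style architecture: a downsampling encoder D maps the input image to a
latent feature map z at 1/2^depth resolution, and an upsampling decoder U with
skip connections restores the input resolution, emitting a raw (pre-sigmoid)
single-channel map A_G. The sigmoid lives downstream in the attention module so
that segmentation pretraining and the attention heads share one bounded map.

The decoder upsamples with nearest-neighbor + convolution (no transposed
convolutions) to keep the attention maps free of checkerboard artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Parameter, Tensor

__all__ = ["EncoderDecoderConfig", "EncoderDecoder"]


@dataclass(frozen=True)
class EncoderDecoderConfig:
    depth: int = 4
    base_channels: int = 16
    in_channels: int = 1
    out_channels: int = 1  # c_g of the raw global map
    skip_connections: bool = True
    kernel: int = 3

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.base_channels < 1 or self.out_channels < 1:
            raise ValueError("channel counts must be >= 1")

    def validate_size(self, image_size: int) -> None:
        if image_size % (2**self.depth) != 0:
            raise ValueError(
                f"image size {image_size} not divisible by 2^depth = {2**self.depth}; "
                "reduce depth or change the input size"
            )


class _Conv:
    def __init__(self, c_in, c_out, kernel, name, rng):
        fan_in = kernel * kernel * c_in
        self.w = Parameter(nn.he_init(rng, (kernel, kernel, c_in, c_out), fan_in), f"{name}.w")
        self.b = Parameter(np.zeros(c_out), f"{name}.b")

    def __call__(self, x, act=True):
        out = nn.conv2d(x, self.w, self.b)
        return nn.relu(out) if act else out

    def params(self):
        return [self.w, self.b]


class EncoderDecoder:
    """Trainable encoder-decoder; channels double at each downsampling level."""

    def __init__(self, config: EncoderDecoderConfig = EncoderDecoderConfig(), *, seed: int = 0, name: str = "gattn"):
        rng = np.random.default_rng(np.random.SeedSequence([0x6A77, int(seed)]))
        self.config = config
        k, base = config.kernel, config.base_channels
        self.enc: list[_Conv] = []
        c_in = config.in_channels
        for lvl in range(config.depth):
            c_out = base * (2**lvl)
            self.enc.append(_Conv(c_in, c_out, k, f"{name}.enc{lvl}", rng))
            c_in = c_out
        self.bottleneck = _Conv(c_in, base * (2**config.depth), k, f"{name}.bottleneck", rng)
        c_in = base * (2**config.depth)
        self.dec: list[_Conv] = []
        for lvl in reversed(range(config.depth)):
            c_skip = base * (2**lvl) if config.skip_connections else 0
            c_out = base * (2**lvl)
            self.dec.append(_Conv(c_in + c_skip, c_out, k, f"{name}.dec{lvl}", rng))
            c_in = c_out
        self.head = _Conv(c_in, config.out_channels, 1, f"{name}.head", rng)

    # -- parameter plumbing ---------------------------------------------
    def params(self) -> list[Parameter]:
        out = []
        for conv in [*self.enc, self.bottleneck, *self.dec, self.head]:
            out.extend(conv.params())
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {p.name: p.data.copy() for p in self.params()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.params():
            p.data[...] = state[p.name]

    # -- forward --------------------------------------------------------
    def encode(self, x):
        """Input -> (latent z at 1/2^depth resolution, list of skip tensors)."""
        t = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))
        if t.data.ndim == 3:
            t = Tensor(t.data[None])
        self.config.validate_size(t.data.shape[1])
        if t.data.shape[1] != t.data.shape[2]:
            self.config.validate_size(t.data.shape[2])
        skips = []
        h = t
        for conv in self.enc:
            h = conv(h)
            skips.append(h)
            h = nn.maxpool2x2(h)
        z = self.bottleneck(h)
        return z, skips

    def decode(self, z, skips):
        """Latent + skips -> raw global map with the input's spatial dims."""
        if len(skips) != len(self.dec):
            raise ValueError(f"expected {len(self.dec)} skip tensors, got {len(skips)}")
        h = z
        for conv, skip in zip(self.dec, reversed(skips)):
            h = nn.upsample_nearest2x(h)
            if self.config.skip_connections:
                if skip.data.shape[:3] != h.data.shape[:3]:
                    raise ValueError(
                        f"skip shape {skip.data.shape} incompatible with decoder level {h.data.shape}"
                    )
                h = nn.concat_channels(h, skip)
            h = conv(h)
        return self.head(h, act=False)

    def forward(self, x):
        """encode then decode; returns the raw (pre-sigmoid) A_G Tensor."""
        z, skips = self.encode(x)
        raw = self.decode(z, skips)
        if np.isnan(raw.data).any():
            raise FloatingPointError("NaN in decoder output")
        return raw

    def forward_array(self, x: np.ndarray) -> np.ndarray:
        """Convenience: numpy in, numpy raw map out (no graph retained)."""
        batched = np.asarray(x).ndim == 4
        out = self.forward(np.asarray(x, dtype=np.float64)).data
        return out if batched else out[0]
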