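"""Synthetic chest-radiograph phantom generator.

Produces radiograph-like grayscale images containing two elliptical "lung
fields" (radiolucent, hence darker than the surrounding body), a paired exact
binary lung mask, and — for disease-positive samples — one or more additive
isotropic Gaussian opacity blobs placed inside the lungs, emulating the faint
ground-glass opacities that mark viral pneumonia on a chest X-ray. Every other
component of the package (segmentation pretraining, alternating training,
ablation, visualization) is testable against these phantoms without any
external image cohort.

The generator is a pure function of ``(spec, seed)``. Pixel noise is truncated
at 3.5 standard deviations so that negative samples provably contain no
lung-interior pixel above ``background mean + 4 * noise_sd`` — class signal is
separable by construction, not just in expectation.

Distortion modes (crop-and-pad, intensity inversion, burned-in text markers,
letterboxing) emulate the acquisition anomalies common in public radiograph
collections.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

__all__ = [
    "PhantomSpec",
    "PhantomSample",
    "generate_sample",
    "generate_dataset",
    "apply_distortion",
    "DISTORTION_KINDS",
]

DISTORTION_KINDS = ("crop_pad", "invert", "burned_text", "letterbox")

# (center_y, center_x, semi_axis_y, semi_axis_x) as fractions of image size
_DEFAULT_LUNGS = (
    (0.50, 0.32, 0.30, 0.17),
    (0.50, 0.68, 0.30, 0.17),
)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity parameters of the phantom population.

    Defaults target a 128 px test-scale phantom; pass ``image_size=480`` and
    rescaled pixel radii for full-scale runs.
    """

    image_size: int = 128
    lung_ellipse_params: tuple = _DEFAULT_LUNGS
    background_noise_sd: float = 0.03
    lesion_count_range: tuple[int, int] = (1, 3)
    lesion_radius_range: tuple[float, float] = (5.0, 12.0)
    lesion_contrast: float = 0.25
    body_level: float = 0.65
    lung_level: float = 0.30
    blur_sigma: float = 0.7
    rng_seed: int = 0

    def __post_init__(self):
        for cy, cx, ay, ax in self.lung_ellipse_params:
            if cy - ay < 0 or cy + ay > 1 or cx - ax < 0 or cx + ax > 1:
                raise ValueError("lung ellipse extends outside the image frame")
        if self.lesion_contrast <= 3.0 * self.background_noise_sd:
            raise ValueError(
                "lesion_contrast must exceed 3x background_noise_sd for separable classes"
            )
        max_semi = max(min(ay, ax) for _, _, ay, ax in self.lung_ellipse_params)
        if self.lesion_radius_range[1] > max_semi * self.image_size:
            raise ValueError("lesion radius exceeds the lung semi-axis; shrink lesion_radius_range")
        if self.lesion_radius_range[0] > self.lesion_radius_range[1]:
            raise ValueError("lesion_radius_range must be (low, high) with low <= high")
        if self.lesion_count_range[0] < 1 or self.lesion_count_range[0] > self.lesion_count_range[1]:
            raise ValueError("lesion_count_range must be (low, high) with 1 <= low <= high")

    def scaled(self, image_size: int) -> "PhantomSpec":
        """The same population at another resolution (pixel radii rescaled)."""
        f = image_size / self.image_size
        lo, hi = self.lesion_radius_range
        return replace(self, image_size=image_size, lesion_radius_range=(lo * f, hi * f))

    def digest(self) -> str:
        h = hashlib.sha256(repr(self).encode()).hexdigest()
        return h[:12]


@dataclass
class PhantomSample:
    image: np.ndarray  # (h, w, 1) float in [0, 1]
    lung_mask: np.ndarray  # (h, w) uint8 in {0, 1}
    label: int  # 0 negative, 1 positive
    provenance: dict = field(default_factory=dict)


def lung_mask_for(spec: PhantomSpec) -> np.ndarray:
    """Exact binary union of the two lung ellipse interiors."""
    n = spec.image_size
    yy, xx = np.mgrid[0:n, 0:n]
    mask = np.zeros((n, n), dtype=bool)
    for cy, cx, ay, ax in spec.lung_ellipse_params:
        mask |= ((yy - cy * n) / (ay * n)) ** 2 + ((xx - cx * n) / (ax * n)) ** 2 <= 1.0
    return mask.astype(np.uint8)


def _truncated_normal(rng: np.random.Generator, sd: float, shape, clip: float = 3.5) -> np.ndarray:
    return np.clip(rng.normal(0.0, sd, size=shape), -clip * sd, clip * sd)


def generate_sample(spec: PhantomSpec, seed: int, label: int | None = None) -> PhantomSample:
    """Deterministically render one phantom.

    If ``label`` is None it is drawn (fair coin) from the sample's own stream.
    Positive samples receive 1..k additive Gaussian opacity bumps whose centers
    lie strictly inside the lung mask.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.rng_seed), int(seed)]))
    n = spec.image_size
    mask = lung_mask_for(spec)
    if label is None:
        label = int(rng.integers(0, 2))
    label = int(label)

    img = np.full((n, n), spec.body_level)
    img[mask == 1] = spec.lung_level
    # mild vignette for body texture
    yy, xx = np.mgrid[0:n, 0:n]
    r2 = ((yy / n - 0.5) ** 2 + (xx / n - 0.5) ** 2)
    img += 0.05 * (0.5 - r2)

    lesions = []
    if label == 1:
        lo, hi = spec.lesion_count_range
        count = int(rng.integers(lo, hi + 1))
        inside = np.argwhere(mask == 1)
        for _ in range(count):
            cy, cx = inside[int(rng.integers(0, len(inside)))]
            radius = float(rng.uniform(*spec.lesion_radius_range))
            sigma = radius / 2.0
            bump = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma**2))
            img += spec.lesion_contrast * bump
            lesions.append((int(cy), int(cx), radius))

    if spec.blur_sigma > 0:
        img = gaussian_filter(img, spec.blur_sigma, mode="nearest")
    img += _truncated_normal(rng, spec.background_noise_sd, (n, n))
    img = np.clip(img, 0.0, 1.0)

    return PhantomSample(
        image=img[..., None],
        lung_mask=mask,
        label=label,
        provenance={"seed": int(seed), "spec": spec.digest(), "lesions": lesions},
    )


def _split_for(index: int, seed: int) -> str:
    """Deterministic 70/15/15 split by hash of (seed, index)."""
    h = hashlib.sha256(f"{seed}:{index}".encode()).digest()
    u = int.from_bytes(h[:8], "big") / 2**64
    if u < 0.70:
        return "train"
    if u < 0.85:
        return "val"
    return "test"


def generate_dataset(
    n: int,
    pos_fraction: float,
    spec: PhantomSpec,
    seed: int,
    out_dir,
) -> "pd.DataFrame":
    """Write ``n`` phantom PNGs + mask PNGs + a CSV manifest; return the manifest.

    Exactly ``round(n * pos_fraction)`` samples are positive. Images and masks
    are 8-bit grayscale PNGs; the manifest has columns
    ``path,mask_path,label,split`` with paths relative to the manifest file.
    """
    from pathlib import Path

    if n < 2:
        raise ValueError("need n >= 2 samples")
    if not 0.0 <= pos_fraction <= 1.0:
        raise ValueError("pos_fraction must be in [0, 1]")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    n_pos = int(round(n * pos_fraction))
    labels = np.array([1] * n_pos + [0] * (n - n_pos))
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xD5]))
    rng.shuffle(labels)

    rows = []
    for i in range(n):
        sample = generate_sample(spec, seed=seed * 100003 + i, label=int(labels[i]))
        img_name = f"phantom_{i:04d}.png"
        mask_name = f"phantom_{i:04d}_mask.png"
        _save_png(sample.image[..., 0], out / img_name)
        _save_png(sample.lung_mask.astype(np.float64), out / mask_name)
        rows.append(
            {
                "path": img_name,
                "mask_path": mask_name,
                "label": int(labels[i]),
                "split": _split_for(i, seed),
            }
        )
    manifest = pd.DataFrame(rows, columns=["path", "mask_path", "label", "split"])
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def _save_png(arr01: np.ndarray, path) -> None:
    data = np.clip(np.round(arr01 * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(data, mode="L").save(path)


def apply_distortion(image: np.ndarray, kind: str, seed: int) -> np.ndarray:
    """Apply one acquisition-anomaly distortion; output has the input's shape.

    kinds: ``crop_pad`` (random crop, zero-padded back), ``invert``
    (photometric negative), ``burned_text`` (bright marker glyph blocks),
    ``letterbox`` (zeroed top/bottom bands).
    """
    img = np.asarray(image, dtype=np.float64)
    squeeze = img.ndim == 3
    work = img[..., 0] if squeeze else img
    h, w = work.shape
    rng = np.random.default_rng(np.random.SeedSequence([0xD157, int(seed)]))

    if kind == "invert":
        out = 1.0 - work
    elif kind == "letterbox":
        out = work.copy()
        band = max(1, h // 8)
        out[:band] = 0.0
        out[h - band :] = 0.0
    elif kind == "crop_pad":
        fh = int(round(h * rng.uniform(0.6, 0.9)))
        fw = int(round(w * rng.uniform(0.6, 0.9)))
        top = int(rng.integers(0, h - fh + 1))
        left = int(rng.integers(0, w - fw + 1))
        out = np.zeros_like(work)
        oy = int(rng.integers(0, h - fh + 1))
        ox = int(rng.integers(0, w - fw + 1))
        out[oy : oy + fh, ox : ox + fw] = work[top : top + fh, left : left + fw]
    elif kind == "burned_text":
        out = work.copy()
        # blocky marker glyphs along the top-left corner, as burned-in annotations
        glyph = max(2, h // 32)
        n_glyphs = int(rng.integers(3, 7))
        y0 = glyph
        for k in range(n_glyphs):
            x0 = glyph + k * 2 * glyph
            if x0 + glyph > w:
                break
            pattern = rng.random((3, 2)) > 0.4
            block = np.kron(pattern, np.ones((glyph // 2 + 1, glyph // 2 + 1)))
            by, bx = block.shape
            out[y0 : y0 + by, x0 : x0 + bx] = np.maximum(out[y0 : y0 + by, x0 : x0 + bx], block)
    else:
        raise ValueError(f"unknown distortion kind {kind!r}; expected one of {DISTORTION_KINDS}")

    out = np.clip(out, 0.0, 1.0)
    return out[..., None] if squeeze else out
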