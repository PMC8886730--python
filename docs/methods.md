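# Methods

## The attention mechanism

`xrattn` implements residual multi-scale gating driven by one shared global
attention map. An encoder-decoder G(·) maps the input image
x ∈ R^{h×w×c} through a downsampling path D to a latent map
z ∈ R^{h'×w'×c'} (h' = h/2^depth) and back through an upsampling path U with
skip connections to a raw map A_G ∈ R^{h×w×c_g} (c_g = 1 by default). The raw
map is bounded once per forward pass, σ(A_G) ∈ (0,1)^{h×w×c_g}, and shared by
all heads. Head j resamples the bounded map to its stage's spatial dims with
bilinear interpolation B_j and adapts channels with a single convolution C_j:

    Ā_j = C_j(B_j(σ(A_G)))          Ā_j ∈ R^{h_j×w_j×c_j}
    F̄_j = Ā_j ⊗ F_j + F_j

The residual form guarantees F̄_j = F_j bit-exactly when Ā_j = 0; with all C_j
weights and biases zero the whole classifier collapses to the plain backbone,
which the test suite asserts end-to-end.

Design choices where the formulation was genuinely open:

* **C_j consumes only the resized prior.** The feature map F_j contributes
  its target shape (h_j, w_j, c_j) and nothing else; no mixing of F_j into the
  head is performed, keeping the head parameter count at c_g·k²·c_j + c_j.
* **"Filter size c_j"** is read as the *number of output filters*; the spatial
  kernel defaults to 1×1 (pure channel adaptation) and is configurable to 3×3.
* **Sigmoid precedes interpolation** — the bounded map is the shared object;
  interpolating a (0,1)-bounded map keeps every local prior inside (0,1)
  (convexity of bilinear weights).
* **One interpolation convention repo-wide**: half-pixel centers with edge
  clamping, used identically for attention priors and image resizing, and
  verified against a brute-force direct evaluation of the formula.
* **Attachment point**: attention gates each *stage output* (post-residual for
  residual backbones), the least invasive placement when the interior of a
  block is not prescribed.
* **"Disabling" attention** is the identity bypass F̄_j = F_j. Zeroed attention
  maps produce the same result under the residual equation, so the two
  readings coincide.

## Backbones

* `small_cnn` — three stages of conv3×3 → relu → 2×2 maxpool with widths
  (8, 16, 32): the desk-scale backbone used by the tests, giving J = 3 heads.
* `resnet50` — the standard 50-layer bottleneck residual layout (stem +
  (3,4,6,3) blocks, ×4 expansion), implemented norm-free with the last
  convolution of every residual branch zero-initialized so each block starts
  as the identity; a width multiplier scales all channel counts. It exists to
  demonstrate the mechanism scales to a realistic backbone; benchmark-scale
  training of it is out of scope here.

The classifier head concatenates global average- and max-pooled features of
the last stage before a dense 2-class softmax layer. The max component
matters for this problem class: focal opacities occupy a tiny fraction of the
image, and a spatial maximum preserves localized detector responses that a
plain average dilutes. The backbone consumes zero-centered intensities
(2x − 1); the attention body receives the raw [0,1] image so that weights
from segmentation pretraining remain directly valid.

## Numerical substrate

All models run on `xrattn.nn`, a reverse-mode autodiff engine over numpy
float64 arrays (convolution as shift-and-matmul with "same" padding, 2×2 max
pooling, nearest upsampling, separable bilinear resizing, softmax
cross-entropy, BCE+Dice segmentation loss, Adam). Float64 keeps results
bit-reproducible across runs on the same platform and lets the test suite
compare gradients against central finite differences at ~1e-7 tolerances.
Adam moments are keyed by parameter name, so a parameter frozen for some
epochs resumes from its own optimizer state.

## Training procedure

**Segmentation pretraining.** σ(A_G) is fit to binary lung masks with an
equally weighted sum of binary cross-entropy and soft Dice loss
(smoothing constant 1.0). At the package's phantom scale (64 images of
64×64, 30 epochs, batch 8, Adam lr 3e-3) the held-out hard Dice (threshold
0.5) is ≈ 0.99.

**Alternating training.** Epochs alternate between the *main* side (backbone
+ classifier head) and the *attention* side (encoder-decoder + all C_j; the
projections belong to the attention block, switchable). Freezing is enforced
by excluding the frozen side from the optimizer step and verified in tests by
bitwise parameter comparison across the epoch. Alternation granularity is
per-epoch with a configurable period. The attention side uses its own,
typically smaller, learning rate: after segmentation pretraining the global
map is already useful, and symmetric learning rates let classification
gradients overwrite it, which destabilizes the gated features (observed as
oscillating training accuracy). The classification loss is 2-class
cross-entropy; the decision rule is argmax (equivalently threshold 0.5).

Reference full-scale defaults carried by `RunConfig`: 480×480 inputs, Adam,
learning rate 8e-5, batch size 16, alternation period 1. The phantom-scale
runs in the tests and the acceptance script override the learning rate
(3e-3 main / 3e-4 attention) because at a few hundred optimizer steps the
full-scale rate barely moves the parameters; this is a scale choice, not a
change to the defaults.

## The phantom generator

`xrattn.phantom` emulates just enough chest-radiograph structure to exercise
every mechanism: a bright "body" field (intensity 0.65) containing two
darker elliptical lung fields (0.30; semi-axes 0.30/0.17 of the image,
disjoint), a mild radial vignette, Gaussian smoothing (σ = 0.7 px), and
pixel noise truncated at ±3.5 sd (sd 0.03). Disease-positive phantoms add
1–3 isotropic Gaussian opacity bumps (amplitude 0.25, radius 5–12 px at the
128-px reference scale, rescaled proportionally at other sizes) whose
centers lie inside the exact elliptical lung mask. Noise truncation makes
negative phantoms provably free of bright outliers in the morphological lung
interior (boundary pixels are excluded from that guarantee because the blur
mixes in the brighter body). A single scalar — maximum lung-interior
intensity — separates the classes at ≥95% accuracy by construction, which
bounds from below what a trained network should achieve.

Distortion modes (`crop_pad`, `invert`, `burned_text`, `letterbox`) emulate
the acquisition anomalies of public radiograph collections and are
seed-deterministic, shape-preserving, and bounded in [0,1].

What the phantoms do **not** model: anatomy (ribs, mediastinum, costophrenic
angles), projection physics, scanner/exposure variation, patient positioning,
multi-focal texture of real ground-glass opacities, or label noise. Passing
phantom-scale tests therefore demonstrates the *mechanics* — shapes,
gradients, freezing, attention focus, ablation arithmetic — not clinical
performance.

## Problem sizes used by the tests and acceptance script

Pretraining: 64 training + 32 held-out phantoms at 64×64, encoder-decoder
depth 3, base width 8. Alternating training: 200 phantoms split 140/30/30,
28 epochs, batch 8. Capacity check: 32 phantoms, alternating training with
early stop, bound 200 epochs. These sizes keep a full suite run on one CPU
core in minutes while leaving every contract observable.

## Evaluation

Sensitivity (100·TP/(TP+FN)), PPV (100·TP/(TP+FP)) and accuracy
(100·(TP+TN)/n) are computed at full precision from the confusion matrix
(rows = true class, columns = predicted class) and rounded half-up only for
presentation, with configurable decimals — published comparison tables mix
one- and two-decimal formatting, and e.g. a 195/197 PPV (98.98) prints as
99.0 at one decimal. Undefined metrics on degenerate prediction vectors
(no positive calls) are reported as NaN rather than aborting a run.

## Known limitations

* Phantom-scale only; no real-data weights are bundled and clinical accuracy
  claims cannot be validated here.
* The norm-free `resnet50` is exercised for contracts (shapes, ablation
  equality, gradient flow) rather than trained to convergence.
* The engine is single-threaded numpy; wall-time scales roughly linearly in
  batch × pixels × channels².
* Checkpoints store raw float64 parameter arrays; no quantization or
  versioned migration.
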