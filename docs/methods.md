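# Methods

## Model

The segmentation network is a nested U-structure: an outer
encoder–decoder of eleven stages, each stage itself a residual U-block
(an inner encoder–decoder whose output is added to a 3×3 projection of
the stage input).  The fixed stage plan is

| stage | En1 | En2 | En3 | En4 | En5 | En6 | De1 | De2 | De3 | De4 | De5 |
|-------|-----|-----|-----|-----|-----|-----|-----|-----|-----|-----|-----|
| block depth | 7 | 6 | 5 | 4 | 4F | 4F | 7 | 6 | 5 | 4 | 4F |

Depth-L blocks contain one input projection, L−1 encoder units with
2×2 max pooling between them, and L−2 decoder units; "4F" is the
dilated variant used at the lowest resolutions, which keeps the spatial
size at every layer and widens the receptive field with dilation rates
2, 4, 8 instead (encoder-chain receptive field 1 + 2·(1+2+4+8) = 31 px,
verified by gradient support).  Every unit is Conv2d(3×3, stride 1,
same padding) + BatchNorm + ReLU.

Three attention mechanisms modulate the features:

* **Attention gate** on every inner skip connection.  With skip
  feature x (resolution H×W) and gating feature g (H×W or H/2×W/2),
  α = sigmoid(ψ(ReLU(W_x·x + up(W_g·g)))), where W_x, W_g, ψ are 1×1
  convolutions and up(·) is bilinear.  α is a single channel broadcast
  over x's channels, and the gated block output is
  ConvBNReLU(concat(α ⊙ x, up(g))).
* **SAM** on the output of every resampling block: channel-wise mean
  and max maps, stacked (2 channels), convolved 7×7 to 1 channel,
  sigmoid, broadcast multiply.
* **CAM** on the output of every dilated block: global mean and max
  pooled C-vectors pass the *same* two-layer bottleneck
  (C → max(1, C/r) → C, r = 16), are summed, sigmoid'd, and rescale
  the channels.

Each of De1–De5 and En6 emits a 1-channel side logit (3×3 conv,
bilinearly upsampled to input size); a 1×1 convolution fuses the six
logits into the final one, and a sigmoid maps all seven to
probabilities.

Design choices where the architecture was genuinely open, recorded as
this package's conventions:

* The gate combines by **multiplication only** (α ⊙ x); α has one
  channel.  The gate's intermediate width defaults to half of x's
  channels.
* W_g·g is bilinearly upsampled before the addition when g is at half
  resolution, keeping α at x's resolution; in 4F blocks gating is at
  equal resolution and the concatenation uses g directly (no
  upsampling).
* The residual addition uses the stage-input projection f₀ (the
  U²-Net residual-block convention); SAM/CAM apply **before** the
  residual addition.
* Channel widths: stage outputs are base_width·(1, 2, 4, 8, 8, 8) over
  En1..En6, mirrored for the decoders; inner (mid) width is half the
  stage output (minimum 2).  The plan is geometric because the stage
  plan fixes only depths, not widths.
* Inter-stage downsampling is 2×2 max pooling, upsampling is bilinear
  (parameter-free).
* En6's side output participates in both the fusion and the loss.
* Initialization is truncated-normal with fan-in scaling (std
  √(2/fan_in), clipped at ±2σ), drawn from a single seeded generator,
  so builds are bit-reproducible.

## Loss

Deep supervision sums, over the fused map and all six side maps with
unit weights,

* Dice loss 1 − (2Σyŷ + ε)/(Σy + Σŷ + ε), ε = 1e-6 (the smoothing
  defines the empty-mask case as loss 0);
* binary cross-entropy −(1/N)Σ[y log ŷ + (1−y) log(1−ŷ)] with ŷ
  clipped to [1e-7, 1−1e-7].

The cross-entropy deliberately includes the background term: an
objective that scores only vessel pixels cannot "equally weigh every
pixel", which is the reason for adding cross-entropy to Dice in the
first place.

## Evaluation

Confusion counts (TP, FP, TN, FN) are tallied exactly per pixel,
optionally restricted to the field-of-view mask (off by default), and
pooled over the whole evaluation set before metrics are computed once
(a per-image mode exists behind a flag):
Acc = (TP+TN)/total, SE = TP/(TP+FN), SP = TN/(TN+FP),
F1 = 2TP/(2TP+FP+FN), and MIoU = ½[TP/(TP+FP+FN) + TN/(TN+FN+FP)].
Zero denominators return 0 with a warning.

## Preprocessing and augmentation

Fixed order: green-channel extraction → normalization to [0,1] →
CLAHE → gamma correction.  CLAHE goes through scikit-image's
`equalize_adapthist`; the user-facing `clahe_clip` (default 2.0) is in
multiples of the uniform histogram bin height and is converted to the
normalized clip limit as clip/256.  Gamma defaults to 1.2 (mildly
darkening, suppressing equalization artifacts); it is a free parameter
of the chain and exposed in the config.

Augmentation is exact bookkeeping: ×4 flips (original, horizontal,
vertical, both), then ×5 translations (original plus one
fixed-magnitude shift — default 50 px — in each cardinal direction,
vacated pixels zero-filled in image, mask and FOV alike).  This
reproduces the canonical dataset expansions 40 → 160 → 800 and
28 → 112 → 560.  The 4:1 train/test split shuffles *source* images
(seeded) and assigns whole groups of augmented variants to one side,
so the split is leakage-free by construction.

## Synthetic phantoms

The generator emulates the structure of a fundus photograph that the
pipeline actually depends on: a circular FOV (radius 0.48·size), a
smooth radial background brighter at the centre, Gaussian noise
(σ = 0.03), and darker curvilinear vessel trees (contrast drop 0.35).
Trees grow as seeded random walks: 4 roots start on the FOV rim
heading inward, advance in 1 px steps with Gaussian heading jitter
(σ = 0.15 rad), stamp disks of the current width (roots 3 px), and
spawn children with probability 0.05 per step at width × 0.7 (pruned
below 1 px, branch angle 0.5–1.0 rad).  Each tree has a total step
budget of 2·size, which keeps the vessel fraction of the FOV in a
fundus-like range (measured 0.15–0.20 at the 128 px defaults).  All
draws come from one generator seeded by the spec, so a `PhantomSpec`
determines its phantom bit for bit.

What the phantoms do **not** emulate: optic disc and macula, pathology
(exudates, hemorrhages), camera vignetting and color, inter-grader
mask ambiguity, and realistic vessel calibre statistics.  Passing the
desk-scale tests therefore demonstrates that the implementation learns
and segments curvilinear dark structures correctly end to end; it
says nothing about clinical-grade accuracy on real fundus images,
which requires the full-width network and the public benchmark
datasets.

## Numerical engine and reproducibility

The network runs on a small reverse-mode autodiff engine over float32
numpy arrays written for this package (stride-1 dilated convolution
via sliding windows + einsum, 2×2 max pooling, bilinear resampling as
separable interpolation matrices, batch normalization with running
statistics, the pooling reductions the attention modules need).
Gradients are validated against central finite differences in the test
suite.  Single-threaded numpy arithmetic plus seeded initialization
and shuffling make builds, training trajectories and evaluation-mode
forwards exactly reproducible; evaluation-mode forwards are bitwise
repeatable.

Optimization is Adam (β = 0.9/0.999, ε = 1e-8) with classic L2 weight
decay 1e-4 folded into the gradient, constant learning rate 1e-3, and
batch size 2.  Images are zero-padded to a multiple of 32 (minimum 64)
before the forward pass and predictions cropped back.

## Problem sizes used in tests and the acceptance script

Desk-scale throughout: base_width 4 (≈ 2.4 × 10⁵ parameters), 64 px
phantoms, 8 training + 4 held-out images, ≤ 200 Adam iterations.
These sizes are the package's reference configuration for CPU
experiments; the same code scales to base_width 16–64 and full-size
images unchanged.

## Known limitations

* No learning-rate schedule (constant rate; a hook exists).
* Whole-image training only — no patch extraction.
* Binary segmentation only; no AUROC/PR or topology-aware metrics.
* The numpy engine is single-threaded and desk-scale; it is not a
  performance substitute for a GPU framework at full width.
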