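# Methods

## Problem setting

Two echocardiography-like domains share anatomy but differ in
appearance: a *source* domain with per-pixel annotations of the
left-ventricle endocardium (LV_endo) and epicardium (LV_epi), and a
*target* domain with images only.  The goal is a single segmentation
network that performs well on the target domain without ever seeing a
target label.  The framework couples a supervised segmentation
generator with two domain discriminators trained adversarially, one on
an internal feature representation and one on the entropy of the
output probabilities.

## Generator (ASDB)

- **Encoder.** Four feature levels at strides 4/8/16/32.  A two-conv
  stem reaches stride 4; each further level is a grouped-convolution
  residual block (1×1 reduce → grouped 3×3 stride 2 → 1×1 expand, with
  a strided 1×1 shortcut), the ResNeXt design pattern at configurable
  width.  The `tiny` preset (channels 12/16/24/32, 4 groups, ~31k
  parameters) is the desk-scale default; a `full` preset widens to
  64/128/256/512 with 32 groups.
- **MLF.** Every level is projected to a common channel width (16 in
  `tiny`), resampled to the stride-4 grid by nearest-neighbour
  upsampling, concatenated, and reweighted by a learned 1×1
  convolution.
- **DAM.** Per level, an attention map
  `a = σ(conv3×3([level, MLF]))` gates the projected level feature
  multiplicatively; a residual add of the level feature keeps the
  block well-behaved when attention saturates (all-zero attention then
  reduces to the identity).  The residual can be disabled in config.
- **Mask branch.** A 1×1 head plus sigmoid per level, on both the
  original projected and the refined features (8 predictions;
  configurable to refined-only, 4).  The fused prediction is their
  arithmetic mean.  Channels are two *independent* sigmoids (endo,
  epi): the regions are nested, so mutually exclusive softmax classes
  would misrepresent the geometry.
- **Boundary branch.** From the two highest-resolution refined levels
  (strides 4 and 8): boundaries are a detail-scale signal.  The target
  is a morphological contour band of total width 2 px around each
  structure (union of endo and epi bands).

The supervised loss sums natural-log binary cross-entropy over all
per-layer mask predictions and adds one mean-squared-error term for the
boundary map.  Probabilities are clipped to `[1e-7, 1−1e-7]` before
logs.

## Discriminators and adversarial losses

Both discriminators are patch-based fully-convolutional classifiers
(five stride-2 3×3 convolutions, leaky-ReLU 0.2, sigmoid patch
outputs); losses average BCE over patches and batch.  The feature
discriminator sees the fused MLF feature; the entropy discriminator
sees the per-channel entropy map of the fused mask, stacked as two
input channels rather than summed.

The entropy of a probability `p` is implemented as the nonnegative
uncertainty `−p·log p` (maximum `1/e` at `p = 1/e`, zero at 0 and 1);
a config flag (`sign="printed"`) switches to the signed form `p·log p`,
which only mirrors the map and does not change discriminability.
The derivative `−(log p + 1)` is taken as 0 at `p = 0`: a fully
saturated prediction receives no entropy gradient.

Discriminator losses are computed on *detached* generator outputs, so
a discriminator step can never move generator weights; the generator's
adversarial losses backpropagate through frozen discriminators whose
optimizers are simply not stepped on that pass.  Each training step
updates the generator first (on `L_seg + λ(L_adv^f + L_adv^e)`), then
each discriminator independently, re-using the same source and target
batches.  Ablation arms disable either adversarial space (`no_eda`,
`no_fda`) or both (`no_da`).

## Training schedule and parameters

| parameter | default | note |
|---|---|---|
| λ (adversarial weight) | 0.01 | typical scale for output-space adversarial segmentation; dimensionless |
| generator optimizer | Adam, lr 2.5e-5 | reference schedule for full-size 200-epoch training |
| discriminator optimizer | SGD, lr 1e-3, momentum 0.9 | lr × 0.2 every 100 epochs |
| batch size | 8 | both domains per step |
| validation | every 10 epochs | source-domain mean Dice selects the checkpoint |
| desk preset | Adam 5e-3, ≤30 epochs | the tiny network needs a much larger step to converge within tens of epochs; 5e-3 reaches source-validation Dice ≈ 0.9 by 30 epochs on 64×64 phantoms |

Validation uses a seeded 10% split of the source set (target labels are
unavailable by construction), with one evaluation before training as
the epoch-0 reference.  No warmup is used.  All randomness (weights,
data order, phantom geometry and style) flows from explicit seeds;
runs are bit-for-bit reproducible on the same platform.

## Phantom generator

Each sample is a sector-cone scan (apex top-center, default 75°):
an elliptical endocardial blood pool (semi-axes 12–20% of the image
width, random rotation and jittered center), an epicardial annulus
obtained by dilating the endocardium by a random margin, a smooth
textured background, and multiplicative gamma-distributed speckle
(shape k, mean 1).  Intensity is gamma-corrected and clipped to
[0, 1]; pixels outside the cone are zero.  Geometry and style consume
*independent* RNG streams, so two configs that differ only in style
parameters (gamma, speckle shape, texture scale) generate identical
mask distributions — a pure appearance shift.  The canonical benchmark
uses domain A (γ=1.0, k=4, texture 8 px) as source and domain B
(γ=0.5, k=2, texture 4 px) as target.

What the phantoms do **not** model: point-spread-function physics,
attenuation and shadowing, papillary muscles, valve structures, view
variation (A2C/A4C), pathology, or temporal coherence.  Passing the
desk-scale tests therefore shows that the adversarial machinery closes
a controlled appearance gap over identical anatomy; it does not certify
performance on clinical cross-vendor data.

## Numerical and engine choices

Networks run on `macs.nn`, a compact reverse-mode autodiff over numpy
(im2col convolutions backed by BLAS, float32 arithmetic with float64
loss reductions), deterministic and single-device by design.  Loss
values at analytic checkpoints (ln 2, 2·ln 2, −p·log p values) hold to
about 1e-6.  BCE gradients vanish in the clipped probability region,
mirroring the saturated-sigmoid regime.  Nearest-neighbour upsampling
is used throughout (mask heads, MLF resampling); predictions are
therefore blocky at the stride-4 scale, a deliberate cost of the tiny
preset.  Probability masks are thresholded at 0.5 before metrics.

Metric conventions: Dice and Jaccard of two empty masks are 1.0;
the Hausdorff distance (full max-min, not 95th percentile) is
undefined for an empty mask — `hausdorff` raises, while batch
evaluation records NaN and averages over defined values.  Contours are
mask pixels with a 4-neighbour outside the mask, with pixel centers as
coordinates and an explicit mm-per-pixel spacing.  Bland–Altman limits
use the sample standard deviation (ddof = 1) and ±1.96.
The boundary band `dilate(m, ⌊w/2⌋) ∧ ¬erode(m, ⌈w/2⌉)` reduces to the
inner contour at width 1 and is complement-symmetric at even widths.

## Desk-scale study conditions

The repository's headline experiment trains on 96 labeled source and
96 unlabeled target phantoms (64×64, batch 8, 30 epochs, tiny preset)
and evaluates on 32 held-out labeled target phantoms, comparing the
full framework with source-only training over three seeds.  The size
was chosen so that a full comparison completes in minutes on one CPU
while the source model still reaches ≈0.9 validation Dice — small
enough to iterate, large enough for the domain gap (target endo Dice
drops of 0.1–0.6 without adaptation) to be meaningful.  Per-seed
variance of adversarial training at this scale is substantial; claims
are made on seed-averaged means, and the intermediate ablation arms
(`no_eda`, `no_fda`) are reported without an ordering assertion.

## Known limitations

- The tiny preset's nearest-upsampled masks cap achievable Dice below
  what an encoder-decoder with learned upsampling would reach.
- The exact DAM block of the deep-attention-feature line of work is
  not reproduced bit-for-bit; the implementation follows the published
  design pattern (concat → conv → sigmoid gate → residual).
- Adversarial training at desk scale is noisy; single-seed comparisons
  between arms are not meaningful.
- The `full` preset is provided for completeness but is not exercised
  by the test suite at full input resolution.
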