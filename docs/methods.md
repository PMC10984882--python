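# Methods

## Problem and scope

`eauscan` implements a complete pipeline for binary detection of rectal
cancer in endoanal ultrasound (EAUS) frames: image enhancement tailored to
the artifacts of 360° radial transrectal imaging, a convolutional
classifier trained with a two-stage transfer-learning protocol, and a
tenfold cross-validated evaluation harness with confidence-interval
reporting. Because clinical EAUS archives are private, the package ships a
seeded phantom generator that emulates the visual features the pipeline
must handle; all quantitative claims made by the test suite are claims
about those phantoms, not about clinical images (see *Phantom realism*
below).

## Preprocessing chain

Raw frames carry colored caliper annotations, device metadata bands, and a
central transducer artifact. The chain runs, in order:

1. **Colored-mark mask.** A pixel is "colored" when its channel spread
   (max − min over R,G,B) exceeds `color_delta_threshold` (default 20 gray
   levels). This flags any saturated annotation hue and is a no-op on pure
   grayscale content.
2. **Inpainting.** Masked pixels are filled by iterative 4-neighbor mean
   (Jacobi) diffusion with boundary values clamped — an approximate
   harmonic fill — stopping when the largest per-pixel update falls below
   0.5 gray levels. The method is deterministic and exact for linear ramps.
3. **Binarization at 8.** Strict greater-than: a pixel at exactly 8 is
   background. The low threshold separates the echo field from the black
   surround without touching tissue texture.
4. **ROI crop.** Connected components are labeled (8-connectivity by
   default) and the image is cropped to the bounding box of the largest
   component — the ultrasound field. Area ties break toward the smallest
   (row, column) origin.
5. **Small-spot removal.** Components with area strictly below
   `min_spot_area` (default 50 px) are dropped; a component at exactly the
   threshold is kept.
6. **Transducer-circle removal.** The transducer face appears as a solid
   near-center disc. A component qualifies when it is hole-free (Euler
   number 1), its fill ratio area/(πr²) — with r estimated as half the mean
   bounding-box side — is at least 0.85, and its centroid lies within 25%
   of the ROI size from the ROI center. The largest qualifying disc is
   masked out; if none qualifies the pipeline logs this and proceeds,
   since circle removal is an enhancement, not a requirement.
7. **Top-hat/bottom-hat enhancement.** With a disk structuring element of
   radius r: `out = clip(g + whitetophat(g) − blacktophat(g), 0, 255)`.
   Bright detail smaller than the disk is amplified and dark detail
   deepened, raising local contrast of the speckled wall layers.

### Contrast improvement ratio (CIR)

Local contrast is Weber-like: `c(x,y) = |p − ā| / (p + ā)` where `ā` is the
mean over the window neighbors of the pixel (center excluded; windows are
clipped at the image border, and pixels with `p + ā = 0` get contrast 0).
The CIR between an original image and its enhancement over a region R is

    CIR = Σ_R (c − c̃)² / Σ_R c²

with `c̃` the enhanced image's contrast map. The structuring-element radius
is selected by sweeping disk radii 1–15 in increasing order and keeping the
argmax CIR. With a positive relative tolerance (default 1e-3) the sweep
stops after the relative improvement over the running best has stayed below
the tolerance for two consecutive radii; a non-positive tolerance forces an
exhaustive sweep. The tolerance-zero path is defined as fully exhaustive on
purpose: a "less than zero improvement" stopping rule could still terminate
before a later maximum on non-monotone CIR profiles, which would break the
invariant that tolerance zero reproduces the exhaustive argmax.

CIR is undefined (raises) when the original region has identically zero
local contrast, e.g. a constant image.

## Classifier

The network is: a learnable grayscale adapter (one Conv2D, three 3×3
filters, same padding) that maps single-channel input to the three channels
a color-image backbone expects → the backbone → global average pooling →
dropout 0.5 → a single-unit sigmoid head. Loss is binary cross-entropy
(implied by the sigmoid head), optimized with Adam.

The engine is written in numpy with explicit im2col convolutions and
hand-derived gradients (verified against numerical differentiation in
development); at the network sizes involved this trains in seconds per
epoch on one CPU core. The built-in `tiny-scratch` backbone is four
Conv-BatchNorm-ReLU blocks (8/12/16/16 channels, three 2×2 max-pools).
Named pretrained families can be registered through `register_backbone`
without touching the training protocol; none are bundled.

Batch-normalization details: running statistics use momentum 0.7 because an
epoch here is only ~10–25 batches and slower updates leave inference
statistics stale for several epochs, which interacts badly with
accuracy-monitored early stopping. Frozen BatchNorm layers run in inference
mode even during training (batch statistics neither used nor accumulated),
the usual transfer-learning convention. Running statistics are part of
weight snapshots, so best-epoch restoration is exact.

### Two-stage training

Stage 1 is transfer learning: the backbone is frozen and only the adapter
and head train, at `stage1_lr` (default 3e-3). Stage 2 is fine-tuning at a
much lower `stage2_lr` (default 1e-5), unfreezing the backbone fully
(`all`), partially (`last-k-layers`, covering the partial-unfreeze regime
with k = 3), or not at all (`head-only`). Both stages monitor validation
accuracy, stop after `patience = 4` epochs without improvement, and restore
the best-epoch weights; a constant-accuracy run therefore stops after
exactly 1 + 4 epochs per stage. For a randomly initialized backbone there
is no feature extractor worth protecting, so stage 1 trains all layers by
default; `freeze_backbone_stage1` forces either behavior.

The stage-1 learning rate of 3e-3 (with batch size 8) was chosen because
at 1e-3 a scratch backbone frequently shows no validation-accuracy movement
within the first four epochs on several seeds, so the protocol's own early
stopping aborts training before learning starts; 3e-3 converges reliably
while stage 2 keeps the "significantly decreased" rate.

Training batches are augmented (test data never is): multiplicative
brightness jitter ±10%, central zoom ±10%, rotation uniform in [0, 360°) —
"small" brightness/zoom changes and an arbitrary angle, quantified here.
Zero-magnitude settings are an exact identity. Augmentation, batch order
and dropout all draw from one seeded generator, making runs reproducible.

## Evaluation

`make_fold_plan` builds the tenfold partition: each round uses ~10% of
images as the test set (via stratified k-fold by default; the label
distribution of 161/133 makes stratification the safe default), ~15% as
validation and ~75% for training. Patient-grouped splitting is available
(`group_by_patient`) but off by default, matching image-level splitting.
Each fold trains a fresh model; held-out probabilities accumulate into a
single prediction vector with exactly one entry per image. A leakage guard
asserts at runtime that no test index appears in its fold's train or
validation sets.

Decisions threshold at 0.5, with probability exactly 0.5 classified
abnormal. The positive class is abnormal (cancer) throughout: sensitivity =
tp/(tp+fn), specificity = tn/(fp+tn), precision = tp/(tp+fp), and NPV =
tn/(tn+fn) are all reported explicitly to keep the orientation unambiguous.
Zero-denominator proportions are reported as undefined (None), not raised.

Proportion CIs are Wilson score intervals with z = 1.96. ROC points come
from grouped thresholds (tied scores move together), AUC is the trapezoidal
area — equal to the tie-corrected Mann–Whitney statistic, which the test
suite verifies pairwise — and the AUC interval uses DeLong's
structural-component variance with a normal approximation. Rendered tables
round half-up to 3 decimals.

## Phantom generator

Each phantom frame contains: a dark background; a bright central transducer
disc separated from the tissue by a thin anechoic halo (which is what makes
the disc a distinct connected component after binarization, as in real
radial probes where the probe face is ringed by the water interface);
five concentric wall layers with alternating bright/dark mean intensities
(defaults 170/60/150/70/120 on a 0–255 scale); multiplicative gamma speckle
with mean 1 (shape 12; larger is smoother); an optional hypoechoic lesion —
a sector spanning configurable angles and radial fractions whose template
intensity is multiplied by (1 − `intensity_drop`), with a ragged angular
boundary; saturated green/yellow caliper crosses with 3–9 px strokes; and a
dark metadata band with bright glyph-like dashes at the top of the frame.
Default frame size is 797×657, the clinical post-crop resolution; the test
suite uses geometrically scaled-down frames (128×112 and 64×64) to keep
runtimes in seconds.

Lesion defaults (70° width, radial span 0.35–0.85 of the field radius,
intensity drop 0.55) make the abnormal class clearly separable — by design:
with a drop ≥ 0.4 a simple sector-mean threshold classifies 50 phantoms
perfectly, which the suite uses as a sanity oracle that downstream learning
failures are model failures, not data failures. `generate_dataset` jitters
geometry (±8%), layer intensities (±10%) and lesion position (uniform
angle) per image, and assigns images to patients round-robin so
patient-grouped splitting is exercisable.

Independent RNG sub-streams drive lesion shape, speckle, metadata glyphs
and marks, so a lesion/no-lesion pair at the same seed shares its speckle
realization — used for paired-comparison tests.

**Phantom realism.** The generator is a first-order emulation: no
point-spread-function convolution, no depth attenuation, no refraction or
shadowing artifacts, no probe-pressure deformation, and lesions are simple
darkened sectors rather than infiltrative masses. Passing tests demonstrate
that the pipeline's machinery is correct and that the classifier can learn
a hypoechoic-disruption signal at realistic noise levels; they do not
demonstrate clinical-grade accuracy on real EAUS images.

## Problem sizes and numerical choices

The scaled-down end-to-end runs use 200 phantoms (100 per class, 40
patients) at 64×64 with the tiny scratch backbone, 5-fold cross-validation
and a 30-epoch cap per stage — sizes chosen so a full run completes in a
couple of minutes on a single core while still exercising every stage of
the protocol. Intensities are float in [0, 255] with clipping after
enhancement; resampling to the backbone input size is bilinear; inputs are
scaled to [0, 1] before the network. All tie-breaks are documented at the
operation that makes them (smallest radius for CIR ties, smallest origin
for bbox ties, abnormal at probability exactly 0.5).

## Known limitations

- No bundled pretrained backbones; the transfer-learning stages are
  exercised with the scratch backbone and the freeze semantics are covered
  by parameter-identity tests.
- DeLong CIs assume asymptotic normality and degrade for very small or
  near-separable samples.
- The inpainting diffusion is O(iterations × masked pixels) and intended
  for sparse annotation masks, not large occlusions.
- Class imbalance handling (161/133 in the motivating dataset) is limited
  to stratified folds; no loss re-weighting is applied.
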