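# Methods

This note documents the models, estimators, and numerical choices behind
`spherovia`, and what the synthetic-data experiments do and do not show.

## The estimation problem

A spheroid's viability is defined as its total ATP content divided by the
median ATP of untreated control spheroids in the same study. The package
estimates this dimensionless quantity (1 = control level; values slightly
above 1 occur and are supported up to 1.3) from a single bright-field
image. Ground-truth labels come from a destructive ATP assay, so a
training set pairs each image with one terminal ATP measurement.

### Control-median normalization

Absolute ATP readouts carry large multiplicative batch effects between
studies (reagent timing, seeding density, plate-reader calibration).
Dividing by the *median* of the same study's controls cancels any per-study
scale factor exactly — the normalized values are invariant under
`ATP → c·ATP` for any `c > 0` — and the median makes the reference robust
to outlier control wells. Grouping is per study by default (per plate
optionally; study plates carry ≥ 12 controls each, and the code warns below
12). Controls imaged on the sample's own day are preferred when present.
Even-sized control groups use the midpoint median. Wells without an ATP
value remain usable for inference but are excluded from the labeled
subset. Statistical outliers are *retained*: only verified technical
failures (empty well, out-of-focus capture, documented pipetting errors)
are excluded, via explicit QC flags.

## The deep regressor

The default model is an 18-layer residual convolutional backbone — 3×3
convolutions with batch normalization and ReLU, four stages of two
residual blocks (64/128/256/512 channels), global average pooling to a
512-dimensional latent vector — followed by an MLP regression head with
four hidden layers of width 32, dropout (rate 0.30) before each hidden
layer, and a scalar output. The default configuration has 11,196,129
trainable parameters (11,176,512 backbone + 19,617 head), i.e. ~11 M.

Preprocessing is fixed and identical at training and inference: crop the
manifest bounding box expanded by 10%, resize to the configured input size
(224 default), replicate the grayscale channel, and standardize
intensities with fixed constants (mean 0.5, sd 0.25 on the [0, 1] scale).
Per-image standardization is deliberately avoided — absolute interior
darkness is itself a viability cue.

Training minimizes MSE with Adam (learning rate 1e-4, weight decay 5e-4
added to the gradient, batch size 32), halves the learning rate when the
validation loss fails to improve by a relative 1e-4 for 5 consecutive
epochs, stops early after 20 epochs without a new validation best (at most
150 epochs), and restores the best-validation weights *including* the
batch-normalization running statistics — parameters from epoch *k* paired
with running statistics from a later epoch are inconsistent and degrade
badly. An ensemble is trained over the cross product of initialization
seeds and 80/20 train/validation split seeds (3 × 3 = 9 models by
default); predictions report the per-image ensemble mean and standard
deviation. Training is deterministic given the seeds and thread count.

The layer framework (`spherovia.nn`) is written in NumPy with explicit
forward/backward passes for every layer (convolution via strided
im2col/col2im, depthwise convolution, batch/layer normalization, max and
global-average pooling, dense, dropout, residual blocks, multi-head
self-attention, GELU) and an Adam optimizer. Every backward pass is
verified against central finite differences in the test suite. Parameters
are float32, the standard working precision for CNN training. Two
additional scaled-down backbones share the interface (an inverted-residual
convolutional net with a 1280-d latent and a patch-embedding transformer
with a 192-d latent); a `tiny_test` backbone (four stride-2 conv blocks,
64-d latent, ~30 k parameters) exists so that the full pipeline trains in
minutes on one CPU.

Data are split chronologically *by study*: every study is entirely on one
side of the cutoff, so no within-study correlation leaks across the
train/test boundary.

## Segmentation and shape features

The default segmenter is classical, since the downstream feature
definitions only require a mask satisfying an accuracy contract (IoU ≥ 0.9
against reference masks on benchmark renders); any learned segmenter
meeting the same contract can be plugged in. The pipeline: Otsu threshold
for a coarse foreground/background split; re-threshold at
`background mean − max(3·background sd, 5% of background level)` — a
single global Otsu clips the partially-attenuated lobes of irregular
spheroids — then morphological closing (disk radius 2% of the smaller
image dimension), hole filling, and largest-connected-component selection.
Blank wells are detected by the absence of pixels clearly below the
background level, or by a foreground/background contrast below 4 background
standard deviations; they raise an error that maps to the `empty_well` QC
reason. On 120 synthetic renders across the viability range the minimum
IoU against the ground-truth mask is 0.95.

Contours are traced at the 0.5 level of the Gaussian-smoothed float mask
(σ = 0.045 × equivalent radius, clipped to [0.7, 2.2] px): an anti-aliased
level set with sub-pixel vertices, rather than the raw pixel staircase.
Tying σ to object size makes boundary descriptors scale-equivariant. The
boundary is resampled to 256 points uniform in arc length, optionally
smoothed with a circular moving average, and oriented counter-clockwise.

Features:

* **Curvature** `k_i = |x'y'' − y'x''| / (x'² + y'²)^{3/2}` with central
  finite differences under periodic boundary conditions; zero-velocity
  points inherit the larger neighboring curvature with a warning. The
  feature vector carries mean, sd, and max, both raw (1/px) and multiplied
  by the equivalent radius `sqrt(A/π)` (dimensionless). For the feature
  path the contour is smoothed over 13 of the 256 points (~5% of the
  boundary): curvature is a second derivative, and lighter smoothing
  measurably inflates it with pixel-quantization noise and breaks scale
  invariance (verified against an analytic curvature oracle).
* **Circularity** `2·sqrt(π·A) / P` with A the mask pixel count and P the
  contour perimeter; 1 for a disk (isoperimetric bound, enforced at
  ≤ 1.02 with discretization slack), `sqrt(π)/2 ≈ 0.886` for a square.
* **Brightness ratio** — mean intensity inside the mask over the mean
  intensity of the background, where background excludes a 5-px dilation
  ring around the mask (the bright/dark halo at the spheroid edge).

## Baselines

Three tabular baselines predict viability from (i) the shape/brightness
features, (ii) the three ordinal pathologist scores (cytoplasmic, nuclear,
contour changes; five grades each, stored analysis-ready with 4 =
control-like — a helper flips to the raw grading orientation), and (iii)
their concatenation. Model selection runs 5-fold cross-validation over
decision trees, gradient-boosted trees, and MLPs with small hyperparameter
grids, scoring by mean CV MSE with ties broken toward the simpler family.
Fixed presets pin the gradient-boosting hyperparameters that win this
selection per feature set (e.g. depth 2, 50 estimators, learning rate 0.1,
min 4 samples per leaf for the shape-feature baseline). Scores enter as
three ordinal integers, not one-hot. The score space has exactly
5³ = 125 combinations; the score-space analysis tabulates their
frequencies and the viability spread within each combination — a handful
of combinations typically dominates, and each covers a wide viability
range, which is precisely why score-based regression saturates.

## Latent-space analysis

Latent vectors (the pooled backbone features) are decomposed with PCA
(top 10 components by default), fit on the analysis cohort, with a
deterministic sign convention (each component's largest-magnitude loading
is positive). Fluorescence biomarker scores are summed channel intensity
inside the mask divided by mask area; bright-field/fluorescence
registration is assumed (same well), and no background subtraction is
applied. Components with |Pearson r| < 0.1 against viability form the
"viability-orthogonal" subspace; the association of a biomarker with that
subspace is the maximum absolute correlation over its components. Because
the maximum over several components inflates naive significance, the
p-value comes from permuting the biomarker values (1,000 permutations by
default) and recomputing the max statistic, with the add-one estimator
`p = (1 + #{null ≥ observed}) / (n_perm + 1)` — never exactly zero, with a
floor of `1/(n_perm+1)`. The test's null calibration (uniform p-values)
and its conservativeness relative to naively testing the best-correlated
component are both verified by simulation in the test suite.

## Dose-response and DILI

Per drug (and imaging day), control-normalized viabilities across a
concentration series are fitted with a four-parameter logistic
`v(c) = bottom + (top − bottom) / (1 + (c/x50)^h)` by bounded least
squares: top ∈ [0.8, 1.2] (labels are control-normalized, so the top is
anchored near 1), bottom ∈ [0, 0.5], Hill slope ∈ [0.3, 6], and the
midpoint parameterized on the log scale within two decades of the tested
range. The reported IC50 is the concentration where the fitted curve
crosses **half the control level** (0.5·top) — a 50% reduction relative to
control, not the curve's own midpoint when the bottom is above zero. If
the fit fails or never crosses within a decade of the tested range, the
estimate falls back to log-linear interpolation between the bracketing
concentrations; if no tested concentration halves viability, the IC50 is
censored above the highest tested concentration. At least 4 distinct
positive concentrations are required.

The margin of safety is MOS = IC50 / Cmax with Cmax the clinical peak
plasma concentration; a censored IC50 yields MOS = +∞, so the drug sorts
as safest rather than being dropped (every drug must carry a score for the
ROC). DILI classification sweeps thresholds over all observed MOS values
(lower MOS ⇒ predicted toxic); the ROC's trapezoid AUC equals the
Mann-Whitney concordance of the negated scores (ties counted half), which
the tests verify against an O(n²) oracle and scikit-learn, and which is
invariant under any strictly increasing transform of MOS. Daily
time-courses take the median viability across replicates per (drug,
concentration, day) — a minimum of 5 replicates is expected, with a
warning below — and refit IC50/MOS per day; day 7 is the default
classification endpoint.

## The synthetic-data generator

The generator defines the study conditions for every test. One well =
one spheroid: a ground-truth viability `v` is drawn (controls near 1,
treated wells uniform on [0, 1.2]), mapped to rendering parameters, and
rendered to a grayscale image; the raw ATP label is
`batch_scale × 800 nM × v × (1 + ε)` with `ε ~ N(0, 0.10)` and a
log-normal (σ = 0.4) per-study batch scale.

The viability → morphology map drives four cues, each monotone in the
viability deficit `d = 1 − clip(v, 0, 1)` and each carrying independent
per-spheroid log-normal heterogeneity:

| cue | form | heterogeneity (log-sd) |
|---|---|---|
| contour irregularity | `0.35·d^1.5`, 3 low-order harmonics | 0.85 |
| core darkening | `0.60·d`, Gaussian radial profile | 0.70 |
| interior granularity | additive speckle, sd `0.5·0.22·d`, grain σ 3 px | 0.12 |
| fragmentation | satellite debris, only below v = 0.25 | Poisson count |

The boundary is `r(θ) = R·(1 + A·Σ w_k cos(kθ + φ_k))` plus fine
viability-independent roughness (orders 10–16, amplitude ≤ 0.05 — even
healthy spheroids have cell-scale boundary texture). Healthy spheroids are
visible because the interior carries a baseline attenuation (25% of the
background level, configurable) plus a darker rim; the dark core term adds
on top. Rendered images pass through per-image optical nuisances drawn
independently of viability: slight defocus (σ 0.3–0.6 px), a linear
illumination gradient (≤ 8% across the frame), exposure scaling (±8%), and
additive Gaussian sensor noise (sd 0.02). Rendering is bit-identical under
fixed seeds.

The heterogeneity magnitudes were calibrated so that the generator
realizes the intended information structure: the two cues visible to the
handcrafted features (shape, brightness) each carry *partial* signal,
while the granular texture — invisible to contour and mean-brightness
summaries, and rendered additively precisely so that it does not entangle
with core darkness — is the most reliable single cue and is readable only
from raw pixels. Under these conditions the feature baseline reaches a
held-out R² around 0.8 and an estimator with access to all pixel cues can
exceed it; this ordering is asserted end-to-end in the acceptance suite.

Dose-response panels follow a descending Hill curve
`v(c) = 1 / (1 + (c / IC50)^h)` with multiplicative noise, with the
apparent IC50 shifted upward on earlier days (onset rate 0.5 per remaining
day) so drug effect sets in monotonically; the final-day curve matches the
nominal IC50 exactly, giving the noiseless round-trip oracle. Biomarker
channels are affine in viability with noise calibrated to a target
correlation (defaults 0.8/0.7/0.75 for the three channels).

**What the synthetic experiments do not show.** The generator's morphology
manifold is low-dimensional and its nuisances are mild compared to real
microscopy (no debris fields, no meniscus shading, no focus stacks, no
microscope-specific optics); real-data accuracy, and in particular
cross-microscope generalization, cannot be inferred from these tests. What
the tests do establish: each pipeline stage is mathematically correct
against closed-form or brute-force oracles; normalization cancels batch
effects exactly; the training loop optimizes, ensembles, and reproduces
deterministically; and when images demonstrably contain more usable signal
than the handcrafted summaries, the image regressor recovers the
difference.

## Scaled-down end-to-end protocol

The acceptance suite trains the `tiny_test` backbone on 12 synthetic
studies of 96 wells (10 studies / 960 labeled images for training, 2 / 192
held out chronologically), on bounding-box crops resized to 64 px, with
dropout 0, learning rate 1e-2, at most 80 epochs, early-stop patience 20,
and a 3-member initialization ensemble. These sizes were chosen so the
whole study runs in a few minutes on one CPU while preserving the
protocol's structure (study-level chronological split, control
normalization, ensemble prediction); the full-size defaults (224 px
input, residual-18 backbone, lr 1e-4, dropout 0.3, 9 models) remain the
configuration defaults. The classical-feature baseline is fitted with its
preset hyperparameters on the same crops and split.

## Known limitations

* The classical segmenter assumes a single dark spheroid on a brighter,
  roughly uniform background; bright-field artifacts that violate this
  (strong vignetting, multiple objects) need the pluggable segmenter
  interface.
* Curvature summaries depend on the smoothing scale; values are comparable
  only within a fixed (n_points, smoothing_window) setting.
* The 4PL fit reports a point estimate; no confidence interval on IC50 is
  propagated into MOS.
* The NumPy training loop is single-threaded BLAS-bound; it is intended
  for the scaled-down backbone and for correctness-critical reference use,
  not for training the full-size model on large datasets.
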