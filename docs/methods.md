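# Methods

`diffage` implements a denoising-diffusion probabilistic model (DDPM) for
scalar regression — predicting brain age from 2D axial slices of T1-weighted
brain MRI — together with the surrounding pipeline: intensity preprocessing
and slice selection, per-slice model training, multi-slice ensembling with
outlier exclusion, and the downstream brain-age-gap statistics. Everything is
exercisable end to end on synthetic phantoms with known ground truth.

## The regression diffusion model

### Forward and reverse process

A subject's age `a` is mapped affinely to `y0 ∈ [-1, 1]` over configured age
bounds (default 3–30 years, matching the developmental range the model
targets). The forward process corrupts `y0` under a linear variance schedule
with `β1 = 1e-4` and `βT = 0.02` (inclusive endpoints; `ᾱ_t = Π_{s≤t}(1-β_s)`):

    y_t = sqrt(ᾱ_t) · y0 + sqrt(1 - ᾱ_t) · ε,   ε ~ N(0, 1).

Inference runs standard DDPM ancestral sampling from `y_T ~ N(0,1)`:

    y_{t-1} = (y_t - β_t/sqrt(1-ᾱ_t) · ε̂) / sqrt(α_t) + σ_t z,  σ_t² = β_t,

with no noise injected at the last step. Several reverse chains (default
`n_draws` = 8) are averaged, the result is clipped to `[-1, 1]` and mapped
back to years. The clip keeps predictions inside the training age range; it
is a deliberate design choice for a bounded regression target.

### Dual-granularity conditional guidance (DCG)

Two auxiliary predictions condition the denoiser at every step:

* **Global prior** `ŷ_g`: the slice passes through a global encoder `τ_g`
  followed by a 1×1 convolution, producing a saliency map; the prior is the
  arithmetic mean of all map responses.
* **Local prior** `ŷ_l`: the top-k salient locations (greedy selection with
  non-max suppression at Chebyshev radius `patch_size/2`, ties broken in
  row-major order) are mapped back to image patches, encoded by a local
  encoder `τ_l`, pooled by gated attention
  `a_k = softmax(wᵀ(tanh(V h_k) ⊙ sigmoid(U h_k)))`, and passed through a
  linear head.

Both priors are trained with an MSE loss against the normalized true age,
added to the diffusion objective with weight `dcg_loss_weight` = 1.0 (joint
training; the alternative of pre-training the guidance network first was not
adopted because joint training keeps the code path single-stage and worked
without pathology). The denoiser receives the priors detached, so the
guidance network is shaped only by its own MSE loss.

### Noise predictor

The denoiser is a multilayer perceptron on the concatenation
`[ρ(x), y_t, ŷ_g, ŷ_l, temb(t)]` ending in a single-output fully connected
layer, where `ρ(x)` is the embedding from a residual convolutional image
encoder and `temb` is a sinusoidal timestep embedding (dimension 16). For a
scalar response, a vector-input denoiser is the natural reduction of a
"U-Net over embeddings"; this package makes that reduction explicit rather
than emulating spatial structure that a scalar target does not have.

### Losses

The training objective is

    L_diff = L_e + 0.5 · (L_MMD_g + L_MMD_l)  (+ 1.0 · L_DCG),

with `L_e` the batch-mean squared norm of `ε - ε̂` and each MMD term the
kernel maximum mean discrepancy between noise predicted under one prior
conditioning (the other prior channel zeroed) and fresh standard-normal
reference draws. The MMD estimator is the biased V-statistic with a Gaussian
RBF kernel — chosen for guaranteed non-negativity — and the bandwidth
defaults to the median pairwise-distance heuristic over the pooled sample.
Reference draws are taken per batch from the training RNG stream.

### Optimization

Adam (`learning_rate` = 3e-3, `batch_size` = 64 by default at desk scale)
with per-step timesteps drawn uniformly from `[1, T]`. Early stopping
monitors a validation objective computed with one fixed draw of
`(t, ε, reference)` so epochs are comparable, with `patience` = 50 epochs by
default; the best-validation parameters are restored. Training aborts with a
diagnostic on non-finite loss. All randomness flows from a single integer
seed; runs are bit-reproducible at a fixed seed in single-threaded mode.

### Architecture profiles

The networks are compact residual CNNs (stem conv + stride-2 residual
blocks, global average pooling, linear head). The `desk` profile — the
package default — uses widths (8, 16), embedding 32, a stem stride of 2 and
`T` = 100 diffusion steps so the full study runs on one CPU in minutes; the
`full` profile widens to (16, 32, 64), stem stride 1, and allows `T` = 1000.
`T` is not dictated by the method; 100 steps proved ample for a scalar
target at desk scale. Neural components are implemented directly on numpy
with a small reverse-mode autodiff core (`diffage.autograd`), which keeps
the package dependency-light and every numerical step inspectable.

## Preprocessing and slice selection

Volumes are resampled to 1 mm isotropic spacing (linear interpolation,
physical extent preserved within one voxel per axis). Intensity
normalization removes background by Otsu thresholding on a 256-bin
histogram, median-filters once with a 3×3×3 kernel, and divides by the
foreground maximum so intensities land on [0, 1] with background exactly 0.
The background mask and the scale are fixed points of this operation;
single-pass median filtering is not exactly idempotent, so a reapplication
may move a small fraction of boundary voxels (filtering to the median root
would cost dozens of passes and over-smooth, and was rejected).

Axial slices with at least `min_nonzero_fraction` = 0.01 non-zero voxels
(counted after background removal — the rule is applied downstream of
normalization, recorded in provenance) are valid; five equidistant
percentile slices (25, 37.5, 50, 62.5, 75) are selected by the nearest-rank
rule `valid[round(p/100 · (len-1))]` with ties rounding half up. The
percentile→index convention and the histogram/kernel sizes are
implementation choices the upstream method leaves open; they are frozen
here and covered by tests.

Rigid registration to an age-appropriate pediatric atlas, skull stripping
and N4 bias-field correction are external-tool boundaries: the pipeline
accepts volumes already processed by those tools and records in the
provenance log whether each ran.

## Ensembling

One model is trained per slice percentile. The consensus is either the
plain mean or the outlier-exclusion rule: compute the mean and sample
(n−1) standard deviation of the slice predictions, drop predictions whose
absolute deviation strictly exceeds one SD in a single pass, and average
the rest. With this convention at least one prediction always survives.
Sample SD, strict inequality and single-pass exclusion are frozen,
documented conventions; an iterated variant was considered and rejected as
unsupported by the rule's plain reading.

## Brain-age-gap statistics

* Gap = predicted − chronological age; accuracy is summarized as MAE with
  the [25th, 75th] percentiles of absolute error (linear-interpolation
  percentile convention).
* Outlier grouping: within each (integer-year age bin × sex) stratum,
  subjects more than one sample SD above/below the stratum mean prediction
  are "Older"/"Younger", otherwise "Average". Strata smaller than 3 records
  are labeled Average with a warning. Integer-year binning is a design
  choice; the stratification rule itself does not prescribe bins.
* Group comparisons: two-sided Mann-Whitney U tests per (measure, sex,
  group-pair) over the four volumetric measures (WMV, GMV, sGMV, VV), with
  Bonferroni adjustment computed as a formula —
  α / (measures × sexes × pairs) = 0.05/16 = 0.003125 for the default
  4×2×2 design — and Cohen's d with pooled sample SD. Both Older-vs-Average
  and Younger-vs-Average pairs are computed and reported.
* Longitudinal: per-interval rates Δvalue/Δage per subject; a subject's
  brain-age rate (mean of interval rates) is categorized
  Accelerated/Decelerated/Stable at ±1 cohort SD (multiplier
  config-exposed); volumetric rates are compared Stable-vs-Accelerated and
  Stable-vs-Decelerated at α / (4 measures × 2 pairs) = 0.00625 (≈ 0.006).
* Optional age-bias correction: a linear fit of gap on age over a held-out
  fit set, subtracted from predictions; off by default because bias
  correction did not help in this design and its value is contested in the
  field.

## Synthetic phantoms and cohorts

The image phantom encodes age geometrically in a nested-sphere head model
on a 32³ grid (1 mm spacing in the NIfTI header): a CSF-like core whose
radius grows linearly with age (2 + 0.15·(age−3) voxels), a white-matter
shell, and a cortical grey-matter band whose thickness shrinks linearly
(4 − 0.09·(age−3) voxels) inside a fixed outer radius of 13 voxels, with
T1w-like tissue intensities (CSF dark, WM bright) and additive Gaussian
noise (SD 0.02, clipped at 0). Linear radius/thickness maps keep the
analytic voxel-count oracle trivial; the fixed outer radius prevents overall
head size from leaking age. Cohort ages are uniform over the age range —
mirroring training-set stratification that flattens the age histogram — and
every generator derives one RNG stream from its seed.

The volumetric table generator emulates WMV/GMV/sGMV/VV columns with
developmental trends (GMV declining, VV growing over the simulated 5–25 y
range) and plants group shifts of `d · residual SD` so pairwise comparisons
recover specified Cohen's d values. The longitudinal generator produces
visits at a configurable interval (default 3 visits, 2 years apart, small
age jitter), subject-level random slopes for brain age (mean 1 y/y, SD 0.3)
and volumetrics, and small per-visit measurement noise (SD 0.2).

**Planted accelerated subgroups.** An accelerated subgroup whose slopes are
drawn with the same between-subject spread as the base population cannot be
recovered with high sensitivity under a mean ± 1 cohort-SD rule: even as the
planted fraction → 0, sensitivity for a +2 SD mean shift is bounded by
Φ(1) ≈ 0.84. The generator therefore models acceleration as a *common
process*: planted subjects share a slope shift of `shift_sd × σ_slope`
(default +2) with their residual slope spread shrunk to 0.25×σ_slope, and
their volumetric growth rates move in the accompanying directions (faster
ventricular growth; slower WMV/GMV/sGMV growth), mirrored for deceleration.
This makes the subgroup a recoverable, biologically coherent entity rather
than a statistical impossibility.

What the phantoms do *not* model: realistic MRI contrast, bias fields,
scanner or site effects, registration error, anatomical asymmetry, or
centile-based normalization of volumetrics. Passing tests on phantoms
demonstrate that the machinery — losses, guidance, sampling, ensembling,
statistics — behaves as specified and can recover a planted image→age
mapping; they say nothing about accuracy on real MRI.

## Problem sizes and numerical choices

The desk-scale study trains on 2000 phantom slices (200 validation, 200
held-out test) at 32×32 with `T` = 100 and `max_epochs` = 10 — sizes chosen
so the complete multi-seed study runs on a single CPU in minutes. Reverse
sampling averages `n_draws` = 8 chains. Evaluation compares against a
predict-the-training-mean baseline and checks slice-ensemble gains of the
outlier-exclusion consensus over single-slice models.

Degenerate inputs are handled explicitly: all-zero volumes pass through
normalization with a warning; empty valid-slice lists are rejected;
ensembles of fewer than two predictions fall back to the plain mean with a
warning; zero-SD prediction sets exclude nothing; strata or groups that are
empty are reported, not silently dropped; non-finite losses abort training.

## Known limitations

* The phantom image→age mapping is far easier than real brain MRI; desk
  accuracies do not transfer.
* The reverse sampler and the number of averaged chains are conventional
  choices; the method's source describes the training objective in detail
  but not the sampler.
* The MMD conditioning terms use the noise prediction `ε̂` under
  single-prior conditioning; which intermediate quantity enters each
  conditioned term is a config-level choice (`ε̂` by default).
* Registration, skull stripping and N4 correction are not reimplemented;
  real-data use assumes those ran upstream.
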