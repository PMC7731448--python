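# Methods

This note records the models, numerical choices and known limitations
behind `seedspec`, in the order the pipeline runs.

## Reflectance calibration

Raw detector counts are converted to relative reflectance per pixel and
band, `R = (S0 − Sb) / (Sw − Sb)`, where `Sw` is a white-standard frame and
`Sb` a lens-capped dark frame. References may be full cubes or anything
broadcastable to the cube. A position where `Sw = Sb` makes the correction
undefined and raises, naming the offending `(row, col, band)`. The
correction is invariant to a common positive gain applied to all three
inputs — tested as a property — so the absolute lamp level does not matter,
only its spatial/spectral shape.

## Segmentation

Segmentation runs on a single working band, by default the band nearest
640.08 nm, where seeds present a sharp outline against a light-absorbing
tray. Stages:

1. **Otsu binarization** (256-bin histogram over the image range, via
   scikit-image, cross-checked in the tests against an exhaustive search
   over all bin thresholds maximizing between-class variance). A constant
   image has no threshold and raises.
2. **Opening** with a disk structuring element (default radius 2 px), plus
   removal of residual components smaller than the element area. Each
   remaining connected component is one seed candidate.
3. **Rim removal** by erosion with a disk of `edge_erosion_px`
   (default 2 px): spherical seeds image with a dim rim whose pixels bias
   the mean spectrum downward.
4. **Hot-spot removal**: the specular bright core at each seed's center.
   The default rule is a second, per-seed Otsu pass
   (`hotspot_method="second_otsu"`, parameter-free); a per-seed quantile
   rule is the tunable fallback. A seed of (numerically) constant intensity
   has an empty hot spot, not an error.
5. **ROI**: `erode(opened) AND NOT hotspot`. Components retaining fewer
   than `min_roi_px` pixels (default 10) are dropped with a warning, since
   their means would be unstable.

**Ordering choice.** The per-seed hot-spot threshold is computed over the
*rim-eroded* component, not the raw opened component. A bright core is a
minority of a seed's pixels; if the dark rim is still present, a bimodal
threshold pass tends to separate rim from body instead and can classify the
whole body as "hot spot", emptying the ROI. Because the hot spot is a
subset of the eroded mask, which is a subset of the opened mask, the ROI
formula and the inclusion chain `roi ⊆ opened ⊆ binarized` are unchanged.
`extract_hotspot` itself accepts any mask, so callers can reproduce either
order.

Mean spectra are averaged per connected component of the ROI, components
numbered in deterministic raster-scan order. Components touching the image
border are kept by default (`keep_border=False` drops them).

## Band selection

The band-by-band Pearson correlation matrix (CCM) is computed across rows
of a spectra table (seed-level or pixel-level). Constant band columns are
detected exactly (zero peak-to-peak range) and rejected by name. Block
summaries average the diagonal sub-matrix including the diagonal.

For 462-band data the default partition is the four blocks
1–90 / 91–190 / 191–225 / 226–462 (1-based, inclusive). For any other band
count the caller must supply blocks: block boundaries come from inspection
of the CCM, and automatic changepoint detection is out of scope.

Equal-interval selection takes `m = min(k, block size)` bands per block at
the `m` evenly spaced positions from block start to block end inclusive
(`m = 1` takes the start). Positions are rounded half away from zero; a
rounding collision shifts to the nearest unused in-block index, ties toward
the lower index. This rule is deterministic and endpoint-preserving; with
the default blocks, requests of 10/20/30/40/50 per block give selections of
40/80/120/155/185 bands (the third block caps at 35).

## The RSLD classifier

The base learner is a linear discriminant with pooled within-class
covariance `Σ = Σ_c Σ_{i∈c}(x_i−μ_c)(x_i−μ_c)ᵀ / (n−C)` and score
`δ_c(x) = xᵀΣ⁻¹μ_c − ½μ_cᵀΣ⁻¹μ_c + log π_c`; priors are empirical class
frequencies. `Σ` is regularized as `Σ + λ·mean(diag Σ)·I` with default
`λ = 1e−4`, so that 30-feature learners stay positive-definite at ~33
training seeds per class; `λ = 0` is allowed and raises a clear error when
a class has fewer than two samples. Scores are evaluated through a single
Cholesky factorization and two triangular solves. Prediction takes the
argmax of `δ`; ties go to the earliest label in first-appearance order, and
posteriors are the softmax of `δ`.

The ensemble draws `k` subspaces of `m` features each, uniformly without
replacement within a learner and independently across learners (a subspace
may recur — the standard random-subspace formulation). Draws come from one
`numpy` PCG64 generator seeded by `rng_seed`, so models are byte-identical
across runs. The vote is the mode of the `k` learner labels; a tied vote is
resolved by the largest posterior sum over the tied labels, then by label
order — deterministic by construction. With one learner on all `d` features
the ensemble reduces exactly to plain LD (tested as an identity).

Defaults `m = 30`, `k = 25` are the operating point where cross-validated
error levels off for seed-variety spectra; both are exposed everywhere
(`--predictors`, `--learners`).

Models serialize to JSON with full float precision (subspace indices stored
as 1-based band numbers).

## Evaluation protocol

A stratified 2/3 train / 1/3 holdout split is drawn once per seed; the
holdout is touched once for final validation. Parameter tuning uses
repeated stratified 10-fold cross-validation on the training partition
only. If the smallest class cannot fill `k` folds the fold count is
downgraded with a warning. Error rate is the mismatch fraction
`E = (1/n) Σ 1[f(x_i) ≠ y_i]` and `A = 1 − E`.

The CV report's `mean_error` is the pooled mismatch fraction over every
prediction made — i.e. the fold-size-weighted mean of the per-fold error
rates, which equals the error recomputed from the confusion matrix exactly.
Per-fold rates are also reported; with stratified folds they differ in size
by at most one sample, so the unweighted mean is within rounding of the
pooled value.

## Phantom generator

The generator emulates the statistical structure the method relies on, with
one integer seed and fixed child-stream offsets so each stage can be tested
independently.

**Class curves.** Each variety's mean spectrum is a smooth curve: base
`0.14 + 0.36·logistic((λ−700)/60)` plus a Gaussian absorption valley at
650 nm (depth 0.08, width 30 nm), with class-specific offset (sd 0.012),
slope tweak (sd 0.012 over the NIR half) and valley-depth jitter (sd 10 %),
all scaled by a `separation` factor (default 1). Values are clipped into
(0, 0.6] with a warning. At separation 0 every class is identical, so
classification accuracy must fall to chance — tested. The curve anchors
keep seed bodies clearly brighter than the tray at the 640-nm working band;
without that floor a global Otsu threshold can split within the seed
population instead of seed-vs-background, which real acquisition setups
avoid by design (dark tray, adequate illumination).

**Noise.** Per-seed deviations are zero-mean Gaussian with marginal sd
`noise_sd` (default 0.01 reflectance units) and block-diagonal correlation:
within each band block every pair correlates at `ρ` (default 0.9,
implemented as `√ρ·shared + √(1−ρ)·independent`), across blocks the noise
is independent. This reproduces the bright diagonal CCM blocks that justify
block-stratified selection, and makes the full-band covariance estimation
problem genuinely hard — the regime where the single LD collapses and the
subspace ensemble does not.

**Scenes.** Seeds are ellipses (default axes 10 × 8 px) on a regular grid
over a dark tray (reflectance 0.02); the canvas is auto-sized so placement
cannot overlap. Each seed's pixels carry its spectrum exactly; a central
disk (radius 3 px) is brightened by `hotspot_boost` (default +40 %) and a
2-px rim ring dimmed by `rim_drop` (default −35 %). Raw counts follow
`DN = dark + R·(white − dark)` with a smooth spatial gain and a gentle lamp
spectrum in the white frame and a constant dark level; the model is
deterministic (no shot noise), so calibration recovers body reflectance to
float precision and the clean-scene end-to-end test can assert recovery to
1e−6. With contamination on, the only recovery error is rim/hot-spot
leakage into the ROI at discretized ellipse boundaries; the end-to-end test
bounds it exactly from the ground-truth masks
(`|mean − truth| ≤ (f_rim·rim_drop + f_hot·boost)·R_max` per band).

**What the phantom does not model** — and hence what passing tests do not
show about real data: touching or overlapping seeds, shape variation beyond
ellipses, specular structure beyond a uniform boost, illumination drift
between sample and reference scans, detector shot/readout noise, and
wavelength miscalibration. Accuracies on phantoms calibrate the machinery,
not field performance.

## Problem sizes

Tests and the acceptance script run phantoms at 15 varieties × 50 seeds
(spectra tables) and 15-seed rendered scenes, with 10 replicates for the
LD-vs-RSLD contrast — large enough for the covariance-collapse regime
(462 features vs ~480 training spectra) while keeping the whole suite in
seconds.

## Known limitations

- ENVI support covers the plain dialect (BIL/BIP/BSQ, uint16/float32/
  float64, header wavelength list); vendor-proprietary raw formats and
  larger-than-memory tiled reading are out of scope.
- No watershed splitting of touching seeds; a scene must present disjoint
  seeds.
- The linear SVM the method is usually compared against is not
  re-implemented; scikit-learn's implementation can serve as an external
  comparator.
- Block boundaries for band counts other than 462 must be supplied by the
  user.
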