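# Methods

## The prediction problem

A line-scan VNIR camera records a hyperspectral cube per fruit: 400 scan
lines × ~1160 cross-track pixels × 300 bands (400–1000 nm at 2 nm).  The
target is the fruit's soluble-solid content (SSC, °Brix) measured by
refractometry.  The modelling unit is one mean reflectance spectrum per fruit
orientation; two orientations per fruit are treated as independent samples
(they share the fruit's SSC reference but carry independent scatter and
noise).

## Reflectance calibration

Raw counts convert to relative reflectance per band via the white/dark
reference images, `R = (I_s − D) / (I_w − D)`.  Two numerical guards close
gaps the textbook formula leaves open:

- **Dead pixels.** Denominators with `|I_w − D| < ε` (default `ε = 1e-6` in
  white-normalized units) are replaced by `±ε` (sign preserved) so the output
  is always finite.
- **Specular glints.** Reflectance is clipped to `[0, clip_max]` with
  `clip_max = 2.0`: glints legitimately exceed 1, but unbounded values
  destabilize preprocessing.

References may be single `(pixel, band)` line frames, broadcast along the
scan axis (the line-scan convention and the default), or full cubes.
Reflectance cubes are stored as float32; raw cubes keep their recorded dtype
(12-bit cameras record into uint16).  The ENVI writer documents the
`(line, pixel, band)` 0-based axis convention; BIL is the default interleave.

## Segmentation

Fruit pixels are brighter than the dark stage throughout the NIR, so a single
threshold at one band separates them.  Defaults: band 800 nm, reflectance
threshold 0.2, both configurable.  The largest 4-connected component is kept
(speckle cleanup) and must contain at least `min_pixels = 50` pixels.  The ROI
is the whole segmented fruit; the mean over its pixels is the sample spectrum.

## Preprocessing

Seven standard transforms, all length- and order-preserving, applied row-wise:
moving average, Savitzky–Golay first derivative, maximum/mean/range
normalization, SNV, MSC.  Choices worth stating:

- **Window widths in nm.** The 6 nm default is interpreted as a *half-width*:
  on a 2 nm grid, center ± 3 bands = a 7-point window (an odd window is
  required).  A total-width reading (3 points) is also supported via
  `window_interpretation="full_width"`; neither reading is asserted as
  uniquely correct.
- **SG derivative**: polynomial order 2, output divided by the grid step so
  units are reflectance per nm (resolution-independent); edges use the
  polynomial fit of the edge window.
- **SNV** uses the sample (n−1) standard deviation — the chemometrics
  convention, and it makes the `[1,2,3] → [−1,0,1]` case exact.
- **MSC** regresses each spectrum on a reference (ordinary least squares,
  `x ≈ a + b·ref`, corrected spectrum `(x − a)/b`).  The reference is the
  calibration-set mean, frozen at fit time and reused for prediction rows —
  the only stateful transform, and the one place leakage is possible, hence
  the explicit fit/transform split.

## PLSR

Single-response NIPALS on mean-centered data; for one response the algorithm
needs no inner iteration (`w_k = X_kᵀy` normalized, `t_k = X_k w_k`, deflate
X only).  Factor extraction halts early if the X residual norm falls below
1e-12.  The factorization is collapsed to regression coefficients
`b_K = W_K (P_KᵀW_K)^{-1} q_{1:K}` for *every* K in one pass, so
cross-validation over factor counts costs one fit per fold — this is why the
NIPALS core is implemented here rather than delegated (scikit-learn's PLS
refits per component count; it serves as an independent cross-check in the
tests instead).

Model selection: leave-one-out CV over factor counts 1..20, optimum at the
RMSECV minimum, ties toward fewer factors.  The cross-validation metrics
(R²_v, RMSEV) are the LOOCV values at the optimal count — no third held-out
subset exists, only calibration and prediction sets.  R² is defined as
`1 − SSres/SStot` about the evaluated set's own mean (not squared
correlation), which makes `RMSE² = (1 − R²)·var(y)` an exact invariant.
The 7:3 split rounds the calibration share half away from zero
(648 → 454/194, 631 → 442/189).  Orientation pairs may split across sets by
default; `group_by_fruit=True` gives the leakage-safe grouped split.

## CARS

Per iteration *i* of *N* = 100: fit PLS on a random 80% of calibration
samples restricted to currently retained bands (the 80% fraction is the
conventional choice in this algorithm family; the factor count for this fit
is chosen by the internal CV, capped at `min(10, bands − 1)` since subsets
shrink below the global cap); enforce the exponentially decreasing schedule
`r_i = a·e^{−k·i}` with boundary conditions `r_1 = 1` and `r_N = 2/p` by
keeping the `round(r_i·p)` largest-|coefficient| bands; then adaptive
reweighted sampling — draw `round(r_i·p)` bands with replacement with
probability ∝ |coefficient| and deduplicate, so the realized subset size is
at most the schedule target.  Each subset is scored by 5-fold CV RMSECV on
the full calibration set (LOOCV × 100 iterations would be needlessly slow;
the final downstream model re-runs LOOCV).  The argmin-RMSECV subset wins;
ties break to the earliest (larger, safer) subset, configurable to fewest
bands.  All-zero coefficient vectors fall back to uniform weights with a
warning; a subset collapsing below 2 bands truncates the schedule and is
recorded.

**Null behavior.** The package's fabrication check is out-of-sample: on
pure-noise y, a CARS-selected PLSR model must have no held-out predictive
power (median R²_p ≈ 0 across seeds).  Comparing the RMSECV-curve minimum to
the full-band RMSECV is *not* used as the null check: the curve minimum is
biased low by selection (a minimum over ~100 noisy evaluations) while the
full-band model is inflated by fitting p > n noise, so that comparison shows
a spurious "improvement" on data with no signal at all.

## Monte Carlo outlier screening

500 random 75/25 train/test splits; PLSR with a factor count fixed *once* by
LOOCV on the full table before screening (re-selecting factors inside each
run would confound the error distributions); per sample, the mean and sd of
its absolute test-set prediction errors.  Cutoffs are `mean + 2.5·sd` of each
statistic's population; a sample is flagged if it exceeds *either* (high bias
or high instability both disqualify).  Runs extend automatically until every
sample has been tested ≥ 20 times.  Cutoffs are floored at 1e-8 °Brix so that
numerically-zero error distributions (exact models on noise-free data) flag
nothing.  Screening runs on the full preprocessed table *before* the 7:3
split, and before CARS.

In the orchestrated pipeline, MSC needs calibration rows that only exist
after the split, while screening precedes the split; the pipeline therefore
screens on a preprocessor fitted to the full table, then re-fits
preprocessing on calibration rows only and freezes it for prediction rows.
Everything downstream of the split — MSC reference, CARS subset, factor
count — derives from calibration data alone (tested by perturbing prediction
rows and asserting the fitted model is unchanged).  Outlier screening is
re-run per preprocessing variant, since each operates on its own transformed
spectra.

## The synthetic generator

The generator defines the study conditions; its defaults are fixed, not
tuning knobs.

- **Layout**: 324 fruits × 2 orientations = 648 spectra on the 300-band grid.
- **SSC population**: truncated normal, mean 9.85, sd 1.08, range
  7.40–12.50 °Brix, drawn by rejection sampling, one value per fruit.
- **Spectrum**: a logistic baseline (≈0.15 at 400 nm rising to ≈0.73 near the
  750 nm chlorophyll edge, then a gentle NIR decline) minus Gaussian
  absorption dips at 470/640/680/880/912/960 nm.  Dip depth responds linearly
  to SSC (small-absorbance Beer–Lambert rationale), with the response
  concentrated in the 880–1000 nm carbohydrate-overtone region (the dominant
  term: +0.014 reflectance per °Brix at 960 nm); the 912 nm local maximum
  sharpens with SSC.
- **Scatter**: per-sample multiplicative gain (sd 0.05), additive offset
  (sd 0.01), and smooth wavelength-dependent scatter — random Legendre
  components of degree 1–3 (sd 0.010/0.006/0.004 reflectance) — standing in
  for peel-thickness and illumination-geometry effects that tilt and bend a
  spectrum rather than merely scaling it.  The smooth components matter: with
  purely iid band noise, every band carries irreducible information and no
  wavelength-selection method could shrink the band set without losing
  accuracy; real reflectance spectra are dominated by exactly this kind of
  smooth, low-rank sample-to-sample variation, which is why CARS works on
  them.
- **Noise and its floor**: iid per-band Gaussian noise.  Because the only SSC
  information is the gradient `g = dR/dSSC`, per-band noise sd σ implies an
  optimal-linear-estimator floor of `σ / ||g⊥||` °Brix, where `g⊥` projects g
  orthogonal to the scatter nuisance directions.  The default template is
  parameterized by that floor — 0.5 °Brix, the error scale relevant to
  field-grade SSC sorting — giving σ ≈ 0.019.  Observed prediction RMSEs can
  sit slightly *below* the floor (≈0.43–0.50): the floor bounds unbiased
  estimators, and PLSR's shrinkage toward the mean trades bias for variance.
- **Outliers**: planted by shifting a sample's SSC *reference* by ±5 error
  floors (±2.5 °Brix) — a reference/spectrum mismatch, the signature Monte
  Carlo screening targets.  17 of 648 by default.
- **Cubes**: a centered disk of template reflectance (plus per-pixel noise)
  on a 0.05-reflectance background, inverted through the calibration equation
  into raw counts with consistent white/dark line frames.  Raw values are
  float32 by default so the noise-free pipeline identity (calibrate → segment
  → extract reproduces the template to ≤ 1e-6) holds exactly; 12-bit
  quantization is available (`quantize_12bit=True`) but adds ~1e-4
  quantization error.
- **Seeding**: all randomness flows from one seed — fruit SSC draws first,
  then per-spectrum gain, offset, smooth scatter and noise in fruit-major
  order — so every run is exactly reproducible.

**What the generator does not emulate**, and hence what passing tests do not
show about real fruit: radiative-transfer and peel-thickness physics,
orientation-dependent spectral differences (orientations are replicate
scatter here), nonlinear SSC–absorbance response, harvest-stage structure
beyond the pooled SSC distribution, and instrument artifacts (smile, keystone,
stray light).  Synthetic results demonstrate that the *pipeline* recovers
known signal under realistic statistical structure, not that a given R² is
attainable on any particular orchard's fruit.

## Problem sizes and runtime choices

The test suite runs the full study layout (648 × 300) for acceptance checks
and a coarser 120 × 100 layout for pipeline-orchestration tests; CARS
planted-signal checks use 100 × 120 instances over 10 seeds, outlier-recall
checks 5 seeds at full size.  The model-comparison analysis script runs the
complete 32-cell grid (minutes); the acceptance script runs one seeded pass
of every stage (~1 minute).

## Known limitations

- PLS1 only; multi-response PLS2, kernel or interval PLS are out of scope.
- Segmentation handles one fruit per scene; no touching-fruit separation or
  calyx landmark detection.
- The CARS subset-size trajectory, like the original algorithm's, is
  stochastic: individual seeds occasionally keep >100 bands when the RMSECV
  curve is flat; medians across seeds are the stable quantity.
- `compare_models` ranks by cross-validated R² (ties by RMSEV); with very few
  prediction samples the prediction-set metrics are noisy and should be read
  with their n in hand.
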