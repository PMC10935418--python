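# citrus-ssc

Predicting the soluble-solid content (SSC, in °Brix — the standard
dissolved-sugar proxy for fruit sweetness) of citrus fruit from
visible–near-infrared (VNIR, 400–1000 nm) hyperspectral reflectance images,
for chemometrics practitioners and post-harvest sorting applications.

The package implements the full workflow as a tested library plus a set of
numbered analysis drivers:

1. **Reflectance calibration** of raw line-scan cubes against white/dark
   references, `R_i = (I_s,i − D_i) / (I_w,i − D_i)` per band *i*, with
   ENVI-style I/O (`hypercube`).
2. **Fruit segmentation and ROI extraction** — threshold one NIR band, keep
   the largest connected component, average all fruit pixels into one
   spectrum per sample (`segmentation`).
3. **Spectral preprocessing** — moving average, Savitzky–Golay first
   derivative, max/mean/range normalization, SNV, MSC (`preprocessing`).
4. **Effective-wavelength selection** by competitive adaptive reweighted
   sampling, CARS: *N* = 100 Monte Carlo iterations, each fitting a PLS model
   on a random 80% of calibration samples, keeping the `round(r_i · p)` bands
   with the largest absolute regression coefficients under the exponentially
   decreasing schedule `r_i = a·e^(−k·i)` (with `r_1 = 1`, `r_N = 2/p`),
   resampling bands with probability ∝ |coefficient|, and scoring each subset
   by RMSECV; the lowest-RMSECV subset wins (`cars`).
5. **Monte Carlo outlier screening** — repeated random train/test PLS fits;
   samples whose prediction-error mean or spread exceeds the population
   mean + 2.5 sd are removed (`outliers`).
6. **PLSR** (single-response NIPALS) with the bilinear model
   `X = T Pᵀ + E`, `Y = U Qᵀ + F`, `U = T B + H`, leave-one-out
   cross-validated choice of the factor count (cap 20), a random 7:3
   calibration/prediction split, and R²/RMSE reporting (`plsr`).
7. **Pipeline orchestration** of the four model variants — PLSR and
   CARS-PLSR, each with and without outlier removal — crossed with all
   preprocessing methods (`pipeline`).

Because no raw fruit data are distributed, the `synthetic` module generates
citrus-like spectra with known ground truth: a smooth reflectance baseline
with absorption dips near 470/640/680/880 nm, a local maximum near 912 nm,
and an SSC-linked O–H overtone absorption near 960 nm; SSC drawn from a
truncated normal (7.40–12.50, mean 9.85, sd 1.08 °Brix); per-sample
gain/offset and smooth wavelength-dependent scatter; per-band noise
calibrated to a chosen °Brix error floor; and optional planted outliers.
Every stage of the pipeline is therefore verifiable against analytic truth.

## Worked example

```python
import citrus_ssc as cs

# 648 spectra from 324 synthetic fruits, two orientations each,
# with 17 planted reference outliers
clean = cs.generate_spectra_dataset(324, seed=20240226)
table, planted = cs.inject_outliers(clean, 17, seed=20240227)

report = cs.mc_outlier_detect(table, seed=1)          # Monte Carlo screening
cal, pred = cs.split_dataset(clean, 0.7, seed=2)      # 7:3 split -> 454/194
cv = cs.cross_validate(cal, max_factors=20, scheme="loo")
model = cs.fit(cal, cv.optimal_factors)
print(cs.evaluate(pred.y, model.predict(pred.X)))
```

Or run the analysis scripts from the repository root:

```
$ python analysis/01_simulate_dataset.py
Generated 648 spectra (300 bands) from 324 fruits; SSC 7.47-12.24 °Brix
(mean 9.84, sd 1.03); 17 planted outliers.
Per-band noise sd 0.0189 -> 0.50 °Brix optimal-estimator floor.

$ python analysis/03_screen_outliers.py
Screened 648 spectra over 500 Monte Carlo runs (4 PLS factors, cutoffs
mean>1.528 or sd>0.113 °Brix).
Flagged 20: recalled 17/17 planted outliers, 3 false flags (0.48% of clean
samples).
```

The first number block says the generator hit the intended population
(SSC mean ≈ 9.85 °Brix) and that per-band noise was calibrated so no
predictor can beat a 0.50 °Brix error floor; the second says the screening
found all 17 samples whose SSC reference no longer matches their spectrum
while wrongly flagging under 0.5% of clean samples.  Steps 02, 04 and 05
exercise cube calibration/extraction, CARS selection (tens of bands,
concentrated in the 850–1000 nm sugar-overtone region), and the 32-cell
model-comparison grid written to `results/model_comparison.csv`.

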