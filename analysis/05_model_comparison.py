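"""The full model-comparison grid: 4 variants x 8 preprocessing methods.

Crosses PLSR and CARS-PLSR with and without Monte Carlo outlier removal over
every preprocessing method, on the contaminated dataset of step 01, and ranks
the 32 cells by cross-validated R².  This is the pipeline's headline table;
expect several minutes of runtime.

Run from the repository root:  python analysis/05_model_comparison.py
"""

import time
from pathlib import Path

import citrus_ssc as cs

SEED = 20240226

results = Path("results")
results.mkdir(exist_ok=True)

clean = cs.generate_spectra_dataset(324, seed=SEED)
table, _ = cs.inject_outliers(clean, 17, seed=SEED + 1)

# per-cell artifacts (models, coefficients, scatter data) are bulky -> scratch/
config = cs.PipelineConfig(seed=SEED + 5, output_dir="scratch/model_grid")

t0 = time.time()
report, _ = cs.run_pipeline(table, config)
ranked = cs.compare_models(report)
ranked.to_csv(results / "model_comparison.csv", index=False)

best = ranked.iloc[0]
print(f"Ran {len(report)} model cells in {time.time() - t0:.0f} s.")
print(ranked[["model", "preprocessing", "R2_v", "RMSEV", "R2_p", "RMSEP",
              "optimal_factors", "n_bands"]].head(8).to_string(index=False))
print(f"\nOptimal: {best['model']} with {best['preprocessing']} preprocessing "
      f"(R2_v {best['R2_v']:.3f}, RMSEV {best['RMSEV']:.3f} °Brix, "
      f"R2_p {best['R2_p']:.3f}, RMSEP {best['RMSEP']:.3f} °Brix, "
      f"{int(best['n_bands'])} bands, {int(best['optimal_factors'])} factors).")
print("Full ranking: results/model_comparison.csv; artifacts: scratch/model_grid/")
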