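"""Generate the synthetic citrus study dataset and summarize it.

Emulates the study layout — 324 fruits, two orientations each (648 spectra),
300-band VNIR grid, truncated-normal SSC population — plus 17 planted
reference outliers.  Full spectra go to scratch/ (they are large); the summary
table the later steps rely on goes to results/.

Run from the repository root:  python analysis/01_simulate_dataset.py
"""

from pathlib import Path

import numpy as np
import pandas as pd

import citrus_ssc as cs

SEED = 20240226

results = Path("results")
scratch = Path("scratch")
results.mkdir(exist_ok=True)
scratch.mkdir(exist_ok=True)

template = cs.default_template()
clean = cs.generate_spectra_dataset(324, template=template, seed=SEED)
table, planted = cs.inject_outliers(clean, 17, seed=SEED + 1)

table.to_csv(scratch / "synthetic_spectra.csv")
pd.DataFrame(
    {
        "sample_id": table.sample_ids,
        "fruit_id": table.fruit_ids,
        "orientation": table.orientation,
        "ssc_brix": table.y,
        "planted_outlier": np.isin(np.arange(table.n_samples), planted),
    }
).to_csv(results / "sample_truth.csv", index=False)

fruit_ssc = clean.y[::2]
summary = pd.DataFrame(
    [
        {
            "n_fruits": 324,
            "n_spectra": table.n_samples,
            "n_bands": table.n_bands,
            "ssc_min": fruit_ssc.min().round(2),
            "ssc_max": fruit_ssc.max().round(2),
            "ssc_mean": fruit_ssc.mean().round(2),
            "ssc_sd": fruit_ssc.std(ddof=1).round(2),
            "planted_outliers": len(planted),
            "noise_floor_brix": round(template.noise_floor_brix(), 3),
            "seed": SEED,
        }
    ]
)
summary.to_csv(results / "dataset_summary.csv", index=False)

print(
    f"Generated {table.n_samples} spectra ({table.n_bands} bands) from 324 fruits; "
    f"SSC {fruit_ssc.min():.2f}-{fruit_ssc.max():.2f} °Brix "
    f"(mean {fruit_ssc.mean():.2f}, sd {fruit_ssc.std(ddof=1):.2f}); "
    f"{len(planted)} planted outliers."
)
print(f"Per-band noise sd {template.noise_sd:.4f} -> "
      f"{template.noise_floor_brix():.2f} °Brix optimal-estimator floor.")
print("Full spectra: scratch/synthetic_spectra.csv; truth: results/sample_truth.csv")
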