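"""Monte Carlo outlier screening of calibration spectra.

Repeated random train/test PLS fits give each sample a distribution of
absolute prediction errors.  Samples whose mean error or error spread sits
far above the population (beyond mean + k_sigma * sd of the respective
statistic) are flagged: a high mean catches reference/spectrum mismatches,
a high spread catches unstable, split-sensitive spectra.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .plsr import MAX_FACTORS_DEFAULT, SpectraTable, cross_validate, fit_xy

__all__ = ["OutlierReport", "mc_outlier_detect"]

# errors at machine-noise scale are treated as zero so exact models flag nothing
_CUTOFF_FLOOR = 1e-8


@dataclass
class OutlierReport:
    """Per-sample Monte Carlo prediction-error summary and outlier flags."""

    mean_error: np.ndarray
    sd_error: np.ndarray
    times_in_test: np.ndarray
    mean_cutoff: float
    sd_cutoff: float
    flags: np.ndarray
    n_runs: int
    train_fraction: float
    k_sigma: float
    factor_count: int
    seed: int | None

    @property
    def n_flagged(self) -> int:
        return int(self.flags.sum())

    def flagged_indices(self) -> np.ndarray:
        return np.flatnonzero(self.flags)


def mc_outlier_detect(
    table: SpectraTable,
    n_runs: int = 500,
    train_fraction: float = 0.75,
    k_sigma: float = 2.5,
    factor_count: int | None = None,
    seed: int | None = None,
    min_test_appearances: int = 20,
) -> OutlierReport:
    """Flag outlier samples from the distribution of Monte Carlo prediction errors.

    Each run splits the table at ``train_fraction``, fits PLSR with
    ``factor_count`` factors on the training part, and records the absolute
    prediction error of every test sample.  When ``factor_count`` is None it
    is fixed once, before any screening, by LOOCV on the full table (cap 20);
    re-selecting factors inside each run would confound the error
    distributions.  Runs are extended in blocks until every sample has been
    tested at least ``min_test_appearances`` times.
    """
    n = table.n_samples
    if n < 20:
        raise ValueError("Monte Carlo outlier detection needs at least 20 samples")
    if not 0.5 <= train_fraction < 1.0:
        raise ValueError("train_fraction must be in [0.5, 1)")
    if np.ptp(table.y) == 0:
        raise ValueError("y is constant; prediction errors are meaningless")

    if factor_count is None:
        cv = cross_validate(table, max_factors=MAX_FACTORS_DEFAULT, scheme="loo")
        factor_count = cv.optimal_factors

    rng = np.random.default_rng(seed)
    n_train = max(2, int(round(train_fraction * n)))

    err_sum = np.zeros(n)
    err_sumsq = np.zeros(n)
    counts = np.zeros(n, dtype=int)

    total_runs = 0

    def _do_runs(k: int) -> None:
        nonlocal total_runs
        for _ in range(k):
            perm = rng.permutation(n)
            train, test = perm[:n_train], perm[n_train:]
            model = fit_xy(table.X[train], table.y[train], factor_count)
            pred = model.predict(table.X[test])
            err = np.abs(pred - table.y[test])
            np.add.at(err_sum, test, err)
            np.add.at(err_sumsq, test, err**2)
            np.add.at(counts, test, 1)
        total_runs += k

    _do_runs(n_runs)
    while counts.min() < max(min_test_appearances, 2):
        _do_runs(max(50, n_runs // 10))

    mean_err = err_sum / counts
    var = (err_sumsq - counts * mean_err**2) / (counts - 1)
    sd_err = np.sqrt(np.maximum(var, 0.0))

    mean_cutoff = max(float(mean_err.mean() + k_sigma * mean_err.std(ddof=1)), _CUTOFF_FLOOR)
    sd_cutoff = max(float(sd_err.mean() + k_sigma * sd_err.std(ddof=1)), _CUTOFF_FLOOR)
    flags = (mean_err > mean_cutoff) | (sd_err > sd_cutoff)

    return OutlierReport(
        mean_error=mean_err,
        sd_error=sd_err,
        times_in_test=counts,
        mean_cutoff=mean_cutoff,
        sd_cutoff=sd_cutoff,
        flags=flags,
        n_runs=total_runs,
        train_fraction=train_fraction,
        k_sigma=k_sigma,
        factor_count=factor_count,
        seed=seed,
    )
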