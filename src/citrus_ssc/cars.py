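"""Competitive adaptive reweighted sampling (CARS) for wavelength selection.

CARS runs N Monte Carlo iterations.  Each iteration (1) fits a PLS model on a
random subset of calibration samples restricted to the currently retained
bands, (2) applies enforced selection — only the round(r_i * p) bands with the
largest absolute collapsed regression coefficients survive, where the
retention ratio r_i follows an exponentially decreasing function with
boundary conditions r_1 = 1 (all p bands) and r_N = 2/p (two bands) — and
(3) applies adaptive reweighted sampling: bands are drawn with replacement
with probability proportional to |coefficient| and the unique draws form the
next retained set.  Each retained set is scored by cross-validated RMSECV on
the full calibration set; the subset with the lowest RMSECV wins.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .plsr import SpectraTable, cross_validate, fit_xy

__all__ = ["CARSResult", "edf_ratio", "cars_select"]


def edf_ratio(iteration: int, n_iterations: int, n_bands: int) -> float:
    """Retention ratio r_i = a * exp(-k*i) of the exponentially decreasing
    function, with a and k solved from r_1 = 1 and r_N = 2/p.
    """
    if n_bands < 3:
        raise ValueError("EDF schedule degenerate for fewer than 3 bands")
    if n_iterations < 2:
        raise ValueError("need at least 2 iterations")
    if not 1 <= iteration <= n_iterations:
        raise ValueError(f"iteration {iteration} outside 1..{n_iterations}")
    denom = n_iterations - 1
    a = (n_bands / 2.0) ** (1.0 / denom)
    k = math.log(n_bands / 2.0) / denom
    return a * math.exp(-k * iteration)


@dataclass
class CARSResult:
    """Full CARS trajectory plus the winning band subset."""

    n_iterations: int
    retained_sets: list[np.ndarray]
    rmsecv_curve: np.ndarray
    ratio_curve: np.ndarray
    n_factors_curve: np.ndarray
    selected_iteration: int            # 0-based index into the trajectory
    selected_bands: np.ndarray         # band indices into the input table
    selected_centers_nm: np.ndarray
    seed: int | None
    truncated: bool = False

    @property
    def n_selected(self) -> int:
        return self.selected_bands.size


def _rmsecv_of_subset(
    table: SpectraTable,
    bands: np.ndarray,
    cv_scheme: str,
    cv_folds: int,
    max_factors: int,
    seed: int,
) -> tuple[float, int]:
    cv = cross_validate(
        (table.X[:, bands], table.y),
        max_factors=min(max_factors, bands.size, table.n_samples - 2),
        scheme=cv_scheme,
        k=cv_folds,
        seed=seed,
    )
    return float(cv.rmsecv[cv.optimal_factors - 1]), cv.optimal_factors


def cars_select(
    calibration: SpectraTable,
    n_iterations: int = 100,
    mc_fraction: float = 0.8,
    cv_scheme: str = "kfold",
    cv_folds: int = 5,
    max_factors: int = 10,
    seed: int | None = None,
    tie_break: str = "first",
) -> CARSResult:
    """Select effective wavelengths by CARS (default 100 Monte Carlo runs).

    Per iteration, a PLS model on ``mc_fraction`` of the calibration samples
    supplies the |coefficient| weights; its factor count is chosen by the same
    internal cross-validation, capped at ``min(max_factors, bands - 1)``.
    RMSECV scoring of each retained set uses 5-fold CV by default (the final
    downstream model re-runs LOOCV).  Fully seed-reproducible.

    ``tie_break``: with equal RMSECV, "first" keeps the earliest (larger,
    safer) subset; "fewest_bands" prefers the smaller subset.
    """
    n, p = calibration.n_samples, calibration.n_bands
    if n < 10:
        raise ValueError("CARS needs at least 10 calibration samples")
    if p < 3:
        raise ValueError("CARS needs at least 3 bands")
    if not 0.0 < mc_fraction <= 1.0:
        raise ValueError("mc_fraction must be in (0, 1]")
    if tie_break not in ("first", "fewest_bands"):
        raise ValueError(f"unknown tie_break {tie_break!r}")

    rng = np.random.default_rng(seed)
    n_sub = max(2, int(round(mc_fraction * n)))

    retained = np.arange(p)
    retained_sets: list[np.ndarray] = []
    rmsecv_curve: list[float] = []
    ratio_curve: list[float] = []
    nf_curve: list[int] = []
    truncated = False

    for i in range(1, n_iterations + 1):
        if retained.size < 2:
            truncated = True
            break
        r_i = edf_ratio(i, n_iterations, p)
        target = max(2, int(round(r_i * p)))

        rows = rng.choice(n, size=n_sub, replace=False)
        Xi = calibration.X[np.ix_(rows, retained)]
        yi = calibration.y[rows]
        # factor count for the weighting fit chosen by the internal CV on the
        # subsample (capped at min(max_factors, bands-1)); a fixed large count
        # would overfit shrinking subsets and blur the coefficient weights
        nf_cap = max(1, min(max_factors, retained.size - 1, n_sub - 2))
        cv_w = cross_validate(
            (Xi, yi), max_factors=nf_cap, scheme=cv_scheme, k=cv_folds,
            seed=int(rng.integers(2**31 - 1)),
        )
        model = fit_xy(Xi, yi, cv_w.optimal_factors)
        coefs = np.abs(model.coef)

        # (2) enforced selection: top |b| bands survive, count per the EDF
        if target < retained.size:
            order = np.argsort(coefs)[::-1]
            keep_local = np.sort(order[:target])
        else:
            keep_local = np.arange(retained.size)
        kept = retained[keep_local]
        kept_w = coefs[keep_local]

        # (3) adaptive reweighted sampling: weighted draw with replacement,
        # deduplicated, so realized size <= the EDF target
        wsum = kept_w.sum()
        if wsum <= 0:
            warnings.warn(
                "all-zero regression coefficients; falling back to uniform weights",
                stacklevel=2,
            )
            probs = np.full(kept.size, 1.0 / kept.size)
        else:
            probs = kept_w / wsum
        draws = rng.choice(kept, size=target, replace=True, p=probs)
        retained = np.unique(draws)
        if retained.size < 2:
            truncated = True
            break

        # (4) score the retained subset on the full calibration set
        rmsecv, nf_opt = _rmsecv_of_subset(
            calibration, retained, cv_scheme, cv_folds, max_factors,
            seed=int(rng.integers(2**31 - 1)),
        )
        retained_sets.append(retained.copy())
        rmsecv_curve.append(rmsecv)
        ratio_curve.append(r_i)
        nf_curve.append(nf_opt)

    if not rmsecv_curve:
        raise RuntimeError("CARS produced no scored subsets (collapsed immediately)")

    rmsecv_arr = np.array(rmsecv_curve)
    if tie_break == "first":
        best = int(np.argmin(rmsecv_arr))
    else:
        m = rmsecv_arr.min()
        candidates = np.flatnonzero(rmsecv_arr == m)
        sizes = np.array([retained_sets[c].size for c in candidates])
        best = int(candidates[np.argmin(sizes)])

    selected = retained_sets[best]
    return CARSResult(
        n_iterations=n_iterations,
        retained_sets=retained_sets,
        rmsecv_curve=rmsecv_arr,
        ratio_curve=np.array(ratio_curve),
        n_factors_curve=np.array(nf_curve),
        selected_iteration=best,
        selected_bands=selected,
        selected_centers_nm=calibration.band_centers[selected],
        seed=seed,
        truncated=truncated,
    )
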