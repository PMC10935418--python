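"""Partial least-squares regression (PLS1) with cross-validated factor choice.

The model is the standard bilinear factorization

    X = T P' + E ,   Y = U Q' + F ,   U = T B + H

fitted by NIPALS on mean-centered data.  For a single response the algorithm
simplifies: each weight vector is w_k = X_k' y (normalized), scores t_k = X_k
w_k, and only X is deflated.  Successive score vectors are mutually
orthogonal, and the factorization collapses to a single coefficient vector in
the original band space, b_K = W_K (P_K' W_K)^{-1} q_{1:K}, computed here for
every factor count 1..K in one pass so that cross-validation over factor
counts costs one fit per fold.

Model selection follows the chemometrics convention: leave-one-out
cross-validation over factor counts capped at 20, optimal count at the RMSECV
minimum (ties toward fewer factors).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpectraTable",
    "PLSRModel",
    "CVResult",
    "Metrics",
    "EvaluationReport",
    "split_dataset",
    "fit",
    "fit_xy",
    "predict",
    "cross_validate",
    "evaluate",
    "MAX_FACTORS_DEFAULT",
]

MAX_FACTORS_DEFAULT = 20  # latent-variable cap used throughout


# ---------------------------------------------------------------------------
# Data container
# ---------------------------------------------------------------------------


@dataclass
class SpectraTable:
    """Per-sample mean spectra with SSC references.

    X holds one spectrum per row (possibly preprocessed or band-subset);
    y holds SSC in °Brix.  ``band_centers`` names the columns in nm.
    """

    X: np.ndarray
    y: np.ndarray
    band_centers: np.ndarray
    sample_ids: np.ndarray | None = None
    orientation: np.ndarray | None = None
    fruit_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.band_centers = np.asarray(self.band_centers, dtype=float).ravel()
        if self.X.shape[0] != self.y.size:
            raise ValueError(f"X has {self.X.shape[0]} rows but y has {self.y.size}")
        if self.X.shape[1] != self.band_centers.size:
            raise ValueError(
                f"X has {self.X.shape[1]} columns but {self.band_centers.size} band centers"
            )
        if not np.all(np.isfinite(self.X)) or not np.all(np.isfinite(self.y)):
            raise ValueError("SpectraTable contains non-finite values")
        n = self.y.size
        if self.sample_ids is None:
            self.sample_ids = np.array([f"S{i:04d}" for i in range(n)])
        else:
            self.sample_ids = np.asarray(self.sample_ids)
        if self.orientation is not None:
            self.orientation = np.asarray(self.orientation)
        if self.fruit_ids is not None:
            self.fruit_ids = np.asarray(self.fruit_ids)

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_bands(self) -> int:
        return self.X.shape[1]

    def take_rows(self, idx) -> "SpectraTable":
        idx = np.asarray(idx)
        return SpectraTable(
            self.X[idx],
            self.y[idx],
            self.band_centers,
            self.sample_ids[idx],
            None if self.orientation is None else self.orientation[idx],
            None if self.fruit_ids is None else self.fruit_ids[idx],
        )

    def take_bands(self, idx) -> "SpectraTable":
        idx = np.asarray(idx)
        return SpectraTable(
            self.X[:, idx],
            self.y,
            self.band_centers[idx],
            self.sample_ids,
            self.orientation,
            self.fruit_ids,
        )

    def with_X(self, X: np.ndarray, band_centers: np.ndarray | None = None) -> "SpectraTable":
        return SpectraTable(
            X,
            self.y,
            self.band_centers if band_centers is None else band_centers,
            self.sample_ids,
            self.orientation,
            self.fruit_ids,
        )

    def to_dataframe(self) -> pd.DataFrame:
        cols = {f"R_{c:g}": self.X[:, j] for j, c in enumerate(self.band_centers)}
        df = pd.DataFrame(
            {"sample_id": self.sample_ids, "ssc_brix": self.y, **cols}
        )
        if self.orientation is not None:
            df.insert(1, "orientation", self.orientation)
        if self.fruit_ids is not None:
            df.insert(1, "fruit_id", self.fruit_ids)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SpectraTable":
        band_cols = [c for c in df.columns if c.startswith("R_")]
        centers = np.array([float(c[2:]) for c in band_cols])
        return cls(
            df[band_cols].to_numpy(float),
            df["ssc_brix"].to_numpy(float),
            centers,
            df["sample_id"].to_numpy() if "sample_id" in df else None,
            df["orientation"].to_numpy() if "orientation" in df else None,
            df["fruit_id"].to_numpy() if "fruit_id" in df else None,
        )

    @classmethod
    def from_csv(cls, path) -> "SpectraTable":
        return cls.from_dataframe(pd.read_csv(path))


# ---------------------------------------------------------------------------
# Dataset split
# ---------------------------------------------------------------------------


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def split_dataset(
    table: SpectraTable,
    calibration_fraction: float = 0.7,
    seed: int | None = None,
    group_by_fruit: bool = False,
) -> tuple[SpectraTable, SpectraTable]:
    """Random disjoint calibration/prediction partition (default 7:3).

    The calibration size is round(fraction * n), rounding half away from zero,
    which reproduces 454/194 for n=648 and 442/189 for n=631.  With
    ``group_by_fruit`` the two orientation spectra of each fruit stay on the
    same side of the split (the leakage-safe alternative); the rounding then
    applies to fruit counts.
    """
    if not 0.0 < calibration_fraction < 1.0:
        raise ValueError("calibration_fraction must be in (0, 1)")
    n = table.n_samples
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    rng = np.random.default_rng(seed)
    if group_by_fruit:
        if table.fruit_ids is None:
            raise ValueError("group_by_fruit requires fruit_ids")
        groups = pd.unique(table.fruit_ids)
        g = len(groups)
        n_cal_g = _round_half_away(calibration_fraction * g)
        if n_cal_g < 1 or n_cal_g >= g:
            raise ValueError("split would leave an empty partition")
        perm = rng.permutation(g)
        cal_groups = set(groups[perm[:n_cal_g]])
        cal_idx = np.flatnonzero([f in cal_groups for f in table.fruit_ids])
        pred_idx = np.flatnonzero([f not in cal_groups for f in table.fruit_ids])
    else:
        n_cal = _round_half_away(calibration_fraction * n)
        if n_cal < 1 or n_cal >= n:
            raise ValueError("split would leave an empty partition")
        perm = rng.permutation(n)
        cal_idx = np.sort(perm[:n_cal])
        pred_idx = np.sort(perm[n_cal:])
    return table.take_rows(cal_idx), table.take_rows(pred_idx)


# ---------------------------------------------------------------------------
# PLS1 NIPALS
# ---------------------------------------------------------------------------


@dataclass
class PLSRModel:
    """Fitted single-response PLSR factorization.

    ``coef_path[:, k-1]`` is the collapsed regression coefficient vector using
    the first k factors; ``intercept_path[k-1]`` the matching intercept.
    ``coef`` / ``intercept`` refer to the full ``n_factors`` model.
    """

    n_factors: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray       # W, (p, F) with unit-norm columns
    x_loadings: np.ndarray    # P, (p, F)
    y_loadings: np.ndarray    # q, (F,)
    x_scores: np.ndarray      # T, (n, F)
    coef_path: np.ndarray     # (p, F)
    intercept_path: np.ndarray  # (F,)
    band_centers: np.ndarray | None = None
    residual_x_norm: float = float("nan")
    residual_y_norm: float = float("nan")

    @property
    def coef(self) -> np.ndarray:
        if self.n_factors == 0:
            return np.zeros(self.x_mean.size)
        return self.coef_path[:, self.n_factors - 1]

    @property
    def intercept(self) -> float:
        if self.n_factors == 0:
            return float(self.y_mean)
        return float(self.intercept_path[self.n_factors - 1])

    @property
    def y_scores(self) -> np.ndarray:
        """U scores of the Y-side factorization (PLS1: u_k = y_res * q_k direction)."""
        return self.x_scores * self.y_loadings  # inner relation U ~ T B with B diagonal

    def predict(self, X_new: np.ndarray, n_factors: int | None = None) -> np.ndarray:
        return predict(self, X_new, n_factors)

    def to_dict(self) -> dict:
        return {
            "n_factors": self.n_factors,
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "band_centers": None if self.band_centers is None else self.band_centers.tolist(),
        }


def fit_xy(
    X: np.ndarray,
    y: np.ndarray,
    n_factors: int,
    tol: float = 1e-12,
) -> PLSRModel:
    """Fit PLS1 by NIPALS on mean-centered (X, y).

    Factor extraction halts early once the X residual norm falls below ``tol``
    (the model records the achieved factor count).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError(f"X has {n} rows but y has {y.size}")
    if n_factors < 0:
        raise ValueError("n_factors must be >= 0")
    if np.ptp(y) == 0:
        raise ValueError("y has zero variance; PLSR undefined")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean

    F = min(n_factors, n - 1, p)
    W = np.zeros((p, F))
    P = np.zeros((p, F))
    q = np.zeros(F)
    T = np.zeros((n, F))
    achieved = 0
    Xk = Xc.copy()
    for k in range(F):
        if np.linalg.norm(Xk) < tol:
            break
        w = Xk.T @ yc
        nw = np.linalg.norm(w)
        if nw < tol:
            break
        w /= nw
        t = Xk @ w
        tt = t @ t
        if tt < tol:
            break
        pvec = Xk.T @ t / tt
        qk = (yc @ t) / tt
        Xk -= np.outer(t, pvec)
        W[:, k], P[:, k], q[k], T[:, k] = w, pvec, qk, t
        achieved = k + 1

    W, P, q, T = W[:, :achieved], P[:, :achieved], q[:achieved], T[:, :achieved]

    # collapsed coefficients for every factor count: R = W (P'W)^{-1}
    R = np.zeros((p, achieved))
    coef_path = np.zeros((p, achieved))
    b = np.zeros(p)
    for k in range(achieved):
        r = W[:, k] - R[:, :k] @ (P[:, :k].T @ W[:, k])
        R[:, k] = r
        b = b + q[k] * r
        coef_path[:, k] = b
    intercept_path = y_mean - x_mean @ coef_path if achieved else np.zeros(0)

    resid_y = yc - T @ q if achieved else yc
    return PLSRModel(
        n_factors=achieved,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        x_scores=T,
        coef_path=coef_path,
        intercept_path=np.atleast_1d(intercept_path),
        residual_x_norm=float(np.linalg.norm(Xk)),
        residual_y_norm=float(np.linalg.norm(resid_y)),
    )


def fit(calibration: SpectraTable, n_factors: int, tol: float = 1e-12) -> PLSRModel:
    """Fit PLS1 on a :class:`SpectraTable` (see :func:`fit_xy`)."""
    model = fit_xy(calibration.X, calibration.y, n_factors, tol)
    model.band_centers = calibration.band_centers
    return model


def predict(model: PLSRModel, X_new: np.ndarray, n_factors: int | None = None) -> np.ndarray:
    """Predict SSC: y_hat = X_new @ b + intercept (collapsed-coefficient path)."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.x_mean.size:
        raise ValueError(
            f"X_new has {X_new.shape[1]} bands but model expects {model.x_mean.size}"
        )
    k = model.n_factors if n_factors is None else min(n_factors, model.n_factors)
    if k == 0:
        return np.full(X_new.shape[0], model.y_mean)
    return X_new @ model.coef_path[:, k - 1] + model.intercept_path[k - 1]


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CVResult:
    rmsecv: np.ndarray          # RMSECV per factor count 1..max_factors
    optimal_factors: int
    scheme: str
    n_fits: int


def _fold_indices(n: int, scheme: str, k: int, seed: int | None) -> list[np.ndarray]:
    if scheme == "loo":
        return [np.array([i]) for i in range(n)]
    if scheme == "kfold":
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        return [perm[i::k] for i in range(min(k, n))]
    raise ValueError(f"unknown CV scheme {scheme!r}; expected 'loo' or 'kfold'")


def cross_validate(
    calibration: SpectraTable | tuple[np.ndarray, np.ndarray],
    max_factors: int = MAX_FACTORS_DEFAULT,
    scheme: str = "loo",
    k: int = 5,
    seed: int | None = None,
) -> CVResult:
    """RMSECV over factor counts 1..max_factors; optimal count at the minimum.

    LOOCV performs exactly n model fits (each fit yields predictions for every
    factor count via the collapsed-coefficient path).  Ties in the RMSECV
    curve break toward fewer factors.
    """
    if isinstance(calibration, SpectraTable):
        X, y = calibration.X, calibration.y
    else:
        X, y = calibration
        X = np.atleast_2d(np.asarray(X, float))
        y = np.asarray(y, float).ravel()
    n, p = X.shape
    if scheme == "loo" and n < 3:
        raise ValueError("LOOCV needs at least 3 samples")
    max_factors = min(max_factors, n - 2, p, MAX_FACTORS_DEFAULT)
    if max_factors < 1:
        raise ValueError("max_factors < 1 after capping; dataset too small")

    folds = _fold_indices(n, scheme, k, seed)
    sse = np.zeros(max_factors)
    counts = np.zeros(max_factors)
    all_idx = np.arange(n)
    for test_idx in folds:
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        model = fit_xy(X[train_mask], y[train_mask], max_factors)
        F = model.n_factors
        if F == 0:
            preds = np.full((test_idx.size, max_factors), model.y_mean)
        else:
            preds = X[test_idx] @ model.coef_path + model.intercept_path
            if F < max_factors:  # pad: extra factors behave like the last achieved
                preds = np.hstack(
                    [preds, np.repeat(preds[:, -1:], max_factors - F, axis=1)]
                )
        err2 = (preds - y[test_idx, None]) ** 2
        sse += err2.sum(axis=0)
        counts += test_idx.size
    rmsecv = np.sqrt(sse / counts)
    optimal = int(np.argmin(rmsecv)) + 1  # argmin takes the first minimum
    label = scheme if scheme == "loo" else f"kfold({k})"
    return CVResult(rmsecv=rmsecv, optimal_factors=optimal, scheme=label, n_fits=len(folds))


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


@dataclass
class Metrics:
    r2: float | None
    rmse: float
    n: int
    label: str = ""


def evaluate(y_true, y_hat, label: str = "") -> Metrics:
    """RMSE and R² = 1 - SSres/SStot (SStot about y_true's own mean).

    With a constant y_true the R² denominator vanishes and R² is reported as
    missing (None).
    """
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y_true.size != y_hat.size:
        raise ValueError("y_true and y_hat lengths differ")
    if y_true.size < 2:
        raise ValueError("need at least 2 values to evaluate")
    ss_res = float(np.sum((y_true - y_hat) ** 2))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    rmse = math.sqrt(ss_res / y_true.size)
    if ss_tot == 0:
        import warnings

        warnings.warn("R² undefined: y_true has zero variance", stacklevel=2)
        r2 = None
    else:
        r2 = 1.0 - ss_res / ss_tot
    return Metrics(r2=r2, rmse=rmse, n=y_true.size, label=label)


@dataclass
class EvaluationReport:
    """One model variant's metrics in the calibration / CV / prediction layout."""

    model: str
    preprocessing: str
    R2_c: float | None
    RMSEC: float
    R2_v: float | None
    RMSEV: float
    R2_p: float | None
    RMSEP: float
    optimal_factors: int
    n_bands: int
    n_calibration: int
    n_prediction: int
    selected_bands_nm: list[float] = field(default_factory=list)

    def to_row(self) -> dict:
        return {
            "model": self.model,
            "preprocessing": self.preprocessing,
            "R2_c": self.R2_c,
            "RMSEC": self.RMSEC,
            "R2_v": self.R2_v,
            "RMSEV": self.RMSEV,
            "R2_p": self.R2_p,
            "RMSEP": self.RMSEP,
            "optimal_factors": self.optimal_factors,
            "n_bands": self.n_bands,
            "n_calibration": self.n_calibration,
            "n_prediction": self.n_prediction,
        }
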