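"""Spectral preprocessing transforms for reflectance spectra.

Implements the standard chemometric toolbox applied to fruit reflectance
before regression: moving-average smoothing, Savitzky-Golay first derivative,
maximum / mean / range normalization, the standard normal variate (SNV) and
multiplicative scatter correction (MSC).

All transforms preserve spectrum length and band order, and operate row-wise
on a spectra matrix.  MSC is the one stateful transform: its reference
spectrum must be learned on calibration rows only and frozen for prediction
rows (no cross-sample leakage).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .hypercube import WavelengthGrid

__all__ = [
    "METHODS",
    "moving_average",
    "sg_first_derivative",
    "normalize",
    "snv",
    "msc",
    "Preprocessor",
]

METHODS = (
    "none",
    "moving_average",
    "sg_first_derivative",
    "norm_max",
    "norm_mean",
    "norm_range",
    "snv",
    "msc",
)


def _window_points(window_nm: float, step_nm: float, interpretation: str) -> int:
    """Convert a window stated in nm to an odd point count on the grid.

    ``half_width``: the nm value is the half-width, so a 6 nm window on a 2 nm
    grid spans center +/- 3 bands = 7 points.  ``full_width``: the nm value is
    the total span, 6 nm / 2 nm = 3 intervals -> 3 points (must come out odd).
    """
    k = window_nm / step_nm
    if abs(k - round(k)) > 1e-9:
        raise ValueError(
            f"window {window_nm} nm is not a multiple of the grid step {step_nm} nm"
        )
    k = int(round(k))
    if interpretation == "half_width":
        return 2 * k + 1
    if interpretation == "full_width":
        if k % 2 == 0:
            raise ValueError(
                f"full-width window of {k} points is even; an odd, centered "
                "window is required"
            )
        return k
    raise ValueError(f"unknown window interpretation {interpretation!r}")


def moving_average(
    spectrum: np.ndarray,
    window_nm: float,
    grid: WavelengthGrid,
    interpretation: str = "half_width",
) -> np.ndarray:
    """Centered running mean; end windows shrink so length is preserved."""
    x = np.asarray(spectrum, dtype=float)
    w = _window_points(window_nm, grid.step_nm, interpretation)
    n = x.size
    if w > n:
        raise ValueError(f"window of {w} points exceeds spectrum length {n}")
    half = w // 2
    csum = np.concatenate(([0.0], np.cumsum(x)))
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def sg_first_derivative(
    spectrum: np.ndarray,
    window_nm: float,
    grid: WavelengthGrid,
    poly_order: int = 2,
    interpretation: str = "half_width",
) -> np.ndarray:
    """Savitzky-Golay first derivative in reflectance units per nm.

    Dividing by the grid step makes the output resolution-independent.  Ends
    use polynomial extrapolation of the edge window fits.
    """
    x = np.asarray(spectrum, dtype=float)
    w = _window_points(window_nm, grid.step_nm, interpretation)
    if w < poly_order + 2:
        raise ValueError(
            f"window of {w} points too small for first derivative of a "
            f"degree-{poly_order} fit (needs >= {poly_order + 2})"
        )
    if x.size < w:
        raise ValueError(f"spectrum of {x.size} points shorter than window {w}")
    return savgol_filter(x, w, poly_order, deriv=1, delta=grid.step_nm, mode="interp")


def normalize(spectrum: np.ndarray, mode: str) -> np.ndarray:
    """Scale a spectrum by its maximum, mean, or min-max range."""
    x = np.asarray(spectrum, dtype=float)
    if mode == "max":
        m = x.max()
        if m == 0:
            raise ValueError("maximum normalization undefined: max(x) = 0")
        return x / m
    if mode == "mean":
        m = x.mean()
        if m == 0:
            raise ValueError("mean normalization undefined: mean(x) = 0")
        return x / m
    if mode == "range":
        lo, hi = x.min(), x.max()
        if hi <= lo:
            raise ValueError("range normalization undefined: max(x) <= min(x)")
        return (x - lo) / (hi - lo)
    raise ValueError(f"unknown normalization mode {mode!r}; expected max, mean or range")


def snv(spectrum: np.ndarray) -> np.ndarray:
    """Standard normal variate: center and scale each spectrum to unit spread.

    Uses the sample (n-1) standard deviation, the chemometrics convention.
    Output has mean 0 and sample sd 1; invariant to affine transforms a*x + b
    of the input.
    """
    x = np.asarray(spectrum, dtype=float)
    if x.size < 2:
        raise ValueError("SNV needs at least 2 points")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("SNV undefined for a constant spectrum (zero spread)")
    return (x - x.mean()) / sd


def msc(
    X: np.ndarray, reference: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Multiplicative scatter correction of a spectra matrix.

    Each spectrum x is regressed on the reference by ordinary least squares,
    x ~ a + b * reference, and corrected to (x - a) / b, removing per-sample
    gain and offset scatter.  When ``reference`` is None it is taken as the
    column-wise mean of ``X`` (so it must be fitted on calibration rows and
    the returned reference reused for any later rows).

    Returns (corrected matrix, reference).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if reference is None:
        if X.shape[0] < 2:
            raise ValueError("MSC needs >= 2 spectra to estimate a mean reference")
        reference = X.mean(axis=0)
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (X.shape[1],):
        raise ValueError(
            f"reference length {reference.size} does not match {X.shape[1]} bands"
        )
    ref_c = reference - reference.mean()
    denom = ref_c @ ref_c
    if denom == 0:
        raise ValueError("MSC reference is constant; regression undefined")
    b = (X - X.mean(axis=1, keepdims=True)) @ ref_c / denom
    if np.any(np.abs(b) < 1e-12):
        bad = np.flatnonzero(np.abs(b) < 1e-12)
        raise ValueError(f"MSC slope ~ 0 for spectra at rows {bad.tolist()}")
    a = X.mean(axis=1) - b * reference.mean()
    corrected = (X - a[:, None]) / b[:, None]
    return corrected, reference


@dataclass
class Preprocessor:
    """A fittable preprocessing step applied row-wise to a spectra matrix.

    ``method`` is one of :data:`METHODS`.  Only MSC has fit state (its
    reference spectrum); every other method is stateless and ``fit`` is a
    no-op.  ``window_nm`` parameterizes smoothing/derivative methods; with the
    default half-width interpretation, 6 nm on a 2 nm grid is a 7-point
    window.
    """

    method: str = "none"
    window_nm: float = 6.0
    poly_order: int = 2
    window_interpretation: str = "half_width"
    msc_reference: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")

    def fit(self, X: np.ndarray, grid: WavelengthGrid | None = None) -> "Preprocessor":
        if self.method == "msc":
            _, self.msc_reference = msc(X)
        return self

    def transform(self, X: np.ndarray, grid: WavelengthGrid | None = None) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        m = self.method
        if m == "none":
            return X.copy()
        if m == "moving_average":
            return np.apply_along_axis(
                moving_average, 1, X, self.window_nm, grid, self.window_interpretation
            )
        if m == "sg_first_derivative":
            return np.apply_along_axis(
                sg_first_derivative, 1, X, self.window_nm, grid,
                self.poly_order, self.window_interpretation,
            )
        if m == "norm_max":
            return np.apply_along_axis(normalize, 1, X, "max")
        if m == "norm_mean":
            return np.apply_along_axis(normalize, 1, X, "mean")
        if m == "norm_range":
            return np.apply_along_axis(normalize, 1, X, "range")
        if m == "snv":
            return np.apply_along_axis(snv, 1, X)
        if m == "msc":
            if self.msc_reference is None:
                raise ValueError("MSC preprocessor must be fitted before transform")
            corrected, _ = msc(X, self.msc_reference)
            return corrected
        raise AssertionError(m)

    def fit_transform(self, X: np.ndarray, grid: WavelengthGrid | None = None) -> np.ndarray:
        return self.fit(X, grid).transform(X, grid)
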