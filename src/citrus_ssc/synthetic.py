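"""Synthetic citrus-like hyperspectral data with known ground truth.

Emulates the statistical structure of VNIR (400-1000 nm) citrus reflectance:
a smooth baseline with pigment and water absorption dips (negative peaks near
470, 640 and 880 nm, a positive peak near 912 nm, and an SSC-linked O-H
overtone absorption near 960 nm), per-sample multiplicative/additive scatter,
per-band noise, an SSC reference distribution matching the study population
(truncated normal, 7.40-12.50 °Brix, mean 9.85, sd 1.08), two orientation
replicates per fruit, and optional planted outlier samples.

The absorption-depth response to SSC is linear (small-absorbance
Beer-Lambert rationale).  Because the only SSC information in a spectrum is
the gradient vector g = dR/dSSC, per-band noise of sd sigma puts an optimal
linear-estimator floor of sigma / ||g_perp|| °Brix on any prediction
(g_perp = g orthogonalized against the constant-offset and mean-spectrum
nuisance directions).  The default template is parameterized by that floor
(0.5 °Brix) rather than by sigma directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hypercube import HyperCube, ReferenceFrame, WavelengthGrid, make_wavelength_grid
from .plsr import SpectraTable

__all__ = [
    "GaussianFeature",
    "SpectrumTemplate",
    "SSCDistribution",
    "default_grid",
    "default_template",
    "generate_spectra_dataset",
    "generate_cube",
    "disk_mask",
    "inject_outliers",
    "generate_latent_data",
]


def default_grid() -> WavelengthGrid:
    """The acquisition grid: 300 bands, 400-1000 nm at 2 nm."""
    return make_wavelength_grid(400.0, 1000.0, 2.0)


@dataclass(frozen=True)
class GaussianFeature:
    """One Gaussian absorption dip: depth(SSC) = depth + sensitivity*(SSC - mean)."""

    center_nm: float
    width_nm: float
    depth: float
    ssc_sensitivity: float = 0.0  # reflectance depth change per °Brix


@dataclass(frozen=True)
class SSCDistribution:
    """Truncated-normal SSC population (°Brix)."""

    mean: float = 9.85
    sd: float = 1.08
    minimum: float = 7.40
    maximum: float = 12.50

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Rejection sampling from the truncated normal."""
        out = np.empty(n)
        filled = 0
        while filled < n:
            draw = rng.normal(self.mean, self.sd, size=2 * (n - filled) + 8)
            ok = draw[(draw >= self.minimum) & (draw <= self.maximum)]
            take = min(ok.size, n - filled)
            out[filled : filled + take] = ok[:take]
            filled += take
        return out


@dataclass
class SpectrumTemplate:
    """Analytic citrus reflectance template over a wavelength grid.

    The scatter model has three parts: a per-sample multiplicative gain and
    additive offset (what MSC corrects), plus smooth wavelength-dependent
    scatter — per-sample random low-order Legendre components — standing in
    for peel-thickness and illumination-geometry effects that tilt and bend a
    spectrum rather than just scaling it.  Per-band noise is iid on top.
    """

    grid: WavelengthGrid
    baseline: np.ndarray
    features: tuple[GaussianFeature, ...]
    gain_sd: float = 0.05       # per-sample multiplicative scatter
    offset_sd: float = 0.01     # per-sample additive scatter
    smooth_scatter_sd: tuple[float, ...] = ()  # sd per Legendre degree 1, 2, ...
    noise_sd: float = 0.0       # per-band additive iid noise
    ssc_mean: float = 9.85      # center of the linear depth response
    ssc_range: tuple[float, float] = (7.40, 12.50)

    def __post_init__(self) -> None:
        self.baseline = np.asarray(self.baseline, dtype=float)
        if self.baseline.shape != (len(self.grid),):
            raise ValueError("baseline length does not match the grid")
        lam = self.grid.centers
        for f in self.features:
            if not (lam[0] <= f.center_nm <= lam[-1]):
                raise ValueError(f"feature center {f.center_nm} nm outside the grid")
            if f.width_nm <= 0 or f.depth <= 0:
                raise ValueError("feature widths and base depths must be positive")
        for ssc in self.ssc_range:
            s = self.clean_spectrum(ssc)
            if s.min() < 0.0 or s.max() > 1.2:
                raise ValueError(
                    f"noise-free spectrum at SSC={ssc} leaves [0, 1.2] "
                    f"(min {s.min():.3f}, max {s.max():.3f})"
                )

    def _profiles(self) -> np.ndarray:
        lam = self.grid.centers
        return np.stack(
            [
                np.exp(-0.5 * ((lam - f.center_nm) / f.width_nm) ** 2)
                for f in self.features
            ]
        )

    def clean_spectrum(self, ssc: float) -> np.ndarray:
        """Noise-free reflectance at a given SSC."""
        profiles = self._profiles()
        depths = np.array(
            [f.depth + f.ssc_sensitivity * (ssc - self.ssc_mean) for f in self.features]
        )
        return self.baseline - depths @ profiles

    def ssc_gradient(self) -> np.ndarray:
        """g = dR/dSSC per band (constant under the linear depth model)."""
        profiles = self._profiles()
        sens = np.array([f.ssc_sensitivity for f in self.features])
        return -(sens @ profiles)

    def smooth_scatter_basis(self) -> np.ndarray:
        """Legendre components (degree 1, 2, ...) over the grid, shape (k, bands)."""
        k = len(self.smooth_scatter_sd)
        if k == 0:
            return np.empty((0, len(self.grid)))
        lam = self.grid.centers
        x = 2.0 * (lam - lam[0]) / (lam[-1] - lam[0]) - 1.0
        return np.stack(
            [np.polynomial.legendre.Legendre.basis(d + 1)(x) for d in range(k)]
        )

    def _nuisance_directions(self) -> np.ndarray:
        """Columns spanning the scatter subspace: offset, gain, smooth components."""
        n = len(self.grid)
        cols = [np.ones(n), self.clean_spectrum(self.ssc_mean)]
        cols.extend(self.smooth_scatter_basis())
        return np.stack(cols, axis=1)

    def noise_floor_brix(self) -> float:
        """Optimal linear-estimator error floor sigma/||g_perp|| (°Brix).

        g is projected orthogonal to the scatter nuisance subspace (constant
        offset, mean spectrum, smooth scatter components); no linear predictor
        on these spectra can beat this floor under iid per-band noise.
        """
        g = self.ssc_gradient()
        qmat, _ = np.linalg.qr(self._nuisance_directions())
        g_perp = g - qmat @ (qmat.T @ g)
        return float(self.noise_sd / np.linalg.norm(g_perp))


# Feature set: pigment dips at 470/640/680 nm (weak SSC response: the 640 nm
# dip flattens slightly as fruit ripen, the blue dip sharpens), a
# water/carbohydrate dip at 880 nm, a small SSC-responsive feature at 912 nm
# (so the local maximum there sharpens with SSC), and the dominant O-H
# second-overtone SSC absorption at 960 nm.  SSC sensitivity is concentrated
# in the 880-1000 nm sugar region (> 98% of the gradient power), matching
# where carbohydrate overtones live.
_DEFAULT_FEATURES = (
    GaussianFeature(470.0, 16.0, 0.080, +0.001),
    GaussianFeature(640.0, 25.0, 0.060, -0.001),
    GaussianFeature(680.0, 10.0, 0.050, 0.0),
    GaussianFeature(880.0, 12.0, 0.045, +0.003),
    GaussianFeature(912.0, 10.0, 0.020, -0.005),
    GaussianFeature(960.0, 20.0, 0.100, +0.014),
)


def default_template(
    grid: WavelengthGrid | None = None,
    noise_floor_brix: float = 0.5,
    gain_sd: float = 0.05,
    offset_sd: float = 0.01,
    smooth_scatter_sd: tuple[float, ...] = (0.010, 0.006, 0.004),
) -> SpectrumTemplate:
    """Citrus template with per-band noise calibrated to a target error floor.

    The baseline rises logistically from ~0.15 at 400 nm to ~0.73 near 750 nm
    (chlorophyll edge) then declines gently into the NIR.  ``noise_floor_brix``
    sets the per-band noise sd via the optimal-estimator bound; 0.5 °Brix
    matches the error scale of field-grade SSC sorting.
    """
    grid = grid or default_grid()
    lam = grid.centers
    baseline = 0.15 + 0.60 / (1.0 + np.exp(-(lam - 560.0) / 55.0))
    baseline = baseline - 4e-4 * np.maximum(lam - 750.0, 0.0)
    tpl = SpectrumTemplate(
        grid=grid,
        baseline=baseline,
        features=_DEFAULT_FEATURES,
        gain_sd=gain_sd,
        offset_sd=offset_sd,
        smooth_scatter_sd=tuple(smooth_scatter_sd),
        noise_sd=1.0,  # placeholder; rescaled below
    )
    tpl.noise_sd = noise_floor_brix / tpl.noise_floor_brix()
    return tpl


def generate_spectra_dataset(
    n_fruits: int = 324,
    orientations: int = 2,
    template: SpectrumTemplate | None = None,
    ssc_dist: SSCDistribution | None = None,
    seed: int | None = None,
) -> SpectraTable:
    """Generate one mean spectrum per fruit orientation with known SSC truth.

    One SSC is drawn per fruit; each orientation replicate gets its own
    multiplicative gain, additive offset, and per-band noise (orientation
    differences are treated as replicate scatter).  Defaults reproduce the
    study layout: 324 fruits x 2 orientations = 648 spectra.

    Randomness splits deterministically from ``seed``: fruit SSC draws first,
    then per-spectrum gain, offset and noise in fruit-major order.
    """
    if n_fruits < 1:
        raise ValueError("n_fruits must be >= 1")
    template = template or default_template()
    ssc_dist = ssc_dist or SSCDistribution()
    rng = np.random.default_rng(seed)

    ssc = ssc_dist.sample(n_fruits, rng)
    n = n_fruits * orientations
    p = len(template.grid)
    basis = template.smooth_scatter_basis()
    smooth_sd = np.asarray(template.smooth_scatter_sd, dtype=float)
    X = np.empty((n, p))
    y = np.empty(n)
    ids, orient, fruit_ids = [], [], []
    row = 0
    for i in range(n_fruits):
        clean = template.clean_spectrum(ssc[i])
        for o in range(orientations):
            gain = 1.0 + rng.normal(0.0, template.gain_sd) if template.gain_sd else 1.0
            offset = rng.normal(0.0, template.offset_sd) if template.offset_sd else 0.0
            smooth = (
                (rng.normal(size=smooth_sd.size) * smooth_sd) @ basis
                if smooth_sd.size
                else 0.0
            )
            noise = (
                rng.normal(0.0, template.noise_sd, size=p) if template.noise_sd else 0.0
            )
            X[row] = gain * clean + offset + smooth + noise
            y[row] = ssc[i]
            ids.append(f"F{i + 1:04d}_o{o + 1}")
            orient.append(f"o{o + 1}")
            fruit_ids.append(f"F{i + 1:04d}")
            row += 1
    return SpectraTable(
        X, y, template.grid.centers,
        sample_ids=np.array(ids),
        orientation=np.array(orient),
        fruit_ids=np.array(fruit_ids),
    )


def disk_mask(
    scene_dims: tuple[int, int], center: tuple[float, float], radius: float
) -> np.ndarray:
    """Analytic disk: pixels whose center lies within ``radius`` of ``center``."""
    ii, jj = np.mgrid[0 : scene_dims[0], 0 : scene_dims[1]]
    return (ii - center[0]) ** 2 + (jj - center[1]) ** 2 <= radius**2


def generate_cube(
    fruit_radius_px: int,
    scene_dims: tuple[int, int] = (80, 80),
    template: SpectrumTemplate | None = None,
    ssc: float = 9.85,
    background_reflectance: float = 0.05,
    seed: int | None = None,
    white_level: float = 3000.0,
    dark_level: float = 100.0,
    quantize_12bit: bool = False,
) -> tuple[HyperCube, ReferenceFrame]:
    """Emit a raw-intensity cube plus white/dark references for one fruit.

    The scene is a centered disk of template reflectance (plus the template's
    per-band noise, per pixel) on a flat dim background.  Raw counts invert
    the calibration equation, raw = R*(white - dark) + dark, so calibrating
    recovers the intended reflectance exactly (up to noise, and up to 12-bit
    quantization if ``quantize_12bit``).  References are single (pixel, band)
    line frames, broadcast along the scan axis.
    """
    if fruit_radius_px < 1:
        raise ValueError("fruit radius must be >= 1 pixel")
    lines, pixels = scene_dims
    if 2 * fruit_radius_px >= min(lines, pixels):
        raise ValueError(f"disk of radius {fruit_radius_px} does not fit in {scene_dims}")
    template = template or default_template()
    rng = np.random.default_rng(seed)
    p = len(template.grid)

    mask = disk_mask(scene_dims, ((lines - 1) / 2.0, (pixels - 1) / 2.0), fruit_radius_px)
    refl = np.full((lines, pixels, p), float(background_reflectance))
    refl[mask] = template.clean_spectrum(ssc)
    if template.noise_sd:
        refl[mask] += rng.normal(0.0, template.noise_sd, size=(int(mask.sum()), p))

    white = np.full((pixels, p), white_level)
    dark = np.full((pixels, p), dark_level)
    raw = refl * (white - dark)[np.newaxis, :, :] + dark[np.newaxis, :, :]
    if quantize_12bit:
        raw = np.clip(np.round(raw), 0, 4095).astype(np.uint16)
    else:
        raw = raw.astype(np.float32)
    cube = HyperCube(raw, template.grid, kind="raw", metadata={"ssc_true": ssc})
    return cube, ReferenceFrame(white=white, dark=dark)


def inject_outliers(
    table: SpectraTable,
    n_outliers: int = 17,
    y_shift_sd_multiples: float = 5.0,
    error_floor_brix: float = 0.5,
    seed: int | None = None,
) -> tuple[SpectraTable, np.ndarray]:
    """Plant reference-value outliers: shift the SSC of random samples.

    Each planted sample's SSC reference moves by +/- (y_shift_sd_multiples *
    error_floor_brix) °Brix — samples whose reference no longer matches their
    spectrum, the signature that Monte Carlo screening should catch.  Returns
    the contaminated table and the planted indices (sorted, distinct).
    """
    n = table.n_samples
    if n_outliers >= n / 10:
        raise ValueError(f"{n_outliers} outliers in {n} samples exceeds the n/10 cap")
    if y_shift_sd_multiples == 0:
        raise ValueError("a zero shift plants no outlier")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=n_outliers, replace=False))
    signs = rng.choice([-1.0, 1.0], size=n_outliers)
    y = table.y.copy()
    y[idx] = y[idx] + signs * y_shift_sd_multiples * error_floor_brix
    out = SpectraTable(
        table.X.copy(), y, table.band_centers,
        table.sample_ids, table.orientation, table.fruit_ids,
    )
    return out, idx


def generate_latent_data(
    n_samples: int = 60,
    n_bands: int = 40,
    rank: int = 3,
    x_noise_sd: float = 0.02,
    y_noise_sd: float = 0.2,
    seed: int | None = None,
) -> SpectraTable:
    """Generic low-rank latent-factor data for factor-count recovery checks.

    X = T A' + noise with ``rank`` orthonormal loading directions and factor
    scores of decreasing scale (rank, rank-1, ..., 1); y loads equally on all
    factors.  With low noise, cross-validated PLSR should recover the planted
    rank as the optimal factor count.
    """
    rng = np.random.default_rng(seed)
    scales = np.arange(rank, 0, -1, dtype=float)
    T = rng.normal(size=(n_samples, rank)) * scales
    A = np.linalg.qr(rng.normal(size=(n_bands, rank)))[0]
    X = T @ A.T + rng.normal(0.0, x_noise_sd, size=(n_samples, n_bands))
    y = T @ np.ones(rank) + rng.normal(0.0, y_noise_sd, size=n_samples)
    centers = 400.0 + 2.0 * np.arange(n_bands)
    return SpectraTable(X, y, centers)
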