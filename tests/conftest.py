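import numpy as np
import pytest
from hypothesis import settings

import citrus_ssc as cs

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid300():
    """The acquisition grid: 300 bands, 400-1000 nm at 2 nm."""
    return cs.make_wavelength_grid(400, 1000, 2)


@pytest.fixture(scope="session")
def small_grid():
    """A 5-band toy grid for hand-computed examples."""
    return cs.make_wavelength_grid(400, 410, 2)


@pytest.fixture(scope="session")
def quiet_template(grid300):
    """Template with all randomness disabled: deterministic spectra."""
    tpl = cs.default_template(
        grid300, noise_floor_brix=0.0, gain_sd=0.0, offset_sd=0.0, smooth_scatter_sd=()
    )
    assert tpl.noise_sd == 0.0
    return tpl


@pytest.fixture(scope="session")
def default_dataset():
    """One seeded realization of the study layout: 324 fruits x 2 = 648 spectra."""
    return cs.generate_spectra_dataset(324, seed=20240226)


@pytest.fixture(scope="session")
def coarse_table():
    """Small fast dataset: 60 fruits on a 100-band grid (for pipeline tests)."""
    grid = cs.make_wavelength_grid(400, 1000, 6)
    tpl = cs.default_template(grid)
    return cs.generate_spectra_dataset(60, template=tpl, seed=42)


def planted_signal_table(seed, n=100, p=120, informative=(10, 30, 55, 80, 100), noise=0.2):
    """Regression data whose y depends linearly on a few known bands."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = X[:, list(informative)].sum(axis=1) + rng.normal(0, noise, n)
    return cs.SpectraTable(X, y, 400.0 + 2.0 * np.arange(p)), list(informative)
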