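"""Spectral preprocessing transforms: smoothing, derivative, normalizations,
SNV and MSC."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import citrus_ssc as cs
from citrus_ssc.preprocessing import (
    Preprocessor,
    moving_average,
    msc,
    normalize,
    sg_first_derivative,
    snv,
)

spectra = st.lists(
    st.floats(min_value=-10, max_value=10, allow_nan=False), min_size=5, max_size=40
).map(np.array)


class TestMovingAverage:
    def test_hand_computed_three_point(self, small_grid):
        # window 2 nm half-width on a 2 nm grid = 3 points; shrinking ends
        out = moving_average(np.array([1.0, 2, 3, 4, 5]), 2.0, small_grid)
        assert np.allclose(out, [1.5, 2, 3, 4, 4.5])

    def test_constant_unchanged(self, small_grid):
        out = moving_average(np.full(5, 3.3), 4.0, small_grid)
        assert np.allclose(out, 3.3)

    def test_linear_ramp_interior_unchanged(self):
        grid = cs.make_wavelength_grid(400, 440, 2)  # 20 points
        x = 0.5 * np.arange(20) + 1.0
        out = moving_average(x, 6.0, grid)  # 7-point window
        assert np.allclose(out[3:-3], x[3:-3])

    def test_window_wider_than_spectrum_rejected(self, small_grid):
        with pytest.raises(ValueError, match="window"):
            moving_average(np.ones(5), 10.0, small_grid)

    def test_non_multiple_window_rejected(self, small_grid):
        with pytest.raises(ValueError, match="multiple"):
            moving_average(np.ones(5), 3.0, small_grid)


class TestSavitzkyGolayDerivative:
    def test_constant_gives_zero(self, small_grid):
        out = sg_first_derivative(np.full(5, 2.5), 4.0, small_grid)
        assert np.allclose(out, 0.0, atol=1e-12)

    def test_linear_ramp_gives_slope_per_nm(self):
        grid = cs.make_wavelength_grid(400, 440, 2)
        slope = 0.37  # per nm
        x = slope * (grid.centers - 400.0) + 1.2
        out = sg_first_derivative(x, 6.0, grid)
        assert np.allclose(out, slope, atol=1e-10)

    def test_quadratic_exact_with_order_two(self):
        grid = cs.make_wavelength_grid(400, 460, 2)
        lam = grid.centers - 430.0
        x = 0.01 * lam**2 - 0.2 * lam + 3.0
        out = sg_first_derivative(x, 6.0, grid, poly_order=2)
        expected = 0.02 * lam - 0.2  # analytic derivative
        assert np.allclose(out, expected, atol=1e-9)

    def test_too_small_window_rejected(self, small_grid):
        with pytest.raises(ValueError, match="window"):
            sg_first_derivative(np.ones(5), 2.0, small_grid, poly_order=3)


class TestNormalize:
    @pytest.mark.parametrize(
        "x,mode,expected",
        [
            ([0.5, 1.0, 2.0], "max", [0.25, 0.5, 1.0]),
            ([1, 2, 3], "mean", [0.5, 1.0, 1.5]),
            ([2, 4, 6], "range", [0.0, 0.5, 1.0]),
        ],
    )
    def test_examples(self, x, mode, expected):
        assert np.allclose(normalize(np.array(x, float), mode), expected)

    @pytest.mark.parametrize(
        "x,mode",
        [([0, -1, 1], "mean"), ([2, 2, 2], "range"), ([0, 0, 0], "max")],
    )
    def test_degenerate_rejected(self, x, mode):
        with pytest.raises(ValueError, match=mode):
            normalize(np.array(x, float), mode)


class TestSNV:
    def test_unit_example(self):
        assert np.allclose(snv(np.array([1.0, 2, 3])), [-1, 0, 1])

    def test_output_standardized(self):
        rng = np.random.default_rng(0)
        out = snv(rng.uniform(size=30))
        assert out.mean() == pytest.approx(0, abs=1e-12)
        assert out.std(ddof=1) == pytest.approx(1, abs=1e-12)

    @given(spectra, st.floats(0.1, 5), st.floats(-3, 3))
    def test_affine_invariance(self, x, a, b):
        if x.std(ddof=1) < 1e-6:
            return
        assert np.allclose(snv(a * x + b), snv(x), atol=1e-7)

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            snv(np.full(5, 1.0))


class TestMSC:
    def test_reference_spectrum_unchanged(self):
        rng = np.random.default_rng(1)
        ref = rng.uniform(0.2, 0.8, size=20)
        corrected, _ = msc(ref[None, :], reference=ref)
        assert np.allclose(corrected[0], ref, atol=1e-12)

    def test_exact_affine_model_corrected(self):
        rng = np.random.default_rng(2)
        ref = rng.uniform(0.2, 0.8, size=20)
        corrected, _ = msc((2.0 * ref + 0.3)[None, :], reference=ref)
        assert np.allclose(corrected[0], ref, atol=1e-12)

    def test_refit_after_correction_is_identity(self):
        """After MSC, regressing each spectrum on the reference gives a~0, b~1."""
        rng = np.random.default_rng(3)
        base = rng.uniform(0.2, 0.8, size=25)
        gains = rng.uniform(0.7, 1.4, size=10)
        offsets = rng.normal(0, 0.1, size=10)
        X = gains[:, None] * base + offsets[:, None] + rng.normal(0, 0.01, (10, 25))
        corrected, ref = msc(X)
        ref_c = ref - ref.mean()
        for row in corrected:
            b = (row - row.mean()) @ ref_c / (ref_c @ ref_c)
            a = row.mean() - b * ref.mean()
            assert abs(b - 1) < 1e-8
            assert abs(a) < 1e-8

    def test_gain_offset_invariance_with_fixed_reference(self):
        rng = np.random.default_rng(4)
        ref = rng.uniform(0.2, 0.8, size=15)
        X = rng.uniform(0.2, 0.8, size=(4, 15))
        c1, _ = msc(X, reference=ref)
        c2, _ = msc(1.7 * X + 0.25, reference=ref)
        assert np.allclose(c1, c2, atol=1e-10)

    def test_single_spectrum_without_reference_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            msc(np.ones((1, 10)) * np.arange(10))

    def test_zero_slope_rejected(self):
        ref = np.arange(10.0)
        X = np.vstack([ref, np.ones(10) * 5 + np.array([0, 1e-13] + [0] * 8)])
        with pytest.raises(ValueError, match="slope"):
            msc(X, reference=ref)


class TestPreprocessor:
    def test_batch_equals_rowwise(self, grid300):
        rng = np.random.default_rng(5)
        X = rng.uniform(0.1, 0.9, size=(6, 300))
        for method in ("moving_average", "sg_first_derivative", "norm_max",
                       "norm_mean", "norm_range", "snv"):
            pp = Preprocessor(method)
            batch = pp.fit_transform(X, grid300)
            rows = np.vstack([pp.transform(X[i : i + 1], grid300) for i in range(6)])
            assert np.allclose(batch, rows), method

    def test_none_is_identity(self, grid300):
        X = np.random.default_rng(6).uniform(size=(3, 300))
        assert np.array_equal(Preprocessor("none").fit_transform(X, grid300), X)

    def test_msc_requires_fit(self):
        with pytest.raises(ValueError, match="fit"):
            Preprocessor("msc").transform(np.ones((3, 10)))

    def test_msc_reference_frozen_from_fit_data(self):
        rng = np.random.default_rng(7)
        cal = rng.uniform(0.2, 0.8, size=(8, 12))
        pp = Preprocessor("msc")
        pp.fit(cal)
        assert np.allclose(pp.msc_reference, cal.mean(axis=0))
        new = rng.uniform(0.2, 0.8, size=(3, 12))
        out1 = pp.transform(new)
        pp.fit(cal)  # refitting on same data is stable
        assert np.allclose(pp.transform(new), out1)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            Preprocessor("fourier")

    def test_length_and_order_preserved(self, grid300):
        rng = np.random.default_rng(8)
        X = rng.uniform(0.1, 0.9, size=(4, 300))
        for method in ("moving_average", "sg_first_derivative", "snv", "norm_range"):
            out = Preprocessor(method).fit_transform(X, grid300)
            assert out.shape == X.shape
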