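"""PLS1 regression: NIPALS factorization, splitting, CV, evaluation."""

import numpy as np
import pytest

import citrus_ssc as cs
from citrus_ssc.plsr import cross_validate, evaluate, fit_xy, split_dataset


def _random_table(n, p, seed, noise=0.1):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = X @ rng.normal(size=p) + rng.normal(0, noise, n)
    return cs.SpectraTable(X, y, 400.0 + 2.0 * np.arange(p))


class TestSplit:
    @pytest.mark.parametrize("n,cal,pred", [(648, 454, 194), (631, 442, 189), (10, 7, 3)])
    def test_seven_three_sizes(self, n, cal, pred):
        t = _random_table(n, 3, 0)
        a, b = split_dataset(t, 0.7, seed=1)
        assert (a.n_samples, b.n_samples) == (cal, pred)

    def test_disjoint_exhaustive_reproducible(self):
        t = _random_table(50, 3, 1)
        a1, b1 = split_dataset(t, 0.7, seed=5)
        a2, b2 = split_dataset(t, 0.7, seed=5)
        assert np.array_equal(a1.sample_ids, a2.sample_ids)
        ids = set(a1.sample_ids) | set(b1.sample_ids)
        assert len(ids) == 50
        assert not (set(a1.sample_ids) & set(b1.sample_ids))

    def test_group_by_fruit_keeps_orientation_pairs_together(self):
        table = cs.generate_spectra_dataset(40, seed=3)
        cal, pred = split_dataset(table, 0.7, seed=2, group_by_fruit=True)
        assert not (set(cal.fruit_ids) & set(pred.fruit_ids))
        assert cal.n_samples + pred.n_samples == 80

    @pytest.mark.parametrize("frac", [0.0, 1.0, -0.2])
    def test_bad_fraction_rejected(self, frac):
        with pytest.raises(ValueError):
            split_dataset(_random_table(10, 3, 0), frac, seed=0)


class TestFitPredict:
    def test_exact_univariate_line(self):
        m = fit_xy(np.array([[1.0], [2.0], [3.0]]), np.array([2.0, 4.0, 6.0]), 1)
        assert np.allclose(m.predict(np.array([[1.0], [2.0], [3.0]])), [2, 4, 6])
        assert m.coef[0] == pytest.approx(2.0)
        assert m.intercept == pytest.approx(0.0, abs=1e-12)

    def test_full_rank_equals_least_squares(self):
        """At n_factors = n_bands (full rank), PLS1 reproduces OLS predictions."""
        rng = np.random.default_rng(0)
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(30, 8))
            y = X @ rng.normal(size=8) + rng.normal(0, 0.3, 30)
            m = fit_xy(X, y, 8)
            Xa = np.column_stack([np.ones(30), X])
            beta = np.linalg.lstsq(Xa, y, rcond=None)[0]
            assert np.allclose(m.predict(X), Xa @ beta, atol=1e-8)

    def test_matches_sklearn_nipals(self):
        """Independent cross-check against scikit-learn's PLS regression."""
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 12))
        y = X[:, :3].sum(axis=1) + rng.normal(0, 0.2, 40)
        for k in (1, 3, 5):
            ours = fit_xy(X, y, k)
            sk = PLSRegression(n_components=k, scale=False).fit(X, y)
            assert np.allclose(ours.predict(X), sk.predict(X).ravel(), atol=1e-8)

    def test_scores_orthogonal(self):
        m = fit_xy(*_xy(60, 20, seed=2), 8)
        G = m.x_scores.T @ m.x_scores
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(G)).max()

    def test_factorization_equals_collapsed_coefficients(self):
        X, y = _xy(50, 15, seed=3)
        m = fit_xy(X, y, 6)
        # prediction via scores/loadings on training data
        via_scores = m.y_mean + m.x_scores @ m.y_loadings
        assert np.allclose(via_scores, m.predict(X), atol=1e-10)

    def test_uncorrelated_y_gives_near_zero_r2(self):
        r2s = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(400, 10))
            y = rng.normal(size=400)  # independent of X
            m = fit_xy(X, y, 1)
            r2s.append(evaluate(y, m.predict(X)).r2)
        assert np.mean(r2s) < 0.05

    def test_centering_invariance(self):
        X, y = _xy(30, 6, seed=4)
        m1 = fit_xy(X, y, 3)
        shift = np.zeros(6)
        shift[2] = 7.5
        m2 = fit_xy(X + shift, y, 3)
        Xn = np.random.default_rng(5).normal(size=(8, 6))
        assert np.allclose(m1.predict(Xn), m2.predict(Xn + shift), atol=1e-8)

    def test_predict_at_centroid_gives_y_mean(self):
        X, y = _xy(30, 6, seed=6)
        m = fit_xy(X, y, 3)
        assert m.predict(m.x_mean[None, :])[0] == pytest.approx(m.y_mean, abs=1e-10)

    def test_zero_factors_predicts_mean(self):
        X, y = _xy(20, 5, seed=7)
        m = fit_xy(X, y, 3)
        assert np.allclose(m.predict(X, n_factors=0), m.y_mean)

    def test_early_halt_on_exhausted_rank(self):
        rng = np.random.default_rng(8)
        t = rng.normal(size=30)
        X = np.outer(t, rng.normal(size=10))  # rank 1
        y = 2 * t + 1
        m = fit_xy(X, y, 5)
        assert m.n_factors == 1
        assert np.allclose(m.predict(X), y, atol=1e-8)

    def test_band_mismatch_rejected(self):
        m = fit_xy(*_xy(20, 5, seed=9), 2)
        with pytest.raises(ValueError, match="bands"):
            m.predict(np.ones((3, 7)))

    def test_constant_y_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            fit_xy(np.random.default_rng(0).normal(size=(10, 3)), np.ones(10), 2)


def _xy(n, p, seed, noise=0.2):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = X @ rng.normal(size=p) + rng.normal(0, noise, n)
    return X, y


class TestCrossValidate:
    def test_noiseless_rank_one_optimal_at_one_factor(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=25)
        X = np.outer(t, rng.uniform(0.5, 1.5, size=12))
        y = 3 * t + 2
        cv = cross_validate((X, y), max_factors=5, scheme="loo")
        assert cv.optimal_factors == 1
        assert cv.rmsecv[0] < 1e-8

    def test_recovers_planted_latent_rank(self):
        hits = sum(
            cross_validate(cs.generate_latent_data(seed=s), 10, "loo").optimal_factors == 3
            for s in range(10)
        )
        assert hits >= 8

    def test_loo_performs_n_fits(self):
        t = _random_table(17, 6, 0)
        cv = cross_validate(t, max_factors=3, scheme="loo")
        assert cv.n_fits == 17

    def test_kfold_reproducible_bitwise(self):
        t = _random_table(40, 10, 1)
        a = cross_validate(t, 6, "kfold", k=5, seed=11)
        b = cross_validate(t, 6, "kfold", k=5, seed=11)
        assert np.array_equal(a.rmsecv, b.rmsecv)
        assert a.optimal_factors == b.optimal_factors

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            cross_validate(_random_table(2, 3, 0), 2, "loo")

    def test_factor_cap_at_twenty(self):
        t = _random_table(100, 50, 2)
        cv = cross_validate(t, max_factors=50)
        assert len(cv.rmsecv) == 20


class TestEvaluate:
    def test_perfect_prediction(self):
        m = evaluate([1, 2, 3], [1, 2, 3])
        assert m.r2 == pytest.approx(1.0)
        assert m.rmse == 0.0

    def test_mean_prediction_gives_zero_r2(self):
        y = np.array([1.0, 2.0, 3.0])
        m = evaluate(y, np.full(3, 2.0))
        assert m.r2 == pytest.approx(0.0)

    def test_hand_computed_rmse(self):
        m = evaluate([1, 2, 3], [1, 2, 4])
        assert m.rmse == pytest.approx(np.sqrt(1 / 3))

    def test_r2_rmse_consistency(self):
        """RMSE^2 = (1 - R^2) * population variance of y."""
        rng = np.random.default_rng(3)
        y = rng.normal(size=50)
        yh = y + rng.normal(0, 0.5, 50)
        m = evaluate(y, yh)
        assert m.rmse**2 == pytest.approx((1 - m.r2) * y.var())

    def test_zero_variance_y_warns_and_reports_missing(self):
        with pytest.warns(UserWarning, match="undefined"):
            m = evaluate([2, 2, 2], [1, 2, 3])
        assert m.r2 is None
        assert m.rmse > 0
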