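import numpy as np
import pandas as pd
import pytest

from craterspec import (
    SpectrumSet,
    evaluate,
    fit_curve,
    fit_lssvm,
    fit_mlr,
    fit_plsr,
    fit_rf,
    lod_loq,
    pca_scores,
    r2,
    rmse,
)
from craterspec.calib_models import lod_loq_from_sigma
from craterspec.errors import ModelError


class TestMetrics:
    def test_r2_identities(self, rng):
        y = rng.uniform(0, 70, 30)
        assert r2(y, y) == pytest.approx(1.0)
        assert r2(y, np.full_like(y, y.mean())) == pytest.approx(0.0, abs=1e-12)
        assert r2(np.array([0.0, 1.0, 2.0]), np.array([0.0, 1.0, 3.0])) == pytest.approx(0.5)

    def test_rmse_examples_and_oracle(self, rng):
        assert rmse(np.array([0.0, 2.0]), np.array([1.0, 1.0])) == pytest.approx(1.0)
        y, yhat = rng.normal(size=50), rng.normal(size=50)
        naive = np.sqrt(sum((a - b) ** 2 for a, b in zip(y, yhat)) / 50)
        assert rmse(y, yhat) == pytest.approx(naive, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ModelError):
            r2(np.ones(5), np.ones(5))
        with pytest.raises(ModelError):
            rmse(np.array([]), np.array([]))


class TestCurve:
    def test_exact_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        m = fit_curve(x, 3.0 * x + 1.0)
        assert m.slope == pytest.approx(3.0)
        assert m.intercept == pytest.approx(1.0)

    def test_r2_equals_squared_pearson(self, rng):
        x = rng.uniform(0, 10, 40)
        y = 2.0 * x + rng.normal(size=40)
        m = fit_curve(x, y)
        rho = np.corrcoef(x, y)[0, 1]
        assert r2(y, m.predict(x)) == pytest.approx(rho**2, abs=1e-12)

    def test_matches_normal_equations(self, rng):
        x = rng.uniform(0, 10, 25)
        y = 1.7 * x + 0.4 + rng.normal(scale=0.3, size=25)
        m = fit_curve(x, y)
        A = np.column_stack([np.ones(25), x])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        assert m.intercept == pytest.approx(beta[0], abs=1e-10)
        assert m.slope == pytest.approx(beta[1], abs=1e-10)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ModelError):
            fit_curve(np.ones(5), np.arange(5.0))


class TestMultivariate:
    def test_mlr_matches_lstsq(self, rng):
        X = rng.normal(size=(30, 4))
        y = X @ np.array([1.0, -2.0, 0.5, 3.0]) + 1.0 + rng.normal(scale=0.1, size=30)
        m = fit_mlr(pd.DataFrame(X, columns=list("abcd")), y)
        A = np.column_stack([np.ones(30), X])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        assert m.intercept == pytest.approx(beta[0], abs=1e-10)
        np.testing.assert_allclose(m.coefficients, beta[1:], atol=1e-10)

    def test_plsr_full_components_equals_ols(self, rng):
        X = rng.normal(size=(25, 4))
        y = X @ np.array([2.0, -1.0, 0.3, 1.5]) + rng.normal(scale=0.2, size=25)
        pls = fit_plsr(X, y, n_components=4)
        ols = fit_mlr(X, y)
        np.testing.assert_allclose(pls.predict(X), ols.predict(X), rtol=1e-6)

    def test_plsr_cv_selects_components(self, rng):
        X = rng.normal(size=(40, 6))
        y = X[:, 0] * 2.0 + rng.normal(scale=0.1, size=40)
        m = fit_plsr(X, y, cv=5, seed=0)
        assert 1 <= m.n_components <= 6
        assert len(m.cv_rmse_path) >= m.n_components

    def test_rf_is_seed_deterministic(self, rng):
        X = rng.normal(size=(30, 3))
        y = rng.normal(size=30)
        a = fit_rf(X, y, n_trees=50, seed=7)
        b = fit_rf(X, y, n_trees=50, seed=7)
        np.testing.assert_array_equal(a.predict(X), b.predict(X))


class TestLssvm:
    def test_dual_system_residual(self, rng):
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        m = fit_lssvm(X, y, gamma=10.0, sigma=1.0)
        K = m._kernel(m.X_train, m.X_train)
        n = len(y)
        A = np.block([
            [np.zeros((1, 1)), np.ones((1, n))],
            [np.ones((n, 1)), K + np.eye(n) / m.gamma],
        ])
        resid = A @ np.concatenate([[m.bias], m.alpha]) - np.concatenate([[0.0], y])
        assert np.linalg.norm(resid) < 1e-8

    def test_linear_kernel_high_gamma_approaches_ols(self, rng):
        X = rng.normal(size=(20, 2))
        y = X @ np.array([1.5, -0.7]) + 0.3 + rng.normal(scale=0.1, size=20)
        ls = fit_lssvm(X, y, gamma=1e8, kernel="linear")
        ols = fit_mlr(X, y)
        np.testing.assert_allclose(ls.predict(X), ols.predict(X), rtol=1e-3)

    def test_cv_grid_is_seeded(self, rng):
        X = rng.normal(size=(30, 3))
        y = X[:, 0] + rng.normal(scale=0.1, size=30)
        a = fit_lssvm(X, y, seed=3)
        b = fit_lssvm(X, y, seed=3)
        assert (a.gamma, a.sigma) == (b.gamma, b.sigma)
        np.testing.assert_array_equal(a.predict(X), b.predict(X))


class TestDetectionLimits:
    def test_forced_three_sigma_rule(self):
        lod, loq = lod_loq_from_sigma(slope=2.0, sigma=1.0)
        assert (lod, loq) == (1.5, 5.0)

    def test_noiseless_curve_has_zero_limits(self):
        y = np.linspace(0, 70, 10)
        x = 4.0 * y + 2.0  # exact intensity response
        m = fit_curve(x, y)
        lod, loq = lod_loq(m)
        assert lod == pytest.approx(0.0, abs=1e-10)
        assert loq == pytest.approx(0.0, abs=1e-10)

    def test_loq_lod_ratio(self, rng):
        y = np.linspace(0, 70, 20)
        x = 4.0 * y + rng.normal(scale=2.0, size=20)
        m = fit_curve(x, y)
        lod, loq = lod_loq(m)
        assert loq / lod == pytest.approx(10.0 / 3.0, rel=1e-12)
        lod_c, loq_c = lod_loq(m, sigma_space="concentration")
        assert loq_c / lod_c == pytest.approx(10.0 / 3.0, rel=1e-12)

    def test_negative_slope_rejected(self, rng):
        y = np.linspace(0, 70, 20)
        x = -4.0 * y + rng.normal(scale=1.0, size=20)
        m = fit_curve(x, y)
        with pytest.raises(ModelError):
            lod_loq(m)


class TestEvaluate:
    def test_noiseless_report(self):
        y = np.linspace(0, 70, 12)
        x = 4.0 * y + 2.0
        m = fit_curve(x, y)
        rep = evaluate(m, (x, y), (x, y))
        assert rep.Rc2 == pytest.approx(1.0)
        assert rep.Rp2 == pytest.approx(1.0)
        assert rep.RMSEC == pytest.approx(0.0, abs=1e-10)
        assert rep.LOD == pytest.approx(0.0, abs=1e-10)

    def test_report_matches_direct_metric_calls(self, rng):
        X = rng.normal(size=(30, 3))
        y = X[:, 0] + rng.normal(scale=0.2, size=30)
        Xp = rng.normal(size=(10, 3))
        yp = Xp[:, 0] + rng.normal(scale=0.2, size=10)
        m = fit_mlr(X, y)
        rep = evaluate(m, (X, y), (Xp, yp))
        assert rep.Rc2 == pytest.approx(r2(y, m.predict(X)))
        assert rep.RMSEP == pytest.approx(rmse(yp, m.predict(Xp)))
        assert rep.LOD is None

    def test_feature_name_mismatch_rejected(self, rng):
        F = pd.DataFrame(rng.normal(size=(20, 2)), columns=["a", "b"])
        y = F["a"].to_numpy() + rng.normal(size=20)
        m = fit_mlr(F, y)
        bad = F.rename(columns={"b": "c"})
        with pytest.raises(ModelError):
            m.predict(bad)


class TestPca:
    def test_rank_one_data(self):
        wl = 210.0 + 0.02 * np.arange(20)
        t = np.array([1.0, 2.0, 3.0, 4.0])
        X = 5.0 + np.outer(t, np.linspace(1, 2, 20))
        ss = SpectrumSet(X, wl, list("abcd"))
        scores, frac = pca_scores(ss, 2)
        assert frac[0] == pytest.approx(1.0)
        assert scores.shape == (4, 2)

    def test_fractions_descend(self, benchmark):
        _, frac = pca_scores(benchmark.spectra, 5)
        assert np.all(np.diff(frac) <= 1e-12)
        assert frac.sum() <= 1.0 + 1e-12

    def test_scores_cluster_by_brand_not_level(self, benchmark):
        from sklearn.metrics import silhouette_score

        scores, _ = pca_scores(benchmark.spectra, 3)
        sil_brand = silhouette_score(scores, benchmark.brand)
        sil_level = silhouette_score(scores, [str(v) for v in benchmark.level_ug_g])
        assert sil_brand > sil_level

    def test_k_out_of_range(self, benchmark):
        with pytest.raises(ModelError):
            pca_scores(benchmark.spectra, benchmark.n + 1)
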