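"""The five GEBV prediction methods: closed forms, samplers, kernels, forest."""

import numpy as np
import pytest

from gsel.io import MarkerMatrix
from gsel.predictors import (
    BayesianLassoGEBV,
    BayesianRidgeGEBV,
    GBLUP,
    GibbsConfig,
    KernelRidgeGEBV,
    RandomForestGEBV,
    RidgeBLUP,
    center_markers,
    fit_predictor,
    gblup,
    predict,
    reml_variance_ratio,
)

SHORT = GibbsConfig(burn_in=1000, n_iter=5000, seed=7)


@pytest.fixture(scope="module")
def toy_Xy():
    rng = np.random.default_rng(42)
    X = rng.integers(0, 2, (60, 120)).astype(float)
    beta = rng.normal(0, 0.2, 120)
    g = X @ beta
    y = g + rng.normal(0, np.std(g), 60)
    return X, y


class TestCenterMarkers:
    def test_constant_column_zeroed(self):
        Xc, mu = center_markers(np.ones((3, 1)))
        assert (Xc == 0).all() and mu[0] == 1.0

    def test_half_half(self):
        Xc, _ = center_markers(np.array([[0.0], [1.0]]))
        np.testing.assert_allclose(Xc.ravel(), [-0.5, 0.5])

    def test_target_uses_training_means(self):
        # training frequency 0.75; a target line of zeros centers to -0.75
        X_train = np.array([[1.0], [1.0], [1.0], [0.0]])
        _, mu = center_markers(X_train)
        Xt, _ = center_markers(np.array([[0.0]]), means=mu)
        assert Xt[0, 0] == pytest.approx(-0.75)


class TestRidgeBLUP:
    def test_constant_y_no_signal(self):
        X = np.array([[0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
        r = RidgeBLUP(h2=0.5).fit(X, np.full(3, 2.5))
        np.testing.assert_allclose(r.marker_effects_, 0.0, atol=1e-12)
        np.testing.assert_allclose(r.predict(X), 2.5)

    def test_infinite_shrinkage(self, toy_Xy):
        X, y = toy_Xy
        r = RidgeBLUP(h2=1e-9).fit(X, y)
        assert np.abs(r.marker_effects_).max() < 1e-4

    def test_matches_explicit_inverse_on_toy(self):
        # independent oracle: solve the 2x2 normal equations by hand
        X = np.array([[0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
        y = np.array([1.0, 2.0, 4.0])
        Xc, _ = center_markers(X)
        yc = y - y.mean()
        lam = 1.0
        beta_expected = np.linalg.inv(Xc.T @ Xc + lam * np.eye(2)) @ Xc.T @ yc
        r = RidgeBLUP(lam=lam).fit(X, y)
        np.testing.assert_allclose(r.marker_effects_, beta_expected, atol=1e-12)

    def test_primal_dual_agree(self, toy_Xy):
        X, y = toy_Xy  # p > n exercises the dual path
        b_dual = RidgeBLUP(lam=5.0).fit(X, y).marker_effects_
        Xc, _ = center_markers(X)
        b_primal = np.linalg.solve(Xc.T @ Xc + 5.0 * np.eye(X.shape[1]), Xc.T @ (y - y.mean()))
        np.testing.assert_allclose(b_dual, b_primal, atol=1e-8)

    def test_invalid_h2(self, toy_Xy):
        X, y = toy_Xy
        with pytest.raises(ValueError, match="h2"):
            RidgeBLUP(h2=1.5).fit(X, y)

    @pytest.mark.parametrize("est", [RidgeBLUP(h2=0.5), GBLUP(delta=1.0), KernelRidgeGEBV()])
    def test_translation_equivariance(self, toy_Xy, est):
        from sklearn.base import clone

        X, y = toy_Xy
        p0 = clone(est).fit(X, y).predict(X)
        p1 = clone(est).fit(X, y + 3.25).predict(X)
        np.testing.assert_allclose(p1, p0 + 3.25, atol=1e-8)


class TestBayesianRidge:
    def test_deterministic_given_seed(self, toy_Xy):
        X, y = toy_Xy
        a = BayesianRidgeGEBV(config=SHORT).fit(X, y)
        b = BayesianRidgeGEBV(config=SHORT).fit(X, y)
        np.testing.assert_array_equal(a.marker_effects_, b.marker_effects_)

    def test_constant_y_effects_near_zero(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 2, (30, 40)).astype(float)
        b = BayesianRidgeGEBV(config=SHORT).fit(X, np.full(30, 3.0))
        assert np.abs(b.marker_effects_).max() < 0.05

    def test_matches_ridge_with_matched_lambda(self, toy_Xy):
        X, y = toy_Xy
        cfg = GibbsConfig(burn_in=2000, n_iter=30000, seed=3)
        b = BayesianRidgeGEBV(config=cfg).fit(X, y)
        lam = b.diagnostics_["sigma2_e_mean"] / b.diagnostics_["sigma2_beta_mean"]
        r = RidgeBLUP(lam=lam).fit(X, y)
        assert np.corrcoef(b.marker_effects_, r.marker_effects_)[0, 1] > 0.97

    def test_residual_variance_calibrated(self):
        # posterior mean of s2_e should sit within its own posterior spread
        # of the simulated residual variance on well-conditioned data
        rng = np.random.default_rng(9)
        X = rng.integers(0, 2, (150, 60)).astype(float)
        beta = rng.normal(0, 0.3, 60)
        sigma_e = 1.0
        y = X @ beta + rng.normal(0, sigma_e, 150)
        cfg = GibbsConfig(burn_in=2000, n_iter=20000, seed=5)
        b = BayesianRidgeGEBV(config=cfg).fit(X, y)
        post = b.sigma2_e_samples_
        assert abs(post.mean() - sigma_e**2) < 3 * post.std()

    def test_non_finite_y_rejected(self, toy_Xy):
        X, y = toy_Xy
        y = y.copy()
        y[0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            BayesianRidgeGEBV(config=SHORT).fit(X, y)


class TestBayesianLasso:
    def test_deterministic_given_seed(self, toy_Xy):
        X, y = toy_Xy
        a = BayesianLassoGEBV(config=SHORT).fit(X, y)
        b = BayesianLassoGEBV(config=SHORT).fit(X, y)
        np.testing.assert_array_equal(a.marker_effects_, b.marker_effects_)

    def test_constant_y_effects_near_zero(self):
        rng = np.random.default_rng(2)
        X = rng.integers(0, 2, (30, 40)).astype(float)
        b = BayesianLassoGEBV(config=SHORT).fit(X, np.full(30, 1.0))
        assert np.abs(b.marker_effects_).max() < 0.05

    def test_differential_shrinkage_on_sparse_truth(self):
        # 5 strong QTLs among 200 nulls: the LASSO prior shrinks null
        # markers harder than the common-variance Gaussian prior
        rng = np.random.default_rng(3)
        X = rng.integers(0, 2, (120, 205)).astype(float)
        beta = np.zeros(205)
        qtl = np.arange(5)
        beta[qtl] = rng.normal(0, 2.0, 5)
        y = X @ beta + rng.normal(0, 1.0, 120)
        cfg = GibbsConfig(burn_in=2000, n_iter=12000, seed=11)
        bl = BayesianLassoGEBV(config=cfg).fit(X, y)
        br = BayesianRidgeGEBV(config=cfg).fit(X, y)
        nulls = np.setdiff1d(np.arange(205), qtl)
        assert np.mean(np.abs(bl.marker_effects_[nulls])) < np.mean(
            np.abs(br.marker_effects_[nulls])
        )


class TestGBLUP:
    def test_identity_kinship_shrinks_toward_mean(self):
        rng = np.random.default_rng(4)
        y = rng.normal(0, 1, 25)
        pred, _ = gblup(np.eye(25), y, delta=1.0)
        np.testing.assert_allclose(pred, y.mean() + (y - y.mean()) / 2, atol=1e-10)

    def test_target_lines_get_mean_under_identity(self):
        rng = np.random.default_rng(5)
        y = rng.normal(0, 1, 10)
        K = np.eye(14)  # 10 training + 4 unrelated target lines
        pred, _ = gblup(K, y, train_idx=np.arange(10), delta=0.5)
        np.testing.assert_allclose(pred[10:], y.mean(), atol=1e-12)

    def test_dual_identity_with_ridge(self):
        rng = np.random.default_rng(6)
        X = rng.integers(0, 2, (20, 50)).astype(float)
        y = rng.normal(0, 1, 20)
        Xc, _ = center_markers(X)
        c, delta = 4.0, 1.7
        pred_k, _ = gblup(Xc @ Xc.T / c, y, delta=delta)
        pred_r = RidgeBLUP(lam=c * delta).fit(X, y).predict(X)
        assert np.max(np.abs(pred_k - pred_r)) < 1e-8

    def test_duplicated_line_strict_singularity(self):
        rng = np.random.default_rng(7)
        X = rng.integers(0, 2, (6, 30)).astype(float)
        X[5] = X[4]
        Xc, _ = center_markers(X)
        with pytest.raises(np.linalg.LinAlgError, match="singular"):
            gblup(Xc @ Xc.T / 5.0, rng.normal(0, 1, 6), delta=0.5, strict=True)
        with pytest.raises(np.linalg.LinAlgError, match="singular"):
            GBLUP(strict=True).fit(X, rng.normal(0, 1, 6))

    def test_reml_recovers_variance_ratio(self):
        # simulate g ~ N(0, s2_g K), e ~ N(0, s2_e I) with known ratio
        rng = np.random.default_rng(8)
        n = 250
        L = rng.normal(0, 1, (n, 40)) / np.sqrt(40)
        K = L @ L.T
        g = L @ rng.normal(0, 1, 40)
        delta_true = 2.0
        y = 1.0 + g + rng.normal(0, np.sqrt(delta_true), n)
        delta, s2g, s2e = reml_variance_ratio(K, y)
        assert delta == pytest.approx(delta_true, rel=0.5)

    def test_estimator_predicts_targets(self, toy_Xy):
        X, y = toy_Xy
        gb = GBLUP().fit(X[:50], y[:50])
        pred = gb.predict(X[50:])
        assert pred.shape == (10,) and np.isfinite(pred).all()


class TestKernelRidge:
    def test_flat_kernel_predicts_mean(self, toy_Xy):
        X, y = toy_Xy
        k = KernelRidgeGEBV(bandwidth=1e12).fit(X, y)
        np.testing.assert_allclose(k.predict(X), y.mean(), atol=1e-4)

    def test_zero_regularization_interpolates(self):
        rng = np.random.default_rng(10)
        X = rng.integers(0, 2, (10, 30)).astype(float)
        y = rng.normal(0, 1, 10)
        k = KernelRidgeGEBV(regularization=0.0).fit(X, y)
        np.testing.assert_allclose(k.predict(X), y, atol=1e-6)

    def test_invariant_to_marker_permutation(self, toy_Xy):
        X, y = toy_Xy
        perm = np.random.default_rng(11).permutation(X.shape[1])
        p0 = KernelRidgeGEBV().fit(X, y).predict(X)
        p1 = KernelRidgeGEBV().fit(X[:, perm], y).predict(X[:, perm])
        np.testing.assert_allclose(p0, p1, atol=1e-10)

    def test_negative_bandwidth_rejected(self, toy_Xy):
        X, y = toy_Xy
        with pytest.raises(ValueError, match="bandwidth"):
            KernelRidgeGEBV(bandwidth=-1.0).fit(X, y)


class TestRandomForest:
    def test_constant_y(self):
        rng = np.random.default_rng(12)
        X = rng.integers(0, 2, (30, 20)).astype(float)
        rf = RandomForestGEBV(n_trees=20, seed=1).fit(X, np.full(30, 4.2))
        np.testing.assert_allclose(rf.predict(X), 4.2)

    def test_deterministic_given_seed(self, toy_Xy):
        X, y = toy_Xy
        a = RandomForestGEBV(n_trees=30, seed=5).fit(X, y).predict(X)
        b = RandomForestGEBV(n_trees=30, seed=5).fit(X, y).predict(X)
        np.testing.assert_array_equal(a, b)

    def test_dominant_marker_captured(self):
        rng = np.random.default_rng(13)
        X = rng.integers(0, 2, (200, 50)).astype(float)
        y = 4.0 * X[:, 0] + rng.normal(0, 1.0, 200)
        rf = RandomForestGEBV(n_trees=100, seed=2).fit(X, y)
        r2 = np.corrcoef(rf.predict(X), y)[0, 1] ** 2
        assert r2 > 0.5

    def test_mtry_bounds(self, toy_Xy):
        X, y = toy_Xy
        with pytest.raises(ValueError, match="mtry"):
            RandomForestGEBV(mtry=X.shape[1] + 1).fit(X, y)


class TestMarkerMatrixAPI:
    def _pop(self, G, pop="p"):
        return MarkerMatrix(
            [f"{pop}{i}" for i in range(G.shape[0])],
            [f"m{j}" for j in range(G.shape[1])],
            G,
            population_id=pop,
        )

    def test_predict_on_training_equals_fitted(self, toy_Xy):
        X, y = toy_Xy
        m = self._pop(X)
        fp = fit_predictor("RIDGE", m, y, h2=0.5)
        np.testing.assert_allclose(predict(fp, m), fp.estimator.predict(X))

    def test_marker_mismatch_reported(self, toy_Xy):
        X, y = toy_Xy
        m = self._pop(X)
        fp = fit_predictor("RIDGE", m, y, h2=0.5)
        other = MarkerMatrix(m.line_ids, [f"q{j}" for j in range(X.shape[1])], X)
        with pytest.raises(ValueError, match="mismatch"):
            predict(fp, other)

    def test_linear_prediction_is_dot_product(self):
        # arithmetic oracle on a 2-marker toy
        X = np.array([[0.0, 1.0], [1.0, 0.0], [1.0, 1.0], [0.0, 0.0]])
        y = np.array([1.0, 2.0, 3.0, 0.0])
        m = self._pop(X)
        fp = fit_predictor("RIDGE", m, y, lam=1.0)
        est = fp.estimator
        target = np.array([[1.0, 1.0]])
        expected = est.intercept_ + (target - est.column_means_) @ est.marker_effects_
        got = predict(fp, self._pop(target, pop="t"))
        np.testing.assert_allclose(got, expected)

    def test_missing_values_rejected(self):
        G = np.array([[0.0, np.nan], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
        m = self._pop(G)
        with pytest.raises(ValueError, match="impute"):
            fit_predictor("RIDGE", m, np.arange(5.0))


class TestGibbsConfig:
    def test_defaults_follow_standard_settings(self):
        cfg = GibbsConfig()
        assert (cfg.S_eps, cfg.df_eps) == (4.5, 3.0)
        assert (cfg.S_beta, cfg.df_beta) == (0.009, 3.0)
        assert cfg.h2_lambda == 0.37
        assert (cfg.burn_in, cfg.n_iter) == (20_000, 60_000)

    @pytest.mark.parametrize(
        "kwargs", [dict(burn_in=100, n_iter=100), dict(S_eps=-1.0), dict(h2_lambda=1.2), dict(thin=0)]
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GibbsConfig(**kwargs)
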