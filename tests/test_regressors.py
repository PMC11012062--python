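import numpy as np
import pytest

from specfuse.crossval import MCCVConfig, kfold_indices
from specfuse.regressors import (ELMModel, PSOConfig, fit_elm, fit_lssvr,
                                 fit_plsr, fit_pso_elm, predict_plsr,
                                 rmsecv_by_lv, simpls_paths, tune_lssvr)


class TestPLSR:
    def test_single_informative_direction(self):
        """One latent variable suffices when only one direction carries y."""
        rng = np.random.default_rng(0)
        raw = rng.standard_normal((30, 6))
        Q, _ = np.linalg.qr(raw - raw.mean(axis=0))  # orthonormal, zero-mean
        X = Q * np.array([3.0, 2.0, 1.5, 1.0, 0.8, 0.5])
        y = 2.0 * X[:, 3]
        B, xm, ym, _ = simpls_paths(X, y, max_lvs=1)
        rmse_1lv = np.sqrt(np.mean(((X - xm) @ B[:, 0] + ym - y) ** 2))
        assert rmse_1lv < 1e-8
        model = fit_plsr(X, y, max_lvs=5, mccv=MCCVConfig(n_repeats=10, seed=1))
        assert np.sqrt(np.mean((model.predict(X) - y) ** 2)) < 1e-8

    def test_full_lv_matches_ols(self):
        """At full rank, PLSR predictions equal the normal-equations fit."""
        rng = np.random.default_rng(7)
        X = rng.standard_normal((20, 5))
        y = X @ rng.standard_normal(5) + 0.3 * rng.standard_normal(20)
        B, xm, ym, n_eff = simpls_paths(X, y, max_lvs=5)
        assert n_eff == 5
        Xc = X - xm
        beta = np.linalg.solve(Xc.T @ Xc, Xc.T @ (y - ym))
        pred_pls = Xc @ B[:, 4] + ym
        pred_ols = Xc @ beta + ym
        assert np.allclose(pred_pls, pred_ols, atol=1e-6)

    def test_matches_sklearn_reference(self):
        """Cross-check SIMPLS coefficients against the library NIPALS fit."""
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(3)
        X = rng.standard_normal((40, 12))
        y = X[:, :4] @ np.array([1.0, -0.5, 0.25, 2.0]) + 0.1 * rng.standard_normal(40)
        for ncomp in (1, 3, 5):
            B, xm, ym, _ = simpls_paths(X, y, max_lvs=ncomp)
            sk = PLSRegression(n_components=ncomp, scale=False).fit(X, y)
            pred_mine = (X - xm) @ B[:, ncomp - 1] + ym
            assert np.allclose(pred_mine, sk.predict(X).ravel(), atol=1e-6)

    def test_zero_variance_column_gets_zero_coefficient(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((25, 6))
        X[:, 2] = 1.0  # the all-ones reference column
        y = X[:, 0] - X[:, 4]
        B, *_ = simpls_paths(X, y, max_lvs=5)
        assert np.all(B[2] == 0)

    def test_permutation_invariance_with_sample_ids(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((24, 8))
        y = X[:, 1] + 0.2 * rng.standard_normal(24)
        ids = [f"s{i}" for i in range(24)]
        m1 = fit_plsr(X, y, max_lvs=6, mccv=MCCVConfig(n_repeats=10, seed=5),
                      sample_ids=ids)
        perm = rng.permutation(24)
        m2 = fit_plsr(X[perm], y[perm], max_lvs=6,
                      mccv=MCCVConfig(n_repeats=10, seed=5),
                      sample_ids=[ids[i] for i in perm])
        assert m1.n_lvs == m2.n_lvs
        assert np.allclose(m1.coef, m2.coef, atol=1e-12)

    def test_predict_contract(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((15, 4))
        y = X @ np.array([1.0, 2.0, -1.0, 0.5])
        model = fit_plsr(X, y, n_lvs=4)
        # calibration-mean input -> mean response
        assert np.allclose(predict_plsr(model, model.x_mean), model.y_mean)
        # affine linearity: centered responses add
        a, b = X[0], X[1]
        c0 = predict_plsr(model, np.zeros(4))
        lhs = predict_plsr(model, a + b) - c0
        rhs = (predict_plsr(model, a) - c0) + (predict_plsr(model, b) - c0)
        assert np.allclose(lhs, rhs, atol=1e-9)
        # hand arithmetic on one sample
        manual = (X[2] - model.x_mean) @ model.coef + model.y_mean
        assert np.allclose(predict_plsr(model, X[2]), manual)
        with pytest.raises(ValueError, match="wavelengths"):
            model.predict(np.zeros((1, 7)))

    def test_constant_y_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_plsr(np.random.default_rng(0).standard_normal((10, 3)),
                     np.ones(10))


class TestLSSVR:
    def test_dual_system_residual(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((20, 3))
        y = rng.standard_normal(20)
        m = fit_lssvr(X, y, gamma=10.0, sigma2=2.0)
        n = X.shape[0]
        from specfuse.regressors import _rbf_kernel
        M = np.zeros((n + 1, n + 1))
        M[0, 1:] = 1; M[1:, 0] = 1
        M[1:, 1:] = _rbf_kernel(X, X, 2.0) + np.eye(n) / 10.0
        sol = np.concatenate([[m.bias], m.alphas])
        rhs = np.concatenate([[0.0], y])
        assert np.linalg.norm(M @ sol - rhs) <= 1e-6 * np.linalg.norm(y)

    def test_interpolation_limit(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((5, 2))
        y = rng.standard_normal(5)
        m = fit_lssvr(X, y, gamma=1e10, sigma2=1.0)
        assert np.max(np.abs(m.predict(X) - y)) < 1e-4

    def test_flat_kernel_limit(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((12, 2))
        y = rng.uniform(5, 7, size=12)
        m = fit_lssvr(X, y, gamma=1.0, sigma2=1e9)
        assert np.max(np.abs(m.predict(X) - y.mean())) < 0.1

    def test_duplicated_point_consistent(self):
        """In the interpolation regime a consistent duplicate is inert.

        (At finite regularization the duplicate doubles that sample's loss
        weight, so exact equality only holds as gamma grows.)
        """
        rng = np.random.default_rng(8)
        X = rng.standard_normal((10, 2))
        y = rng.standard_normal(10)
        Xd = np.vstack([X, X[0]])
        yd = np.concatenate([y, [y[0]]])
        m1 = fit_lssvr(X, y, gamma=1e8, sigma2=1.5)
        m2 = fit_lssvr(Xd, yd, gamma=1e8, sigma2=1.5)
        grid = rng.standard_normal((20, 2))
        assert np.allclose(m1.predict(grid), m2.predict(grid), atol=1e-4)


class TestTuneLSSVR:
    def test_sine_fit_and_argmin_property(self):
        X = np.linspace(0, 2 * np.pi, 40)[:, None]
        y = np.sin(X).ravel()
        g, s2 = tune_lssvr(X, y, cv_folds=10, seed=1)
        m = fit_lssvr(X, y, g, s2)
        assert np.sqrt(np.mean((m.predict(X) - y) ** 2)) < 0.05

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((30, 3))
        y = X[:, 0] + 0.1 * rng.standard_normal(30)
        assert tune_lssvr(X, y, seed=4, cv_folds=5) == \
            tune_lssvr(X, y, seed=4, cv_folds=5)

    def test_degenerate_X_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            tune_lssvr(np.ones((12, 3)), np.arange(12.0), cv_folds=3)


class TestELM:
    def test_least_squares_orthogonality(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((40, 5))
        y = rng.standard_normal(40)
        m = fit_elm(X, y, hidden_nodes=12, seed=3)
        H = m.hidden(X)
        resid = H.T @ (H @ m.output_weights - y)
        assert np.max(np.abs(resid)) <= 1e-6

    def test_beats_or_matches_ols_on_linear_data(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((60, 4))
        y = X @ np.array([1.0, -1.0, 0.5, 2.0]) + 0.05 * rng.standard_normal(60)
        m = fit_elm(X, y, hidden_nodes=40, seed=1)
        rmse_elm = np.sqrt(np.mean((m.predict(X) - y) ** 2))
        design = np.column_stack([X, np.ones(60)])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        rmse_ols = np.sqrt(np.mean((design @ beta - y) ** 2))
        assert rmse_elm <= rmse_ols + 1e-6

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((20, 3))
        y = rng.standard_normal(20)
        m1 = fit_elm(X, y, 8, seed=5)
        m2 = fit_elm(X, y, 8, seed=5)
        assert np.array_equal(m1.input_weights, m2.input_weights)
        assert np.array_equal(m1.output_weights, m2.output_weights)


@pytest.fixture(scope="module")
def pso_fitted():
    rng = np.random.default_rng(12)
    X = rng.standard_normal((50, 4))
    y = np.tanh(X[:, 0]) + 0.5 * X[:, 1] ** 2 + 0.05 * rng.standard_normal(50)
    pso = PSOConfig(swarm_size=12, n_iterations=20, seed=7)
    return X, y, pso, fit_pso_elm(X, y, hidden_nodes=8, pso=pso)


class TestPSOELM:

    def test_gbest_monotone_nonincreasing(self, pso_fitted):
        *_, model = pso_fitted
        assert np.all(np.diff(model.pso_history) <= 0)

    def test_improves_on_unoptimized_elm(self, pso_fitted):
        """CV fitness of the swarm optimum never exceeds the plain ELM's."""
        X, y, pso, model = pso_fitted
        from specfuse.crossval import derive_seed
        folds = list(kfold_indices(50, 5, seed=derive_seed(pso.seed, "pso-folds")))
        elm = fit_elm(X, y, hidden_nodes=8, seed=pso.seed)
        H = elm.hidden(X)
        sse = cnt = 0
        for train, val in folds:
            beta, *_ = np.linalg.lstsq(H[train], y[train], rcond=None)
            e = H[val] @ beta - y[val]
            sse += e @ e
            cnt += val.size
        assert model.pso_history[-1] <= np.sqrt(sse / cnt) + 1e-12

    def test_deterministic_given_seed(self, pso_fitted):
        X, y, pso, model = pso_fitted
        again = fit_pso_elm(X, y, hidden_nodes=8, pso=pso)
        assert np.array_equal(model.output_weights, again.output_weights)
        assert np.array_equal(model.pso_history, again.pso_history)


def test_rmsecv_pools_heldout_errors():
    """RMSECV equals the pooled root mean square over held-out folds."""
    rng = np.random.default_rng(13)
    X = rng.standard_normal((18, 4))
    y = X[:, 0] + 0.1 * rng.standard_normal(18)
    folds = list(kfold_indices(18, 3, seed=0))
    rms = rmsecv_by_lv(X, y, folds, max_lvs=2)
    sse = np.zeros(2)
    for train, val in folds:
        for lv in (1, 2):
            B, xm, ym, _ = simpls_paths(X[train], y[train], lv)
            e = (X[val] - xm) @ B[:, lv - 1] + ym - y[val]
            sse[lv - 1] += e @ e
    assert np.allclose(rms, np.sqrt(sse / 18), atol=1e-12)
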