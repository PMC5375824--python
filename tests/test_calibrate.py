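import numpy as np
import pytest

from leafnir import (fit_bpnn, fit_pcr, fit_plsr, fit_smlr, loo_cv_curve,
                     predict)
from leafnir.calibrate import RegressionModel, _nipals_pls1


def ols_fitted(X, y):
    A = np.hstack([np.ones((X.shape[0], 1)), X])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return A @ coef


class TestPCR:
    def test_full_components_equals_ols(self, rng):
        X = rng.normal(size=(20, 5))
        y = rng.normal(size=20)
        m = fit_pcr(X, y, 5)
        assert np.allclose(predict(m, X), ols_fitted(X, y), atol=1e-8)

    def test_constant_y(self, rng):
        X = rng.normal(size=(15, 4))
        m = fit_pcr(X, np.full(15, 24.0), 3)
        assert np.allclose(m.coefficients, 0.0, atol=1e-10)
        assert m.intercept == pytest.approx(24.0)

    def test_matches_eigendecomposition_oracle(self, rng):
        # independent oracle: covariance eigenvectors + least squares on scores
        X = rng.normal(size=(30, 40))
        y = rng.normal(size=30)
        k = 3
        Xc = X - X.mean(0)
        yc = y - y.mean()
        evals, evecs = np.linalg.eigh(Xc.T @ Xc)
        V = evecs[:, np.argsort(evals)[::-1][:k]]
        T = Xc @ V
        g, *_ = np.linalg.lstsq(T, yc, rcond=None)
        beta = V @ g
        m = fit_pcr(X, y, k)
        # eigenvector signs are arbitrary; compare folded-back coefficients
        assert np.allclose(m.coefficients, beta, atol=1e-8)

    def test_rank_deficiency_rejected(self, rng):
        X = np.tile(rng.normal(size=(10, 1)), (1, 6))
        with pytest.raises(ValueError, match="rank"):
            fit_pcr(X, rng.normal(size=10), 3)


class TestPLSR:
    def test_first_weight_is_xty_direction(self, rng):
        X = rng.normal(size=(25, 30))
        y = rng.normal(size=25)
        Xc = X - X.mean(0)
        yc = y - y.mean()
        W, _, _ = _nipals_pls1(Xc, yc, 1)
        w_ref = Xc.T @ yc
        w_ref /= np.linalg.norm(w_ref)
        assert np.allclose(np.abs(W[:, 0] @ w_ref), 1.0, atol=1e-10)

    def test_noiseless_rank3_target_recovered(self, rng):
        basis = rng.normal(size=(3, 50))
        scores = rng.normal(size=(30, 3))
        X = scores @ basis
        y = scores @ np.array([1.0, -2.0, 0.5])
        m = fit_plsr(X, y, max_factors=8)
        assert m.meta["n_factors"] <= 3
        assert np.sqrt(np.mean((predict(m, X) - y) ** 2)) < 1e-6

    def test_full_factors_equals_ols_on_full_rank(self, rng):
        X = rng.normal(size=(30, 6))
        y = rng.normal(size=30)
        m = fit_plsr(X, y, n_factors=6)
        assert np.allclose(predict(m, X), ols_fitted(X, y), atol=1e-6)

    def test_matches_reference_implementation_per_factor(self, rng):
        # cross-check against an established PLS implementation
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.normal(size=(40, 200))
        y = X[:, :5] @ rng.normal(size=5) + 0.1 * rng.normal(size=40)
        for a in range(1, 11):
            mine = predict(fit_plsr(X, y, n_factors=a), X)
            ref = sklearn.PLSRegression(n_components=a, scale=False).fit(X, y)
            assert np.allclose(mine, ref.predict(X).ravel(), atol=1e-6), a

    def test_serialization_round_trip(self, tmp_path, rng):
        X = rng.normal(size=(20, 12))
        y = rng.normal(size=20)
        m = fit_plsr(X, y, n_factors=3)
        p = tmp_path / "m.json"
        m.to_json(p)
        back = RegressionModel.from_json(p)
        assert np.allclose(predict(back, X), predict(m, X), atol=1e-12)


class TestLOOCurve:
    def test_equals_brute_force_refits(self, rng):
        X = rng.normal(size=(12, 6))
        y = rng.normal(size=12)
        curve = loo_cv_curve(X, y, 4)
        brute = np.zeros((12, 4))
        for i in range(12):
            keep = np.arange(12) != i
            for a in range(1, 5):
                m = fit_plsr(X[keep], y[keep], n_factors=a)
                brute[i, a - 1] = (predict(m, X[i:i + 1])[0] - y[i]) ** 2
        assert np.allclose(curve, np.sqrt(brute.mean(0)), atol=1e-8)

    def test_compression_is_exact_for_wide_problems(self, rng):
        # p >> n exercises the SVD-compressed path against direct refits
        X = rng.normal(size=(10, 80))
        y = rng.normal(size=10)
        curve = loo_cv_curve(X, y, 3)
        brute = np.zeros((10, 3))
        for i in range(10):
            keep = np.arange(10) != i
            for a in range(1, 4):
                m = fit_plsr(X[keep], y[keep], n_factors=a)
                brute[i, a - 1] = (predict(m, X[i:i + 1])[0] - y[i]) ** 2
        assert np.allclose(curve, np.sqrt(brute.mean(0)), atol=1e-8)

    def test_pure_noise_curve_rises_after_first_factor(self):
        # Monte Carlo: overfitting grows with factors when y is noise
        diffs = []
        for rep in range(50):
            r = np.random.default_rng(rep)
            X = r.normal(size=(20, 30))
            y = r.normal(size=20)
            c = loo_cv_curve(X, y, 8)
            diffs.append(c[7] - c[0])
        assert np.mean(diffs) > 0


class TestSMLR:
    def test_constant_y_selects_nothing(self, rng):
        X = rng.normal(size=(30, 20))
        m = fit_smlr(X, np.full(30, 25.0), max_terms=5)
        assert m.meta["n_terms"] == 0
        assert np.allclose(predict(m, X), 25.0)

    def test_single_band_reduces_to_simple_regression(self, rng):
        X = rng.normal(size=(30, 1))
        y = 2.0 * X[:, 0] + rng.normal(scale=0.1, size=30)
        m = fit_smlr(X, y, p_enter=0.05, max_terms=3)
        assert m.meta["n_terms"] == 1
        y_null = rng.normal(size=30)  # unrelated target: band should not enter
        m2 = fit_smlr(X, y_null, p_enter=1e-6, max_terms=3)
        assert m2.meta["n_terms"] == 0

    def test_collinear_candidates_skipped(self, rng):
        x = rng.normal(size=30)
        X = np.column_stack([x, x, rng.normal(size=30)])
        y = x + 0.01 * rng.normal(size=30)
        m = fit_smlr(X, y, max_terms=3)
        sel = m.meta["selected_wavelengths_nm"]
        assert not (0.0 in sel and 1.0 in sel)  # duplicated band enters once


class TestBPNN:
    def test_linear_target_learned(self, rng):
        basis = rng.normal(size=(3, 30))
        scores = rng.normal(size=(80, 3))
        X = scores @ basis + 0.001 * rng.normal(size=(80, 30))
        y = scores @ np.array([2.0, -1.0, 0.5]) + 25.0
        m = fit_bpnn(X, y, variance_target=0.95, hidden_sizes=(2,), n_restarts=10,
                     train_params={"max_iterations": 3000}, rng=rng)
        rmse = np.sqrt(np.mean((predict(m, X) - y) ** 2))
        assert rmse < 0.05 * y.std()

    def test_zero_iterations_is_deterministic_initial_net(self, rng):
        X = rng.normal(size=(30, 10))
        y = rng.normal(size=30)
        kw = dict(variance_target=0.9, hidden_sizes=(4,), n_restarts=2,
                  train_params={"max_iterations": 0})
        m1 = fit_bpnn(X, y, rng=np.random.default_rng(3), **kw)
        m2 = fit_bpnn(X, y, rng=np.random.default_rng(3), **kw)
        assert np.allclose(predict(m1, X), predict(m2, X), atol=1e-12)

    def test_pc_count_honours_variance_target(self, rng):
        basis = rng.normal(size=(5, 40))
        X = rng.normal(size=(60, 5)) @ basis + 0.01 * rng.normal(size=(60, 40))
        m = fit_bpnn(X, rng.normal(size=60), variance_target=0.99,
                     hidden_sizes=(2,), n_restarts=1,
                     train_params={"max_iterations": 1}, rng=rng)
        assert m.meta["n_components"] <= 6
        assert m.meta["variance_captured"] >= 0.99


class TestPredict:
    def test_grid_mismatch_rejected(self, rng):
        X = rng.normal(size=(20, 5))
        m = fit_pcr(X, rng.normal(size=20), 2)
        with pytest.raises(ValueError, match="grid mismatch"):
            predict(m, rng.normal(size=(3, 7)))

    def test_zero_coefficient_model_is_constant(self):
        m = RegressionModel(method="PCR", wavelengths=np.arange(4.0),
                            intercept=25.0, coefficients=np.zeros(4))
        assert np.allclose(predict(m, np.eye(4)), 25.0)
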