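import warnings

import numpy as np
import pytest

import respigate as rg
from respigate.exceptions import ConvergenceWarning, InputError, ParameterError
from respigate.predictors import (AdaptiveLinearPredictor, ConstantVelocityKF,
                                  admm_lasso, dummy_pair, fit_l2l1, fit_ols,
                                  fit_ridge, kalman_predict, lasso_lambda_max)


class TestOLS:
    def test_single_column_slope(self):
        beta = fit_ols(np.array([[1.0], [2.0], [3.0]]), [2.0, 4.0, 6.0])
        assert beta == pytest.approx([2.0])

    def test_exact_interpolation_of_noiseless_labels(self, rng):
        X = rng.normal(size=(40, 15))
        beta_true = rng.normal(size=15)
        beta = fit_ols(X, X @ beta_true)
        assert np.max(np.abs(beta - beta_true)) < 1e-8

    def test_matches_normal_equations_oracle(self, rng):
        X = rng.normal(size=(50, 15))
        y = rng.normal(size=50)
        oracle = np.linalg.inv(X.T @ X) @ X.T @ y
        assert np.max(np.abs(fit_ols(X, y) - oracle)) < 1e-8

    def test_rank_deficient_returns_minimum_norm(self, rng):
        X = np.tile(rng.normal(size=(30, 1)), (1, 4))  # rank 1
        y = rng.normal(size=30)
        beta = fit_ols(X, y)
        # minimum-norm solution spreads weight equally over tied columns
        assert np.allclose(beta, beta[0])

    def test_empty_raises(self):
        with pytest.raises(InputError):
            fit_ols(np.empty((0, 3)), [])


class TestRidge:
    def test_zero_lambda_reduces_to_ols(self, rng):
        X = rng.normal(size=(40, 8))
        y = rng.normal(size=40)
        beta, lam = fit_ridge(X, y, [0.0])
        assert lam == 0.0
        assert np.max(np.abs(beta - fit_ols(X, y))) < 1e-10

    def test_orthonormal_design_shrinks_by_1_plus_lambda(self, rng):
        q, _ = np.linalg.qr(rng.normal(size=(30, 5)))
        y = rng.normal(size=30)
        ols = fit_ols(q, y)
        lam = 0.7
        beta, _ = fit_ridge(q, y, [lam])
        assert np.allclose(beta, ols / (1 + lam), atol=1e-10)

    def test_loocv_matches_explicit_leave_one_out_refits(self, rng):
        X = rng.normal(size=(30, 5))
        y = rng.normal(size=30)
        grid = [0.01, 0.1, 1.0, 10.0]
        _, _, path = fit_ridge(X, y, grid, return_path=True)
        for g, lam in enumerate(grid):
            errs = []
            for i in range(30):
                keep = np.arange(30) != i
                Xi, yi = X[keep], y[keep]
                b = np.linalg.solve(Xi.T @ Xi + lam * np.eye(5), Xi.T @ yi)
                errs.append((y[i] - X[i] @ b) ** 2)
            assert abs(path[g] - np.mean(errs)) < 1e-8

    def test_coefficient_norm_non_increasing_in_lambda(self, rng):
        X = rng.normal(size=(40, 10))
        y = rng.normal(size=40)
        lams = np.logspace(-3, 3, 13)
        norms = [np.linalg.norm(fit_ridge(X, y, [lam])[0]) for lam in lams]
        assert np.all(np.diff(norms) <= 1e-12)

    def test_negative_lambda_raises(self, rng):
        with pytest.raises(ParameterError):
            fit_ridge(np.eye(3), np.ones(3), [-1.0])


def _ista_lasso(X, y, lam, iters=200_000, tol=1e-10):
    """Proximal-gradient oracle for ||y - Xb||^2 + lam ||b||_1."""
    L = 2.0 * np.linalg.eigvalsh(X.T @ X).max()
    step = 1.0 / L
    b = np.zeros(X.shape[1])
    for _ in range(iters):
        grad = 2.0 * X.T @ (X @ b - y)
        b_new = np.sign(b - step * grad) * np.maximum(
            np.abs(b - step * grad) - step * lam, 0.0)
        if np.max(np.abs(b_new - b)) < tol:
            return b_new
        b = b_new
    return b


class TestLasso:
    def test_zero_lambda_matches_ols(self, rng):
        X = rng.normal(size=(30, 6))
        y = rng.normal(size=30)
        assert np.max(np.abs(admm_lasso(X, y, 0.0) - fit_ols(X, y))) < 1e-6

    def test_lambda_at_or_above_lambda_max_gives_exact_zero(self, rng):
        X = rng.normal(size=(40, 10))
        y = rng.normal(size=40)
        lam_max = lasso_lambda_max(X, y)
        for lam in (lam_max, 1.5 * lam_max):
            beta = admm_lasso(X, y, lam)
            assert np.all(beta == 0.0)

    def test_matches_ista_oracle(self, rng):
        X = rng.normal(size=(40, 10))
        y = rng.normal(size=40)
        lam = 0.1 * lasso_lambda_max(X, y)
        ours = admm_lasso(X, y, lam, tol=1e-10, max_iter=20000)
        oracle = _ista_lasso(X, y, lam)
        assert np.max(np.abs(ours - oracle)) < 1e-5

    def test_l1_norm_non_increasing_in_lambda(self, rng):
        X = rng.normal(size=(50, 8))
        y = rng.normal(size=50)
        lams = np.linspace(0.01, 1.0, 8) * lasso_lambda_max(X, y)
        norms = [np.abs(admm_lasso(X, y, lam)).sum() for lam in lams]
        assert np.all(np.diff(norms) <= 1e-6)

    def test_non_convergence_warns_not_raises(self, rng):
        X = rng.normal(size=(30, 6))
        y = rng.normal(size=30)
        with pytest.warns(ConvergenceWarning):
            beta, info = admm_lasso(X, y, 0.05 * lasso_lambda_max(X, y),
                                    max_iter=2, return_info=True)
        assert not info["converged"]
        assert beta.shape == (6,)


class TestL2L1GCV:
    def test_single_zero_candidate_equals_ols(self, rng):
        X = rng.normal(size=(30, 6))
        y = rng.normal(size=30)
        beta, lam = fit_l2l1(X, y, [0.0])
        assert lam == 0.0
        assert np.max(np.abs(beta - fit_ols(X, y))) < 1e-6

    def test_gcv_values_match_direct_formula(self, rng):
        X = rng.normal(size=(40, 8))
        y = rng.normal(size=40)
        lam_max = lasso_lambda_max(X, y)
        grid = np.array([0.05, 0.2, 0.8]) * lam_max
        # recompute GCV per candidate and check the winner
        scores = []
        for lam in grid:
            b = admm_lasso(X, y, lam)
            df = int(np.count_nonzero(b))
            rss = float(np.sum((y - X @ b) ** 2))
            scores.append(40 * rss / (40 - df) ** 2)
        _, lam_sel = fit_l2l1(X, y, grid)
        assert lam_sel == pytest.approx(grid[int(np.argmin(scores))])

    def test_sparse_support_recovery(self):
        r = np.random.default_rng(77)
        X = r.normal(size=(200, 15))
        beta_true = np.zeros(15)
        beta_true[[2, 7, 11]] = [3.0, -2.0, 1.5]
        y = X @ beta_true + 0.01 * r.normal(size=200)
        beta, _ = fit_l2l1(X, y)
        support = set(np.flatnonzero(np.abs(beta) > 1e-6))
        assert {2, 7, 11} <= support


class TestPredictPair:
    def test_persistence_beta_returns_last_sample(self):
        m = 15
        e_last = np.zeros(m)
        e_last[-1] = 1.0
        model = rg.PredictorModel(e_last, e_last, m=m)
        x = np.arange(m, dtype=float)
        assert rg.predict_pair(model, x) == (x[-1], x[-1])

    def test_zero_window_gives_zero(self, rng):
        model = rg.PredictorModel(rng.normal(size=15), rng.normal(size=15))
        assert rg.predict_pair(model, np.zeros(15)) == (0.0, 0.0)

    def test_matches_manual_dot_product(self, rng):
        bp, bl, x = rng.normal(size=(3, 15))
        model = rg.PredictorModel(bp, bl)
        got = rg.predict_pair(model, x)
        want = (sum(b * v for b, v in zip(bp, x)),
                sum(b * v for b, v in zip(bl, x)))
        assert got[0] == pytest.approx(want[0], abs=1e-12)
        assert got[1] == pytest.approx(want[1], abs=1e-12)

    def test_length_mismatch_raises(self, rng):
        model = rg.PredictorModel(rng.normal(size=15), rng.normal(size=15))
        with pytest.raises(InputError):
            rg.predict_pair(model, np.zeros(10))

    def test_dummy_pair(self):
        assert dummy_pair([1.0, 2.0, 9.0]) == (9.0, 9.0)

    def test_model_json_round_trip(self, rng, tmp_path):
        model = rg.PredictorModel(rng.normal(size=15), rng.normal(size=15),
                                  horizon_j=2, lam=0.3, method="ridge",
                                  n_train=99)
        path = tmp_path / "model.json"
        model.save(path)
        back = rg.PredictorModel.load(path)
        assert np.array_equal(back.beta_prev, model.beta_prev)
        assert back.lam == model.lam and back.method == "ridge"
        assert back.horizon_j == 2 and back.n_train == 99


class TestAdaptivePredictor:
    def test_burn_in_emits_nothing_but_fits(self, liver_trace):
        ap = AdaptiveLinearPredictor(m=15, horizon_j=3, burn_in_samples=150)
        preds = [ap.step(t, v) for t, v in
                 zip(liver_trace.times[:150], liver_trace.si[:150])]
        assert all(p is None for p in preds)
        assert ap.model.beta_last is not None  # fitted at sample 150

    def test_refit_disabled_equals_static_burn_in_model(self, liver_trace):
        m, j, burn = 15, 3, 150
        ap = AdaptiveLinearPredictor(m=m, horizon_j=j, burn_in_samples=burn,
                                     refit_every=10**9)
        got = []
        for t, v in zip(liver_trace.times[:300], liver_trace.si[:300]):
            p = ap.step(t, v)
            if p is not None:
                got.append(p)
        # static model: fit on the pairs fully observed within the burn-in
        y = liver_trace.si
        n_pairs = burn - m - j + 1
        X = np.lib.stride_tricks.sliding_window_view(y[:n_pairs + m - 1], m)
        bp = fit_ols(X, y[m + j - 2:m + j - 2 + n_pairs])
        bl = fit_ols(X, y[m + j - 1:m + j - 1 + n_pairs])
        want = [(float(y[k - m + 1:k + 1] @ bp), float(y[k - m + 1:k + 1] @ bl))
                for k in range(burn, 300)]
        assert np.allclose(got, want, atol=1e-10)

    def test_stream_replay_equals_batch_refit_oracle(self, liver_trace):
        m, j, burn = 8, 3, 40
        ap = AdaptiveLinearPredictor(m=m, horizon_j=j, burn_in_samples=burn)
        y = liver_trace.si[:120]
        t = liver_trace.times[:120]
        for k in range(y.size):
            ap.step(t[k], y[k])
            if k + 1 < burn:
                continue
            # batch oracle: OLS on all windows of the prefix with J=j labels
            n_pairs = k + 1 - m - j + 1
            X = np.lib.stride_tricks.sliding_window_view(
                y[:n_pairs + m - 1], m)
            bl = fit_ols(X, y[m + j - 1:m + j - 1 + n_pairs])
            bp = fit_ols(X, y[m + j - 2:m + j - 2 + n_pairs])
            assert np.max(np.abs(ap._betas[j] - bl)) < 1e-8
            assert np.max(np.abs(ap._betas[j - 1] - bp)) < 1e-8

    def test_out_of_order_sample_raises(self):
        ap = AdaptiveLinearPredictor(m=3, horizon_j=2, burn_in_samples=10)
        ap.step(0.0, 1.0)
        with pytest.raises(InputError):
            ap.step(0.0, 2.0)


class TestKalman:
    def test_noiseless_ramp_extrapolates_linearly(self):
        t = np.arange(120) * 0.2
        y = 2.0 + 1.5 * t
        pred = kalman_predict(y, horizon=0.6, dt=0.2)
        assert pred == pytest.approx(y[-1] + 1.5 * 0.6, abs=1e-6)

    def test_constant_signal_predicts_constant(self):
        pred = kalman_predict(np.full(60, 7.0), horizon=0.6, dt=0.2)
        assert pred == pytest.approx(7.0, abs=1e-9)

    def test_matches_statsmodels_state_space_oracle(self, rng):
        from statsmodels.tsa.statespace.kalman_filter import KalmanFilter
        dt, q, r = 0.2, 1.0, 0.25
        t = np.arange(100) * dt
        y = 10 + 5 * np.sin(2 * np.pi * t / 4) + 0.1 * rng.normal(size=t.size)
        kf = KalmanFilter(k_endog=1, k_states=2, tolerance=0.0)
        kf["design"] = np.array([[1.0, 0.0]])
        kf["transition"] = np.array([[1.0, dt], [0.0, 1.0]])
        kf["selection"] = np.eye(2)
        kf["state_cov"] = q * np.array([[dt**3 / 3, dt**2 / 2],
                                        [dt**2 / 2, dt]])
        kf["obs_cov"] = np.array([[r]])
        kf.initialize_known(np.array([y[0], 0.0]), np.diag([r, 100.0]))
        kf.bind(y.reshape(-1, 1))
        oracle = kf.filter().filtered_state.T
        ours = ConstantVelocityKF(dt=dt, q=q, r=r).filter(y)
        assert np.max(np.abs(ours - oracle)) < 1e-9

    def test_too_few_samples_raises(self):
        with pytest.raises(InputError):
            kalman_predict([1.0], horizon=0.4)


class TestNoiselessRecursionExactness:
    def test_ols_mae_zero_on_held_out_windows(self, ar_trace):
        ws = rg.make_windows(ar_trace, "si", m=15, J=3)
        train, _, test = rg.split_windows(ws)
        for j in (2, 3):
            beta = fit_ols(train.inputs, train.horizon_labels(j))
            err = np.abs(test.inputs @ beta - test.horizon_labels(j))
            assert err.mean() < 1e-8
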