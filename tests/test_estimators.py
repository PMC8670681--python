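import numpy as np
import pytest

from mdqr import (CombinedEstimate, IndividualEstimate, ModelParams,
                  QuantileModelSpec, build_block_weights, combine_md,
                  compute_spatial_lag, confidence_intervals, estimate_Ji,
                  estimate_Si, estimate_Vi_iv, fit_iv_feqr, fit_iv_mdqr,
                  fit_mdqr, fit_qr, fit_unit_ivqr, fit_unit_qr,
                  generate_panel, make_instruments, quantile_process)
from mdqr.simulate import PanelData


def make_individual(theta, V, tau=0.5, unit_id=0, flagged=False):
    return IndividualEstimate(
        unit_id=unit_id, tau=tau, rho_hat=float(theta[0]),
        beta_hat=np.atleast_1d(theta[1:]), eta_hat=0.0,
        gamma_hat=np.zeros(1), gamma_profile=np.zeros((1, 1)),
        rho_grid=np.array([0.5]), V_hat=np.asarray(V, float), flagged=flagged)


class TestUnitQr:
    def test_noiseless_recovery(self):
        rng = np.random.default_rng(0)
        T = 40
        D = rng.normal(size=T)
        X = rng.normal(size=(T, 1))
        y = 0.5 * D + X[:, 0] + 2.0
        res = fit_unit_qr(y, D, X, 0.5)
        assert np.allclose(res.theta, [0.5, 1.0], atol=1e-7)
        assert res.eta == pytest.approx(2.0, abs=1e-7)
        assert not res.rank_deficient

    def test_zero_spatial_lag_collinear_with_intercept(self):
        rng = np.random.default_rng(1)
        T = 30
        X = rng.normal(size=(T, 1))
        y = X[:, 0] + rng.normal(size=T)
        res = fit_unit_qr(y, np.zeros(T), X, 0.5)
        assert res.rank_deficient


class TestUnitIvqr:
    def test_singleton_grid_returns_that_rho(self):
        rng = np.random.default_rng(2)
        T = 40
        D = rng.normal(size=T)
        X = rng.normal(size=(T, 1))
        om = rng.normal(size=(T, 1))
        y = 0.2 * D + X[:, 0] + rng.normal(size=T)
        spec = QuantileModelSpec(rho_grid=np.array([0.5]))
        est = fit_unit_ivqr(y, D, X, om, spec)
        assert est.rho_hat == 0.5

    def test_near_noiseless_data_selects_true_rho(self):
        # gamma profile has its exhaustive minimum at the generating rho
        rng = np.random.default_rng(3)
        T = 60
        D = rng.normal(size=T)
        X = rng.normal(size=(T, 1))
        om = (D + 0.3 * rng.normal(size=T))[:, None]   # relevant instrument
        y = 0.5 * D + X[:, 0] + 1.0 + 1e-3 * rng.normal(size=T)
        spec = QuantileModelSpec()
        est = fit_unit_ivqr(y, D, X, om, spec)
        assert est.rho_hat == pytest.approx(0.5, abs=1e-9)
        norms = np.abs(est.gamma_profile[:, 0])
        sel = np.where(est.rho_grid == 0.5)[0][0]
        assert np.argmin(norms) == sel

    def test_instrument_identical_to_covariate_rejected(self):
        rng = np.random.default_rng(4)
        T = 40
        D = rng.normal(size=T)
        X = rng.normal(size=(T, 1))
        y = D + X[:, 0] + rng.normal(size=T)
        with pytest.raises(ValueError, match="collinear"):
            fit_unit_ivqr(y, D, X, X.copy(), QuantileModelSpec())

    def test_rho_hat_always_on_grid(self, sim_panel, w20):
        panel, inst = sim_panel
        spec = QuantileModelSpec()
        D = compute_spatial_lag(panel, w20)
        est = fit_unit_ivqr(panel.y[0], D[0], panel.X[0], inst.omega[0], spec)
        assert est.rho_hat in spec.rho_grid


class TestMoments:
    def test_Si_orthonormal_columns(self):
        T = 8
        om = np.eye(T)[:, :1] * np.sqrt(T)   # unit sample second moment
        X = np.eye(T)[:, 1:2] * np.sqrt(T)
        S = estimate_Si(om, X, 0.5)
        assert np.allclose(S, 0.25 * np.eye(2))

    def test_Si_tau_factor_scales(self):
        rng = np.random.default_rng(5)
        om = rng.normal(size=(30, 1))
        X = rng.normal(size=(30, 2))
        S50 = estimate_Si(om, X, 0.5)
        S25 = estimate_Si(om, X, 0.25)
        assert np.allclose(S25, 0.75 * S50)

    def test_Si_brute_force_oracle(self):
        rng = np.random.default_rng(6)
        T = 17
        om = rng.normal(size=(T, 2))
        X = rng.normal(size=(T, 1))
        S = estimate_Si(om, X, 0.3)
        acc = np.zeros((3, 3))
        for t in range(T):
            xs = np.concatenate([om[t], X[t]])
            acc += np.outer(xs, xs)
        assert np.allclose(S, 0.3 * 0.7 * acc / T, atol=1e-12)

    def test_Ji_mean_density_near_standard_normal_at_zero(self):
        rng = np.random.default_rng(7)
        T = 20000
        resid = rng.standard_normal(T)
        om = rng.normal(size=(T, 1))
        X = rng.normal(size=(T, 1))
        D = rng.normal(size=T)
        _, diag = estimate_Ji(resid, om, D, X, 0.5)
        assert diag["mean_density"] == pytest.approx(0.3989, abs=0.01)

    def test_Ji_doubling_residuals_halves_density(self):
        rng = np.random.default_rng(8)
        T = 200
        resid = rng.standard_normal(T)
        om = rng.normal(size=(T, 1))
        X = rng.normal(size=(T, 1))
        D = rng.normal(size=T)
        _, d1 = estimate_Ji(resid, om, D, X, 0.5)
        _, d2 = estimate_Ji(2 * resid, om, D, X, 0.5)
        assert d2["mean_density"] == pytest.approx(d1["mean_density"] / 2)

    def test_Ji_constant_density_factors_out(self):
        rng = np.random.default_rng(9)
        T = 50
        resid = rng.standard_normal(T)
        X = rng.normal(size=(T, 1))
        D = rng.normal(size=T)
        # x* = xtilde when the instrument column equals D
        J, diag = estimate_Ji(resid, D[:, None], D, X, 0.5,
                              density_mode="unit_average")
        xt = np.column_stack([D, X])
        c = diag["mean_density"]
        assert np.allclose(J, c * xt.T @ xt / T, rtol=1e-10)

    def test_Ji_degenerate_residuals_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            estimate_Ji(np.ones(20), np.ones((20, 1)), np.ones(20),
                        np.ones((20, 1)), 0.5)


class TestViIv:
    def test_identity_case(self):
        assert np.allclose(estimate_Vi_iv(np.eye(2), 0.25 * np.eye(2)),
                           0.25 * np.eye(2))

    def test_diagonal_closed_form(self):
        V = estimate_Vi_iv(np.diag([2.0, 1.0]), np.eye(2))
        assert np.allclose(V, np.diag([0.25, 1.0]))

    def test_random_just_identified_oracle(self):
        rng = np.random.default_rng(10)
        J = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        S = rng.normal(size=(3, 3))
        S = S @ S.T + np.eye(3)
        V = estimate_Vi_iv(J, S, ridge_eps=0.0)
        Jin = np.linalg.inv(J)
        assert np.allclose(V, Jin @ S @ Jin.T, atol=1e-10)

    def test_overidentified_uses_pseudo_inverse(self):
        rng = np.random.default_rng(11)
        J = rng.normal(size=(4, 2))
        S = np.eye(4)
        V = estimate_Vi_iv(J, S, ridge_eps=0.0)
        Jp = np.linalg.pinv(J)
        assert V.shape == (2, 2)
        assert np.allclose(V, Jp @ S @ Jp.T, atol=1e-10)

    def test_rank_deficient_J_raises(self):
        J = np.array([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(np.linalg.LinAlgError):
            estimate_Vi_iv(J, np.eye(2))


class TestCombine:
    def test_equal_covariances_give_arithmetic_mean(self):
        rng = np.random.default_rng(12)
        thetas = rng.normal(size=(6, 2))
        ests = [make_individual(t, np.eye(2) * 0.3, unit_id=i)
                for i, t in enumerate(thetas)]
        comb = combine_md(ests)
        assert np.allclose(comb.theta_hat, thetas.mean(axis=0), atol=1e-12)

    def test_single_unit_passthrough(self):
        est = make_individual(np.array([0.4, 1.1]), np.eye(2))
        comb = combine_md([est])
        assert np.allclose(comb.theta_hat, [0.4, 1.1])

    def test_two_units_hand_weighted(self):
        t1, t2 = np.array([0.4, 1.0]), np.array([0.6, 2.0])
        comb = combine_md([make_individual(t1, np.eye(2)),
                           make_individual(t2, 3 * np.eye(2), unit_id=1)])
        assert np.allclose(comb.theta_hat, (3 * t1 + t2) / 4)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            combine_md([])

    def test_mixed_tau_rejected(self):
        ests = [make_individual(np.zeros(2), np.eye(2), tau=0.5),
                make_individual(np.zeros(2), np.eye(2), tau=0.25, unit_id=1)]
        with pytest.raises(ValueError, match="quantile"):
            combine_md(ests)

    def test_too_many_flagged_units_abort(self):
        ests = [make_individual(np.zeros(2), np.eye(2), unit_id=i,
                                flagged=(i < 2)) for i in range(5)]
        with pytest.raises(ValueError, match="flagged"):
            combine_md(ests)


class TestPanelEstimators:
    def test_iv_mdqr_rho_on_grid_and_sane(self, sim_panel, w20):
        panel, inst = sim_panel
        spec = QuantileModelSpec()
        est = fit_iv_mdqr(panel, w20, inst, spec)
        assert est.method == "iv_mdqr"
        assert np.min(np.abs(spec.rho_grid - est.rho_hat)) < 0.05
        assert abs(est.rho_hat - 0.5) < 0.2
        assert abs(est.beta_hat[0] - 1.0) < 0.2
        # combined covariance is symmetric positive definite
        assert np.allclose(est.V_combined, est.V_combined.T)
        assert np.linalg.eigvalsh(est.V_combined).min() > 0

    def test_mdqr_overestimates_rho(self, sim_panel, w20):
        # endogeneity bias: the uncorrected estimator overshoots
        panel, inst = sim_panel
        md = fit_mdqr(panel, w20, QuantileModelSpec())
        iv = fit_iv_mdqr(panel, w20, inst, QuantileModelSpec())
        assert md.rho_hat - 0.5 > 0.03
        assert abs(iv.rho_hat - 0.5) < abs(md.rho_hat - 0.5)

    def test_iv_feqr_close_to_truth(self, sim_panel, w20):
        panel, inst = sim_panel
        est = fit_iv_feqr(panel, w20, inst, QuantileModelSpec())
        assert est.rho_hat in QuantileModelSpec().rho_grid
        assert abs(est.rho_hat - 0.5) < 0.2

    def test_iv_feqr_singleton_grid_matches_pooled_dummy_oracle(self, w20):
        rng = np.random.default_rng(13)
        params = ModelParams(rho=0.5, beta=np.array([1.0]),
                             eta=rng.standard_normal(20))
        panel = generate_panel(params, w20, 25, 0.5, "homoscedastic", seed=rng)
        inst = make_instruments(panel, w20, "spatial_lag_X")
        spec = QuantileModelSpec(rho_grid=np.array([0.5]))
        est = fit_iv_feqr(panel, w20, inst, spec)
        # oracle: explicit pooled QR with unit dummies at rho=0.5
        D = compute_spatial_lag(panel, w20)
        N, T = panel.y.shape
        resp = (panel.y - 0.5 * D).reshape(-1)
        Z = np.kron(np.eye(N), np.ones((T, 1)))
        design = np.hstack([panel.X.reshape(N * T, 1), Z,
                            inst.omega.reshape(N * T, 1)])
        oracle = fit_qr(resp, design, 0.5)
        assert est.beta_hat[0] == pytest.approx(oracle.coefficients[0],
                                                abs=1e-6)

    def test_scale_equivariance_of_iv_mdqr(self, sim_panel, w20):
        panel, inst = sim_panel
        spec = QuantileModelSpec()
        base = fit_iv_mdqr(panel, w20, inst, spec)
        c = 3.7
        scaled_panel = PanelData(y=c * panel.y, X=panel.X,
                                 y_burn=None if panel.y_burn is None
                                 else c * panel.y_burn)
        scaled = fit_iv_mdqr(scaled_panel, w20, inst, spec)
        assert scaled.rho_hat == pytest.approx(base.rho_hat, abs=1e-10)
        assert np.allclose(scaled.beta_hat, c * base.beta_hat, rtol=1e-5)


class TestInference:
    def test_ci_halfwidth_closed_form(self):
        est = CombinedEstimate(theta_hat=np.zeros(2), V_combined=np.eye(2),
                               n_units=100, n_periods=100, tau=0.5,
                               method="iv_mdqr")
        ci = confidence_intervals(est, 0.95)
        half = (ci[:, 1] - ci[:, 0]) / 2
        assert np.allclose(half, 1.959964 / 100, atol=1e-6)

    def test_ci_monotone_in_level(self):
        est = CombinedEstimate(theta_hat=np.zeros(2), V_combined=np.eye(2),
                               n_units=50, n_periods=50, tau=0.5,
                               method="iv_mdqr")
        narrow = confidence_intervals(est, 0.5)
        wide = confidence_intervals(est, 0.95)
        assert np.all(wide[:, 1] - wide[:, 0] > narrow[:, 1] - narrow[:, 0])

    def test_invalid_level_rejected(self):
        est = CombinedEstimate(theta_hat=np.zeros(2), V_combined=np.eye(2),
                               n_units=50, n_periods=50, tau=0.5,
                               method="iv_mdqr")
        with pytest.raises(ValueError):
            confidence_intervals(est, 1.5)


class TestQuantileProcess:
    def test_single_tau_equals_direct_fit(self, sim_panel, w20):
        panel, inst = sim_panel
        spec = QuantileModelSpec()
        table = quantile_process(panel, w20, inst, spec, [0.5])
        direct = fit_iv_mdqr(panel, w20, inst, spec)
        rho_row = table[table["param"] == "rho"].iloc[0]
        assert rho_row["estimate"] == pytest.approx(direct.rho_hat)

    def test_rows_sorted_by_tau(self, sim_panel, w20):
        panel, inst = sim_panel
        table = quantile_process(panel, w20, inst, QuantileModelSpec(),
                                 [0.75, 0.25, 0.5])
        taus = table["tau"].to_numpy()
        assert np.all(np.diff(taus) >= 0)
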