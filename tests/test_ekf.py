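"""Continuous-discrete EKF: prediction, update, filtering, smoothing.

Oracles: closed-form linear ODE/SDE solutions, a textbook discrete Kalman
filter on the exactly discretized linear system, and brute-force joint-
Gaussian conditioning for the smoother.
"""

import numpy as np
import pytest

from sdemem import models
from sdemem.kalman import (FilterState, FilterError, ekf_filter, ekf_predict,
                           ekf_update, rts_smooth)
from conftest import make_linear_model


@pytest.fixture(scope="module")
def lin():
    return make_linear_model(n_wiener=1)


class TestPredict:
    def test_linear_closed_form(self, lin):
        # dx = -x dt, no noise: xhat(t) = x0 e^-t, P(t) = P0 e^-2t
        phi = np.array([1.0, 1.0, 0.0])
        out = ekf_predict(FilterState(0.0, [1.0], [[0.5]]), lin, phi, 1.0)
        assert out.mean[0] == pytest.approx(np.exp(-1.0), rel=1e-8)
        assert out.cov[0, 0] == pytest.approx(0.5 * np.exp(-2.0), rel=1e-8)

    def test_zero_interval_is_identity(self, lin):
        st = FilterState(2.0, [1.3], [[0.7]])
        out = ekf_predict(st, lin, np.array([1.0, 1.0, 0.0]), 2.0)
        assert out.mean[0] == st.mean[0] and out.cov[0, 0] == st.cov[0, 0]

    def test_constant_diffusion_covariance_growth(self, lin):
        # k = 0: dP/dt = sigma^2, so P grows by sigma^2 * dt exactly
        phi = np.array([0.0, 1.0, 0.4])
        out = ekf_predict(FilterState(0.0, [2.0], [[0.1]]), lin, phi, 2.5)
        assert out.cov[0, 0] == pytest.approx(0.1 + 0.16 * 2.5, rel=1e-8)

    def test_backwards_time_rejected(self, lin):
        with pytest.raises(ValueError):
            ekf_predict(FilterState(1.0, [1.0], [[0.0]]), lin,
                        np.array([1.0, 1.0, 0.0]), 0.5)


class TestUpdate:
    def test_scalar_hand_computed(self, lin):
        phi = np.array([1.0, 1.0, 0.0])
        new, eps, R, K = ekf_update(FilterState(0.0, [1.0], [[1.0]]), [2.0],
                                    lin, phi)
        assert R[0, 0] == pytest.approx(2.0)
        assert K[0, 0] == pytest.approx(0.5)
        assert eps[0] == pytest.approx(1.0)
        assert new.mean[0] == pytest.approx(1.5)
        assert new.cov[0, 0] == pytest.approx(0.5)

    def test_zero_covariance_blocks_information(self, lin):
        phi = np.array([1.0, 1.0, 0.0])
        new, eps, R, K = ekf_update(FilterState(0.0, [1.0], [[0.0]]), [5.0],
                                    lin, phi)
        assert K[0, 0] == 0.0
        assert new.mean[0] == 1.0
        assert new.cov[0, 0] == 0.0

    def test_zero_residual_keeps_mean(self, lin):
        phi = np.array([1.0, 0.5, 0.0])
        st = FilterState(0.0, [1.0], [[0.3]])
        new, eps, R, K = ekf_update(st, [1.0], lin, phi)
        assert eps[0] == 0.0
        assert new.mean[0] == 1.0
        assert new.cov[0, 0] < st.cov[0, 0]

    def test_singular_R_raises(self, lin):
        phi = np.array([1.0, 0.0, 0.0])    # s = 0 and P = 0
        with pytest.raises(FilterError, match="singular"):
            ekf_update(FilterState(0.0, [1.0], [[0.0]]), [1.0], lin, phi)


def exact_discrete_kalman(a, sig, s2, x0, times, ys):
    """Textbook discrete KF on the exactly discretized linear SDE
    dx = a x dt + sig dW, y = x + e."""
    eps_list, R_list, xf_list, Pf_list, xp_list, Pp_list = ([] for _ in
                                                            range(6))
    x, P, tprev = x0, 0.0, 0.0
    for t, y in zip(times, ys):
        dt = t - tprev
        F = np.exp(a * dt)
        Q = (sig ** 2 * (np.exp(2 * a * dt) - 1) / (2 * a) if a != 0
             else sig ** 2 * dt)
        x, P = F * x, F * P * F + Q
        xp_list.append(x)
        Pp_list.append(P)
        R = P + s2
        K = P / R
        e = y - x
        eps_list.append(e)
        R_list.append(R)
        x, P = x + K * e, P - K * R * K
        xf_list.append(x)
        Pf_list.append(P)
        tprev = t
    return (np.array(eps_list), np.array(R_list), np.array(xf_list),
            np.array(Pf_list), np.array(xp_list), np.array(Pp_list))


class TestFilter:
    def test_matches_exact_discrete_kalman(self, lin):
        a, sig, s = -0.7, 0.5, 0.3
        phi = np.array([-a, s, sig])
        times = np.array([0.5, 1.0, 2.0, 3.5, 5.0])
        rng = np.random.default_rng(1)
        ys = np.exp(a * times) + rng.normal(0, 0.3, times.size)
        traj = ekf_filter(lin, phi, times, ys[:, None])
        eps, R, xf, Pf, xp, Pp = exact_discrete_kalman(a, sig, s ** 2, 1.0,
                                                       times, ys)
        assert np.allclose(traj.residuals[:, 0], eps, rtol=1e-8)
        assert np.allclose(traj.output_cov[:, 0, 0], R, rtol=1e-8)
        assert np.allclose(traj.mean_filt[:, 0], xf, rtol=1e-8)
        assert np.allclose(traj.cov_filt[:, 0, 0], Pf, rtol=1e-8,
                           atol=1e-12)

    def test_ode_limit_residuals(self, app1):
        # sigma = 0, P0 = 0: R_k = s^2 and residuals are plain ODE residuals
        from scipy.integrate import solve_ivp

        phi = np.array([0.1, 0.5, 3.0, 1.0, 0.1, 0.0])
        times = np.arange(1.0, 98.0, 8.0)
        ys = np.ones((13, 1))
        traj = ekf_filter(app1.dynamic, phi, times, ys)
        assert np.allclose(traj.output_cov[:, 0, 0], 0.01)
        sol = solve_ivp(lambda t, x: app1.dynamic.drift(x, 0, t, phi),
                        [0, 100], [20.0, 0.0], t_eval=times, rtol=1e-10,
                        atol=1e-12)
        assert np.allclose(traj.residuals[:, 0], 1.0 - sol.y[1], atol=1e-7)

    def test_empty_observation_list(self, lin):
        traj = ekf_filter(lin, np.array([1.0, 1.0, 0.0]), np.array([]),
                          np.zeros((0, 1)))
        assert traj.n_obs == 0
        assert traj.initial.mean[0] == 1.0

    def test_residual_identity(self, lin):
        phi = np.array([0.5, 0.4, 0.2])
        times = np.array([1.0, 2.0, 3.0])
        ys = np.array([[0.5], [0.4], [0.1]])
        traj = ekf_filter(lin, phi, times, ys)
        assert np.allclose(traj.residuals, ys - traj.ypred)

    def test_covariance_psd_and_update_contraction(self, app1):
        # P stays symmetric PSD and diag(P) shrinks at every update
        phi = np.array([0.12, 0.6, 2.0, 1.1, 0.1, 0.08])
        times = np.arange(1.0, 98.0, 8.0)
        rng = np.random.default_rng(4)
        ys = np.abs(rng.normal(3, 1, (13, 1)))
        traj = ekf_filter(app1.dynamic, phi, times, ys)
        for k in range(traj.n_obs):
            Pp, Pf = traj.cov_pred[k], traj.cov_filt[k]
            assert np.allclose(Pp, Pp.T)
            assert np.min(np.linalg.eigvalsh(Pp)) >= -1e-10
            assert np.min(np.linalg.eigvalsh(Pf)) >= -1e-10
            assert np.all(np.diag(Pf) <= np.diag(Pp) + 1e-12)

    def test_filter_equals_chained_predict_update(self, app1):
        phi = np.array([0.12, 0.6, 2.0, 1.1, 0.1, 0.08])
        times = np.array([1.0, 9.0, 17.0])
        ys = np.array([[2.0], [6.0], [8.0]])
        traj = ekf_filter(app1.dynamic, phi, times, ys)
        st = FilterState(0.0, app1.dynamic.initial_state(phi),
                         np.zeros((2, 2)))
        for k in range(3):
            st = ekf_predict(st, app1.dynamic, phi, times[k])
            assert np.allclose(st.mean, traj.mean_pred[k], rtol=1e-7,
                               atol=1e-10)
            st, eps, R, _ = ekf_update(st, ys[k], app1.dynamic, phi)
            assert np.allclose(eps, traj.residuals[k], rtol=1e-7, atol=1e-9)
            assert np.allclose(R, traj.output_cov[k], rtol=1e-7, atol=1e-10)

    def test_output_sd_dips_at_observations(self, app1):
        # Between observations the predicted output sd grows (system noise
        # accumulates); the update pulls it down again.
        phi = np.array([0.1, 0.5, 3.0, 1.0, 0.1, 0.1])
        times = np.arange(1.0, 98.0, 8.0)
        ys = np.full((13, 1), 3.0)
        traj = ekf_filter(app1.dynamic, phi, times, ys)
        traj.dense_prediction(points_per_interval=10)
        sd = traj.dense["output_sd"][:, 0]
        # at the end of each interval (just before an update) the sd must
        # exceed the sd at the start of the next interval (just after)
        ends = sd[9::10][1:-1]
        starts = sd[10::10][:len(ends)]
        assert np.all(ends[1:] >= starts[1:])


class TestSmoother:
    def test_single_observation_equals_filter(self, lin):
        phi = np.array([0.5, 0.4, 0.3])
        traj = ekf_filter(lin, phi, np.array([1.0]), np.array([[0.7]]))
        sm = rts_smooth(traj)
        assert np.allclose(sm.mean[0], traj.mean_filt[0])
        assert np.allclose(sm.cov[0], traj.cov_filt[0])

    def test_deterministic_limit_is_ode(self, app1):
        from scipy.integrate import solve_ivp

        phi = np.array([0.1, 0.5, 3.0, 1.0, 0.1, 0.0])
        times = np.arange(1.0, 98.0, 8.0)
        traj = ekf_filter(app1.dynamic, phi, times, np.ones((13, 1)))
        sm = rts_smooth(traj)
        sol = solve_ivp(lambda t, x: app1.dynamic.drift(x, 0, t, phi),
                        [0, 100], [20.0, 0.0], t_eval=times, rtol=1e-10,
                        atol=1e-12)
        assert np.allclose(sm.mean[:, 1], sol.y[1], atol=1e-7)
        assert np.allclose(sm.cov, 0.0, atol=1e-12)

    def test_matches_joint_gaussian_conditioning(self, lin):
        # 3-observation linear SDE: condition the joint Gaussian latent
        # vector on all observations by brute force
        a, sig, s = -0.6, 0.7, 0.25
        phi = np.array([-a, s, sig])
        times = np.array([1.0, 2.0, 3.0])
        ys = np.array([0.9, 0.2, 0.4])
        traj = ekf_filter(lin, phi, times, ys[:, None])
        sm = rts_smooth(traj)

        mu = np.exp(a * times) * 1.0
        var = sig ** 2 * (np.exp(2 * a * times) - 1) / (2 * a)
        C = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                lo, hi = min(times[i], times[j]), max(times[i], times[j])
                C[i, j] = np.exp(a * (hi - lo)) * var[min(i, j)]
        Sy = C + s ** 2 * np.eye(3)
        cond_mean = mu + C @ np.linalg.solve(Sy, ys - mu)
        cond_cov = C - C @ np.linalg.solve(Sy, C)
        assert np.allclose(sm.mean[:, 0], cond_mean, atol=1e-6)
        assert np.allclose(sm.cov[:, 0, 0], np.diag(cond_cov), atol=1e-6)

    def test_smoothed_no_worse_than_filtered(self, lin):
        phi = np.array([0.4, 0.3, 0.5])
        times = np.linspace(1, 10, 8)
        rng = np.random.default_rng(2)
        ys = rng.normal(0, 1, (8, 1))
        traj = ekf_filter(lin, phi, times, ys)
        sm = rts_smooth(traj)
        assert np.allclose(sm.mean[-1], traj.mean_filt[-1])
        for k in range(8):
            diff = traj.cov_filt[k] - sm.cov[k]
            assert np.min(np.linalg.eigvalsh(diff)) >= -1e-10


class TestGridInvariance:
    def test_extra_prediction_nodes_do_not_change_likelihood_terms(self,
                                                                   app1):
        # inserting pure input-break points must leave eps and R unchanged
        phi = np.array([0.1, 0.5, 3.0, 1.0, 0.1, 0.05])
        times = np.arange(1.0, 98.0, 8.0)
        ys = np.full((13, 1), 2.0)
        base = ekf_filter(app1.dynamic, phi, times, ys)
        u = models.PiecewiseConstantInput(
            breaks=[0.5, 3.0, 20.0, 55.5], values=[0.0, 0.0, 0.0, 0.0])
        split = ekf_filter(app1.dynamic, phi, times, ys, u=u)
        assert np.allclose(split.residuals, base.residuals, rtol=1e-8,
                           atol=1e-12)
        assert np.allclose(split.output_cov, base.output_cov, rtol=1e-8)
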