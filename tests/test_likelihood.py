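"""Individual NLL, FOCE/FOCEI Hessians and the Laplace population objective.

Oracles: hand-evaluated scalar cases, conjugate Gaussian marginalization on
the linear mixed toy (where the Laplace approximation is exact), and a
finite-difference decomposition of the FOCEI Hessian.
"""

import numpy as np
import pytest
from scipy.stats import norm

from sdemem import likelihood as lk
from sdemem import models, simulate
from sdemem.estimation import fit_population, inner_optimize
from conftest import make_mean_population


def mean_subject(y, sid=1, t=1.0):
    times = np.atleast_1d(np.asarray(t, float))
    return simulate.SubjectData(id=sid, times=times,
                                y=np.atleast_1d(np.asarray(y, float)))


class TestIndividualNll:
    """Hand-evaluated scalar cases: one observation with unit R."""

    def test_zero_residual_unit_R(self):
        # eps=0, R=1, eta=0, omega=1: -l = log(2 pi)
        pm = make_mean_population()
        sub = mean_subject(0.5)     # y equals h(x)=mu=0.5 -> eps=0
        theta = np.array([0.5, 1.0])  # s=1 -> R=1
        val = lk.individual_nll(np.zeros(1), sub, theta, np.eye(1),
                                pm.dynamic, pm.pmap)
        assert val == pytest.approx(np.log(2 * np.pi), rel=1e-10)

    def test_prior_quadratic(self):
        # same but eta=1: adds 1/2 eta^2/omega^2 = 0.5
        pm = make_mean_population()
        sub = mean_subject(1.5)     # mu_i = 0.5 + 1 = 1.5 -> eps = 0
        theta = np.array([0.5, 1.0])
        val = lk.individual_nll(np.ones(1), sub, theta, np.eye(1),
                                pm.dynamic, pm.pmap)
        assert val == pytest.approx(np.log(2 * np.pi) + 0.5, rel=1e-10)

    def test_doubling_omega_shifts_by_half_log_two(self):
        pm = make_mean_population()
        sub = mean_subject(0.5)
        theta = np.array([0.5, 1.0])
        v1 = lk.individual_nll(np.zeros(1), sub, theta, np.eye(1),
                               pm.dynamic, pm.pmap)
        v2 = lk.individual_nll(np.zeros(1), sub, theta, 2 * np.eye(1),
                               pm.dynamic, pm.pmap)
        assert v2 - v1 == pytest.approx(0.5 * np.log(2), rel=1e-10)

    def test_singular_omega_rejected(self):
        pm = make_mean_population()
        with pytest.raises(ValueError, match="positive definite"):
            lk.individual_nll(np.zeros(1), mean_subject(0.5),
                              np.array([0.5, 1.0]), np.zeros((1, 1)),
                              pm.dynamic, pm.pmap)


class TestFoceHessian:
    def test_single_observation_hand_value(self):
        # deps/deta = -1, R = 1, omega = 1: Dl = -1 - 1 = -2
        pm = make_mean_population()
        sub = mean_subject(0.9)
        theta = np.array([0.5, 1.0])
        H = lk.foce_hessian(np.zeros(1), sub, theta, np.eye(1), pm.dynamic,
                            pm.pmap)
        assert H[0, 0] == pytest.approx(-2.0, rel=1e-8)

    def test_no_observations_prior_curvature(self):
        pm = make_mean_population()
        sub = simulate.SubjectData(id=1, times=np.array([]),
                                   y=np.zeros((0, 1)))
        omega = np.array([[0.25]])
        H = lk.foce_hessian(np.zeros(1), sub, np.array([0.5, 1.0]), omega,
                            pm.dynamic, pm.pmap)
        assert np.allclose(H, -np.linalg.inv(omega))

    def test_orthogonal_sensitivities_leave_prior_cross_term(self):
        # two random effects with disjoint observation support: the data
        # cross term vanishes, leaving -(Omega^-1)_12
        eps = np.array([[0.3], [0.1]])
        R = np.tile(np.eye(1), (2, 1, 1))
        e1 = np.zeros((2, 1, 2))
        e1[0, 0, 0] = -1.0          # obs 1 only feels eta1
        e1[1, 0, 1] = -1.0          # obs 2 only feels eta2
        R1 = np.zeros((2, 1, 1, 2))
        omega = np.array([[0.5, 0.1], [0.1, 0.4]])
        H = lk.foce_hessian(np.zeros(2), None, None, omega, None, None,
                            sens=(eps, R, e1, R1))
        Winv = np.linalg.inv(omega)
        assert H[0, 1] == pytest.approx(-Winv[0, 1])
        assert H[0, 0] == pytest.approx(-1.0 - Winv[0, 0])


class TestFoceiHessian:
    def test_reduces_to_foce_without_interaction(self, app1, app1_dataset):
        # sigma = 0 and additive error: dR/deta = 0, FOCEI == FOCE
        theta = models.APP1_START.copy()
        theta[-1] = 0.0
        theta_s, _ = app1.split(theta)
        omega = app1.omega(theta)
        eta = np.array([0.2, -0.1])
        sub = app1_dataset[0]
        Hf = lk.foce_hessian(eta, sub, theta_s, omega, app1.dynamic,
                             app1.pmap)
        Hi = lk.focei_hessian(eta, sub, theta_s, omega, app1.dynamic,
                              app1.pmap)
        assert np.allclose(Hf, Hi, rtol=1e-12, atol=1e-12)

    def test_differs_with_interaction(self, app1, app1_dataset):
        theta_s, _ = app1.split(models.APP1_TRUE)
        omega = app1.omega(models.APP1_TRUE)
        eta = np.array([0.1, 0.1])
        sub = app1_dataset[0]
        Hf = lk.foce_hessian(eta, sub, theta_s, omega, app1.dynamic,
                             app1.pmap)
        Hi = lk.focei_hessian(eta, sub, theta_s, omega, app1.dynamic,
                              app1.pmap)
        assert not np.allclose(Hf, Hi)

    def test_matches_finite_difference_decomposition(self):
        # scalar synthetic case: all first-order inputs specified
        # numerically; the FOCEI Hessian must equal the FD second
        # derivative of the objective built from linearized eps(eta), R(eta)
        eps0, R0, de, dR, W = 0.4, 1.3, -0.8, 0.6, 0.7

        def nll(eta):
            e = eps0 + de * eta
            r = R0 + dR * eta
            return 0.5 * (e * e / r + np.log(2 * np.pi * r)
                          + eta * eta / W + np.log(2 * np.pi * W))

        h = 1e-4
        fd = (nll(h) - 2 * nll(0.0) + nll(-h)) / h ** 2
        eps = np.array([[eps0]])
        R = np.array([[[R0]]])
        e1 = np.array([[[de]]])
        R1 = np.array([[[[dR]]]])
        H = lk.focei_hessian(np.zeros(1), None, None, np.array([[W]]), None,
                             None, sens=(eps, R, e1, R1))
        assert -H[0, 0] == pytest.approx(fd, abs=1e-6)

    def test_trace_term_scales_quadratically(self):
        # with eps = 0 only the 1/2 Tr(R^-1 dR R^-1 dR) interaction term
        # survives; halving dR quarters it
        W = np.array([[1.0]])
        eps = np.zeros((1, 1))
        R = np.array([[[2.0]]])
        e1 = np.zeros((1, 1, 1))

        def interaction(drval):
            R1 = np.array([[[[drval]]]])
            return (lk.focei_hessian(np.zeros(1), None, None, W, None, None,
                                     sens=(eps, R, e1, R1))
                    - lk.foce_hessian(np.zeros(1), None, None, W, None,
                                      None, sens=(eps, R, e1, R1)))[0, 0]

        assert interaction(0.4) == pytest.approx(4 * interaction(0.2),
                                                 rel=1e-10)


class TestLaplacePopulation:
    def test_exact_on_linear_mixed_toy(self):
        # y_ij = theta + eta_i + e_ij, one observation per subject:
        # marginal is N(theta, omega^2 + s^2) and Laplace is exact
        pm = make_mean_population()
        theta = np.array([0.4, 0.3, 0.6])    # mu, s, omega
        rng = np.random.default_rng(0)
        ys = rng.normal(0.4, 0.5, 5)
        ds = simulate.Dataset([mean_subject(y, sid=i) for i, y in
                               enumerate(ys)])
        for method in ("foce", "focei"):
            val = lk.laplace_population_nll(theta, ds, pm, method=method)
            exact = -np.sum(norm.logpdf(ys, loc=0.4,
                                        scale=np.sqrt(0.36 + 0.09)))
            assert val == pytest.approx(exact, abs=1e-8)

    def test_vanishing_omega_approaches_fixed_effects_likelihood(self):
        pm = make_mean_population()
        ys = [0.7, 0.2]
        ds = simulate.Dataset([mean_subject(y, sid=i) for i, y in
                               enumerate(ys)])
        theta = np.array([0.4, 0.3, 1e-5])
        val = lk.laplace_population_nll(theta, ds, pm, method="foce")
        exact = -np.sum(norm.logpdf(np.asarray(ys), loc=0.4, scale=0.3))
        assert val == pytest.approx(exact, abs=1e-4)

    def test_single_subject_additivity(self):
        pm = make_mean_population()
        theta = np.array([0.4, 0.3, 0.6])
        subs = [mean_subject(0.8, sid=1), mean_subject(0.1, sid=2)]
        total = lk.laplace_population_nll(theta, simulate.Dataset(subs), pm,
                                          method="focei")
        parts = [lk.laplace_population_nll(theta,
                                           simulate.Dataset([s_]), pm,
                                           method="focei")
                 for s_ in subs]
        assert total == pytest.approx(sum(parts), rel=1e-12)

    def test_matches_hand_rolled_ode_foce_reference(self, app1):
        """With sigma = 0 and additive error, the EKF/Laplace machinery
        reduces to a standard ODE-based FOCE population objective; check
        against an independent implementation (ODE solver + numerical inner
        optimization + finite-difference Gauss-Newton Hessian)."""
        from scipy.integrate import solve_ivp
        from scipy.optimize import minimize

        theta = np.array([0.12, 0.6, 2.5, 1.1, 0.12, 0.45, 0.05, 0.25, 0.0])
        theta_s, _ = app1.split(theta)
        omega = app1.omega(theta)
        Winv = np.linalg.inv(omega)
        _, logdet_om = np.linalg.slogdet(omega)
        design = simulate.app1_design(n_subjects=3, seed=33)
        pop = models.PopulationParameters(
            theta=app1.split(models.APP1_TRUE)[0],
            omega_factor=app1.omega_factor(models.APP1_TRUE))
        ds = simulate.simulate_population_dataset(app1.dynamic, pop,
                                                  app1.pmap, design)
        times = design.observation_times
        s2 = theta_s[4] ** 2

        def residuals(eta, ysub):
            phi = app1.pmap.transform(theta_s, None, eta)
            sol = solve_ivp(lambda t, x: app1.dynamic.drift(x, 0, t, phi),
                            [0, times[-1]], [20.0, 0.0], t_eval=times,
                            rtol=1e-10, atol=1e-12)
            return ysub[:, 0] - sol.y[1]

        def nll(eta, ysub):
            r = residuals(eta, ysub)
            return (0.5 * np.sum(r ** 2 / s2 + np.log(2 * np.pi * s2))
                    + 0.5 * eta @ Winv @ eta
                    + 0.5 * (logdet_om + 2 * np.log(2 * np.pi)))

        ref_total = 0.0
        for sub in ds:
            res = minimize(nll, np.zeros(2), args=(sub.y,),
                           method="Nelder-Mead",
                           options={"xatol": 1e-9, "fatol": 1e-12})
            eta = res.x
            J = np.zeros((13, 2))
            for a in range(2):
                ep = eta.copy()
                ep[a] += 1e-6
                em = eta.copy()
                em[a] -= 1e-6
                J[:, a] = (residuals(ep, sub.y)
                           - residuals(em, sub.y)) / 2e-6
            M = J.T @ J / s2 + Winv          # -Dl (FOCE)
            _, logdetM = np.linalg.slogdet(M)
            ref_total += res.fun + 0.5 * (logdetM - 2 * np.log(2 * np.pi))

        val = lk.laplace_population_nll(theta, ds, app1, method="foce")
        assert val == pytest.approx(ref_total, abs=1e-5)

    def test_subject_reordering_invariance(self, app1, app1_dataset):
        theta = models.APP1_TRUE
        v1 = lk.laplace_population_nll(theta, app1_dataset, app1,
                                       method="focei")
        reordered = simulate.Dataset(list(app1_dataset)[::-1])
        v2 = lk.laplace_population_nll(theta, reordered, app1,
                                       method="focei")
        assert v1 == pytest.approx(v2, rel=1e-10)
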