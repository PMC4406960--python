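"""Nested optimization, standard errors, replicate-study driver."""

import numpy as np
import pytest
from sklearn.base import clone

from sdemem import models, simulate
from sdemem.estimation import (SDEMEMEstimator, compute_rse, fit_population,
                               inner_optimize, replicate_study)
from conftest import (make_mean_population,
                      make_mean_population_fixed_effects_only)


def mean_subject(y, sid=1, times=(1.0,)):
    times = np.asarray(times, float)
    return simulate.SubjectData(id=sid, times=times,
                                y=np.asarray(y, float).reshape(-1))


class TestInnerOptimize:
    def test_posterior_mode_closed_form(self):
        # one observation, h = theta + eta: eta* = w^2 (y-theta)/(w^2+s^2)
        pm = make_mean_population()
        theta = np.array([0.4, 0.3])
        omega = np.array([[0.36]])
        y = 1.1
        fit = inner_optimize(mean_subject([y]), theta, omega, pm.dynamic,
                             pm.pmap, method="foce")
        expect = 0.36 * (y - 0.4) / (0.36 + 0.09)
        assert fit.eta_star[0] == pytest.approx(expect, abs=1e-7)
        assert fit.converged

    def test_no_observations_prior_mode(self):
        pm = make_mean_population()
        sub = simulate.SubjectData(id=1, times=np.array([]),
                                   y=np.zeros((0, 1)))
        fit = inner_optimize(sub, np.array([0.4, 0.3]), np.array([[0.25]]),
                             pm.dynamic, pm.pmap)
        assert fit.eta_star[0] == 0.0
        assert np.allclose(fit.hessian, -4.0)

    def test_warm_start_is_a_fixed_point(self, app1, app1_dataset):
        theta_s, _ = app1.split(models.APP1_TRUE)
        omega = app1.omega(models.APP1_TRUE)
        fit = inner_optimize(app1_dataset[0], theta_s, omega, app1.dynamic,
                             app1.pmap, method="focei")
        refit = inner_optimize(app1_dataset[0], theta_s, omega, app1.dynamic,
                               app1.pmap, eta0=fit.eta_star, method="focei")
        assert refit.n_iter <= 1
        assert np.allclose(refit.eta_star, fit.eta_star, atol=1e-6)

    def test_hessian_negative_definite_at_optimum(self, app1, app1_dataset):
        theta_s, _ = app1.split(models.APP1_TRUE)
        omega = app1.omega(models.APP1_TRUE)
        fit = inner_optimize(app1_dataset[1], theta_s, omega, app1.dynamic,
                             app1.pmap, method="focei")
        assert np.all(np.linalg.eigvalsh(-fit.hessian) > 0)


class TestFitPopulation:
    def test_gaussian_mle_closed_form(self):
        # one subject, no random effects: mu and s are the plain Gaussian
        # maximum likelihood estimates
        pm = make_mean_population_fixed_effects_only()
        rng = np.random.default_rng(8)
        ys = rng.normal(0.7, 0.25, 12)
        ds = simulate.Dataset([mean_subject(ys, times=np.arange(1.0, 13.0))])
        est = fit_population(ds, pm, start=np.array([0.3, 0.5]),
                             method="foce", gtol=1e-8)
        assert est.converged
        assert est.theta[0] == pytest.approx(np.mean(ys), abs=1e-6)
        assert est.theta[1] == pytest.approx(np.std(ys), abs=1e-6)

    def test_objective_decreases_across_accepted_iterations(self):
        pm = make_mean_population()
        rng = np.random.default_rng(1)
        ys = rng.normal(0.5, 0.5, 8)
        ds = simulate.Dataset([mean_subject([y], sid=i)
                               for i, y in enumerate(ys)])
        est = fit_population(ds, pm, method="focei")
        vals = [v for _, _, v in est.trace]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_recovers_structural_parameters_on_ode_data(self, app1):
        # noise-free dynamics (sigma = 0), small measurement error and
        # small pinned inter-individual variability: the ODE-mode fit
        # recovers the structural parameters to ~1% (larger free IIV would
        # add random-effect sampling noise well above 1% at this n)
        true = models.APP1_TRUE.copy()
        true[4] = 0.02                     # s small
        true[5:8] = [0.01, 0.0, 0.01]      # small IIV
        true[8] = 0.0                      # no system noise
        design = simulate.app1_design(n_subjects=12, seed=21)
        pop = models.PopulationParameters(theta=app1.split(true)[0],
                                          omega_factor=app1.omega_factor(true))
        ds = simulate.simulate_population_dataset(app1.dynamic, pop,
                                                  app1.pmap, design)
        start = true.copy()
        start[[0, 1, 2, 3]] = [0.15, 0.7, 2.0, 1.5]
        start[4] = 0.1
        est = fit_population(ds, app1, start=start, method="focei",
                             fixed={"sigma": 0.0, "omega11": 0.01,
                                    "omega12": 0.0, "omega22": 0.01},
                             gtol=1e-3)
        assert est.converged
        for idx in [0, 1, 2, 3]:
            assert est.theta[idx] == pytest.approx(true[idx], rel=0.01)

    def test_fixed_mask_is_respected(self):
        pm = make_mean_population()
        ys = np.array([0.2, 0.8, 0.5, 0.6])
        ds = simulate.Dataset([mean_subject([y], sid=i)
                               for i, y in enumerate(ys)])
        est = fit_population(ds, pm, fixed={"s": 0.11}, method="foce")
        assert est.theta[1] == 0.11
        assert "s" in est.fixed

    def test_foce_and_focei_coincide_without_interaction(self):
        # additive error, static state: dR/deta = 0, so the two conditional
        # methods optimize the same objective
        pm = make_mean_population()
        rng = np.random.default_rng(3)
        ys = rng.normal(0.5, 0.5, 10)
        ds = simulate.Dataset([mean_subject([y], sid=i)
                               for i, y in enumerate(ys)])
        est_foce = fit_population(ds, pm, method="foce", gtol=1e-6)
        est_focei = fit_population(ds, pm, method="focei", gtol=1e-6)
        assert np.allclose(est_foce.theta, est_focei.theta, atol=1e-4)

    def test_unknown_fixed_name_rejected(self):
        pm = make_mean_population()
        ds = simulate.Dataset([mean_subject([0.5])])
        with pytest.raises(KeyError):
            fit_population(ds, pm, fixed={"nope": 1.0})


class TestComputeRse:
    def test_linear_mixed_toy_matches_fisher_information(self):
        # RSE(mu) = 100 sqrt((w^2+s^2)/n)/mu
        pm = make_mean_population()
        rng = np.random.default_rng(5)
        n = 24
        mu, s, om = 0.8, 0.3, 0.5
        ys = rng.normal(mu, np.sqrt(s ** 2 + om ** 2), n)
        ds = simulate.Dataset([mean_subject([y], sid=i)
                               for i, y in enumerate(ys)])
        est = fit_population(ds, pm, start=np.array([mu, s, om]),
                             method="focei", gtol=1e-6)
        rse = compute_rse(est, ds, pm)
        expect = 100 * np.sqrt((est.theta[1] ** 2 + est.theta[2] ** 2) / n) \
            / est.theta[0]
        assert rse[0] == pytest.approx(expect, rel=0.02)

    def test_doubling_data_shrinks_rse(self):
        pm = make_mean_population()
        rng = np.random.default_rng(6)
        ys = rng.normal(0.8, 0.6, 16)
        ds1 = simulate.Dataset([mean_subject([y], sid=i)
                                for i, y in enumerate(ys)])
        ds2 = simulate.Dataset([mean_subject([y], sid=i)
                                for i, y in enumerate(np.r_[ys, ys])])
        est1 = fit_population(ds1, pm, method="focei")
        est2 = fit_population(ds2, pm, method="focei")
        r1 = compute_rse(est1, ds1, pm)
        r2 = compute_rse(est2, ds2, pm)
        assert r2[0] / r1[0] == pytest.approx(1 / np.sqrt(2), rel=0.05)

    def test_fixed_parameter_reported_absent(self):
        pm = make_mean_population()
        ys = np.array([0.3, 0.6, 0.9, 0.4, 0.6, 0.2])
        ds = simulate.Dataset([mean_subject([y], sid=i)
                               for i, y in enumerate(ys)])
        est = fit_population(ds, pm, fixed={"s": 0.3}, method="foce")
        rse = compute_rse(est, ds, pm)
        assert np.isnan(rse[1])
        assert np.isfinite(rse[0])


class TestReplicateStudy:
    def _toy_design(self):
        return simulate.StudyDesign(n_subjects=6,
                                    observation_times=[1.0, 2.0],
                                    seed=0, step=0.5)

    def test_deterministic_given_master_seed(self):
        pm = make_mean_population()
        true = np.array([0.5, 0.3, 0.4])
        r1 = replicate_study(pm, true, self._toy_design(), 3, master_seed=7,
                             modes=("sde",), method="foce")
        r2 = replicate_study(pm, true, self._toy_design(), 3, master_seed=7,
                             modes=("sde",), method="foce")
        assert r1.estimates.equals(r2.estimates)

    def test_single_replicate_has_no_spread(self):
        pm = make_mean_population()
        true = np.array([0.5, 0.3, 0.4])
        res = replicate_study(pm, true, self._toy_design(), 1,
                              master_seed=3, modes=("sde",), method="foce")
        assert res.n_replicates == 1
        assert np.isnan(res.summary["sde"]["sd"]).all()
        assert np.isnan(res.summary["sde"]["rse_percent"]).all()

    def test_recovers_toy_parameters_in_mean(self):
        pm = make_mean_population()
        true = np.array([0.5, 0.3, 0.4])
        res = replicate_study(pm, true, self._toy_design(), 6, master_seed=1,
                              modes=("sde",), method="foce")
        m = res.summary["sde"]["mean"]
        assert m["mu"] == pytest.approx(0.5, abs=0.25)
        assert res.excluded["sde"] == 0


class TestSklearnInterface:
    def test_get_set_params_and_clone(self):
        estimator = SDEMEMEstimator(model="one_compartment_abs_mm",
                                    method="focei", gtol=1e-3)
        params = estimator.get_params()
        assert params["method"] == "focei"
        c = clone(estimator)
        assert c.get_params()["gtol"] == 1e-3
        c.set_params(method="foce")
        assert c.method == "foce"

    def test_fit_and_predict_on_toy(self):
        pm = make_mean_population()
        rng = np.random.default_rng(2)
        ys = rng.normal(0.6, 0.5, 8)
        ds = simulate.Dataset([mean_subject([y], sid=i + 1)
                               for i, y in enumerate(ys)])
        df = ds.to_frame()
        estimator = SDEMEMEstimator(model=pm, method="foce").fit(df)
        assert estimator.converged_
        assert estimator.theta_["mu"] == pytest.approx(np.mean(ys), abs=0.2)
        preds = estimator.predict(df)
        assert preds.shape == (8,)
        # one-step predictions condition on each subject's posterior-mode
        # random effect: mu + w^2 (y - mu)/(w^2 + s^2)
        mu, s, om = estimator.theta_
        shrink = om ** 2 / (om ** 2 + s ** 2)
        assert np.allclose(preds, mu + shrink * (ys - mu), atol=1e-5)
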