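import numpy as np
import pytest
import sympy as sp

from sdemem import models, simulate


@pytest.fixture(scope="session")
def app1():
    """The shipped two-state PK population model (compiled once)."""
    return models.one_compartment_pk(jit=True)


@pytest.fixture(scope="session")
def niac_pm():
    return models.niac(jit=True)


@pytest.fixture(scope="session")
def app1_dataset(app1):
    """A small simulated population (3 subjects) at the study truth."""
    design = simulate.app1_design(n_subjects=3, seed=42)
    pop = models.PopulationParameters(
        theta=app1.split(models.APP1_TRUE)[0],
        omega_factor=app1.omega_factor(models.APP1_TRUE))
    return simulate.simulate_population_dataset(app1.dynamic, pop, app1.pmap,
                                                design)


def make_linear_model(n_wiener=0, x0_param=False):
    """Scalar linear model dx = -k x dt (+ sigma dW), y = x + e.

    params: (k, s, sigma) or (x0, k, s, sigma) when the initial state is a
    parameter.
    """
    x = sp.Symbol("x")
    k, s, sig = sp.symbols("k s sigma")
    params = [k, s, sig]
    x0 = sp.Matrix([1])
    if x0_param:
        x0sym = sp.Symbol("x0")
        params = [x0sym] + params
        x0 = sp.Matrix([x0sym])
    diffusion = sp.Matrix([[sig]]) if n_wiener else sp.Matrix([[sp.Integer(0)]])
    return models.DynamicModel(
        states=[x], params=params, drift=sp.Matrix([-k * x]),
        diffusion=diffusion, measurement=sp.Matrix([x]),
        measurement_cov=sp.Matrix([[s ** 2]]), initial_state=x0,
        name="linear_test")


def make_mean_model():
    """Static toy: x constant at its (parametric) initial value x0 = mu,
    y = x + e; linear in everything, so Laplace is exact."""
    x = sp.Symbol("x")
    mu, s = sp.symbols("mu s")
    return models.DynamicModel(
        states=[x], params=[mu, s], drift=sp.Matrix([sp.Integer(0)]),
        diffusion=sp.Matrix([[sp.Integer(0)]]), measurement=sp.Matrix([x]),
        measurement_cov=sp.Matrix([[s ** 2]]),
        initial_state=sp.Matrix([mu]), name="mean_test")


def make_mean_population(omega0=0.5, additive_eta=True):
    """PopulationModel around make_mean_model with one additive random
    effect on the mean: y_ij = theta + eta_i + e_ij."""
    mu, s = sp.symbols("mu s")
    e1 = sp.Symbol("eta1")
    pmap = models.IndividualParameterMap(
        theta_syms=[mu, s], eta_syms=[e1],
        exprs=[mu + e1 if additive_eta else mu * sp.exp(e1), s])
    pm = models.PopulationModel(
        name="mean_toy", dynamic=make_mean_model(), pmap=pmap,
        theta_names=["mu", "s", "omega"], struct_idx=[0, 1], omega_idx=[2],
        default_start=np.array([0.5, 0.3, omega0]), jit=False)
    # the additive-mean parameter itself may be any sign
    pm.scales[0] = "identity"
    return pm


def make_mean_population_fixed_effects_only():
    """No random effects: plain Gaussian mean/variance estimation."""
    mu, s = sp.symbols("mu s")
    pmap = models.IndividualParameterMap(theta_syms=[mu, s], eta_syms=[],
                                         exprs=[mu, s])
    pm = models.PopulationModel(
        name="mean_fixed", dynamic=make_mean_model(), pmap=pmap,
        theta_names=["mu", "s"], struct_idx=[0, 1], omega_idx=[],
        default_start=np.array([0.5, 0.3]), jit=False)
    pm.scales[0] = "identity"
    return pm
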