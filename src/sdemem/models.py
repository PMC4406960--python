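"""Declarative model library for stochastic differential mixed-effects models.

A structural model (:class:`DynamicModel`) is an Itô stochastic differential
equation with discrete-time measurements,

    dx = f(x, u, t, phi) dt + Sigma(xhat, u, t, phi) dW,      x(0) = x0(phi)
    y_j = h(x(t_j), u, t_j, phi) + e_j,  e_j ~ N(0, S(x, u, t_j, phi)),

declared symbolically (sympy expressions) so that the filtering and
sensitivity machinery can differentiate it exactly.  By convention the
diffusion matrix ``Sigma`` is evaluated at the *state estimate* produced by
the extended Kalman filter rather than at the latent state: the EKF cannot
handle truly state-dependent system noise, but substituting the filtered
conditional mean gives a proportional-like noise model.  During simulation,
where no filter runs, the current simulated state is substituted into the
same function.

The population layer maps fixed effects theta and subject-level random
effects eta ~ N(0, Omega) to individual parameters phi = g(theta, Z, eta),
with Omega parameterized through an upper-triangular factor U (Omega = U Uᵀ)
to guarantee positive semidefiniteness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import sympy as sp

__all__ = [
    "TIME",
    "INPUT",
    "DynamicModel",
    "IndividualParameterMap",
    "PopulationParameters",
    "PopulationModel",
    "PiecewiseConstantInput",
    "build_omega",
    "map_individual_parameters",
    "one_compartment_pk_model",
    "one_compartment_pk_map",
    "one_compartment_pk",
    "niac_model",
    "niac_map",
    "niac",
    "get_model",
    "MODEL_REGISTRY",
    "APP1_TRUE",
    "APP1_START",
    "NIAC_START",
    "NIAC_SYNTH_TRUE",
]

#: canonical time and input symbols shared by all model declarations
TIME = sp.Symbol("t")
INPUT = sp.Symbol("u_in")


class PiecewiseConstantInput:
    """Piecewise-constant time function, e.g. an infusion schedule.

    ``u(t) = values[j]`` for ``breaks[j] <= t < breaks[j+1]``; zero before the
    first break and after the last (an implicit trailing zero segment).
    """

    def __init__(self, breaks: Sequence[float] = (), values: Sequence[float] = ()):
        breaks = np.asarray(breaks, dtype=float)
        values = np.asarray(values, dtype=float)
        if breaks.ndim != 1 or values.ndim != 1:
            raise ValueError("breaks and values must be one-dimensional")
        if breaks.size != values.size:
            raise ValueError("need one value per break point")
        if breaks.size and np.any(np.diff(breaks) <= 0):
            raise ValueError("break points must be strictly increasing")
        self.breaks = breaks
        self.values = values

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        if self.breaks.size == 0:
            return np.zeros_like(t) if t.ndim else 0.0
        idx = np.searchsorted(self.breaks, t, side="right") - 1
        vals = np.where(idx >= 0, self.values[np.clip(idx, 0, None)], 0.0)
        return vals if t.ndim else float(vals)

    @property
    def is_zero(self) -> bool:
        return self.breaks.size == 0 or not np.any(self.values)

    def segment_points(self, t0: float, t1: float) -> np.ndarray:
        """Interior break points falling strictly inside (t0, t1)."""
        b = self.breaks
        return b[(b > t0) & (b < t1)]

    @classmethod
    def zero(cls) -> "PiecewiseConstantInput":
        return cls()

    @classmethod
    def infusion(cls, rate: float, duration: float, start: float = 0.0):
        """Constant-rate infusion of given duration starting at ``start``."""
        return cls([start, start + duration], [rate, 0.0])


class DynamicModel:
    """Symbolically declared structural SDE model with discrete measurements.

    Parameters
    ----------
    states : sequence of sympy.Symbol
        State variables x.
    params : sequence of sympy.Symbol
        Individual parameters phi (structural plus error-model parameters).
    drift : sympy Matrix (n x 1)
        Drift f(x, u, t, phi).
    diffusion : sympy Matrix (n x q)
        Diffusion Sigma; ``q = 0`` columns means a pure ODE model.  Evaluated
        at the filter's state estimate during filtering and at the simulated
        state during simulation.
    measurement : sympy Matrix (m x 1)
        Output function h.
    measurement_cov : sympy Matrix (m x m)
        Measurement-error covariance S (symmetric, PSD).
    initial_state : sympy Matrix (n x 1)
        Initial condition x0(phi); may depend on the parameters.
    state_names, param_names : optional labels (default: symbol names).
    input : PiecewiseConstantInput, optional
        Default exogenous input u(t); zero if omitted.
    validate_params : callable(phi) -> None, optional
        Raises ValueError for invalid individual parameter vectors.
    """

    def __init__(
        self,
        states,
        params,
        drift,
        diffusion,
        measurement,
        measurement_cov,
        initial_state,
        state_names=None,
        param_names=None,
        input: PiecewiseConstantInput | None = None,
        validate_params: Callable | None = None,
        name: str = "model",
    ):
        self.states = list(states)
        self.params = list(params)
        self.n_states = len(self.states)
        self.n_params = len(self.params)

        def _mat(expr, rows, cols, what):
            m = sp.Matrix(expr)
            if m.shape != (rows, cols):
                raise ValueError(
                    f"{what} must have shape {(rows, cols)}, got {m.shape}"
                )
            return m

        self._f = _mat(drift, self.n_states, 1, "drift")
        self._Sigma = sp.Matrix(diffusion)
        if self._Sigma.shape[0] != self.n_states:
            raise ValueError("diffusion must have one row per state")
        self.n_wiener = self._Sigma.shape[1]
        self._h = sp.Matrix(measurement)
        if self._h.shape[1] != 1:
            raise ValueError("measurement must be a column vector")
        self.n_outputs = self._h.shape[0]
        self._S = _mat(measurement_cov, self.n_outputs, self.n_outputs,
                       "measurement_cov")
        if sp.simplify(self._S - self._S.T) != sp.zeros(*self._S.shape):
            raise ValueError("measurement_cov must be symmetric")
        self._x0 = _mat(initial_state, self.n_states, 1, "initial_state")

        self.state_names = list(state_names or [str(s) for s in self.states])
        self.param_names = list(param_names or [str(s) for s in self.params])
        self.input = input if input is not None else PiecewiseConstantInput.zero()
        self.validate_params = validate_params
        self.name = name
        #: preferred execution mode for the filtering kernels; set True by
        #: PopulationModel for the shipped (hot-path) models
        self.default_jit = False

        args = (self.states, INPUT, TIME, self.params)
        self._drift_fn = sp.lambdify(args, self._f, modules="numpy")
        self._diff_fn = sp.lambdify(args, self._Sigma, modules="numpy")
        self._meas_fn = sp.lambdify(args, self._h, modules="numpy")
        self._meas_jac_fn = sp.lambdify(args, self._h.jacobian(self.states),
                                        modules="numpy")
        self._mcov_fn = sp.lambdify(args, self._S, modules="numpy")
        self._x0_fn = sp.lambdify((self.params,), self._x0, modules="numpy")
        self._compiled = {}

    # ------------------------------------------------------------------
    # callable field contracts
    # ------------------------------------------------------------------
    def drift(self, x, u, t, phi):
        """Drift vector f(x, u, t, phi)."""
        return np.asarray(self._drift_fn(np.asarray(x, float), u, t,
                                         np.asarray(phi, float)),
                          dtype=float).reshape(self.n_states)

    def diffusion(self, x_est, u, t, phi):
        """Diffusion matrix Sigma evaluated at a state *estimate*."""
        out = np.asarray(self._diff_fn(np.asarray(x_est, float), u, t,
                                       np.asarray(phi, float)), dtype=float)
        return out.reshape(self.n_states, self.n_wiener)

    def measurement(self, x, u, t, phi):
        """Output vector h(x, u, t, phi)."""
        return np.asarray(self._meas_fn(np.asarray(x, float), u, t,
                                        np.asarray(phi, float)),
                          dtype=float).reshape(self.n_outputs)

    def measurement_jac(self, x, u, t, phi):
        """Output Jacobian C = dh/dx."""
        out = np.asarray(self._meas_jac_fn(np.asarray(x, float), u, t,
                                           np.asarray(phi, float)), dtype=float)
        return out.reshape(self.n_outputs, self.n_states)

    def measurement_cov(self, x, u, t, phi):
        """Measurement covariance S(x, u, t, phi)."""
        out = np.asarray(self._mcov_fn(np.asarray(x, float), u, t,
                                       np.asarray(phi, float)), dtype=float)
        return out.reshape(self.n_outputs, self.n_outputs)

    def initial_state(self, phi):
        """Initial state x0(phi)."""
        phi = np.asarray(phi, dtype=float)
        self.check_params(phi)
        return np.asarray(self._x0_fn(phi), dtype=float).reshape(self.n_states)

    def check_params(self, phi):
        if len(phi) != self.n_params:
            raise ValueError(
                f"expected {self.n_params} individual parameters, got {len(phi)}"
            )
        if self.validate_params is not None:
            self.validate_params(np.asarray(phi, dtype=float))

    # ------------------------------------------------------------------
    def compiled(self, jit: bool = False):
        """Compiled filtering/sensitivity kernels (cached per jit flag)."""
        if jit not in self._compiled:
            from ._compile import CompiledDynamics

            self._compiled[jit] = CompiledDynamics(self, jit=jit)
        return self._compiled[jit]

    def __repr__(self):
        return (f"DynamicModel({self.name!r}, n_states={self.n_states}, "
                f"n_wiener={self.n_wiener}, n_outputs={self.n_outputs})")


class IndividualParameterMap:
    """Map phi = g(theta, Z, eta) from population to individual parameters.

    Declared symbolically; covariates Z are carried through the interface but
    unused by the built-in models.  ``transform(theta, Z, eta)`` evaluates g;
    with ``eta = 0`` it returns the typical-subject parameter vector.
    """

    def __init__(self, theta_syms, eta_syms, exprs):
        self.theta_syms = list(theta_syms)
        self.eta_syms = list(eta_syms)
        self.exprs = sp.Matrix(exprs)
        self.n_random = len(self.eta_syms)
        self.n_theta = len(self.theta_syms)
        self.n_phi = self.exprs.shape[0]
        eta_set = set(self.eta_syms)
        #: indices of phi entries that depend on any random effect
        self.random_rows = [
            i for i in range(self.n_phi)
            if self.exprs[i].free_symbols & eta_set
        ]

        th, et = self.theta_syms, self.eta_syms
        self._g = sp.lambdify((th, et), self.exprs, modules="numpy")
        self._g_theta = sp.lambdify((th, et), self.exprs.jacobian(th),
                                    modules="numpy")
        if self.n_random:
            J_eta = self.exprs.jacobian(et)
            self._g_eta = sp.lambdify((th, et), J_eta, modules="numpy")
            # second derivatives needed by the population-gradient chain rule
            g_ee = [[sp.diff(J_eta[:, a], e) for e in et] for a in range(len(et))]
            self._g_eta_eta = sp.lambdify(
                (th, et),
                [[list(g_ee[a][b]) for b in range(len(et))] for a in range(len(et))],
                modules="numpy",
            )
            g_et = [[sp.diff(J_eta[:, a], s) for s in th] for a in range(len(et))]
            self._g_eta_theta = sp.lambdify(
                (th, et),
                [[list(g_et[a][b]) for b in range(len(th))] for a in range(len(et))],
                modules="numpy",
            )
        else:
            self._g_eta = None
            self._g_eta_eta = None
            self._g_eta_theta = None

    def transform(self, theta, Z=None, eta=None):
        """Individual parameters phi = g(theta, Z, eta)."""
        theta = np.asarray(theta, dtype=float)
        if eta is None:
            eta = np.zeros(self.n_random)
        eta = np.asarray(eta, dtype=float)
        if eta.shape != (self.n_random,):
            raise ValueError(
                f"expected {self.n_random} random effects, got shape {eta.shape}"
            )
        if theta.shape != (self.n_theta,):
            raise ValueError(
                f"expected {self.n_theta} fixed effects, got shape {theta.shape}"
            )
        return np.asarray(self._g(theta, eta), dtype=float).reshape(self.n_phi)

    __call__ = transform

    def jac_theta(self, theta, eta):
        return np.asarray(self._g_theta(theta, eta), float).reshape(
            self.n_phi, self.n_theta)

    def jac_eta(self, theta, eta):
        return np.asarray(self._g_eta(theta, eta), float).reshape(
            self.n_phi, self.n_random)

    def hess_eta_eta(self, theta, eta):
        """d2 phi / d eta_a d eta_b, shape (n_phi, r, r)."""
        arr = np.asarray(self._g_eta_eta(theta, eta), float)
        return arr.reshape(self.n_random, self.n_random, self.n_phi).transpose(2, 0, 1)

    def hess_eta_theta(self, theta, eta):
        """d2 phi / d eta_a d theta_m, shape (n_phi, r, n_theta)."""
        arr = np.asarray(self._g_eta_theta(theta, eta), float)
        return arr.reshape(self.n_random, self.n_theta, self.n_phi).transpose(2, 0, 1)


@dataclass
class PopulationParameters:
    """Fixed effects plus the upper-triangular factor of Omega.

    ``theta`` holds the structural and error-model parameters on their natural
    scale; ``omega_factor`` is the upper-triangular U with Omega = U Uᵀ.
    """

    theta: np.ndarray
    omega_factor: np.ndarray

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        self.omega_factor = np.asarray(self.omega_factor, dtype=float)
        if not np.all(np.isfinite(self.theta)) or not np.all(
            np.isfinite(self.omega_factor)
        ):
            raise ValueError("population parameters must be finite")

    @property
    def omega(self) -> np.ndarray:
        return build_omega(self.omega_factor)


def build_omega(omega_factor) -> np.ndarray:
    """Random-effects covariance Omega = U Uᵀ from its upper-triangular factor.

    Raises ValueError if the factor is not square upper-triangular.  The
    product is symmetric positive semidefinite by construction; for the 2x2
    case it equals [[w11^2 + w12^2, w12 w22], [w12 w22, w22^2]].
    """
    U = np.asarray(omega_factor, dtype=float)
    if U.ndim != 2 or U.shape[0] != U.shape[1]:
        raise ValueError("omega factor must be a square matrix")
    if not np.allclose(U, np.triu(U)):
        raise ValueError("omega factor must be upper-triangular")
    return U @ U.T


def map_individual_parameters(pmap: IndividualParameterMap, theta, Z=None, eta=None):
    """Evaluate phi = g(theta, Z, eta) through an IndividualParameterMap."""
    return pmap.transform(theta, Z, eta)


# ---------------------------------------------------------------------------
# population-model bundle
# ---------------------------------------------------------------------------

def _triu_indices(r):
    return [(i, j) for i in range(r) for j in range(i, r)]


@dataclass
class PopulationModel:
    """A DynamicModel together with its population parameter layer.

    ``theta_names`` is the full fixed-effect vector in reporting order,
    containing the structural/error parameters fed to the individual map and
    the entries of the upper-triangular Omega factor.  ``struct_idx`` selects
    the map arguments from theta, ``omega_idx`` the factor entries (row-major
    upper triangle: w11, w12, ..., w22, ...).
    """

    name: str
    dynamic: DynamicModel
    pmap: IndividualParameterMap
    theta_names: list
    struct_idx: np.ndarray
    omega_idx: np.ndarray
    default_start: np.ndarray
    sigma_name: str = "sigma"
    default_method: str = "focei"
    jit: bool = True
    _extra: dict = field(default_factory=dict)

    def __post_init__(self):
        self.struct_idx = np.asarray(self.struct_idx, dtype=int)
        self.omega_idx = np.asarray(self.omega_idx, dtype=int)
        self.default_start = np.asarray(self.default_start, dtype=float)
        self.n_theta = len(self.theta_names)
        self.n_random = self.pmap.n_random
        self._tri = _triu_indices(self.n_random)
        if len(self._tri) != self.omega_idx.size:
            raise ValueError("omega_idx size does not match n_random")
        self.dynamic.default_jit = bool(self.jit)
        # log scale for positivity except the sign-free off-diagonal factor
        # entries of U
        offdiag = {self.omega_idx[k] for k, (i, j) in enumerate(self._tri) if i != j}
        self.scales = [
            "identity" if i in offdiag else "log" for i in range(self.n_theta)
        ]

    # -- theta bookkeeping ----------------------------------------------
    def split(self, theta):
        theta = np.asarray(theta, dtype=float)
        return theta[self.struct_idx], theta[self.omega_idx]

    def omega_factor(self, theta) -> np.ndarray:
        _, w = self.split(theta)
        r = self.n_random
        U = np.zeros((r, r))
        for k, (i, j) in enumerate(self._tri):
            U[i, j] = w[k]
        return U

    def omega(self, theta) -> np.ndarray:
        return build_omega(self.omega_factor(theta))

    def omega_derivs(self, theta) -> np.ndarray:
        """dOmega/dw_k for each factor entry, shape (n_tri, r, r)."""
        U = self.omega_factor(theta)
        r = self.n_random
        out = np.zeros((len(self._tri), r, r))
        for k, (i, j) in enumerate(self._tri):
            E = np.zeros((r, r))
            E[i, j] = 1.0
            out[k] = E @ U.T + U @ E.T
        return out

    def phi(self, theta, eta=None):
        ts, _ = self.split(theta)
        return self.pmap.transform(ts, None, eta)

    def compiled(self):
        return self.dynamic.compiled(jit=self.jit)


# ---------------------------------------------------------------------------
# built-in model 1: one-compartment PK, first-order absorption,
# Michaelis-Menten elimination, system noise proportional to the predicted
# plasma concentration
# ---------------------------------------------------------------------------

#: simulation truth of the replicate study
#: theta = (ka, Vm, Km, V, s, w11, w12, w22, sigma)
APP1_TRUE = np.array([0.1, 0.5, 3.0, 1.0, 0.1, 0.5, 0.1, 0.3, 0.05])
#: estimation starting values of the replicate study
APP1_START = np.array([0.2, 1.0, 1.0, 2.0, 0.5, 0.1, 0.0, 0.1, 0.01])

APP1_THETA_NAMES = ["ka", "Vm", "Km", "V", "s", "omega11", "omega12",
                    "omega22", "sigma"]


def one_compartment_pk_model(error_model: str = "additive",
                             mass_balance_noise: bool = False) -> DynamicModel:
    """Two-state PK model: GI-tract amount A and plasma concentration C.

        dA = -ka_i A dt,                          A(0) = 20 mg
        V dC = (ka_i A - Vm_i C / (Km + C)) dt + sigma Chat dW,  C(0) = 0
        y = C + e,  e ~ N(0, s^2)

    The system noise is proportional to the filter's predicted concentration
    Chat and enters the plasma equation only (it models uncertainty in the
    elimination process, so no mass-balance pairing with the absorption
    state); ``mass_balance_noise=True`` instead adds the same noise term with
    opposite sign to the amount equation, conserving mass.
    """
    A, C = sp.symbols("A C")
    ka, Vm, Km, V, s, sig = sp.symbols("ka_i Vm_i Km V s sigma")
    drift = sp.Matrix([
        -ka * A,
        (ka * A - Vm * C / (Km + C)) / V,
    ])
    if mass_balance_noise:
        diffusion = sp.Matrix([[-sig * C], [sig * C / V]])
    else:
        diffusion = sp.Matrix([[sp.Integer(0)], [sig * C / V]])
    h = sp.Matrix([C])
    if error_model == "additive":
        S = sp.Matrix([[s ** 2]])
    elif error_model == "proportional":
        S = sp.Matrix([[(s * C) ** 2]])
    else:
        raise ValueError(f"unknown error model {error_model!r}")
    return DynamicModel(
        states=[A, C],
        params=[ka, Vm, Km, V, s, sig],
        drift=drift,
        diffusion=diffusion,
        measurement=h,
        measurement_cov=S,
        initial_state=sp.Matrix([20, 0]),
        state_names=["amount_gi [mg]", "conc_plasma [mg/L]"],
        name="one_compartment_abs_mm",
    )


def one_compartment_pk_map() -> IndividualParameterMap:
    """Log-normal inter-individual variability on ka and Vm."""
    ka, Vm, Km, V, s, sig = sp.symbols("ka Vm Km V s sigma")
    e1, e2 = sp.symbols("eta1 eta2")
    return IndividualParameterMap(
        theta_syms=[ka, Vm, Km, V, s, sig],
        eta_syms=[e1, e2],
        exprs=[ka * sp.exp(e1), Vm * sp.exp(e2), Km, V, s, sig],
    )


def one_compartment_pk(error_model: str = "additive",
                       mass_balance_noise: bool = False,
                       jit: bool = True) -> PopulationModel:
    return PopulationModel(
        name="one_compartment_abs_mm",
        dynamic=one_compartment_pk_model(error_model, mass_balance_noise),
        pmap=one_compartment_pk_map(),
        theta_names=list(APP1_THETA_NAMES),
        struct_idx=[0, 1, 2, 3, 4, 8],
        omega_idx=[5, 6, 7],
        default_start=APP1_START,
        default_method="focei",
        jit=jit,
    )


# ---------------------------------------------------------------------------
# built-in model 2: NiAc disposition (structure only; exercised on synthetic
# data).  One-compartment turnover with endogenous synthesis, capacity-limited
# elimination, infusion input and a steady-state initial condition.
# ---------------------------------------------------------------------------

NIAC_THETA_NAMES = ["Vm", "Km", "Vc", "Synt", "s", "omega", "sigma"]
#: estimation starting values (structural values from the original
#: deterministic analysis of the rat study)
NIAC_START = np.array([1.8, 23.0, 0.319, 0.00125, 0.1, 0.1, 0.01])
#: truth used for the synthetic parameter-recovery study (the stochastic
#: disposition-model estimates reported for the rat data)
NIAC_SYNTH_TRUE = np.array([1.35, 13.6, 0.32, 0.0018, 0.241, 0.133, 0.033])


def _niac_validate(phi):
    if phi[0] <= phi[3]:
        raise ValueError(
            "NiAc model requires V_m > Synt for a well-defined steady-state "
            f"initial condition (got V_m={phi[0]}, Synt={phi[3]})"
        )


def niac_model(error_model: str = "proportional") -> DynamicModel:
    """One-state NiAc disposition model.

        Vc dc = (u + Synt - Vm_i c / (Km + c)) dt + sigma chat dW,
        c(0) = Synt Km / (Vm_i - Synt)

    with proportional residual error S = (s chat)^2 by default (additive
    available as a config switch).  The initial condition is the drug-free
    steady state, so the drift vanishes there when u = 0.
    """
    c = sp.Symbol("c")
    Vm, Km, Vc, Synt, s, sig = sp.symbols("Vm_i Km Vc Synt s sigma")
    drift = sp.Matrix([(INPUT + Synt - Vm * c / (Km + c)) / Vc])
    diffusion = sp.Matrix([[sig * c / Vc]])
    h = sp.Matrix([c])
    if error_model == "proportional":
        S = sp.Matrix([[(s * c) ** 2]])
    elif error_model == "additive":
        S = sp.Matrix([[s ** 2]])
    else:
        raise ValueError(f"unknown error model {error_model!r}")
    return DynamicModel(
        states=[c],
        params=[Vm, Km, Vc, Synt, s, sig],
        drift=drift,
        diffusion=diffusion,
        measurement=h,
        measurement_cov=S,
        initial_state=sp.Matrix([Synt * Km / (Vm - Synt)]),
        state_names=["conc_niac [umol/L]"],
        validate_params=_niac_validate,
        name="niac_disposition",
    )


def niac_map() -> IndividualParameterMap:
    """Log-normal inter-individual variability on Vm only."""
    Vm, Km, Vc, Synt, s, sig = sp.symbols("Vm Km Vc Synt s sigma")
    e1 = sp.Symbol("eta1")
    return IndividualParameterMap(
        theta_syms=[Vm, Km, Vc, Synt, s, sig],
        eta_syms=[e1],
        exprs=[Vm * sp.exp(e1), Km, Vc, Synt, s, sig],
    )


def niac(error_model: str = "proportional", jit: bool = True) -> PopulationModel:
    return PopulationModel(
        name="niac_disposition",
        dynamic=niac_model(error_model),
        pmap=niac_map(),
        theta_names=list(NIAC_THETA_NAMES),
        struct_idx=[0, 1, 2, 3, 4, 6],
        omega_idx=[5],
        default_start=NIAC_START,
        default_method="foce",
        jit=jit,
    )


MODEL_REGISTRY = {
    "one_compartment_abs_mm": one_compartment_pk,
    "niac_disposition": niac,
}


def get_model(name: str, **config) -> PopulationModel:
    """Look up a registered population model by name."""
    try:
        builder = MODEL_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; available: {sorted(MODEL_REGISTRY)}"
        ) from None
    return builder(**config)
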