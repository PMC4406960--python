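"""Synthetic-data generation: Euler-Maruyama simulation of SDMEM datasets.

The replicate simulation study this package is validated on draws, per
subject, random effects eta_i ~ N(0, U Uᵀ), maps them to individual
parameters, integrates the latent SDE with the Euler-Maruyama scheme

    x_{t+h} = x_t + f(x_t, u, t, phi) h + Sigma(x_t, u, t, phi) sqrt(h) z,
    z ~ N(0, I_q),

and adds measurement noise drawn from S(x(t_k)) at the observation times.
During simulation the (state-estimate-dependent) diffusion function is
evaluated at the current simulated state; no filter runs here.

The default internal step of 0.01 min is adequate for the shipped
PK-timescale models (strong order 0.5; verified against the
Ornstein-Uhlenbeck stationary law and the noise-free ODE limit in the test
suite).  Latent states are never clipped inside the integration; clipping
would silently bias the moments of the proportional-noise models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _core
from .models import (DynamicModel, IndividualParameterMap,
                     PiecewiseConstantInput, PopulationParameters)

__all__ = [
    "StudyDesign",
    "SubjectData",
    "Dataset",
    "simulate_individual_path",
    "simulate_population_dataset",
    "app1_design",
]

DEFAULT_STEP = 0.01  # minutes


@dataclass
class StudyDesign:
    """Sampling design of a (simulated) population study.

    ``inputs`` optionally assigns a PiecewiseConstantInput per subject (one
    entry recycled for all, or one per subject) for infusion designs; the
    model default input is used if omitted.
    """

    n_subjects: int
    observation_times: np.ndarray
    seed: int = 0
    step: float = DEFAULT_STEP
    t0: float = 0.0
    inputs: list = None

    def __post_init__(self):
        self.observation_times = np.asarray(self.observation_times,
                                            dtype=float)
        if self.observation_times.ndim != 1 or np.any(
            np.diff(self.observation_times) <= 0
        ):
            raise ValueError("observation times must be strictly increasing")
        if np.any(self.observation_times < self.t0):
            raise ValueError("observation times must be nonnegative "
                             "(not precede t0)")
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")

    def input_for(self, i: int):
        if self.inputs is None:
            return None
        if len(self.inputs) == 1:
            return self.inputs[0]
        return self.inputs[i]


def app1_design(n_subjects: int = 20, seed: int = 0,
                step: float = DEFAULT_STEP) -> StudyDesign:
    """The replicate-study design: 20 subjects, observations at
    t = 1, 9, 17, ..., 97 minutes."""
    return StudyDesign(n_subjects=n_subjects,
                       observation_times=np.arange(1.0, 98.0, 8.0),
                       seed=seed, step=step)


def niac_design(n_group1: int = 8, n_group2: int = 7, seed: int = 0,
                step: float = DEFAULT_STEP) -> StudyDesign:
    """Synthetic two-infusion-group design for the NiAc disposition model.

    Group 1 receives 0.67 umol min^-1 kg^-1 over 30 min (20 umol/kg total),
    group 2 receives 0.17 umol min^-1 kg^-1 over 300 min (51 umol/kg); a
    shared sampling grid covers the infusion, washout and the long infusion
    tail.
    """
    from .models import PiecewiseConstantInput

    times = np.array([5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 35.0, 40.0, 50.0,
                      60.0, 90.0, 150.0, 210.0, 270.0, 300.0, 310.0, 330.0,
                      360.0])
    u1 = PiecewiseConstantInput.infusion(0.67, 30.0)
    u2 = PiecewiseConstantInput.infusion(0.17, 300.0)
    inputs = [u1] * n_group1 + [u2] * n_group2
    return StudyDesign(n_subjects=n_group1 + n_group2,
                       observation_times=times, seed=seed, step=step,
                       inputs=inputs)


@dataclass
class SubjectData:
    """Observations (and, when simulated, the latent truth) for one subject."""

    id: object
    times: np.ndarray
    y: np.ndarray
    input: PiecewiseConstantInput = None
    eta_true: np.ndarray = None
    phi_true: np.ndarray = None
    latent: np.ndarray = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.y.ndim == 1:
            self.y = self.y[:, None]
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError(
                f"subject {self.id}: times must be strictly increasing")

    @property
    def n_obs(self) -> int:
        return len(self.times)


@dataclass
class Dataset:
    """A collection of per-subject longitudinal records."""

    subjects: list = field(default_factory=list)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    def __getitem__(self, i):
        return self.subjects[i]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            for t, yv in zip(s.times, s.y):
                rows.append((s.id, t, float(yv[0])))
        return pd.DataFrame(rows, columns=["ID", "TIME", "DV"])

    def truth_frame(self) -> pd.DataFrame:
        """Per-subject simulated truth (random effects and parameters)."""
        rows = []
        for s in self.subjects:
            if s.eta_true is None:
                continue
            row = {"ID": s.id}
            row.update({f"eta{j + 1}": v for j, v in enumerate(s.eta_true)})
            if s.phi_true is not None:
                row.update({f"phi{j + 1}": v for j, v in enumerate(s.phi_true)})
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------

def _sim_segments(t0, times, u: PiecewiseConstantInput, step):
    nodes = [t0]
    obs_seg = []
    prev = t0
    for k, tk in enumerate(times):
        for br in u.segment_points(prev, tk):
            nodes.append(br)
            obs_seg.append(-1)
        nodes.append(tk)
        obs_seg.append(k)
        prev = tk
    seg_t = np.asarray(nodes, dtype=float)
    seg_u = np.array([u(0.5 * (a + b)) if b > a else u(a)
                      for a, b in zip(seg_t[:-1], seg_t[1:])], dtype=float)
    nsteps = np.maximum(np.ceil((seg_t[1:] - seg_t[:-1]) / step - 1e-9), 0
                        ).astype(np.int64)
    nsteps[(seg_t[1:] > seg_t[:-1]) & (nsteps == 0)] = 1
    return seg_t, np.atleast_1d(seg_u), np.asarray(obs_seg, np.int64), nsteps


def simulate_individual_path(model: DynamicModel, phi, design: StudyDesign,
                             step: float = None, seed: int = None, u=None,
                             store_path: bool = False):
    """Simulate one latent path and its noisy observations.

    Returns ``(path, observations)`` where ``path`` is a dict with the latent
    states at the observation times (and the dense path when
    ``store_path=True``) and ``observations`` is the (K, m) array of measured
    values.  The same seed reproduces the output bitwise.
    """
    step = design.step if step is None else float(step)
    if step <= 0:
        raise ValueError("step must be positive")
    phi = np.asarray(phi, dtype=float)
    model.check_params(phi)
    u = u if u is not None else model.input
    times = design.observation_times
    seed = design.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    comp = model.compiled(jit=model.default_jit)
    n, q, m = comp.n, comp.q, comp.m
    seg_t, seg_u, obs_seg, nsteps = _sim_segments(design.t0, times, u, step)
    tot = int(nsteps.sum())
    zr = rng.standard_normal((tot, max(q, 1))) if q > 0 else np.zeros((tot, 1))

    x0 = model.initial_state(phi)
    if store_path:
        full_t = np.zeros(tot + 1)
        full_x = np.zeros((tot + 1, n))
        full_t[0] = design.t0
        full_x[0] = x0
    else:
        full_t = np.zeros(1)
        full_x = np.zeros((1, n))

    path_nodes = comp.kernels.em(seg_t, seg_u, nsteps, phi, x0, zr,
                                 comp.fn_f_raw, comp.fn_sig_raw, n, q,
                                 bool(store_path), full_t, full_x)

    K = len(times)
    latent = np.zeros((K, n))
    for s_i, k in enumerate(obs_seg):
        if k >= 0:
            latent[k] = path_nodes[s_i + 1]

    ys = np.zeros((K, m))
    for k in range(K):
        tk = times[k]
        hx = model.measurement(latent[k], u(tk), tk, phi)
        S = model.measurement_cov(latent[k], u(tk), tk, phi)
        e = rng.multivariate_normal(np.zeros(m), S) if m > 1 else (
            rng.standard_normal(1) * np.sqrt(max(S[0, 0], 0.0)))
        ys[k] = hx + e
    path = {"times": times.copy(), "latent": latent}
    if store_path:
        path["dense_t"] = full_t
        path["dense_x"] = full_x
    return path, ys


def simulate_population_dataset(model: DynamicModel,
                                population: PopulationParameters,
                                pmap: IndividualParameterMap,
                                design: StudyDesign) -> Dataset:
    """Simulate a full population dataset.

    Draws eta_i ~ N(0, U Uᵀ) independently per subject, maps to phi_i and
    simulates each subject independently with a subject-specific stream
    spawned from the design seed; the true eta_i/phi_i and latent states are
    retained on the returned Dataset.
    """
    omega = population.omega
    r = omega.shape[0]
    if r != pmap.n_random:
        raise ValueError("omega dimension does not match the parameter map")
    ss = np.random.SeedSequence(design.seed)
    eta_rng = np.random.default_rng(ss.spawn(1)[0])
    child_seeds = ss.spawn(design.n_subjects + 1)[1:]

    try:
        L = np.linalg.cholesky(omega + 1e-300 * np.eye(max(r, 1)))
    except np.linalg.LinAlgError:
        # PSD but singular omega: use an eigenvalue square root
        w, V = np.linalg.eigh(omega)
        L = V @ np.diag(np.sqrt(np.clip(w, 0, None)))

    subjects = []
    for i in range(design.n_subjects):
        eta = L @ eta_rng.standard_normal(r) if r else np.zeros(0)
        phi = pmap.transform(population.theta, None, eta)
        u = design.input_for(i)
        path, ys = simulate_individual_path(
            model, phi, design, seed=child_seeds[i], u=u)
        subjects.append(SubjectData(
            id=i + 1, times=design.observation_times.copy(), y=ys,
            input=u if u is not None else model.input,
            eta_true=eta, phi_true=phi, latent=path["latent"]))
    return Dataset(subjects)
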