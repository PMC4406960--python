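"""Continuous-discrete extended Kalman filter and fixed-interval smoother.

Between observations the state estimate xhat and its covariance P are
propagated by the prediction ODEs

    d xhat/dt = f(xhat, u, t, phi)
    d P/dt    = A P + P Aᵀ + Sigma Sigmaᵀ,      A = df/dx |_{xhat},

with continuous relinearization (A and Sigma re-evaluated along xhat inside
the integrator).  At an observation y_k the one-step output prediction,
residual and output covariance are

    yhat = h(xhat),  eps_k = y_k - yhat,  R_k = C P Cᵀ + S,  C = dh/dx,

and the Kalman update is K = P Cᵀ R⁻¹, xhat⁺ = xhat + K eps,
P⁺ = P - K R Kᵀ (re-symmetrized).  These residuals and output covariances
are exactly the ingredients of the individual likelihood.

The default initial covariance is P0 = 0: both shipped models define the
initial state exactly given the individual parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _core
from .models import DynamicModel, PiecewiseConstantInput

__all__ = [
    "FilterState",
    "FilterTrajectory",
    "SmoothedTrajectory",
    "FilterError",
    "ekf_predict",
    "ekf_update",
    "ekf_filter",
    "rts_smooth",
]


class FilterError(RuntimeError):
    """Numerical failure inside the filter (integration or singular R)."""


@dataclass
class FilterState:
    """Filter mean and covariance at a point in time."""

    time: float
    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self):
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        n = self.mean.shape[0]
        if self.cov.shape != (n, n):
            raise ValueError("covariance shape does not match state dimension")


@dataclass
class FilterTrajectory:
    """Per-observation EKF quantities for one subject.

    ``residuals[k] = y[k] - ypred[k]`` exactly, and ``output_cov[k]`` is the
    one-step output covariance R_{k|k-1}; these feed the likelihood.  The
    pre/post means and covariances and the per-interval transition matrices
    support smoothing and diagnostic plots.
    """

    times: np.ndarray
    y: np.ndarray
    ypred: np.ndarray
    residuals: np.ndarray
    output_cov: np.ndarray
    gain: np.ndarray
    mean_pred: np.ndarray
    cov_pred: np.ndarray
    mean_filt: np.ndarray
    cov_filt: np.ndarray
    transition: np.ndarray
    initial: FilterState
    model: DynamicModel = None
    phi: np.ndarray = None
    input: PiecewiseConstantInput = None
    dense: dict = field(default_factory=dict)

    @property
    def n_obs(self) -> int:
        return len(self.times)

    def to_frame(self):
        """Per-observation table (time, y, prediction, filtered mean,
        output sd) for plotting/export."""
        import pandas as pd

        rows = {"time": self.times, "y": self.y[:, 0],
                "y_pred": self.ypred[:, 0],
                "residual": self.residuals[:, 0],
                "output_sd": np.sqrt(self.output_cov[:, 0, 0])}
        for i in range(self.mean_filt.shape[1]):
            rows[f"mean_filt_{i}"] = self.mean_filt[:, i]
            rows[f"mean_pred_{i}"] = self.mean_pred[:, i]
        return pd.DataFrame(rows)

    def dense_prediction(self, points_per_interval: int = 20):
        """Inter-observation prediction grid (time, mean, cov, output sd).

        Integrates the prediction ODE from each filtered state across the
        following interval; useful for uncertainty-band plots where the
        output sd dips at observations and grows between them.
        """
        comp = self.model.compiled(jit=False)
        n = comp.n
        u = self.input or PiecewiseConstantInput.zero()
        t_all, w_all = [], []
        t_prev = self.initial.time
        w = np.concatenate([self.initial.mean, self.initial.cov.ravel()])
        for k in range(self.n_obs + 1):
            t_next = self.times[k] if k < self.n_obs else None
            if t_next is None:
                break
            grid = np.linspace(t_prev, t_next, points_per_interval + 1)[1:]
            seg_u = np.array([u(0.5 * (a + b))
                              for a, b in zip(np.r_[t_prev, grid[:-1]], grid)])
            out, status = _core.predict_grid(t_prev, grid, seg_u,
                                             np.asarray(self.phi, float), w,
                                             1e-8, 1e-10, comp.kernels, n,
                                             comp.p)
            if status != 0:
                raise FilterError("dense prediction failed")
            t_all.append(grid)
            w_all.append(out)
            w = np.concatenate([self.mean_filt[k], self.cov_filt[k].ravel()])
            t_prev = t_next
        t_grid = np.concatenate(t_all)
        w_grid = np.vstack(w_all)
        means = w_grid[:, :n]
        covs = w_grid[:, n:].reshape(-1, n, n)
        out_sd = np.empty((len(t_grid), self.model.n_outputs))
        for i, (tt, xx, PP) in enumerate(zip(t_grid, means, covs)):
            C = self.model.measurement_jac(xx, u(tt), tt, self.phi)
            S = self.model.measurement_cov(xx, u(tt), tt, self.phi)
            out_sd[i] = np.sqrt(np.clip(np.diag(C @ PP @ C.T + S), 0, None))
        self.dense = {"t": t_grid, "mean": means, "cov": covs,
                      "output_sd": out_sd}
        return self.dense


@dataclass
class SmoothedTrajectory:
    """Fixed-interval smoothed means/covariances at the observation times."""

    times: np.ndarray
    mean: np.ndarray
    cov: np.ndarray


# ---------------------------------------------------------------------------
# segment construction shared by filter and simulator
# ---------------------------------------------------------------------------

def build_segments(t0, times, u: PiecewiseConstantInput):
    """Integration segments: boundaries at observations and input breaks.

    Returns (seg_t, seg_u, seg_obs) where seg_obs[i] is the observation index
    closed by segment i, or -1 for a pure input-break segment.
    """
    times = np.asarray(times, dtype=float)
    if times.size and times[0] < t0:
        raise ValueError("observation times must not precede the initial time")
    if np.any(np.diff(times) <= 0):
        raise ValueError("observation times must be strictly increasing")
    nodes = [t0]
    seg_obs = []
    prev = t0
    for k, tk in enumerate(times):
        for br in u.segment_points(prev, tk):
            nodes.append(br)
            seg_obs.append(-1)
        nodes.append(tk)
        seg_obs.append(k)
        prev = tk
    seg_t = np.asarray(nodes, dtype=float)
    seg_u = np.array([u(0.5 * (a + b)) if b > a else u(a)
                      for a, b in zip(seg_t[:-1], seg_t[1:])], dtype=float)
    return seg_t, np.atleast_1d(seg_u), np.asarray(seg_obs, dtype=np.int64)


def run_filter_pass(model: DynamicModel, phi, times, ys, *, P0=None, u=None,
                    t0=0.0, order=0, D=None, D2=None, pairs=None,
                    rtol=1e-8, atol=1e-10, want_phi=False, jit=None):
    """Low-level driver wrapper; returns the raw per-observation arrays.

    ``D`` (p x d) maps parameter directions to phi-space; ``pairs`` lists
    direction index pairs for second-order sensitivities, with ``D2`` the
    corresponding second derivatives of phi.
    """
    phi = np.asarray(phi, dtype=float)
    model.check_params(phi)
    if jit is None:
        jit = model.default_jit
    comp = model.compiled(jit=bool(jit))
    n, m, p = comp.n, comp.m, comp.p
    nw = comp.nw
    ys = np.asarray(ys, dtype=float).reshape(-1, m)
    times = np.asarray(times, dtype=float)
    if ys.shape[0] != times.shape[0]:
        raise ValueError("times and observations must align")
    u = u if u is not None else model.input
    seg_t, seg_u, seg_obs = build_segments(t0, times, u)

    if P0 is None:
        P0 = np.zeros((n, n))
    P0 = np.asarray(P0, dtype=float).reshape(n, n)
    x0, x0J, x0J2 = comp.x0_and_derivs(phi)
    w0 = np.concatenate([x0, P0.ravel()])

    if D is None:
        D = np.zeros((p, 0))
    D = np.ascontiguousarray(np.asarray(D, dtype=float).reshape(p, -1))
    d = D.shape[1]
    if pairs is None:
        pairs = []
    pa = np.ascontiguousarray([a for a, _ in pairs], dtype=np.int64)
    pb = np.ascontiguousarray([b for _, b in pairs], dtype=np.int64)
    npair = len(pairs)
    if D2 is None:
        D2 = np.zeros((p, npair))
    D2 = np.ascontiguousarray(np.asarray(D2, dtype=float).reshape(p, npair))

    W0 = np.zeros((nw, d))
    W0[:n, :] = x0J @ D
    W20 = np.zeros((nw, npair))
    for q_, (a, b) in enumerate(pairs):
        W20[:n, q_] = x0J @ D2[:, q_] + np.einsum(
            "ijk,j,k->i", x0J2, D[:, a], D[:, b])

    out = _core.filter_pass(ys, seg_t, seg_u, seg_obs, phi, w0, W0, W20, D,
                            D2, pa, pb, float(rtol), float(atol), int(order),
                            bool(want_phi), comp.kernels, n, m, p)
    status = out[-1]
    if status == 1:
        raise FilterError(
            f"prediction ODE integration failed (model {model.name}, "
            f"phi={phi})")
    if status == 2:
        raise FilterError(
            f"singular one-step output covariance R (model {model.name}); "
            "check the measurement-error model (S = 0 with an uninformative "
            "state covariance leaves R non-invertible)")
    return out


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def ekf_predict(state: FilterState, model: DynamicModel, phi, t_next,
                u=None, rtol=1e-8, atol=1e-10) -> FilterState:
    """Propagate mean and covariance from ``state.time`` to ``t_next``.

    Integrates the joint mean/covariance ODE with A and Sigma continuously
    re-evaluated along the predicted mean.
    """
    if t_next < state.time:
        raise ValueError("t_next must not precede the current state time")
    if t_next == state.time:
        return FilterState(state.time, state.mean.copy(), state.cov.copy())
    phi = np.asarray(phi, dtype=float)
    model.check_params(phi)
    comp = model.compiled(jit=False)
    u = u if u is not None else model.input
    n = comp.n
    breaks = u.segment_points(state.time, t_next)
    grid = np.r_[breaks, t_next]
    seg_u = np.array([u(0.5 * (a + b)) for a, b in
                      zip(np.r_[state.time, grid[:-1]], grid)])
    w0 = np.concatenate([state.mean, state.cov.ravel()])
    out, status = _core.predict_grid(state.time, grid, seg_u, phi, w0,
                                     float(rtol), float(atol), comp.kernels,
                                     n, comp.p)
    if status != 0:
        raise FilterError(
            f"prediction ODE integration failed between t={state.time} and "
            f"t={t_next}")
    w = out[-1]
    P = w[n:].reshape(n, n)
    return FilterState(float(t_next), w[:n], 0.5 * (P + P.T))


def ekf_update(state: FilterState, y, model: DynamicModel, phi, u=None):
    """Linearized measurement update at ``state.time``.

    Returns (updated state, residual, output covariance, Kalman gain).
    """
    phi = np.asarray(phi, dtype=float)
    y = np.atleast_1d(np.asarray(y, dtype=float))
    uval = (u if np.isscalar(u) else
            (model.input(state.time) if u is None else u(state.time)))
    t = state.time
    x, P = state.mean, state.cov
    C = model.measurement_jac(x, uval, t, phi)
    S = model.measurement_cov(x, uval, t, phi)
    R = C @ P @ C.T + S
    sign, _ = np.linalg.slogdet(R)
    if sign <= 0 or not np.all(np.isfinite(R)):
        raise FilterError("singular output covariance R in update")
    Kg = P @ C.T @ np.linalg.inv(R)
    eps = y - model.measurement(x, uval, t, phi)
    x_new = x + Kg @ eps
    P_new = P - Kg @ R @ Kg.T
    P_new = 0.5 * (P_new + P_new.T)
    return FilterState(t, x_new, P_new), eps, R, Kg


def ekf_filter(model: DynamicModel, phi, times, ys, P0=None, u=None, t0=0.0,
               rtol=1e-8, atol=1e-10, jit=None) -> FilterTrajectory:
    """Run the full forward filter for one subject.

    Alternates prediction and update through all observations starting from
    (x0(phi), P0); P0 defaults to zero (exactly known initial state).
    """
    phi = np.asarray(phi, dtype=float)
    times = np.asarray(times, dtype=float)
    n, m = model.n_states, model.n_outputs
    u = u if u is not None else model.input
    x0 = model.initial_state(phi)
    if P0 is None:
        P0 = np.zeros((n, n))
    P0 = np.asarray(P0, dtype=float).reshape(n, n)
    init = FilterState(t0, x0, P0)
    ys = np.asarray(ys, dtype=float).reshape(-1, m)
    if times.size == 0:
        empty = np.zeros((0, m))
        return FilterTrajectory(
            times=times, y=ys, ypred=empty, residuals=empty,
            output_cov=np.zeros((0, m, m)), gain=np.zeros((0, n, m)),
            mean_pred=np.zeros((0, n)), cov_pred=np.zeros((0, n, n)),
            mean_filt=np.zeros((0, n)), cov_filt=np.zeros((0, n, n)),
            transition=np.zeros((0, n, n)), initial=init, model=model,
            phi=phi, input=u)

    (eps, Rm, xpred, xfilt, *_rest, Phi, status) = run_filter_pass(
        model, phi, times, ys, P0=P0, u=u, t0=t0, order=0, rtol=rtol,
        atol=atol, want_phi=True, jit=jit)

    K = len(times)
    mean_pred = xpred[:, :n]
    cov_pred = xpred[:, n:].reshape(K, n, n)
    mean_filt = xfilt[:, :n]
    cov_filt = xfilt[:, n:].reshape(K, n, n)
    gain = np.zeros((K, n, m))
    ypred = np.zeros((K, m))
    for k in range(K):
        uval = u(times[k])
        C = model.measurement_jac(mean_pred[k], uval, times[k], phi)
        gain[k] = cov_pred[k] @ C.T @ np.linalg.inv(Rm[k])
        ypred[k] = ys[k] - eps[k]
    return FilterTrajectory(
        times=times, y=ys, ypred=ypred, residuals=eps, output_cov=Rm,
        gain=gain, mean_pred=mean_pred, cov_pred=cov_pred,
        mean_filt=mean_filt, cov_filt=cov_filt, transition=Phi,
        initial=init, model=model, phi=phi, input=u)


def rts_smooth(traj: FilterTrajectory) -> SmoothedTrajectory:
    """Fixed-interval (Rauch-Tung-Striebel-type) smoothing pass.

    Conditions each filtered state on all of the subject's observations by a
    backward recursion over the linearized system,

        G_k = P_{k|k} Phi_{k+1}ᵀ P_{k+1|k}⁻¹
        xs_k = xhat_{k|k} + G_k (xs_{k+1} - xhat_{k+1|k})
        Ps_k = P_{k|k} + G_k (Ps_{k+1} - P_{k+1|k}) G_kᵀ,

    where Phi_{k+1} is the state-transition matrix of the linearized dynamics
    across (t_k, t_{k+1}].  A pseudo-inverse handles the deterministic limit
    (P identically zero), where smoothing reduces to the filtered solution.
    """
    K = traj.n_obs
    if K == 0:
        return SmoothedTrajectory(traj.times, np.zeros((0, 0)),
                                  np.zeros((0, 0, 0)))
    xs = traj.mean_filt.copy()
    Ps = traj.cov_filt.copy()
    for k in range(K - 2, -1, -1):
        Ppred = traj.cov_pred[k + 1]
        G = traj.cov_filt[k] @ traj.transition[k + 1].T @ np.linalg.pinv(
            Ppred, rcond=1e-12)
        xs[k] = traj.mean_filt[k] + G @ (xs[k + 1] - traj.mean_pred[k + 1])
        Ps[k] = traj.cov_filt[k] + G @ (Ps[k + 1] - Ppred) @ G.T
        Ps[k] = 0.5 * (Ps[k] + Ps[k].T)
    return SmoothedTrajectory(traj.times.copy(), xs, Ps)
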