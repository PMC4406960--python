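"""Sensitivity-equation machinery: exact gradients of the EKF outputs and of
the inner/outer objectives.

Instead of finite-differencing the objective (which is non-smooth at the
tolerance of an adaptive ODE solver), the prediction ODEs of the filter are
augmented with forward sensitivities of the state mean and covariance with
respect to the individual parameters, and the measurement update is
differentiated algebraically; this yields deps/dp and dR/dp for every
observation to solver accuracy (first *and* second order, the latter needed
by the population gradient).

Population-level chain rule: the Laplace objective per subject is

    F_i(theta) = -l_i(eta*(theta), theta) + 1/2 log|-Dl_i(eta*, theta)|
                 - r/2 log(2 pi)

with eta*(theta) defined by the inner stationarity d(-l_i)/deta = 0.  Its
exact gradient uses the implicit-function term
d eta*/d theta = -H_ee⁻¹ H_et  (H = exact Hessian of -l_i, assembled from
first- and second-order sensitivities), and the derivative of the
log-determinant term differentiates the *approximate* (first-order-only)
Hessian Dl, which again needs nothing beyond second-order sensitivities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import likelihood as lk
from .kalman import run_filter_pass
from .models import DynamicModel, IndividualParameterMap, PopulationModel

__all__ = [
    "SensitivityBundle",
    "filter_sensitivities",
    "inner_gradient",
    "outer_gradient",
    "SubjectWorkspace",
]


@dataclass
class SensitivityBundle:
    """Per-observation derivatives of the EKF outputs for a direction block."""

    block: str
    directions: np.ndarray          # (p, d) map from directions to phi-space
    deps: np.ndarray                # (K, m, d)
    dR: np.ndarray                  # (K, m, m, d)
    dx_pred: np.ndarray             # (K, n, d) predicted-mean sensitivities
    dP_pred: np.ndarray             # (K, n, n, d)
    eps: np.ndarray
    R: np.ndarray


def filter_sensitivities(model: DynamicModel, phi, data_i, block="phi",
                         D=None, theta=None, eta=None, pmap=None, jit=None,
                         rtol=1e-8, atol=1e-10) -> SensitivityBundle:
    """First-order sensitivities of eps, R, xhat and P for one subject.

    ``block='phi'`` differentiates w.r.t. the individual parameters
    themselves; ``block='eta'`` chains through an IndividualParameterMap
    (requires theta/eta/pmap); a custom direction matrix may be passed
    directly as ``D``.
    """
    p = model.n_params
    if D is None:
        if block == "phi":
            D = np.eye(p)
        elif block == "eta":
            if pmap is None or theta is None or eta is None:
                raise ValueError("eta block needs pmap, theta and eta")
            D = pmap.jac_eta(np.asarray(theta, float), np.asarray(eta, float))
        else:
            raise ValueError(f"unknown sensitivity block {block!r}")
    out = run_filter_pass(model, phi, data_i.times, data_i.y,
                          u=getattr(data_i, "input", None), order=1, D=D,
                          jit=jit, rtol=rtol, atol=atol)
    eps, R, xpred = out[0], out[1], out[2]
    e1, R1, W1pred = out[4], out[5], out[6]
    n = model.n_states
    K = eps.shape[0]
    d = np.asarray(D).shape[1]
    dx = W1pred[:, :n, :]
    dP = W1pred[:, n:, :].reshape(K, n, n, d)
    return SensitivityBundle(block=block, directions=np.asarray(D, float),
                             deps=e1, dR=R1, dx_pred=dx, dP_pred=dP,
                             eps=eps, R=R)


def inner_gradient(eta, data_i, theta, omega, model, pmap, sens=None,
                   jit=None, rtol=1e-8, atol=1e-10):
    """Gradient of the inner objective -l_i w.r.t. the random effects."""
    eta = np.asarray(eta, float)
    omega = np.atleast_2d(np.asarray(omega, float))
    if sens is None:
        phi = pmap.transform(theta, None, eta)
        sens = filter_sensitivities(model, phi, data_i, block="eta",
                                    theta=theta, eta=eta, pmap=pmap, jit=jit,
                                    rtol=rtol, atol=atol)
    prior_grad = np.linalg.solve(omega, eta)
    if sens.eps.shape[0] == 0:
        return prior_grad
    pr = lk.prep_residuals(sens.eps, sens.R)
    g, _ = lk.grad_data_nll(pr, sens.deps, sens.dR)
    return g + prior_grad


# ---------------------------------------------------------------------------
# population-objective machinery
# ---------------------------------------------------------------------------

def _select_pairs(p, random_rows):
    """Second-order phi pairs needed by the population gradient: at least
    one index must belong to a random-effect-dependent phi row."""
    rset = set(int(i) for i in random_rows)
    pairs = [(a, b) for a in range(p) for b in range(a, p)
             if a in rset or b in rset]
    index = {pair: i for i, pair in enumerate(pairs)}
    return pairs, index


class SubjectWorkspace:
    """Cached filtering/sensitivity computations for one subject.

    Used by the nested optimizer: value/gradient of the inner objective in
    eta directions, and the exact value/gradient of the subject's Laplace
    contribution in full population-parameter space.
    """

    def __init__(self, pm: PopulationModel, data_i, jit=None,
                 rtol=1e-8, atol=1e-10, grad_rtol=None):
        self.pm = pm
        self.data = data_i
        self.jit = pm.jit if jit is None else jit
        self.rtol = rtol
        self.atol = atol
        # the second-order (gradient) pass may run at a looser tolerance
        # than the objective-value passes; the population gradient is only
        # used for search directions and curvature
        self.grad_rtol = rtol if grad_rtol is None else grad_rtol
        self.grad_atol = atol if grad_rtol is None else grad_rtol * 1e-2
        self.p = pm.dynamic.n_params
        self.r = pm.n_random
        self.q_full = pm.n_theta
        self.rand_rows = list(pm.pmap.random_rows)
        self.pairs, self.pair_index = _select_pairs(self.p, self.rand_rows)
        self.eta_star = np.zeros(self.r)
        self.n_inner_calls = 0

    # -- inner problem ---------------------------------------------------
    def inner_value_grad(self, theta_full, eta):
        """(-l_i, d(-l_i)/deta) at eta."""
        pm = self.pm
        theta_s, _ = pm.split(theta_full)
        omega = pm.omega(theta_full)
        phi = pm.pmap.transform(theta_s, None, eta)
        self.n_inner_calls += 1
        if self.r:
            D = pm.pmap.jac_eta(theta_s, eta)
            out = run_filter_pass(pm.dynamic, phi, self.data.times,
                                  self.data.y,
                                  u=getattr(self.data, "input", None),
                                  order=1, D=D, jit=self.jit,
                                  rtol=self.rtol, atol=self.atol)
            eps, R, e1, R1 = out[0], out[1], out[4], out[5]
        else:
            out = run_filter_pass(pm.dynamic, phi, self.data.times,
                                  self.data.y,
                                  u=getattr(self.data, "input", None),
                                  order=0, jit=self.jit, rtol=self.rtol,
                                  atol=self.atol)
            eps, R = out[0], out[1]
            e1 = R1 = None
        if eps.shape[0]:
            pr = lk.prep_residuals(eps, R)
            val = lk.data_nll(None, None, prep=pr)
        else:
            pr = None
            val = 0.0
        grad = np.zeros(self.r)
        if self.r:
            val += lk.prior_nll(eta, omega)
            grad = np.linalg.solve(omega, eta)
            if pr is not None:
                gd, _ = lk.grad_data_nll(pr, e1, R1)
                grad = grad + gd
        self._last_eta_sens = (eps, R, e1, R1)
        return val, grad

    # -- full pass and chain rule ---------------------------------------
    def chained_pass(self, theta_full, eta):
        """Order-2 phi-space pass chained to eta/theta space.

        Returns a dict with residuals, first-order sensitivities in eta and
        full-theta directions, and the second-order blocks (eta x eta) and
        (eta x [theta, eta]) required by the exact population gradient.
        """
        pm = self.pm
        p, r, q_full = self.p, self.r, self.q_full
        theta_s, _ = pm.split(theta_full)
        phi = pm.pmap.transform(theta_s, None, eta)
        out = run_filter_pass(pm.dynamic, phi, self.data.times, self.data.y,
                              u=getattr(self.data, "input", None), order=2,
                              D=np.eye(p), pairs=self.pairs, jit=self.jit,
                              rtol=self.grad_rtol, atol=self.grad_atol)
        eps, R = out[0], out[1]
        e1p, R1p, e2p, R2p = out[4], out[5], out[8], out[9]
        K, m = eps.shape

        nr = len(self.rand_rows)
        # expand the selected pairs to dense (rand_row, any) second tensors
        e2 = np.zeros((K, m, nr, p))
        R2 = np.zeros((K, m, m, nr, p))
        for ci, c in enumerate(self.rand_rows):
            for cp in range(p):
                qi = self.pair_index.get((min(c, cp), max(c, cp)))
                e2[:, :, ci, cp] = e2p[:, :, qi]
                R2[:, :, :, ci, cp] = R2p[:, :, :, qi]

        Gh = pm.pmap.jac_eta(theta_s, eta) if r else np.zeros((p, 0))
        Gt = pm.pmap.jac_theta(theta_s, eta)
        Ghr = Gh[self.rand_rows, :] if r else np.zeros((0, 0))

        res = {"eps": eps, "R": R, "phi": phi}
        res["e1_eta"] = np.einsum("kxc,ca->kxa", e1p, Gh)
        res["R1_eta"] = np.einsum("kxyc,ca->kxya", R1p, Gh)
        # full-theta firsts: structural dims chained, omega dims zero
        e1_th = np.zeros((K, m, q_full))
        R1_th = np.zeros((K, m, m, q_full))
        e1_s = np.einsum("kxc,cm->kxm", e1p, Gt)
        R1_s = np.einsum("kxyc,cm->kxym", R1p, Gt)
        e1_th[:, :, pm.struct_idx] = e1_s
        R1_th[:, :, :, pm.struct_idx] = R1_s
        res["e1_th"] = e1_th
        res["R1_th"] = R1_th

        if r:
            Hee = pm.pmap.hess_eta_eta(theta_s, eta)
            Het = pm.pmap.hess_eta_theta(theta_s, eta)
            e2_ee = (np.einsum("kxij,ia,jb->kxab", e2, Ghr, Gh)
                     + np.einsum("kxc,cab->kxab", e1p, Hee))
            R2_ee = (np.einsum("kxyij,ia,jb->kxyab", R2, Ghr, Gh)
                     + np.einsum("kxyc,cab->kxyab", R1p, Hee))
            e2_es = (np.einsum("kxij,ia,jm->kxam", e2, Ghr, Gt)
                     + np.einsum("kxc,cam->kxam", e1p, Het))
            R2_es = (np.einsum("kxyij,ia,jm->kxyam", R2, Ghr, Gt)
                     + np.einsum("kxyc,cam->kxyam", R1p, Het))
            e2_et = np.zeros((K, m, r, q_full))
            R2_et = np.zeros((K, m, m, r, q_full))
            e2_et[:, :, :, pm.struct_idx] = e2_es
            R2_et[:, :, :, :, pm.struct_idx] = R2_es
            res.update(e2_ee=e2_ee, R2_ee=R2_ee, e2_et=e2_et, R2_et=R2_et)
        return res

    def laplace_value_grad(self, theta_full, eta_star, method):
        """Exact (value, d/dtheta_full) of this subject's Laplace term."""
        pm = self.pm
        r, q_full = self.r, self.q_full
        theta_full = np.asarray(theta_full, float)
        eta_star = np.asarray(eta_star, float)
        interaction = method.lower() == "focei"

        cp = self.chained_pass(theta_full, eta_star)
        eps, R = cp["eps"], cp["R"]
        K = eps.shape[0]
        have_data = K > 0

        # prior pieces
        if r:
            omega = pm.omega(theta_full)
            Winv = np.linalg.inv(omega)
            Winv_eta = Winv @ eta_star
            dOmega = pm.omega_derivs(theta_full)   # (n_tri, r, r)
        value = 0.0
        grad = np.zeros(q_full)

        if have_data:
            pr = lk.prep_residuals(eps, R)
            value += lk.data_nll(None, None, prep=pr)
            gth, _ = lk.grad_data_nll(pr, cp["e1_th"], cp["R1_th"])
            grad += gth
        if r:
            value += lk.prior_nll(eta_star, omega)
            for k_, m_ in enumerate(pm.omega_idx):
                dOm = dOmega[k_]
                grad[m_] += (-0.5 * float(Winv_eta @ dOm @ Winv_eta)
                             + 0.5 * float(np.trace(Winv @ dOm)))
        if r == 0:
            return value, grad, {"floored": False}

        # inner gradient (for the implicit term; ~0 at a converged optimum)
        g_eta = Winv_eta.copy()
        if have_data:
            gd, _ = lk.grad_data_nll(pr, cp["e1_eta"], cp["R1_eta"])
            g_eta = g_eta + gd

        # approximate Hessian of l and its directional derivatives
        if have_data:
            fo = lk.fo_d2_filter(pr, cp["e1_eta"], cp["R1_eta"],
                                 cp["e1_eta"], cp["R1_eta"],
                                 interaction=interaction)
        else:
            fo = np.zeros((r, r))
        M = fo + Winv                   # = -Dl
        M, floored = lk.floor_negdef(M)
        sign, logdetM = np.linalg.slogdet(M)
        value += 0.5 * (logdetM - r * lk.LOG2PI)
        Minv = np.linalg.inv(M)

        # directions: all theta_full, then eta
        dM_dirs = q_full + r
        if have_data:
            e1M = np.concatenate([cp["e1_th"], cp["e1_eta"]], axis=2)
            R1M = np.concatenate([cp["R1_th"], cp["R1_eta"]], axis=3)
            e2AM = np.concatenate([cp["e2_et"], cp["e2_ee"]], axis=3)
            R2AM = np.concatenate([cp["R2_et"], cp["R2_ee"]], axis=4)
            dfo = lk.d_fo_d2_filter(pr, cp["e1_eta"], cp["R1_eta"], e1M, R1M,
                                    e2AM, R2AM, interaction=interaction)
        else:
            dfo = np.zeros((r, r, dM_dirs))
        dM = dfo.copy()                 # d(-Dl)/d(direction)
        for k_, m_ in enumerate(pm.omega_idx):
            dM[:, :, m_] += -Winv @ dOmega[k_] @ Winv
        half_tr = 0.5 * np.einsum("ab,bam->m", Minv, dM)
        dF_theta = grad + half_tr[:q_full]
        dF_eta = g_eta + half_tr[q_full:]

        # exact Hessian blocks for d eta*/d theta
        if have_data:
            Hee = (lk.exact_d2_filter(pr, cp["e1_eta"], cp["R1_eta"],
                                      cp["e1_eta"], cp["R1_eta"],
                                      cp["e2_ee"], cp["R2_ee"]) + Winv)
            Het = lk.exact_d2_filter(pr, cp["e1_eta"], cp["R1_eta"],
                                     cp["e1_th"], cp["R1_th"],
                                     cp["e2_et"], cp["R2_et"])
        else:
            Hee = Winv.copy()
            Het = np.zeros((r, q_full))
        for k_, m_ in enumerate(pm.omega_idx):
            Het[:, m_] += -Winv @ dOmega[k_] @ Winv_eta
        Hee = 0.5 * (Hee + Hee.T)
        try:
            deta = -np.linalg.solve(Hee, Het)      # (r, q_full)
        except np.linalg.LinAlgError:
            deta = -np.linalg.pinv(Hee) @ Het

        total_grad = dF_theta + dF_eta @ deta
        return value, total_grad, {"floored": floored, "inner_grad": g_eta,
                                   "M": M}


def outer_gradient(theta_full, dataset, pm: PopulationModel, method=None,
                   eta_stars=None, jit=None, rtol=1e-8, atol=1e-10,
                   return_value=False):
    """Gradient of -log L w.r.t. the full population parameter vector.

    Solves each subject's inner problem (unless converged eta* values are
    supplied) and accumulates the exact per-subject Laplace gradients.
    """
    from .estimation import inner_optimize

    method = method or pm.default_method
    theta_full = np.asarray(theta_full, float)
    theta_s, _ = pm.split(theta_full)
    omega = pm.omega(theta_full) if pm.n_random else np.zeros((0, 0))
    total = np.zeros(pm.n_theta)
    value = 0.0
    for i, data_i in enumerate(dataset):
        if eta_stars is not None:
            eta = np.asarray(eta_stars[i], float)
        else:
            fit = inner_optimize(data_i, theta_s, omega, pm.dynamic, pm.pmap,
                                 method=method, jit=jit, rtol=rtol, atol=atol)
            eta = fit.eta_star
        ws = SubjectWorkspace(pm, data_i, jit=jit, rtol=rtol, atol=atol)
        v, g, _ = ws.laplace_value_grad(theta_full, eta, method)
        total += g
        value += v
    if return_value:
        return value, total
    return total
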