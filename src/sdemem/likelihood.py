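"""Individual and population likelihood approximations (Laplace/FOCE/FOCEI).

For subject i with EKF one-step residuals eps_ij and output covariances
R_ij, the a-posteriori log-likelihood of the random effects eta_i is

    l_i(eta) = -1/2 sum_j (eps_ijᵀ R_ij⁻¹ eps_ij + log|2 pi R_ij|)
               - 1/2 etaᵀ Omega⁻¹ eta - 1/2 log|2 pi Omega|,

and the marginal population likelihood is approximated by the Laplace
method around the inner mode eta* = argmax l_i:

    log L(theta) ≈ sum_i l_i(eta*) - 1/2 log| -Dl_i(eta*) / (2 pi) |,

where Dl_i is an approximation of the Hessian of l_i built from first-order
sensitivities of eps and R only:

  FOCE   (Dl)_ab = -sum_j  deps_aᵀ R⁻¹ deps_b            - (Omega⁻¹)_ab
  FOCEI  adds all dR/deta interaction terms (the quadratic-form derivatives
         and the 1/2 Tr(R⁻¹ dR_a R⁻¹ dR_b) term),

so FOCEI reduces exactly to FOCE when dR/deta = 0.  Second derivatives of
eps and R are dropped in both (first-order conditional approximation).

All assembly helpers below are batched over the observation index with the
convention eps (K, m), R (K, m, m), first-order sensitivities (K, m, d) /
(K, m, m, d) and second-order (K, m, dA, dB) / (K, m, m, dA, dB).
"""

from __future__ import annotations

import numpy as np

from .kalman import run_filter_pass
from .models import DynamicModel, IndividualParameterMap

__all__ = [
    "individual_nll",
    "foce_hessian",
    "focei_hessian",
    "laplace_population_nll",
    "data_nll",
    "prior_nll",
]

LOG2PI = float(np.log(2.0 * np.pi))
#: eigenvalue floor applied to -Dl before its log-determinant when the
#: approximate Hessian is not positive definite at the inner optimum
HESSIAN_EIG_FLOOR = 1e-8


# ---------------------------------------------------------------------------
# batched ingredients
# ---------------------------------------------------------------------------

def prep_residuals(eps, R):
    """Precompute R⁻¹, R⁻¹ eps and log-determinants for a residual series."""
    eps = np.asarray(eps, float)
    R = np.asarray(R, float)
    Ri = np.linalg.inv(R)
    w = np.einsum("kxy,ky->kx", Ri, eps)
    sign, logdet = np.linalg.slogdet(R)
    if np.any(sign <= 0):
        raise np.linalg.LinAlgError("non-positive-definite output covariance")
    return {"eps": eps, "R": R, "Ri": Ri, "w": w, "logdet": logdet}


def data_nll(eps, R, prep=None):
    """-log p(data | eta): 1/2 sum_j (epsᵀR⁻¹eps + log|2 pi R|)."""
    pr = prep if prep is not None else prep_residuals(eps, R)
    m = pr["eps"].shape[1] if pr["eps"].ndim > 1 else 1
    quad = float(np.einsum("kx,kx->", pr["eps"], pr["w"]))
    return 0.5 * (quad + float(np.sum(pr["logdet"])) +
                  m * LOG2PI * pr["eps"].shape[0])


def prior_nll(eta, omega):
    """-log p(eta): 1/2 etaᵀ Omega⁻¹ eta + 1/2 log|2 pi Omega|."""
    eta = np.asarray(eta, float)
    r = eta.shape[0]
    if r == 0:
        return 0.0
    omega = np.asarray(omega, float)
    sign, logdet = np.linalg.slogdet(omega)
    if sign <= 0:
        raise ValueError("omega must be positive definite")
    Wi_eta = np.linalg.solve(omega, eta)
    return 0.5 * (float(eta @ Wi_eta) + logdet + r * LOG2PI)


def grad_data_nll(pr, e1, R1):
    """Gradient of the data part of -l w.r.t. the sensitivity directions.

    g_a = sum_j [ deps_aᵀ R⁻¹ eps - 1/2 epsᵀR⁻¹ dR_a R⁻¹ eps
                  + 1/2 Tr(R⁻¹ dR_a) ].
    """
    Ri, w = pr["Ri"], pr["w"]
    C = np.einsum("kxy,kyza->kxza", Ri, R1)        # R⁻¹ dR_a
    v = np.einsum("kxza,kz->kxa", C, w)            # R⁻¹ dR_a R⁻¹ eps
    g = (np.einsum("kxa,kx->a", e1, w)
         - 0.5 * np.einsum("kx,kxa->a", pr["eps"], v)
         + 0.5 * np.einsum("kxxa->a", C))
    return g, {"C": C, "v": v}


def fo_d2_filter(pr, e1A, R1A, e1B, R1B, interaction=True):
    """First-order-only second derivative of the data part of -l.

    Cross block over direction sets A and B; with ``interaction=False`` only
    the Gauss-Newton residual term survives (the FOCE approximation).
    """
    Ri, w = pr["Ri"], pr["w"]
    out = np.einsum("kxa,kxy,kyb->ab", e1A, Ri, e1B)
    if not interaction:
        return out
    CA = np.einsum("kxy,kyza->kxza", Ri, R1A)
    CB = np.einsum("kxy,kyzb->kxzb", Ri, R1B)
    vA = np.einsum("kxza,kz->kxa", CA, w)
    vB = np.einsum("kxzb,kz->kxb", CB, w)
    out = out - np.einsum("kxa,kxb->ab", e1A, vB)
    out = out - np.einsum("kxb,kxa->ab", e1B, vA)
    out = out + 0.5 * (np.einsum("kxa,kxyb,ky->ab", vA, R1B, w)
                       + np.einsum("kxb,kxya,ky->ba", vB, R1A, w).T)
    out = out - 0.5 * np.einsum("kxya,kyxb->ab", CA, CB)
    return out


def exact_d2_filter(pr, e1A, R1A, e1B, R1B, e2, R2):
    """Exact second derivative of the data part of -l (needs second-order
    sensitivities e2 (K,m,dA,dB) and R2 (K,m,m,dA,dB))."""
    Ri, w = pr["Ri"], pr["w"]
    out = fo_d2_filter(pr, e1A, R1A, e1B, R1B, interaction=True)
    out = out + np.einsum("kxab,kx->ab", e2, w)
    out = out - 0.5 * np.einsum("kx,kxyab,ky->ab", w, R2, w)
    out = out + 0.5 * np.einsum("kxy,kyxab->ab", Ri, R2)
    return out


def d_fo_d2_filter(pr, e1A, R1A, e1M, R1M, e2AM, R2AM, interaction=True):
    """Directional derivatives of ``fo_d2_filter`` over the A x A block.

    Differentiates the first-order-only Hessian block (a, b in A) along each
    direction m in M, using the second-order sensitivities e2AM, R2AM
    (derivatives of the A-direction sensitivities along M).  Returns an
    (dA, dA, dM) array.  This is the "no third-order sensitivities" rule:
    the approximate Hessian itself never contains second derivatives of eps
    or R, so its exact gradient needs nothing beyond second order.
    """
    Ri, w = pr["Ri"], pr["w"]
    ahat = np.einsum("kxy,kya->kxa", Ri, e1A)            # R⁻¹ deps_a
    # S1 = e1_aᵀ Ri e1_b
    dS1 = (np.einsum("kxam,kxy,kyb->abm", e2AM, Ri, e1A)
           + np.einsum("kxa,kxy,kybm->abm", e1A, Ri, e2AM)
           - np.einsum("kxa,kxym,kyb->abm", ahat, R1M, ahat))
    if not interaction:
        return dS1

    CA = np.einsum("kxy,kyza->kxza", Ri, R1A)
    CM = np.einsum("kxy,kyzm->kxzm", Ri, R1M)
    vA = np.einsum("kxza,kz->kxa", CA, w)
    vM = np.einsum("kxzm,kz->kxm", CM, w)
    # dw/dm = Ri deps_m - v_m
    dw = np.einsum("kxy,kym->kxm", Ri, e1M) - vM
    # dv_a/dm = -C_m v_a + Ri dR_am w + C_a dw
    dvA = (-np.einsum("kxzm,kza->kxam", CM, vA)
           + np.einsum("kxy,kyzam,kz->kxam", Ri, R2AM, w)
           + np.einsum("kxza,kzm->kxam", CA, dw))

    # S2 = -e1_aᵀ v_b - e1_bᵀ v_a
    dS2 = -(np.einsum("kxam,kxb->abm", e2AM, vA)
            + np.einsum("kxa,kxbm->abm", e1A, dvA)
            + np.einsum("kxbm,kxa->abm", e2AM, vA)
            + np.einsum("kxb,kxam->abm", e1A, dvA))
    # S3 = 1/2 (v_aᵀ R_b w + v_bᵀ R_a w)
    half = (np.einsum("kxam,kxyb,ky->abm", dvA, R1A, w)
            + np.einsum("kxa,kxybm,ky->abm", vA, R2AM, w)
            + np.einsum("kxa,kxyb,kym->abm", vA, R1A, dw))
    dS3 = 0.5 * (half + half.transpose(1, 0, 2))
    # S4 = -1/2 Tr(C_a C_b)
    # dC_a = -C_m C_a + Ri dR_am
    dCA = (-np.einsum("kxzm,kzya->kxyam", CM, CA)
           + np.einsum("kxz,kzyam->kxyam", Ri, R2AM))
    halft = np.einsum("kxyam,kyxb->abm", dCA, CA)
    dS4 = -0.5 * (halft + halft.transpose(1, 0, 2))
    return dS1 + dS2 + dS3 + dS4


def floor_negdef(M):
    """Eigenvalue-floor a nominally positive definite matrix.

    Returns (floored matrix, True if flooring was needed).  Used on -Dl at
    the inner optimum, which can lose positive definiteness for boundary
    fits (especially under FOCEI, whose trace term is not sign-definite).
    """
    M = 0.5 * (M + M.T)
    w, V = np.linalg.eigh(M)
    if np.all(w >= HESSIAN_EIG_FLOOR):
        return M, False
    w = np.maximum(w, HESSIAN_EIG_FLOOR)
    return (V * w) @ V.T, True


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def _eta_pass(eta, data_i, theta, model, pmap, order=1, jit=None,
              rtol=1e-8, atol=1e-10):
    eta = np.asarray(eta, float)
    theta = np.asarray(theta, float)
    phi = pmap.transform(theta, None, eta)
    D = pmap.jac_eta(theta, eta) if (order >= 1 and pmap.n_random) else None
    out = run_filter_pass(model, phi, data_i.times, data_i.y,
                          u=getattr(data_i, "input", None), order=order,
                          D=D, jit=jit, rtol=rtol, atol=atol)
    return out


def individual_nll(eta, data_i, theta, omega, model: DynamicModel,
                   pmap: IndividualParameterMap, jit=None,
                   rtol=1e-8, atol=1e-10) -> float:
    """Negative a-posteriori log-likelihood -l_i(eta) for one subject."""
    omega = np.atleast_2d(np.asarray(omega, float))
    out = _eta_pass(eta, data_i, theta, model, pmap, order=0, jit=jit,
                    rtol=rtol, atol=atol)
    pr = prep_residuals(out[0], out[1])
    return data_nll(None, None, prep=pr) + prior_nll(eta, omega)


def _eta_sensitivities(eta, data_i, theta, model, pmap, jit, rtol, atol):
    out = _eta_pass(eta, data_i, theta, model, pmap, order=1, jit=jit,
                    rtol=rtol, atol=atol)
    eps, R, e1, R1 = out[0], out[1], out[4], out[5]
    return eps, R, e1, R1


def foce_hessian(eta, data_i, theta, omega, model, pmap, sens=None,
                 jit=None, rtol=1e-8, atol=1e-10):
    """FOCE approximate Hessian Dl of l_i at eta (negative definite).

    ``sens`` may supply precomputed (eps, R, deps/deta, dR/deta) to avoid a
    filter pass.
    """
    omega = np.atleast_2d(np.asarray(omega, float))
    r = omega.shape[0]
    if sens is None:
        if len(np.atleast_1d(eta)) != r:
            raise ValueError("eta length must match omega dimension")
        sens = _eta_sensitivities(eta, data_i, theta, model, pmap, jit,
                                  rtol, atol)
    eps, R, e1, R1 = sens
    Winv = np.linalg.inv(omega)
    if eps.shape[0] == 0:
        return -Winv
    if e1.shape[2] != r:
        raise ValueError("sensitivity directions must match omega dimension")
    pr = prep_residuals(eps, R)
    return -fo_d2_filter(pr, e1, R1, e1, R1, interaction=False) - Winv


def focei_hessian(eta, data_i, theta, omega, model, pmap, sens=None,
                  jit=None, rtol=1e-8, atol=1e-10):
    """FOCEI approximate Hessian Dl of l_i at eta.

    Retains all dR/deta interaction terms of the first-order-only expansion;
    equals ``foce_hessian`` entrywise whenever dR/deta vanishes.
    """
    omega = np.atleast_2d(np.asarray(omega, float))
    if sens is None:
        sens = _eta_sensitivities(eta, data_i, theta, model, pmap, jit,
                                  rtol, atol)
    eps, R, e1, R1 = sens
    Winv = np.linalg.inv(omega)
    if eps.shape[0] == 0:
        return -Winv
    pr = prep_residuals(eps, R)
    return -fo_d2_filter(pr, e1, R1, e1, R1, interaction=True) - Winv


def approximate_hessian(method, eta, data_i, theta, omega, model, pmap,
                        sens=None, **kw):
    if method.lower() == "foce":
        return foce_hessian(eta, data_i, theta, omega, model, pmap, sens, **kw)
    if method.lower() == "focei":
        return focei_hessian(eta, data_i, theta, omega, model, pmap, sens,
                             **kw)
    raise ValueError(f"unknown method {method!r} (use 'foce' or 'focei')")


def laplace_subject_nll(fit, n_random):
    """-[l_i(eta*) - 1/2 log|-Dl_i/(2 pi)|] from an IndividualFit-like pair.

    ``fit`` is (inner nll value, Dl matrix).
    """
    nll, Dl = fit
    if n_random == 0:
        return nll, False
    M, floored = floor_negdef(-np.asarray(Dl, float))
    sign, logdet = np.linalg.slogdet(M)
    return nll + 0.5 * (logdet - n_random * LOG2PI), floored


def laplace_population_nll(theta_full, dataset, pm, method=None,
                           jit=None, rtol=1e-8, atol=1e-10,
                           return_parts=False):
    """Laplace-approximated population objective -log L(theta | Y).

    ``pm`` is a PopulationModel bundling the dynamic model, the individual
    parameter map and the theta layout; ``theta_full`` is the full
    fixed-effect vector including the Omega-factor entries.  Each subject's
    inner problem is solved to its mode before the Laplace correction is
    added; contributions are additive over subjects.
    """
    from .estimation import inner_optimize  # nested optimization lives there

    method = method or pm.default_method
    theta_s, _ = pm.split(theta_full)
    omega = pm.omega(theta_full)
    parts = []
    for data_i in dataset:
        fit = inner_optimize(data_i, theta_s, omega, pm.dynamic, pm.pmap,
                             method=method, jit=jit, rtol=rtol, atol=atol)
        contrib, _ = laplace_subject_nll((fit.inner_nll, fit.hessian),
                                         pm.n_random)
        parts.append(contrib)
    total = float(np.sum(parts))
    if return_parts:
        return total, np.asarray(parts)
    return total
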