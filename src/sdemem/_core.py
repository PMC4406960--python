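"""Numerical cores: EKF forward pass with forward sensitivities, and
Euler-Maruyama simulation.

The inner loops (prediction-ODE right-hand side, adaptive Dormand-Prince
RK45 stepping over one segment, and the sensitivity-propagating measurement
update) are written in a restricted style so the same source runs either as
plain Python (convenient for small ad-hoc models, no JIT latency) or
compiled with numba (used for the shipped models, where the nested
optimization makes many thousands of filter passes).  The pass itself is
orchestrated from Python segment by segment; only the tight loops are
compiled, which keeps numba compilation times moderate.

State layout of one integration vector Z:

    Z[0:nw]                      w = (xhat, vec P)
    Z[nw : nw*(1+d)]             W, first-order sensitivities, (nw, d) C-order
    Z[nw*(1+d) : nw*(1+d+npair)] W2, second-order sensitivities, (nw, npair)
    Z[... : ... + n*n]           Phi, state-transition matrix (smoothing only)

Directions are columns of D = dphi/ds for an arbitrary parameterization s;
D2 holds d2phi/ds_a ds_b for the requested pairs, so sensitivities w.r.t.
eta (through a nonlinear map) and w.r.t. phi itself use the same kernels.
"""

from __future__ import annotations

import numpy as np

try:
    import numba

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency
    HAVE_NUMBA = False

# generous for smooth PK-scale dynamics; a low cap makes diverging trial
# parameter points (e.g. wild line-search steps) fail fast
MAX_STEPS_PER_SEGMENT = 400


# ---------------------------------------------------------------------------
# kernels (plain source; jitted copies are created at module bottom)
# ---------------------------------------------------------------------------

def _rhs(tt, uu, Zc, dZ, par, D, D2, pa, pb, Gz, Gzz, Za, Zb, order,
         want_phi, n, p, g0f, gzf, gzzf):
    nw = n + n * n
    nz = nw + p
    d = D.shape[1]
    npair = pa.shape[0]
    iphi = nw * (1 + d + npair)
    dZ[:] = 0.0
    w = Zc[:nw]
    g0f(tt, uu, w, par, dZ[:nw])
    if order >= 1 or want_phi:
        for i in range(nw):
            for j in range(nz):
                Gz[i, j] = 0.0
        gzf(tt, uu, w, par, Gz)
    if order >= 1:
        for r in range(d):
            for i in range(nw):
                acc = 0.0
                for j in range(nw):
                    acc += Gz[i, j] * Zc[nw + j * d + r]
                for j2 in range(p):
                    acc += Gz[i, nw + j2] * D[j2, r]
                dZ[nw + i * d + r] = acc
    if order >= 2 and npair > 0:
        for i in range(nw):
            for j in range(nz):
                for k_ in range(nz):
                    Gzz[i, j, k_] = 0.0
        gzzf(tt, uu, w, par, Gzz)
        base2 = nw * (1 + d)
        for q_ in range(npair):
            a = pa[q_]
            b = pb[q_]
            for j in range(nw):
                Za[j] = Zc[nw + j * d + a]
                Zb[j] = Zc[nw + j * d + b]
            for j2 in range(p):
                Za[nw + j2] = D[j2, a]
                Zb[nw + j2] = D[j2, b]
            for i in range(nw):
                acc = 0.0
                for j in range(nw):
                    acc += Gz[i, j] * Zc[base2 + j * npair + q_]
                for j2 in range(p):
                    acc += Gz[i, nw + j2] * D2[j2, q_]
                for j in range(nz):
                    gij = 0.0
                    for k_ in range(nz):
                        gij += Gzz[i, j, k_] * Zb[k_]
                    acc += Za[j] * gij
                dZ[base2 + i * npair + q_] = acc
    if want_phi:
        for i in range(n):
            for j in range(n):
                acc = 0.0
                for k_ in range(n):
                    acc += Gz[i, k_] * Zc[iphi + k_ * n + j]
                dZ[iphi + i * n + j] = acc


def _rk45_segment(t0v, t1v, uu, Z, par, D, D2, pa, pb, Gz, Gzz, Za, Zb,
                  k1, k2, k3, k4, k5, k6, k7, Ztmp, Znew, rtol, atol,
                  order, want_phi, n, p, nerr, rhsf, g0f, gzf, gzzf):
    """Adaptive Dormand-Prince RK45 from t0v to t1v; returns a status flag
    (0 ok, 1 failure).

    The local error is controlled over the first ``nerr`` components
    (state/covariance and first-order sensitivities); second-order
    sensitivity components ride along with the accepted step sequence."""
    ntot = Z.shape[0]
    t = t0v
    h = t1v - t0v
    nstep = 0
    while t < t1v - 1e-12 * max(1.0, abs(t1v)):
        nstep += 1
        if nstep > MAX_STEPS_PER_SEGMENT:
            return 1
        if t + h > t1v:
            h = t1v - t
        rhsf(t, uu, Z, k1, par, D, D2, pa, pb, Gz, Gzz, Za, Zb, order,
             want_phi, n, p, g0f, gzf, gzzf)
        for i in range(ntot):
            Ztmp[i] = Z[i] + h * 0.2 * k1[i]
        rhsf(t + 0.2 * h, uu, Ztmp, k2, par, D, D2, pa, pb, Gz, Gzz, Za, Zb,
             order, want_phi, n, p, g0f, gzf, gzzf)
        for i in range(ntot):
            Ztmp[i] = Z[i] + h * (3.0 / 40.0 * k1[i] + 9.0 / 40.0 * k2[i])
        rhsf(t + 0.3 * h, uu, Ztmp, k3, par, D, D2, pa, pb, Gz, Gzz, Za, Zb,
             order, want_phi, n, p, g0f, gzf, gzzf)
        for i in range(ntot):
            Ztmp[i] = Z[i] + h * (44.0 / 45.0 * k1[i] - 56.0 / 15.0 * k2[i]
                                  + 32.0 / 9.0 * k3[i])
        rhsf(t + 0.8 * h, uu, Ztmp, k4, par, D, D2, pa, pb, Gz, Gzz, Za, Zb,
             order, want_phi, n, p, g0f, gzf, gzzf)
        for i in range(ntot):
            Ztmp[i] = Z[i] + h * (19372.0 / 6561.0 * k1[i]
                                  - 25360.0 / 2187.0 * k2[i]
                                  + 64448.0 / 6561.0 * k3[i]
                                  - 212.0 / 729.0 * k4[i])
        rhsf(t + 8.0 / 9.0 * h, uu, Ztmp, k5, par, D, D2, pa, pb, Gz, Gzz,
             Za, Zb, order, want_phi, n, p, g0f, gzf, gzzf)
        for i in range(ntot):
            Ztmp[i] = Z[i] + h * (9017.0 / 3168.0 * k1[i]
                                  - 355.0 / 33.0 * k2[i]
                                  + 46732.0 / 5247.0 * k3[i]
                                  + 49.0 / 176.0 * k4[i]
                                  - 5103.0 / 18656.0 * k5[i])
        rhsf(t + h, uu, Ztmp, k6, par, D, D2, pa, pb, Gz, Gzz, Za, Zb,
             order, want_phi, n, p, g0f, gzf, gzzf)
        for i in range(ntot):
            Znew[i] = Z[i] + h * (35.0 / 384.0 * k1[i]
                                  + 500.0 / 1113.0 * k3[i]
                                  + 125.0 / 192.0 * k4[i]
                                  - 2187.0 / 6784.0 * k5[i]
                                  + 11.0 / 84.0 * k6[i])
        rhsf(t + h, uu, Znew, k7, par, D, D2, pa, pb, Gz, Gzz, Za, Zb,
             order, want_phi, n, p, g0f, gzf, gzzf)
        err = 0.0
        for i in range(nerr):
            e4 = Z[i] + h * (5179.0 / 57600.0 * k1[i]
                             + 7571.0 / 16695.0 * k3[i]
                             + 393.0 / 640.0 * k4[i]
                             - 92097.0 / 339200.0 * k5[i]
                             + 187.0 / 2100.0 * k6[i]
                             + 1.0 / 40.0 * k7[i])
            sc = atol + rtol * max(abs(Z[i]), abs(Znew[i]))
            de = abs(Znew[i] - e4) / sc
            if de > err:
                err = de
        if not np.isfinite(err):
            h *= 0.2
            if h < 1e-14 * max(1.0, abs(t1v)):
                return 1
            continue
        if err <= 1.0:
            t = t + h
            for i in range(ntot):
                Z[i] = Znew[i]
            fac = 5.0 if err == 0.0 else min(5.0, max(0.2, 0.9 * err ** -0.2))
            hrem = t1v - t
            h = h * fac
            if hrem > 0 and h > hrem:
                h = hrem
            if h <= 0.0:
                h = 1e-12
        else:
            h = h * max(0.2, 0.9 * err ** -0.2)
    return 0


def _apply_update(t1v, uu, Z, par, y, Hout, Hz, Hzz, V1, V2, D, D2, pa, pb,
                  Za, Zb, eps_k, R_k, eps1_k, R1_k, eps2_k, R2_k, order,
                  n, m, p, h0f, hzf, hzzf):
    """Measurement update with sensitivity propagation, in place on Z.

    Returns det(R) (caller rejects non-positive values)."""
    nw = n + n * n
    nz = nw + p
    no = nw + m + m * m
    d = D.shape[1]
    npair = pa.shape[0]
    Hout[:] = 0.0
    h0f(t1v, uu, Z[:nw], par, y, Hout)
    if m == 1:
        detR = Hout[nw + m]
    else:
        detR = (Hout[nw + m] * Hout[nw + m + 3]
                - Hout[nw + m + 1] * Hout[nw + m + 2])
    if not (detR > 0.0) or not np.isfinite(detR):
        return detR
    for i in range(m):
        eps_k[i] = Hout[nw + i]
        for j in range(m):
            R_k[i, j] = Hout[nw + m + i * m + j]

    if order >= 1:
        for i in range(no):
            for j in range(nz):
                Hz[i, j] = 0.0
        hzf(t1v, uu, Z[:nw], par, y, Hz)
        for r in range(d):
            for i in range(no):
                acc = 0.0
                for j in range(nw):
                    acc += Hz[i, j] * Z[nw + j * d + r]
                for j2 in range(p):
                    acc += Hz[i, nw + j2] * D[j2, r]
                V1[i, r] = acc
    if order >= 2 and npair > 0:
        for i in range(no):
            for j in range(nz):
                for k_ in range(nz):
                    Hzz[i, j, k_] = 0.0
        hzzf(t1v, uu, Z[:nw], par, y, Hzz)
        base2 = nw * (1 + d)
        for q_ in range(npair):
            a = pa[q_]
            b = pb[q_]
            for j in range(nw):
                Za[j] = Z[nw + j * d + a]
                Zb[j] = Z[nw + j * d + b]
            for j2 in range(p):
                Za[nw + j2] = D[j2, a]
                Zb[nw + j2] = D[j2, b]
            for i in range(no):
                acc = 0.0
                for j in range(nw):
                    acc += Hz[i, j] * Z[base2 + j * npair + q_]
                for j2 in range(p):
                    acc += Hz[i, nw + j2] * D2[j2, q_]
                for j in range(nz):
                    hij = 0.0
                    for k_ in range(nz):
                        hij += Hzz[i, j, k_] * Zb[k_]
                    acc += Za[j] * hij
                V2[i, q_] = acc

    # write updated state (covariance block symmetrized)
    for i in range(n):
        Z[i] = Hout[i]
    for i in range(n):
        for j in range(n):
            Z[n + i * n + j] = 0.5 * (Hout[n + i * n + j]
                                      + Hout[n + j * n + i])
    if order >= 1:
        for r in range(d):
            for i in range(n):
                Z[nw + i * d + r] = V1[i, r]
            for i in range(n):
                for j in range(n):
                    Z[nw + (n + i * n + j) * d + r] = 0.5 * (
                        V1[n + i * n + j, r] + V1[n + j * n + i, r])
            for i in range(m):
                eps1_k[i, r] = V1[nw + i, r]
                for j in range(m):
                    R1_k[i, j, r] = V1[nw + m + i * m + j, r]
    if order >= 2:
        base2 = nw * (1 + d)
        for q_ in range(npair):
            for i in range(n):
                Z[base2 + i * npair + q_] = V2[i, q_]
            for i in range(n):
                for j in range(n):
                    Z[base2 + (n + i * n + j) * npair + q_] = 0.5 * (
                        V2[n + i * n + j, q_] + V2[n + j * n + i, q_])
            for i in range(m):
                eps2_k[i, q_] = V2[nw + i, q_]
                for j in range(m):
                    R2_k[i, j, q_] = V2[nw + m + i * m + j, q_]
    return detR


def _em_segments(seg_t, seg_u, nsteps, par, x0, zr, f_raw, sig_raw, n, q,
                 store_full, full_t, full_x):
    """Euler-Maruyama over input/observation segments (pre-drawn normals)."""
    nseg = seg_u.shape[0]
    x = x0.copy()
    path = np.zeros((nseg + 1, n))
    path[0] = x0
    fbuf = np.zeros(n)
    sbuf = np.zeros((n, max(q, 1)))
    idx = 0
    for s in range(nseg):
        t = seg_t[s]
        span = seg_t[s + 1] - t
        ns = nsteps[s]
        if ns > 0:
            h = span / ns
            sq = np.sqrt(h)
            for _ in range(ns):
                for i in range(n):
                    fbuf[i] = 0.0
                f_raw(t, seg_u[s], x, par, fbuf)
                if q > 0:
                    for i in range(n):
                        for j in range(q):
                            sbuf[i, j] = 0.0
                    sig_raw(t, seg_u[s], x, par, sbuf)
                for i in range(n):
                    inc = h * fbuf[i]
                    for j in range(q):
                        inc += sq * sbuf[i, j] * zr[idx, j]
                    x[i] = x[i] + inc
                t += h
                idx += 1
                if store_full:
                    full_t[idx] = t
                    for i in range(n):
                        full_x[idx, i] = x[i]
        path[s + 1] = x
    return path


# ---------------------------------------------------------------------------
# Python-level orchestration
# ---------------------------------------------------------------------------

class FilterKernels:
    """Kernel set (plain or jitted) bound to one compiled model."""

    def __init__(self, comp, jit):
        self.comp = comp
        if jit and HAVE_NUMBA:
            self.rhs = _rhs_jit
            self.rk45 = _rk45_jit
            self.update = _update_jit
            self.em = _em_jit
        else:
            self.rhs = _rhs
            self.rk45 = _rk45_segment
            self.update = _apply_update
            self.em = _em_segments


def filter_pass(ys, seg_t, seg_u, seg_obs, par, w0, W0, W20, D, D2, pa, pb,
                rtol, atol, order, want_phi, kern, n, m, p):
    """Forward continuous-discrete EKF pass with forward sensitivities.

    Integrates the prediction ODEs segment by segment (segments end at
    observation times and at input break points) and applies the linearized
    measurement update at observations, propagating first- and second-order
    sensitivities through both maps.  Returns per-observation residuals,
    output covariances, pre/post filter states, their sensitivities,
    per-interval transition matrices (if requested) and a status flag
    (0 = ok, 1 = integrator failure, 2 = singular output covariance).
    """
    comp = kern.comp
    nw = n + n * n
    nz = nw + p
    no = nw + m + m * m
    K = ys.shape[0]
    d = D.shape[1]
    npair = pa.shape[0]
    nseg = seg_u.shape[0]

    ntot = nw * (1 + d + npair)
    iphi = ntot
    if want_phi:
        ntot += n * n

    eps = np.zeros((K, m))
    Rm = np.zeros((K, m, m))
    xpred = np.zeros((K, nw))
    xfilt = np.zeros((K, nw))
    eps1 = np.zeros((K, m, d))
    R1 = np.zeros((K, m, m, d))
    W1pred = np.zeros((K, nw, d))
    W1filt = np.zeros((K, nw, d))
    eps2 = np.zeros((K, m, npair))
    R2 = np.zeros((K, m, m, npair))
    Phi = np.zeros((K, n, n))

    Z = np.zeros(ntot)
    Z[:nw] = w0
    if d:
        Z[nw:nw * (1 + d)] = W0.reshape(-1)
    if npair:
        Z[nw * (1 + d):nw * (1 + d + npair)] = W20.reshape(-1)
    if want_phi:
        for i in range(n):
            Z[iphi + i * n + i] = 1.0

    Gz = np.zeros((nw, nz))
    Gzz = np.zeros((nw, nz, nz))
    Hout = np.zeros(no)
    Hz = np.zeros((no, nz))
    Hzz = np.zeros((no, nz, nz))
    Za = np.zeros(nz)
    Zb = np.zeros(nz)
    V1 = np.zeros((no, d))
    V2 = np.zeros((no, npair))
    ks = [np.zeros(ntot) for _ in range(9)]
    nerr = ntot if npair == 0 else nw * (1 + d)

    status = 0
    for s in range(nseg):
        t0, t1 = seg_t[s], seg_t[s + 1]
        uu = seg_u[s]
        if t1 > t0:
            st = kern.rk45(t0, t1, uu, Z, par, D, D2, pa, pb, Gz, Gzz, Za,
                           Zb, *ks, rtol, atol, order, want_phi, n, p, nerr,
                           kern.rhs, comp.fn_g0, comp.fn_gz, comp.fn_gzz)
            if st != 0:
                status = 1
                break
        kobs = seg_obs[s]
        if kobs < 0:
            continue
        xpred[kobs] = Z[:nw]
        if d:
            W1pred[kobs] = Z[nw:nw * (1 + d)].reshape(nw, d)
        detR = kern.update(t1, uu, Z, par, ys[kobs], Hout, Hz, Hzz, V1, V2,
                           D, D2, pa, pb, Za, Zb, eps[kobs], Rm[kobs],
                           eps1[kobs], R1[kobs], eps2[kobs], R2[kobs],
                           order, n, m, p, comp.fn_h0, comp.fn_hz,
                           comp.fn_hzz)
        if not (detR > 0.0) or not np.isfinite(detR):
            status = 2
            break
        xfilt[kobs] = Z[:nw]
        if d:
            W1filt[kobs] = Z[nw:nw * (1 + d)].reshape(nw, d)
        if want_phi:
            Phi[kobs] = Z[iphi:iphi + n * n].reshape(n, n)
            Z[iphi:iphi + n * n] = np.eye(n).reshape(-1)
    return (eps, Rm, xpred, xfilt, eps1, R1, W1pred, W1filt, eps2, R2, Phi,
            status)


def predict_grid(t0, t_grid, seg_u, par, w0, rtol, atol, kern, n, p):
    """Integrate the mean/covariance prediction ODE, recording at t_grid."""
    nw = n + n * n
    nz = nw + p
    G = t_grid.shape[0]
    out = np.zeros((G, nw))
    Z = w0.copy()
    D = np.zeros((p, 0))
    D2 = np.zeros((p, 0))
    pa = np.zeros(0, dtype=np.int64)
    pb = np.zeros(0, dtype=np.int64)
    Gz = np.zeros((nw, nz))
    Gzz = np.zeros((nw, nz, nz))
    Za = np.zeros(nz)
    Zb = np.zeros(nz)
    ks = [np.zeros(nw) for _ in range(9)]
    comp = kern.comp
    t = t0
    for gidx in range(G):
        t1 = t_grid[gidx]
        if t1 > t:
            st = kern.rk45(t, t1, seg_u[gidx], Z, par, D, D2, pa, pb, Gz,
                           Gzz, Za, Zb, *ks, rtol, atol, 0, False, n, p, nw,
                           kern.rhs, comp.fn_g0, comp.fn_gz, comp.fn_gzz)
            if st != 0:
                return out, 1
            t = t1
        out[gidx] = Z
    return out, 0


if HAVE_NUMBA:
    _rhs_jit = numba.njit(_rhs, cache=False)
    _rk45_jit = numba.njit(_rk45_segment, cache=False)
    _update_jit = numba.njit(_apply_update, cache=False)
    _em_jit = numba.njit(_em_segments, cache=False)
else:  # pragma: no cover
    _rhs_jit = _rhs
    _rk45_jit = _rk45_segment
    _update_jit = _apply_update
    _em_jit = _em_segments
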