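"""Code generation: symbolic model -> numerical filtering/sensitivity kernels.

For a declared model the EKF needs, between observations, the joint
mean/covariance prediction ODE

    d xhat/dt = f(xhat),     dP/dt = A P + P Aᵀ + Sigma Sigmaᵀ,

with A = df/dx relinearized continuously along xhat, and at observations the
algebraic update map

    C = dh/dx,  R = C P Cᵀ + S,  K = P Cᵀ R⁻¹,
    eps = y - h(xhat),  xhat⁺ = xhat + K eps,  P⁺ = P - K R Kᵀ.

Writing w = (xhat, vec P) and z = (w, phi), both maps are differentiated
symbolically up to second order in z.  Forward sensitivities of any order are
then propagated by generic tensor contractions (see ``_core``), which keeps
the hand-written code model-independent: first-order sensitivities obey
dW_r/dt = G_w W_r + G_phi D_r and second-order ones pick up the bilinear
G_zz : Z_r Z_s term, and likewise through the update map.

The generated scalar-assignment sources are exec'd and optionally wrapped in
``numba.njit``; only nonzero tensor entries are emitted, so callers must zero
the output arrays beforehand.
"""

from __future__ import annotations

import math

import numpy as np
import sympy as sp
from sympy.printing.pycode import PythonCodePrinter

from .models import DynamicModel, INPUT, TIME

__all__ = ["CompiledDynamics"]

_printer = PythonCodePrinter()


def _emit(fname, args, targets, subs):
    """Render a filler function assigning ``target = expr`` for each pair.

    ``targets`` is a list of (target_string, sympy_expr); zero expressions are
    skipped.  Common subexpressions are pulled out with cse.
    """
    pairs = [(tgt, e) for tgt, e in targets if e != 0]
    exprs = [e.xreplace(subs) for _, e in pairs]
    repl, red = sp.cse(exprs, symbols=sp.numbered_symbols("zz"))
    lines = [f"def {fname}({', '.join(args)}):"]
    for sym, e in repl:
        lines.append(f"    {sym} = {_printer.doprint(e)}")
    for (tgt, _), e in zip(pairs, red):
        lines.append(f"    {tgt} = {_printer.doprint(e)}")
    if len(lines) == 1:
        lines.append("    pass")
    return "\n".join(lines)


def _compile_source(src, fname):
    ns = {"math": math}
    exec(src, ns)
    return ns[fname]


class CompiledDynamics:
    """Generated prediction/update kernels and derivative tensors for a model.

    Attributes
    ----------
    n, m, p, q : state / output / parameter / Wiener dimensions
    nw : filter state dimension n + n**2 (mean plus flattened covariance)
    no : update-map output dimension nw + m + m**2 (new state, residual, R)
    nz : differentiation variables nw + p
    """

    def __init__(self, model: DynamicModel, jit: bool = False):
        self.model = model
        self.jit = bool(jit)
        n, p, m, q = (model.n_states, model.n_params, model.n_outputs,
                      model.n_wiener)
        if m > 2:
            raise NotImplementedError(
                "symbolic update-map inversion implemented for <= 2 outputs"
            )
        self.n, self.p, self.m, self.q = n, p, m, q
        self.nw = n + n * n
        self.no = self.nw + m + m * m
        self.nz = self.nw + p

        x = sp.Matrix(model.states)
        par = model.params
        f, Sigma, h, S, x0 = (model._f, model._Sigma, model._h, model._S,
                              model._x0)

        Psym = sp.Matrix(n, n, lambda i, j: sp.Symbol(f"_P_{i}_{j}"))
        ysym = [sp.Symbol(f"_y_{i}") for i in range(m)]
        wsyms = list(x) + list(Psym)
        zvars = wsyms + list(par)

        subs = {}
        for i, s_ in enumerate(wsyms):
            subs[s_] = sp.Symbol(f"w[{i}]")
        for i, s_ in enumerate(par):
            subs[s_] = sp.Symbol(f"par[{i}]")
        for i, s_ in enumerate(ysym):
            subs[s_] = sp.Symbol(f"y[{i}]")
        subs[TIME] = sp.Symbol("t")
        subs[INPUT] = sp.Symbol("u_")
        xsubs = {s_: sp.Symbol(f"x[{i}]") for i, s_ in enumerate(x)}
        xsubs.update({par[i]: sp.Symbol(f"par[{i}]") for i in range(p)})
        xsubs[TIME] = sp.Symbol("t")
        xsubs[INPUT] = sp.Symbol("u_")

        # ---- prediction map G0(w, phi) --------------------------------
        A = f.jacobian(x)
        dP = A * Psym + Psym * A.T + Sigma * Sigma.T
        G0 = sp.Matrix.vstack(f, dP.reshape(n * n, 1))
        Gz = G0.jacobian(zvars)

        # ---- update map H(w, phi; y) ----------------------------------
        C = h.jacobian(x)
        R = C * Psym * C.T + S
        Rinv = R.inv()
        K = Psym * C.T * Rinv
        eps = sp.Matrix(ysym) - h
        xplus = x + K * eps
        Pplus = Psym - K * R * K.T
        Hout = sp.Matrix.vstack(
            xplus, Pplus.reshape(n * n, 1), eps, R.reshape(m * m, 1)
        )
        Hz = Hout.jacobian(zvars)

        std_args = ("t", "u_", "w", "par")

        def _tensor_targets(mat, arr, vec=False):
            if vec:
                return [(f"{arr}[{i}]", mat[i]) for i in range(mat.shape[0])]
            return [
                (f"{arr}[{i}, {j}]", mat[i, j])
                for i in range(mat.shape[0])
                for j in range(mat.shape[1])
            ]

        def _second_targets(jac, arr):
            out = []
            for i in range(jac.shape[0]):
                for j in range(self.nz):
                    e = jac[i, j]
                    if e == 0:
                        continue
                    for k in range(j, self.nz):
                        d = sp.diff(e, zvars[k])
                        if d == 0:
                            continue
                        out.append((f"{arr}[{i}, {j}, {k}]", d))
                        if k != j:
                            out.append((f"{arr}[{i}, {k}, {j}]", d))
            return out

        sources = {
            "g0": _emit("g0", std_args + ("out",),
                        _tensor_targets(G0, "out", vec=True), subs),
            "gz": _emit("gz", std_args + ("out",),
                        _tensor_targets(Gz, "out"), subs),
            "gzz": _emit("gzz", std_args + ("out",),
                         _second_targets(Gz, "out"), subs),
            "h0": _emit("h0", std_args + ("y", "out"),
                        _tensor_targets(Hout, "out", vec=True), subs),
            "hz": _emit("hz", std_args + ("y", "out"),
                        _tensor_targets(Hz, "out"), subs),
            "hzz": _emit("hzz", std_args + ("y", "out"),
                         _second_targets(Hz, "out"), subs),
            # raw model functions for simulation
            "f_raw": _emit("f_raw", ("t", "u_", "x", "par", "out"),
                           [(f"out[{i}]", f[i]) for i in range(n)], xsubs),
            "sig_raw": _emit("sig_raw", ("t", "u_", "x", "par", "out"),
                             [(f"out[{i}, {j}]", Sigma[i, j])
                              for i in range(n) for j in range(max(q, 1))
                              if q > 0], xsubs),
            # initial state and its parameter derivatives
            "x0f": _emit("x0f", ("par", "out"),
                         [(f"out[{i}]", x0[i]) for i in range(n)],
                         subs),
            "x0j": _emit("x0j", ("par", "out"),
                         [(f"out[{i}, {j}]", sp.diff(x0[i], par[j]))
                          for i in range(n) for j in range(p)], subs),
            "x0jj": _emit("x0jj", ("par", "out"),
                          [(f"out[{i}, {j}, {k}]",
                            sp.diff(x0[i], par[j], par[k]))
                           for i in range(n) for j in range(p)
                           for k in range(p)], subs),
        }
        self.sources = sources
        fns = {name: _compile_source(src, name) for name, src in sources.items()}
        if self.jit:
            import numba

            fns = {name: numba.njit(fn, cache=False)
                   for name, fn in fns.items()}
        self.__dict__.update({f"fn_{k}": v for k, v in fns.items()})
        from ._core import FilterKernels

        self.kernels = FilterKernels(self, self.jit)

    # convenience evaluators (used by tests and the reference filter path)
    def x0_and_derivs(self, par):
        n, p = self.n, self.p
        x0 = np.zeros(n)
        J = np.zeros((n, p))
        J2 = np.zeros((n, p, p))
        self.fn_x0f(par, x0)
        self.fn_x0j(par, J)
        self.fn_x0jj(par, J2)
        return x0, J, J2
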