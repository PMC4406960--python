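# Methods

## Model class

`sdemem` estimates parameters of stochastic differential mixed-effects
models (SDMEMs): nonlinear mixed-effects models whose within-subject
dynamics are an Itô SDE rather than an ODE,

    dx_i = f(x_i, u_i, t, phi_i) dt + Σ(x̂_i, u_i, t, phi_i) dW_i,
    x_i(0) = x0(phi_i),
    y_ij  = h(x_i, u_i, t_ij, phi_i) + e_ij,   e_ij ~ N(0, S),

with individual parameters phi_i = g(θ, Z_i, η_i), random effects
η_i ~ N(0, Ω), and three separated sources of variability: measurement
error (S), inter-individual variability (Ω) and system noise (Σ dW).  The
diffusion is allowed to depend on the *filtered state estimate* x̂ rather
than the latent state: an extended Kalman filter cannot propagate truly
state-dependent diffusions, but substituting the conditional mean yields a
proportional-like system noise while keeping the filter recursions valid.
The simulator substitutes the current simulated state into the same
function, so one model object serves both roles.

Ω is parameterized through an upper-triangular factor U (Ω = U Uᵀ), which
keeps it positive semidefinite for any real entries and lets the
off-diagonal factor entries carry correlation sign-free.

Models are *declared symbolically* (sympy expressions for f, Σ, h, S, x0
and the map g).  This is not cosmetic: the entire gradient machinery
differentiates the model declaration exactly (see below), so hand-coded
derivative callbacks are never needed and model misspecification of
derivatives is impossible by construction.

## State estimation: continuous-discrete EKF

Between observations the conditional mean and covariance solve

    dx̂/dt = f(x̂, u, t, phi)
    dP/dt = A P + P Aᵀ + Σ Σᵀ,        A = ∂f/∂x |_{x̂},

with A and Σ re-evaluated continuously along x̂ inside the integrator
(continuous relinearization).  At an observation,

    C = ∂h/∂x,  R = C P Cᵀ + S,  K = P Cᵀ R⁻¹,
    ε = y − h(x̂),  x̂⁺ = x̂ + Kε,  P⁺ = P − K R Kᵀ  (re-symmetrized).

The default initial covariance is P0 = 0 because both shipped models define
x(0) exactly given phi; it is configurable.  The first observation's
predictive density uses the propagation from (x0, P0) to t_1.

The covariance ODE is the Lyapunov form with the transpose on the second
term; a form without it would not preserve symmetry.

Integration uses an adaptive Dormand–Prince RK45 with rtol 1e-8 /
atol 1e-10 by default — tight, because the outer optimizer differentiates
through the solve.  The tolerance is applied per segment between
observations and input break points; piecewise-constant infusions are
handled by splitting segments at break points, so the right-hand side seen
by the integrator is always smooth.  The core loops run either as plain
Python (ad-hoc/toy models) or numba-compiled (the shipped models); both
execute the same source.

Smoothing uses a Rauch–Tung–Striebel-type backward pass over the
linearized system, with the state-transition matrix Φ of each interval
integrated alongside the forward pass (dΦ/dt = AΦ).  A pseudo-inverse in
the backward gain handles the deterministic limit P ≡ 0, where smoothing
collapses to the filtered (ODE) trajectory rather than erroring.

## Likelihood approximation

The individual a-posteriori log-likelihood of the random effects is

    l_i(η) = −½ Σ_j (ε_ijᵀ R_ij⁻¹ ε_ij + log|2π R_ij|)
             − ½ ηᵀ Ω⁻¹ η − ½ log|2π Ω|,

with ε and R produced by the filter.  The marginal population likelihood is
approximated by Laplace's method around the inner mode η*:

    −log L(θ) ≈ Σ_i [ −l_i(η*) + ½ log|−Δl_i(η*)| − (r/2) log 2π ],

where Δl_i is an approximate Hessian of l_i built from first-order
sensitivities of ε and R only (second derivatives of ε and R are dropped):

* FOCE:  (Δl)_ab = −Σ_j ∂ε_jᵀ/∂η_a R_j⁻¹ ∂ε_j/∂η_b − (Ω⁻¹)_ab.
* FOCEI: additionally keeps every ∂R/∂η interaction term arising from
  differentiating l twice — the residual/covariance cross terms, the
  double-covariance quadratic form, and ½Tr(R⁻¹ ∂R_a R⁻¹ ∂R_b) — and
  reduces exactly to FOCE when ∂R/∂η ≡ 0 (verified as a test invariant).

FOCEI matters for SDMEMs even under additive measurement error, because R
depends on η through the state covariance propagation.  The FOCEI trace
term is not sign-definite, so −Δl can lose positive definiteness at
boundary fits; before the log-determinant its eigenvalues are floored at
1e-8 and the occurrence is flagged.  (This is also why FOCE is the default
for the NiAc-structure model, where proportional residual error makes the
interaction terms large.)

## Gradients: forward sensitivity equations

Finite-differencing a nested, adaptively-integrated objective is noisy at
exactly the scale an optimizer needs; instead all gradients are assembled
from forward sensitivities computed to solver accuracy.

Writing w = (x̂, vec P) and z = (w, phi), the prediction map ẇ = G(w, phi)
and the update map (w⁺, ε, R) = H(w, phi; y) are differentiated
symbolically to second order in z at model-compile time.  First-order
sensitivities W_r = ∂w/∂s_r along arbitrary parameter directions
(D = ∂phi/∂s) obey Ẇ_r = G_w W_r + G_phi D_r, and second-order ones add
the bilinear term G_zz : Z_r Z_s; the update propagates both algebraically
through H_z and H_zz.  Because the directions are abstract, sensitivities
w.r.t. η (through a nonlinear map g, including its second derivatives) and
w.r.t. phi itself use the same kernels.

From per-observation (ε, R, ∂ε, ∂R, ∂²ε, ∂²R) the package assembles:

* the inner gradient ∂(−l_i)/∂η (first order only),
* the exact inner Hessian ∂²(−l_i)/∂η² and mixed block ∂²(−l_i)/∂η∂θ,
* the approximate Hessian Δl_i and its exact directional derivatives
  dΔl_i/dθ and dΔl_i/dη.  Δl_i itself contains only first-order
  sensitivities, so its exact derivative needs nothing beyond second order
  — no third-order sensitivities ever arise.

The total outer gradient then follows from the implicit-function theorem:

    dF_i/dθ = ∂F_i/∂θ + ∂F_i/∂η · dη*/dθ,
    dη*/dθ = −[∂²(−l)/∂η²]⁻¹ ∂²(−l)/∂η∂θ,

with ∂F_i/∂(·) = −∂l_i/∂(·) + ½Tr[(−Δl)⁻¹ d(−Δl)/d(·)].  This gradient is
exact for the approximate objective (up to solver tolerance) and is
validated in the test suite against central finite differences of the full
nested objective on both shipped models and against the closed-form
marginal-likelihood gradient of a conjugate Gaussian toy.

Adaptive-step error control runs over the state and first-order blocks;
second-order components follow the accepted step sequence.  The gradient
pass may run at a looser tolerance (1e-6 during population fits) than the
value passes (1e-8): line-search decisions use the high-precision value,
the gradient is only a direction.

## Nested optimization

Inner problem (per subject): BFGS (scipy) on −l_i(η) with the sensitivity
gradient, gtol 1e-6 (∞-norm), max 200 iterations, warm-started at the
subject's previous optimum across outer iterations and falling back to the
prior mode η = 0 when a stale warm start strands it.

Outer problem: a damped BFGS with Armijo backtracking written for this
package, on a transformed scale (log for positivity-constrained
parameters; natural scale for off-diagonal Ω-factor entries).  Trial
points where the filter or an inner problem fails return a large penalty
and are simply rejected by the backtracking — this is the reason for not
using a Wolfe line search, whose derivative interpolation misbehaves on
penalty cliffs.  The objective is monotone across accepted iterations by
construction.  Two pragmatic guards matter in practice: the
sufficient-decrease test tolerates the objective's numerical noise floor,
and a failed line search triggers a *re-anchoring* re-evaluation of the
current point — the nested objective is mildly warm-start path-dependent
(a subject's inner mode can jump basins between evaluations), so a stale
baseline can make every trial step look uphill.  Convergence: gradient ∞-norm ≤ 1e-4 (transformed scale) by
default; the replicate-study driver stops at 1e-3, where the estimates are
already stable to <1e-4 relative and only the gradient norm keeps
polishing.  Divergent trial evaluations restore the warm-start state so a
rejected step cannot poison later ones.

Standard errors: RSE% per parameter from the inverse outer Hessian,
obtained by central finite differences of the sensitivity-equation
gradient on the transformed scale (step 1e-4) and delta-method-mapped to
the natural scale; for log-parameters RSE% = 100·SE(log θ).  A
non-positive-definite Hessian triggers a warning and a pseudo-inverse.

## Synthetic data

The simulator is first-class: it defines the study conditions the
estimator is validated under.

* Latent paths: Euler–Maruyama with internal step 0.01 min (strong order
  0.5), sub-stepped so segment boundaries fall on observation times and
  infusion break points.  The scheme and step are not prescribed by the
  model class; they are verified against the Ornstein–Uhlenbeck stationary
  law (σ²/2k within Monte-Carlo error) and the noise-free ODE limit
  (error linear in the step, ~5e-4 of the concentration scale at 0.01).
* States are never clipped inside the integration — the proportional
  diffusion already vanishes at zero, and silent clipping would bias
  moments.
* Random effects are drawn η_i ~ N(0, U Uᵀ); subject streams are spawned
  from the design seed, replicate seeds from a master seed and the
  replicate index, so studies are reproducible bitwise.
* Measurement noise is drawn from S evaluated at the latent state.

The replicate validation study simulates 20 subjects with observations at
t = 1, 9, …, 97 min from the two-state model (first-order absorption from
a 20 mg oral dose, Michaelis–Menten elimination, system noise proportional
to the predicted plasma concentration entering the elimination equation
only) at truth ka=0.1 min⁻¹, Vm=0.5 mg·min⁻¹, Km=3 mg·L⁻¹, V=1 L, s=0.1
mg·L⁻¹, ω11=0.5, ω12=0.1, ω22=0.3, σ=0.05 L·min⁻¹, and refits each dataset
by FOCEI from deliberately displaced starting values (ka=0.2, Vm=1, Km=1,
V=2, s=0.5, ω11=0.1, ω12=0, ω22=0.1, σ=0.01).  The reference analysis used
100 replicates; this package's acceptance run uses 10 and the test suite 6,
sized so each reported mean carries a Monte-Carlo standard error of a few
percent.  What passing shows: the three variability sources are separable
on data *generated by the model itself* under this design; it does not
show robustness to model misspecification beyond the deliberate ODE-mode
(σ pinned at 0) comparison, where the measurement-error standard deviation
absorbs the neglected system noise (~six-fold inflation).

The NiAc (nicotinic acid) disposition structure — one-compartment turnover
with endogenous synthesis, capacity-limited elimination, steady-state
initial condition c(0) = Synt·Km/(Vm−Synt), infusion input and
proportional residual error — is exercised on synthetic data only: 15
subjects in two infusion groups (0.67 µmol·min⁻¹·kg⁻¹ over 30 min /
0.17 over 300 min) on an 18-point sampling grid chosen to cover infusion,
washout and the long-infusion tail.  The real rat dataset behind the
original analysis is not publicly available, so parameter recovery is
asserted against the synthetic truth within 3 Hessian-based standard
errors of a single desk-scale fit.

## Numerical choices and degenerate inputs

* R singular (S = 0 with an uninformative P) raises a filtering error
  naming the cause; integration failures fail fast (step-count cap 2000
  per segment) so that diverging trial parameter points cost little.
* Zero observations: the inner mode is exactly η = 0 with curvature −Ω⁻¹.
* Zero random effects (r = 0): the machinery degrades to plain maximum
  likelihood; the Laplace correction is identically zero.
* Models with no diffusion columns (q = 0) are ordinary ODE mixed-effects
  models and take the same code path with ΣΣᵀ ≡ 0.
* Filter covariances are re-symmetrized after every update (and so are
  their sensitivities); predicted/filtered P stay PSD to −1e-10.

## Known limitations

* Output dimension ≤ 2 (symbolic inversion of R in the compiled update
  map); both shipped models are scalar-output.
* First-order EKF linearization: strongly nonlinear measurement or drift
  nonlinearity *within* one inter-observation interval is linearized, as
  in any EKF-based approach; no unscented/particle options.
* The Laplace/FOCE(I) objective is an approximation; it is exact only for
  models linear in η with Gaussian everything (asserted in tests).
* Euler–Maruyama is weak order 1: moments of simulated data carry O(step)
  bias, which at step 0.01 min is well below the parameter-recovery
  Monte-Carlo error here, but matters if the step is raised.
* The sign of the off-diagonal factor entries (ω12) is weakly identified
  at n = 20 subjects (replicate RSE well above 100%, as in the reference
  analysis); its point estimate should not be over-interpreted.
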