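# Methods

## Model and output semantics

The object computed is the cumulative first-passage probability of a 1D
diffusion `dX = mu(t,X) dt + sigma dW` between absorbing boundaries
`alpha(t) < beta(t)`:

    F(tau, y) = P[ hit alpha first, no later than tau | X_0 = y ].

`F` solves a backward Kolmogorov equation in reversed time with data 1 on
the lower boundary, 0 on the upper, and 0 initially.  Because boundary and
initial data disagree at one corner, `F` is discontinuous there; every step
of the pipeline exists to route around that singularity.

Only cumulative probabilities are exposed, not decision-time densities.
The lower boundary is the reference outcome; upper-boundary probabilities
are obtained by the reflection `x -> 1-x`, `v -> -v` (`reflect_problem`).

## Transformation chain

1. **Unit diffusion, reversed time** (`models.rescale_to_unit_diffusion`):
   `ttilde = (sigma^2/2)(tau - t)` absorbs the diffusion coefficient and the
   time reversal; boundaries and drift are composed with the reversed clock
   and the drift is scaled by `2/sigma^2`.  All reversal bookkeeping lives
   in this one function; downstream code never sees original time.
2. **Space flattening and time warp** (`transform`): the affine map
   `xi = (1-x) a + x b` fixes the strip to `(0,1)`; the warp `theta` with
   `theta' = (b - a)^2` keeps the equation's diffusion coefficient at one.
   The warped horizon is `T = integral of (b-a)^{-2}`.  The transformed
   drift picks up an advection term from the boundary motion:
   `v = (b-a) [vtilde + (1-x) a' + x b']`.
3. **Unit time**: `vhat(t,x) = v(tT, x)`; the PDE on `(0,1)^2` reads
   `u_t = T (u_xx + vhat u_x)`.

The warp inverse is the explicit integral, evaluated by adaptive panel
quadrature (15-point Gauss–Legendre per panel, two-half error control) and
represented as a cubic Hermite spline whose nodal slopes are the *exact*
integrand values.  Panels are refined until both the quadrature increment
and the spline's midpoint reproduction meet the tolerance (default 1e-12
relative), so the spline is as accurate as the integrals.  `theta` itself is
the spline inverse polished by three Newton steps with the exact ODE
derivative; round-trip error is at roundoff.  For the collapsing-bounds
family the warp is rational and a closed form is provided; the quadrature
warp reproduces it to better than 1e-10 relative over the whole parameter
box, so the generic path never dominates the error budget.  The quantity
`b(theta(t)) - a(theta(t))` is always recomputed from `a`, `b`, `theta`
directly rather than through any precomposed display.

## Constant-drift reference

The singular part is `u(v0, T)`, the solution with drift frozen at the
corner value `v0 = vhat(0,0)`.  Two independent representations are
implemented (`constdrift`); each is used where it converges fastest and
they cross-validate each other to 1e-10:

* **Spectral (long-time)**: with physical time `s = tT` and steady profile
  `u_inf(x) = (e^{-v0 x} - e^{-v0}) / (1 - e^{-v0})`,

      u = u_inf - sum_n b_n e^{-v0 x/2} sin(n pi x) e^{-(n^2 pi^2 + v0^2/4) s}.

  The coefficients are the sine coefficients of `u_inf e^{v0 x/2}` and
  collapse to the closed form `b_n = 2 n pi / (v0^2/4 + n^2 pi^2)`
  (verified against numerical quadrature in the tests).  Truncation uses
  the exponential tail bound at tolerance 1e-12.
* **Image/Girsanov (short-time)**: by the Markov property
  `u(s,x) = u_inf(x) - Int p(s,x,y) u_inf(y) dy` with `p` the killed
  transition density, expanded as a Girsanov-tilted method-of-images sum of
  heat kernels; every term reduces to erf differences in closed form.  Tail
  differences of erf are computed through erfc to avoid cancellation, which
  matters at the strong drifts (|v0| up to ~40) the linear-drift family
  reaches.  The sinh-ratio form of `u_inf e^{v0 y/2}` keeps the driftless
  limit seamless; below |v0| = 1e-8 the exact driftless formula is used.

The switchover sits at physical time `s = 0.05`, where both series need
only a handful of terms; continuity across the switch is tested at the
series tolerance.  The corner itself is never evaluated by quadrature; the
limit convention at `t = 0` is 1 on the lower boundary and 0 elsewhere.

The half-space heat layer `Erfc(x / 2 sqrt(t))` is exposed separately; it
is the carrier of the corner singularity and a finite-difference check
confirms it solves the heat equation.

## Residual problem and minimal-residual discretization

The computed unknown is `e = u(v) - u(v0)`, which has homogeneous data and
is provably smoother than either term.  Its forcing is used in
integrated-by-parts form,

    f(z) = Int Int T u(v0) ( -vhat_x z - (vhat - v0) z_x ),

which requires only *values* of the reference solution — its derivative is
singular at the corner — and is bounded near the corner because
`vhat - v0` vanishes there.  Gauss points are interior to cells, so the
data discontinuity is never sampled.  An optional geometric refinement of
the corner cell was considered and rejected: quadrature convergence tests
show the 4x4 Gauss rule already resolves the forcing to the level where
errors are indistinguishable at all mesh sizes used.

Spaces on a uniform n-by-n tensor mesh of the unit square:

* trial `X_h`: continuous piecewise bilinears, zero at `x in {0,1}`, free
  at `t in {0,1}`; the initial condition enters weakly through the
  initial-trace mass matrix `C`;
* test `Y_h`: (discontinuous piecewise linear in t) x (same P1 in x), so
  `X_h` is a subspace of `Y_h` and the discrete inf-sup condition of the
  underlying theory applies.

The discrete solution minimizes `||B w - f||_{Y_h'}^2 + ||gamma_0 w||^2`,
realized as a sparse saddle-point system factorized directly (sizes up to
n = 256 pose no difficulty); the block residual is verified below 1e-10
after every solve.  Constant-coefficient matrix blocks are exact Kronecker
products of 1D element matrices; drift-dependent blocks use per-cell 4x4
Gauss quadrature (exact for the polynomial factors).

**Energy matrix and the shift `lam`.**  The dual norm on `Y_h` is realized
through the SPD matrix `A_s` built from the symmetric part of the spatial
operator.  A direct computation gives
`A_s(z,z) = T ||z_x||^2 + (T/2) Int (vhat_x) z^2`, so `A_s` is definite
outright whenever `vhat_x >= 0`, or when `sup|vhat| < pi` (Poincare).  For
steeply *decreasing* drifts — the linear-drift family reaches
`vhat_x = -32` — definiteness can fail, and `auto_shift` adds
`lam = (T/2) sup (vhat_x)_-` times the mass matrix to `A_s` only.  This is
a deliberate design choice: the theory permits any spectrally equivalent
energy on `Y_h`, and shifting only `A_s` avoids the alternative of solving
for an exponentially transformed unknown `w e^{-lam t}`, whose scale factor
`e^{lam}` overflows double precision at the shift sizes these drifts would
require.  `B`, the forcing, and the reported solution are untouched by
`lam`.

**Error reporting** uses the discrete equivalent of the norm on
`L2(H^1_0) ∩ H^1(H^-1)`:
`||w||^2 = (Bw)^T A_gram^{-1} (Bw) + w^T C w` with `A_gram` the plain
`d_x` Gram matrix on `Y_h` — deliberately *not* the shifted `A_s`, so
reported errors are comparable across drifts.  Convergence studies measure
`||e_{h/2} - e_h||` (coarse field prolonged by exact nodal interpolation,
difference measured in the finer system's norm) and report the
least-squares slope of log error against log h.

**Study conditions.**  Convergence is assessed per family as the maximum of
this error over the parameter points {all-lo corner, all-hi corner, center}
for h = 2^-2 … 2^-6 (finest companion solve at h = 2^-7).  Per-point slopes
are first order asymptotically; at extreme corners with drift boundary
layers of width ~1/40 the coarsest meshes are preasymptotic and the
per-point least-squares slope can sit below the asymptotic rate, while the
max-over-points curve (the protocol used throughout, matching how the
error-versus-h tables are produced by `cmd convergence`) is governed by the
largest, first-order-decaying error.

## Sparse interpolation

The emulator interpolates `rho -> e_h(rho)` (FEM coefficient vectors on one
shared mesh, so interpolating coefficients is exactly interpolating the
field) with the Smolyak construction on nested Clenshaw–Curtis abscissae:
level 1 is {0}, level i+1 the 2^i + 1 cosine extrema, level 0 the zero
operator.  Since the zero operator annihilates its difference term, the sum
effectively runs over indices `i in N^N` with `|i|_1 <= q`, consistent with
the requirement `q >= N`.  Difference products are expanded into signed
full tensor interpolants whose coefficients are accumulated per tensor
index; evaluation is barycentric per level.  Nodes are symmetrized cosines
(`(cos(j pi/m) - cos((m-j) pi/m))/2`), which makes plus/minus pairs exact
negatives and keeps nesting bitwise exact, so node caching across levels is
safe and the interpolation property holds to machine precision.

The Lebesgue-constant bound `(#{i : |i|_1 <= q})^2 = binom(q+N, N)^2` is
exposed and checked against sampled estimates.  The default parameter test
set is `{-1, -0.5, 0.5, 1}^N`; the variant including 0 is available
(`include_zero`), since both appear in practice.  Interpolation error over
the test set is nonincreasing in q for the linear-drift family at h = 2^-4,
but its absolute size at small q is substantial — consistent with the
known caveat that sparse interpolation of these solution manifolds needs
either large q or adaptivity (the latter is out of scope here).

## Monte-Carlo oracle

`montecarlo` simulates the SDE directly with Euler–Maruyama: default
10^5 paths and dt = 1e-4 tau, seeded and bitwise reproducible.  Naive Euler
misses within-step boundary excursions, biasing hitting probabilities down
by O(sqrt(dt)); each surviving step therefore also samples the
Brownian-bridge crossing probability `exp(-2 d_start d_end / (sigma^2 dt))`
for both boundaries frozen at the step's left endpoint.  When both
boundaries flag a crossing in one step — probability
`exp(-2 d_a d_b / (sigma^2 dt))`, negligible at the default step — the hit
is assigned proportionally to the two crossing probabilities; this is an
approximation to sampling the two bridge crossing times and is documented
as such.  The crosscheck band is `3 se + c h` with `c = 1` as an a priori
constant for the pointwise PDE error at mesh width h.

The oracle shares nothing with the PDE pipeline beyond the model
definition, so agreement (typically a few 1e-4 to a few 1e-3 at the default
settings) validates the rescaling, warp, drift transform, series reference,
solver and pull-back jointly.

## What the built-in families do and do not cover

The three families span time-dependent drift, space-dependent drift, and
moving boundaries, with horizons 0.1–2.5 and drifts up to |v0| ~ 40 after
transformation — but all have affine-in-x drift and boundaries, analytic in
their parameters.  Passing tests demonstrate correctness of the method on
this class; they do not exercise non-smooth drifts, boundaries that are
merely continuous (the transform assumes C^1), or horizons past a boundary
collapse, all of which are rejected with explicit errors.  A `custom`
family accepts sympy-parsed expressions for drift and boundaries with
analytic derivatives supplied by the user; no numerical differentiation is
performed anywhere.

## Numerical defaults

| quantity | default | rationale |
|---|---|---|
| series tolerance | 1e-12 | keeps the reference far below FEM error |
| series switchover | s = 0.05 | both series need <= ~15 terms there |
| warp tolerance | 1e-12 relative | warp must never dominate the budget |
| quadrature | 4x4 Gauss per cell | exact for polynomial factors; convergence-tested |
| solver mesh | n = 64 | pointwise F error well below MC resolution |
| shift `lam` | auto | 0 unless `A_s` needs it; see above |
| MC paths / dt | 1e5 / 1e-4 tau | 3 se ~ 5e-3; bridge correction removes dt bias |

Degenerate inputs: boundaries that touch before the horizon are rejected at
rescaling (dense sign check) and again by the warp quadrature (divergence
guard); `rho` outside the cube, start points outside `[alpha(0), beta(0)]`,
non-dyadic mesh lists for refinement studies, and `q < N` all raise
immediately with messages naming the violated condition.
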