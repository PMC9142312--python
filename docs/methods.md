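# Methods

## Model

The package implements the three-species tumor–host–effector competition
system

    D^{q1} x = a x (1 − y)(1 + z) − x² y
    D^{q2} y = b y (1 − z)(1 + x) − y² z
    D^{q3} z = c z (1 − x)(1 + y) − z² x

with Caputo derivative orders `q_i ∈ (0, 1]` and positive growth rates
`a, b, c` (1/time). The algebraic form was fixed by requiring internal
consistency of the canonical parameter set `(a, b, c) = (0.7455, 0.7367,
0.5619)`: it simultaneously yields the boundary equilibria
`(0, −1, b/(b−1))` (and cyclic analogues), an extinction-state Jacobian
`diag(a, b, c)`, an interior coexistence equilibrium at
`(0.5961, 0.6718, 0.6364)` (4 decimals), and a coexistence spectrum
`0.0712 ± 1.0922i, −1.3498` whose sum equals the analytic Jacobian trace.
No competing bracketing of the interaction terms satisfies all four checks,
and the obvious alternatives introduce divisions by zero at the boundary
equilibria. The negative real eigenvalue (not a positive one) is the
consistent choice: it matches the trace and the saddle-focus geometry.

States are never clipped to the positive octant; three equilibria have
negative coordinates and must be reachable by the analysis code even though
negative populations carry no biological meaning.

## Caputo Adams–Bashforth–Moulton solver

`fractumor.solver` implements the standard one-pass predictor–corrector
(PECE) product-quadrature scheme on a uniform grid `t_n = n h`: a fractional
rectangle-rule predictor with weights `ω_{j,n+1} = (h^q/q)((n−j+1)^q −
(n−j)^q)` and prefactor `1/Γ(q)`, then a single fractional trapezoid
corrector with the classic `η` weights and prefactor `h^q/Γ(q+2)`,
evaluating the right-hand side at the predicted state. Incommensurate
systems share one grid; each equation keeps weight tables for its own order.
At `q = 1` the weights reduce *exactly* to the rectangle and trapezoid
rules.

Numerical verification (all in the test suite):

- constant forcing `D^q u = 1` reproduces `t^q/Γ(q+1)` to ~1e−11 (the
  product-trapezoid quadrature is exact for piecewise-linear integrands);
- linear relaxation `D^q u = −u` matches an arbitrary-precision
  Mittag-Leffler series `E_q(−t^q)` to better than 1e−3 at `h = 1e−3`
  (observed ~2e−7);
- the `q = 1` limit matches an adaptive classical integrator on the full
  model to ~2e−5 over `t ∈ [0, 50]` at `h = 1e−3`.

Defaults: `h = 0.01`, `t_end = 500` for single runs, with the first 60% of
every analyzed series discarded as transient. Wide parameter sweeps use
`h = 0.02`, `t_end = 150` (resolution documented in every experiment
manifest). Cost is O(N²) in the step count because the full memory is kept;
an optional truncated-memory window exists for exploration but is labelled
approximate — truncation errors on this model are large and can even
destabilize the integration for short windows, so no quantitative result in
the package uses it.

Divergent trajectories (non-finite state or max-norm above 1e6) abort with
the failing step index and the partial trajectory attached; parameter scans
record such points as a `diverged` regime instead of failing.

## Equilibria and Matignon stability

The four closed-form equilibria are returned symbolically exactly (an
equilibrium whose defining rate equals 1 is undefined and omitted with a
warning). The coexistence equilibrium is refined by damped Newton iteration
with the analytic Jacobian and backtracking line search (residual tolerance
1e−12, max 100 iterations, default guess `(0.5, 0.5, 0.5)`); failure is
reported explicitly, never replaced by a fallback value.

For commensurate order `q`, an equilibrium is asymptotically stable iff
every Jacobian eigenvalue satisfies `|arg λ| > q π/2`. Reports carry the
per-eigenvalue margins and the chaos-threshold order
`q* = (2/π) min |arg λ|`, capped at 2 when all eigenvalues are negative
real, 0 when a positive real eigenvalue makes the point unstable at every
order, and undefined for a zero eigenvalue. For the canonical parameters
`q* = 0.9585`, i.e. the necessary condition for chaos around the coexistence
point is `q > 0.96` after rounding. For incommensurate orders the theorem
does not directly apply; reports evaluate the condition at
`max(q1, q2, q3)` and are flagged `heuristic_incommensurate`. The
generalized (common-denominator) Matignon condition is noted here as the
rigorous alternative but is not implemented.

## Largest Lyapunov exponent

The LLE is computed with Benettin-style renormalization applied to the
fractional variational system `D^q δ = J(x(t)) δ` along the fiducial
trajectory, discretized with the very same ABM weights (the Jacobian is
evaluated at the corrected state of each step). Two points motivated this
construction over the naive two-trajectory method:

1. the ABM update reconstructs `u_{n+1}` from `u_0` plus the entire
   right-hand-side history, so rescaling a perturbed trajectory's current
   state alone does not change its future at all; and
2. rescaling its whole history difference instead multiplies the stored
   initial-time separation by the stretch factor at every renormalization,
   which grows without bound whenever the dynamics contract.

For the *linear* variational system, by contrast, rescaling the complete
tangent history is exact — renormalization becomes a pure floating-point
range device and the classic log-stretch bookkeeping carries over
unchanged. Defaults: initial amplitude 1e−8 with a seeded random direction
(the package's only randomness), renormalization every 1.0 time units,
first 40% of intervals discarded; the result records the running-estimate
trace and flags non-convergence when the final 20% of the trace spreads by
more than 20%.

Validation: `du/dt = −u` gives `−0.9999`; at `q = 1` the estimates agree to
~1e−3 with an independent classical (adaptive-integrator) Benettin and
tangent-linear computation.

Known limitation: because the nonlocal reconstruction represents `δ(t)` as
`δ_0` plus a memory integral, *exponentially* contracting tangent flows are
representable only while `|λ| t ≲ 30` (beyond that, cancellation exhausts
double precision and the integration aborts). Matignon-stable fractional
regimes decay algebraically (Mittag-Leffler tails), so in practice this
constrains only integer-order strongly-damped test problems.

## Regime classification and scans

Bifurcation diagrams use strict local maxima of one state variable after
discarding the transient (60% by default). Classification:

- **stable** — the trajectory converges to that parameter point's own
  coexistence equilibrium: final distance < 1e−2 and either still shrinking
  (versus the distance at 80% of the run) or already below 1e−3, the
  solver's near-equilibrium discretization-bias scale at the sweep
  resolution. Convergence is judged on the trajectory, not on peak
  statistics, because fractional relaxation is algebraic and a converging
  run can carry a slowly decaying peak train for hundreds of time units.
  Without an equilibrium reference, a fallback amplitude rule is used
  (post-transient oscillation amplitude < 1e−2 and not growing), which also
  keeps genuine small-spread period-1 cycles out of the stable bin.
- **periodic** — at most 16 distinct peak clusters (cluster tolerance
  1e−3).
- **chaotic** — largest Lyapunov exponent above 0.005.
- **periodic-or-chaotic** — many clusters but no LLE available; scans in
  `auto` mode compute the LLE exactly for such points.

These thresholds are package choices (the underlying study states none);
they separate the canonical exemplar points `q = 0.95 / 0.97` and
`b = 0.28 / 0.45 / 0.53` at the default scan settings, and the commensurate
sweep's stability onset (0.960 on a 0.005 grid) agrees with the analytic
`q* = 0.9585` to within one grid step.

## Empirical caveats at the canonical parameters

Two honest discrepancies, established with step-size and seed robustness
checks and left visible in the acceptance tests:

- At `q = 0.995` the computed LLE is positive but small (≈ +0.0005 at
  `t_end = 300`, ≈ +0.0013 at 500; unchanged at `h = 0.005`), below the
  0.005 chaos threshold, and the orbit settles onto a period-1 cycle
  (x-peaks ≈ 3.87) by `t ≈ 1500`: the irregular dynamics near `q = 1` is a
  long chaotic transient rather than a sustained attractor. The same holds
  for the integer-order system, which migrates to a large periodic orbit
  (x-peaks ≈ 12.2) with LLE ≈ 0 under two independent methods.
- In the incommensurate `q1` sweep (`q2 = q3 = 1`) trajectories still
  converge to the coexistence equilibrium up to `q1 ≈ 0.85` (final distance
  ~3e−4 at `h = 0.01`, `t_end = 300`); sustained oscillation begins at
  `q1 ≈ 0.86`, which the package reports as the stability boundary.

## Experiments and provenance

Every named experiment is a fully resolved configuration (parameters,
orders, initial condition, grid, solver settings); outputs are CSV/JSON
plus regenerated plots, and each run writes a manifest recording the
configuration, package version, seed and artifact list. Custom experiments
are YAML files validated field by field. The fixtures bundle (weight
tables, short trajectories with a classical cross-check) regenerates
bit-identically for a fixed seed and is checksummed in its manifest.
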