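# Methods

## Model

Four infinite populations — government, public hospitals, pharmaceutical
enterprises, the public — each mix two strategies with frequencies
`x, y, z, w ∈ [0,1]`. A pure strategy profile is a corner of the unit
4-cube, encoded as bits `(gov, hosp, pharma, public)` with 1 = the active
strategy (strict regulation / strong enforcement / self-discipline /
participation). The payoff tensor assigns each player a utility at each of
the 16 profiles, every entry a signed sum of the 18 parameters.

Under replicator dynamics each frequency grows in proportion to its
strategy's payoff advantage over the population average, which for a
two-strategy population reduces to

    dp/dt = p (1 − p) · B(p₋),     B = E_active − E_passive,

where `B` weights the player's eight relevant tensor entries by the *other*
three frequencies. Consequences used throughout:

- `B` never depends on the player's own frequency, so each face of the
  cube is invariant and all 16 vertices are fixed points;
- `B` is multilinear in the opponents, so the Jacobian is available in
  closed form, is diagonal at every vertex, and each single-variable slice
  of `B` is affine (thresholds are unique roots);
- four parameters — `R_g, L_g, L_p, S_p` — cancel out of every `B` and
  provably never influence the dynamics. They default to 1.0 each and stay
  configurable; nothing downstream depends on the choice.

### Canonical vs. printed right-hand sides

The canonical system of record is derived from the payoff tensor at run
time. The literal published closed forms are also implemented
(`printed_rhs`, CLI flag `--as-printed`) for cross-checking only. The
hospital, pharma and public printed forms agree with the tensor exactly.
The government printed form carries `C_g` in one term where the tensor
derivation yields `k_g` (the loose-regulation expected payoff behind it
uses `R_g − C_g` where the payoff table prints `R_g − k_g`); the gap is
`x(1−x)·y·z·w·(C_g − k_g)`, equal to 0.03125 at the baseline uniform state.
No reported limit in the sweep experiments changes between the two modes.

One payoff-table cell is corrected relative to its printed form: at
(loose, weak, no-self-discipline, non-participating) the printed table
shows `S_c − k_c`, but the credibility term is defined to act only under
public participation and the published expected-payoff expansion uses
`S_c` for that profile; the tensor stores `S_c`.

## Parameters

Baseline values: `R_g=10, R_h=2, R_c=4, k_g=5, k_h=2, k_c=6, S_h=10,
S_c=5, D_h=6, D_c=6, C_p=1, C_g=6, C_h=4, C_c=3, α=0.5` (utility units;
`α` dimensionless). They satisfy the four convergence conditions
`C_g − αD_h − k_g < 0`, `D_h − C_h − S_h + R_h + 2k_h < 0`,
`−D_c + C_c + S_c − 2k_c < 0`, `(α−1)D_h + C_p < 0`, making
`(1, 0, 1, 1)` the unique ESS. Parameter files are flat YAML/JSON maps
keyed by the symbol names.

## Numerics

**ODE integration.** Adaptive explicit Runge–Kutta (scipy `RK45`,
rtol 1e−8, atol 1e−10) over `t ∈ [0, 100]` by default — the experiments'
"100 iterations" are interpreted as continuous time on [0, 100]; 2001
equally spaced samples are stored. The state is never clipped: the
replicator form preserves the cube structurally, and any excursion beyond
1e−6 outside [0, 1] raises an error.

**Convergence detection.** A trajectory has converged to a vertex when its
max-norm distance is below tol = 0.01 at the end *and* throughout the final
10% of the time span (the experiments report asymptotes only as 0 or 1,
hence the absolute ball). The first-passage time is the earliest sampled
time inside the ball.

**Vertex classification.** Eigenvalues at a vertex are the Jacobian
diagonal; labels use a sign tolerance of 1e−9, with values inside the band
labelled `critical` (mirroring the uncertain-stability case). Canonical
eigenvalue expressions are generated from the tensor — symbolically for the
feasibility shortcut, numerically elsewhere — never transcribed from the
published stability tables, which contain typos that `condition_table`
flags instead of reproducing: the strict-regulation rows (1,1,0,0) and
(1,1,0,1) print `D_h` in the fourth eigenvalue where the derivation gives
`D_c`; row (1,0,1,1) prints `(1−α)D_h + C_p` where the derivation gives
`(α−1)D_h + C_p`; row (1,1,1,1) prints `k_c` in the second eigenvalue where
the derivation gives `k_h`. All loose-regulation rows agree. The
consistency flag compares formulas across several random admissible
parameter sets, so it detects formula-level disagreement, not a single
coincidence.

**Feasibility search.** For each strict-regulation vertex, 100 000
parameter sets are drawn uniformly (quantities in (0, 10), `α` in (0, 1),
fixed seed 20250909 by default); a vertex is stabilizable if some draw
makes all four eigenvalues negative. Since the inequalities are linear in
the parameters, feasible regions carry non-trivial volume and this draw
count is robust. An analytic shortcut runs first: a symbolic eigenvalue
whose expansion has only non-negative coefficients (checked across a dense
`α` grid, the coefficients being affine in `α`) and no constant term can
never be negative — this certifies the two infeasible vertices
((1,1,1,0) via `C_g + R_c + R_h`, (1,1,1,1) via `C_p`) rather than relying
on sampling to fail.

**Thresholds.** Affinity of each single-variable payoff-difference slice
is asserted by a midpoint collinearity check (tolerance 1e−9 relative);
roots inside [0, 1] are refined by bisection to 1e−10, roots outside are
reported with the uniform drift sign.

**Basin volumes.** The basin is the region of the opponents' cube with
positive drift, estimated under the uniform measure by midpoint-rule grid
quadrature (`round(n^(1/3))` nodes per axis) or Monte Carlo with binomial
standard errors. The published closed-form volume integrals are *not*
implemented as oracles: they are internally inconsistent (one result keeps
a variable that was integrated over; another substitutes a credibility gain
for a reward inside the drift), so numerical estimation over the cube is
the system of record and the two estimators cross-check each other.

**Comparative statics.** Basin sensitivities use central finite
differences with an absolute step of 0.5 on the grid estimator with shared
nodes: the grid volume is a fraction of sign-flipped cells, so the step
must be large enough to flip some. The hospital's claimed signs are
evaluated at the low short-term-benefit setting `S_h = 4` (a value used by
the published sweeps): at the baseline `S_h = 10` the hospital bracket is
negative on the whole cube (maximum −2), the basin is identically zero and
carries no sign information. Government, pharma and public basins are
interior at the baseline and are evaluated there.

## Time-delayed variants

One player reacts with lag `τ`: every occurrence of its frequency — its own
logistic factor and growth bracket, and the other three players' brackets —
is read at `t − τ`; the pre-history is the constant initial state.
Integration is by the method of steps with a fixed step (classic
fourth-order Runge–Kutta per step; with the step fixed by the delay an
embedded error estimate adds nothing, so none is used) and cubic Hermite
interpolation of the stored history. The step defaults to
`min(τ/10, 0.05, 1/maxB)`, where `maxB` bounds the payoff differences over
the cube corners; the caps keep the explicit scheme inside its stability
region for the large random witness parameter sets of the delay suites. A
user-supplied step larger than `τ/2` is rejected; `τ = 0` falls back to
the ODE path.

**Cube projection.** Unlike the plain system, the delayed equations do not
preserve the cube: the delayed player's own rate carries the *lagged*
logistic factor, which is still nonzero when the current frequency reaches
0 or 1, so the frequency overshoots, and the quadratic logistic then
amplifies the excursion without bound (at the baseline with τ ≥ 0.5 the
literal system diverges). Frequencies are probabilities, so the integrator
treats the cube as a hard constraint and projects (componentwise clamps)
the state after each step — the standard projected-dynamical-system
treatment. Components started exactly at 0 or 1 remain pinned without any
projection, and once a projected component's lag window passes its rate
vanishes. With projection the delayed runs reproduce the reported
phenomenology: the limit vertex is invariant across τ ∈ {0, 0.5, 1, 2}
(the default grid; the source experiments never state their τ values) for
all three delayed players, while first-passage times shift with τ. The
claim that convergence is uniformly *faster* under longer delays is
measured and reported per run, never asserted: at the baseline it holds for
the pharma variant but reverses for the hospital variant.

Delay-suite panels (six per variant) use parameter sets produced by the
feasibility search as witnesses for each stabilizable strict-regulation
vertex, drawn with a fixed seed so the suites are fully reproducible; the
panel configs record the parameter sets used.

## Known limitations and flagged discrepancies

- At `C_g = 12` the passive-vertex eigenvalue `D_c + D_h − C_g` is exactly
  zero, so the strict-regulation frequency decays without an exponential
  tail and plateaus near 0.016 by t = 100 instead of entering the
  0.01-ball; the reported "stabilizing at 0" is approached but not attained
  at this horizon.
- The published narrative that the self-discipline frequency stabilizes at
  0 when `S_c = 13` contradicts the corresponding stability condition
  (`−D_c + C_c + S_c − 2k_c = −2 < 0` keeps z = 1 locally stable there);
  the simulator reports the condition and the actual ESS.
- Only the 16 pure vertices are classified; interior equilibria,
  finite-population (stochastic) dynamics, distributed or state-dependent
  delays, and stability analysis of the delayed characteristic equation are
  out of scope.
- No attempt is made to estimate parameters from real healthcare-sector
  data; all experiments are synthetic parameter studies, so passing tests
  certify the dynamics and their comparative statics, not any empirical
  claim about carbon emissions.
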