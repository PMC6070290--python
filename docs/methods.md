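# Methods

## Model

Two state variables: the cooperator fraction `x ∈ [0,1]` and the resource
stock `y ≥ 0`. Strategy frequencies follow the replicator equation
`ẋ = x(1−x)(P_L − P_V)`; the resource follows logistic growth minus total
consumption, `ẏ = r y (1 − y/R_m) − N[b_l x + (1−x) b_v]`. Payoffs are the
harvests themselves, with the violator's expected fine subtracted:
`P_L = b_l = b_m y / R_m`, `P_V = b_l(1+α) − pβ`. Substituting gives the
two-dimensional autonomous system implemented in `model_core.vector_field`;
the package keeps both the generic composition and the substituted form and
property-tests their equality.

Assumptions worth keeping in mind:

- **Well-mixed population.** Frequencies suffice; no network structure.
- **Expected fines in the ODE.** Detection is a per-time-unit probability,
  but the mean-field equations use `pβ` as a continuous expected fine
  rate. Stochastic per-agent detection appears only in the Monte Carlo
  module. (This is also why `p` and `β` enter the deterministic analysis
  only through their product.)
- **Payoff = harvest.** No production function transforming income into
  fitness, no time-scale separation between strategy and resource dynamics,
  no structured population; these are all deliberate non-goals.

## Parameters

| symbol | meaning | constraint | study default |
|---|---|---|---|
| `r` | intrinsic resource growth rate (per time) | > 0 | 0.3–1.0 |
| `R_m` | carrying capacity (resource units) | > 0 | 1000 |
| `N` | population size | positive integer | 1000 |
| `b_m` | maximal per-capita allocation (resource/time) | > 0, advisory `b_m ≤ R_m/N` | 0.5 |
| `alpha` | defection severity | > 0 | 0.5 |
| `p` | detection probability per time unit | 0 < p < 1 | 0.01–0.5 |
| `beta` | fine on detection (payoff units) | > 0 | 0.1–0.5 |

`b_m > R_m/N` (the community's nominal total draw exceeding a full pool) is
accepted with a logged warning so sweeps can probe the constraint. A
`permissive` flag admits the edge values `p ∈ {0, 1}` and `β = 0` for
sweeps; these sit in non-hyperbolic territory and are excluded from the
analytic regime classification.

## Equilibria and stability

The five closed-form fixed points are enumerated directly; candidates
outside the physical domain are dropped, and coincident candidates (e.g.
the sustainable-cooperation point colliding with `(1,0)` when `r = e_c`)
are merged keeping the boundary-family label, so the admissible count is
always between 2 and 5. The boundary y-coordinates are
`R_m − b_m N/r` (full cooperation) and `R_m − b_m N(1+α)/r` (full
defection), obtained by solving `ẏ = 0` at `x = 1` and `x = 0`; a residual
oracle (`‖vector_field‖ < 1e−9·max(1, R_m)` at every reported point) guards
the algebra.

Stability comes from the eigenvalues of the analytic Jacobian. The four
boundary Jacobians are triangular, so their eigenvalues are the diagonal
entries; the interior Jacobian has zero upper-left entry and negative
trace. An eigenvalue is treated as zero when its real part is within
`1e−9 · max(1, spectral radius)` (configurable); such points are labelled
`non_hyperbolic` and the analytic classifier defers to numerical
integration rather than encoding centre-manifold results. Saddles are
counted as unstable for regime bookkeeping: almost every trajectory leaves
them (the origin in the slow-growth regime is such a saddle — its
resource direction is attracting but the strategy direction repels).

`classify_regime` applies the threshold table from the README. Within the
coexistence window the interior resource level is exactly
`y* = pβ R_m/(b_m α)` — linear in the expected fine with slope
`R_m/(b_m α)` — while the interior cooperator fraction carries a
`pβ`-independent offset, which is why weakening institutions drags the
equilibrium toward the depleted-resource axis faster than toward full
defection.

## Numerical integration

Adaptive explicit Runge–Kutta (scipy's RK45) with `rtol = 1e−8` and
`atol = 1e−10` (scaled by `R_m` in the resource coordinate; the system is
non-stiff at these scales). Stored states are projected back into
`x ∈ [0,1]`, `y ≥ 0`; projection magnitudes above `1e−9` (relative) are
logged — in practice drift stays at rounding level. Convergence is declared
when `‖vector_field‖∞ < 1e−8 · max(1, R_m)` at the final state; state
stagnation is deliberately not used, since slow manifolds stall the state
long before the flow vanishes.

`find_attractor` integrates in doubling horizons (default start 2000 time
units, cap 128 000) because interior points with a weak expected fine are
slowly decaying spirals (slowest mode `∝ pβ r/(α b_m)`). Terminal states
are matched to equilibria in scaled `(x, y/R_m)` coordinates within
`1e−3` — far above solver error, far below inter-equilibrium spacing at the
parameter scales above. Phase-diagram sweeps label each `(r, pβ)` cell
analytically (holding `β` at the template value, permissively setting
`p = pβ/β`) and can cross-check a random fraction of cells by integration;
a mismatch raises a consistency error naming the cell. Cells are
independent, so results do not depend on evaluation order.

Default initial condition where one is needed: `(x₀, y₀) = (0.5, R_m/2)`.
The depicted regimes are initial-condition independent away from boundary
cases, so the choice only affects transients.

## Individual-based Monte Carlo

One step: (1) realize payoffs at `y(t)` — cooperators deterministic, each
defector independently detected with probability `p` and fined `β`;
(2) update the resource with the *pre-imitation* strategies via the
discrete map `y(t+1) = y + r y(1 − y/R_m) − Σᵢ harvestᵢ`, floored at zero
(extinction is absorbing); (3) each agent draws one uniform partner and
imitates a strictly better-paid partner with probability
`q = (P_j − P_i)/M`, committed synchronously against the frozen step
payoffs.

Choices that the discrete scheme leaves open, pinned here:

- **Normalization `M`.** Defined as the maximum possible payoff gap; at
  resource level `y` the best-off agent is an undetected defector and the
  worst-off is a cooperator (gap `α y b_m/R_m`) or a detected defector
  (gap `β`), so `M = max(α y b_m/R_m, β)`. This keeps `q ∈ [0,1]` exactly
  (property-tested). A resource-independent alternative
  `M = max(α b_m, β)` is available (`m_rule="static"`) for sensitivity
  checks; it rescales the imitation clock but not the attractors.
- **Update order.** Payoffs are frozen per step; the resource update uses
  step-`t` strategies (as the discrete map is written); imitation commits
  synchronously. This makes a run a pure function of `(params, config)`.
- **Determinism.** A single seeded generator with a fixed draw order
  (initial shuffle; then per step: one detection uniform per agent, one
  partner index per agent, one adoption uniform per agent) makes runs
  bit-reproducible. Initial cooperators are placed by exact count
  `round(N x₀)` to remove initial-condition variance.
- **Absorption.** A monomorphic strategy vector can never change, so after
  absorption the run stops drawing random numbers and only the resource
  map continues.

Under this scheme the expected one-step strategy drift is proportional to
`x̄(1−x̄)(pβ − α y b_m/R_m)/M` — the mean-field replicator sign — so for
`N = 1000` ensemble means land on the ODE attractor in every regime with a
robustly attracting fixed point (the agreement tests use 20 seeded runs of
5000 steps each).

### Finite-population absorption (known deviation)

At the weak-institution coexistence set (`r = 0.6`, `p = 0.01`, `β = 0.1`)
the interior attractor sits at `x* ≈ 0.61`, `y*/R_m = 0.004`, approached
through a near-boundary spiral whose first excursion sends `y` to
astronomically small values while `x̄` climbs above 0.97. A population of
1000 agents hits the absorbing boundary `x̄ = 1` during that excursion
(typically between steps 1200 and 1600), after which the resource recovers
to the full-cooperation level `R_m − b_m N/r`. The mean-field prediction
therefore fails for this parameter set at `N = 1000`: this is a real
property of the finite stochastic system (absorbing boundaries versus a
weakly attracting interior point), not a numerical artefact, and the
corresponding agreement test is left failing on purpose to document it.
More generally, passing ABM tests show agreement for robust attractors;
they do not certify mean-field behaviour near fragile ones, nor say
anything about structured populations or payoff nonlinearities that the
generator does not emulate.

## Problem sizes

The test and acceptance workloads use the study's own scales: `N = 1000`
agents, 5000-step Monte Carlo runs, 20-run ensembles, ODE horizons of
2000 time units (extended adaptively for slow spirals), a 50×50 analytic
sweep for the equilibrium-count bound, and 200 random parameter sets for
the regime/integration consistency check. The full suite completes in
about a minute on a single CPU.

## Limitations

- Non-hyperbolic boundary cases (`r = e_c`, `r = e_d`, `pβ = τ_c`,
  `pβ = τ_d`) are flagged, not analysed; the package reports
  `boundary_case` and lets numerical integration answer observable
  questions there.
- The zero-fine limit `pβ → 0` is outside the classifier's domain.
- The CSV/JSON writers embed parameters and version but no schema
  versioning beyond that.
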