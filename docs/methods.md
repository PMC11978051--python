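# Methods

## Model

One growth cycle consists of four stages applied to a population of `S`
genotypes with frequencies `f_i` summing to 1 and total mass `E`:

1. **Fission.** Genotype `i` produces `N_i(0) = f_i E / m_i` daughter cells
   of mass `m_i`.  Daughter mass is a compound trait (mature mass over
   2^divisions) treated as a single continuous heritable value.
2. **Fusion window.** For a fixed duration `T` daughters fuse pairwise by
   mass action; a pair of genotypes `(i, j)` fuses at the average of their
   rates, `(alpha_i + alpha_j)/2`.  Unfused counts obey
   `dN_i/dt = -Σ_j ((alpha_i+alpha_j)/2) N_i N_j`.  Fused-cell counts
   accumulate as `dF_ij/dt = ((alpha_i+alpha_j)/2) N_i N_j` for `i ≠ j` and
   `dF_ii/dt = alpha_i N_i² / 2`.  The factor 1/2 on the diagonal counts
   fused *cells* (an i–i fusion consumes two cells and produces one); it is
   the unique convention under which per-genotype cell number,
   `N_i(T) + 2 F_ii + Σ_{j≠i} F_ij = N_i(0)`, is conserved and the
   monomorphic window has the closed form `N(T) = N_0/(1 + alpha N_0 T)`.
3. **Survival.** Unfused cells survive with probability `S(m_i)`, fused
   cells with `S(m_i + m_j)` discounted by `1 - C`.  The cost `C ∈ [0, 1]`
   aggregates fusion failure, hindered growth of the binucleate cell and
   failed nuclear segregation — at the frequency level all three act as
   the same multiplicative factor, so a single scalar is exposed.
4. **Renormalization.**
   `f_i' ∝ N_i(T) S(m_i) + (1-C)[2 F_ii S(2m_i) + Σ_{j≠i} F_ij S(m_i+m_j)]`;
   each fused cell credits one unit to each parental nucleus.  This makes
   costless fusion between equal-mass genotypes exactly frequency-neutral,
   and with every `alpha = 0` the update reduces (to machine precision and
   by code path) to the fission-only update `f_i' ∝ (f_i E/m_i) S(m_i)`.
   Zero total surviving weight raises an explicit extinction error.

### Survival families

* **Vance**: `S(m; beta) = exp(-beta/m)`.  Increasing in `m`, harshness
  `beta` is the mass at which survival is `1/e`.  Convex for `m < beta/2`,
  which penalizes very small cells — an implicit minimum viable size.
* **Threshold-linear**: `S(m; gamma) = 1 - exp(-gamma m)` for
  `m ≥ m_min`, else 0.  Here larger `gamma` is *more benign*; the package
  exposes an explicit `harsher_than` comparator per family rather than
  assuming one ordering.  Without the explicit `m_min` this family selects
  for infinitely small daughters; with it, the fused/unfused survival ratio
  `1 + e^{-gamma m}` is bounded by 2, giving the cost ceiling
  `C_max = 1 - 1/(1 + e^{-gamma m_min})` (= 1/2 when `m_min → 0`).

## Stochastic evolutionary engine

Between events the frequency dynamics above are deterministic
(infinite-population; no drift — genotypes are lost only by pruning).
Stochastic events occur on the discrete cycle clock with geometric waiting
times, the discrete analogue of a Gillespie scheme:

* **Mutation**, rate `mu` per trait per cycle (superposed into one clock of
  rate `mu × #traits` with a uniform trait choice — an exact superposition).
  The ancestor is drawn by frequency; the mutant shifts one trait by
  `±δm` or `±δα` with equal probability and is seeded at
  `min(10⁻³, f_ancestor/2)` transferred from its ancestor.  Proposals below
  `alpha = 0` or `m_floor` are discarded with the event consumed, so
  boundary traits are not biased upward by reflection.
* **Environment switching**: fixed, scheduled (switch at listed cycles), or
  a two-state telegraph process with per-cycle switch probabilities
  `lambda_12`, `lambda_21` (geometric residence; occupancy
  `P1 = lambda_21/(lambda_12+lambda_21)`).
* Plastic genotypes carry four traits `(m1, alpha1, m2, alpha2)` and express
  the pair matching the active environment; all traits are linked (no
  recombination).

Defaults: `E = 100`, `T = 1`, `mu = 0.01`, `δm = δα = 0.02`,
pruning threshold `10⁻⁶`, `m_floor = 10⁻³`, genotypes whose traits coincide
within `10⁻¹²` are merged, and a hard cap of 1000 concurrent genotypes
guards against a mis-set pruning threshold.  `ET = 100` puts the system in
the large-`ET` regime where the closed-form limits below are accurate.
Identical configuration + seed reproduces trajectories bitwise.

## Adaptive dynamics

The selection gradients (with `K = (1-C) e^{beta/(2m)}` the cost-discounted
survival gain of a same-size fused pair) are

    H_m = -[4m(m-beta) + ET·alpha·K (4m-beta)] / [4m² (m + ET·alpha·K)]
    H_alpha = -m (1-K) ln(1 + ET·alpha/m) / [2 alpha (ET·alpha·K + m)]

with the analytic limit `H_alpha(m, 0) = (K-1) ET / (2m)` on the boundary.
Anchors fixing sign and grouping: `H_m(m,0) = (beta-m)/m²`;
`H_m → -(4m-beta)/(4m²)` as `alpha → ∞`; `H_alpha(m,0)` changes sign at
`m = -beta/(2 ln(1-C))`; and the two bifurcation costs below.  The interior
fixed point is `m* = -beta/(2 ln(1-C))` with `alpha*` obtained by solving
`H_m = 0` there (`alpha* = 4m*(beta-m*)/[ET(4m*-beta)]`), flagged
nonphysical when negative.  `alpha* = 0` exactly at `C = 1 - e^{-1/2}` and
`m* = beta/4` exactly at `C = 1 - e^{-2}`.

The flow `(dm, dalpha)/dtau = (H_m, H_alpha)` is restricted to
`alpha ≥ 0`: on the boundary with `H_alpha < 0` the alpha-dynamics are
clamped to zero.  Numerically the flow integrates the *normalized* field
`v/(1+|v|)` — identical trajectories and fixed points with bounded speed,
so regions where the gradients blow up (`m ≪ beta`) remain integrable; tau
is an abstract evolutionary time and only trajectories and endpoints are
meaningful.  Integration is segmented: interior segments hand over to
boundary segments through terminal events (alpha reaching 0 with
`H_alpha < 0`; `H_alpha` turning positive on the axis), which keeps the
right-hand side smooth within every segment.  Termination: gradient norm
below `10⁻⁸` (converged), alpha exceeding `10³/ET` (classified as
divergence to obligate fusion, with `m` reported against `beta/4`), or tau
budget exhaustion (inconclusive).

`C_Base(ET)` — the cost at which the zero-fusion basin grows to cover the
whole axis — is the root of

    8(1+2L)²[5+L(5+2L)] - (ET)²(2+L)⁴ ln(6/(2+L) - 3) = 0,  L = ln(1-C),

bracketed in `L ∈ (-2, -1/2)` (the `L = -1/2` endpoint is a trivial double
root shared with the lower bifurcation, so the bracket starts just inside).
The root is monotone in `ET` and approaches the bifurcation bounds in the
small/large-`ET` limits; convergence to the upper bound is slow
(`~ET^{-1/2}`), a property of the defining linearization.

Separatrices are computed two ways: backward integration from the interior
saddle along its stable eigendirections (finite-difference Jacobian), and a
forward-flow classification on an `(m, alpha)` lattice.  The traced stable
manifold hugs the `alpha = 0` axis once alpha falls below integration
tolerance, so the *axis intercept* of the basin boundary is computed
operationally by bisecting forward-flow outcomes along the axis
(`axis_basin_boundary`); at `C = C_Base` it sits at the origin to within
the linearization error.

## Switching environments with plasticity

With costless, instantaneous plasticity each environment's trait pair
evolves under its own gradients, time-scaled by occupancy — decoupled flows
sharing only the initial condition `m1(0) = m2(0) = m0`, `alpha(0) = 0`.
Because the flow integrator normalizes speed, the occupancy factor is
absorbed entirely; endpoints are provably occupancy-independent and are
asserted so in tests.  Two parsimonious starts are analysed:

* adapted to environment 1 (`m0 = beta1`): fusion evolves in environment 2
  iff `beta2 > 2 ln(1/(1-C)) beta1` (large-`ET`);
* bet-hedged (`m0 = m_BH = P1 beta1 + (1-P1) beta2`, the non-plastic ESS
  under switching faster than the evolutionary timescale): fusion evolves
  in environment `i` iff `m_BH` lies below that environment's saddle mass
  `-beta_i/(2 ln(1-C))`.

The printed closed-form inequalities in `(beta2/beta1, C, P1)` are
implemented alongside the saddle-mass comparisons and asserted equal on
every call (the env-2 inequality holds trivially when its denominator
changes sign near the upper cost bound).  Boundary equalities are
classified conservatively as "within basin" (no fusion) with a `10⁻⁹` tie
tolerance.  Since `m_BH` is a convex combination of the betas it can never
lie below the more benign environment's saddle mass, so from a bet-hedged
start fusion in *both* environments is impossible inside the cost band and
facultative fusion always arises in the harsher environment.

## Numerical choices

* **Fusion kinetics**: adaptive embedded Cash–Karp RK4(5) with
  `rtol = 10⁻¹⁰`, `atol = 10⁻¹²`, compiled with numba because the
  simulator integrates the window once per growth cycle (10⁵–10⁶ times per
  run).  Monomorphic and all-`alpha = 0` windows use exact closed forms;
  the numeric path is cross-checked in tests against the closed form
  (≤10⁻⁸ relative) and a fine-step Euler oracle.  Step collapse raises a
  diagnostic error rather than returning partial results.
* **Invasion oracle**: central finite difference (step `10⁻⁵`·trait,
  one-sided at the `alpha = 0` boundary) of the log per-cycle growth ratio
  of a rare mutant (frequency `10⁻⁶`) over its resident, computed through
  the full cycle update.  It shares no code with the closed-form gradients
  and is used only as an independent cross-check of their signs and zero
  crossings.
* **Root finding**: Brent's method at `xtol = 10⁻¹⁴` for bifurcation costs
  and `C_Base`.

## Problem sizes used in tests and reproduction script

ESS-recovery runs use 2×10⁵ cycles (the trait cloud equilibrates within
~10⁴ cycles from the standard start; the long tail tightens the time
average).  The four cost-regime portraits are reproduced at 10⁵ cycles with
early termination once the mean fusion rate exceeds 12.5 mutational steps
(`alpha ≥ 0.25`), which operationally classifies escape to obligate fusion;
the basin-covering regime is demonstrated from `m0 = 0.5`, where its
outcome differs from the bistable regime's at the same start.  Facultative
fusion uses ten 4×10⁴-cycle plastic runs.  These sizes were chosen as the
smallest at which the compared quantities are comfortably inside their
tolerances.

## What the generator emulates — and what it does not

The synthetic populations capture: the quality–quantity trade-off of
daughter size, mass-action fusion encounters, multiplicative fusion costs,
mutation-limited trait evolution, and geometric environmental switching.
They deliberately omit: demographic stochasticity (finite-N drift),
recombination between the linked traits, costs of plasticity or sensing,
mating types, fusions of more than two cells, and explicit mature-mass /
division-count dynamics (collapsed into `m`).  Passing tests therefore
demonstrate internal consistency of the model and agreement between its
stochastic and analytic treatments — not that real populations evolve this
way; the model's contact with biology is through its qualitative
predictions (e.g. stress-induced fusion at intermediate costs).

## Known limitations

* The evolutionary-branching behaviour expected at high fusion rates is out
  of scope; flows reaching the obligate-fusion manifold are reported as
  diverging rather than followed further.
* `C_Base` derives from a linearized separatrix; its agreement with the
  fully nonlinear basin boundary is approximate (tested at the 5%-of-beta
  level at the axis intercept) and its large-`ET` convergence is slow.
* The closed-form facultative conditions are large-`ET` limits; the package
  offers finite-`ET` numerical basin checks rather than silently mixing the
  two regimes.
* Threshold-linear analysis is limited to boundary-gradient signs and the
  cost ceiling; its full interior phase portrait is not derived here.
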