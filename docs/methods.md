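# Methods

## Model and assumptions

The population is well mixed and of fixed size N ≥ 3. Strategy update follows
the pairwise-comparison rule: a focal player imitates a randomly chosen model
with probability `(1 + e^{−β Δf})⁻¹`, where Δf is the payoff difference after
the institution has added θ to each cooperator's payoff (reward) or subtracted
θ from each defector's (punishment), with unit incentive efficiency. Mutations
are assumed rare enough that at most two strategies coexist (small-mutation
limit); the long-run cooperation frequency then follows from the two fixation
probabilities alone, and the cost accounting reduces to a single absorbing
birth–death chain over the number of cooperators.

Both supported games — Donation game (`b > c > 0`) and Public Goods game
(`1 < r < n ≤ N`) — have an i-independent cooperator–defector payoff gap δ < 0.
This is load-bearing: it makes the Fermi factors state-independent, the
transient block tridiagonal with constant up/down tilt, and the cooperation
frequency a single logistic in β(N−1)(δ+θ). Games where δ depends on the state
(general Prisoner's Dilemma payoff matrices, collective-risk games) are out of
scope.

Costs are accounted per chain step (one imitation event), with the fundamental
matrix convention that the starting state counts as one visit and self-loops
count separately. This convention is pinned down by the worked-example values
the test suite reproduces (E = 23.602, 25.6124, 26.446 in the N = 3 Donation
game at β = 10), and the Monte-Carlo simulator uses the identical accounting.

## Parameters that matter

| parameter | units | meaning | notes |
|---|---|---|---|
| N | individuals | population size | ≥ 3; optimizer warns above 100 (see limitations) |
| β | 1/payoff | selection intensity | β = 0 allowed only in limit checks; rescaling payoffs rescales β |
| θ | payoff | per-capita incentive | enters dynamics only through δ + θ |
| ω | — | required cooperation frequency | strictly inside (0, 1) |
| b, c, r, n | payoff / — | game parameters | dilemma conditions enforced at construction |

## Numerical choices

**Linear algebra.** Only rows 1 and N−1 of the fundamental matrix are needed;
they are obtained by solving `(I−U)ᵀx = e₁, e_{N−1}`. Two paths exist: a
scalar banded solve (`scipy.linalg.solve_banded`, LAPACK) for single
evaluations, and a Thomas-algorithm elimination vectorized across a whole θ
grid for the optimizer's scans. `I−U` is an M-matrix, for which elimination
without pivoting is stable; both paths are tested against dense inversion to
1e−10.

**Fermi factors and fixation products.** All logistic factors are evaluated in
saturating form (never exponentiating a large positive argument) and the
fixation-probability products are accumulated in the log domain, so selection
intensities of 10³ and beyond stay finite. At β = 1000 the exact cost matches
the piecewise strong-selection limits to well under 1 %.

**Derivatives of E.** `E(θ)` is differentiated by complex-step: the solver
accepts complex θ and `E'(θ) = Im E(θ + ih)/h` with `h = 1e−20` is exact to
machine precision, with no cancellation and no step-size tuning. Central
differences were the obvious alternative; complex-step was chosen because the
monotonicity classification near β\* hinges on the sign of derivative minima
that approach zero, where finite-difference noise (~1e−9 here) is the
binding constraint.

**Monotonicity scan and β\*.** The scan window is θ ∈ (1e−6, −δ + 50/β]
(extended to 2θ₀ under a constraint): stationary points satisfy
θ = log(u)/β − δ with u an O(1) root, so the non-monotone region concentrates
near −δ with width O(1/β). The derivative is sampled on a 2000-point grid and
the few deepest local-minimum basins are refined by bounded scalar
minimization (sampling noise produces many spurious shallow minima; refining
every one is wasted work). E is declared non-decreasing if the refined minimum
derivative exceeds −1e−9. β\* is the bisection boundary of that predicate to
relative tolerance 1e−4, from an automatically expanded bracket; failure to
bracket raises rather than truncating. β\* is invariant under doubling the
grid, and the printed thresholds 5.752 (N = 3) and 3.039 (N = 50) are
recovered to three decimals.

**Stationary points.** θ₂ is the largest sign change of E′ on the grid,
refined by Brent's method to 1e−6; if the grid shows no sign change but the
refined minimum of E′ is negative (a dip narrower than the spacing), brackets
are rebuilt by walking outward from the dip. More than two sign changes
triggers a warning. Ties in the final cost comparison go to θ₀ (the weak
inequality E(θ₀) ≤ E(θ₂) selects θ₀).

**Knife edges.** The strong-selection limit's middle branch is selected by
exact floating comparison with −δ; callers wanting the knife-edge value must
pass θ = −δ literally.

## What the simulator emulates — and what it does not

`mc_oracle` replays exactly the abstraction the analysis lives in: the
embedded birth–death chain with self-loops, a mutant seeded at state 1 or N−1,
costs accrued per step from the starting state until absorption. Agreement (at
3 standard errors, 200 000 replicates) therefore validates the linear algebra
and the accounting conventions — it does **not** test the modelling
assumptions themselves (small-mutation limit, well-mixedness, i-independent
δ, unit incentive efficiency). Conclusions about real populations inherit
those assumptions.

## Problem sizes used in tests

The suite runs desk-scale configurations: N ≤ 50 for exact-value and bound
checks (N = 120 once, to exercise the conjecture warning), population sizes
2000 and 128 000 for the large-N ratio (an O(N) solve each), and 200 000
Monte-Carlo replicates for the stochastic comparisons — about ten seconds in
total. The brute-force optimality checks use 10⁴-point θ grids at N ≤ 20.

## Limitations

- The two-sign-change structure of E′ above β\* is proven only up to a finite
  population bound and verified numerically up to N = 100; for larger N the
  optimizer still runs, scans for *all* sign changes, and attaches a warning.
- The large-N ratio E/[N²θ/2(ln N + γ)] converges only logarithmically: the
  residual decays like 1/ln N and is still ≈ 8 % at N = 5·10⁵. The test suite
  therefore checks convergence by fitting `a + b/ln N` at two population sizes
  and comparing the extrapolated intercept with the closed-form constant
  (agreement ≈ 0.5 %); direct comparison at any reachable N would mislead.
- Smoothness of θ ↦ E(θ) is relied on as continuity plus exact
  differentiation of the solver output; no symbolic stationary-point
  polynomials are constructed, and β\* is defined operationally as the
  monotonicity boundary.
- Arbitrary mutation rates, more than two strategies, structured populations,
  and non-unit incentive efficiency ratios are out of scope.
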