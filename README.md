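# evoincentives

Cost-efficient institutional incentives for cooperation in finite populations.

An external institution (a regulator, a funding body, a platform operator) can
promote cooperation by paying a per-capita incentive θ — rewarding each
cooperator or punishing each defector — in a population playing a cooperation
dilemma. Doing so is expensive, and the natural question is a constrained
minimization: **what is the cheapest θ that still guarantees a desired long-run
frequency of cooperation ω?** `evoincentives` answers this exactly for
well-mixed finite populations evolving under pairwise-comparison (Fermi)
dynamics in the small-mutation limit, for the Donation game (DG, benefit `b`,
cost `c`) and the Public Goods game (PGG, contribution `c`, multiplier `r`,
group size `n`).

## The model

The number of cooperators `i ∈ {0, …, N}` performs an absorbing birth–death
Markov chain: one imitation event moves `i` by at most one, with

    u_{i,i±1} = (N−i)/N · i/N · (1 + e^{∓β(δ+θ)})⁻¹,

where β is the intensity of selection and δ = Π_C(i) − Π_D(i) < 0 is the
(i-independent) payoff disadvantage of cooperators. The fundamental matrix
`(I−U)⁻¹` of the transient block gives expected sojourn counts; with a mutant
appearing equally likely at state 1 or N−1, the expected total cost of the
scheme is

    E_r(θ) = θ/2 · Σ_i (n_{1i} + n_{N−1,i}) · i        (reward)
    E_p(θ) = θ/2 · Σ_i (n_{1i} + n_{N−1,i}) · (N−i)    (punishment)

The long-run cooperation frequency is ρ_{D,C}/(ρ_{D,C}+ρ_{C,D}) =
(1 + e^{−β(N−1)(δ+θ)})⁻¹, so the constraint "frequency ≥ ω" inverts to a
closed-form minimum incentive θ₀(ω) = log(ω/(1−ω))/((N−1)β) − δ.

The key structural fact is a **phase transition in β**: below a threshold β\*
the cost E(θ) is non-decreasing, so θ\* = θ₀; above β\* it develops an interior
local minimum θ₂, and the optimum is whichever of θ₀ and θ₂ is feasible and
cheaper. The package locates β\* by bisection on a monotonicity scan of E and
θ₂ by root-finding on the (complex-step, machine-precision) derivative of E.
Closed-form sandwich bounds and the weak-selection (β→0), strong-selection
(β→∞) and large-N limits are provided as calculators and as test oracles, and
a seeded Monte-Carlo simulator of the chain validates every exact quantity.

## Worked example

The cheapest reward sustaining at least 70 % cooperation in a Donation game
with b = 1.8, c = 1 in a population of N = 3 under strong selection β = 10:

```sh
evoincentives optimize --game dg --b 1.8 --c 1 -N 3 --beta 10 --omega 0.7 --mode reward
```

prints

```
theta* = 2.15977  E(theta*) = 25.6124  [branch: theta2_wins]
```

with the full decision record as JSON: δ = −1.9, the constraint needs at least
θ₀ = 1.94236, the phase transition sits at β\* = 5.7522 < 10, so the interior
local minimum θ₂ = 2.15977 competes with θ₀ — and wins, because
E(θ₀) = 26.446 > 25.6124 = E(θ₂). The institution should over-shoot the
minimum feasible incentive: paying more per cooperator makes full cooperation
fixate faster and lowers the *total* bill. The same call in Python:

```python
from evoincentives import donation_game, EvoParams, optimize

res = optimize(donation_game(b=1.8, c=1.0), EvoParams(N=3, beta=10.0),
               mode="reward", omega=0.7)
res.theta_star      # 2.1597681…
res.cost_at_optimum # 25.612352…
res.branch          # 'theta2_wins'
```

Other entry points: `cost` (E(θ) with the per-state visit profile), `sweep`
(CSV/JSON tables of E_r, E_p, cooperation frequency and bounds along a θ, β,
N or ω axis, optionally plotted), `betastar`, `limits` (all asymptotic
formulas), `compare` (E_r − E_p, which flips sign exactly at θ = −δ) and
`simulate` (the Monte-Carlo validator). Every output embeds the full
parameter set and package version; exit codes are 0/1/2 for
success/validation error/runtime error.

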