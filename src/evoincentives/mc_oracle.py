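"""Seeded Monte-Carlo simulation of the imitation chain, for validation.

Replays the absorbing birth--death chain step by step (self-loops included,
so sojourn counts match the fundamental-matrix convention directly) and
accumulates one cost increment per occupied transient state, including the
starting state.  Means and standard errors over replicates give independent
stochastic estimates of the expected visit counts, the total incentive cost
and the fixation probability, against which the exact linear-algebra results
are checked.  All randomness flows from a single ``numpy`` Generator seeded
explicitly, so every result is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .games import GameSpec
from .markov_cost import EvoParams, IncentiveScheme, _updown

__all__ = ["SimConfig", "SimResult", "simulate", "estimate_fixation"]


@dataclass(frozen=True)
class SimConfig:
    """Replicate count, RNG seed and starting rule for the simulator.

    ``start_rule='half_half'`` places the initial mutant at state 1 or
    ``N - 1`` with probability 1/2 each (the convention behind the averaged
    visit counts); ``'fixed_state'`` always starts at ``start_state``.
    """

    replicates: int
    seed: int
    start_rule: str = "half_half"
    start_state: int = 1

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError(f"replicates must be >= 1, got {self.replicates}")
        if self.start_rule not in ("half_half", "fixed_state"):
            raise ValueError(f"unknown start_rule {self.start_rule!r}")


@dataclass(frozen=True)
class SimResult:
    """Monte-Carlo estimates with standard errors."""

    mean_cost: float
    se_cost: float
    visit_means: np.ndarray
    visit_ses: np.ndarray
    fixation_estimate: float
    fixation_se: float
    replicates: int
    seed: int

    def to_json(self, **kwargs) -> str:
        d = asdict(self)
        d["visit_means"] = list(self.visit_means)
        d["visit_ses"] = list(self.visit_ses)
        return json.dumps(d, **kwargs)


def _run_walks(
    game: GameSpec, params: EvoParams, theta: float, config: SimConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized absorption walks.

    Returns ``(sojourns, fixed)``: per-replicate sojourn counts over the
    transient states 1..N-1 (the starting state counts once) and a boolean
    flag for absorption at the all-cooperator state.
    """
    N, R = params.N, config.replicates
    rng = np.random.default_rng(config.seed)
    up, down = _updown(game, params, theta)  # indexed by state-1

    if config.start_rule == "half_half":
        states = np.where(rng.random(R) < 0.5, 1, N - 1)
    else:
        if not 1 <= config.start_state <= N - 1:
            raise ValueError(f"start_state {config.start_state} outside 1..{N - 1}")
        states = np.full(R, config.start_state)

    sojourns = np.zeros((R, N - 1), dtype=np.int64)
    fixed = np.zeros(R, dtype=bool)
    idx = np.arange(R)
    while idx.size:
        s = states[idx]
        sojourns[idx, s - 1] += 1
        u = rng.random(idx.size)
        go_down = u < down[s - 1]
        go_up = ~go_down & (u < down[s - 1] + up[s - 1])
        states[idx] = s - go_down + go_up
        fixed[idx[states[idx] == N]] = True
        idx = idx[(states[idx] > 0) & (states[idx] < N)]
    return sojourns, fixed


def simulate(
    game: GameSpec, params: EvoParams, scheme: IncentiveScheme, config: SimConfig
) -> SimResult:
    """Estimate expected visit counts and total incentive cost by simulation.

    The cost of one replicate is exactly
    ``theta * sum_i w_i * (sojourns in i)`` with ``w_i = i`` (reward) or
    ``N - i`` (punishment), so per-replicate cost conservation holds by
    construction.
    """
    sojourns, fixed = _run_walks(game, params, scheme.theta, config)
    R, N = config.replicates, params.N
    i = np.arange(1, N)
    w = i if scheme.mode == "reward" else N - i
    costs = scheme.theta * sojourns @ w
    sqrtR = np.sqrt(R)
    p_fix = fixed.mean()
    return SimResult(
        mean_cost=float(costs.mean()),
        se_cost=float(costs.std(ddof=1) / sqrtR) if R > 1 else float("nan"),
        visit_means=sojourns.mean(axis=0),
        visit_ses=sojourns.std(axis=0, ddof=1) / sqrtR if R > 1 else np.full(N - 1, np.nan),
        fixation_estimate=float(p_fix),
        fixation_se=float(np.sqrt(p_fix * (1 - p_fix) / R)),
        replicates=R,
        seed=config.seed,
    )


def estimate_fixation(
    game: GameSpec, params: EvoParams, theta: float, config: SimConfig
) -> tuple[float, float]:
    """Fixation proportion of the invading mutant, with binomial SE.

    Start at state 1 for a single cooperator mutant (``rho_DC``, absorption at
    the all-cooperator state) or at state ``N - 1`` for a single defector
    mutant (``rho_CD``, absorption at the all-defector state); requires
    ``start_rule='fixed_state'``.  Other start states report absorption at
    the all-cooperator state.
    """
    if config.start_rule != "fixed_state":
        raise ValueError("fixation estimation requires start_rule='fixed_state'")
    _, fixed = _run_walks(game, params, theta, config)
    p = float(fixed.mean())
    if config.start_state == params.N - 1 and config.start_state != 1:
        p = 1.0 - p  # the defector mutant fixates iff cooperators do not
    return p, float(np.sqrt(p * (1 - p) / config.replicates))
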