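"""Closed-form bounds and asymptotic limits of the expected incentive cost.

For every finite ``N`` the expected total cost is sandwiched by

    N^2 theta / 2 * (H_N + 1/(N-1))  <=  E(theta)  <=  N(N-1) theta (H_N + 1),

with ``H_N = sum_{j=1}^{N-1} 1/j`` the harmonic number; so ``E`` grows like
``N^2 H_N theta``.  The exact limit constants are available in three regimes:

* large population: ``E(theta) / [N^2 theta/2 (ln N + gamma)]`` converges to a
  game-dependent constant;
* weak selection (``beta -> 0``): ``E -> N^2 theta H_N``, identical for reward
  and punishment;
* strong selection (``beta -> inf``): a piecewise limit with an exact
  three-way branch on ``theta`` vs ``-delta`` — below the neutral-tilt point
  reward is the cheaper scheme, above it punishment is.

These formulas serve both as user-facing calculators and as convergence
oracles for the exact fundamental-matrix computation.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import json
import math

import numpy as np

from .games import GameSpec, delta as game_delta

__all__ = [
    "EULER_GAMMA",
    "LimitReport",
    "harmonic_number",
    "finite_bounds",
    "largeN_normalizer",
    "largeN_ratio_limit",
    "weak_selection_limit",
    "strong_selection_limit",
    "limit_report",
]

# Euler–Mascheroni constant, 16 digits
EULER_GAMMA = 0.5772156649015329


def harmonic_number(N: int) -> float:
    """Partial harmonic sum ``H_N = sum_{j=1}^{N-1} 1/j`` (requires ``N >= 2``)."""
    if not (isinstance(N, int) and N >= 2):
        raise ValueError(f"harmonic number needs an integer N >= 2, got {N}")
    return float(np.sum(1.0 / np.arange(1, N)))


def finite_bounds(N: int, theta: float) -> tuple[float, float]:
    """Finite-population sandwich ``(lower, upper)`` containing ``E(theta)``."""
    if N < 3:
        raise ValueError(f"finite bounds require N >= 3, got {N}")
    if theta < 0:
        raise ValueError(f"theta must be >= 0, got {theta}")
    h = harmonic_number(N)
    lower = N**2 * theta / 2 * (h + 1 / (N - 1))
    upper = N * (N - 1) * theta * (h + 1)
    return (lower, upper)


def largeN_normalizer(N: int, theta: float) -> float:
    """The large-``N`` scale ``N^2 theta / 2 * (ln N + gamma)`` of the cost."""
    return N**2 * theta / 2 * (math.log(N) + EULER_GAMMA)


def largeN_ratio_limit(game: GameSpec, beta: float, theta: float) -> float:
    """Limit of ``E(theta) / largeN_normalizer(N, theta)`` as ``N -> inf``.

    ``1 + e^{-beta |theta - c|}`` for the Donation game; the Public Goods game
    picks up an extra factor ``e^{beta c r / n}`` on the exponential term.
    """
    if beta <= 0:
        raise ValueError(f"the large-N limit requires beta > 0, got {beta}")
    base = math.exp(-beta * abs(theta - game.c))
    if game.kind == "DG":
        return 1.0 + base
    return 1.0 + base * math.exp(beta * game.c * game.r / game.n)


def weak_selection_limit(N: int, theta: float) -> float:
    """``lim_{beta -> 0} E(theta) = N^2 theta H_N`` (same for both schemes)."""
    if N < 3:
        raise ValueError(f"weak-selection limit requires N >= 3, got {N}")
    return N**2 * theta * harmonic_number(N)


def strong_selection_limit(N: int, theta: float, delta: float, mode: str) -> float:
    """``lim_{beta -> inf} E(theta)`` — piecewise in ``theta`` vs ``-delta``.

    Reward:      ``N^2 theta/2 (1/(N-1) + H_N)`` below, ``N^2 theta H_N`` at,
                 ``N^2 theta/2 (1 + H_N)`` above ``-delta``.
    Punishment:  the mirrored branches (cheap side and dear side swap).
    The knife-edge middle branch is selected by exact floating comparison of
    ``theta`` with ``-delta``.
    """
    if N < 3:
        raise ValueError(f"strong-selection limit requires N >= 3, got {N}")
    if mode not in ("reward", "punishment"):
        raise ValueError(f"mode must be 'reward' or 'punishment', got {mode!r}")
    h = harmonic_number(N)
    pivot = -delta
    if theta == pivot:
        return N**2 * theta * h
    low = theta < pivot
    if mode == "reward":
        factor = (1 / (N - 1) + h) if low else (1 + h)
    else:
        factor = (1 + h) if low else (h + 1 / (N - 1))
    return N**2 * theta / 2 * factor


@dataclass(frozen=True)
class LimitReport:
    """All bound/limit quantities for one ``(game, N, beta, theta)`` setting."""

    N: int
    beta: float
    theta: float
    harmonic: float
    lower_bound: float
    upper_bound: float
    largeN_normalizer: float
    largeN_ratio: float
    weak_limit: float
    strong_limit_reward: float
    strong_limit_punishment: float

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), **kwargs)


def limit_report(game: GameSpec, N: int, beta: float, theta: float) -> LimitReport:
    """Evaluate every closed-form bound and limit at the given parameters."""
    d = game_delta(game, N)
    lower, upper = finite_bounds(N, theta)
    return LimitReport(
        N=N,
        beta=beta,
        theta=theta,
        harmonic=harmonic_number(N),
        lower_bound=lower,
        upper_bound=upper,
        largeN_normalizer=largeN_normalizer(N, theta),
        largeN_ratio=largeN_ratio_limit(game, beta, theta),
        weak_limit=weak_selection_limit(N, theta),
        strong_limit_reward=strong_selection_limit(N, theta, d, "reward"),
        strong_limit_punishment=strong_selection_limit(N, theta, d, "punishment"),
    )
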