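"""Expected incentive cost from the absorbing birth--death imitation chain.

The population state is the number of cooperators ``i`` in ``{0, ..., N}``;
``0`` and ``N`` are absorbing (monomorphic) states.  One step of the chain is
one pairwise-comparison (Fermi) imitation event under per-capita incentive
``theta``: the number of cooperators moves by at most one, with

    u_{i,i+1} = (N-i)/N * i/N * logistic(+beta * (delta + theta))
    u_{i,i-1} = (N-i)/N * i/N * logistic(-beta * (delta + theta))

where ``delta`` is the i-independent payoff difference of the game.  Reward
and punishment shift payoffs by the same ``+theta`` for the focal comparison,
so both schemes share one chain; they differ only in what each visit costs
(``theta * i`` for reward, ``theta * (N - i)`` for punishment).

Expected sojourn counts come from the fundamental matrix ``(I - U)^{-1}`` of
the transient block, with the standard convention that the starting state
counts as one visit.  A mutant appears at state 1 or ``N-1`` with equal
probability, so the expected number of visits to state ``i`` is
``v_i = (n_{1,i} + n_{N-1,i}) / 2`` and the expected total institutional cost
is ``E(theta) = theta * sum_i w_i v_i``.

Only the two needed rows of the fundamental matrix are computed, by solving
``(I - U)^T x = e_1`` and ``e_{N-1}`` with a banded (Thomas-style) solver in
O(N); the optimizer evaluates ``E`` thousands of times.  All Fermi factors go
through a saturating logistic so selection intensities up to ``1e3`` and
beyond never overflow.  The solver path also accepts complex ``theta``, which
gives machine-precision derivatives of ``E`` by complex-step differentiation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded
from scipy.special import expit, logsumexp

from .games import GameSpec, delta as game_delta

__all__ = [
    "EvoParams",
    "IncentiveScheme",
    "VisitProfile",
    "CostResult",
    "transition_probs",
    "transition_kernel",
    "expected_visits",
    "expected_cost",
    "cost_value",
    "cost_values",
    "fundamental_matrix_dense",
    "fixation_probabilities",
    "cooperation_frequency",
]


@dataclass(frozen=True)
class EvoParams:
    """Population size ``N`` (>= 3) and selection intensity ``beta`` (>= 0).

    ``beta = 0`` (neutral drift) is accepted here so that weak-selection
    limits can be checked against the exact computation, but the optimizer
    refuses it: under neutral selection incentives cannot steer the dynamics.
    """

    N: int
    beta: float

    def __post_init__(self) -> None:
        if not (isinstance(self.N, int) and self.N >= 3):
            raise ValueError(f"population size must be an integer >= 3, got N={self.N}")
        if self.beta < 0:
            raise ValueError(f"selection intensity must be >= 0, got beta={self.beta}")


@dataclass(frozen=True)
class IncentiveScheme:
    """Incentive mode (``'reward'`` or ``'punishment'``) and per-capita ``theta >= 0``."""

    mode: str
    theta: float

    def __post_init__(self) -> None:
        if self.mode not in ("reward", "punishment"):
            raise ValueError(f"mode must be 'reward' or 'punishment', got {self.mode!r}")
        if self.theta < 0:
            raise ValueError(f"per-capita incentive must be >= 0, got theta={self.theta}")


@dataclass(frozen=True)
class VisitProfile:
    """Expected sojourn counts ``v_i`` over the transient states ``i = 1..N-1``.

    ``visits[k]`` is the expected number of visits to the state with ``k + 1``
    cooperators (0-based storage of the 1-based transient states), averaged
    over a mutant appearing at state 1 or ``N - 1`` with probability 1/2, and
    counting the starting state as one visit.
    """

    visits: np.ndarray

    @property
    def states(self) -> np.ndarray:
        """Cooperator counts 1..N-1 matching ``visits``."""
        return np.arange(1, len(self.visits) + 1)


@dataclass(frozen=True)
class CostResult:
    """Expected total cost ``E(theta)`` and the visit profile behind it."""

    scheme: IncentiveScheme
    expected_cost: float
    profile: VisitProfile


def _logistic(z):
    """Saturating logistic ``1 / (1 + exp(-z))``; complex-safe, never overflows."""
    if np.iscomplexobj(z):
        z = np.asarray(z, dtype=complex)
        out = np.empty_like(z)
        pos = z.real >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
        ez = np.exp(z[~pos])
        out[~pos] = ez / (1.0 + ez)
        return out
    return expit(z)


def transition_probs(
    game: GameSpec, params: EvoParams, theta: float, i: int
) -> tuple[float, float, float]:
    """One-step probabilities ``(down, stay, up)`` at transient state ``i``.

    The incentive enters only through the shifted payoff difference
    ``delta + theta``, identically for reward and punishment.
    """
    if not 1 <= i <= params.N - 1:
        raise ValueError(f"state i={i} outside the transient range 1..{params.N - 1}")
    N = params.N
    x = params.beta * (game_delta(game, N) + theta)
    g = (N - i) * i / N**2
    up = g * _logistic(x)
    down = g * _logistic(-x)
    return (down, 1.0 - up - down, up)


def transition_kernel(game: GameSpec, params: EvoParams, theta: float) -> np.ndarray:
    """Full ``(N+1) x (N+1)`` one-step matrix over states 0..N (absorbing ends).

    Dense construction, intended for inspection and as a test oracle; the
    production cost path never materializes it.
    """
    N = params.N
    P = np.zeros((N + 1, N + 1))
    P[0, 0] = 1.0
    P[N, N] = 1.0
    for i in range(1, N):
        down, stay, up = transition_probs(game, params, theta, i)
        P[i, i - 1] = down
        P[i, i] = stay
        P[i, i + 1] = up
    return P


def _updown(game: GameSpec, params: EvoParams, theta) -> tuple[np.ndarray, np.ndarray]:
    N = params.N
    i = np.arange(1, N)
    g = (N - i) * i / N**2
    x = params.beta * (game_delta(game, N) + theta)
    up = g * _logistic(np.broadcast_to(x, i.shape).copy())
    down = g * _logistic(np.broadcast_to(-x, i.shape).copy())
    return up, down


def _visit_vector(game: GameSpec, params: EvoParams, theta) -> np.ndarray:
    """``v_i = (n_{1,i} + n_{N-1,i}) / 2`` via two banded solves of ``(I-U)^T x = e``."""
    N = params.N
    up, down = _updown(game, params, theta)
    m = N - 1  # transient states
    dtype = complex if np.iscomplexobj(up) else float
    # (I - U)^T in banded storage: diag up+down, super -down[i+1], sub -up[i-1]
    ab = np.zeros((3, m), dtype=dtype)
    ab[1, :] = up + down
    if m > 1:
        ab[0, 1:] = -down[1:]
        ab[2, :-1] = -up[:-1]
    rhs = np.zeros((m, 2), dtype=dtype)
    rhs[0, 0] = 1.0
    rhs[-1, 1] = 1.0
    rows = solve_banded((1, 1), ab, rhs)
    v = 0.5 * (rows[:, 0] + rows[:, 1])
    if not np.iscomplexobj(v):
        assert np.all(np.isfinite(v)) and np.all(v > 0), "invalid sojourn counts"
    return v


def expected_visits(game: GameSpec, params: EvoParams, theta: float) -> VisitProfile:
    """Expected sojourn counts under incentive ``theta`` (reward = punishment chain)."""
    if theta < 0:
        raise ValueError(f"per-capita incentive must be >= 0, got theta={theta}")
    return VisitProfile(visits=_visit_vector(game, params, theta))


def cost_value(game: GameSpec, params: EvoParams, theta, mode: str):
    """Expected total cost ``E(theta)`` as a bare scalar.

    Accepts complex ``theta`` (the imaginary part propagates through the
    banded solve), enabling complex-step differentiation of ``E``.
    """
    if mode not in ("reward", "punishment"):
        raise ValueError(f"mode must be 'reward' or 'punishment', got {mode!r}")
    N = params.N
    v = _visit_vector(game, params, theta)
    i = np.arange(1, N)
    w = i if mode == "reward" else N - i
    return theta * np.sum(w * v)


def cost_values(game: GameSpec, params: EvoParams, thetas, mode: str) -> np.ndarray:
    """``E(theta)`` for a whole grid of incentives in one vectorized pass.

    Solves the batch of tridiagonal systems ``(I - U)^T x = e`` by the Thomas
    algorithm, vectorized across the grid.  ``I - U`` is an M-matrix (positive
    diagonal, non-positive off-diagonals), for which elimination without
    pivoting is stable.  Accepts complex grids for complex-step derivatives.
    The optimizer's monotonicity and stationary-point scans run through here.
    """
    if mode not in ("reward", "punishment"):
        raise ValueError(f"mode must be 'reward' or 'punishment', got {mode!r}")
    thetas = np.atleast_1d(np.asarray(thetas))
    N = params.N
    m = N - 1
    i = np.arange(1, N)
    g = ((N - i) * i / N**2)[:, None]  # (m, 1)
    x = params.beta * (game_delta(game, N) + thetas)  # (B,)
    up = g * _logistic(x)[None, :]  # (m, B) by broadcasting over the grid
    down = g * _logistic(-x)[None, :]

    # (I - U)^T rows: sub -up[i-1], diag up[i]+down[i], super -down[i+1]
    diag = up + down
    sub = -up[:-1]  # enters row i from row i-1
    sup = -down[1:]  # enters row i from row i+1

    dtype = diag.dtype
    B = diag.shape[1]
    rhs = np.zeros((m, 2, B), dtype=dtype)
    rhs[0, 0] = 1.0
    rhs[-1, 1] = 1.0

    # forward elimination
    cp = np.empty((m - 1, B), dtype=dtype)
    dp = np.empty((m, 2, B), dtype=dtype)
    cp[0] = sup[0] / diag[0]
    dp[0] = rhs[0] / diag[0]
    for k in range(1, m):
        denom = diag[k] - sub[k - 1] * cp[k - 1]
        if k < m - 1:
            cp[k] = sup[k] / denom
        dp[k] = (rhs[k] - sub[k - 1] * dp[k - 1]) / denom
    # back substitution
    xsol = np.empty((m, 2, B), dtype=dtype)
    xsol[-1] = dp[-1]
    for k in range(m - 2, -1, -1):
        xsol[k] = dp[k] - cp[k] * xsol[k + 1]

    v = 0.5 * (xsol[:, 0, :] + xsol[:, 1, :])  # (m, B)
    w = (i if mode == "reward" else N - i)[:, None]
    return thetas * np.sum(w * v, axis=0)


def expected_cost(game: GameSpec, params: EvoParams, scheme: IncentiveScheme) -> CostResult:
    """Expected total cost of the incentive scheme, with its visit profile.

    ``E_r(theta) = theta * sum_i i * v_i`` for reward,
    ``E_p(theta) = theta * sum_i (N - i) * v_i`` for punishment.
    """
    profile = expected_visits(game, params, scheme.theta)
    i = profile.states
    w = i if scheme.mode == "reward" else params.N - i
    e = float(scheme.theta * np.sum(w * profile.visits))
    return CostResult(scheme=scheme, expected_cost=e, profile=profile)


def fundamental_matrix_dense(game: GameSpec, params: EvoParams, theta: float) -> np.ndarray:
    """Dense ``(I - U)^{-1}`` over the transient states (test oracle, O(N^3))."""
    N = params.N
    P = transition_kernel(game, params, theta)
    U = P[1:N, 1:N]
    return np.linalg.inv(np.eye(N - 1) - U)


def fixation_probabilities(
    game: GameSpec, params: EvoParams, theta: float
) -> tuple[float, float]:
    """Fixation probabilities ``(rho_DC, rho_CD)`` of a single mutant.

    ``rho_DC`` is the probability a lone cooperator takes over an all-defector
    population; ``rho_CD`` the reverse.  Computed as
    ``(1 + sum_i prod_{k<=i} T-(k)/T+(k))^{-1}`` with the products accumulated
    in the log domain, which stays finite for arbitrarily strong selection.
    At ``beta = 0`` both equal ``1/N`` (neutral drift).
    """
    N = params.N
    x = params.beta * (game_delta(game, N) + theta)

    def rho(a: float) -> float:
        # log of the per-step ratio (1 + e^{-a}) / (1 + e^{a}) = e^{-a}
        log_ratio = np.logaddexp(0.0, -a) - np.logaddexp(0.0, a)
        log_terms = log_ratio * np.arange(1, N)  # cumulative products
        log_sum = logsumexp(np.concatenate(([0.0], log_terms)))
        return float(np.exp(-log_sum))

    return (rho(x), rho(-x))


def cooperation_frequency(game: GameSpec, params: EvoParams, theta: float) -> float:
    """Long-run frequency of cooperation ``rho_DC / (rho_DC + rho_CD)``.

    In the small-mutation limit the population hops between the two
    monomorphic states with rates given by the fixation probabilities; the
    ratio collapses to the closed form
    ``1 / (1 + exp(-beta (N-1) (delta + theta)))``.
    """
    x = params.beta * (params.N - 1) * (game_delta(game, params.N) + theta)
    return float(expit(x))
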