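"""Cooperation dilemmas: the Donation game and the Public Goods game.

Both games share the property that the difference in average payoff between a
cooperator and a defector,

    delta = Pi_C(i) - Pi_D(i),

does not depend on the number of cooperators ``i``.  This i-independence is
what reduces the transient block of the imitation Markov chain to a tridiagonal
matrix with constant Fermi factors, and everything downstream (costs,
fixation probabilities, the optimizer) relies on it.  ``delta`` is strictly
negative for admissible parameters: defection is individually favoured, which
is what makes the game a cooperation dilemma and an incentive necessary.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

__all__ = [
    "GameSpec",
    "donation_game",
    "public_goods_game",
    "payoff_C",
    "payoff_D",
    "delta",
    "payoff_C_sum",
    "payoff_D_sum",
]


@dataclass(frozen=True)
class GameSpec:
    """A cooperation dilemma and its payoff parameters.

    Parameters
    ----------
    kind :
        ``"DG"`` (Donation game: a cooperator pays ``c`` to give ``b`` to the
        partner) or ``"PGG"`` (Public Goods game: contributions ``c`` in
        groups of ``n`` are multiplied by ``r`` and shared).
    c :
        Cost of cooperation (payoff units), ``c > 0``.
    b :
        Benefit of cooperation, DG only; the dilemma requires ``b > c``.
    r :
        Multiplication factor of the common pool, PGG only; the dilemma
        requires ``1 < r < n``.
    n :
        Group size, PGG only, integer ``>= 2``.
    """

    kind: str
    c: float
    b: float | None = None
    r: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("DG", "PGG"):
            raise ValueError(f"unknown game kind {self.kind!r}; expected 'DG' or 'PGG'")
        if not self.c > 0:
            raise ValueError(f"cost of cooperation must be positive, got c={self.c}")
        if self.kind == "DG":
            if self.b is None:
                raise ValueError("DG requires a benefit b")
            if not self.b > self.c:
                raise ValueError(f"DG requires b > c, got b={self.b}, c={self.c}")
        else:
            if self.r is None or self.n is None:
                raise ValueError("PGG requires multiplier r and group size n")
            if not (isinstance(self.n, int) and self.n >= 2):
                raise ValueError(f"PGG group size must be an integer >= 2, got n={self.n}")
            if not 1 < self.r < self.n:
                raise ValueError(f"PGG requires 1 < r < n, got r={self.r}, n={self.n}")

    def validate_population(self, N: int) -> None:
        """Check that the game can be played in a population of size ``N``."""
        if not (isinstance(N, int) and N >= 2):
            raise ValueError(f"population size must be an integer >= 2, got N={N}")
        if self.kind == "PGG" and self.n > N:
            raise ValueError(f"PGG group size n={self.n} exceeds population size N={N}")


def donation_game(b: float, c: float) -> GameSpec:
    """Donation game with benefit ``b`` and cost ``c`` (``b > c > 0``)."""
    return GameSpec(kind="DG", c=c, b=b)


def public_goods_game(c: float, r: float, n: int) -> GameSpec:
    """Public Goods game with contribution ``c``, multiplier ``r``, group size ``n``."""
    return GameSpec(kind="PGG", c=c, r=r, n=n)


def _check_state(game: GameSpec, N: int, i: int) -> None:
    game.validate_population(N)
    if not 1 <= i <= N - 1:
        raise ValueError(f"cooperator count i={i} outside the mixed range 1..{N - 1}")


def payoff_C(game: GameSpec, N: int, i: int) -> float:
    """Average payoff of a cooperator when ``i`` of the ``N`` players cooperate.

    DG: ``((i-1)(b-c) + (N-i)(-c)) / (N-1)``.
    PGG: closed form ``(rc/n)(1 + (i-1)(n-1)/(N-1)) - c`` of the
    hypergeometric group-sampling average (see :func:`payoff_C_sum`).
    """
    _check_state(game, N, i)
    if game.kind == "DG":
        return ((i - 1) * (game.b - game.c) + (N - i) * (-game.c)) / (N - 1)
    return game.r * game.c / game.n * (1 + (i - 1) * (game.n - 1) / (N - 1)) - game.c


def payoff_D(game: GameSpec, N: int, i: int) -> float:
    """Average payoff of a defector when ``i`` of the ``N`` players cooperate.

    DG: ``i b / (N-1)``.  PGG: ``rc(n-1) i / (n(N-1))``.
    """
    _check_state(game, N, i)
    if game.kind == "DG":
        return i * game.b / (N - 1)
    return game.r * game.c * (game.n - 1) * i / (game.n * (N - 1))


def delta(game: GameSpec, N: int) -> float:
    """The i-independent payoff difference ``Pi_C(i) - Pi_D(i)`` (always < 0).

    DG: ``-(c + b/(N-1))``.  PGG: ``-c (1 - r(N-n)/(n(N-1)))``.
    """
    game.validate_population(N)
    if game.kind == "DG":
        d = -(game.c + game.b / (N - 1))
    else:
        d = -game.c * (1 - game.r * (N - game.n) / (game.n * (N - 1)))
    # a cooperation dilemma has delta < 0 for all admissible parameters
    assert d < 0, f"delta={d} is not negative; parameters violate the dilemma condition"
    return d


# -- explicit hypergeometric sums: the test oracle for the PGG closed forms --

def payoff_C_sum(game: GameSpec, N: int, i: int) -> float:
    """PGG cooperator payoff by explicit summation over group compositions.

    Averages the payoff ``(j+1) r c / n - c`` of a cooperator whose group
    contains ``j`` other cooperators, over the hypergeometric distribution of
    sampling ``n - 1`` co-players from the remaining ``N - 1`` individuals.
    Binomial coefficients with out-of-range arguments are zero, so the sum is
    well defined even when ``i < n``.  Production code uses the linear closed
    form in :func:`payoff_C`; this sum exists to cross-validate it.
    """
    if game.kind != "PGG":
        raise ValueError("explicit group-sampling sums are defined for the PGG only")
    _check_state(game, N, i)
    n, r, c = game.n, game.r, game.c
    denom = comb(N - 1, n - 1)
    total = 0.0
    for j in range(n):
        w = comb(i - 1, j) * comb(N - i, n - 1 - j)
        total += w * ((j + 1) * r * c / n - c)
    return total / denom


def payoff_D_sum(game: GameSpec, N: int, i: int) -> float:
    """PGG defector payoff by explicit summation (oracle for :func:`payoff_D`)."""
    if game.kind != "PGG":
        raise ValueError("explicit group-sampling sums are defined for the PGG only")
    _check_state(game, N, i)
    n, r, c = game.n, game.r, game.c
    denom = comb(N - 1, n - 1)
    total = 0.0
    for j in range(n):
        w = comb(i, j) * comb(N - 1 - i, n - 1 - j)
        total += w * (j * r * c / n)
    return total / denom
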