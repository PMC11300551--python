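"""Cooperation dilemmas: the Donation Game and the Public Goods Game.

Both games share the structural property that makes the downstream analysis
tractable: the gap between the average payoff of a cooperator and that of a
defector,

    delta = Pi_C(j) - Pi_D(j),

does not depend on the number of cooperators ``j`` and is strictly negative
(defection dominates).  Games without this property (snowdrift, general
prisoner's dilemma, collective-risk games) are deliberately out of scope.

Payoffs are population averages in a well-mixed population of ``N`` players:
for the Donation Game every player is matched against each of the other
``N - 1`` players; for the Public Goods Game groups of size ``n`` are drawn
by multivariate hypergeometric sampling from the population.
"""

from __future__ import annotations

import enum
import json
from dataclasses import asdict, dataclass
from math import comb


class Variant(str, enum.Enum):
    """Which cooperation dilemma a :class:`GameSpec` describes."""

    DG = "dg"
    PGG = "pgg"


class InvalidGameError(ValueError):
    """Raised when a game parameterisation violates the model assumptions."""


@dataclass(frozen=True)
class GameSpec:
    """A cooperation dilemma and its parameters.

    Parameters
    ----------
    variant:
        ``Variant.DG`` (Donation Game) or ``Variant.PGG`` (Public Goods Game).
    N:
        Population size, ``N >= 2``.
    B:
        Donation Game benefit (payoff units); requires ``B > c``.
    c:
        Cost of cooperation (payoff units), used by both games; ``c > 0``.
    r:
        Public-goods multiplication factor, ``1 < r < n``.
    n:
        Public-goods group size, ``2 <= n <= N``.
    force:
        Skip the ``delta < 0`` validation (exploration escape hatch).  All
        analytic results downstream assume ``delta < 0``.
    """

    variant: Variant
    N: int
    B: float | None = None
    c: float | None = None
    r: float | None = None
    n: int | None = None
    force: bool = False

    def __post_init__(self) -> None:
        if self.N < 2:
            raise InvalidGameError(f"population size N={self.N} must be >= 2")
        if self.variant is Variant.DG:
            if self.B is None or self.c is None:
                raise InvalidGameError("DG requires benefit B and cost c")
            if not (self.B > self.c > 0):
                raise InvalidGameError(
                    f"DG requires B > c > 0, got B={self.B}, c={self.c}"
                )
        elif self.variant is Variant.PGG:
            if self.c is None or self.r is None or self.n is None:
                raise InvalidGameError("PGG requires c, r and group size n")
            if self.c <= 0:
                raise InvalidGameError(f"PGG cost c={self.c} must be positive")
            if not (2 <= self.n <= self.N):
                raise InvalidGameError(
                    f"PGG group size n={self.n} must satisfy 2 <= n <= N={self.N}"
                )
            if self.r <= 1:
                raise InvalidGameError(f"PGG multiplier r={self.r} must exceed 1")
            if self.r >= self.n and not self.force:
                raise InvalidGameError(
                    f"PGG multiplier r={self.r} must satisfy r < n={self.n} for "
                    "a social dilemma; pass force=True to explore anyway"
                )
        else:  # pragma: no cover - enum is exhaustive
            raise InvalidGameError(f"unknown variant {self.variant!r}")
        if not self.force and self.delta() >= 0:
            raise InvalidGameError(
                f"payoff gap delta={self.delta()} >= 0 is outside the model's "
                "scope (cooperation must be dominated); pass force=True to "
                "explore anyway"
            )

    # -- payoffs ------------------------------------------------------------

    def payoffs(self, j: int) -> tuple[float, float]:
        """Average payoffs ``(Pi_C, Pi_D)`` in a state with ``j`` cooperators."""
        if self.variant is Variant.DG:
            return dg_payoffs(self, j)
        return pgg_payoffs(self, j)

    def delta(self) -> float:
        """The j-independent payoff gap ``Pi_C - Pi_D`` (negative)."""
        return payoff_difference(self)

    # -- (de)serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["variant"] = self.variant.value
        return {k: v for k, v in d.items() if v is not None}

    @classmethod
    def from_dict(cls, d: dict) -> "GameSpec":
        d = dict(d)
        d["variant"] = Variant(d["variant"])
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "GameSpec":
        return cls.from_dict(json.loads(s))


def donation_game(N: int, B: float = 2.0, c: float = 1.0, **kw) -> GameSpec:
    """Convenience constructor for the Donation Game."""
    return GameSpec(Variant.DG, N=N, B=B, c=c, **kw)


def public_goods_game(N: int, c: float = 1.0, r: float = 2.0, n: int = 4, **kw) -> GameSpec:
    """Convenience constructor for the Public Goods Game."""
    return GameSpec(Variant.PGG, N=N, c=c, r=r, n=n, **kw)


def dg_payoffs(game: GameSpec, j: int) -> tuple[float, float]:
    """Donation Game average payoffs ``(Pi_C(j), Pi_D(j))``.

    ``Pi_C`` averages the focal cooperator's pairwise payoffs against the
    other ``j - 1`` cooperators (each worth ``B - c``) and ``N - j`` defectors
    (each worth ``-c``); ``Pi_D`` averages ``B`` against ``j`` cooperators and
    ``0`` against the other defectors.  ``Pi_C`` requires ``1 <= j <= N - 1``
    (a cooperator must exist and the state must be transient); ``Pi_D``
    requires ``0 <= j <= N - 1``.
    """
    if game.variant is not Variant.DG:
        raise InvalidGameError("dg_payoffs requires a Donation Game spec")
    N, B, c = game.N, game.B, game.c
    if not 0 <= j <= N - 1:
        raise InvalidGameError(f"cooperator count j={j} out of range [0, {N - 1}]")
    pi_d = j * B / (N - 1)
    if j < 1:
        raise InvalidGameError("Pi_C is undefined with no cooperator (j >= 1)")
    pi_c = ((j - 1) * (B - c) + (N - j) * (-c)) / (N - 1)
    return pi_c, pi_d


def pgg_payoffs(game: GameSpec, j: int) -> tuple[float, float]:
    """Public Goods Game average payoffs ``(Pi_C(j), Pi_D(j))``.

    The focal player's group of size ``n`` contains a hypergeometric number
    of co-players of each strategy drawn from the remaining ``N - 1``
    individuals; the closed forms below are the exact expectations of the
    per-group payoff ``(contributions * r / n) - (c if cooperating)``.
    """
    if game.variant is not Variant.PGG:
        raise InvalidGameError("pgg_payoffs requires a Public Goods Game spec")
    N, c, r, n = game.N, game.c, game.r, game.n
    if not 1 <= j <= N - 1:
        raise InvalidGameError(f"cooperator count j={j} out of range [1, {N - 1}]")
    pi_c = (r * c / n) * (1 + (j - 1) * (n - 1) / (N - 1)) - c
    pi_d = (r * c * (n - 1)) / (n * (N - 1)) * j
    return pi_c, pi_d


def pgg_payoffs_hypergeometric(game: GameSpec, j: int) -> tuple[float, float]:
    """PGG payoffs by explicit hypergeometric summation (brute-force oracle).

    Sums the group-composition distribution directly instead of using the
    closed forms; binomial coefficients follow the sampling convention
    ``C(m, k) = 0`` for ``k > m`` or ``m < 0``.
    """
    N, c, r, n = game.N, game.c, game.r, game.n
    denom = comb(N - 1, n - 1)
    pi_c = 0.0
    pi_d = 0.0
    for i in range(n):  # i co-players of the focal's opposite-relevant type
        w_c = comb(j - 1, i) * comb(N - j, n - 1 - i) / denom if j >= 1 else 0.0
        w_d = comb(j, i) * comb(N - 1 - j, n - 1 - i) / denom
        pi_c += w_c * ((i + 1) * r * c / n - c)
        pi_d += w_d * (i * r * c / n)
    return pi_c, pi_d


@dataclass(frozen=True)
class ConstantGapGame:
    """A game specified only through its constant payoff gap.

    Everything downstream of the payoff functions depends on the game only
    through ``N`` and ``delta``; supplying the gap directly (as figure-style
    parameterisations do) sidesteps the payoff bookkeeping.
    """

    N: int
    gap: float
    force: bool = False

    def __post_init__(self) -> None:
        if self.N < 2:
            raise InvalidGameError(f"population size N={self.N} must be >= 2")
        if not self.force and self.gap >= 0:
            raise InvalidGameError(
                f"payoff gap delta={self.gap} >= 0 is outside the model's "
                "scope; pass force=True to explore anyway"
            )

    def delta(self) -> float:
        return self.gap


def payoff_difference(game: GameSpec) -> float:
    """The constant payoff gap ``delta = Pi_C(j) - Pi_D(j)``.

    DG: ``-(c + B/(N-1))``.  PGG: ``-c (1 - r(N-n)/(n(N-1)))``.  Negative for
    every validated parameterisation.
    """
    N = game.N
    if game.variant is Variant.DG:
        return -(game.c + game.B / (N - 1))
    return -game.c * (1 - game.r * (N - game.n) / (game.n * (N - 1)))
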