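"""Fixation probabilities, cooperation frequency, and cost minimisation.

In the small-mutation limit the population hops between the two homogeneous
states through rare fixation events, so the long-run fraction of time spent
all-cooperating is ``rho_DC / (rho_DC + rho_CD)``, where ``rho_DC`` is the
probability a single cooperator mutant takes over an all-defector population
(and conversely for ``rho_CD``).  Because the payoff gap is state-independent
the fixation ratio telescopes to ``exp(beta [(N-1) delta + t theta])``, which
inverts into the minimal per-capita incentive ``theta_0(omega)`` guaranteeing
a target cooperation frequency ``omega``; the constrained cost minimisation
``min_{theta >= theta_0} E(theta)`` then collapses to ``theta_0`` for t = 1
(proven monotone) and is solved by a deterministic grid-plus-refinement
search otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from . import chain as _chain
from . import closed_form as _cf
from .chain import ChainError, EvolutionParams, IncentiveScheme, Start
from .games import GameSpec


@dataclass(frozen=True)
class FixationPair:
    """Fixation probability of a lone cooperator (rho_DC) / defector (rho_CD)."""

    rho_DC: float
    rho_CD: float
    log_rho_DC: float
    log_rho_CD: float

    @property
    def ratio(self) -> float:
        return math.exp(self.log_rho_DC - self.log_rho_CD)


@dataclass(frozen=True)
class ThresholdResult:
    """Minimal per-capita incentive theta0 achieving cooperation level omega."""

    omega: float
    theta0: float


@dataclass(frozen=True)
class OptimiseResult:
    theta_star: float
    E_star: float
    theta0: float
    method: str


def _softplus(x: float) -> float:
    # log(1 + e^x), overflow-safe
    if x > 30.0:
        return x + math.log1p(math.exp(-x))
    return math.log1p(math.exp(x))


def _gaps(game: GameSpec, scheme: IncentiveScheme, gap_convention: str) -> np.ndarray:
    N = game.N
    delta = game.delta()
    return np.array(
        [delta + _chain._gap_shift(scheme, k, N, gap_convention) for k in range(1, N)]
    )


def fixation_probabilities(
    game: GameSpec,
    scheme: IncentiveScheme,
    params: EvolutionParams,
    *,
    gap_convention: str = "cost",
) -> FixationPair:
    """Fixation probabilities of single mutants under the incentivised chain.

    Computed from the product form
    ``rho = (1 + sum_i prod_{k<=i} u_{k,k-1}/u_{k,k+1})**-1`` entirely in log
    space; each one-step ratio is evaluated through the two Fermi logistic
    terms rather than the telescoped exponent, so this route is an
    independent check of the closed identity
    ``rho_DC/rho_CD = exp(beta [(N-1) delta + t theta])``.
    """
    scheme.validate_for(params.N)
    if params.mu != 0.0:
        raise ChainError("fixation probabilities assume the small-mutation limit")
    beta = params.beta
    gaps = _gaps(game, scheme, gap_convention)
    # log of u_{k,k-1}/u_{k,k+1} = log[(1+e^{beta g})^-1 / (1+e^{-beta g})^-1]
    log_q = np.array([_softplus(-beta * g) - _softplus(beta * g) for g in gaps])
    S = np.cumsum(log_q)  # ascending-direction products, states 1..N-1
    log_rho_DC = -logsumexp(np.concatenate(([0.0], S)))
    T = np.cumsum(-log_q[::-1])  # descending products from state N-1
    log_rho_CD = -logsumexp(np.concatenate(([0.0], T)))
    return FixationPair(
        rho_DC=math.exp(log_rho_DC),
        rho_CD=math.exp(log_rho_CD),
        log_rho_DC=log_rho_DC,
        log_rho_CD=log_rho_CD,
    )


def fixation_ratio_exponent(
    game: GameSpec, scheme: IncentiveScheme, params: EvolutionParams,
    *, gap_convention: str = "cost",
) -> float:
    """The closed-form exponent: ``log(rho_DC/rho_CD) = beta sum_k gap_k``.

    Equals ``beta [(N-1) delta + t theta]`` for reward with unit efficiency.
    """
    return params.beta * float(np.sum(_gaps(game, scheme, gap_convention)))


def cooperation_frequency(
    game: GameSpec,
    scheme: IncentiveScheme,
    params: EvolutionParams,
    *,
    gap_convention: str = "cost",
) -> float:
    """Long-run fraction of time spent all-cooperating, rho_DC/(rho_DC+rho_CD)."""
    fp = fixation_probabilities(game, scheme, params, gap_convention=gap_convention)
    # 1 / (1 + rho_CD/rho_DC), stable through the log ratio
    return float(_chain.fermi_probability(1.0, fp.log_rho_DC - fp.log_rho_CD))


def theta_min(omega: float, beta: float, N: int, delta: float, t: int) -> ThresholdResult:
    """Minimal per-capita incentive guaranteeing cooperation frequency omega.

    ``theta_0 = (1/t) (log(omega/(1-omega))/beta - (N-1) delta)``.  May be
    negative for small omega (no incentive needed); callers clamp at zero.
    """
    if not 0 < omega < 1:
        raise ChainError(f"target cooperation fraction omega={omega} must lie in (0,1)")
    if beta <= 0:
        raise ChainError("theta_min requires beta > 0")
    if t < 1:
        raise ChainError("threshold t must be >= 1")
    theta0 = (math.log(omega / (1 - omega)) / beta - (N - 1) * delta) / t
    return ThresholdResult(omega=omega, theta0=theta0)


def optimise_cost(
    game: GameSpec,
    scheme_family: IncentiveScheme,
    params: EvolutionParams,
    omega: float,
    *,
    theta_max: float | None = None,
    grid_points: int = 2001,
) -> OptimiseResult:
    """Minimise the expected cost subject to cooperation frequency >= omega.

    ``scheme_family`` fixes the incentive kind, efficiency ratios and
    threshold; its ``theta`` is ignored.  For t = 1 with the equal or
    all-defector start the cost is proven monotone in theta, so the minimiser
    is ``theta* = max(theta_0, 0)``.  Otherwise a deterministic dense grid on
    ``[max(theta_0, 0), theta_max]`` with bounded local refinement is used
    (monotonicity is only conjectured below the critical threshold).
    """
    N, delta = params.N, game.delta()
    t = scheme_family.t
    theta0 = theta_min(omega, params.beta, N, delta, t).theta0
    lo = max(theta0, 0.0)

    def E(theta: float) -> float:
        scheme = IncentiveScheme(
            scheme_family.kind, theta, t, scheme_family.a, scheme_family.b
        )
        return _chain.expected_cost(game, scheme, params)

    if t == 1 and params.start in (Start.EQUAL, Start.ALLDEF):
        return OptimiseResult(theta_star=lo, E_star=E(lo), theta0=theta0, method="analytic")

    if theta_max is None:
        theta_max = lo + 10.0 * abs(delta) * (N - 1) / t
    if theta_max < lo:
        raise ChainError(
            f"infeasible: theta_max={theta_max} < theta_0={theta0}; no theta "
            "meets the cooperation target within the allowed budget"
        )
    grid = np.linspace(lo, theta_max, grid_points)
    vals = np.array([E(th) for th in grid])
    k = int(np.argmin(vals))
    a = grid[max(k - 1, 0)]
    b = grid[min(k + 1, grid_points - 1)]
    if a < b:
        res = minimize_scalar(E, bounds=(a, b), method="bounded",
                              options={"xatol": 1e-10})
        if res.fun <= vals[k]:
            return OptimiseResult(float(res.x), float(res.fun), theta0, "grid+refine")
    return OptimiseResult(float(grid[k]), float(vals[k]), theta0, "grid+refine")
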