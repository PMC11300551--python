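"""Birth-death chain of the incentivised Fermi imitation process.

The population state is the number of cooperators ``i in {0, ..., N}``.  Each
generation, a random pair (imitator, role model) is sampled; the imitator
copies the role model's strategy with the Fermi probability
``(1 + exp(-beta * (f_model - f_imitator)))**-1``.  The institution pays a
per-generation incentive ``theta_j`` (reward / punishment / mixed) whenever
the cooperator count ``j`` is positive but does not exceed the threshold
``t``; the incentive shifts the cooperator-defector payoff gap inside the
Fermi exponent by ``theta_j / j``.

Without mutation the chain is absorbing at ``S_0`` and ``S_N``; the expected
total institutional cost is a weighted sum of the fundamental matrix
``(I - U)**-1`` over transient states.  With mutation no state is absorbing
and the cost is accumulated until the first visit to a homogeneous state.

All matrices are dense: the population sizes of interest are small and the
tridiagonal structure is exploited through banded solves, not sparsity.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import mpmath as mp
import numpy as np
from scipy.linalg import solve_banded

from .games import GameSpec


class ChainError(ValueError):
    """Raised for chain configurations with no defined answer."""


class Kind(str, enum.Enum):
    """Incentive scheme family."""

    REWARD = "reward"
    PUNISHMENT = "punishment"
    MIXED = "mixed"


class Start(str, enum.Enum):
    """Start-state convention for the small-mutation cost.

    ``EQUAL``   : mutants appear equally likely at S_0 and S_N (average of the
                  rows i=1 and i=N-1 of the fundamental matrix).
    ALLDEF      : dynamics starts at S_0 (row i=1).
    WEIGHTED    : rows weighted by the long-run fixation frequencies
                  f_D = 1/(r+1), f_C = r/(r+1) with r = exp(beta (N-1)(delta+theta)).
    """

    EQUAL = "equal"
    ALLDEF = "alldef"
    WEIGHTED = "weighted"


@dataclass(frozen=True)
class IncentiveScheme:
    """Incentive kind, per-capita amount and efficiency ratios.

    ``theta`` is the per-capita payoff effect; providing it costs the
    institution ``theta/a`` per rewarded cooperator and ``theta/b`` per
    punished defector.  Incentives are paid only in states with
    ``1 <= j <= t`` cooperators.
    """

    kind: Kind
    theta: float
    t: int
    a: float = 1.0
    b: float = 1.0

    def __post_init__(self) -> None:
        if self.theta < 0:
            raise ChainError(f"per-capita incentive theta={self.theta} must be >= 0")
        if self.a <= 0 or self.b <= 0:
            raise ChainError("efficiency ratios a, b must be positive")
        if self.t < 1:
            raise ChainError(f"threshold t={self.t} must be >= 1")

    def validate_for(self, N: int) -> None:
        if not 1 <= self.t <= N - 1:
            raise ChainError(f"threshold t={self.t} must satisfy 1 <= t <= N-1={N - 1}")


@dataclass(frozen=True)
class EvolutionParams:
    """Population size, selection intensity, mutation rate, start convention."""

    N: int
    beta: float
    mu: float = 0.0
    start: Start = Start.EQUAL

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ChainError(f"population size N={self.N} must be >= 2")
        if self.beta < 0:
            raise ChainError(f"selection intensity beta={self.beta} must be >= 0")
        if not 0 <= self.mu <= 1:
            raise ChainError(f"mutation rate mu={self.mu} must lie in [0, 1]")


def fermi_probability(beta: float, payoff_gap: float) -> float:
    """Imitation probability ``(1 + exp(-beta * payoff_gap))**-1``.

    Evaluated piecewise so that ``|beta * payoff_gap|`` up to 1e4 neither
    overflows nor returns NaN (it saturates to 0 or 1).
    """
    x = beta * payoff_gap
    if x >= 0:
        return 1.0 / (1.0 + np.exp(-x))
    ex = np.exp(x)
    return ex / (1.0 + ex)


def per_generation_cost(scheme: IncentiveScheme, j: int, N: int) -> float:
    """Institutional cost ``theta_j`` paid in a state with ``j`` cooperators.

    Reward ``j theta / a``, punishment ``(N - j) theta / b``, mixed
    ``min(j/a, (N-j)/b) theta`` — each gated to zero outside ``1 <= j <= t``
    (in particular the homogeneous states j=0 and j=N cost nothing, since
    ``t <= N - 1``).
    """
    if not 0 <= j <= N:
        raise ChainError(f"cooperator count j={j} out of range [0, {N}]")
    if j == 0 or j > scheme.t:
        return 0.0
    if scheme.kind is Kind.REWARD:
        return j * scheme.theta / scheme.a
    if scheme.kind is Kind.PUNISHMENT:
        return (N - j) * scheme.theta / scheme.b
    return min(j / scheme.a, (N - j) / scheme.b) * scheme.theta


def _gap_shift(scheme: IncentiveScheme, j: int, N: int, convention: str) -> float:
    """Incentive-induced shift of the Fermi payoff gap in state ``j``.

    ``"cost"`` (default): ``theta_j / j`` — the institution's per-cooperator
    outlay added to the cooperator payoff, for all three schemes.
    ``"effect"``: the per-capita payoff effect ``theta`` (reward raises each
    cooperator's payoff by theta; punishment lowers each defector's by theta;
    either way the gap shifts by +theta while the state is incentivised).
    The two coincide for reward with a = 1.
    """
    if j == 0 or j > scheme.t:
        return 0.0
    if convention == "cost":
        return per_generation_cost(scheme, j, N) / j
    if convention == "effect":
        return scheme.theta
    raise ChainError(f"unknown gap convention {convention!r}")


def transition_matrix(
    game: GameSpec,
    scheme: IncentiveScheme,
    params: EvolutionParams,
    *,
    gap_convention: str = "cost",
) -> np.ndarray:
    """Row-stochastic tridiagonal transition matrix over states ``S_0..S_N``.

    For ``mu = 0`` the hop probabilities are
    ``u_{i,i+-1} = (N-i)/N * i/N * (1 + exp(-+ beta*(delta + shift_i)))**-1``
    (absorbing at 0 and N); for ``mu > 0`` the imitation term is mixed with
    mutation, ``u_{i,i+1} = (N-i)/N * (mu + (1-mu) * i/N * fermi)`` and
    symmetrically for ``u_{i,i-1}``.
    """
    scheme.validate_for(params.N)
    if game.N != params.N:
        raise ChainError(f"game.N={game.N} != params.N={params.N}")
    N, beta, mu = params.N, params.beta, params.mu
    delta = game.delta()
    U = np.zeros((N + 1, N + 1))
    for i in range(1, N):
        gap = delta + _gap_shift(scheme, i, N, gap_convention)
        p_up = fermi_probability(beta, gap)
        p_dn = fermi_probability(beta, -gap)
        if mu == 0.0:
            U[i, i + 1] = (N - i) * i / N**2 * p_up
            U[i, i - 1] = (N - i) * i / N**2 * p_dn
        else:
            U[i, i + 1] = (N - i) / N * (mu + (1 - mu) * i / N * p_up)
            U[i, i - 1] = i / N * (mu + (1 - mu) * (N - i) / N * p_dn)
        U[i, i] = max(1.0 - U[i, i + 1] - U[i, i - 1], 0.0)  # clamp -eps dust
    if mu == 0.0:
        U[0, 0] = 1.0
        U[N, N] = 1.0
    else:
        U[0, 1] = mu
        U[0, 0] = 1.0 - mu
        U[N, N - 1] = mu
        U[N, N] = 1.0 - mu
    return U


def transient_block(U: np.ndarray) -> np.ndarray:
    """Restriction of ``U`` to the transient states ``S_1..S_{N-1}``."""
    return U[1:-1, 1:-1]


def _needs_precision(game: GameSpec, scheme: IncentiveScheme, params: EvolutionParams) -> bool:
    # 1 - a*d style denominators cancel in double precision once the Fermi
    # exponents grow; for t=2 two such denominators compound, so the switch
    # keys on the sum of the incentivised and free exponents.
    delta = game.delta()
    return params.beta * (abs(delta) + abs(delta + scheme.theta)) > 10.0


def _visit_matrix_mp(
    game: GameSpec,
    scheme: IncentiveScheme,
    params: EvolutionParams,
    gap_convention: str,
    dps: int,
) -> "mp.matrix":
    """Fundamental matrix of the mu=0 chain in mpmath arithmetic."""
    N, beta = params.N, mp.mpf(params.beta)
    delta = mp.mpf(game.delta())
    n = N - 1
    with mp.workdps(dps):
        V = mp.zeros(n, n)
        for i in range(1, N):
            gap = delta + mp.mpf(_gap_shift(scheme, i, N, gap_convention))
            w = mp.mpf((N - i) * i) / N**2
            p_up = 1 / (1 + mp.e**(-beta * gap))
            p_dn = 1 / (1 + mp.e**(beta * gap))
            V[i - 1, i - 1] = w  # p_up + p_dn = 1 exactly
            if i + 1 <= N - 1:
                V[i - 1, i] = -w * p_up
            if i - 1 >= 1:
                V[i - 1, i - 2] = -w * p_dn
        return mp.inverse(V) if n > 1 else mp.matrix([[1 / V[0, 0]]])


def fundamental_matrix(U_transient: np.ndarray) -> np.ndarray:
    """Expected sojourn counts ``n = (I - U)**-1`` of an absorbing chain.

    ``U_transient`` is the transient restriction (states ``S_1..S_{N-1}``);
    the result's entry ``[i-1, j-1]`` is the expected number of generations
    spent in ``S_j`` starting from ``S_i`` before absorption.  Solved as a
    banded (tridiagonal) linear system, never by explicit inversion.
    """
    n = U_transient.shape[0]
    V = np.eye(n) - U_transient
    ab = np.zeros((3, n))
    ab[0, 1:] = np.diagonal(V, 1)
    ab[1, :] = np.diagonal(V)
    ab[2, :-1] = np.diagonal(V, -1)
    try:
        with np.errstate(divide="ignore", invalid="ignore"):  # caught below
            sol = solve_banded((1, 1), ab, np.eye(n))
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise ChainError(f"transient system is singular: {exc}") from exc
    if not np.all(np.isfinite(sol)):
        raise ChainError(
            "transient system is singular or near-singular — is the chain "
            "actually absorbing (mu = 0 with absorbing homogeneous states)?"
        )
    return sol


def expected_cost(
    game: GameSpec,
    scheme: IncentiveScheme,
    params: EvolutionParams,
    *,
    gap_convention: str = "cost",
    precise: bool | None = None,
    dps: int | None = None,
) -> float:
    """Expected total incentive cost ``E(theta)`` in the small-mutation limit.

    Start conventions (``params.start``):

    * ``EQUAL``    : ``E = 1/2 sum_j (n_{1j} + n_{N-1,j}) theta_j``
    * ``ALLDEF``   : ``E = sum_j n_{1j} theta_j``
    * ``WEIGHTED`` : ``E = sum_j (f_D n_{1j} + f_C n_{N-1,j}) theta_j`` with
      ``f_D = 1/(r+1)``, ``r = exp(beta (N-1)(delta + theta))``.

    ``precise=None`` auto-switches to mpmath when strong selection makes the
    double-precision solve lose more than ~6 digits.
    """
    scheme.validate_for(params.N)
    if params.mu != 0.0:
        raise ChainError(
            "expected_cost assumes the small-mutation limit (mu = 0); use "
            "expected_cost_general_mutation for mu > 0"
        )
    N = params.N
    theta_vec = [per_generation_cost(scheme, j, N) for j in range(1, N)]
    if precise is None:
        precise = _needs_precision(game, scheme, params)
    if precise:
        if dps is None:
            delta = game.delta()
            span = params.beta * (abs(delta) + abs(delta + scheme.theta))
            dps = 40 + int(0.5 * span)
        with mp.workdps(dps):
            M = _visit_matrix_mp(game, scheme, params, gap_convention, dps)
            row1 = [M[0, j] for j in range(N - 1)]
            rowN = [M[N - 2, j] for j in range(N - 1)]
            wD, wC = _start_weights_mp(game, scheme, params)
            total = mp.fsum(
                (wD * r1 + wC * rN) * th
                for r1, rN, th in zip(row1, rowN, theta_vec)
            )
            return float(total)
    U = transition_matrix(game, scheme, params, gap_convention=gap_convention)
    nmat = fundamental_matrix(transient_block(U))
    wD, wC = _start_weights(game, scheme, params)
    return float(np.dot(wD * nmat[0] + wC * nmat[-1], theta_vec))


def _start_weights(game, scheme, params) -> tuple[float, float]:
    if params.start is Start.EQUAL:
        return 0.5, 0.5
    if params.start is Start.ALLDEF:
        return 1.0, 0.0
    # weighted: long-run chance the next mutant arises at S_0 vs S_N
    x = params.beta * (params.N - 1) * (game.delta() + scheme.theta)
    fD = fermi_probability(1.0, -x)  # 1/(1+e^x)
    return fD, 1.0 - fD


def _start_weights_mp(game, scheme, params):
    if params.start is Start.EQUAL:
        return mp.mpf("0.5"), mp.mpf("0.5")
    if params.start is Start.ALLDEF:
        return mp.mpf(1), mp.mpf(0)
    x = mp.mpf(params.beta) * (params.N - 1) * (mp.mpf(game.delta()) + mp.mpf(scheme.theta))
    fD = 1 / (1 + mp.e**x)
    return fD, 1 - fD


def expected_cost_general_mutation(
    game: GameSpec,
    scheme: IncentiveScheme,
    params: EvolutionParams,
    i_start: int,
    *,
    gap_convention: str = "cost",
) -> float:
    """Expected incentive cost from ``S_{i_start}`` until a homogeneous state.

    With mutation no state is absorbing, so "total cost" is defined (as in
    the small-mutation analyses it generalises) as the cost accumulated until
    the population first reaches a homogeneous state ``S_0`` or ``S_N`` —
    strictly after leaving the start when the start itself is homogeneous.
    Homogeneous states accrue no incentive cost (``theta_0 = theta_N = 0``
    under the threshold gate), so a homogeneous start contributes only its
    neighbour's cost-to-hit.
    """
    scheme.validate_for(params.N)
    if params.mu <= 0.0:
        raise ChainError(
            "expected_cost_general_mutation requires mu > 0; for mu = 0 use "
            "expected_cost"
        )
    N = params.N
    if not 0 <= i_start <= N:
        raise ChainError(f"start state {i_start} out of range [0, {N}]")
    U = transition_matrix(game, scheme, params, gap_convention=gap_convention)
    # stop at the first homogeneous visit: treat S_0, S_N as absorbing
    nmat = fundamental_matrix(transient_block(U))
    theta_vec = np.array([per_generation_cost(scheme, j, N) for j in range(1, N)])
    costs = nmat @ theta_vec  # cost-to-absorption from each transient state
    if i_start == 0:
        return float(costs[0])  # leaves S_0 only to S_1; dwell at S_0 is free
    if i_start == N:
        return float(costs[-1])
    return float(costs[i_start - 1])
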