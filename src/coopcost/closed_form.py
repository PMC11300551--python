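"""Closed-form incentive costs for thresholds t = 1 and t = 2.

For the Donation and Public Goods games the payoff gap ``delta`` is constant
across states, so the transient part of ``I - U`` factors as
``diag{i(N-i)/N^2} * W`` with ``W`` tridiagonal over four logistic
coefficients::

    a = (1 + e^{-beta (delta + theta)})^{-1}    (up-hop, incentivised states)
    b = (1 + e^{-beta delta})^{-1}              (up-hop, free states)
    c = (1 + e^{ beta (delta + theta)})^{-1}    (down-hop, incentivised states)
    d = (1 + e^{ beta delta})^{-1}              (down-hop, free states)

(the ``a, b`` here are the logistic coefficients, not the incentive
efficiency ratios, which live on :class:`~coopcost.chain.IncentiveScheme`).
The inverse of a tridiagonal matrix obeys second-order linear recurrences;
for t = 1 and t = 2 the relevant entries of ``W^{-1}`` reduce to the sequence

    yhat_0 = yhat_1 = 1,   yhat_j = yhat_{j-1} - (bd) yhat_{j-2},

whose coefficients in powers of (bd) are signed binomials
``(-1)^k C(j-k, k)`` and whose value also has a closed form in the roots of
``x^2 - x + bd = 0``.  This module implements that machinery, the resulting
cost formulas, their theta-derivatives, and the neutral-drift (beta -> 0) and
strong-selection (beta -> inf) limits.

Double precision suffices except where ``1 - a d``-type denominators cancel
under strong selection; every cost entry point auto-switches to mpmath with
an exponent-scaled working precision in that regime.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction
from math import comb

import mpmath as mp
import numpy as np

from . import chain as _chain
from .chain import ChainError, EvolutionParams, IncentiveScheme, Kind, Start
from .games import GameSpec

__all__ = [
    "LogisticCoefficients",
    "RecurrencePolynomial",
    "RootPair",
    "logistic_coefficients",
    "w_matrix",
    "yhat",
    "yhat_coefficients",
    "root_pair",
    "tridiag_inverse_entry",
    "cost_t1",
    "cost_t1_derivative",
    "cost_t2",
    "neutral_drift_limit",
    "strong_selection_limit",
]


# --------------------------------------------------------------------------
# logistic coefficients
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LogisticCoefficients:
    """The four Fermi hop coefficients a, b, c, d (probabilities in (0,1))."""

    a_co: float
    b_co: float
    c_co: float
    d_co: float

    @property
    def bd(self) -> float:
        return self.b_co * self.d_co

    @property
    def ad(self) -> float:
        return self.a_co * self.d_co


def logistic_coefficients(beta: float, delta: float, theta: float) -> LogisticCoefficients:
    """Hop coefficients for gap ``delta + theta`` (incentivised) and ``delta``.

    ``a + c = 1`` and ``b + d = 1`` by logistic symmetry; ``b*d < 1/4``
    whenever ``beta * delta != 0``.
    """
    if beta < 0:
        raise ChainError("beta must be >= 0")
    sig = _chain.fermi_probability
    return LogisticCoefficients(
        a_co=sig(beta, delta + theta),
        b_co=sig(beta, delta),
        c_co=sig(beta, -(delta + theta)),
        d_co=sig(beta, -delta),
    )


def w_matrix(N: int, t: int, coeffs: LogisticCoefficients) -> np.ndarray:
    """The (N-1)x(N-1) tridiagonal factor W of ``I - U = diag{i(N-i)/N^2} W``.

    Rows 1..t (incentivised) carry superdiagonal -a and, from row 2, subdiagonal
    -c; rows t+1..N-1 (free) carry subdiagonal -d and superdiagonal -b.  The
    diagonal is 1.
    """
    if not 1 <= t <= N - 1:
        raise ChainError(f"threshold t={t} must satisfy 1 <= t <= N-1={N - 1}")
    n = N - 1
    W = np.eye(n)
    for row in range(1, n + 1):  # 1-indexed state
        if row < n:
            W[row - 1, row] = -coeffs.a_co if row <= t else -coeffs.b_co
        if row > 1:
            W[row - 1, row - 2] = -coeffs.c_co if row <= t else -coeffs.d_co
    return W


# --------------------------------------------------------------------------
# the yhat sequence
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RecurrencePolynomial:
    """Integer coefficients m_k of ``yhat_j = sum_k m_k (bd)^k``."""

    j: int
    coeffs: tuple[int, ...]

    def __call__(self, bd) -> float:
        # Horner in ascending powers
        acc = 0
        for m in reversed(self.coeffs):
            acc = acc * bd + m
        return acc


def yhat_coefficients(j: int, method: str = "binomial") -> RecurrencePolynomial:
    """Exact integer coefficients of ``yhat_j`` in powers of ``bd``.

    ``method="binomial"`` uses ``m_k = (-1)^k C(j-k, k)``; ``"recurrence"``
    iterates the defining recurrence on integer coefficient vectors.  Both are
    exact (Python integers).
    """
    if j < 0:
        raise ChainError("yhat coefficients are defined for j >= 0")
    if method == "binomial":
        return RecurrencePolynomial(
            j, tuple((-1) ** k * comb(j - k, k) for k in range(j // 2 + 1))
        )
    if method == "recurrence":
        prev2, prev1 = [1], [1]  # yhat_0, yhat_1
        if j == 0:
            return RecurrencePolynomial(0, (1,))
        for _ in range(2, j + 1):
            width = max(len(prev1), len(prev2) + 1)
            cur = [0] * width
            for k, m in enumerate(prev1):
                cur[k] += m
            for k, m in enumerate(prev2):
                cur[k + 1] -= m
            prev2, prev1 = prev1, cur
        return RecurrencePolynomial(j, tuple(prev1))
    raise ChainError(f"unknown coefficient method {method!r}")


@dataclass(frozen=True)
class RootPair:
    """Real roots of the characteristic equation ``x^2 - x + bd = 0``."""

    x1: float
    x2: float


def root_pair(bd: float) -> RootPair:
    if bd > 0.25:
        raise ChainError(f"bd={bd} > 1/4: characteristic roots are complex")
    s = math.sqrt(1.0 - 4.0 * bd)
    return RootPair((1.0 + s) / 2.0, (1.0 - s) / 2.0)


_ROOT_DEGENERACY = 1e-8


def yhat(j: int, bd, method: str = "recurrence"):
    """Evaluate ``yhat_j`` at the product ``bd``.

    Three interchangeable evaluators: the forward recurrence (valid for every
    ``bd``; also the route taken for ``j = -1``, the empty-matrix convention
    ``yhat_{-1} = 0``), the signed-binomial closed form, and the
    characteristic-root form (real roots need ``bd <= 1/4``; within 1e-8 of
    the degenerate double root it falls back to the recurrence).  Works on
    floats, Fractions and mpmath numbers alike.
    """
    if j < -1:
        raise ChainError("yhat is defined for j >= -1")
    if j == -1:
        return 0 * bd
    if method == "recurrence":
        prev2, prev1 = 1 + 0 * bd, 1 + 0 * bd  # yhat_0, yhat_1 in bd's arithmetic
        if j == 0:
            return prev2
        for _ in range(2, j + 1):
            prev2, prev1 = prev1, prev1 - bd * prev2
        return prev1
    if method == "binomial":
        return yhat_coefficients(j)(bd)
    if method == "roots":
        if abs(bd - 0.25) < _ROOT_DEGENERACY:
            return yhat(j, bd, method="recurrence")
        r = root_pair(float(bd))
        x1, x2 = r.x1, r.x2
        return (x1 * x2 * (x1 ** (j - 1) - x2 ** (j - 1)) - (x1**j - x2**j)) / (x2 - x1)
    raise ChainError(f"unknown yhat method {method!r}")


# --------------------------------------------------------------------------
# generic tridiagonal inverse entries
# --------------------------------------------------------------------------

def tridiag_inverse_entry(A: np.ndarray, i: int, j: int) -> float:
    """Entry ``(A^{-1})[i, j]`` of a tridiagonal matrix via linear recurrences.

    Zero-based indices.  Uses the z-recurrence from the top, the y-recurrence
    from the bottom, and the signed off-diagonal product form; raises on a
    zero pivot (degenerate leading/trailing submatrix).
    """
    n = A.shape[0]
    if A.shape != (n, n):
        raise ChainError("A must be square")
    if not (0 <= i < n and 0 <= j < n):
        raise ChainError("index out of range")
    diag = np.diagonal(A)
    sub = np.concatenate(([0.0], np.diagonal(A, -1)))  # sub[i] = A[i, i-1]
    sup = np.concatenate((np.diagonal(A, 1), [0.0]))  # sup[i] = A[i, i+1]

    z = np.empty(n + 1)
    z[0], z[1] = 1.0, diag[0]
    for k in range(1, n):
        z[k + 1] = diag[k] * z[k] - sub[k] * sup[k - 1] * z[k - 1]
    y = np.empty(n + 2)
    y[n + 1], y[n] = 1.0, diag[n - 1]
    for k in range(n - 2, -1, -1):
        y[k + 1] = diag[k] * y[k + 2] - sub[k + 1] * sup[k] * y[k + 3]
    # y[k+1] holds the 1-indexed y_{k+1} of the backward recurrence

    if z[j] == 0.0 or y[j + 2] == 0.0:
        raise ChainError("degenerate tridiagonal matrix: zero recurrence pivot")
    low = sub[j] * sup[j - 1] * z[j - 1] / z[j] if j > 0 else 0.0
    up = sub[j + 1] * sup[j] * y[j + 3] / y[j + 2] if j < n - 1 else 0.0
    phi_jj = 1.0 / (diag[j] - low - up)
    if i == j:
        return phi_jj
    if i < j:
        prod = np.prod(sup[i:j])
        if z[j] == 0.0:
            raise ChainError("degenerate tridiagonal matrix: zero z pivot")
        return (-1.0) ** (j - i) * prod * z[i] / z[j] * phi_jj
    prod = np.prod(sub[j + 1 : i + 1])
    return (-1.0) ** (i - j) * prod * y[i + 2] / y[j + 2] * phi_jj


# --------------------------------------------------------------------------
# cost formulas
# --------------------------------------------------------------------------

def _resolve_start(params: EvolutionParams, start) -> Start:
    return Start(start) if start is not None else params.start


def _effective_shift(scheme: IncentiveScheme, N: int, t: int) -> float:
    """Gap shift theta_j / j, which must be j-independent for j <= t."""
    shifts = [
        _chain.per_generation_cost(scheme, j, N) / j for j in range(1, t + 1)
    ]
    if any(abs(s - shifts[0]) > 1e-12 * max(1.0, abs(shifts[0])) for s in shifts):
        raise ChainError(
            "closed-form costs need a state-independent gap shift over "
            "j <= t (reward schemes, or t = 1); use the matrix path in "
            "coopcost.chain for this scheme"
        )
    return shifts[0]


def _backend(beta: float, delta: float, shift: float, precise: bool | None, dps: int | None):
    """Pick float or mpmath arithmetic and return (exp, one, dps_ctx)."""
    if precise is None:
        precise = beta * (abs(delta) + abs(delta + shift)) > 10.0
    if not precise:
        return None
    if dps is None:
        dps = 40 + int(0.5 * beta * (abs(delta) + abs(delta + shift)))
    return dps


def _coeffs_generic(beta, delta, shift, use_mp: bool):
    if use_mp:
        beta, delta, shift = mp.mpf(beta), mp.mpf(delta), mp.mpf(shift)
        e = mp.exp
        one = mp.mpf(1)
    else:
        e = math.exp
        one = 1.0
    a = one / (one + e(-beta * (delta + shift)))
    b = one / (one + e(-beta * delta))
    c = one / (one + e(beta * (delta + shift)))
    d = one / (one + e(beta * delta))
    bd = one / (2 + e(beta * delta) + e(-beta * delta))
    return a, b, c, d, bd


def _phi_t1(N, a, b, c, d, bd):
    """(phi_{1,1}, phi_{N-1,1}) of W^{-1} for t = 1."""
    y2 = yhat(N - 2, bd)
    y3 = yhat(N - 3, bd)
    phi11 = 1 / (1 - a * d * y3 / y2)
    phiN1 = d ** (N - 2) / y2 * phi11
    return phi11, phiN1


def _phi_t2(N, a, b, c, d, bd):
    """Entries (phi_{1,j}, phi_{N-1,j}) for j = 1, 2 of W^{-1} for t = 2."""
    y3 = yhat(N - 3, bd)
    y4 = yhat(N - 4, bd)
    y2 = y3 - a * d * y4  # t=2 matrix: y_2 = y_3 - (ad) y_4
    phi11 = 1 / (1 - a * c * y3 / y2)
    phiN1 = c * d ** (N - 3) / y2 * phi11
    phi22 = 1 / (1 - a * c - a * d * y4 / y3)
    phi12 = a * phi22
    phiN2 = d ** (N - 3) / y3 * phi22
    return (phi11, phiN1), (phi12, phiN2)


def _assemble(N, t, scheme, phi_pairs, wD, wC):
    """E = sum_j (wD n_{1j} + wC n_{N-1,j}) theta_j with n = phi N^2/(j(N-j))."""
    total = 0
    for j, (phi1, phiN) in enumerate(phi_pairs, start=1):
        theta_j = _chain.per_generation_cost(scheme, j, N)
        total = total + (wD * phi1 + wC * phiN) * N**2 / (j * (N - j)) * theta_j
    return total


def _weights(params, delta, scheme, use_mp):
    st = params.start
    if st is Start.EQUAL:
        half = mp.mpf("0.5") if use_mp else 0.5
        return half, half
    if st is Start.ALLDEF:
        return (mp.mpf(1), mp.mpf(0)) if use_mp else (1.0, 0.0)
    x = params.beta * (params.N - 1) * (delta + scheme.theta)
    if use_mp:
        fD = 1 / (1 + mp.exp(mp.mpf(x)))
    else:
        fD = _chain.fermi_probability(1.0, -x)
    return fD, 1 - fD


def cost_t1(
    game: GameSpec,
    scheme: IncentiveScheme,
    params: EvolutionParams,
    start=None,
    *,
    precise: bool | None = None,
    dps: int | None = None,
) -> float:
    """Closed-form expected incentive cost for threshold t = 1 (mu = 0).

    Equal start: ``N^2 theta / (2(N-1)) (1 + d^{N-2}/y2) / (1 - a d y3/y2)``
    with ``y2 = yhat_{N-2}``, ``y3 = yhat_{N-3}``; the all-defector start
    drops the ``d^{N-2}`` reflection term and the 1/2; the weighted start
    reweights the same two rows of ``W^{-1}`` by the long-run fixation
    frequencies.
    """
    params = EvolutionParams(params.N, params.beta, params.mu, _resolve_start(params, start))
    if scheme.t != 1:
        raise ChainError(f"cost_t1 requires t=1, got t={scheme.t}")
    if params.mu != 0.0:
        raise ChainError("cost_t1 assumes the small-mutation limit (mu = 0)")
    scheme.validate_for(params.N)
    N, delta = params.N, game.delta()
    shift = _effective_shift(scheme, N, 1)
    dps_needed = _backend(params.beta, delta, shift, precise, dps)
    use_mp = dps_needed is not None
    ctx = mp.workdps(dps_needed) if use_mp else _nullcontext()
    with ctx:
        a, b, c, d, bd = _coeffs_generic(params.beta, delta, shift, use_mp)
        phi_pairs = [_phi_t1(N, a, b, c, d, bd)]
        wD, wC = _weights(params, delta, scheme, use_mp)
        return float(_assemble(N, 1, scheme, phi_pairs, wD, wC))


def cost_t2(
    game: GameSpec,
    scheme: IncentiveScheme,
    params: EvolutionParams,
    start=None,
    *,
    precise: bool | None = None,
    dps: int | None = None,
) -> float:
    """Closed-form expected incentive cost for threshold t = 2 (mu = 0, N >= 4).

    Combines the four entries ``(W^{-1})_{1,1}, (W^{-1})_{N-1,1},
    (W^{-1})_{1,2}, (W^{-1})_{N-1,2}`` with the start-convention weights.  For
    N = 3 the threshold t = 2 equals the full-invest case t = N - 1, which has
    a different matrix structure; that call is routed to the generic matrix
    path with a warning.
    """
    params = EvolutionParams(params.N, params.beta, params.mu, _resolve_start(params, start))
    if scheme.t != 2:
        raise ChainError(f"cost_t2 requires t=2, got t={scheme.t}")
    if params.mu != 0.0:
        raise ChainError("cost_t2 assumes the small-mutation limit (mu = 0)")
    scheme.validate_for(params.N)
    N, delta = params.N, game.delta()
    if N == 3:
        warnings.warn(
            "t=2 with N=3 is the full-invest threshold t=N-1; using the "
            "generic fundamental-matrix path",
            stacklevel=2,
        )
        return _chain.expected_cost(game, scheme, params)
    shift = _effective_shift(scheme, N, 2)
    dps_needed = _backend(params.beta, delta, shift, precise, dps)
    use_mp = dps_needed is not None
    ctx = mp.workdps(dps_needed) if use_mp else _nullcontext()
    with ctx:
        a, b, c, d, bd = _coeffs_generic(params.beta, delta, shift, use_mp)
        pair1, pair2 = _phi_t2(N, a, b, c, d, bd)
        wD, wC = _weights(params, delta, scheme, use_mp)
        return float(_assemble(N, 2, scheme, [pair1, pair2], wD, wC))


def cost_t1_derivative(
    game: GameSpec,
    scheme: IncentiveScheme,
    params: EvolutionParams,
    start=None,
    *,
    precise: bool | None = None,
    dps: int | None = None,
) -> float:
    """d E_r / d theta for t = 1 (reward; equal or all-defector start).

    Equal start:
    ``N^2/(2(N-1)) (y2 + d^{N-2}) / (y2 - a d y3) [1 + theta d y3 beta
    e^{-beta(delta+theta)} a^2 / (y2 - a d y3)]``; the all-defector variant
    replaces the first factor by ``y2``.  Strictly positive for theta > 0.
    """
    params = EvolutionParams(params.N, params.beta, params.mu, _resolve_start(params, start))
    if scheme.t != 1:
        raise ChainError(f"cost_t1_derivative requires t=1, got t={scheme.t}")
    if scheme.kind is not Kind.REWARD:
        raise ChainError("the closed-form derivative is stated for reward schemes")
    if params.start is Start.WEIGHTED:
        raise ChainError(
            "the derivative formulas cover the equal and all-defector starts"
        )
    N, delta = params.N, game.delta()
    shift = scheme.theta / scheme.a
    dps_needed = _backend(params.beta, delta, shift, precise, dps)
    use_mp = dps_needed is not None
    ctx = mp.workdps(dps_needed) if use_mp else _nullcontext()
    with ctx:
        beta = mp.mpf(params.beta) if use_mp else params.beta
        th = mp.mpf(scheme.theta) / mp.mpf(scheme.a) if use_mp else shift
        a, b, c, d, bd = _coeffs_generic(params.beta, delta, shift, use_mp)
        y2 = yhat(N - 2, bd)
        y3 = yhat(N - 3, bd)
        den = y2 - a * d * y3
        ex = mp.exp if use_mp else math.exp
        dv = mp.mpf(delta) if use_mp else delta
        bracket = 1 + th * d * y3 * beta * ex(-beta * (dv + th)) * a**2 / den
        if params.start is Start.EQUAL:
            lead = N**2 / (2 * (N - 1)) * (y2 + d ** (N - 2)) / den
        else:
            lead = N**2 / (N - 1) * y2 / den
        # chain rule for the efficiency ratio: E(theta) = Etilde(theta / a)
        return float(lead * bracket / scheme.a)


class _nullcontext:
    def __enter__(self):
        return None

    def __exit__(self, *exc):
        return False


# --------------------------------------------------------------------------
# asymptotic limits
# --------------------------------------------------------------------------

def neutral_P(N: int) -> Fraction:
    """P(N) = yhat_{N-2}(1/4), exact rational."""
    return yhat(N - 2, Fraction(1, 4))


def neutral_Q(N: int) -> Fraction:
    """Q(N) = yhat_{N-3}(1/4), exact rational."""
    return yhat(N - 3, Fraction(1, 4))


def neutral_drift_limit(N: int, theta: float, start=Start.EQUAL) -> float:
    """lim_{beta -> 0} E_r(theta) for t = 1, in exact rational arithmetic.

    Equal start: ``N^2 theta/(N-1) (P + 2^{-(N-2)}) * 2/(4P - Q)``;
    all-defector: ``N^2 theta/(N-1) * 4P/(4P - Q)`` with ``P = yhat_{N-2}(1/4)``,
    ``Q = yhat_{N-3}(1/4)``.  The weighted start coincides with the equal one
    (the fixation-frequency weights tend to 1/2).
    """
    start = Start(start)
    P, Q = neutral_P(N), neutral_Q(N)
    base = Fraction(N**2, N - 1)
    if start in (Start.EQUAL, Start.WEIGHTED):
        val = base * (P + Fraction(1, 2 ** (N - 2))) * Fraction(2) / (4 * P - Q)
    else:
        val = base * 4 * P / (4 * P - Q)
    return float(val) * theta


def strong_selection_limit(N: int, theta: float, delta: float, start=Start.EQUAL) -> float:
    """lim_{beta -> inf} E_r(theta) for t = 1 (same for all start conventions).

    ``+inf`` when ``delta + theta > 0`` (the incentive overcomes the gap and
    the chain keeps re-entering the paid state), ``2 N^2 theta/(N-1)`` on the
    knife edge ``delta + theta = 0``, and ``N^2 theta/(N-1)`` when the
    incentive leaves cooperation dominated.
    """
    Start(start)  # validate
    if delta + theta > 0:
        return math.inf
    if delta + theta == 0:
        return 2 * N**2 * theta / (N - 1)
    return N**2 * theta / (N - 1)
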