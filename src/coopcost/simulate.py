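"""Seeded Monte-Carlo simulation of the incentivised Fermi process.

This is the package's independent verification oracle: trajectories are
sampled from the exact one-step tridiagonal transition probabilities and the
per-generation incentive cost is accumulated until absorption (mu = 0) or
until the first visit to a homogeneous state (mu > 0), mirroring the
definition the analytic cost functions use.  It doubles as the parameter
sweep / fixture generator.

Reproducibility: replicates are simulated in fixed-size batches of 10_000,
each batch driven by its own Philox counter-based generator spawned from the
run seed, so (i) the same seed reproduces results bit-identically and (ii)
two runs covering disjoint batch ranges (via ``replicate_offset``) merge
exactly into the statistics of one combined run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import chain as _chain
from . import closed_form as _cf
from .chain import ChainError, EvolutionParams, IncentiveScheme, Kind, Start
from .games import GameSpec

BATCH_SIZE = 10_000


@dataclass(frozen=True)
class SimulationResult:
    """Summary statistics of a batch of cost trajectories."""

    replicates: int
    mean_cost: float
    se_cost: float
    mean_visits: np.ndarray  # per-state average sojourn counts, length N+1
    absorbed_at: float  # fraction of replicates ending at S_N
    guard_hits: int  # replicates stopped by the max-steps guard

    def merge(self, other: "SimulationResult") -> "SimulationResult":
        """Exact pooled statistics of two disjoint runs."""
        n1, n2 = self.replicates, other.replicates
        n = n1 + n2
        mean = (n1 * self.mean_cost + n2 * other.mean_cost) / n
        # pool second moments: se^2 * n = var/... reconstruct sums of squares
        ss1 = (self.se_cost**2) * n1 * (n1 - 1) + n1 * self.mean_cost**2
        ss2 = (other.se_cost**2) * n2 * (n2 - 1) + n2 * other.mean_cost**2
        var = (ss1 + ss2 - n * mean**2) / (n - 1)
        visits = (n1 * self.mean_visits + n2 * other.mean_visits) / n
        return SimulationResult(
            replicates=n,
            mean_cost=mean,
            se_cost=float(np.sqrt(max(var, 0.0) / n)),
            mean_visits=visits,
            absorbed_at=(n1 * self.absorbed_at + n2 * other.absorbed_at) / n,
            guard_hits=self.guard_hits + other.guard_hits,
        )


def _resolve_starts(i_start, N: int, size: int, rng: np.random.Generator) -> np.ndarray:
    if i_start == "equal":
        # mutant equally likely at S_0 or S_N -> dynamics enters at S_1 or S_{N-1}
        return np.where(rng.random(size) < 0.5, 1, N - 1).astype(np.int64)
    i = int(i_start)
    if not 0 <= i <= N:
        raise ChainError(f"start state {i} out of range [0, {N}]")
    return np.full(size, i, dtype=np.int64)


def simulate_cost(
    game: GameSpec,
    scheme: IncentiveScheme,
    params: EvolutionParams,
    i_start,
    replicates: int,
    seed: int,
    *,
    replicate_offset: int = 0,
    max_steps: int = 10_000_000,
    gap_convention: str = "cost",
) -> SimulationResult:
    """Monte-Carlo estimate of the expected total incentive cost.

    ``i_start`` is a state index ``0..N`` or ``"equal"`` (start at S_1 or
    S_{N-1} with probability 1/2 each, the equal-start convention).  Each
    generation spent in a transient state ``j`` accrues ``theta_j``; a
    trajectory ends on reaching a homogeneous state (strictly after leaving
    it, if it started there).  ``replicate_offset`` must be a multiple of the
    batch size and selects which batch substreams this run consumes.
    """
    if replicates < 1:
        raise ChainError("replicates must be >= 1")
    if replicate_offset % BATCH_SIZE:
        raise ChainError(f"replicate_offset must be a multiple of {BATCH_SIZE}")
    scheme.validate_for(params.N)
    N = params.N
    U = _chain.transition_matrix(game, scheme, params, gap_convention=gap_convention)
    up = np.diagonal(U, 1).copy()  # up[s] = P(s -> s+1), s = 0..N-1
    dn = np.concatenate(([0.0], np.diagonal(U, -1)))  # dn[s] = P(s -> s-1)
    up = np.concatenate((up, [0.0]))
    if params.mu == 0.0 and i_start not in ("equal",) and int(i_start) in (0, N):
        raise ChainError(
            "a homogeneous start never leaves under mu = 0; the cost is 0 by "
            "convention — start from a transient state instead"
        )
    theta_vec = np.array(
        [_chain.per_generation_cost(scheme, j, N) for j in range(N + 1)]
    )

    first_batch = replicate_offset // BATCH_SIZE
    n_batches = -(-replicates // BATCH_SIZE)
    children = np.random.SeedSequence(seed).spawn(first_batch + n_batches)

    total = None
    done = 0
    for b in range(n_batches):
        size = min(BATCH_SIZE, replicates - done)
        res = _run_batch(
            children[first_batch + b], size, N, up, dn, theta_vec, i_start, max_steps
        )
        total = res if total is None else total.merge(res)
        done += size
    if total.guard_hits:
        warnings.warn(
            f"{total.guard_hits} trajectories hit the {max_steps}-step guard; "
            "their partial costs are included",
            stacklevel=2,
        )
    return total


def _run_batch(seed_seq, size, N, up, dn, theta_vec, i_start, max_steps):
    rng = np.random.Generator(np.random.Philox(seed_seq))
    states = _resolve_starts(i_start, N, size, rng)
    costs = np.zeros(size)
    visits = np.zeros((size, N + 1))
    left_start = np.zeros(size, dtype=bool)
    start_states = states.copy()
    alive = np.ones(size, dtype=bool)

    steps = 0
    idx_all = np.arange(size)
    while True:
        active = idx_all[alive]
        if active.size == 0 or steps >= max_steps:
            break
        s = states[active]
        costs[active] += theta_vec[s]
        np.add.at(visits, (active, s), 1)
        u = rng.random(active.size)
        move_up = u < up[s]
        move_dn = (~move_up) & (u < up[s] + dn[s])
        s_new = s + move_up.astype(np.int64) - move_dn.astype(np.int64)
        states[active] = s_new
        left_start[active] |= s_new != start_states[active]
        stopped = ((s_new == 0) | (s_new == N)) & left_start[active]
        alive[active[stopped]] = False
        steps += 1

    guard_hits = int(np.count_nonzero(alive))
    n = size
    mean = float(costs.mean())
    se = float(costs.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return SimulationResult(
        replicates=n,
        mean_cost=mean,
        se_cost=se,
        mean_visits=visits.mean(axis=0),
        absorbed_at=float(np.mean(states == N)),
        guard_hits=guard_hits,
    )


# --------------------------------------------------------------------------
# parameter sweeps
# --------------------------------------------------------------------------

def generate_sweep(config: dict, seed: int | None = None) -> pd.DataFrame:
    """Long-format table of analytic (and optionally simulated) costs.

    ``config`` keys:

    * ``game``: a :class:`GameSpec`, a game dict, or a list of either.
    * ``t``, ``beta``, ``theta``: grids (lists).
    * ``mu``: grid, default ``[0.0]``.
    * ``start``: start conventions for mu = 0 (default ``["equal"]``).
    * ``i_start``: start states for mu > 0 cells (default ``[0]``).
    * ``kind``: scheme kinds (default ``["reward"]``); ``a``, ``b`` scalars.
    * ``simulate``: optional dict, e.g. ``{"replicates": 10000}``, to add
      Monte-Carlo columns (requires ``seed``).

    One row per grid cell; deterministic given ``seed`` (cells are visited in
    a fixed order and each gets an independent substream).
    """
    games = config["game"]
    if not isinstance(games, (list, tuple)):
        games = [games]
    games = [g if isinstance(g, GameSpec) else GameSpec.from_dict(g) for g in games]
    ts = list(config["t"])
    betas = list(config["beta"])
    thetas = list(config["theta"])
    mus = list(config.get("mu", [0.0]))
    starts = [Start(s) for s in config.get("start", ["equal"])]
    i_starts = list(config.get("i_start", [0]))
    kinds = [Kind(k) for k in config.get("kind", ["reward"])]
    a = float(config.get("a", 1.0))
    b = float(config.get("b", 1.0))
    sim_cfg = config.get("simulate")
    if sim_cfg and seed is None:
        raise ChainError("simulated sweeps require a seed")
    for t in ts:
        if t < 1:
            raise ChainError(f"invalid threshold grid entry t={t}")

    rows = []
    cell = 0
    for game in games:
        N = game.N
        for kind in kinds:
            for t in ts:
                if t > N - 1:
                    continue
                for beta in betas:
                    for mu in mus:
                        start_iter = starts if mu == 0.0 else i_starts
                        for start in start_iter:
                            for theta in thetas:
                                scheme = IncentiveScheme(kind, theta, t, a, b)
                                params = EvolutionParams(N, beta, mu)
                                row = {
                                    "variant": game.variant.value,
                                    "N": N,
                                    "kind": kind.value,
                                    "t": t,
                                    "beta": beta,
                                    "mu": mu,
                                    "theta": theta,
                                    "a": a,
                                    "b": b,
                                }
                                if mu == 0.0:
                                    params = EvolutionParams(N, beta, 0.0, start)
                                    row["start"] = start.value
                                    row["E"], row["method"] = _analytic(
                                        game, scheme, params
                                    )
                                    sim_start = (
                                        "equal" if start is Start.EQUAL else 1
                                    )
                                else:
                                    row["start"] = f"state({start})"
                                    row["E"] = _chain.expected_cost_general_mutation(
                                        game, scheme, params, start
                                    )
                                    row["method"] = "matrix"
                                    sim_start = start
                                if sim_cfg:
                                    res = simulate_cost(
                                        game, scheme, params, sim_start,
                                        int(sim_cfg["replicates"]),
                                        seed + cell,
                                    )
                                    row["E_sim"] = res.mean_cost
                                    row["se_sim"] = res.se_cost
                                rows.append(row)
                                cell += 1
    return pd.DataFrame(rows)


def _analytic(game, scheme, params):
    if scheme.kind is Kind.REWARD and scheme.t == 1:
        return _cf.cost_t1(game, scheme, params), "closed_form"
    if scheme.kind is Kind.REWARD and scheme.t == 2 and params.N >= 4:
        return _cf.cost_t2(game, scheme, params), "closed_form"
    return _chain.expected_cost(game, scheme, params), "matrix"
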