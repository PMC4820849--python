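"""Minimum-set reserve selection: greedy, simulated annealing, exact oracle.

The problem: choose the cheapest set of available planning units (always
including the locked-in ones) whose summed feature amounts meet every
representation target.  Real prioritizations run a stochastic heuristic many
times and read relative priority out of per-unit selection frequencies; both
behaviours are reproduced here with explicit seeding so runs are bit-for-bit
repeatable.

Three solvers share the same contract:

* :func:`greedy_solve` — iterative best cost-effectiveness (shortfall reduced
  per dollar) with a final drop pass removing redundant units;
* :func:`anneal_solve` — simulated annealing over add/drop moves with a
  shortfall penalty, geometric cooling and a greedy repair/trim finish;
* :func:`brute_force_solve` — exact subset enumeration, refusing instances
  with more than 20 free units; the test oracle.

Locked-in units contribute their amounts but (by default) not their cost:
reported cost is new investment.
"""

from __future__ import annotations

import dataclasses
from typing import Literal

import numpy as np
import pandas as pd

from .strategy import Problem, _FEAS_RTOL

__all__ = [
    "SolverConfig",
    "Solution",
    "Ensemble",
    "greedy_solve",
    "anneal_solve",
    "brute_force_solve",
    "run_ensemble",
    "solve",
]


@dataclasses.dataclass(frozen=True)
class SolverConfig:
    method: Literal["greedy", "anneal", "brute_force"] = "anneal"
    n_runs: int = 100
    initial_temperature: float | None = None  # None: auto from move energies
    cooling: float = 0.9995
    iterations: int = 20_000
    shortfall_penalty_scale: float = 10.0
    include_locked_cost: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if not 0 < self.cooling < 1:
            raise ValueError("cooling must be in (0, 1)")
        if self.shortfall_penalty_scale <= 0:
            raise ValueError("shortfall_penalty_scale must be > 0")


@dataclasses.dataclass
class Solution:
    """A selected unit set with its cost and per-feature representation."""

    selected: np.ndarray  # sorted unit ids, superset of locked-in
    total_cost_usd: float
    representation: np.ndarray  # effective amount per feature
    feasible: bool
    seed: int


@dataclasses.dataclass
class Ensemble:
    solutions: list[Solution]
    selection_frequency: pd.Series  # unit_id -> number of runs selecting it
    best: Solution | None  # least-cost feasible run, if any


def _solution_from_mask(
    problem: Problem, mask: np.ndarray, seed: int, include_locked_cost: bool = False
) -> Solution:
    rep = problem.amounts @ mask
    cost_mask = mask if include_locked_cost else (mask & ~problem.locked_in)
    return Solution(
        selected=np.sort(problem.unit_ids[mask]),
        total_cost_usd=float(problem.cost[cost_mask].sum()),
        representation=rep,
        feasible=bool(np.all(rep >= problem.targets * (1 - _FEAS_RTOL))),
        seed=seed,
    )


def _shortfall(problem: Problem, rep: np.ndarray) -> np.ndarray:
    return np.maximum(problem.targets - rep, 0.0)


def _greedy_fill(problem: Problem, mask: np.ndarray, order: np.ndarray) -> None:
    """Add best shortfall-per-dollar units in place until no gain remains.

    ``order`` is a permutation of unit indices; argmax over it resolves score
    ties in favour of the earliest unit in that shuffled order.
    """
    rep = problem.amounts @ mask
    cost = np.maximum(problem.cost, 1e-12)
    while True:
        short = _shortfall(problem, rep)
        if short.max() <= _FEAS_RTOL * max(problem.targets.max(), 1.0):
            break
        gain = np.minimum(problem.amounts, short[:, None]).sum(axis=0)
        gain[mask] = 0.0
        score = gain / cost
        ordered = score[order]
        k = int(np.argmax(ordered))
        if ordered[k] <= 0:
            break  # nothing reduces the shortfall further
        j = order[k]
        mask[j] = True
        rep = rep + problem.amounts[:, j]


def _drop_pass(problem: Problem, mask: np.ndarray) -> None:
    """Remove redundant non-locked units (costliest first), keeping feasibility."""
    rep = problem.amounts @ mask
    tol = problem.targets * (1 - _FEAS_RTOL)
    if not np.all(rep >= tol):
        return
    candidates = np.flatnonzero(mask & ~problem.locked_in)
    for j in candidates[np.argsort(-problem.cost[candidates])]:
        new_rep = rep - problem.amounts[:, j]
        if np.all(new_rep >= tol):
            mask[j] = False
            rep = new_rep


def greedy_solve(problem: Problem, seed: int = 0) -> Solution:
    """Cost-effectiveness greedy heuristic with a redundancy drop pass."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(problem.n_units)
    mask = problem.locked_in.copy()
    _greedy_fill(problem, mask, order)
    _drop_pass(problem, mask)
    return _solution_from_mask(problem, mask, seed)


def _penalty_coef(problem: Problem, scale: float) -> np.ndarray:
    """Per-feature penalty for one unit of *fractional* shortfall.

    Normalized by a cheapest-covering-cost estimate (target × best cost per
    amount among units holding the feature) so the penalty scale is
    dimensionless: scale > 1 makes fixing a shortfall always cheaper than
    paying its penalty.
    """
    coef = np.zeros(problem.n_features)
    cost = np.maximum(problem.cost, 1e-12)
    for i in range(problem.n_features):
        j = problem.amounts[i] > 0
        if not j.any() or problem.targets[i] <= 0:
            continue
        best_rate = (cost[j] / problem.amounts[i, j]).min()  # $ per amount
        coef[i] = scale * problem.targets[i] * best_rate
    return coef


def anneal_solve(problem: Problem, cfg: SolverConfig, seed: int = 0) -> Solution:
    """Simulated annealing over single-unit add/drop moves.

    Objective = selected (non-locked) cost + Σ_f coef_f × fractional
    shortfall_f, minimized by Metropolis acceptance under geometric cooling.
    Each run starts from a greedy fill under its own seed-shuffled tie-break,
    so the annealing phase explores around (and can only improve on) a
    feasible incumbent; the best state seen is repaired and trimmed before
    return.  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    n = problem.n_units
    free = np.flatnonzero(~problem.locked_in)
    if free.size == 0:
        mask = problem.locked_in.copy()
        return _solution_from_mask(
            problem, mask, seed, cfg.include_locked_cost
        )
    coef = _penalty_coef(problem, cfg.shortfall_penalty_scale)
    tgt = np.maximum(problem.targets, 1e-12)
    # sparse column view: features each unit actually holds
    col_rows = [np.flatnonzero(problem.amounts[:, j] > 0) for j in range(n)]
    col_amts = [problem.amounts[rows, j] for j, rows in enumerate(col_rows)]

    mask = problem.locked_in.copy()
    _greedy_fill(problem, mask, rng.permutation(n))
    incumbent = mask.copy()
    _drop_pass(problem, incumbent)
    rep = problem.amounts @ mask

    def penalty(r: np.ndarray) -> float:
        return float((coef * np.maximum(problem.targets - r, 0.0) / tgt).sum())

    def delta_e(j: int, adding: bool) -> float:
        rows, amts = col_rows[j], col_amts[j]
        d = amts if adding else -amts
        r_old = rep[rows]
        s_old = np.maximum(problem.targets[rows] - r_old, 0.0)
        s_new = np.maximum(problem.targets[rows] - (r_old + d), 0.0)
        dpen = float((coef[rows] * (s_new - s_old) / tgt[rows]).sum())
        return (problem.cost[j] if adding else -problem.cost[j]) + dpen

    # auto temperature: median |ΔE| of sampled moves from the start state
    if cfg.initial_temperature is None:
        probe = rng.choice(free, size=min(200, free.size * 4), replace=True)
        energies = [abs(delta_e(j, not mask[j])) for j in probe]
        temp = float(np.median(energies)) or 1.0
    else:
        temp = float(cfg.initial_temperature)

    cur_obj = float(problem.cost[mask & ~problem.locked_in].sum()) + penalty(rep)
    best_obj = cur_obj
    best_mask = mask.copy()

    picks = rng.integers(0, free.size, size=cfg.iterations)
    us = rng.random(cfg.iterations)
    for t in range(cfg.iterations):
        j = free[picks[t]]
        adding = not mask[j]
        dE = delta_e(j, adding)
        if dE <= 0 or (temp > 0 and us[t] < np.exp(-dE / temp)):
            mask[j] = adding
            rows = col_rows[j]
            rep[rows] += col_amts[j] if adding else -col_amts[j]
            cur_obj += dE
            if cur_obj < best_obj - 1e-12:
                best_obj = cur_obj
                best_mask = mask.copy()
        temp *= cfg.cooling

    mask = best_mask
    _greedy_fill(problem, mask, rng.permutation(n))
    _drop_pass(problem, mask)
    annealed = _solution_from_mask(problem, mask, seed, cfg.include_locked_cost)
    fallback = _solution_from_mask(problem, incumbent, seed, cfg.include_locked_cost)
    # never return worse than the trimmed construction incumbent
    if (fallback.feasible, -fallback.total_cost_usd) > (
        annealed.feasible, -annealed.total_cost_usd
    ):
        return fallback
    return annealed


def brute_force_solve(problem: Problem, max_free_units: int = 20) -> Solution:
    """Exact minimum-cost feasible subset by full enumeration (test oracle).

    Refuses instances with more than ``max_free_units`` non-locked units.
    Cost ties break lexicographically on the sorted selected unit ids.  If no
    subset is feasible, returns the least-shortfall (then least-cost) subset
    with ``feasible=False``.
    """
    free = np.flatnonzero(~problem.locked_in)
    nf = free.size
    if nf > max_free_units:
        raise ValueError(
            f"{nf} free units exceeds the enumeration guard ({max_free_units})"
        )
    bits = (np.arange(2**nf)[:, None] >> np.arange(nf)) & 1  # subsets × units
    rep_locked = problem.amounts @ problem.locked_in
    rep = rep_locked[:, None] + problem.amounts[:, free] @ bits.T
    short = np.maximum(problem.targets[:, None] - rep, 0.0).sum(axis=0)
    costs = bits @ problem.cost[free]
    feasible = short <= _FEAS_RTOL * max(problem.targets.max(), 1.0)
    if feasible.any():
        pool = np.flatnonzero(feasible)
        cmin = costs[pool].min()
        pool = pool[costs[pool] <= cmin + 1e-9]
    else:
        smin = short.min()
        pool = np.flatnonzero(short <= smin + 1e-12)
        cmin = costs[pool].min()
        pool = pool[costs[pool] <= cmin + 1e-9]
    # lexicographic tie-break on selected id tuples
    def key(ix: int) -> tuple:
        sel = problem.unit_ids[free[bits[ix].astype(bool)]]
        return tuple(np.sort(sel))

    winner = min(pool.tolist(), key=key)
    mask = problem.locked_in.copy()
    mask[free[bits[winner].astype(bool)]] = True
    return _solution_from_mask(problem, mask, 0)


def solve(problem: Problem, cfg: SolverConfig, seed: int | None = None) -> Solution:
    s = cfg.seed if seed is None else seed
    if cfg.method == "greedy":
        return greedy_solve(problem, s)
    if cfg.method == "anneal":
        return anneal_solve(problem, cfg, s)
    if cfg.method == "brute_force":
        return brute_force_solve(problem)
    raise ValueError(f"unknown method {cfg.method!r}")


def run_ensemble(problem: Problem, cfg: SolverConfig) -> Ensemble:
    """Run the solver ``n_runs`` times (seeds seed+0 … seed+n−1).

    Selection frequency counts, per unit, the runs that selected it (always
    ``n_runs`` for locked-in units); ``best`` is the least-cost feasible run.
    """
    solutions = [solve(problem, cfg, cfg.seed + i) for i in range(cfg.n_runs)]
    counts = np.zeros(problem.n_units, dtype=int)
    for sol in solutions:
        counts += np.isin(problem.unit_ids, sol.selected)
    freq = pd.Series(counts, index=pd.Index(problem.unit_ids, name="unit_id"))
    feas = [s for s in solutions if s.feasible]
    best = min(feas, key=lambda s: s.total_cost_usd) if feas else None
    return Ensemble(solutions=solutions, selection_frequency=freq, best=best)
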