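"""Four attitudes to conflict risk, and the reliability mathematics behind them.

A reserve network faces probabilistic loss: each selected unit i is destroyed
by conflict with probability p_i, independently.  The four planning strategies
transform the minimum-set selection problem before any solver sees it:

* **ignorant** — risk is ignored entirely.
* **avoiding** — units with risk above a threshold θ become unavailable.
* **accounting** — every unit stays available but contributes its
  risk-discounted effective amount a·(1−p), so meeting a target in
  expectation requires extra, safer area; an explicit reliability loop then
  inflates targets until each feature's survival probability reaches ρ.
* **sensitive** — threshold exclusion followed by accounting.

The reliability of a portfolio for one feature is the probability that the
surviving amount still meets the target.  With equal unit amounts and a
common loss probability this is a binomial tail (the classic worked example:
six units at 25% loss risk protect a three-unit target with probability
0.962); with heterogeneous risks and amounts it is a Poisson-binomial-style
quantity computed here by exact outcome enumeration up to 20 units and by
Monte Carlo above that.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

__all__ = [
    "StrategySpec",
    "Problem",
    "STRATEGY_NAMES",
    "meeting_probability",
    "meeting_probability_hetero",
    "required_units",
    "apply_strategy",
    "enforce_reliability",
    "count_abandoned",
]

STRATEGY_NAMES = ("ignorant", "avoiding", "accounting", "sensitive")

_FEAS_RTOL = 1e-9


@dataclasses.dataclass(frozen=True)
class StrategySpec:
    """Parameters of one attitude to risk.

    ``threshold`` (θ) is the maximum tolerable risk for avoiding/sensitive;
    ``reliability`` (ρ) the required per-feature survival probability for
    accounting/sensitive; ``target_fraction`` (T) the share of each feature's
    total extent that must be represented.
    """

    name: str
    threshold: float = 0.35
    reliability: float = 0.95
    target_fraction: float = 0.30

    def __post_init__(self) -> None:
        if self.name not in STRATEGY_NAMES:
            raise ValueError(f"unknown strategy {self.name!r}")
        if not 0 <= self.threshold <= 1:
            raise ValueError("threshold must be in [0, 1]")
        if not 0 < self.reliability < 1:
            raise ValueError("reliability must be in (0, 1)")
        if not 0 < self.target_fraction <= 1:
            raise ValueError("target_fraction must be in (0, 1]")


@dataclasses.dataclass
class Problem:
    """A strategy-transformed minimum-set selection instance.

    Arrays are aligned: ``cost``, ``risk`` and ``locked_in`` over
    ``unit_ids`` (the available units); ``amounts`` (effective) and
    ``raw_amounts`` are features × units.  ``targets`` may have been capped
    at the available effective amount (``capped`` flags which).
    """

    unit_ids: np.ndarray
    cost: np.ndarray
    risk: np.ndarray
    feature_ids: list[str]
    amounts: np.ndarray
    raw_amounts: np.ndarray
    targets: np.ndarray
    locked_in: np.ndarray
    capped: np.ndarray
    strategy: str = "ignorant"

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def feasible(self, selected_mask: np.ndarray) -> bool:
        rep = self.amounts @ selected_mask
        return bool(np.all(rep >= self.targets * (1 - _FEAS_RTOL)))


def meeting_probability(n_selected: int, n_required: int, p_loss: float) -> float:
    """P(a target needing ``n_required`` units survives out of ``n_selected``).

    Units are lost independently with probability ``p_loss``; the target is
    met iff at most ``n_selected − n_required`` units are lost (binomial
    tail).  Returns 0 when fewer units are selected than required.
    """
    if n_selected < 0 or n_required < 0:
        raise ValueError("counts must be non-negative")
    if not 0 <= p_loss <= 1:
        raise ValueError("p_loss must be in [0, 1]")
    if n_selected < n_required:
        return 0.0
    return float(binom.cdf(n_selected - n_required, n_selected, p_loss))


def meeting_probability_hetero(
    p_vector: Sequence[float],
    amounts: Sequence[float],
    target: float,
    exact_limit: int = 20,
    n_reps: int = 100_000,
    rng: np.random.Generator | int | None = None,
    return_se: bool = False,
):
    """Probability that surviving amounts sum to >= target under unequal risks.

    Each unit survives independently with probability 1 − p_i and contributes
    its amount if it does.  Exact by outcome enumeration for up to
    ``exact_limit`` units (2^n outcomes); Monte Carlo with ``n_reps``
    replicates above that.  With ``return_se=True`` a (probability,
    standard error) pair is returned (se = 0 on the exact path).
    """
    p = np.asarray(p_vector, float)
    a = np.asarray(amounts, float)
    if p.shape != a.shape:
        raise ValueError("p_vector and amounts must have equal length")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("loss probabilities must be in [0, 1]")
    if np.any(a < 0):
        raise ValueError("amounts must be non-negative")
    total = a.sum()
    if target > total * (1 + _FEAS_RTOL):
        warnings.warn(
            "target exceeds the total available amount; meeting probability is 0",
            stacklevel=2,
        )
        return (0.0, 0.0) if return_se else 0.0
    if target <= 0:
        return (1.0, 0.0) if return_se else 1.0
    n = len(p)
    if n <= exact_limit:
        # iterative doubling over units: every survive/lose outcome once
        sums = np.zeros(1)
        probs = np.ones(1)
        for pi, ai in zip(p, a):
            sums = np.concatenate([sums + ai, sums])
            probs = np.concatenate([probs * (1 - pi), probs * pi])
        val = float(probs[sums >= target * (1 - _FEAS_RTOL)].sum())
        return (val, 0.0) if return_se else val
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    survive = gen.random((n_reps, n)) >= p
    met = (survive @ a) >= target * (1 - _FEAS_RTOL)
    val = float(met.mean())
    se = float(np.sqrt(val * (1 - val) / n_reps))
    return (val, se) if return_se else val


def required_units(n_required: int, p_loss: float, reliability: float) -> int:
    """Smallest n with ``meeting_probability(n, n_required, p_loss) >= ρ``."""
    if n_required < 0:
        raise ValueError("n_required must be non-negative")
    if not 0 <= p_loss <= 1 or p_loss == 1:
        raise ValueError("p_loss must be in [0, 1)")
    if not 0 < reliability < 1:
        raise ValueError("reliability must be in (0, 1)")
    n = n_required
    while meeting_probability(n, n_required, p_loss) < reliability:
        n += 1
    return n


def _risk_series(risks) -> pd.Series:
    if isinstance(risks, pd.DataFrame):
        return risks.set_index("unit_id")["p"]
    if isinstance(risks, pd.Series):
        return risks
    return pd.Series(dict(risks))


def apply_strategy(
    units: pd.DataFrame,
    risks,
    features: pd.DataFrame,
    spec: StrategySpec,
) -> Problem:
    """Transform raw units/features into a strategy-specific :class:`Problem`.

    Targets are T × total raw extent of each feature (over every unit, even
    ones the strategy excludes), then capped at the total available effective
    amount where that would otherwise make the problem infeasible; the
    ``capped`` flags record where.  Locked-in units are always retained,
    whatever their risk.

    ``risks`` may be a risk frame (``unit_id, p``), a Series indexed by
    unit_id, or a mapping.
    """
    risk = _risk_series(risks)
    missing = set(units["unit_id"]) - set(risk.index)
    if missing:
        raise ValueError(f"risks missing for {len(missing)} units")
    locked = (units["status"] == "locked_in").to_numpy()
    p_all = risk.loc[units["unit_id"]].to_numpy(float)

    if spec.name in ("avoiding", "sensitive"):
        keep = (p_all <= spec.threshold) | locked
    else:
        keep = np.ones(len(units), bool)

    sub = units.loc[keep].reset_index(drop=True)
    unit_ids = sub["unit_id"].to_numpy()
    cost = sub["cost_usd"].to_numpy(float)
    p = risk.loc[unit_ids].to_numpy(float)
    locked_in = (sub["status"] == "locked_in").to_numpy()

    feature_ids = sorted(features["feature_id"].unique())
    f_index = {f: i for i, f in enumerate(feature_ids)}
    u_index = {u: j for j, u in enumerate(unit_ids)}

    raw = np.zeros((len(feature_ids), len(unit_ids)))
    totals = np.zeros(len(feature_ids))
    for fid, uid, amt in features[["feature_id", "unit_id", "amount_km2"]].itertuples(
        index=False
    ):
        i = f_index[fid]
        totals[i] += amt
        j = u_index.get(uid)
        if j is not None:
            raw[i, j] += amt

    if spec.name in ("accounting", "sensitive"):
        amounts = raw * (1.0 - p)[None, :]
    else:
        amounts = raw.copy()

    targets = spec.target_fraction * totals
    avail_eff = amounts.sum(axis=1)
    capped = targets > avail_eff * (1 + _FEAS_RTOL)
    targets = np.minimum(targets, avail_eff)
    return Problem(
        unit_ids=unit_ids,
        cost=cost,
        risk=p,
        feature_ids=feature_ids,
        amounts=amounts,
        raw_amounts=raw,
        targets=targets,
        locked_in=locked_in,
        capped=capped,
        strategy=spec.name,
    )


def enforce_reliability(
    problem: Problem,
    features: pd.DataFrame,
    risks,
    spec: StrategySpec,
    solver: Callable[[Problem], "object"],
    max_iterations: int = 20,
    inflation: float = 1.1,
    seed: int = 0,
) -> tuple[Problem, pd.DataFrame]:
    """Inflate targets until every feature's survival probability reaches ρ.

    Iteratively: solve the problem, compute each feature's reliability (the
    probability its *raw* surviving amount in the selected set still meets the
    original T-fraction target), and multiply the working target of every
    unreliable feature by ``inflation`` (capped at the available effective
    amount).  Stops when all features are reliable, every unreliable feature
    is capped, or ``max_iterations`` is reached; never raises on
    non-convergence — unmet features are flagged in the returned report
    (columns ``feature_id, target, achieved_reliability, inflated_target,
    capped, met``).
    """
    if spec.name not in ("accounting", "sensitive"):
        raise ValueError("reliability enforcement applies to accounting/sensitive")
    prob = dataclasses.replace(
        problem,
        targets=problem.targets.copy(),
        capped=problem.capped.copy(),
    )
    base_targets = prob.targets.copy()
    totals = _feature_totals(features, prob.feature_ids)
    goal = spec.target_fraction * totals  # reliability is judged against this
    avail_eff = prob.amounts.sum(axis=1)
    rng = np.random.default_rng(seed)

    rel = np.zeros(prob.n_features)
    for _ in range(max_iterations):
        sol = solver(prob)
        sel_mask = np.isin(prob.unit_ids, sol.selected)
        rel = _portfolio_reliability(prob, sel_mask, goal, rng)
        unmet = rel < spec.reliability
        inflatable = unmet & ~prob.capped
        if not inflatable.any():
            break
        new_t = prob.targets.copy()
        new_t[inflatable] *= inflation
        over = new_t > avail_eff * (1 + _FEAS_RTOL)
        prob.capped = prob.capped | over
        prob.targets = np.minimum(new_t, avail_eff)
    report = pd.DataFrame(
        {
            "feature_id": prob.feature_ids,
            "target": goal,
            "achieved_reliability": rel,
            "inflated_target": prob.targets,
            "capped": prob.capped,
            "met": rel >= spec.reliability,
        }
    )
    # keep base targets where no inflation happened (guards float drift)
    prob.targets = np.maximum(prob.targets, np.minimum(base_targets, avail_eff))
    return prob, report


def _feature_totals(features: pd.DataFrame, feature_ids: list[str]) -> np.ndarray:
    tot = features.groupby("feature_id")["amount_km2"].sum()
    return tot.reindex(feature_ids, fill_value=0.0).to_numpy(float)


def _portfolio_reliability(
    prob: Problem, sel_mask: np.ndarray, goal: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    rel = np.zeros(prob.n_features)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # unattainable targets simply score 0
        for i in range(prob.n_features):
            j = sel_mask & (prob.raw_amounts[i] > 0)
            rel[i] = meeting_probability_hetero(
                prob.risk[j], prob.raw_amounts[i, j], goal[i], rng=rng
            )
    return rel


def count_abandoned(features: pd.DataFrame, problem: Problem) -> int:
    """Features whose entire extent lies outside the available units."""
    avail = set(problem.unit_ids.tolist())
    inside = features[features["unit_id"].isin(avail)]
    present = inside.groupby("feature_id")["amount_km2"].sum()
    n = 0
    for fid in features["feature_id"].unique():
        if present.get(fid, 0.0) <= 0.0:
            n += 1
    return n
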