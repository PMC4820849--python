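"""End-to-end orchestration: data → risk model → strategies → solver → evaluation.

:func:`run_sweep` reproduces the headline comparison of the analysis: for each
requested strategy × risk-threshold × risk-scale × risk-bound combination it
builds the strategy-transformed problem, enforces reliability where the
strategy calls for it, runs a solver ensemble, evaluates the best network by
Monte Carlo, and records one row (targets met with percentile interval, cost,
ROI, abandoned features).  Planning may use fine-scale risk, a national-scale
layer (within-nation mean of fine risk), or the upper/lower confidence bound
of fine risk (sensitivity runs); evaluation always uses the fine-scale point
estimate, so networks planned under different beliefs are judged against the
same world.
"""

from __future__ import annotations

import dataclasses
import logging
import zlib
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import risk as risk_mod
from . import solver as solver_mod
from . import strategy as strategy_mod
from .evaluation import EvaluationConfig, evaluate
from .solver import SolverConfig
from .strategy import StrategySpec
from .synthetic import (
    ConflictProcessConfig,
    Landscape,
    LandscapeConfig,
    generate_conflict_history,
    generate_landscape,
)

logger = logging.getLogger("conflictplan")

__all__ = [
    "RunConfig",
    "national_risk",
    "fit_fine_risk",
    "run_sweep",
    "spending_correlation",
    "reference_config",
]

DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.0, 1.0001, 0.05), 2))


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Full configuration of a sweep run.

    Windows are inclusive year spans: the risk model is calibrated on
    ``calibration_window`` predictors against ``validation_window`` exposure,
    then applied to ``prediction_window`` histories to estimate risk over the
    coming management horizon.
    """

    landscape: LandscapeConfig = LandscapeConfig()
    conflict: ConflictProcessConfig = ConflictProcessConfig()
    strategies: tuple[str, ...] = ("ignorant", "avoiding", "accounting", "sensitive")
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    risk_scales: tuple[str, ...] = ("fine",)
    risk_bounds: tuple[str, ...] = ("point",)
    reliability: float = 0.95
    target_fraction: float = 0.30
    calibration_window: tuple[int, int] = (2000, 2008)
    validation_window: tuple[int, int] = (2009, 2014)
    prediction_window: tuple[int, int] = (2005, 2014)
    solver: SolverConfig = SolverConfig(n_runs=25, iterations=15_000)
    evaluation: EvaluationConfig = EvaluationConfig(n_reps=500)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not 0 <= t <= 1 for t in self.thresholds):
            raise ValueError("thresholds must lie in [0, 1]")
        if list(self.thresholds) != sorted(self.thresholds):
            raise ValueError("thresholds must be sorted")
        for s in self.strategies:
            if s not in strategy_mod.STRATEGY_NAMES:
                raise ValueError(f"unknown strategy {s!r}")
        for sc in self.risk_scales:
            if sc not in ("fine", "national"):
                raise ValueError(f"unknown risk scale {sc!r}")
        for b in self.risk_bounds:
            if b not in ("point", "ci_low", "ci_high"):
                raise ValueError(f"unknown risk bound {b!r}")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        kwargs = dict(data)
        if "landscape" in kwargs:
            kwargs["landscape"] = LandscapeConfig(**kwargs["landscape"])
        if "conflict" in kwargs:
            c = dict(kwargs["conflict"])
            if "years" in c:
                c["years"] = tuple(c["years"])
            kwargs["conflict"] = ConflictProcessConfig(**c)
        if "solver" in kwargs:
            kwargs["solver"] = SolverConfig(**kwargs["solver"])
        if "evaluation" in kwargs:
            kwargs["evaluation"] = EvaluationConfig(**kwargs["evaluation"])
        for key in (
            "strategies", "thresholds", "risk_scales", "risk_bounds",
            "calibration_window", "validation_window", "prediction_window",
        ):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def _derive_seed(master: int, *tags: object) -> int:
    """Stable sub-stream seed below 2**31 (process-independent)."""
    digest = [zlib.crc32(repr(t).encode()) for t in tags]
    h = np.random.SeedSequence([int(master) % (2**31)] + digest)
    return int(h.generate_state(1)[0] % (2**31))


def national_risk(units: pd.DataFrame, nations: dict, fine_risk) -> pd.Series:
    """National-scale risk layer: each unit gets its nation's mean fine risk.

    Within-nation variance of the result is exactly zero, which is the
    property that makes national-scale planning coarse: exclusion or
    discounting acts on whole nations at once.
    """
    if isinstance(fine_risk, pd.DataFrame):
        fine_risk = fine_risk.set_index("unit_id")["p"]
    ids = units["unit_id"]
    unmapped = [u for u in ids if u not in nations]
    if unmapped:
        raise ValueError(f"units not mapped to a nation: {unmapped[:5]}")
    nat = ids.map(nations)
    p = fine_risk.loc[ids].to_numpy(float)
    means = pd.Series(p).groupby(nat.to_numpy()).mean()
    out = pd.Series(means.loc[nat].to_numpy(), index=pd.Index(ids, name="unit_id"),
                    name="p")
    return out


def fit_fine_risk(
    units: pd.DataFrame,
    events,
    calibration_window: tuple[int, int],
    validation_window: tuple[int, int],
    prediction_window: tuple[int, int],
    radius_km: float = 30.0,
) -> tuple[pd.DataFrame, risk_mod.RiskModel]:
    """Fit the logistic risk model and predict per-unit risk with CIs."""
    tallies = risk_mod.assign_exposure(units, events, radius_km)
    ids = units["unit_id"].to_numpy()
    X_cal = risk_mod.build_predictors(tallies, calibration_window, ids)
    y = risk_mod.label_response(tallies, validation_window, ids, calibration_window)
    model = risk_mod.fit_risk_model(X_cal, y.loc[X_cal["unit_id"]].to_numpy())
    X_pred = risk_mod.build_predictors(tallies, prediction_window, ids)
    risk = risk_mod.predict_risk(model, X_pred)
    return risk, model


def _plan_risk_layer(
    risk: pd.DataFrame, units: pd.DataFrame, nations: dict, scale: str, bound: str
) -> pd.Series:
    col = {"point": "p", "ci_low": "ci_low", "ci_high": "ci_high"}[bound]
    fine = risk.set_index("unit_id")[col].rename("p")
    if scale == "fine":
        return fine
    return national_risk(units, nations, fine)


def _evaluate_combo(
    landscape: Landscape,
    risk: pd.DataFrame,
    strategy_name: str,
    theta: float,
    scale: str,
    bound: str,
    cfg: RunConfig,
) -> dict:
    units, features, nations = landscape
    plan_risk = _plan_risk_layer(risk, units, nations, scale, bound)
    spec = StrategySpec(
        name=strategy_name,
        threshold=theta,
        reliability=cfg.reliability,
        target_fraction=cfg.target_fraction,
    )
    problem = strategy_mod.apply_strategy(units, plan_risk, features, spec)
    combo_seed = _derive_seed(cfg.seed, strategy_name, scale, bound,
                              theta if strategy_name in ("avoiding", "sensitive")
                              else -1)
    if strategy_name in ("accounting", "sensitive"):
        problem, _ = strategy_mod.enforce_reliability(
            problem, features, plan_risk, spec,
            solver=lambda pr: solver_mod.greedy_solve(pr, combo_seed),
            seed=combo_seed,
        )
    scfg = dataclasses.replace(cfg.solver, seed=combo_seed)
    ensemble = solver_mod.run_ensemble(problem, scfg)
    if ensemble.best is not None:
        best, infeasible = ensemble.best, False
    else:  # no feasible run: report the cheapest run, flagged
        best = min(ensemble.solutions, key=lambda s: s.total_cost_usd)
        infeasible = True
    abandoned = strategy_mod.count_abandoned(features, problem)
    eval_risk = risk.set_index("unit_id")["p"]  # fine point estimate, always
    ecfg = dataclasses.replace(
        cfg.evaluation,
        seed=_derive_seed(cfg.seed, "eval", strategy_name, scale, bound, theta),
        target_fraction=cfg.target_fraction,
    )
    report = evaluate(best, features, eval_risk, ecfg, abandoned=abandoned)
    return {
        "strategy": strategy_name,
        "threshold": theta,
        "risk_scale": scale,
        "risk_bound": bound,
        "targets_met_median": report.median_targets_met,
        "targets_met_lo": report.targets_met_ci[0],
        "targets_met_hi": report.targets_met_ci[1],
        "total_cost_usd": report.total_cost_usd,
        "roi": report.roi,
        "abandoned": abandoned,
        "infeasible": infeasible,
    }


def run_sweep(cfg: RunConfig, landscape: Landscape | None = None,
              events=None) -> pd.DataFrame:
    """Run the full strategy × threshold × scale × bound comparison.

    Generates (or accepts) a landscape and conflict history, fits fine-scale
    risk, and returns one row per requested combination.  Threshold-free
    strategies (ignorant, accounting) are solved once per scale/bound and
    their row is replicated across the threshold grid.  Fully deterministic
    under ``cfg.seed``.
    """
    if landscape is None:
        lcfg = dataclasses.replace(
            cfg.landscape, seed=_derive_seed(cfg.seed, "landscape"))
        landscape = generate_landscape(lcfg)
    if events is None:
        ccfg = dataclasses.replace(
            cfg.conflict, seed=_derive_seed(cfg.seed, "conflict"))
        events = generate_conflict_history(ccfg, landscape)
    logger.info("landscape: %d units, %d feature records, %d events",
                len(landscape.units), len(landscape.features), len(events))
    risk, model = fit_fine_risk(
        landscape.units, events,
        cfg.calibration_window, cfg.validation_window, cfg.prediction_window,
    )
    logger.info("risk model pseudo-R2 = %.3f", model.pseudo_r2)
    rows = []
    for scale in cfg.risk_scales:
        for bound in cfg.risk_bounds:
            for name in cfg.strategies:
                if name in ("ignorant", "accounting"):
                    row = _evaluate_combo(
                        landscape, risk, name, cfg.thresholds[0], scale, bound, cfg)
                    for theta in cfg.thresholds:
                        rows.append({**row, "threshold": theta})
                else:
                    for theta in cfg.thresholds:
                        logger.info("combo %s θ=%.2f %s/%s", name, theta, scale, bound)
                        rows.append(_evaluate_combo(
                            landscape, risk, name, theta, scale, bound, cfg))
    return pd.DataFrame(rows)


def spending_correlation(
    biodiversity: Sequence[float], spending: Sequence[float]
) -> tuple[float, float]:
    """Spearman rank correlation (with tie handling) between regional
    biodiversity and conservation spending totals; two-sided p-value."""
    b = np.asarray(biodiversity, float)
    s = np.asarray(spending, float)
    if b.shape != s.shape or b.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    if len(b) < 4:
        raise ValueError("need at least 4 paired observations")
    if np.all(b == b[0]) or np.all(s == s[0]):
        raise ValueError("correlation undefined for a constant vector")
    res = stats.spearmanr(b, s)
    return float(res.statistic), float(res.pvalue)


def reference_config(seed: int = 42) -> RunConfig:
    """The reference desk-scale comparison: 30×30 grid, 40 species + 6
    ecoregions, biodiversity-coupled conflict, 25 solver runs, 500 reps."""
    return RunConfig(
        landscape=LandscapeConfig(n_rows=30, n_cols=30, n_species=40,
                                  n_ecoregions=6, seed=seed),
        conflict=ConflictProcessConfig(biodiversity_coupling=2.0, seed=seed),
        strategies=("ignorant", "avoiding", "accounting"),
        thresholds=(0.10,),
        risk_scales=("fine", "national"),
        solver=SolverConfig(n_runs=25, iterations=15_000, seed=seed),
        evaluation=EvaluationConfig(n_reps=500, seed=seed),
        seed=seed,
    )
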