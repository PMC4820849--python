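"""Per-unit conflict-risk estimation from geocoded event histories.

Armed-conflict incidents affect more than the cell they fall in: actors and
displaced people move, so each incident is given a circular *impact zone*
(default radius 30 km) and every planning unit whose centroid lies inside the
zone is deemed to have experienced the conflict.  From the resulting per-unit,
per-year exposure tallies three predictors are built over a calibration window
(incident count, summed fatalities, years since the last incident) and a
logistic regression is fitted against presence/absence of exposure in a later,
disjoint validation window.  The fitted model converts a unit's recent conflict
history into the probability of at least one incident over the next five-year
horizon, with a 95% confidence interval obtained on the linear-predictor scale
and back-transformed so the bounds stay inside [0, 1].
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import expit
import statsmodels.api as sm

__all__ = [
    "ConflictEvent",
    "RiskModel",
    "RiskFitError",
    "PREDICTOR_COLUMNS",
    "assign_exposure",
    "build_predictors",
    "label_response",
    "fit_risk_model",
    "predict_risk",
    "events_to_frame",
]

#: predictor columns, in model order
PREDICTOR_COLUMNS = ("n_events", "n_fatalities", "years_since_last")


@dataclasses.dataclass(frozen=True)
class ConflictEvent:
    """A geocoded armed-conflict incident (planar km coordinates)."""

    x_km: float
    y_km: float
    year: int
    fatalities: int

    def __post_init__(self) -> None:
        if self.fatalities < 0:
            raise ValueError("fatalities must be >= 0")


class RiskFitError(RuntimeError):
    """Raised when the logistic risk model cannot be fitted."""


@dataclasses.dataclass
class RiskModel:
    """Fitted logistic conflict-risk model.

    Coefficients are ordered (intercept, n_events, n_fatalities,
    years_since_last).  ``pseudo_r2`` is McFadden's
    1 - loglik_model / loglik_null.
    """

    beta0: float
    beta_events: float
    beta_fatalities: float
    beta_years: float
    se: dict[str, float]
    z: dict[str, float]
    loglik_model: float
    loglik_null: float
    pseudo_r2: float
    cov: np.ndarray
    log1p_fatalities: bool = False

    @property
    def coefficients(self) -> np.ndarray:
        return np.array(
            [self.beta0, self.beta_events, self.beta_fatalities, self.beta_years]
        )

    def summary_dict(self) -> dict:
        names = ("intercept",) + PREDICTOR_COLUMNS
        return {
            "coefficients": dict(zip(names, self.coefficients.tolist())),
            "se": self.se,
            "z": self.z,
            "loglik_model": self.loglik_model,
            "loglik_null": self.loglik_null,
            "pseudo_r2": self.pseudo_r2,
            "log1p_fatalities": self.log1p_fatalities,
        }


def events_to_frame(events: Iterable[ConflictEvent]) -> pd.DataFrame:
    """Tabulate events as (event_id, x_km, y_km, year, fatalities)."""
    rows = [
        (i, e.x_km, e.y_km, int(e.year), int(e.fatalities))
        for i, e in enumerate(events)
    ]
    return pd.DataFrame(
        rows, columns=["event_id", "x_km", "y_km", "year", "fatalities"]
    )


def _events_frame(events) -> pd.DataFrame:
    if isinstance(events, pd.DataFrame):
        return events
    return events_to_frame(events)


def assign_exposure(
    units: pd.DataFrame, events, radius_km: float = 30.0
) -> pd.DataFrame:
    """Tally exposing incidents per unit and year using circular impact zones.

    A unit is exposed to an incident iff the Euclidean distance between the
    unit centroid and the incident location is <= ``radius_km``; one incident
    can expose many units.

    Parameters
    ----------
    units
        Frame with columns ``unit_id, x_km, y_km`` (centroids).
    events
        Sequence of :class:`ConflictEvent` or an events frame.
    radius_km
        Impact-zone radius around each incident (default 30 km).

    Returns
    -------
    Frame with columns ``unit_id, year, n_events, n_fatalities``, one row per
    exposed (unit, year); unexposed combinations are absent.
    """
    if radius_km < 0:
        raise ValueError("radius_km must be non-negative")
    ev = _events_frame(events)
    cols = ["unit_id", "year", "n_events", "n_fatalities"]
    if ev.empty:
        return pd.DataFrame(columns=cols).astype(
            {"unit_id": int, "year": int, "n_events": int, "n_fatalities": int}
        )
    tree = cKDTree(units[["x_km", "y_km"]].to_numpy(float))
    hits = tree.query_ball_point(ev[["x_km", "y_km"]].to_numpy(float), r=radius_km)
    unit_ids = units["unit_id"].to_numpy()
    uidx, years, fats = [], [], []
    for (_, row), idx in zip(ev.iterrows(), hits):
        if not idx:
            continue
        uidx.extend(idx)
        years.extend([int(row["year"])] * len(idx))
        fats.extend([int(row["fatalities"])] * len(idx))
    if not uidx:
        return pd.DataFrame(columns=cols).astype(int)
    tall = pd.DataFrame(
        {
            "unit_id": unit_ids[np.asarray(uidx)],
            "year": years,
            "n_fatalities": fats,
        }
    )
    out = (
        tall.groupby(["unit_id", "year"], as_index=False)
        .agg(n_events=("n_fatalities", "size"), n_fatalities=("n_fatalities", "sum"))
    )
    return out[cols]


def _check_window(window: Sequence[int]) -> tuple[int, int]:
    start, end = int(window[0]), int(window[1])
    if end < start:
        raise ValueError(f"empty year window {window!r}")
    return start, end


def build_predictors(
    tallies: pd.DataFrame,
    calibration_window: Sequence[int],
    unit_ids: Sequence[int],
    censor_value: int | None = None,
) -> pd.DataFrame:
    """Aggregate exposure tallies into per-unit model predictors.

    ``years_since_last`` is (window end - year of last exposure); units never
    exposed inside the window receive the censored value, by default window
    length + 1.

    Returns a frame indexed 0..n-1 with columns ``unit_id`` plus
    :data:`PREDICTOR_COLUMNS`, one row per unit in ``unit_ids``.
    """
    start, end = _check_window(calibration_window)
    if censor_value is None:
        censor_value = (end - start + 1) + 1
    base = pd.DataFrame({"unit_id": np.asarray(unit_ids)})
    if tallies.empty:
        sub = tallies
    else:
        sub = tallies[(tallies["year"] >= start) & (tallies["year"] <= end)]
    if sub.empty:
        base["n_events"] = 0
        base["n_fatalities"] = 0
        base["years_since_last"] = censor_value
        return base
    agg = sub.groupby("unit_id").agg(
        n_events=("n_events", "sum"),
        n_fatalities=("n_fatalities", "sum"),
        last_year=("year", "max"),
    )
    out = base.merge(agg, on="unit_id", how="left")
    out["n_events"] = out["n_events"].fillna(0).astype(int)
    out["n_fatalities"] = out["n_fatalities"].fillna(0).astype(int)
    ysl = end - out["last_year"]
    out["years_since_last"] = ysl.fillna(censor_value).astype(int)
    return out.drop(columns=["last_year"])


def label_response(
    tallies: pd.DataFrame,
    validation_window: Sequence[int],
    unit_ids: Sequence[int],
    calibration_window: Sequence[int] | None = None,
) -> pd.Series:
    """0/1 response: did the unit experience >=1 exposing incident in the window?

    If ``calibration_window`` is given, the validation window must lie strictly
    after it (disjoint, later years).
    """
    vstart, vend = _check_window(validation_window)
    if calibration_window is not None:
        cstart, cend = _check_window(calibration_window)
        if vstart <= cend:
            raise ValueError(
                "validation window must be disjoint from and after the "
                f"calibration window ({cstart}-{cend} vs {vstart}-{vend})"
            )
    ids = np.asarray(unit_ids)
    labels = pd.Series(0, index=ids, name="response")
    if not tallies.empty:
        sub = tallies[(tallies["year"] >= vstart) & (tallies["year"] <= vend)]
        exposed = np.intersect1d(sub["unit_id"].unique(), ids)
        labels.loc[exposed] = 1
    return labels


def _design_matrix(predictors: pd.DataFrame, log1p_fatalities: bool) -> np.ndarray:
    missing = [c for c in PREDICTOR_COLUMNS if c not in predictors.columns]
    if missing:
        raise ValueError(f"predictor columns missing: {missing}")
    X = predictors[list(PREDICTOR_COLUMNS)].to_numpy(float)
    if log1p_fatalities:
        X = X.copy()
        X[:, 1] = np.log1p(X[:, 1])
    return sm.add_constant(X, has_constant="add")


def fit_risk_model(
    predictors: pd.DataFrame,
    response: Sequence[int],
    log1p_fatalities: bool = False,
) -> RiskModel:
    """Fit the three-covariate logistic risk model by maximum likelihood.

    Raises :class:`RiskFitError` on degenerate input (no response variation,
    perfect separation — named by covariate when attributable to one — or
    non-convergence).
    """
    y = np.asarray(response, float)
    if y.ndim != 1 or len(y) != len(predictors):
        raise ValueError("response length must match predictors")
    if len(y) < 4:
        raise RiskFitError("need at least 4 observations")
    if np.all(y == y[0]):
        raise RiskFitError("response has no variation (all "
                           f"{int(y[0])}s); cannot fit")
    X = _design_matrix(predictors, log1p_fatalities)
    # single-covariate complete separation check (gives a nameable culprit)
    for j, name in enumerate(PREDICTOR_COLUMNS, start=1):
        col = X[:, j]
        if col.std() == 0:
            continue
        lo1, hi1 = col[y == 1].min(), col[y == 1].max()
        lo0, hi0 = col[y == 0].min(), col[y == 0].max()
        if lo1 > hi0 or hi1 < lo0:
            raise RiskFitError(f"perfect separation on covariate '{name}'")
    # zero-variance covariates are collinear with the intercept: drop them
    # from the fit and report a zero coefficient (intercept-only limit)
    keep = np.array([True] + [X[:, j].std() > 0 for j in range(1, X.shape[1])])
    try:
        res = sm.Logit(y, X[:, keep]).fit(disp=0, maxiter=100, tol=1e-8)
    except Exception as exc:  # pragma: no cover - statsmodels internals
        raise RiskFitError(f"logistic fit failed: {exc}") from exc
    kept_params = np.asarray(res.params, float)
    if not np.all(np.isfinite(kept_params)) or not np.all(np.isfinite(res.bse)):
        raise RiskFitError("non-finite coefficients (possible separation)")
    params = np.zeros(X.shape[1])
    params[keep] = kept_params
    bse = np.zeros(X.shape[1])
    bse[keep] = np.asarray(res.bse, float)
    cov = np.zeros((X.shape[1], X.shape[1]))
    cov[np.ix_(keep, keep)] = np.asarray(res.cov_params(), float)
    names = ("intercept",) + PREDICTOR_COLUMNS
    se = dict(zip(names, bse.tolist()))
    zvals = {
        n: (params[i] / se[n] if se[n] > 0 else float("nan"))
        for i, n in enumerate(names)
    }
    llf, llnull = float(res.llf), float(res.llnull)
    pseudo_r2 = 1.0 - llf / llnull if llnull != 0 else 0.0
    # numerical noise can leave a vanishingly negative value
    if -1e-9 < pseudo_r2 < 0:
        pseudo_r2 = 0.0
    return RiskModel(
        beta0=float(params[0]),
        beta_events=float(params[1]),
        beta_fatalities=float(params[2]),
        beta_years=float(params[3]),
        se=se,
        z=zvals,
        loglik_model=llf,
        loglik_null=llnull,
        pseudo_r2=pseudo_r2,
        cov=cov,
        log1p_fatalities=log1p_fatalities,
    )


def predict_risk(
    model: RiskModel, predictors: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Predict per-unit risk with a (1 - alpha) confidence interval.

    The interval is normal on the linear-predictor scale, using the
    coefficient covariance, then transformed through the inverse logit so
    0 <= ci_low <= p <= ci_high <= 1 holds for every unit.

    Returns a frame with columns ``unit_id, p, ci_low, ci_high``.
    """
    from scipy.stats import norm

    X = _design_matrix(predictors, model.log1p_fatalities)
    beta = model.coefficients
    if X.shape[1] != beta.size:
        raise ValueError("predictor columns do not match the fitted model")
    eta = X @ beta
    var = np.einsum("ij,jk,ik->i", X, model.cov, X)
    se_eta = np.sqrt(np.clip(var, 0.0, None))
    zcrit = norm.ppf(1 - alpha / 2)
    out = pd.DataFrame(
        {
            "unit_id": predictors["unit_id"].to_numpy()
            if "unit_id" in predictors.columns
            else np.arange(len(predictors)),
            "p": expit(eta),
            "ci_low": expit(eta - zcrit * se_eta),
            "ci_high": expit(eta + zcrit * se_eta),
        }
    )
    return out
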