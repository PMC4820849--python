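"""CSV/JSON dialects shared by the CLI and the pipeline.

All tables are plain CSV: units (unit_id, row, col, x_km, y_km, area_km2,
cost_usd, status, nation_id), features long format (feature_id,
feature_class, unit_id, amount_km2), events (event_id, x_km, y_km, year,
fatalities), risk (unit_id, p, ci_low, ci_high).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .risk import ConflictEvent, RiskModel, events_to_frame
from .solver import Ensemble

UNIT_COLUMNS = [
    "unit_id", "row", "col", "x_km", "y_km",
    "area_km2", "cost_usd", "status", "nation_id",
]
FEATURE_COLUMNS = ["feature_id", "feature_class", "unit_id", "amount_km2"]
EVENT_COLUMNS = ["event_id", "x_km", "y_km", "year", "fatalities"]
RISK_COLUMNS = ["unit_id", "p", "ci_low", "ci_high"]


def write_units(units: pd.DataFrame, path) -> None:
    units[UNIT_COLUMNS].to_csv(path, index=False)


def read_units(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_features(features: pd.DataFrame, path) -> None:
    features[FEATURE_COLUMNS].to_csv(path, index=False)


def read_features(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_events(events, path) -> None:
    frame = events if isinstance(events, pd.DataFrame) else events_to_frame(events)
    frame[EVENT_COLUMNS].to_csv(path, index=False)


def read_events(path) -> list[ConflictEvent]:
    frame = pd.read_csv(path)
    return [
        ConflictEvent(r.x_km, r.y_km, int(r.year), int(r.fatalities))
        for r in frame.itertuples()
    ]


def write_risk(risk: pd.DataFrame, path) -> None:
    risk[RISK_COLUMNS].to_csv(path, index=False)


def read_risk(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_model_summary(model: RiskModel, path, windows: dict | None = None) -> None:
    payload = model.summary_dict()
    if windows:
        payload["windows"] = windows
    Path(path).write_text(json.dumps(payload, indent=2))


def write_ensemble(ensemble: Ensemble, csv_path, json_path) -> None:
    best_sel = set() if ensemble.best is None else set(ensemble.best.selected.tolist())
    freq = ensemble.selection_frequency
    table = pd.DataFrame(
        {
            "unit_id": freq.index,
            "selected": [int(u in best_sel) for u in freq.index],
            "frequency": freq.to_numpy(),
        }
    )
    table.to_csv(csv_path, index=False)
    summary: dict = {"n_runs": len(ensemble.solutions)}
    if ensemble.best is not None:
        summary["best"] = {
            "total_cost_usd": ensemble.best.total_cost_usd,
            "feasible": ensemble.best.feasible,
            "n_selected": int(len(ensemble.best.selected)),
            "representation": np.asarray(ensemble.best.representation).tolist(),
        }
    else:
        summary["best"] = None
    Path(json_path).write_text(json.dumps(summary, indent=2))
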