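import numpy as np
import pandas as pd
import pytest

from conflictplan import (
    ConflictProcessConfig,
    LandscapeConfig,
    Problem,
    generate_conflict_history,
    generate_landscape,
)


def make_problem(
    n_units: int,
    n_features: int,
    rng: np.random.Generator,
    target_fraction: float = 0.4,
    density: float = 0.5,
    locked: int = 0,
    risk: np.ndarray | None = None,
) -> Problem:
    """Random minimum-set instance for solver tests."""
    amounts = rng.random((n_features, n_units)) * (
        rng.random((n_features, n_units)) < density
    )
    # every feature occurs somewhere
    for i in range(n_features):
        if not (amounts[i] > 0).any():
            amounts[i, rng.integers(n_units)] = rng.random() + 0.1
    cost = rng.uniform(1.0, 10.0, n_units)
    locked_in = np.zeros(n_units, bool)
    if locked:
        locked_in[rng.choice(n_units, size=locked, replace=False)] = True
    targets = target_fraction * amounts.sum(axis=1)
    return Problem(
        unit_ids=np.arange(n_units),
        cost=cost,
        risk=np.zeros(n_units) if risk is None else risk,
        feature_ids=[f"f{i}" for i in range(n_features)],
        amounts=amounts,
        raw_amounts=amounts.copy(),
        targets=targets,
        locked_in=locked_in,
        capped=np.zeros(n_features, bool),
    )


def toy_units(costs, risks=None, status=None) -> pd.DataFrame:
    n = len(costs)
    return pd.DataFrame(
        {
            "unit_id": np.arange(n),
            "row": 0,
            "col": np.arange(n),
            "x_km": 10.0 * np.arange(n),
            "y_km": 0.0,
            "area_km2": 100.0,
            "cost_usd": costs,
            "status": status if status is not None else ["available"] * n,
            "nation_id": 0,
        }
    )


def toy_features(amounts_by_feature: dict) -> pd.DataFrame:
    rows = []
    for fid, amounts in amounts_by_feature.items():
        for uid, amt in enumerate(amounts):
            if amt > 0:
                rows.append((fid, "species", uid, float(amt)))
    return pd.DataFrame(
        rows, columns=["feature_id", "feature_class", "unit_id", "amount_km2"]
    )


@pytest.fixture(scope="session")
def small_landscape():
    return generate_landscape(
        LandscapeConfig(n_rows=10, n_cols=10, n_species=8, n_ecoregions=4,
                        n_nations=2, locked_in_fraction=0.1, seed=3)
    )


@pytest.fixture(scope="session")
def small_history(small_landscape):
    cfg = ConflictProcessConfig(n_hotspots=2, hotspot_intensity=3.0,
                                years=(2000, 2014), seed=3)
    return generate_conflict_history(cfg, small_landscape)
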