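"""Synthetic landscapes, biodiversity features, nations and conflict histories.

The generators produce desk-scale inputs with the statistical structure the
planning analysis assumes about real continental data:

* a regular grid of planning units with a spatially autocorrelated, strictly
  positive land-cost surface (log-normal marginal, Gaussian-kernel smoothed);
* compact, disc-shaped species ranges with jittered boundaries, and an
  ecoregion layer that tessellates the grid exactly (Voronoi partition);
* contiguous nation blocks so a national-scale risk layer (constant within
  nation) can be contrasted with fine-scale risk;
* a clustered spatio-temporal conflict point process with year-to-year
  hotspot persistence (history predicts the future) and an optional positive
  coupling between hotspot placement and species richness, emulating the
  empirical tendency of armed conflict to concentrate in biodiverse regions.

Everything is deterministic under the config seed.
"""

from __future__ import annotations

import dataclasses
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .risk import ConflictEvent

__all__ = [
    "ConfigurationError",
    "LandscapeConfig",
    "ConflictProcessConfig",
    "Landscape",
    "generate_landscape",
    "generate_conflict_history",
    "species_richness",
]


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


@dataclasses.dataclass(frozen=True)
class LandscapeConfig:
    """Geometry and statistical parameters of a synthetic landscape.

    Distances are km, areas km², costs USD.  ``cost_autocorrelation_range_km``
    is the Gaussian smoothing scale of the log-cost field;
    ``species_range_radius_km`` the mean radius of species range discs;
    ``locked_in_fraction`` the share of units already protected (forcibly
    included in every plan).
    """

    n_rows: int = 30
    n_cols: int = 30
    cell_size_km: float = 10.0
    cost_mean_usd: float = 1_000_000.0
    cost_autocorrelation_range_km: float = 50.0
    n_species: int = 40
    species_range_radius_km: float = 50.0
    n_ecoregions: int = 6
    locked_in_fraction: float = 0.05
    n_nations: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_rows", "n_cols", "n_species", "n_ecoregions", "n_nations"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.cell_size_km <= 0:
            raise ConfigurationError("cell_size_km must be > 0")
        if not 0 <= self.locked_in_fraction <= 1:
            raise ConfigurationError("locked_in_fraction must be in [0, 1]")
        if self.cost_mean_usd <= 0:
            raise ConfigurationError("cost_mean_usd must be > 0")
        extent = max(self.n_rows, self.n_cols) * self.cell_size_km
        if self.species_range_radius_km > extent:
            raise ConfigurationError(
                "species_range_radius_km exceeds the grid extent"
            )
        if self.n_ecoregions > self.n_rows * self.n_cols:
            raise ConfigurationError("n_ecoregions exceeds the number of cells")


@dataclasses.dataclass(frozen=True)
class ConflictProcessConfig:
    """Clustered spatio-temporal conflict point process.

    Each year every hotspot emits Poisson(``hotspot_intensity``) incidents,
    scattered around it with an isotropic Gaussian of scale
    ``hotspot_dispersion_km``.  Between years a hotspot is retained with
    probability ``persistence`` and otherwise relocated; relocation (and
    initial placement) weights cells by exp(coupling × standardized species
    richness), so ``biodiversity_coupling`` > 0 concentrates conflict in
    species-rich cells.  Fatalities per incident follow a gamma-Poisson
    (negative binomial) mixture with the given mean and overdispersion.
    """

    n_hotspots: int = 3
    hotspot_intensity: float = 5.0
    hotspot_dispersion_km: float = 15.0
    persistence: float = 0.85
    fatality_mean: float = 3.0
    fatality_overdispersion: float = 1.0
    biodiversity_coupling: float = 0.0
    years: tuple[int, int] = (2000, 2014)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.persistence <= 1:
            raise ConfigurationError("persistence must be in [0, 1]")
        if self.hotspot_intensity < 0:
            raise ConfigurationError("hotspot_intensity must be >= 0")
        if self.biodiversity_coupling < 0:
            raise ConfigurationError("biodiversity_coupling must be >= 0")
        if self.years[1] < self.years[0]:
            raise ConfigurationError(f"empty year span {self.years!r}")
        if self.n_hotspots < 1:
            raise ConfigurationError("n_hotspots must be >= 1")


class Landscape(NamedTuple):
    """Units table, long-format feature table, and unit -> nation map."""

    units: pd.DataFrame
    features: pd.DataFrame
    nations: dict[int, int]


def _autocorrelated_cost(cfg: LandscapeConfig, rng: np.random.Generator) -> np.ndarray:
    """Log-normal cost field with Gaussian-kernel spatial smoothing."""
    z = rng.standard_normal((cfg.n_rows, cfg.n_cols))
    sigma_cells = cfg.cost_autocorrelation_range_km / cfg.cell_size_km
    if sigma_cells > 0:
        z = gaussian_filter(z, sigma=sigma_cells, mode="reflect")
        sd = z.std()
        if sd > 0:
            z = z / sd
    log_sd = 0.5  # moderate cost heterogeneity (~1.6x multiplicative spread)
    field = np.exp(log_sd * z)
    return cfg.cost_mean_usd * field / field.mean()


def generate_landscape(cfg: LandscapeConfig) -> Landscape:
    """Generate planning units, species + ecoregion features and nations.

    Returns a :class:`Landscape`.  Units carry ``unit_id, row, col, x_km,
    y_km, area_km2, cost_usd, status, nation_id``; features are long format
    ``feature_id, feature_class, unit_id, amount_km2`` where ecoregion amounts
    tessellate the grid exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_rows * cfg.n_cols
    rows, cols = np.divmod(np.arange(n), cfg.n_cols)
    x = (cols + 0.5) * cfg.cell_size_km
    y = (rows + 0.5) * cfg.cell_size_km
    area = cfg.cell_size_km**2

    cost = _autocorrelated_cost(cfg, rng).ravel()

    status = np.full(n, "available", dtype=object)
    n_locked = int(round(cfg.locked_in_fraction * n))
    if n_locked:
        status[rng.choice(n, size=n_locked, replace=False)] = "locked_in"

    # contiguous nation blocks: Voronoi cells of random nation seeds
    nation_id = _voronoi_labels(x, y, cfg.n_nations, rng)

    units = pd.DataFrame(
        {
            "unit_id": np.arange(n),
            "row": rows,
            "col": cols,
            "x_km": x,
            "y_km": y,
            "area_km2": area,
            "cost_usd": cost,
            "status": status,
            "nation_id": nation_id,
        }
    )

    feats: list[pd.DataFrame] = []
    # species: jittered discs around a random centre cell
    for s in range(cfg.n_species):
        centre = rng.integers(n)
        radius = max(
            cfg.cell_size_km * 0.75,
            rng.normal(cfg.species_range_radius_km, 0.3 * cfg.species_range_radius_km),
        )
        d = np.hypot(x - x[centre], y - y[centre])
        jitter = rng.normal(0.0, 0.15 * cfg.cell_size_km, size=n)
        member = (d + jitter) <= radius
        member[centre] = True
        ids = np.flatnonzero(member)
        feats.append(
            pd.DataFrame(
                {
                    "feature_id": f"sp{s:03d}",
                    "feature_class": "species",
                    "unit_id": ids,
                    "amount_km2": area,
                }
            )
        )
    # ecoregions: exact Voronoi tessellation (every cell in exactly one)
    eco = _voronoi_labels(x, y, cfg.n_ecoregions, rng)
    for e in range(cfg.n_ecoregions):
        ids = np.flatnonzero(eco == e)
        if ids.size == 0:
            continue
        feats.append(
            pd.DataFrame(
                {
                    "feature_id": f"eco{e:02d}",
                    "feature_class": "ecoregion",
                    "unit_id": ids,
                    "amount_km2": area,
                }
            )
        )
    features = pd.concat(feats, ignore_index=True)
    nations = dict(zip(units["unit_id"].tolist(), units["nation_id"].tolist()))
    return Landscape(units=units, features=features, nations=nations)


def _voronoi_labels(
    x: np.ndarray, y: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    seeds = rng.choice(len(x), size=min(k, len(x)), replace=False)
    d = np.hypot(x[:, None] - x[seeds][None, :], y[:, None] - y[seeds][None, :])
    return d.argmin(axis=1)


def species_richness(landscape: Landscape) -> pd.Series:
    """Number of species features present per unit (index: unit_id)."""
    sp = landscape.features[landscape.features["feature_class"] == "species"]
    rich = sp.groupby("unit_id").size()
    return rich.reindex(landscape.units["unit_id"], fill_value=0)


def _placement_weights(landscape: Landscape, coupling: float) -> np.ndarray:
    rich = species_richness(landscape).to_numpy(float)
    if coupling == 0 or rich.std() == 0:
        w = np.ones(len(rich))
    else:
        z = (rich - rich.mean()) / rich.std()
        w = np.exp(coupling * z)
    return w / w.sum()


def generate_conflict_history(
    cfg: ConflictProcessConfig, landscape: Landscape
) -> list[ConflictEvent]:
    """Simulate a clustered, temporally persistent conflict event history.

    Events fall within the grid bounds (scatter is clipped to the landscape
    extent), carry an integer year inside the configured span and a
    non-negative fatality count.  Deterministic under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    units = landscape.units
    x = units["x_km"].to_numpy()
    y = units["y_km"].to_numpy()
    cell = float(units["area_km2"].iloc[0]) ** 0.5
    xmax = x.max() + cell / 2
    ymax = y.max() + cell / 2
    weights = _placement_weights(landscape, cfg.biodiversity_coupling)

    def draw_hotspots(k: int) -> np.ndarray:
        return rng.choice(len(x), size=k, replace=True, p=weights)

    hotspots = draw_hotspots(cfg.n_hotspots)
    events: list[ConflictEvent] = []
    y0, y1 = cfg.years
    for year in range(y0, y1 + 1):
        for h in hotspots:
            n_ev = rng.poisson(cfg.hotspot_intensity)
            if n_ev == 0:
                continue
            ex = np.clip(
                x[h] + rng.normal(0, cfg.hotspot_dispersion_km, n_ev), 0, xmax
            )
            ey = np.clip(
                y[h] + rng.normal(0, cfg.hotspot_dispersion_km, n_ev), 0, ymax
            )
            fatals = _draw_fatalities(cfg, rng, n_ev)
            events.extend(
                ConflictEvent(float(a), float(b), year, int(f))
                for a, b, f in zip(ex, ey, fatals)
            )
        # hotspot turnover between years
        keep = rng.random(len(hotspots)) < cfg.persistence
        if not keep.all():
            fresh = draw_hotspots(int((~keep).sum()))
            hotspots = np.concatenate([hotspots[keep], fresh])
    return events


def _draw_fatalities(
    cfg: ConflictProcessConfig, rng: np.random.Generator, n: int
) -> np.ndarray:
    if cfg.fatality_mean <= 0:
        return np.zeros(n, dtype=int)
    od = cfg.fatality_overdispersion
    if od <= 0:
        return rng.poisson(cfg.fatality_mean, n)
    lam = rng.gamma(shape=1.0 / od, scale=cfg.fatality_mean * od, size=n)
    return rng.poisson(lam)
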