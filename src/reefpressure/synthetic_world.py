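"""Seeded synthetic study system: rasters, polygons and metric tables.

The generator builds a fully self-contained analogue of the global inputs the
pipeline was designed for, with known ground truth at every stage:

* a rectangular plane (abstract equal-area CRS, unit = km) whose top band is
  land, split into vertical country strips; each country's marine strip is its
  EEZ, bounded seaward by a designated 200-nm limit (the bottom map edge), so
  the EEZs tile the marine area without overlap;
* reef planning units (BCUs) placed in the marine band, each spanning 1-3
  adjacent countries' EEZs, with a membership table (BCUID -> countries)
  emitted alongside the geometry; the topmost BCU deliberately overlaps land
  to emulate the data-resolution artifacts the 200-nm clipping removes;
* 19 stressor intensity fields (4 climate, 5 land, 10 marine) for two periods,
  built as smoothed seeded noise in [0, 1]; land-sourced stressors decay with
  distance from the coast; period-2 fields shift by a per-category mean trend
  (climate up, marine down, land ~flat) plus seeded noise; the seven stressors
  without comparable two-period data are flagged change-ineligible and copied
  unchanged between periods;
* binary habitat rasters, with a "reef" habitat concentrated inside BCUs, and
  a nonnegative habitat x stressor vulnerability matrix;
* a long-format country x metric management table per category, derived from a
  latent per-country "commitment" value plus noise on heterogeneous scales,
  with direction flags, region labels, and missing entries at a configurable
  rate; the latent truth is retained for recovery tests.

Identical configurations (including the seed) reproduce identical outputs at
file level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt, gaussian_filter
from shapely import contains_xy
from shapely.geometry import box
from shapely.ops import unary_union

from .grid import Grid
from .impact_model import (
    CATEGORIES,
    HabitatLayer,
    StressorLayer,
    VulnerabilityMatrix,
)
from .io import write_geojson, write_raster
from .zonal import Zone

__all__ = [
    "WorldConfig",
    "GenerationError",
    "SyntheticGeometry",
    "SyntheticWorld",
    "generate_geometry",
    "generate_stressors",
    "generate_habitats",
    "generate_vulnerability",
    "generate_metrics",
    "generate_world",
    "write_world",
    "DEFAULT_STRESSOR_NAMES",
    "CHANGE_INELIGIBLE",
]

# Stressor name registry mirroring the 19-pressure climate/land/marine split
# used in global cumulative-impact layers.
DEFAULT_STRESSOR_NAMES: dict[str, list[str]] = {
    "climate": ["sst-anomaly", "uv-anomaly", "ocean-acidification", "sea-level-rise"],
    "land": [
        "nutrient-pollution",
        "organic-pollution",
        "inorganic-pollution",
        "direct-human",
        "light-pollution",
    ],
    "marine": [
        "shipping",
        "invasive-species",
        "ocean-pollution",
        "artisanal-fishing",
        "demersal-destructive-fishing",
        "demersal-nondest-high-bycatch",
        "demersal-nondest-low-bycatch",
        "pelagic-high-bycatch",
        "pelagic-low-bycatch",
        "commercial-night-fishing",
    ],
}

# Stressors excluded from the two-period change analysis: either no data in
# both periods or no difference between periods.
CHANGE_INELIGIBLE = frozenset(
    {
        "sea-level-rise",
        "shipping",
        "invasive-species",
        "ocean-pollution",
        "ocean-acidification",
        "artisanal-fishing",
        "inorganic-pollution",
    }
)

DEFAULT_METRICS: dict[str, list[tuple[str, str]]] = {
    "climate": [
        ("eba-strategies", "higher_better"),
        ("ndc-coastal-mention", "higher_better"),
        ("co2-per-gdp-change", "lower_better"),
        ("co2-per-capita-change", "lower_better"),
    ],
    "marine": [
        ("mpa-coral-coverage", "higher_better"),
        ("fisheries-management", "higher_better"),
        ("icri-membership", "higher_better"),
        ("reef-conservation-funding", "higher_better"),
    ],
    "land": [
        ("icm-policies", "higher_better"),
        ("terrestrial-pa-coverage", "higher_better"),
    ],
}

_REGIONS = (
    "Northern Synthetica",
    "Southern Synthetica",
    "Eastern Archipelago",
    "Western Archipelago",
)

# BCU country-span probabilities follow the observed share of planning units
# crossing 1, 2 or 3 national borders (38/50, 8/50, 4/50).
_SPAN_PROBS = (0.76, 0.16, 0.08)


class GenerationError(ValueError):
    """Raised when a configuration cannot be realised as a valid world."""


@dataclass
class WorldConfig:
    """Parameters of the synthetic study system.

    ``trend`` is the signed mean intensity shift from period 1 to period 2 per
    category, on the [0, 1] intensity scale. Defaults follow the observed
    directions of change in cumulative-impact layers: climate pressures
    rising, marine pressures falling, land pressures roughly flat.
    """

    grid_shape: tuple[int, int] = (64, 64)
    cell_size: float = 1.0
    n_countries: int = 6
    n_bcus: int = 8
    n_stressors_per_category: dict[str, int] = field(
        default_factory=lambda: {"climate": 4, "land": 5, "marine": 10}
    )
    n_habitats: int = 3
    trend: dict[str, float] = field(
        default_factory=lambda: {"climate": 0.12, "land": 0.002, "marine": -0.04}
    )
    temporal_noise_sd: float = 0.02
    smooth_sigma: float = 3.0
    land_fraction: float = 0.25
    metric_missing_rate: float = 0.15
    metric_noise_sd: float = 0.1
    metrics_per_category: dict[str, list[tuple[str, str]]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_METRICS.items()}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.grid_shape
        if rows <= 0 or cols <= 0:
            raise ValueError("grid_shape must be positive")
        if self.n_bcus < 1:
            raise ValueError("n_bcus must be >= 1")
        if self.n_countries < 2:
            raise ValueError("n_countries must be >= 2")
        if not 0 <= self.metric_missing_rate < 1:
            raise ValueError("metric_missing_rate must be in [0, 1)")
        if set(self.n_stressors_per_category) != set(CATEGORIES):
            raise ValueError(f"n_stressors_per_category must cover {CATEGORIES}")
        if set(self.trend) != set(CATEGORIES):
            raise ValueError(f"trend must cover {CATEGORIES}")
        if not 0 < self.land_fraction < 1:
            raise ValueError("land_fraction must be in (0, 1)")

    @property
    def grid(self) -> Grid:
        return Grid(shape=tuple(self.grid_shape), cell_size=self.cell_size)

    def stressor_names(self) -> dict[str, list[str]]:
        names = {}
        for cat in CATEGORIES:
            n = self.n_stressors_per_category[cat]
            base = DEFAULT_STRESSOR_NAMES[cat]
            cat_names = list(base[:n])
            cat_names += [f"{cat}-extra-{i}" for i in range(n - len(cat_names))]
            names[cat] = cat_names
        return names

    def country_codes(self) -> list[str]:
        return [f"C{i:02d}" for i in range(self.n_countries)]


def _rng(config: WorldConfig, stage: int) -> np.random.Generator:
    # per-stage streams: each operation is reproducible on its own
    return np.random.default_rng([config.seed, stage])


@dataclass
class SyntheticGeometry:
    grid: Grid
    eez_zones: list[Zone]
    land_zones: list[Zone]
    bcu_zones: list[Zone]
    membership: pd.DataFrame  # columns: country, bcuid
    coast_y: float


def generate_geometry(config: WorldConfig) -> SyntheticGeometry:
    """Lay out countries, EEZs and BCUs on the plane.

    Each BCU occupies its own horizontal band of the marine area and spans
    1-3 adjacent countries' EEZ strips; the band height shrinks with
    ``n_bcus`` and generation fails if bands become thinner than two raster
    cells (the units could then no longer be resolved against the grid while
    keeping the 1-3 country rule meaningful).
    """
    rng = _rng(config, 1)
    grid = config.grid
    xmin, ymin, xmax, ymax = grid.extent
    width = xmax - xmin
    height = ymax - ymin
    coast_y = ymax - config.land_fraction * height
    strip_w = width / config.n_countries
    codes = config.country_codes()

    land_zones, eez_zones = [], []
    for i, code in enumerate(codes):
        x0, x1 = xmin + i * strip_w, xmin + (i + 1) * strip_w
        land_zones.append(
            Zone(zone_id=f"land-{code}", kind="land", country=code,
                 geometry=box(x0, coast_y, x1, ymax))
        )
        eez_zones.append(
            Zone(zone_id=f"eez-{code}", kind="eez", country=code,
                 geometry=box(x0, ymin, x1, coast_y))
        )

    marine_h = coast_y - ymin
    slot_h = marine_h / config.n_bcus
    if slot_h < 2 * grid.cell_size:
        raise GenerationError(
            f"n_bcus={config.n_bcus} too large: BCU bands of {slot_h:.2f} km are "
            f"thinner than two cells, so BCUs spanning 1-3 countries cannot be "
            f"placed on this grid"
        )

    bcu_zones = []
    rows = []
    max_span = min(3, config.n_countries)
    probs = np.array(_SPAN_PROBS[:max_span])
    probs /= probs.sum()
    for b in range(config.n_bcus):
        bcuid = b + 1
        span = int(rng.choice(np.arange(1, max_span + 1), p=probs))
        c0 = int(rng.integers(0, config.n_countries - span + 1))
        if span == 1:
            x0 = xmin + (c0 + 0.2) * strip_w
            x1 = xmin + (c0 + 0.8) * strip_w
        else:
            x0 = xmin + (c0 + 0.5) * strip_w
            x1 = xmin + (c0 + span - 0.5) * strip_w
        y0 = ymin + b * slot_h + 0.15 * slot_h
        y1 = ymin + (b + 1) * slot_h - 0.15 * slot_h
        if b == config.n_bcus - 1:
            # topmost unit spills onto land: the clipping stage must trim it
            y1 = coast_y + 0.2 * (ymax - coast_y)
        bcu_zones.append(
            Zone(zone_id=f"bcu-{bcuid}", kind="bcu", bcuid=bcuid,
                 geometry=box(x0, y0, x1, y1))
        )
        for c in range(c0, c0 + span):
            rows.append({"country": codes[c], "bcuid": bcuid})

    membership = pd.DataFrame(rows, columns=["country", "bcuid"])
    return SyntheticGeometry(
        grid=grid,
        eez_zones=eez_zones,
        land_zones=land_zones,
        bcu_zones=bcu_zones,
        membership=membership,
        coast_y=coast_y,
    )


def _smooth_unit_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    lo, hi = f.min(), f.max()
    if hi == lo:
        return np.full(shape, 0.5)
    return (f - lo) / (hi - lo)


def _land_mask(geometry: SyntheticGeometry) -> np.ndarray:
    xs, ys = geometry.grid.cell_centers()
    land = unary_union([z.geometry for z in geometry.land_zones])
    return contains_xy(land, xs, ys)


def generate_stressors(
    config: WorldConfig, geometry: SyntheticGeometry
) -> list[StressorLayer]:
    """Generate both periods of every stressor as smooth seeded fields in [0, 1].

    Land cells are missing (the impact layers describe the marine area only).
    Change-ineligible stressors get identical fields in both periods.
    """
    rng = _rng(config, 2)
    grid = geometry.grid
    land = _land_mask(geometry)
    # distance from land in km, for the coastal decay of land-sourced stressors
    dist_km = distance_transform_edt(~land) * grid.cell_size
    decay_km = max(grid.cell_size, 0.25 * (grid.extent[3] - grid.extent[1]))
    coastal_decay = np.exp(-dist_km / decay_km)

    layers: list[StressorLayer] = []
    names = config.stressor_names()
    for cat in CATEGORIES:
        for name in names[cat]:
            base = _smooth_unit_field(rng, grid.shape, config.smooth_sigma)
            if cat == "land":
                base = base * coastal_decay
            eligible = name not in CHANGE_INELIGIBLE
            if eligible:
                noise = config.temporal_noise_sd * gaussian_filter(
                    rng.standard_normal(grid.shape), sigma=config.smooth_sigma,
                    mode="reflect",
                )
                later = np.clip(base + config.trend[cat] + noise, 0.0, 1.0)
            else:
                later = base.copy()
            for period, fld in ((2008, base), (2013, later)):
                intensity = fld.copy()
                intensity[land] = np.nan
                layers.append(
                    StressorLayer(
                        name=name, category=cat, period=period,
                        intensity=intensity, change_eligible=eligible,
                    )
                )
    return layers


def generate_habitats(
    config: WorldConfig, geometry: SyntheticGeometry
) -> list[HabitatLayer]:
    """Binary habitat presence rasters; habitat 0 is reef, concentrated in BCUs."""
    rng = _rng(config, 3)
    grid = geometry.grid
    land = _land_mask(geometry)
    xs, ys = grid.cell_centers()
    bcu_union = unary_union([z.geometry for z in geometry.bcu_zones])
    in_bcu = contains_xy(bcu_union, xs, ys)

    habitats: list[HabitatLayer] = []
    for h in range(config.n_habitats):
        fld = _smooth_unit_field(rng, grid.shape, config.smooth_sigma)
        if h == 0:
            presence = (in_bcu | (fld > 0.85)) & ~land
            name = "reef"
        else:
            presence = (fld > 0.45) & ~land
            name = f"habitat-{h}"
        habitats.append(HabitatLayer(name=name, presence=presence.astype(float)))
    return habitats


def generate_vulnerability(
    config: WorldConfig, habitats: list[HabitatLayer], stressors: list[StressorLayer]
) -> VulnerabilityMatrix:
    """Seeded nonnegative mu weights over every habitat x stressor pair."""
    rng = _rng(config, 4)
    habitat_names = [h.name for h in habitats]
    stressor_names = sorted({s.name for s in stressors})
    mu = rng.uniform(0.2, 1.0, size=(len(habitat_names), len(stressor_names)))
    return VulnerabilityMatrix(
        pd.DataFrame(mu, index=habitat_names, columns=stressor_names)
    )


@dataclass
class SyntheticMetrics:
    table: pd.DataFrame  # country, category, metric, raw_value, direction, region
    latent: pd.DataFrame  # country x category latent commitment in [0, 1]


def generate_metrics(
    config: WorldConfig, countries: list[str] | None = None
) -> SyntheticMetrics:
    """Country x metric management table with latent ground truth.

    Each country holds a latent per-category commitment in [0, 1]. Raw metric
    values are affine transforms of (commitment + noise) on heterogeneous
    scales; lower_better metrics decrease with commitment. Cells go missing
    independently at ``metric_missing_rate``.
    """
    rng = _rng(config, 5)
    if countries is None:
        countries = config.country_codes()
    regions = {c: _REGIONS[i % len(_REGIONS)] for i, c in enumerate(countries)}

    latent = pd.DataFrame(
        rng.uniform(0.0, 1.0, size=(len(countries), len(CATEGORIES))),
        index=pd.Index(countries, name="country"),
        columns=list(CATEGORIES),
    )

    rows = []
    for cat in CATEGORIES:
        for metric, direction in config.metrics_per_category[cat]:
            scale = rng.uniform(0.5, 50.0)
            offset = rng.uniform(-5.0, 5.0)
            for country in countries:
                commit = latent.at[country, cat]
                signal = commit if direction == "higher_better" else 1.0 - commit
                noise = rng.normal(0.0, config.metric_noise_sd)
                raw = offset + scale * (signal + noise)
                if rng.random() < config.metric_missing_rate:
                    raw = np.nan
                rows.append(
                    {
                        "country": country,
                        "category": cat,
                        "metric": metric,
                        "raw_value": raw,
                        "direction": direction,
                        "region": regions[country],
                    }
                )
    table = pd.DataFrame(rows)
    return SyntheticMetrics(table=table, latent=latent)


@dataclass
class SyntheticWorld:
    config: WorldConfig
    geometry: SyntheticGeometry
    stressors: list[StressorLayer]
    habitats: list[HabitatLayer]
    vulnerability: VulnerabilityMatrix
    metrics: SyntheticMetrics


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Run every generation stage with stage-local seeded streams."""
    geometry = generate_geometry(config)
    stressors = generate_stressors(config, geometry)
    habitats = generate_habitats(config, geometry)
    vuln = generate_vulnerability(config, habitats, stressors)
    metrics = generate_metrics(config)
    return SyntheticWorld(
        config=config,
        geometry=geometry,
        stressors=stressors,
        habitats=habitats,
        vulnerability=vuln,
        metrics=metrics,
    )


def write_world(world: SyntheticWorld, outdir: str | Path) -> None:
    """Serialize a world: TIFF rasters, GeoJSON polygons, CSV tables."""
    outdir = Path(outdir)
    (outdir / "stressors").mkdir(parents=True, exist_ok=True)
    (outdir / "habitats").mkdir(exist_ok=True)
    grid = world.geometry.grid

    for s in world.stressors:
        write_raster(outdir / "stressors" / f"{s.name}_{s.period}.tif", s.intensity, grid)
    for h in world.habitats:
        write_raster(outdir / "habitats" / f"{h.name}.tif", h.presence, grid)

    crs = grid.crs
    for fname, zones in (
        ("eez.geojson", world.geometry.eez_zones),
        ("land.geojson", world.geometry.land_zones),
        ("bcu.geojson", world.geometry.bcu_zones),
    ):
        write_geojson(
            outdir / fname,
            [z.geometry for z in zones],
            [
                {"zone_id": z.zone_id, "kind": z.kind, "bcuid": z.bcuid,
                 "country": z.country}
                for z in zones
            ],
            crs=crs,
        )

    world.geometry.membership.to_csv(outdir / "membership.csv", index=False)
    world.vulnerability.to_csv(outdir / "vulnerability.csv")
    world.metrics.table.to_csv(outdir / "metrics.csv", index=False)
    world.metrics.latent.to_csv(outdir / "latent_truth.csv")
    registry = pd.DataFrame(
        [
            {"stressor": s.name, "category": s.category,
             "change_eligible": s.change_eligible}
            for s in world.stressors
            if s.period == 2008
        ]
    )
    registry.to_csv(outdir / "stressor_registry.csv", index=False)
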