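"""Pipeline orchestration: simulate -> impact -> zones -> index -> association.

A single run configuration (YAML) drives every stage; each stage reads its
inputs from and writes its outputs under the run directory, so stages can be
re-run individually from the CLI or executed end to end with
:func:`run_pipeline`, which also writes a manifest (config hash, seed, row and
cell counts). Reruns with an identical configuration reproduce identical CSV
outputs at file level.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import classify_quadrants, fit_index_regression, sensitivity_refit
from .grid import Grid
from .impact_model import (
    CATEGORIES,
    HabitatLayer,
    ImpactStack,
    StressorLayer,
    VulnerabilityMatrix,
    change_in_impact,
    compute_impact,
    rescale_stressor,
)
from .io import read_geojson, read_raster, write_geojson, write_raster
from .management_index import build_category_index
from .synthetic_world import WorldConfig, generate_world, write_world
from .zonal import (
    Zone,
    clip_bcus,
    membership_counts,
    summaries_to_frame,
    summarize_bcus,
    summarize_countries,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "load_membership_fixture",
    "run_pipeline",
    "stage_simulate",
    "stage_impact",
    "stage_zones",
    "stage_index",
    "stage_assoc",
]

_FIXTURE_SHA256 = "fea5e2570bfb0560fdd48ac6d1206c79749fd71bfa142f17951b0a9963ad0c90"


def load_membership_fixture() -> pd.DataFrame:
    """Packaged country <-> BCU membership table (columns country, iso3, bcuid).

    The file's checksum is verified on load; a mismatch means the packaged
    fixture was corrupted.
    """
    ref = resources.files("reefpressure.data") / "table1_membership.csv"
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise ValueError(
            f"membership fixture checksum mismatch: {digest} != {_FIXTURE_SHA256}"
        )
    from io import BytesIO

    return pd.read_csv(BytesIO(raw))


@dataclass
class RunConfig:
    """Validated configuration of a pipeline run."""

    out_dir: str
    seed: int = 0
    simulate: dict | None = None
    world_dir: str | None = None
    habitat_agg: str = "mean"
    clip_quantile: float = 0.9999
    country_aggregation: str = "mean_of_portions"
    outlier_rule: str = "iqr"
    outlier_exclude: list[str] = dc_field(default_factory=list)
    collinearity_alpha: float = 0.05
    stressor_registry: dict[str, dict] | None = None

    def validate(self) -> None:
        errors = []
        if self.simulate is None and self.world_dir is None:
            errors.append("one of 'simulate' or 'world_dir' is required")
        if self.simulate is not None and self.world_dir is not None:
            errors.append("'simulate' and 'world_dir' are mutually exclusive")
        if self.habitat_agg not in ("mean", "sum"):
            errors.append(f"habitat_agg: {self.habitat_agg!r} not in ('mean', 'sum')")
        if not 0 < self.clip_quantile <= 1:
            errors.append(f"clip_quantile: {self.clip_quantile} not in (0, 1]")
        if self.country_aggregation not in ("mean_of_portions", "pooled"):
            errors.append(
                f"country_aggregation: {self.country_aggregation!r} "
                "not in ('mean_of_portions', 'pooled')"
            )
        if self.outlier_rule not in ("iqr", "named"):
            errors.append(f"outlier_rule: {self.outlier_rule!r} not in ('iqr', 'named')")
        if not 0 < self.collinearity_alpha < 1:
            errors.append(f"collinearity_alpha: {self.collinearity_alpha} not in (0, 1)")
        if self.simulate is not None:
            try:
                self.world_config()
            except (TypeError, ValueError) as exc:
                errors.append(f"simulate: {exc}")
        if errors:
            raise ValueError("invalid run config:\n  " + "\n  ".join(errors))

    def world_config(self) -> WorldConfig:
        kwargs = dict(self.simulate or {})
        kwargs.setdefault("seed", self.seed)
        if "grid_shape" in kwargs:
            kwargs["grid_shape"] = tuple(kwargs["grid_shape"])
        return WorldConfig(**kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"invalid run config:\n  unknown fields: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def canonical_hash(self) -> str:
        doc = json.dumps(
            {k: getattr(self, k) for k in self.__dataclass_fields__},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(doc.encode()).hexdigest()


# ---------------------------------------------------------------------------
# world loading


def _zones_from_geojson(path: Path) -> list[Zone]:
    geoms, props = read_geojson(path)
    out = []
    for g, p in zip(geoms, props):
        out.append(
            Zone(
                zone_id=p["zone_id"], kind=p["kind"], geometry=g,
                bcuid=p.get("bcuid"), country=p.get("country"),
            )
        )
    return out


def _load_registry(cfg: RunConfig, world_dir: Path) -> pd.DataFrame:
    if cfg.stressor_registry is not None:
        return pd.DataFrame(
            [
                {"stressor": name, **vals}
                for name, vals in cfg.stressor_registry.items()
            ]
        )
    reg_path = world_dir / "stressor_registry.csv"
    if not reg_path.exists():
        raise ValueError("no stressor registry: provide 'stressor_registry' in the config")
    return pd.read_csv(reg_path)


def _load_stressors(cfg: RunConfig, world_dir: Path) -> tuple[list[StressorLayer], Grid]:
    registry = _load_registry(cfg, world_dir).set_index("stressor")
    layers = []
    grid = None
    for path in sorted((world_dir / "stressors").glob("*.tif")):
        name, period = path.stem.rsplit("_", 1)
        if name not in registry.index:
            raise ValueError(f"stressor {name!r} missing from the category registry")
        arr, g = read_raster(path)
        grid = grid or g
        row = registry.loc[name]
        layers.append(
            StressorLayer(
                name=name, category=row["category"], period=int(period),
                intensity=arr, change_eligible=bool(row["change_eligible"]),
            )
        )
    if not layers:
        raise ValueError(f"no stressor rasters under {world_dir / 'stressors'}")
    return layers, grid


def _load_habitats(world_dir: Path) -> list[HabitatLayer]:
    return [
        HabitatLayer(name=p.stem, presence=read_raster(p)[0])
        for p in sorted((world_dir / "habitats").glob("*.tif"))
    ]


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: RunConfig) -> Path:
    """Generate the synthetic world and write it under <out>/world."""
    world_dir = Path(cfg.out_dir) / "world"
    world = generate_world(cfg.world_config())
    write_world(world, world_dir)
    logger.info("simulate: wrote world to %s", world_dir)
    return world_dir


def _resolve_world_dir(cfg: RunConfig) -> Path:
    if cfg.world_dir is not None:
        return Path(cfg.world_dir)
    return Path(cfg.out_dir) / "world"


def stage_impact(cfg: RunConfig) -> Path:
    """Compute snapshot CHI (2013), jointly rescaled stacks and change rasters."""
    world_dir = _resolve_world_dir(cfg)
    impact_dir = Path(cfg.out_dir) / "impact"
    impact_dir.mkdir(parents=True, exist_ok=True)

    layers, grid = _load_stressors(cfg, world_dir)
    habitats = _load_habitats(world_dir)
    vuln = VulnerabilityMatrix.from_csv(world_dir / "vulnerability.csv")
    by_name: dict[str, dict[int, StressorLayer]] = {}
    for s in layers:
        by_name.setdefault(s.name, {})[s.period] = s
    periods = sorted({s.period for s in layers})

    # snapshot: within-period rescale of the later period
    snap_period = periods[-1]
    snap_layers = [
        StressorLayer(
            name=n, category=d[snap_period].category, period=snap_period,
            intensity=rescale_stressor(d[snap_period].intensity, cfg.clip_quantile),
            change_eligible=d[snap_period].change_eligible,
        )
        for n, d in sorted(by_name.items())
    ]
    snapshot = compute_impact(snap_layers, habitats, vuln, habitat_agg=cfg.habitat_agg)
    write_raster(impact_dir / f"chi_{snap_period}.tif", snapshot.total, grid)
    for cat in CATEGORIES:
        write_raster(
            impact_dir / f"chi_{snap_period}_{cat}.tif", snapshot.per_category[cat], grid
        )

    if len(periods) == 2:
        early, late = periods
        joint_stacks = {}
        for period in periods:
            jlayers = [
                StressorLayer(
                    name=n, category=d[period].category, period=period,
                    intensity=rescale_stressor(
                        d[period].intensity, cfg.clip_quantile,
                        joint=[d[early].intensity, d[late].intensity],
                    ),
                    change_eligible=d[period].change_eligible,
                )
                for n, d in sorted(by_name.items())
            ]
            joint_stacks[period] = compute_impact(
                jlayers, habitats, vuln, habitat_agg=cfg.habitat_agg
            )
        eligibility = {n: d[late].change_eligible for n, d in by_name.items()}
        delta_total, delta_cat = change_in_impact(
            joint_stacks[early], joint_stacks[late], eligibility
        )
        write_raster(impact_dir / "delta_chi.tif", delta_total, grid)
        for cat in CATEGORIES:
            write_raster(impact_dir / f"delta_chi_{cat}.tif", delta_cat[cat], grid)
    logger.info("impact: wrote rasters to %s", impact_dir)
    return impact_dir


def _load_stack(impact_dir: Path, period: int) -> tuple[ImpactStack, Grid]:
    total, grid = read_raster(impact_dir / f"chi_{period}.tif")
    per_cat = {
        cat: read_raster(impact_dir / f"chi_{period}_{cat}.tif")[0] for cat in CATEGORIES
    }
    return ImpactStack(total=total, per_category=per_cat, per_stressor={}), grid


def stage_zones(cfg: RunConfig, snap_period: int = 2013) -> Path:
    """Clip BCUs to EEZs and write BCU/country summary tables."""
    world_dir = _resolve_world_dir(cfg)
    impact_dir = Path(cfg.out_dir) / "impact"
    zones_dir = Path(cfg.out_dir) / "zones"
    zones_dir.mkdir(parents=True, exist_ok=True)

    bcu_zones = _zones_from_geojson(world_dir / "bcu.geojson")
    eez_zones = _zones_from_geojson(world_dir / "eez.geojson")
    portions = clip_bcus(bcu_zones, eez_zones)
    write_geojson(
        zones_dir / "portions.geojson",
        [z.geometry for z in portions],
        [
            {"zone_id": z.zone_id, "kind": z.kind, "bcuid": z.bcuid, "country": z.country}
            for z in portions
        ],
    )

    stack, grid = _load_stack(impact_dir, snap_period)
    delta_path = impact_dir / "delta_chi.tif"
    delta_total = read_raster(delta_path)[0] if delta_path.exists() else None
    delta_cat = (
        {cat: read_raster(impact_dir / f"delta_chi_{cat}.tif")[0] for cat in CATEGORIES}
        if delta_path.exists()
        else None
    )

    bcu_summ = summarize_bcus(portions, stack, grid, delta_total, delta_cat)
    summaries_to_frame(bcu_summ).to_csv(zones_dir / "bcu_summary.csv", index=False)
    country_summ = summarize_countries(
        portions, stack, grid, delta_total, delta_cat, mode=cfg.country_aggregation
    )
    summaries_to_frame(country_summ).to_csv(zones_dir / "country_summary.csv", index=False)
    alt_mode = "pooled" if cfg.country_aggregation == "mean_of_portions" else "mean_of_portions"
    alt = summarize_countries(portions, stack, grid, delta_total, delta_cat, mode=alt_mode)
    summaries_to_frame(alt).to_csv(
        zones_dir / f"country_summary_{alt_mode}.csv", index=False
    )
    logger.info("zones: %d portions, %d BCUs, %d countries",
                len(portions), len(bcu_summ), len(country_summ))
    return zones_dir


def stage_index(cfg: RunConfig) -> Path:
    """Build the three per-country management indices from the metric table."""
    world_dir = _resolve_world_dir(cfg)
    index_dir = Path(cfg.out_dir) / "index"
    index_dir.mkdir(parents=True, exist_ok=True)
    table = pd.read_csv(world_dir / "metrics.csv")

    idx_rows, comp_frames, reports = [], [], []
    for cat in CATEGORIES:
        indices, components, report = build_category_index(table, cat)
        for m in indices:
            idx_rows.append({"country": m.country, "category": m.category, "score": m.score})
        comp = components.reset_index().melt(
            id_vars="country", var_name="metric", value_name="score"
        )
        comp["category"] = cat
        flag_map = {(m.country, k): v for m in indices for k, v in m.imputed.items()}
        comp["imputed"] = [
            flag_map[(r.country, r.metric)] for r in comp.itertuples()
        ]
        comp_frames.append(comp)
        report = report.assign(category=cat)
        reports.append(report)

    pd.DataFrame(idx_rows).to_csv(index_dir / "management_index.csv", index=False)
    pd.concat(comp_frames, ignore_index=True).to_csv(
        index_dir / "components.csv", index=False
    )
    pd.concat(reports, ignore_index=True).to_csv(
        index_dir / "collinearity.csv", index=False
    )
    logger.info("index: wrote indices for %d categories", len(CATEGORIES))
    return index_dir


def stage_assoc(cfg: RunConfig) -> Path:
    """Regress impacts on indices, classify quadrants, run sensitivity refits."""
    out = Path(cfg.out_dir)
    assoc_dir = out / "assoc"
    assoc_dir.mkdir(parents=True, exist_ok=True)

    country = pd.read_csv(out / "zones" / "country_summary.csv").set_index("country")
    bcu = pd.read_csv(out / "zones" / "bcu_summary.csv")
    index = pd.read_csv(out / "index" / "management_index.csv").pivot(
        index="country", columns="category", values="score"
    )
    shared = sorted(set(country.index) & set(index.index))

    reg_rows = []
    for cat in CATEGORIES:
        for response, col in (("mean", f"mean_{cat}"), ("delta", f"delta_{cat}")):
            if col not in country.columns or country[col].isna().all():
                continue
            x = index.loc[shared, cat]
            y = country.loc[shared, col]
            try:
                full = fit_index_regression(x, y)
                outliers, refit = sensitivity_refit(
                    x, y, rule=cfg.outlier_rule, exclude=cfg.outlier_exclude
                )
            except ValueError as exc:
                logger.warning("assoc: skipping %s/%s (%s)", cat, response, exc)
                continue
            for label, res in (("full", full), ("outliers_removed", refit)):
                reg_rows.append(
                    {
                        "category": cat, "response": response, "fit": label,
                        "slope": res.slope, "intercept": res.intercept,
                        "r_squared": res.r_squared,
                        "r_squared_adj": res.r_squared_adj,
                        "p_value": res.p_value, "n": res.n,
                        "outliers_removed": ";".join(res.outliers_removed),
                    }
                )
    pd.DataFrame(reg_rows).to_csv(assoc_dir / "regressions.csv", index=False)

    quad_rows = []

    def _quads(units, x, y, x_axis, y_axis, level):
        labels, _counts = classify_quadrants(units, x, y, x_axis=x_axis, y_axis=y_axis)
        for lab in labels:
            quad_rows.append(
                {
                    "level": level, "unit_id": lab.unit_id,
                    "x_axis": lab.x_axis, "y_axis": lab.y_axis,
                    "quadrant": lab.quadrant,
                }
            )

    bcu_units = bcu["zone_id"].astype(str).tolist()
    bx = bcu.set_index("zone_id")["mean_land"]
    by = bcu.set_index("zone_id")["mean_marine"]
    if len(bcu_units) >= 2:
        _quads(bcu_units, bx, by, "mean_land", "mean_marine", "bcu")
    if len(shared) >= 2:
        _quads(
            shared, country.loc[shared, "mean_land"], country.loc[shared, "mean_marine"],
            "mean_land", "mean_marine", "country",
        )
        for cat in CATEGORIES:
            _quads(
                shared, index.loc[shared, cat], country.loc[shared, f"mean_{cat}"],
                f"{cat}_index", f"mean_{cat}", "country",
            )
    pd.DataFrame(quad_rows).to_csv(assoc_dir / "quadrants.csv", index=False)
    logger.info("assoc: %d regression rows, %d quadrant labels",
                len(reg_rows), len(quad_rows))
    return assoc_dir


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and write a manifest; returns the manifest dict."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cfg.simulate is not None:
        stage_simulate(cfg)
    stage_impact(cfg)
    stage_zones(cfg)
    stage_index(cfg)
    stage_assoc(cfg)

    world_dir = _resolve_world_dir(cfg)
    membership = pd.read_csv(world_dir / "membership.csv")
    counts = membership_counts(membership)
    bcu_rows = len(pd.read_csv(out / "zones" / "bcu_summary.csv"))
    country_rows = len(pd.read_csv(out / "zones" / "country_summary.csv"))
    manifest = {
        "package_version": __version__,
        "config_hash": cfg.canonical_hash(),
        "seed": cfg.seed,
        "n_bcus": counts.n_bcus,
        "n_countries": counts.n_countries,
        "bcu_summary_rows": bcu_rows,
        "country_summary_rows": country_rows,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
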