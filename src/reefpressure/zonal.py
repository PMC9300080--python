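"""Zonal reduction of impact rasters over BCU and country polygons.

Planning units (BCUs) are first clipped to the 200-nm national jurisdictions
(EEZs), producing one *portion* per BCU x country; rasters are then reduced to
per-BCU and per-country summary tables. Cells belong to a zone when their
centre falls inside the zone geometry. A BCU is one ecological unit, so its
summary pools the cells of all of its portions; the country summary defaults
to the unweighted mean of the country's portion means, with a cell-pooled
alternative.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from shapely import contains_xy, make_valid
from shapely.geometry.base import BaseGeometry
from shapely.prepared import prep

from .grid import Grid
from .impact_model import CATEGORIES, ImpactStack

logger = logging.getLogger(__name__)

__all__ = [
    "Zone",
    "ZoneImpactSummary",
    "clip_bcus",
    "zone_cell_mask",
    "zonal_mean",
    "summarize_bcus",
    "summarize_countries",
    "membership_counts",
    "MembershipCounts",
    "summaries_to_frame",
]

_ZONE_KINDS = {"bcu", "bcu_country_portion", "country_union", "eez", "land"}


@dataclass
class Zone:
    """A polygon analysis unit on the plane."""

    zone_id: str
    kind: str
    geometry: BaseGeometry
    bcuid: int | None = None
    country: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in _ZONE_KINDS:
            raise ValueError(f"zone {self.zone_id!r}: unknown kind {self.kind!r}")
        if not self.geometry.is_valid:
            repaired = make_valid(self.geometry)
            if not repaired.is_valid:
                raise ValueError(f"zone {self.zone_id!r}: invalid geometry")
            self.geometry = repaired
        if self.geometry.is_empty:
            raise ValueError(f"zone {self.zone_id!r}: empty geometry")
        if self.kind == "bcu_country_portion" and (
            self.bcuid is None or self.country is None
        ):
            raise ValueError(
                f"zone {self.zone_id!r}: bcu_country_portion requires bcuid and country"
            )


@dataclass
class ZoneImpactSummary:
    """Per-zone impact statistics: snapshot means, contributions and change."""

    zone_id: str
    kind: str
    mean_chi: float
    mean_per_category: dict[str, float]
    pct_contribution: dict[str, float]
    delta_chi: float = np.nan
    delta_per_category: dict[str, float] = field(default_factory=dict)
    n_cells: int = 0
    bcuid: int | None = None
    country: str | None = None


def clip_bcus(bcu_zones: Iterable[Zone], eez_zones: Iterable[Zone]) -> list[Zone]:
    """Intersect every BCU with every EEZ; one portion per non-empty overlap.

    Portions inherit the BCU id and the EEZ's country; land overlaps (outside
    every EEZ) are discarded, which is exactly the 200-nm clipping step.
    """
    portions: list[Zone] = []
    for bcu in bcu_zones:
        for eez in eez_zones:
            inter = make_valid(bcu.geometry).intersection(make_valid(eez.geometry))
            if inter.is_empty or inter.area == 0:
                continue
            portions.append(
                Zone(
                    zone_id=f"bcu{bcu.bcuid}-{eez.country}",
                    kind="bcu_country_portion",
                    geometry=inter,
                    bcuid=bcu.bcuid,
                    country=eez.country,
                )
            )
    return portions


def zone_cell_mask(grid: Grid, geometry: BaseGeometry) -> np.ndarray:
    """Boolean mask of cells whose centres fall inside the geometry."""
    xs, ys = grid.cell_centers()
    return contains_xy(make_valid(geometry), xs, ys)


def zonal_mean(raster: np.ndarray, grid: Grid, zone: Zone) -> float:
    """Mean of non-missing cells whose centres fall inside the zone.

    Returns NaN (with a logged warning) when the zone captures no cell centre
    or only missing cells.
    """
    if raster.shape != grid.shape:
        raise ValueError("raster and grid shape mismatch")
    mask = zone_cell_mask(grid, zone.geometry)
    vals = raster[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        logger.warning("zonal_mean: zone %s contains no usable cells", zone.zone_id)
        return float("nan")
    return float(vals.mean())


def _masked_stats(
    mask: np.ndarray,
    stack: ImpactStack,
    delta_total: np.ndarray | None,
    delta_cat: dict[str, np.ndarray] | None,
) -> tuple[float, dict, dict, float, dict, int]:
    def _mean(raster: np.ndarray) -> float:
        vals = raster[mask]
        vals = vals[np.isfinite(vals)]
        return float(vals.mean()) if vals.size else float("nan")

    mean_chi = _mean(stack.total)
    cat_means = {cat: _mean(stack.per_category[cat]) for cat in CATEGORIES}
    if np.isfinite(mean_chi) and mean_chi > 0:
        pct = {cat: cat_means[cat] / mean_chi for cat in CATEGORIES}
    else:
        pct = {cat: float("nan") for cat in CATEGORIES}
    d_total = _mean(delta_total) if delta_total is not None else float("nan")
    d_cat = (
        {cat: _mean(delta_cat[cat]) for cat in CATEGORIES} if delta_cat else {}
    )
    n_cells = int(np.sum(mask & np.isfinite(stack.total)))
    return mean_chi, cat_means, pct, d_total, d_cat, n_cells


def summarize_bcus(
    portions: Iterable[Zone],
    stack: ImpactStack,
    grid: Grid,
    delta_total: np.ndarray | None = None,
    delta_per_category: dict[str, np.ndarray] | None = None,
) -> list[ZoneImpactSummary]:
    """One summary per BCU, pooling cells across all of its country portions."""
    by_bcu: dict[int, np.ndarray] = {}
    for p in portions:
        if p.kind != "bcu_country_portion":
            raise ValueError(f"expected bcu_country_portion zones, got {p.kind!r}")
        mask = zone_cell_mask(grid, p.geometry)
        by_bcu[p.bcuid] = by_bcu.get(p.bcuid, np.zeros(grid.shape, bool)) | mask

    out = []
    for bcuid in sorted(by_bcu):
        mean_chi, cat_means, pct, d_total, d_cat, n = _masked_stats(
            by_bcu[bcuid], stack, delta_total, delta_per_category
        )
        out.append(
            ZoneImpactSummary(
                zone_id=f"bcu-{bcuid}", kind="bcu", bcuid=bcuid,
                mean_chi=mean_chi, mean_per_category=cat_means,
                pct_contribution=pct, delta_chi=d_total,
                delta_per_category=d_cat, n_cells=n,
            )
        )
    return out


def summarize_countries(
    portions: Iterable[Zone],
    stack: ImpactStack,
    grid: Grid,
    delta_total: np.ndarray | None = None,
    delta_per_category: dict[str, np.ndarray] | None = None,
    mode: str = "mean_of_portions",
) -> list[ZoneImpactSummary]:
    """One summary per country from its BCU portions.

    ``mode="mean_of_portions"`` (default) averages the portion-level means
    with equal weight; ``mode="pooled"`` pools every cell of the country's
    portions before averaging. Countries whose portions capture no usable
    cells are excluded with a warning.
    """
    if mode not in ("mean_of_portions", "pooled"):
        raise ValueError(f"unknown country aggregation mode {mode!r}")
    by_country: dict[str, list[Zone]] = {}
    for p in portions:
        if p.kind != "bcu_country_portion":
            raise ValueError(f"expected bcu_country_portion zones, got {p.kind!r}")
        by_country.setdefault(p.country, []).append(p)

    out = []
    for country in sorted(by_country):
        zones = by_country[country]
        if mode == "pooled":
            mask = np.zeros(grid.shape, bool)
            for z in zones:
                mask |= zone_cell_mask(grid, z.geometry)
            mean_chi, cat_means, pct, d_total, d_cat, n = _masked_stats(
                mask, stack, delta_total, delta_per_category
            )
        else:
            per_portion = []
            n = 0
            for z in zones:
                mask = zone_cell_mask(grid, z.geometry)
                stats = _masked_stats(mask, stack, delta_total, delta_per_category)
                if np.isfinite(stats[0]):
                    per_portion.append(stats)
                    n += stats[5]
            if not per_portion:
                logger.warning(
                    "summarize_countries: %s has no usable portions; excluded", country
                )
                continue
            mean_chi = float(np.mean([s[0] for s in per_portion]))
            cat_means = {
                cat: float(np.mean([s[1][cat] for s in per_portion]))
                for cat in CATEGORIES
            }
            pct = (
                {cat: cat_means[cat] / mean_chi for cat in CATEGORIES}
                if mean_chi > 0
                else {cat: float("nan") for cat in CATEGORIES}
            )
            d_total = (
                float(np.nanmean([s[3] for s in per_portion]))
                if delta_total is not None
                else float("nan")
            )
            d_cat = (
                {
                    cat: float(np.nanmean([s[4][cat] for s in per_portion]))
                    for cat in CATEGORIES
                }
                if delta_per_category
                else {}
            )
        if not np.isfinite(mean_chi):
            logger.warning(
                "summarize_countries: %s has no usable cells; excluded", country
            )
            continue
        out.append(
            ZoneImpactSummary(
                zone_id=f"country-{country}", kind="country_union", country=country,
                mean_chi=mean_chi, mean_per_category=cat_means,
                pct_contribution=pct, delta_chi=d_total,
                delta_per_category=d_cat, n_cells=n,
            )
        )
    return out


class MembershipCounts(NamedTuple):
    n_countries: int
    n_bcus: int
    bcus_per_country: dict[str, int]
    countries_per_bcu_hist: dict[int, int]


def membership_counts(table: pd.DataFrame, country_col: str = "country") -> MembershipCounts:
    """Exact counts from a (country, bcuid) membership table.

    The histogram maps the number of member countries (1, 2, 3, ...) to how
    many BCUs have that count. Duplicate rows indicate a corrupted table and
    raise.
    """
    if table.empty:
        raise ValueError("membership table is empty")
    pairs = table[[country_col, "bcuid"]]
    if pairs.duplicated().any():
        dups = pairs[pairs.duplicated()].to_dict("records")
        raise ValueError(f"duplicate membership rows: {dups}")
    per_bcu = pairs.groupby("bcuid")[country_col].nunique()
    hist = dict(sorted(Counter(per_bcu.to_numpy()).items()))
    return MembershipCounts(
        n_countries=int(pairs[country_col].nunique()),
        n_bcus=int(pairs["bcuid"].nunique()),
        bcus_per_country=pairs.groupby(country_col)["bcuid"].nunique().to_dict(),
        countries_per_bcu_hist=hist,
    )


def summaries_to_frame(summaries: Iterable[ZoneImpactSummary]) -> pd.DataFrame:
    """Tidy one-row-per-zone table of the summary statistics."""
    rows = []
    for s in summaries:
        row = {
            "zone_id": s.zone_id,
            "kind": s.kind,
            "bcuid": s.bcuid,
            "country": s.country,
            "n_cells": s.n_cells,
            "mean_chi": s.mean_chi,
            "delta_chi": s.delta_chi,
        }
        for cat in CATEGORIES:
            row[f"mean_{cat}"] = s.mean_per_category.get(cat, np.nan)
            row[f"pct_{cat}"] = s.pct_contribution.get(cat, np.nan)
            row[f"delta_{cat}"] = s.delta_per_category.get(cat, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
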