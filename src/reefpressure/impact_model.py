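"""Cumulative human impact (CHI) from stressor intensities and habitat vulnerability.

The cumulative-impact model scores every raster cell by combining, for each
anthropogenic stressor, the stressor's rescaled intensity with the
vulnerability of the habitats present in that cell:

    impact_s(cell) = intensity_s(cell) * A_h[ presence_h(cell) * mu(h, s) ]

where ``mu(h, s) >= 0`` is the vulnerability weight of habitat ``h`` to
stressor ``s`` and ``A_h`` aggregates over habitats — by default the mean over
habitats present in the cell (``habitat_agg="mean"``), with plain summation
available as ``habitat_agg="sum"``. Cells with no habitat score 0. Total CHI
is the sum of per-stressor impacts, and each stressor belongs to exactly one
source category (climate, land or marine), so CHI partitions exactly into
three category layers.

Change in CHI between two periods is computed only over stressors whose data
are comparable across both periods; excluded layers contribute exactly zero to
the change. For the change analysis, intensities must be rescaled jointly over
both periods (one shared clip value), whereas a single-snapshot analysis
rescales within-period.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CATEGORIES = ("climate", "land", "marine")

__all__ = [
    "CATEGORIES",
    "StressorLayer",
    "HabitatLayer",
    "VulnerabilityMatrix",
    "ImpactStack",
    "rescale_stressor",
    "compute_impact",
    "change_in_impact",
]


@dataclass
class StressorLayer:
    """One stressor's rescaled intensity raster for one period.

    ``intensity`` holds values in [0, 1]; NaN marks missing cells.
    ``change_eligible`` is False for stressors lacking comparable data across
    both periods, which excludes them from the change-in-impact analysis.
    """

    name: str
    category: str
    period: int
    intensity: np.ndarray
    change_eligible: bool = True

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"stressor {self.name!r}: category {self.category!r} not one of {CATEGORIES}"
            )
        vals = self.intensity[np.isfinite(self.intensity)]
        if vals.size and (vals.min() < -1e-12 or vals.max() > 1 + 1e-12):
            raise ValueError(f"stressor {self.name!r}: intensities outside [0, 1]")


@dataclass
class HabitatLayer:
    """Binary presence raster for one habitat type."""

    name: str
    presence: np.ndarray

    def __post_init__(self) -> None:
        vals = np.unique(self.presence[np.isfinite(self.presence)])
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"habitat {self.name!r}: presence raster is not binary")


class VulnerabilityMatrix:
    """Nonnegative habitat x stressor vulnerability weights mu.

    Backed by a DataFrame with habitats as rows and stressors as columns;
    lookups must be complete over every (habitat, stressor) pair used.
    """

    def __init__(self, mu: pd.DataFrame):
        if (mu.to_numpy() < 0).any():
            raise ValueError("vulnerability weights must be nonnegative")
        self.mu = mu.astype(float)

    @property
    def habitats(self) -> list[str]:
        return list(self.mu.index)

    @property
    def stressors(self) -> list[str]:
        return list(self.mu.columns)

    def weight(self, habitat: str, stressor: str) -> float:
        try:
            return float(self.mu.at[habitat, stressor])
        except KeyError:
            raise KeyError(f"no vulnerability weight for ({habitat!r}, {stressor!r})")

    def submatrix(self, habitats: list[str], stressors: list[str]) -> np.ndarray:
        missing = [h for h in habitats if h not in self.mu.index]
        missing += [s for s in stressors if s not in self.mu.columns]
        if missing:
            raise KeyError(f"vulnerability matrix missing entries for: {missing}")
        return self.mu.loc[habitats, stressors].to_numpy()

    @classmethod
    def from_csv(cls, path) -> "VulnerabilityMatrix":
        return cls(pd.read_csv(path, index_col=0))

    def to_csv(self, path) -> None:
        self.mu.to_csv(path)


@dataclass
class ImpactStack:
    """Per-stressor, per-category and total impact rasters for one period.

    Invariants: at every cell the category rasters sum to ``total`` and each
    category raster is the sum of its member per-stressor rasters.
    """

    total: np.ndarray
    per_category: dict[str, np.ndarray]
    per_stressor: dict[str, np.ndarray]
    stressor_category: dict[str, str] = field(default_factory=dict)


def rescale_stressor(
    raw: np.ndarray,
    clip_quantile: float = 0.9999,
    joint: list[np.ndarray] | None = None,
) -> np.ndarray:
    """Rescale a raw stressor raster to [0, 1].

    Values are log(x+1)-transformed, clipped at the ``clip_quantile`` quantile
    of the transformed values, and divided by that clip value. If ``joint`` is
    given (a list of rasters, e.g. the same stressor in both periods), the
    clip value is computed over the pooled transformed values of all of them —
    the mode required for a two-period change analysis; otherwise it is
    computed within the single raster.

    A zero clip value (e.g. an all-zero raster) yields an all-zero output with
    a logged warning. An all-missing raster is an error.
    """
    if not 0 < clip_quantile <= 1:
        raise ValueError("clip_quantile must be in (0, 1]")
    raw = np.asarray(raw, dtype=float)
    if not np.isfinite(raw).any():
        raise ValueError("cannot rescale an all-missing raster")
    if np.nanmin(raw) < 0:
        raise ValueError("raw stressor values must be nonnegative")
    transformed = np.log1p(raw)
    pool = [transformed] if joint is None else [np.log1p(np.asarray(r, float)) for r in joint]
    pooled = np.concatenate([p[np.isfinite(p)].ravel() for p in pool])
    if pooled.size == 0:
        raise ValueError("cannot rescale: joint pool is all-missing")
    clip_val = float(np.quantile(pooled, clip_quantile))
    if clip_val == 0.0:
        logger.warning("rescale_stressor: clip value is 0; returning all-zero raster")
        out = np.zeros_like(transformed)
        out[~np.isfinite(raw)] = np.nan
        return out
    return np.minimum(transformed, clip_val) / clip_val


def _habitat_weight_field(
    habitats: list[HabitatLayer],
    vuln: VulnerabilityMatrix,
    stressor_names: list[str],
    habitat_agg: str,
) -> np.ndarray:
    """Per-cell habitat-aggregated vulnerability, shape (n_stressors, rows, cols)."""
    presence = np.stack([np.nan_to_num(h.presence, nan=0.0) for h in habitats])
    mu = vuln.submatrix([h.name for h in habitats], stressor_names)  # (H, S)
    # weighted sum over habitats present in each cell
    weighted = np.einsum("hrc,hs->src", presence, mu)
    if habitat_agg == "mean":
        n_present = presence.sum(axis=0)
        weighted = weighted / np.maximum(1.0, n_present)
    elif habitat_agg != "sum":
        raise ValueError(f"habitat_agg must be 'mean' or 'sum', got {habitat_agg!r}")
    return weighted


def compute_impact(
    stressors: list[StressorLayer],
    habitats: list[HabitatLayer],
    vuln: VulnerabilityMatrix,
    habitat_agg: str = "mean",
) -> ImpactStack:
    """Build the full impact stack from stressor, habitat and vulnerability data.

    Per-stressor impact at a cell is the stressor intensity times the
    habitat-aggregated vulnerability (see module docstring). Missing intensity
    cells contribute 0 to sums unless *every* stressor is missing there, in
    which case the cell is missing in the totals; missing-cell counts are
    logged.
    """
    if not stressors:
        raise ValueError("no stressor layers given")
    shapes = {s.intensity.shape for s in stressors} | {h.presence.shape for h in habitats}
    if len(shapes) > 1:
        for layer in [*stressors, *habitats]:
            arr = layer.intensity if isinstance(layer, StressorLayer) else layer.presence
            if arr.shape != stressors[0].intensity.shape:
                raise ValueError(
                    f"layer {layer.name!r} grid {arr.shape} does not match "
                    f"{stressors[0].intensity.shape}"
                )
    names = [s.name for s in stressors]
    if len(set(names)) != len(names):
        raise ValueError("duplicate stressor names")

    weights = _habitat_weight_field(habitats, vuln, names, habitat_agg)

    per_stressor: dict[str, np.ndarray] = {}
    all_missing = np.ones(stressors[0].intensity.shape, dtype=bool)
    n_missing_cells = 0
    for i, s in enumerate(stressors):
        missing = ~np.isfinite(s.intensity)
        n_missing_cells += int(missing.sum())
        all_missing &= missing
        intensity = np.nan_to_num(s.intensity, nan=0.0)
        per_stressor[s.name] = intensity * weights[i]
    if n_missing_cells:
        logger.info("compute_impact: %d missing stressor cells treated as 0", n_missing_cells)

    per_category = {
        cat: np.sum(
            [per_stressor[s.name] for s in stressors if s.category == cat] or
            [np.zeros_like(all_missing, dtype=float)],
            axis=0,
        )
        for cat in CATEGORIES
    }
    total = sum(per_category.values())
    if all_missing.any():
        total = total.copy()
        total[all_missing] = np.nan
        for cat in per_category:
            per_category[cat][all_missing] = np.nan
    return ImpactStack(
        total=total,
        per_category=per_category,
        per_stressor=per_stressor,
        stressor_category={s.name: s.category for s in stressors},
    )


def change_in_impact(
    stack_2008: ImpactStack,
    stack_2013: ImpactStack,
    eligibility: dict[str, bool],
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Change in CHI between two periods over change-eligible stressors only.

    Returns ``(delta_total, delta_per_category)`` where each raster is the sum
    over eligible stressors of (impact_2013 - impact_2008). Ineligible
    stressors contribute exactly zero. Both stacks must cover the same
    stressor set and should have been built from jointly rescaled intensities.
    """
    names = list(stack_2008.per_stressor)
    if set(names) != set(stack_2013.per_stressor):
        raise ValueError("the two impact stacks cover different stressor sets")
    missing_flags = [n for n in names if n not in eligibility]
    if missing_flags:
        raise ValueError(f"missing change-eligibility flag for: {missing_flags}")

    shape = stack_2008.total.shape
    delta_cat = {cat: np.zeros(shape) for cat in CATEGORIES}
    for name in names:
        if not eligibility[name]:
            continue
        d = stack_2013.per_stressor[name] - stack_2008.per_stressor[name]
        delta_cat[stack_2008.stressor_category[name]] += d
    delta_total = sum(delta_cat.values())
    return delta_total, delta_cat
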