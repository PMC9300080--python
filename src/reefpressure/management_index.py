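"""Per-country management indices from raw policy/management metric tables.

Each impact category (climate, marine, land) gets a composite index per
country: every component metric X is min-max normalized across the analyzed
country set, (X - Xmin) / (Xmax - Xmin), inverted for metrics where lower raw
values indicate better management; countries missing a metric receive the mean
normalized score of the other countries in their UN-style geopolitical region
(falling back to the global mean when the whole region is missing); the index
is the equal-weight arithmetic mean of the completed component scores.
Component pairs are screened for collinearity with Pearson correlation, but no
component is ever dropped — equal weighting is retained regardless.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ManagementIndex",
    "normalize_metric",
    "impute_regional",
    "compute_index",
    "collinearity_check",
    "build_category_index",
]

REQUIRED_COLUMNS = ("country", "category", "metric", "raw_value", "direction", "region")


@dataclass
class ManagementIndex:
    """Composite score per (country, category) with component provenance."""

    country: str
    category: str
    score: float
    components: dict[str, float]
    imputed: dict[str, bool]


def normalize_metric(values: pd.Series, direction: str = "higher_better") -> pd.Series:
    """Directional min-max normalization of one metric across countries.

    Missing values stay missing. When every observed value is identical the
    spread is degenerate; all observed scores are set to 0.5 with a warning.
    """
    if direction not in ("higher_better", "lower_better"):
        raise ValueError(f"unknown direction {direction!r}")
    v = values.astype(float)
    observed = v.dropna()
    if len(observed) < 2:
        raise ValueError("normalize_metric needs >= 2 observed values")
    xmin, xmax = observed.min(), observed.max()
    if xmax == xmin:
        logger.warning("normalize_metric: degenerate spread (Xmax == Xmin); scores = 0.5")
        out = v.copy()
        out[v.notna()] = 0.5
        return out
    score = (v - xmin) / (xmax - xmin)
    if direction == "lower_better":
        score = 1.0 - score
    return score


def impute_regional(
    scores: pd.Series, regions: pd.Series
) -> tuple[pd.Series, pd.Series]:
    """Fill missing normalized scores from regional means.

    Returns (completed scores, boolean imputed flags). A missing score takes
    the mean observed score of countries in the same region; an entirely
    unobserved region takes the global observed mean. All-missing metrics are
    unusable and raise.
    """
    scores = scores.astype(float)
    regions = regions.reindex(scores.index)
    if regions.isna().any():
        raise ValueError("every country needs a region label")
    if scores.isna().all():
        raise ValueError("metric has no observed values in any country")
    flags = scores.isna()
    global_mean = scores.mean()
    regional_means = scores.groupby(regions).mean()
    out = scores.copy()
    for country in scores.index[flags]:
        fill = regional_means.get(regions[country])
        if pd.isna(fill):
            fill = global_mean
            logger.info(
                "impute_regional: region %r has no observed values for %s; "
                "using the global mean", regions[country], country,
            )
        out[country] = fill
    return out, flags


def compute_index(components: pd.DataFrame) -> pd.Series:
    """Equal-weight mean of completed component scores, per country (rows)."""
    if components.shape[1] == 0:
        raise ValueError("no components in category")
    if components.isna().any().any():
        raise ValueError("components must be complete after imputation")
    return components.mean(axis=1)


def collinearity_check(components: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise Pearson screen of a category's components.

    Returns one row per component pair with r, R^2 and the two-sided p-value
    of the usual t test on r (n - 2 df); pairs with p < alpha are flagged.
    Constant components yield undefined correlations, reported as NaN and
    unflagged. Nothing is dropped.
    """
    cols = list(components.columns)
    rows = []
    for a, b in combinations(cols, 2):
        pair = components[[a, b]].dropna()
        if len(pair) < 3:
            raise ValueError(f"collinearity_check: fewer than 3 complete pairs for ({a}, {b})")
        xa, xb = pair[a].to_numpy(), pair[b].to_numpy()
        if np.ptp(xa) == 0 or np.ptp(xb) == 0:
            rows.append(
                {"component_a": a, "component_b": b, "n": len(pair),
                 "r": np.nan, "r_squared": np.nan, "p_value": np.nan,
                 "flagged": False, "note": "constant component"}
            )
            continue
        r, p = stats.pearsonr(xa, xb)
        rows.append(
            {"component_a": a, "component_b": b, "n": len(pair),
             "r": r, "r_squared": r * r, "p_value": p,
             "flagged": bool(p < alpha), "note": ""}
        )
    return pd.DataFrame(rows)


def build_category_index(
    table: pd.DataFrame, category: str
) -> tuple[list[ManagementIndex], pd.DataFrame, pd.DataFrame]:
    """Full index construction for one category from the long metric table.

    Returns (indices, completed component matrix, collinearity report). The
    component matrix has countries as rows and metrics as columns.
    """
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValueError(f"metric table missing columns: {missing_cols}")
    sub = table[table["category"] == category]
    if sub.empty:
        raise ValueError(f"no metrics for category {category!r}")
    if sub.duplicated(["country", "metric"]).any():
        raise ValueError("duplicate (country, metric) rows")

    countries = sorted(sub["country"].unique())
    regions = (
        sub.drop_duplicates("country").set_index("country")["region"].reindex(countries)
    )
    completed = {}
    flags = {}
    for metric, grp in sub.groupby("metric"):
        raw = grp.set_index("country")["raw_value"].reindex(countries)
        direction = grp["direction"].iloc[0]
        scores = normalize_metric(raw, direction)
        completed[metric], flags[metric] = impute_regional(scores, regions)
        n_imp = int(flags[metric].sum())
        if n_imp:
            logger.info(
                "build_category_index: %s/%s imputed for %d countries: %s",
                category, metric, n_imp,
                ", ".join(flags[metric].index[flags[metric]]),
            )
    components = pd.DataFrame(completed, index=pd.Index(countries, name="country"))
    flag_df = pd.DataFrame(flags, index=components.index)
    scores = compute_index(components)
    report = collinearity_check(components)
    indices = [
        ManagementIndex(
            country=c, category=category, score=float(scores[c]),
            components=components.loc[c].to_dict(),
            imputed=flag_df.loc[c].to_dict(),
        )
        for c in countries
    ]
    return indices, components, report
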