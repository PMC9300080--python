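"""Impact-versus-management association: OLS fits, quadrants, outlier refits.

Per-country mean impacts (or mean changes in impact) are regressed on the
corresponding management index with ordinary least squares. The headline
goodness-of-fit statistic is *adjusted* R^2, which can be negative for fits
worse than the intercept-only model; raw R^2 is also reported. Countries (or
BCUs) are additionally classified into quadrants around the across-unit
medians of two axes, with values equal to the median counted as "high".
Sensitivity refits drop outliers — either by 1.5 x IQR fences on either
variable or by an explicit named-unit exclusion list — and refit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "RegressionResult",
    "QuadrantLabel",
    "fit_index_regression",
    "classify_quadrants",
    "iqr_outliers",
    "sensitivity_refit",
]


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    r_squared_adj: float
    p_value: float  # two-sided test on the slope
    n: int
    outliers_removed: list[str] = field(default_factory=list)


@dataclass
class QuadrantLabel:
    unit_id: str
    x_axis: str
    y_axis: str
    quadrant: str  # high_x_high_y | high_x_low_y | low_x_high_y | low_x_low_y


def _aligned(x: pd.Series, y: pd.Series) -> pd.DataFrame:
    df = pd.DataFrame({"x": x, "y": y}).dropna()
    return df


def fit_index_regression(x: pd.Series, y: pd.Series) -> RegressionResult:
    """OLS of per-country impact (y) on the management index (x)."""
    df = _aligned(x, y)
    if len(df) < 3:
        raise ValueError("need at least 3 complete (x, y) pairs")
    if np.ptp(df["x"].to_numpy()) == 0:
        raise ValueError("zero variance in x")
    X = sm.add_constant(df["x"].to_numpy())
    fit = sm.OLS(df["y"].to_numpy(), X).fit()
    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        r_squared_adj=float(fit.rsquared_adj),
        p_value=float(fit.pvalues[1]),
        n=len(df),
    )


def classify_quadrants(
    units: Sequence[str], x: pd.Series, y: pd.Series,
    x_axis: str = "x", y_axis: str = "y",
) -> tuple[list[QuadrantLabel], dict[str, int]]:
    """Median-split both axes; ties at the median classify as high."""
    units = list(units)
    if len(units) < 2:
        raise ValueError("need at least 2 units")
    xv = x.reindex(units)
    yv = y.reindex(units)
    if xv.isna().any() or yv.isna().any():
        raise ValueError("x and y must be complete over the unit set")
    x_med = float(np.median(xv.to_numpy()))
    y_med = float(np.median(yv.to_numpy()))
    labels = []
    counts = {
        "high_x_high_y": 0, "high_x_low_y": 0,
        "low_x_high_y": 0, "low_x_low_y": 0,
    }
    for u in units:
        hx = "high" if xv[u] >= x_med else "low"
        hy = "high" if yv[u] >= y_med else "low"
        q = f"{hx}_x_{hy}_y"
        counts[q] += 1
        labels.append(QuadrantLabel(unit_id=u, x_axis=x_axis, y_axis=y_axis, quadrant=q))
    return labels, counts


def iqr_outliers(x: pd.Series, y: pd.Series, k: float = 1.5) -> list[str]:
    """Units beyond k x IQR fences on either variable."""
    df = _aligned(x, y)
    out: set[str] = set()
    for col in ("x", "y"):
        v = df[col]
        q1, q3 = v.quantile(0.25), v.quantile(0.75)
        iqr = q3 - q1
        lo, hi = q1 - k * iqr, q3 + k * iqr
        out |= set(df.index[(v < lo) | (v > hi)])
    return sorted(out)


def sensitivity_refit(
    x: pd.Series,
    y: pd.Series,
    rule: str = "iqr",
    k: float = 1.5,
    exclude: Iterable[str] | None = None,
) -> tuple[list[str], RegressionResult]:
    """Identify outliers, drop them and refit.

    ``rule="iqr"`` uses 1.5 x IQR fences on either variable (k configurable);
    ``rule="named"`` drops exactly the units in ``exclude``, replicating a
    reported sensitivity analysis whose outlier procedure is only given as a
    list of unit names.
    """
    df = _aligned(x, y)
    if len(df) < 5:
        raise ValueError("need at least 5 complete pairs for a sensitivity refit")
    if rule == "iqr":
        outliers = iqr_outliers(x, y, k=k)
    elif rule == "named":
        outliers = sorted(set(exclude or []) & set(df.index))
    else:
        raise ValueError(f"unknown outlier rule {rule!r}")
    kept = df.drop(index=outliers)
    if len(kept) < 3:
        raise ValueError("outlier rule leaves fewer than 3 points")
    result = fit_index_regression(kept["x"], kept["y"])
    result.outliers_removed = list(outliers)
    return list(outliers), result
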