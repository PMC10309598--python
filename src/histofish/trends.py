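"""Correlation/trend statistics and historical-comparison arithmetic.

Pearson correlations with two-sided t-test p-values and the least-squares
line tie the decadal indicators to corpus size (sampling-effort bias) and
time (trophic decline); percent-change and tonnage utilities reproduce the
arithmetic used when comparing newspaper records against official landing
reports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .aggregate import round_half_up
from .indicators import IndicatorSeries


class UndefinedCorrelationError(ValueError):
    """Raised when either series is constant (zero variance)."""


class InsufficientDataError(ValueError):
    """Raised when fewer than three complete pairs remain."""


class UndefinedBaselineError(ValueError):
    """Raised when a percent change is requested against a non-positive base."""


class InsufficientOverlapError(ValueError):
    """Raised when two decadal series share no decades."""


@dataclass(frozen=True)
class TrendResult:
    """Pearson r, R² = r², two-sided p (t-distribution, n−2 df) and the
    OLS line fitted on the same pairs."""

    r: float
    r_squared: float
    p_value: float
    slope: float
    intercept: float
    n_points: int

    def as_dict(self) -> dict:
        return {
            "r": self.r,
            "r_squared": self.r_squared,
            "p_value": self.p_value,
            "slope": self.slope,
            "intercept": self.intercept,
            "n_points": self.n_points,
        }


def _paired(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"series lengths differ: {x.shape} vs {y.shape}")
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


def pearson_trend(x, y) -> TrendResult:
    """Pearson correlation plus OLS line with pairwise missing deletion.

    Missing entries (NaN in either series) are removed pairwise — sparse
    early decades drop out rather than being imputed.  Requires ≥ 3
    complete pairs and non-constant series.
    """
    xv, yv = _paired(x, y)
    if xv.size < 3:
        raise InsufficientDataError(
            f"{xv.size} complete pairs; at least 3 required"
        )
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise UndefinedCorrelationError("constant series: correlation undefined")
    pr = stats.pearsonr(xv, yv)
    fit = stats.linregress(xv, yv)
    r = float(pr.statistic)
    return TrendResult(
        r=r,
        r_squared=r * r,
        p_value=float(pr.pvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n_points=int(xv.size),
    )


def series_trend(series: IndicatorSeries) -> TrendResult:
    """Trend of an indicator against its decade labels (missing dropped)."""
    s = series.as_series()
    return pearson_trend(s.index.to_numpy(dtype=float), s.to_numpy())


def percent_change(v0: float, v1: float) -> tuple[int, float]:
    """Percent change from ``v0`` to ``v1``: (half-up integer, raw value)."""
    if v0 <= 0:
        raise UndefinedBaselineError(f"baseline must be positive, got {v0}")
    if v1 < 0:
        raise ValueError(f"end value must be non-negative, got {v1}")
    raw = 100.0 * (v1 - v0) / v0
    return int(round_half_up(raw, 0)), raw


def tonnage_estimate(count: int, mean_weight_kg: float) -> float:
    """Total catch in tonnes from a head count and a mean weight in kg."""
    if count < 0:
        raise ValueError(f"count must be non-negative, got {count}")
    if not (mean_weight_kg > 0 and np.isfinite(mean_weight_kg)):
        raise ValueError(f"mean weight must be positive and finite, got {mean_weight_kg}")
    return count * mean_weight_kg / 1000.0


# -- landings comparison ----------------------------------------------


def landings_inv_fis(landings: pd.DataFrame) -> pd.Series:
    """Decadal invertebrate/fish tonnage ratio from a landings table.

    ``landings`` has columns (year, group ∈ {fish, invertebrate}, tonnes);
    tonnes are summed to decades before the ratio.  Decades with zero fish
    tonnage are missing.
    """
    required = {"year", "group", "tonnes"}
    if not required <= set(landings.columns):
        raise ValueError(f"landings table needs columns {sorted(required)}")
    bad = set(landings["group"].unique()) - {"fish", "invertebrate"}
    if bad:
        raise ValueError(f"unknown landings groups {sorted(bad)}")
    df = landings.assign(decade=(landings["year"] // 10) * 10)
    decadal = df.pivot_table(
        index="decade", columns="group", values="tonnes", aggfunc="sum", fill_value=0.0
    )
    for col in ("fish", "invertebrate"):
        if col not in decadal:
            decadal[col] = 0.0
    ratio = decadal["invertebrate"] / decadal["fish"].where(decadal["fish"] > 0)
    return ratio.rename("landings_inv_fis")


def compare_with_landings(
    indicator: IndicatorSeries, landings: pd.DataFrame
) -> tuple[pd.DataFrame, TrendResult | None]:
    """Align a newspaper Inv/Fis series with landings Inv/Fis by decade.

    Returns the decade-aligned table and, where ≥ 3 complete pairs exist,
    the Pearson trend between the two ratio series.  The correlation is
    exploratory: the two signals measure different things (media presence
    vs catch volume).
    """
    news = indicator.as_series().rename("newspaper_inv_fis")
    land = landings_inv_fis(landings)
    overlap = news.index.intersection(land.index)
    if len(overlap) == 0:
        raise InsufficientOverlapError(
            "newspaper and landings series share no decades"
        )
    table = pd.concat([news.loc[overlap], land.loc[overlap]], axis=1)
    table.index.name = "decade"
    trend: TrendResult | None
    try:
        trend = pearson_trend(
            table["newspaper_inv_fis"].to_numpy(), table["landings_inv_fis"].to_numpy()
        )
    except (InsufficientDataError, UndefinedCorrelationError):
        trend = None
    return table, trend


def read_landings_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["year"] = df["year"].astype(int)
    df["tonnes"] = df["tonnes"].astype(float)
    return df
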