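"""Downstream analyses of fitted flowering models.

Long-term trends of the estimated true dates (days per decade, via OLS
of the posterior median on calendar year), credible-interval coverage of
the observation record, and side-by-side comparison of fits driven by
two different weather stations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ObservationTable
from .model import StateSummary

__all__ = ["TrendFit", "fit_trend", "trend_over_draws", "coverage_fraction", "compare_stations"]


@dataclass(frozen=True)
class TrendFit:
    """OLS trend of a per-year quantity on calendar year.

    ``slope_days_per_decade`` is ten times the per-year slope; a negative
    slope means the date is advancing, and ``advance_days_per_decade``
    reports that advance as a positive magnitude (0 when the trend is
    toward later dates).
    """

    slope_days_per_decade: float
    advance_days_per_decade: float
    r_squared: float
    p_value: float
    n_years: int


def fit_trend(years, medians) -> TrendFit:
    """Ordinary least squares of per-year medians on year.

    Requires at least 3 distinct years.  The p-value is the standard
    two-sided t test on the slope.
    """
    years = np.asarray(years, dtype=float)
    medians = np.asarray(medians, dtype=float)
    if years.shape != medians.shape or years.ndim != 1:
        raise ValueError("years and medians must be 1-D and equally long")
    keep = ~np.isnan(medians)
    years, medians = years[keep], medians[keep]
    if len(years) < 3:
        raise ValueError("need at least 3 (year, median) pairs")
    if len(np.unique(years)) != len(years):
        raise ValueError("years must be distinct")
    if np.ptp(years) == 0:
        raise ValueError("zero variance in years")
    if np.ptp(medians) == 0:  # perfectly flat: slope 0, nothing explained
        return TrendFit(0.0, 0.0, 0.0, 1.0, int(len(years)))
    res = stats.linregress(years, medians)
    slope10 = 10.0 * res.slope
    return TrendFit(
        slope_days_per_decade=float(slope10),
        advance_days_per_decade=float(-slope10) if slope10 < 0 else 0.0,
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue) if not np.isnan(res.pvalue) else 1.0,
        n_years=int(len(years)),
    )


def trend_over_draws(draws) -> pd.DataFrame:
    """Posterior distribution of the trend slope, one OLS fit per draw.

    An extension beyond the point-estimate trend: propagates state
    uncertainty into the slope.  Returns quantiles of the slope in
    days/decade.
    """
    years = np.asarray(draws.years, dtype=float)
    flat = draws.alpha.reshape(-1, len(years))
    yc = years - years.mean()
    slopes = 10.0 * (flat @ yc) / (yc @ yc)
    qs = np.quantile(slopes, [0.025, 0.25, 0.5, 0.75, 0.975])
    return pd.DataFrame(
        {"quantile": [0.025, 0.25, 0.5, 0.75, 0.975], "slope_days_per_decade": qs}
    )


def coverage_fraction(observations: ObservationTable, summary: StateSummary) -> float:
    """Fraction of observed (year, doy) records inside the 95% interval of alpha."""
    alpha = summary.quantity("alpha")
    sub = observations.frame[observations.frame["phenophase"] == summary.phenophase]
    sub = sub[sub["year"].isin(alpha.index)]
    if sub.empty:
        raise ValueError("no observations overlap the summarized years")
    lo = alpha.loc[sub["year"], "lo95"].to_numpy()
    hi = alpha.loc[sub["year"], "hi95"].to_numpy()
    doy = sub["doy"].to_numpy(dtype=float)
    return float(np.mean((doy >= lo) & (doy <= hi)))


def compare_stations(summary_a: StateSummary, summary_b: StateSummary):
    """Contrast two fits of the same phenophase driven by different stations.

    Returns ``(per_year, coefficients)``: per overlapping year the
    difference of alpha medians (a minus b), and per coefficient the
    difference of pooled medians.  With predictors differing only by an
    additive offset, alpha deltas should sit near zero while the
    intercept delta absorbs the offset.
    """
    a = summary_a.quantity("alpha")
    b = summary_b.quantity("alpha")
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError("summaries share no years")
    per_year = pd.DataFrame(
        {
            "year": common.to_numpy(),
            "alpha_median_a": a.loc[common, "median"].to_numpy(),
            "alpha_median_b": b.loc[common, "median"].to_numpy(),
        }
    )
    per_year["delta"] = per_year["alpha_median_a"] - per_year["alpha_median_b"]

    ca = summary_a.coefficients.set_index("quantity")
    cb = summary_b.coefficients.set_index("quantity")
    names = ca.index.intersection(cb.index)
    coefficients = pd.DataFrame(
        {
            "quantity": names.to_numpy(),
            "pooled_median_a": ca.loc[names, "pooled_median"].to_numpy(),
            "pooled_median_b": cb.loc[names, "pooled_median"].to_numpy(),
        }
    )
    coefficients["delta"] = (
        coefficients["pooled_median_a"] - coefficients["pooled_median_b"]
    )
    return per_year, coefficients
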