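"""Per-year temperature predictors and calendar utilities.

Three windowed averages of daily station temperatures drive the flowering
models, one per physiological stage of bud development:

* ``ex1`` — mean daily *minimum* temperature from 1 December of the
  previous calendar year to 28/29 February (90 or 91 days): winter chilling
  that releases flower-bud endodormancy.
* ``ex2`` — mean daily *mean* temperature over 1-31 March: early-spring
  heat forcing bud growth.
* ``ex3`` — mean daily *mean* temperature over 1-10 April: heat forcing
  the final stages of flowering and leaf-out.

A predictor for year ``t`` never reads a date outside
[1 Dec ``t-1``, 10 Apr ``t``].
"""

from __future__ import annotations

import calendar
import datetime as _dt

import numpy as np
import pandas as pd

from .io import DailyTemperatureSeries

__all__ = [
    "WINDOWS",
    "date_to_doy",
    "doy_to_date",
    "window_day_count",
    "window_dates",
    "compute_predictors",
]

#: window label -> (predictor column, temperature field)
WINDOWS = {
    "winter": ("ex1", "tmin_c"),
    "march": ("ex2", "tmean_c"),
    "april10": ("ex3", "tmean_c"),
}

#: Fraction of days in a window allowed to be missing before the
#: predictor itself is marked missing.
DEFAULT_MISSING_TOLERANCE = 0.10


def date_to_doy(date) -> int:
    """1-based ordinal day of year (1 Jan = 1)."""
    d = pd.Timestamp(date)
    return int(d.dayofyear)


def doy_to_date(year: int, doy: int) -> _dt.date:
    """Inverse of :func:`date_to_doy`; validates the DOY range for ``year``."""
    n_days = 366 if calendar.isleap(year) else 365
    if not 1 <= doy <= n_days:
        raise ValueError(f"doy {doy} out of range for year {year} (1..{n_days})")
    return _dt.date(year, 1, 1) + _dt.timedelta(days=doy - 1)


def window_day_count(year: int, window: str) -> int:
    """Number of calendar days in a predictor window for ``year``.

    ``winter`` is 90 days, or 91 when February of ``year`` has 29 days;
    ``march`` is 31; ``april10`` is 10.
    """
    if window == "winter":
        return 91 if calendar.isleap(year) else 90
    if window == "march":
        return 31
    if window == "april10":
        return 10
    raise ValueError(f"unknown window {window!r}")


def window_dates(year: int, window: str) -> pd.DatetimeIndex:
    """Calendar dates of a predictor window.  Winter spans Dec(year-1)..Feb(year)."""
    if window == "winter":
        end_day = 29 if calendar.isleap(year) else 28
        return pd.date_range(f"{year - 1}-12-01", f"{year}-02-{end_day:02d}", freq="D")
    if window == "march":
        return pd.date_range(f"{year}-03-01", f"{year}-03-31", freq="D")
    if window == "april10":
        return pd.date_range(f"{year}-04-01", f"{year}-04-10", freq="D")
    raise ValueError(f"unknown window {window!r}")


def compute_predictors(
    series: DailyTemperatureSeries,
    years,
    missing_policy=None,
) -> pd.DataFrame:
    """Compute the per-year predictor table ``year,ex1,ex2,ex3``.

    Each predictor is the arithmetic mean of the daily values present in
    its window.  Days absent from the series count as missing; when the
    missing fraction exceeds the window's tolerance (``missing_policy``
    maps window label to a fraction, default 10% everywhere) the predictor
    is NaN for that year.  Years entirely outside the series simply get
    NaN predictors — that is expected at the edges of station coverage,
    not an error.
    """
    years = _year_range(years)
    policy = {w: DEFAULT_MISSING_TOLERANCE for w in WINDOWS}
    policy.update(missing_policy or {})
    unknown = set(policy) - set(WINDOWS)
    if unknown:
        raise ValueError(f"missing_policy has unknown window(s) {sorted(unknown)}")

    by_date = series.frame.set_index(pd.DatetimeIndex(series.frame["date"]))
    rows = []
    for year in years:
        row = {"year": int(year)}
        for window, (col, temp_field) in WINDOWS.items():
            dates = window_dates(int(year), window)
            vals = by_date[temp_field].reindex(dates).to_numpy(dtype=float)
            n_missing = int(np.isnan(vals).sum())
            if n_missing / len(dates) > policy[window] + 1e-12:
                row[col] = np.nan
            else:
                row[col] = float(np.nanmean(vals)) if n_missing < len(dates) else np.nan
        rows.append(row)
    return pd.DataFrame(rows, columns=["year", "ex1", "ex2", "ex3"])


def _year_range(years) -> np.ndarray:
    # a 2-tuple is an inclusive (first, last) range; anything else iterable
    # is an explicit list of years
    if isinstance(years, tuple) and len(years) == 2 and np.isscalar(years[0]):
        first, last = int(years[0]), int(years[1])
        if last < first:
            raise ValueError(f"inverted year range {first}..{last}")
        return np.arange(first, last + 1)
    arr = np.asarray(list(years), dtype=int)
    if arr.size == 0:
        raise ValueError("empty year range")
    return arr
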