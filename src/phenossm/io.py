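"""Readers and writers for the tabular formats the pipeline touches.

All formats are comma-separated UTF-8 with a mandatory header row and
ISO-8601 dates.  Readers validate strictly and never impute: a missing
temperature stays missing (NaN) until the predictor layer decides what to
do with it.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PHENOPHASES",
    "DEFAULT_SOURCE_PRECEDENCE",
    "DailyTemperatureSeries",
    "ObservationTable",
    "read_temperature_csv",
    "write_temperature_csv",
    "read_observations_csv",
    "write_observations_csv",
    "select_observations",
    "write_state_summary_csv",
    "read_state_summary_csv",
    "write_draws_csv",
    "read_draws_csv",
]

#: The four modelled flowering phenophases: first flowering, first full
#: bloom, last full bloom, last flowering.
PHENOPHASES = ("FFL", "FFB", "LFB", "LFL")

#: When several sources report a date for the same (year, phenophase),
#: the fitting layer keeps the highest-ranked source.  Website feeds are
#: treated as the primary observation stream; unlisted sources rank last.
DEFAULT_SOURCE_PRECEDENCE = ("website", "municipal", "private", "literature", "photograph")

_TEMP_BOUNDS = (-50.0, 50.0)


@dataclass(frozen=True)
class DailyTemperatureSeries:
    """Dated daily minimum/mean air temperatures for one station.

    ``frame`` has columns ``date`` (datetime64), ``tmin_c`` and
    ``tmean_c`` (float degC, NaN = missing).  Dates are strictly
    increasing with no duplicates; present temperatures lie in
    [-50, 50] degC.
    """

    station_id: str
    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        f = self.frame
        required = {"date", "tmin_c", "tmean_c"}
        missing = required - set(f.columns)
        if missing:
            raise ValueError(f"temperature frame missing columns: {sorted(missing)}")
        dates = pd.to_datetime(f["date"])
        if len(dates) > 1 and not dates.is_monotonic_increasing:
            raise ValueError("dates must be strictly increasing")
        if dates.duplicated().any():
            dup = dates[dates.duplicated()].iloc[0]
            raise ValueError(f"duplicate date {dup.date()}")
        for col in ("tmin_c", "tmean_c"):
            vals = pd.to_numeric(f[col], errors="raise")
            bad = vals[(vals < _TEMP_BOUNDS[0]) | (vals > _TEMP_BOUNDS[1])]
            if len(bad):
                raise ValueError(
                    f"{col} out of bounds {_TEMP_BOUNDS} at {dates.iloc[bad.index[0]].date()}: "
                    f"{bad.iloc[0]!r}"
                )

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class ObservationTable:
    """Observed phenophase dates: rows of (year, phenophase, doy, source).

    Multiple sources may report the same (year, phenophase); the table keeps
    them all and :func:`select_observations` resolves conflicts for fitting.
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        f = self.frame
        required = {"year", "phenophase", "doy", "source"}
        missing = required - set(f.columns)
        if missing:
            raise ValueError(f"observation frame missing columns: {sorted(missing)}")
        if f.empty:
            return
        bad_phase = set(f["phenophase"]) - set(PHENOPHASES)
        if bad_phase:
            raise ValueError(f"unknown phenophase label(s): {sorted(bad_phase)}")
        doy = f["doy"].to_numpy()
        years = f["year"].to_numpy()
        if ((doy < 1) | (doy > 366)).any():
            i = int(np.flatnonzero((doy < 1) | (doy > 366))[0])
            raise ValueError(f"doy out of [1, 366] in year {years[i]}: {doy[i]}")
        nonleap_366 = (doy == 366) & ~np.array([calendar.isleap(int(y)) for y in years])
        if nonleap_366.any():
            y = int(years[np.flatnonzero(nonleap_366)[0]])
            raise ValueError(f"doy 366 in non-leap year {y}")
        dup = f.duplicated(subset=["year", "phenophase", "source"])
        if dup.any():
            row = f[dup].iloc[0]
            raise ValueError(
                f"duplicate record for ({row['year']}, {row['phenophase']}, {row['source']})"
            )

    def __len__(self) -> int:
        return len(self.frame)


def read_temperature_csv(path, schema_options=None, station_id=None) -> DailyTemperatureSeries:
    """Read a daily temperature CSV into a validated series.

    Parameters
    ----------
    path
        CSV with a header row.  Default columns ``date,tmin_c,tmean_c``;
        blank cells are missing.
    schema_options
        Optional mapping from the logical names ``date``/``tmin``/``tmean``
        to the column names actually present in the file.
    station_id
        Label attached to the series; defaults to the file stem.
    """
    schema_options = dict(schema_options or {})
    cols = {
        "date": schema_options.get("date", "date"),
        "tmin": schema_options.get("tmin", "tmin_c"),
        "tmean": schema_options.get("tmean", "tmean_c"),
    }
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    for logical, name in cols.items():
        if name not in raw.columns:
            raise ValueError(f"column {name!r} (for {logical}) not found in {path}")
    dates = pd.to_datetime(raw[cols["date"]], format="%Y-%m-%d", errors="coerce")
    if dates.isna().any():
        i = int(dates.isna().idxmax())
        raise ValueError(
            f"malformed date {raw[cols['date']].iloc[i]!r} at row {i + 2} of {path}"
        )

    def _numeric(col: str) -> pd.Series:
        s = raw[col].str.strip().replace({"": None, "NA": None})
        return pd.to_numeric(s, errors="raise")

    frame = pd.DataFrame(
        {"date": dates, "tmin_c": _numeric(cols["tmin"]), "tmean_c": _numeric(cols["tmean"])}
    )
    sid = station_id if station_id is not None else _stem(path)
    return DailyTemperatureSeries(station_id=sid, frame=frame)


def write_temperature_csv(series: DailyTemperatureSeries, path) -> None:
    """Write ``date,tmin_c,tmean_c``, temperatures rounded to 0.1 degC."""
    out = series.frame.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    for col in ("tmin_c", "tmean_c"):
        out[col] = out[col].round(1)
    out.to_csv(path, index=False, float_format="%.1f")


def read_observations_csv(path) -> ObservationTable:
    """Read ``year,phenophase,doy,source`` rows; labels normalised to upper case."""
    raw = pd.read_csv(path)
    required = {"year", "phenophase", "doy", "source"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"observation file {path} missing columns {sorted(missing)}")
    frame = pd.DataFrame(
        {
            "year": raw["year"].astype(int),
            "phenophase": raw["phenophase"].astype(str).str.strip().str.upper(),
            "doy": raw["doy"].astype(int),
            "source": raw["source"].astype(str).str.strip(),
        }
    )
    return ObservationTable(frame=frame)


def write_observations_csv(table: ObservationTable, path) -> None:
    table.frame.to_csv(path, index=False)


def select_observations(
    table: ObservationTable,
    phenophase: str,
    precedence=DEFAULT_SOURCE_PRECEDENCE,
) -> pd.Series:
    """Resolve one observed DOY per year for a phenophase.

    When sources conflict within a year the highest-ranked source in
    ``precedence`` wins; sources not listed rank below all listed ones and
    tie-break alphabetically (deterministic).  Returns a Series indexed by
    year.
    """
    if phenophase not in PHENOPHASES:
        raise ValueError(f"unknown phenophase {phenophase!r}")
    sub = table.frame[table.frame["phenophase"] == phenophase]
    if sub.empty:
        return pd.Series(dtype=float, name="doy")
    rank = {src: i for i, src in enumerate(precedence)}
    n = len(precedence)
    sub = sub.assign(_rank=sub["source"].map(lambda s: rank.get(s, n)))
    sub = sub.sort_values(["year", "_rank", "source"], kind="stable")
    best = sub.groupby("year", sort=True).first()
    return best["doy"].astype(float).rename("doy")


_SUMMARY_QUANTITIES = ("alpha", "mu", "beta", "gamma")


def write_state_summary_csv(summary, path) -> None:
    """Serialize per-year posterior summaries: ``year,quantity,median,lo95,hi95``."""
    per_year = summary.per_year if hasattr(summary, "per_year") else summary
    if per_year is None or len(per_year) == 0:
        raise ValueError("refusing to write an empty state summary")
    out = per_year.loc[:, ["year", "quantity", "median", "lo95", "hi95"]].copy()
    bad = set(out["quantity"]) - set(_SUMMARY_QUANTITIES)
    if bad:
        raise ValueError(f"unknown summary quantity {sorted(bad)}")
    out.to_csv(path, index=False, float_format="%.6f")


def read_state_summary_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    required = {"year", "quantity", "median", "lo95", "hi95"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"summary file {path} missing columns {sorted(missing)}")
    bad = set(frame["quantity"]) - set(_SUMMARY_QUANTITIES)
    if bad:
        raise ValueError(f"unknown summary quantity {sorted(bad)}")
    return frame


def write_draws_csv(draws, path) -> None:
    """Write retained draws in long format: ``chain,iteration,parameter,value``.

    States are labelled ``<name>[<year>]`` (e.g. ``alpha[1989]``) and
    variance SDs by their name (e.g. ``sigma_phi``).
    """
    chunks = []
    n_chains, n_draws = draws.alpha.shape[:2]
    it = np.tile(np.arange(n_draws), n_chains)
    ch = np.repeat(np.arange(n_chains), n_draws)
    for j, name in enumerate(draws.coef_names):
        for k, year in enumerate(draws.years):
            chunks.append(
                pd.DataFrame(
                    {
                        "chain": ch,
                        "iteration": it,
                        "parameter": f"{name}[{year}]",
                        "value": draws.states[:, :, k, j].ravel(),
                    }
                )
            )
    for k, year in enumerate(draws.years):
        chunks.append(
            pd.DataFrame(
                {
                    "chain": ch,
                    "iteration": it,
                    "parameter": f"alpha[{year}]",
                    "value": draws.alpha[:, :, k].ravel(),
                }
            )
        )
    for j, name in enumerate(draws.sigma_names):
        chunks.append(
            pd.DataFrame(
                {"chain": ch, "iteration": it, "parameter": name, "value": draws.sigmas[:, :, j].ravel()}
            )
        )
    pd.concat(chunks, ignore_index=True).to_csv(path, index=False)


def read_draws_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    required = {"chain", "iteration", "parameter", "value"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"draws file {path} missing columns {sorted(missing)}")
    return frame


def _stem(path) -> str:
    import os

    return os.path.splitext(os.path.basename(str(path)))[0]
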