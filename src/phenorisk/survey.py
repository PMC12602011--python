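"""Survey ingestion, CPUE transformation and data screening.

The analysis scale is natural-log transformed catch per unit effort,
``ln(CPUE + 1)``, on a monthly grid per taxon and station. Screening
mirrors common monitoring-data practice: station series must carry a
minimum number of nonzero detections (group-specific thresholds), full
monthly series are split into 12 annual-scale month-specific series, and
each taxon-station-month stratum is kept only if the taxon was present
with some regularity (nonzero in a minimum fraction of surveyed years).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .synthetic import SURVEY_COLUMNS, VALID_GROUPS

__all__ = [
    "MonthSeries",
    "read_survey_table",
    "compute_cpue_series",
    "filter_by_detections",
    "split_months",
    "filter_month_strata",
    "write_series_csv",
    "read_series_csv",
    "DEFAULT_MIN_NONZERO_FISH",
    "DEFAULT_MIN_NONZERO_ZOOP",
    "DEFAULT_MIN_PRESENCE",
]

logger = logging.getLogger(__name__)

#: Minimum nonzero detections for a fish station series to be retained.
DEFAULT_MIN_NONZERO_FISH = 50
#: Minimum nonzero detections for a zooplankton station series.
DEFAULT_MIN_NONZERO_ZOOP = 234
#: Minimum fraction of surveyed years a month-stratum must be present in.
DEFAULT_MIN_PRESENCE = 0.30

#: Columns of the tidy (long) series table used between screening stages.
SERIES_COLUMNS = [
    "taxon",
    "station",
    "region",
    "group",
    "year",
    "month",
    "value",
    "observed",
]


@dataclass
class MonthSeries:
    """One taxon x station x calendar-month annual series.

    ``values[i]`` is ln(CPUE + 1) in ``years[i]``; ``observed[i]`` is False
    for years in which the station-month survey did not happen (the value
    there is NaN and must be ignored).
    """

    taxon: str
    station: str
    region: str
    group: str
    month: int
    years: np.ndarray
    values: np.ndarray
    observed: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        if not (len(self.years) == len(self.values) == len(self.observed)):
            raise ValueError("years, values and observed must have equal length")
        if not 1 <= self.month <= 12:
            raise ValueError(f"month must lie in 1..12, got {self.month}")
        obs_vals = self.values[self.observed]
        if not np.all(np.isfinite(obs_vals)):
            raise ValueError("observed values must be finite")
        if np.any(obs_vals < 0):
            raise ValueError("log(CPUE + 1) values must be non-negative")

    @property
    def n_observed(self) -> int:
        return int(self.observed.sum())

    @property
    def n_nonzero(self) -> int:
        return int(np.sum(self.values[self.observed] > 0))


def read_survey_table(path: str | Path) -> pd.DataFrame:
    """Read the standard survey CSV into a validated record table.

    Malformed rows (non-positive effort, negative count, unparseable date
    or count) are dropped and reported with their line numbers; a missing
    required column is a hard failure naming the column.
    """
    df = pd.read_csv(path, comment="#")
    for col in SURVEY_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"survey table {path} is missing required column {col!r}")
    # header is line 1, first data row line 2
    lineno = pd.RangeIndex(2, len(df) + 2)

    dates = pd.to_datetime(df["date"], errors="coerce")
    counts = pd.to_numeric(df["count"], errors="coerce")
    efforts = pd.to_numeric(df["effort"], errors="coerce")
    bad = (
        dates.isna()
        | counts.isna()
        | efforts.isna()
        | (counts < 0)
        | (efforts <= 0)
        | ~df["group"].isin(VALID_GROUPS)
    )
    if bad.any():
        for ln in lineno[bad.to_numpy()]:
            logger.warning("%s: dropped malformed row at line %d", path, ln)
    df = df.loc[~bad].copy()
    df["year"] = dates[~bad].dt.year
    df["month"] = dates[~bad].dt.month
    df["count"] = counts[~bad]
    df["effort"] = efforts[~bad]
    return df.reset_index(drop=True)


def compute_cpue_series(records: pd.DataFrame, start_year: int) -> pd.DataFrame:
    """Build the tidy monthly ln(CPUE+1) table from survey records.

    CPUE = count / effort per tow; multiple tows in the same station-month
    are averaged on the CPUE scale before the log transform. A station-month
    is *surveyed* if any record (any taxon) exists for it; a taxon absent
    from a surveyed station-month gets value 0. Years before ``start_year``
    are dropped, and every (taxon, station) series is expanded onto the full
    year x month grid of its station with unsurveyed cells flagged.
    """
    if records.empty:
        raise ValueError("no survey records")
    rec = records[records["year"] >= start_year].copy()
    if rec.empty:
        raise ValueError(f"no survey records at or after start_year={start_year}")
    rec["cpue"] = rec["count"] / rec["effort"]

    cell = (
        rec.groupby(["taxon", "station", "region", "group", "year", "month"])["cpue"]
        .mean()
        .reset_index()
    )
    cell["value"] = np.log1p(cell["cpue"])

    # survey coverage per station: which (year, month) cells happened
    surveyed = rec[["station", "year", "month"]].drop_duplicates()
    year_span = rec.groupby("station")["year"].agg(["min", "max"])

    out = []
    meta = cell[["taxon", "station", "region", "group"]].drop_duplicates()
    surveyed_idx = {
        st: set(map(tuple, g[["year", "month"]].to_numpy()))
        for st, g in surveyed.groupby("station")
    }
    for row in meta.itertuples(index=False):
        y0, y1 = year_span.loc[row.station]
        grid = pd.MultiIndex.from_product(
            [range(int(y0), int(y1) + 1), range(1, 13)], names=["year", "month"]
        ).to_frame(index=False)
        grid["taxon"], grid["station"] = row.taxon, row.station
        grid["region"], grid["group"] = row.region, row.group
        sset = surveyed_idx[row.station]
        grid["observed"] = [
            (y, m) in sset for y, m in zip(grid["year"], grid["month"])
        ]
        out.append(grid)
    full = pd.concat(out, ignore_index=True)
    full = full.merge(
        cell[["taxon", "station", "year", "month", "value"]],
        on=["taxon", "station", "year", "month"],
        how="left",
    )
    full.loc[full["observed"] & full["value"].isna(), "value"] = 0.0
    full.loc[~full["observed"], "value"] = np.nan
    return full[SERIES_COLUMNS].sort_values(
        ["taxon", "station", "year", "month"], kind="stable"
    ).reset_index(drop=True)


def filter_by_detections(
    series: pd.DataFrame,
    min_nonzero_fish: int = DEFAULT_MIN_NONZERO_FISH,
    min_nonzero_zoop: int = DEFAULT_MIN_NONZERO_ZOOP,
) -> pd.DataFrame:
    """Retain taxon x station full monthly series with enough detections.

    A series is kept iff its number of nonzero-CPUE surveyed months is >=
    the group threshold (inclusive). Operates before month-splitting.
    """
    unknown = set(series["group"].unique()) - set(VALID_GROUPS)
    if unknown:
        raise ValueError(f"unknown group label(s): {sorted(unknown)}")
    thresholds = {"fish": min_nonzero_fish, "zooplankton": min_nonzero_zoop}

    nonzero = (
        series.assign(nz=(series["value"] > 0) & series["observed"])
        .groupby(["taxon", "station", "group"])["nz"]
        .sum()
        .reset_index()
    )
    nonzero["keep"] = nonzero.apply(
        lambda r: r["nz"] >= thresholds[r["group"]], axis=1
    )
    for r in nonzero[~nonzero["keep"]].itertuples(index=False):
        logger.info(
            "dropped series taxon=%s station=%s: %d nonzero detections < %d "
            "(detection-count rule)",
            r.taxon, r.station, r.nz, thresholds[r.group],
        )
    kept = nonzero.loc[nonzero["keep"], ["taxon", "station"]]
    return series.merge(kept, on=["taxon", "station"]).reset_index(drop=True)


def split_months(series: pd.DataFrame) -> list[MonthSeries]:
    """Split full monthly series into 12 annual-scale month-specific series.

    The union of the 12 outputs is exactly the input; a year whose survey
    for that month did not happen is flagged unobserved.
    """
    out: list[MonthSeries] = []
    for (taxon, station, region, group, month), g in series.groupby(
        ["taxon", "station", "region", "group", "month"], sort=True
    ):
        g = g.sort_values("year")
        if len(g) < 2:
            logger.info(
                "month series taxon=%s station=%s month=%d spans <2 years; skipped",
                taxon, station, month,
            )
            continue
        out.append(
            MonthSeries(
                taxon=taxon,
                station=station,
                region=region,
                group=group,
                month=int(month),
                years=g["year"].to_numpy(),
                values=g["value"].to_numpy(),
                observed=g["observed"].to_numpy(),
            )
        )
    return out


def filter_month_strata(
    month_series: Iterable[MonthSeries],
    min_presence: float = DEFAULT_MIN_PRESENCE,
) -> list[MonthSeries]:
    """Keep month strata in which the taxon was present with regularity.

    Presence fraction = (surveyed years with nonzero value) / (surveyed
    years); a stratum is retained iff the fraction is >= ``min_presence``.
    Strata with zero surveyed years are dropped with a warning.
    """
    kept = []
    for s in month_series:
        if s.n_observed == 0:
            logger.warning(
                "month series taxon=%s station=%s month=%d has no observed years; "
                "dropped", s.taxon, s.station, s.month,
            )
            continue
        frac = s.n_nonzero / s.n_observed
        if frac >= min_presence:
            kept.append(s)
        else:
            logger.info(
                "dropped stratum taxon=%s station=%s month=%d: presence %.1f%% "
                "< %.1f%% (presence rule)",
                s.taxon, s.station, s.month, 100 * frac, 100 * min_presence,
            )
    return kept


def series_to_frame(month_series: Sequence[MonthSeries]) -> pd.DataFrame:
    """Tidy frame (SERIES_COLUMNS) holding the given month series."""
    frames = []
    for s in month_series:
        frames.append(
            pd.DataFrame(
                {
                    "taxon": s.taxon,
                    "station": s.station,
                    "region": s.region,
                    "group": s.group,
                    "year": s.years,
                    "month": s.month,
                    "value": s.values,
                    "observed": s.observed,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=SERIES_COLUMNS)
    return pd.concat(frames, ignore_index=True)[SERIES_COLUMNS]


def frame_to_series(frame: pd.DataFrame) -> list[MonthSeries]:
    """Inverse of :func:`series_to_frame`."""
    return split_months(frame)


def write_series_csv(frame: pd.DataFrame, path: str | Path, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        frame.to_csv(fh, index=False)


def read_series_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = set(SERIES_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"series table {path} is missing column(s) {sorted(missing)}")
    return df
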