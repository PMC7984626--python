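"""Weekly ILI series, MMWR epi-weeks, flu-season indexing and CSV I/O.

A :class:`WeeklySeries` holds one row per week: the ILI-positive visit
count at the emergency department plus covariates (weekly-averaged min/max
temperature, flu-immunization rate among ILI visits, annual city
population).  Seasons are ~52-week blocks starting near the last week of
August; they are the unit of cross-validation throughout the package.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WeeklySeries",
    "SeasonIndex",
    "mmwr_week",
    "build_season_index",
    "label_high_volume",
    "read_weekly_csv",
    "write_forecast_csv",
]

REQUIRED_COLUMNS = (
    "week_start",
    "ili_count",
    "temp_min",
    "temp_max",
    "immunization_rate",
    "population",
)

DEFAULT_SEASON_START_EPIWEEK = 35


# ---------------------------------------------------------------------------
# MMWR epi-weeks
# ---------------------------------------------------------------------------

def _mmwr_year_start(year: int) -> dt.date:
    """Sunday starting MMWR week 1 of `year` (the week containing Jan 4)."""
    jan4 = dt.date(year, 1, 4)
    return jan4 - dt.timedelta(days=(jan4.weekday() + 1) % 7)


def mmwr_week(day: dt.date) -> tuple[int, int]:
    """Return ``(epi_year, epi_week)`` for a calendar date.

    MMWR convention: weeks run Sunday-Saturday and week 1 is the week
    containing January 4, so epi-weeks number 1..52 or 1..53 depending on
    the year.
    """
    if isinstance(day, (pd.Timestamp, dt.datetime)):
        day = day.date() if hasattr(day, "date") else day
    for year in (day.year + 1, day.year, day.year - 1):
        start = _mmwr_year_start(year)
        if day >= start:
            return year, (day - start).days // 7 + 1
    raise ValueError(f"cannot assign an MMWR week to {day!r}")  # pragma: no cover


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

class WeeklySeries:
    """Validated weekly series of ILI counts and covariates.

    Wraps a :class:`pandas.DataFrame` with one row per week, strictly
    increasing ``week_start`` dates at 7-day spacing, nonnegative integer
    counts and immunization rates in [0, 1].
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"missing required column(s): {', '.join(missing)}")
        frame["week_start"] = pd.to_datetime(frame["week_start"]).dt.normalize()
        frame = frame.reset_index(drop=True)
        counts = frame["ili_count"]
        bad = counts[(counts < 0) | counts.isna()]
        if len(bad):
            rows = ", ".join(str(i) for i in bad.index[:5])
            raise ValueError(f"ili_count must be a nonnegative number (rows: {rows})")
        frame["ili_count"] = counts.astype(float).round().astype(int)
        imm = frame["immunization_rate"].astype(float)
        if ((imm < 0) | (imm > 1)).any():
            raise ValueError("immunization_rate must lie in [0, 1]")
        diffs = frame["week_start"].diff().dropna()
        if len(diffs):
            off = frame["week_start"][1:][diffs != pd.Timedelta(days=7)]
            if len(off):
                dates = ", ".join(d.date().isoformat() for d in off[:5])
                raise ValueError(
                    f"weeks must be strictly increasing with 7-day spacing; "
                    f"gap or duplicate at: {dates}"
                )
        self.frame = frame

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def counts(self) -> np.ndarray:
        return self.frame["ili_count"].to_numpy()

    @property
    def week_starts(self) -> pd.Series:
        return self.frame["week_start"]

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out["week_start"] = out["week_start"].dt.date
        out.to_csv(path, index=False, float_format="%.8g")


@dataclasses.dataclass
class SeasonIndex:
    """Partition of the weekly record into flu seasons.

    ``season_id[i]`` and ``week_of_season[i]`` (1-based) describe week ``i``;
    ``seasons`` maps season id to the ordered week positions it contains.
    Seasons shorter than ``min_complete`` weeks (leading/trailing partials)
    are flagged, not rejected.
    """

    season_id: np.ndarray
    week_of_season: np.ndarray
    epi_year: np.ndarray
    epi_week: np.ndarray
    seasons: dict[str, np.ndarray]
    partial_seasons: tuple[str, ...]
    season_start_epiweek: int

    @property
    def season_ids(self) -> list[str]:
        return list(self.seasons)

    def complete_seasons(self) -> list[str]:
        return [s for s in self.seasons if s not in self.partial_seasons]

    def positions(self, season: str) -> np.ndarray:
        return self.seasons[season]


def build_season_index(
    week_starts: Iterable,
    season_start_epiweek: int = DEFAULT_SEASON_START_EPIWEEK,
    min_complete: int = 52,
) -> SeasonIndex:
    """Assign every week an MMWR epi-week and a flu-season label.

    A new season begins at the first week whose epi-week reaches
    ``season_start_epiweek`` (default 35, roughly the last week of August).
    Seasons are named ``"2012-13"`` style.  Rejects gaps or duplicates.
    """
    weeks = pd.to_datetime(pd.Series(list(week_starts))).dt.normalize()
    if weeks.empty:
        raise ValueError("no weeks provided")
    diffs = weeks.diff().dropna()
    off = weeks[1:][diffs != pd.Timedelta(days=7)]
    if len(off):
        dates = ", ".join(d.date().isoformat() for d in off[:5])
        raise ValueError(f"gap or duplicate weeks at: {dates}")

    epi = [mmwr_week(d.date()) for d in weeks]
    epi_year = np.array([e[0] for e in epi])
    epi_week = np.array([e[1] for e in epi])
    season_year = np.where(epi_week >= season_start_epiweek, epi_year, epi_year - 1)
    season_id = np.array(
        [f"{y}-{(y + 1) % 100:02d}" for y in season_year], dtype=object
    )

    seasons: dict[str, np.ndarray] = {}
    week_of_season = np.zeros(len(weeks), dtype=int)
    for sid in pd.unique(season_id):
        pos = np.flatnonzero(season_id == sid)
        seasons[sid] = pos
        week_of_season[pos] = np.arange(1, len(pos) + 1)

    partial = tuple(s for s, pos in seasons.items() if len(pos) < min_complete)
    return SeasonIndex(
        season_id=season_id,
        week_of_season=week_of_season,
        epi_year=epi_year,
        epi_week=epi_week,
        seasons=seasons,
        partial_seasons=partial,
        season_start_epiweek=season_start_epiweek,
    )


def label_high_volume(series: WeeklySeries, index: SeasonIndex) -> np.ndarray:
    """Boolean mask of high-volume weeks: top 25% of counts within each season.

    Exactly ``ceil(0.25 * n)`` weeks per season are labelled high, chosen by
    descending count with ties at the boundary broken in favour of the
    earlier week.
    """
    counts = series.counts
    if len(counts) != len(index.season_id):
        raise ValueError("series and season index cover different numbers of weeks")
    high = np.zeros(len(counts), dtype=bool)
    for sid, pos in index.seasons.items():
        n_high = math.ceil(0.25 * len(pos))
        # stable sort on -count keeps earlier weeks first among ties
        order = np.argsort(-counts[pos], kind="stable")
        high[pos[order[:n_high]]] = True
    return high


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_weekly_csv(path) -> WeeklySeries:
    """Read a weekly series CSV (columns per :data:`REQUIRED_COLUMNS`)."""
    frame = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    try:
        frame["week_start"] = pd.to_datetime(frame["week_start"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: unparseable week_start date: {exc}") from exc
    if not pd.api.types.is_numeric_dtype(frame["ili_count"]):
        bad = frame[pd.to_numeric(frame["ili_count"], errors="coerce").isna()]
        rows = ", ".join(str(i) for i in bad.index[:5])
        raise ValueError(f"{path}: non-numeric ili_count (rows: {rows})")
    return WeeklySeries(frame)


def write_forecast_csv(forecasts: Sequence, path) -> None:
    """Write forecasts as one row per (model, horizon) with 99 centiles."""
    rows = []
    for fc in forecasts:
        row = {
            "made_at_week": fc.made_at_week,
            "horizon": fc.horizon,
            "model": fc.model,
            "point": fc.point,
        }
        for c in range(1, 100):
            row[f"q{c:02d}"] = fc.centiles[c - 1]
        row["pi_lower_90"] = fc.centiles[4]   # q05
        row["pi_upper_90"] = fc.centiles[94]  # q95
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.8g")
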