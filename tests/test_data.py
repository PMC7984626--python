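"""Season indexing, MMWR epi-weeks, volume labels and CSV round trips."""

import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest

from ilistack.data import (
    SeasonIndex,
    WeeklySeries,
    build_season_index,
    label_high_volume,
    mmwr_week,
    read_weekly_csv,
)


def mmwr_oracle(day: dt.date):
    """Independent MMWR calculator: walk week-by-week from a known anchor.

    2010-01-03 is the Sunday starting MMWR week 1 of 2010.
    """
    anchor = dt.date(2010, 1, 3)
    sunday = day - dt.timedelta(days=(day.weekday() + 1) % 7)
    # enumerate year starts around the target and pick the governing one
    year = sunday.year
    starts = {}
    for y in (year - 1, year, year + 1):
        jan4 = dt.date(y, 1, 4)
        starts[y] = jan4 - dt.timedelta(days=(jan4.weekday() + 1) % 7)
    gov = max((y for y in starts if starts[y] <= sunday), key=lambda y: starts[y])
    week = (sunday - starts[gov]).days // 7 + 1
    assert (sunday - anchor).days % 7 == 0  # sanity: Sundays align
    return gov, week


def test_mmwr_agrees_with_independent_oracle(rng):
    base = dt.date(2005, 1, 1).toordinal()
    for off in rng.integers(0, 365 * 25, size=1000):
        day = dt.date.fromordinal(int(base + off))
        assert mmwr_week(day) == mmwr_oracle(day)


def test_mmwr_week53_years():
    # 2014 is a 53-week MMWR year: Jan 2 2015 still belongs to 2014 week 53
    assert mmwr_week(dt.date(2015, 1, 2)) == (2014, 53)
    assert mmwr_week(dt.date(2015, 1, 4)) == (2015, 1)


def _weeks(start: str, n: int) -> pd.Series:
    return pd.Series(pd.date_range(start, periods=n, freq="7D"))


class TestSeasonIndex:
    def test_366_weeks_make_7_seasons_of_52_or_53(self):
        idx = build_season_index(_weeks("2012-08-26", 366))
        lengths = [len(p) for p in idx.seasons.values()]
        assert len(lengths) in (7, 8)
        full = lengths[:7]
        assert all(l in (52, 53) for l in full[:6])
        assert 53 in lengths  # a 53-MMWR-week year falls in this range

    def test_single_season_identity_partition(self):
        weeks = _weeks("2013-09-01", 30)
        idx = build_season_index(weeks)
        assert len(idx.seasons) == 1
        assert list(idx.week_of_season) == list(range(1, 31))

    def test_partition_exhaustive_and_disjoint(self, default_index):
        all_pos = np.concatenate(list(default_index.seasons.values()))
        assert sorted(all_pos) == list(range(len(default_index.season_id)))

    def test_gap_rejected_with_dates(self):
        weeks = list(_weeks("2013-09-01", 10))
        bad = weeks[:5] + [w + pd.Timedelta(days=14) for w in weeks[5:]]
        with pytest.raises(ValueError, match="gap or duplicate"):
            build_season_index(bad)

    def test_partial_final_season_flagged(self):
        idx = build_season_index(_weeks("2012-08-26", 52 + 14))
        assert len(idx.seasons) == 2
        assert idx.partial_seasons == (list(idx.seasons)[1],)


class TestHighVolume:
    def _series(self, counts, start="2013-09-01"):
        n = len(counts)
        return WeeklySeries(pd.DataFrame({
            "week_start": _weeks(start, n),
            "ili_count": counts,
            "temp_min": np.zeros(n),
            "temp_max": np.zeros(n),
            "immunization_rate": np.zeros(n),
            "population": np.full(n, 1000),
        }))

    def test_top_quarter_of_increasing_octet(self):
        s = self._series(list(range(1, 9)))
        idx = build_season_index(s.week_starts)
        high = label_high_volume(s, idx)
        assert set(s.counts[high]) == {7, 8}

    def test_ties_favour_earlier_weeks(self):
        s = self._series([5] * 8)
        idx = build_season_index(s.week_starts)
        high = label_high_volume(s, idx)
        assert list(np.flatnonzero(high)) == [0, 1]

    def test_348_weeks_in_7_seasons_yield_89_high(self, rng):
        # season lengths consistent with the study's printed totals
        lengths = [51] * 6 + [42]
        assert sum(lengths) == 348
        counts = rng.integers(52, 500, size=348)
        s = self._series(list(counts))
        pos = 0
        seasons = {}
        sid_arr = np.empty(348, dtype=object)
        wos = np.zeros(348, dtype=int)
        for k, L in enumerate(lengths):
            seasons[f"s{k}"] = np.arange(pos, pos + L)
            sid_arr[pos:pos + L] = f"s{k}"
            wos[pos:pos + L] = np.arange(1, L + 1)
            pos += L
        idx = SeasonIndex(
            season_id=sid_arr, week_of_season=wos,
            epi_year=np.zeros(348, int), epi_week=np.zeros(348, int),
            seasons=seasons, partial_seasons=(), season_start_epiweek=35,
        )
        assert label_high_volume(s, idx).sum() == 89

    def test_per_season_share_in_band(self, default_series, default_index):
        high = label_high_volume(default_series, default_index)
        for sid, pos in default_index.seasons.items():
            share = high[pos].mean()
            n = len(pos)
            assert 0.25 <= share <= 0.25 + 1.0 / n
            assert high[pos].sum() == math.ceil(0.25 * n)


class TestCsv:
    def test_round_trip(self, tmp_path, default_series):
        p = tmp_path / "weekly.csv"
        default_series.to_csv(p)
        back = read_weekly_csv(p)
        assert np.array_equal(back.counts, default_series.counts)
        assert (back.week_starts == default_series.week_starts).all()
        np.testing.assert_allclose(
            back.frame["temp_min"], default_series.frame["temp_min"], rtol=1e-6
        )

    def test_negative_count_names_row(self, tmp_path):
        p = tmp_path / "bad.csv"
        pd.DataFrame({
            "week_start": ["2013-09-01", "2013-09-08"],
            "ili_count": [5, -2],
            "temp_min": [0, 0], "temp_max": [0, 0],
            "immunization_rate": [0, 0], "population": [1, 1],
        }).to_csv(p, index=False)
        with pytest.raises(ValueError, match="rows: 1"):
            read_weekly_csv(p)

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        pd.DataFrame({"week_start": ["2013-09-01"], "ili_count": [5]}).to_csv(
            p, index=False)
        with pytest.raises(ValueError, match="missing required column"):
            read_weekly_csv(p)
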