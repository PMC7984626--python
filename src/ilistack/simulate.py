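"""Synthetic multi-season weekly ILI series with covariates.

The generator emulates the marginal structure of weekly ILI-positive ED
visit data at a high-volume pediatric hospital: a constant off-peak
baseline plus one Gaussian-bump epidemic wave per season (season-specific
peak height, location and width), negative-binomial observation noise,
an annual temperature sinusoid with its trough in winter (anti-correlated
with counts), an immunization-rate ramp to a plateau, and linear
population growth.  Defaults are calibrated so the overall mean weekly
count is ~210 and the top-quartile ("high-volume") weekly mean ~330.
"""

from __future__ import annotations

import dataclasses
import datetime as dt

import numpy as np
import pandas as pd
from scipy import stats

from .data import (
    DEFAULT_SEASON_START_EPIWEEK,
    SeasonIndex,
    WeeklySeries,
    build_season_index,
)

__all__ = ["SimulationConfig", "simulate_dataset", "summarize"]


@dataclasses.dataclass
class SimulationConfig:
    """Parameters of the synthetic weekly ILI generator.

    Rates are visits/week, temperatures degrees Celsius, population persons.
    ``dispersion`` is the negative-binomial size parameter (``inf`` gives
    noise-free rounded counts).
    """

    n_seasons: int = 7
    start_date: dt.date = dt.date(2012, 8, 26)  # a Sunday in MMWR week 35
    season_start_epiweek: int = DEFAULT_SEASON_START_EPIWEEK
    last_season_weeks: int | None = None  # truncate the final season (partial)
    baseline_rate: float = 150.0
    peak_height_range: tuple[float, float] = (160.0, 340.0)
    peak_week_range: tuple[float, float] = (14.0, 22.0)
    peak_width_range: tuple[float, float] = (4.0, 7.0)
    dispersion: float = 30.0
    temp_min_mean: float = -3.0
    temp_max_mean: float = 14.0
    temp_amplitude: float = 13.0
    temp_noise_sd: float = 3.0
    immunization_plateau: float = 0.23
    immunization_noise_sd: float = 0.02
    population_start: int = 1_200_000
    population_growth: int = 20_000
    seed: int = 0

    def validate(self) -> None:
        if self.n_seasons < 1:
            raise ValueError("n_seasons must be >= 1")
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        if not self.dispersion > 0:
            raise ValueError("dispersion must be positive")
        for name in ("peak_height_range", "peak_week_range", "peak_width_range"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"{name} is empty")


def _week_dates(config: SimulationConfig) -> tuple[pd.DatetimeIndex, SeasonIndex]:
    """Consecutive weekly dates covering exactly ``n_seasons`` flu seasons."""
    # generate a generous run, index it, then truncate to n_seasons
    n_weeks = 54 * (config.n_seasons + 1)
    dates = pd.date_range(config.start_date, periods=n_weeks, freq="7D")
    idx = build_season_index(dates, config.season_start_epiweek)
    keep_ids = list(idx.seasons)[: config.n_seasons]
    keep = np.concatenate([idx.seasons[s] for s in keep_ids])
    if config.last_season_weeks is not None:
        last = idx.seasons[keep_ids[-1]][: config.last_season_weeks]
        keep = np.concatenate([np.concatenate([idx.seasons[s] for s in keep_ids[:-1]]), last])
    dates = dates[keep]
    return dates, build_season_index(dates, config.season_start_epiweek)


def latent_curve(
    length: int, baseline: float, height: float, peak_week: float, width: float
) -> np.ndarray:
    """Baseline plus Gaussian epidemic bump over week-of-season 1..length."""
    t = np.arange(1, length + 1, dtype=float)
    return baseline + height * np.exp(-0.5 * ((t - peak_week) / width) ** 2)


def simulate_dataset(config: SimulationConfig) -> WeeklySeries:
    """Draw one synthetic weekly series; identical seeds give identical data."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    dates, idx = _week_dates(config)
    n = len(dates)

    mu = np.empty(n)
    for k, (sid, pos) in enumerate(idx.seasons.items()):
        h = rng.uniform(*config.peak_height_range)
        p = rng.uniform(*config.peak_week_range)
        w = rng.uniform(*config.peak_width_range)
        mu[pos] = latent_curve(len(pos), config.baseline_rate, h, p, w)

    if np.isinf(config.dispersion):
        counts = np.round(mu).astype(int)
    else:
        r = config.dispersion
        counts = rng.negative_binomial(r, r / (r + mu))

    # annual sinusoid, trough in mid-January (day-of-year ~15)
    doy = dates.dayofyear.to_numpy(dtype=float)
    phase = np.cos(2.0 * np.pi * (doy - 15.0) / 365.25)
    tmin = config.temp_min_mean - config.temp_amplitude * phase
    tmax = config.temp_max_mean - config.temp_amplitude * phase
    if config.temp_noise_sd > 0:
        tmin = tmin + rng.normal(0.0, config.temp_noise_sd, n)
        tmax = tmax + rng.normal(0.0, config.temp_noise_sd, n)

    imm = np.empty(n)
    for sid, pos in idx.seasons.items():
        half = max(len(pos) // 2, 1)
        ramp = np.minimum(np.arange(len(pos)) / half, 1.0)
        imm[pos] = config.immunization_plateau * ramp
    if config.immunization_noise_sd > 0:
        imm = imm + rng.normal(0.0, config.immunization_noise_sd, n)
    imm = np.clip(imm, 0.0, 1.0)

    pop = np.empty(n, dtype=int)
    for k, (sid, pos) in enumerate(idx.seasons.items()):
        pop[pos] = config.population_start + k * config.population_growth

    frame = pd.DataFrame(
        {
            "week_start": dates,
            "ili_count": counts,
            "temp_min": tmin,
            "temp_max": tmax,
            "immunization_rate": imm,
            "population": pop,
        }
    )
    return WeeklySeries(frame)


_SUMMARY_VARIABLES = ("ili_count", "temp_min", "temp_max", "immunization_rate", "population")


def summarize(series: WeeklySeries, high: np.ndarray) -> pd.DataFrame:
    """Descriptive table: overall/high/low-volume means, SDs and Welch t.

    One row per variable; the t statistic tests the high-minus-low volume
    mean difference with unequal variances (Welch).
    """
    high = np.asarray(high, dtype=bool)
    if high.sum() < 2 or (~high).sum() < 2:
        raise ValueError("each volume stratum needs at least 2 weeks")
    rows = []
    for var in _SUMMARY_VARIABLES:
        x = series.frame[var].to_numpy(dtype=float)
        hi, lo = x[high], x[~high]
        if hi.std(ddof=1) == 0.0 and lo.std(ddof=1) == 0.0:
            # degenerate strata: zero difference scores 0, any difference +/-inf
            diff = hi.mean() - lo.mean()
            t = 0.0 if diff == 0 else np.copysign(np.inf, diff)
        else:
            t = float(stats.ttest_ind(hi, lo, equal_var=False).statistic)
        rows.append(
            {
                "variable": var,
                "mean_all": x.mean(),
                "sd_all": x.std(ddof=1),
                "mean_high": hi.mean(),
                "sd_high": hi.std(ddof=1),
                "mean_low": lo.mean(),
                "sd_low": lo.std(ddof=1),
                "t_high_minus_low": t,
            }
        )
    return pd.DataFrame(rows).set_index("variable")
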