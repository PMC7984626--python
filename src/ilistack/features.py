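"""Predictor construction for the regression-type members (QRF, LR).

All features at forecast origin ``t`` use only data observable at ``t``:
lagged counts and covariates, the current epi-week, population, a year
trend, the local slope of the ILI curve, and the count of upward weekly
movements over the preceding three weeks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import SeasonIndex, WeeklySeries

__all__ = [
    "QRF_FEATURES",
    "LR_BASE_FEATURES",
    "build_feature_frame",
    "build_feature_row",
    "slope_at",
    "upward_count_at",
]

# 16 predictors; the random-forest member samples sqrt(16) = 4 per split
QRF_FEATURES = (
    "ili_lag0", "ili_lag1", "ili_lag2", "ili_lag3",
    "tmin_lag0", "tmin_lag1", "tmin_lag2",
    "tmax_lag0", "tmax_lag1", "tmax_lag2",
    "imm_lag0", "imm_lag1", "imm_lag2",
    "epi_week", "population", "year_trend",
)

# LR adds epi-week fixed effects and the categorical upward count on top
LR_BASE_FEATURES = (
    "ili_lag0", "tmin_lag0", "tmax_lag0", "imm_lag0",
    "population", "year_trend", "slope",
)

MAX_LAG = 3  # deepest lag used by any feature -> burn-in length


def slope_at(counts: np.ndarray, t: int) -> float:
    """Slope of the ILI curve at week t: the first difference y_t - y_{t-1}."""
    if t < 1:
        raise ValueError("slope needs one preceding week (burn-in)")
    return float(counts[t] - counts[t - 1])


def upward_count_at(counts: np.ndarray, t: int) -> int:
    """Number of weekly rises over the preceding three weeks (0..3)."""
    if t < MAX_LAG:
        raise ValueError("upward count needs three preceding weeks (burn-in)")
    return int(sum(counts[t - j] > counts[t - j - 1] for j in range(3)))


def build_feature_frame(series: WeeklySeries, index: SeasonIndex) -> pd.DataFrame:
    """All features for every week position; rows in the burn-in are NaN.

    Columns cover the union of the QRF and LR schemas; model-specific
    designs subset them.
    """
    f = series.frame
    counts = series.counts.astype(float)
    n = len(f)
    first_year = int(index.epi_year.min())
    cols: dict[str, np.ndarray] = {}
    for lag in range(4):
        cols[f"ili_lag{lag}"] = pd.Series(counts).shift(lag).to_numpy()
    for lag in range(3):
        cols[f"tmin_lag{lag}"] = f["temp_min"].shift(lag).to_numpy()
        cols[f"tmax_lag{lag}"] = f["temp_max"].shift(lag).to_numpy()
        cols[f"imm_lag{lag}"] = f["immunization_rate"].shift(lag).to_numpy()
    cols["epi_week"] = index.epi_week.astype(float)
    cols["population"] = f["population"].to_numpy(dtype=float)
    cols["year_trend"] = (index.epi_year - first_year).astype(float)
    slope = np.full(n, np.nan)
    upward = np.full(n, np.nan)
    for t in range(MAX_LAG, n):
        slope[t] = slope_at(counts, t)
        upward[t] = upward_count_at(counts, t)
    cols["slope"] = slope
    cols["upward_count"] = upward
    out = pd.DataFrame(cols)
    out.iloc[:MAX_LAG] = np.nan  # uniform burn-in across schemas
    return out


def build_feature_row(
    series: WeeklySeries, index: SeasonIndex, t: int, schema: tuple[str, ...]
) -> np.ndarray:
    """Feature vector at week position ``t`` for the given schema."""
    if t < MAX_LAG:
        raise ValueError(
            f"week position {t} is inside the {MAX_LAG}-week burn-in; "
            "not enough trailing history for the configured lags"
        )
    frame = build_feature_frame(series, index)
    return frame.iloc[t][list(schema)].to_numpy(dtype=float)
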