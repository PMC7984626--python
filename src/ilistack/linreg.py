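"""Covariate linear-regression member.

One OLS fit per forecast horizon (the target is the count l weeks ahead)
on: current ILI count, current min/max temperature, immunization rate,
population, year trend, epi-week fixed effects, the slope of the ILI
curve, and a 4-level categorical counting upward movements over the
preceding three weeks.  Forecast centiles are Gaussian around the point
with the prediction standard error (parameter plus residual variance).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .features import LR_BASE_FEATURES
from .forecast import ForecastDistribution, gaussian_centiles

__all__ = ["LrFit", "lr_design", "lr_fit", "lr_forecast", "LinearMember"]


def lr_design(
    frame: pd.DataFrame,
    epi_levels: tuple[int, ...] | None = None,
    upward_levels: tuple[int, ...] = (0, 1, 2, 3),
) -> tuple[pd.DataFrame, tuple[int, ...]]:
    """Design matrix: base covariates + drop-one dummies for epi-week and
    the upward-movement category.

    ``epi_levels`` fixes the dummy schema (training levels) so test rows
    align; unseen levels fall to the baseline.
    """
    X = frame[list(LR_BASE_FEATURES)].copy()
    if epi_levels is None:
        epi_levels = tuple(sorted(frame["epi_week"].astype(int).unique()))
    ew = frame["epi_week"].astype(int)
    for lvl in epi_levels[1:]:  # first level is the baseline
        X[f"epiweek_{lvl}"] = (ew == lvl).astype(float)
    up = frame["upward_count"].astype(int)
    for lvl in upward_levels[1:]:
        X[f"upward_{lvl}"] = (up == lvl).astype(float)
    X = X.drop(columns=["epi_week"], errors="ignore")
    return X, epi_levels


@dataclasses.dataclass
class LrFit:
    """OLS results plus the dummy schema used to build the design."""

    results: object  # statsmodels RegressionResults
    epi_levels: tuple[int, ...]
    columns: tuple[str, ...]

    @property
    def alpha(self) -> float:
        return float(self.results.params["const"])

    @property
    def beta(self) -> pd.Series:
        return self.results.params.drop("const")

    @property
    def residual_sd(self) -> float:
        return float(np.sqrt(self.results.mse_resid))


def _aliased_columns(X: pd.DataFrame) -> list[str]:
    """Columns exactly collinear with the intercept + preceding columns."""
    arr = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(arr) == arr.shape[1]:
        return []
    bad = []
    base = np.ones((len(X), 1))
    r = 1
    for j, name in enumerate(X.columns):
        cand = np.column_stack([base, X.iloc[:, j].to_numpy(dtype=float)])
        r_new = np.linalg.matrix_rank(cand)
        if r_new == r:
            bad.append(name)
        else:
            base, r = cand, r_new
    return bad


def lr_fit(frame: pd.DataFrame, target: np.ndarray,
           epi_levels: tuple[int, ...] | None = None) -> LrFit:
    """OLS of the shifted target on the LR design built from ``frame``.

    Aliased fixed-effect dummies (exactly reproducible from the other
    columns, common on short samples) are dropped with a warning, as R's
    ``lm`` does; collinearity among the substantive covariates is an
    error naming the columns.
    """
    X, levels = lr_design(frame, epi_levels)
    bad = _aliased_columns(X)
    if bad:
        substantive = [c for c in bad if c in LR_BASE_FEATURES]
        if substantive:
            raise ValueError(
                f"rank-deficient design; collinear column(s): {', '.join(substantive)}"
            )
        logging.getLogger(__name__).warning(
            "dropping aliased dummy column(s): %s", ", ".join(bad)
        )
        X = X.drop(columns=bad)
    res = sm.OLS(np.asarray(target, dtype=float), sm.add_constant(X)).fit()
    return LrFit(results=res, epi_levels=levels, columns=tuple(X.columns))


def lr_forecast_many(
    fit: LrFit,
    rows: pd.DataFrame,
    made_at_weeks: np.ndarray,
    horizon: int = 1,
) -> list[ForecastDistribution]:
    """Batch forecasts: one design build and one prediction-SE pass."""
    X, _ = lr_design(rows, fit.epi_levels)
    X = X.reindex(columns=list(fit.columns), fill_value=0.0)
    exog = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    pred = fit.results.get_prediction(exog)
    points = np.asarray(pred.predicted_mean, dtype=float)
    ses = np.asarray(pred.se_obs, dtype=float)  # parameter + residual variance
    return [
        ForecastDistribution(
            made_at_week=int(t), horizon=horizon, point=float(p),
            centiles=gaussian_centiles(float(p), float(se)), model="lr",
        ).floored()
        for t, p, se in zip(made_at_weeks, points, ses)
    ]


def lr_forecast(
    fit: LrFit,
    row: pd.DataFrame,
    made_at_week: int = 0,
    horizon: int = 1,
    level: float = 0.90,
) -> ForecastDistribution:
    """Point plus Gaussian centiles using the prediction SE at the row."""
    return lr_forecast_many(fit, row, np.array([made_at_week]), horizon)[0]


class LinearMember:
    """Harness-facing wrapper holding one fit per horizon."""

    name = "lr"

    def __init__(self):
        self.fits: dict[int, LrFit] = {}

    def fit(self, frame: pd.DataFrame, targets: dict[int, np.ndarray]) -> "LinearMember":
        levels = None
        for h, y in targets.items():
            f = lr_fit(frame, y, epi_levels=levels)
            levels = f.epi_levels
            self.fits[h] = f
        return self

    def forecast(self, row: pd.DataFrame, horizon: int, made_at_week: int = 0
                 ) -> ForecastDistribution:
        return lr_forecast(self.fits[horizon], row, made_at_week, horizon)
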