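"""STL-adjusted ARIMA(2,0,1) member.

Seasonality is removed from the weekly counts by STL decomposition; an
ARIMA(2,0,1) model (CSS-ML via statsmodels) is fitted to the adjusted
series.  Multi-step forecasts follow the standard recursion — future
innovations set to zero, forecasts fed back as lagged values — and the
l-step forecast SD accumulates psi weights:
``sd_l^2 = sigma^2 * sum_{j<l} psi_j^2``.  Centiles are Gaussian around
the point, and the seasonal component (indexed by epi-week) is re-added
to the point and every centile.  These intervals ignore STL estimation
uncertainty and may undercover; this is deliberate.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from statsmodels.tsa.arima.model import ARIMA as _SmARIMA
from statsmodels.tsa.seasonal import STL

from .forecast import ForecastDistribution, gaussian_centiles

__all__ = ["ArimaFit", "stl_adjust", "seasonal_profile", "fit_arima",
           "arima_forecast", "ArimaMember"]

DEFAULT_ORDER = (2, 0, 1)
STL_PERIOD = 52


def stl_adjust(series: np.ndarray, period: int = STL_PERIOD) -> tuple[np.ndarray, np.ndarray]:
    """STL decomposition; returns (seasonal, adjusted) with exact reconstruction."""
    series = np.asarray(series, dtype=float)
    if series.size < 2 * period:
        raise ValueError(f"need at least two full periods ({2 * period} weeks) for STL")
    res = STL(series, period=period).fit()
    seasonal = np.asarray(res.seasonal)
    return seasonal, series - seasonal


def seasonal_profile(seasonal: np.ndarray, epi_weeks: np.ndarray) -> np.ndarray:
    """Average the STL seasonal by epi-week; week 53 folds into week 52.

    Returns a length-52 vector indexed by epi-week - 1.
    """
    ew = np.minimum(np.asarray(epi_weeks, dtype=int), 52)
    prof = np.zeros(52)
    for w in range(1, 53):
        hit = ew == w
        prof[w - 1] = seasonal[hit].mean() if hit.any() else 0.0
    return prof


@dataclasses.dataclass
class ArimaFit:
    """Estimated ARIMA(2,0,1) in intercept form plus the seasonal profile."""

    beta: float          # intercept: y_hat = beta + phi1*y[t-1] + phi2*y[t-2] + theta1*e[t-1]
    phi1: float
    phi2: float
    theta1: float
    innovation_sd: float
    seasonal: np.ndarray  # length-52 epi-week profile

    def __post_init__(self):
        roots = np.roots([-self.phi2, -self.phi1, 1.0])  # 1 - phi1 z - phi2 z^2
        if np.any(np.abs(roots) <= 1.0 + 1e-8):
            raise ValueError(
                f"non-stationary AR polynomial: roots {np.round(roots, 4)} "
                "not outside the unit circle"
            )

    def psi_weights(self, n: int) -> np.ndarray:
        """MA-infinity weights psi_0..psi_{n-1} of the ARMA(2,1) process."""
        psi = np.zeros(n)
        psi[0] = 1.0
        if n > 1:
            psi[1] = self.phi1 + self.theta1
        for j in range(2, n):
            psi[j] = self.phi1 * psi[j - 1] + self.phi2 * psi[j - 2]
        return psi

    def forecast_sd(self, horizon: int) -> float:
        psi = self.psi_weights(horizon)
        return float(self.innovation_sd * np.sqrt(np.sum(psi**2)))


def fit_arima(
    adjusted: np.ndarray, epi_weeks: np.ndarray, order: tuple[int, int, int] = DEFAULT_ORDER
) -> tuple[ArimaFit, np.ndarray]:
    """Fit the ARMA on the demeaned adjusted series (statsmodels, CSS-ML).

    ``adjusted`` should already be seasonally adjusted; the seasonal
    profile is attached separately via :class:`ArimaFit`.
    """
    adjusted = np.asarray(adjusted, dtype=float)
    mean = adjusted.mean()
    res = _SmARIMA(adjusted - mean, order=order, trend="n").fit()
    p, q = order[0], order[2]
    ar = list(res.arparams) + [0.0] * (2 - p)
    ma = list(res.maparams) + [0.0] * (1 - q)
    phi1, phi2 = ar[0], ar[1]
    theta1 = ma[0]
    beta = mean * (1.0 - phi1 - phi2)
    fit = ArimaFit(
        beta=beta, phi1=phi1, phi2=phi2, theta1=theta1,
        innovation_sd=float(np.sqrt(res.params[res.param_names.index("sigma2")])),
        seasonal=np.zeros(52),
    )
    return fit, res.params


def _innovations(fit: ArimaFit, a: np.ndarray) -> np.ndarray:
    """One-step innovations of the adjusted history (presample terms zero)."""
    e = np.zeros(a.size)
    for t in range(a.size):
        pred = fit.beta
        if t >= 1:
            pred += fit.phi1 * a[t - 1] + fit.theta1 * e[t - 1]
        if t >= 2:
            pred += fit.phi2 * a[t - 2]
        e[t] = a[t] - pred
    return e


def arima_forecast(
    fit: ArimaFit,
    adjusted_history: np.ndarray,
    horizon: int,
    target_epi_week: int,
    made_at_week: int = 0,
    level: float = 0.90,
) -> ForecastDistribution:
    """Forecast ``horizon`` steps past the end of the adjusted history.

    The seasonal value for the target epi-week is re-added to the point
    and all centiles.
    """
    a = np.asarray(adjusted_history, dtype=float)
    if a.size < 2:
        raise ValueError("need at least 2 adjusted observations")
    e = _innovations(fit, a)
    # recursion with future innovations set to zero
    hist = list(a)
    last_e = e[-1]
    preds = []
    for step in range(1, horizon + 1):
        pred = fit.beta + fit.phi1 * hist[-1] + fit.phi2 * hist[-2]
        if step == 1:
            pred += fit.theta1 * last_e
        preds.append(pred)
        hist.append(pred)
    point = preds[-1]
    sd = fit.forecast_sd(horizon)
    s = fit.seasonal[min(int(target_epi_week), 52) - 1]
    return ForecastDistribution(
        made_at_week=made_at_week,
        horizon=horizon,
        point=point + s,
        centiles=gaussian_centiles(point + s, sd),
        model="arima",
    ).floored()


class ArimaMember:
    """Harness-facing wrapper: fit on a training record, forecast a season."""

    name = "arima"

    def __init__(self, order: tuple[int, int, int] = DEFAULT_ORDER, period: int = STL_PERIOD):
        self.order = order
        self.period = period
        self.fit_: ArimaFit | None = None

    def fit(self, counts: np.ndarray, epi_weeks: np.ndarray) -> "ArimaMember":
        seasonal, adjusted = stl_adjust(counts, self.period)
        prof = seasonal_profile(seasonal, epi_weeks)
        fit, _ = fit_arima(adjusted, epi_weeks, self.order)
        fit.seasonal = prof
        self.fit_ = fit
        return self

    def forecast(
        self,
        history_counts: np.ndarray,
        history_epi_weeks: np.ndarray,
        horizon: int,
        target_epi_week: int,
        made_at_week: int = 0,
    ) -> ForecastDistribution:
        if self.fit_ is None:
            raise RuntimeError("fit() must be called first")
        ew = np.minimum(np.asarray(history_epi_weeks, dtype=int), 52)
        adj = np.asarray(history_counts, dtype=float) - self.fit_.seasonal[ew - 1]
        return arima_forecast(
            self.fit_, adj, horizon, target_epi_week, made_at_week=made_at_week
        )

    def forecast_many(
        self,
        counts: np.ndarray,
        epi_weeks: np.ndarray,
        origins_by_horizon: dict[int, np.ndarray],
    ) -> dict[tuple[int, int], ForecastDistribution]:
        """Forecasts from many origins with one innovations pass.

        Innovations at week t depend only on weeks <= t, so the filter run
        over the full record gives every origin its own e_t.
        """
        if self.fit_ is None:
            raise RuntimeError("fit() must be called first")
        fit = self.fit_
        ew = np.minimum(np.asarray(epi_weeks, dtype=int), 52)
        adj = np.asarray(counts, dtype=float) - fit.seasonal[ew - 1]
        e = _innovations(fit, adj)
        out: dict[tuple[int, int], ForecastDistribution] = {}
        max_h = max(origins_by_horizon)
        sds = {h: fit.forecast_sd(h) for h in origins_by_horizon}
        for t in sorted(set(np.concatenate(list(origins_by_horizon.values())))):
            preds = []
            prev2, prev1 = adj[t - 1], adj[t]
            for step in range(1, max_h + 1):
                pred = fit.beta + fit.phi1 * prev1 + fit.phi2 * prev2
                if step == 1:
                    pred += fit.theta1 * e[t]
                preds.append(pred)
                prev2, prev1 = prev1, pred
            for h, ts in origins_by_horizon.items():
                if t not in ts:
                    continue
                s = fit.seasonal[min(int(ew[t + h]), 52) - 1] if t + h < ew.size else 0.0
                point = preds[h - 1] + s
                out[(t, h)] = ForecastDistribution(
                    made_at_week=int(t), horizon=h, point=point,
                    centiles=gaussian_centiles(point, sds[h]), model=self.name,
                ).floored()
        return out
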