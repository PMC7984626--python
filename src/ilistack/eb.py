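"""Empirical-Bayes epidemic-curve forecaster.

Past flu seasons are smoothed into piecewise-quadratic trajectories
(:func:`smooth_season`).  Candidate futures for the current season are
formed by resampling those trajectories with their peak height, peak
location and pacing perturbed: the height and location targets are drawn
uniformly from the pool of smoothed peaks and the pacing (a time-dilation
factor about the peak) is uniform on [0.75, 1.25].  Each candidate is
weighted by a Gaussian likelihood of the season observed so far, noise
drawn from the source trajectory's residual level is injected, and the
forecast at week t+l is the likelihood-weighted median of the sample,
with weighted percentiles giving the forecast centiles.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from ._weighted import weighted_median, weighted_percentiles
from .forecast import CENTILES, ForecastDistribution
from .trendfilter import cv_trend_filter

logger = logging.getLogger(__name__)

__all__ = [
    "SmoothedTrajectory",
    "TransformedCurve",
    "smooth_season",
    "sample_transformed_curve",
    "likelihood_weight",
    "EmpiricalBayes",
]

DEFAULT_PACING_RANGE = (0.75, 1.25)
DEFAULT_N_SAMPLES = 100_000
_SIGMA_FLOOR = 1e-6


@dataclasses.dataclass
class SmoothedTrajectory:
    """One past season's smoothed epidemic curve and its noise level."""

    season_id: str
    values: np.ndarray        # f_s over weeks of season
    sigma: float              # residual SD of the smoothing fit
    cv_lambda: float = np.nan

    @property
    def peak_height(self) -> float:
        return float(self.values.max())

    @property
    def peak_week(self) -> int:
        """0-based week-of-season of the smoothed peak."""
        return int(np.argmax(self.values))


@dataclasses.dataclass
class TransformedCurve:
    """A resampled candidate trajectory for the current season."""

    values: np.ndarray
    source_season: str
    height_target: float
    location_target: int
    pacing: float
    sigma: float
    weight: float = 1.0


def smooth_season(
    y: np.ndarray, season_id: str = "", cv_folds: int = 5, seed: int | None = None
) -> SmoothedTrajectory:
    """Smooth one season's counts by CV-tuned quadratic trend filtering."""
    y = np.asarray(y, dtype=float)
    f, lam = cv_trend_filter(y, cv_folds=cv_folds, seed=seed)
    sigma = max(float(np.std(y - f)), _SIGMA_FLOOR)
    return SmoothedTrajectory(season_id=season_id, values=f, sigma=sigma, cv_lambda=lam)


def _transform(
    source: np.ndarray,
    height_target: float,
    location_target: float,
    pacing: float,
    grid_length: int,
) -> np.ndarray:
    """Scale to the target peak height, shift the peak to the target week,
    dilate time about the peak by 1/pacing; edge-hold outside the source."""
    peak = float(np.argmax(source))
    scale = height_target / source.max()
    t = np.arange(grid_length, dtype=float)
    u = peak + (t - location_target) * pacing
    return scale * np.interp(u, np.arange(source.size, dtype=float), source)


def sample_transformed_curve(
    pool: list[SmoothedTrajectory],
    rng: np.random.Generator,
    pacing_range: tuple[float, float] = DEFAULT_PACING_RANGE,
    grid_length: int | None = None,
) -> TransformedCurve:
    """Draw one transformed candidate curve from the pool.

    The source trajectory, the peak-height target and the peak-location
    target are each drawn uniformly (and independently) from the pool; the
    pacing parameter is uniform on ``pacing_range``.
    """
    if not pool:
        raise ValueError("trajectory pool is empty")
    if grid_length is None:
        grid_length = max(tr.values.size for tr in pool)
    src = pool[rng.integers(len(pool))]
    height = pool[rng.integers(len(pool))].peak_height
    loc = pool[rng.integers(len(pool))].peak_week
    pacing = float(rng.uniform(*pacing_range))
    values = _transform(src.values, height, loc, pacing, grid_length)
    return TransformedCurve(
        values=values,
        source_season=src.season_id,
        height_target=height,
        location_target=loc,
        pacing=pacing,
        sigma=src.sigma,
    )


def likelihood_weight(
    curve_values: np.ndarray, observed_to_date: np.ndarray, sigma: float
) -> float:
    """Unnormalized Gaussian likelihood of the season observed so far.

    Computed in log space; callers comparing a batch should use
    :func:`batch_weights` which rescales so the best curve has weight 1.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    obs = np.asarray(observed_to_date, dtype=float)
    if obs.size == 0:
        return 1.0
    sq = float(np.sum((obs - curve_values[: obs.size]) ** 2))
    return float(np.exp(-sq / (2.0 * sigma**2)))


def batch_weights(
    curve_matrix: np.ndarray, sigmas: np.ndarray, observed_to_date: np.ndarray
) -> np.ndarray:
    """Likelihood weights for a batch of curves, max-rescaled to 1.

    With no observations yet (forecast before the season starts) all
    curves get equal weight.
    """
    obs = np.asarray(observed_to_date, dtype=float)
    n = curve_matrix.shape[0]
    if obs.size == 0:
        return np.ones(n)
    sq = np.sum((curve_matrix[:, : obs.size] - obs[None, :]) ** 2, axis=1)
    logw = -sq / (2.0 * sigmas**2)
    w = np.exp(logw - logw.max())
    return w


class EmpiricalBayes:
    """Empirical-Bayes member forecaster over a pool of smoothed seasons."""

    name = "eb"

    def __init__(
        self,
        n_samples: int = DEFAULT_N_SAMPLES,
        pacing_range: tuple[float, float] = DEFAULT_PACING_RANGE,
        cv_folds: int = 5,
        grid_length: int = 53,
    ):
        self.n_samples = n_samples
        self.pacing_range = pacing_range
        self.cv_folds = cv_folds
        self.grid_length = grid_length
        self.pool: list[SmoothedTrajectory] = []

    def fit(
        self,
        season_counts: dict[str, np.ndarray],
        smoothed: dict[str, SmoothedTrajectory] | None = None,
    ) -> "EmpiricalBayes":
        """Build the trajectory pool from complete past seasons.

        ``smoothed`` lets callers supply precomputed smooths (the LOSO
        harness smooths each season once and reuses it across folds).
        """
        if len(season_counts) < 1:
            raise ValueError("need at least one past season")
        self.pool = []
        for sid, y in season_counts.items():
            if smoothed is not None and sid in smoothed:
                self.pool.append(smoothed[sid])
            else:
                self.pool.append(smooth_season(np.asarray(y), season_id=sid,
                                               cv_folds=self.cv_folds))
        return self

    # -- batch sampling ----------------------------------------------------

    def sample_matrix(
        self, rng: np.random.Generator, n_samples: int | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Sample ``n`` transformed curves; returns (values (n, L), sigmas)."""
        if not self.pool:
            raise ValueError("fit() must be called first")
        n = self.n_samples if n_samples is None else n_samples
        L = self.grid_length
        n_pool = len(self.pool)
        max_src = max(tr.values.size for tr in self.pool)
        C = np.stack(
            [np.pad(tr.values, (0, max_src - tr.values.size), mode="edge")
             for tr in self.pool]
        )
        lengths = np.array([tr.values.size for tr in self.pool])
        heights = np.array([tr.peak_height for tr in self.pool])
        locs = np.array([tr.peak_week for tr in self.pool], dtype=float)
        sig = np.array([tr.sigma for tr in self.pool])

        src = rng.integers(0, n_pool, n)
        h = heights[rng.integers(0, n_pool, n)]
        loc = locs[rng.integers(0, n_pool, n)]
        pac = rng.uniform(self.pacing_range[0], self.pacing_range[1], n)

        peak_src = locs[src]
        t = np.arange(L, dtype=float)
        u = peak_src[:, None] + (t[None, :] - loc[:, None]) * pac[:, None]
        u = np.clip(u, 0.0, (lengths[src] - 1).astype(float)[:, None])
        i0 = np.floor(u).astype(int)
        frac = u - i0
        i1 = np.minimum(i0 + 1, (lengths[src] - 1)[:, None])
        rows = src[:, None]
        V = C[rows, i0] * (1.0 - frac) + C[rows, i1] * frac
        V *= (h / heights[src])[:, None]
        return V, sig[src]

    def forecast(
        self,
        observed_to_date: np.ndarray,
        horizons: tuple[int, ...],
        rng: np.random.Generator,
        n_samples: int | None = None,
        made_at_week: int = 0,
    ) -> dict[int, ForecastDistribution]:
        """Forecast 1-4 weeks past the last observed week of the season.

        ``observed_to_date`` holds the current season's counts through the
        forecast origin.  Weights are computed against the noiseless
        transformed curves, then per-source noise is injected into the
        forecast values (weight first, noise last).
        """
        obs = np.asarray(observed_to_date, dtype=float)
        V, sig = self.sample_matrix(rng, n_samples)
        w = batch_weights(V, sig, obs)
        if w.sum() <= 0 or not np.isfinite(w.sum()):
            logger.warning("all EB likelihood weights vanished; using uniform weights")
            w = np.ones(V.shape[0])
        out: dict[int, ForecastDistribution] = {}
        for h in horizons:
            j = obs.size + h - 1
            if j >= self.grid_length:
                raise ValueError(
                    f"horizon {h} runs past the season grid ({self.grid_length} weeks)"
                )
            vals = V[:, j] + rng.normal(0.0, sig)
            point = max(weighted_median(vals, w), 0.0)
            q = np.maximum(weighted_percentiles(vals, w, CENTILES), 0.0)
            out[h] = ForecastDistribution(
                made_at_week=made_at_week, horizon=h, point=point,
                centiles=q, model=self.name,
            )
        return out


def eb_forecast(
    history,
    index,
    current_week: int,
    horizon: int,
    n_samples: int = DEFAULT_N_SAMPLES,
    rng: np.random.Generator | None = None,
    cv_folds: int = 5,
) -> ForecastDistribution:
    """One-shot EB forecast from a weekly record at a global week position.

    Smooths all complete seasons before the current one, then forecasts
    ``horizon`` weeks past ``current_week``.
    """
    rng = np.random.default_rng() if rng is None else rng
    sid = index.season_id[current_week]
    past = {
        s: history.counts[pos]
        for s, pos in index.seasons.items()
        if s != sid and s not in index.partial_seasons and pos[0] < current_week
    }
    if len(past) < 2:
        raise ValueError("need at least 2 complete past seasons")
    model = EmpiricalBayes(n_samples=n_samples, cv_folds=cv_folds).fit(past)
    start = index.seasons[sid][0]
    obs = history.counts[start : current_week + 1]
    return model.forecast(obs, (horizon,), rng, made_at_week=current_week)[horizon]
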