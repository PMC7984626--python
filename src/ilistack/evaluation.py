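"""Forecast evaluation: error metrics, log scores, coverage, and the
leave-one-season-out harness.

The log score is the ED-forecasting variant of the CDC flu-challenge
score: the natural log of the fraction of forecast centiles 1..98 falling
within +/-25 visits of the realized count, floored at -5 (and set to -5
outright when the observation falls below the 1st or above the 99th
centile).
"""

from __future__ import annotations

import dataclasses
import logging
import pathlib
import time

import numpy as np
import pandas as pd

from .data import SeasonIndex, WeeklySeries, label_high_volume
from .ensemble import WeightVector, ensemble_forecast, naive_weights, stack_weights
from .forecast import ForecastDistribution
from .members import (
    MEMBER_NAMES,
    MemberSettings,
    build_stacking_panels,
    eligible_origins,
    forecast_season,
    smooth_all_seasons,
)

logger = logging.getLogger(__name__)

__all__ = [
    "point_metrics",
    "log_score",
    "within_tolerance_rate",
    "coverage_rate",
    "loso_evaluate",
    "EvaluationReport",
]

LOG_SCORE_FLOOR = -5.0
LOG_SCORE_TOLERANCE = 25.0


def point_metrics(predictions: np.ndarray, observations: np.ndarray
                  ) -> tuple[float, float, float]:
    """(MAE, RMSE, MAPE%) of a set of point forecasts.

    MAPE is reported in percent and requires strictly positive
    observations.
    """
    pred = np.asarray(predictions, dtype=float)
    obs = np.asarray(observations, dtype=float)
    if pred.shape != obs.shape or pred.size == 0:
        raise ValueError("predictions and observations must match and be nonempty")
    zero = np.flatnonzero(obs == 0)
    if zero.size:
        raise ValueError(f"MAPE undefined: zero observation at index {zero[0]}")
    err = pred - obs
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    mape = float(np.mean(np.abs(err) / obs) * 100.0)
    return mae, rmse, mape


def log_score(
    forecast: ForecastDistribution,
    observed: float,
    tolerance: float = LOG_SCORE_TOLERANCE,
) -> float:
    """Centile-band log score, floored at -5.

    ``log(count of centiles 1..98 within [y - tol, y + tol] / 98)``; -5 if
    the observation falls outside the (q01, q99) range or no centile is in
    the band.
    """
    q = forecast.centiles
    if observed < q[0] or observed > q[98]:
        return LOG_SCORE_FLOOR
    inside = np.sum((q[:98] >= observed - tolerance) & (q[:98] <= observed + tolerance))
    if inside == 0:
        return LOG_SCORE_FLOOR
    return max(float(np.log(inside / 98.0)), LOG_SCORE_FLOOR)


def within_tolerance_rate(
    predictions: np.ndarray, observations: np.ndarray, rel_tol: float = 0.20
) -> float:
    """Percent of point forecasts within ``rel_tol`` of the observation."""
    pred = np.asarray(predictions, dtype=float)
    obs = np.asarray(observations, dtype=float)
    if np.any(obs <= 0):
        raise ValueError("observations must be positive")
    return float(100.0 * np.mean(np.abs(pred - obs) / obs <= rel_tol))


def coverage_rate(
    forecasts: list[ForecastDistribution],
    observations: np.ndarray,
    level: float = 0.90,
) -> float:
    """Percent of observations inside the central prediction interval."""
    obs = np.asarray(observations, dtype=float)
    if len(forecasts) != obs.size:
        raise ValueError("one observation per forecast required")
    hits = [
        lo <= y <= hi
        for (lo, hi), y in zip((f.interval(level) for f in forecasts), obs)
    ]
    return float(100.0 * np.mean(hits))


# ---------------------------------------------------------------------------
# LOSO harness
# ---------------------------------------------------------------------------

ALL_MODELS = MEMBER_NAMES + ("se", "naive")


@dataclasses.dataclass
class EvaluationReport:
    """Per-forecast records plus the aggregated metric tables."""

    forecasts: pd.DataFrame        # model, season, origin, horizon, point, observed, ...
    metrics_pooled: pd.DataFrame   # (model, horizon) -> MAE/RMSE/MAPE/coverage
    logscore_by_season: pd.DataFrame
    within20_by_season: pd.DataFrame
    weights: pd.DataFrame          # (horizon, heldout season, member) -> weight
    partial_seasons: tuple[str, ...] = ()

    def write(self, outdir) -> None:
        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.metrics_pooled.to_csv(out / "metrics_pooled.csv")
        self.logscore_by_season.to_csv(out / "logscore_by_season.csv")
        self.within20_by_season.to_csv(out / "within20_by_season.csv")
        self.weights.round(2).to_csv(out / "stacking_weights.csv")
        cov = self.metrics_pooled[["coverage_90"]]
        cov.to_csv(out / "coverage.csv")
        self.forecasts.to_csv(out / "forecasts.csv", index=False,
                              float_format="%.6g")


def _aggregate(records: pd.DataFrame, series: WeeklySeries, index: SeasonIndex
               ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    pooled_rows = []
    for (model, h), g in records.groupby(["model", "horizon"]):
        mae, rmse, mape = point_metrics(g["point"], g["observed"])
        cov = 100.0 * np.mean((g["q05"] <= g["observed"]) & (g["observed"] <= g["q95"]))
        pooled_rows.append(
            {"model": model, "horizon": h, "MAE": mae, "RMSE": rmse,
             "MAPE": mape, "coverage_90": cov}
        )
    pooled = pd.DataFrame(pooled_rows).set_index(["model", "horizon"]).sort_index()

    ls = (
        records.groupby(["model", "horizon", "season"])["log_score"]
        .mean().unstack("season")
    )
    ls["all_seasons"] = records.groupby(["model", "horizon"])["log_score"].mean()

    high = label_high_volume(series, index)
    rec1 = records[records["horizon"] == 1].copy()
    rec1["high_volume"] = high[rec1["made_at"].to_numpy() + 1]
    w20_rows = []
    for model, g in rec1.groupby("model"):
        row = {"model": model, "stratum": "all"}
        for season, gs in g.groupby("season"):
            row[season] = within_tolerance_rate(gs["point"], gs["observed"])
        row["all_seasons"] = within_tolerance_rate(g["point"], g["observed"])
        w20_rows.append(row)
        gh = g[g["high_volume"]]
        row = {"model": model, "stratum": "high_volume"}
        for season, gs in gh.groupby("season"):
            if len(gs):
                row[season] = within_tolerance_rate(gs["point"], gs["observed"])
        if len(gh):
            row["all_seasons"] = within_tolerance_rate(gh["point"], gh["observed"])
        w20_rows.append(row)
    w20 = pd.DataFrame(w20_rows).set_index(["model", "stratum"])
    return pooled, ls, w20


def loso_evaluate(
    series: WeeklySeries,
    index: SeasonIndex,
    horizons: tuple[int, ...] = (1, 2, 3, 4),
    members: tuple[str, ...] = MEMBER_NAMES,
    settings: MemberSettings | None = None,
    seed: int = 0,
) -> EvaluationReport:
    """Hold out each flu season once; train, stack, forecast, and score.

    For every test season the stacking weights are re-estimated per
    horizon on an inner hold-one-season-out panel that never sees the test
    season.  The stacked weights' in-panel squared error is checked
    against every member and the naive ensemble on every run.
    """
    settings = settings or MemberSettings()
    if len(index.seasons) < 3:
        raise ValueError("leave-one-season-out evaluation needs at least 3 seasons")
    smooth_cache = smooth_all_seasons(
        series, index, settings.eb_cv_folds, settings.min_pool_season_weeks
    )
    from .features import build_feature_frame

    feature_frame = build_feature_frame(series, index)
    counts = series.counts

    records = []
    weight_rows = []
    use_ensembles = len(members) >= 1
    logger.info("LOSO evaluation: members=%s horizons=%s seed=%d",
                ",".join(members), horizons, seed)
    for s in index.seasons:
        if not len(eligible_origins(index, s, max(horizons), settings.burn_in)):
            logger.info("season %s too short to evaluate; skipped", s)
            continue
        t_fold = time.time()
        weights: dict[int, WeightVector] = {}
        panels = (
            build_stacking_panels(
                series, index, horizons, settings, seed, exclude_season=s,
                members=members, smooth_cache=smooth_cache,
                feature_frame=feature_frame,
            )
            if len(members) > 1
            else {}
        )
        for h in horizons:
            if len(members) > 1:
                panel = panels[h]
                wv = stack_weights(panel)
                obj = panel.objective(wv.w)
                for m in range(len(members)):
                    e = np.eye(len(members))[m]
                    if obj > panel.objective(e) + 1e-7 * (1 + panel.objective(e)):
                        raise RuntimeError(
                            f"stacking objective not optimal vs member {members[m]}"
                        )
                if obj > panel.objective(naive_weights(len(members)).w) + 1e-7:
                    raise RuntimeError("stacking objective not optimal vs naive")
            else:
                wv = naive_weights(1, members)
            wv.horizon = h
            wv.heldout_season = s
            weights[h] = wv
            for m, w_m in zip(members, wv.w):
                weight_rows.append(
                    {"horizon": h, "heldout_season": s, "member": m, "weight": w_m}
                )

        fcs = forecast_season(
            series, index, s, horizons, settings, seed,
            members=members, smooth_cache=smooth_cache,
            feature_frame=feature_frame,
        )
        missing = [m for m in members if m not in fcs]
        if missing:
            logger.warning("season %s: members failed: %s", s, missing)
        for h in horizons:
            for t in eligible_origins(index, s, h, settings.burn_in):
                obs = float(counts[t + h])
                member_fcs = []
                for m in members:
                    fc = fcs.get(m, {}).get((t, h))
                    if fc is not None:
                        member_fcs.append(fc)
                        records.append(_record(m, s, fc, obs))
                if use_ensembles and len(member_fcs) == len(members):
                    se = ensemble_forecast(weights[h], member_fcs, model="se")
                    nv = ensemble_forecast(
                        naive_weights(len(members), members), member_fcs,
                        model="naive")
                    records.append(_record("se", s, se, obs))
                    records.append(_record("naive", s, nv, obs))
        logger.info("season %s evaluated in %.1fs", s, time.time() - t_fold)

    rec = pd.DataFrame(records)
    pooled, ls, w20 = _aggregate(rec, series, index)
    weights_frame = (
        pd.DataFrame(weight_rows)
        .set_index(["horizon", "member", "heldout_season"])["weight"]
        .unstack("heldout_season")
        if weight_rows else pd.DataFrame()
    )
    return EvaluationReport(
        forecasts=rec,
        metrics_pooled=pooled,
        logscore_by_season=ls,
        within20_by_season=w20,
        weights=weights_frame,
        partial_seasons=index.partial_seasons,
    )


def _record(model: str, season: str, fc: ForecastDistribution, obs: float) -> dict:
    lo, hi = fc.interval(0.90)
    return {
        "model": model,
        "season": season,
        "made_at": fc.made_at_week,
        "horizon": fc.horizon,
        "point": max(fc.point, 0.0),
        "observed": obs,
        "q05": lo,
        "q95": hi,
        "log_score": log_score(fc, obs),
    }
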