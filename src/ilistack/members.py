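"""Training and forecasting orchestration for the four member models.

Everything here follows the leave-one-season-out protocol: a member is
trained on all weeks outside the excluded seasons and then forecasts the
eligible weeks of one target season at each horizon.  Prediction-time
inputs (lagged counts, season-to-date) always come from the observable
history; exclusion only restricts what a model is *trained* on.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from ._weighted import weighted_median, weighted_percentiles
from .arima import ArimaMember
from .data import SeasonIndex, WeeklySeries
from .eb import EmpiricalBayes, SmoothedTrajectory, batch_weights, smooth_season
from .ensemble import StackingPanel
from .features import MAX_LAG, QRF_FEATURES, build_feature_frame
from .forecast import CENTILES, ForecastDistribution
from .linreg import lr_fit, lr_forecast_many
from .qrf import QuantileForest

logger = logging.getLogger(__name__)

__all__ = ["MemberSettings", "MEMBER_NAMES", "forecast_season",
           "build_stacking_panel", "eligible_origins", "smooth_all_seasons"]

MEMBER_NAMES = ("eb", "arima", "qrf", "lr")


@dataclasses.dataclass
class MemberSettings:
    """Tunable sizes and orders for the member models.

    Defaults are the study configuration (EB 1e5 Monte-Carlo samples, QRF
    2000 trees / 4 predictors per split, ARIMA(2,0,1), 3-week burn-in);
    evaluation harness runs may pass smaller sizes.
    """

    burn_in: int = MAX_LAG
    eb_n_samples: int = 100_000
    eb_pacing: tuple[float, float] = (0.75, 1.25)
    eb_cv_folds: int = 5
    qrf_n_trees: int = 2000
    qrf_m_try: int = 4
    qrf_min_leaf: int = 10
    arima_order: tuple[int, int, int] = (2, 0, 1)
    stl_period: int = 52
    min_pool_season_weeks: int = 40  # seasons shorter than this are not EB sources


def eligible_origins(index: SeasonIndex, season: str, horizon: int,
                     burn_in: int = MAX_LAG) -> np.ndarray:
    """Global week positions of valid forecast origins within a season.

    An origin needs ``burn_in`` preceding weeks within the season (and
    globally) and its target ``t + horizon`` must stay inside the season.
    """
    pos = index.seasons[season]
    wos = index.week_of_season[pos]
    ok = (wos >= burn_in + 1) & (wos + horizon <= len(pos)) & (pos >= burn_in)
    return pos[ok]


def smooth_all_seasons(
    series: WeeklySeries, index: SeasonIndex, cv_folds: int = 5,
    min_weeks: int = 40,
) -> dict[str, SmoothedTrajectory]:
    """Smooth every sufficiently long season once (shared across folds)."""
    cache: dict[str, SmoothedTrajectory] = {}
    for sid, pos in index.seasons.items():
        if len(pos) >= min_weeks:
            cache[sid] = smooth_season(series.counts[pos], season_id=sid,
                                       cv_folds=cv_folds)
    return cache


def _rng_for(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed)] + [int(s) for s in stream])


def _training_rows(
    index: SeasonIndex, horizon: int, banned: set[str], n_weeks: int,
    feature_ok: np.ndarray,
) -> np.ndarray:
    """Row positions t usable for supervised training at a horizon.

    The window [t - MAX_LAG, t + horizon] must avoid all banned seasons so
    neither features nor target leak held-out data.
    """
    banned_mask = np.isin(index.season_id, list(banned))
    t = np.arange(n_weeks)
    ok = feature_ok & (t + horizon < n_weeks)
    for dt in range(-MAX_LAG, horizon + 1):
        j = np.clip(t + dt, 0, n_weeks - 1)
        ok &= ~banned_mask[j]
    return t[ok]


def forecast_season(
    series: WeeklySeries,
    index: SeasonIndex,
    test_season: str,
    horizons: tuple[int, ...],
    settings: MemberSettings,
    seed: int,
    exclude: tuple[str, ...] = (),
    members: tuple[str, ...] = MEMBER_NAMES,
    smooth_cache: dict[str, SmoothedTrajectory] | None = None,
    feature_frame: pd.DataFrame | None = None,
) -> dict[str, dict[tuple[int, int], ForecastDistribution]]:
    """Train each member without ``test_season`` (and ``exclude``) and
    forecast the test season's eligible weeks at every horizon.

    Returns ``{member: {(origin_position, horizon): forecast}}``; a member
    that fails to train is logged and omitted.
    """
    banned = set(exclude) | {test_season}
    train_seasons = [s for s in index.seasons if s not in banned]
    if not train_seasons:
        raise ValueError("no training seasons left")
    counts = series.counts
    n = len(series)
    if feature_frame is None:
        feature_frame = build_feature_frame(series, index)
    feature_ok = ~feature_frame.isna().any(axis=1).to_numpy()
    origins = {h: eligible_origins(index, test_season, h, settings.burn_in)
               for h in horizons}
    season_pos = index.seasons[test_season]
    season_start = season_pos[0]
    out: dict[str, dict[tuple[int, int], ForecastDistribution]] = {}
    s_ord = list(index.seasons).index(test_season)

    if "eb" in members:
        try:
            pool = {
                s: counts[index.seasons[s]] for s in train_seasons
                if len(index.seasons[s]) >= settings.min_pool_season_weeks
            }
            if len(pool) < 2:
                raise ValueError("need at least 2 complete seasons for the EB pool")
            eb = EmpiricalBayes(
                n_samples=settings.eb_n_samples,
                pacing_range=settings.eb_pacing,
                cv_folds=settings.eb_cv_folds,
            ).fit(pool, smoothed=smooth_cache)
            rng = _rng_for(seed, 0, s_ord, len(banned))
            V, sig = eb.sample_matrix(rng)
            fcs: dict[tuple[int, int], ForecastDistribution] = {}
            all_origins = sorted(set(np.concatenate([origins[h] for h in horizons])))
            for t in all_origins:
                obs = counts[season_start: t + 1].astype(float)
                w = batch_weights(V, sig, obs)
                if w.sum() <= 0 or not np.isfinite(w.sum()):
                    logger.warning("EB weights vanished at origin %d; using uniform", t)
                    w = np.ones(V.shape[0])
                for h in horizons:
                    if t not in origins[h]:
                        continue
                    j = obs.size + h - 1
                    vals = V[:, j] + rng.normal(0.0, sig)
                    point = max(weighted_median(vals, w), 0.0)
                    q = np.maximum(weighted_percentiles(vals, w, CENTILES), 0.0)
                    fcs[(t, h)] = ForecastDistribution(
                        made_at_week=t, horizon=h, point=point, centiles=q,
                        model="eb",
                    )
            out["eb"] = fcs
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("EB member failed on season %s: %s", test_season, exc)

    if "arima" in members:
        try:
            train_pos = np.concatenate([index.seasons[s] for s in train_seasons])
            train_pos.sort()
            member = ArimaMember(order=settings.arima_order,
                                 period=settings.stl_period)
            member.fit(counts[train_pos], index.epi_week[train_pos])
            out["arima"] = member.forecast_many(
                counts.astype(float), index.epi_week, origins
            )
        except Exception as exc:
            logger.warning("ARIMA member failed on season %s: %s", test_season, exc)

    if "qrf" in members:
        try:
            fcs = {}
            X_all = feature_frame[list(QRF_FEATURES)].to_numpy(dtype=float)
            for h in horizons:
                rows = _training_rows(index, h, banned, n, feature_ok)
                qrf = QuantileForest(
                    n_trees=settings.qrf_n_trees, m_try=settings.qrf_m_try,
                    min_samples_leaf=settings.qrf_min_leaf,
                    random_state=int(_rng_for(seed, 1, s_ord, h).integers(2**31)),
                ).fit(X_all[rows], counts[rows + h].astype(float))
                ts = origins[h]
                for t, fc in zip(ts, qrf.predict_distribution_many(
                        X_all[ts], ts, horizon=h)):
                    fcs[(t, h)] = fc
            out["qrf"] = fcs
        except Exception as exc:
            logger.warning("QRF member failed on season %s: %s", test_season, exc)

    if "lr" in members:
        try:
            fcs = {}
            for h in horizons:
                rows = _training_rows(index, h, banned, n, feature_ok)
                fit = lr_fit(feature_frame.iloc[rows], counts[rows + h].astype(float))
                ts = origins[h]
                for t, fc in zip(ts, lr_forecast_many(
                        fit, feature_frame.iloc[ts], ts, horizon=h)):
                    fcs[(t, h)] = fc
            out["lr"] = fcs
        except Exception as exc:
            logger.warning("LR member failed on season %s: %s", test_season, exc)

    return out


def build_stacking_panels(
    series: WeeklySeries,
    index: SeasonIndex,
    horizons: tuple[int, ...],
    settings: MemberSettings,
    seed: int,
    exclude_season: str | None = None,
    members: tuple[str, ...] = MEMBER_NAMES,
    smooth_cache: dict[str, SmoothedTrajectory] | None = None,
    feature_frame: pd.DataFrame | None = None,
) -> dict[int, StackingPanel]:
    """Hold out each available season in turn, collect member predictions.

    The evaluation season (``exclude_season``) is removed before the loop,
    so no panel row sees it in training or as a hold-out.  All horizons
    share one training pass per held-out season.  Rows with any missing
    member prediction are dropped listwise.
    """
    excluded = (exclude_season,) if exclude_season else ()
    loop_seasons = [s for s in index.seasons if s not in excluded]
    usable = [s for s in loop_seasons
              if len(eligible_origins(index, s, max(horizons), settings.burn_in))]
    if len(usable) < 3:
        raise ValueError(
            f"stacking needs at least 3 seasons after excluding {exclude_season!r}; "
            f"have {len(usable)}"
        )
    counts = series.counts
    rows: dict[int, list] = {h: [] for h in horizons}
    for s in usable:
        fcs = forecast_season(
            series, index, s, tuple(horizons), settings, seed,
            exclude=excluded, members=members,
            smooth_cache=smooth_cache, feature_frame=feature_frame,
        )
        for h in horizons:
            for t in eligible_origins(index, s, h, settings.burn_in):
                row = {"season": s, "origin": t, "y": float(counts[t + h])}
                complete = True
                for m in members:
                    fc = fcs.get(m, {}).get((t, h))
                    if fc is None:
                        complete = False
                        break
                    row[m] = fc.point
                if complete:
                    rows[h].append(row)
    panels = {}
    for h in horizons:
        expected = sum(
            len(eligible_origins(index, s, h, settings.burn_in)) for s in usable
        )
        if expected - len(rows[h]):
            logger.warning("stacking panel h=%d: dropped %d incomplete rows",
                           h, expected - len(rows[h]))
        frame = pd.DataFrame(rows[h])
        panels[h] = StackingPanel(
            predictions=frame[list(members)],
            observed=frame["y"].to_numpy(),
            horizon=h,
            seasons=frame["season"].to_numpy(),
        )
    return panels


def build_stacking_panel(
    series: WeeklySeries,
    index: SeasonIndex,
    horizon: int,
    settings: MemberSettings,
    seed: int,
    exclude_season: str | None = None,
    members: tuple[str, ...] = MEMBER_NAMES,
    smooth_cache: dict[str, SmoothedTrajectory] | None = None,
    feature_frame: pd.DataFrame | None = None,
) -> StackingPanel:
    """Single-horizon convenience wrapper over :func:`build_stacking_panels`."""
    return build_stacking_panels(
        series, index, (horizon,), settings, seed, exclude_season=exclude_season,
        members=members, smooth_cache=smooth_cache, feature_frame=feature_frame,
    )[horizon]
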