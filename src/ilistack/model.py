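"""Model/Results interface to the stacked ensemble.

:class:`StackedILIForecaster` is built from a weekly record;
``fit()`` estimates the per-horizon stacking weights on hold-one-season-
out panels and returns a :class:`StackedEnsembleResults` carrying the
weights, panel diagnostics and a ``summary()`` table.  Forecasting and
full leave-one-season-out evaluation hang off the results object.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import (
    DEFAULT_SEASON_START_EPIWEEK,
    SeasonIndex,
    WeeklySeries,
    build_season_index,
    read_weekly_csv,
)
from .ensemble import WeightVector, ensemble_forecast, naive_weights, stack_weights
from .evaluation import EvaluationReport, loso_evaluate
from .forecast import ForecastDistribution
from .members import (
    MEMBER_NAMES,
    MemberSettings,
    build_stacking_panels,
    forecast_season,
    smooth_all_seasons,
)

__all__ = ["StackedILIForecaster", "StackedEnsembleResults"]


class StackedILIForecaster:
    """Stacked-ensemble forecaster of weekly ILI visit counts.

    Parameters
    ----------
    series : WeeklySeries
        The weekly record (counts + covariates).
    members : tuple of str
        Member models to stack, out of ``("eb", "arima", "qrf", "lr")``.
    horizons : tuple of int
        Forecast horizons in weeks (subset of 1..4).
    settings : MemberSettings, optional
        Member model sizes; defaults are the full study configuration.
    """

    def __init__(
        self,
        series: WeeklySeries,
        index: SeasonIndex | None = None,
        members: tuple[str, ...] = MEMBER_NAMES,
        horizons: tuple[int, ...] = (1, 2, 3, 4),
        settings: MemberSettings | None = None,
    ):
        if not members:
            raise ValueError("at least one member model is required")
        bad = [m for m in members if m not in MEMBER_NAMES]
        if bad:
            raise ValueError(f"unknown member(s): {bad}")
        if not set(horizons) <= {1, 2, 3, 4}:
            raise ValueError("horizons must be a subset of {1, 2, 3, 4}")
        self.series = series
        self.index = index or build_season_index(series.week_starts)
        self.members = tuple(members)
        self.horizons = tuple(horizons)
        self.settings = settings or MemberSettings()

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame,
                       season_start_epiweek: int = DEFAULT_SEASON_START_EPIWEEK,
                       **kwargs) -> "StackedILIForecaster":
        series = WeeklySeries(frame)
        index = build_season_index(series.week_starts, season_start_epiweek)
        return cls(series, index=index, **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "StackedILIForecaster":
        return cls.from_dataframe(read_weekly_csv(path).frame, **kwargs)

    def fit(self, exclude_season: str | None = None, seed: int = 0
            ) -> "StackedEnsembleResults":
        """Estimate stacking weights per horizon.

        ``exclude_season`` removes one season entirely (the evaluation
        season in a LOSO run, or the in-progress season when forecasting
        live).
        """
        smooth_cache = smooth_all_seasons(
            self.series, self.index, self.settings.eb_cv_folds,
            self.settings.min_pool_season_weeks,
        )
        weights: dict[int, WeightVector] = {}
        panels = (
            build_stacking_panels(
                self.series, self.index, self.horizons, self.settings, seed,
                exclude_season=exclude_season, members=self.members,
                smooth_cache=smooth_cache,
            )
            if len(self.members) > 1
            else {}
        )
        for h in self.horizons:
            if len(self.members) > 1:
                wv = stack_weights(panels[h])
            else:
                wv = naive_weights(1, self.members)
            wv.horizon = h
            wv.heldout_season = exclude_season
            weights[h] = wv
        return StackedEnsembleResults(self, weights, panels, seed,
                                      smooth_cache=smooth_cache)

    def evaluate(self, seed: int = 0) -> EvaluationReport:
        """Full leave-one-season-out evaluation (weights re-fit per fold)."""
        return loso_evaluate(
            self.series, self.index, horizons=self.horizons,
            members=self.members, settings=self.settings, seed=seed,
        )


class StackedEnsembleResults:
    """Fitted stacking weights plus forecasting and diagnostics."""

    def __init__(self, model: StackedILIForecaster,
                 weights: dict[int, WeightVector], panels: dict, seed: int,
                 smooth_cache=None):
        self.model = model
        self.weights = weights
        self.panels = panels
        self.seed = seed
        self._smooth_cache = smooth_cache

    @property
    def weights_frame(self) -> pd.DataFrame:
        """Stacking weights, horizons in rows and members in columns."""
        return pd.DataFrame(
            {h: wv.as_series() for h, wv in self.weights.items()}
        ).T.rename_axis("horizon")

    def forecast(self, made_at_week: int, horizons: tuple[int, ...] | None = None
                 ) -> list[ForecastDistribution]:
        """Member, stacked and naive forecasts from a given week position.

        The season containing the origin is never part of member training
        (its weeks up to the origin still feed the season-to-date inputs).
        """
        horizons = horizons or self.model.horizons
        index = self.model.index
        season = index.season_id[made_at_week]
        fcs = forecast_season(
            self.model.series, index, season, tuple(horizons),
            self.model.settings, self.seed, members=self.model.members,
            smooth_cache=self._smooth_cache,
        )
        out: list[ForecastDistribution] = []
        for h in horizons:
            member_fcs = []
            for m in self.model.members:
                fc = fcs.get(m, {}).get((made_at_week, h))
                if fc is None:
                    raise ValueError(
                        f"no {m} forecast at week {made_at_week}, horizon {h}; "
                        "origin may be in the burn-in or run past the season"
                    )
                member_fcs.append(fc)
                out.append(fc)
            if len(self.model.members) > 1:
                out.append(ensemble_forecast(self.weights[h], member_fcs, model="se"))
                out.append(
                    ensemble_forecast(
                        naive_weights(len(self.model.members), self.model.members),
                        member_fcs, model="naive",
                    )
                )
        return out

    def summary(self) -> str:
        """Text table: stacking weights per horizon and panel diagnostics."""
        lines = ["Stacked ensemble weights", "=" * 48]
        wf = self.weights_frame
        lines.append(wf.round(2).to_string())
        if self.panels:
            lines.append("")
            lines.append("In-panel RMSE (held-out predictions)")
            lines.append("-" * 48)
            rows = []
            for h, panel in self.panels.items():
                row = {"horizon": h, "n_rows": len(panel)}
                for m in panel.members:
                    e_m = np.eye(len(panel.members))[list(panel.members).index(m)]
                    row[m] = np.sqrt(panel.objective(e_m))
                row["stacked"] = np.sqrt(panel.objective(self.weights[h].w))
                rows.append(row)
            lines.append(
                pd.DataFrame(rows).set_index("horizon").round(2).to_string()
            )
        return "\n".join(lines)
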