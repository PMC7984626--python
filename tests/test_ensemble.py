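"""Stacking weights against a brute-force simplex grid, ensemble forecast
arithmetic, and panel bookkeeping."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ilistack import (
    ForecastDistribution,
    MemberSettings,
    StackingPanel,
    build_stacking_panel,
    ensemble_forecast,
    naive_weights,
    stack_weights,
)
from ilistack.ensemble import simplex_lstsq
from ilistack.members import build_stacking_panels, eligible_origins


def grid_search_simplex(F, y, step=0.01):
    """Brute-force search of the weight simplex at fixed resolution."""
    M = F.shape[1]
    best_w, best_obj = None, np.inf
    ticks = np.arange(0, 1 + step / 2, step)
    for combo in itertools.product(ticks, repeat=M - 1):
        s = sum(combo)
        if s > 1 + 1e-9:
            continue
        w = np.array(list(combo) + [1 - s])
        obj = np.mean((y - F @ w) ** 2)
        if obj < best_obj:
            best_obj, best_w = obj, w
    return best_w, best_obj


def _panel(F, y, members=None):
    members = members or tuple(f"m{i}" for i in range(F.shape[1]))
    return StackingPanel(
        predictions=pd.DataFrame(F, columns=list(members)),
        observed=np.asarray(y, float), horizon=1,
        seasons=np.array(["s"] * len(y)),
    )


class TestStackWeights:
    def test_perfect_member_takes_all_weight(self, rng):
        # all rivals biased the same way, so no convex combination cancels
        y = rng.normal(100, 20, 80)
        F = np.column_stack([y, y + 50, y + 50, y + 50])
        wv = stack_weights(_panel(F, y))
        np.testing.assert_allclose(wv.w, [1, 0, 0, 0], atol=1e-6)
        assert _panel(F, y).objective(wv.w) < 1e-10

    def test_identical_members_equal_weights_flagged(self, rng):
        y = rng.normal(size=40)
        f = rng.normal(size=40)
        F = np.column_stack([f, f, f])
        wv = stack_weights(_panel(F, y))
        assert wv.degenerate
        np.testing.assert_allclose(wv.w, 1 / 3)

    def test_planted_weight_recovery(self, rng):
        H = 200
        f1 = rng.normal(0, 10, H)
        f2 = rng.normal(0, 10, H)
        y = 0.3 * f1 + 0.7 * f2
        F = np.column_stack([f1, f2, rng.normal(0, 10, H), rng.normal(0, 10, H)])
        wv = stack_weights(_panel(F, y))
        np.testing.assert_allclose(wv.w, [0.3, 0.7, 0, 0], atol=0.05)

    def test_agrees_with_grid_oracle(self, rng):
        for rep in range(5):
            H = int(rng.integers(10, 51))
            y = rng.normal(100, 15, H)
            F = y[:, None] + rng.normal(0, 20, (H, 3))
            w = simplex_lstsq(F, y)
            w_grid, obj_grid = grid_search_simplex(F, y)
            obj = np.mean((y - F @ w) ** 2)
            # solver must be at least as good as the grid, up to grid tolerance
            assert obj <= obj_grid + 1e-9
            np.testing.assert_allclose(w, w_grid, atol=0.02)

    def test_objective_dominates_members_and_naive(self, rng):
        for rep in range(20):
            y = rng.normal(100, 15, 60)
            F = y[:, None] + rng.normal(0, 25, (60, 4))
            panel = _panel(F, y)
            wv = stack_weights(panel)
            obj = panel.objective(wv.w)
            for m in range(4):
                assert obj <= panel.objective(np.eye(4)[m]) + 1e-9
            assert obj <= panel.objective(np.full(4, 0.25)) + 1e-9

    def test_too_few_rows_rejected(self, rng):
        F = rng.normal(size=(2, 4))
        with pytest.raises(ValueError, match="rows"):
            simplex_lstsq(F, np.zeros(2))


class TestNaiveWeights:
    def test_four_members(self):
        np.testing.assert_allclose(naive_weights(4).w, 0.25)

    def test_single_member(self):
        np.testing.assert_allclose(naive_weights(1).w, [1.0])

    @pytest.mark.parametrize("m", [2, 3, 5, 9])
    def test_sums_to_one(self, m):
        assert naive_weights(m).w.sum() == pytest.approx(1.0)


def _fc(point, q_shift=0.0, h=1, t=0, model="x"):
    centiles = point + q_shift + np.linspace(-30, 30, 99)
    return ForecastDistribution(made_at_week=t, horizon=h, point=point,
                                centiles=centiles, model=model)


class TestEnsembleForecast:
    def test_unit_weight_projects_single_member(self):
        fcs = [_fc(10), _fc(20), _fc(30), _fc(40)]
        from ilistack.ensemble import WeightVector

        w = WeightVector(np.array([0, 0, 1.0, 0]), ("a", "b", "c", "d"))
        out = ensemble_forecast(w, fcs)
        assert out.point == 30
        np.testing.assert_allclose(out.centiles, fcs[2].centiles)

    def test_equal_weights_average_points(self):
        fcs = [_fc(10), _fc(20), _fc(30), _fc(40)]
        out = ensemble_forecast(naive_weights(4), fcs)
        assert out.point == pytest.approx(25.0)

    def test_weighted_q90(self):
        from ilistack.ensemble import WeightVector

        f1 = _fc(100.0)
        f2 = _fc(120.0)
        w = WeightVector(np.array([0.5, 0.5]), ("a", "b"))
        out = ensemble_forecast(w, [f1, f2])
        expected = 0.5 * f1.centiles[89] + 0.5 * f2.centiles[89]
        assert out.centiles[89] == pytest.approx(expected)
        assert out.centiles[89] == pytest.approx(110 + np.linspace(-30, 30, 99)[89])

    def test_monotone_centiles_inherited(self, rng):
        fcs = []
        for _ in range(4):
            q = np.sort(rng.normal(100, 20, 99))
            fcs.append(ForecastDistribution(0, 1, 100.0, q))
        out = ensemble_forecast(naive_weights(4), fcs)
        assert np.all(np.diff(out.centiles) >= 0)

    def test_mismatched_horizons_rejected(self):
        with pytest.raises(ValueError, match="share"):
            ensemble_forecast(naive_weights(2), [_fc(10, h=1), _fc(10, h=2)])


class TestPanelBookkeeping:
    def test_row_count_matches_protocol(self, small_series, small_index,
                                        fast_settings):
        """H = sum over included seasons of (length - burn_in - horizon)."""
        h = 2
        panel = build_stacking_panel(
            small_series, small_index, h, fast_settings, seed=0,
            exclude_season=list(small_index.seasons)[-1],
            members=("arima", "lr"),
        )
        included = [s for s in small_index.seasons
                    if s != list(small_index.seasons)[-1]]
        expected = sum(
            len(small_index.seasons[s]) - fast_settings.burn_in - h
            for s in included
        )
        assert len(panel) == expected
        # every row's held-out season is one of the included seasons
        assert set(panel.seasons) == set(included)

    def test_truth_telling_member_column_equals_observed(
            self, small_series, small_index, fast_settings, monkeypatch):
        """A member predicting the realized count exactly yields a panel
        column equal to the observed column."""
        import ilistack.members as members_mod

        real = members_mod.forecast_season

        def oracle_member(series, index, test_season, horizons, settings,
                          seed, **kw):
            out = real(series, index, test_season, horizons, settings, seed,
                       **kw)
            counts = series.counts
            for h in horizons:
                for t in eligible_origins(index, test_season, h,
                                          settings.burn_in):
                    true = float(counts[t + h])
                    out.setdefault("lr", {})[(t, h)] = ForecastDistribution(
                        made_at_week=int(t), horizon=h, point=true,
                        centiles=np.full(99, true))
            return out

        monkeypatch.setattr(members_mod, "forecast_season", oracle_member)
        panel = members_mod.build_stacking_panel(
            small_series, small_index, 1, fast_settings, seed=0,
            members=("arima", "lr"),
        )
        np.testing.assert_allclose(panel.predictions["lr"], panel.observed)
        wv = stack_weights(panel)
        assert wv.w[list(panel.members).index("lr")] > 0.99
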