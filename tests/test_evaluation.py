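"""Metric definitions and the leave-one-season-out harness."""

import numpy as np
import pytest

from ilistack import (
    ForecastDistribution,
    coverage_rate,
    log_score,
    point_metrics,
    within_tolerance_rate,
)


class TestPointMetrics:
    def test_two_point_hand_example(self):
        mae, rmse, mape = point_metrics([10, 20], [12, 16])
        assert mae == pytest.approx(3.0)
        assert rmse == pytest.approx(np.sqrt(10))
        assert mape == pytest.approx(100 * (2 / 12 + 4 / 16) / 2)

    def test_perfect_predictions(self):
        mae, rmse, mape = point_metrics([5, 7, 9], [5, 7, 9])
        assert (mae, rmse, mape) == (0.0, 0.0, 0.0)

    def test_rmse_dominates_mae(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 30))
            pred = rng.normal(100, 20, n)
            obs = rng.uniform(50, 150, n)
            mae, rmse, _ = point_metrics(pred, obs)
            assert rmse >= mae - 1e-12
            if np.allclose(np.abs(pred - obs), np.abs(pred - obs)[0]):
                assert rmse == pytest.approx(mae)

    def test_mape_scale_invariant(self, rng):
        pred = rng.uniform(10, 100, 20)
        obs = rng.uniform(10, 100, 20)
        _, _, m1 = point_metrics(pred, obs)
        _, _, m2 = point_metrics(10 * pred, 10 * obs)
        assert m1 == pytest.approx(m2)

    def test_zero_observation_names_index(self):
        with pytest.raises(ValueError, match="index 1"):
            point_metrics([1.0, 1.0], [1.0, 0.0])


def _fc(centiles, h=1):
    return ForecastDistribution(0, h, float(np.median(centiles)),
                                np.sort(np.asarray(centiles, float)))


class TestLogScore:
    def test_full_band_scores_zero(self):
        fc = _fc(np.full(99, 100.0))
        assert log_score(fc, 100) == 0.0

    def test_half_band_scores_log_half(self):
        # 49 of the first 98 centiles inside +/-25 of the observation
        q = np.concatenate([np.full(49, 100.0), np.full(49, 1000.0), [2000.0]])
        fc = _fc(q)
        assert log_score(fc, 100) == pytest.approx(np.log(0.5))

    def test_observation_outside_tails_scores_floor(self):
        fc = _fc(np.linspace(50, 150, 99))
        assert log_score(fc, 200) == -5.0
        assert log_score(fc, 10) == -5.0

    def test_always_in_range(self, rng):
        for _ in range(200):
            fc = _fc(np.sort(rng.normal(100, 30, 99)))
            s = log_score(fc, float(rng.uniform(0, 200)))
            assert -5.0 <= s <= 0.0

    def test_empty_band_without_tail_rule(self):
        # observation within (q01, q99) but no centile inside the band
        q = np.concatenate([[0.0], np.full(97, 200.0), [400.0]])
        fc = _fc(q)
        assert log_score(fc, 100) == -5.0


class TestWithinTolerance:
    def test_inside_and_outside_20pct(self):
        assert within_tolerance_rate([85], [100]) == 100.0
        assert within_tolerance_rate([79], [100]) == 0.0

    def test_half_in(self):
        rate = within_tolerance_rate([85, 79, 120, 121], [100, 100, 100, 100])
        assert rate == pytest.approx(50.0)


class TestCoverage:
    def test_observation_at_median_always_covered(self, rng):
        fcs = [_fc(np.sort(rng.normal(100, 10, 99))) for _ in range(20)]
        obs = [fc.centiles[49] for fc in fcs]
        assert coverage_rate(fcs, obs) == 100.0

    def test_degenerate_forecasts_cover_nothing(self, rng):
        fcs = [_fc(np.full(99, 100.0)) for _ in range(50)]
        obs = 100 + rng.normal(0, 10, 50)
        obs[np.abs(obs - 100) < 1e-6] += 1.0
        assert coverage_rate(fcs, obs) == pytest.approx(0.0)

    def test_gaussian_forecasts_cover_at_nominal_rate(self, rng):
        """Monte-Carlo oracle: exact Gaussian predictive distributions cover
        the truth at 90% +/- 1% over 10^4 pairs."""
        from ilistack.forecast import gaussian_centiles

        n = 10_000
        mu = rng.uniform(50, 150, n)
        sd = 10.0
        obs = mu + rng.normal(0, sd, n)
        fcs = [ForecastDistribution(0, 1, m, gaussian_centiles(m, sd))
               for m in mu]
        assert coverage_rate(fcs, obs) == pytest.approx(90.0, abs=1.0)


@pytest.fixture(scope="module")
def report(small_series, small_index, fast_settings):
    from ilistack import loso_evaluate

    return loso_evaluate(small_series, small_index, horizons=(1, 2),
                         members=("arima", "qrf", "lr"),
                         settings=fast_settings, seed=0)


class TestLosoHarness:

    def test_rmse_at_least_mae_everywhere(self, report):
        mp = report.metrics_pooled
        assert (mp["RMSE"] >= mp["MAE"] - 1e-9).all()

    def test_all_models_and_ensembles_reported(self, report):
        models = set(report.metrics_pooled.index.get_level_values("model"))
        assert models == {"arima", "qrf", "lr", "se", "naive"}

    def test_log_scores_within_range(self, report):
        ls = report.logscore_by_season.to_numpy()
        ls = ls[~np.isnan(ls)]
        assert np.all((ls >= -5.0) & (ls <= 0.0))

    def test_weights_rows_sum_to_one(self, report):
        sums = report.weights.groupby("horizon").sum().sum(axis=1) / 4
        # 4 held-out seasons per horizon, each weight vector sums to 1
        np.testing.assert_allclose(sums, 1.0, atol=1e-6)

    def test_report_csvs_written(self, report, tmp_path):
        report.write(tmp_path)
        for name in ("metrics_pooled.csv", "logscore_by_season.csv",
                     "within20_by_season.csv", "coverage.csv",
                     "stacking_weights.csv"):
            assert (tmp_path / name).exists()

    def test_single_member_ensemble_projects(self, small_series, small_index,
                                             fast_settings):
        from ilistack import loso_evaluate

        rep = loso_evaluate(small_series, small_index, horizons=(1,),
                            members=("lr",), settings=fast_settings, seed=0)
        mp = rep.metrics_pooled
        for col in ("MAE", "RMSE", "MAPE"):
            assert mp.loc[("se", 1), col] == pytest.approx(
                mp.loc[("lr", 1), col])
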