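# Methods

This note documents the models implemented in `ilistack`, the choices made
where the design was genuinely open, and what the synthetic data generator
does and does not emulate.

## Problem setting

The package forecasts the weekly count of influenza-like-illness (ILI)
positive visits at a single emergency department, 1–4 weeks ahead. The
record is organized into flu seasons of 52–53 weeks starting near the last
week of August (configurable start epi-week, default 35). Epi-weeks follow
the MMWR convention: weeks run Sunday–Saturday and week 1 is the week
containing January 4. Seasons are the unit of cross-validation throughout.

At week *t* every forecaster emits, for horizon ℓ ∈ {1,…,4}, a point
forecast ŷ_{t+ℓ} and a vector of 99 forecast centiles — the universal
probabilistic interface that the ensemble, the log score and the coverage
analysis all consume. Points are left unfloored internally and floored at
zero on report; centile vectors are floored at zero (counts).

## Member forecasters

**Empirical Bayes (EB).** Each past season is smoothed by quadratic
(order-2) ℓ₁ trend filtering: minimize ½‖y−f‖² + λ‖D₃f‖₁, with λ chosen by
K-fold cross-validation (folds interleave week positions) over a
log-spaced grid spanning three decades below the smallest λ that forces a
single quadratic. The solver is ADMM with a dense direct solve per
iteration (a season is ~52 points); CV solves are warm-started down the λ
path at tolerance 1e-4 — they only rank λ — and the final fit is solved at
1e-7. The residual SD σ_s of each fit is the season's noise level.
Candidate futures for the current season are drawn by sampling a source
trajectory, a peak-height target and a peak-week target uniformly (and
independently) from the pool, plus a pacing factor uniform on
[0.75, 1.25]; the source curve is scaled so its maximum equals the height
target, shifted so its argmax sits at the location target, and time-dilated
about the peak by 1/pacing, with edge-hold interpolation outside the
source domain. Each candidate receives a Gaussian likelihood weight
exp(−Σ_t (y_t − f̃_t)²/2σ_s²) against the season observed so far (computed
in log space, max-rescaled); weighting precedes noise injection
(N(0, σ_s²), keyed to the source trajectory). The point forecast is the
weighted median of the sampled values at t+ℓ — the smallest ranked value
with at most half the total weight strictly on either side — and the
centiles are weighted percentiles of the same sample. The default sample
size is 10⁵; the evaluation harness and tests use 8×10²–10⁴ with
correspondingly widened tolerances, and one sample matrix is shared across
the origins of a test season (each forecast remains a valid draw from the
same sampler; weights are origin-specific).

**STL-adjusted ARIMA.** STL removes seasonality (period 52, the 53rd
epi-week folded into the 52nd's seasonal index); an ARIMA(2,0,1) is fitted
to the demeaned adjusted series by state-space ML (statsmodels). The order
is fixed at (2,0,1). Multi-step forecasts use the standard recursion with
future innovations set to zero and forecasts fed back as lags; one-step
innovations come from a filter pass with presample terms zero. The ℓ-step
forecast SD is σ̂√(Σ_{j<ℓ} ψ_j²) with ψ the MA(∞) weights; centiles are
Gaussian. The seasonal value of the target epi-week is re-added to the
point and all centiles. These intervals ignore STL estimation uncertainty
and are expected to undercover; that is replicated deliberately, not
corrected.

**Quantile regression forest (QRF).** 2000 bagged trees, m = 4 predictors
sampled per split (the √P heuristic with P = 16 predictors), minimum leaf
size 10. The predictor set: ILI count at lags 0–3, min and max temperature
at lags 0–2, immunization rate at lags 0–2, current epi-week, population,
and a year trend — 16 in total; the year trend completes the set to P = 16
and carries the small secular drift. The point forecast is the plain
forest mean. Centiles come from the weighted empirical CDF of the training
targets, with weights the average co-leaf frequency with the query across
trees; quantiles interpolate with plotting positions (C_i − w_i)/(W − w_i),
which reduces to the usual linear-interpolation sample quantile under
equal weights.

**Linear regression (LR).** One OLS fit per horizon (target shifted by ℓ)
on: current ILI count, current min/max temperature, immunization rate,
population, year trend, epi-week fixed effects (drop-one dummies), the
slope of the ILI curve (first difference y_t − y_{t−1}), and a 4-level
categorical counting upward movements over the preceding three weeks.
Dummy levels absent or aliased in a training fold are dropped
automatically (as R's `lm` marks aliased terms); collinearity among the
substantive covariates is an error naming the columns. Forecast centiles
are Gaussian with the prediction SE (parameter plus residual variance).

## Stacked ensemble

The ensemble forecast is ŷ^SE = Σ_m w_m ŷ^m with w on the probability
simplex. Weights minimize the mean squared error of held-out predictions:
each available season is held out in turn, every member is trained without
it and predicts its weeks, and the simplex-constrained least-squares
problem is solved on the pooled panel — separately per horizon and per
evaluation fold. The evaluation season is removed before this inner loop,
so weights never see their test season. The solver is SLSQP with exact
gradients, multistart (equal weights plus every unit vector), and a 1e-9
ridge that steers flat optimal faces to the minimum-norm solution; tests
verify it against a 0.01-resolution brute-force simplex grid. Degenerate
panels (all member columns identical) fall back to equal weights with a
flag. Rows with a missing member prediction are dropped listwise. The
naive ensemble uses w_m = 1/M. Ensemble centiles are the weighted average
of member centile vectors — a deliberately simple ("back-of-the-envelope")
interval whose coverage is reported rather than theoretically justified.

## Evaluation

Leave-one-season-out: each season is held out once, members (and the inner
stacking loop) are trained on the rest, and every eligible week of the
held-out season is forecast at every horizon. An origin is eligible if it
has a 3-week burn-in inside its season (lag features) and its target stays
inside the season. Metrics: MAE, RMSE, MAPE (percent) pooled per
(model, horizon); the centile-band log score — log of the fraction of
centiles 1–98 within ±25 visits of the observed count, floored at −5
(natural log; −5 also applies when the observation falls outside the
1st–99th centile range) — averaged per (model, horizon, season); the
percentage of 1-week forecasts within 20% of the observed count per season
and for high-volume weeks (top 25% of counts within each season,
ceil(0.25·n) weeks, ties to the earlier week); and the 90%-interval
coverage rate using the q05–q95 centile interval uniformly for all models
(the parametric members' Gaussian centiles make this identical to their
c·σ̂ intervals). The stacked weights' in-panel squared error is checked
against every member and the naive ensemble on every run — both are
feasible points of the stacking problem, so a violation is a solver bug
and raises.

## Synthetic data generator

Each season's latent mean is a constant baseline plus one Gaussian bump
with season-specific peak height, week and width drawn uniformly from
configured ranges; observed counts are negative-binomial (size 30 —
overdispersion comparable to a weekly-count SD of roughly half the mean).
Temperatures follow an annual sinusoid with its trough in mid-January
(winter anti-correlated with counts); the immunization rate ramps to a
plateau of 0.23 by mid-season; population grows linearly across seasons.
Defaults (baseline 150/week, peaks 160–340 above baseline at weeks 14–22,
widths 4–7 weeks, 7 calendar seasons from late August 2012) were
calibrated once so the overall mean weekly count lands near 210 with SD
near 105 and the top-quartile weekly mean near 330–355, and then frozen.
The generator emulates marginal and seasonal structure only: it has no
mechanistic transmission dynamics, no strain mixture, no reporting
artifacts, no holiday effects, and its covariates carry weaker predictive
signal than real surveillance covariates may. Passing tests therefore
demonstrate that the pipeline's contracts hold and that stacking behaves
as designed on data of this shape — not that real-data error magnitudes
would match.

## Problem sizes and numerical choices

The test suite and the acceptance script scale Monte-Carlo sizes down from
the full study configuration (EB 10⁵ → 8×10²–5×10³ samples; QRF 2000 → 50–200
trees; trend-filter CV 5 → 3 folds in the heaviest loops) — these sizes
give stable pooled metrics on ~350-week datasets while keeping full runs
fast; code defaults remain the full configuration. Other numerical
choices: σ_s floored at 1e-6; likelihood weights max-rescaled before
exponentiation, with a uniform-weight fallback (logged) if all weights
underflow; weighted-median boundary comparisons use a 1e-12 slack;
negative AR roots are rejected (stationarity) naming the roots; weekly
records must be gap-free (7-day spacing) or are rejected naming the dates.

## Known limitations

- Stacking weights are constant within a fold; time-varying weights are
  out of scope.
- The ARIMA member treats spliced training records (a held-out season
  removed from the middle) as contiguous for STL and estimation; the
  seasonal index is epi-week-based, which absorbs most of the phase error.
- Member training in a fold may see lag features that cross a season
  boundary; rows whose lag window touches a held-out season are dropped,
  at the cost of a few rows per boundary.
- The EB season grid is fixed at 53 weeks with edge-hold beyond the
  source domain; forecasts past a season's end are not attempted.
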