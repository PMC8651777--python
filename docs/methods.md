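# Methods

## The estimation problem

A dated intervention (the motivating case: US state-of-emergency
declarations in March 2020) may shift ambient pollutant concentrations.
Simple before/after comparisons confound the intervention with trend,
seasonality, weather, and autocorrelation. This package estimates the
shift counterfactually: a seasonal ARIMA model with exogenous weather
regressors is trained on several years of weekly state-level data and
projected over a short forecast window (default 16 weeks) *as if the
intervention had not happened*; the observed-minus-predicted deviations
`δ_i = C_obs,i − C_pred,i` are then contrasted before versus after the
intervention week:

    Δ = median(δ, before) − median(δ, after)

Positive `Δ` means observations sat further below the counterfactual
after the intervention — a decline attributable to it, provided the
deviations were centred near zero beforehand. For two pollutants the
ratio `ρ = Δ_NO2 / Δ_PM2.5` summarises whether they moved together
(`ρ > 0`) or apart (`ρ < 0`).

Crucially, the forecasting stage never sees the intervention date; the
date enters only in the final before/after split. This is what licenses
the causal reading of a post-intervention deviation.

## Bagged SARIMA

Point forecasts from a single SARIMA fit are fragile at this series
length, and their analytic intervals ignore specification uncertainty.
Both problems are addressed by bagging over bootstrap replicates of the
training series:

1. Transform the training series with Box-Cox (λ chosen per series by
   Guerrero's subseries coefficient-of-variation criterion, clamped to
   [0, 1]; a strictly-positive offset of half the smallest positive
   value is applied first when zeros occur).
2. Decompose additively with STL into trend, seasonal, and remainder.
   The seasonal Loess window is effectively infinite by default:
   pollutant seasonality is treated as stable across the training years.
3. Resample the remainder with a moving-block bootstrap (block length 24
   weeks by default — long enough to retain within-season dependence,
   short enough to leave many distinct blocks in a ~260-week training
   series), re-assemble, and invert the transform. The original series
   is kept as replicate 0 so the bag always contains the untouched fit.
4. Fit the SARIMA model to each replicate and project the horizon using
   the *observed* forecast-period weather — the counterfactual removes
   the intervention, not the weather.
5. Average the replicate paths into the bagged prediction `C_pred` and
   take empirical 2.5/97.5 percentiles as the 95% band.

### Model specification and order selection

The model is SARIMAX(p,d,q)(P,D,Q)_m with temperature, precipitation,
and humidity as linear regressors, fit by maximum likelihood
(statsmodels). Orders are chosen by a Hyndman–Khandakar-style stepwise
search minimising bias-corrected AIC: `d` by repeated KPSS tests, `D`
by the STL seasonal-strength heuristic (threshold 0.64), then a
deterministic neighbourhood walk over (p, q, P, Q) with ties broken
toward fewer parameters. Search caps default to p,q ≤ 2 and P,Q ≤ 1,
D ≤ 1, d ≤ 2 — at weekly seasonality (m = 52) only five seasonal cycles
fit in a five-year window, so richer seasonal orders are not estimable.
During the search the innovation variance is concentrated out of the
likelihood (same optimum, one fewer free parameter, measurably faster);
final and replicate fits are full ML.

Orders are selected once, on the original training series, and replicate
fits re-estimate coefficients only, warm-started from the original fit
(`order_policy="fixed"`). Re-running the search per replicate is
supported but costs roughly two orders of magnitude more at full scale;
the order uncertainty it would add is small relative to the remainder
resampling the bag already carries.

### What a replicate contributes to the bag

Each replicate contributes one *simulated* future trajectory drawn from
its fitted model (`path_mode="simulate"`), not its mean forecast path.
The distinction matters for calibration: the spread of mean paths across
replicates reflects only parameter/fit uncertainty and produced ~59%
coverage of null observations by the nominal 95% band in our
experiments, while simulated trajectories add innovation uncertainty and
produce ~95% coverage. The bagged mean is unaffected in expectation
(at B = 50 it acquires Monte-Carlo noise of roughly `σ_pred/√B`, a few
hundredths of a unit at desk scale). Mean-path mode remains available
for users who want a smooth point forecast only. Replicates whose fits
fail to converge are dropped and logged; the run aborts if more than
half drop.

## Uncertainty and significance of Δ

The same before/after contrast is recomputed against every replicate
trajectory, giving B draws of Δ whose 2.5/97.5 percentiles form the 95%
interval; the effect is "significant" when the interval excludes zero.
At desk-scale B = 50 the empirical percentiles are noisy and the
interval is mildly anticonservative (observed null false-positive rates
of roughly 8–13% across seeds at nominal 5%); larger B tightens this.
No multiplicity correction is applied across states — conclusions are
reported per state. A Wilcoxon-style sensitivity check can be run by the
user on the deviation windows, but the percentile interval is the
primary procedure. The week containing the intervention date is assigned
to the *after* window (the intervention acts within that week); the
opposite convention differs by one week and can be obtained by passing
`t_int_week + 1`.

## Model assessment

* **APE** — the signed mean of the horizon's deviations. Signed on
  purpose: over- and under-prediction cancel, so APE measures systematic
  displacement. Computed both for the real forecast year and for a
  validation run whose split is shifted back (default `max(horizon, m)`
  weeks) so that training and evaluation both predate the intervention;
  similar APE magnitudes in the two runs indicate the forecasting
  machinery, not the intervention, is not the source of deviations.
* **MASE** — in-sample mean absolute error scaled by the training
  window's one-step naive error (mean |Y_t − Y_{t−1}|). Values below 1
  mean the model beats carrying last week's value forward. The first
  `m + 1` fitted values are excluded: under seasonal differencing they
  are start-up artefacts of the state-space filter.

## The synthetic generator

One state's weekly concentration is

    Y_t = baseline + trend·t + amplitude·sin(2πt/period)
          + β_weather·(W_t − W̄) + AR(p) noise
          − δ_true·1[t ≥ intervention week]        (floored at 0)

with weather `W_t` itself seasonal plus noise (temperature ±10 units,
humidity ±15, precipitation non-negative). Defaults: 5 "years" of
history at a 12-week seasonal period (a deliberately compressed year
that exercises every code path — seasonal differencing, seasonal AR/MA
terms, STL — at a fraction of the m = 52 fitting cost; full-scale runs
set `seasonal_period=52`), 16-week horizon, intervention at forecast
week 9 (both windows length 8, the middle of the real panel's 8–10 week
"before" range), AR(1) noise with φ = 0.5 and unit SD, baseline 30 —
far above the injected declines of U(1, 8) units, so the non-negativity
floor almost never binds (when baseline ≈ δ_true, flooring biases the
injected shift; recovery tests therefore keep baseline ≫ δ_true).
Per-state streams are sub-seeded by a stable hash of (master seed,
state id, stream name): states are individually reproducible and
mutually independent.

The covariate generator draws emission-source shares (fire, stationary,
mobile, biogenic) from a Dirichlet and drops biogenic, log-normal
population densities, and cycled Census regions; effect outcomes follow
the full main-effects + two-factor-interaction design with per-state
noise SDs drawn from a configurable range, and those true SDs are
returned so tests can form oracle inverse-variance weights.

What the generator does **not** emulate: spatial correlation between
states, monitor-level sampling within a state, missing-data patterns
beyond short gaps, heavy-tailed pollution episodes (wildfires), or
weather–pollution interactions that change between training and forecast
periods. Passing recovery tests therefore demonstrate internal
correctness of the estimator under its own assumptions, not robustness
to these real-data features.

## Heterogeneity regression

Per-state effects Δ_j are regressed on the three source shares, log
population density (right-skewed across states), and region dummies
(Northeast reference), plus all two-factor interactions among those five
predictors; continuous predictors are centred before products are formed
so main effects keep their at-the-mean interpretation. The fit is
weighted least squares; the recommended weights are inverse bootstrap
variances of the Δ̂_j (heteroscedasticity across states is the point of
weighting — this is the single most consequential free choice in the
module, and an equal-weights sensitivity fit is one argument away).
Rank-deficient design columns are dropped greedily in column order and
reported; a single-level region drops the factor with a warning.

## Numerical and degenerate-input choices

* Box-Cox inversion clamps its argument to the transform's range:
  resampled remainders can step just below the λ > 0 floor.
* A moving-block resample with block length equal to the series length
  is defined as the identity (the only block is the series itself).
* Weekly bins are half-open 7-day intervals anchored at the first
  forecast day; a trailing partial calendar week is dropped.
* Gaps of more than two consecutive missing weeks, or any boundary gap,
  are hard errors rather than imputation targets.
* Constant training series make MASE undefined (NaN, logged), as does a
  zero PM2.5 effect for the ratio ρ.
* Effect estimation requires both windows non-empty
  (`2 ≤ t_int_week ≤ horizon`).

## Verification scale

The test-suite and acceptance-script experiments run at: effect recovery
20 states × B = 50; null calibration 80–100 states × B = 50; MASE 50
series of length 300 (orders selected on one reference realisation,
coefficients refit per series); WMLR recovery 100 replicates of 40
states. These sizes give Monte-Carlo error comfortably inside the
asserted bounds while keeping a full verification run in the
tens-of-minutes range on one CPU. Full-scale analyses (m = 52,
B = 1000) use the same code paths with the documented defaults.
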