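# Methods

## Epidemiological model

Daily death counts `Y_t` in one stratum are modelled as overdispersed
Poisson with

```
log E[Y_t] = α + Σ_{l=0}^{L} f(T_{t−l}; l) + seasonal/trend terms
```

- **Exposure basis.** `f(·; l)` is a natural cubic spline of daily mean
  temperature: piecewise cubic, C² at the knots, second derivative zero at
  the boundary knots, linear beyond them.  Internal knots sit at the
  empirical 50th/90th percentiles of the analysis-period (warm-season)
  temperatures; boundary knots at the observed min/max.  The implementation
  uses the *cardinal* basis (each column interpolates 1 at one knot, 0 at
  the others, with the lower-boundary cardinal function dropped so the
  model intercept is identified); it spans exactly the same function space
  as any other natural-spline parameterisation, which the tests verify
  against an independent truncated-power construction.
- **Lag structure.** The lag window is 0–3 days with an unconstrained
  stratum per integer lag (the richest choice for so short a window; the
  lag basis is swappable in principle but only strata are implemented).
  Cross-basis columns are ordered exposure-major with the lag index
  fastest; prediction contrasts depend on this ordering, so it is fixed.
- **Lags before subsetting.** Lagged temperatures are built on the full
  contiguous calendar *first*, and only then are outcome rows restricted to
  May–September: early-May rows take their lags from late April, never from
  the previous season's September.  Calendar gaps split the series into
  blocks, each with its own 3-day burn-in; rows with incomplete lag history
  are masked, not zero-filled or imputed.
- **Seasonality and trend.** An intercept, year main effects (first year as
  reference), a 4-df natural spline of the day of the year (internal knots
  at equally spaced percentiles of the analysis-day distribution), and the
  full product of the spline columns with the year dummies.  The year main
  effects are kept alongside the interaction so the design follows standard
  factor-expansion semantics and stays full-rank.
- **Estimation.** Quasi-Poisson via IRLS (statsmodels' Poisson GLM): point
  estimates equal Poisson ML; the covariance is scaled by the Pearson
  dispersion `φ = X²/(n−p)`.  Overdispersion therefore widens intervals but
  never moves point estimates — a property the tests assert.
- **Curve, MMT, RRs.** The overall cumulative association at temperature T
  sums the lag-specific spline contributions; its Wald variance uses the
  cross-basis block of the dispersion-scaled covariance.  The MMT is the
  curve's minimum on a 0.1 °C grid restricted to the 1st–99th percentile of
  the analysis temperatures (ties break toward the cooler temperature).
  RRs at requested percentiles are `exp` of the centered log-RR with
  `exp(log RR ± 1.96·se)` intervals.  In the stratified city run the
  whole-population fit fixes the city MMT, and every sex and sex × age
  stratum is centered there (a flag allows per-stratum minima instead);
  exposure knots are computed once from the whole-population analysis
  temperatures and shared across strata so curves are comparable
  (per-stratum knots available via the same flag mechanism).  MMT
  percentiles are reported on the warm-season temperature scale — the
  scale the analysis data live on.

## Survey model

The outcome is the number of "yes" answers (0–11) to eleven symptom items;
any missing item voids the outcome (a partially answered battery is
indistinguishable from a low count), and estimation is complete-case
(listwise deletion), with every drop counted by reason.  Predictors are
coded as in the study's table: female; age in raw years (matching the
per-year coefficient scale); partnership; living alone; two education
dummies vs. up-to-primary; good / very good financial situation vs. the
four reference answers; (almost) always using air conditioning during
heat; self-rated health 0–10; cardiovascular, hypertension, diabetes,
respiratory and depression indicators; obesity as BMI ≥ 30 (WHO
convention); regular smoking; weekly physical activity.

The fit is weighted least squares with the post-stratification weights
treated as probability weights — they enter both the estimator and the
HC1 sandwich meat `Σ wᵢ²eᵢ²xᵢxᵢᵀ` with small-sample factor `n/(n−p)` —
and t-based p-values on `n−p` degrees of freedom.  An unweighted fit is
available behind a flag.  VIFs from auxiliary regressions screen
collinearity; perfectly collinear columns report `inf` and a warning.

## Synthetic data generators

The mortality registers behind the epidemiological arm are restricted, so
validation is by parameter recovery on synthetic data.

**Temperature** is a yearly sinusoid plus stationary AR(1) noise.  City
profiles were calibrated once so the simulated warm-season distributions
match the published summaries: Warsaw (mean 9.5 °C, amplitude 10.5 °C,
AR 0.7, innovation SD 2.5 °C, 17 years) reproduces the 90th/99th
warm-season percentiles near 22.7/26.5 °C; Madrid (15.4 °C, 13.4 °C,
AR 0.7, 2.5 °C, 10 years) puts the 90th percentile near 30.7 °C.  Two
compromises are inherent to this two-parameter seasonal family: the Madrid
99th percentile runs ~1.5 °C warm, and 15.5 °C falls at roughly the 2nd–3rd
rather than the 5th warm-season percentile — cold enough tails to keep the
MMT inside the 1st–99th percentile search band, which recovery requires.

**Truth curve.** The generating exposure–response curve is an exact member
of the natural-spline family the model fits, built on the same knot rule
from the same simulated temperatures, so recovery error is estimator error,
never approximation error.  Its three coefficients solve
`f(P90)−f(MMT)=log RR₉₀`, `f(P99)−f(MMT)=log RR₉₉`, plus a third condition
pinning the cold side.  The default third condition is **stationarity**,
`f′(MMT)=0`, which makes the configured MMT the exact argmin of the curve
(implied cold-side rise ≈ 1–2% at the series minimum).  A cold-side *value*
anchor (`f(min)−f(MMT)=log cold_RR`) is available instead, but a value
anchor alone leaves the curve's true minimum ~2.5–3 °C above the nominal
MMT, which silently breaks MMT-recovery experiments — the reason
stationarity is the default.

**Deaths.**  `log μ_t = log(baseline) + 0.1·cos(2π(doy−15)/365.25) +
Σ_l w_l f(T_{t−l})` with lag weights `w = (0.4, 0.3, 0.2, 0.1)` summing to
one (so the cumulative association equals `f` exactly), a winter-peaked
log-scale seasonal term of amplitude 0.1, and negative-binomial counts with
variance = mean × 1.3 (Poisson when the overdispersion factor is 1; the
true register overdispersion is unknown, so 1.3 is a flagged guess).
Baselines of 46.6 (Warsaw) and 69.6 (Madrid) deaths/day reproduce the
published warm-season totals (~121,240 over 17 seasons; ~106,420 over 10)
within 2% in expectation.  The stratified Madrid generator splits the city
baseline over six sex × age strata (women 85+ at 10 deaths/day carrying
their published elevated risk; other strata at the whole-population
anchors).

**Survey.**  Covariates are drawn independently per a configurable rule set
(Bernoulli indicators; age uniform on 65–95; health binomial(10, p);
mutually exclusive dummy groups for education and financial situation; BMI
normal with the obesity indicator derived at the cutoff).  The latent
outcome `y* = intercept + x′β + N(0, σ)` is rounded and clipped to [0, 11],
then scattered across the 11 symptom items so outcome construction is
exercised end to end; weights are lognormal near 1, normalized to mean 1.
The rounded/clipped Gaussian keeps the OLS estimand equal to the generating
β as long as clipping is rare, so the default covariate frequencies were
chosen to center the latent count near 4.9 with small spread (<2% of latent
draws outside [0, 11]); they are a numerical design choice, *not* a
representation of the surveyed populations.  With the default anchoring
(intercept 3, residual SD 2) this keeps moderate coefficients unbiased;
indicators that shift the latent count by ~3 symptoms (the education
dummies) place their subgroup near the floor and are structurally
attenuated by 5–10% — a known limitation of any bounded-outcome generator,
documented in the recovery tests.

## What the recovery experiments do and do not show

Passing tests show the estimators recover a truth *inside the fitted model
family* under clean conditions: no measurement error in temperature, no
missing register days, independent counts given the covariates, independent
survey covariates, weights uncorrelated with outcomes.  They do not show
that the published register-based estimates are correct, nor do they probe
model misspecification (wrong knots, longer lags, harvesting), spatial
temperature heterogeneity, or informative survey non-response.

A small upward bias (≈1–2% on the RR scale) is expected and observed in
percentile-RR recovery because risks are referenced at the *estimated*
MMT — the argmin of a noisy curve — rather than the true one; the
acceptance tolerance (0.05 on the RR scale) accommodates it.  Under a flat
(null) generating surface the MMT is undefined, so null-calibration
experiments center the curve at a fixed reference temperature; against the
estimated argmin every RR would exceed 1 by construction.

## Numerical choices

- Quantiles use linear order-statistic interpolation throughout.
- IRLS convergence: relative deviance change < 1e-9, ≤ 100 iterations;
  non-convergence warns and is flagged in diagnostics, never silent.
- MMT grid: 0.1 °C; ties toward the cooler temperature.
- Wald 95% intervals use z = 1.96 on the log-RR scale.
- Curve evaluation beyond the boundary knots extrapolates linearly (the
  natural condition) and is flagged in the output.
- Rank-deficient designs fail loudly, naming the collinear columns.
- Degenerate temperature distributions (constant series) make the knot
  system singular and are rejected with an explicit message.
- All randomness flows through numpy Generators seeded from a single
  integer; replicate seeds derive from a `SeedSequence` and stay below
  2³¹.  Identical configuration + seed reproduces every generator and the
  full pipeline bit-for-bit.

## Problem sizes

Recovery experiments use the full study dimensions — 17 (Warsaw) and 10
(Madrid) simulated warm seasons of daily counts, n = 1,050 surveys — with
25 replicates for the mortality arm and 50 for the survey arm; the
null-calibration suite uses a 5-year city at 100 replicates.  These sizes
give Monte-Carlo standard errors a few times smaller than the reported
effects while keeping the whole validation suite around a minute of CPU.
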