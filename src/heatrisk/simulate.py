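"""Synthetic study-data generators with known ground truth.

Two generators stand in for data that cannot be redistributed:

* a daily temperature/mortality generator whose exposure-lag-response surface
  is an exact member of the natural-spline family the DLNM fits (so recovery
  experiments measure estimator error, not approximation error), and
* a survey generator producing the 0-11 heat-experience count from a rounded,
  clipped Gaussian latent variable, which keeps the OLS estimand equal to the
  generating coefficients as long as clipping is rare.

Temperature is a yearly sinusoid plus stationary AR(1) noise.  Daily death
counts are negative binomial around

    log mu_t = log(baseline) + seasonal term + sum_l w_l f(T_{t-l})

with lag weights ``w`` summing to one, so the cumulative association over the
lag window equals the calibrated curve ``f`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .splines import SplineSpec, ns_basis, percentile_knots

__all__ = [
    "TempConfig",
    "TruthCurve",
    "EpiSimConfig",
    "SurveySimConfig",
    "DEFAULT_LAG_WEIGHTS",
    "simulate_temperature",
    "calibrate_truth",
    "simulate_deaths",
    "simulate_epi_dataset",
    "simulate_city",
    "simulate_survey",
]

DEFAULT_LAG_WEIGHTS = (0.4, 0.3, 0.2, 0.1)
WARM_MONTHS = frozenset({5, 6, 7, 8, 9})


def _rng(seed):
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _check_finite(obj, fields):
    for name in fields:
        v = getattr(obj, name)
        if not np.all(np.isfinite(np.asarray(v, dtype=float))):
            raise ValueError(f"{type(obj).__name__}.{name} must be finite, got {v!r}")


@dataclass(frozen=True)
class TempConfig:
    """Sinusoid-plus-AR(1) daily mean temperature model for one city.

    ``noise_sd`` is the innovation SD; the marginal SD of the noise is
    ``noise_sd / sqrt(1 - ar_coefficient**2)``.
    """

    annual_mean: float
    seasonal_amplitude: float
    peak_day_of_year: int = 200
    ar_coefficient: float = 0.7
    noise_sd: float = 2.5
    n_years: int = 10
    start_year: int = 2010

    def __post_init__(self):
        _check_finite(self, ["annual_mean", "seasonal_amplitude", "peak_day_of_year",
                             "ar_coefficient", "noise_sd"])
        if self.noise_sd < 0:
            raise ValueError(f"TempConfig.noise_sd must be >= 0, got {self.noise_sd}")
        if not 0 <= self.ar_coefficient < 1:
            raise ValueError(f"TempConfig.ar_coefficient must be in [0,1), got {self.ar_coefficient}")
        if self.n_years < 1:
            raise ValueError(f"TempConfig.n_years must be >= 1, got {self.n_years}")
        if not 1 <= self.peak_day_of_year <= 366:
            raise ValueError(f"TempConfig.peak_day_of_year must be in 1..366, got {self.peak_day_of_year}")


@dataclass
class TruthCurve:
    """Generative cumulative exposure-response curve, in the fitted spline family.

    ``f`` is anchored so that f(mmt_temp) = 0 exactly; lag weights distribute
    it over the 0..3 day window and sum to one.
    """

    spline_spec: SplineSpec
    theta: np.ndarray
    mmt_temp: float
    lag_weights: tuple = DEFAULT_LAG_WEIGHTS

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.shape != (self.spline_spec.df,):
            raise ValueError(
                f"theta length {self.theta.shape} != basis dimension {self.spline_spec.df}"
            )
        w = np.asarray(self.lag_weights, dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("lag_weights must be non-negative and sum to 1")

    def f(self, temps) -> np.ndarray:
        """Cumulative log-RR at ``temps``, zero at the generative MMT."""
        temps = np.atleast_1d(np.asarray(temps, dtype=float))
        B = ns_basis(temps, self.spline_spec)
        B0 = ns_basis([self.mmt_temp], self.spline_spec)
        return (B - B0) @ self.theta


@dataclass(frozen=True)
class EpiSimConfig:
    """Full specification of one city's synthetic mortality series."""

    temp: TempConfig
    rr90: float
    rr99: float
    mmt_temp: float
    baseline_daily_deaths: float
    cold_rr: float = None  # None = stationary MMT calibration (the default)
    seasonal_baseline_amplitude: float = 0.1  # log scale
    seasonal_baseline_peak_doy: int = 15  # winter mortality peak
    overdispersion: float = 1.3
    lag_weights: tuple = DEFAULT_LAG_WEIGHTS

    def __post_init__(self):
        if min(self.rr90, self.rr99) <= 0 or (self.cold_rr is not None and self.cold_rr <= 0):
            raise ValueError("RR anchors must be > 0")
        if self.baseline_daily_deaths <= 0:
            raise ValueError("baseline_daily_deaths must be > 0")
        if self.overdispersion < 1:
            raise ValueError(f"overdispersion must be >= 1, got {self.overdispersion}")


def simulate_temperature(config: TempConfig, seed=None) -> pd.DataFrame:
    """Daily mean temperature over full calendar years.

    temperature = annual_mean
                + seasonal_amplitude * cos(2*pi*(doy - peak)/365.25)
                + AR(1) noise (stationary initialization).
    """
    rng = _rng(seed)
    start = f"{config.start_year}-01-01"
    end = f"{config.start_year + config.n_years - 1}-12-31"
    dates = pd.date_range(start, end, freq="D")
    doy = dates.dayofyear.to_numpy()
    seasonal = config.annual_mean + config.seasonal_amplitude * np.cos(
        2 * np.pi * (doy - config.peak_day_of_year) / 365.25
    )
    n = len(dates)
    ar, sd = config.ar_coefficient, config.noise_sd
    eps = rng.normal(0.0, sd, n)
    noise = np.empty(n)
    noise[0] = eps[0] / np.sqrt(1 - ar**2) if sd > 0 else 0.0
    for t in range(1, n):
        noise[t] = ar * noise[t - 1] + eps[t]
    return pd.DataFrame({"date": dates, "tmean": seasonal + noise})


def calibrate_truth(warm_temps, rr90, rr99, cold_rr=None, mmt_temp=None,
                    lag_weights=DEFAULT_LAG_WEIGHTS) -> TruthCurve:
    """Solve for the natural-spline curve hitting the requested RR anchors.

    The basis has internal knots at the empirical 50th/90th percentiles of
    ``warm_temps`` and boundary knots at its min/max, matching what the
    fitted model will build from the same temperatures.  Two hot-side
    conditions always hold:

        f(P90) - f(mmt) = log rr90
        f(P99) - f(mmt) = log rr99

    The third condition pins the cold side.  By default it is stationarity,
    ``f'(mmt) = 0``, which makes the configured MMT the exact minimum of the
    curve (with a mild implied cold-side rise).  Passing ``cold_rr`` instead
    anchors the value at the coldest observed temperature,
    ``f(min) - f(mmt) = log cold_rr``; note that a value anchor does not by
    itself place the curve's minimum at ``mmt_temp``.
    """
    from .splines import ns_basis_deriv

    warm = np.asarray(warm_temps, dtype=float)
    if warm.size == 0:
        raise ValueError("calibrate_truth: empty temperature vector")
    if mmt_temp is None:
        raise ValueError("calibrate_truth: mmt_temp is required")
    if min(rr90, rr99) <= 0 or (cold_rr is not None and cold_rr <= 0):
        raise ValueError("RR anchors must be > 0")
    lo, hi = float(warm.min()), float(warm.max())
    if not lo <= mmt_temp <= hi:
        raise ValueError(f"mmt_temp {mmt_temp} outside temperature range [{lo:.2f}, {hi:.2f}]")
    knots = percentile_knots(warm, [50.0, 90.0])
    spec = SplineSpec(internal_knots=tuple(knots), boundary_knots=(lo, hi))
    hot = np.array([np.percentile(warm, 90), np.percentile(warm, 99)])
    B0 = ns_basis([mmt_temp], spec)
    rows = [ns_basis(hot, spec) - B0]
    b = [np.log(rr90), np.log(rr99)]
    if cold_rr is None:
        rows.append(ns_basis_deriv([mmt_temp], spec))
        b.append(0.0)
    else:
        rows.append(ns_basis([lo], spec) - B0)
        b.append(np.log(cold_rr))
    A = np.vstack(rows)
    try:
        theta = np.linalg.solve(A, np.asarray(b))
    except np.linalg.LinAlgError as err:
        raise ValueError(
            "calibrate_truth: singular anchor system (degenerate temperature distribution)"
        ) from err
    return TruthCurve(spline_spec=spec, theta=theta, mmt_temp=float(mmt_temp),
                      lag_weights=tuple(lag_weights))


def expected_deaths(series: pd.DataFrame, truth: TruthCurve, config: EpiSimConfig) -> np.ndarray:
    """Per-day expected count (NaN where the lag history is incomplete)."""
    temps = series["tmean"].to_numpy(dtype=float)
    doy = pd.DatetimeIndex(series["date"]).dayofyear.to_numpy()
    n = temps.shape[0]
    w = np.asarray(truth.lag_weights, dtype=float)
    L = w.shape[0] - 1
    if n < L + 1:
        raise ValueError(f"series must cover at least {L + 1} consecutive days")
    fvals = np.where(np.isfinite(temps), 0.0, np.nan)
    ok = np.isfinite(temps)
    fvals[ok] = truth.f(temps[ok])
    lag_term = np.full(n, np.nan)
    for t in range(L, n):
        window = fvals[t - L: t + 1][::-1]  # lag 0 first
        lag_term[t] = np.dot(w, window)  # NaN if any lagged temp missing
    season = config.seasonal_baseline_amplitude * np.cos(
        2 * np.pi * (doy - config.seasonal_baseline_peak_doy) / 365.25
    )
    return config.baseline_daily_deaths * np.exp(season + lag_term)


def simulate_deaths(series: pd.DataFrame, truth: TruthCurve, config: EpiSimConfig,
                    seed=None) -> pd.DataFrame:
    """Draw daily death counts for a temperature series.

    Counts are Poisson when ``overdispersion == 1`` and negative binomial with
    variance = mean * overdispersion otherwise.  Days with incomplete lag
    history (the first ``max_lag`` days, and any day whose lag window touches
    a missing temperature) carry a missing count, never an imputed one.
    """
    rng = _rng(seed)
    mu = expected_deaths(series, truth, config)
    deaths = np.full(mu.shape, np.nan)
    ok = np.isfinite(mu)
    phi = config.overdispersion
    if phi == 1.0:
        deaths[ok] = rng.poisson(mu[ok])
    else:
        r = mu[ok] / (phi - 1.0)
        p = 1.0 / phi
        deaths[ok] = rng.negative_binomial(r, p)
    out = series.copy()
    out["deaths"] = pd.array(
        [int(d) if np.isfinite(d) else None for d in deaths], dtype="Int64"
    )
    return out


def simulate_epi_dataset(config: EpiSimConfig, seed=None):
    """Temperature + calibrated truth + death counts in one call.

    Returns ``(daily_series, truth_curve)``; the truth is calibrated on the
    realized warm-season (May-September) temperatures, so the generating RR
    at the simulated 90th/99th warm-season percentiles equals the configured
    anchors exactly.
    """
    rng = _rng(seed)
    series = simulate_temperature(config.temp, rng)
    months = pd.DatetimeIndex(series["date"]).month
    warm = series.loc[np.isin(months, sorted(WARM_MONTHS)), "tmean"].to_numpy()
    truth = calibrate_truth(
        warm, config.rr90, config.rr99, config.cold_rr, config.mmt_temp,
        lag_weights=config.lag_weights,
    )
    series = simulate_deaths(series, truth, config, rng)
    return series, truth


def simulate_city(temp_config: TempConfig, strata: dict, seed=None,
                  cold_rr: float = None, overdispersion: float = 1.3,
                  lag_weights=DEFAULT_LAG_WEIGHTS):
    """Simulate a stratified city sharing one temperature series.

    ``strata`` maps ``(sex, age_group)`` to a dict with keys ``baseline``,
    ``rr90``, ``rr99`` and ``mmt_temp``.  Every stratum gets its own truth
    curve (calibrated on the shared warm-season temperatures) and independent
    count noise.  Returns ``(long_frame, truths)`` where the frame has one
    row per date x stratum.
    """
    rng = _rng(seed)
    temps = simulate_temperature(temp_config, rng)
    months = pd.DatetimeIndex(temps["date"]).month
    warm = temps.loc[np.isin(months, sorted(WARM_MONTHS)), "tmean"].to_numpy()
    frames, truths = [], {}
    for (sex, age_group), spec in strata.items():
        truth = calibrate_truth(
            warm, spec["rr90"], spec["rr99"], spec.get("cold_rr", cold_rr),
            spec["mmt_temp"], lag_weights=lag_weights,
        )
        cfg = EpiSimConfig(
            temp=temp_config, rr90=spec["rr90"], rr99=spec["rr99"],
            mmt_temp=spec["mmt_temp"], baseline_daily_deaths=spec["baseline"],
            cold_rr=spec.get("cold_rr", cold_rr), overdispersion=overdispersion,
            lag_weights=tuple(lag_weights),
        )
        df = simulate_deaths(temps, truth, cfg, rng)
        df["sex"] = sex
        df["age_group"] = age_group
        frames.append(df)
        truths[(sex, age_group)] = truth
    return pd.concat(frames, ignore_index=True), truths


# ---------------------------------------------------------------------------
# survey generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurveySimConfig:
    """Generating model for synthetic survey microdata.

    ``beta`` maps encoded-predictor names to generating coefficients;
    ``covariate_model`` maps the same names to drawing rules:

    * ``("bernoulli", p)`` - 0/1 indicator
    * ``("uniform_int", lo, hi)`` - integer, inclusive bounds (age)
    * ``("binomial", n, p)`` - bounded integer score (self-rated health)
    * ``("group_indicator", group, p)`` - mutually exclusive dummies within
      ``group`` (education, financial situation); at most one is 1
    * ``("bmi_normal", mean, sd)`` - draws a BMI; the indicator is
      BMI >= ``bmi_cutoff``
    """

    n: int
    beta: dict
    intercept: float
    residual_sd: float
    covariate_model: dict
    bmi_cutoff: float = 30.0
    weight_sd: float = 0.1  # lognormal sigma of the post-stratification weights

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("SurveySimConfig.n must be >= 1")
        if self.residual_sd < 0:
            raise ValueError("SurveySimConfig.residual_sd must be >= 0")
        missing = [k for k in self.beta if k not in self.covariate_model]
        if missing:
            raise ValueError(f"beta names without a covariate rule: {missing}")


def _draw_covariates(config: SurveySimConfig, rng):
    """Draw the encoded design columns; returns (design df, extras dict)."""
    n = config.n
    cols = {}
    extras = {}
    groups = {}
    for name, rule in config.covariate_model.items():
        kind = rule[0]
        if kind == "group_indicator":
            groups.setdefault(rule[1], []).append((name, rule[2]))
    for name, rule in config.covariate_model.items():
        kind = rule[0]
        if kind == "bernoulli":
            cols[name] = rng.binomial(1, rule[1], n)
        elif kind == "uniform_int":
            cols[name] = rng.integers(rule[1], rule[2] + 1, n)
        elif kind == "binomial":
            cols[name] = rng.binomial(rule[1], rule[2], n)
        elif kind == "bmi_normal":
            bmi = np.clip(rng.normal(rule[1], rule[2], n), 14.0, 55.0)
            extras["bmi"] = np.round(bmi, 1)
            cols[name] = (extras["bmi"] >= config.bmi_cutoff).astype(int)
        elif kind == "group_indicator":
            pass  # drawn jointly below
        else:
            raise ValueError(f"unknown covariate rule {rule!r} for {name}")
    for group, members in groups.items():
        probs = [p for _, p in members]
        p_ref = 1.0 - sum(probs)
        if p_ref < 0:
            raise ValueError(f"group {group!r} probabilities exceed 1")
        draw = rng.choice(len(members) + 1, size=n, p=probs + [p_ref])
        for i, (name, _) in enumerate(members):
            cols[name] = (draw == i).astype(int)
    design = pd.DataFrame({name: cols[name] for name in config.beta})
    return design, extras


_FIN_GOOD = "I live (we live) frugally and there is enough for everything."
_FIN_VERY_GOOD = "There is enough for everything without saving in any particular way"
_FIN_REFERENCE = (
    "I live (we live) very frugally to save for bigger purchases.",
    "There is enough money only for the cheapest food and clothes",
    "There is enough money only for the cheapest food, not enough for clothes.",
    "There is not enough money even for the cheapest food or clothes.",
)


def _raw_from_design(design: pd.DataFrame, extras: dict, rng) -> pd.DataFrame:
    """Reconstruct raw respondent records consistent with the encoded design."""
    n = len(design)
    raw = pd.DataFrame(index=design.index)
    raw["sex"] = np.where(design["female"] == 1, "female", "male")
    raw["age"] = design["age"]
    raw["marital_status"] = np.where(
        design["married"] == 1, "married_or_partnership", "no_partnership"
    )
    raw["household"] = np.where(design["lives_alone"] == 1, "alone", "with_others")
    raw["education"] = np.select(
        [design["educ_secondary"] == 1, design["educ_tertiary"] == 1],
        ["secondary", "tertiary_or_postsecondary"],
        default="up_to_primary",
    )
    ref_fin = rng.choice(len(_FIN_REFERENCE), size=n)
    raw["financial_situation"] = np.select(
        [design["fin_good"] == 1, design["fin_very_good"] == 1],
        [_FIN_GOOD, _FIN_VERY_GOOD],
        default=None,
    )
    mask = raw["financial_situation"].isna()
    raw.loc[mask, "financial_situation"] = np.asarray(_FIN_REFERENCE)[ref_fin[mask.to_numpy()]]
    raw["ac_use"] = np.where(design["ac_always"] == 1, "almost_always", "less_often")
    raw["self_rated_health"] = design["health"]
    for c in ("cardio", "hypertension", "diabetes", "respiratory", "depression"):
        raw[c] = design[c]
    raw["bmi"] = extras.get("bmi", np.full(n, np.nan))
    raw["smokes"] = design["smokes"]
    raw["physically_active_weekly"] = design["phys_active"]
    return raw


def simulate_survey(config: SurveySimConfig, seed=None, return_design: bool = False):
    """Generate survey microdata with a known OLS-generating process.

    The latent outcome ``y* = intercept + x'beta + N(0, residual_sd)`` is
    rounded to the nearest integer and clipped to [0, 11]; the count is then
    scattered over 11 binary symptom items so the outcome-building step can
    be exercised end to end.  Post-stratification weights are lognormal near
    1, normalized to mean 1.

    Returns the raw survey table; with ``return_design=True`` also the
    encoded design and the latent outcomes.
    """
    rng = _rng(seed)
    design, extras = _draw_covariates(config, rng)
    beta = np.array([config.beta[name] for name in design.columns], dtype=float)
    latent = config.intercept + design.to_numpy(dtype=float) @ beta
    latent = latent + rng.normal(0.0, config.residual_sd, config.n)
    y = np.clip(np.rint(latent), 0, 11).astype(int)

    raw = _raw_from_design(design, extras, rng)
    symptoms = np.zeros((config.n, 11), dtype=int)
    for i, count in enumerate(y):
        if count > 0:
            symptoms[i, rng.choice(11, size=count, replace=False)] = 1
    for k in range(11):
        raw[f"symptom_{k + 1:02d}"] = symptoms[:, k]
    w = rng.lognormal(0.0, config.weight_sd, config.n) if config.weight_sd > 0 else np.ones(config.n)
    raw["weight"] = w / w.mean()
    raw = raw[[c for c in raw.columns if c.startswith("symptom_")] +
              [c for c in raw.columns if not c.startswith("symptom_")]]
    if return_design:
        return raw, design, latent
    return raw
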