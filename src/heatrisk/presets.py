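"""Ready-made study profiles for the two cities.

The temperature profiles are tuned so the simulated warm-season (May-Sep)
distributions match the cities' observed summaries: Warsaw's 90th/99th
percentiles near 22.7/26.5 degC over 17 seasons (2002-2018), Madrid's near
30.7/33.6 degC over 10 seasons (2010-2019).  Baseline death rates reproduce
the cities' warm-season totals (about 121,240 deaths over Warsaw's 17 seasons,
about 106,420 over Madrid's 10), i.e. roughly 46.6 and 69.6 deaths/day.

The RR anchors are the published whole-population cumulative heat-mortality
estimates used as generating truth in recovery experiments: Warsaw 1.16 at
the 90th and 1.39 at the 99th percentile with MMT 8.5 degC; Madrid 1.23 and
1.44 with MMT 15.5 degC; Madrid women aged 85+ 1.42 and 1.76.

The survey coefficient vectors are the two cities' published OLS estimates
for the 0-11 heat-experience count among adults 65+; they serve as
generating truth for the survey recovery experiments.  The covariate
frequencies in the default generating model are chosen so the latent count
stays well inside [0, 11] (clipping below 2%), not to mirror the survey's
sample composition.
"""

from __future__ import annotations

from .simulate import EpiSimConfig, SurveySimConfig, TempConfig

__all__ = [
    "warsaw_temp_config",
    "madrid_temp_config",
    "warsaw_epi_config",
    "madrid_epi_config",
    "madrid_city_strata",
    "WARSAW_SURVEY_BETA",
    "MADRID_SURVEY_BETA",
    "warsaw_survey_config",
    "madrid_survey_config",
]


def warsaw_temp_config() -> TempConfig:
    return TempConfig(
        annual_mean=9.5, seasonal_amplitude=10.5, peak_day_of_year=200,
        ar_coefficient=0.7, noise_sd=2.5, n_years=17, start_year=2002,
    )


def madrid_temp_config() -> TempConfig:
    return TempConfig(
        annual_mean=15.4, seasonal_amplitude=13.4, peak_day_of_year=200,
        ar_coefficient=0.7, noise_sd=2.5, n_years=10, start_year=2010,
    )


def warsaw_epi_config() -> EpiSimConfig:
    """Warsaw whole-population profile: 17 warm seasons, ~46.6 deaths/day."""
    return EpiSimConfig(
        temp=warsaw_temp_config(), rr90=1.16, rr99=1.39, mmt_temp=8.5,
        baseline_daily_deaths=46.6,
    )


def madrid_epi_config() -> EpiSimConfig:
    """Madrid whole-population profile: 10 warm seasons, ~69.6 deaths/day."""
    return EpiSimConfig(
        temp=madrid_temp_config(), rr90=1.23, rr99=1.44, mmt_temp=15.5,
        baseline_daily_deaths=69.6,
    )


def madrid_city_strata() -> dict:
    """Sex x age strata for a stratified Madrid simulation.

    The women-85+ stratum carries its published elevated risk (1.42 / 1.76);
    all other strata use the whole-population anchors.  Baselines sum to the
    city-wide ~69.6 deaths/day.
    """
    whole = {"rr90": 1.23, "rr99": 1.44, "mmt_temp": 15.5}
    women85 = {"rr90": 1.42, "rr99": 1.76, "mmt_temp": 15.5}
    return {
        ("male", "25-64"): {**whole, "baseline": 9.0},
        ("male", "65-84"): {**whole, "baseline": 19.0},
        ("male", "85+"): {**whole, "baseline": 7.6},
        ("female", "25-64"): {**whole, "baseline": 6.0},
        ("female", "65-84"): {**whole, "baseline": 18.0},
        ("female", "85+"): {**women85, "baseline": 10.0},
    }


# encoded-predictor coefficient vectors (heat-experience count, adults 65+)
WARSAW_SURVEY_BETA = {
    "female": 0.677,
    "age": -0.00310,
    "married": 0.0782,
    "lives_alone": -0.457,
    "educ_secondary": -3.120,
    "educ_tertiary": -2.823,
    "fin_good": -0.732,
    "fin_very_good": -0.715,
    "ac_always": 0.891,
    "health": -0.296,
    "cardio": 0.564,
    "hypertension": 0.113,
    "diabetes": 0.298,
    "respiratory": 1.114,
    "depression": 1.801,
    "obesity": 0.239,
    "smokes": -0.166,
    "phys_active": 0.523,
}

MADRID_SURVEY_BETA = {
    "female": 0.653,
    "age": -0.0226,
    "married": -0.271,
    "lives_alone": -0.366,
    "educ_secondary": 0.569,
    "educ_tertiary": 0.531,
    "fin_good": -0.506,
    "fin_very_good": -0.893,
    "ac_always": 0.697,
    "health": -0.226,
    "cardio": 0.978,
    "hypertension": -0.121,
    "diabetes": 0.370,
    "respiratory": 0.114,
    "depression": 0.718,
    "obesity": 0.0174,
    "smokes": 0.206,
    "phys_active": 0.597,
}

# Covariate frequencies keep the latent count centered near 5.5 with small
# spread so that fewer than 2% of latent draws fall outside [0, 11]; high-
# prevalence indicators contribute mean shift at little variance cost.
_WARSAW_COVARIATE_MODEL = {
    "female": ("bernoulli", 0.80),
    "age": ("uniform_int", 65, 95),
    "married": ("bernoulli", 0.90),
    "lives_alone": ("bernoulli", 0.10),
    "educ_secondary": ("group_indicator", "education", 0.015),
    "educ_tertiary": ("group_indicator", "education", 0.010),
    "fin_good": ("group_indicator", "financial", 0.08),
    "fin_very_good": ("group_indicator", "financial", 0.03),
    "ac_always": ("bernoulli", 0.65),
    "health": ("binomial", 10, 0.10),
    "cardio": ("bernoulli", 0.90),
    "hypertension": ("bernoulli", 0.50),
    "diabetes": ("bernoulli", 0.30),
    "respiratory": ("bernoulli", 0.10),
    "depression": ("bernoulli", 0.10),
    "obesity": ("bmi_normal", 28.0, 3.5),
    "smokes": ("bernoulli", 0.05),
    "phys_active": ("bernoulli", 0.90),
}

_MADRID_COVARIATE_MODEL = {
    **_WARSAW_COVARIATE_MODEL,
    "educ_secondary": ("group_indicator", "education", 0.30),
    "educ_tertiary": ("group_indicator", "education", 0.30),
    "fin_good": ("group_indicator", "financial", 0.15),
    "fin_very_good": ("group_indicator", "financial", 0.05),
    "ac_always": ("bernoulli", 0.30),
    "health": ("binomial", 10, 0.50),
    "cardio": ("bernoulli", 0.40),
    "hypertension": ("bernoulli", 0.50),
    "diabetes": ("bernoulli", 0.30),
    "married": ("bernoulli", 0.60),
}


def warsaw_survey_config(n: int = 1050, intercept: float = 3.0,
                         residual_sd: float = 2.0) -> SurveySimConfig:
    """Default synthetic survey: Warsaw coefficients, 1,050 respondents."""
    return SurveySimConfig(
        n=n, beta=dict(WARSAW_SURVEY_BETA), intercept=intercept,
        residual_sd=residual_sd, covariate_model=dict(_WARSAW_COVARIATE_MODEL),
    )


def madrid_survey_config(n: int = 1061, intercept: float = 6.8,
                         residual_sd: float = 2.0) -> SurveySimConfig:
    """Madrid profile: 1,061 respondents; the larger intercept offsets the
    strongly negative age and health contributions so the count stays
    interior."""
    return SurveySimConfig(
        n=n, beta=dict(MADRID_SURVEY_BETA), intercept=intercept,
        residual_sd=residual_sd, covariate_model=dict(_MADRID_COVARIATE_MODEL),
    )
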