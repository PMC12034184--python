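"""Survey analysis of heat-related experiences among older adults.

The outcome is the number of "yes" answers (0-11) to eleven symptom items
(sweating/clammy skin, dry or red skin, muscle cramps, headache, dizziness,
nausea, weakness, confusion, palpitations, chest pain, breathing difficulty)
asked as "during increased heat, do you experience X more often or more
strongly than usual?".  Predictors are encoded exactly as in the study's
coefficient table: a female indicator, age in raw years, partnership and
living-alone indicators, two education dummies against up-to-primary, two
financial-situation dummies against the four reference answers, an indicator
for (almost) always using air conditioning during heat, self-rated health on
0-10, five condition indicators, BMI-based obesity (cutoff 30 kg/m2 by
default), regular smoking, and weekly physical activity.

Estimation is complete-case weighted least squares with HC1 robust standard
errors (see :mod:`heatrisk.regression`); collinearity is screened with VIFs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regression import OLSFit, fit_wls_robust, vif

__all__ = [
    "SYMPTOM_COLUMNS",
    "PREDICTOR_ORDER",
    "build_outcome",
    "encode_predictors",
    "run_survey_model",
    "HeatExperienceOLS",
    "HeatExperienceResults",
]

SYMPTOM_COLUMNS = tuple(f"symptom_{k:02d}" for k in range(1, 12))

# design order mirrors the published coefficient table
PREDICTOR_ORDER = (
    "female", "age", "married", "lives_alone",
    "educ_secondary", "educ_tertiary", "fin_good", "fin_very_good", "ac_always",
    "health", "cardio", "hypertension", "diabetes", "respiratory", "depression",
    "obesity", "smokes", "phys_active",
)

_EDUCATION_LEVELS = {"up_to_primary", "secondary", "tertiary_or_postsecondary"}
_FIN_GOOD = "I live (we live) frugally and there is enough for everything."
_FIN_VERY_GOOD = "There is enough for everything without saving in any particular way"
_FIN_REFERENCE = {
    "I live (we live) very frugally to save for bigger purchases.",
    "There is enough money only for the cheapest food and clothes",
    "There is enough money only for the cheapest food, not enough for clothes.",
    "There is not enough money even for the cheapest food or clothes.",
}
_FIN_ALL = _FIN_REFERENCE | {_FIN_GOOD, _FIN_VERY_GOOD}
_MARITAL = {"married_or_partnership", "no_partnership", "single", "widowed", "divorced"}
_HOUSEHOLD = {"alone", "with_others"}
_AC = {"almost_always", "less_often"}
_SEX = {"male", "female"}


def build_outcome(records: pd.DataFrame) -> pd.Series:
    """Count of "yes" symptom answers per respondent, 0-11.

    Any missing item makes the whole outcome missing (complete-case rule):
    a partially answered battery cannot be distinguished from a low count.
    """
    missing_cols = [c for c in SYMPTOM_COLUMNS if c not in records.columns]
    if missing_cols:
        raise ValueError(f"survey table lacks symptom columns: {missing_cols}")
    items = records[list(SYMPTOM_COLUMNS)].apply(pd.to_numeric, errors="coerce")
    bad = ~(items.isin([0, 1]) | items.isna())
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"symptom answers must be 0/1/missing; offending value in column "
            f"{bad.columns[c]} at row {records.index[r]}"
        )
    out = items.sum(axis=1)
    out[items.isna().any(axis=1)] = np.nan
    return out.rename("heat_experiences")


def _check_labels(col: pd.Series, valid: set, what: str) -> None:
    unknown = sorted(set(col.dropna().unique()) - valid)
    if unknown:
        raise ValueError(f"unknown {what} labels {unknown}; valid: {sorted(valid)}")


def encode_predictors(records: pd.DataFrame, bmi_obesity_cutoff: float = 30.0) -> pd.DataFrame:
    """Encode raw respondent records into the model's design columns.

    Returns one row per input record (rows with missing fields keep NaN in
    the affected columns; listwise deletion happens at fit time).
    """
    df = records
    _check_labels(df["sex"], _SEX, "sex")
    _check_labels(df["marital_status"], _MARITAL, "marital_status")
    _check_labels(df["household"], _HOUSEHOLD, "household")
    _check_labels(df["education"], _EDUCATION_LEVELS, "education")
    _check_labels(df["financial_situation"], _FIN_ALL, "financial_situation")
    _check_labels(df["ac_use"], _AC, "ac_use")

    age = pd.to_numeric(df["age"], errors="coerce")
    if (age.dropna() < 65).any():
        raise ValueError("survey respondents must be aged 65+")
    health = pd.to_numeric(df["self_rated_health"], errors="coerce")
    if ((health.dropna() < 0) | (health.dropna() > 10)).any():
        raise ValueError("self_rated_health must lie in [0, 10]")

    if "bmi" in df.columns:
        bmi = pd.to_numeric(df["bmi"], errors="coerce")
    elif {"height_cm", "weight_kg"} <= set(df.columns):
        h = pd.to_numeric(df["height_cm"], errors="coerce") / 100.0
        bmi = pd.to_numeric(df["weight_kg"], errors="coerce") / h**2
    else:
        raise ValueError("survey table needs either a 'bmi' column or height_cm/weight_kg")

    def _ind(cond, source):
        out = cond.astype(float)
        out[source.isna()] = np.nan
        return out

    enc = pd.DataFrame(index=df.index)
    enc["female"] = _ind(df["sex"] == "female", df["sex"])
    enc["age"] = age
    enc["married"] = _ind(df["marital_status"] == "married_or_partnership",
                          df["marital_status"])
    enc["lives_alone"] = _ind(df["household"] == "alone", df["household"])
    enc["educ_secondary"] = _ind(df["education"] == "secondary", df["education"])
    enc["educ_tertiary"] = _ind(df["education"] == "tertiary_or_postsecondary",
                                df["education"])
    enc["fin_good"] = _ind(df["financial_situation"] == _FIN_GOOD,
                           df["financial_situation"])
    enc["fin_very_good"] = _ind(df["financial_situation"] == _FIN_VERY_GOOD,
                                df["financial_situation"])
    enc["ac_always"] = _ind(df["ac_use"] == "almost_always", df["ac_use"])
    enc["health"] = health
    for col in ("cardio", "hypertension", "diabetes", "respiratory", "depression",
                "smokes"):
        enc[col] = pd.to_numeric(df[col], errors="coerce")
    enc["obesity"] = _ind(bmi >= bmi_obesity_cutoff, bmi)
    enc["phys_active"] = pd.to_numeric(df["physically_active_weekly"], errors="coerce")
    return enc[list(PREDICTOR_ORDER)]


@dataclass
class HeatExperienceResults:
    """Fitted survey regression with diagnostics and a tidy table."""

    ols: OLSFit
    vif: pd.Series
    drops: pd.DataFrame  # per-reason drop counts
    n_input: int
    weighted: bool

    @property
    def n_used(self) -> int:
        return self.ols.n_obs

    @staticmethod
    def _stars(p: float) -> str:
        return "***" if p < 0.01 else "**" if p < 0.05 else "*" if p < 0.1 else ""

    def to_frame(self) -> pd.DataFrame:
        """Coefficient table in the study's layout: term, estimate, RSE, p, stars."""
        tab = self.ols.to_frame()
        tab["stars"] = [self._stars(p) for p in tab["p"]]
        return tab

    def summary(self) -> str:
        lines = [
            f"Heat-experience OLS ({'weighted' if self.weighted else 'unweighted'}, "
            f"HC1 robust SE)",
            f"  observations used: {self.n_used} of {self.n_input} "
            f"(dropped: {int(self.drops['n'].sum())})",
            f"  R-squared: {self.ols.r_squared:.3f}   Prob > F: {self.ols.f_pvalue:.3g}",
            f"  max VIF: {self.vif.max():.2f}",
            "",
            f"  {'term':<16}{'coef.':>9}  {'RSE':>8}",
        ]
        for _, row in self.to_frame().iterrows():
            lines.append(
                f"  {row['term']:<16}{row['estimate']:>9.3f}{row['stars']:<3}"
                f"({row['robust_se']:.3f})"
            )
        return "\n".join(lines)


class HeatExperienceOLS:
    """Weighted robust OLS of the 0-11 heat-experience count on Table-style predictors.

    Parameters
    ----------
    data : DataFrame
        Raw survey records (symptom items, raw predictor fields, and a
        ``weight`` column of post-stratification weights).
    weighted : bool
        Fit with the post-stratification weights (default) or unweighted.
    bmi_obesity_cutoff : float
        BMI threshold for the obesity indicator.
    """

    def __init__(self, data: pd.DataFrame, weighted: bool = True,
                 bmi_obesity_cutoff: float = 30.0):
        self.data = data
        self.weighted = weighted
        self.bmi_obesity_cutoff = bmi_obesity_cutoff

    @classmethod
    def from_csv(cls, path, **kwargs) -> "HeatExperienceOLS":
        return cls(pd.read_csv(path), **kwargs)

    def fit(self) -> HeatExperienceResults:
        df = self.data
        n_input = len(df)
        y = build_outcome(df)
        X = encode_predictors(df, bmi_obesity_cutoff=self.bmi_obesity_cutoff)
        if self.weighted:
            if "weight" not in df.columns:
                raise ValueError("weighted fit requires a 'weight' column")
            w = pd.to_numeric(df["weight"], errors="coerce")
        else:
            w = pd.Series(1.0, index=df.index)

        miss_y = y.isna()
        miss_x = X.isna().any(axis=1)
        miss_w = w.isna() | (w <= 0)
        keep = ~(miss_y | miss_x | miss_w)
        drops = pd.DataFrame(
            {
                "reason": ["missing_symptom_item", "missing_predictor", "invalid_weight"],
                "n": [
                    int(miss_y.sum()),
                    int((miss_x & ~miss_y).sum()),
                    int((miss_w & ~miss_y & ~miss_x).sum()),
                ],
            }
        )
        if int(keep.sum()) < 2 * (len(PREDICTOR_ORDER) + 1):
            raise ValueError(
                f"too few complete cases ({int(keep.sum())}) for "
                f"{len(PREDICTOR_ORDER) + 1} parameters"
            )
        Xk = X[keep]
        constant = [c for c in Xk.columns if Xk[c].nunique() <= 1]
        if constant:
            raise ValueError(f"zero-variance predictor column(s): {constant}")
        design = Xk.copy()
        design.insert(0, "const", 1.0)
        fit = fit_wls_robust(y[keep].to_numpy(), design, w[keep].to_numpy())
        vifs = vif(design)
        return HeatExperienceResults(ols=fit, vif=vifs, drops=drops,
                                     n_input=n_input, weighted=self.weighted)


def run_survey_model(records: pd.DataFrame, weighted: bool = True,
                     bmi_obesity_cutoff: float = 30.0) -> HeatExperienceResults:
    """Functional wrapper: complete-case weighted robust OLS + VIF + drop log."""
    return HeatExperienceOLS(records, weighted=weighted,
                             bmi_obesity_cutoff=bmi_obesity_cutoff).fit()
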