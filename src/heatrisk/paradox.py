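"""Vulnerability-paradox detection.

A group exhibits the vulnerability paradox when its objective heat-mortality
risk is elevated while its self-reported heat experiences are not (or are
reduced): the people most endangered by heat receive the weakest subjective
warning signal.  This module pairs an epidemiological risk contrast (an RR
with its 95% CI, optionally against a comparator group) with the matching
survey coefficient and applies a declared, configurable decision rule:

* risk elevated: RR > 1 with CI lower bound > 1; for group contrasts, the
  exposed group's CI must additionally lie above the comparator's point RR;
* experiences elevated: positive coefficient with p < alpha_survey; "no" for
  a significantly negative coefficient, or for one whose magnitude falls
  below a declared negligibility bound; otherwise indeterminate;
* verdict "paradox" iff risk is elevated and experiences are not.

The rule is one faithful formalization of a narrative concept; thresholds
default to a 95% CI on the epidemiological side and the coefficient table's
weakest star level (p < 0.1) on the survey side.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["FactorPair", "ParadoxAssessment", "assess", "assess_table"]


@dataclass
class FactorPair:
    """One factor's paired evidence: epidemiological contrast + survey term."""

    factor: str
    rr: float
    ci_low: float
    ci_high: float
    coef: float
    se: float
    p_value: float
    comparator_rr: float = None  # point RR of the reference group, if a group contrast
    epi_source: str = ""
    survey_source: str = ""

    def __post_init__(self):
        if min(self.rr, self.ci_low, self.ci_high) <= 0:
            raise ValueError("RR and CI bounds must be positive")
        if not 0 <= self.p_value <= 1:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass
class ParadoxAssessment:
    factor: str
    risk_elevated: str  # yes / no / indeterminate
    experiences_elevated: str
    verdict: str  # paradox / aligned / indeterminate
    reason: str = ""

    def as_dict(self) -> dict:
        return {
            "factor": self.factor,
            "risk_elevated": self.risk_elevated,
            "experiences_elevated": self.experiences_elevated,
            "verdict": self.verdict,
            "reason": self.reason,
        }


def assess(pair: FactorPair, alpha_epi: float = 0.05, alpha_survey: float = 0.1,
           negligible_coef: float = 0.1) -> ParadoxAssessment:
    """Apply the paradox rule to one factor.

    ``alpha_epi`` is carried by the CI supplied in the pair (a 95% CI encodes
    alpha 0.05); it is recorded for provenance rather than recomputed.
    """
    del alpha_epi  # encoded in the CI itself
    # epidemiological side
    if pd.isna(pair.rr) or pd.isna(pair.ci_low):
        risk = "indeterminate"
        reason = "missing epidemiological contrast"
    elif pair.rr > 1 and pair.ci_low > 1 and (
            pair.comparator_rr is None or pair.ci_low > pair.comparator_rr):
        risk = "yes"
        reason = ""
    elif pair.ci_high < 1:
        risk = "no"
        reason = ""
    else:
        risk = "indeterminate"
        reason = "epidemiological CI spans 1"

    # survey side
    if pd.isna(pair.coef) or pd.isna(pair.p_value):
        exp = "indeterminate"
        reason = (reason + "; " if reason else "") + "missing survey term"
    elif pair.p_value < alpha_survey:
        exp = "yes" if pair.coef > 0 else "no"
    elif abs(pair.coef) < negligible_coef:
        exp = "no"  # declared-negligible effect
    else:
        exp = "indeterminate"

    if risk == "yes" and exp == "no":
        verdict = "paradox"
    elif risk == "indeterminate" or exp == "indeterminate":
        verdict = "indeterminate"
    elif risk == "yes" and exp == "yes":
        verdict = "aligned"
    else:
        verdict = "aligned" if risk == exp else "indeterminate"
    return ParadoxAssessment(factor=pair.factor, risk_elevated=risk,
                             experiences_elevated=exp, verdict=verdict, reason=reason)


def assess_table(rr_table: pd.DataFrame, survey_fit: pd.DataFrame,
                 mapping: pd.DataFrame, alpha_survey: float = 0.1,
                 negligible_coef: float = 0.1) -> pd.DataFrame:
    """Assess every factor in a mapping file.

    ``mapping`` columns: ``factor``, ``rr_stratum``, ``rr_percentile``,
    ``survey_term`` and optionally ``comparator_stratum``.  The RR side is
    looked up in the pipeline's ``rr_table.csv``, the survey side in
    ``survey_fit.csv``; a factor whose rows are missing from either input is
    an error (never a silent paradox).
    """
    rows = []
    for _, m in mapping.iterrows():
        sel = rr_table[(rr_table["stratum"] == m["rr_stratum"]) &
                       (rr_table["percentile"] == m["rr_percentile"])]
        if sel.empty:
            raise ValueError(
                f"factor {m['factor']!r}: no RR entry for stratum "
                f"{m['rr_stratum']!r} at percentile {m['rr_percentile']}"
            )
        term = survey_fit[survey_fit["term"] == m["survey_term"]]
        if term.empty:
            raise ValueError(
                f"factor {m['factor']!r}: survey term {m['survey_term']!r} not found"
            )
        comparator = None
        comp = m.get("comparator_stratum")
        if isinstance(comp, str) and comp:
            csel = rr_table[(rr_table["stratum"] == comp) &
                            (rr_table["percentile"] == m["rr_percentile"])]
            if csel.empty:
                raise ValueError(
                    f"factor {m['factor']!r}: comparator stratum {comp!r} not found"
                )
            comparator = float(csel["rr"].iloc[0])
        pair = FactorPair(
            factor=m["factor"],
            rr=float(sel["rr"].iloc[0]),
            ci_low=float(sel["ci_low"].iloc[0]),
            ci_high=float(sel["ci_high"].iloc[0]),
            coef=float(term["estimate"].iloc[0]),
            se=float(term["robust_se"].iloc[0]),
            p_value=float(term["p"].iloc[0]),
            comparator_rr=comparator,
            epi_source=f"{m['rr_stratum']}@P{m['rr_percentile']}",
            survey_source=str(m["survey_term"]),
        )
        a = assess(pair, alpha_survey=alpha_survey, negligible_coef=negligible_coef)
        row = a.as_dict()
        row.update({"rr": pair.rr, "ci_low": pair.ci_low, "ci_high": pair.ci_high,
                    "coef": pair.coef, "p": pair.p_value,
                    "epi_source": pair.epi_source, "survey_source": pair.survey_source})
        rows.append(row)
    return pd.DataFrame(rows)
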