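"""Readers/writers for the fixed CSV schemas and the run configuration file.

CSV dialect is fixed: comma-separated, UTF-8, '.' decimal, ISO-8601 dates,
header row mandatory.  The daily-series schema is ``date, deaths, tmean``
plus optional ``sex`` and ``age_group`` stratum labels; a missing death count
is an empty field.
"""

from __future__ import annotations

import pathlib

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "read_daily_series",
    "write_daily_series",
    "read_survey",
    "write_survey",
    "load_run_config",
    "write_effective_config",
    "VALID_SEX",
    "VALID_AGE_GROUPS",
]

VALID_SEX = ("male", "female", "all")
VALID_AGE_GROUPS = ("25-64", "65-84", "85+", "all")


def _fail_rows(mask: pd.Series, message: str) -> None:
    if mask.any():
        lines = (np.flatnonzero(mask.to_numpy()) + 2).tolist()  # 1-based + header
        raise ValueError(f"{message} (line{'s' if len(lines) > 1 else ''} "
                         f"{lines[:10]}{'...' if len(lines) > 10 else ''})")


def read_daily_series(path) -> pd.DataFrame:
    """Read and validate a daily mortality-temperature series."""
    df = pd.read_csv(path)
    required = {"date", "deaths", "tmean"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")

    dates = pd.to_datetime(df["date"], format="ISO8601", errors="coerce")
    _fail_rows(dates.isna(), f"{path}: unparseable ISO dates")
    df["date"] = dates

    deaths = pd.to_numeric(df["deaths"], errors="coerce")
    has_value = df["deaths"].notna() & (df["deaths"].astype(str).str.strip() != "")
    _fail_rows(has_value & deaths.isna(), f"{path}: non-numeric death counts")
    _fail_rows(deaths.notna() & (deaths < 0), f"{path}: negative death counts")
    _fail_rows(deaths.notna() & (deaths % 1 != 0), f"{path}: non-integer death counts")
    df["deaths"] = deaths

    tmean = pd.to_numeric(df["tmean"], errors="coerce")
    _fail_rows(df["tmean"].notna() & tmean.isna(), f"{path}: non-numeric temperatures")
    df["tmean"] = tmean

    keys = ["date"]
    for col, valid in (("sex", VALID_SEX), ("age_group", VALID_AGE_GROUPS)):
        if col in df.columns:
            bad = sorted(set(df[col].dropna()) - set(valid))
            if bad:
                raise ValueError(f"{path}: unknown {col} labels {bad}; "
                                 f"valid: {list(valid)}")
            keys.append(col)
    if df.duplicated(subset=keys).any():
        first = df[df.duplicated(subset=keys)].iloc[0]
        raise ValueError(f"{path}: duplicate (date, stratum) record on "
                         f"{first['date'].date()}")
    return df


def write_daily_series(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    deaths = pd.to_numeric(out["deaths"], errors="coerce")
    out["deaths"] = deaths.map(lambda v: "" if pd.isna(v) else str(int(v)))
    out.to_csv(path, index=False)


def read_survey(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    from .survey import SYMPTOM_COLUMNS

    missing = [c for c in SYMPTOM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing symptom columns {missing}")
    return df


def write_survey(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


_KNOWN_KEYS = {
    "mode", "seed", "input", "output", "log_level",
    "analysis", "epi_sim", "survey_sim", "city",
}
_ANALYSIS_KEYS = {"warm_months", "knot_percentiles", "max_lag", "seasonal_df",
                  "mmt_bounds", "rr_percentiles", "mmt_grid_step", "shared_knots"}
_EPI_KEYS = {"temp", "rr90", "rr99", "mmt_temp", "baseline_daily_deaths", "cold_rr",
             "seasonal_baseline_amplitude", "seasonal_baseline_peak_doy",
             "overdispersion", "lag_weights"}
_TEMP_KEYS = {"annual_mean", "seasonal_amplitude", "peak_day_of_year",
              "ar_coefficient", "noise_sd", "n_years", "start_year"}
_SURVEY_KEYS = {"n", "beta", "intercept", "residual_sd", "covariate_model",
                "bmi_cutoff", "weight_sd"}


def load_run_config(path) -> dict:
    """Load a YAML run configuration, rejecting unknown keys."""
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    for key, allowed in (
        (None, _KNOWN_KEYS),
        ("analysis", _ANALYSIS_KEYS),
        ("epi_sim", _EPI_KEYS),
        ("survey_sim", _SURVEY_KEYS),
    ):
        section = cfg if key is None else cfg.get(key, {})
        if not isinstance(section, dict):
            raise ValueError(f"{path}: section {key!r} must be a mapping")
        unknown = set(section) - allowed
        if unknown:
            raise ValueError(f"{path}: unknown configuration keys "
                             f"{sorted(unknown)} in section {key or 'top level'}")
    temp = cfg.get("epi_sim", {}).get("temp", {})
    if temp and (set(temp) - _TEMP_KEYS):
        raise ValueError(f"{path}: unknown temperature keys {sorted(set(temp) - _TEMP_KEYS)}")
    return cfg


def write_effective_config(cfg: dict, outdir) -> pathlib.Path:
    """Echo the effective configuration so any run can be reproduced exactly."""
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "effective_config.yaml"
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return path
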