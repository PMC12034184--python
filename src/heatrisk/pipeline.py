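"""City-level heat-mortality analysis.

The estimator is a quasi-Poisson DLNM: daily death counts regressed on a
temperature x lag cross-basis (natural spline with internal knots at the
50th/90th percentile of the analysis-period temperatures, unconstrained lag
strata over 0-3 days) plus seasonality/trend control (a natural spline of the
day of the year with four degrees of freedom, its interaction with calendar
year, and year main effects).

Only warm-season (May-September) days contribute outcome rows, but lagged
temperatures are built on the full contiguous calendar first, so early-May
rows draw their lags from late April rather than from the previous season.

``HeatMortalityDLNM`` is the model object; ``fit()`` returns a
``HeatMortalityResults`` carrying the fitted curve, the empirical MMT, and
percentile relative risks.  ``run_city`` orchestrates the stratified analysis:
the whole-population model fixes the city MMT, which then serves as the
reference for every sex and sex x age stratum.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .association import (ExposureResponseCurve, MMTResult, RRBundle,
                          cumulative_curve, find_mmt, rr_at)
from .regression import GLMFit, fit_quasipoisson
from .splines import (CrossBasis, LagSpec, SplineSpec, cross_basis,
                      lag_matrix, percentile_knots)

__all__ = [
    "AnalysisConfig",
    "PreparedSeries",
    "HeatMortalityDLNM",
    "HeatMortalityResults",
    "StratifiedResults",
    "prepare_series",
    "build_seasonal_design",
    "run_stratum",
    "run_city",
]

SEXES = ("male", "female")
AGE_GROUPS = ("25-64", "65-84", "85+")


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable analysis settings, echoed verbatim into every output bundle."""

    warm_months: tuple = (5, 6, 7, 8, 9)
    knot_percentiles: tuple = (50.0, 90.0)
    max_lag: int = 3
    seasonal_df: int = 4
    mmt_bounds: tuple = (1.0, 99.0)
    rr_percentiles: tuple = (90.0, 99.0)
    mmt_grid_step: float = 0.1
    shared_knots: bool = True

    def to_dict(self) -> dict:
        return {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(self).items()}


@dataclass
class PreparedSeries:
    """Warm-season analysis rows plus the cross-basis built on full-year lags."""

    frame: pd.DataFrame  # analysis rows: date, deaths, tmean
    crossbasis: CrossBasis  # restricted to analysis rows; all rows valid
    spline_spec: SplineSpec
    temps: np.ndarray  # analysis-row temperature distribution


def prepare_series(raw: pd.DataFrame, config: AnalysisConfig,
                   spline_spec: SplineSpec = None) -> PreparedSeries:
    """Lag on the full calendar, then restrict outcomes to warm months.

    Gaps in the calendar split the series into contiguous blocks, each with
    its own lag burn-in.  Exposure knots come from the retained analysis-row
    temperatures unless a shared ``spline_spec`` is supplied.
    """
    df = raw.copy()
    df["date"] = pd.to_datetime(df["date"])
    df = df.sort_values("date").reset_index(drop=True)
    if df["date"].duplicated().any():
        dup = df.loc[df["date"].duplicated(), "date"].iloc[0]
        raise ValueError(f"duplicate date in series: {dup.date()}")
    gap = df["date"].diff().dt.days.fillna(1)
    block_ids = (gap > 1).cumsum().to_numpy()

    tmean = df["tmean"].to_numpy(dtype=float)
    _, lag_valid = lag_matrix(tmean, config.max_lag, block_ids=block_ids)
    months = df["date"].dt.month.to_numpy()
    deaths = pd.to_numeric(df["deaths"], errors="coerce").to_numpy(dtype=float)
    analysis = (
        lag_valid
        & np.isin(months, config.warm_months)
        & np.isfinite(deaths)
        & np.isfinite(tmean)
    )
    if analysis.sum() == 0:
        raise ValueError("no analysis rows: check warm_months and lag coverage")
    temps = tmean[analysis]
    if spline_spec is None:
        knots = percentile_knots(temps, config.knot_percentiles)
        spline_spec = SplineSpec(
            internal_knots=tuple(knots),
            boundary_knots=(float(temps.min()), float(temps.max())),
        )
    cb_full = cross_basis(tmean, spline_spec, LagSpec(config.max_lag), block_ids=block_ids)
    cb = CrossBasis(
        matrix=cb_full.matrix[analysis],
        spline_spec=spline_spec,
        lag_spec=cb_full.lag_spec,
        valid_rows=np.ones(int(analysis.sum()), dtype=bool),
        series=temps,
    )
    frame = df.loc[analysis, ["date", "deaths", "tmean"]].reset_index(drop=True)
    frame["deaths"] = deaths[analysis]
    return PreparedSeries(frame=frame, crossbasis=cb, spline_spec=spline_spec, temps=temps)


def build_seasonal_design(dates, seasonal_df: int = 4) -> pd.DataFrame:
    """Seasonality/trend control design.

    Columns: intercept, year main-effect dummies (reference = first year), a
    natural spline of the day of the year with ``seasonal_df`` degrees of
    freedom (internal knots at equally spaced percentiles), and all products
    of the spline columns with the year dummies.
    """
    dates = pd.DatetimeIndex(dates)
    doy = dates.dayofyear.to_numpy(dtype=float)
    years = dates.year.to_numpy()
    uyears = np.unique(years)
    for y in uyears:
        if len(np.unique(doy[years == y])) < seasonal_df + 1:
            raise ValueError(f"year {y} has too few distinct days to support a "
                             f"{seasonal_df}-df seasonal spline")
    probs = [100.0 * i / seasonal_df for i in range(1, seasonal_df)]
    internal = percentile_knots(doy, probs) if probs else np.array([])
    spec = SplineSpec(internal_knots=tuple(internal),
                      boundary_knots=(float(doy.min()), float(doy.max())))
    S = pd.DataFrame(
        {"const": np.ones(len(dates))},
        index=pd.RangeIndex(len(dates)),
    )
    from .splines import ns_basis

    B = ns_basis(doy, spec)
    year_dummies = {f"year_{y}": (years == y).astype(float) for y in uyears[1:]}
    for name, col in year_dummies.items():
        S[name] = col
    for j in range(B.shape[1]):
        S[f"doy_ns{j + 1}"] = B[:, j]
    for j in range(B.shape[1]):
        for name, col in year_dummies.items():
            S[f"doy_ns{j + 1}:{name}"] = B[:, j] * col
    return S


@dataclass
class HeatMortalityResults:
    """Fitted DLNM: curve, MMT, percentile RRs, and fit diagnostics."""

    label: str
    glm: GLMFit
    curve: ExposureResponseCurve
    mmt: MMTResult
    rr: RRBundle
    config: AnalysisConfig
    spline_spec: SplineSpec

    def rr_at(self, percentiles) -> RRBundle:
        return rr_at(self.curve, percentiles, label=self.label)

    def curve_frame(self) -> pd.DataFrame:
        return self.curve.to_frame(self.label)

    def diagnostics(self) -> dict:
        return {
            "stratum": self.label,
            "n_obs": self.glm.n_obs,
            "n_params": self.glm.n_params,
            "dispersion": self.glm.dispersion,
            "converged": self.glm.converged,
            "n_iter": self.glm.n_iter,
            "reference_temp": self.curve.reference_temp,
        }

    def summary(self) -> str:
        lines = [
            f"Heat-mortality DLNM [{self.label}]",
            f"  observations: {self.glm.n_obs}, parameters: {self.glm.n_params}, "
            f"dispersion: {self.glm.dispersion:.3f}",
            f"  MMT: {self.mmt.mmt_temp:.1f} degC "
            f"(~{self.mmt.mmt_percentile:.0f}th percentile); "
            f"curve reference: {self.curve.reference_temp:.1f} degC",
        ]
        for e in self.rr.entries:
            lines.append(
                f"  RR at P{e['percentile']:.0f} ({e['temp']:.1f} degC): "
                f"{e['rr']:.2f} [95% CI: {e['ci_low']:.2f}-{e['ci_high']:.2f}]"
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Exposure-response curve with a 95% pointwise band."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c = self.curve
        rr = np.exp(c.log_rr)
        ax.plot(c.temp_grid, rr, color="firebrick")
        ax.fill_between(c.temp_grid, np.exp(c.log_rr - 1.96 * c.se),
                        np.exp(c.log_rr + 1.96 * c.se), alpha=0.2, color="firebrick")
        ax.axhline(1.0, color="grey", lw=0.8)
        ax.axvline(self.mmt.mmt_temp, color="firebrick", ls="--", lw=0.8)
        ax.set_xlabel("mean temperature (degC)")
        ax.set_ylabel("relative risk")
        ax.set_title(self.label)
        return ax


class HeatMortalityDLNM:
    """Quasi-Poisson distributed-lag model of daily deaths on temperature.

    Parameters
    ----------
    data : DataFrame
        Daily series with columns ``date``, ``deaths``, ``tmean`` for a single
        stratum, covering full calendar years (so May lags reach into April).
    config : AnalysisConfig
    spline_spec : SplineSpec, optional
        Pre-computed exposure knots (for sharing across strata).
    label : str
        Stratum label carried into all outputs.
    """

    def __init__(self, data: pd.DataFrame, config: AnalysisConfig = None,
                 spline_spec: SplineSpec = None, label: str = "all"):
        self.config = config or AnalysisConfig()
        self.label = label
        self.prepared = prepare_series(data, self.config, spline_spec=spline_spec)
        self.seasonal = build_seasonal_design(self.prepared.frame["date"],
                                              self.config.seasonal_df)
        cb = self.prepared.crossbasis
        self.design = np.hstack([cb.matrix, self.seasonal.to_numpy(dtype=float)])
        self.design_names = cb.column_names() + list(self.seasonal.columns)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "HeatMortalityDLNM":
        from .io import read_daily_series

        return cls(read_daily_series(path), **kwargs)

    def _grid(self) -> np.ndarray:
        t = self.prepared.temps
        step = self.config.mmt_grid_step
        n = int(np.ceil((t.max() - t.min()) / step)) + 1
        return t.min() + step * np.arange(n)

    def fit(self, reference_mmt: float = None) -> HeatMortalityResults:
        """Fit the quasi-Poisson DLNM and derive curve, MMT and RRs.

        When ``reference_mmt`` is given (the city-wide MMT), the curve and the
        RRs are centered there; the stratum's own empirical MMT is still
        reported.
        """
        pr = self.prepared
        glm = fit_quasipoisson(pr.frame["deaths"].to_numpy(), self.design,
                               names=self.design_names)
        grid = self._grid()
        provisional = cumulative_curve(glm, pr.crossbasis, grid,
                                       reference=float(pr.temps.min()), temps=pr.temps)
        mmt = find_mmt(provisional, self.config.mmt_bounds)
        ref = mmt.mmt_temp if reference_mmt is None else float(reference_mmt)
        curve = cumulative_curve(glm, pr.crossbasis, grid, reference=ref, temps=pr.temps)
        rr = rr_at(curve, self.config.rr_percentiles, label=self.label)
        return HeatMortalityResults(
            label=self.label, glm=glm, curve=curve, mmt=mmt, rr=rr,
            config=self.config, spline_spec=pr.spline_spec,
        )


def run_stratum(series: pd.DataFrame, config: AnalysisConfig = None,
                reference_mmt: float = None, spline_spec: SplineSpec = None,
                label: str = "all") -> HeatMortalityResults:
    """Fit one stratum's DLNM (thin functional wrapper over the model class)."""
    model = HeatMortalityDLNM(series, config=config, spline_spec=spline_spec, label=label)
    return model.fit(reference_mmt=reference_mmt)


@dataclass
class StratifiedResults:
    """Whole-city analysis bundle: overall fit, per-stratum fits, city MMT."""

    overall: HeatMortalityResults
    by_sex: dict
    by_stratum: dict
    failures: dict
    city_mmt: MMTResult
    config: AnalysisConfig

    def _all_results(self):
        yield "all", self.overall
        for sex, res in self.by_sex.items():
            yield sex, res
        for (sex, age), res in self.by_stratum.items():
            yield f"{sex}_{age}", res

    def rr_table(self) -> pd.DataFrame:
        return pd.concat([res.rr.to_frame() for _, res in self._all_results()],
                         ignore_index=True)

    def curves_frame(self) -> pd.DataFrame:
        return pd.concat([res.curve_frame() for _, res in self._all_results()],
                         ignore_index=True)

    def mmt_frame(self) -> pd.DataFrame:
        rows = [
            {"stratum": label, "mmt_temp": res.mmt.mmt_temp,
             "mmt_percentile": res.mmt.mmt_percentile}
            for label, res in self._all_results()
        ]
        return pd.DataFrame(rows)

    def diagnostics_frame(self) -> pd.DataFrame:
        rows = [res.diagnostics() for _, res in self._all_results()]
        for factor, reason in self.failures.items():
            rows.append({"stratum": factor, "n_obs": 0, "converged": False,
                         "dispersion": np.nan, "n_params": 0, "n_iter": 0,
                         "reference_temp": np.nan, "failure": reason})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        parts = [self.overall.summary()]
        parts += [res.summary() for _, res in list(self._all_results())[1:]]
        if self.failures:
            parts.append("Failed strata: " + ", ".join(
                f"{k} ({v})" for k, v in self.failures.items()))
        return "\n\n".join(parts)


def _aggregate(df: pd.DataFrame, keys=None) -> pd.DataFrame:
    """Sum stratum death counts per date; missing counts propagate."""
    wide = df.pivot_table(index="date", columns=keys, values="deaths",
                          aggfunc="first", dropna=False)
    deaths = wide.sum(axis=1, skipna=False)
    tmean = df.groupby("date")["tmean"].first()
    return pd.DataFrame({"date": deaths.index, "deaths": deaths.to_numpy(),
                         "tmean": tmean.reindex(deaths.index).to_numpy()})


def run_city(series: pd.DataFrame, config: AnalysisConfig = None) -> StratifiedResults:
    """Stratified city analysis mirroring the study design.

    Fits the whole-population model first, extracts the city MMT, then fits
    sex strata and sex x age strata centered at that MMT.  With
    ``config.shared_knots`` (the default) every stratum reuses the exposure
    knots computed from the whole-population analysis temperatures, so the
    stratum curves are directly comparable.  A failed stratum is recorded,
    not fatal.
    """
    config = config or AnalysisConfig()
    df = series.copy()
    df["date"] = pd.to_datetime(df["date"])
    for col in ("sex", "age_group"):
        if col not in df.columns:
            df[col] = "all"

    strata_df = df[(df["sex"] != "all") | (df["age_group"] != "all")]
    if "all" in set(df["sex"]) and (df["sex"] == "all").any() and \
            (df.loc[df["sex"] == "all", "age_group"] == "all").any():
        overall_df = df[(df["sex"] == "all") & (df["age_group"] == "all")][
            ["date", "deaths", "tmean"]]
    else:
        overall_df = _aggregate(strata_df, keys=["sex", "age_group"])

    overall_model = HeatMortalityDLNM(overall_df, config=config, label="all")
    overall = overall_model.fit()
    city_mmt = overall.mmt
    shared_spec = overall.spline_spec if config.shared_knots else None

    by_sex, by_stratum, failures = {}, {}, {}
    present_sexes = [s for s in SEXES if (strata_df["sex"] == s).any()]
    for sex in present_sexes:
        sub = strata_df[strata_df["sex"] == sex]
        try:
            agg = _aggregate(sub, keys=["age_group"])
            by_sex[sex] = run_stratum(agg, config, reference_mmt=city_mmt.mmt_temp,
                                      spline_spec=shared_spec, label=sex)
        except Exception as err:  # noqa: BLE001 - stratum failures are recorded
            failures[sex] = str(err)
        ages = [a for a in AGE_GROUPS if ((sub["age_group"] == a).any())]
        for age in ages:
            stratum = sub[sub["age_group"] == age][["date", "deaths", "tmean"]]
            try:
                by_stratum[(sex, age)] = run_stratum(
                    stratum, config, reference_mmt=city_mmt.mmt_temp,
                    spline_spec=shared_spec, label=f"{sex}_{age}")
            except Exception as err:  # noqa: BLE001
                failures[f"{sex}_{age}"] = str(err)
    return StratifiedResults(overall=overall, by_sex=by_sex, by_stratum=by_stratum,
                             failures=failures, city_mmt=city_mmt, config=config)
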