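"""From a fitted DLNM to the epidemiological quantities of interest.

The overall cumulative exposure-response association at temperature T is the
sum over the lag window of the lag-specific spline contributions.  With the
strata lag basis the cumulative contrast vector c(T) is the exposure-basis
row at T repeated once per lag stratum; centering at a reference temperature
(the minimum mortality temperature, MMT) gives

    log RR(T) = (c(T) - c(ref))' beta_cb
    var       = (c(T) - c(ref))' Sigma_cb (c(T) - c(ref))

using the cross-basis sub-block of the dispersion-scaled covariance.
Confidence intervals are Wald on the log scale (z = 1.96 for 95%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regression import GLMFit
from .splines import CrossBasis, ns_basis

__all__ = [
    "ExposureResponseCurve",
    "MMTResult",
    "RRBundle",
    "cumulative_curve",
    "find_mmt",
    "rr_at",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class ExposureResponseCurve:
    """Centered cumulative log-RR over a temperature grid, with pointwise SE."""

    temp_grid: np.ndarray
    log_rr: np.ndarray
    se: np.ndarray
    reference_temp: float
    temps: np.ndarray  # analysis-period temperature sample, for percentile lookups
    extrapolated: np.ndarray  # grid points outside the boundary knots

    def temp_of_percentile(self, p: float) -> float:
        return float(np.percentile(self.temps, p))

    def percentile_of(self, temp: float) -> float:
        t = np.sort(self.temps)
        return float(np.searchsorted(t, temp, side="right")) / t.size * 100.0

    def nearest_index(self, temp: float) -> int:
        return int(np.argmin(np.abs(self.temp_grid - temp)))

    def to_frame(self, label: str = "all") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stratum": label,
                "temp": self.temp_grid,
                "log_rr": self.log_rr,
                "se": self.se,
                "extrapolated": self.extrapolated,
            }
        )


@dataclass
class MMTResult:
    """Empirical minimum mortality temperature and its sample percentile."""

    mmt_temp: float
    mmt_percentile: float


@dataclass
class RRBundle:
    """Relative risks with 95% CIs at requested temperature percentiles."""

    label: str
    entries: list  # of dict(percentile, temp, rr, ci_low, ci_high)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.entries)
        df.insert(0, "stratum", self.label)
        return df

    def rr(self, percentile: float) -> float:
        for e in self.entries:
            if e["percentile"] == percentile:
                return e["rr"]
        raise KeyError(f"no entry at percentile {percentile}")


def _cumulative_contrast(temp, cb: CrossBasis) -> np.ndarray:
    """Contrast rows mapping cross-basis coefficients to the cumulative curve."""
    temp = np.atleast_1d(np.asarray(temp, dtype=float))
    B = ns_basis(temp, cb.spline_spec)  # n x d
    n_lag = cb.lag_spec.df
    # exposure-major ordering: repeat each exposure column across its lag block
    return np.repeat(B, n_lag, axis=1)


def cumulative_curve(fit: GLMFit, cb: CrossBasis, temp_grid, reference: float,
                     temps=None) -> ExposureResponseCurve:
    """Overall cumulative exposure-response curve centered at ``reference``.

    The leading columns of the fitted design must be ``cb``'s columns in
    cross-basis order; only that coefficient sub-block is used.
    ``temps`` is the analysis-period temperature sample backing percentile
    lookups (defaults to the exposure series the cross-basis was built from).
    """
    temp_grid = np.asarray(temp_grid, dtype=float)
    if temp_grid.ndim != 1 or np.any(np.diff(temp_grid) <= 0):
        raise ValueError("temp_grid must be strictly increasing")
    k = cb.n_columns
    beta = fit.beta[:k]
    cov = fit.cov[:k, :k]
    delta = _cumulative_contrast(temp_grid, cb) - _cumulative_contrast(reference, cb)
    log_rr = delta @ beta
    var = np.einsum("ij,jk,ik->i", delta, cov, delta)
    se = np.sqrt(np.maximum(var, 0.0))
    if temps is None:
        temps = cb.series[np.isfinite(cb.series)]
    lo, hi = cb.spline_spec.boundary_knots
    extrapolated = (temp_grid < lo) | (temp_grid > hi)
    return ExposureResponseCurve(
        temp_grid=temp_grid,
        log_rr=log_rr,
        se=se,
        reference_temp=float(reference),
        temps=np.asarray(temps, dtype=float),
        extrapolated=extrapolated,
    )


def find_mmt(curve: ExposureResponseCurve, bounds=(1.0, 99.0)) -> MMTResult:
    """Grid temperature minimizing the cumulative log-RR within percentile bounds.

    Ties break toward the lower temperature.  The default search window is
    the 1st-99th percentile of the analysis temperature distribution.
    """
    lo_t = curve.temp_of_percentile(bounds[0])
    hi_t = curve.temp_of_percentile(bounds[1])
    inside = (curve.temp_grid >= lo_t) & (curve.temp_grid <= hi_t)
    if not inside.any():
        raise ValueError(
            f"MMT bounds {bounds} map to [{lo_t:.2f}, {hi_t:.2f}] degC, outside the grid"
        )
    sub = np.flatnonzero(inside)
    best = sub[np.argmin(curve.log_rr[inside])]  # argmin takes the first (coolest) tie
    mmt = float(curve.temp_grid[best])
    return MMTResult(mmt_temp=mmt, mmt_percentile=curve.percentile_of(mmt))


def rr_at(curve: ExposureResponseCurve, percentiles, label: str = "all") -> RRBundle:
    """RR = exp(log RR) with Wald 95% CI at the grid point nearest each percentile."""
    entries = []
    for p in np.atleast_1d(percentiles):
        if not 0 <= p <= 100:
            raise ValueError(f"percentile {p} outside [0, 100]")
        t = curve.temp_of_percentile(p)
        i = curve.nearest_index(t)
        lrr, se = curve.log_rr[i], curve.se[i]
        entries.append(
            {
                "percentile": float(p),
                "temp": float(curve.temp_grid[i]),
                "rr": float(np.exp(lrr)),
                "ci_low": float(np.exp(lrr - Z95 * se)),
                "ci_high": float(np.exp(lrr + Z95 * se)),
            }
        )
    return RRBundle(label=label, entries=entries)
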