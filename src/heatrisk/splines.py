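"""Natural cubic spline bases, lagged exposure matrices, and the DLNM cross-basis.

The exposure basis is a natural cubic spline: piecewise cubic, C2-continuous
at its knots, with zero second derivative at the boundary knots and linear
extrapolation beyond them.  The basis returned here is the *cardinal* natural
spline basis: column ``j`` is the natural interpolating spline taking the
value 1 at knot ``j+1`` and 0 at every other knot (the cardinal function
attached to the lower boundary knot is dropped, so an intercept can live in
the surrounding regression design without rank deficiency).  With ``k``
internal knots the basis has ``k + 1`` columns.

The lag structure is unconstrained ("strata"): one stratum per integer lag,
so the lag basis over a 0..L window is the (L+1)-dimensional identity and the
cross-basis is the exposure basis evaluated at each lagged temperature.
Cross-basis columns are ordered exposure-major: column ``j*(L+1) + l`` is
exposure function ``j`` at lag ``l`` (the lag index varies fastest).  This
ordering is fixed because cumulative-association contrast vectors must match
it exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "SplineSpec",
    "LagSpec",
    "CrossBasis",
    "percentile_knots",
    "ns_basis",
    "lag_matrix",
    "cross_basis",
]


@dataclass(frozen=True)
class SplineSpec:
    """Knot layout of a natural cubic spline basis.

    Parameters
    ----------
    internal_knots : tuple of float
        Interior knots, strictly inside the boundary interval.
    boundary_knots : (float, float)
        Interval ends where the spline becomes linear.
    """

    internal_knots: tuple
    boundary_knots: tuple

    def __post_init__(self):
        internal = tuple(float(v) for v in self.internal_knots)
        boundary = tuple(float(v) for v in self.boundary_knots)
        object.__setattr__(self, "internal_knots", internal)
        object.__setattr__(self, "boundary_knots", boundary)
        if len(boundary) != 2 or not boundary[0] < boundary[1]:
            raise ValueError(f"boundary_knots must be an increasing pair, got {boundary}")
        if any(not np.isfinite(v) for v in internal + boundary):
            raise ValueError("spline knots must be finite")
        if list(internal) != sorted(internal):
            raise ValueError(f"internal_knots must be sorted ascending, got {internal}")
        if internal and (internal[0] <= boundary[0] or internal[-1] >= boundary[1]):
            raise ValueError(
                f"internal knots {internal} must lie strictly inside boundary {boundary}"
            )

    @property
    def df(self) -> int:
        """Basis dimension (internal knot count + 1)."""
        return len(self.internal_knots) + 1

    @property
    def all_knots(self) -> np.ndarray:
        return np.array([self.boundary_knots[0], *self.internal_knots, self.boundary_knots[1]])


@dataclass(frozen=True)
class LagSpec:
    """Lag window and lag-basis form (only the unconstrained 'strata' form)."""

    max_lag: int
    basis_type: str = "strata"

    def __post_init__(self):
        if self.max_lag < 0:
            raise ValueError(f"max_lag must be >= 0, got {self.max_lag}")
        if self.basis_type != "strata":
            raise ValueError(f"unsupported lag basis_type {self.basis_type!r}")

    @property
    def df(self) -> int:
        return self.max_lag + 1


@dataclass
class CrossBasis:
    """Exposure x lag design block plus the specs needed to rebuild contrasts."""

    matrix: np.ndarray
    spline_spec: SplineSpec
    lag_spec: LagSpec
    valid_rows: np.ndarray
    series: np.ndarray = field(repr=False, default=None)

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def column_names(self) -> list:
        L = self.lag_spec.max_lag
        return [f"cb_ns{j + 1}_lag{l}" for j in range(self.spline_spec.df) for l in range(L + 1)]


def percentile_knots(values, probs) -> np.ndarray:
    """Empirical quantiles by linear order-statistic interpolation, sorted.

    ``probs`` are percentages in (0, 100).
    """
    values = np.asarray(values, dtype=float)
    probs = np.atleast_1d(np.asarray(probs, dtype=float))
    if values.size == 0:
        raise ValueError("percentile_knots: empty value vector")
    if not np.all(np.isfinite(values)):
        raise ValueError("percentile_knots: values contain non-finite entries")
    if np.any((probs <= 0) | (probs >= 100)):
        raise ValueError(f"percentile probabilities must lie in (0, 100), got {probs}")
    return np.sort(np.percentile(values, probs, method="linear"))


class _NaturalSplineBasis:
    """Callable cardinal natural-spline basis for a fixed SplineSpec."""

    def __init__(self, spec: SplineSpec):
        self.spec = spec
        knots = spec.all_knots
        self._splines = []
        for j in range(1, len(knots)):  # drop the cardinal function at the lower boundary
            y = np.zeros(len(knots))
            y[j] = 1.0
            self._splines.append(CubicSpline(knots, y, bc_type="natural"))
        self._lo, self._hi = spec.boundary_knots

    def __call__(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        bad = np.flatnonzero(~np.isfinite(x))
        if bad.size:
            raise ValueError(f"ns_basis: non-finite values at indices {bad.tolist()[:10]}")
        out = np.empty((x.size, len(self._splines)))
        below = x < self._lo
        above = x > self._hi
        inside = ~(below | above)
        for j, s in enumerate(self._splines):
            col = np.empty_like(x)
            col[inside] = s(x[inside])
            # natural boundary condition: linear extrapolation
            if below.any():
                col[below] = s(self._lo) + s.derivative()(self._lo) * (x[below] - self._lo)
            if above.any():
                col[above] = s(self._hi) + s.derivative()(self._hi) * (x[above] - self._hi)
            out[:, j] = col
        return out

    def deriv(self, x) -> np.ndarray:
        """First derivative of each basis column at ``x``."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if np.any(~np.isfinite(x)):
            raise ValueError("ns_basis derivative: non-finite input")
        out = np.empty((x.size, len(self._splines)))
        clipped = np.clip(x, self._lo, self._hi)  # derivative is constant beyond bounds
        for j, s in enumerate(self._splines):
            out[:, j] = s.derivative()(clipped)
        return out


def ns_basis(x, spec: SplineSpec) -> np.ndarray:
    """Evaluate the natural cubic spline basis at ``x``; returns n x spec.df."""
    return _NaturalSplineBasis(spec)(x)


def ns_basis_deriv(x, spec: SplineSpec) -> np.ndarray:
    """First derivative of the natural spline basis columns at ``x``."""
    return _NaturalSplineBasis(spec).deriv(x)


def lag_matrix(series, max_lag: int, block_ids=None):
    """Lagged copies of a daily series.

    Column ``l`` holds the series shifted by ``l`` days (value at day ``t-l``
    aligned to row ``t``).  Rows whose lag history crosses a block boundary
    (or the start of the series) are flagged invalid, never zero-filled.

    Parameters
    ----------
    series : 1-d array
        Values ordered by contiguous calendar day.
    max_lag : int
        Largest lag, in days.
    block_ids : 1-d array, optional
        Identifier per row; rows with different ids are treated as separate
        contiguous blocks, each with its own burn-in.

    Returns
    -------
    (matrix, valid) : n x (max_lag+1) float array, boolean mask
    """
    series = np.asarray(series, dtype=float)
    n = series.shape[0]
    if max_lag < 0:
        raise ValueError("max_lag must be >= 0")
    if block_ids is None:
        block_ids = np.zeros(n, dtype=int)
    else:
        block_ids = np.asarray(block_ids)
        if block_ids.shape[0] != n:
            raise ValueError("block_ids must match series length")
    mat = np.full((n, max_lag + 1), np.nan)
    valid = np.ones(n, dtype=bool)
    for l in range(max_lag + 1):
        if l == 0:
            mat[:, 0] = series
        else:
            mat[l:, l] = series[:-l]
            same_block = np.zeros(n, dtype=bool)
            same_block[l:] = block_ids[l:] == block_ids[:-l]
            mat[~same_block, l] = np.nan
            valid &= same_block
    valid &= np.all(np.isfinite(mat), axis=1)
    return mat, valid


def cross_basis(series, spline_spec, lag_spec: LagSpec, block_ids=None) -> CrossBasis:
    """Build the DLNM cross-basis for a daily exposure series.

    With the strata lag basis, column ``(j, l)`` at row ``t`` is exposure
    basis function ``j`` evaluated at ``series[t-l]``.  Passing
    ``spline_spec=None`` uses the identity exposure basis (a single linear
    column), which reduces the cross-basis to the plain lag matrix.
    """
    series = np.asarray(series, dtype=float)
    lagmat, valid = lag_matrix(series, lag_spec.max_lag, block_ids=block_ids)
    n = series.shape[0]
    n_lag = lag_spec.df
    if spline_spec is None:
        d = 1
        basis = lambda v: v.reshape(-1, 1)  # noqa: E731 - identity exposure basis
    else:
        d = spline_spec.df
        basis = _NaturalSplineBasis(spline_spec)
    mat = np.full((n, d * n_lag), np.nan)
    for l in range(n_lag):
        col = lagmat[:, l]
        ok = np.isfinite(col)
        if ok.any():
            B = basis(col[ok])
            for j in range(d):
                mat[ok, j * n_lag + l] = B[:, j]
    mat[~valid, :] = np.nan
    return CrossBasis(matrix=mat, spline_spec=spline_spec, lag_spec=lag_spec,
                      valid_rows=valid, series=series)
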