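"""Core estimators: quasi-Poisson GLM, weighted robust OLS, and VIF diagnostics.

Fitting is delegated to statsmodels; these wrappers pin down the exact
estimator variants used throughout the package and return plain result
containers:

* quasi-Poisson: Poisson-score IRLS (point estimates identical to Poisson
  maximum likelihood) with the covariance scaled by the Pearson dispersion
  ``phi = X2 / (n - p)``;
* weighted least squares with an HC1 sandwich covariance, bread
  ``(X'WX)^-1``, meat ``sum_i w_i^2 e_i^2 x_i x_i'``, small-sample factor
  ``n/(n-p)``, and t-based p-values on ``n - p`` degrees of freedom
  (survey-statistics convention);
* variance inflation factors from auxiliary regressions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["GLMFit", "OLSFit", "fit_quasipoisson", "fit_wls_robust", "vif"]


@dataclass
class GLMFit:
    """Quasi-Poisson fit: coefficients plus dispersion-scaled covariance."""

    beta: np.ndarray
    cov: np.ndarray
    dispersion: float
    n_obs: int
    n_params: int
    converged: bool
    n_iter: int
    names: list = field(default_factory=list)

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


@dataclass
class OLSFit:
    """Weighted least-squares fit with HC1 (sandwich) standard errors."""

    beta: pd.Series
    robust_se: pd.Series
    t_stats: pd.Series
    p_values: pd.Series
    cov: pd.DataFrame
    n_obs: int
    r_squared: float
    f_pvalue: float

    def to_frame(self) -> pd.DataFrame:
        """Tidy coefficient table (term, estimate, robust_se, t, p)."""
        return pd.DataFrame(
            {
                "term": self.beta.index,
                "estimate": self.beta.values,
                "robust_se": self.robust_se.values,
                "t": self.t_stats.values,
                "p": self.p_values.values,
            }
        )


def _check_full_rank(X: np.ndarray, names) -> None:
    """Raise naming (nearly) collinear columns if X is rank deficient."""
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # pivoted QR: pivots with negligible R diagonal index the dependent columns
        import scipy.linalg

        _, r, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(n, p) * np.finfo(float).eps
        bad = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol] + [
            names[j] for j in piv[len(diag):]
        ]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def _as_matrix(X):
    if isinstance(X, pd.DataFrame):
        return X.values.astype(float), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, [f"x{j}" for j in range(X.shape[1])]


def fit_quasipoisson(y, X, names=None, max_iter: int = 100, tol: float = 1e-9) -> GLMFit:
    """Fit a log-link quasi-Poisson GLM by IRLS.

    Point estimates equal Poisson ML; the covariance is
    ``phi * (X'WX)^-1`` with ``phi`` the Pearson chi-square over ``n - p``.
    """
    Xmat, colnames = _as_matrix(X)
    if names is not None:
        colnames = list(names)
    y = np.asarray(y, dtype=float)
    if y.shape[0] != Xmat.shape[0]:
        raise ValueError("y and X have different numbers of rows")
    if np.any(~np.isfinite(y)) or np.any(~np.isfinite(Xmat)):
        raise ValueError("y and X must be finite (exclude masked rows before fitting)")
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    n, p = Xmat.shape
    if n <= p:
        raise ValueError(f"need n_obs > n_params, got n={n}, p={p}")
    _check_full_rank(Xmat, colnames)

    model = sm.GLM(y, Xmat, family=sm.families.Poisson())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(scale="X2", maxiter=max_iter, tol=tol)
    n_iter = len(res.fit_history["deviance"]) - 1
    converged = bool(res.converged)
    if not converged:
        warnings.warn("quasi-Poisson IRLS did not converge", RuntimeWarning)
    return GLMFit(
        beta=np.asarray(res.params, dtype=float),
        cov=np.asarray(res.cov_params(), dtype=float),
        dispersion=float(res.scale),
        n_obs=n,
        n_params=p,
        converged=converged,
        n_iter=n_iter,
        names=colnames,
    )


def fit_wls_robust(y, X, w=None) -> OLSFit:
    """Weighted least squares with HC1 sandwich covariance.

    Weights are treated as probability weights: they enter both the point
    estimator and the sandwich meat.  ``w=None`` fits unweighted OLS.
    """
    Xmat, colnames = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    n, p = Xmat.shape
    if w is None:
        w = np.ones(n)
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0) or np.any(~np.isfinite(w)):
        raise ValueError("weights must be positive and finite")
    if y.shape[0] != n or w.shape[0] != n:
        raise ValueError("y, X and w must have matching lengths")
    _check_full_rank(Xmat, colnames)

    res = sm.WLS(y, Xmat, weights=w).fit(cov_type="HC1", use_t=True)
    idx = pd.Index(colnames, name="term")
    return OLSFit(
        beta=pd.Series(res.params, index=idx),
        robust_se=pd.Series(res.bse, index=idx),
        t_stats=pd.Series(res.tvalues, index=idx),
        p_values=pd.Series(res.pvalues, index=idx),
        cov=pd.DataFrame(res.cov_params(), index=idx, columns=idx),
        n_obs=int(res.nobs),
        r_squared=float(res.rsquared),
        f_pvalue=float(res.f_pvalue),
    )


def vif(X, intercept_name: str = None) -> pd.Series:
    """Variance inflation factors, one per non-intercept column.

    ``VIF_j = 1 / (1 - R^2_j)`` from regressing column j on all the others
    (including the intercept).  Perfectly collinear columns report ``inf``.
    """
    Xmat, colnames = _as_matrix(X)
    const_cols = [j for j in range(Xmat.shape[1]) if np.ptp(Xmat[:, j]) == 0]
    if intercept_name is not None:
        const_cols = [j for j in const_cols if colnames[j] == intercept_name] or const_cols
    if not const_cols:
        raise ValueError("vif: design must contain an intercept column")
    out = {}
    for j in range(Xmat.shape[1]):
        if j in const_cols:
            continue
        others = np.delete(Xmat, j, axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r2 = sm.OLS(Xmat[:, j], others).fit().rsquared
        out[colnames[j]] = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
    s = pd.Series(out, name="vif")
    if np.isinf(s).any():
        warnings.warn(
            f"perfect collinearity: infinite VIF for {list(s.index[np.isinf(s)])}",
            RuntimeWarning,
        )
    return s
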