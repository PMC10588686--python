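"""Closing statistics: trait-space PCA and specialization regressions."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = ["PCAResult", "RegressionResult", "pca", "linreg"]


@dataclass
class PCAResult:
    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    cumulative_percent: np.ndarray
    loadings: pd.DataFrame      # variables x axes
    contributions: pd.DataFrame  # percent per variable per axis, sums to 100
    scores: pd.DataFrame        # observations x axes


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    F: float
    df1: int
    df2: int
    p_value: float
    weights_used: bool
    n: int


def pca(X: pd.DataFrame, standardize: bool = True) -> PCAResult:
    """Principal component analysis of a species x variable table.

    With ``standardize=True`` (the default) the decomposition is of the
    correlation matrix, so percent variance is eigenvalue/p.  Axis signs
    follow the convention that the largest-magnitude loading on each axis
    is positive.  Per-variable contributions are 100 x squared loading
    (eigenvectors are unit length, so they sum to 100 per axis).
    """
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA needs at least 2 rows and 2 columns")
    if X.isna().any().any():
        raise ValueError("PCA input contains missing values")
    M = X.to_numpy(dtype=float)
    sd = M.std(axis=0, ddof=1)
    constant = [c for c, s in zip(X.columns, sd) if s == 0]
    if constant:
        raise ValueError(f"constant column(s) not allowed in PCA: {constant}")
    Z = M - M.mean(axis=0)
    if standardize:
        Z = Z / sd
        C = np.corrcoef(M, rowvar=False)
    else:
        C = np.cov(M, rowvar=False)
    eigval, eigvec = np.linalg.eigh(C)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # sign convention: biggest |loading| per axis positive
    for k in range(eigvec.shape[1]):
        j = int(np.argmax(np.abs(eigvec[:, k])))
        if eigvec[j, k] < 0:
            eigvec[:, k] = -eigvec[:, k]
    percent = 100.0 * eigval / eigval.sum()
    axes = [f"PC{k + 1}" for k in range(len(eigval))]
    loadings = pd.DataFrame(eigvec, index=X.columns, columns=axes)
    contributions = 100.0 * loadings**2 / (loadings**2).sum(axis=0)
    scores = pd.DataFrame(Z @ eigvec, index=X.index, columns=axes)
    return PCAResult(
        eigenvalues=eigval,
        percent_variance=percent,
        cumulative_percent=np.cumsum(percent),
        loadings=loadings,
        contributions=contributions,
        scores=scores,
    )


def linreg(x, y, weights=None) -> RegressionResult:
    """Simple (optionally weighted) least-squares regression of y on x.

    Reports slope, intercept, R^2, the overall F statistic with
    ``df2 = n - 2`` and its p-value.  A common weighting in network
    studies is the square root of each species' total interaction
    frequency; pass it via ``weights``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        if np.any(weights < 0):
            raise ValueError("weights must be nonnegative")
        mask &= np.isfinite(weights)
        weights = weights[mask]
    x, y = x[mask], y[mask]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 finite observations")
    if np.ptp(x) == 0:
        raise ValueError("predictor has zero variance")
    X = sm.add_constant(x)
    model = sm.WLS(y, X, weights=weights) if weights is not None else sm.OLS(y, X)
    res = model.fit()
    r2 = float(res.rsquared)
    df2 = n - 2
    if r2 >= 1.0:
        F, p = float("inf"), 0.0
    else:
        F = df2 * r2 / (1.0 - r2)
        p = float(sps.f.sf(F, 1, df2)) if F > 0 else 1.0
    return RegressionResult(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=r2,
        F=float(F),
        df1=1,
        df2=df2,
        p_value=p,
        weights_used=weights is not None,
        n=n,
    )
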