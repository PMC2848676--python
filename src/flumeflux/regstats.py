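"""Regression helpers: OLS, hierarchical partitioning, z-scores, CV bootstrap.

Hierarchical partitioning (Chevan & Stone) decomposes the full-model R² of a
multiple regression into per-predictor independent contributions I_j by
averaging, over all hierarchy levels, the mean R² increase obtained when the
predictor joins every possible subset of the others.  The joint contribution
J_j is the remainder of the predictor's marginal R².  The identity
``sum_j I_j = R²_full`` holds exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import statsmodels.api as sm

__all__ = [
    "RegressionModel",
    "PartitionResult",
    "ols",
    "hierarchical_partition",
    "zscore",
    "cv_bootstrap",
]


@dataclass(frozen=True)
class RegressionModel:
    response: str
    predictors: tuple[str, ...]
    coefficients: np.ndarray  # unstandardized slopes, one per predictor
    intercept: float
    r_squared: float
    n: int
    conf_int: np.ndarray | None = None  # (p, 2) 95% CI on slopes


@dataclass(frozen=True)
class PartitionResult:
    predictors: tuple[str, ...]
    independent: np.ndarray  # I_j, R² units
    joint: np.ndarray  # J_j = marginal R²_j - I_j
    r_squared_full: float


def ols(y, X, names: tuple[str, ...] | None = None,
        response: str = "y") -> RegressionModel:
    """Ordinary least squares of y on the columns of X (intercept added)."""
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    n, p = X.shape
    if n <= p:
        raise ValueError("need more observations than predictors")
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    if np.linalg.matrix_rank(sm.add_constant(X)) < p + 1:
        raise ValueError("rank-deficient design matrix")
    names = names or tuple(f"x{i}" for i in range(p))
    return RegressionModel(
        response=response, predictors=tuple(names),
        coefficients=np.asarray(fit.params[1:]), intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared), n=n,
        conf_int=np.asarray(fit.conf_int()[1:]),
    )


def _subset_r2(y: np.ndarray, X: np.ndarray, cols: tuple[int, ...]) -> float:
    if not cols:
        return 0.0
    Z = sm.add_constant(X[:, list(cols)])
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    resid = y - Z @ beta
    tss = np.sum((y - y.mean()) ** 2)
    return float(1.0 - resid @ resid / tss) if tss > 0 else 0.0


def hierarchical_partition(y, X, names: tuple[str, ...] | None = None,
                           max_predictors: int = 12) -> PartitionResult:
    """Independent and joint R² contributions of each predictor.

    Fits all 2^k subset models.  For predictor j, the independent
    contribution is the average over levels h = 0..k-1 of the mean R²
    increase from adding j to a size-h subset of the other predictors.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    k = X.shape[1]
    if k > max_predictors:
        raise ValueError(f"{k} predictors would need 2^{k} fits; cap is {max_predictors}")
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < k:
        raise ValueError("collinear predictors; partition undefined")
    r2 = {}
    for size in range(k + 1):
        for cols in combinations(range(k), size):
            r2[cols] = _subset_r2(y, X, cols)
    indep = np.zeros(k)
    for j in range(k):
        others = [i for i in range(k) if i != j]
        level_means = []
        for h in range(k):
            gains = [r2[tuple(sorted(S + (j,)))] - r2[S]
                     for S in combinations(others, h)]
            level_means.append(np.mean(gains))
        indep[j] = np.mean(level_means)
    marginal = np.array([r2[(j,)] for j in range(k)])
    names = names or tuple(f"x{i}" for i in range(k))
    return PartitionResult(predictors=tuple(names), independent=indep,
                           joint=marginal - indep,
                           r_squared_full=r2[tuple(range(k))])


def zscore(values) -> np.ndarray:
    """Standardize to mean 0, sample SD 1."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance; z-scores undefined")
    return (x - x.mean()) / sd


def cv_bootstrap(values, B: int = 1000, level: float = 0.95,
                 seed: int | np.random.Generator = 0) -> tuple[float, float, float]:
    """Coefficient of variation with a percentile bootstrap confidence interval.

    CV = sample SD / mean.  ``B`` resamples with replacement; the interval is
    the (alpha/2, 1-alpha/2) percentile pair of the resampled CVs.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    if x.mean() == 0:
        raise ValueError("CV undefined for zero mean")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cv = float(x.std(ddof=1) / x.mean())
    idx = rng.integers(0, x.size, size=(B, x.size))
    samples = x[idx]
    means = samples.mean(axis=1)
    means[means == 0] = np.nan
    cvs = samples.std(ddof=1, axis=1) / means
    alpha = 1.0 - level
    lo, hi = np.nanpercentile(cvs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return cv, float(lo), float(hi)
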