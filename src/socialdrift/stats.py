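"""Statistical layer: rank correlation, distribution comparison, regression.

Thin, typed wrappers around scipy.stats and statsmodels matching how the
quantities are reported downstream: Spearman's rho between RA° and each
fitted diffusion parameter, a two-sample Kolmogorov–Smirnov test for
between-treatment differences, and per-treatment OLS with adjusted R².
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import islice, permutations

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "KSResult",
    "RegressionResult",
    "ConstantInputError",
    "spearman",
    "ks_two_sample",
    "ols_adjusted_r2",
]

#: below this sample size the Spearman p-value is computed by exact permutation
EXACT_PERMUTATION_N = 10


class ConstantInputError(ValueError):
    """A constant vector makes the statistic undefined."""


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int


@dataclass(frozen=True)
class KSResult:
    D: float
    p_value: float
    n1: int
    n2: int


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    slope_p: float
    intercept_p: float
    adjusted_r2: float
    n: int


def _exact_spearman_p(xr: np.ndarray, yr: np.ndarray, rho_obs: float) -> float:
    """Two-sided permutation p-value over all orderings of the y ranks.

    For fixed marginal ranks, rho is an increasing affine function of
    sum(xr * yr), so permutations are compared on that inner product.
    """
    n = xr.size
    sx, sy = xr.std(), yr.std()
    mx, my = xr.mean(), yr.mean()
    obs = abs(rho_obs)
    count = 0
    total = 0
    gen = permutations(yr)
    chunk = 200_000
    while True:
        block = list(islice(gen, chunk))
        if not block:
            break
        dots = np.asarray(block, dtype=float) @ xr
        rho_p = (dots / n - mx * my) / (sx * sy)
        count += int(np.count_nonzero(np.abs(rho_p) >= obs - 1e-12))
        total += len(block)
    return count / total


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with two-sided p-value.

    Ties get average ranks.  For n <= 10 the p-value is an exact
    permutation probability; larger samples use the t approximation.
    Constant input raises :class:`ConstantInputError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("correlation undefined for a constant vector")
    rho, p = sps.spearmanr(x, y)
    if x.size <= EXACT_PERMUTATION_N:
        xr = sps.rankdata(x)
        yr = sps.rankdata(y)
        p = _exact_spearman_p(xr, yr, float(rho))
    return CorrelationResult(rho=float(rho), p_value=float(p), n=int(x.size))


def ks_two_sample(x, y, method: str = "asymp") -> KSResult:
    """Two-sample Kolmogorov–Smirnov test.

    D is the supremum distance between the empirical CDFs; the p-value uses
    the asymptotic Kolmogorov distribution by default (``method='exact'``
    switches to the exact null distribution).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    res = sps.ks_2samp(x, y, method=method)
    return KSResult(D=float(res.statistic), p_value=float(res.pvalue), n1=int(x.size), n2=int(y.size))


def ols_adjusted_r2(y, x) -> RegressionResult:
    """OLS of a response on a single predictor, reporting adjusted R².

    Used for regressions of RA° on one diffusion parameter per treatment.
    Constant predictor raises :class:`ConstantInputError`.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if y.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ConstantInputError("regression undefined for a constant predictor")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_se=float(fit.bse[1]),
        intercept_se=float(fit.bse[0]),
        slope_p=float(fit.pvalues[1]),
        intercept_p=float(fit.pvalues[0]),
        adjusted_r2=float(fit.rsquared_adj),
        n=int(y.size),
    )
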