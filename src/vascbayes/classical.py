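"""Frequentist sanity-check statistics: Pearson correlation with a Fisher-z
confidence interval, the Welch two-sample t-test, and a two-sided
variance-ratio F-test."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CorrTestResult",
    "TwoSampleResult",
    "VarianceRatioResult",
    "fisher_z_ci",
    "pearson_test",
    "welch_ttest",
    "variance_ratio_test",
]


@dataclass(frozen=True)
class CorrTestResult:
    r: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    level: float


@dataclass(frozen=True)
class TwoSampleResult:
    mean_diff: float
    ci_low: float
    ci_high: float
    t: float
    df: float
    p: float


@dataclass(frozen=True)
class VarianceRatioResult:
    f: float
    df1: int
    df2: int
    p: float


def fisher_z_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Confidence interval for a correlation via Fisher's z-transform:
    ``tanh(atanh(r) +/- z / sqrt(n - 3))``.  ``|r| = 1`` degenerates to
    ``(r, r)``."""
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    if n < 4:
        raise ValueError("need n >= 4 for a Fisher-z interval")
    if abs(r) > 1:
        raise ValueError("|r| cannot exceed 1")
    if abs(r) == 1:
        return (r, r)
    z = stats.norm.ppf((1 + level) / 2)
    half = z / math.sqrt(n - 3)
    zr = math.atanh(r)
    return (math.tanh(zr - half), math.tanh(zr + half))


def _check_vector(v, name: str, min_len: int):
    v = np.asarray(v, float)
    if v.ndim != 1 or len(v) < min_len:
        raise ValueError(f"{name} must be a vector of length >= {min_len}")
    if np.isnan(v).any():
        raise ValueError(f"{name} contains missing values")
    return v


def pearson_test(x, y, level: float = 0.95) -> CorrTestResult:
    """Pearson correlation with a two-sided t-transform p-value and a
    Fisher-z confidence interval."""
    x = _check_vector(x, "x", 4)
    y = _check_vector(y, "y", 4)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    for v, name in ((x, "x"), (y, "y")):
        if v.var(ddof=1) == 0:
            raise ValueError(f"{name} is constant; correlation undefined")
    n = len(x)
    r, p = stats.pearsonr(x, y)
    lo, hi = fisher_z_ci(float(r), n, level)
    return CorrTestResult(r=float(r), ci_low=lo, ci_high=hi, p=float(p),
                          n=n, level=level)


def welch_ttest(x, y, level: float = 0.95) -> TwoSampleResult:
    """Two-sample t-test with Welch-Satterthwaite degrees of freedom and a
    confidence interval for ``mean(x) - mean(y)``."""
    x = _check_vector(x, "x", 2)
    y = _check_vector(y, "y", 2)
    res = stats.ttest_ind(x, y, equal_var=False)
    ci = res.confidence_interval(level)
    return TwoSampleResult(mean_diff=float(x.mean() - y.mean()),
                           ci_low=float(ci.low), ci_high=float(ci.high),
                           t=float(res.statistic), df=float(res.df),
                           p=float(res.pvalue))


def variance_ratio_test(x, y) -> VarianceRatioResult:
    """F-test of equal variances, ``f = var(x)/var(y)``, two-sided p obtained
    by doubling the smaller tail."""
    x = _check_vector(x, "x", 2)
    y = _check_vector(y, "y", 2)
    vy = y.var(ddof=1)
    if vy == 0:
        raise ValueError("y has zero variance; ratio undefined")
    f = float(x.var(ddof=1) / vy)
    df1, df2 = len(x) - 1, len(y) - 1
    p = 2 * min(stats.f.cdf(f, df1, df2), stats.f.sf(f, df1, df2))
    return VarianceRatioResult(f=f, df1=df1, df2=df2, p=float(min(p, 1.0)))
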