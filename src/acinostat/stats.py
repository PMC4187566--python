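"""Validation statistics: coefficient of variation, group comparisons, correlation.

These are the summary statistics used to validate lobe-based acinar counting:
the coefficient of variation normalizes the spread of counts and volumes
across animals, t-tests/ANOVA compare mean acinar volumes between lobes, and
linear regression with an R-squared-based category classifies correlations
between morphometric parameters (e.g., number of acini vs. lung volume).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "cv",
    "cv_from",
    "compare_groups",
    "correlate",
    "classify_r_squared",
    "CorrelationReport",
    "GroupComparison",
]

#: R-squared thresholds separating "none" / "weak" / "strong" correlation.
R2_NONE_MAX = 0.5
R2_WEAK_MAX = 0.7


@dataclass(frozen=True)
class CorrelationReport:
    """Least-squares line plus the R²-based correlation verdict."""

    r_squared: float
    r: float
    category: Literal["none", "weak", "strong"]
    slope: float
    intercept: float


@dataclass(frozen=True)
class GroupComparison:
    """Outcome of a two-group t-test or a one-way ANOVA F-test."""

    statistic: float
    p_value: float
    significant: bool
    test: Literal["t", "anova"]
    alpha: float


def cv(values: Sequence[float]) -> float:
    """Coefficient of variation SD/mean of a sample (SD with n-1 denominator).

    Requires at least two values and a nonzero mean.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("cv requires at least 2 values")
    m = x.mean()
    if m == 0:
        raise ValueError("cv undefined for zero mean")
    return float(x.std(ddof=1) / m)


def cv_from(mean: float, sd: float) -> float:
    """Coefficient of variation from a published mean and SD."""
    if mean == 0:
        raise ValueError("cv undefined for zero mean")
    return float(sd / mean)


def compare_groups(
    groups: Sequence[Sequence[float]],
    alpha: float = 0.05,
    equal_var: bool = False,
) -> GroupComparison:
    """Compare group means: two-sided t-test for 2 groups, one-way ANOVA for more.

    Parameters
    ----------
    groups : sequences of measurements, one per group; each needs n >= 2.
    alpha : significance level for the decision.
    equal_var : two-group case only; False (default) uses Welch's t-test,
        True the classic pooled-variance test.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    if any(g.size < 2 for g in gs):
        raise ValueError("every group needs at least two values")
    if all(g.std(ddof=1) == 0 for g in gs):
        raise ValueError("degenerate: zero variance in every group")
    if len(gs) == 2:
        res = sps.ttest_ind(gs[0], gs[1], equal_var=equal_var)
        test: Literal["t", "anova"] = "t"
    else:
        res = sps.f_oneway(*gs)
        test = "anova"
    p = float(res.pvalue)
    return GroupComparison(float(res.statistic), p, p < alpha, test, alpha)


def classify_r_squared(r_squared: float) -> Literal["none", "weak", "strong"]:
    """Correlation category from R²: none (R² ≤ 0.5), weak (0.5 < R² ≤ 0.7),
    strong (0.7 < R²)."""
    if not 0.0 <= r_squared <= 1.0:
        raise ValueError(f"r_squared must be in [0, 1], got {r_squared}")
    if r_squared <= R2_NONE_MAX:
        return "none"
    if r_squared <= R2_WEAK_MAX:
        return "weak"
    return "strong"


def correlate(x: Sequence[float], y: Sequence[float]) -> CorrelationReport:
    """Least-squares regression of y on x with the categorical R² verdict."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("x and y must have equal length")
    if xa.size < 3:
        raise ValueError("need at least 3 points")
    if xa.std() == 0:
        raise ValueError("zero variance in x")
    res = sps.linregress(xa, ya)
    r = float(res.rvalue)
    r2 = r * r
    return CorrelationReport(
        r_squared=r2,
        r=r,
        category=classify_r_squared(r2),
        slope=float(res.slope),
        intercept=float(res.intercept),
    )
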