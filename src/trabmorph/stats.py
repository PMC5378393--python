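"""Two-group statistics for morphometric and biochemical variables.

Per-group summaries report mean, SEM and CV; group comparisons run a
two-sided variance-ratio test first to decide between the pooled-variance and
Welch two-sample t-tests, and effect sizes are reported as percent change
relative to the baseline group (positive = decrease).  No multiple-testing
correction is applied by default — each variable is tested at the raw alpha —
with an optional Bonferroni column available downstream.

Rounding (round-half-up, applied only at report formatting) follows the
presentation conventions of the source study: two decimals for morphometric
percent changes, nearest integer for biochemistry.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "GroupComparison",
    "summarize",
    "compare_groups",
    "percent_change",
    "round_half_up",
]


@dataclass
class GroupSummary:
    n: int
    mean: float
    sem: float
    cv: float  # %, 100 * sd / mean (nan when mean == 0)

    @property
    def sd(self) -> float:
        return self.sem * np.sqrt(self.n)


@dataclass
class GroupComparison:
    baseline: GroupSummary
    comparison: GroupSummary
    variance_test_p: float  # the equal-variance screen ("z test" in reports)
    test_used: str  # "pooled" | "unequal-variance"
    t_statistic: float
    p_value: float
    percent_change: float  # % vs baseline; positive = decrease
    significant: bool
    alpha: float = 0.05
    flag: str | None = None


def summarize(values: list[float] | np.ndarray) -> GroupSummary:
    """Mean, SEM (sd/sqrt(n) with the n-1 sd) and CV (%) of one group."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError(f"group summary needs n >= 2, got n = {x.size}")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    cv = 100.0 * sd / mean if mean != 0 else float("nan")
    return GroupSummary(n=int(x.size), mean=mean, sem=sd / np.sqrt(x.size), cv=cv)


def _variance_ratio_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided variance-ratio (F) test for equality of variances."""
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        return 1.0
    if vb == 0 or va == 0:
        return 0.0
    f = va / vb
    p = 2.0 * min(
        sps.f.cdf(f, a.size - 1, b.size - 1),
        sps.f.sf(f, a.size - 1, b.size - 1),
    )
    return float(min(p, 1.0))


def compare_groups(
    a: list[float] | np.ndarray,
    b: list[float] | np.ndarray,
    alpha: float = 0.05,
) -> GroupComparison:
    """Two-sample comparison of baseline ``a`` against ``b``.

    The equal-variance screen is a two-sided variance-ratio test at the same
    alpha; if equality is not rejected the pooled-variance t-test is used,
    otherwise Welch's unequal-variance t-test.  Two-sided throughout.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    sa = summarize(a)
    sb = summarize(b)
    flag = None
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if sa.mean == sb.mean:
            # degenerate: identical constants; no evidence of difference
            var_p, test_used, t, p = 1.0, "pooled", 0.0, 1.0
            flag = "zero variance in both groups with equal means"
        else:
            var_p, test_used, t, p = 1.0, "pooled", float("inf"), 0.0
            flag = "zero variance in both groups with different means"
    else:
        var_p = _variance_ratio_p(a, b)
        equal_var = var_p >= alpha
        test_used = "pooled" if equal_var else "unequal-variance"
        t, p = sps.ttest_ind(a, b, equal_var=equal_var)
        t, p = float(t), float(p)
    if sa.mean == 0:
        pct = float("nan")
        flag = flag or "zero baseline mean: percent change undefined"
    else:
        pct = percent_change(sa.mean, sb.mean)
    return GroupComparison(
        baseline=sa,
        comparison=sb,
        variance_test_p=var_p,
        test_used=test_used,
        t_statistic=t,
        p_value=p,
        percent_change=pct,
        significant=bool(p < alpha),
        alpha=alpha,
        flag=flag,
    )


def percent_change(baseline_mean: float, comparison_mean: float) -> float:
    """100 * (baseline - comparison) / baseline; positive = decrease.

    Full precision — report rounding is applied only at formatting time.
    """
    if baseline_mean == 0:
        raise ValueError("percent change undefined for zero baseline")
    return 100.0 * (baseline_mean - comparison_mean) / baseline_mean


def round_half_up(value: float, decimals: int = 0) -> float:
    """Decimal round-half-up (0.5 always rounds away from zero)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
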