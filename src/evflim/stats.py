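"""Group-comparison statistics for lifetime distributions.

Thin, typed wrappers over the standard SciPy procedures used throughout the
analysis: two-sided Student's (or Welch's) t-test, one-way ANOVA,
Tukey-Kramer (or Bonferroni) multiple comparisons, and ordinary
least-squares regression with the slope F-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "RegressionResult",
    "two_sample_ttest",
    "one_way_anova",
    "multiple_comparisons",
    "linear_fit",
    "significance_stars",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    test_name: str
    group_sizes: tuple[int, ...]
    groups: tuple[str, ...] = ()


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def _as_groups(groups) -> list[np.ndarray]:
    return [np.asarray(g, dtype=float).ravel() for g in groups]


def two_sample_ttest(a, b, equal_var: bool = True) -> TestResult:
    """Two-sided two-sample t-test (pooled variance by default, Welch when
    ``equal_var=False``)."""
    a, b = _as_groups([a, b])
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            raise ValueError("zero variance in both groups with equal means")
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    if equal_var:
        df: float = float(len(a) + len(b) - 2)
        name = "student_t"
    else:
        df = float(res.df)
        name = "welch_t"
    return TestResult(
        statistic=float(res.statistic),
        df=df,
        p_value=float(res.pvalue),
        test_name=name,
        group_sizes=(len(a), len(b)),
    )


def one_way_anova(groups) -> TestResult:
    """One-way ANOVA; F on (k-1, N-k) degrees of freedom."""
    gs = _as_groups(groups)
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in gs):
        raise ValueError("each group needs n >= 2")
    grand = np.concatenate(gs)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in gs)
    if ssw == 0:
        raise ValueError("zero within-group variance: F is undefined")
    res = sps.f_oneway(*gs)
    k = len(gs)
    n = len(grand)
    return TestResult(
        statistic=float(res.statistic),
        df=(float(k - 1), float(n - k)),
        p_value=float(res.pvalue),
        test_name="one_way_anova",
        group_sizes=tuple(len(g) for g in gs),
    )


def multiple_comparisons(
    groups, method: str = "tukey", names: list[str] | None = None
) -> list[TestResult]:
    """All pairwise comparisons with familywise adjustment.

    ``tukey`` (default) applies the Tukey-Kramer honest-significant-
    difference procedure; ``bonferroni`` multiplies pairwise pooled-t
    p-values by the number of pairs.  k groups yield k*(k-1)/2 results,
    symmetric in pair order.
    """
    gs = _as_groups(groups)
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    if names is None:
        names = [f"group{i}" for i in range(len(gs))]
    if len(names) != len(gs):
        raise ValueError("names length must match groups")
    pairs = list(combinations(range(len(gs)), 2))
    n_total = sum(len(g) for g in gs)
    df_within = float(n_total - len(gs))
    out: list[TestResult] = []
    if method == "tukey":
        res = sps.tukey_hsd(*gs)
        for i, j in pairs:
            out.append(
                TestResult(
                    statistic=float(res.statistic[i, j]),
                    df=df_within,
                    p_value=float(res.pvalue[i, j]),
                    test_name="tukey_hsd",
                    group_sizes=(len(gs[i]), len(gs[j])),
                    groups=(names[i], names[j]),
                )
            )
        return out
    if method == "bonferroni":
        m = len(pairs)
        for i, j in pairs:
            t = two_sample_ttest(gs[i], gs[j])
            out.append(
                TestResult(
                    statistic=t.statistic,
                    df=t.df,
                    p_value=min(1.0, t.p_value * m),
                    test_name="bonferroni_t",
                    group_sizes=t.group_sizes,
                    groups=(names[i], names[j]),
                )
            )
        return out
    raise ValueError(f"unknown method {method!r}")


def linear_fit(x, y) -> RegressionResult:
    """Ordinary least squares of y on x; p-value is the slope F-test (which
    equals the two-sided t-test on the slope for simple regression)."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must be equal-length with n >= 3")
    res = sps.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=int(x.size),
    )


def significance_stars(p: float) -> str:
    """Figure-caption stars: *** p<0.001, ** p<0.01, * p<0.05, ns otherwise."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
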