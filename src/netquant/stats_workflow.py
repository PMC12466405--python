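"""Group-comparison statistics for NAE assays.

The assay compares a metric (mean nuclear area, or % NETotic nuclei) between
two conditions at each incubation time.  The workflow is the classical
parametric one: normality is screened with the D'Agostino–Pearson K² and
Shapiro–Wilk tests; percentage metrics failing normality are passed through
the variance-stabilising arcsine-square-root transform; groups are then
compared with the pooled-variance Student's t-test at α = 0.05, and summary
tables carry two-sided t-based 95 % confidence intervals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateDataError

ALPHA_DEFAULT = 0.05
#: Minimum n for the Shapiro–Wilk test.
SHAPIRO_MIN_N = 3
#: Minimum n for the D'Agostino–Pearson K² test.
K2_MIN_N = 8


@dataclass
class GroupSample:
    """Per-animal/per-replicate values of one metric in one condition."""

    values: list[float]
    label: str = ""
    time_min: float | None = None
    is_percentage: bool = False

    def __post_init__(self) -> None:
        if len(self.values) < 1:
            raise ValueError("a group needs at least one value")
        if not all(math.isfinite(v) for v in self.values):
            raise ValueError("group values must be finite")


@dataclass
class TTestResult:
    t_stat: float
    df: int
    p_value: float


@dataclass
class NormalityResult:
    k2_p: float | None
    shapiro_p: float | None
    k2_skipped: bool
    shapiro_skipped: bool
    is_normal: bool


@dataclass
class GroupComparison:
    t_stat: float
    df: int
    p_value: float
    transformed: bool
    alpha: float
    significant: bool


def t_confidence_interval(
    mean: float, sd: float, n: int, level: float = 0.95
) -> tuple[float, float]:
    """Two-sided t-based confidence interval from summary statistics.

    Returns ``mean ± t_{(1+level)/2, n-1} * sd / sqrt(n)``.
    """
    if n < 2:
        raise ValueError("confidence interval requires n >= 2")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    tcrit = stats.t.ppf((1 + level) / 2, df=n - 1)
    half = tcrit * sd / math.sqrt(n)
    return mean - half, mean + half


def assess_normality(values: list[float]) -> NormalityResult:
    """Screen a sample with the K² and Shapiro–Wilk normality tests.

    Tests below their validity floor (n ≥ 8 for K², n ≥ 3 for Shapiro–Wilk)
    are skipped and flagged; ``is_normal`` holds when every computed test has
    p ≥ 0.05.  A constant sample is degenerate for both tests.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size >= 1 and np.ptp(arr) == 0 and arr.size > 1:
        raise DegenerateDataError("constant sample: normality tests undefined")
    k2_p: float | None = None
    shapiro_p: float | None = None
    if arr.size >= K2_MIN_N:
        with warnings.catch_warnings():
            # scipy warns that kurtosistest is approximate below n=20; the
            # workflow accepts the approximation down to its n>=8 floor
            warnings.simplefilter("ignore")
            _, k2_p = stats.normaltest(arr)
        k2_p = float(k2_p)
    if arr.size >= SHAPIRO_MIN_N:
        _, shapiro_p = stats.shapiro(arr)
        shapiro_p = float(shapiro_p)
    computed = [p for p in (k2_p, shapiro_p) if p is not None]
    return NormalityResult(
        k2_p=k2_p,
        shapiro_p=shapiro_p,
        k2_skipped=arr.size < K2_MIN_N,
        shapiro_skipped=arr.size < SHAPIRO_MIN_N,
        is_normal=all(p >= 0.05 for p in computed) if computed else True,
    )


def arcsine_transform(values, variance_stabilizing: bool = True) -> list[float]:
    """Arcsine transform of percentages in [0, 100].

    The default is the variance-stabilising form for proportions,
    ``arcsin(sqrt(p/100))`` in radians; ``variance_stabilizing=False``
    restores the literal ``arcsin(p/100)``.
    """
    out = []
    for v in values:
        if not 0 <= v <= 100:
            raise ValueError(f"percentage {v} outside [0, 100]")
        p = v / 100.0
        out.append(math.asin(math.sqrt(p)) if variance_stabilizing else math.asin(p))
    return out


def students_t_test(a: GroupSample, b: GroupSample, two_sided: bool = True,
                    welch: bool = False) -> TTestResult:
    """Two-sample t-test; pooled-variance (Student) by default.

    Degrees of freedom are ``n_a + n_b - 2`` for the pooled form.  Zero
    pooled variance with equal means yields t = 0, p = 1; with unequal means
    it is degenerate data.
    """
    xa = np.asarray(a.values, dtype=float)
    xb = np.asarray(b.values, dtype=float)
    if xa.size < 2 or xb.size < 2:
        raise ValueError("t-test requires n >= 2 per group")
    if not welch:
        pooled_num = ((xa.size - 1) * xa.var(ddof=1) + (xb.size - 1) * xb.var(ddof=1))
        if pooled_num == 0:
            if xa.mean() == xb.mean():
                return TTestResult(t_stat=0.0, df=xa.size + xb.size - 2, p_value=1.0)
            raise DegenerateDataError("zero pooled variance with unequal means")
    res = stats.ttest_ind(
        xa, xb, equal_var=not welch,
        alternative="two-sided" if two_sided else "greater",
    )
    df = int(xa.size + xb.size - 2) if not welch else int(res.df)
    return TTestResult(t_stat=float(res.statistic), df=df, p_value=float(res.pvalue))


def compare_groups(
    a: GroupSample,
    b: GroupSample,
    alpha: float = ALPHA_DEFAULT,
    variance_stabilizing: bool = True,
) -> GroupComparison:
    """Full comparison of one metric between two conditions.

    Both groups are screened for normality; if either fails and the metric is
    a percentage, the arcsine transform is applied to both before the
    pooled-variance t-test.  Significance is declared at p < alpha.
    """
    norm_a = assess_normality(a.values)
    norm_b = assess_normality(b.values)
    transformed = False
    va, vb = a.values, b.values
    if (not norm_a.is_normal or not norm_b.is_normal) and a.is_percentage and b.is_percentage:
        va = arcsine_transform(va, variance_stabilizing)
        vb = arcsine_transform(vb, variance_stabilizing)
        transformed = True
    res = students_t_test(
        GroupSample(values=list(va), label=a.label, time_min=a.time_min),
        GroupSample(values=list(vb), label=b.label, time_min=b.time_min),
    )
    return GroupComparison(
        t_stat=res.t_stat,
        df=res.df,
        p_value=res.p_value,
        transformed=transformed,
        alpha=alpha,
        significant=res.p_value < alpha,
    )
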