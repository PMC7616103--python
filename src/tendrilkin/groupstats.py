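"""Descriptive summaries and the group-comparison battery.

The analysis battery mirrors standard practice for small-sample kinematic
studies: a Shapiro-Wilk normality gate, a Kruskal-Wallis rank test across
the three conditions for duration and mean velocity, pairwise post-hoc
comparisons (Tukey HSD, or rank-based Dunn with Bonferroni adjustment —
offered because Tukey after a Kruskal-Wallis is unconventional), and a
pooled-variance two-sample Student t test with Cohen's d for the
submovement measures, which only exist for the two grasping conditions.

The pooled t test is implemented directly from summary statistics::

    sp^2 = [(n1-1) sd1^2 + (n2-1) sd2^2] / (n1 + n2 - 2)
    t    = (m1 - m2) / (sp * sqrt(1/n1 + 1/n2)),   df = n1 + n2 - 2
    d    = (m1 - m2) / sp

so that published group means/SDs can be re-analysed without raw data. The
raw-sample entry point computes the summaries and delegates, guaranteeing
the two paths agree exactly.

Cohen's d standard error uses the large-sample approximation
SE(d) = sqrt((n1+n2)/(n1*n2) + d^2 / (2*(n1+n2))) with a normal-quantile
95% CI; exact noncentral-t intervals are out of scope.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ContractError, InsufficientDataError

_Z975 = 1.959963984540054


@dataclass
class GroupSummary:
    """Descriptive statistics of one condition's values for one measure."""

    condition: str
    n: int
    mean: float
    sd: float
    median: float
    iqr: float
    p25: float
    p50: float
    p75: float
    min: float
    max: float
    shapiro_p: float


@dataclass
class TestResult:
    """Outcome of one statistical comparison."""

    test: str
    statistic: float
    df: float
    p: float
    groups: tuple[str, ...] = ()
    effect_size: float | None = None
    effect_se: float | None = None
    effect_ci_low: float | None = None
    effect_ci_high: float | None = None


def summarize_group(values: np.ndarray, condition: str = "") -> GroupSummary:
    """Moments, linear-interpolation percentiles, and a Shapiro-Wilk p value.

    Percentiles use linear interpolation between order statistics (the
    default of the common statistics suites); IQR is p75 - p25 under the
    same rule.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise InsufficientDataError("group summary needs n >= 3")
    p25, p50, p75 = np.percentile(values, [25, 50, 75])
    if np.ptp(values) == 0:
        shapiro_p = float("nan")  # Shapiro-Wilk undefined for constant data
    else:
        shapiro_p = float(stats.shapiro(values).pvalue)
    return GroupSummary(
        condition=condition,
        n=len(values),
        mean=float(np.mean(values)),
        sd=float(np.std(values, ddof=1)),
        median=float(p50),
        iqr=float(p75 - p25),
        p25=float(p25),
        p50=float(p50),
        p75=float(p75),
        min=float(np.min(values)),
        max=float(np.max(values)),
        shapiro_p=shapiro_p,
    )


def kruskal_wallis(groups: list[np.ndarray], labels: tuple[str, ...] = ()) -> TestResult:
    """Tie-corrected Kruskal-Wallis H across k groups, chi-square p with k-1 df.

    All values identical across all groups is a degenerate but valid input:
    H = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ContractError("kruskal_wallis needs >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    df = len(groups) - 1
    if np.ptp(pooled) == 0:
        return TestResult(test="kruskal_wallis", statistic=0.0, df=df, p=1.0,
                          groups=tuple(labels))
    h, p = stats.kruskal(*groups)
    return TestResult(test="kruskal_wallis", statistic=float(h), df=df, p=float(p),
                      groups=tuple(labels))


def _cohens_d_ci(d: float, n1: int, n2: int) -> tuple[float, float, float]:
    se = math.sqrt((n1 + n2) / (n1 * n2) + d**2 / (2 * (n1 + n2)))
    return se, d - _Z975 * se, d + _Z975 * se


def student_t_pooled(
    n1: int, mean1: float, sd1: float,
    n2: int, mean2: float, sd2: float,
    labels: tuple[str, str] = ("group1", "group2"),
) -> TestResult:
    """Two-sided pooled-variance Student t test from summary statistics.

    Returns t, df = n1 + n2 - 2, the two-sided p, and Cohen's d with its
    large-sample SE and 95% CI.
    """
    if n1 < 2 or n2 < 2:
        raise ContractError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ContractError("standard deviations must be >= 0")
    if sd1 == 0 and sd2 == 0:
        raise ContractError("pooled t undefined when both group SDs are zero")
    df = n1 + n2 - 2
    sp = math.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df)
    t = (mean1 - mean2) / (sp * math.sqrt(1.0 / n1 + 1.0 / n2))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    d = (mean1 - mean2) / sp
    se, lo, hi = _cohens_d_ci(d, n1, n2)
    return TestResult(
        test="student_t", statistic=float(t), df=float(df), p=p, groups=tuple(labels),
        effect_size=float(d), effect_se=se, effect_ci_low=lo, effect_ci_high=hi,
    )


def student_t_from_samples(
    x1: np.ndarray, x2: np.ndarray, labels: tuple[str, str] = ("group1", "group2")
) -> TestResult:
    """Pooled t test from raw samples; agrees exactly with the summary path."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    return student_t_pooled(
        len(x1), float(np.mean(x1)), float(np.std(x1, ddof=1)),
        len(x2), float(np.mean(x2)), float(np.std(x2, ddof=1)),
        labels=labels,
    )


def _dunn_bonferroni(groups, labels):
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    # tie correction term for the variance of mean ranks
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (12.0 * (n_total - 1))
    var_unit = n_total * (n_total + 1) / 12.0 - tie_term
    mean_ranks, sizes = [], []
    offset = 0
    for g in groups:
        mean_ranks.append(float(np.mean(ranks[offset : offset + len(g)])))
        sizes.append(len(g))
        offset += len(g)
    pairs = list(itertools.combinations(range(len(groups)), 2))
    results = []
    for i, k in pairs:
        if var_unit <= 0:  # every pooled value identical
            z, p_adj = 0.0, 1.0
        else:
            z = (mean_ranks[i] - mean_ranks[k]) / math.sqrt(
                var_unit * (1.0 / sizes[i] + 1.0 / sizes[k])
            )
            p_adj = min(1.0, 2.0 * float(stats.norm.sf(abs(z))) * len(pairs))
        results.append(
            TestResult(test="pairwise_posthoc", statistic=float(z), df=float("nan"),
                       p=p_adj, groups=(labels[i], labels[k]))
        )
    return results


def pairwise_posthoc(
    groups: list[np.ndarray],
    labels: tuple[str, ...] | None = None,
    method: str = "tukey_hsd",
) -> list[TestResult]:
    """All pairwise comparisons within a family of >= 3 groups.

    ``tukey_hsd``: mean differences against the studentized range (pooled
    SE). ``dunn_bonferroni``: pairwise rank z statistics with Bonferroni
    family adjustment, the conventional follow-up to a Kruskal-Wallis test.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ContractError("post-hoc comparison needs >= 2 groups")
    if len(groups) < 3:
        raise ContractError("family adjustment is defined for >= 3 groups")
    if labels is None:
        labels = tuple(f"group{i + 1}" for i in range(len(groups)))
    if method == "dunn_bonferroni":
        return _dunn_bonferroni(groups, labels)
    if method != "tukey_hsd":
        raise ContractError(f"unknown post-hoc method {method!r}")
    if np.ptp(np.concatenate(groups)) == 0:
        return [
            TestResult(test="pairwise_posthoc", statistic=0.0, df=float("nan"), p=1.0,
                       groups=(labels[i], labels[k]))
            for i, k in itertools.combinations(range(len(groups)), 2)
        ]
    res = stats.tukey_hsd(*groups)
    results = []
    for i, k in itertools.combinations(range(len(groups)), 2):
        results.append(
            TestResult(test="pairwise_posthoc", statistic=float(res.statistic[i, k]),
                       df=float("nan"), p=float(res.pvalue[i, k]),
                       groups=(labels[i], labels[k]))
        )
    return results


def normality_test(values: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk W and p (delegated); valid for 3 <= n <= 5000."""
    values = np.asarray(values, dtype=float)
    if not 3 <= len(values) <= 5000:
        raise ContractError("Shapiro-Wilk requires 3 <= n <= 5000")
    res = stats.shapiro(values)
    return float(res.statistic), float(res.pvalue)


__all__ = [
    "GroupSummary",
    "TestResult",
    "summarize_group",
    "kruskal_wallis",
    "student_t_pooled",
    "student_t_from_samples",
    "pairwise_posthoc",
    "normality_test",
]
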