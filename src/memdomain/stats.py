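"""Statistical routines: split-sampling sufficiency test and group comparisons.

The split test checks whether a set of per-ROI measurements is large
enough to be internally consistent: the values are randomly split into
two halves, compared with a two-tailed unequal-variance (Welch) t-test,
and the procedure is repeated (default 15 times); the mean p-value is
reported and sampling is deemed sufficient when it is >= 0.1.

Group comparisons are thin wrappers over the standard routines: Welch
t-test, exact Mann-Whitney, and one-way ANOVA with Tukey's HSD for
multi-group families.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "SplitTestResult",
    "split_sufficiency_test",
    "GroupComparison",
    "compare_groups",
]

SUFFICIENCY_THRESHOLD = 0.1


@dataclass
class SplitTestResult:
    """Outcome of the split-sampling sufficiency test."""

    p_split: float
    p_values: np.ndarray
    n_repetitions: int
    sufficient: bool


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-tailed Welch t-test p-value with the degenerate-variance rule."""
    if np.var(a) == 0 and np.var(b) == 0:
        return 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    p = sps.ttest_ind(a, b, equal_var=False).pvalue
    return float(p) if np.isfinite(p) else 1.0


def split_sufficiency_test(values, n_repetitions: int = 15,
                           seed: int | np.random.Generator = 0) -> SplitTestResult:
    """Random-split sampling-sufficiency test.

    Each repetition permutes the values, splits them into two halves
    (the first half takes the extra element when the count is odd) and
    applies a two-tailed Welch t-test; the reported p_split is the mean
    p-value over repetitions and sampling is sufficient when
    p_split >= 0.1.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 4:
        raise ValueError("need at least 4 values")
    if n_repetitions < 1:
        raise ValueError("n_repetitions must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    half = (len(values) + 1) // 2
    ps = np.empty(n_repetitions)
    for i in range(n_repetitions):
        perm = rng.permutation(values)
        ps[i] = _welch_p(perm[:half], perm[half:])
    p_split = float(ps.mean())
    return SplitTestResult(p_split=p_split, p_values=ps,
                           n_repetitions=n_repetitions,
                           sufficient=p_split >= SUFFICIENCY_THRESHOLD)


@dataclass
class GroupComparison:
    """p-value(s) with per-group effect summaries."""

    method: str
    p_value: float | None
    pairwise_p: dict | None
    means: list
    medians: list
    sems: list
    statistic: float | None = None


def _summaries(groups):
    means = [float(np.mean(g)) for g in groups]
    medians = [float(np.median(g)) for g in groups]
    sems = [float(sps.sem(g)) if len(g) > 1 else np.nan for g in groups]
    return means, medians, sems


def compare_groups(*groups, method: str = "welch_t") -> GroupComparison:
    """Compare groups of measurements.

    ``method`` is one of ``welch_t`` (two-tailed unequal-variance
    t-test, 2 groups), ``mann_whitney`` (exact where possible, 2
    groups) or ``anova_tukey`` (one-way ANOVA plus Tukey-adjusted
    pairwise p-values, >= 2 groups).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least 2 values")
    means, medians, sems = _summaries(groups)

    if method == "welch_t":
        if len(groups) != 2:
            raise ValueError("welch_t compares exactly 2 groups")
        p = _welch_p(groups[0], groups[1])
        stat = sps.ttest_ind(groups[0], groups[1], equal_var=False).statistic \
            if not (np.var(groups[0]) == 0 and np.var(groups[1]) == 0) else 0.0
        return GroupComparison(method, p, None, means, medians, sems,
                               statistic=float(stat) if np.isfinite(stat) else 0.0)

    if method == "mann_whitney":
        if len(groups) != 2:
            raise ValueError("mann_whitney compares exactly 2 groups")
        a, b = groups
        if np.array_equal(np.sort(a), np.sort(b)):
            # fully tied identical samples: no evidence of difference
            u = len(a) * len(b) / 2.0
            return GroupComparison(method, 1.0, None, means, medians, sems,
                                   statistic=u)
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
        return GroupComparison(method, float(res.pvalue), None, means,
                               medians, sems, statistic=float(res.statistic))

    if method == "anova_tukey":
        if all(np.var(g) == 0 for g in groups):
            eq = all(np.isclose(g.mean(), groups[0].mean()) for g in groups)
            p = 1.0 if eq else 0.0
            pairs = {(i, j): p for i in range(len(groups))
                     for j in range(i + 1, len(groups))}
            return GroupComparison(method, p, pairs, means, medians, sems)
        f = sps.f_oneway(*groups)
        hsd = sps.tukey_hsd(*groups)
        pairs = {}
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                pairs[(i, j)] = float(hsd.pvalue[i, j])
        return GroupComparison(method, float(f.pvalue), pairs, means,
                               medians, sems, statistic=float(f.statistic))

    raise ValueError(f"unknown method: {method!r}")
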