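"""t-tests, one-way ANOVA with Tukey HSD, and Bonferroni bookkeeping.

Applied to replicate-level metric tables (each subsample replicate is
treated as an observation, reproducing the study's procedure; the
pseudo-replication caveat is documented in the methods note).  The
default two-sample test is Welch's unequal-variance t; a pooled-variance
variant is available by flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class GroupComparison:
    groups: list
    statistic: float
    p: float
    alternative: str = "two-sided"
    tukey_p: dict = field(default_factory=dict)


def t_test(
    x, y, alternative: str = "two-sided", welch: bool = True
) -> GroupComparison:
    """Two-sample t-test (Welch by default; ``alternative`` as in scipy)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs >= 2 values")
    if x.std() == 0 and y.std() == 0:
        if x.mean() == y.mean():
            warnings.warn("both groups constant and equal; p set to 1", stacklevel=2)
            return GroupComparison([0, 1], 0.0, 1.0, alternative)
    stat, p = stats.ttest_ind(x, y, equal_var=not welch, alternative=alternative)
    return GroupComparison([0, 1], float(stat), float(p), alternative)


def anova_tukey(values, groups) -> GroupComparison:
    """One-way fixed-effects ANOVA plus Tukey HSD pairwise comparisons.

    Groups with a single value are excluded with a warning.  Returns the
    ANOVA F and p with per-pair studentized-range adjusted p-values.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if len(values) != len(groups):
        raise ValueError("values and groups differ in length")
    names, data = [], []
    for g in dict.fromkeys(groups):  # preserve order
        v = values[groups == g]
        if len(v) < 2:
            warnings.warn(f"excluding group {g!r} with a single value", stacklevel=2)
            continue
        names.append(g)
        data.append(v)
    if len(data) < 2:
        raise ValueError("need >= 2 groups with >= 2 values")
    if all(np.ptp(v) == 0 for v in data) and len({v[0] for v in data}) == 1:
        f_stat, p = 0.0, 1.0
        tukey = {(a, b): 1.0 for i, a in enumerate(names) for b in names[i + 1:]}
    else:
        f_stat, p = stats.f_oneway(*data)
        res = stats.tukey_hsd(*data)
        tukey = {
            (names[i], names[j]): float(res.pvalue[i, j])
            for i in range(len(names))
            for j in range(i + 1, len(names))
        }
    return GroupComparison(names, float(f_stat), float(p), "two-sided", tukey)


def bonferroni(alpha: float, m: int) -> float:
    """Family-wise corrected threshold alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m
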