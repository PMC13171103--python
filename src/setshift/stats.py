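"""Shared inferential statistics.

Group comparisons follow a single decision rule: two-tailed Wilcoxon
rank-sum (normal approximation with tie correction, no continuity
correction) when both samples exceed 7 observations, otherwise a
two-tailed pooled-variance t-test.  Mixed sizes are keyed to the smaller
sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class TestResult:
    statistic: float
    p: float
    test_name: str  # "ranksum" | "pooled_t"
    n1: int
    n2: int


def compare_groups(x, y) -> TestResult:
    """Rank-sum for n > 7 per group, pooled t otherwise.

    The rank-sum statistic reported is the sum of ranks of the first
    sample in the combined ranking.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    if n1 == 1 and n2 == 1:
        raise ValueError("cannot compare two single observations")
    if min(n1, n2) > 7:
        ranks = stats.rankdata(np.concatenate([x, y]))
        w = float(ranks[:n1].sum())
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        return TestResult(statistic=w, p=float(res.pvalue), test_name="ranksum", n1=n1, n2=n2)
    res = stats.ttest_ind(x, y, equal_var=True)
    return TestResult(
        statistic=float(res.statistic), p=float(res.pvalue), test_name="pooled_t", n1=n1, n2=n2
    )
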