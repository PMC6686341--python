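"""Pre- vs postfire trend comparison within each fire category.

For each category the per-lek prefire slopes are compared with the
postfire slopes.  Normality of each slope vector is screened with a
Shapiro-Wilk test at alpha = 0.05; if both vectors pass, a Welch
two-sample t test (unequal variances, Welch-Satterthwaite df) is used,
otherwise a two-sided Wilcoxon rank-sum (Mann-Whitney) test.  The Welch
route is two-sample rather than paired: with n pre and n post slopes the
Satterthwaite df is non-integer (e.g. 8.30 for n = 9), which a paired test
would not produce.  Sign convention: statistic > 0 iff mean(pre) >
mean(post).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats

__all__ = ["TestKind", "CategoryComparison", "compare_pre_post"]

logger = logging.getLogger(__name__)

SHAPIRO_ALPHA = 0.05


class TestKind(str, Enum):
    WELCH_T = "welch_t"
    WILCOXON = "wilcoxon"
    DEGENERATE = "degenerate"


@dataclass
class CategoryComparison:
    category: str
    n_leks: int
    pre_slopes: np.ndarray
    post_slopes: np.ndarray
    test_used: TestKind
    statistic: float
    df: float | None
    p_value: float


def compare_pre_post(
    pre: np.ndarray,
    post: np.ndarray,
    *,
    category: str = "",
    paired: bool = False,
) -> CategoryComparison:
    """Two-sided pre/post comparison with a normality-gated test choice.

    For the Wilcoxon route the reported statistic is the Mann-Whitney U of
    the *pre* sample (the rank sum of pre minus its minimum n1(n1+1)/2).
    ``paired=True`` switches the normal route to a paired t test (offered
    for sensitivity; the default matches the two-sample convention).
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if len(pre) < 3 or len(post) < 3:
        raise ValueError("need at least 3 slopes per sample")
    if not (np.all(np.isfinite(pre)) and np.all(np.isfinite(post))):
        raise ValueError("slopes must be finite; drop non-estimable leks first")

    if np.ptp(pre) == 0 and np.ptp(post) == 0:
        logger.warning("category %s: zero variance in both samples", category)
        return CategoryComparison(
            category, len(pre), pre, post, TestKind.DEGENERATE, 0.0, None, 1.0
        )

    def _normal(v: np.ndarray) -> bool:
        if np.ptp(v) == 0:
            return False  # Shapiro is undefined for constant input
        return stats.shapiro(v).pvalue > SHAPIRO_ALPHA

    if _normal(pre) and _normal(post):
        if paired:
            if len(pre) != len(post):
                raise ValueError("paired test needs equal-length samples")
            res = stats.ttest_rel(pre, post)
            df = float(len(pre) - 1)
        else:
            res = stats.ttest_ind(pre, post, equal_var=False)
            df = float(res.df)
        return CategoryComparison(
            category, len(pre), pre, post, TestKind.WELCH_T,
            float(res.statistic), df, float(res.pvalue),
        )

    res = stats.mannwhitneyu(pre, post, alternative="two-sided", method="auto")
    return CategoryComparison(
        category, len(pre), pre, post, TestKind.WILCOXON,
        float(res.statistic), None, float(res.pvalue),
    )
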