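"""Age-group comparison: one-way ANOVA with Bonferroni post-hoc tests.

Per-retina values (n = 4 retinas per age group) are compared across ages
by classical one-way ANOVA; pairwise comparisons use t statistics on the
pooled ANOVA mean-square error with a Bonferroni multiplier equal to the
number of pairs.  Significance is starred at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps

ALPHA = 0.05


class DegenerateVarianceError(ValueError):
    """All groups identical with zero within-group variance: F undefined."""


@dataclass
class PairwiseComparison:
    groups: tuple[int, int]          # indices into the group list
    mean_difference: float
    t: float
    p_raw: float
    p_adjusted: float                # min(1, p_raw * n_pairs)

    @property
    def significant(self) -> bool:
        return self.p_adjusted < ALPHA


@dataclass
class GroupComparison:
    """One-way ANOVA result plus Bonferroni-adjusted pairwise tests."""

    group_labels: tuple
    group_means: tuple[float, ...]
    f_statistic: float
    p_value: float
    pairwise: list[PairwiseComparison]
    alpha: float = ALPHA

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def pair(self, label_a, label_b) -> PairwiseComparison:
        i = self.group_labels.index(label_a)
        j = self.group_labels.index(label_b)
        key = tuple(sorted((i, j)))
        for c in self.pairwise:
            if c.groups == key:
                return c
        raise KeyError((label_a, label_b))


def anova_bonferroni(groups: list, labels=None) -> GroupComparison:
    """Classical one-way ANOVA with pooled-MSE Bonferroni pairwise tests.

    Each element of ``groups`` is one age group's per-retina values
    (n >= 2 each).  Pairwise t tests share the pooled within-group
    mean-square error on N - k degrees of freedom; adjusted p values are
    ``min(1, raw p x number of pairs)``.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    for g in arrays:
        if g.size < 2:
            raise ValueError("each group needs n >= 2")
        if not np.isfinite(g).all():
            raise ValueError("groups must contain finite values")
    if labels is None:
        labels = tuple(range(len(arrays)))
    labels = tuple(labels)

    k = len(arrays)
    n_total = sum(g.size for g in arrays)
    df_within = n_total - k
    means = [float(g.mean()) for g in arrays]
    ss_within = sum(float(((g - g.mean()) ** 2).sum()) for g in arrays)
    if ss_within == 0 and len(set(means)) == 1:
        raise DegenerateVarianceError(
            "zero within-group variance with equal means: F is undefined")
    f_stat, p_val = sps.f_oneway(*arrays)

    mse = ss_within / df_within
    n_pairs = k * (k - 1) // 2
    pairwise = []
    for i, j in combinations(range(k), 2):
        diff = means[j] - means[i]
        se = np.sqrt(mse * (1.0 / arrays[i].size + 1.0 / arrays[j].size))
        if se == 0:
            t = np.inf if diff != 0 else 0.0
            p_raw = 0.0 if diff != 0 else 1.0
        else:
            t = diff / se
            p_raw = 2.0 * sps.t.sf(abs(t), df_within)
        pairwise.append(PairwiseComparison(
            (i, j), diff, float(t), float(p_raw), min(1.0, float(p_raw) * n_pairs)))
    return GroupComparison(labels, tuple(means), float(f_stat), float(p_val), pairwise)


def stars(p: float, alpha: float = ALPHA) -> str:
    """Significance marker used in the report tables."""
    return "*" if p < alpha else ""
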