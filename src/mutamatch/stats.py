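"""Cohort-level statistics: correlation, normality, size bins, ANOVA/Tukey.

The analysis relates a gene's full-length (FL) nucleotide size to each
mutability factor: a Pearson correlation (two-sided p from the
t-distribution) of FL against telomere proximity and against A+T content,
and a comparison of both factors across three FL-size groups
(1-3000, 3001-6000, 6001+ bases) by one-way ANOVA followed by Tukey's
multiple-comparison test (Tukey-Kramer for unequal group sizes).
Significance is assessed at alpha = 0.05, two-sided throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "PearsonResult",
    "PairwiseComparison",
    "AnovaTukeyResult",
    "SIZE_BIN_EDGES",
    "SIZE_BIN_LABELS",
    "ALPHA",
    "pearson_with_p",
    "assign_size_bin",
    "anova_tukey",
    "shapiro_wilk",
]

ALPHA = 0.05

# FL-size bins in bases; the last bin is open-ended (its display label caps
# at 17,000 only cosmetically — observed sizes exceed it).
SIZE_BIN_EDGES = (3000, 6000)
SIZE_BIN_LABELS = ("1-3000", "3001-6000", "6001-17,000")


@dataclass(frozen=True)
class PearsonResult:
    r: float
    p: float
    n: int


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    mean_diff: float
    p_adjusted: float

    @property
    def significant(self) -> bool:
        return self.p_adjusted < ALPHA


@dataclass(frozen=True)
class AnovaTukeyResult:
    F: float
    p_overall: float
    pairwise: tuple[PairwiseComparison, ...]


def pearson_with_p(x, y) -> PearsonResult:
    """Product-moment correlation with a two-sided t-distribution p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError(f"need n >= 3 for a correlation p-value, got n = {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    res = sps.pearsonr(x, y)
    return PearsonResult(r=float(res.statistic), p=float(res.pvalue), n=n)


def assign_size_bin(fl_size: int) -> int:
    """1-based FL-size bin: 1-3000 -> 1, 3001-6000 -> 2, 6001+ -> 3."""
    if fl_size < 1:
        raise ValueError(f"full-length size must be >= 1 bp, got {fl_size}")
    if fl_size <= SIZE_BIN_EDGES[0]:
        return 1
    if fl_size <= SIZE_BIN_EDGES[1]:
        return 2
    return 3


def anova_tukey(groups, labels=None) -> AnovaTukeyResult:
    """One-way ANOVA plus Tukey's multiple-comparison test.

    Unequal group sizes use the Tukey-Kramer adjustment.  If every value
    in every group is identical the result is F = 0, p = 1 (no evidence of
    any difference) rather than an error.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    for i, g in enumerate(arrays):
        if g.size < 2:
            raise ValueError(f"group {i} has fewer than 2 values")
    if labels is None:
        labels = [f"group{i+1}" for i in range(len(arrays))]
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        pairwise = tuple(
            PairwiseComparison(labels[i], labels[j], 0.0, 1.0)
            for i in range(len(arrays)) for j in range(i + 1, len(arrays))
        )
        return AnovaTukeyResult(F=0.0, p_overall=1.0, pairwise=pairwise)
    F, p = sps.f_oneway(*arrays)
    codes = np.concatenate([np.full(g.size, lab, dtype=object) for g, lab in zip(arrays, labels)])
    tukey = pairwise_tukeyhsd(pooled, codes, alpha=ALPHA)
    i1, i2 = np.triu_indices(len(tukey.groupsunique), 1)
    pairwise = tuple(
        PairwiseComparison(
            group_a=str(tukey.groupsunique[a]), group_b=str(tukey.groupsunique[b]),
            mean_diff=float(diff), p_adjusted=float(padj),
        )
        for a, b, diff, padj in zip(i1, i2, tukey.meandiffs, tukey.pvalues)
    )
    return AnovaTukeyResult(F=float(F), p_overall=float(p), pairwise=pairwise)


def shapiro_wilk(x) -> tuple[float, float]:
    """Shapiro-Wilk normality test (W, p) for 3 <= n <= 5000."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or not (3 <= x.size <= 5000):
        raise ValueError("Shapiro-Wilk requires a 1-D vector with 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("constant vector: normality test undefined")
    w, p = sps.shapiro(x)
    return float(w), float(p)
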