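"""Cross-condition and cross-tissue comparative statistics.

Given per-context regulatory calls (liver/kidney x control/TM), this
module quantifies how much regulatory variation is cryptic — present in
only one condition or tissue: set overlaps with a hypergeometric
enrichment test, shifts in the cis fraction with a two-proportion test,
effect-magnitude comparisons (Welch t on |log2 parental ratios|), and
correlation of shared effects across contexts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cistrans import RegulatoryCall


@dataclass
class OverlapSummary:
    n_a_only: int
    n_b_only: int
    n_common: int
    universe_n: int
    p_hyper: float


@dataclass
class MagnitudeSummary:
    label: str
    n: int
    mean_abs_log2: float
    sd_abs_log2: float


def overlap_analysis(set_a: set, set_b: set, universe: set) -> OverlapSummary:
    """Partition two gene sets and test their overlap against chance.

    ``p_hyper`` is the upper-tail hypergeometric probability of drawing
    at least the observed overlap when |B| genes are sampled from the
    universe and |A| of them are marked.  The universe should contain
    only genes testable in both contexts.
    """
    set_a, set_b, universe = set(set_a), set(set_b), set(universe)
    for name, s in (("A", set_a), ("B", set_b)):
        stray = s - universe
        if stray:
            raise ValueError(f"set {name} element {next(iter(stray))!r} outside universe")
    common = set_a & set_b
    k = len(common)
    p = stats.hypergeom.sf(k - 1, len(universe), len(set_a), len(set_b))
    return OverlapSummary(
        n_a_only=len(set_a) - k,
        n_b_only=len(set_b) - k,
        n_common=k,
        universe_n=len(universe),
        p_hyper=float(p),
    )


def proportion_shift_test(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float, float]:
    """Two-sided two-proportion z-test of k1/n1 vs k2/n2.

    Equivalent to a Pearson chi-square without continuity correction on
    the 2x2 table.  Returns (prop1, prop2, p).
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0 or not 0 <= k <= n:
            raise ValueError(f"invalid proportion {k}/{n}")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        if p1 == p2:
            return p1, p2, 1.0
        raise ValueError("degenerate pooled proportion with unequal group proportions")
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (p1 - p2) / se
    return p1, p2, float(2 * stats.norm.sf(abs(z)))


def magnitude_summary(calls: list[RegulatoryCall], label: str) -> MagnitudeSummary:
    mags = np.array([abs(c.parental_log2) for c in calls])
    return MagnitudeSummary(
        label=label,
        n=len(mags),
        mean_abs_log2=float(mags.mean()) if len(mags) else np.nan,
        sd_abs_log2=float(mags.std(ddof=1)) if len(mags) > 1 else np.nan,
    )


def magnitude_and_correlation(
    calls_a: list[RegulatoryCall],
    calls_b: list[RegulatoryCall],
    label_a: str = "A",
    label_b: str = "B",
) -> tuple[MagnitudeSummary, MagnitudeSummary, float, float]:
    """Compare effect magnitudes between two call sets and correlate shared genes.

    Returns (summary_a, summary_b, welch_p, r2) where ``welch_p`` is the
    two-sided Welch t-test on |log2(B6/CAST)| and ``r2`` the squared
    Pearson correlation of parental log2 ratios over genes present in
    both sets (NaN when fewer than 3 genes are shared).
    """
    sum_a = magnitude_summary(calls_a, label_a)
    sum_b = magnitude_summary(calls_b, label_b)
    mags_a = [abs(c.parental_log2) for c in calls_a]
    mags_b = [abs(c.parental_log2) for c in calls_b]
    if len(mags_a) > 1 and len(mags_b) > 1:
        welch_p = float(stats.ttest_ind(mags_a, mags_b, equal_var=False).pvalue)
    else:
        welch_p = np.nan
    by_a = {c.gene_id: c.parental_log2 for c in calls_a}
    by_b = {c.gene_id: c.parental_log2 for c in calls_b}
    common = sorted(set(by_a) & set(by_b))
    if len(common) < 3:
        r2 = np.nan
    else:
        xa = np.array([by_a[g] for g in common])
        xb = np.array([by_b[g] for g in common])
        if np.std(xa) == 0 or np.std(xb) == 0:
            r2 = np.nan
        else:
            r2 = float(stats.pearsonr(xa, xb).statistic ** 2)
    return sum_a, sum_b, welch_p, r2


def category_sets(calls: list[RegulatoryCall], category: str) -> set[str]:
    """Genes carrying a given regulatory category in a call list."""
    return {c.gene_id for c in calls if c.category == category}


def cryptic_partition(
    calls_a: list[RegulatoryCall],
    calls_b: list[RegulatoryCall],
    category: str,
) -> pd.Series:
    """Unique-to-A / unique-to-B / common partition for one category.

    The union of the two category sets is the denominator, matching the
    "unique to control / unique to stress / common" style of reporting.
    """
    a = category_sets(calls_a, category)
    b = category_sets(calls_b, category)
    union = len(a | b)
    return pd.Series(
        {
            "n_a_only": len(a - b),
            "n_b_only": len(b - a),
            "n_common": len(a & b),
            "n_union": union,
            "frac_a_only": len(a - b) / union if union else np.nan,
            "frac_b_only": len(b - a) / union if union else np.nan,
            "frac_common": len(a & b) / union if union else np.nan,
        }
    )
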