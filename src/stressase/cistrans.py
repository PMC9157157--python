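"""Cis/trans regulatory classification from parental and F1 allelic ratios.

The logic of the F1 design: a cis-acting variant changes one allele's
expression and travels with it into the hybrid, so the F1 allelic ratio
mirrors the parental ratio.  A trans-acting variant affects both F1
alleles equally (they share one cellular environment), so parental
divergence with balanced F1 alleles points to trans.  Three exact tests
per gene x tissue x condition make that comparison:

* ``p_parent`` — Fisher exact of the pooled parental counts against the
  remaining library mass (is total expression divergent between B6 and
  CAST?);
* ``p_allelic`` — exact binomial of the F1 B6-allele count against 0.5
  (is the hybrid imbalanced?);
* ``p_ct`` — Fisher exact of parental counts vs allelic counts (do the
  two ratios disagree?).

After BH adjustment within each test family (per tissue x condition) a
gene is classified at a 0.1% FDR cutoff:

========== =========== =========== =======
category   q_parent    q_allelic   q_ct
========== =========== =========== =======
cis        sig         sig         ns
trans      sig         ns          sig
cis+trans  sig         sig         sig  (same sign, allelic attenuated)
cis x trans sig        sig         sig  (opposed sign or amplified)
conserved  ns          ns          ns
ambiguous  any other pattern
========== =========== =========== =======

A chi-square test between conditions then flags regulatory effects that
exist only under stress (or only at baseline) — cryptic regulatory
variation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ase import GeneAlleleCounts
from .normde import bh_adjust, estimate_size_factors
from .types import CountMatrix

logger = logging.getLogger(__name__)

CATEGORIES = ("cis", "trans", "cis_plus_trans", "cis_times_trans", "conserved", "ambiguous")


@dataclass
class RegulatoryTestTriple:
    gene_id: str
    tissue: str
    condition: str
    parental_b6: int
    parental_cast: int
    allelic_b6: int
    allelic_cast: int
    p_parent: float = np.nan
    p_allelic: float = np.nan
    p_ct: float = np.nan
    q_parent: float = np.nan
    q_allelic: float = np.nan
    q_ct: float = np.nan
    untestable: bool = False


@dataclass
class RegulatoryCall:
    gene_id: str
    tissue: str
    condition: str
    parental_log2: float
    allelic_log2: float
    category: str
    condition_specific: str = "untested"
    chi2_p: float = np.nan


def _log2_ratio(a: float, b: float) -> float:
    """log2(a/b) with a +0.5 pseudocount guard against zeros."""
    if a > 0 and b > 0:
        return float(np.log2(a / b))
    return float(np.log2((a + 0.5) / (b + 0.5)))


def regulatory_tests(
    triple: RegulatoryTestTriple, library_b6: int, library_cast: int
) -> RegulatoryTestTriple:
    """Fill the three raw p-values for one gene.

    ``library_b6`` / ``library_cast`` are the pooled normalized totals of
    the analyzed gene set in each parental strain; the parental test
    contrasts this gene's share of each library.
    """
    pb6, pcast = triple.parental_b6, triple.parental_cast
    ab6, acast = triple.allelic_b6, triple.allelic_cast
    if pb6 == 0 and pcast == 0:
        triple.untestable = True
        logger.warning("gene %s: zero pooled parental counts; untestable", triple.gene_id)
        return triple
    parent_table = np.array([[pb6, pcast], [library_b6 - pb6, library_cast - pcast]])
    if (parent_table < 0).any():
        raise ValueError(f"gene {triple.gene_id}: counts exceed library totals")
    triple.p_parent = stats.fisher_exact(parent_table, alternative="two-sided")[1]
    n_allelic = ab6 + acast
    if n_allelic > 0:
        triple.p_allelic = stats.binomtest(ab6, n_allelic, 0.5, alternative="two-sided").pvalue
        ct_table = np.array([[pb6, pcast], [ab6, acast]])
        triple.p_ct = stats.fisher_exact(ct_table, alternative="two-sided")[1]
    else:
        triple.untestable = True
    return triple


def classify_regulatory(t: RegulatoryTestTriple, fdr: float = 0.001) -> RegulatoryCall:
    """Assign the regulatory category from the adjusted significance pattern."""
    parental_log2 = _log2_ratio(t.parental_b6, t.parental_cast)
    allelic_log2 = _log2_ratio(t.allelic_b6, t.allelic_cast)

    def sig(q: float) -> bool:
        return bool(q < fdr) if not np.isnan(q) else False

    sp, sa, sc = sig(t.q_parent), sig(t.q_allelic), sig(t.q_ct)
    if t.untestable:
        category = "ambiguous"
    elif sp and sa and not sc:
        category = "cis"
    elif sp and not sa and sc:
        category = "trans"
    elif sp and sa and sc:
        same_sign = np.sign(allelic_log2) == np.sign(parental_log2)
        if same_sign and abs(allelic_log2) < abs(parental_log2):
            category = "cis_plus_trans"
        else:
            category = "cis_times_trans"
    elif not sp and not sa and not sc:
        category = "conserved"
    else:
        category = "ambiguous"
    return RegulatoryCall(
        gene_id=t.gene_id,
        tissue=t.tissue,
        condition=t.condition,
        parental_log2=parental_log2,
        allelic_log2=allelic_log2,
        category=category,
    )


def pooled_parental_counts(cm: CountMatrix, tissue: str) -> pd.DataFrame:
    """Replicate-pooled, size-factor-normalized parental counts per gene.

    Size factors are estimated across the tissue's parental samples
    (both strains, both conditions) so strain totals are comparable;
    normalized counts are summed over replicates and rounded to the
    nearest integer for the exact tests.  Columns: b6_control, cast_control,
    b6_tm, cast_tm.
    """
    sub = cm.subset(tissue=tissue)
    keep = sub.samples["genotype"].isin(["B6", "CAST"])
    ids = list(sub.samples.index[keep])
    sub = CountMatrix(sub.counts[ids], sub.samples.loc[ids])
    s = estimate_size_factors(sub)
    norm = sub.counts / s
    out = {}
    for geno, label in (("B6", "b6"), ("CAST", "cast")):
        for cond, suffix in (("control", "control"), ("TM", "tm")):
            cols = sub.samples.index[
                (sub.samples["genotype"] == geno) & (sub.samples["condition"] == cond)
            ]
            out[f"{label}_{suffix}"] = norm[list(cols)].sum(axis=1).round().astype(int)
    return pd.DataFrame(out, index=sub.counts.index)


def regulatory_analysis(
    parental: pd.DataFrame,
    allelic: list[GeneAlleleCounts],
    tissue: str,
    condition: str,
    fdr: float = 0.001,
) -> tuple[list[RegulatoryCall], list[RegulatoryTestTriple]]:
    """Classify every testable gene in one tissue x condition.

    ``parental`` comes from :func:`pooled_parental_counts`; ``allelic``
    from the ASE aggregation (already filtered).  BH adjustment is
    applied separately to each of the three test families within this
    tissue x condition.

    The parental test runs against balanced library margins (the mean of
    the two strains' totals on both sides).  Median-of-ratios
    normalization pins a non-divergent gene at a 1:1 ratio, so 1:1 is
    the correct null; raw library totals can be skewed by a handful of
    strongly divergent, highly expressed genes, which would bias the
    test for every other gene.
    """
    suffix = "tm" if condition == "TM" else "control"
    by_gene = {
        gc.gene_id: gc for gc in allelic if gc.tissue == tissue and gc.condition == condition
    }
    genes = [g for g in sorted(by_gene) if g in parental.index]
    if len(genes) < len(by_gene):
        logger.info(
            "%d allelic gene(s) missing from parental counts", len(by_gene) - len(genes)
        )
    lib_b6 = int(parental.loc[genes, f"b6_{suffix}"].sum())
    lib_cast = int(parental.loc[genes, f"cast_{suffix}"].sum())
    lib = int(round(0.5 * (lib_b6 + lib_cast)))
    triples = []
    for gene in genes:
        gc = by_gene[gene]
        t = RegulatoryTestTriple(
            gene_id=gene,
            tissue=tissue,
            condition=condition,
            parental_b6=int(parental.loc[gene, f"b6_{suffix}"]),
            parental_cast=int(parental.loc[gene, f"cast_{suffix}"]),
            allelic_b6=gc.b6_count,
            allelic_cast=gc.cast_count,
        )
        triples.append(regulatory_tests(t, lib, lib))
    for attr in ("p_parent", "p_allelic", "p_ct"):
        qs = bh_adjust([getattr(t, attr) for t in triples])
        for t, q in zip(triples, qs):
            setattr(t, attr.replace("p_", "q_"), q)
    calls = [classify_regulatory(t, fdr=fdr) for t in triples]
    return calls, triples


def condition_specificity_test(
    control: RegulatoryTestTriple | None,
    tm: RegulatoryTestTriple | None,
    control_call: str,
    tm_call: str,
    alpha: float = 0.05,
) -> tuple[str, float]:
    """Is a cis/trans effect present in only one condition?

    Chi-square (Pearson, no continuity correction) compares the two
    conditions' allelic tables for cis calls, or parental tables for
    trans calls; Fisher exact replaces it when an expected cell drops
    below 1.  The stress_only / control_only flag requires the call to
    exist in exactly one condition AND the between-condition test to
    reject at ``alpha``.
    """
    focal = {"cis", "trans"}
    in_ctrl = control_call in focal
    in_tm = tm_call in focal
    if not in_ctrl and not in_tm:
        return "untested", np.nan
    if control is None or tm is None:
        return "untested", np.nan
    # table choice follows the call type; a cis call anywhere uses the allelic table
    call_types = {c for c in (control_call, tm_call) if c in focal}
    if "cis" in call_types:
        table = np.array(
            [[control.allelic_b6, control.allelic_cast], [tm.allelic_b6, tm.allelic_cast]]
        )
    else:
        table = np.array(
            [[control.parental_b6, control.parental_cast], [tm.parental_b6, tm.parental_cast]]
        )
    if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
        return "untested", np.nan
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if expected.min() < 1:
        logger.info("expected cell < 1; falling back to Fisher exact")
        p = stats.fisher_exact(table, alternative="two-sided")[1]
    else:
        p = stats.chi2_contingency(table, correction=False)[1]
    if in_ctrl and in_tm:
        return "both", p
    if p < alpha:
        return ("stress_only" if in_tm else "control_only"), p
    return "untested", p


def attach_condition_specificity(
    calls_control: list[RegulatoryCall],
    calls_tm: list[RegulatoryCall],
    triples_control: list[RegulatoryTestTriple],
    triples_tm: list[RegulatoryTestTriple],
    alpha: float = 0.05,
) -> None:
    """Fill the condition_specific flag on every cis/trans call in place."""
    t_ctrl = {t.gene_id: t for t in triples_control}
    t_tm = {t.gene_id: t for t in triples_tm}
    c_ctrl = {c.gene_id: c for c in calls_control}
    c_tm = {c.gene_id: c for c in calls_tm}
    for gene in set(c_ctrl) | set(c_tm):
        call_c = c_ctrl.get(gene)
        call_t = c_tm.get(gene)
        flag, p = condition_specificity_test(
            t_ctrl.get(gene),
            t_tm.get(gene),
            call_c.category if call_c else "ambiguous",
            call_t.category if call_t else "ambiguous",
            alpha=alpha,
        )
        for call in (call_c, call_t):
            if call is not None:
                call.condition_specific = flag
                call.chi2_p = p


def calls_frame(calls: list[RegulatoryCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "tissue": c.tissue,
                "condition": c.condition,
                "parental_log2": c.parental_log2,
                "allelic_log2": c.allelic_log2,
                "category": c.category,
                "condition_specific": c.condition_specific,
                "chi2_p": c.chi2_p,
            }
            for c in calls
        ]
    )
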