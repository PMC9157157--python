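"""Allele-specific expression (ASE) in the F1 hybrid.

In a B6 x CAST F1, both alleles share one trans environment, so the
allelic ratio reads out cis-regulatory differences directly.  This
module pools SNP-level allele counts to gene level (replicates combined
to increase coverage), tests whether the allelic ratio shifts between
control and TM with a two-sided Fisher exact test at 5% FDR, and
cross-tabulates significant shifts against the gene's total-transcript
response.

Gene filters follow the study design: a gene is testable in a tissue
only if it has at least 2 informative SNPs and at least 20 pooled allele
counts in at least one condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .normde import bh_adjust
from .types import SnpAlleleRecord, SnpTable

logger = logging.getLogger(__name__)


@dataclass
class GeneAlleleCounts:
    """Replicate- and SNP-pooled allele counts for one gene x tissue x condition."""

    gene_id: str
    tissue: str
    condition: str
    b6_count: int
    cast_count: int
    n_snps: int

    @property
    def total(self) -> int:
        return self.b6_count + self.cast_count

    @property
    def prop_b6(self) -> float:
        return self.b6_count / self.total if self.total else np.nan


@dataclass
class AseAggregationLog:
    """Why SNP records or genes were dropped during aggregation."""

    used_records: int = 0
    non_f1_records: int = 0
    allele_mismatch: int = 0
    unknown_snp: int = 0
    genes_kept: int = 0
    genes_too_few_snps: int = 0
    genes_low_count: int = 0
    dropped_counts: int = 0  # allele counts in dropped records/genes
    kept_counts: int = 0


@dataclass
class AseChangeResult:
    """Control vs TM allelic-ratio comparison for one gene x tissue."""

    gene_id: str
    tissue: str
    prop_b6_control: float
    prop_b6_tm: float
    p: float
    q: float = np.nan
    significant: bool = False
    total_change: str = "none"
    counts: tuple[int, int, int, int] = (0, 0, 0, 0)  # b6_ctrl, cast_ctrl, b6_tm, cast_tm


def aggregate_allele_counts(
    records: list[SnpAlleleRecord],
    snps: SnpTable,
    meta: pd.DataFrame,
    min_snps: int = 2,
    min_count: int = 20,
) -> tuple[list[GeneAlleleCounts], AseAggregationLog]:
    """Pool F1 SNP-level allele counts to gene x tissue x condition.

    ``meta`` is a sample sheet indexed by sample_id.  The SNP table
    resolves which observed allele is B6- vs CAST-derived; records whose
    ref/alt pair disagrees with it are tallied as allele mismatches and
    excluded.  An informative SNP is one with >=1 pooled read for the
    gene; genes with fewer than ``min_snps`` informative SNPs in either
    condition, or fewer than ``min_count`` pooled counts in both
    conditions, are dropped (per tissue).
    """
    log = AseAggregationLog()
    # (gene, tissue, condition) -> {(contig, pos) -> [b6, cast]}
    pools: dict[tuple[str, str, str], dict[tuple[str, int], list[int]]] = {}
    for rec in records:
        if not rec.gene_id:
            continue
        if rec.sample_id not in meta.index:
            raise KeyError(f"sample {rec.sample_id!r} absent from sample sheet")
        row = meta.loc[rec.sample_id]
        if row["genotype"] != "F1":
            log.non_f1_records += 1
            log.dropped_counts += rec.ref_count + rec.alt_count
            continue
        alleles = snps.lookup(rec.contig, rec.position)
        if alleles is None:
            log.unknown_snp += 1
            log.dropped_counts += rec.ref_count + rec.alt_count
            continue
        b6, cast = alleles
        if {rec.ref_allele, rec.alt_allele} != {b6, cast}:
            log.allele_mismatch += 1
            log.dropped_counts += rec.ref_count + rec.alt_count
            continue
        if rec.ref_allele == b6:
            b6_n, cast_n = rec.ref_count, rec.alt_count
        else:
            b6_n, cast_n = rec.alt_count, rec.ref_count
        key = (rec.gene_id, row["tissue"], row["condition"])
        snp_key = (rec.contig, rec.position)
        cell = pools.setdefault(key, {}).setdefault(snp_key, [0, 0])
        cell[0] += b6_n
        cell[1] += cast_n
        log.used_records += 1
    # apply gene-level filters per tissue
    out: list[GeneAlleleCounts] = []
    gene_tissues = sorted({(g, t) for (g, t, _) in pools})
    for gene, tissue in gene_tissues:
        per_cond: dict[str, tuple[int, int, int]] = {}
        for cond in ("control", "TM"):
            snp_cells = pools.get((gene, tissue, cond), {})
            informative = {k: v for k, v in snp_cells.items() if v[0] + v[1] > 0}
            b6_total = sum(v[0] for v in informative.values())
            cast_total = sum(v[1] for v in informative.values())
            per_cond[cond] = (b6_total, cast_total, len(informative))
        n_snps = [per_cond[c][2] for c in ("control", "TM")]
        totals = [per_cond[c][0] + per_cond[c][1] for c in ("control", "TM")]
        if min(n_snps) < min_snps:
            log.genes_too_few_snps += 1
            log.dropped_counts += sum(totals)
            continue
        if max(totals) < min_count:
            log.genes_low_count += 1
            log.dropped_counts += sum(totals)
            continue
        log.genes_kept += 1
        for cond in ("control", "TM"):
            b6_total, cast_total, n_inf = per_cond[cond]
            log.kept_counts += b6_total + cast_total
            out.append(
                GeneAlleleCounts(
                    gene_id=gene, tissue=tissue, condition=cond,
                    b6_count=b6_total, cast_count=cast_total, n_snps=n_inf,
                )
            )
    if log.allele_mismatch:
        logger.info("excluded %d allele-mismatch record(s)", log.allele_mismatch)
    if log.genes_too_few_snps or log.genes_low_count:
        logger.info(
            "ASE filters dropped %d gene(s) with <%d informative SNPs and %d with <%d counts",
            log.genes_too_few_snps, min_snps, log.genes_low_count, min_count,
        )
    return out, log


def ase_change_test(control: GeneAlleleCounts, tm: GeneAlleleCounts) -> AseChangeResult:
    """Two-sided Fisher exact test: does the allelic ratio shift under TM?

    The 2x2 table is [[b6_ctrl, cast_ctrl], [b6_tm, cast_tm]].  A
    zero-margin table (one condition entirely uncounted) yields a
    missing p.
    """
    if control.gene_id != tm.gene_id or control.tissue != tm.tissue:
        raise ValueError("control and TM rows must describe the same gene and tissue")
    table = np.array([[control.b6_count, control.cast_count], [tm.b6_count, tm.cast_count]])
    if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
        p = np.nan
        if table.sum(axis=1).min() == 0:
            logger.warning("gene %s: one condition has zero counts; p missing", control.gene_id)
    else:
        p = stats.fisher_exact(table, alternative="two-sided")[1]
    return AseChangeResult(
        gene_id=control.gene_id,
        tissue=control.tissue,
        prop_b6_control=control.prop_b6,
        prop_b6_tm=tm.prop_b6,
        p=p,
        counts=(control.b6_count, control.cast_count, tm.b6_count, tm.cast_count),
    )


def ase_analysis(
    gene_counts: list[GeneAlleleCounts],
    tissue: str,
    fdr: float = 0.05,
) -> list[AseChangeResult]:
    """Run the ASE-change test for every testable gene in one tissue.

    BH adjustment spans all tested genes in the tissue; significance at
    q < ``fdr``.
    """
    by_gene: dict[str, dict[str, GeneAlleleCounts]] = {}
    for gc in gene_counts:
        if gc.tissue == tissue:
            by_gene.setdefault(gc.gene_id, {})[gc.condition] = gc
    results = []
    for gene in sorted(by_gene):
        conds = by_gene[gene]
        if "control" in conds and "TM" in conds:
            results.append(ase_change_test(conds["control"], conds["TM"]))
    qs = bh_adjust([r.p for r in results])
    for r, q in zip(results, qs):
        r.q = q
        r.significant = bool(q < fdr) if not np.isnan(q) else False
    return results


def classify_total_change(
    ase_results: list[AseChangeResult], de_results: pd.DataFrame
) -> list[AseChangeResult]:
    """Attach each gene's total-transcript response class to its ASE result.

    ``de_results`` is the F1 differential-expression table for the same
    tissue (indexed by gene_id with a ``responsive`` column).  Genes
    absent from it are classed "none" and flagged as untested; a
    significant ASE change with no total-transcript change is the
    candidate compensatory pattern.
    """
    untested = 0
    for r in ase_results:
        if r.gene_id in de_results.index:
            r.total_change = de_results.loc[r.gene_id, "responsive"]
        else:
            r.total_change = "none"
            untested += 1
    if untested:
        logger.info("%d ASE gene(s) had no total-expression test (untested total)", untested)
    return ase_results


def ase_summary(ase_results: list[AseChangeResult]) -> pd.DataFrame:
    """Among significant ASE-change genes, the split by total-transcript class."""
    sig = [r for r in ase_results if r.significant]
    counts = {"up": 0, "down": 0, "none": 0}
    for r in sig:
        counts[r.total_change] += 1
    n = len(sig)
    return pd.DataFrame(
        {
            "total_change": list(counts),
            "n_genes": list(counts.values()),
            "fraction": [c / n if n else np.nan for c in counts.values()],
        }
    )


def ase_results_frame(results: list[AseChangeResult]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": r.gene_id,
            "tissue": r.tissue,
            "b6_control": r.counts[0],
            "cast_control": r.counts[1],
            "b6_tm": r.counts[2],
            "cast_tm": r.counts[3],
            "prop_b6_control": r.prop_b6_control,
            "prop_b6_tm": r.prop_b6_tm,
            "p": r.p,
            "q": r.q,
            "significant": r.significant,
            "total_change": r.total_change,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
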