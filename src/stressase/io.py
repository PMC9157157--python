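"""Readers and writers for the pipeline's file formats.

Formats handled here: TSV count matrices with a CSV sample sheet,
ASEReadCounter-style allele-count TSVs with a BED of gene spans for
SNP-to-gene assignment, strain-allele SNP tables, and the FASTA/VCF pair
consumed by the reference N-masking utility.

Coordinate conventions: VCF and allele-count tables are 1-based
inclusive; BED is 0-based half-open.  All conversion happens at read
time and everything downstream is 1-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .types import SAMPLE_SHEET_COLUMNS, CountMatrix, SampleMeta, SnpAlleleRecord, SnpTable

logger = logging.getLogger(__name__)

_ASE_REQUIRED = ("contig", "position", "refAllele", "altAllele", "refCount", "altCount")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a CSV sample sheet into a DataFrame indexed by sample_id."""
    sheet = pd.read_csv(path, dtype={"sample_id": str})
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet is missing column(s) {missing}")
    # SampleMeta validates factor levels
    for row in sheet.itertuples(index=False):
        SampleMeta(
            sample_id=row.sample_id,
            genotype=row.genotype,
            tissue=row.tissue,
            condition=row.condition,
            replicate=int(row.replicate),
        )
    if sheet["sample_id"].duplicated().any():
        dup = sheet["sample_id"][sheet["sample_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate sample id {dup!r} in sample sheet")
    return sheet.set_index("sample_id")


def read_counts(path: str | Path, sample_sheet: str | Path | pd.DataFrame) -> CountMatrix:
    """Read a gene x sample TSV of raw counts and join it to its sample sheet.

    The TSV's first column holds gene ids; every other column must name a
    sample present in the sheet.  Samples in the sheet but absent from
    the TSV are dropped with a warning; TSV columns absent from the
    sheet are an error.
    """
    sheet = sample_sheet if isinstance(sample_sheet, pd.DataFrame) else read_sample_sheet(sample_sheet)
    table = pd.read_csv(path, sep="\t", index_col=0)
    unknown = [c for c in table.columns if c not in sheet.index]
    if unknown:
        raise ValueError(f"unknown sample {unknown[0]}")
    absent = [s for s in sheet.index if s not in table.columns]
    if absent:
        logger.warning("sample sheet entries absent from count table: %s", absent)
        sheet = sheet.drop(index=absent)
    # preserve TSV column order
    sheet = sheet.loc[list(table.columns)]
    arr = table.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        frac = arr != np.floor(arr)
        if frac.any():
            g, s = np.argwhere(frac)[0]
            raise ValueError(
                f"non-integer count {arr[g, s]!r} for gene {table.index[g]!r}, "
                f"sample {table.columns[s]!r}"
            )
        table = table.astype(np.int64)
    return CountMatrix(table, sheet)


def write_counts(cm: CountMatrix, counts_path: str | Path, sheet_path: str | Path) -> None:
    """Write a CountMatrix back to TSV + CSV, inverse of :func:`read_counts`."""
    out = cm.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(counts_path, sep="\t")
    sheet = cm.samples.copy()
    sheet.index.name = "sample_id"
    sheet.to_csv(sheet_path)


def read_bed_spans(path: str | Path) -> dict[str, IntervalTree]:
    """Read gene spans from BED (0-based half-open; >=3 columns, name in col 4).

    Returns one interval tree per contig holding 1-based inclusive gene
    spans.  Strand, if present, is accepted and ignored: allele counting
    downstream is unstranded.
    """
    trees: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"BED line {lineno}: fewer than 3 columns")
            contig, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"BED line {lineno}: start {start} >= end {end}")
            name = parts[3] if len(parts) >= 4 and parts[3] else f"{contig}:{start}-{end}"
            # BED [start, end) 0-based  ->  1-based inclusive [start+1, end]
            trees.setdefault(contig, IntervalTree()).addi(start + 1, end + 1, name)
    return trees


@dataclass
class SnpAssignmentLog:
    """Accounting of SNP-to-gene assignment; all records are conserved."""

    assigned: int = 0
    intergenic: int = 0
    multi_gene: int = 0
    multi_gene_snps: list[tuple[str, int]] = field(default_factory=list)

    @property
    def total(self) -> int:
        return self.assigned + self.intergenic + self.multi_gene


def read_snp_allele_counts(
    path: str | Path, gene_spans: str | Path | dict[str, IntervalTree]
) -> tuple[list[SnpAlleleRecord], SnpAssignmentLog]:
    """Read an ASEReadCounter-style TSV and assign each SNP to a gene.

    Required columns: contig, position, refAllele, altAllele, refCount,
    altCount; a ``sample`` column is used if present (else the file stem
    becomes the sample id); extra columns are ignored.  SNPs overlapping
    zero spans or two or more spans are excluded from gene aggregation
    and tallied in the returned log.
    """
    trees = gene_spans if isinstance(gene_spans, dict) else read_bed_spans(gene_spans)
    table = pd.read_csv(path, sep="\t", dtype={"contig": str})
    missing = [c for c in _ASE_REQUIRED if c not in table.columns]
    if missing:
        raise ValueError(f"allele-count table is missing column(s) {missing}")
    sample_col = "sample" if "sample" in table.columns else None
    default_sample = Path(path).stem
    records: list[SnpAlleleRecord] = []
    log = SnpAssignmentLog()
    for lineno, row in enumerate(table.itertuples(index=False), 2):
        try:
            pos = int(row.position)
            rec_kwargs = dict(
                contig=str(row.contig),
                position=pos,
                ref_allele=str(row.refAllele),
                alt_allele=str(row.altAllele),
                ref_count=int(row.refCount),
                alt_count=int(row.altCount),
                sample_id=str(getattr(row, sample_col)) if sample_col else default_sample,
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed allele-count row at line {lineno}: {exc}") from exc
        hits = trees.get(rec_kwargs["contig"], IntervalTree())[pos]
        if len(hits) == 0:
            log.intergenic += 1
            continue
        if len(hits) > 1:
            log.multi_gene += 1
            log.multi_gene_snps.append((rec_kwargs["contig"], pos))
            continue
        log.assigned += 1
        records.append(SnpAlleleRecord(gene_id=next(iter(hits)).data, **rec_kwargs))
    if log.multi_gene:
        logger.info("excluded %d multi-gene SNP record(s)", log.multi_gene)
    if log.intergenic:
        logger.info("excluded %d intergenic SNP record(s)", log.intergenic)
    return records, log


def read_snp_table(path: str | Path) -> SnpTable:
    """Read a strain-allele table (contig, position, b6_allele, cast_allele)."""
    table = pd.read_csv(path, sep="\t", dtype={"contig": str})
    required = ("contig", "position", "b6_allele", "cast_allele")
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"SNP table is missing column(s) {missing}")
    snps = SnpTable()
    for row in table.itertuples(index=False):
        snps.add(str(row.contig), int(row.position), str(row.b6_allele), str(row.cast_allele))
    return snps


def write_snp_table(snps: SnpTable, path: str | Path) -> None:
    rows = [
        {"contig": c, "position": p, "b6_allele": b6, "cast_allele": cast}
        for (c, p), (b6, cast) in sorted(snps.alleles.items())
    ]
    pd.DataFrame(rows, columns=["contig", "position", "b6_allele", "cast_allele"]).to_csv(
        path, sep="\t", index=False
    )


def write_allele_counts(records: list[SnpAlleleRecord], path: str | Path) -> None:
    """Write SNP allele records in the ASEReadCounter-style layout we read."""
    rows = [
        {
            "contig": r.contig,
            "position": r.position,
            "variantID": f"{r.contig}:{r.position}",
            "refAllele": r.ref_allele,
            "altAllele": r.alt_allele,
            "refCount": r.ref_count,
            "altCount": r.alt_count,
            "totalCount": r.ref_count + r.alt_count,
            "sample": r.sample_id,
        }
        for r in records
    ]
    cols = ["contig", "position", "variantID", "refAllele", "altAllele",
            "refCount", "altCount", "totalCount", "sample"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def mask_reference(
    reference: str | Path, variants: str | Path, output: str | Path
) -> dict[str, int]:
    """Write a copy of ``reference`` with every biallelic SNV position set to N.

    Masking known strain-discriminating SNVs removes the reference-allele
    mapping advantage when aligning F1 hybrid reads.  Indels and
    multiallelic records are skipped (masking them would shift
    coordinates); the returned dict tallies masked and skipped records.
    Idempotent: masking an already-masked FASTA with the same VCF is a
    no-op.
    """
    from cyvcf2 import VCF
    from pyfaidx import Fasta

    fasta = Fasta(str(reference), as_raw=True)
    seqs = {name: bytearray(str(fasta[name][:]), "ascii") for name in fasta.keys()}
    stats = {"masked": 0, "skipped_indel": 0, "skipped_multiallelic": 0}
    for rec in VCF(str(variants)):
        if rec.CHROM not in seqs:
            raise ValueError(f"contig {rec.CHROM!r} absent from reference FASTA")
        if len(rec.ALT) != 1:
            stats["skipped_multiallelic"] += 1
            continue
        if len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            stats["skipped_indel"] += 1
            continue
        pos = rec.POS  # 1-based
        seq = seqs[rec.CHROM]
        if pos > len(seq):
            raise ValueError(
                f"VCF position {rec.CHROM}:{pos} beyond contig length {len(seq)}"
            )
        seq[pos - 1] = ord("N")
        stats["masked"] += 1
    with open(output, "w") as out:
        for name, seq in seqs.items():
            out.write(f">{name}\n")
            text = seq.decode("ascii")
            for i in range(0, len(text), 60):
                out.write(text[i : i + 60] + "\n")
    if stats["skipped_indel"] or stats["skipped_multiallelic"]:
        logger.info(
            "masking skipped %d indel and %d multiallelic record(s)",
            stats["skipped_indel"], stats["skipped_multiallelic"],
        )
    return stats
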