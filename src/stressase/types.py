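"""Core containers shared across the pipeline.

The experiment crosses two inbred mouse strains (B6 = C57BL/6J, the
reference strain; CAST = CAST/EiJ) and their F1 hybrid, samples two
tissues (liver, kidney) under control and tunicamycin (TM, an ER-stress
inducer) treatment, and measures gene expression by RNA-seq.  Total
expression lives in a :class:`CountMatrix`; allele-resolved expression in
the F1 arrives as per-SNP read counts (:class:`SnpAlleleRecord`) that a
:class:`SnpTable` of strain-discriminating SNPs maps back to parental
chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENOTYPES = ("B6", "CAST", "F1")
TISSUES = ("liver", "kidney")
CONDITIONS = ("control", "TM")

#: Columns every sample sheet must provide.
SAMPLE_SHEET_COLUMNS = ("sample_id", "genotype", "tissue", "condition", "replicate")


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one RNA-seq library."""

    sample_id: str
    genotype: str
    tissue: str
    condition: str
    replicate: int

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(
                f"sample {self.sample_id}: genotype {self.genotype!r} not in {GENOTYPES}"
            )
        if self.tissue not in TISSUES:
            raise ValueError(
                f"sample {self.sample_id}: tissue {self.tissue!r} not in {TISSUES}"
            )
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"sample {self.sample_id}: condition {self.condition!r} not in {CONDITIONS}"
            )
        if int(self.replicate) < 1:
            raise ValueError(f"sample {self.sample_id}: replicate must be >= 1")


@dataclass
class CountMatrix:
    """Gene x sample matrix of raw read counts plus sample metadata.

    ``counts`` is a DataFrame indexed by gene id with one column per
    sample; ``samples`` is a DataFrame indexed by sample id with columns
    genotype / tissue / condition / replicate, in the same order as the
    count columns.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.samples.index):
            raise ValueError("count columns and sample sheet rows disagree in order")
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r}")
        if self.samples.index.has_duplicates:
            dup = self.samples.index[self.samples.index.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                bad = np.argwhere(arr != np.round(arr))[0]
                raise ValueError(
                    f"non-integer count for gene {self.counts.index[bad[0]]!r}, "
                    f"sample {self.counts.columns[bad[1]]!r}"
                )
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts are not allowed")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def subset(
        self,
        genotype: str | None = None,
        tissue: str | None = None,
        condition: str | None = None,
    ) -> "CountMatrix":
        """Restrict to samples matching the given factor levels."""
        keep = pd.Series(True, index=self.samples.index)
        for col, val in (("genotype", genotype), ("tissue", tissue), ("condition", condition)):
            if val is not None:
                keep &= self.samples[col] == val
        ids = list(self.samples.index[keep])
        return CountMatrix(self.counts[ids], self.samples.loc[ids])

    def require_replicates(self, min_reps: int = 2) -> None:
        """Refuse analyses whose design cells are under-replicated."""
        sizes = self.samples.groupby(
            ["genotype", "tissue", "condition"], observed=True
        ).size()
        thin = sizes[sizes < min_reps]
        if len(thin):
            cell = thin.index[0]
            raise ValueError(
                f"design cell {cell} has {int(thin.iloc[0])} replicate(s); "
                f"need at least {min_reps}"
            )


@dataclass(frozen=True)
class SnpAlleleRecord:
    """One ASEReadCounter-style row: allele read counts at one SNP in one sample."""

    contig: str
    position: int  # 1-based
    ref_allele: str
    alt_allele: str
    ref_count: int
    alt_count: int
    sample_id: str
    gene_id: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(
                f"{self.contig}:{self.position}: ref and alt alleles are identical"
            )
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError(f"{self.contig}:{self.position}: negative allele count")


@dataclass
class SnpTable:
    """Strain-discriminating biallelic SNVs: which base each strain carries.

    Indexed by (contig, 1-based position) -> (b6_allele, cast_allele).
    """

    alleles: dict[tuple[str, int], tuple[str, str]] = field(default_factory=dict)

    def add(self, contig: str, position: int, b6: str, cast: str) -> None:
        if b6 == cast:
            raise ValueError(f"{contig}:{position}: strains carry the same allele")
        key = (contig, int(position))
        if key in self.alleles:
            raise ValueError(f"duplicate SNP at {contig}:{position}")
        self.alleles[key] = (b6, cast)

    def lookup(self, contig: str, position: int) -> tuple[str, str] | None:
        return self.alleles.get((contig, int(position)))

    def __len__(self) -> int:
        return len(self.alleles)
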