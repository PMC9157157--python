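"""End-to-end orchestration: normalization/DE -> ASE -> cis/trans -> comparisons.

``run_pipeline`` takes files on disk (or in-memory objects via
``run_objects``), runs every stage per tissue, and writes stage TSVs
plus a machine-readable JSON summary into the output directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import ase as asecore
from . import cistrans as ct
from . import compare
from . import io as iolib
from . import normde
from .types import CountMatrix, SnpAlleleRecord, SnpTable, GENOTYPES

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All thresholds with the study's defaults."""

    base_mean_min: float = 5.0
    fold: float = 1.5
    de_fdr: float = 0.05
    ase_fdr: float = 0.05
    ct_fdr: float = 0.001
    specificity_alpha: float = 0.05
    min_snps: int = 2
    min_count: int = 20
    tissues: tuple[str, ...] = ("liver", "kidney")
    seed: int = 0

    def validate(self) -> None:
        for name in ("de_fdr", "ase_fdr", "ct_fdr", "specificity_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.fold <= 1:
            raise ValueError("fold cutoff must exceed 1")
        if self.base_mean_min < 0 or self.min_snps < 1 or self.min_count < 0:
            raise ValueError("invalid filter threshold")


@dataclass
class PipelineResult:
    de: dict[tuple[str, str], pd.DataFrame] = field(default_factory=dict)
    interaction: dict[str, pd.DataFrame] = field(default_factory=dict)
    lrt: dict[str, pd.DataFrame] = field(default_factory=dict)
    ase: dict[str, list] = field(default_factory=dict)
    calls: dict[tuple[str, str], list] = field(default_factory=dict)
    triples: dict[tuple[str, str], list] = field(default_factory=dict)
    ase_log: object = None
    summary: dict = field(default_factory=dict)


def run_objects(
    cm: CountMatrix,
    records: list[SnpAlleleRecord],
    snps: SnpTable,
    cfg: PipelineConfig | None = None,
) -> PipelineResult:
    """Run every stage on in-memory inputs."""
    cfg = cfg or PipelineConfig()
    cfg.validate()
    cm.require_replicates(2)
    res = PipelineResult()
    tissues = [t for t in cfg.tissues if t in set(cm.samples["tissue"])]

    for tissue in tissues:
        for geno in GENOTYPES:
            res.de[(geno, tissue)] = normde.de_analysis(
                cm, geno, tissue, fdr=cfg.de_fdr, fold=cfg.fold,
                base_mean_min=cfg.base_mean_min,
            )
    if len(tissues) == 2:
        for geno in GENOTYPES:
            res.interaction[geno] = normde.interaction_test(
                cm, geno, fdr=cfg.de_fdr, base_mean_min=cfg.base_mean_min
            )
    for tissue in tissues:
        res.lrt[tissue] = normde.genotype_lrt_test(
            cm, tissue, fdr=cfg.de_fdr, base_mean_min=cfg.base_mean_min
        )

    gene_counts, res.ase_log = asecore.aggregate_allele_counts(
        records, snps, cm.samples, min_snps=cfg.min_snps, min_count=cfg.min_count
    )
    for tissue in tissues:
        results = asecore.ase_analysis(gene_counts, tissue, fdr=cfg.ase_fdr)
        asecore.classify_total_change(results, res.de[("F1", tissue)])
        res.ase[tissue] = results

        parental = ct.pooled_parental_counts(cm, tissue)
        per_cond = {}
        for cond in ("control", "TM"):
            calls, triples = ct.regulatory_analysis(
                parental, gene_counts, tissue, cond, fdr=cfg.ct_fdr
            )
            res.calls[(tissue, cond)] = calls
            res.triples[(tissue, cond)] = triples
            per_cond[cond] = (calls, triples)
        ct.attach_condition_specificity(
            per_cond["control"][0], per_cond["TM"][0],
            per_cond["control"][1], per_cond["TM"][1],
            alpha=cfg.specificity_alpha,
        )

    res.summary = _summarize(res, tissues, cfg)
    return res


def _summarize(res: PipelineResult, tissues: list[str], cfg: PipelineConfig) -> dict:
    summary: dict = {"thresholds": vars(cfg).copy()}
    summary["thresholds"]["tissues"] = list(cfg.tissues)
    de_counts = {}
    for (geno, tissue), table in res.de.items():
        de_counts[f"{geno}_{tissue}"] = {
            "expressed": int(len(table)),
            "up": int((table["responsive"] == "up").sum()),
            "down": int((table["responsive"] == "down").sum()),
        }
    summary["de"] = de_counts
    summary["lrt"] = {
        t: int(table["genotype_dependent"].sum()) for t, table in res.lrt.items()
    }
    summary["interaction"] = {
        g: int(table["tissue_dependent"].sum()) for g, table in res.interaction.items()
    }
    ase_summary = {}
    for tissue, results in res.ase.items():
        sig = [r for r in results if r.significant]
        ase_summary[tissue] = {
            "tested": len(results),
            "significant": len(sig),
            "total_change": {
                cls: sum(1 for r in sig if r.total_change == cls)
                for cls in ("up", "down", "none")
            },
        }
    summary["ase"] = ase_summary
    cat_summary = {}
    for (tissue, cond), calls in res.calls.items():
        tally = {}
        for c in calls:
            tally[c.category] = tally.get(c.category, 0) + 1
        cat_summary[f"{tissue}_{cond}"] = tally
    summary["regulatory_categories"] = cat_summary
    cryptic = {}
    for tissue in tissues:
        key_c, key_t = (tissue, "control"), (tissue, "TM")
        if key_c in res.calls and key_t in res.calls:
            for cat in ("cis", "trans"):
                part = compare.cryptic_partition(res.calls[key_c], res.calls[key_t], cat)
                cryptic[f"{tissue}_{cat}"] = {k: float(v) for k, v in part.items()}
    summary["cryptic_partitions"] = cryptic
    if res.ase_log is not None:
        summary["ase_filtering"] = {
            "genes_kept": res.ase_log.genes_kept,
            "genes_too_few_snps": res.ase_log.genes_too_few_snps,
            "genes_low_count": res.ase_log.genes_low_count,
            "allele_mismatch_records": res.ase_log.allele_mismatch,
        }
    return summary


def write_outputs(res: PipelineResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for (geno, tissue), table in res.de.items():
        table.to_csv(outdir / f"de_{geno}_{tissue}.tsv", sep="\t")
    for geno, table in res.interaction.items():
        table.to_csv(outdir / f"interaction_{geno}.tsv", sep="\t")
    for tissue, table in res.lrt.items():
        table.to_csv(outdir / f"lrt_{tissue}.tsv", sep="\t")
    for tissue, results in res.ase.items():
        asecore.ase_results_frame(results).to_csv(
            outdir / f"ase_change_{tissue}.tsv", sep="\t", index=False
        )
    call_frames = [ct.calls_frame(calls) for calls in res.calls.values() if calls]
    if call_frames:
        pd.concat(call_frames, ignore_index=True).to_csv(
            outdir / "regulatory_calls.tsv", sep="\t", index=False
        )
    with open(outdir / "summary.json", "w") as fh:
        json.dump(res.summary, fh, indent=2, default=str)


def run_pipeline(
    counts_path: str | Path,
    sheet_path: str | Path,
    allele_counts_path: str | Path,
    bed_path: str | Path,
    snp_table_path: str | Path,
    outdir: str | Path,
    cfg: PipelineConfig | None = None,
) -> PipelineResult:
    """File-based entry point: read inputs, run all stages, write a report."""
    cm = iolib.read_counts(counts_path, sheet_path)
    records, _ = iolib.read_snp_allele_counts(allele_counts_path, bed_path)
    snps = iolib.read_snp_table(snp_table_path)
    res = run_objects(cm, records, snps, cfg)
    write_outputs(res, outdir)
    return res
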