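"""Synthetic parental + F1 count data with known regulatory architecture.

The generator mirrors the generative assumptions of the F1 design so
every pipeline stage can be exercised against ground truth:

* each gene has a baseline mean (log-normal across genes) and a
  per-tissue baseline offset;
* a cis effect of ``c`` log2 units multiplies the B6 allele wherever it
  occurs (B6 parent, B6 allele in the F1); a trans effect of ``t`` log2
  units multiplies whole-animal B6 expression but, because both F1
  alleles share the hybrid's trans environment, leaves the F1 allelic
  ratio untouched — so the expected F1 B6-allele fraction is
  ``2^c / (1 + 2^c)`` regardless of ``t``, and the parental ratio is
  ``2^(c+t)``;
* F1 total expression is the mid-parent (no dominance);
* ER stress multiplies means by ``2^r`` for responsive genes, with
  optional tissue- and genotype-specific response modifiers; a
  genotype-specific response difference between the parents is, by
  construction, a stress-only trans effect and is recorded as such;
* stress-only regulatory effects are active under TM only — the cryptic
  variation the pipeline is meant to recover;
* replicate counts are negative-binomial around mean x size factor; F1
  allelic totals are a binomial thinning of the F1 count (reads
  overlapping informative SNPs), split binomially between alleles and
  multinomially across the gene's SNPs, so SNP-level counts sum exactly
  to the allelic totals.

Defaults emulate the study's scale at desk size: 3 replicates per
genotype x tissue x condition, NB dispersion 0.1, a majority of genes
conserved with cis effects outnumbering trans.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import CountMatrix, SnpAlleleRecord, SnpTable, GENOTYPES

_GENE_SPAN = 1_000  # bases covered by each simulated gene
_GENE_STRIDE = 2_000


@dataclass
class SimConfig:
    """Knobs of the generative model (log2 effect units throughout)."""

    n_genes: int = 2000
    replicates: int = 3
    tissues: tuple[str, ...] = ("liver", "kidney")
    #: log-normal baseline mean counts: exp(Normal(meanlog, sdlog))
    baseline_meanlog: float = 5.0
    baseline_sdlog: float = 1.0
    tissue_baseline_sd: float = 1.0
    dispersion: float = 0.1
    size_factor_sdlog: float = 0.15
    # regulatory architecture
    frac_cis: float = 0.10
    frac_trans: float = 0.05
    frac_cis_plus_trans: float = 0.05
    frac_cis_times_trans: float = 0.025
    #: |effect| = effect_min + Exponential(effect_scale), random sign
    effect_min: float = 1.0
    effect_scale: float = 0.5
    frac_stress_only: float = 0.4
    # ER-stress response
    frac_responsive: float = 0.25
    response_sd: float = 1.5
    prob_tissue_modifier: float = 0.2
    tissue_modifier_sd: float = 1.0
    prob_genotype_modifier: float = 0.0
    genotype_modifier_sd: float = 0.5
    #: n_snps = 1 + Poisson(snps_per_gene_rate); support >= 1 exercises the filter
    snps_per_gene_rate: float = 2.0
    #: fraction of a gene's F1 reads overlapping informative SNPs
    ase_capture: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        fracs = (
            self.frac_cis, self.frac_trans, self.frac_cis_plus_trans,
            self.frac_cis_times_trans,
        )
        if any(f < 0 for f in fracs) or sum(fracs) > 1:
            raise ValueError("category fractions must be >= 0 and sum to <= 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if not 0 < self.ase_capture <= 1:
            raise ValueError("ase_capture must be in (0, 1]")
        if self.replicates < 2:
            raise ValueError("need >= 2 replicates per design cell")


@dataclass
class SimData:
    """Everything :func:`simulate_experiment` produces."""

    counts: CountMatrix
    records: list[SnpAlleleRecord]
    snps: SnpTable
    truth: pd.DataFrame
    gene_spans: list[tuple[str, int, int, str]]  # BED-style 0-based half-open


def _expected_category(c: float, t: float) -> str:
    if c == 0 and t == 0:
        return "conserved"
    if t == 0:
        return "cis"
    if c == 0:
        return "trans"
    # allelic_log2 = c, parental_log2 = c + t
    if np.sign(c) == np.sign(c + t) and abs(c) < abs(c + t):
        return "cis_plus_trans"
    return "cis_times_trans"


def _nb(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    r = 1.0 / dispersion
    mean = np.maximum(mean, 1e-12)
    return rng.negative_binomial(r, r / (r + mean))


def simulate_experiment(cfg: SimConfig) -> SimData:
    """Draw one complete experiment (counts, F1 allele counts, truth)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    gene_ids = [f"gene{i:05d}" for i in range(n)]

    baseline = np.exp(rng.normal(cfg.baseline_meanlog, cfg.baseline_sdlog, n))
    tissue_offset = {
        t: (rng.normal(0.0, cfg.tissue_baseline_sd, n) if i else np.zeros(n))
        for i, t in enumerate(cfg.tissues)
    }

    probs = [cfg.frac_cis, cfg.frac_trans, cfg.frac_cis_plus_trans, cfg.frac_cis_times_trans]
    probs.append(1.0 - sum(probs))
    category = rng.choice(
        ["cis", "trans", "cis_plus_trans", "cis_times_trans", "conserved"],
        size=n, p=probs,
    )

    def effect(size: int) -> np.ndarray:
        mag = cfg.effect_min + rng.exponential(cfg.effect_scale, size)
        return mag * rng.choice([-1.0, 1.0], size)

    cis = np.where(np.isin(category, ["cis", "cis_plus_trans", "cis_times_trans"]), effect(n), 0.0)
    trans = np.where(np.isin(category, ["trans", "cis_plus_trans", "cis_times_trans"]), effect(n), 0.0)
    # cis x trans: force opposed signs so the intended category is realized
    flip = (category == "cis_times_trans") & (np.sign(cis) == np.sign(trans))
    trans[flip] *= -1.0
    # cis + trans: force same sign (attenuated allelic vs parental ratio)
    align = (category == "cis_plus_trans") & (np.sign(cis) != np.sign(trans))
    trans[align] *= -1.0

    has_effect = category != "conserved"
    stress_only = has_effect & (rng.random(n) < cfg.frac_stress_only)

    responsive = rng.random(n) < cfg.frac_responsive
    response = np.where(responsive, rng.normal(0.0, cfg.response_sd, n), 0.0)
    tissue_mod = responsive & (rng.random(n) < cfg.prob_tissue_modifier)
    tissue_mod_delta = np.where(tissue_mod, rng.normal(0.0, cfg.tissue_modifier_sd, n), 0.0)
    geno_mod = responsive & (rng.random(n) < cfg.prob_genotype_modifier)
    # parent-specific response difference: a stress-only trans effect
    geno_trans_delta = np.where(geno_mod, rng.normal(0.0, cfg.genotype_modifier_sd, n), 0.0)

    n_snps = 1 + rng.poisson(cfg.snps_per_gene_rate, n)

    snps = SnpTable()
    gene_spans = []
    snp_positions: list[np.ndarray] = []
    for i, gene in enumerate(gene_ids):
        start0 = i * _GENE_STRIDE
        gene_spans.append(("chr1", start0, start0 + _GENE_SPAN, gene))
        pos = start0 + 100 + 10 * np.arange(n_snps[i])  # 0-based -> store 1-based
        pos = pos + 1
        snp_positions.append(pos)
        for p in pos:
            snps.add("chr1", int(p), "A", "G")

    def cis_active(cond: str) -> np.ndarray:
        return np.where(stress_only & (cond != "TM"), 0.0, cis)

    def trans_active(cond: str) -> np.ndarray:
        t_eff = np.where(stress_only & (cond != "TM"), 0.0, trans)
        if cond == "TM":
            t_eff = t_eff + geno_trans_delta
        return t_eff

    count_cols: dict[str, np.ndarray] = {}
    sheet_rows = []
    records: list[SnpAlleleRecord] = []
    for tissue in cfg.tissues:
        for cond in ("control", "TM"):
            c_eff = cis_active(cond)
            t_eff = trans_active(cond)
            resp = np.zeros(n)
            if cond == "TM":
                resp = response + (tissue_mod_delta if tissue == cfg.tissues[-1] else 0.0)
            base = baseline * 2.0 ** (tissue_offset[tissue] + resp)
            # divergence is split symmetrically between the strains so that
            # neither library is systematically heavier: the parental ratio
            # is still 2^(c+t) and the F1 B6-allele fraction 2^c/(1+2^c)
            mean_b6 = base * 2.0 ** (+(c_eff + t_eff) / 2.0)
            mean_cast = base * 2.0 ** (-(c_eff + t_eff) / 2.0)
            mean_f1 = 0.5 * (mean_cast + mean_b6)
            p_b6 = 2.0 ** c_eff / (1.0 + 2.0 ** c_eff)
            for geno, mean in (("B6", mean_b6), ("CAST", mean_cast), ("F1", mean_f1)):
                for rep in range(1, cfg.replicates + 1):
                    sid = f"{geno}_{tissue}_{cond}_{rep}"
                    sf = np.exp(rng.normal(0.0, cfg.size_factor_sdlog))
                    y = _nb(rng, mean * sf, cfg.dispersion)
                    count_cols[sid] = y
                    sheet_rows.append(
                        {"sample_id": sid, "genotype": geno, "tissue": tissue,
                         "condition": cond, "replicate": rep}
                    )
                    if geno != "F1":
                        continue
                    allelic_total = rng.binomial(y, cfg.ase_capture)
                    b6_allele = rng.binomial(allelic_total, p_b6)
                    cast_allele = allelic_total - b6_allele
                    for i, gene in enumerate(gene_ids):
                        k = n_snps[i]
                        b6_split = rng.multinomial(b6_allele[i], np.full(k, 1.0 / k))
                        cast_split = rng.multinomial(cast_allele[i], np.full(k, 1.0 / k))
                        for j, pos in enumerate(snp_positions[i]):
                            records.append(
                                SnpAlleleRecord(
                                    contig="chr1", position=int(pos),
                                    ref_allele="A", alt_allele="G",
                                    ref_count=int(b6_split[j]), alt_count=int(cast_split[j]),
                                    sample_id=sid, gene_id=gene,
                                )
                            )

    counts = pd.DataFrame(count_cols, index=gene_ids)
    samples = pd.DataFrame(sheet_rows).set_index("sample_id")
    cm = CountMatrix(counts, samples)

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "category": category,
            "cis_log2": cis,
            "trans_log2": trans,
            "stress_only": stress_only,
            "responsive": responsive,
            "response_log2": response,
            "tissue_mod_delta": tissue_mod_delta,
            "geno_trans_delta_tm": geno_trans_delta,
            "n_snps": n_snps,
            "expected_category_control": [
                _expected_category(c, t)
                for c, t in zip(cis_active("control"), trans_active("control"))
            ],
            "expected_category_tm": [
                _expected_category(c, t)
                for c, t in zip(cis_active("TM"), trans_active("TM"))
            ],
        }
    ).set_index("gene_id")
    return SimData(counts=cm, records=records, snps=snps, truth=truth, gene_spans=gene_spans)


def recovery_benchmark_config(seed: int = 0) -> SimConfig:
    """Frozen configuration for the cis/trans recovery benchmark.

    The pooled-count exact tests assume counting noise dominates, so the
    benchmark is drawn in that regime: near-Poisson dispersion (1e-4)
    and baselines deep enough that every retained gene has >= 500 pooled
    allelic reads per condition; planted |log2 effects| are >= 1
    (``effect_min``).  One tissue suffices: the benchmark scores the
    classifier and the stress-only flag, which compare conditions within
    a tissue.  With realistic biological dispersion (the 0.1 default)
    the pooled exact tests are anticonservative — see docs/methods.md.
    """
    return SimConfig(
        n_genes=2000,
        replicates=3,
        tissues=("liver",),
        dispersion=1e-4,
        baseline_meanlog=6.5,
        baseline_sdlog=0.3,
        seed=seed,
    )


def null_calibration_config(seed: int = 0, n_genes: int = 2000) -> SimConfig:
    """Frozen null configuration for type-I-error checks of the NB tests.

    No regulatory effects, no ER-stress response; NB dispersion 0.1 with
    3 replicates per cell — the regime in which the differential tests
    must hold their nominal size.
    """
    return SimConfig(
        n_genes=n_genes,
        replicates=3,
        tissues=("liver",),
        dispersion=0.1,
        frac_cis=0.0,
        frac_trans=0.0,
        frac_cis_plus_trans=0.0,
        frac_cis_times_trans=0.0,
        frac_responsive=0.0,
        seed=seed,
    )


def classify_simulated(sim: SimData, tissue: str | None = None, fdr: float = 0.001,
                       specificity_alpha: float = 0.05):
    """Run ASE aggregation + cis/trans classification on simulated data.

    Returns (calls_control, calls_tm) for one tissue with
    condition-specificity flags attached.
    """
    from .ase import aggregate_allele_counts
    from .cistrans import (
        attach_condition_specificity,
        pooled_parental_counts,
        regulatory_analysis,
    )

    tissue = tissue or sim.counts.samples["tissue"].iloc[0]
    gene_counts, _ = aggregate_allele_counts(sim.records, sim.snps, sim.counts.samples)
    parental = pooled_parental_counts(sim.counts, tissue)
    per = {}
    for cond in ("control", "TM"):
        per[cond] = regulatory_analysis(parental, gene_counts, tissue, cond, fdr=fdr)
    attach_condition_specificity(
        per["control"][0], per["TM"][0], per["control"][1], per["TM"][1],
        alpha=specificity_alpha,
    )
    return per["control"][0], per["TM"][0]


# ---------------------------------------------------------------------------
# evaluation against truth


def _check_ids(call_genes: set[str], truth: pd.DataFrame) -> None:
    stray = sorted(call_genes - set(truth.index))
    if stray:
        raise ValueError(f"calls reference gene(s) absent from truth: {stray[:10]}")


def confusion_matrix(calls, truth: pd.DataFrame, condition: str) -> pd.DataFrame:
    """Expected-vs-called category cross-tabulation for one condition.

    Rows are the planted (expected) categories for that condition;
    columns the pipeline's calls.  Genes not called (filtered upstream)
    appear in an ``uncalled`` column.
    """
    from .cistrans import CATEGORIES

    by_gene = {c.gene_id: c.category for c in calls}
    _check_ids(set(by_gene), truth)
    col = "expected_category_tm" if condition == "TM" else "expected_category_control"
    cats = list(CATEGORIES) + ["uncalled"]
    mat = pd.DataFrame(0, index=list(CATEGORIES), columns=cats)
    for gene, expected in truth[col].items():
        called = by_gene.get(gene, "uncalled")
        mat.loc[expected, called] += 1
    return mat


def category_metrics(confusion: pd.DataFrame) -> pd.DataFrame:
    """Per-category sensitivity and empirical FDR from a confusion matrix."""
    rows = []
    for cat in confusion.index:
        truth_n = confusion.loc[cat].sum()
        called_n = confusion[cat].sum()
        tp = confusion.loc[cat, cat]
        rows.append(
            {
                "category": cat,
                "n_truth": int(truth_n),
                "n_called": int(called_n),
                "sensitivity": tp / truth_n if truth_n else np.nan,
                "fdr": (called_n - tp) / called_n if called_n else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("category")


def focal_accuracy(confusion: pd.DataFrame, classes=("cis", "trans", "conserved")) -> float:
    """Classification accuracy over genes planted as one of ``classes``.

    Genes the pipeline never classified (``uncalled`` — e.g. dropped by
    the informative-SNP filter) are excluded: this scores the
    classifier, not the coverage of the filters.
    """
    sub = confusion.loc[list(classes)]
    correct = sum(sub.loc[c, c] for c in classes)
    total = sub.to_numpy().sum() - sub["uncalled"].sum()
    return correct / total if total else np.nan


def conserved_false_call_rate(confusion: pd.DataFrame) -> float:
    """Fraction of planted-conserved genes called as any regulatory category."""
    row = confusion.loc["conserved"]
    total = row.sum()
    false = total - row["conserved"] - row.get("uncalled", 0)
    denom = total - row.get("uncalled", 0)
    return false / denom if denom else np.nan


def stress_only_sensitivity(calls_tm, truth: pd.DataFrame, category: str = "cis") -> float:
    """Among planted stress-only genes of one category, the fraction the
    pipeline both called correctly under TM and flagged stress_only."""
    by_gene = {c.gene_id: c for c in calls_tm}
    _check_ids(set(by_gene), truth)
    planted = truth.index[(truth["category"] == category) & truth["stress_only"]]
    if len(planted) == 0:
        return np.nan
    hits = sum(
        1
        for g in planted
        if g in by_gene
        and by_gene[g].category == category
        and by_gene[g].condition_specific == "stress_only"
    )
    return hits / len(planted)


@dataclass
class TruthEvaluation:
    confusion_control: pd.DataFrame
    confusion_tm: pd.DataFrame
    metrics_control: pd.DataFrame
    metrics_tm: pd.DataFrame
    focal_accuracy_tm: float
    conserved_false_rate_tm: float
    stress_only_sens: float


def evaluate_against_truth(calls_control, calls_tm, truth: pd.DataFrame) -> TruthEvaluation:
    """Score a full set of regulatory calls against the planted architecture."""
    conf_c = confusion_matrix(calls_control, truth, "control")
    conf_t = confusion_matrix(calls_tm, truth, "TM")
    return TruthEvaluation(
        confusion_control=conf_c,
        confusion_tm=conf_t,
        metrics_control=category_metrics(conf_c),
        metrics_tm=category_metrics(conf_t),
        focal_accuracy_tm=focal_accuracy(conf_t),
        conserved_false_rate_tm=conserved_false_call_rate(conf_t),
        stress_only_sens=stress_only_sensitivity(calls_tm, truth),
    )
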