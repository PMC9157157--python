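"""Normalization, expression filtering, and the total-expression tests.

Three questions are asked of total (non-allelic) expression:

1. Does a gene respond to ER stress?  Per genotype x tissue, a
   negative-binomial (NB) GLM with a condition term; a gene is
   "responsive" when it clears a 1.5-fold change at 5% FDR.
2. Does the response differ between tissues?  Per genotype, NB model
   ``~ tissue + condition + tissue:condition``; the interaction
   coefficient isolates differential response from baseline tissue
   differences.
3. Does the response differ between genetic backgrounds?  Per tissue, a
   likelihood-ratio test of ``~ genotype + condition +
   genotype:condition`` against the no-interaction reduction (2 df with
   three genotypes).

Counts are normalized with median-of-ratios size factors.  Dispersion is
a per-gene method-of-moments estimate on normalized counts with no
sharing across genes; with 2-3 replicates per cell that plug-in estimate
is noisy, so Wald statistics are referred to a t distribution on the
residual degrees of freedom and the LRT to an F distribution scaled by
the full model's Pearson dispersion.  Both choices were checked by null
simulation (see docs/methods.md); the naive normal / chi-square
references are anticonservative at these sample sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .types import CountMatrix, GENOTYPES

logger = logging.getLogger(__name__)

LN2 = np.log(2.0)
#: Lower floor for the method-of-moments dispersion estimate.
MIN_DISPERSION = 1e-8


@dataclass
class DEResult:
    """Per-gene ER-stress response: TM vs control within one genotype x tissue."""

    gene_id: str
    base_mean: float
    log2fc: float
    p: float
    q: float = np.nan
    responsive: str = "none"


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min_{j >= i} p_(j) * m / j, clipped at 1.  NaNs pass through
    and do not count toward m.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if ((pv < 0) | (pv > 1)).any():
        bad = pv[(pv < 0) | (pv > 1)][0]
        raise ValueError(f"p-value {bad} outside [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    qv = np.empty(m)
    qv[order] = q
    out[ok] = qv
    return out


def estimate_size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For each gene with non-zero counts in every sample, take the ratio of
    each sample's count to the gene's geometric mean; the per-sample
    median of those ratios is the size factor.
    """
    table = counts.counts if isinstance(counts, CountMatrix) else counts
    arr = table.to_numpy(dtype=float)
    eligible = (arr > 0).all(axis=1)
    if not eligible.any():
        raise ValueError("cannot normalize: no gene has non-zero counts in every sample")
    logs = np.log(arr[eligible])
    log_geomean = logs.mean(axis=1)
    ratios = np.exp(logs - log_geomean[:, None])
    s = np.median(ratios, axis=0)
    return pd.Series(s, index=table.columns, name="size_factor")


def normalize_and_filter(
    counts: CountMatrix | pd.DataFrame,
    size_factors: pd.Series,
    base_mean_min: float = 5.0,
) -> tuple[pd.DataFrame, pd.Index]:
    """Divide counts by size factors; keep genes with base mean >= threshold.

    The base mean is the mean normalized count over the samples in the
    analysis group; the >= 5 boundary is inclusive.
    """
    table = counts.counts if isinstance(counts, CountMatrix) else counts
    missing = [s for s in table.columns if s not in size_factors.index]
    if missing:
        raise ValueError(f"size factors missing for sample(s) {missing}")
    norm = table / size_factors[table.columns]
    expressed = norm.index[norm.mean(axis=1) >= base_mean_min]
    return norm, expressed


def _mom_dispersion(y_norm: np.ndarray, groups: np.ndarray) -> float:
    """Method-of-moments NB dispersion pooled over design cells.

    Under NB, Var = mu + alpha mu^2 within a cell; alpha is estimated by
    pooling (var - mean) against mean^2 across cells, weighted by the
    within-cell degrees of freedom, then floored.
    """
    num = den = 0.0
    for g in np.unique(groups):
        yy = y_norm[groups == g]
        if len(yy) < 2:
            continue
        m = yy.mean()
        v = yy.var(ddof=1)
        w = len(yy) - 1
        num += (v - m) * w
        den += m * m * w
    alpha = num / den if den > 0 else 0.0
    return max(alpha, MIN_DISPERSION)


def _fit_nb_wald(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    cells: np.ndarray,
    size_factors: np.ndarray,
    coef_index: int,
) -> tuple[float, float]:
    """Fit an NB GLM and return (coef, two-sided p) for one coefficient.

    The Wald statistic is referred to t(n - p); returns (nan, nan) when
    the fit fails to converge.
    """
    alpha = _mom_dispersion(y / size_factors, cells)
    try:
        fit = sm.GLM(
            y, X, family=sm.families.NegativeBinomial(alpha=alpha), offset=offset
        ).fit()
    except Exception:
        return np.nan, np.nan
    if not np.all(np.isfinite(fit.params)) or not np.all(np.isfinite(fit.bse)):
        return np.nan, np.nan
    coef = fit.params[coef_index]
    se = fit.bse[coef_index]
    if se == 0:
        return coef, np.nan
    df = len(y) - X.shape[1]
    pval = 2.0 * stats.t.sf(abs(coef / se), df) if df > 0 else np.nan
    return coef, pval


def nb_fold_change_test(
    control: np.ndarray,
    tm: np.ndarray,
    s_control: np.ndarray,
    s_tm: np.ndarray,
    gene_id: str = "",
) -> DEResult:
    """ER-stress response test for one gene: NB GLM of TM vs control.

    ``control`` / ``tm`` are raw replicate counts; size factors enter as
    a log offset so the condition coefficient is the log fold change
    (converted to base 2).  When one condition is entirely zero the
    reported log2fc falls back to a +0.5 pseudocount on normalized
    means; the p-value is from the GLM (missing when the fit fails).
    """
    control = np.asarray(control, float)
    tm = np.asarray(tm, float)
    if len(control) < 2 or len(tm) < 2:
        raise ValueError(f"gene {gene_id!r}: need >=2 replicates per condition")
    y = np.concatenate([control, tm])
    s = np.concatenate([np.asarray(s_control, float), np.asarray(s_tm, float)])
    cond = np.concatenate([np.zeros(len(control)), np.ones(len(tm))])
    X = np.column_stack([np.ones_like(cond), cond])
    norm = y / s
    base_mean = norm.mean()
    m_ctrl = norm[cond == 0].mean()
    m_tm = norm[cond == 1].mean()
    coef, pval = _fit_nb_wald(y, X, np.log(s), cond, s, 1)
    if m_ctrl == 0 or m_tm == 0 or not np.isfinite(coef):
        log2fc = np.log2((m_tm + 0.5) / (m_ctrl + 0.5))
    else:
        log2fc = coef / LN2
    if np.isnan(pval):
        logger.warning("gene %s: NB fit did not converge; p set to missing", gene_id)
    return DEResult(gene_id=gene_id, base_mean=base_mean, log2fc=log2fc, p=pval)


def classify_responsive(log2fc: float, q: float, fdr: float = 0.05, fold: float = 1.5) -> str:
    if np.isnan(q) or q >= fdr:
        return "none"
    if log2fc >= np.log2(fold):
        return "up"
    if log2fc <= -np.log2(fold):
        return "down"
    return "none"


def de_analysis(
    cm: CountMatrix,
    genotype: str,
    tissue: str,
    fdr: float = 0.05,
    fold: float = 1.5,
    base_mean_min: float = 5.0,
) -> pd.DataFrame:
    """ER-stress response (TM vs control) for every expressed gene.

    Size factors are computed within the genotype x tissue analysis
    group; BH adjustment spans the expressed gene set.
    """
    sub = cm.subset(genotype=genotype, tissue=tissue)
    for cond in ("control", "TM"):
        if (sub.samples["condition"] == cond).sum() < 2:
            raise ValueError(
                f"({genotype}, {tissue}, {cond}): fewer than 2 replicates"
            )
    s = estimate_size_factors(sub)
    _, expressed = normalize_and_filter(sub, s, base_mean_min)
    is_tm = (sub.samples["condition"] == "TM").to_numpy()
    ctrl_ids = list(sub.samples.index[~is_tm])
    tm_ids = list(sub.samples.index[is_tm])
    rows = []
    for gene in expressed:
        res = nb_fold_change_test(
            sub.counts.loc[gene, ctrl_ids].to_numpy(),
            sub.counts.loc[gene, tm_ids].to_numpy(),
            s[ctrl_ids].to_numpy(),
            s[tm_ids].to_numpy(),
            gene_id=gene,
        )
        rows.append((gene, res.base_mean, res.log2fc, res.p))
    out = pd.DataFrame(rows, columns=["gene_id", "base_mean", "log2fc", "p"])
    out["q"] = bh_adjust(out["p"])
    out["responsive"] = [
        classify_responsive(lfc, q, fdr, fold) for lfc, q in zip(out["log2fc"], out["q"])
    ]
    return out.set_index("gene_id")


def interaction_test(
    cm: CountMatrix,
    genotype: str,
    fdr: float = 0.05,
    base_mean_min: float = 5.0,
) -> pd.DataFrame:
    """Tissue-dependent ER-stress response within one genotype.

    Model ``~ tissue + condition + tissue:condition``; the Wald test on
    the interaction term asks whether the TM/control fold change differs
    between liver and kidney, controlling for baseline tissue
    differences.  ``delta_log2fc`` is liver log2fc minus kidney log2fc.
    """
    sub = cm.subset(genotype=genotype)
    for t in ("liver", "kidney"):
        for c in ("control", "TM"):
            if ((sub.samples["tissue"] == t) & (sub.samples["condition"] == c)).sum() < 2:
                raise ValueError(f"missing or under-replicated design cell ({t}, {c})")
    s = estimate_size_factors(sub)
    _, expressed = normalize_and_filter(sub, s, base_mean_min)
    is_liver = (sub.samples["tissue"] == "liver").to_numpy(float)
    is_tm = (sub.samples["condition"] == "TM").to_numpy(float)
    X = np.column_stack([np.ones_like(is_tm), is_liver, is_tm, is_liver * is_tm])
    cells = (is_liver * 2 + is_tm).astype(int)
    sf = s.to_numpy()
    offset = np.log(sf)
    rows = []
    for gene in expressed:
        y = sub.counts.loc[gene].to_numpy(float)
        coef, pval = _fit_nb_wald(y, X, offset, cells, sf, 3)
        rows.append((gene, coef / LN2 if np.isfinite(coef) else np.nan, pval))
    out = pd.DataFrame(rows, columns=["gene_id", "delta_log2fc", "p"])
    out["q"] = bh_adjust(out["p"])
    out["tissue_dependent"] = out["q"] < fdr
    return out.set_index("gene_id")


def genotype_lrt_test(
    cm: CountMatrix,
    tissue: str,
    fdr: float = 0.05,
    base_mean_min: float = 5.0,
) -> pd.DataFrame:
    """Genotype-dependent ER-stress response within one tissue.

    Likelihood-ratio test of ``~ genotype + condition +
    genotype:condition`` against the reduction without the interaction
    (2 df across B6 / CAST / F1).  The deviance difference is referred
    to F(2, n - p) after scaling by the full model's Pearson dispersion,
    which keeps the null calibrated at 2-3 replicates per cell.
    Per-genotype log2 fold changes are reported from pseudocounted
    normalized means.
    """
    sub = cm.subset(tissue=tissue)
    for g in GENOTYPES:
        for c in ("control", "TM"):
            if ((sub.samples["genotype"] == g) & (sub.samples["condition"] == c)).sum() < 2:
                raise ValueError(f"missing or under-replicated design cell ({g}, {c})")
    s = estimate_size_factors(sub)
    norm, expressed = normalize_and_filter(sub, s, base_mean_min)
    geno = sub.samples["genotype"].to_numpy()
    is_tm = (sub.samples["condition"] == "TM").to_numpy(float)
    g_dummies = np.column_stack([(geno == g).astype(float) for g in GENOTYPES[1:]])
    X_red = np.column_stack([np.ones_like(is_tm), g_dummies, is_tm])
    X_full = np.column_stack([X_red, g_dummies * is_tm[:, None]])
    geno_codes = np.searchsorted(np.array(GENOTYPES), geno)
    cells = geno_codes * 2 + is_tm.astype(int)
    sf = s.to_numpy()
    offset = np.log(sf)
    n, p_full = X_full.shape
    rows = []
    for gene in expressed:
        y = sub.counts.loc[gene].to_numpy(float)
        alpha = _mom_dispersion(y / sf, cells)
        fam = sm.families.NegativeBinomial(alpha=alpha)
        try:
            fit_full = sm.GLM(y, X_full, family=fam, offset=offset).fit()
            fit_red = sm.GLM(y, X_red, family=fam, offset=offset).fit()
            dev = fit_red.deviance - fit_full.deviance
            scale = max(fit_full.pearson_chi2 / (n - p_full), 1.0)
            pval = stats.f.sf((dev / 2.0) / scale, 2, n - p_full)
        except Exception:
            pval = np.nan
            logger.warning("gene %s: LRT fit did not converge; p set to missing", gene)
        fcs = []
        gnorm = norm.loc[gene]
        for g in GENOTYPES:
            m_ctrl = gnorm[(geno == g) & (is_tm == 0)].mean()
            m_tm = gnorm[(geno == g) & (is_tm == 1)].mean()
            fcs.append(np.log2((m_tm + 0.5) / (m_ctrl + 0.5)))
        rows.append((gene, pval, *fcs))
    out = pd.DataFrame(
        rows, columns=["gene_id", "p", "log2fc_B6", "log2fc_CAST", "log2fc_F1"]
    )
    out["q"] = bh_adjust(out["p"])
    out["genotype_dependent"] = out["q"] < fdr
    return out.set_index("gene_id")


def interaction_and_lrt_tests(
    cm: CountMatrix,
    fdr: float = 0.05,
    base_mean_min: float = 5.0,
) -> tuple[dict[str, pd.DataFrame], dict[str, pd.DataFrame]]:
    """Run the tissue-interaction test per genotype and the LRT per tissue."""
    interactions = {
        g: interaction_test(cm, g, fdr=fdr, base_mean_min=base_mean_min) for g in GENOTYPES
    }
    lrts = {
        t: genotype_lrt_test(cm, t, fdr=fdr, base_mean_min=base_mean_min)
        for t in sorted(cm.samples["tissue"].unique())
    }
    return interactions, lrts
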