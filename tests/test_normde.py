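"""Normalization, BH adjustment, and the negative-binomial tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from stressase import normde
from stressase.normde import (
    bh_adjust,
    classify_responsive,
    de_analysis,
    estimate_size_factors,
    genotype_lrt_test,
    interaction_test,
    nb_fold_change_test,
    normalize_and_filter,
)

from conftest import bh_oracle, make_cm, make_samples


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        table = pd.DataFrame({"s1": [5, 10, 3], "s2": [5, 10, 3]}, index=list("abc"))
        assert np.allclose(estimate_size_factors(table), [1.0, 1.0])

    def test_hand_computed_median_of_ratios(self):
        # geomeans 4 and 8; ratios (0.5, 0.5) and (2, 2)
        table = pd.DataFrame({"s1": [2, 4], "s2": [8, 16]}, index=["g1", "g2"])
        assert np.allclose(estimate_size_factors(table), [0.5, 2.0])

    def test_single_sample_is_unity(self):
        table = pd.DataFrame({"s1": [4, 9]}, index=["g1", "g2"])
        assert np.allclose(estimate_size_factors(table), [1.0])

    def test_zero_count_genes_excluded_from_median(self):
        table = pd.DataFrame({"s1": [2, 0], "s2": [8, 100]}, index=["g1", "g2"])
        # only g1 eligible: geomean 4, ratios 0.5 and 2
        assert np.allclose(estimate_size_factors(table), [0.5, 2.0])

    def test_invariant_under_global_rescaling(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(rng.poisson(50, (30, 4)) + 1, columns=list("abcd"))
        s1 = estimate_size_factors(table)
        s2 = estimate_size_factors(table * 3)
        assert np.allclose(s1, s2)

    def test_all_zero_matrix_refuses(self):
        table = pd.DataFrame({"s1": [0, 0], "s2": [0, 3]})
        with pytest.raises(ValueError, match="cannot normalize"):
            estimate_size_factors(table)


class TestNormalizeFilter:
    def test_base_mean_boundary_is_inclusive(self):
        table = pd.DataFrame({"s1": [5, 4, 0], "s2": [5, 4, 0]}, index=["a", "b", "c"])
        s = pd.Series([1.0, 1.0], index=["s1", "s2"])
        _, expressed = normalize_and_filter(table, s, base_mean_min=5)
        assert list(expressed) == ["a"]

    def test_normalization_cancels_size_factor(self):
        table = pd.DataFrame({"s1": [10], "s2": [20]}, index=["a"])
        s = pd.Series([1.0, 2.0], index=["s1", "s2"])
        norm, _ = normalize_and_filter(table, s, base_mean_min=0)
        assert norm.loc["a", "s1"] == norm.loc["a", "s2"] == 10


class TestBHAdjust:
    def test_single_pvalue_unchanged(self):
        assert bh_adjust([0.04]) == pytest.approx([0.04])

    def test_hand_computed_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_nan_passes_through_and_excluded_from_m(self):
        q = bh_adjust([0.01, np.nan, 0.02])
        assert np.isnan(q[1])
        assert np.allclose([q[0], q[2]], [0.02, 0.02])

    def test_out_of_range_is_an_error(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=60))
    def test_matches_brute_force_and_dominates_p(self, pvals):
        p = np.array(pvals)
        q = bh_adjust(p)
        assert np.allclose(q, bh_oracle(p))
        assert (q >= p - 1e-12).all()

    def test_matches_statsmodels_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        for _ in range(20):
            p = rng.random(rng.integers(1, 200))
            q = bh_adjust(p)
            q_sm = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(q, q_sm)


class TestFoldChangeTest:
    def test_identical_counts_give_zero_fold_change(self):
        res = nb_fold_change_test([10, 10, 10], [10, 10, 10], np.ones(3), np.ones(3), "g")
        assert res.log2fc == pytest.approx(0.0, abs=1e-6)
        assert classify_responsive(res.log2fc, 0.5) == "none"

    def test_responsive_classification_rule(self):
        # 1.6-fold at q = 0.01 is responsive; 1.3-fold is not
        assert classify_responsive(np.log2(1.6), 0.01) == "up"
        assert classify_responsive(np.log2(1.3), 0.01) == "none"
        assert classify_responsive(-np.log2(1.6), 0.01) == "down"
        assert classify_responsive(np.log2(1.6), 0.2) == "none"

    def test_boundary_fold_is_inclusive(self):
        assert classify_responsive(np.log2(1.5), 0.01) == "up"

    def test_requires_two_replicates(self):
        with pytest.raises(ValueError, match="replicates"):
            nb_fold_change_test([10], [10, 10], [1.0], np.ones(2), "g")

    def test_zero_condition_uses_pseudocount_fold_change(self):
        res = nb_fold_change_test([0, 0, 0], [10, 12, 8], np.ones(3), np.ones(3), "g")
        assert np.isfinite(res.log2fc)
        assert res.log2fc == pytest.approx(np.log2(10.5 / 0.5), abs=0.2)

    def test_power_monotone_in_effect_size(self):
        # planted 1.5x vs 4x fold change at matched depth: stronger effect,
        # smaller p on average
        rng = np.random.default_rng(7)
        n, reps, disp = 150, 3, 0.05
        pvals = {}
        for fold in (1.5, 4.0):
            ps = []
            for _ in range(n):
                mu = 200.0
                r = 1 / disp
                ctrl = rng.negative_binomial(r, r / (r + mu), reps)
                tm = rng.negative_binomial(r, r / (r + mu * fold), reps)
                ps.append(nb_fold_change_test(ctrl, tm, np.ones(reps), np.ones(reps), "g").p)
            pvals[fold] = np.nanmean(np.array(ps) < 0.05)
        assert pvals[4.0] > pvals[1.5] > 0.3


def _two_tissue_cm(rng, gene_means, n_background=80):
    """gene_means: list of dicts {(tissue, cond): mean} for one genotype.

    Background genes at a flat mean are appended so size-factor
    estimation has a stable reference set.
    """
    spec = [
        ("B6", t, c, r) for t in ("liver", "kidney") for c in ("control", "TM") for r in (1, 2, 3)
    ]
    samples = make_samples(spec)
    disp = 0.05
    r = 1 / disp
    means = [lambda row, gm=gm: gm[(row["tissue"], row["condition"])] for gm in gene_means]
    means += [lambda row: 300.0] * n_background
    cols = {}
    for sid, row in samples.iterrows():
        mus = np.array([m(row) for m in means])
        cols[sid] = rng.negative_binomial(r, r / (r + mus))
    return make_cm(cols, samples)


class TestInteraction:
    def test_planted_interaction_detected_baseline_difference_ignored(self):
        rng = np.random.default_rng(11)
        genes = [
            # 2-fold up in kidney, 2-fold down in liver: true interaction
            {("kidney", "control"): 300, ("kidney", "TM"): 600,
             ("liver", "control"): 300, ("liver", "TM"): 150},
            # 10x baseline difference between tissues, same 2x response: no interaction
            {("kidney", "control"): 100, ("kidney", "TM"): 200,
             ("liver", "control"): 1000, ("liver", "TM"): 2000},
        ]
        cm = _two_tissue_cm(rng, genes)
        res = interaction_test(cm, "B6", base_mean_min=0)
        assert res.loc["g0", "p"] < 0.01
        assert res.loc["g1", "p"] > 0.05

    def test_missing_design_cell_is_named(self):
        samples = make_samples(
            [("B6", "liver", "control", r) for r in (1, 2)]
            + [("B6", "liver", "TM", r) for r in (1, 2)]
        )
        cm = make_cm({s: [5] for s in samples.index}, samples)
        with pytest.raises(ValueError, match=r"kidney.*control"):
            interaction_test(cm, "B6")


class TestGenotypeLrt:
    def test_planted_genotype_specific_response_detected(self):
        rng = np.random.default_rng(13)
        spec = [
            (g, "liver", c, r)
            for g in ("B6", "CAST", "F1")
            for c in ("control", "TM")
            for r in (1, 2, 3)
        ]
        samples = make_samples(spec)
        disp, rr = 0.05, 1 / 0.05
        # g0: CAST responds 4x, B6/F1 flat; g1: all genotypes respond 2x
        means = {
            "g0": {("B6", "control"): 200, ("B6", "TM"): 200,
                   ("CAST", "control"): 200, ("CAST", "TM"): 800,
                   ("F1", "control"): 200, ("F1", "TM"): 200},
            "g1": {("B6", "control"): 200, ("B6", "TM"): 400,
                   ("CAST", "control"): 200, ("CAST", "TM"): 400,
                   ("F1", "control"): 200, ("F1", "TM"): 400},
        }
        genes = ["g0", "g1"] + [f"bg{i}" for i in range(80)]
        cols = {}
        for sid, row in samples.iterrows():
            mus = np.array(
                [means[g][(row["genotype"], row["condition"])] for g in ("g0", "g1")]
                + [300.0] * 80
            )
            cols[sid] = rng.negative_binomial(rr, rr / (rr + mus))
        cm = make_cm(cols, samples, genes=genes)
        res = genotype_lrt_test(cm, "liver", base_mean_min=0)
        assert res.loc["g0", "p"] < 0.01
        assert res.loc["g1", "p"] > 0.05
        # reported per-genotype fold changes track the planted responses
        assert res.loc["g0", "log2fc_CAST"] == pytest.approx(2.0, abs=0.6)
        assert abs(res.loc["g0", "log2fc_B6"]) < 0.6

    def test_missing_genotype_is_named(self):
        samples = make_samples(
            [("B6", "liver", c, r) for c in ("control", "TM") for r in (1, 2)]
        )
        cm = make_cm({s: [5] for s in samples.index}, samples)
        with pytest.raises(ValueError, match="CAST"):
            genotype_lrt_test(cm, "liver")


class TestDeAnalysis:
    def test_under_replicated_group_refuses(self):
        samples = make_samples(
            [("B6", "liver", "control", 1), ("B6", "liver", "TM", 1), ("B6", "liver", "TM", 2)]
        )
        cm = make_cm({s: [5, 6] for s in samples.index}, samples)
        with pytest.raises(ValueError, match="fewer than 2 replicates"):
            de_analysis(cm, "B6", "liver")

    def test_detects_planted_response_and_respects_fold_cutoff(self):
        rng = np.random.default_rng(5)
        spec = [("B6", "liver", c, r) for c in ("control", "TM") for r in (1, 2, 3)]
        samples = make_samples(spec)
        disp, rr = 0.02, 1 / 0.02
        # g0: 4x up; g1: 1.2x up (below 1.5-fold cutoff); g2: flat
        means = {"g0": (200, 800), "g1": (200, 240), "g2": (200, 200)}
        cols = {}
        for sid, row in samples.iterrows():
            i = 0 if row["condition"] == "control" else 1
            mus = np.array([means[g][i] for g in ("g0", "g1", "g2")])
            cols[sid] = rng.negative_binomial(rr, rr / (rr + mus))
        cm = make_cm(cols, samples, genes=["g0", "g1", "g2"])
        res = de_analysis(cm, "B6", "liver")
        assert res.loc["g0", "responsive"] == "up"
        assert res.loc["g1", "responsive"] == "none"
        assert res.loc["g2", "responsive"] == "none"
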