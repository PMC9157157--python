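"""Allele-count aggregation, the ASE-change test, and total-change classing."""

import numpy as np
import pandas as pd
import pytest

from stressase.ase import (
    AseChangeResult,
    GeneAlleleCounts,
    aggregate_allele_counts,
    ase_analysis,
    ase_change_test,
    classify_total_change,
)
from stressase.types import SnpAlleleRecord, SnpTable

from conftest import fisher_two_sided_oracle, make_samples


@pytest.fixture
def f1_meta():
    return make_samples(
        [("F1", "liver", "control", r) for r in (1, 2, 3)]
        + [("F1", "liver", "TM", r) for r in (1, 2, 3)]
    )


def _snps(positions):
    t = SnpTable()
    for p in positions:
        t.add("chr1", p, "A", "G")
    return t


def _rec(pos, ref_n, alt_n, sample, gene="geneA", ref="A", alt="G"):
    return SnpAlleleRecord(
        contig="chr1", position=pos, ref_allele=ref, alt_allele=alt,
        ref_count=ref_n, alt_count=alt_n, sample_id=sample, gene_id=gene,
    )


class TestAggregation:
    def test_hand_summation_across_snps(self, f1_meta):
        snps = _snps([10, 20])
        recs = [
            _rec(10, 10, 5, "F1_liver_control_1"),
            _rec(20, 8, 7, "F1_liver_control_1"),
            _rec(10, 15, 10, "F1_liver_TM_1"),
            _rec(20, 10, 10, "F1_liver_TM_1"),
        ]
        out, log = aggregate_allele_counts(recs, snps, f1_meta)
        by = {(g.condition): g for g in out}
        assert (by["control"].b6_count, by["control"].cast_count) == (18, 12)
        assert by["control"].n_snps == 2

    def test_single_informative_snp_gene_excluded(self, f1_meta):
        snps = _snps([10])
        recs = [
            _rec(10, 30, 30, "F1_liver_control_1"),
            _rec(10, 30, 30, "F1_liver_TM_1"),
        ]
        out, log = aggregate_allele_counts(recs, snps, f1_meta)
        assert out == [] and log.genes_too_few_snps == 1

    def test_min_count_in_at_least_one_condition(self, f1_meta):
        snps = _snps([10, 20])
        low = [  # 15 and 12 pooled: both below 20 -> excluded
            _rec(10, 8, 2, "F1_liver_control_1"), _rec(20, 3, 2, "F1_liver_control_1"),
            _rec(10, 5, 2, "F1_liver_TM_1"), _rec(20, 3, 2, "F1_liver_TM_1"),
        ]
        out, log = aggregate_allele_counts(low, snps, f1_meta)
        assert out == [] and log.genes_low_count == 1
        ok = [  # 15 and 25: retained because one condition reaches 20
            _rec(10, 8, 2, "F1_liver_control_1"), _rec(20, 3, 2, "F1_liver_control_1"),
            _rec(10, 10, 5, "F1_liver_TM_1"), _rec(20, 6, 4, "F1_liver_TM_1"),
        ]
        out, log = aggregate_allele_counts(ok, snps, f1_meta)
        assert log.genes_kept == 1
        assert {g.condition: g.total for g in out} == {"control": 15, "TM": 25}

    def test_allele_mismatch_tallied_and_excluded(self, f1_meta):
        snps = _snps([10, 20])
        recs = [
            _rec(10, 20, 10, "F1_liver_control_1"),
            _rec(20, 5, 5, "F1_liver_control_1", ref="C", alt="T"),  # disagrees with table
            _rec(10, 20, 10, "F1_liver_TM_1"),
            _rec(20, 5, 5, "F1_liver_TM_1"),
        ]
        out, log = aggregate_allele_counts(recs, snps, f1_meta)
        assert log.allele_mismatch == 1

    def test_swapped_ref_alt_mapped_through_snp_table(self, f1_meta):
        snps = SnpTable()
        snps.add("chr1", 10, "A", "G")
        snps.add("chr1", 20, "G", "A")  # here the CAST allele is the reference base
        recs = [
            _rec(10, 30, 10, "F1_liver_control_1"),          # ref=A=B6: 30 B6 / 10 CAST
            _rec(20, 12, 25, "F1_liver_control_1"),          # ref=A=CAST: 25 B6 / 12 CAST
            _rec(10, 30, 30, "F1_liver_TM_1"),
            _rec(20, 10, 10, "F1_liver_TM_1"),
        ]
        out, _ = aggregate_allele_counts(recs, snps, f1_meta)
        ctrl = next(g for g in out if g.condition == "control")
        assert (ctrl.b6_count, ctrl.cast_count) == (55, 22)

    def test_count_conservation_through_aggregation(self, f1_meta):
        rng = np.random.default_rng(3)
        snps = _snps([10, 20, 30])
        recs = []
        for sid in f1_meta.index:
            for pos in (10, 20, 30):
                recs.append(_rec(pos, int(rng.integers(0, 30)), int(rng.integers(0, 30)), sid))
        out, log = aggregate_allele_counts(recs, snps, f1_meta)
        total_in = sum(r.ref_count + r.alt_count for r in recs)
        assert log.kept_counts + log.dropped_counts == total_in
        assert sum(g.total for g in out) == log.kept_counts

    def test_non_f1_records_ignored(self):
        meta = make_samples(
            [("B6", "liver", "control", 1), ("F1", "liver", "control", 1),
             ("F1", "liver", "TM", 1)]
        )
        snps = _snps([10, 20])
        recs = [
            _rec(10, 50, 50, "B6_liver_control_1"),
            _rec(10, 15, 15, "F1_liver_control_1"),
            _rec(20, 15, 15, "F1_liver_control_1"),
            _rec(10, 15, 15, "F1_liver_TM_1"),
            _rec(20, 15, 15, "F1_liver_TM_1"),
        ]
        out, log = aggregate_allele_counts(recs, snps, meta)
        assert log.non_f1_records == 1
        assert next(g for g in out if g.condition == "control").total == 60


def _gac(b6, cast, cond, gene="geneA", n_snps=2):
    return GeneAlleleCounts(gene_id=gene, tissue="liver", condition=cond,
                            b6_count=b6, cast_count=cast, n_snps=n_snps)


class TestAseChangeTest:
    def test_identical_allele_counts_give_p_one(self):
        res = ase_change_test(_gac(40, 60, "control"), _gac(40, 60, "TM"))
        assert res.p == pytest.approx(1.0)

    def test_matches_enumeration_oracle_and_is_significant(self):
        res = ase_change_test(_gac(63, 37, "control"), _gac(30, 70, "TM"))
        assert res.p == pytest.approx(fisher_two_sided_oracle(63, 37, 30, 70), rel=1e-9)
        assert res.p < 1e-3
        assert res.prop_b6_control == pytest.approx(0.63)
        assert res.prop_b6_tm == pytest.approx(0.30)

    def test_zero_margin_condition_gives_missing_p(self):
        res = ase_change_test(_gac(0, 0, "control"), _gac(30, 30, "TM"))
        assert np.isnan(res.p)

    def test_deep_pctp_like_shift_is_significant_at_fdr(self):
        # one strongly shifted gene among balanced ones
        counts = [_gac(630, 370, "control"), _gac(300, 700, "TM")]
        for i in range(9):
            counts += [
                _gac(100, 100, "control", gene=f"null{i}"),
                _gac(103, 97, "TM", gene=f"null{i}"),
            ]
        results = ase_analysis(counts, "liver", fdr=0.05)
        by = {r.gene_id: r for r in results}
        assert by["geneA"].significant
        assert sum(r.significant for r in results) == 1


class TestTotalChangeClass:
    def _de(self, responsive):
        return pd.DataFrame({"responsive": responsive}, index=["geneA"])

    def _sig_ase(self):
        r = AseChangeResult("geneA", "liver", 0.6, 0.4, 1e-5, 1e-4, True)
        return [r]

    def test_upregulated_total_maps_to_up(self):
        res = classify_total_change(self._sig_ase(), self._de(["up"]))
        assert res[0].total_change == "up"

    def test_no_total_change_is_candidate_compensation(self):
        res = classify_total_change(self._sig_ase(), self._de(["none"]))
        assert res[0].total_change == "none"

    def test_gene_absent_from_de_flagged_none(self):
        de = pd.DataFrame({"responsive": []})
        res = classify_total_change(self._sig_ase(), de)
        assert res[0].total_change == "none"
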