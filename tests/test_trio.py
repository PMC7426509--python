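"""Unit tests for trio QC, TDT, LD, and the set-based test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import trioweave as tw
from trioweave.genes import GeneModel
from trioweave.synthetic import CohortConfig, duplicate_snp, gen_trio_panel
from trioweave.trio import MISSING, TrioPanelError, transmission_counts

from conftest import make_panel
from oracles import hwe_oracle, tdt_oracle_snp


def flip_alleles(panel):
    """Relabel minor <-> major: dosage d -> 2 - d, missing untouched."""

    def fl(a):
        return np.where(a == MISSING, MISSING, 2 - a).astype(np.int8)

    return tw.TrioPanel(
        family_ids=panel.family_ids,
        snp_ids=panel.snp_ids,
        chrom=panel.chrom,
        pos=panel.pos,
        father=fl(panel.father),
        mother=fl(panel.mother),
        child=fl(panel.child),
    )


class TestMendelErrors:
    @pytest.mark.parametrize(
        "f, m, c, is_error",
        [
            (0, 0, 1, True),  # no minor allele available
            (0, 2, 1, False),  # obligate heterozygote
            (0, 2, 0, True),
            (0, 2, 2, True),
            (1, 1, 0, False),
            (1, 1, 1, False),
            (1, 1, 2, False),
            (2, 2, 1, True),
            (0, 1, 2, True),
        ],
    )
    def test_single_trio_consistency(self, f, m, c, is_error):
        panel = make_panel([f], [m], [c])
        snp_rate, fam_rate = tw.mendel_errors(panel)
        assert snp_rate.iloc[0] == (1.0 if is_error else 0.0)
        assert fam_rate.iloc[0] == (1.0 if is_error else 0.0)

    def test_missing_member_uninformative(self):
        panel = make_panel([MISSING], [0], [2])
        snp_rate, _ = tw.mendel_errors(panel)
        assert snp_rate.iloc[0] == 0.0


class TestHweExact:
    def test_single_individual(self):
        assert tw.hwe_exact_p(1, 0, 0) == 1.0

    def test_all_heterozygous_extreme(self):
        p = tw.hwe_exact_p(0, 20, 0)
        assert p == pytest.approx(hwe_oracle(0, 20, 0), rel=1e-9)
        assert p < 0.001

    def test_monomorphic_is_one(self):
        assert tw.hwe_exact_p(15, 0, 0) == 1.0

    @settings(deadline=None, derandomize=True, max_examples=80)
    @given(st.integers(0, 15), st.integers(0, 15), st.integers(0, 15))
    def test_allele_relabel_symmetry_and_oracle(self, a, h, b):
        if a + h + b == 0:
            return
        p = tw.hwe_exact_p(a, h, b)
        assert p == pytest.approx(tw.hwe_exact_p(b, h, a), abs=1e-12)
        assert p == pytest.approx(hwe_oracle(a, h, b), rel=1e-9, abs=1e-12)


class TestTdt:
    def test_b_only_transmissions(self):
        # 10 trios: het father, hom-major mother, child het -> b=10
        panel = make_panel([1] * 10, [0] * 10, [1] * 10)
        res = tw.tdt(panel, "snp0")
        assert (res.b, res.c) == (10, 0)
        assert res.chi2 == pytest.approx(10.0)

    def test_balanced_transmissions_null(self):
        panel = make_panel([1] * 14, [0] * 14, [1] * 7 + [0] * 7)
        res = tw.tdt(panel, "snp0")
        assert (res.b, res.c) == (7, 7)
        assert res.chi2 == 0.0
        assert res.p_value == 1.0

    def test_chi2_and_p_worked_example(self):
        # b=30, c=20 -> chi2 = 100/50 = 2.0, p = sf_chi2_1(2.0) ~ 0.1573
        panel = make_panel([1] * 50, [0] * 50, [1] * 30 + [0] * 20)
        res = tw.tdt(panel, "snp0")
        assert (res.b, res.c) == (30, 20)
        assert res.chi2 == pytest.approx(2.0)
        assert res.p_value == pytest.approx(0.15730, abs=1e-4)

    def test_both_het_counting(self):
        panel = make_panel([1, 1, 1], [1, 1, 1], [0, 1, 2])
        res = tw.tdt(panel, "snp0")
        # child 0 -> c+=2; child 1 -> b+=1,c+=1; child 2 -> b+=2
        assert (res.b, res.c) == (3, 3)

    def test_uninformative_flag(self):
        panel = make_panel([0, 2], [0, 2], [0, 2])
        res = tw.tdt(panel, "snp0")
        assert res.uninformative and res.chi2 == 0.0 and res.p_value == 1.0

    def test_allele_relabel_swaps_b_c(self, rng):
        sim = gen_trio_panel(CohortConfig(n_trios=30, n_snps=20, n_genes=5, missing_rate=0.1))
        res = tw.tdt_all(sim.panel)
        res_fl = tw.tdt_all(flip_alleles(sim.panel))
        np.testing.assert_array_equal(res["b"], res_fl["c"])
        np.testing.assert_array_equal(res["c"], res_fl["b"])
        np.testing.assert_allclose(res["chi2"], res_fl["chi2"])

    def test_matches_bruteforce_enumerator(self):
        sim = gen_trio_panel(
            CohortConfig(n_trios=40, n_snps=30, n_genes=5, missing_rate=0.05, seed=7)
        )
        panel = sim.panel
        B, C = transmission_counts(panel)
        for j in range(panel.n_snps):
            b, c = tdt_oracle_snp(panel.father[:, j], panel.mother[:, j], panel.child[:, j])
            assert (int(B[:, j].sum()), int(C[:, j].sum())) == (b, c)


class TestQcFilter:
    def test_exclusion_reasons(self):
        cfg = CohortConfig(n_trios=40, n_snps=10, n_genes=5, missing_rate=0.0, seed=3)
        panel = gen_trio_panel(cfg).panel
        # SNP 0: 13 of 120 genotypes missing (10.8% > 10%)
        father = panel.father.copy()
        father[:13, 0] = MISSING
        # SNP 1: make monomorphic (MAF 0 < 0.05)
        mother = panel.mother.copy()
        child = panel.child.copy()
        father[:, 1] = 0
        mother[:, 1] = 0
        child[:, 1] = 0
        # SNP 2: all founders heterozygous -> HWE exact p << 0.001
        father[:, 2] = 1
        mother[:, 2] = 1
        child[:, 2] = 1
        panel = tw.TrioPanel(
            family_ids=panel.family_ids,
            snp_ids=panel.snp_ids,
            chrom=panel.chrom,
            pos=panel.pos,
            father=father,
            mother=mother,
            child=child,
        )
        cleaned, report = tw.qc_filter(panel, tw.QcThresholds())
        reasons = dict(zip(report.snps_dropped["snp_id"], report.snps_dropped["reason"]))
        assert "missingness" in reasons[panel.snp_ids[0]]
        assert "maf" in reasons[panel.snp_ids[1]]
        assert "hwe" in reasons[panel.snp_ids[2]]
        assert set(cleaned.snp_ids) <= set(panel.snp_ids)

    def test_family_mendel_drop_and_masking(self):
        # family 0 has errors at 2 of 3 SNPs (rate > 0.05) -> dropped
        father = np.array([[0, 0, 0], [1, 1, 1], [1, 1, 1], [1, 1, 1]], dtype=np.int8)
        mother = np.array([[0, 0, 0], [0, 0, 0], [0, 0, 0], [0, 0, 0]], dtype=np.int8)
        child = np.array([[2, 2, 0], [1, 0, 1], [0, 1, 1], [1, 1, 0]], dtype=np.int8)
        panel = make_panel(father, mother, child)
        cleaned, report = tw.qc_filter(
            panel,
            tw.QcThresholds(min_maf=0.0, hwe_alpha=0.0, max_missing=1.0, max_snp_mendel=1.0),
        )
        assert list(report.families_dropped["family_id"]) == ["F0"]
        assert cleaned.n_families == 3

    def test_all_families_excluded_raises(self):
        panel = make_panel([[0, 0]], [[0, 0]], [[2, 2]])
        with pytest.raises(TrioPanelError):
            tw.qc_filter(panel, tw.QcThresholds())


class TestLdR2:
    def test_duplicated_snp_is_one(self):
        sim = gen_trio_panel(CohortConfig(n_trios=20, n_snps=5, n_genes=2, missing_rate=0.0))
        panel = duplicate_snp(sim.panel, "rs000001", "rs_dup")
        assert tw.ld_r2(panel, "rs000001", "rs_dup") == pytest.approx(1.0)

    def test_orthogonal_dosages_zero(self):
        father = np.array([[0, 0], [0, 1], [2, 0], [2, 1]], dtype=np.int8)
        mother = np.array([[0, 1], [0, 0], [2, 1], [2, 0]], dtype=np.int8)
        child = np.array([[0, 0], [0, 0], [2, 0], [2, 0]], dtype=np.int8)
        panel = make_panel(father, mother, child)
        assert tw.ld_r2(panel, "snp0", "snp1") == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_correlation(self):
        father = np.array([[0, 1], [1, 2], [2, 0]], dtype=np.int8)
        mother = np.array([[1, 1], [0, 2], [2, 1]], dtype=np.int8)
        child = np.array([[1, 1], [1, 2], [2, 0]], dtype=np.int8)
        panel = make_panel(father, mother, child)
        x = [0, 1, 2, 1, 0, 2]
        y = [1, 2, 0, 1, 2, 1]
        r = np.corrcoef(x, y)[0, 1]
        assert tw.ld_r2(panel, "snp0", "snp1") == pytest.approx(r * r)

    def test_monomorphic_returns_zero_with_warning(self):
        father = np.array([[0, 1], [0, 0]], dtype=np.int8)
        mother = np.array([[0, 1], [0, 2]], dtype=np.int8)
        child = np.array([[0, 1], [0, 1]], dtype=np.int8)
        panel = make_panel(father, mother, child)
        with pytest.warns(UserWarning, match="monomorphic"):
            assert tw.ld_r2(panel, "snp0", "snp1") == 0.0


class TestSnpsNearGene:
    gene = GeneModel(gene_id="G", chrom="chr1", start=100_000, end=110_000)

    def make(self, positions, chroms=None):
        n = len(positions)
        return make_panel(
            [[1] * n], [[0] * n], [[1] * n], pos=positions, chrom=chroms or ["chr1"] * n
        )

    def test_inclusive_window_bounds(self):
        panel = self.make([80_000, 79_999, 130_000, 130_001])
        got = tw.snps_near_gene(self.gene, panel, window=20_000)
        assert got == ["snp0", "snp2"]

    def test_other_chromosome_excluded(self):
        panel = self.make([105_000, 105_000], chroms=["chr1", "chr2"])
        assert tw.snps_near_gene(self.gene, panel, window=20_000) == ["snp0"]


class TestSetBasedTest:
    def make_informative_panel(self, seed=0, n_snps=6):
        return gen_trio_panel(
            CohortConfig(n_trios=50, n_snps=n_snps, n_genes=2, missing_rate=0.0, seed=seed)
        ).panel

    def test_single_snp_observed_stat(self):
        panel = make_panel([1] * 40, [0] * 40, [1] * 30 + [0] * 10)
        res = tw.set_based_test(panel, ["snp0"], n_perm=200, seed=1)
        expected = tw.tdt(panel, "snp0").chi2
        assert res.observed_stat == pytest.approx(expected)
        assert res.representative_snp_ids == ["snp0"]

    def test_perfect_ld_pruned_to_one_representative(self):
        panel = make_panel([1] * 40, [0] * 40, [1] * 35 + [0] * 5)
        for i in range(9):
            panel = duplicate_snp(panel, "snp0", f"dup{i}")
        res = tw.set_based_test(panel, list(panel.snp_ids), n_perm=200, seed=1)
        assert len(res.representative_snp_ids) == 1

    def test_fixed_seed_bitwise_reproducible(self):
        panel = self.make_informative_panel(seed=5)
        a = tw.set_based_test(panel, list(panel.snp_ids), n_perm=500, seed=42)
        b = tw.set_based_test(panel, list(panel.snp_ids), n_perm=500, seed=42)
        assert a == b

    def test_low_perm_warning_and_empty_selection(self):
        panel = make_panel([0, 2], [0, 2], [0, 2])  # uninformative everywhere
        with pytest.warns(UserWarning, match="n_perm"):
            res = tw.set_based_test(panel, ["snp0"], n_perm=50, seed=0)
        assert res.empty_selection and res.empirical_p == 1.0

    def test_empty_snp_set_rejected(self):
        panel = self.make_informative_panel()
        with pytest.raises(TrioPanelError):
            tw.set_based_test(panel, [], n_perm=200, seed=0)

    def test_max_reps_cap(self):
        panel = self.make_informative_panel(seed=11, n_snps=12)
        res = tw.set_based_test(
            panel, list(panel.snp_ids), max_reps=2, snp_p_enter=1.0, n_perm=100, seed=0
        )
        assert len(res.representative_snp_ids) <= 2


class TestIntegrate:
    def test_strict_empirical_threshold(self):
        import pandas as pd

        # one overwhelming SNP: with n_perm=19 the best attainable
        # empirical p is exactly 1/20 = 0.05, which the strict < excludes
        panel = make_panel(
            [1] * 60, [0] * 60, [1] * 60, pos=[105_000], chrom=["chr1"]
        )
        genes = [GeneModel(gene_id="G1", chrom="chr1", start=100_000, end=110_000)]
        de = pd.DataFrame({"gene_id": ["G1"], "p_value": [0.001], "q_value": [0.01]})
        res = tw.set_based_test(panel, ["snp0"], n_perm=19, seed=0)
        assert res.empirical_p == pytest.approx(0.05)
        with pytest.warns(UserWarning):
            table = tw.integrate(de, panel, genes, n_perm=19, seed=0)
        assert len(table) == 0

    def test_no_candidates_warns_empty(self):
        import pandas as pd

        panel = make_panel([1] * 10, [0] * 10, [1] * 10)
        genes = [GeneModel(gene_id="G1", chrom="chr1", start=0, end=10_000)]
        de = pd.DataFrame({"gene_id": ["G1"], "p_value": [0.9], "q_value": [0.9]})
        with pytest.warns(UserWarning, match="no DE candidate"):
            table = tw.integrate(de, panel, genes, n_perm=100, seed=0)
        assert len(table) == 0

    def test_gene_without_nearby_snps_skipped(self):
        import pandas as pd

        panel = make_panel([1] * 10, [0] * 10, [1] * 10, pos=[10_000_000])
        genes = [GeneModel(gene_id="G1", chrom="chr1", start=0, end=10_000)]
        de = pd.DataFrame({"gene_id": ["G1"], "p_value": [0.001], "q_value": [0.01]})
        table = tw.integrate(de, panel, genes, n_perm=100, seed=0)
        assert len(table) == 0
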