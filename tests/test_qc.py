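"""Quality-control filters: HWE, planted failures, Mendelian logic, samples."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import triovc as tv
from triovc.qc import MENDELIAN_ERROR_TABLE


def brute_force_mendel_error(father: int, mother: int, child: int) -> bool:
    """Independent oracle: enumerate every parental gamete combination."""
    gametes = {0: {0}, 1: {0, 1}, 2: {1}}
    possible = {gf + gm for gf in gametes[father] for gm in gametes[mother]}
    return child not in possible


class TestHWE:
    def test_exact_proportions_give_p_one(self):
        assert tv.hwe_test(25, 50, 25) == 1.0

    def test_hand_computed_chi_square(self):
        # counts (30, 40, 30), expected (25, 50, 25): statistic 4, 1 df
        p = tv.hwe_test(30, 40, 30)
        assert abs(p - 0.0455) < 5e-4

    def test_complete_het_deficit(self):
        # statistic 200 on 1 df
        assert tv.hwe_test(100, 0, 100) < 1e-40

    def test_monomorphic_site_is_not_flagged(self):
        assert tv.hwe_test(50, 0, 0) == 1.0

    def test_invalid_counts(self):
        with pytest.raises(tv.InputError):
            tv.hwe_test(-1, 2, 3)
        with pytest.raises(tv.InputError):
            tv.hwe_test(0, 0, 0)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(0, 500), st.integers(0, 500), st.integers(0, 500))
    def test_valid_probability_and_allele_symmetry(self, a, h, b):
        if a + h + b == 0:
            return
        p = tv.hwe_test(a, h, b)
        assert 0.0 <= p <= 1.0
        assert p == pytest.approx(tv.hwe_test(b, h, a))  # allele relabeling


class TestVariantFilters:
    def test_planted_failures_one_per_criterion(self):
        rng = np.random.default_rng(0)
        n, m = 400, 10
        dos = rng.binomial(2, 0.3, size=(n, m)).astype(float)
        dos[:, 2] = 0.0                      # monomorphic -> MAF
        dos[: int(0.05 * n), 5] = np.nan     # 5% missing -> call rate
        dos[:, 7] = 1.0                      # all hets -> extreme HWE failure
        geno = tv.GenotypeData(dos)
        rep = tv.variant_filters(geno)
        assert rep.variant_pass.sum() == 7
        assert rep.variant_reason[2] == "maf"
        assert rep.variant_reason[5] == "call_rate"
        assert rep.variant_reason[7] == "hwe"

    def test_first_failing_label_order_maf_wins(self):
        # a monomorphic SNP that also has poor call rate is labelled "maf"
        dos = np.zeros((100, 1))
        dos[:10, 0] = np.nan
        rep = tv.variant_filters(tv.GenotypeData(dos))
        assert rep.variant_reason[0] == "maf"

    def test_null_exclusion_rate_matches_alpha(self):
        rng = np.random.default_rng(1)
        dos = rng.binomial(2, 0.3, size=(500, 2000)).astype(float)
        thr = tv.QCThresholds(hwe_alpha=0.05)
        rep = tv.variant_filters(tv.GenotypeData(dos), thr)
        rate = np.mean([r == "hwe" for r in rep.variant_reason])
        assert 0.03 < rate < 0.075  # type-I error of the HWE stage

    def test_founders_only_hwe_with_trios(self):
        params = tv.SimParams(n_trios=300, n_snps=300, seed=8)
        geno, trios = tv.simulate_trio_genotypes(params)
        rep = tv.variant_filters(geno, tv.QCThresholds(hwe_alpha=0.001), trios)
        # null simulation: HWE holds among founders, nearly everything passes
        assert rep.variant_pass.mean() > 0.98

    def test_empty_input_rejected(self):
        with pytest.raises(tv.InputError):
            tv.variant_filters(tv.GenotypeData(np.empty((0, 0))))

    def test_idempotent_and_permutation_invariant(self):
        rng = np.random.default_rng(2)
        dos = rng.binomial(2, rng.uniform(0.05, 0.5, 50), size=(300, 50)).astype(float)
        dos[rng.random(dos.shape) < 0.005] = np.nan
        geno = tv.GenotypeData(dos)
        rep = tv.variant_filters(geno)
        filtered = geno.select_variants(rep.variant_pass)
        rep2 = tv.variant_filters(filtered)
        assert rep2.variant_pass.all()

        perm = rng.permutation(50)
        rep_p = tv.variant_filters(geno.select_variants(perm))
        assert np.array_equal(rep_p.variant_pass, rep.variant_pass[perm])


class TestMendelianScan:
    def test_hand_cases(self):
        assert brute_force_mendel_error(0, 0, 1)
        for child in (0, 1, 2):
            assert not brute_force_mendel_error(1, 1, child)

    def test_all_27_combinations_against_oracle(self):
        combos = [(f, m, o) for f in range(3) for m in range(3) for o in range(3)]
        expected = {c: brute_force_mendel_error(*c) for c in combos}
        assert sum(expected.values()) == 12
        for (f, m, o), err in expected.items():
            assert MENDELIAN_ERROR_TABLE[f, m, o] == err

    def test_scan_counts_planted_errors_and_skips_soft_calls(self):
        # trio rows: offspring 0, mother 1, father 2
        dos = np.array(
            [
                [1.0, 2.0, 0.5, np.nan],
                [0.0, 1.0, 1.0, 1.0],
                [0.0, 1.0, 1.0, 1.0],
            ]
        )
        trios = tv.TrioIndex(offspring=[0], mother=[1], father=[2])
        rep = tv.mendelian_error_scan(tv.GenotypeData(dos), trios)
        # SNP 0: parents 0/0, child 1 -> error; SNP 1 fine;
        # SNP 2 soft offspring, SNP 3 missing offspring -> skipped
        assert rep.trio_mendel_errors.tolist() == [1]
        assert rep.snp_mendel_errors.tolist() == [1, 0, 0, 0]
        assert rep.n_soft_calls_skipped == 2

    def test_out_of_range_trio_rejected(self):
        geno = tv.GenotypeData(np.zeros((3, 2)))
        trios = tv.TrioIndex(offspring=[0], mother=[1], father=[5])
        with pytest.raises(tv.InputError):
            tv.mendelian_error_scan(geno, trios)


class TestSampleFilters:
    def test_null_samples_retained_with_f_near_zero(self):
        rng = np.random.default_rng(3)
        dos = rng.binomial(2, 0.4, size=(200, 2000)).astype(float)
        rep = tv.sample_filters(tv.GenotypeData(dos))
        assert rep.sample_pass.all()
        assert np.abs(rep.details["fhet"]).max() < 0.15

    def test_all_homozygous_sample_excluded(self):
        rng = np.random.default_rng(4)
        dos = rng.binomial(2, 0.5, size=(100, 500)).astype(float)
        dos[0] = np.where(dos[0] == 1.0, 2.0, dos[0])  # kill every het
        rep = tv.sample_filters(tv.GenotypeData(dos))
        assert not rep.sample_pass[0]
        assert rep.sample_reason[0] == "fhet"
        assert rep.details["fhet"][0] == pytest.approx(1.0, abs=1e-12)

    def test_low_call_rate_sample_excluded(self):
        rng = np.random.default_rng(5)
        dos = rng.binomial(2, 0.3, size=(50, 400)).astype(float)
        dos[7, rng.random(400) < 0.10] = np.nan
        rep = tv.sample_filters(tv.GenotypeData(dos))
        assert not rep.sample_pass[7]
        assert rep.sample_reason[7] == "call_rate"
        assert rep.sample_pass.sum() == 49

    def test_degenerate_expected_heterozygosity(self):
        # dosages all zero -> allele freq 0 -> expected het 0; the variant
        # filter would remove these SNPs, but the sample filter must not
        # divide by zero when handed such input directly
        dos = np.zeros((5, 4))
        rep = tv.sample_filters(tv.GenotypeData(dos))
        assert (~rep.sample_pass).all()
        assert all(r == "degenerate_heterozygosity" for r in rep.sample_reason)
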