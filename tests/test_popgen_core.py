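"""Classical statistics: theta, frequencies, F_ST, LD, MK test."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest

from colsel import (
    allele_frequency,
    hudson_fst_pair,
    hudson_fst_snp,
    ld_decay_profile,
    ld_r2_matrix,
    ld_r2_pair,
    mk_test,
    sfs_fraction_below,
    simulate_population_pair,
    simulate_two_haplogroup_locus,
    watterson_theta,
)
from colsel.synthetic import PopulationPairParams, TwoHaplogroupParams

from conftest import genotype_table, small_haplotype_matrix


class TestWattersonTheta:
    @pytest.mark.parametrize(
        "S,n,L,expected",
        [
            (0, 10, 1000, 0.0),
            (5, 2, 1000, 0.005),              # a_1 = 1
            (10, 10, 1000, 10 / (sum(1 / i for i in range(1, 10)) * 1000)),
        ],
    )
    def test_values(self, S, n, L, expected):
        assert watterson_theta(S, n, L) == pytest.approx(expected, rel=1e-12)

    def test_harmonic_denominator_hand_sum(self):
        # a_9 summed directly
        assert watterson_theta(10, 10, 1000) == pytest.approx(
            10 / (2.8289682539682537 * 1000), rel=1e-12
        )

    def test_scales_linearly_in_S_and_inversely_in_L(self):
        base = watterson_theta(7, 40, 500)
        assert watterson_theta(14, 40, 500) == pytest.approx(2 * base)
        assert watterson_theta(7, 40, 1000) == pytest.approx(base / 2)

    def test_single_copy_rejected(self):
        with pytest.raises(ValueError):
            watterson_theta(1, 1, 100)


class TestAlleleFrequency:
    def test_worked_example_five_het_one_hom_of_twenty(self):
        """5 heterozygotes + 1 homozygous carrier in 20 diploids -> 17.5%."""
        rows = [[1]] * 5 + [[2]] + [[0]] * 14
        assert allele_frequency(genotype_table(rows), 0) == 0.175

    def test_monomorphic_reference_is_zero(self):
        assert allele_frequency(genotype_table([[0]] * 8), 0) == 0.0

    def test_missing_genotypes_leave_the_denominator(self):
        rows = [[1]] * 3 + [[0]] * 5 + [[-1]] * 2
        assert allele_frequency(genotype_table(rows), 0) == 3 / 16

    def test_all_missing_is_an_error(self):
        with pytest.raises(ValueError):
            allele_frequency(genotype_table([[-1], [-1]]), 0)


class TestSfsFraction:
    def test_strictly_below(self):
        assert sfs_fraction_below([0.001, 0.02, 0.5], 0.01) == pytest.approx(1 / 3)
        assert sfs_fraction_below([0.01, 0.01], 0.01) == 0.0

    def test_uniform_null_close_to_cutoff(self):
        rng = np.random.default_rng(0)
        freqs = rng.random(1000)
        se = np.sqrt(0.01 * 0.99 / 1000)
        assert abs(sfs_fraction_below(freqs, 0.01) - 0.01) < 3 * se

    def test_empty_list_error(self):
        with pytest.raises(ValueError):
            sfs_fraction_below([], 0.01)


class TestHudsonFstSnp:
    def test_fixed_difference_is_one(self):
        assert hudson_fst_snp(1.0, 100, 0.0, 100) == pytest.approx(1.0)

    def test_panmixia_limit_is_zero(self):
        assert hudson_fst_snp(0.5, 10**9, 0.5, 10**9) == pytest.approx(0.0, abs=1e-8)

    def test_plug_in_arithmetic(self):
        # hw -> 0.18, hb = 0.82 at large n
        assert hudson_fst_snp(0.9, 10**9, 0.1, 10**9) == pytest.approx(
            1 - 0.18 / 0.82, abs=1e-8
        )

    def test_monomorphic_in_both_is_undefined_flag(self):
        assert np.isnan(hudson_fst_snp(0.0, 100, 0.0, 100))

    def test_unbiased_near_zero_under_binomial_resampling(self):
        rng = np.random.default_rng(1)
        k1 = rng.binomial(60, 0.4, 4000)
        k2 = rng.binomial(60, 0.4, 4000)
        vals = hudson_fst_snp(k1 / 60, 60, k2 / 60, 60)
        assert abs(np.nanmean(vals)) < 0.01


class TestHudsonFstPair:
    def test_identical_populations_mean_near_zero(self):
        rng = np.random.default_rng(3)
        block = rng.binomial(2, 0.3, (100, 200)).astype(np.int8)
        gt = genotype_table(
            np.vstack([block, block]), population=["A"] * 100 + ["B"] * 100
        )
        res = hudson_fst_pair(gt, "A", "B")
        assert abs(res.mean_fst) <= 0.01

    def test_engineered_fixed_difference_snp_is_one(self):
        rows = np.zeros((20, 2), dtype=np.int8)
        rows[:10, 0] = 2
        rows[:, 1] = [0, 2] * 10  # shared polymorphism keeps the pair defined
        gt = genotype_table(rows, population=["A"] * 10 + ["B"] * 10)
        res = hudson_fst_pair(gt, "A", "B")
        assert dict(res.per_snp)[0] == pytest.approx(1.0)

    def test_balding_nichols_truth_recovered(self):
        gt = simulate_population_pair(
            PopulationPairParams(fst_true=0.15, n_sites=2000, n_per_pop=100, seed=7)
        )
        res = hudson_fst_pair(gt, "A", "B")
        assert res.mean_fst_ratio_of_averages == pytest.approx(0.15, abs=0.02)

    def test_no_polymorphic_snp_is_an_error(self):
        gt = genotype_table([[0], [0]], population=["A", "B"])
        with pytest.raises(ValueError):
            hudson_fst_pair(gt, "A", "B")


class TestLdR2:
    def test_complete_ld(self):
        hm = small_haplotype_matrix([[1, 1, 0, 0], [1, 1, 0, 0]])
        assert ld_r2_pair(hm, 0, 1) == pytest.approx(1.0)

    def test_independence(self):
        hm = small_haplotype_matrix([[1, 1, 0, 0], [1, 0, 1, 0]])
        assert ld_r2_pair(hm, 0, 1) == pytest.approx(0.0, abs=1e-12)

    def test_haplotype_count_arithmetic(self):
        # AB=3, Ab=1, aB=1, ab=3 -> D = 0.125, r2 = 0.25
        a = [1, 1, 1, 1, 0, 0, 0, 0]
        b = [1, 1, 1, 0, 1, 0, 0, 0]
        hm = small_haplotype_matrix([a, b])
        assert ld_r2_pair(hm, 0, 1) == pytest.approx(0.25)

    def test_invariant_to_allele_label_swap(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            a = rng.integers(0, 2, 12)
            b = rng.integers(0, 2, 12)
            if len(set(a)) < 2 or len(set(b)) < 2:
                continue
            hm = small_haplotype_matrix([a, b])
            hm_swapped = small_haplotype_matrix([1 - a, b])
            assert ld_r2_pair(hm, 0, 1) == pytest.approx(
                ld_r2_pair(hm_swapped, 0, 1)
            )

    def test_monomorphic_site_is_an_error(self):
        hm = small_haplotype_matrix([[1, 1, 1, 1], [1, 0, 1, 0]])
        with pytest.raises(ValueError):
            ld_r2_pair(hm, 0, 1)


class TestLdMatrix:
    def _random_hm(self, seed, n_hap=30, n_sites=8):
        rng = np.random.default_rng(seed)
        while True:
            cols = rng.integers(0, 2, (n_sites, n_hap))
            if all(0 < c.mean() < 1 for c in cols):
                return small_haplotype_matrix(cols)

    def test_maf_filter_applied_before_pairs(self):
        cols = [[1, 0] * 10, [0, 1] * 10, [1] * 19 + [0],   # MAF 0.05 edge kept
                [0] * 19 + [1], [1] * 18 + [0, 0]]
        cols[3] = [0] * 19 + [1]                              # MAF 0.05 kept
        hm = small_haplotype_matrix(cols)
        # sites 0,1: MAF .5; 2,3: MAF .05 (kept, boundary); 4: MAF 0.1
        r2, kept = ld_r2_matrix(hm, maf_min=0.06)
        assert kept.tolist() == [0, 1, 4]
        assert r2.shape == (3, 3)
        assert np.allclose(np.diag(r2), 1.0)
        # the filter is strict-below: MAF exactly at the cutoff is retained
        r2_all, kept_all = ld_r2_matrix(hm, maf_min=0.05)
        assert kept_all.tolist() == [0, 1, 2, 3, 4]

    def test_matches_pairwise_oracle(self):
        hm = self._random_hm(5)
        r2, kept = ld_r2_matrix(hm, maf_min=0.05)
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                assert r2[i, j] == pytest.approx(
                    ld_r2_pair(hm, int(kept[i]), int(kept[j]))
                )

    def test_invariant_to_haplotype_order(self):
        hm = self._random_hm(6)
        rng = np.random.default_rng(0)
        perm = rng.permutation(hm.n_haplotypes)
        shuffled = small_haplotype_matrix(hm.alleles.T[:, perm])
        a, _ = ld_r2_matrix(hm)
        b, _ = ld_r2_matrix(shuffled)
        assert np.allclose(a, b)

    def test_too_few_retained_sites_error(self):
        hm = small_haplotype_matrix([[1] * 19 + [0], [0] * 19 + [1]])
        with pytest.raises(ValueError, match="MAF"):
            ld_r2_matrix(hm, maf_min=0.2)


class TestLdDecay:
    def test_single_pair_single_bin(self):
        hm = small_haplotype_matrix([[1, 1, 0, 0], [1, 0, 1, 0]], positions=[0, 50])
        means, empty = ld_decay_profile(hm, [0], [(0, 100)])
        assert means[0] == pytest.approx(ld_r2_pair(hm, 0, 1))
        assert not empty[0]

    def test_no_recombination_profile_is_flat_and_high(self):
        hm, truth = simulate_two_haplogroup_locus(
            TwoHaplogroupParams(seed=21, t_within=2.8e4)
        )
        # restrict to common sites (the haplogroup-defining ones)
        common = [s for s in range(hm.n_sites)
                  if 0.2 < hm.alleles[:, s].mean() < 0.8]
        hm2 = hm.take_sites(common)
        bins = [(0, 4000), (4000, 8000), (8000, 16000)]
        means, empty = ld_decay_profile(hm2, [0], bins)
        assert np.all(means[~empty] > 0.8)

    def test_empty_bin_flagged_not_zero(self):
        hm = small_haplotype_matrix([[1, 1, 0, 0], [1, 0, 1, 0]], positions=[0, 50])
        means, empty = ld_decay_profile(hm, [0], [(1000, 2000)])
        assert empty[0] and np.isnan(means[0])


def exact_fisher_two_sided(a, b, c, d):
    """Independent oracle: exhaustive hypergeometric tail in exact rationals."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    p_obs = Fraction(comb(r1, a) * comb(r2, c1 - a), denom)
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        p_k = Fraction(comb(r1, k) * comb(r2, c1 - k), denom)
        if p_k <= p_obs:
            total += p_k
    return total


class TestMkTest:
    def test_equal_ratios_are_null(self):
        res = mk_test(10, 5, 20, 10)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_cell_matches_enumeration_oracle(self):
        res = mk_test(20, 0, 50, 50)
        assert res.p_value == pytest.approx(
            float(exact_fisher_two_sided(20, 0, 50, 50)), rel=1e-9
        )
        assert res.haldane_corrected

    def test_maf_filter_recomputes_polymorphism_counts(self):
        res = mk_test(
            5, 3, 10, 6, maf_exclude=0.05,
            replacement_freqs=[0.01, 0.02, 0.10, 0.20, 0.30],
            neutral_freqs=[0.04] * 6 + [0.5] * 4,
        )
        assert (res.replacement_poly, res.neutral_poly) == (3, 4)
        assert res.maf_cutoff == 0.05

    def test_all_zero_table_error(self):
        with pytest.raises(ValueError):
            mk_test(0, 0, 0, 0)

    def test_random_tables_match_enumeration_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(60):
            a, b, c, d = rng.integers(0, 16, 4)
            if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                continue
            res = mk_test(int(a), int(b), int(c), int(d))
            assert res.p_value == pytest.approx(
                float(exact_fisher_two_sided(int(a), int(b), int(c), int(d))),
                rel=1e-9, abs=1e-12,
            )
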