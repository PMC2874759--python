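import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as ss

from fundusnp.popgen import (
    MISSING,
    GenotypeMatrix,
    amova,
    classify_cross_species,
    fis_permutation_test,
    fst_matrix,
    hwe_exact_test,
    locus_stats,
    mantel_test,
    pairwise_fst,
    qc_filter,
    summarize_population,
)
from fundusnp.synth import PopSimConfig, simulate_genotype_matrix


def gm_from_codes(codes, populations, regions=None, low_prob=None) -> GenotypeMatrix:
    return GenotypeMatrix(
        np.asarray(codes, dtype=np.int8),
        populations=populations,
        regions=regions,
        low_prob=low_prob,
    )


# ---------------------------------------------------------------------------
# locus statistics and summaries
# ---------------------------------------------------------------------------

class TestLocusStats:
    def test_hand_computed_example(self):
        # 10 called, 4 Aa, 6 AA: H_O=0.4, p=0.8, H_E=2*0.8*0.2*(20/19)
        g = np.array([[1]] * 4 + [[0]] * 6)
        st = locus_stats(g)
        assert st["h_obs"][0] == pytest.approx(0.4)
        assert st["p"][0] == pytest.approx(0.8)
        assert st["h_exp"][0] == pytest.approx(2 * 0.8 * 0.2 * 20 / 19)
        assert bool(st["polymorphic"][0])

    def test_monomorphic_locus(self):
        st = locus_stats(np.zeros((8, 1), dtype=int))
        assert st["h_obs"][0] == 0 and st["h_exp"][0] == 0
        assert not bool(st["polymorphic"][0])

    def test_expected_het_unbiased_under_hwe(self):
        # mean H_E over 5000 simulated HWE samples matches 2pq within 3 SE
        rng = np.random.default_rng(12)
        n = 10
        for p in (0.1, 0.3, 0.5):
            g = rng.binomial(2, 1 - p, size=(n, 5000))
            st = locus_stats(g)
            vals = st["h_exp"].to_numpy()
            se = vals.std(ddof=1) / np.sqrt(len(vals))
            assert abs(vals.mean() - 2 * p * (1 - p)) < 3 * se


class TestSummarize:
    def test_all_hom_locus_is_monomorphic(self):
        gm = gm_from_codes(np.zeros((5, 3), dtype=int), ["p"] * 5)
        with pytest.raises(ValueError):
            # F undefined when every locus is monomorphic
            summarize_population(gm, "p")

    def test_summary_values(self):
        codes = np.array(
            [[1, 0], [1, 0], [1, 0], [1, 0], [0, 0], [0, 0], [0, 0], [0, 0], [0, 0], [0, 2]]
        )
        gm = gm_from_codes(codes, ["p"] * 10)
        s = summarize_population(gm, "p")
        assert s.P_O == pytest.approx(100.0)
        assert s.H_O == pytest.approx((0.4 + 0.0) / 2)
        h_e1 = 2 * 0.8 * 0.2 * 20 / 19
        h_e2 = 2 * 0.9 * 0.1 * 20 / 19
        assert s.H_E == pytest.approx((h_e1 + h_e2) / 2)
        assert s.F == pytest.approx(1 - s.H_O / s.H_E)

    def test_population_needs_two_individuals(self):
        gm = gm_from_codes([[1]], ["p"])
        with pytest.raises(ValueError):
            summarize_population(gm, "p")


class TestFisPermutation:
    def test_deterministic_given_seed(self):
        gm, _ = simulate_genotype_matrix(
            PopSimConfig(n_regions=1, pops_per_region=1, inds_per_pop=15, n_loci=30,
                         fst=0.0, missing_rate=0.0, seed=5)
        )
        a = fis_permutation_test(gm, "pop1", n_perm=300, seed=9)
        b = fis_permutation_test(gm, "pop1", n_perm=300, seed=9)
        assert a == b

    def test_all_heterozygotes_extreme(self):
        gm = gm_from_codes(np.ones((10, 4), dtype=int), ["p"] * 10)
        f, p = fis_permutation_test(gm, "p", n_perm=500, seed=3)
        assert f < 0
        assert p < 0.05

    def test_pvalue_uniform_under_hwe(self):
        # alleles drawn independently per copy IS the permutation null, so
        # the p-value should be uniform across repeated datasets
        rng = np.random.default_rng(31)
        ps = []
        for rep in range(200):
            g = rng.binomial(2, 0.4, size=(20, 25)).astype(np.int8)
            gm = gm_from_codes(g, ["p"] * 20)
            try:
                _, p = fis_permutation_test(gm, "p", n_perm=199, seed=rep)
            except ValueError:
                continue
            ps.append(p)
        assert ss.kstest(ps, "uniform").pvalue > 0.01

    def test_monomorphic_population_raises(self):
        gm = gm_from_codes(np.zeros((10, 3), dtype=int), ["p"] * 10)
        with pytest.raises(ValueError):
            fis_permutation_test(gm, "p", n_perm=200, seed=0)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

class TestQcFilter:
    def _gm(self, codes, low_prob=None):
        codes = np.asarray(codes, dtype=np.int8)
        return gm_from_codes(codes, ["p1"] * (codes.shape[0] // 2) + ["p2"] * (codes.shape[0] - codes.shape[0] // 2), low_prob=low_prob)

    def test_call_rate_rule(self):
        # locus 0 called in 89/100 individuals -> removed at 0.90
        codes = np.zeros((100, 2), dtype=np.int8)
        codes[:11, 0] = MISSING
        codes[::2, 1] = 1  # keep locus 1 clean and polymorphic
        gm = self._gm(codes)
        out, report = qc_filter(gm, min_call_rate=0.90)
        assert out.loci == ["locus1"]
        assert report["fail_call_rate"].tolist() == [True]

    def test_low_probability_rule(self):
        codes = np.tile(np.array([[0], [1]], dtype=np.int8), (10, 1))
        lp = np.zeros((20, 1), dtype=bool)
        lp[:11, 0] = True  # 55% flagged
        gm = self._gm(codes, low_prob=lp)
        out, report = qc_filter(gm)
        assert out.n_loci == 0
        assert report["fail_low_probability"].tolist() == [True]

    def test_clean_locus_retained(self):
        codes = np.zeros((20, 1), dtype=np.int8)
        codes[:2, 0] = 1  # 10% heterozygotes, no missing
        out, report = qc_filter(self._gm(codes))
        assert out.n_loci == 1 and len(report) == 0

    def test_het_excess_rule(self):
        codes = np.ones((20, 1), dtype=np.int8)  # all heterozygous everywhere
        out, report = qc_filter(self._gm(codes), het_excess_threshold=0.60)
        assert out.n_loci == 0
        assert report["fail_het_excess"].tolist() == [True]

    def test_missingness_rule(self):
        codes = np.zeros((20, 2), dtype=np.int8)
        codes[::2, :] = 1
        codes[0, 0] = MISSING  # 5% missing at locus 0
        out, _ = qc_filter(self._gm(codes), min_call_rate=0.0, max_missing_per_locus=0.04)
        assert out.loci == ["locus1"]


# ---------------------------------------------------------------------------
# HWE exact test
# ---------------------------------------------------------------------------

def hwe_enumeration_oracle(n_AA, n_Aa, n_aa) -> float:
    """Independent enumeration with exact integer combinatorics."""
    from fractions import Fraction

    n = n_AA + n_Aa + n_aa
    n_a = n_Aa + 2 * n_aa
    n_rare = min(n_a, 2 * n - n_a)
    if n_rare == 0:
        return 1.0
    weights = {}
    for h in range(n_rare % 2, n_rare + 1, 2):
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        weights[h] = Fraction(2**h * math.factorial(n),
                              math.factorial(h) * math.factorial(rare_hom) * math.factorial(common_hom))
    total = sum(weights.values())
    p_obs = weights[n_Aa]
    return float(sum(w for w in weights.values() if w <= p_obs) / total)


class TestHweExact:
    @pytest.mark.parametrize(
        "counts",
        [(25, 50, 25), (50, 0, 50), (10, 0, 0), (3, 5, 2), (40, 10, 0), (1, 1, 1),
         (0, 2, 0), (12, 40, 48), (7, 0, 7)],
    )
    def test_matches_enumeration_oracle(self, counts):
        assert hwe_exact_test(*counts) == pytest.approx(hwe_enumeration_oracle(*counts), rel=1e-10)

    def test_modal_configuration_near_one(self):
        assert hwe_exact_test(25, 50, 25) >= 0.99

    def test_extreme_het_deficit_tiny(self):
        assert hwe_exact_test(50, 0, 50) < 1e-3

    def test_monomorphic_is_one(self):
        assert hwe_exact_test(12, 0, 0) == 1.0

    def test_type_one_error_conservative(self):
        rng = np.random.default_rng(4)
        rejections = 0
        n_trials = 400
        for _ in range(n_trials):
            g = rng.binomial(2, 0.3, size=30)
            p = hwe_exact_test(int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum()))
            rejections += p < 0.05
        # discrete exact tests are conservative: rate at or below nominal
        assert rejections / n_trials <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_trials)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)


# ---------------------------------------------------------------------------
# cross-species classification
# ---------------------------------------------------------------------------

class TestClassifyCrossSpecies:
    def _pair(self, codes_a, codes_b):
        a = gm_from_codes(np.asarray(codes_a, dtype=np.int8), ["pa"] * len(codes_a))
        b = gm_from_codes(np.asarray(codes_b, dtype=np.int8), ["pb"] * len(codes_b))
        return a, b

    def test_fixed_difference(self):
        a, b = self._pair([[0], [0], [0]], [[2], [2]])
        assert classify_cross_species(a, b)["locus0"] == "FIXED_DIFFERENCE"

    def test_unamplified(self):
        a, b = self._pair([[0], [1], [2]], [[MISSING], [MISSING]])
        assert classify_cross_species(a, b)["locus0"] == "UNAMPLIFIED"

    def test_poly_both_and_one_sided(self):
        a, b = self._pair([[0, 1, 0], [1, 0, 0], [2, 1, 0]], [[0, 0, 0], [1, 0, 0]])
        labels = classify_cross_species(a, b)
        assert labels["locus0"] == "POLY_BOTH"
        assert labels["locus1"] == "POLY_A_ONLY"
        assert labels["locus2"] == "MONO_SHARED"

    def test_disjoint_loci_error(self):
        a = GenotypeMatrix(np.zeros((2, 1), dtype=np.int8), loci=["x"], populations=["p", "p"])
        b = GenotypeMatrix(np.zeros((2, 1), dtype=np.int8), loci=["y"], populations=["p", "p"])
        with pytest.raises(ValueError):
            classify_cross_species(a, b)


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

def amova_distance_oracle(gm: GenotypeMatrix) -> dict:
    """Brute-force sums-of-squared-deviations decomposition via pairwise
    allele-copy mismatch distances, per locus, summed over loci.

    Independent route: explicit O(n^2) pairwise distances rather than the
    mean-square equations.  Returns percentage of variance per stratum for a
    balanced complete-data design.
    """
    g = gm.genotypes
    pops = np.unique(gm.populations)
    regions = np.unique(gm.regions)
    ss_total = ss_wp = ss_ap = 0.0
    df_a = len(regions) - 1
    df_b = len(pops) - len(regions)
    n_tot = 0
    # allele copies per individual: expand genotype to two 0/1 copies
    for j in range(gm.n_loci):
        col = g[:, j]
        copies = []
        labels = []
        rlabels = []
        for i, v in enumerate(col):
            if v == MISSING:
                continue
            copies += [1 if v >= 1 else 0, 1 if v == 2 else 0]
            labels += [gm.populations[i]] * 2
            rlabels += [gm.regions[i]] * 2
        y = np.array(copies, dtype=float)
        labels = np.array(labels)
        rlabels = np.array(rlabels)
        n = len(y)
        d2 = (y[:, None] - y[None, :]) ** 2
        ss_total += d2.sum() / (2 * n)
        for pop in pops:
            m = labels == pop
            ss_wp += d2[np.ix_(m, m)].sum() / (2 * m.sum())
        for reg in regions:
            m = rlabels == reg
            ss_ar_part = d2[np.ix_(m, m)].sum() / (2 * m.sum())
            ss_ap += ss_ar_part
        n_tot += n
    ss_regions = ss_total - ss_ap  # among regions
    ss_pops = ss_ap - ss_wp  # among pops within regions
    # balanced design: equal copies per population
    n_per_pop = n_tot / gm.n_loci / len(pops)
    n_per_region = n_per_pop * len(pops) / len(regions)
    df_c = n_tot / gm.n_loci - len(pops)
    sig_c = ss_wp / (gm.n_loci * df_c)
    sig_b = (ss_pops / (gm.n_loci * df_b) - sig_c) / n_per_pop
    sig_a = (ss_regions / (gm.n_loci * df_a) - sig_c - n_per_pop * sig_b) / n_per_region
    total = sig_a + sig_b + sig_c
    return {
        "among_regions": 100 * sig_a / total,
        "among_pops_within_regions": 100 * sig_b / total,
        "within_pops": 100 * sig_c / total,
    }


class TestAmova:
    def test_panmictic_phi_st_near_zero(self):
        gm, _ = simulate_genotype_matrix(
            PopSimConfig(n_regions=1, pops_per_region=4, inds_per_pop=25, n_loci=150,
                         fst=0.0, missing_rate=0.0, seed=8)
        )
        res = amova(gm, n_perm=99, seed=1)
        assert abs(res.phi["Phi_ST"]) < 0.02
        assert abs(res.percentages["among_pops"]) < 2.0

    def test_single_population_all_within(self):
        gm, _ = simulate_genotype_matrix(
            PopSimConfig(n_regions=1, pops_per_region=1, inds_per_pop=20, n_loci=40,
                         fst=0.0, missing_rate=0.0, seed=2)
        )
        res = amova(gm, n_perm=49, seed=1)
        assert res.percentages["within_pops"] == pytest.approx(100.0)

    def test_two_region_design_matches_distance_oracle(self):
        # regions at allele frequencies 0.2 vs 0.8, pops within region identical
        rng = np.random.default_rng(10)
        n, loci = 20, 80
        blocks = []
        for freq in (0.2, 0.2, 0.8, 0.8):
            blocks.append(rng.binomial(2, freq, size=(n, loci)))
        gm = gm_from_codes(
            np.vstack(blocks),
            populations=["p1"] * n + ["p2"] * n + ["p3"] * n + ["p4"] * n,
            regions=["north"] * (2 * n) + ["south"] * (2 * n),
        )
        res = amova(gm, n_perm=99, seed=4)
        oracle = amova_distance_oracle(gm)
        assert res.percentages["among_regions"] > 30
        for k in res.percentages:
            assert res.percentages[k] == pytest.approx(oracle[k], abs=5.0)

    def test_percentages_sum_to_100_and_pvalues_in_unit_interval(self):
        gm, _ = simulate_genotype_matrix(
            PopSimConfig(n_regions=2, pops_per_region=2, inds_per_pop=10, n_loci=50,
                         fst=0.1, fct=0.1, missing_rate=0.05, seed=6)
        )
        res = amova(gm, n_perm=99, seed=3)
        assert sum(res.percentages.values()) == pytest.approx(100.0, abs=1e-6)
        for p in res.p_values.values():
            assert 0.0 < p <= 1.0


# ---------------------------------------------------------------------------
# Weir-Cockerham theta
# ---------------------------------------------------------------------------

class TestPairwiseFst:
    def test_symmetry(self):
        gm, _ = simulate_genotype_matrix(
            PopSimConfig(n_regions=1, pops_per_region=2, inds_per_pop=15, n_loci=60,
                         fst=0.2, missing_rate=0.02, seed=14)
        )
        assert pairwise_fst(gm, "pop1", "pop2") == pytest.approx(
            pairwise_fst(gm, "pop2", "pop1")
        )

    def test_identical_frequencies_near_zero(self):
        rng = np.random.default_rng(9)
        g = rng.binomial(2, 0.4, size=(200, 100)).astype(np.int8)
        gm = gm_from_codes(g, ["a"] * 100 + ["b"] * 100)
        assert abs(pairwise_fst(gm, "a", "b")) < 0.02

    def test_recovers_design_differentiation(self):
        for design in (0.05, 0.2, 0.44):
            gm, _ = simulate_genotype_matrix(
                PopSimConfig(n_regions=1, pops_per_region=2, inds_per_pop=20,
                             n_loci=300, fst=design, missing_rate=0.0,
                             seed=int(design * 1000))
            )
            theta = pairwise_fst(gm, "pop1", "pop2")
            assert theta == pytest.approx(design, abs=0.05)

    def test_no_shared_polymorphic_loci_raises(self):
        gm = gm_from_codes(np.zeros((10, 3), dtype=np.int8), ["a"] * 5 + ["b"] * 5)
        with pytest.raises(ValueError):
            pairwise_fst(gm, "a", "b")


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------

class TestMantel:
    def test_identical_matrices_perfect_correlation(self):
        d = np.abs(np.subtract.outer(np.arange(6.0), np.arange(6.0)))
        res = mantel_test(d, d, n_perm=999, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p_value < 0.02

    def test_matches_scikit_bio(self):
        skbio_mantel = pytest.importorskip("skbio.stats.distance").mantel
        from skbio import DistanceMatrix

        rng = np.random.default_rng(2)
        n = 12
        a = rng.random((n, n)); a = (a + a.T) / 2; np.fill_diagonal(a, 0)
        b = a + rng.normal(0, 0.1, (n, n)); b = (b + b.T) / 2; np.fill_diagonal(b, 0)
        b = np.abs(b)
        ours = mantel_test(a, b, n_perm=999, seed=5)
        r_ref, p_ref, _ = skbio_mantel(
            DistanceMatrix(a), DistanceMatrix(b), method="pearson",
            permutations=999, alternative="greater",
        )
        assert ours.r == pytest.approx(r_ref, abs=1e-9)
        assert abs(ours.p_value - p_ref) < 0.02

    def test_small_matrix_rejected(self):
        d = np.zeros((3, 3))
        with pytest.raises(ValueError):
            mantel_test(d, d, n_perm=99, seed=0)

    def test_label_alignment(self):
        d = np.abs(np.subtract.outer(np.arange(5.0), np.arange(5.0)))
        labels = ["a", "b", "c", "d", "e"]
        df1 = pd.DataFrame(d, index=labels, columns=labels)
        shuffled = ["c", "a", "e", "b", "d"]
        df2 = df1.loc[shuffled, shuffled]
        res = mantel_test(df2, df1, n_perm=499, seed=1)
        assert res.r == pytest.approx(1.0)

    def test_fst_matrix_symmetric_zero_diagonal(self):
        gm, _ = simulate_genotype_matrix(
            PopSimConfig(n_regions=1, pops_per_region=3, inds_per_pop=12, n_loci=50,
                         fst=0.1, missing_rate=0.0, seed=21)
        )
        m = fst_matrix(gm)
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 0.0)
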