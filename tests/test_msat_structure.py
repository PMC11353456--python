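import itertools
import math

import numpy as np
import pytest

from riverpopgen.datatypes import MISSING, PopulationAssignment
from riverpopgen.msat_structure import (
    _enumerate_hwe_p,
    _genotype_table,
    _mcmc_hwe_p,
    assign_individuals,
    exact_differentiation,
    fishers_method,
    fstats,
    hwe_tests,
    msat_diversity,
    nei_distance,
    private_allele_nm,
    robertson_hill_f,
    unbiased_he,
)

from conftest import make_genotypes


def _popmap(gm):
    return PopulationAssignment(
        dict(zip(gm.sample_ids, gm.populations)),
        {p: (0.0, 0.0) for p in set(gm.populations)},
    )


# ---------------------------------------------------------------------------
# diversity


def test_monomorphic_locus():
    gm = make_genotypes([[(5, 5)], [(5, 5)], [(5, 5)]], ["A"] * 3)
    res = msat_diversity(gm, _popmap(gm))
    assert res.alleles_per_locus["L1"] == 1
    assert res.he_per_locus["L1"] == pytest.approx(0.0)


def test_single_heterozygote_unbiased_he():
    gm = make_genotypes([[(4, 6)]], ["A"])
    res = msat_diversity(gm, _popmap(gm))
    assert res.ho_per_locus["L1"] == pytest.approx(1.0)
    # 2n = 2: unbiased He = 2/(2-1) * (1 - 0.5) = 1.0
    assert res.he_per_locus["L1"] == pytest.approx(1.0)


def test_diversity_matches_counting_oracle():
    rng = np.random.default_rng(1)
    genos = [
        [(int(a), int(b)) for a, b in rng.integers(3, 7, (2, 2))]
        for _ in range(10)
    ]
    gm = make_genotypes(genos, ["A"] * 5 + ["B"] * 5)
    res = msat_diversity(gm, _popmap(gm))
    for li, locus in enumerate(gm.loci):
        flat = [x for g in genos for x in g[li]]
        vals, counts = np.unique(flat, return_counts=True)
        n2 = len(flat)
        p2 = np.sum((counts / n2) ** 2)
        assert res.he_per_locus[locus] == pytest.approx(
            n2 / (n2 - 1) * (1 - p2)
        )
        het = np.mean([g[li][0] != g[li][1] for g in genos])
        assert res.ho_per_locus[locus] == pytest.approx(het)
        assert res.alleles_per_locus[locus] == len(vals)


def test_unbiased_he_at_least_plugin():
    rng = np.random.default_rng(0)
    for _ in range(20):
        counts = {i: int(c) for i, c in enumerate(rng.integers(1, 10, 4))}
        n2 = sum(counts.values())
        p2 = sum((c / n2) ** 2 for c in counts.values())
        assert unbiased_he(counts) >= (1 - p2) - 1e-12


# ---------------------------------------------------------------------------
# Hardy-Weinberg


def test_robertson_hill_f_hwe_proportions():
    genos = [[(1, 1)]] * 25 + [[(1, 2)]] * 50 + [[(2, 2)]] * 25
    gm = make_genotypes(genos, ["A"] * 100)
    assert robertson_hill_f(gm.alleles[:, 0, :]) == pytest.approx(0.0)


def test_robertson_hill_f_all_homozygotes():
    genos = [[(1, 1)]] * 5 + [[(2, 2)]] * 5
    gm = make_genotypes(genos, ["A"] * 10)
    assert robertson_hill_f(gm.alleles[:, 0, :]) == pytest.approx(1.0)


def test_hwe_mcmc_within_3se_of_enumeration():
    # a 3-allele, n = 10 genotype table
    genos = (
        [[(1, 1)]] * 2 + [[(1, 2)]] * 2 + [[(2, 2)]] * 2
        + [[(2, 3)]] * 2 + [[(3, 3)]] * 1 + [[(1, 3)]] * 1
    )
    gm = make_genotypes(genos, ["A"] * 10)
    table = _genotype_table(gm.alleles[:, 0, :])
    p_exact = _enumerate_hwe_p(table)
    p_mcmc, se = _mcmc_hwe_p(table, 2000, 20, 2000, seed=4)
    assert abs(p_mcmc - p_exact) <= max(3 * se, 0.02)


def test_hwe_all_homozygote_small_p_and_fisher_df():
    genos = [[(1, 1), (1, 1)]] * 6 + [[(2, 2), (2, 2)]] * 6
    gm = make_genotypes(genos, ["A"] * 12)
    res = hwe_tests(gm, _popmap(gm), mcmc=(500, 10, 200), seed=0)
    for locus in gm.loci:
        assert res.p[(locus, "A")] < 0.01
        assert res.rh_f[locus] == pytest.approx(1.0)
    chi2, df, p = res.fisher_global
    assert df == 2 * 2  # two combined valid tests -> df is twice the count


def test_fishers_method_skips_undefined():
    chi2, df, p = fishers_method([0.5, np.nan, 0.1])
    assert df == 4
    assert chi2 == pytest.approx(-2 * (math.log(0.5) + math.log(0.1)))


# ---------------------------------------------------------------------------
# F-statistics


def test_fst_zero_for_identical_frequencies():
    genos = [[(1, 2)]] * 20
    gm = make_genotypes(genos, ["A"] * 10 + ["B"] * 10)
    res = fstats(gm, _popmap(gm), randomizations=50, seed=0)
    assert res.multilocus[1] == pytest.approx(0.0, abs=1e-9)


def test_fst_one_for_fixed_differences():
    genos = [[(1, 1)]] * 8 + [[(9, 9)]] * 8
    gm = make_genotypes(genos, ["A"] * 8 + ["B"] * 8)
    res = fstats(gm, _popmap(gm), randomizations=100, seed=0)
    assert res.multilocus[1] == pytest.approx(1.0)
    assert res.pairwise_nm[0, 1] == pytest.approx(0.0)
    assert res.g_test_p < 0.05


def test_merged_identical_population_fst_zero():
    rng = np.random.default_rng(3)
    genos = [
        [(int(a), int(b)) for a, b in rng.integers(2, 8, (3, 2))]
        for _ in range(12)
    ]
    # population B is a copy of A's genotypes
    gm = make_genotypes(genos + genos, ["A"] * 12 + ["B"] * 12)
    res = fstats(gm, _popmap(gm), randomizations=10, seed=0)
    assert res.pairwise_fst[0, 1] == pytest.approx(0.0, abs=0.05)


# ---------------------------------------------------------------------------
# Nei distance


def test_nei_distance_identical_and_disjoint():
    genos = [[(1, 2)]] * 10
    gm = make_genotypes(genos, ["A"] * 5 + ["B"] * 5)
    pops, D = nei_distance(gm, _popmap(gm))
    assert D[0, 1] == pytest.approx(0.0, abs=1e-9)
    genos = [[(1, 1)]] * 4 + [[(9, 9)]] * 4
    gm = make_genotypes(genos, ["A"] * 4 + ["B"] * 4)
    pops, D = nei_distance(gm, _popmap(gm))
    assert math.isinf(D[0, 1])


def test_nei_distance_two_locus_hand_example():
    # pop A: L1 all (1,1), L2 all (1,2); pop B: L1 all (1,2), L2 all (2,2)
    genos_a = [[(1, 1), (1, 2)]] * 4
    genos_b = [[(1, 2), (2, 2)]] * 4
    gm = make_genotypes(genos_a + genos_b, ["A"] * 4 + ["B"] * 4)
    pops, D = nei_distance(gm, _popmap(gm))
    n2 = 8.0

    def unb(p2):
        return (n2 * p2 - 1) / (n2 - 1)

    jx = (unb(1.0) + unb(0.5)) / 2
    jy = (unb(0.5) + unb(1.0)) / 2
    jxy = ((1.0 * 0.5 + 0.0 * 0.5) + (0.5 * 0.0 + 0.5 * 1.0)) / 2
    expected = -math.log(jxy / math.sqrt(jx * jy))
    assert D[0, 1] == pytest.approx(expected)


# ---------------------------------------------------------------------------
# exact differentiation


def test_exact_differentiation_identical_pops():
    genos = [[(1, 2)]] * 12
    gm = make_genotypes(genos, ["A"] * 6 + ["B"] * 6)
    per_locus, combined = exact_differentiation(gm, _popmap(gm), "genic", seed=0)
    assert per_locus["L1"] == pytest.approx(1.0)


def test_exact_differentiation_fixed_difference():
    genos = [[(1, 1)]] * 6 + [[(9, 9)]] * 6
    gm = make_genotypes(genos, ["A"] * 6 + ["B"] * 6)
    # genic: 12 vs 12 gene copies; exact p = 2 * 12!^2 / 24!
    per_locus, combined = exact_differentiation(gm, _popmap(gm), "genic", seed=0)
    assert per_locus["L1"] == pytest.approx(7.396023e-07, rel=1e-4)
    assert combined[2] < 0.001
    # genotypic: 6 vs 6 individuals; exact p = 2 / C(12, 6)
    per_locus, combined = exact_differentiation(
        gm, _popmap(gm), "genotypic", seed=0
    )
    assert per_locus["L1"] == pytest.approx(2 / 924)
    assert combined[2] < 0.01


def test_bonferroni_threshold_arithmetic():
    # 28 pairwise tests at family alpha 0.05 -> per-test 0.0018
    assert 0.05 / 28 == pytest.approx(0.00179, abs=1e-5)


# ---------------------------------------------------------------------------
# private alleles


def test_private_alleles_absent_flagged():
    genos = [[(1, 2)]] * 8
    gm = make_genotypes(genos, ["A"] * 4 + ["B"] * 4)
    nm, p1, k = private_allele_nm(gm, _popmap(gm))
    assert k == 0 and np.isnan(nm)


def test_private_allele_high_frequency_gives_small_nm():
    # pop A privately owns allele 9 at high frequency
    genos_a = [[(9, 9)]] * 6
    genos_b = [[(1, 2)]] * 6
    gm = make_genotypes(genos_a + genos_b, ["A"] * 6 + ["B"] * 6)
    nm_high, p1_high, _ = private_allele_nm(gm, _popmap(gm))
    # lower private frequency -> larger Nm (monotone regression)
    genos_a2 = [[(9, 1)]] + [[(1, 2)]] * 5
    gm2 = make_genotypes(genos_a2 + genos_b, ["A"] * 6 + ["B"] * 6)
    nm_low, p1_low, _ = private_allele_nm(gm2, _popmap(gm2))
    assert p1_high > p1_low
    assert nm_high < nm_low


def test_private_allele_single_population_error():
    gm = make_genotypes([[(1, 2)]] * 4, ["A"] * 4)
    with pytest.raises(ValueError):
        private_allele_nm(gm, _popmap(gm))


# ---------------------------------------------------------------------------
# assignment


def test_assignment_to_diagnostic_population():
    genos_a = [[(1, 1), (3, 3)]] * 5
    genos_b = [[(9, 9), (7, 7)]] * 5
    focal = [[(1, 1), (3, 3)]]  # carries only A alleles but lives in B
    gm = make_genotypes(
        genos_a + focal + genos_b, ["A"] * 5 + ["B"] * 6
    )
    res = assign_individuals(gm, _popmap(gm), exclusion_sims=200, seed=0)
    assert res.assigned[5] == "A"
    assert res.L_ratio[5] < 1.0


def test_resident_of_only_population_has_l_ratio_one():
    gm = make_genotypes([[(1, 2)], [(2, 2)], [(1, 1)]], ["A"] * 3)
    res = assign_individuals(gm, _popmap(gm), exclusion_sims=100, seed=0)
    assert np.allclose(res.L_ratio, 1.0)


def test_leave_one_out_matches_recount_oracle():
    rng = np.random.default_rng(5)
    genos = [
        [(int(a), int(b)) for a, b in rng.integers(1, 5, (2, 2))]
        for _ in range(8)
    ]
    gm = make_genotypes(genos, ["A"] * 4 + ["B"] * 4)
    res = assign_individuals(gm, _popmap(gm), exclusion_sims=50, seed=0)
    # recompute individual 0's home likelihood from scratch without it
    sub = 0.01
    ll = 0.0
    for li in range(2):
        flat = [x for g in genos[1:4] for x in g[li]]
        vals, counts = np.unique(flat, return_counts=True)
        freqs = dict(zip(vals.tolist(), (counts / len(flat)).tolist()))
        a, b = sorted(genos[0][li])
        fa = freqs.get(a, 0) or sub
        fb = freqs.get(b, 0) or sub
        ll += math.log(fa * fb if a == b else 2 * fa * fb)
    home_idx = res.populations.index("A")
    assert res.log_likelihoods[0, home_idx] == pytest.approx(ll)


def test_assignment_invariant_to_locus_and_individual_order():
    rng = np.random.default_rng(6)
    genos = [
        [(int(a), int(b)) for a, b in rng.integers(1, 4, (3, 2))]
        for _ in range(10)
    ]
    pops = ["A"] * 5 + ["B"] * 5
    gm = make_genotypes(genos, pops)
    res = assign_individuals(gm, _popmap(gm), exclusion_sims=10, seed=0)
    # permute loci
    perm = [2, 0, 1]
    genos_p = [[g[i] for i in perm] for g in genos]
    gm2 = make_genotypes(genos_p, pops, loci=[f"L{i + 1}" for i in perm])
    res2 = assign_individuals(gm2, _popmap(gm2), exclusion_sims=10, seed=0)
    assert np.allclose(res.log_likelihoods, res2.log_likelihoods)
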