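import math

import numpy as np
import pytest

from riverpopgen.coalescent import sim_microsat_locus
from riverpopgen.datatypes import GenotypeMatrix
from riverpopgen.msat_demography import (
    gw_m_ratio,
    gw_null_distribution,
    kimmel_beta,
    reich_g_test,
    reich_k_test,
    unbiased_fourth_moment,
    unbiased_variance,
    zhivotovsky_sk,
)
from riverpopgen.simulate import SimulationConfig, simulate_microsatellites

from conftest import make_genotypes


def equilibrium_gm(rng, theta=5.0, n_loci=10, n_ind=30, p_s=1.0):
    arr = np.zeros((n_ind, n_loci, 2), dtype=np.int64)
    for l in range(n_loci):
        a = sim_microsat_locus(2 * n_ind, theta, rng, p_s=p_s)
        arr[:, l, 0] = a[:n_ind]
        arr[:, l, 1] = a[n_ind:]
    loci = tuple(f"L{l}" for l in range(n_loci))
    return GenotypeMatrix(
        tuple(f"i{k}" for k in range(n_ind)), loci, arr, {l: 2 for l in loci}
    )


def bottleneck_gm(seed, crash_factor=0.02, t_crash=50.0, t_end=2000.0):
    cfg = SimulationConfig(
        seed=seed,
        sites=[("one", 0.0, 0.0, 2)],
        edges=[],
        ne=2000.0,
        msat_sample_sizes=[30],
        msat_mut_rate=1e-3,
        history=[(t_crash, crash_factor), (t_end, 1.0)],
    )
    return simulate_microsatellites(cfg)


# ---------------------------------------------------------------------------
# M ratio


def test_m_ratio_direct_arithmetic():
    gm = make_genotypes(
        [[(50, 50), (30, 30), (7, 7)], [(52, 52), (36, 36), (8, 8)],
         [(50, 52), (30, 36), (9, 9)]],
        ["A"] * 3,
    )
    res = gw_m_ratio(gm)
    assert res.per_locus["L1"] == pytest.approx(2 / 3)     # {50, 52}
    assert res.per_locus["L2"] == pytest.approx(2 / 7)     # {30, 36}
    assert res.per_locus["L3"] == pytest.approx(1.0)       # {7, 8, 9}: k = r
    assert res.mean_m == pytest.approx((2 / 3 + 2 / 7 + 1.0) / 3)


def test_m_ratio_monomorphic_convention():
    gm = make_genotypes([[(5, 5)], [(5, 5)]], ["A"] * 2)
    res = gw_m_ratio(gm)
    assert res.per_locus["L1"] == 1.0
    assert res.monomorphic == ["L1"]


def test_m_ratio_scale_invariant_to_repeat_units():
    # same data expressed in bp/2 vs directly in repeats
    gm1 = make_genotypes([[(25, 26)], [(26, 28)]], ["A"] * 2)
    gm2 = make_genotypes([[(25, 26)], [(26, 28)]], ["A"] * 2)
    assert gw_m_ratio(gm1).mean_m == gw_m_ratio(gm2).mean_m


def test_gw_null_low_theta_mean_one():
    null = gw_null_distribution(0.01, 1.0, 3.5, 20, reps=300, seed=1)
    assert null.mean > 0.97


def test_gw_null_multistep_lowers_m():
    n1 = gw_null_distribution(3.0, 1.0, 3.5, 40, reps=400, seed=2)
    n2 = gw_null_distribution(3.0, 0.8, 3.5, 40, reps=400, seed=3)
    assert n1.mean > n2.mean


def test_gw_null_mean_monotone_in_theta():
    means = [
        gw_null_distribution(th, 0.9, 3.5, 30, reps=300, seed=4).mean
        for th in (0.5, 2.0, 8.0)
    ]
    assert means[0] > means[1] > means[2]


def test_gw_null_domain_checks():
    with pytest.raises(ValueError):
        gw_null_distribution(-1.0, 0.9, 3.5, 10)
    with pytest.raises(ValueError):
        gw_null_distribution(1.0, 0.0, 3.5, 10)


# ---------------------------------------------------------------------------
# imbalance index


def test_beta_undefined_for_monomorphic_data():
    gm = make_genotypes([[(5, 5), (7, 7)], [(5, 5), (7, 7)]], ["A"] * 2)
    res = kimmel_beta(gm)
    assert not res.defined


def test_beta_equilibrium_centered_on_zero():
    rng = np.random.default_rng(10)
    lnb = [kimmel_beta(equilibrium_gm(rng)).ln_beta for _ in range(60)]
    assert abs(np.nanmean(lnb)) < 0.25


def test_beta_exceeds_one_after_bottleneck_and_recovery():
    betas = [kimmel_beta(bottleneck_gm(seed)).beta for seed in range(15)]
    assert np.nanmedian(betas) > 1.0


def test_beta_invariant_to_allele_size_shift():
    rng = np.random.default_rng(3)
    gm = equilibrium_gm(rng, n_ind=20)
    shifted = GenotypeMatrix(
        gm.sample_ids, gm.loci, gm.alleles + 7, gm.repeat_units
    )
    assert kimmel_beta(shifted).beta == pytest.approx(kimmel_beta(gm).beta)


# ---------------------------------------------------------------------------
# S_k expansion index


def test_sk_hand_computation_two_allele_locus():
    # both loci: alleles 10 and 11, one repeat apart, balanced
    genos = [[(10, 10), (10, 11)], [(11, 11), (10, 11)],
             [(10, 11), (10, 10)], [(10, 11), (11, 11)]]
    gm = make_genotypes(genos, ["A"] * 4)
    res = zhivotovsky_sk(gm, r_k=6.3)
    sizes = np.array([10.0, 10, 10, 11, 11, 11, 10, 11])  # locus 1 copies
    v = unbiased_variance(sizes)
    k4 = unbiased_fourth_moment(sizes)
    # both loci have identical allele-size multisets
    expected = 1 - (k4 - 6.3 * v / 2) / (5 * v**2)
    assert res.s_k == pytest.approx(expected)
    # identical loci leave no between-locus spread: jackknife t undefined
    assert res.jackknife_se == 0.0


def test_sk_equilibrium_near_zero():
    # many loci keep the finite-locus positive bias of the plug-in V^2 small
    rng = np.random.default_rng(21)
    sks = [
        zhivotovsky_sk(
            equilibrium_gm(rng, n_loci=40, n_ind=50), r_k=1.0
        ).s_k
        for _ in range(40)
    ]
    assert abs(np.nanmean(sks)) < 0.15


def test_sk_negative_with_depressed_v_after_bottleneck():
    res = [zhivotovsky_sk(bottleneck_gm(seed, t_crash=20.0)) for seed in range(15)]
    sks = [r.s_k for r in res if r.defined]
    assert np.nanmedian(sks) < 0.0


def test_sk_invariant_to_allele_size_shift():
    rng = np.random.default_rng(8)
    gm = equilibrium_gm(rng, n_ind=20)
    shifted = GenotypeMatrix(
        gm.sample_ids, gm.loci, gm.alleles + 11, gm.repeat_units
    )
    assert zhivotovsky_sk(shifted).s_k == pytest.approx(
        zhivotovsky_sk(gm).s_k
    )


# ---------------------------------------------------------------------------
# Reich k and g


def test_reich_k_binomial_equals_mass_summation():
    res_p = reich_k_test(
        make_genotypes(
            [[(10 + i % 3, 10 + (i + j) % 4) for j in range(10)]
             for i in range(12)],
            ["A"] * 12,
        )
    )
    # oracle: exhaustive summation of the binomial mass function
    n, npos, q = res_p.n_polymorphic, res_p.n_positive, res_p.p_pos
    mass = sum(
        math.comb(n, k) * q**k * (1 - q) ** (n - k) for k in range(npos + 1)
    )
    assert res_p.binomial_p == pytest.approx(mass)


def test_reich_k_monomorphic_loci_excluded():
    genos = [[(5, 5), (10, 11)], [(5, 5), (11, 12)], [(5, 5), (10, 12)],
             [(5, 5), (11, 11)]]
    gm = make_genotypes(genos, ["A"] * 4)
    res = reich_k_test(gm)
    assert res.n_polymorphic == 1


def test_reich_g_equal_variances_minimal():
    # two loci with identical allele-size multisets -> interlocus variance 0
    genos = [[(10, 12), (20, 22)], [(11, 11), (21, 21)], [(12, 10), (22, 20)],
             [(11, 12), (21, 22)]]
    gm = make_genotypes(genos, ["A"] * 4)
    res = reich_g_test(gm, seed=0, reps=200)
    assert res.g == pytest.approx(0.0)
    assert res.p < 0.5  # only null ties at exactly zero spread can match


def test_reich_g_tabulated_not_available():
    gm = make_genotypes([[(10, 12)], [(11, 11)]], ["A"] * 2)
    with pytest.raises(ValueError):
        reich_g_test(gm, cutoff_source="tabulated")


def test_reich_g_expansion_power_exceeds_size():
    """Expansion compresses the spread of per-locus variances, so the g
    test rejects more often than its 5% size."""
    rej = 0
    for seed in range(12):
        cfg = SimulationConfig(
            seed=seed,
            sites=[("one", 0.0, 0.0, 2)],
            edges=[],
            ne=5000.0,
            msat_sample_sizes=[25],
            msat_mut_rate=2e-4,
            history=[(80.0, 0.002)],
        )
        gm = simulate_microsatellites(cfg)
        res = reich_g_test(gm, seed=seed, reps=150)
        if res.defined and res.p < 0.05:
            rej += 1
    assert rej / 12 > 0.05
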