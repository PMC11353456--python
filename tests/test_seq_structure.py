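import itertools
import math

import numpy as np
import pytest

from riverpopgen.datatypes import HaplotypeAlignment, PopulationAssignment
from riverpopgen.seq_structure import (
    amova,
    enumerate_exact_p,
    haplotype_contingency,
    hudson_heterogeneity,
    islandmodel_nm,
    kimura2p_matrix,
    kimura2p_pair,
    mcmc_exact_p,
    pairwise_differences,
    pairwise_exact_tests,
)


def _aln(seqs, pops):
    ids = tuple(f"s{i}" for i in range(len(seqs)))
    aln = HaplotypeAlignment(ids, tuple(seqs))
    popmap = PopulationAssignment(
        dict(zip(ids, pops)),
        {p: (0.0, float(hash(p) % 7)) for p in set(pops)},
    )
    return aln, popmap


# ---------------------------------------------------------------------------
# island model


def test_islandmodel_nm_printed_conversions():
    assert round(islandmodel_nm(0.3771, "haploid"), 2) == 0.83
    assert round(islandmodel_nm(0.2504, "haploid"), 2) == 1.50
    assert round(islandmodel_nm(0.2509, "haploid"), 2) == 1.49


def test_islandmodel_nm_limits_and_modes():
    assert islandmodel_nm(0.5, "haploid") == pytest.approx(0.5)
    assert math.isinf(islandmodel_nm(0.0))
    assert islandmodel_nm(1.0) == 0.0
    assert islandmodel_nm(0.2, "diploid") == pytest.approx(1.0)
    with pytest.raises(ValueError):
        islandmodel_nm(1.2)


def test_islandmodel_nm_monotone_and_invertible():
    fs = np.linspace(0.01, 1.0, 50)
    nms = [islandmodel_nm(f) for f in fs]
    assert all(a > b for a, b in zip(nms, nms[1:]))
    for f in (0.05, 0.3, 0.9):
        nm = islandmodel_nm(f)
        assert 1.0 / (1.0 + 2.0 * nm) == pytest.approx(f)


# ---------------------------------------------------------------------------
# Kimura 2P


def test_kimura2p_closed_form_and_identity():
    assert kimura2p_pair(0.0, 0.0) == 0.0
    assert kimura2p_pair(0.10, 0.05) == pytest.approx(0.1702, abs=1e-4)
    assert np.isnan(kimura2p_pair(0.5, 0.2))  # saturated


def test_kimura2p_net_distance_zero_on_self():
    seqs = ["AAAAAAAAAA", "AAAAAAAAAG", "AAAATAAAAG", "AAAATAAAAA"]
    aln, popmap = _aln(seqs, ["A", "A", "B", "B"])
    res = kimura2p_matrix(aln, popmap)
    assert np.allclose(np.diag(res.d_net), 0.0)
    assert np.allclose(res.d_between, res.d_between.T, equal_nan=True)


# ---------------------------------------------------------------------------
# contingency and exact tests


def test_contingency_df_and_null():
    # 15 haplotypes x 10 populations -> df = 126
    rng = np.random.default_rng(0)
    haps = ["".join(rng.choice(list("ACGT"), 12)) for _ in range(15)]
    seqs, pops = [], []
    for p in range(10):
        for h in range(15):
            seqs.append(haps[h])
            pops.append(f"P{p}")
    aln, popmap = _aln(seqs, pops)
    chi2, df, p = haplotype_contingency(aln, popmap)
    assert df == 126
    # identical distributions in every population -> chi2 = 0
    assert chi2 == pytest.approx(0.0)


def test_exact_enumeration_fixed_table():
    # [[5,0],[0,5]]: only the two extreme tables are as improbable
    p = enumerate_exact_p(np.array([[5, 0], [0, 5]]))
    assert p == pytest.approx(2 / 252)


def test_mcmc_tracks_enumeration():
    table = np.array([[5, 0], [0, 5]])
    p_exact = enumerate_exact_p(table)
    p, se = mcmc_exact_p(table, 2000, 20, 1000, seed=1)
    assert abs(p - p_exact) <= max(3 * se, 0.01)


def test_pairwise_exact_identical_pops_and_determinism():
    seqs = ["AAAA"] * 6
    aln, popmap = _aln(seqs, ["A", "A", "A", "B", "B", "B"])
    res = pairwise_exact_tests(aln, popmap, seed=3)
    assert res.exact_p[0, 1] == pytest.approx(1.0)
    res2 = pairwise_exact_tests(aln, popmap, seed=3)
    assert np.array_equal(res.exact_p, res2.exact_p, equal_nan=True)


# ---------------------------------------------------------------------------
# Hudson statistics vs enumeration oracle


def _oracle_kst(d, labels):
    """Independent K_ST implementation: weighted within vs total mean."""
    labels = np.asarray(labels)
    n = len(labels)
    pairs = list(itertools.combinations(range(n), 2))
    kt = np.mean([d[i, j] for i, j in pairs])
    ks = 0.0
    for pop in np.unique(labels):
        members = np.flatnonzero(labels == pop)
        within = [d[i, j] for i, j in itertools.combinations(members, 2)]
        ks += len(members) / n * np.mean(within)
    return 1.0 - ks / kt


def test_hudson_statistics_match_enumeration_oracle():
    seqs = [
        "AAAAAAAA",
        "AAAAAAAT",
        "TTTTAAAA",
        "TTTTAAAT",
    ]
    labels = ["A", "A", "B", "B"]
    aln, popmap = _aln(seqs, labels)
    d = pairwise_differences(aln)
    res = hudson_heterogeneity(aln, popmap, perms=3000, seed=5)
    assert res.statistics["K_ST"] == pytest.approx(_oracle_kst(d, labels))
    # exact permutation p by full enumeration of the 4!/(2!2!) label splits
    obs = _oracle_kst(d, labels)
    exceed = total = 0
    for combo in itertools.combinations(range(4), 2):
        perm = np.array(["B"] * 4)
        perm[list(combo)] = "A"
        total += 1
        if _oracle_kst(d, perm) >= obs - 1e-12:
            exceed += 1
    p_exact = exceed / total
    assert res.p_values["K_ST"] == pytest.approx(p_exact, abs=0.03)
    # S_nn by hand: every sequence's nearest neighbour is its own pop mate
    assert res.statistics["S_nn"] == pytest.approx(1.0)


def test_hudson_null_split_statistics_near_zero():
    rng = np.random.default_rng(2)
    base = list("ACGT" * 5)
    seqs = []
    for _ in range(12):
        s = base.copy()
        pos = rng.integers(0, 20, 3)
        for p in pos:
            s[p] = rng.choice(list("ACGT"))
        seqs.append("".join(s))
    aln, popmap = _aln(seqs, ["A"] * 6 + ["B"] * 6)
    res = hudson_heterogeneity(aln, popmap, perms=300, seed=7)
    assert abs(res.statistics["K_ST"]) < 0.2
    assert res.p_values["K_ST"] > 0.05


def test_fixed_difference_pops_maximal_kst():
    seqs = ["AAAAAAAAAA"] * 3 + ["TTTTTAAAAA"] * 3
    labels = ["A"] * 3 + ["B"] * 3
    aln, popmap = _aln(seqs, labels)
    res = hudson_heterogeneity(aln, popmap, perms=2000, seed=9)
    assert res.statistics["K_ST"] == pytest.approx(1.0)  # no within variation
    # exact enumeration: 2 of C(6,3)=20 label splits recreate the partition
    assert res.p_values["K_ST"] == pytest.approx(0.1, abs=0.025)


def test_permutation_p_never_zero(toy_alignment, toy_popmap):
    res = hudson_heterogeneity(toy_alignment, toy_popmap, perms=50, seed=0)
    for p in res.p_values.values():
        assert not np.isfinite(p) or p > 0


# ---------------------------------------------------------------------------
# AMOVA


def _amova_input(seqs, pops):
    return _aln(seqs, pops)


def test_amova_identical_sequences_zero_components():
    aln, popmap = _amova_input(
        ["ACGTACGT"] * 8, ["A", "A", "B", "B", "C", "C", "D", "D"]
    )
    res = amova(
        aln, popmap, {"A": "g1", "B": "g1", "C": "g2", "D": "g2"},
        perms=50, seed=0,
    )
    for v in res.variance_components.values():
        assert v == pytest.approx(0.0, abs=1e-12)


def test_amova_fixed_groups_all_variance_among_groups():
    seqs = ["AAAAAAAA"] * 4 + ["TTTTTTTT"] * 4
    pops = ["A", "A", "B", "B", "C", "C", "D", "D"]
    aln, popmap = _amova_input(seqs, pops)
    res = amova(
        aln, popmap, {"A": "g1", "B": "g1", "C": "g2", "D": "g2"},
        perms=100, seed=0,
    )
    assert res.percentages["among_groups"] == pytest.approx(100.0, abs=1e-6)
    assert res.phi["phi_CT"] == pytest.approx(1.0)


def test_amova_components_match_matrix_oracle():
    rng = np.random.default_rng(4)
    seqs = []
    for _ in range(8):
        seqs.append("".join(rng.choice(list("ACGT"), 16)))
    pops = ["A", "A", "B", "B", "C", "C", "D", "D"]
    grouping = {"A": "g1", "B": "g1", "C": "g2", "D": "g2"}
    aln, popmap = _amova_input(seqs, pops)
    res = amova(aln, popmap, grouping, perms=10, seed=0)

    # independent dense evaluation of the nested decomposition
    d2 = pairwise_differences(aln) ** 2
    labels = popmap.labels_for(aln.sample_ids)
    groups = [grouping[l] for l in labels]

    def ssd(idx):
        idx = list(idx)
        tot = 0.0
        for i in idx:
            for j in idx:
                tot += d2[i, j]
        return tot / (2 * len(idx))

    N = 8
    ssd_total = ssd(range(N))
    ssd_wp = sum(
        ssd([i for i in range(N) if labels[i] == p]) for p in "ABCD"
    )
    ssd_wg = sum(
        ssd([i for i in range(N) if groups[i] == g]) for g in ("g1", "g2")
    )
    assert res.ssd["within_pops"] == pytest.approx(ssd_wp)
    assert res.ssd["among_groups"] == pytest.approx(ssd_total - ssd_wg)
    assert res.ssd["among_pops_within_groups"] == pytest.approx(
        ssd_wg - ssd_wp
    )
    # percentages sum to 100
    assert sum(res.percentages.values()) == pytest.approx(100.0, abs=1e-9)
    # variance components from the oracle's expected mean squares
    msd_wp = ssd_wp / (N - 4)
    assert res.variance_components["within_pops"] == pytest.approx(msd_wp)
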