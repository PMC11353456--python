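import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riverpopgen.datatypes import HaplotypeAlignment, PopulationAssignment
from riverpopgen.spatial import (
    DistanceClassScheme,
    aida_autocorrelation,
    ay_correlogram,
    distogram,
    geo_distance_matrix,
    great_circle_km,
    gregorius_distance,
    landscape_idw,
    mantel_test,
    shared_haplotype_proportion,
)


# ---------------------------------------------------------------------------
# geographic distances


def test_geo_distance_self_zero_and_symmetry():
    popmap = PopulationAssignment(
        {"a": "P1", "b": "P2"},
        {"P1": (-14.5, -65.0), "P2": (-12.0, -65.1)},
    )
    pops, d = geo_distance_matrix(popmap)
    assert d[0, 0] == 0.0
    assert d[0, 1] == d[1, 0] > 0


def test_river_network_distance_additive():
    popmap = PopulationAssignment(
        {"a": "P1", "b": "P2", "c": "P3"},
        {"P1": (0.0, 0.0), "P2": (0.0, 0.1), "P3": (0.0, 0.2)},
    )
    net = [("P1", "P2", 10.0), ("P2", "P3", 10.0)]
    pops, d = geo_distance_matrix(popmap, "river_network", net)
    assert d[pops.index("P1"), pops.index("P3")] == pytest.approx(20.0)


def test_river_distance_dominates_great_circle():
    rng = np.random.default_rng(0)
    for _ in range(10):
        coords = {f"P{i}": (float(rng.uniform(-2, 2)), float(rng.uniform(-2, 2)))
                  for i in range(5)}
        popmap = PopulationAssignment(
            {f"s{i}": f"P{i}" for i in range(5)}, coords
        )
        # river network: a random spanning path weighted by great circles
        order = rng.permutation(5)
        net = []
        for a, b in zip(order, order[1:]):
            la1, lo1 = coords[f"P{a}"]
            la2, lo2 = coords[f"P{b}"]
            net.append((f"P{a}", f"P{b}", great_circle_km(la1, lo1, la2, lo2)))
        pops, d_river = geo_distance_matrix(popmap, "river_network", net)
        _, d_gc = geo_distance_matrix(popmap)
        assert np.all(d_river >= d_gc - 1e-9)


def test_river_network_unreachable_pair_raises():
    popmap = PopulationAssignment(
        {"a": "P1", "b": "P2"}, {"P1": (0, 0), "P2": (1, 1)}
    )
    with pytest.raises(ValueError):
        geo_distance_matrix(popmap, "river_network", [("P1", "P1", 0.0)])


# ---------------------------------------------------------------------------
# Mantel


def test_mantel_perfect_correlation():
    rng = np.random.default_rng(1)
    m = rng.random((6, 6))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0)
    r, p = mantel_test(m, m.copy(), perms=200, seed=0)
    assert r == pytest.approx(1.0)
    assert p < 0.05


def test_mantel_invariant_to_affine_transforms():
    rng = np.random.default_rng(2)
    a = rng.random((7, 7))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0)
    b = rng.random((7, 7))
    b = (b + b.T) / 2
    np.fill_diagonal(b, 0)
    r1, _ = mantel_test(a, b, perms=10, seed=0)
    r2, _ = mantel_test(2.5 * a + 1, 0.3 * b + 7, perms=10, seed=0)
    assert r1 == pytest.approx(r2)


def test_mantel_sign_on_anticorrelated_input():
    n = 8
    geo = np.abs(np.subtract.outer(np.arange(n, dtype=float), np.arange(n)))
    gen = geo.max() - geo
    np.fill_diagonal(gen, 0)
    r, _ = mantel_test(gen, geo, perms=100, seed=0)
    assert r < 0


def test_mantel_constant_matrix_flagged():
    m = np.zeros((5, 5))
    r, p = mantel_test(m, m, perms=10, seed=0)
    assert np.isnan(r)


# ---------------------------------------------------------------------------
# distance classes and Ay


def test_distance_class_assignment_half_open():
    s = DistanceClassScheme((0.0, 10.0, 20.0))
    assert s.assign(0.0) == 0
    assert s.assign(10.0) == 1
    assert s.assign(20.0) == 1  # inclusive top edge
    assert s.assign(25.0) == -1


def test_ay_identical_individuals_zero():
    n = 10
    coords = np.column_stack([np.linspace(0, 1, n), np.zeros(n)])
    res = ay_correlogram(np.zeros((n, n)), coords, 3, perms=20, seed=0)
    for c in res.classes:
        assert res.ay[c] == 0.0


def test_ay_maximally_distinct_individuals_one():
    n = 10
    g = np.ones((n, n)) - np.eye(n)
    coords = np.column_stack([np.linspace(0, 1, n), np.zeros(n)])
    res = ay_correlogram(g, coords, 3, perms=20, seed=0)
    for c in res.classes:
        assert res.ay[c] == pytest.approx(1.0)


def test_ay_increases_along_a_cline():
    n = 16
    pos = np.linspace(0, 3, n)
    gen = np.abs(np.subtract.outer(pos, pos))
    gen = gen / gen.max()
    coords = np.column_stack([pos, np.zeros(n)])
    res = ay_correlogram(gen, coords, 4, perms=50, seed=1)
    vals = [res.ay[c] for c in sorted(res.classes)]
    assert all(a < b for a, b in zip(vals, vals[1:]))


def test_ay_requires_normalised_input():
    with pytest.raises(ValueError):
        ay_correlogram(np.full((4, 4), 2.0), np.zeros((4, 2)), 2, 10, 0)


# ---------------------------------------------------------------------------
# AIDA II / cc


def _locality_alignment():
    # two haplotypes across 4 localities: nearby localities share haplotypes
    seqs, pops = [], []
    hapA, hapB = "AAAA", "AATT"
    layout = {
        "L1": (0.0, 0.0, [hapA, hapA]),
        "L2": (0.1, 0.1, [hapA, hapA]),
        "L3": (0.0, 2.0, [hapB, hapB]),
        "L4": (0.2, 2.1, [hapB, hapB]),
    }
    coords = {}
    for name, (la, lo, haps) in layout.items():
        coords[name] = (la, lo)
        for h in haps:
            seqs.append(h)
            pops.append(name)
    ids = tuple(f"s{i}" for i in range(len(seqs)))
    aln = HaplotypeAlignment(ids, tuple(seqs))
    popmap = PopulationAssignment(dict(zip(ids, pops)), coords)
    return aln, popmap


def test_aida_toy_matches_double_sum_oracle():
    aln, popmap = _locality_alignment()
    res = aida_autocorrelation(
        aln, popmap, "distance_classes", 2, perms=100, seed=0
    )
    # oracle: direct double sums on centered indicators for class 0
    n = aln.n
    X = []
    m = aln.to_matrix()
    for col in m.T:
        vals = np.unique(col)
        if len(vals) < 2:
            continue
        for v in vals:
            X.append((col == v).astype(float))
    X = np.column_stack(X)
    X = X - X.mean(axis=0)
    labels = popmap.labels_for(aln.sample_ids)
    coords = popmap.coordinates
    from riverpopgen.spatial import great_circle_km as gck

    def klass(i, j):
        la1, lo1 = coords[labels[i]]
        la2, lo2 = coords[labels[j]]
        d = gck(la1, lo1, la2, lo2)
        return res.scheme.assign(d)

    for c in res.classes:
        num = den = 0.0
        W = 0
        for i in range(n):
            for j in range(n):
                if i != j and klass(i, j) == c:
                    num += float(X[i] @ X[j])
                    W += 1
        den = float(np.sum(X**2))
        assert res.moran_ii[c] == pytest.approx(n / W * num / den)
    # nearby same-haplotype pairs: strong positive II in the first class
    assert res.moran_ii[0] > 0
    assert res.moran_ii[max(res.classes)] < 0


def test_aida_random_data_near_null_expectation():
    rng = np.random.default_rng(5)
    n = 24
    seqs = ["".join(rng.choice(list("AT"), 8)) for _ in range(n)]
    ids = tuple(f"s{i}" for i in range(n))
    pops = [f"P{i % 6}" for i in range(n)]
    coords = {f"P{k}": (0.0, float(k)) for k in range(6)}
    aln = HaplotypeAlignment(ids, tuple(seqs))
    popmap = PopulationAssignment(dict(zip(ids, pops)), coords)
    res = aida_autocorrelation(aln, popmap, "distance_classes", 3, 200, seed=2)
    for c in res.classes:
        assert abs(res.moran_ii[c] - (-1 / (n - 1))) < 0.15
        assert res.moran_p[c] > 0.01


def test_aida_graph_connectivity_runs():
    aln, popmap = _locality_alignment()
    for mode in ("gabriel", "delaunay_pruned"):
        res = aida_autocorrelation(aln, popmap, mode, perms=50, seed=0)
        assert len(res.classes) >= 1


# ---------------------------------------------------------------------------
# distogram metrics


def test_gregorius_hand_values():
    assert gregorius_distance([0.5, 0.5, 0.0], [0.25, 0.25, 0.5]) == 0.5
    assert gregorius_distance([1, 0], [0, 1]) == 1.0
    assert gregorius_distance([0.3, 0.7], [0.3, 0.7]) == 0.0


@settings(max_examples=50, deadline=None)
@given(
    st.lists(st.floats(0.01, 1.0), min_size=3, max_size=3),
    st.lists(st.floats(0.01, 1.0), min_size=3, max_size=3),
)
def test_gregorius_metric_properties(p, q):
    p = np.array(p) / np.sum(p)
    q = np.array(q) / np.sum(q)
    assert gregorius_distance(p, q) == pytest.approx(gregorius_distance(q, p))
    assert gregorius_distance(p, p) == pytest.approx(0.0)
    assert gregorius_distance(p, q) <= 1.0 + 1e-12


def test_shared_haplotypes_endpoints():
    assert shared_haplotype_proportion([0.5, 0.5, 0], [0, 0, 1.0]) == 0.0
    assert shared_haplotype_proportion([0.5, 0.5], [0.9, 0.1]) == 1.0


def test_distogram_identical_and_disjoint():
    coords = np.array([[0, 0], [0, 1], [0, 2], [0, 3]], dtype=float)
    same = np.tile([0.5, 0.5, 0.0], (4, 1))
    res = distogram(same, coords, 2, "gregorius", mc_reps=50, seed=0)
    assert all(v == 0.0 for v in res.values.values())
    disjoint = np.array(
        [[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 1, 0], [0, 0, 0, 1]], dtype=float
    )
    res = distogram(disjoint, coords, 2, "gregorius", mc_reps=50, seed=0)
    assert all(v == pytest.approx(1.0) for v in res.values.values())
    res = distogram(disjoint, coords, 2, "shared_haplotypes", 50, seed=0)
    assert all(v == 0.0 for v in res.values.values())


# ---------------------------------------------------------------------------
# IDW landscape


def test_idw_flat_surface_for_uniform_distance():
    coords = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
    g = np.full((4, 4), 0.42)
    np.fill_diagonal(g, 0)
    grid = landscape_idw(coords, g, grid=(5, 5))
    assert np.allclose(grid.surface, 0.42)


def test_idw_exact_hit_returns_midpoint_value():
    coords = np.array([[0, 0], [0, 2], [2, 0]], dtype=float)
    g = np.array([[0, 1.0, 2.0], [1.0, 0, 3.0], [2.0, 3.0, 0]])
    grid = landscape_idw(coords, g, grid=(3, 3), connectivity="all_pairs")
    # node (0, 1) coincides with the midpoint of sites 0 and 1
    yi = list(grid.grid_lat).index(0.0)
    xi = list(grid.grid_lon).index(1.0)
    assert grid.surface[yi, xi] == pytest.approx(1.0)


def test_idw_three_midpoint_hand_computation():
    coords = np.array([[0, 0], [0, 2], [2, 0]], dtype=float)
    g = np.array([[0, 1.0, 2.0], [1.0, 0, 3.0], [2.0, 3.0, 0]])
    grid = landscape_idw(coords, g, grid=(3, 3), connectivity="all_pairs")
    mids = grid.midpoints
    vals = grid.midpoint_values
    la, lo = 2.0, 2.0  # corner node, not a midpoint
    d = np.sqrt((mids[:, 0] - la) ** 2 + (mids[:, 1] - lo) ** 2)
    w = 1.0 / d
    expected = np.sum(w * vals) / np.sum(w)
    yi = list(grid.grid_lat).index(la)
    xi = list(grid.grid_lon).index(lo)
    assert grid.surface[yi, xi] == pytest.approx(expected)


def test_idw_rejects_degenerate_input():
    with pytest.raises(ValueError):
        landscape_idw(np.zeros((3, 2)), np.zeros((3, 3)))
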