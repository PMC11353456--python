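"""Spatial genetic structure.

Normalised Mantel tests, Ay distance-class correlograms, AIDA-style
molecular autocorrelation (Moran-type II and Geary-type cc on indicator-
coded sequence data) with distance-class or graph connectivity, distograms
on population haplotype frequencies (Gregorius and shared-haplotype
metrics) with Monte-Carlo envelopes, inverse-distance-weighted genetic
landscapes, and great-circle / river-network geographic distances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import Delaunay

from .datatypes import HaplotypeAlignment, PopulationAssignment

EARTH_RADIUS_KM = 6371.0


def great_circle_km(lat1, lon1, lat2, lon2) -> float:
    """Haversine distance in km between decimal-degree coordinates."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


def geo_distance_matrix(
    popmap: PopulationAssignment,
    mode: str = "great_circle",
    network: list[tuple[str, str, float]] | None = None,
) -> tuple[list[str], np.ndarray]:
    """Pairwise geographic distances (km) between populations.

    ``great_circle`` uses the haversine formula on the stored coordinates;
    ``river_network`` takes shortest along-network paths on a weighted edge
    list ``(site_a, site_b, km)`` — every population must be a network node
    and all pairs must be connected.
    """
    pops = [p for p in popmap.populations if p in popmap.coordinates]
    P = len(pops)
    out = np.zeros((P, P))
    if mode == "great_circle":
        for i in range(P):
            for j in range(i + 1, P):
                la1, lo1 = popmap.coordinates[pops[i]]
                la2, lo2 = popmap.coordinates[pops[j]]
                out[i, j] = out[j, i] = great_circle_km(la1, lo1, la2, lo2)
        return pops, out
    if mode != "river_network":
        raise ValueError("mode must be 'great_circle' or 'river_network'")
    if network is None:
        raise ValueError("river_network mode needs an edge list")
    g = nx.Graph()
    for a, b, km in network:
        g.add_edge(a, b, weight=float(km))
    missing = [p for p in pops if p not in g]
    if missing:
        raise ValueError(f"populations not on the river network: {missing}")
    lengths = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
    for i in range(P):
        for j in range(i + 1, P):
            try:
                out[i, j] = out[j, i] = lengths[pops[i]][pops[j]]
            except KeyError:
                raise ValueError(
                    f"no river path between {pops[i]} and {pops[j]}"
                )
    return pops, out


# ---------------------------------------------------------------------------
# Mantel


def mantel_test(
    gen_dist: np.ndarray,
    geo_dist: np.ndarray,
    perms: int = 10000,
    seed: int | None = None,
    log_geo: bool = False,
) -> tuple[float, float]:
    """Normalised Mantel test: Pearson r between distance matrices.

    ``log_geo`` takes the natural log of the geographic distances first
    (zero distances are left untransformed at zero).  Significance by joint
    row/column permutation of one matrix; p counts permutations with
    |r| >= |r_obs|, as (exceedances + 1)/(perms + 1).
    """
    A = np.asarray(gen_dist, dtype=float)
    B = np.asarray(geo_dist, dtype=float)
    if A.shape != B.shape or A.shape[0] != A.shape[1]:
        raise ValueError("matrices must be square and of equal order")
    if log_geo:
        B = B.copy()
        pos = B > 0
        B[pos] = np.log(B[pos])
    iu = np.triu_indices(A.shape[0], 1)
    a, b = A[iu], B[iu]
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan, np.nan
    r_obs = float(np.corrcoef(a, b)[0, 1])
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(perms):
        perm = rng.permutation(A.shape[0])
        bp = B[np.ix_(perm, perm)][iu]
        if np.std(bp) == 0:
            continue
        if abs(np.corrcoef(a, bp)[0, 1]) >= abs(r_obs):
            exceed += 1
    p = (exceed + 1.0) / (perms + 1.0)
    return r_obs, p


# ---------------------------------------------------------------------------
# distance classes


@dataclass(frozen=True)
class DistanceClassScheme:
    """Ordered half-open distance classes [lo, hi) in km."""

    boundaries: tuple[float, ...]  # len = classes + 1, strictly increasing

    def __post_init__(self) -> None:
        b = self.boundaries
        if len(b) < 2 or any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError("boundaries must be strictly increasing")

    @property
    def n_classes(self) -> int:
        return len(self.boundaries) - 1

    def assign(self, d: float) -> int:
        """Class index for a distance, or -1 if out of range."""
        b = self.boundaries
        if d < b[0] or d >= b[-1]:
            # the upper edge is inclusive so the maximum pair is kept
            if d == b[-1]:
                return self.n_classes - 1
            return -1
        return int(np.searchsorted(b, d, side="right")) - 1

    @classmethod
    def equal_pair_counts(
        cls, distances: np.ndarray, n_classes: int
    ) -> "DistanceClassScheme":
        """Quantile boundaries giving each class about the same pair count."""
        d = np.sort(np.asarray(distances, dtype=float))
        qs = np.linspace(0, 1, n_classes + 1)
        b = np.quantile(d, qs)
        b[-1] = b[-1] + 1e-9
        # collapse duplicate boundaries (heavily tied distances)
        out = [b[0]]
        for x in b[1:]:
            if x > out[-1]:
                out.append(x)
        return cls(tuple(out))


# ---------------------------------------------------------------------------
# Ay correlogram


@dataclass
class CorrelogramResult:
    scheme: DistanceClassScheme
    classes: list[int]
    ay: dict[int, float] = field(default_factory=dict)
    ay_p: dict[int, float] = field(default_factory=dict)
    v: float = np.nan
    v_p: float = np.nan
    moran_ii: dict[int, float] = field(default_factory=dict)
    moran_p: dict[int, float] = field(default_factory=dict)
    geary_cc: dict[int, float] = field(default_factory=dict)
    geary_p: dict[int, float] = field(default_factory=dict)
    bonferroni_alpha: float = np.nan
    significant: dict[int, bool] = field(default_factory=dict)
    n_pairs: dict[int, int] = field(default_factory=dict)


def _pair_geo(coords: np.ndarray) -> np.ndarray:
    n = len(coords)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = great_circle_km(
                coords[i, 0], coords[i, 1], coords[j, 0], coords[j, 1]
            )
    return out


def ay_correlogram(
    gen_dist: np.ndarray,
    coords: np.ndarray,
    scheme: DistanceClassScheme | int = 5,
    perms: int = 10000,
    seed: int | None = None,
) -> CorrelogramResult:
    """Ay statistic per geographic distance class.

    ``gen_dist`` must be normalised to [0, 1] (0 = identical, 1 = maximally
    dissimilar); Ay for a class is the mean normalised distance among pairs
    falling in it.  Per-class two-sided p and the p of V (the variance of
    Ay across classes, a portmanteau heterogeneity measure) come from
    permuting individuals over locations.
    """
    gen = np.asarray(gen_dist, dtype=float)
    if gen.min() < 0 or gen.max() > 1 + 1e-9:
        raise ValueError("gen_dist must be normalised to [0, 1]")
    geo = _pair_geo(np.asarray(coords, dtype=float))
    n = gen.shape[0]
    iu = np.triu_indices(n, 1)
    if isinstance(scheme, int):
        scheme = DistanceClassScheme.equal_pair_counts(geo[iu], scheme)
    classes_of_pair = np.array([scheme.assign(d) for d in geo[iu]])
    classes = [c for c in range(scheme.n_classes)
               if np.sum(classes_of_pair == c) >= 2]

    def ay_of(g: np.ndarray) -> np.ndarray:
        vals = g[iu]
        return np.array(
            [vals[classes_of_pair == c].mean() for c in classes]
        )

    obs = ay_of(gen)
    v_obs = float(np.var(obs)) if len(obs) > 1 else np.nan
    rng = np.random.default_rng(seed)
    ge_hi = np.zeros(len(classes))
    ge_lo = np.zeros(len(classes))
    v_ge = 0
    for _ in range(perms):
        perm = rng.permutation(n)
        g = gen[np.ix_(perm, perm)]
        sim = ay_of(g)
        ge_hi += sim >= obs
        ge_lo += sim <= obs
        if np.isfinite(v_obs) and np.var(sim) >= v_obs:
            v_ge += 1
    res = CorrelogramResult(scheme, classes)
    for k, c in enumerate(classes):
        res.ay[c] = float(obs[k])
        p_hi = (ge_hi[k] + 1.0) / (perms + 1.0)
        p_lo = (ge_lo[k] + 1.0) / (perms + 1.0)
        res.ay_p[c] = float(min(1.0, 2.0 * min(p_hi, p_lo)))
        res.n_pairs[c] = int(np.sum(classes_of_pair == c))
    res.v = v_obs
    res.v_p = (v_ge + 1.0) / (perms + 1.0) if np.isfinite(v_obs) else np.nan
    res.bonferroni_alpha = 0.05 / max(len(classes), 1)
    res.significant = {c: res.ay_p[c] < res.bonferroni_alpha for c in classes}
    return res


# ---------------------------------------------------------------------------
# AIDA II / cc


def gabriel_graph(coords: np.ndarray) -> list[tuple[int, int]]:
    """Gabriel graph: (i, j) linked iff no k lies in their diametric circle."""
    n = len(coords)
    d = _pair_geo(coords)
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            ok = True
            for k in range(n):
                if k in (i, j):
                    continue
                if d[i, k] ** 2 + d[j, k] ** 2 <= d[i, j] ** 2:
                    ok = False
                    break
            if ok:
                edges.append((i, j))
    return edges


def delaunay_edges(coords: np.ndarray) -> list[tuple[int, int]]:
    """Delaunay triangulation edges on (lon, lat); planar edges never cross,
    so no further pruning is required after construction."""
    pts = np.asarray(coords, dtype=float)[:, ::-1]  # x=lon, y=lat
    tri = Delaunay(pts)
    edges = set()
    for simplex in tri.simplices:
        for a in range(3):
            i, j = sorted((simplex[a], simplex[(a + 1) % 3]))
            edges.add((int(i), int(j)))
    return sorted(edges)


def _indicator_matrix(alignment: HaplotypeAlignment) -> np.ndarray:
    """Centered indicator coding of every allele at every segregating site."""
    m = alignment.restrict(alignment.complete_sites()).to_matrix()
    cols = []
    for col in m.T:
        vals = np.unique(col)
        if len(vals) < 2:
            continue
        for v in vals:
            cols.append((col == v).astype(float))
    if not cols:
        return np.zeros((alignment.n, 0))
    X = np.column_stack(cols)
    return X - X.mean(axis=0)


def aida_autocorrelation(
    alignment: HaplotypeAlignment,
    popmap: PopulationAssignment,
    connectivity: str = "distance_classes",
    scheme: DistanceClassScheme | int = 6,
    perms: int = 1000,
    seed: int | None = None,
) -> CorrelogramResult:
    """Moran-type II and Geary-type cc on indicator-coded sequences.

    Individuals sit at their population's coordinates.  With
    ``distance_classes`` connectivity, pair weights follow km classes;
    with ``gabriel`` or ``delaunay_pruned``, classes are shortest-path step
    counts on the locality graph.  The spatially random expectation of II
    is -1/(n-1); significance is permutational with per-class Bonferroni
    correction.
    """
    labels = popmap.labels_for(alignment.sample_ids)
    pops = sorted(set(labels))
    if len(pops) < 3:
        raise ValueError("need at least 3 localities")
    pop_coords = np.array([popmap.coordinates[p] for p in pops])
    pop_idx = np.array([pops.index(l) for l in labels])
    n = alignment.n

    if connectivity == "distance_classes":
        geo = _pair_geo(pop_coords)
        iu_p = np.triu_indices(len(pops), 1)
        if isinstance(scheme, int):
            scheme = DistanceClassScheme.equal_pair_counts(geo[iu_p], scheme)
        pop_class = np.full((len(pops), len(pops)), -1)
        for i in range(len(pops)):
            for j in range(len(pops)):
                if i != j:
                    pop_class[i, j] = scheme.assign(geo[i, j])
    elif connectivity in ("gabriel", "delaunay_pruned"):
        edges = (
            gabriel_graph(pop_coords)
            if connectivity == "gabriel"
            else delaunay_edges(pop_coords)
        )
        g = nx.Graph(edges)
        g.add_nodes_from(range(len(pops)))
        pop_class = np.full((len(pops), len(pops)), -1)
        steps = dict(nx.all_pairs_shortest_path_length(g))
        max_step = 0
        for i in steps:
            for j, s in steps[i].items():
                if i != j:
                    pop_class[i, j] = s - 1
                    max_step = max(max_step, s)
        scheme = DistanceClassScheme(tuple(float(x) for x in range(max_step + 1)))
    else:
        raise ValueError(f"unknown connectivity {connectivity!r}")

    X = _indicator_matrix(alignment)
    denom = float(np.sum(X**2))
    cross = X @ X.T  # sum_s z_is z_js
    sq = np.add.outer(np.sum(X**2, axis=1), np.sum(X**2, axis=1)) - 2 * cross

    def stats_for(assignment: np.ndarray) -> dict[int, tuple[float, float]]:
        out = {}
        cls = pop_class[np.ix_(assignment, assignment)]
        np.fill_diagonal(cls, -1)
        for c in range(scheme.n_classes):
            w = cls == c
            W = int(w.sum())
            if W == 0:
                continue
            ii = (n / W) * float(cross[w].sum()) / denom
            ccv = ((n - 1) / (2.0 * W)) * float(sq[w].sum()) / denom
            out[c] = (ii, ccv)
        return out

    obs = stats_for(pop_idx)
    classes = sorted(obs)
    rng = np.random.default_rng(seed)
    hi_ii = {c: 0 for c in classes}
    lo_ii = {c: 0 for c in classes}
    hi_cc = {c: 0 for c in classes}
    lo_cc = {c: 0 for c in classes}
    for _ in range(perms):
        sim = stats_for(rng.permutation(pop_idx))
        for c in classes:
            if c not in sim:
                continue
            ii, ccv = sim[c]
            hi_ii[c] += ii >= obs[c][0]
            lo_ii[c] += ii <= obs[c][0]
            hi_cc[c] += ccv >= obs[c][1]
            lo_cc[c] += ccv <= obs[c][1]
    res = CorrelogramResult(scheme, classes)
    for c in classes:
        res.moran_ii[c] = obs[c][0]
        res.geary_cc[c] = obs[c][1]
        res.moran_p[c] = min(
            1.0,
            2.0
            * min(
                (hi_ii[c] + 1.0) / (perms + 1.0),
                (lo_ii[c] + 1.0) / (perms + 1.0),
            ),
        )
        res.geary_p[c] = min(
            1.0,
            2.0
            * min(
                (hi_cc[c] + 1.0) / (perms + 1.0),
                (lo_cc[c] + 1.0) / (perms + 1.0),
            ),
        )
    res.bonferroni_alpha = 0.05 / max(len(classes), 1)
    res.significant = {
        c: res.moran_p[c] < res.bonferroni_alpha for c in classes
    }
    return res


# ---------------------------------------------------------------------------
# distograms


def gregorius_distance(p: np.ndarray, q: np.ndarray) -> float:
    """Gregorius's genetic distance: half the L1 distance of frequency vectors."""
    return 0.5 * float(np.sum(np.abs(np.asarray(p) - np.asarray(q))))


def shared_haplotype_proportion(p: np.ndarray, q: np.ndarray) -> float:
    """Proportion of haplotypes in common (of the union present in either)."""
    a = np.asarray(p) > 0
    b = np.asarray(q) > 0
    union = np.sum(a | b)
    return float(np.sum(a & b) / union) if union else np.nan


@dataclass
class DistogramResult:
    scheme: DistanceClassScheme
    classes: list[int]
    values: dict[int, float]
    envelope_low: dict[int, float]
    envelope_high: dict[int, float]
    outside: dict[int, bool]
    metric: str


def distogram(
    pop_freqs: np.ndarray,
    coords: np.ndarray,
    scheme: DistanceClassScheme | int = 5,
    metric: str = "gregorius",
    mc_reps: int = 10000,
    seed: int | None = None,
) -> DistogramResult:
    """Distance-class means of a population-pair genetic metric with a
    Monte-Carlo envelope from randomising population locations (95% CI)."""
    fn = {
        "gregorius": gregorius_distance,
        "shared_haplotypes": shared_haplotype_proportion,
    }[metric]
    F = np.asarray(pop_freqs, dtype=float)
    P = F.shape[0]
    if P < 2:
        raise ValueError("need at least 2 populations")
    geo = _pair_geo(np.asarray(coords, dtype=float))
    iu = np.triu_indices(P, 1)
    if isinstance(scheme, int):
        scheme = DistanceClassScheme.equal_pair_counts(geo[iu], scheme)
    gvals = np.array([fn(F[i], F[j]) for i, j in zip(*iu)])
    cls = np.array([scheme.assign(d) for d in geo[iu]])
    classes = [c for c in range(scheme.n_classes) if np.any(cls == c)]
    obs = {c: float(gvals[cls == c].mean()) for c in classes}
    rng = np.random.default_rng(seed)
    sims = {c: [] for c in classes}
    for _ in range(mc_reps):
        perm = rng.permutation(P)
        gperm = np.array(
            [fn(F[perm[i]], F[perm[j]]) for i, j in zip(*iu)]
        )
        for c in classes:
            sims[c].append(gperm[cls == c].mean())
    lo = {c: float(np.percentile(sims[c], 2.5)) for c in classes}
    hi = {c: float(np.percentile(sims[c], 97.5)) for c in classes}
    outside = {c: not (lo[c] <= obs[c] <= hi[c]) for c in classes}
    return DistogramResult(scheme, classes, obs, lo, hi, outside, metric)


# ---------------------------------------------------------------------------
# genetic landscape


@dataclass
class LandscapeGrid:
    grid_lat: np.ndarray
    grid_lon: np.ndarray
    surface: np.ndarray
    exponent: float
    midpoints: np.ndarray  # (k, 2) lat/lon
    midpoint_values: np.ndarray


def landscape_idw(
    coords: np.ndarray,
    gen_dist: np.ndarray,
    grid: tuple[int, int] = (50, 50),
    a: float = 1.0,
    connectivity: str = "delaunay",
) -> LandscapeGrid:
    """Inverse-distance-weighted genetic landscape.

    Midpoints of the connectivity network (Delaunay edges by default, all
    pairs otherwise) carry the corresponding pairwise genetic distance; the
    surface value at a grid node is the IDW mean with weights 1/d^a, and a
    node coinciding with a midpoint takes that midpoint's value exactly.
    """
    pts = np.asarray(coords, dtype=float)
    if len(pts) < 3:
        raise ValueError("need at least 3 samples")
    if np.allclose(pts, pts[0]):
        raise ValueError("degenerate coordinates")
    G = np.asarray(gen_dist, dtype=float)
    if connectivity == "delaunay":
        pairs = delaunay_edges(pts)
    else:
        n = len(pts)
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    mids = np.array([(pts[i] + pts[j]) / 2.0 for i, j in pairs])
    vals = np.array([G[i, j] for i, j in pairs])
    if np.allclose(mids, mids[0]):
        raise ValueError("all connectivity midpoints coincide")
    nx_, ny_ = grid
    lat = np.linspace(pts[:, 0].min(), pts[:, 0].max(), ny_)
    lon = np.linspace(pts[:, 1].min(), pts[:, 1].max(), nx_)
    surf = np.zeros((ny_, nx_))
    for yi, la in enumerate(lat):
        for xi, lo in enumerate(lon):
            d = np.sqrt((mids[:, 0] - la) ** 2 + (mids[:, 1] - lo) ** 2)
            hit = d == 0
            if hit.any():
                surf[yi, xi] = vals[hit][0]
                continue
            w = 1.0 / d**a
            surf[yi, xi] = float(np.sum(w * vals) / np.sum(w))
    return LandscapeGrid(lat, lon, surf, a, mids, vals)
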