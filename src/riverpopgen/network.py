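"""Median-joining haplotype networks and rho-statistic dating.

The network starts from the minimum-spanning network over the distinct
sampled haplotypes and greedily adds median (Steiner) consensus sequences
of triplets whenever they reduce the total spanning cost, then prunes
medians that no longer help — the parsimonious (epsilon = 0) behaviour of
the classical median-joining construction, with an epsilon relaxation for
retaining near-minimal alternative links.

Dating: rho is the mean mutational distance from a designated ancestral
node to the sampled individuals; its standard error follows the classical
branch-weighted estimator; multiplying by a years-per-mutation rate turns
both into years.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree

from .datatypes import HaplotypeAlignment


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _distance_matrix(seqs: list[str]) -> np.ndarray:
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _hamming(seqs[i], seqs[j])
    return d


def _mst_cost(d: np.ndarray) -> float:
    return float(minimum_spanning_tree(d).sum())


def _msn_edges(d: np.ndarray, epsilon: int = 0) -> list[tuple[int, int, int]]:
    """Minimum-spanning-network edges: pairs whose direct distance does not
    exceed the minimax path weight between them (plus epsilon)."""
    n = d.shape[0]
    mst = minimum_spanning_tree(d).toarray()
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(n):
            if mst[i, j] > 0:
                g.add_edge(i, j, weight=mst[i, j])
    # minimax path weight via the MST (max edge on the unique tree path)
    minimax = np.zeros((n, n))
    for src in range(n):
        seen = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v in g.neighbors(u):
                if v not in seen:
                    seen[v] = max(seen[u], g[u][v]["weight"])
                    stack.append(v)
        for v, w in seen.items():
            minimax[src, v] = w
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] <= minimax[i, j] + epsilon:
                edges.append((i, j, int(d[i, j])))
    return edges


def _majority_median(a: str, b: str, c: str) -> str:
    out = []
    for x, y, z in zip(a, b, c):
        if x == y or x == z:
            out.append(x)
        elif y == z:
            out.append(y)
        else:
            out.append(x)  # three-way tie: keep the first (deterministic)
    return "".join(out)


@dataclass
class MJNetwork:
    sequences: list[str]          # node sequences, sampled first
    counts: list[int]             # sample counts (0 for median vectors)
    is_median: list[bool]
    edges: list[tuple[int, int, int]]  # (u, v, mutational steps)
    epsilon: int
    node_ids: list[str] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return len(self.sequences)

    def total_cost(self) -> int:
        """Minimum spanning cost over the final node set.

        The edge list is the full minimum-spanning network (alternative
        equally short links are retained), so the spanning cost — not the sum of
        all retained edges — is the quantity medians can only reduce.
        """
        return int(round(_mst_cost(_distance_matrix(list(self.sequences)))))

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for i in range(self.n_nodes):
            g.add_node(i, count=self.counts[i], median=self.is_median[i])
        for u, v, w in self.edges:
            g.add_edge(u, v, weight=w)
        return g


def haplotype_counts(alignment: HaplotypeAlignment) -> tuple[list[str], list[int]]:
    """Distinct haplotypes (on complete sites) and their sample counts."""
    aln = alignment.restrict(alignment.complete_sites())
    seen: dict[str, int] = {}
    for s in aln.sequences:
        seen[s] = seen.get(s, 0) + 1
    seqs = list(seen)
    return seqs, [seen[s] for s in seqs]


def median_joining_network(
    haplotypes: list[str],
    counts: list[int] | None = None,
    epsilon: int = 0,
    max_rounds: int = 50,
) -> MJNetwork:
    """Median-joining network over distinct aligned haplotypes.

    Candidate medians are per-site majority consensus sequences of node
    triplets; a median is added while it strictly reduces the spanning
    cost (ties broken lexicographically for determinism), and unsampled
    medians that stop reducing the cost are pruned.
    """
    if len(haplotypes) < 2:
        raise ValueError("need at least 2 distinct haplotypes")
    L = {len(h) for h in haplotypes}
    if len(L) != 1:
        raise ValueError("haplotypes must be aligned to equal length")
    if len(set(haplotypes)) != len(haplotypes):
        raise ValueError("haplotypes must be distinct")
    counts = list(counts) if counts is not None else [1] * len(haplotypes)
    n_sampled = len(haplotypes)
    nodes = list(haplotypes)

    for _ in range(max_rounds):
        d = _distance_matrix(nodes)
        base = _mst_cost(d)
        best_gain = 0.0
        best_m = None
        node_set = set(nodes)
        seen_candidates = set()
        for i, j, k in itertools.combinations(range(len(nodes)), 3):
            m = _majority_median(nodes[i], nodes[j], nodes[k])
            if m in node_set or m in seen_candidates:
                continue
            seen_candidates.add(m)
            dm = np.array([_hamming(m, s) for s in nodes])
            d_ext = np.zeros((len(nodes) + 1, len(nodes) + 1))
            d_ext[:-1, :-1] = d
            d_ext[-1, :-1] = dm
            d_ext[:-1, -1] = dm
            gain = base - _mst_cost(d_ext)
            if gain > best_gain + 1e-9 or (
                abs(gain - best_gain) <= 1e-9
                and best_m is not None
                and gain > 0
                and m < best_m
            ):
                best_gain = gain
                best_m = m
        if best_m is None or best_gain <= 0:
            break
        nodes.append(best_m)

    # prune medians that no longer reduce the spanning cost
    changed = True
    while changed:
        changed = False
        for idx in range(len(nodes) - 1, n_sampled - 1, -1):
            others = nodes[:idx] + nodes[idx + 1:]
            if _mst_cost(_distance_matrix(others)) <= _mst_cost(
                _distance_matrix(nodes)
            ):
                nodes.pop(idx)
                changed = True

    d = _distance_matrix(nodes)
    edges = _msn_edges(d, epsilon)
    all_counts = counts + [0] * (len(nodes) - n_sampled)
    is_median = [False] * n_sampled + [True] * (len(nodes) - n_sampled)
    ids = [f"H{i + 1}" for i in range(n_sampled)] + [
        f"mv{i + 1}" for i in range(len(nodes) - n_sampled)
    ]
    return MJNetwork(nodes, all_counts, is_median, edges, epsilon, ids)


@dataclass
class RhoResult:
    rho: float
    sigma_rho: float
    years_per_mutation: float
    t_years: float
    t_sd_years: float
    root: int


def rho_dating(
    network: MJNetwork, root: int, years_per_mutation: float = 166667.0
) -> RhoResult:
    """Rho dating from a designated ancestral node.

    rho is the count-weighted mean shortest-path mutational distance from
    the root to the sampled haplotypes; its standard error sums, over the
    branches of the shortest-path tree, (descendants^2 x branch length)
    divided by n^2.  T = rho x years-per-mutation.

    The default rate corresponds to a 400-site sequence evolving at 1.5%
    per million years (one mutation per 166,667 years); the printed
    166,167-year variant used elsewhere can be passed explicitly.
    """
    g = network.graph()
    if root not in g:
        raise ValueError(f"root {root} not in network")
    if not nx.is_connected(g):
        raise ValueError("network is disconnected")
    dist, paths = nx.single_source_dijkstra(g, root, weight="weight")
    n = sum(network.counts)
    rho = (
        sum(network.counts[v] * dist[v] for v in g.nodes) / n
    )
    # shortest-path tree with deterministic tie-breaking (nx returns one
    # fixed path per node); descendants counted through each tree edge
    tree = nx.DiGraph()
    for v, path in paths.items():
        for a, b in zip(path, path[1:]):
            tree.add_edge(a, b, weight=g[a][b]["weight"])
    # accumulate sampled counts bottom-up through the tree
    order = list(nx.topological_sort(tree))
    subtotal = {v: network.counts[v] for v in g.nodes}
    for v in reversed(order):
        for u in tree.predecessors(v):
            subtotal[u] += subtotal[v]
    var = 0.0
    for a, b, data in tree.edges(data=True):
        var += subtotal[b] ** 2 * data["weight"]
    sigma = float(np.sqrt(var) / n)
    return RhoResult(
        float(rho),
        sigma,
        years_per_mutation,
        float(rho * years_per_mutation),
        float(sigma * years_per_mutation),
        root,
    )
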