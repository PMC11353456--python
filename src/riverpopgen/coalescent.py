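"""Light single-deme coalescent used for null distributions.

This module simulates neutral constant-size genealogies and drops mutations
on them under either the infinite-sites model (for sequence neutrality
statistics) or the generalised stepwise model (for microsatellite
demography tests).  Time is measured in units of 2N generations, so a
mutation rate of ``theta / 2`` per lineage per unit time gives an expected
pairwise difference of ``theta`` — the usual ``theta = 4 N mu`` convention.

It is deliberately minimal: unstructured, constant-size, no recombination.
Structured river-network simulations live in :mod:`riverpopgen.simulate`
and use msprime.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def sim_tree(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one Kingman coalescent genealogy of ``n`` tips.

    Returns ``(parent, blen)`` over nodes ``0..2n-2``; tips are ``0..n-1``,
    internal nodes are created in coalescence order, the root is ``2n-2``
    (so ``parent[child] > child`` always).  ``blen`` is in units of 2N
    generations; the root branch length is 0.
    """
    m = 2 * n - 1
    parent = np.full(m, -1, dtype=np.int64)
    node_time = np.zeros(m)
    active = list(range(n))
    t = 0.0
    nxt = n
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i = int(rng.integers(k))
        j = int(rng.integers(k - 1))
        if j >= i:
            j += 1
        a, b = active[i], active[j]
        parent[a] = nxt
        parent[b] = nxt
        node_time[nxt] = t
        # replace the two children by the new node
        hi, lo = max(i, j), min(i, j)
        active[lo] = nxt
        active.pop(hi)
        nxt += 1
    blen = np.zeros(m)
    has_parent = parent >= 0
    blen[has_parent] = node_time[parent[has_parent]] - node_time[has_parent]
    return parent, blen


@dataclass
class SiteSummary:
    """Infinite-sites summary of one simulated (or observed) sample."""

    n: int
    S: int                 # segregating sites
    k_bar: float           # mean pairwise differences
    eta_s: int             # singleton sites (minor-allele count 1)
    singletons_per_seq: np.ndarray  # U_i for the R2 statistic
    K: int                 # number of distinct haplotypes


def sim_infinite_sites(n: int, theta: float, rng: np.random.Generator) -> SiteSummary:
    """One neutral replicate summarised without building sequences.

    Each mutation defines a site whose derived-allele count equals the
    number of tips below its branch; haplotype identity follows from
    contracting mutation-free branches.
    """
    parent, blen = sim_tree(n, rng)
    m = len(parent)
    # leaf bitmask per node (n <= a few hundred, Python ints handle it)
    mask = [0] * m
    for i in range(n):
        mask[i] = 1 << i
    for node in range(m - 1):
        mask[parent[node]] |= mask[node]
    full = (1 << n) - 1

    muts = rng.poisson(theta / 2.0 * blen)
    S = int(muts.sum())
    npairs = n * (n - 1) / 2.0
    k_bar = 0.0
    eta_s = 0
    U = np.zeros(n, dtype=np.int64)
    for node in range(m - 1):
        mb = int(muts[node])
        if mb == 0:
            continue
        c = mask[node].bit_count()
        k_bar += mb * c * (n - c) / npairs
        if c == 1:
            eta_s += mb
            U[mask[node].bit_length() - 1] += mb
        elif c == n - 1:
            eta_s += mb
            U[(full ^ mask[node]).bit_length() - 1] += mb

    # haplotype classes: union-find over mutation-free branches
    comp = list(range(m))

    def find(x: int) -> int:
        while comp[x] != x:
            comp[x] = comp[comp[x]]
            x = comp[x]
        return x

    for node in range(m - 1):
        if muts[node] == 0:
            ra, rb = find(node), find(parent[node])
            if ra != rb:
                comp[ra] = rb
    K = len({find(i) for i in range(n)})
    return SiteSummary(n, S, k_bar, eta_s, U, K)


def sim_tree_sudden_expansion(
    n: int, t_switch: float, rate_factor: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Coalescent genealogy with a coalescence-rate change at ``t_switch``.

    Time runs in units of 2N1 generations (the present-day size); pastward
    of ``t_switch`` the coalescence rate is multiplied by ``rate_factor``
    (= N1/N0, large for a sudden expansion from a small ancestral size).
    """
    m = 2 * n - 1
    parent = np.full(m, -1, dtype=np.int64)
    node_time = np.zeros(m)
    active = list(range(n))
    t = 0.0
    nxt = n
    while len(active) > 1:
        k = len(active)
        rate = k * (k - 1) / 2.0
        if t < t_switch:
            dt = rng.exponential(1.0 / rate)
            if t + dt > t_switch:
                t = t_switch
                continue
            t += dt
        else:
            t += rng.exponential(1.0 / (rate * rate_factor))
        i = int(rng.integers(k))
        j = int(rng.integers(k - 1))
        if j >= i:
            j += 1
        a, b = active[i], active[j]
        parent[a] = nxt
        parent[b] = nxt
        node_time[nxt] = t
        hi, lo = max(i, j), min(i, j)
        active[lo] = nxt
        active.pop(hi)
        nxt += 1
    blen = np.zeros(m)
    has_parent = parent >= 0
    blen[has_parent] = node_time[parent[has_parent]] - node_time[has_parent]
    return parent, blen


def sim_pairwise_diffs_sudden_expansion(
    n: int,
    tau: float,
    theta0: float,
    theta1: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Pairwise difference counts for one sample under sudden expansion.

    The present-day mutation-scaled size is ``theta1``; at mutational time
    ``tau`` before present the size drops to ``theta0``.  Returns the
    n(n-1)/2 pairwise difference counts.
    """
    t_switch = tau / theta1 if theta1 > 0 else 0.0
    factor = max(theta1 / max(theta0, 1e-6), 1e-6)
    parent, blen = sim_tree_sudden_expansion(n, t_switch, factor, rng)
    m = len(parent)
    mask = [0] * m
    for i in range(n):
        mask[i] = 1 << i
    for node in range(m - 1):
        mask[parent[node]] |= mask[node]
    muts = rng.poisson(theta1 / 2.0 * blen)
    diffs = np.zeros((n, n), dtype=np.int64)
    for node in range(m - 1):
        mb = int(muts[node])
        if mb == 0:
            continue
        below = mask[node]
        members = [i for i in range(n) if (below >> i) & 1]
        others = [i for i in range(n) if not (below >> i) & 1]
        for i in members:
            for j in others:
                diffs[i, j] += mb
                diffs[j, i] += mb
    return diffs[np.triu_indices(n, 1)]


def _signed_steps(k: int, p_s: float, delta_g: float, rng: np.random.Generator) -> int:
    """Net allele-size change from ``k`` two-phase mutations.

    Single-step with probability ``p_s``; otherwise a multi-step mutation of
    size 2, 3, ... with a geometric tail and mean ``delta_g`` (a size-1
    "multi-step" change would be a contradiction); sign symmetric.
    """
    if k == 0:
        return 0
    sizes = np.ones(k, dtype=np.int64)
    multi = rng.random(k) >= p_s
    nm = int(multi.sum())
    if nm:
        if delta_g <= 1.0:
            raise ValueError("delta_g must exceed 1 repeat unit")
        sizes[multi] = 1 + rng.geometric(1.0 / (delta_g - 1.0), nm)
    signs = rng.integers(0, 2, k) * 2 - 1
    return int((sizes * signs).sum())


def sim_microsat_locus(
    n_genes: int,
    theta: float,
    rng: np.random.Generator,
    p_s: float = 1.0,
    delta_g: float = 3.5,
    ancestral: int = 50,
) -> np.ndarray:
    """Allele sizes (repeat units) for one locus at mutation–drift equilibrium.

    Generalised stepwise mutation on a coalescent genealogy; a reflective
    floor keeps allele sizes >= 1 repeat (it essentially never binds at the
    default ancestral size).
    """
    parent, blen = sim_tree(n_genes, rng)
    m = len(parent)
    muts = rng.poisson(theta / 2.0 * blen)
    step = np.zeros(m, dtype=np.int64)
    for node in np.flatnonzero(muts):
        step[node] = _signed_steps(int(muts[node]), p_s, delta_g, rng)
    value = np.zeros(m, dtype=np.int64)
    value[m - 1] = ancestral
    for node in range(m - 2, -1, -1):
        v = value[parent[node]] + step[node]
        while v < 1:
            v = 2 - v
        value[node] = v
    return value[:n_genes]
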