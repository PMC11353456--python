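"""Between-population differentiation for sequence data.

Covers the Hudson-family permutation statistics (H_ST, K_ST, K_ST*, Z_S,
Z_S*, S_nn), fixation-type indices from haplotype frequencies and sequence
distances (gamma_ST, N_ST, F_ST), the haplotype x population contingency
chi-square, pairwise exact probability tests (full enumeration or Markov
chain), Kimura two-parameter distances with net distances, hierarchical
AMOVA, and the infinite-island conversion of a fixation index into Nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .datatypes import HaplotypeAlignment, PopulationAssignment

# ---------------------------------------------------------------------------
# helpers


def _complete_matrix(alignment: HaplotypeAlignment) -> np.ndarray:
    return alignment.restrict(alignment.complete_sites()).to_matrix()


def pairwise_differences(alignment: HaplotypeAlignment) -> np.ndarray:
    """n x n matrix of pairwise nucleotide differences (complete deletion)."""
    m = _complete_matrix(alignment)
    n = m.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        d[i, i + 1:] = np.sum(m[i + 1:] != m[i], axis=1)
    return d + d.T


def _pop_indices(
    alignment: HaplotypeAlignment, popmap: PopulationAssignment
) -> tuple[list[str], np.ndarray]:
    labels = popmap.labels_for(alignment.sample_ids)
    pops = sorted(set(labels))
    idx = np.array([pops.index(p) for p in labels])
    return pops, idx


# ---------------------------------------------------------------------------
# island-model gene flow


def islandmodel_nm(F: float, ploidy_mode: str = "haploid") -> float:
    """Infinite-island gene flow from a fixation index.

    Haploid (organelle) mode: Nm = (1 - F) / (2 F); diploid (nuclear) mode:
    Nm = (1 - F) / (4 F).  F = 0 maps to infinity, F = 1 to 0.
    """
    if not 0.0 <= F <= 1.0:
        raise ValueError(f"fixation index must be in [0, 1], got {F}")
    div = {"haploid": 2.0, "diploid": 4.0}[ploidy_mode]
    if F == 0.0:
        return math.inf
    return (1.0 - F) / (div * F)


# ---------------------------------------------------------------------------
# Hudson-family statistics


@dataclass
class HeterogeneityResult:
    populations: list[str]
    chi2: float
    df: int
    chi2_p: float
    statistics: dict[str, float]
    p_values: dict[str, float]
    nm: dict[str, float]
    perms: int
    small_pops: list[str] = field(default_factory=list)


def _hap_diversity_unbiased(counts: np.ndarray) -> float:
    n = counts.sum()
    if n < 2:
        return np.nan
    p = counts / n
    return n / (n - 1.0) * (1.0 - float(np.sum(p**2)))


def _gamma_st(hap_idx: np.ndarray, pop_idx: np.ndarray, n_pops: int) -> float:
    """Nei's gamma_ST from haplotype frequencies with the Nei & Chesser
    small-sample corrections (haploid data)."""
    n_h = hap_idx.max() + 1
    table = np.zeros((n_h, n_pops))
    for h, p in zip(hap_idx, pop_idx):
        table[h, p] += 1
    sizes = table.sum(axis=0)
    keep = sizes > 0
    table = table[:, keep]
    sizes = sizes[keep]
    s = len(sizes)
    freqs = table / sizes
    n_tilde = s / np.sum(1.0 / sizes)  # harmonic mean sample size
    hs_plug = 1.0 - float(np.mean(np.sum(freqs**2, axis=0)))
    Hs = n_tilde / (n_tilde - 1.0) * hs_plug
    xbar = freqs.mean(axis=1)
    Ht = 1.0 - float(np.sum(xbar**2)) + Hs / (n_tilde * s)
    if Ht <= 0:
        return np.nan
    return 1.0 - Hs / Ht


def _hudson_stats(
    d: np.ndarray,
    hap_idx: np.ndarray,
    pop_idx: np.ndarray,
    n_pops: int,
    ranks: np.ndarray,
) -> dict[str, float]:
    n = len(pop_idx)
    iu = np.triu_indices(n, 1)
    same = pop_idx[iu[0]] == pop_idx[iu[1]]
    dvals = d[iu]
    log_d = np.log1p(dvals)

    sizes = np.bincount(pop_idx, minlength=n_pops)
    w = sizes / n

    K_j = np.full(n_pops, np.nan)
    Ks_j = np.full(n_pops, np.nan)
    Z_j = np.full(n_pops, np.nan)
    Zs_j = np.full(n_pops, np.nan)
    H_j = np.full(n_pops, np.nan)
    for j in range(n_pops):
        if sizes[j] < 2:
            continue
        mask = same & (pop_idx[iu[0]] == j)
        K_j[j] = dvals[mask].mean()
        Ks_j[j] = log_d[mask].mean()
        Z_j[j] = ranks[mask].mean()
        Zs_j[j] = np.log(ranks[mask].mean())
        counts = np.bincount(hap_idx[pop_idx == j])
        H_j[j] = _hap_diversity_unbiased(counts[counts > 0])

    ok = ~np.isnan(K_j)
    w_ok = w[ok] / w[ok].sum()
    K_S = float(np.sum(w_ok * K_j[ok]))
    K_T = float(dvals.mean())
    Ks_S = float(np.sum(w_ok * Ks_j[ok]))
    Ks_T = float(log_d.mean())
    K_ST = 1.0 - K_S / K_T if K_T > 0 else np.nan
    K_ST_star = 1.0 - Ks_S / Ks_T if Ks_T > 0 else np.nan

    H_S = float(np.sum(w_ok * H_j[ok]))
    counts_all = np.bincount(hap_idx)
    H_T = _hap_diversity_unbiased(counts_all[counts_all > 0])
    H_ST = 1.0 - H_S / H_T if H_T and H_T > 0 else np.nan

    Z_S = float(np.sum(w_ok * Z_j[ok]))
    Z_S_star = float(np.sum(w_ok * Zs_j[ok]))

    # S_nn: nearest neighbours share weight equally on ties
    snn_sum = 0.0
    for i in range(n):
        row = d[i].copy()
        row[i] = np.inf
        dmin = row.min()
        nn = np.flatnonzero(row == dmin)
        snn_sum += np.mean(pop_idx[nn] == pop_idx[i])
    S_nn = snn_sum / n

    gamma_st = _gamma_st(hap_idx, pop_idx, n_pops)

    # N_ST: unweighted mean within-population diversity vs pooled total
    pi_S = float(np.mean(K_j[ok]))
    N_ST = 1.0 - pi_S / K_T if K_T > 0 else np.nan
    # F_ST (Hudson, Slatkin & Maddison): 1 - Hw / Hb with equal pop weights
    Hw = pi_S
    hb_vals = []
    for a in range(n_pops):
        for b in range(a + 1, n_pops):
            if sizes[a] == 0 or sizes[b] == 0:
                continue
            hb_vals.append(d[np.ix_(pop_idx == a, pop_idx == b)].mean())
    Hb = float(np.mean(hb_vals)) if hb_vals else np.nan
    F_ST = 1.0 - Hw / Hb if Hb and Hb > 0 else np.nan

    return {
        "H_ST": H_ST,
        "K_ST": K_ST,
        "K_ST_star": K_ST_star,
        "Z_S": Z_S,
        "Z_S_star": Z_S_star,
        "S_nn": float(S_nn),
        "gamma_ST": float(gamma_st),
        "N_ST": float(N_ST),
        "F_ST": float(F_ST),
    }


#: statistics for which population structure lowers the value
_LOWER_TAIL = {"Z_S", "Z_S_star"}


def hudson_heterogeneity(
    alignment: HaplotypeAlignment,
    popmap: PopulationAssignment,
    perms: int = 10000,
    seed: int | None = None,
) -> HeterogeneityResult:
    """Hudson-family differentiation statistics with permutation nulls.

    p-values count permutations at least as extreme as the observed value,
    as (exceedances + 1) / (perms + 1); for the rank statistics Z_S and
    Z_S* structure lowers the statistic, so the lower tail is counted.
    """
    pops, pop_idx = _pop_indices(alignment, popmap)
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    d = pairwise_differences(alignment)
    seen, labels = alignment.restrict(
        alignment.complete_sites()
    ).haplotype_classes()
    hap_idx = np.array([seen[s] for s in labels])

    iu = np.triu_indices(len(pop_idx), 1)
    ranks = sps.rankdata(d[iu])

    obs = _hudson_stats(d, hap_idx, pop_idx, len(pops), ranks)

    rng = np.random.default_rng(seed)
    exceed = {k: 0 for k in obs}
    for _ in range(perms):
        perm = rng.permutation(pop_idx)
        sim = _hudson_stats(d, hap_idx, perm, len(pops), ranks)
        for k, v in sim.items():
            if not np.isfinite(obs[k]) or not np.isfinite(v):
                continue
            if k in _LOWER_TAIL:
                exceed[k] += v <= obs[k]
            else:
                exceed[k] += v >= obs[k]
    pvals = {
        k: (exceed[k] + 1.0) / (perms + 1.0) if np.isfinite(obs[k]) else np.nan
        for k in obs
    }

    chi2, df, chi2_p = haplotype_contingency(alignment, popmap)

    nm = {}
    for key in ("gamma_ST", "N_ST", "F_ST"):
        F = obs[key]
        nm[key] = islandmodel_nm(min(max(F, 0.0), 1.0)) if np.isfinite(F) else np.nan

    sizes = np.bincount(pop_idx, minlength=len(pops))
    small = [p for p, s in zip(pops, sizes) if s < 2]
    return HeterogeneityResult(
        pops, chi2, df, chi2_p, obs, pvals, nm, perms, small
    )


def haplotype_contingency(
    alignment: HaplotypeAlignment, popmap: PopulationAssignment
) -> tuple[float, int, float]:
    """Pearson chi-square on the haplotype x population count table.

    Returns (chi2, df, asymptotic p) with df = (H - 1)(P - 1).  With few
    haplotypes per cell the asymptotic p is rough; use the permutation or
    exact machinery for inference.
    """
    pops, pop_idx = _pop_indices(alignment, popmap)
    seen, labels = alignment.restrict(
        alignment.complete_sites()
    ).haplotype_classes()
    hap_idx = np.array([seen[s] for s in labels])
    H = hap_idx.max() + 1
    table = np.zeros((H, len(pops)))
    for h, p in zip(hap_idx, pop_idx):
        table[h, p] += 1
    df = (H - 1) * (len(pops) - 1)
    if df == 0:
        return 0.0, 0, np.nan
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        cells = (table - expected) ** 2 / expected
    chi2 = float(np.nansum(cells[expected > 0]))
    p = float(sps.chi2.sf(chi2, df))
    return chi2, df, p


# ---------------------------------------------------------------------------
# exact tests on contingency tables


def _log_table_prob(table: np.ndarray, lgamma=math.lgamma) -> float:
    """log multivariate hypergeometric probability of a count table."""
    r = table.sum(axis=1)
    c = table.sum(axis=0)
    N = table.sum()
    out = (
        sum(lgamma(x + 1) for x in r)
        + sum(lgamma(x + 1) for x in c)
        - lgamma(N + 1)
        - sum(lgamma(x + 1) for x in table.ravel())
    )
    return out


def enumerate_exact_p(table: np.ndarray, max_tables: int = 1_000_000) -> float:
    """Exact probability test by full enumeration over fixed margins.

    p is the total probability of tables no more probable than the observed
    one.  Raises ``RuntimeError`` if the table space exceeds ``max_tables``.
    """
    table = np.asarray(table, dtype=np.int64)
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    logp_obs = _log_table_prob(table)
    tol = 1e-9
    total = 0.0
    count = 0

    R, C = len(rows), len(cols)
    work = np.zeros((R, C), dtype=np.int64)

    def rec(r: int, col_rem: np.ndarray):
        nonlocal total, count
        if r == R - 1:
            work[r] = col_rem
            count += 1
            if count > max_tables:
                raise RuntimeError("table space too large for enumeration")
            lp = _log_table_prob(work)
            if lp <= logp_obs + tol:
                total += math.exp(lp)
            return
        # enumerate row r with fixed sum rows[r], bounded by col_rem
        def rec_cell(c: int, rem: int):
            if c == C - 1:
                if rem <= col_rem[c]:
                    work[r, c] = rem
                    rec(r + 1, col_rem - work[r])
                return
            for v in range(min(rem, col_rem[c]) + 1):
                work[r, c] = v
                rec_cell(c + 1, rem - v)

        rec_cell(0, int(rows[r]))

    rec(0, cols.copy())
    return total


def mcmc_exact_p(
    table: np.ndarray,
    dememorization: int = 10000,
    batches: int = 20,
    iters_per_batch: int = 5000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Markov-chain exact probability test (Raymond & Rousset style).

    A Metropolis walk over tables with the observed margins; the p-value is
    the chain frequency of tables no more probable than the observed one,
    with a standard error from batch means.
    """
    rng = np.random.default_rng(seed)
    cur = np.asarray(table, dtype=np.int64).copy()
    R, C = cur.shape
    logp_obs = _log_table_prob(cur)
    logp_cur = logp_obs
    tol = 1e-9

    def step():
        nonlocal logp_cur
        i1, i2 = rng.choice(R, 2, replace=False)
        j1, j2 = rng.choice(C, 2, replace=False)
        # propose +1/-1 swap preserving margins
        if rng.random() < 0.5:
            delta = [(i1, j1, 1), (i2, j2, 1), (i1, j2, -1), (i2, j1, -1)]
        else:
            delta = [(i1, j1, -1), (i2, j2, -1), (i1, j2, 1), (i2, j1, 1)]
        for i, j, dv in delta:
            if cur[i, j] + dv < 0:
                return
        for i, j, dv in delta:
            cur[i, j] += dv
        logp_new = _log_table_prob(cur)
        if math.log(rng.random()) < logp_new - logp_cur:
            logp_cur = logp_new
        else:
            for i, j, dv in delta:
                cur[i, j] -= dv

    for _ in range(dememorization):
        step()
    batch_means = []
    for _ in range(batches):
        hits = 0
        for _ in range(iters_per_batch):
            step()
            if logp_cur <= logp_obs + tol:
                hits += 1
        batch_means.append(hits / iters_per_batch)
    p = float(np.mean(batch_means))
    se = float(np.std(batch_means, ddof=1) / math.sqrt(batches))
    return p, se


@dataclass
class PairwiseSeqResult:
    populations: list[str]
    d_within: np.ndarray
    d_between: np.ndarray
    d_net: np.ndarray
    saturated_pairs: int
    exact_p: np.ndarray | None = None
    exact_se: np.ndarray | None = None
    nm: np.ndarray | None = None


def kimura2p_pair(p_ts: float, p_tv: float) -> float:
    """Kimura two-parameter distance from transition/transversion proportions."""
    w1 = 1.0 - 2.0 * p_ts - p_tv
    w2 = 1.0 - 2.0 * p_tv
    if w1 <= 0 or w2 <= 0:
        return np.nan  # saturated
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


_PURINES = (ord("A"), ord("G"))


def kimura2p_matrix(
    alignment: HaplotypeAlignment, popmap: PopulationAssignment
) -> PairwiseSeqResult:
    """Kimura 2P distances within, between and net between populations.

    Sites are compared pairwise-complete (gaps/Ns removed per pair).
    Saturated pairs (log argument <= 0) are dropped from the group means
    and counted in ``saturated_pairs``.
    """
    pops, pop_idx = _pop_indices(alignment, popmap)
    m = alignment.to_matrix()
    n = m.shape[0]
    valid = (m != ord("-")) & (m != ord("N"))
    purine = np.isin(m, _PURINES)
    d = np.full((n, n), np.nan)
    np.fill_diagonal(d, 0.0)
    saturated = 0
    for i in range(n):
        for j in range(i + 1, n):
            ok = valid[i] & valid[j]
            L = int(ok.sum())
            if L == 0:
                saturated += 1
                continue
            diff = (m[i] != m[j]) & ok
            ts = diff & (purine[i] == purine[j])
            P = float(ts.sum()) / L
            Q = float((diff & ~ts).sum()) / L
            val = kimura2p_pair(P, Q)
            if np.isnan(val):
                saturated += 1
            d[i, j] = d[j, i] = val

    P_ = len(pops)
    d_within = np.full(P_, np.nan)
    d_between = np.full((P_, P_), np.nan)
    for a in range(P_):
        ia = np.flatnonzero(pop_idx == a)
        if len(ia) >= 2:
            block = d[np.ix_(ia, ia)][np.triu_indices(len(ia), 1)]
            d_within[a] = np.nanmean(block)
        elif len(ia) == 1:
            d_within[a] = 0.0
        d_between[a, a] = d_within[a]
        for b in range(a + 1, P_):
            ib = np.flatnonzero(pop_idx == b)
            block = d[np.ix_(ia, ib)]
            d_between[a, b] = d_between[b, a] = np.nanmean(block)
    d_net = d_between - 0.5 * (d_within[:, None] + d_within[None, :])
    np.fill_diagonal(d_net, 0.0)
    return PairwiseSeqResult(pops, d_within, d_between, d_net, saturated)


def pairwise_exact_tests(
    alignment: HaplotypeAlignment,
    popmap: PopulationAssignment,
    mcmc: tuple[int, int, int] = (10000, 20, 5000),
    seed: int | None = None,
    enumeration_limit: int = 1_000_000,
) -> PairwiseSeqResult:
    """Per-pair exact probability tests on haplotype count tables.

    Uses full enumeration when the table space is small enough, otherwise
    the Markov-chain estimate with batch-mean standard errors.  Also fills
    the Kimura 2P distance fields and per-pair island-model Nm from
    pairwise F_ST (haploid divisor).
    """
    res = kimura2p_matrix(alignment, popmap)
    pops, pop_idx = _pop_indices(alignment, popmap)
    seen, labels = alignment.restrict(
        alignment.complete_sites()
    ).haplotype_classes()
    hap_idx = np.array([seen[s] for s in labels])
    d = pairwise_differences(alignment)

    P_ = len(pops)
    pmat = np.full((P_, P_), np.nan)
    semat = np.full((P_, P_), np.nan)
    nmmat = np.full((P_, P_), np.nan)
    rng = np.random.default_rng(seed)
    for a in range(P_):
        for b in range(a + 1, P_):
            sel = (pop_idx == a) | (pop_idx == b)
            sub_h = hap_idx[sel]
            sub_p = (pop_idx[sel] == b).astype(int)
            haps = np.unique(sub_h)
            table = np.zeros((len(haps), 2), dtype=np.int64)
            for h, pp in zip(sub_h, sub_p):
                table[np.searchsorted(haps, h), pp] += 1
            try:
                p = enumerate_exact_p(table, max_tables=enumeration_limit)
                se = 0.0
            except RuntimeError:
                p, se = mcmc_exact_p(
                    table, *mcmc, seed=int(rng.integers(2**31))
                )
            pmat[a, b] = pmat[b, a] = p
            semat[a, b] = semat[b, a] = se

            # pairwise F_ST (Hudson, Slatkin & Maddison) -> haploid Nm
            ia = np.flatnonzero(pop_idx == a)
            ib = np.flatnonzero(pop_idx == b)
            hw = []
            if len(ia) >= 2:
                hw.append(d[np.ix_(ia, ia)][np.triu_indices(len(ia), 1)].mean())
            if len(ib) >= 2:
                hw.append(d[np.ix_(ib, ib)][np.triu_indices(len(ib), 1)].mean())
            hb = d[np.ix_(ia, ib)].mean()
            if hw and hb > 0:
                fst = 1.0 - float(np.mean(hw)) / hb
                nmmat[a, b] = nmmat[b, a] = islandmodel_nm(
                    min(max(fst, 0.0), 1.0)
                )
    res.exact_p = pmat
    res.exact_se = semat
    res.nm = nmmat
    return res


# ---------------------------------------------------------------------------
# AMOVA


@dataclass
class AmovaResult:
    grouping: dict[str, str]
    df: dict[str, int]
    ssd: dict[str, float]
    variance_components: dict[str, float]
    percentages: dict[str, float]
    phi: dict[str, float]
    p_values: dict[str, float]
    perms: int


def _ssd_of(d2: np.ndarray, idx: np.ndarray) -> float:
    """Sum of squared deviations of a set: (1/n) sum_{i<j} d2_ij."""
    if len(idx) < 2:
        return 0.0
    sub = d2[np.ix_(idx, idx)]
    return float(sub[np.triu_indices(len(idx), 1)].sum() / len(idx))


def _amova_components(
    d2: np.ndarray, pop_idx: np.ndarray, grp_of_pop: np.ndarray
) -> tuple[dict, dict, dict, dict]:
    N = len(pop_idx)
    pops = np.unique(pop_idx)
    groups = np.unique(grp_of_pop[pops])
    P, G = len(pops), len(groups)
    grp_idx = grp_of_pop[pop_idx]

    ssd_total = _ssd_of(d2, np.arange(N))
    ssd_wp = sum(_ssd_of(d2, np.flatnonzero(pop_idx == p)) for p in pops)
    ssd_wg = sum(_ssd_of(d2, np.flatnonzero(grp_idx == g)) for g in groups)
    ssd_ap = ssd_wg - ssd_wp
    ssd_ag = ssd_total - ssd_wg

    df_ag = G - 1
    df_ap = P - G
    df_wp = N - P

    n_j = np.array([np.sum(pop_idx == p) for p in pops], dtype=float)
    n_g = np.array([np.sum(grp_idx == g) for g in groups], dtype=float)
    grp_of = grp_of_pop[pops]
    sum_nj2_over_ng = sum(
        np.sum(n_j[grp_of == g] ** 2) / n_g[gi]
        for gi, g in enumerate(groups)
    )
    sigma_c = ssd_wp / df_wp if df_wp > 0 else 0.0
    if df_ap > 0:
        n1 = (N - sum_nj2_over_ng) / df_ap
        sigma_b = (ssd_ap / df_ap - sigma_c) / n1 if n1 > 0 else np.nan
    else:
        sigma_b = np.nan
    if df_ag > 0:
        n2 = (sum_nj2_over_ng - np.sum(n_j**2) / N) / df_ag
        n3 = (N - np.sum(n_g**2) / N) / df_ag
        msd_ag = ssd_ag / df_ag
        sb = 0.0 if not np.isfinite(sigma_b) else sigma_b
        sigma_a = (msd_ag - sigma_c - n2 * sb) / n3 if n3 > 0 else np.nan
    else:
        sigma_a = np.nan

    comps = {
        "among_groups": sigma_a,
        "among_pops_within_groups": sigma_b,
        "within_pops": sigma_c,
    }
    total = sum(v for v in comps.values() if np.isfinite(v))
    pct = {
        k: (100.0 * v / total if np.isfinite(v) and total != 0 else np.nan)
        for k, v in comps.items()
    }
    sa = sigma_a if np.isfinite(sigma_a) else 0.0
    sb = sigma_b if np.isfinite(sigma_b) else 0.0
    phi = {
        "phi_ST": (sa + sb) / total if total != 0 else np.nan,
        "phi_CT": sa / total if total != 0 and df_ag > 0 else np.nan,
        "phi_SC": sb / (sb + sigma_c) if (sb + sigma_c) != 0 and df_ap > 0 else np.nan,
    }
    meta = {
        "df": {"among_groups": df_ag, "among_pops_within_groups": df_ap,
               "within_pops": df_wp},
        "ssd": {"among_groups": ssd_ag, "among_pops_within_groups": ssd_ap,
                "within_pops": ssd_wp, "total": ssd_total},
    }
    return comps, pct, phi, meta


def amova(
    alignment: HaplotypeAlignment,
    popmap: PopulationAssignment,
    grouping: dict[str, str],
    perms: int = 1000,
    seed: int | None = None,
) -> AmovaResult:
    """Hierarchical analysis of molecular variance on pairwise differences.

    Distances are pairwise nucleotide differences (Phi-type AMOVA); the
    squared distances enter the classical nested sums-of-squares
    decomposition.  Permutation schemes: individuals among populations
    (phi_ST), individuals among populations within groups (phi_SC), whole
    populations among groups (phi_CT).
    """
    pops, pop_idx = _pop_indices(alignment, popmap)
    missing = [p for p in pops if p not in grouping]
    if missing:
        raise ValueError(f"populations missing from grouping: {missing}")
    groups = sorted(set(grouping.values()))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    grp_of_pop = np.array([groups.index(grouping[p]) for p in pops])

    d = pairwise_differences(alignment)
    d2 = d**2

    comps, pct, phi, meta = _amova_components(d2, pop_idx, grp_of_pop)

    rng = np.random.default_rng(seed)
    exceed = {k: 0 for k in phi}
    valid = {k: np.isfinite(v) for k, v in phi.items()}
    for _ in range(perms):
        # phi_ST: individuals among populations, ignoring groups
        perm_idx = rng.permutation(pop_idx)
        _, _, phi1, _ = _amova_components(d2, perm_idx, grp_of_pop)
        if valid["phi_ST"] and np.isfinite(phi1["phi_ST"]):
            exceed["phi_ST"] += phi1["phi_ST"] >= phi["phi_ST"]
        # phi_SC: individuals among pops within their group
        perm2 = pop_idx.copy()
        for g in range(len(groups)):
            sel = np.flatnonzero(grp_of_pop[pop_idx] == g)
            perm2[sel] = pop_idx[sel][rng.permutation(len(sel))]
        _, _, phi2, _ = _amova_components(d2, perm2, grp_of_pop)
        if valid["phi_SC"] and np.isfinite(phi2["phi_SC"]):
            exceed["phi_SC"] += phi2["phi_SC"] >= phi["phi_SC"]
        # phi_CT: whole populations among groups
        perm_g = grp_of_pop.copy()
        perm_g = perm_g[rng.permutation(len(perm_g))]
        _, _, phi3, _ = _amova_components(d2, pop_idx, perm_g)
        if valid["phi_CT"] and np.isfinite(phi3["phi_CT"]):
            exceed["phi_CT"] += phi3["phi_CT"] >= phi["phi_CT"]
    pvals = {
        k: ((exceed[k] + 1.0) / (perms + 1.0) if valid[k] else np.nan)
        for k in phi
    }
    return AmovaResult(
        dict(grouping), meta["df"], meta["ssd"], comps, pct, phi, pvals, perms
    )
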