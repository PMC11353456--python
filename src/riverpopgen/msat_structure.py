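"""Microsatellite diversity, Hardy-Weinberg tests, F-statistics, genetic
distance, exact differentiation, private-allele gene flow and assignment.

Estimators follow the classical sources: unbiased expected heterozygosity
(Nei), the Robertson-Hill minimum-variance inbreeding estimator, Weir &
Cockerham variance-component F-statistics (the procedure extended to
microsatellites by Michalakis & Excoffier), Nei's (1978) unbiased distance,
Markov-chain exact tests on contingency tables, the Barton-Slatkin
private-allele gene-flow regression, and likelihood-based assignment with
Monte-Carlo exclusion probabilities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .datatypes import MISSING, GenotypeMatrix, PopulationAssignment
from .seq_structure import enumerate_exact_p, mcmc_exact_p

# ---------------------------------------------------------------------------
# diversity


@dataclass
class MsatDiversityResult:
    populations: list[str]
    loci: list[str]
    alleles_per_locus: dict[str, int]
    mna: float
    mna_sd: float
    mna_per_pop: dict[str, float]
    ho_per_locus: dict[str, float]
    he_per_locus: dict[str, float]
    ho_overall: float
    he_overall: float
    per_pop_he: dict[str, float]
    per_pop_ho: dict[str, float]
    excluded_loci: list[str] = field(default_factory=list)


def _pop_rows(gm: GenotypeMatrix, popmap: PopulationAssignment) -> dict[str, np.ndarray]:
    labels = [popmap.pop_of(s) for s in gm.sample_ids]
    pops = sorted(set(labels))
    return {p: np.flatnonzero([l == p for l in labels]) for p in pops}


def unbiased_he(counts: dict[int, int]) -> float:
    """Nei's unbiased expected heterozygosity 2n(1 - sum p^2)/(2n - 1)."""
    n2 = sum(counts.values())
    if n2 < 2:
        return np.nan
    p = np.array(list(counts.values())) / n2
    return n2 / (n2 - 1.0) * (1.0 - float(np.sum(p**2)))


def observed_ho(gm: GenotypeMatrix, locus: int, rows=None) -> float:
    a = gm.alleles[:, locus, :] if rows is None else gm.alleles[rows, locus, :]
    ok = np.all(a != MISSING, axis=1)
    if not ok.any():
        return np.nan
    return float(np.mean(a[ok, 0] != a[ok, 1]))


def msat_diversity(
    gm: GenotypeMatrix, popmap: PopulationAssignment
) -> MsatDiversityResult:
    rows = _pop_rows(gm, popmap)
    pops = list(rows)
    alleles_per_locus = {}
    ho_l, he_l = {}, {}
    excluded = []
    for li, locus in enumerate(gm.loci):
        counts = gm.allele_counts(li)
        if not counts:
            excluded.append(locus)
            continue
        alleles_per_locus[locus] = len(counts)
        ho_l[locus] = observed_ho(gm, li)
        he_l[locus] = unbiased_he(counts)
    ks = np.array(list(alleles_per_locus.values()), dtype=float)
    mna = float(ks.mean()) if len(ks) else np.nan
    mna_sd = float(ks.std(ddof=1)) if len(ks) > 1 else np.nan
    mna_pop = {}
    he_pop, ho_pop = {}, {}
    for p, ridx in rows.items():
        kvals, hes, hos = [], [], []
        for li, locus in enumerate(gm.loci):
            counts = gm.allele_counts(li, ridx)
            if not counts:
                continue
            kvals.append(len(counts))
            hes.append(unbiased_he(counts))
            hos.append(observed_ho(gm, li, ridx))
        mna_pop[p] = float(np.mean(kvals)) if kvals else np.nan
        he_pop[p] = float(np.nanmean(hes)) if hes else np.nan
        ho_pop[p] = float(np.nanmean(hos)) if hos else np.nan
    return MsatDiversityResult(
        pops,
        list(gm.loci),
        alleles_per_locus,
        mna,
        mna_sd,
        mna_pop,
        ho_l,
        he_l,
        float(np.nanmean(list(ho_l.values()))) if ho_l else np.nan,
        float(np.nanmean(list(he_l.values()))) if he_l else np.nan,
        he_pop,
        ho_pop,
        excluded,
    )


# ---------------------------------------------------------------------------
# Hardy-Weinberg


def robertson_hill_f(genotypes: np.ndarray) -> float:
    """Robertson & Hill's minimum-variance inbreeding estimator.

    Score estimator at f = 0: f = [sum_i n_ii (1-p_i)/p_i - n_het] / (n(k-1)),
    whose sampling variance is approximately 1/(n(k-1)).
    """
    ok = np.all(genotypes != MISSING, axis=1)
    g = genotypes[ok]
    n = len(g)
    if n == 0:
        return np.nan
    alleles, counts = np.unique(g.ravel(), return_counts=True)
    k = len(alleles)
    if k < 2:
        return np.nan
    p = dict(zip(alleles.tolist(), (counts / (2 * n)).tolist()))
    hom = g[:, 0] == g[:, 1]
    n_het = int((~hom).sum())
    s = 0.0
    for a in alleles:
        n_aa = int(np.sum(hom & (g[:, 0] == a)))
        s += n_aa * (1.0 - p[a]) / p[a]
    return float((s - n_het) / (n * (k - 1)))


def _log_geno_table_prob(table: np.ndarray) -> float:
    """Levene's conditional probability of a symmetric genotype count table.

    ``table`` is (k, k) upper-triangular genotype counts (n_ij for i <= j).
    P = n! 2^H prod_i c_i! / ((2n)! prod_{i<=j} n_ij!) with H heterozygotes.
    """
    k = table.shape[0]
    n = int(np.triu(table).sum())
    c = np.zeros(k, dtype=np.int64)
    H = 0
    for i in range(k):
        c[i] += 2 * table[i, i]
        for j in range(i + 1, k):
            c[i] += table[i, j]
            c[j] += table[i, j]
            H += table[i, j]
    lg = math.lgamma
    out = lg(n + 1) + H * math.log(2.0) + sum(lg(x + 1) for x in c) - lg(2 * n + 1)
    for i in range(k):
        for j in range(i, k):
            out -= lg(table[i, j] + 1)
    return out


def _enumerate_hwe_p(table: np.ndarray, max_tables: int = 500_000) -> float:
    """Exact HWE p by enumerating genotype tables with the allele counts."""
    k = table.shape[0]
    c = np.zeros(k, dtype=np.int64)
    for i in range(k):
        c[i] += 2 * table[i, i]
        for j in range(i + 1, k):
            c[i] += table[i, j]
            c[j] += table[i, j]
    logp_obs = _log_geno_table_prob(table)
    tol = 1e-9
    cells = [(i, j) for i in range(k) for j in range(i, k)]
    work = np.zeros((k, k), dtype=np.int64)
    total = 0.0
    count = 0

    def rec(ci: int, rem: np.ndarray):
        nonlocal total, count
        if ci == len(cells):
            if np.all(rem == 0):
                count += 1
                if count > max_tables:
                    raise RuntimeError("genotype table space too large")
                lp = _log_geno_table_prob(work)
                if lp <= logp_obs + tol:
                    total += math.exp(lp)
            return
        i, j = cells[ci]
        if i == j:
            vmax = rem[i] // 2
        else:
            vmax = min(rem[i], rem[j])
        # prune: remaining cells must be able to absorb remaining alleles
        for v in range(vmax + 1):
            work[i, j] = v
            new_rem = rem.copy()
            if i == j:
                new_rem[i] -= 2 * v
            else:
                new_rem[i] -= v
                new_rem[j] -= v
            rec(ci + 1, new_rem)
        work[i, j] = 0

    rec(0, c.copy())
    return total


def _mcmc_hwe_p(
    table: np.ndarray,
    dememorization: int,
    batches: int,
    iters_per_batch: int,
    seed: int,
) -> tuple[float, float]:
    """Guo & Thompson style chain over genotype tables with fixed alleles."""
    rng = np.random.default_rng(seed)
    k = table.shape[0]
    cur = np.triu(np.asarray(table, dtype=np.int64)).copy()
    logp_obs = _log_geno_table_prob(cur)
    logp_cur = logp_obs
    tol = 1e-9

    def cellget(i, j):
        return cur[min(i, j), max(i, j)]

    def celladd(i, j, v):
        cur[min(i, j), max(i, j)] += v

    def step():
        nonlocal logp_cur
        # pick two allele pairs: move (a,b)+(c,d) -> (a,c)+(b,d)
        a, b = rng.integers(0, k, 2)
        c, dd = rng.integers(0, k, 2)
        if cellget(a, b) == 0 or cellget(c, dd) == 0:
            return
        if (min(a, b), max(a, b)) == (min(c, dd), max(c, dd)) and cellget(a, b) < 2:
            return
        delta = {}
        for (i, j), v in (((a, b), -1), ((c, dd), -1), ((a, c), 1), ((b, dd), 1)):
            key = (min(i, j), max(i, j))
            delta[key] = delta.get(key, 0) + v
        if any(cur[key] + v < 0 for key, v in delta.items()):
            return
        for key, v in delta.items():
            cur[key] += v
        logp_new = _log_geno_table_prob(cur)
        if math.log(rng.random()) < logp_new - logp_cur:
            logp_cur = logp_new
        else:
            for key, v in delta.items():
                cur[key] -= v

    for _ in range(dememorization):
        step()
    means = []
    for _ in range(batches):
        hits = 0
        for _ in range(iters_per_batch):
            step()
            if logp_cur <= logp_obs + tol:
                hits += 1
        means.append(hits / iters_per_batch)
    return float(np.mean(means)), float(np.std(means, ddof=1) / math.sqrt(batches))


def _genotype_table(genotypes: np.ndarray) -> np.ndarray | None:
    ok = np.all(genotypes != MISSING, axis=1)
    g = genotypes[ok]
    if len(g) == 0:
        return None
    alleles = np.unique(g.ravel())
    if len(alleles) < 2:
        return None
    amap = {a: i for i, a in enumerate(alleles.tolist())}
    k = len(alleles)
    table = np.zeros((k, k), dtype=np.int64)
    for a, b in g:
        i, j = sorted((amap[a], amap[b]))
        table[i, j] += 1
    return table


@dataclass
class HweResult:
    populations: list[str]
    loci: list[str]
    p: dict[tuple[str, str], float]
    se: dict[tuple[str, str], float]
    rh_f: dict[str, float]
    fis: dict[str, float]
    fisher_per_pop: dict[str, tuple[float, int, float]]
    fisher_per_locus: dict[str, tuple[float, int, float]]
    fisher_global: tuple[float, int, float]


def fishers_method(pvals) -> tuple[float, int, float]:
    """Fisher's combination: chi2 = -2 sum ln p, df = 2 x number of tests."""
    ps = [p for p in pvals if np.isfinite(p)]
    if not ps:
        return np.nan, 0, np.nan
    chi2 = -2.0 * float(np.sum(np.log(np.maximum(ps, 1e-300))))
    df = 2 * len(ps)
    return chi2, df, float(sps.chi2.sf(chi2, df))


def hwe_tests(
    gm: GenotypeMatrix,
    popmap: PopulationAssignment,
    mcmc: tuple[int, int, int] = (10000, 20, 5000),
    seed: int | None = None,
    enumeration_limit: int = 200_000,
) -> HweResult:
    """Exact Hardy-Weinberg tests per locus and population.

    Small genotype-table spaces are enumerated (Levene's conditional
    distribution); larger ones use the Markov-chain method with the given
    (dememorization, batches, iterations-per-batch).  Per-locus and
    per-population combinations use Fisher's method.
    """
    rows = _pop_rows(gm, popmap)
    pops = list(rows)
    rng = np.random.default_rng(seed)
    p_out, se_out = {}, {}
    rh, fis = {}, {}
    for li, locus in enumerate(gm.loci):
        rh[locus] = robertson_hill_f(gm.alleles[:, li, :])
        fis[locus] = weir_cockerham_fis_single(gm.alleles[:, li, :])
        for pop, ridx in rows.items():
            table = _genotype_table(gm.alleles[ridx, li, :])
            if table is None:
                p_out[(locus, pop)] = np.nan
                se_out[(locus, pop)] = np.nan
                continue
            try:
                p = _enumerate_hwe_p(table, max_tables=enumeration_limit)
                se = 0.0
            except RuntimeError:
                p, se = _mcmc_hwe_p(table, *mcmc, seed=int(rng.integers(2**31)))
            p_out[(locus, pop)] = p
            se_out[(locus, pop)] = se
    fisher_pop = {
        pop: fishers_method([p_out[(l, pop)] for l in gm.loci])
        for pop in pops
    }
    fisher_locus = {
        l: fishers_method([p_out[(l, pop)] for pop in pops]) for l in gm.loci
    }
    fisher_global = fishers_method(list(p_out.values()))
    return HweResult(
        pops, list(gm.loci), p_out, se_out, rh, fis,
        fisher_pop, fisher_locus, fisher_global,
    )


def weir_cockerham_fis_single(genotypes: np.ndarray) -> float:
    """Single-sample F_IS = 1 - Ho/He (unbiased He)."""
    ok = np.all(genotypes != MISSING, axis=1)
    g = genotypes[ok]
    if len(g) == 0:
        return np.nan
    alleles, counts = np.unique(g.ravel(), return_counts=True)
    if len(alleles) < 2:
        return np.nan
    he = unbiased_he(dict(zip(alleles.tolist(), counts.tolist())))
    ho = float(np.mean(g[:, 0] != g[:, 1]))
    return 1.0 - ho / he if he > 0 else np.nan


# ---------------------------------------------------------------------------
# Weir & Cockerham F-statistics


def _wc_components_locus(
    gm: GenotypeMatrix, li: int, rows: dict[str, np.ndarray]
) -> tuple[float, float, float]:
    """Summed variance components (a, b, c) over alleles at one locus."""
    pops = [p for p, r in rows.items()]
    data = []
    for p in pops:
        g = gm.alleles[rows[p], li, :]
        ok = np.all(g != MISSING, axis=1)
        g = g[ok]
        if len(g):
            data.append(g)
        else:
            data.append(None)
    usable = [g for g in data if g is not None]
    r = len(usable)
    if r < 2:
        return 0.0, 0.0, 0.0
    n_i = np.array([len(g) for g in usable], dtype=float)
    nbar = n_i.mean()
    nc = (r * nbar - np.sum(n_i**2) / (r * nbar)) / (r - 1)
    alleles = np.unique(np.concatenate([g.ravel() for g in usable]))
    A = B = Cc = 0.0
    for al in alleles:
        p_i = np.array([np.mean(g == al) for g in usable])
        h_i = np.array(
            [np.mean((g[:, 0] == al) != (g[:, 1] == al)) for g in usable]
        )
        pbar = float(np.sum(n_i * p_i) / (r * nbar))
        s2 = float(np.sum(n_i * (p_i - pbar) ** 2) / ((r - 1) * nbar))
        hbar = float(np.sum(n_i * h_i) / (r * nbar))
        if nbar <= 1 or nc <= 0:
            continue
        a = (
            nbar
            / nc
            * (
                s2
                - 1.0
                / (nbar - 1)
                * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0)
            )
        )
        b = (
            nbar
            / (nbar - 1)
            * (
                pbar * (1 - pbar)
                - (r - 1) / r * s2
                - (2 * nbar - 1) / (4 * nbar) * hbar
            )
        )
        c = hbar / 2.0
        A += a
        B += b
        Cc += c
    return A, B, Cc


@dataclass
class FstatsResult:
    populations: list[str]
    loci: list[str]
    per_locus: dict[str, tuple[float, float, float]]  # F_IS, F_ST, F_IT
    multilocus: tuple[float, float, float]
    pairwise_fst: np.ndarray
    pairwise_nm: np.ndarray
    g_test_p: float
    low_confidence_pairs: list[tuple[str, str]]
    randomizations: int


def _g_statistic(gm: GenotypeMatrix, rows: dict[str, np.ndarray]) -> float:
    """Log-likelihood G on per-locus allele x population tables, summed."""
    G = 0.0
    for li in range(gm.n_loci):
        tables = []
        for p, r in rows.items():
            cnt = gm.allele_counts(li, r)
            tables.append(cnt)
        alleles = sorted({a for t in tables for a in t})
        if len(alleles) < 2:
            continue
        obs = np.array(
            [[t.get(a, 0) for a in alleles] for t in tables], dtype=float
        )
        rs = obs.sum(axis=1, keepdims=True)
        cs = obs.sum(axis=0, keepdims=True)
        if obs.sum() == 0:
            continue
        exp = rs * cs / obs.sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = obs * np.log(obs / exp)
        G += 2.0 * float(np.nansum(terms[obs > 0]))
    return G


def fstats(
    gm: GenotypeMatrix,
    popmap: PopulationAssignment,
    randomizations: int = 10000,
    seed: int | None = None,
) -> FstatsResult:
    """Weir & Cockerham F-statistics with G-test randomization significance.

    Multilocus values sum the variance components over loci (negative
    per-locus components are retained, not truncated).  Pairwise F_ST uses
    the same estimator on each population pair; pairwise Nm applies the
    diploid island model (1 - F)/(4F).
    """
    rows = _pop_rows(gm, popmap)
    pops = list(rows)
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    per_locus = {}
    At = Bt = Ct = 0.0
    for li, locus in enumerate(gm.loci):
        a, b, c = _wc_components_locus(gm, li, rows)
        tot = a + b + c
        fst = a / tot if tot != 0 else np.nan
        fit = 1 - c / tot if tot != 0 else np.nan
        fis = 1 - c / (b + c) if (b + c) != 0 else np.nan
        per_locus[locus] = (fis, fst, fit)
        At += a
        Bt += b
        Ct += c
    tot = At + Bt + Ct
    multi = (
        1 - Ct / (Bt + Ct) if (Bt + Ct) != 0 else np.nan,
        At / tot if tot != 0 else np.nan,
        1 - Ct / tot if tot != 0 else np.nan,
    )

    P = len(pops)
    pair_fst = np.full((P, P), np.nan)
    pair_nm = np.full((P, P), np.nan)
    low_conf = []
    from .seq_structure import islandmodel_nm

    for i in range(P):
        for j in range(i + 1, P):
            sub = {pops[i]: rows[pops[i]], pops[j]: rows[pops[j]]}
            A = B = C = 0.0
            for li in range(gm.n_loci):
                a, b, c = _wc_components_locus(gm, li, sub)
                A += a
                B += b
                C += c
            tt = A + B + C
            fst = A / tt if tt != 0 else np.nan
            pair_fst[i, j] = pair_fst[j, i] = fst
            if np.isfinite(fst):
                if fst <= 0:
                    pair_nm[i, j] = pair_nm[j, i] = math.inf
                else:
                    pair_nm[i, j] = pair_nm[j, i] = islandmodel_nm(
                        min(fst, 1.0), "diploid"
                    )
            if len(rows[pops[i]]) < 2 or len(rows[pops[j]]) < 2:
                low_conf.append((pops[i], pops[j]))

    g_obs = _g_statistic(gm, rows)
    rng = np.random.default_rng(seed)
    labels = np.concatenate([[p] * len(r) for p, r in rows.items()])
    all_rows = np.concatenate(list(rows.values()))
    exceed = 0
    for _ in range(randomizations):
        perm = rng.permutation(labels)
        prows = {
            p: all_rows[np.flatnonzero(perm == p)] for p in pops
        }
        if _g_statistic(gm, prows) >= g_obs:
            exceed += 1
    g_p = (exceed + 1.0) / (randomizations + 1.0)
    return FstatsResult(
        pops, list(gm.loci), per_locus, multi, pair_fst, pair_nm,
        g_p, low_conf, randomizations,
    )


# ---------------------------------------------------------------------------
# Nei's (1978) unbiased distance


def nei_distance(
    gm: GenotypeMatrix, popmap: PopulationAssignment
) -> tuple[list[str], np.ndarray]:
    """Nei's (1978) unbiased genetic distance matrix between populations.

    D = -ln( J_xy / sqrt(J_x J_y) ) with the homozygosities J_x, J_y given
    the small-sample correction (2n sum p^2 - 1)/(2n - 1), averaged across
    loci before forming the identity.  Pairs with zero shared identity are
    reported infinite.
    """
    rows = _pop_rows(gm, popmap)
    pops = list(rows)
    P = len(pops)
    D = np.zeros((P, P))
    for i in range(P):
        for j in range(i + 1, P):
            jx = jy = jxy = 0.0
            nloc = 0
            for li in range(gm.n_loci):
                cx = gm.allele_counts(li, rows[pops[i]])
                cy = gm.allele_counts(li, rows[pops[j]])
                if not cx or not cy:
                    continue
                n2x = sum(cx.values())
                n2y = sum(cy.values())
                if n2x < 2 or n2y < 2:
                    continue
                px = {a: c / n2x for a, c in cx.items()}
                py = {a: c / n2y for a, c in cy.items()}
                sx = sum(v**2 for v in px.values())
                sy = sum(v**2 for v in py.values())
                jx += (n2x * sx - 1.0) / (n2x - 1.0)
                jy += (n2y * sy - 1.0) / (n2y - 1.0)
                jxy += sum(px[a] * py.get(a, 0.0) for a in px)
                nloc += 1
            if nloc == 0:
                D[i, j] = D[j, i] = np.nan
                continue
            jx, jy, jxy = jx / nloc, jy / nloc, jxy / nloc
            if jxy <= 0 or jx <= 0 or jy <= 0:
                D[i, j] = D[j, i] = math.inf
            else:
                D[i, j] = D[j, i] = max(-math.log(jxy / math.sqrt(jx * jy)), 0.0)
    return pops, D


# ---------------------------------------------------------------------------
# exact genic / genotypic differentiation


def exact_differentiation(
    gm: GenotypeMatrix,
    popmap: PopulationAssignment,
    mode: str = "genic",
    mcmc: tuple[int, int, int] = (10000, 20, 5000),
    seed: int | None = None,
    enumeration_limit: int = 200_000,
) -> tuple[dict[str, float], tuple[float, int, float]]:
    """Per-locus exact differentiation tests and Fisher's global combination.

    ``genic`` tests allele x population tables (gene copies); ``genotypic``
    tests genotype x population tables.  Enumeration is used where the table
    space is small, else the Markov chain.
    """
    if mode not in ("genic", "genotypic"):
        raise ValueError("mode must be 'genic' or 'genotypic'")
    rows = _pop_rows(gm, popmap)
    pops = list(rows)
    if len(pops) < 2 or any(len(r) == 0 for r in rows.values()):
        raise ValueError("need >= 2 non-empty populations")
    rng = np.random.default_rng(seed)
    per_locus = {}
    for li, locus in enumerate(gm.loci):
        if mode == "genic":
            cats = sorted(
                {a for r in rows.values() for a in gm.allele_counts(li, r)}
            )
            if len(cats) < 2:
                per_locus[locus] = np.nan
                continue
            table = np.array(
                [
                    [gm.allele_counts(li, r).get(a, 0) for r in rows.values()]
                    for a in cats
                ],
                dtype=np.int64,
            )
        else:
            genos: dict[tuple[int, int], int] = {}
            cols = []
            for r in rows.values():
                g = gm.alleles[r, li, :]
                ok = np.all(g != MISSING, axis=1)
                col: dict[tuple[int, int], int] = {}
                for a, b in g[ok]:
                    key = (int(a), int(b))
                    col[key] = col.get(key, 0) + 1
                    genos.setdefault(key, 0)
                cols.append(col)
            if len(genos) < 2:
                per_locus[locus] = np.nan
                continue
            keys = sorted(genos)
            table = np.array(
                [[c.get(k, 0) for c in cols] for k in keys], dtype=np.int64
            )
        table = table[:, table.sum(axis=0) > 0]
        if table.shape[1] < 2:
            per_locus[locus] = np.nan
            continue
        try:
            p = enumerate_exact_p(table, max_tables=enumeration_limit)
        except RuntimeError:
            p, _ = mcmc_exact_p(table, *mcmc, seed=int(rng.integers(2**31)))
        per_locus[locus] = p
    combined = fishers_method(list(per_locus.values()))
    return per_locus, combined


# ---------------------------------------------------------------------------
# private alleles


def private_allele_nm(
    gm: GenotypeMatrix, popmap: PopulationAssignment
) -> tuple[float, float, int]:
    """Gene flow from the mean frequency of private alleles.

    Uses the Barton-Slatkin log-linear calibration for samples of 25
    (ln p(1) = -0.505 ln Nm - 2.44) with the multiplicative sample-size
    correction 25/n-bar.  Returns (Nm, mean private-allele frequency,
    number of private alleles); raises if only one population is mapped.
    """
    rows = _pop_rows(gm, popmap)
    if len(rows) < 2:
        raise ValueError("private-allele gene flow needs >= 2 populations")
    freqs = []
    sizes = []
    for li in range(gm.n_loci):
        per_pop = {p: gm.allele_counts(li, r) for p, r in rows.items()}
        owners: dict[int, list[str]] = {}
        for p, cnt in per_pop.items():
            for a in cnt:
                owners.setdefault(a, []).append(p)
        for a, pops_with in owners.items():
            if len(pops_with) == 1:
                p = pops_with[0]
                cnt = per_pop[p]
                tot = sum(cnt.values())
                freqs.append(cnt[a] / tot)
        for p, cnt in per_pop.items():
            tot = sum(cnt.values())
            if tot:
                sizes.append(tot / 2.0)
    if not freqs:
        return np.nan, np.nan, 0
    p1 = float(np.mean(freqs))
    nbar = float(np.mean(sizes))
    ln_nm = (math.log(p1) + 2.44) / (-0.505)
    nm = math.exp(ln_nm) * 25.0 / nbar
    return nm, p1, len(freqs)


# ---------------------------------------------------------------------------
# assignment


@dataclass
class AssignmentResult:
    sample_ids: list[str]
    populations: list[str]
    log_likelihoods: np.ndarray  # (n, P)
    assigned: list[str | None]
    home: list[str]
    L_ratio: np.ndarray  # L_home / L_max on the likelihood scale
    exclusion_p: np.ndarray  # (n, P)
    migrant_p: np.ndarray
    first_generation_migrant: np.ndarray
    criterion: str
    alpha: float


def _allele_freqs(
    gm: GenotypeMatrix,
    li: int,
    rows: np.ndarray,
    exclude: int | None,
    criterion: str,
    alleles: np.ndarray,
) -> np.ndarray:
    use = rows if exclude is None else rows[rows != exclude]
    g = gm.alleles[use, li, :] if len(use) else np.empty((0, 2), dtype=np.int64)
    ok = np.all(g != MISSING, axis=1)
    vals = g[ok].ravel()
    counts = np.array([np.sum(vals == a) for a in alleles], dtype=float)
    tot = counts.sum()
    if criterion == "bayesian":
        # Rannala & Mountain posterior-predictive frequencies
        k = len(alleles)
        return (counts + 1.0 / k) / (tot + 1.0)
    freqs = counts / tot if tot > 0 else np.zeros_like(counts)
    return freqs


def _geno_loglik(
    a: int, b: int, freqs: np.ndarray, alleles: np.ndarray, substitute: float
) -> float:
    def f(x):
        idx = np.searchsorted(alleles, x)
        if idx < len(alleles) and alleles[idx] == x and freqs[idx] > 0:
            return freqs[idx]
        return substitute

    pa, pb = f(a), f(b)
    if a == b:
        return math.log(pa * pb)
    return math.log(2.0 * pa * pb)


def assign_individuals(
    gm: GenotypeMatrix,
    popmap: PopulationAssignment,
    criterion: str = "frequency",
    exclusion_sims: int = 10000,
    alpha: float = 0.01,
    seed: int | None = None,
    substitute_freq: float = 0.01,
) -> AssignmentResult:
    """Likelihood assignment with leave-one-out and Monte-Carlo exclusion.

    The frequency criterion scores each multilocus genotype against each
    candidate population's allele frequencies (leave-one-out at home;
    unobserved alleles get a fixed substitute frequency so likelihoods stay
    finite).  The Bayesian criterion uses posterior-predictive frequencies.
    Exclusion p-values simulate genotypes from each candidate population;
    a first-generation migrant is flagged when the L = L_home / L_max
    ratio falls below the alpha quantile of its simulated null.
    """
    if criterion not in ("frequency", "bayesian"):
        raise ValueError("criterion must be 'frequency' or 'bayesian'")
    rows = _pop_rows(gm, popmap)
    pops = list(rows)
    P = len(pops)
    n = gm.n
    home = [popmap.pop_of(s) for s in gm.sample_ids]
    alleles_by_locus = [
        np.array(sorted(gm.allele_counts(li))) for li in range(gm.n_loci)
    ]

    loglik = np.zeros((n, P))
    genotyped = gm.genotyped_mask()
    for s in range(n):
        for pi, pop in enumerate(pops):
            excl = s if home[s] == pop else None
            ll = 0.0
            for li in range(gm.n_loci):
                if not genotyped[s, li]:
                    continue
                freqs = _allele_freqs(
                    gm, li, rows[pop], excl, criterion, alleles_by_locus[li]
                )
                a, b = gm.alleles[s, li, :]
                ll += _geno_loglik(
                    int(a), int(b), freqs, alleles_by_locus[li], substitute_freq
                )
            loglik[s, pi] = ll

    assigned: list[str | None] = []
    for s in range(n):
        if not genotyped[s].any():
            assigned.append(None)
        else:
            assigned.append(pops[int(np.argmax(loglik[s]))])
    home_idx = np.array([pops.index(h) for h in home])
    l_home = loglik[np.arange(n), home_idx]
    l_max = loglik.max(axis=1)
    L_ratio = np.exp(l_home - l_max)

    rng = np.random.default_rng(seed)
    # cached per (pop, locus) frequencies and substituted log-frequencies
    freq_cache = [
        [
            _allele_freqs(gm, li, rows[pop], None, criterion, alleles_by_locus[li])
            for li in range(gm.n_loci)
        ]
        for pop in pops
    ]
    logf_cache = [
        [
            np.log(np.where(f > 0, f, substitute_freq))
            for f in freq_cache[pi]
        ]
        for pi in range(P)
    ]
    log2 = math.log(2.0)
    # reference genotypes from each population's full-sample frequencies
    # (for the per-population exclusion p)
    sim_ll = np.zeros((P, exclusion_sims, P))
    for pi in range(P):
        lls = np.zeros((exclusion_sims, P))
        for li in range(gm.n_loci):
            fr = freq_cache[pi][li]
            tot = fr.sum()
            if tot <= 0:
                continue
            pr = fr / tot
            draws = rng.choice(len(pr), size=(exclusion_sims, 2), p=pr)
            het = draws[:, 0] != draws[:, 1]
            for qi in range(P):
                lf = logf_cache[qi][li]
                lls[:, qi] += lf[draws[:, 0]] + lf[draws[:, 1]] + het * log2
        sim_ll[pi] = lls

    exclusion_p = np.zeros((n, P))
    for s in range(n):
        for pi in range(P):
            ref = sim_ll[pi, :, pi]
            exclusion_p[s, pi] = (np.sum(ref <= loglik[s, pi]) + 1.0) / (
                exclusion_sims + 1.0
            )

    # Migrant null: a resident and its whole reference sample are simulated
    # together, and the simulated focal is scored against the leave-one-out
    # frequencies of its own simulated sample.  Scoring simulated residents
    # against the very empirical frequencies they were drawn from would make
    # them look too much at home and flag real residents en masse.
    migrant_p = np.zeros(n)
    sim_idx = np.arange(exclusion_sims)
    for s in range(n):
        pi = home_idx[s]
        n_home = len(rows[pops[pi]])
        lls = np.zeros((exclusion_sims, P))
        for li in range(gm.n_loci):
            base = freq_cache[pi][li]
            tot = base.sum()
            if tot <= 0 or n_home < 2:
                continue
            k = len(base)
            pr = base / tot
            draws = rng.choice(k, size=(exclusion_sims, 2 * n_home), p=pr)
            counts = np.stack(
                [(draws == j).sum(axis=1) for j in range(k)], axis=1
            ).astype(float)
            focal = draws[:, :2]
            for col in range(2):
                np.subtract.at(counts, (sim_idx, focal[:, col]), 1.0)
            loo_f = counts / (2 * n_home - 2)
            lf_home = np.log(np.where(loo_f > 0, loo_f, substitute_freq))
            het = focal[:, 0] != focal[:, 1]
            for qi in range(P):
                if qi == pi:
                    lls[:, qi] += (
                        lf_home[sim_idx, focal[:, 0]]
                        + lf_home[sim_idx, focal[:, 1]]
                        + het * log2
                    )
                else:
                    lf = logf_cache[qi][li]
                    lls[:, qi] += lf[focal[:, 0]] + lf[focal[:, 1]] + het * log2
        ref = np.exp(lls[:, pi] - lls.max(axis=1))
        migrant_p[s] = (np.sum(ref <= L_ratio[s]) + 1.0) / (exclusion_sims + 1.0)
    flags = migrant_p < alpha
    return AssignmentResult(
        list(gm.sample_ids), pops, loglik, assigned, home, L_ratio,
        exclusion_p, migrant_p, flags, criterion, alpha,
    )
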