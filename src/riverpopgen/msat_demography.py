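"""Microsatellite demographic-change tests.

Four families of tests that read demographic history out of allele-size
distributions at unlinked microsatellite loci:

* the imbalance index beta — ratio of a variance-based to a
  homozygosity-based estimator of theta = 4*Ne*mu; beta > 1 (ln beta > 0)
  signals growth from an earlier bottleneck;
* the kurtosis expansion index S_k — positive under expansion, negative
  after a bottleneck, zero at mutation-drift equilibrium;
* the M-ratio — observed allelic states over the allele-size range,
  depressed after bottlenecks, with critical values from equilibrium
  coalescent simulation under the two-phase mutation model;
* the intralocus kurtosis (k) and interlocus variance (g) tests — signs of
  per-locus kurtosis statistics and the spread of allele-size variances
  across loci, both lowered by population expansion.

All allele sizes are in repeat units; statistics treat the input matrix as
one population (subset the matrix for per-population runs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .coalescent import sim_microsat_locus
from .datatypes import MISSING, GenotypeMatrix

# ---------------------------------------------------------------------------
# helpers


def _locus_sizes(gm: GenotypeMatrix, li: int) -> np.ndarray:
    a = gm.alleles[:, li, :]
    return a[a != MISSING].astype(float)


def unbiased_variance(x: np.ndarray) -> float:
    return float(np.var(x, ddof=1)) if len(x) >= 2 else np.nan


def unbiased_fourth_moment(x: np.ndarray) -> float:
    """Unbiased estimator of the fourth central moment (h-statistic)."""
    n = len(x)
    if n < 4:
        return np.nan
    m2 = float(np.mean((x - x.mean()) ** 2))
    m4 = float(np.mean((x - x.mean()) ** 4))
    num = n * (n**2 - 2 * n + 3) * m4 - 3 * n * (2 * n - 3) * m2**2
    den = (n - 1) * (n - 2) * (n - 3)
    return num / den


def _jackknife(values: np.ndarray) -> tuple[float, float]:
    """(mean of delete-one estimates, jackknife standard error)."""
    L = len(values)
    mean = float(np.mean(values))
    var = (L - 1) / L * float(np.sum((values - mean) ** 2))
    return mean, math.sqrt(var)


# ---------------------------------------------------------------------------
# imbalance index beta


@dataclass
class KimmelBetaResult:
    beta: float
    ln_beta: float
    theta_v: float
    theta_p0: float
    jackknife_se: float   # s.e. of ln beta
    t: float
    df: int
    p: float
    per_locus_theta_v: dict[str, float]
    per_locus_theta_p0: dict[str, float]
    defined: bool = True


def _theta_v(sizes: np.ndarray) -> float:
    v = unbiased_variance(sizes)
    return 2.0 * v if np.isfinite(v) else np.nan


def _theta_p0(sizes: np.ndarray) -> float:
    """Invert the single-step equilibrium homozygosity P0 = 1/sqrt(1+2*theta)."""
    n2 = len(sizes)
    if n2 < 2:
        return np.nan
    vals, counts = np.unique(sizes, return_counts=True)
    p = counts / n2
    p0 = (n2 * float(np.sum(p**2)) - 1.0) / (n2 - 1.0)  # unbiased homozygosity
    if p0 <= 0:
        return np.nan
    return (1.0 / p0**2 - 1.0) / 2.0


def _unbiased_homozygosity(sizes: np.ndarray) -> float:
    n2 = len(sizes)
    if n2 < 2:
        return np.nan
    vals, counts = np.unique(sizes, return_counts=True)
    p = counts / n2
    return (n2 * float(np.sum(p**2)) - 1.0) / (n2 - 1.0)


def _invert_p0(p0: float) -> float:
    if not np.isfinite(p0) or p0 <= 0:
        return np.nan
    return (1.0 / p0**2 - 1.0) / 2.0


def kimmel_beta(gm: GenotypeMatrix) -> KimmelBetaResult:
    """Imbalance index beta = theta_V / theta_P0 with delete-one-locus
    jackknife significance on ln beta (Student t, loci-1 df).

    theta_V averages 2 * (allele-size variance) over loci; theta_P0 inverts
    the single-step equilibrium homozygosity P0 = 1/sqrt(1 + 2 theta) at
    the multilocus mean homozygosity (inverting after averaging keeps the
    convexity bias of the inversion small).
    """
    tv, tp, p0s = {}, {}, {}
    for li, locus in enumerate(gm.loci):
        sizes = _locus_sizes(gm, li)
        tv[locus] = _theta_v(sizes)
        p0s[locus] = _unbiased_homozygosity(sizes)
        tp[locus] = _invert_p0(p0s[locus])
    loci = [
        l for l in gm.loci
        if np.isfinite(tv[l]) and np.isfinite(p0s[l]) and p0s[l] > 0
    ]
    if len(loci) < 2 or all(tv[l] == 0 for l in loci):
        return KimmelBetaResult(
            np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, 0, np.nan,
            tv, tp, defined=False,
        )
    tv_arr = np.array([tv[l] for l in loci])
    p0_arr = np.array([p0s[l] for l in loci])
    theta_v = float(tv_arr.mean())
    theta_p0 = _invert_p0(float(p0_arr.mean()))
    if not np.isfinite(theta_p0) or theta_p0 <= 0 or theta_v <= 0:
        return KimmelBetaResult(
            np.nan, np.nan, theta_v, theta_p0, np.nan, np.nan, 0, np.nan,
            tv, tp, defined=False,
        )
    beta = theta_v / theta_p0
    ln_beta = math.log(beta)
    L = len(loci)
    deletions = []
    for i in range(L):
        tvi = np.delete(tv_arr, i).mean()
        tpi = _invert_p0(float(np.delete(p0_arr, i).mean()))
        deletions.append(
            math.log(tvi / tpi) if tpi and tpi > 0 and tvi > 0 else np.nan
        )
    deletions = np.array(deletions)
    deletions = deletions[np.isfinite(deletions)]
    _, se = _jackknife(deletions)
    t = ln_beta / se if se > 0 else np.nan
    p = 2.0 * float(sps.t.sf(abs(t), L - 1)) if np.isfinite(t) else np.nan
    return KimmelBetaResult(
        beta, ln_beta, theta_v, theta_p0, se, t, L - 1, p, tv, tp
    )


# ---------------------------------------------------------------------------
# S_k expansion index


@dataclass
class SkResult:
    s_k: float
    v_bar: float
    k_bar: float
    r_k: float
    sigma2_m: float
    jackknife_se: float
    t: float
    df: int
    p: float
    per_locus_v: dict[str, float]
    defined: bool = True


def zhivotovsky_sk(
    gm: GenotypeMatrix, r_k: float = 6.3, sigma2_m: float = 2.39
) -> SkResult:
    """Kurtosis expansion index S_k = 1 - (K - R_k V / 2) / (5 V^2).

    V and K are the bias-corrected allele-size variance and fourth central
    moment, averaged over loci.  R_k = k_m / sigma_m^2 is a property of the
    mutation process (6.3 for dinucleotide repeats); sigma2_m is carried
    for theta conversion and reporting.  Significance by delete-one-locus
    jackknife t test.
    """
    v_l, k_l = {}, {}
    for li, locus in enumerate(gm.loci):
        sizes = _locus_sizes(gm, li)
        v_l[locus] = unbiased_variance(sizes)
        k_l[locus] = unbiased_fourth_moment(sizes)
    loci = [l for l in gm.loci if np.isfinite(v_l[l]) and np.isfinite(k_l[l])]
    if len(loci) < 2:
        return SkResult(
            np.nan, np.nan, np.nan, r_k, sigma2_m, np.nan, np.nan, 0, np.nan,
            v_l, defined=False,
        )
    V = np.array([v_l[l] for l in loci])
    K = np.array([k_l[l] for l in loci])

    def sk_of(v_arr, k_arr):
        vb = v_arr.mean()
        kb = k_arr.mean()
        if vb <= 0:
            return np.nan
        return 1.0 - (kb - r_k * vb / 2.0) / (5.0 * vb**2)

    s_k = sk_of(V, K)
    if not np.isfinite(s_k):
        return SkResult(
            np.nan, float(V.mean()), float(K.mean()), r_k, sigma2_m,
            np.nan, np.nan, 0, np.nan, v_l, defined=False,
        )
    L = len(loci)
    deletions = np.array(
        [sk_of(np.delete(V, i), np.delete(K, i)) for i in range(L)]
    )
    _, se = _jackknife(deletions)
    t = s_k / se if se > 0 else np.nan
    p = 2.0 * float(sps.t.sf(abs(t), L - 1)) if np.isfinite(t) else np.nan
    return SkResult(
        float(s_k), float(V.mean()), float(K.mean()), r_k, sigma2_m,
        se, t, L - 1, p, v_l,
    )


# ---------------------------------------------------------------------------
# M-ratio


@dataclass
class MRatioResult:
    per_locus: dict[str, float]
    mean_m: float
    monomorphic: list[str] = field(default_factory=list)


def gw_m_ratio(gm: GenotypeMatrix) -> MRatioResult:
    """M = k / r per locus: allele count over allelic states spanned.

    r counts the inclusive range in repeat units (max - min + 1), so two
    alleles two repeats apart give M = 2/3.  Monomorphic loci have M = 1 by
    convention and are flagged.
    """
    per = {}
    mono = []
    for li, locus in enumerate(gm.loci):
        sizes = _locus_sizes(gm, li)
        if len(sizes) == 0:
            continue
        k = len(np.unique(sizes))
        r = int(sizes.max() - sizes.min()) + 1
        per[locus] = k / r
        if k == 1:
            mono.append(locus)
    mean_m = float(np.mean(list(per.values()))) if per else np.nan
    return MRatioResult(per, mean_m, mono)


@dataclass
class MRatioNull:
    theta: float
    p_s: float
    delta_g: float
    n_genes: int
    n_loci: int
    reps: int
    simulated: np.ndarray
    mean: float
    m_c: float
    observed_m: float | None = None
    rank_p: float | None = None
    significant_reduction: bool | None = None


def gw_null_distribution(
    theta: float,
    p_s: float,
    delta_g: float,
    n_genes: int,
    reps: int = 10000,
    seed: int | None = None,
    n_loci: int = 1,
    observed_m: float | None = None,
) -> MRatioNull:
    """Equilibrium null distribution of the (multilocus mean) M-ratio.

    Each replicate simulates ``n_loci`` independent loci of ``n_genes``
    lineages under the two-phase mutation model (single-step with
    probability ``p_s``, otherwise a 2+geometric step of mean ``delta_g``)
    and records the mean M across loci.  M_c is the 5th percentile;
    an observed mean M below M_c indicates a significant reduction in
    population size.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    if not 0 < p_s <= 1:
        raise ValueError("p_s must be in (0, 1]")
    rng = np.random.default_rng(seed)
    sims = np.empty(reps)
    for b in range(reps):
        mvals = np.empty(n_loci)
        for l in range(n_loci):
            a = sim_microsat_locus(n_genes, theta, rng, p_s=p_s, delta_g=delta_g)
            mvals[l] = len(np.unique(a)) / (a.max() - a.min() + 1)
        sims[b] = mvals.mean()
    mean = float(sims.mean())
    m_c = float(np.percentile(sims, 5))
    rank_p = None
    sig = None
    if observed_m is not None:
        rank_p = float((np.sum(sims <= observed_m) + 1.0) / (reps + 1.0))
        sig = observed_m < m_c
    return MRatioNull(
        theta, p_s, delta_g, n_genes, n_loci, reps, sims, mean, m_c,
        observed_m, rank_p, sig,
    )


# ---------------------------------------------------------------------------
# Reich intralocus k and interlocus g tests


def reich_k_statistic(sizes: np.ndarray) -> float:
    """Per-locus kurtosis statistic, negative in expectation under expansion.

    k = 2 V^2 + V/2 - m4: at single-step mutation-drift equilibrium the
    fourth central moment satisfies E[m4] = 2 E[V^2] + E[V]/2 (coalescent
    moment identity, checked by simulation), so E[k] ~ 0 with a slight
    excess of positive signs.  Expansion drives allele-size distributions
    towards smooth compound-Poisson shapes with m4 ~ 3 V^2 and V
    concentrated, pushing k below zero.  Only the sign feeds the binomial
    test, insulating it from the constant choices.
    """
    if len(sizes) < 4:
        return np.nan
    v = unbiased_variance(sizes)
    m4 = unbiased_fourth_moment(sizes)
    return 2.0 * v * v + v / 2.0 - m4


@dataclass
class ReichKResult:
    per_locus_k: dict[str, float]
    n_polymorphic: int
    n_positive: int
    p_pos: float
    binomial_p: float


def reich_k_test(gm: GenotypeMatrix, p_pos: float = 0.515) -> ReichKResult:
    """Binomial sign test on per-locus kurtosis statistics.

    Under constant size each polymorphic locus is positive with probability
    ``p_pos`` (slightly above one half); the one-tailed p is the
    probability of at most the observed number of positive-k loci.
    """
    per = {}
    for li, locus in enumerate(gm.loci):
        sizes = _locus_sizes(gm, li)
        if len(np.unique(sizes)) < 2:
            continue  # monomorphic loci carry no sign information
        k = reich_k_statistic(sizes)
        if np.isfinite(k):
            per[locus] = k
    n = len(per)
    npos = sum(1 for v in per.values() if v > 0)
    p = float(sps.binom.cdf(npos, n, p_pos)) if n else np.nan
    return ReichKResult(per, n, npos, p_pos, p)


@dataclass
class ReichGResult:
    g: float
    per_locus_v: dict[str, float]
    cutoff: float
    p: float
    reps: int
    theta_hat: float
    defined: bool = True


def reich_g_test(
    gm: GenotypeMatrix,
    cutoff_source: str = "simulated",
    seed: int | None = None,
    reps: int = 1000,
    p_s: float = 1.0,
    delta_g: float = 3.5,
) -> ReichGResult:
    """Interlocus test: is the spread of per-locus allele-size variances
    lower than constant size predicts (a sign of expansion)?

    The statistic is the squared coefficient of variation of V across
    polymorphic loci, g = Var_l(V_l) / V_bar^2, which is free of the
    mutation-rate scale.  Its null distribution is generated by
    constant-size coalescent simulation matched to the locus count, sample
    size, and theta_hat = 2 V_bar; the cutoff is the 5th percentile and low
    observed g rejects constant size.
    """
    if cutoff_source != "simulated":
        raise ValueError(
            "only cutoff_source='simulated' is supported; tabulated "
            "cutoffs require the original source tables"
        )
    v_l = {}
    n_genes = []
    for li, locus in enumerate(gm.loci):
        sizes = _locus_sizes(gm, li)
        if len(np.unique(sizes)) < 2:
            continue
        v_l[locus] = unbiased_variance(sizes)
        n_genes.append(len(sizes))
    L = len(v_l)
    if L < 2:
        return ReichGResult(np.nan, v_l, np.nan, np.nan, 0, np.nan, False)
    V = np.array(list(v_l.values()))
    vbar = float(V.mean())
    g_obs = float(np.var(V, ddof=1) / vbar**2)
    theta_hat = 2.0 * vbar
    n_use = int(round(np.mean(n_genes)))
    rng = np.random.default_rng(seed)
    g_sims = np.empty(reps)
    for b in range(reps):
        vs = np.empty(L)
        for l in range(L):
            a = sim_microsat_locus(n_use, theta_hat, rng, p_s=p_s, delta_g=delta_g)
            vs[l] = np.var(a, ddof=1)
        vb = vs.mean()
        g_sims[b] = np.var(vs, ddof=1) / vb**2 if vb > 0 else np.nan
    g_sims = g_sims[np.isfinite(g_sims)]
    cutoff = float(np.percentile(g_sims, 5))
    p = float((np.sum(g_sims <= g_obs) + 1.0) / (len(g_sims) + 1.0))
    return ReichGResult(g_obs, v_l, cutoff, p, reps, theta_hat)
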