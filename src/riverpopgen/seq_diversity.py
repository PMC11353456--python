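"""Within-sample sequence diversity and demographic neutrality statistics.

Implements the classical control-region toolkit: haplotype number and
diversity, nucleotide diversity, Watterson's theta, Tajima's D, Fu & Li's
D* and F* (no outgroup), Fu's F_S, the R2 statistic, and the pairwise
mismatch distribution with a sudden-expansion model fit and Harpending's
raggedness.  Significance of the neutrality statistics comes from neutral
constant-size coalescent simulation conditioned on theta-hat = k_bar.

Site handling: positions containing any gap or N are removed before all
statistics (complete deletion), so segregating sites, pi and haplotype
identity refer to one consistent site set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .coalescent import SiteSummary, sim_infinite_sites
from .datatypes import HaplotypeAlignment


# ---------------------------------------------------------------------------
# observed-data summaries

def _harmonic(n: int, power: int = 1) -> float:
    i = np.arange(1, n)
    return float(np.sum(1.0 / i**power))


def site_summary(alignment: HaplotypeAlignment) -> SiteSummary:
    """Infinite-sites style summary of an observed alignment.

    Multi-allelic sites contribute ``alleles - 1`` mutations; singleton
    count follows the minor-allele-count-1 convention used when no outgroup
    is available.
    """
    aln = alignment.restrict(alignment.complete_sites())
    m = aln.to_matrix()
    n = aln.n
    S = 0
    eta = 0
    eta_s = 0
    U = np.zeros(n, dtype=np.int64)
    k_sum = 0.0
    for col in m.T:
        vals, counts = np.unique(col, return_counts=True)
        if len(vals) == 1:
            continue
        S += 1
        eta += len(vals) - 1
        k_sum += (n * n - np.sum(counts.astype(float) ** 2)) / 2.0
        for v, c in zip(vals, counts):
            if c == 1:
                eta_s += 1
                U[int(np.flatnonzero(col == v)[0])] += 1
    npairs = n * (n - 1) / 2.0
    k_bar = k_sum / npairs if npairs else 0.0
    seen, labels = aln.haplotype_classes()
    return SiteSummary(n, S, k_bar, eta_s, U, len(seen))


# ---------------------------------------------------------------------------
# diversity

@dataclass
class DiversityResult:
    n: int
    n_sites: int
    H: int
    haplotype_freqs: dict[int, int]
    H_d: float
    H_d_sd: float
    pi: float
    pi_sd: float
    k_bar: float
    S: int
    theta_seq: float
    theta_seq_sd: float


def diversity_stats(alignment: HaplotypeAlignment) -> DiversityResult:
    """Haplotype and nucleotide diversity of one sample.

    H_d = n (1 - sum p_i^2) / (n - 1); pi is the mean pairwise difference
    per analysed site; theta_seq = S / a1.  Standard errors follow the
    classical large-sample estimators (Nei 1987 for H_d and pi; the
    total variance of S for Watterson's theta).
    """
    if alignment.n < 2:
        raise ValueError("diversity statistics need at least 2 sequences")
    sites = alignment.complete_sites()
    aln = alignment.restrict(sites)
    n, L = aln.n, aln.length
    summ = site_summary(alignment)

    seen, labels = aln.haplotype_classes()
    counts = np.zeros(len(seen), dtype=np.int64)
    for seq in aln.sequences:
        counts[seen[seq]] += 1
    p = counts / n
    sum_p2 = float(np.sum(p**2))
    sum_p3 = float(np.sum(p**3))
    H_d = n * (1.0 - sum_p2) / (n - 1)
    var_hd = (
        2.0
        / (n * (n - 1))
        * (2 * (n - 2) * (sum_p3 - sum_p2**2) + sum_p2 - sum_p2**2)
    )
    H_d_sd = float(np.sqrt(max(var_hd, 0.0)))

    pi = summ.k_bar / L if L else 0.0
    var_pi = (
        (n + 1) / (3.0 * (n - 1) * L) * pi
        + 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1)) * pi**2
    ) if L else 0.0
    pi_sd = float(np.sqrt(max(var_pi, 0.0)))

    a1 = _harmonic(n)
    a2 = _harmonic(n, 2)
    theta = summ.S / a1
    var_theta = (a1 * theta + a2 * theta**2) / a1**2
    theta_sd = float(np.sqrt(max(var_theta, 0.0)))

    return DiversityResult(
        n=n,
        n_sites=L,
        H=len(seen),
        haplotype_freqs={i: int(c) for i, c in enumerate(counts)},
        H_d=float(H_d),
        H_d_sd=H_d_sd,
        pi=float(pi),
        pi_sd=pi_sd,
        k_bar=float(summ.k_bar),
        S=int(summ.S),
        theta_seq=float(theta),
        theta_seq_sd=theta_sd,
    )


# ---------------------------------------------------------------------------
# neutrality statistics

def tajimas_d(n: int, S: int, k_bar: float) -> float:
    if S == 0:
        return np.nan
    a1 = _harmonic(n)
    a2 = _harmonic(n, 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    denom = np.sqrt(e1 * S + e2 * S * (S - 1))
    return float((k_bar - S / a1) / denom) if denom > 0 else np.nan


def fu_li_dstar_fstar(n: int, S: int, k_bar: float, eta_s: int) -> tuple[float, float]:
    """Fu & Li's D* and F* without an outgroup (singleton-based)."""
    if S == 0 or n < 3:
        return np.nan, np.nan
    a1 = _harmonic(n)
    a2 = _harmonic(n, 2)
    an1 = a1 + 1.0 / n  # a_{n+1}
    cn = 2.0 * (n * a1 - 2 * (n - 1)) / ((n - 1) * (n - 2))
    dn = (
        cn
        + (n - 2) / (n - 1) ** 2
        + (2.0 / (n - 1)) * (1.5 - (2 * an1 - 3) / (n - 2) - 1.0 / n)
    )
    v_d = (
        (n / (n - 1.0)) ** 2 * a2
        + a1**2 * dn
        - 2.0 * n * a1 * (a1 + 1) / (n - 1.0) ** 2
    ) / (a1**2 + a2)
    u_d = (n / (n - 1.0)) * (a1 - n / (n - 1.0)) - v_d
    num_d = (n / (n - 1.0)) * S - a1 * eta_s
    den_d = np.sqrt(u_d * S + v_d * S**2)
    Dstar = float(num_d / den_d) if den_d > 0 else np.nan

    v_f = (
        (2.0 * n**3 + 110.0 * n**2 - 255.0 * n + 153.0) / (9.0 * n**2 * (n - 1))
        + 2.0 * (n - 1) * a1 / n**2
        - 8.0 * a2 / n
    ) / (a1**2 + a2)
    u_f = (
        (4.0 * n**2 + 19.0 * n + 3.0 - 12.0 * (n + 1) * an1)
        / (3.0 * n * (n - 1))
    ) / a1 - v_f
    num_f = k_bar - (n - 1.0) / n * eta_s
    den_f = np.sqrt(u_f * S + v_f * S**2)
    Fstar = float(num_f / den_f) if den_f > 0 else np.nan
    return Dstar, Fstar


def _log_stirling_first(n: int) -> np.ndarray:
    """log of unsigned Stirling numbers of the first kind |s(n, k)|, k=0..n."""
    log_s = np.full((n + 1, n + 1), -np.inf)
    log_s[0, 0] = 0.0
    for m in range(1, n + 1):
        prev = log_s[m - 1]
        cur = np.full(n + 1, -np.inf)
        # |s(m, k)| = (m-1) |s(m-1, k)| + |s(m-1, k-1)|
        with np.errstate(divide="ignore"):
            cur[1:] = np.logaddexp(np.log(m - 1) + prev[1:], prev[:-1])
            if m == 1:
                cur[1] = 0.0
        log_s[m] = cur
    return log_s[n]


def fus_fs(n: int, k_bar: float, K: int) -> float:
    """Fu's F_S from the Ewens sampling distribution at theta = k_bar.

    S' = P(K' >= K | theta); F_S = ln(S' / (1 - S')), computed in log space
    so that samples of n ~ 100 do not overflow.
    """
    if k_bar <= 0 or K <= 1:
        return np.nan
    theta = k_bar
    log_s = _log_stirling_first(n)
    ks = np.arange(n + 1)
    with np.errstate(divide="ignore"):
        log_terms = log_s + ks * np.log(theta)
    log_norm = float(np.logaddexp.reduce(log_terms[1:]))
    log_p = log_terms[1:] - log_norm  # P(K' = k), k = 1..n
    p_ge = float(np.exp(np.logaddexp.reduce(log_p[K - 1:])))
    p_ge = min(max(p_ge, 1e-300), 1 - 1e-15)
    return float(np.log(p_ge) - np.log1p(-p_ge))


def r2_statistic(n: int, S: int, k_bar: float, U: np.ndarray) -> float:
    """Ramos-Onsins & Rozas R2: singletons per sequence vs k_bar / 2."""
    if S == 0:
        return np.nan
    return float(np.sqrt(np.mean((U - k_bar / 2.0) ** 2)) / S)


def _stats_from_summary(s: SiteSummary) -> dict[str, float]:
    D = tajimas_d(s.n, s.S, s.k_bar)
    Dstar, Fstar = fu_li_dstar_fstar(s.n, s.S, s.k_bar, s.eta_s)
    Fs = fus_fs(s.n, s.k_bar, s.K)
    R2 = r2_statistic(s.n, s.S, s.k_bar, s.singletons_per_seq)
    return {
        "tajima_D": D,
        "fuli_Dstar": Dstar,
        "fuli_Fstar": Fstar,
        "fu_Fs": Fs,
        "R2": R2,
    }


@dataclass
class NeutralityResult:
    n: int
    S: int
    k_bar: float
    defined: bool
    statistics: dict[str, float] = field(default_factory=dict)
    p_values: dict[str, float] = field(default_factory=dict)
    coalescent_reps: int = 0


#: statistics whose evidence for expansion/growth is in the lower tail
_LOWER_TAIL = {"fu_Fs", "R2"}


def neutrality_tests(
    alignment: HaplotypeAlignment,
    coalescent_reps: int = 10000,
    seed: int | None = None,
) -> NeutralityResult:
    """Neutrality statistics with coalescent p-values.

    The null is a constant-size neutral coalescent conditioned on
    theta-hat = k_bar.  For Tajima's D and Fu & Li's D*/F* the reported p
    is two-sided (twice the smaller tail); for Fu's F_S and R2 it is the
    lower tail, where expansion pushes those statistics.
    """
    obs = site_summary(alignment)
    if obs.S == 0 or obs.n < 3:
        return NeutralityResult(obs.n, obs.S, obs.k_bar, defined=False)
    stats = _stats_from_summary(obs)
    rng = np.random.default_rng(seed)
    sims = {name: [] for name in stats}
    for _ in range(coalescent_reps):
        s = sim_infinite_sites(obs.n, obs.k_bar, rng)
        sim_stats = _stats_from_summary(s)
        for name, v in sim_stats.items():
            sims[name].append(v)
    pvals = {}
    for name, v_obs in stats.items():
        arr = np.asarray(sims[name])
        arr = arr[np.isfinite(arr)]
        if not np.isfinite(v_obs) or len(arr) == 0:
            pvals[name] = np.nan
            continue
        B = len(arr)
        p_low = (np.sum(arr <= v_obs) + 1.0) / (B + 1.0)
        p_high = (np.sum(arr >= v_obs) + 1.0) / (B + 1.0)
        if name in _LOWER_TAIL:
            pvals[name] = float(p_low)
        else:
            pvals[name] = float(min(1.0, 2.0 * min(p_low, p_high)))
    return NeutralityResult(
        obs.n, obs.S, obs.k_bar, True, stats, pvals, coalescent_reps
    )


# ---------------------------------------------------------------------------
# mismatch distribution

def _eq_mismatch(theta: float, jmax: int) -> np.ndarray:
    """Equilibrium pairwise-difference distribution F_j = theta^j/(theta+1)^(j+1)."""
    j = np.arange(jmax + 1)
    if theta <= 0:
        out = np.zeros(jmax + 1)
        out[0] = 1.0
        return out
    return np.exp(j * np.log(theta) - (j + 1) * np.log(theta + 1.0))


def sudden_expansion_mismatch(
    tau: float, theta0: float, theta1: float, jmax: int
) -> np.ndarray:
    """Expected mismatch distribution under the sudden-expansion model.

    A population at equilibrium theta0 jumps to theta1 at mutational time
    tau before present; the pairwise-difference distribution is the
    classical convolution of the old equilibrium with Poisson(tau)
    mutations, damped by lineage coalescence in the expanded phase.
    """
    Fj1 = _eq_mismatch(theta1, jmax)
    Fj0 = _eq_mismatch(theta0, jmax)
    diff = Fj0 - Fj1
    j = np.arange(jmax + 1)
    from scipy.special import gammaln

    log_pois = np.where(
        j == 0, 0.0, j * np.log(tau) - gammaln(j + 1)
    ) if tau > 0 else np.where(j == 0, 0.0, -np.inf)
    pois = np.exp(log_pois)
    conv = np.convolve(pois, diff)[: jmax + 1]
    damp = np.exp(-tau * (1.0 + 1.0 / theta1)) if theta1 > 0 else 0.0
    out = Fj1 + damp * conv
    return np.clip(out, 0.0, None)


def raggedness(freqs: np.ndarray) -> float:
    """Harpending's raggedness: sum of squared successive-class differences."""
    x = np.asarray(freqs, dtype=float)
    return float(np.sum(np.diff(x) ** 2))


@dataclass
class MismatchResult:
    observed: np.ndarray
    n_pairs: int
    tau: float
    theta0: float
    theta1: float
    ssd: float
    rg: float
    p_ssd: float
    p_rg: float
    applicable: bool


_THETA1_CAP = 1e4  # the expanded size is weakly identified; cap like the
                   # classical implementations do


def _fit_sudden_expansion(
    freqs: np.ndarray, starts: tuple | None = None
) -> tuple[float, float, float, float]:
    jmax = len(freqs) - 1
    mean_d = float(np.sum(np.arange(jmax + 1) * freqs))

    def ssd(params):
        tau, th0, th1 = params
        if tau < 0 or th0 < 0 or th1 <= 0 or th1 > _THETA1_CAP:
            return 1e6
        return float(
            np.sum((freqs - sudden_expansion_mismatch(tau, th0, th1, jmax)) ** 2)
        )

    if starts is None:
        starts = (
            (max(mean_d, 0.1), max(mean_d / 10, 0.01), max(10 * mean_d, 1.0)),
            (max(mean_d / 2, 0.1), 0.01, _THETA1_CAP / 10),
        )
    best = None
    for x0 in starts:
        res = optimize.minimize(
            ssd,
            x0=list(x0),
            method="Nelder-Mead",
            options={"xatol": 1e-5, "fatol": 1e-11, "maxiter": 1000},
        )
        if best is None or res.fun < best.fun:
            best = res
    tau, th0, th1 = (max(float(v), 0.0) for v in best.x)
    return tau, th0, min(th1, _THETA1_CAP), float(best.fun)


def mismatch_distribution(
    alignment: HaplotypeAlignment,
    bootstrap_reps: int = 500,
    seed: int | None = None,
) -> MismatchResult:
    """Observed mismatch distribution with sudden-expansion fit.

    p-values for the sum of squared deviations (SSD) and raggedness come
    from a coalescent parametric bootstrap: samples are simulated under the
    fitted sudden-expansion history (so replicate histograms share the
    genealogical correlation structure of real data), refitted, and the
    observed SSD and raggedness are ranked against the simulated ones.
    """
    if alignment.n < 3:
        raise ValueError("mismatch distribution needs at least 3 sequences")
    aln = alignment.restrict(alignment.complete_sites())
    m = aln.to_matrix()
    n = aln.n
    diffs = []
    for i in range(n):
        for j in range(i + 1, n):
            diffs.append(int(np.sum(m[i] != m[j])))
    diffs = np.asarray(diffs)
    n_pairs = len(diffs)
    jmax = int(diffs.max())
    observed = np.bincount(diffs, minlength=jmax + 1).astype(float)
    freqs = observed / n_pairs
    if jmax == 0:
        return MismatchResult(
            observed, n_pairs, 0.0, 0.0, 0.0, 0.0, raggedness(freqs),
            np.nan, np.nan, applicable=False,
        )
    tau, th0, th1, ssd_obs = _fit_sudden_expansion(freqs)
    rg_obs = raggedness(freqs)

    from .coalescent import sim_pairwise_diffs_sudden_expansion

    rng = np.random.default_rng(seed)
    n_ssd = n_rg = 0
    for _ in range(bootstrap_reps):
        sim_d = sim_pairwise_diffs_sudden_expansion(n, tau, th0, th1, rng)
        sim = np.bincount(sim_d, minlength=jmax + 1).astype(float)
        sim = sim / sim.sum()
        mean_b = float(np.sum(np.arange(len(sim)) * sim))
        _, _, _, ssd_b = _fit_sudden_expansion(
            sim, starts=((max(tau, 0.1), max(th0, 0.01), th1),
                         (max(mean_b, 0.1), max(mean_b / 10, 0.01), th1)),
        )
        if ssd_b >= ssd_obs:
            n_ssd += 1
        if raggedness(sim) >= rg_obs:
            n_rg += 1
    p_ssd = (n_ssd + 1.0) / (bootstrap_reps + 1.0)
    p_rg = (n_rg + 1.0) / (bootstrap_reps + 1.0)
    return MismatchResult(
        observed, n_pairs, tau, th0, th1, ssd_obs, rg_obs, p_ssd, p_rg, True
    )
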