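"""The four microsatellite demographic-change tests.

The synthetic population crashed to 1% of its size and recovered 300
generations ago, so the imbalance index should exceed 1, the kurtosis
index S_k should be negative, and the M-ratio should sit near or below
its equilibrium critical value.
"""

from riverpopgen import (
    gw_m_ratio,
    gw_null_distribution,
    kimmel_beta,
    reich_g_test,
    reich_k_test,
    study_like_fixture,
    zhivotovsky_sk,
)

ds = study_like_fixture(seed=1)
gm = ds.genotypes

kb = kimmel_beta(gm)
print(f"imbalance beta = {kb.beta:.3f} (ln beta = {kb.ln_beta:.3f}), "
      f"t = {kb.t:.2f}, p = {kb.p:.3f}")

zk = zhivotovsky_sk(gm)  # R_k = 6.3 for dinucleotide repeats
print(f"S_k = {zk.s_k:.3f} (V = {zk.v_bar:.3f}), t = {zk.t:.2f}, p = {zk.p:.3f}")

mr = gw_m_ratio(gm)
print(f"mean M-ratio = {mr.mean_m:.4f}")
null = gw_null_distribution(
    theta=2.227, p_s=0.8682, delta_g=3.5, n_genes=2 * gm.n,
    reps=2000, seed=8, n_loci=gm.n_loci, observed_m=mr.mean_m,
)
print(f"equilibrium mean M = {null.mean:.4f}, critical M_c = {null.m_c:.4f}")
print(f"rank p of observed mean M = {null.rank_p:.3f} "
      f"(significant reduction: {null.significant_reduction})")

rk = reich_k_test(gm)
print(f"intralocus k: {rk.n_positive}/{rk.n_polymorphic} positive, "
      f"binomial p = {rk.binomial_p:.3f}")
rg = reich_g_test(gm, seed=9, reps=500)
print(f"interlocus g = {rg.g:.3f} (cutoff {rg.cutoff:.3f}), p = {rg.p:.3f}")
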