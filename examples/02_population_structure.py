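"""Between-site differentiation for the maternal sequence marker.

Computes the Hudson-family statistics with permutation significance,
converts fixation indices to island-model gene-flow estimates, and runs
the pairwise exact probability tests with Kimura 2P distances.
"""

import numpy as np

from riverpopgen import (
    hudson_heterogeneity,
    islandmodel_nm,
    pairwise_exact_tests,
    study_like_fixture,
)

ds = study_like_fixture(seed=1)

het = hudson_heterogeneity(ds.alignment, ds.popmap, perms=2000, seed=3)
print(f"chi2 = {het.chi2:.1f} (df = {het.df}), p = {het.chi2_p:.3g}")
for name in ("H_ST", "K_ST", "K_ST_star", "S_nn", "gamma_ST", "N_ST", "F_ST"):
    line = f"{name:10s} = {het.statistics[name]:7.4f}  p = {het.p_values[name]:.4f}"
    if name in het.nm:
        line += f"  Nm = {het.nm[name]:.2f}"
    print(line)

# the island-model conversion on its own: a fixation index of 0.25 for a
# maternal (haploid) marker corresponds to ~1.5 female migrants/generation
print(f"\nNm at F = 0.25 (haploid): {islandmodel_nm(0.25, 'haploid'):.2f}")

pw = pairwise_exact_tests(ds.alignment, ds.popmap, mcmc=(1000, 10, 500), seed=4)
iu = np.triu_indices(len(pw.populations), 1)
sig = np.sum(pw.exact_p[iu] < 0.05)
print(f"{sig} of {len(pw.exact_p[iu])} site pairs differ at p < 0.05")
print(f"mean net Kimura 2P distance: {np.nanmean(pw.d_net[iu]):.4f}")
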