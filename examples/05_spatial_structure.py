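"""Spatial genetic structure: isolation by distance, distance-class
correlograms, distograms and an IDW genetic landscape.
"""

import numpy as np

from riverpopgen import (
    ay_correlogram,
    aida_autocorrelation,
    distogram,
    geo_distance_matrix,
    landscape_idw,
    mantel_test,
    study_like_fixture,
)
from riverpopgen.seq_structure import pairwise_differences

ds = study_like_fixture(seed=1)
aln, popmap = ds.alignment, ds.popmap

# population-level matrices for the Mantel test
pops, geo = geo_distance_matrix(popmap)
d = pairwise_differences(aln)
labels = popmap.labels_for(aln.sample_ids)
idx = {p: [i for i, l in enumerate(labels) if l == p] for p in pops}
gen = np.zeros_like(geo)
for i, a in enumerate(pops):
    for j in range(i + 1, len(pops)):
        gen[i, j] = gen[j, i] = d[np.ix_(idx[a], idx[pops[j]])].mean()

r, p = mantel_test(gen, geo, perms=5000, seed=10)
print(f"Mantel r = {r:.3f} (r^2 = {r**2:.3f}), p = {p:.4f}")
r_log, p_log = mantel_test(gen, geo, perms=5000, seed=10, log_geo=True)
print(f"log-distance Mantel r = {r_log:.3f}, p = {p_log:.4f}")

coords = np.array([popmap.coordinates[l] for l in labels])
ay = ay_correlogram(d / d.max(), coords, scheme=5, perms=1000, seed=11)
print("\nAy correlogram (0 = identical, 1 = maximally dissimilar):")
for c in ay.classes:
    print(f"  class {c}: Ay = {ay.ay[c]:.3f}, p = {ay.ay_p[c]:.3f}")
print(f"V (variance of Ay across classes) = {ay.v:.4f}, p = {ay.v_p:.3f}")

aida = aida_autocorrelation(aln, popmap, "distance_classes", 6, 500, seed=12)
print("\nMoran II / Geary cc per class:")
for c in aida.classes:
    print(f"  class {c}: II = {aida.moran_ii[c]:+.3f}, "
          f"cc = {aida.geary_cc[c]:.3f}")

# distogram on haplotype frequency vectors
seen, _ = aln.haplotype_classes()
freqs = np.zeros((len(pops), len(seen)))
for i, l in enumerate(labels):
    freqs[pops.index(l), seen[aln.sequences[i]]] += 1
freqs = freqs / freqs.sum(axis=1, keepdims=True)
pop_coords = np.array([popmap.coordinates[p] for p in pops])
dg = distogram(freqs, pop_coords, 4, "gregorius", mc_reps=2000, seed=13)
print("\nGregorius distogram class means (with 95% envelope flags):")
for c in dg.classes:
    mark = "*" if dg.outside[c] else ""
    print(f"  class {c}: d = {dg.values[c]:.3f} {mark}")

surface = landscape_idw(coords, d / d.max(), grid=(30, 30))
print(f"\nIDW landscape: surface range "
      f"{surface.surface.min():.3f}..{surface.surface.max():.3f} "
      f"over a {surface.surface.shape} grid")
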