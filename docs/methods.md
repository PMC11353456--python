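# Methods

This note documents the models and estimators implemented in
`riverpopgen`, the choices made where the design was genuinely open, and
what the synthetic-data generator does and does not emulate.

## Data model

Sequences are haploid, aligned, over `{A, C, G, T, -, N}`; sites carrying
any gap or N are removed before all diversity, neutrality and haplotype
computations (complete deletion), so segregating sites, π and haplotype
identity refer to one consistent site set.  Kimura 2P distances are the
one exception: they compare sites pairwise-complete, because distances
lose less information that way and do not need to agree site-for-site
with the haplotype partition.  Microsatellite alleles are stored in
repeat units (size / repeat length) because every demographic statistic —
allele-size variance V, kurtosis K, the M-ratio's range r — is defined on
repeat counts.  Missing alleles are explicit; a half-called genotype is
treated as missing.  Analyses use per-locus available-case exclusion; no
imputation anywhere.

## Sequence diversity and neutrality

Haplotype diversity uses the small-sample correction n(1−Σp²)/(n−1) with
Nei's large-sample variance; π is the mean pairwise difference per site;
Watterson's θ is S/a₁.  Tajima's D, Fu & Li's D*/F* (no outgroup,
singleton = minor-allele-count 1) and the R2 statistic follow the
classical formulas; Fu's F_S is computed from the Ewens sampling
distribution at θ = k̄ through an unsigned-Stirling-number recurrence in
log space, which stays finite at n ≈ 100 where the direct products
overflow.

Significance comes from a neutral constant-size coalescent conditioned on
θ̂ = k̄ (not on S; conditioning on the mean pairwise diversity is the
choice that matches how the statistics are centred).  Each replicate is
summarised without building sequences: a mutation on a branch defines a
site whose derived count is the number of tips below, and haplotype
number follows from contracting mutation-free branches.  D, D* and F* are
tested two-sided (twice the smaller tail); F_S and R2 lower-tailed, the
direction that expansion pushes them.  Permutation and simulation
p-values are always (exceedances + 1)/(reps + 1) and therefore never 0.

The mismatch distribution is fitted to the sudden-expansion model
F_j(τ, θ₀, θ₁) = F̂_j(θ₁) + e^{−τ(1+1/θ₁)} Σᵢ τ^{j−i}/(j−i)! [F̂ᵢ(θ₀) −
F̂ᵢ(θ₁)] by Nelder–Mead least squares (θ₁ capped at 10⁴ — the expanded
size is weakly identified, as in the classical implementations).  The SSD
and raggedness p-values use a coalescent parametric bootstrap: replicate
samples are simulated under the fitted history (a coalescence-rate jump
of θ₁/θ₀ at time τ/θ₁) and refitted, so the bootstrap histograms carry
the genealogical correlation between pairs that a multinomial resample
would miss.

## Sequence differentiation

K_ST = 1 − K_S/K_T on mean pairwise differences with sample-size weights
n_j/n; K_ST* uses log(1+d)-transformed distances; H_ST the same
construction on unbiased haplotype diversities; Z_S and Z_S* are the
weighted mean (and log of the mean) within-population rank of the
pairwise distances, tested lower-tailed since structure shortens
within-population distances.  S_nn is the mean fraction of nearest
neighbours in the same population, ties sharing weight equally.  γ_ST
comes from haplotype frequencies with the Nei–Chesser small-sample
corrections; N_ST contrasts the unweighted mean within-population
diversity with the pooled total; F_ST is the within/between contrast
(1 − H_w/H_b) with populations weighted equally.  Single-individual
populations are excluded from within-population terms and flagged.

Exact probability tests on haplotype (and genic/genotypic) contingency
tables enumerate the full table space when it is small (≤ ~10⁵–10⁶
tables) and otherwise run a Metropolis chain over tables with fixed
margins, with batch-mean standard errors; the Hardy–Weinberg analogue
uses Levene's conditional distribution over genotype tables.  AMOVA is
the standard nested sums-of-squares decomposition on squared pairwise
differences (Φ-type), with the three classical permutation schemes
(individuals among populations, individuals within groups, whole
populations among groups).

Island-model gene flow: Nm = (1−F)/(2F) for organelle (haploid) markers
and (1−F)/(4F) for nuclear diploid markers.  The haploid divisor is
validated against the published conversions (0.3771 → 0.83,
0.2504 → 1.50, 0.2509 → 1.49).

## Microsatellites

Expected heterozygosity uses the 2n/(2n−1) unbiased correction.  The
Robertson–Hill inbreeding estimator is implemented as the score estimator
at f = 0, f̂ = [Σᵢ n_ii(1−p̂ᵢ)/p̂ᵢ − n_het]/(n(k−1)), whose sampling
variance ≈ 1/(n(k−1)) is the minimum-variance property that estimator is
used for.  F-statistics are Weir–Cockerham variance components summed
over alleles and loci, negative components retained so multilocus sums
stay unbiased; significance comes from G-statistic randomisation of
genotypes among populations.  Nei's (1978) distance applies the
small-sample homozygosity correction per locus, averages the three
identity terms across loci, and reports pairs with zero shared identity
as infinite.  Private-allele gene flow uses the log-linear calibration
for samples of 25, ln p̄(1) = −0.505 ln Nm − 2.44, with the 25/n̄
multiplicative sample-size correction.  Assignment scores multilocus
genotypes against leave-one-out (home) or full (elsewhere) allele
frequencies — substitute frequency 0.01 for unobserved alleles, or
Rannala–Mountain posterior-predictive frequencies under the Bayesian
criterion — with exclusion p-values from genotypes simulated out of each
candidate population.  The first-generation-migrant test on
L = L_home/L_max simulates each null replicate as a resident *plus its
whole reference sample*, scoring the simulated focal leave-one-out within
its own simulated sample; this keeps the null L distribution
out-of-sample in the same way the observed statistic is.  (Scoring
simulated residents against the empirical frequencies they were drawn
from makes them look too much at home and flags half the true residents;
the joint construction brings the false-flag rate near nominal under
genuine structure, though it stays somewhat inflated when differentiation
is essentially zero — a known weakness of likelihood-ratio migrant
detection at F_ST ≈ 0.)

## Microsatellite demography

* **Imbalance index.**  θ_V = 2V̄ (single-step expectation E[V] = θ/2) and
  θ_P0 from the unbiased homozygosity inverted through
  P₀ = 1/√(1+2θ); the inversion is applied to the multilocus mean
  homozygosity, because inverting per locus and averaging inflates θ_P0
  through the convexity of the inversion and biases ln β low.  β > 1
  signals growth from an earlier bottleneck; significance is a
  delete-one-locus jackknife t with loci−1 df.
* **S_k.**  S_k = 1 − (K̄ − R_k V̄/2)/(5V̄²) with bias-corrected variance
  and fourth central moment averaged over loci; R_k = 6.3 (dinucleotide
  mutational kurtosis/variance ratio), σ²_m = 2.39 carried for θ
  conversion.  The printed form of this formula has unbalanced
  parentheses; this reading is the only one with the documented sign
  behaviour (positive under expansion, negative after bottlenecks,
  zero at equilibrium).  Note a finite-locus property of the statistic
  itself: the denominator squares the across-locus mean of V, so with L
  loci E[S_k] at equilibrium is positive by O(Var(V)/(L·E[V]²)) — about
  +0.15 at L = 10 and halved at L = 20; the equilibrium test therefore
  uses many loci, and strongly negative observed values (the bottleneck
  signal) are unaffected.
* **M-ratio.**  M = k/r per locus with r = (max − min in repeat units)+1,
  the inclusive-state-count convention under which two alleles two
  repeats apart give M = 2/3.  The equilibrium null simulates coalescent
  loci under the two-phase model: single-step with probability p_s,
  otherwise a multi-step change of 2, 3, … repeats with a geometric tail
  and mean Δ_g (default 3.5); the support starts at 2 because a one-unit
  "multi-step" mutation is a contradiction, and because only this reading
  reproduces the published equilibrium values (mean M ≈ 0.814, M_c ≈
  0.709 at θ = 2.227, p_s = 0.8682, 122 genes).  M_c is the 5th
  percentile of the per-replicate multilocus mean M (10 loci for the
  emulated study); the single-locus 5th percentile is far lower (≈ 0.38)
  because rare large jumps blow up r at individual loci.
* **Reich k and g.**  The intralocus statistic is
  k = 2V̂² + V̂/2 − m̂4, built from the single-step equilibrium moment
  identity E[m₄] = 2E[V²] + E[V]/2 (verified by simulation across a θ
  grid); expansion drives allele-size distributions towards smooth
  compound-Poisson shapes (m₄ ≈ 3V², V concentrated) and k negative.
  Only the sign enters the one-tailed binomial test at p_pos = 0.515.
  The interlocus g statistic is the squared coefficient of variation of
  per-locus V, with its null distribution simulated at matched locus
  count, sample size and θ̂ = 2V̄; low g (below the 5th-percentile
  cutoff) indicates expansion.  Published cutoff tables are not bundled;
  only the simulated cutoff source is provided.

## Spatial statistics

Geographic distances are haversine great-circle km, or shortest paths on
a user-supplied river network.  Distance classes default to
equal-pair-count (quantile) boundaries, half-open [lo, hi) with an
inclusive top edge.  The Mantel statistic is the Pearson correlation of
the off-diagonal entries (hence invariant to affine transforms of either
matrix), tested by joint row/column permutation, with an optional log
transform of geographic distance.  Ay is the mean normalised genetic
distance among pairs within a class — 0 when everyone in the class is
identical, 1 when maximally dissimilar — with per-class two-sided
permutation p and an across-class variance statistic V.  The AIDA-style
II and cc code every allele at every segregating site as a centred
indicator and aggregate the Moran and Geary quadratic forms over sites;
the spatially random expectation of II is −1/(n−1); connectivity can be
km classes or hop counts on Gabriel or Delaunay locality graphs (planar
Delaunay edges cannot cross, so construction itself is the pruning).
Bonferroni correction across classes uses α/classes.  Distograms compare
Gregorius distance (half the L1 distance of haplotype frequency vectors)
or the shared-haplotype proportion (of the union) against a 95%
location-randomisation envelope.  The genetic landscape assigns each
connectivity-edge midpoint its pair's genetic distance and interpolates
on a grid with weights 1/dᵃ (default a = 1, 50×50), returning the
midpoint value exactly at zero distance.

## Network and dating

The median-joining construction starts from the distinct haplotypes,
repeatedly adds the per-site majority consensus of a node triplet when it
strictly lowers the minimum spanning cost (ties broken lexicographically
for determinism), prunes medians that stop helping, and reports the
ε-relaxed minimum-spanning network over the final node set (every link
that ties the minimax path weight is retained, so alternative equally
short connections stay visible).  The spanning cost — what medians can
only reduce — is reported separately from the retained-edge list.  ρ is
the count-weighted mean shortest-path mutational distance from a
user-chosen root; σ_ρ sums descendants² × branch length over the
shortest-path tree, divided by n².  The default conversion is one
mutation per 166,667 years (400 sites at 1.5% per million years); the
alternative printed figure of 166,167 years can be passed explicitly, and
the two differ by 0.3%.

## The synthetic generator

`SimulationConfig` describes a river metapopulation: sites with
coordinates and sample sizes, stepping-stone migration along river
edges only, separate female and male per-generation migration rates, a
piecewise size history shared by all sites, an HKY sequence marker
(κ = 10, control-region-like) and two-phase microsatellites.  Ancestry is
msprime's structured coalescent; sequence mutations are msprime's HKY;
microsatellite mutations are dropped on the simulated genealogies by the
same two-phase layer the M-ratio null uses, so generator and test share
one mutation model.  The maternal marker uses the female effective size
(half the autosomal size by default) and female migration only; autosomes
use the mean of the female and male rates.

The study-like fixture places 10 sites at the emulated study's
coordinates with its sample sizes (82 sequences; 61 genotyped
individuals allocated largest-remainder), philopatric females
(0.003/generation to each adjacent site, ≈ 1.5 female migrants per
generation) against mobile males (0.05), and a crash to 1% of size
between 300 and 8,000 generations ago.  These values were calibrated once
against the emulated design's stated features — about 15 control-region
haplotypes with two dominant ones, maternal gene flow near 1.5
migrants/generation, microsatellite θ near 2 — and produce mean H ≈ 16,
two dominant haplotypes carrying ~half the sample, maternal F_ST ≈ 0.4
against microsatellite F_ST ≈ 0.01, β > 1, S_k ≈ −2.6 and mean M ≈ 0.83.

What the generator does **not** emulate: sequencing or genotyping error,
allele dropout and stutter, departures from neutrality, within-site
kin structure, temporally varying migration, or recombination (none is
expected for the markers modelled).  Passing tests therefore show that
the estimators behave correctly on clean data generated under the model
assumptions, not that they are robust to the technical artefacts of real
datasets.

Problem sizes in the test suite (sample sizes of 20–122, 4–40 loci,
hundreds of replicates for calibration checks, 10,000 replicates for the
M-ratio null) were chosen as the smallest designs at which the checked
expectations are comfortably resolvable against Monte-Carlo noise.

## Known limitations

* The exact-test Markov chain uses a simple Metropolis ±1 swap; heavily
  sparse tables mix slowly, which the batch standard error makes visible
  but does not cure.
* The Barton–Slatkin private-allele calibration uses the n = 25
  regression line with a multiplicative sample-size correction rather
  than interpolating the original three regression lines.
* The median-joining search adds one best median per round (greedy); on
  pathological inputs a non-greedy search could find a cheaper Steiner
  topology, though the brute-force checks on small toys agree exactly.
* The AIDA site-weighting aggregates indicator covariances over all
  sites and alleles jointly, the natural multivariate reading of the
  method; per-site averaging variants exist and would differ slightly.
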