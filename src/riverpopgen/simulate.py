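"""Synthetic river-metapopulation data generator.

Simulates the joint study design the analyses assume: sampling sites on a
branching river network, stepping-stone migration restricted to adjacent
sites, sex-biased dispersal (philopatric females, mobile males), piecewise
population-size history, a ~400 bp control-region-like maternal sequence
marker, and diploid dinucleotide microsatellites under the two-phase
mutation model.

Ancestry comes from msprime (structured coalescent); sequence mutations
use the HKY model with a transition bias, while microsatellite mutations
are dropped on the simulated genealogies by this package's own two-phase
layer so that the generator and the demographic tests share one mutation
model.

The maternal marker is simulated with the female migration rates and the
female effective size; autosomal microsatellites use the mean of the
female and male rates.  This reproduces mechanistically the philopatry
contrast in which maternal-marker differentiation exceeds nuclear-marker
differentiation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import msprime
import numpy as np

from .coalescent import _signed_steps
from .datatypes import GenotypeMatrix, HaplotypeAlignment, PopulationAssignment

# coordinates and sample sizes of the emulated sampling design:
# (site name, latitude, longitude, sequences sampled)
STUDY_SITES: list[tuple[str, float, float, int]] = [
    ("IbareMamore", -14.550, -65.003, 36),
    ("MiddleMamore", -13.445, -65.235, 10),
    ("Bolivar", -12.393, -65.159, 3),
    ("ElCorte", -11.925, -65.054, 5),
    ("Secure", -15.333, -65.020, 3),
    ("UpperIbare", -14.333, -64.900, 5),
    ("Tijamuchi", -14.450, -65.900, 2),
    ("ElAzul", -11.972, -65.036, 2),
    ("SanMartin", -13.300, -63.417, 2),
    ("Ipurupuru", -14.302, -65.050, 14),
]

#: river-network adjacency (stepping-stone migration runs along these)
STUDY_EDGES: list[tuple[str, str]] = [
    ("Secure", "IbareMamore"),
    ("UpperIbare", "IbareMamore"),
    ("Tijamuchi", "IbareMamore"),
    ("Ipurupuru", "IbareMamore"),
    ("IbareMamore", "MiddleMamore"),
    ("MiddleMamore", "Bolivar"),
    ("Bolivar", "ElCorte"),
    ("ElCorte", "ElAzul"),
    ("ElAzul", "SanMartin"),
]


@dataclass
class SimulationConfig:
    """Full generative description of a river metapopulation."""

    seed: int = 0
    sites: list[tuple[str, float, float, int]] = field(
        default_factory=lambda: list(STUDY_SITES)
    )
    edges: list[tuple[str, str]] = field(default_factory=lambda: list(STUDY_EDGES))
    #: diploid effective size per site (autosomal markers)
    ne: float = 1000.0
    #: female effective size per site (maternal marker); default ne / 2
    female_ne: float | None = None
    #: per-generation probability of moving to each adjacent site
    female_migration: float = 0.003
    male_migration: float = 0.05
    #: piecewise history: (time in generations ago, size factor applied
    #: to all sites pastward of that time); times increasing into the past
    history: list[tuple[float, float]] = field(default_factory=list)
    # sequence marker
    seq_length: int = 400
    seq_mut_rate: float = 3e-6  # per site per generation
    ts_tv_ratio: float = 10.0
    # microsatellites
    n_loci: int = 10
    msat_mut_rate: float = 5e-4  # per locus per generation
    p_s: float = 0.88
    delta_g: float = 3.5
    repeat_unit: int = 2
    msat_sample_sizes: list[int] | None = None  # default scaled from sites
    generation_time_years: float = 7.0

    def __post_init__(self) -> None:
        if any(s[3] < 1 for s in self.sites):
            raise ValueError("every site needs a sample size >= 1")
        names = [s[0] for s in self.sites]
        if len(set(names)) != len(names):
            raise ValueError("duplicate site names")
        for a, b in self.edges:
            if a not in names or b not in names:
                raise ValueError(f"edge ({a}, {b}) references unknown site")
        times = [t for t, _ in self.history]
        if times != sorted(times):
            raise ValueError("history times must increase into the past")

    @property
    def site_names(self) -> list[str]:
        return [s[0] for s in self.sites]

    def coordinates(self) -> dict[str, tuple[float, float]]:
        return {name: (lat, lon) for name, lat, lon, _ in self.sites}

    def msat_sizes(self) -> list[int]:
        """Microsatellite sample sizes; default scales the sequence sizes
        to the study's 61 genotyped individuals (largest-remainder)."""
        if self.msat_sample_sizes is not None:
            return list(self.msat_sample_sizes)
        seq_sizes = np.array([s[3] for s in self.sites], dtype=float)
        total = int(round(seq_sizes.sum() * 61.0 / 82.0))
        raw = seq_sizes * total / seq_sizes.sum()
        base = np.floor(raw).astype(int)
        base = np.maximum(base, 1)
        rem = total - base.sum()
        order = np.argsort(-(raw - np.floor(raw)))
        i = 0
        while rem > 0:
            base[order[i % len(base)]] += 1
            rem -= 1
            i += 1
        return base.tolist()


def _demography(
    config: SimulationConfig, sizes: float, migration: float
) -> msprime.Demography:
    dem = msprime.Demography()
    for name in config.site_names:
        dem.add_population(name=name, initial_size=sizes)
    for a, b in config.edges:
        dem.set_symmetric_migration_rate([a, b], migration)
    for t, factor in config.history:
        for name in config.site_names:
            dem.add_population_parameters_change(
                time=t, population=name, initial_size=sizes * factor
            )
    dem.sort_events()
    return dem


def simulate_sequences(
    config: SimulationConfig,
) -> tuple[HaplotypeAlignment, PopulationAssignment]:
    """Control-region-like alignment via the structured coalescent.

    Maternal transmission: female effective sizes and female migration
    rates, haploid samples, HKY mutations with the configured transition
    bias on a finite ``seq_length``-site sequence.
    """
    nf = config.female_ne if config.female_ne is not None else config.ne / 2.0
    dem = _demography(config, nf, config.female_migration)
    samples = {name: s[3] for name, s in zip(config.site_names, config.sites)}
    ts = msprime.sim_ancestry(
        samples=samples,
        demography=dem,
        ploidy=1,
        sequence_length=config.seq_length,
        random_seed=(config.seed % 2**31) + 1,
    )
    ts = msprime.sim_mutations(
        ts,
        rate=config.seq_mut_rate,
        model=msprime.HKY(kappa=config.ts_tv_ratio),
        random_seed=(config.seed % 2**31) + 2,
    )
    rng = np.random.default_rng(config.seed + 3)
    ref = rng.choice(list("ACGT"), size=config.seq_length)
    n = ts.num_samples
    chars = np.tile(ref, (n, 1))
    for var in ts.variants():
        pos = int(var.site.position)
        alleles = var.alleles
        for i, g in enumerate(var.genotypes):
            chars[i, pos] = alleles[g]

    sample_ids = []
    labels = []
    pop_of_node = {}
    for pop in ts.populations():
        pop_of_node[pop.id] = pop.metadata["name"]
    counters = {name: 0 for name in config.site_names}
    node_pops = [ts.node(u).population for u in ts.samples()]
    for u, p in zip(ts.samples(), node_pops):
        name = pop_of_node[p]
        counters[name] += 1
        sample_ids.append(f"{name}_{counters[name]:02d}")
        labels.append(name)
    seqs = tuple("".join(row) for row in chars)
    aln = HaplotypeAlignment(tuple(sample_ids), seqs)
    popmap = PopulationAssignment(
        dict(zip(sample_ids, labels)), config.coordinates()
    )
    return aln, popmap


def _drop_msat_mutations(
    ts, mu: float, p_s: float, delta_g: float, rng: np.random.Generator
) -> np.ndarray:
    """Two-phase mutations on a single-tree sequence; returns sample alleles."""
    tree = ts.first()
    value = np.zeros(ts.num_nodes, dtype=np.int64)
    for u in tree.nodes(order="preorder"):
        parent = tree.parent(u)
        if parent == -1:
            value[u] = 50
            continue
        blen = tree.branch_length(u)
        k = rng.poisson(mu * blen)
        v = value[parent] + _signed_steps(int(k), p_s, delta_g, rng)
        while v < 1:
            v = 2 - v
        value[u] = v
    return value[ts.samples()]


def simulate_microsatellites(config: SimulationConfig) -> GenotypeMatrix:
    """Diploid microsatellite genotypes on the river network.

    Autosomal transmission: migration is the mean of the female and male
    rates; each locus is an independent non-recombining msprime genealogy
    with this package's two-phase mutation layer dropped on it.
    """
    mig = 0.5 * (config.female_migration + config.male_migration)
    dem = _demography(config, config.ne, mig)
    sizes = config.msat_sizes()
    samples = {name: k for name, k in zip(config.site_names, sizes)}
    rng = np.random.default_rng(config.seed + 7)
    n_ind = sum(sizes)
    arr = np.zeros((n_ind, config.n_loci, 2), dtype=np.int64)
    reps = msprime.sim_ancestry(
        samples=samples,
        demography=dem,
        ploidy=2,
        num_replicates=config.n_loci,
        random_seed=(config.seed % 2**31) + 11,
    )
    ind_pops: list[str] | None = None
    for li, ts in enumerate(reps):
        alleles = _drop_msat_mutations(
            ts, config.msat_mut_rate, config.p_s, config.delta_g, rng
        )
        node_of_sample = {u: i for i, u in enumerate(ts.samples())}
        if ind_pops is None:
            ind_pops = []
            pop_names = {p.id: p.metadata["name"] for p in ts.populations()}
            for ind in ts.individuals():
                ind_pops.append(pop_names[ts.node(ind.nodes[0]).population])
        for ii, ind in enumerate(ts.individuals()):
            a = alleles[node_of_sample[ind.nodes[0]]]
            b = alleles[node_of_sample[ind.nodes[1]]]
            arr[ii, li] = (a, b)
    counters: dict[str, int] = {}
    ids = []
    for p in ind_pops:
        counters[p] = counters.get(p, 0) + 1
        ids.append(f"{p}_m{counters[p]:02d}")
    loci = tuple(f"Loc{li + 1:02d}" for li in range(config.n_loci))
    return GenotypeMatrix(
        tuple(ids),
        loci,
        arr,
        {l: config.repeat_unit for l in loci},
        tuple(ind_pops),
    )


@dataclass
class SyntheticDataset:
    alignment: HaplotypeAlignment
    popmap: PopulationAssignment
    genotypes: GenotypeMatrix
    config: SimulationConfig

    def msat_popmap(self) -> PopulationAssignment:
        return self.genotypes.popmap(self.config.coordinates())


def study_like_fixture(seed: int = 0) -> SyntheticDataset:
    """A dataset emulating the study design: 10 river sites with the
    printed coordinates and sample sizes (82 sequences, 61 genotyped
    individuals), philopatric females and mobile males, and a moderate
    historical bottleneck."""
    config = SimulationConfig(
        seed=seed,
        history=[(300.0, 0.01), (8000.0, 1.0)],
    )
    aln, popmap = simulate_sequences(config)
    gm = simulate_microsatellites(config)
    return SyntheticDataset(aln, popmap, gm, config)
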