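import numpy as np
import pytest

from riverpopgen.datatypes import (
    GenotypeMatrix,
    HaplotypeAlignment,
    PopulationAssignment,
)


@pytest.fixture
def toy_alignment():
    """Six 20-bp sequences in two populations, three haplotypes."""
    seqs = (
        "ACGTACGTACGTACGTACGT",
        "ACGTACGTACGTACGTACGT",
        "ACGTACGTACGAACGTACGT",
        "ACGAACGTACGAACGTACGT",
        "ACGAACGTACGAACGTACGT",
        "ACGAACGTACGAACGAACGT",
    )
    ids = tuple(f"s{i}" for i in range(6))
    return HaplotypeAlignment(ids, seqs)


@pytest.fixture
def toy_popmap():
    return PopulationAssignment(
        {f"s{i}": ("A" if i < 3 else "B") for i in range(6)},
        {"A": (-14.0, -65.0), "B": (-12.0, -65.1)},
    )


def make_genotypes(geno_lists, populations=None, loci=None):
    """Build a GenotypeMatrix from per-individual lists of (a, b) pairs."""
    n = len(geno_lists)
    L = len(geno_lists[0])
    arr = np.array(geno_lists, dtype=np.int64)
    loci = tuple(loci or (f"L{i + 1}" for i in range(L)))
    return GenotypeMatrix(
        tuple(f"ind{i}" for i in range(n)),
        loci,
        arr,
        {l: 2 for l in loci},
        tuple(populations) if populations is not None else None,
    )


@pytest.fixture
def study_fixture():
    from riverpopgen.simulate import study_like_fixture

    return study_like_fixture(seed=1)
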