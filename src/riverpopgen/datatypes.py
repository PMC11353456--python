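"""Core in-memory containers shared by every analysis stage.

Three containers cover the two marker types and their geography:

* :class:`HaplotypeAlignment` — an aligned set of haploid sequences
  (mitochondrial control-region-like, typically ~400 bp).
* :class:`PopulationAssignment` — sample → population labels plus decimal
  latitude/longitude per population (negative = south/west).
* :class:`GenotypeMatrix` — diploid microsatellite genotypes with allele
  sizes expressed in repeat units, because every allele-size statistic
  (variance, kurtosis, M-ratio) is defined on repeat counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SEQ_ALPHABET = frozenset("ACGT-N")

#: sentinel for a missing allele in a GenotypeMatrix
MISSING = -1


class AlignmentError(ValueError):
    """Raised for ragged alignments or illegal sequence characters."""


class MappingError(KeyError):
    """Raised when a sample cannot be mapped to a population."""


@dataclass(frozen=True)
class HaplotypeAlignment:
    """Aligned haploid sequences over the alphabet ``{A, C, G, T, -, N}``."""

    sample_ids: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.sequences):
            raise AlignmentError("sample_ids and sequences differ in length")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise AlignmentError("duplicate sample ids")
        if self.sequences:
            L = len(self.sequences[0])
            for sid, seq in zip(self.sample_ids, self.sequences):
                if len(seq) != L:
                    raise AlignmentError(
                        f"sequence {sid!r} has length {len(seq)}, expected {L}"
                    )
                bad = set(seq) - SEQ_ALPHABET
                if bad:
                    raise AlignmentError(
                        f"illegal character(s) {sorted(bad)} in sequence {sid!r}"
                    )

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def to_matrix(self) -> np.ndarray:
        """(n, L) uint8 matrix of character codes."""
        return np.frombuffer(
            "".join(self.sequences).encode(), dtype=np.uint8
        ).reshape(self.n, self.length)

    def complete_sites(self) -> np.ndarray:
        """Indices of sites free of gaps and Ns in every sequence."""
        m = self.to_matrix()
        ok = ~np.any((m == ord("-")) | (m == ord("N")), axis=0)
        return np.flatnonzero(ok)

    def restrict(self, sites: np.ndarray) -> "HaplotypeAlignment":
        m = self.to_matrix()[:, sites]
        seqs = tuple(row.tobytes().decode() for row in m)
        return HaplotypeAlignment(self.sample_ids, seqs)

    def subset(self, sample_ids) -> "HaplotypeAlignment":
        wanted = list(sample_ids)
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in wanted if s not in idx]
        if missing:
            raise MappingError(f"samples not in alignment: {missing}")
        return HaplotypeAlignment(
            tuple(wanted), tuple(self.sequences[idx[s]] for s in wanted)
        )

    def haplotype_classes(self) -> tuple[dict[str, int], list[str]]:
        """Map sequence string → haplotype index, and per-sample labels."""
        seen: dict[str, int] = {}
        labels = []
        for seq in self.sequences:
            if seq not in seen:
                seen[seq] = len(seen)
            labels.append(seq)
        return seen, labels


@dataclass(frozen=True)
class PopulationAssignment:
    """Sample → population labels plus per-population coordinates."""

    sample_to_pop: dict[str, str]
    coordinates: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pop, (lat, lon) in self.coordinates.items():
            if not (np.isfinite(lat) and np.isfinite(lon)):
                raise ValueError(f"non-finite coordinates for population {pop!r}")

    @property
    def populations(self) -> list[str]:
        """Population labels in first-appearance order."""
        out: list[str] = []
        for p in self.sample_to_pop.values():
            if p not in out:
                out.append(p)
        return out

    def pop_of(self, sample: str) -> str:
        try:
            return self.sample_to_pop[sample]
        except KeyError:
            raise MappingError(f"sample {sample!r} missing from population map")

    def samples_of(self, pop: str) -> list[str]:
        return [s for s, p in self.sample_to_pop.items() if p == pop]

    def labels_for(self, sample_ids) -> list[str]:
        return [self.pop_of(s) for s in sample_ids]


@dataclass(frozen=True)
class GenotypeMatrix:
    """Diploid genotypes at microsatellite loci, allele sizes in repeat units.

    ``alleles`` has shape ``(n_samples, n_loci, 2)``; missing alleles are
    coded :data:`MISSING`.  Genotypes are unordered pairs; constructors
    normalise each pair so ``alleles[..., 0] <= alleles[..., 1]``.
    """

    sample_ids: tuple[str, ...]
    loci: tuple[str, ...]
    alleles: np.ndarray
    repeat_units: dict[str, int] = field(default_factory=dict)
    populations: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.alleles, dtype=np.int64)
        if arr.shape != (len(self.sample_ids), len(self.loci), 2):
            raise ValueError(
                f"alleles shape {arr.shape} != "
                f"({len(self.sample_ids)}, {len(self.loci)}, 2)"
            )
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("duplicate locus names")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        valid = arr != MISSING
        if np.any(arr[valid] <= 0):
            raise ValueError("allele sizes must be positive in repeat units")
        # half-missing genotypes are treated as fully missing
        half = valid[..., 0] != valid[..., 1]
        arr = arr.copy()
        arr[half] = MISSING
        arr = np.sort(arr, axis=-1)
        # sort puts MISSING (-1) first which is fine as a canonical order
        object.__setattr__(self, "alleles", arr)

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def locus_index(self, locus: str) -> int:
        return self.loci.index(locus)

    def genotyped_mask(self) -> np.ndarray:
        """(n, n_loci) bool — True where the genotype is complete."""
        return np.all(self.alleles != MISSING, axis=-1)

    def allele_counts(self, locus_idx: int, sample_idx=None) -> dict[int, int]:
        """Counts of each allele (gene copies) at a locus."""
        a = self.alleles[:, locus_idx, :]
        if sample_idx is not None:
            a = a[sample_idx]
        a = a[a != MISSING]
        vals, counts = np.unique(a, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def subset(self, sample_idx) -> "GenotypeMatrix":
        sample_idx = np.asarray(sample_idx)
        pops = (
            tuple(np.asarray(self.populations)[sample_idx].tolist())
            if self.populations is not None
            else None
        )
        return GenotypeMatrix(
            tuple(np.asarray(self.sample_ids)[sample_idx].tolist()),
            self.loci,
            self.alleles[sample_idx],
            self.repeat_units,
            pops,
        )

    def popmap(
        self, coordinates: dict[str, tuple[float, float]] | None = None
    ) -> PopulationAssignment:
        """Build a :class:`PopulationAssignment` from the embedded labels."""
        if self.populations is None:
            raise MappingError("genotype matrix carries no population labels")
        return PopulationAssignment(
            dict(zip(self.sample_ids, self.populations)), coordinates or {}
        )
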