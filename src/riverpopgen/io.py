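"""Readers and writers for the formats the pipeline touches.

FASTA for aligned sequences (via Biopython), Genepop (2- or 3-digit allele
coding) for microsatellite genotypes, a CSV population map
(``sample,population,lat,lon``), and TSV report tables.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datatypes import (
    MISSING,
    GenotypeMatrix,
    HaplotypeAlignment,
    MappingError,
    PopulationAssignment,
)


def read_popmap(popmap_path) -> PopulationAssignment:
    df = pd.read_csv(popmap_path)
    required = {"sample", "population", "lat", "lon"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"popmap must have columns {sorted(required)}, got {list(df.columns)}"
        )
    sample_to_pop = dict(zip(df["sample"].astype(str), df["population"].astype(str)))
    coords: dict[str, tuple[float, float]] = {}
    for _, row in df.iterrows():
        coords[str(row["population"])] = (float(row["lat"]), float(row["lon"]))
    return PopulationAssignment(sample_to_pop, coords)


def read_fasta_with_popmap(
    fasta_path, popmap_path
) -> tuple[HaplotypeAlignment, PopulationAssignment]:
    """Read an aligned FASTA plus its CSV population map.

    Every FASTA record must appear in the popmap; the alignment invariants
    (equal lengths, restricted alphabet) are enforced by the container.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    aln = HaplotypeAlignment(
        tuple(r.id for r in records),
        tuple(str(r.seq).upper() for r in records),
    )
    popmap = read_popmap(popmap_path)
    unmapped = [s for s in aln.sample_ids if s not in popmap.sample_to_pop]
    if unmapped:
        raise MappingError(f"FASTA records missing from popmap: {unmapped}")
    return aln, popmap


def write_fasta(alignment: HaplotypeAlignment, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in zip(alignment.sample_ids, alignment.sequences)
    ]
    SeqIO.write(records, str(path), "fasta-2line")


def write_popmap(popmap: PopulationAssignment, path) -> None:
    rows = []
    for sample, pop in popmap.sample_to_pop.items():
        lat, lon = popmap.coordinates.get(pop, (np.nan, np.nan))
        rows.append({"sample": sample, "population": pop, "lat": lat, "lon": lon})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_genepop(path, repeat_units: dict[str, int] | None = None) -> GenotypeMatrix:
    """Parse a Genepop file into a :class:`GenotypeMatrix`.

    Allele coding is auto-detected: genotype tokens of 4 digits are 2-digit
    coding, 6 digits are 3-digit coding.  ``00``/``000`` is a missing allele.
    When ``repeat_units`` is given, allele sizes (base pairs) are divided by
    the per-locus repeat unit and must divide exactly.
    """
    text = Path(path).read_text()
    lines = [ln.rstrip("\n") for ln in text.splitlines() if ln.strip()]
    if len(lines) < 3:
        raise ValueError("Genepop file too short")
    # line 0 is the title
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        loci.extend(tok.strip() for tok in lines[i].split(",") if tok.strip())
        i += 1
    if i == len(lines):
        raise ValueError("no 'Pop' block found")

    sample_ids: list[str] = []
    pops: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    pop_counter = 0
    current_pop = None
    for ln in lines[i:]:
        if ln.strip().lower() == "pop":
            pop_counter += 1
            current_pop = f"pop{pop_counter}"
            continue
        if "," not in ln:
            raise ValueError(f"malformed individual line (no comma): {ln!r}")
        name, geno = ln.split(",", 1)
        name = name.strip()
        tokens = geno.split()
        if len(tokens) != len(loci):
            raise ValueError(
                f"individual {name!r} has {len(tokens)} genotypes, "
                f"expected {len(loci)}"
            )
        genos = []
        for tok in tokens:
            if len(tok) == 4:
                w = 2
            elif len(tok) == 6:
                w = 3
            else:
                raise ValueError(f"bad genotype token {tok!r} for {name!r}")
            a, b = int(tok[:w]), int(tok[w:])
            genos.append((a, b))
        # Genepop allows duplicate names across pops; disambiguate
        uid = name
        k = 1
        while uid in sample_ids:
            k += 1
            uid = f"{name}.{k}"
        sample_ids.append(uid)
        pops.append(current_pop)
        rows.append(genos)

    arr = np.full((len(sample_ids), len(loci), 2), MISSING, dtype=np.int64)
    for r, genos in enumerate(rows):
        for c, (a, b) in enumerate(genos):
            if a == 0 or b == 0:
                continue
            if repeat_units is not None:
                unit = repeat_units[loci[c]]
                if a % unit or b % unit:
                    raise ValueError(
                        f"allele size not divisible by repeat unit {unit} "
                        f"at locus {loci[c]!r}: {a}/{b}"
                    )
                a, b = a // unit, b // unit
            arr[r, c] = (a, b)
    return GenotypeMatrix(
        tuple(sample_ids),
        tuple(loci),
        arr,
        dict(repeat_units or {}),
        tuple(pops),
    )


def write_genepop(gm: GenotypeMatrix, path, title: str = "riverpopgen export") -> None:
    """Write a 3-digit Genepop file (allele sizes back in base pairs)."""
    if gm.populations is None:
        raise MappingError("genotype matrix carries no population labels")
    buf = _io.StringIO()
    buf.write(title + "\n")
    for locus in gm.loci:
        buf.write(locus + "\n")
    units = np.array([gm.repeat_units.get(l, 1) for l in gm.loci])
    order: list[str] = []
    for p in gm.populations:
        if p not in order:
            order.append(p)
    for pop in order:
        buf.write("Pop\n")
        for s, (sid, plab) in enumerate(zip(gm.sample_ids, gm.populations)):
            if plab != pop:
                continue
            toks = []
            for c in range(gm.n_loci):
                a, b = gm.alleles[s, c]
                if a == MISSING:
                    toks.append("000000")
                else:
                    toks.append(f"{a * units[c]:03d}{b * units[c]:03d}")
            buf.write(f"{sid} ,  " + " ".join(toks) + "\n")
    Path(path).write_text(buf.getvalue())


def write_report(results: dict[str, pd.DataFrame], out_dir) -> list[str]:
    """Write one TSV per analysis table plus a human-readable summary.

    ``results`` maps a table name to a DataFrame; tables are written in
    sorted-name order so repeated calls are byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    summary_lines = []
    for name in sorted(results):
        df = results[name]
        dest = out_dir / f"{name}.tsv"
        df.to_csv(dest, sep="\t", index=False, float_format="%.6g")
        written.append(str(dest))
        summary_lines.append(f"{name}: {len(df)} rows x {len(df.columns)} columns")
    summary = out_dir / "summary.txt"
    summary.write_text("\n".join(summary_lines) + ("\n" if summary_lines else ""))
    written.append(str(summary))
    return written
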