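"""Core data model for annotated circular genomes.

Coordinates are 0-based half-open everywhere inside the package; the 1-based
closed convention appears only at the GFF3 boundary.  On a circular genome an
interval whose ``end`` exceeds the genome length denotes a feature that wraps
across the origin (``end - start`` is always the feature length).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN")
UNAMBIGUOUS = frozenset("ACGT")

#: feature kinds the model recognises
FEATURE_KINDS = frozenset(
    {"CDS", "tRNA", "rRNA", "intron", "exon", "pseudogene", "spacer"}
)

#: kinds that count as "genic" when computing intergenic spacers
GENIC_KINDS = frozenset({"CDS", "tRNA", "rRNA", "exon"})

_KIND_ALIASES = {
    "cds": "CDS",
    "trna": "tRNA",
    "rrna": "rRNA",
    "intron": "intron",
    "exon": "exon",
    "pseudogene": "pseudogene",
    "spacer": "spacer",
    "gene": "CDS",
    "mrna": "CDS",
    "tmrna": "tRNA",
    "misc_feature": "spacer",
}


class GenomeError(ValueError):
    """Raised for malformed sequences, annotations or coordinates."""


@dataclass(frozen=True, order=True)
class Interval:
    """Half-open genomic interval; ``end > start`` after circular normalization."""

    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise GenomeError(f"empty or inverted interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise GenomeError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneAnnotation:
    name: str
    start: int
    end: int
    strand: str
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise GenomeError(f"unknown feature kind {self.kind!r} for {self.name}")
        if self.end <= self.start or self.start < 0:
            raise GenomeError(
                f"bad coordinates [{self.start}, {self.end}) for {self.name}"
            )
        if self.strand not in ("+", "-"):
            raise GenomeError(f"bad strand {self.strand!r} for {self.name}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AnnotatedGenome:
    """A (usually circular) DNA sequence plus typed feature annotations."""

    id: str
    sequence: str
    topology: str = "circular"
    features: list[GeneAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - IUPAC_DNA
        if bad:
            pos = next(i for i, c in enumerate(self.sequence) if c in bad)
            raise GenomeError(
                f"{self.id}: non-IUPAC character {self.sequence[pos]!r} at position {pos}"
            )
        if self.topology not in ("circular", "linear"):
            raise GenomeError(f"bad topology {self.topology!r}")
        self._check_features()

    def _check_features(self) -> None:
        n = len(self.sequence)
        for f in self.features:
            if not 0 <= f.start < n:
                raise GenomeError(f"{self.id}: feature {f.name} start {f.start} outside genome")
            if f.end - f.start > n:
                raise GenomeError(f"{self.id}: feature {f.name} longer than genome")
            if f.end > n and self.topology != "circular":
                raise GenomeError(f"{self.id}: feature {f.name} wraps a linear genome")
        self.features.sort(key=lambda f: (f.start, f.end, f.name))

    @property
    def length(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int) -> str:
        """Subsequence [start, end); indices beyond length wrap on circles."""
        n = self.length
        if end - start > n:
            raise GenomeError("requested span longer than genome")
        if 0 <= start and end <= n:
            return self.sequence[start:end]
        if self.topology != "circular":
            raise GenomeError("coordinates outside a linear genome")
        return "".join(self.sequence[i % n] for i in range(start, end))


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_fasta(path, topology: str = "circular") -> list[AnnotatedGenome]:
    """Read a (multi-)FASTA into genomes with empty feature lists.

    A ``topology=linear`` tag in the record description overrides the
    caller-supplied default; sequences are upper-cased.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise GenomeError(f"{path}: empty or unreadable FASTA")
    genomes = []
    for rec in records:
        topo = topology
        if "topology=linear" in rec.description:
            topo = "linear"
        elif "topology=circular" in rec.description:
            topo = "circular"
        genomes.append(AnnotatedGenome(id=rec.id, sequence=str(rec.seq), topology=topo))
    return genomes


def write_fasta(genomes, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for g in [genomes] if isinstance(genomes, AnnotatedGenome) else genomes:
            fh.write(f">{g.id} topology={g.topology}\n")
            for i in range(0, g.length, width):
                fh.write(g.sequence[i : i + width] + "\n")


def read_gff3(path, genome: AnnotatedGenome, strict: bool = False) -> AnnotatedGenome:
    """Attach GFF3 features to *genome* (coordinates converted to 0-based half-open).

    Unknown feature types are mapped through a small alias table; with
    ``strict=True`` unmapped types raise instead of being skipped.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    feats = []
    for f in db.all_features():
        if f.seqid != genome.id:
            raise GenomeError(
                f"{path}: seqid {f.seqid!r} does not match genome {genome.id!r}"
            )
        ftype = f.featuretype
        kind = ftype if ftype in FEATURE_KINDS else _KIND_ALIASES.get(ftype.lower())
        if kind is None:
            if strict:
                raise GenomeError(f"{path}: unknown feature type {ftype!r}")
            warnings.warn(f"{path}: skipping unknown feature type {ftype!r}")
            continue
        start = f.start - 1  # 1-based closed -> 0-based half-open
        end = f.end
        if not 0 <= start < genome.length:
            raise GenomeError(f"{path}: feature start {f.start} outside {genome.id}")
        if end - start > genome.length or (end > genome.length and genome.topology != "circular"):
            raise GenomeError(f"{path}: feature end {f.end} outside {genome.id}")
        name = f.attributes.get("Name", f.attributes.get("ID", [ftype]))[0]
        feats.append(GeneAnnotation(name=name, start=start, end=end, strand=f.strand, kind=kind))
    out = AnnotatedGenome(genome.id, genome.sequence, genome.topology, feats)
    return out


def write_gff3(genome: AnnotatedGenome, path) -> None:
    """Serialize features as GFF3 (wrap features keep end > genome length)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {genome.length}\n")
        for i, f in enumerate(genome.features, 1):
            attrs = f"ID={f.name}.{i};Name={f.name}"
            fh.write(
                "\t".join(
                    [genome.id, "mitoblocks", f.kind, str(f.start + 1), str(f.end),
                     ".", f.strand, ".", attrs]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Statistics and circular arithmetic
# ---------------------------------------------------------------------------

def gc_content(genome: AnnotatedGenome) -> float:
    """(G+C)/(A+C+G+T); ambiguity codes excluded from both sides of the ratio."""
    if not genome.sequence:
        raise GenomeError("empty sequence")
    counts = {b: genome.sequence.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        raise GenomeError("sequence contains only ambiguity codes")
    return (counts["G"] + counts["C"]) / denom


def _genic_mask(genome: AnnotatedGenome, genic_kinds=GENIC_KINDS) -> np.ndarray:
    mask = np.zeros(genome.length, dtype=bool)
    n = genome.length
    for f in genome.features:
        if f.kind not in genic_kinds:
            continue
        if f.end <= n:
            mask[f.start : f.end] = True
        else:  # wraps the origin
            mask[f.start :] = True
            mask[: f.end - n] = True
    return mask


def intergenic_intervals(genome: AnnotatedGenome, genic_kinds=GENIC_KINDS) -> list[Interval]:
    """Complement of the union of genic features on the circle.

    A gene-free genome yields one full-circle interval; genes tiling the
    whole circle yield an empty list.  The interval crossing the origin is
    reported in wrap notation (end > length).
    """
    n = genome.length
    mask = _genic_mask(genome, genic_kinds)
    if not mask.any():
        return [Interval(0, n)]
    if mask.all():
        return []
    free = ~mask
    # run starts: free position whose (circular) predecessor is genic
    starts = np.flatnonzero(free & ~np.roll(free, 1))
    out = []
    for s in starts:
        e = s
        while free[e % n]:
            e += 1
        out.append(Interval(int(s), int(e)))
    return sorted(out, key=lambda iv: iv.start)


def rotate(genome: AnnotatedGenome, offset: int) -> AnnotatedGenome:
    """Move the origin to *offset*; features shift modulo length."""
    n = genome.length
    if genome.topology != "circular":
        raise GenomeError("cannot rotate a linear genome")
    if not 0 <= offset < n:
        raise GenomeError(f"offset {offset} out of range [0, {n})")
    seq = genome.sequence[offset:] + genome.sequence[:offset]
    feats = []
    for f in genome.features:
        s = (f.start - offset) % n
        feats.append(replace(f, start=s, end=s + f.length))
    return AnnotatedGenome(genome.id, seq, genome.topology, feats)


def genome_stats(genomes) -> "pd.DataFrame":
    """Per-genome summary: length, GC%, feature counts, unique gene names."""
    import pandas as pd

    rows = []
    for g in [genomes] if isinstance(genomes, AnnotatedGenome) else genomes:
        row = {
            "genome": g.id,
            "length_bp": g.length,
            "gc_pct": round(100 * gc_content(g), 1),
            "n_features": len(g.features),
            "n_unique_genes": len({f.name for f in g.features}),
        }
        for kind in sorted(FEATURE_KINDS):
            row[f"n_{kind}"] = sum(1 for f in g.features if f.kind == kind)
        rows.append(row)
    return pd.DataFrame(rows)
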