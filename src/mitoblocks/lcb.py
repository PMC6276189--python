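"""Locally collinear block (LCB) decomposition of a genome pair.

Anchors are maximal exact matches, unique in both genomes (either strand),
found by merging unique shared k-mers along diagonals (k = the minimum
anchor length).  Greedy chaining of strand- and order-consistent anchors
yields blocks; the observed genome's block order relative to the reference
is read off as a signed permutation.  Repeat copies are automatically
excluded from anchor candidacy by the uniqueness requirement — which is
load-bearing: it is precisely what makes block boundaries fall at the
repeat copies flanking rearrangement junctions.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

from .genome import AnnotatedGenome, Interval, intergenic_intervals, reverse_complement
from .repeats import RepeatPair


class LCBError(ValueError):
    pass


@dataclass(frozen=True)
class Anchor:
    """A maximal exact match unique in both genomes.

    posA/posB are the leftmost forward-strand coordinates of the matched
    span in each genome; relative_strand is "same" or "opposite".
    """

    posA: int
    posB: int
    length: int
    relative_strand: str


@dataclass(frozen=True)
class CollinearBlock:
    label: str
    intervalA: Interval
    intervalB: Interval
    sign: int  # +1 same strand, -1 inverted
    n_anchors: int


@dataclass(frozen=True)
class JunctionAssociation:
    junction: str
    repeat_label: str | None
    distance: int
    intergenic: bool


# ---------------------------------------------------------------------------
# anchors
# ---------------------------------------------------------------------------

def _kmer_positions(seq: str, k: int, circular: bool) -> dict[str, list[int]]:
    n = len(seq)
    ext = seq + seq[: k - 1] if circular else seq
    out: dict[str, list[int]] = {}
    limit = n if circular else n - k + 1
    acgt = set("ACGT")
    for i in range(limit):
        kmer = ext[i : i + k]
        if set(kmer) <= acgt:
            out.setdefault(kmer, []).append(i)
    return out


def find_anchors(
    genomeA: AnnotatedGenome,
    genomeB: AnnotatedGenome,
    min_anchor_len: int = 25,
) -> list[Anchor]:
    """Maximal exact matches of length ≥ min_anchor_len unique in both
    genomes, both strands searched; circular sequences are indexed with wrap
    padding.  Sorted by posA."""
    k = min_anchor_len
    if genomeA.length < k or genomeB.length < k:
        return []
    nA, nB = genomeA.length, genomeB.length
    idxA = _kmer_positions(genomeA.sequence, k, genomeA.topology == "circular")
    idxBf = _kmer_positions(genomeB.sequence, k, genomeB.topology == "circular")
    rcB = reverse_complement(genomeB.sequence)
    idxBr = _kmer_positions(rcB, k, genomeB.topology == "circular")

    # unique shared k-mer seeds: (posA, posB_forward_leftmost, strand)
    seeds = []
    for kmer, posA in idxA.items():
        if len(posA) != 1:
            continue
        fwd = idxBf.get(kmer, [])
        rev = idxBr.get(kmer, [])
        if len(fwd) + len(rev) != 1:
            continue
        if fwd:
            seeds.append((posA[0], fwd[0], "same"))
        else:
            # leftmost forward coordinate of the k-mer found at rcB[p:p+k]
            seeds.append((posA[0], (nB - rev[0] - k) % nB, "opposite"))

    # merge consecutive seeds along diagonals into maximal runs
    def diag_key(a, b, strand):
        return (strand, (b - a) % nB if strand == "same" else (a + b) % nB)

    by_diag: dict[tuple, list[tuple[int, int]]] = {}
    for a, b, strand in seeds:
        by_diag.setdefault(diag_key(a, b, strand), []).append((a, b))
    anchors = []
    for (strand, _), pts in by_diag.items():
        pts.sort()
        run_start = 0
        for i in range(1, len(pts) + 1):
            end_run = i == len(pts) or pts[i][0] != pts[i - 1][0] + 1
            if end_run:
                a0, b0 = pts[run_start]
                run_len = i - run_start
                length = run_len + k - 1
                if strand == "same":
                    posB = b0
                else:
                    posB = pts[i - 1][1]  # leftmost forward coordinate
                anchors.append(Anchor(a0, posB, length, strand))
                run_start = i
    anchors.sort(key=lambda x: x.posA)
    return anchors


# ---------------------------------------------------------------------------
# chaining
# ---------------------------------------------------------------------------

def _labels():
    for c in string.ascii_uppercase:
        yield c
    for c1 in string.ascii_uppercase:
        for c2 in string.ascii_uppercase:
            yield c1 + c2


def chain_anchors(
    anchors: list[Anchor],
    max_gap: int = 5000,
    min_block: int = 1000,
) -> list[CollinearBlock]:
    """Greedy chaining of posA-sorted anchors into collinear blocks.

    Consecutive anchors join a chain iff they share relative strand, both
    coordinate gaps are ≤ max_gap, and the B coordinate is monotone in the
    strand-consistent direction.  Chains spanning < min_block on A are
    dropped; after dropping, adjacent compatible chains are re-merged (tiny
    spurious chains from near-identical repeat copies would otherwise split
    a block).  Surviving chains are labelled A, B, C … in A order.
    """
    if not anchors:
        return []

    def compatible(prev: Anchor, nxt: Anchor) -> bool:
        if prev.relative_strand != nxt.relative_strand:
            return False
        gap_a = nxt.posA - (prev.posA + prev.length)
        if gap_a > max_gap or gap_a < -prev.length:
            return False
        if prev.relative_strand == "same":
            gap_b = nxt.posB - (prev.posB + prev.length)
            return -prev.length <= gap_b <= max_gap
        gap_b = prev.posB - (nxt.posB + nxt.length)
        return -nxt.length <= gap_b <= max_gap

    chains: list[list[Anchor]] = [[anchors[0]]]
    for a in anchors[1:]:
        if compatible(chains[-1][-1], a):
            chains[-1].append(a)
        else:
            chains.append([a])

    def span_a(chain):
        return chain[-1].posA + chain[-1].length - chain[0].posA

    chains = [c for c in chains if span_a(c) >= min_block]
    # re-merge: noise chains between two halves of one block are gone now
    merged: list[list[Anchor]] = []
    for c in chains:
        if merged and compatible(merged[-1][-1], c[0]):
            merged[-1].extend(c)
        else:
            merged.append(c)

    blocks = []
    for lab, chain in zip(_labels(), merged):
        strand = chain[0].relative_strand
        a_start = chain[0].posA
        a_end = chain[-1].posA + chain[-1].length
        b_lo = min(x.posB for x in chain)
        b_hi = max(x.posB + x.length for x in chain)
        blocks.append(
            CollinearBlock(
                label=lab,
                intervalA=Interval(a_start, a_end),
                intervalB=Interval(b_lo, b_hi),
                sign=1 if strand == "same" else -1,
                n_anchors=len(chain),
            )
        )
    return blocks


def blocks_to_permutation(
    blocks: list[CollinearBlock], max_overlap: int = 50
) -> tuple[int, ...]:
    """Signed order of the blocks in genome B relative to their A order.

    Adjacent blocks may overlap by a few bases on B — an exact match can
    run a short way past a rearrangement breakpoint by chance — but an
    overlap beyond ``max_overlap`` signals a chaining bug and raises.
    """
    if not blocks:
        return ()
    in_a = sorted(blocks, key=lambda b: b.intervalA.start)
    rank = {b.label: i + 1 for i, b in enumerate(in_a)}
    in_b = sorted(blocks, key=lambda b: b.intervalB.start)
    for x, y in zip(in_b, in_b[1:]):
        if x.intervalB.end - y.intervalB.start > max_overlap:
            raise LCBError(
                f"blocks {x.label} and {y.label} overlap on genome B (chaining bug)"
            )
    return tuple(b.sign * rank[b.label] for b in in_b)


# ---------------------------------------------------------------------------
# junction / repeat association
# ---------------------------------------------------------------------------

def junction_repeat_association(
    blocks: list[CollinearBlock],
    repeats: list[RepeatPair],
    genome: AnnotatedGenome,
    window: int = 100,
) -> list[JunctionAssociation]:
    """Associate repeat copies with the junctions between B-adjacent blocks.

    A copy is associated when it overlaps the inter-block gap or lies within
    ``window`` bp of either facing block boundary.  Each junction is also
    flagged for falling inside an intergenic spacer of the (observed)
    genome.  Junctions with no nearby copy yield one row with repeat_label
    None.
    """
    in_b = sorted(blocks, key=lambda b: b.intervalB.start)
    spacers = intergenic_intervals(genome) if genome.features else []
    n = genome.length

    def in_spacer(pos: int) -> bool:
        return any(iv.start <= pos < iv.end or pos + n < iv.end for iv in spacers)

    out = []
    for x, y in zip(in_b, in_b[1:]):
        gap_lo, gap_hi = x.intervalB.end, y.intervalB.start
        name = f"{x.label}-{y.label}"
        intergenic = in_spacer(gap_lo) and in_spacer(max(gap_lo, gap_hi - 1))
        found = False
        for rp in repeats:
            for copy in (rp.copy1, rp.copy2):
                # distance from the junction gap to the copy (0 if overlapping)
                if copy.end > gap_lo - window and copy.start < gap_hi + window:
                    d = max(0, max(gap_lo - copy.end, copy.start - gap_hi))
                    out.append(
                        JunctionAssociation(
                            junction=name,
                            repeat_label=rp.label,
                            distance=d,
                            intergenic=intergenic,
                        )
                    )
                    found = True
        if not found:
            out.append(JunctionAssociation(name, None, 0, intergenic))
    return out


def blocks_table(blocks) -> "pd.DataFrame":
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "label": b.label,
                "A_start": b.intervalA.start,
                "A_end": b.intervalA.end,
                "B_start": b.intervalB.start,
                "B_end": b.intervalB.end,
                "sign": b.sign,
                "n_anchors": b.n_anchors,
            }
            for b in blocks
        ]
    )


def junctions_table(assocs) -> "pd.DataFrame":
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "junction": a.junction,
                "repeat": a.repeat_label or "",
                "distance_bp": a.distance,
                "intergenic": a.intergenic,
            }
            for a in assocs
        ]
    )
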