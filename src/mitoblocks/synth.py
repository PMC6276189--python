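"""Synthetic annotated circular genomes with planted repeats and inversions.

The generator builds the study conditions downstream stages are tested
against: a ~160 kb circular genome dense with single-copy gene cassettes,
planted direct/inverted repeat pairs of 100–600 bp at 90–100% identity, and
a recorded series of repeat-mediated inversions.  ``make_two_inversion_case``
reproduces the canonical two-event configuration: five gene regions A–E, an
inverted 566 bp pair (13 mismatches) flanking segment C–D, a 435 bp pair
(18 mismatches) positioned so the second event becomes possible after the
first, eight decoy pairs, and the applied inversions giving the observed
block order (1, 4, −2, −3, 5).

Planted mismatches are placed with pairwise gap ≥ 3 (so no mismatch run
ever reaches the detector's stop threshold) and with a guaranteed clean
stretch ≥ 24 bp (a seedable exact k-mer survives even after a midpoint
crossover redistributes mismatch columns between copies).  After all events
the three bases flanking each copy end are hardened to mismatch their
partner columns, so gapless extension stops exactly at the planted
boundary and recovery of length and identity is exact.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .genome import (
    AnnotatedGenome,
    GeneAnnotation,
    Interval,
    intergenic_intervals,
    reverse_complement,
)
from .rearrange import (
    InversionEvent,
    RepeatPlacement,
    Scenario,
    identity_permutation,
)
from .repeats import RepeatPair, _COMPLEMENT

_BASES = np.array(list("ACGT"))

#: minimum clean stretch kept free of mismatches inside planted repeats,
#: large enough for the default 21-mer seed with margin
SEED_RUN = 24

#: minimum spacing between planted mismatch columns (detector stops at 3)
MISMATCH_GAP = 3


class SynthesisError(ValueError):
    pass


@dataclass
class SequenceInversion:
    """A recombination event at the sequence scale: segment [start, end)
    reverse-complemented in place."""

    start: int
    end: int
    mediating_repeat: str | None = None


@dataclass
class SyntheticTruth:
    """Ground truth of a generated comparison case."""

    planted_repeats: list[RepeatPair]
    applied_scenario: Scenario
    expected_blocks: tuple[int, ...]
    seed: int
    parameters: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        doc = {
            "seed": self.seed,
            "expected_blocks": list(self.expected_blocks),
            "applied_scenario": [
                {"segment": list(ev.segment), "mediating_repeat": ev.mediating_repeat}
                for ev in self.applied_scenario.events
            ],
            "planted_repeats": [
                {
                    "label": p.label,
                    "copy1": [p.copy1.start, p.copy1.end],
                    "copy2": [p.copy2.start, p.copy2.end],
                    "orientation": p.orientation,
                    "length": p.length,
                    "identity": round(p.identity, 6),
                    "n_mismatches": len(p.mismatch_positions),
                }
                for p in self.planted_repeats
            ],
            "parameters": self.parameters,
        }
        text = json.dumps(doc, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


# ---------------------------------------------------------------------------
# random genome
# ---------------------------------------------------------------------------

def _random_sequence(rng, length: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(_BASES, size=length, p=p))

def generate_genome(
    length: int,
    n_genes: int = 70,
    mean_gene_len: int = 900,
    gc: float = 0.45,
    seed: int = 0,
    id: str = "synthetic",
) -> AnnotatedGenome:
    """Random circular genome with non-overlapping genes gene001.. placed in
    evenly spaced slots with jittered offsets, separated by spacers.
    Deterministic for a fixed seed."""
    if not 0 < gc < 1:
        raise SynthesisError("gc must be in (0,1)")
    if length < n_genes * mean_gene_len:
        raise SynthesisError(
            f"cannot pack {n_genes} genes of mean {mean_gene_len} bp into {length} bp"
        )
    # domain-separated stream: the same user seed passed to different
    # generator stages must not yield correlated sequences
    rng = np.random.default_rng([seed, 101])
    seq = _random_sequence(rng, length, gc)
    slot = length / n_genes
    min_spacer = 80
    feats = []
    kinds = ["CDS"] * 8 + ["tRNA", "rRNA"]
    for i in range(n_genes):
        glen = int(np.clip(rng.normal(mean_gene_len, 0.2 * mean_gene_len),
                           60, 2 * mean_gene_len))
        lo = int(i * slot)
        max_off = int(slot) - glen - min_spacer
        if max_off < 0:
            raise SynthesisError("infeasible packing: slots too small")
        off = int(rng.integers(0, max_off + 1))
        start = lo + off
        feats.append(
            GeneAnnotation(
                name=f"gene{i + 1:03d}",
                start=start,
                end=start + glen,
                strand="+" if rng.random() < 0.5 else "-",
                kind=kinds[int(rng.integers(0, len(kinds)))],
            )
        )
    return AnnotatedGenome(id=id, sequence=seq, topology="circular", features=feats)


# ---------------------------------------------------------------------------
# planting repeats
# ---------------------------------------------------------------------------

def _sample_mismatch_columns(rng, length, mismatches, per_half: bool, max_tries=2000):
    """Columns with pairwise gap ≥ MISMATCH_GAP, ≥4 bp clear of both ends,
    and a clean run ≥ SEED_RUN overall (or in each half when per_half)."""
    if mismatches == 0:
        return []
    lo, hi = 4, length - 4
    if hi - lo < mismatches * MISMATCH_GAP:
        raise SynthesisError("too many mismatches for the repeat length")

    def runs_ok(cols):
        def max_gap(a, b, inner):
            pts = [a - 1] + inner + [b]
            return max(q - p - 1 for p, q in zip(pts, pts[1:]))

        if per_half:
            h = length // 2
            left = [c for c in cols if c < h]
            right = [c for c in cols if c >= h]
            return (max_gap(0, h, left) >= SEED_RUN
                    and max_gap(h, length, right) >= SEED_RUN)
        return max_gap(0, length, cols) >= SEED_RUN

    for _ in range(max_tries):
        cols = sorted(rng.choice(np.arange(lo, hi), size=mismatches, replace=False))
        cols = [int(c) for c in cols]
        if any(b - a < MISMATCH_GAP for a, b in zip(cols, cols[1:])):
            continue
        if runs_ok(cols):
            return cols
    raise SynthesisError("could not satisfy mismatch placement constraints")


def plant_repeat_pair(
    genome: AnnotatedGenome,
    length: int,
    mismatches: int,
    orientation: str,
    loc1: Interval,
    loc2: Interval,
    seed: int = 0,
    label: str | None = None,
    allow_gene_overlap: bool = False,
    per_half_seed_run: bool = False,
    harden: bool = True,
) -> tuple[AnnotatedGenome, RepeatPair]:
    """Write a fresh repeat pair into the genome at loc1/loc2.

    copy2 equals copy1 (reverse-complemented when inverted) with exactly
    ``mismatches`` substituted columns; truth identity is
    (length − mismatches)/length.  Both locations must be intergenic (with a
    4 bp margin for flank hardening) unless ``allow_gene_overlap``.
    """
    if loc1.length != length or loc2.length != length:
        raise SynthesisError("locations must have the requested length")
    if mismatches >= length:
        raise SynthesisError("mismatches must be < length")
    if (loc1.start, loc1.end) > (loc2.start, loc2.end):
        raise SynthesisError("loc1 must precede loc2")
    n = genome.length
    if min(loc2.start - loc1.end, (loc1.start + n) - loc2.end) < 8:
        raise SynthesisError("repeat copies too close (need 8 bp separation)")
    if not allow_gene_overlap:
        spacers = intergenic_intervals(genome)
        for loc in (loc1, loc2):
            ok = any(
                iv.start + 4 <= loc.start and loc.end + 4 <= iv.end for iv in spacers
            )
            if not ok:
                raise SynthesisError(
                    f"location [{loc.start},{loc.end}) overlaps a gene feature "
                    "(pass allow_gene_overlap=True to override)"
                )
    rng = np.random.default_rng([seed, 102])
    copy1 = _random_sequence(rng, length, 0.5)
    cols = _sample_mismatch_columns(rng, length, mismatches, per_half_seed_run)
    edited = list(copy1)
    for c in cols:
        choices = [b for b in "ACGT" if b != copy1[c]]
        edited[c] = choices[int(rng.integers(0, 3))]
    copy2 = "".join(edited)
    if orientation == "inverted":
        copy2 = reverse_complement(copy2)
    elif orientation != "direct":
        raise SynthesisError(f"bad orientation {orientation!r}")

    seq = list(genome.sequence)
    seq[loc1.start : loc1.end] = copy1
    seq[loc2.start : loc2.end] = copy2
    pair = RepeatPair(
        copy1=Interval(loc1.start, loc1.end),
        copy2=Interval(loc2.start, loc2.end),
        orientation=orientation,
        length=length,
        identity=(length - mismatches) / length,
        mismatch_positions=tuple(cols),
        label=label,
    )
    if harden:
        _harden_pair_flanks(seq, pair, n, rng)
    out = AnnotatedGenome(genome.id, "".join(seq), genome.topology, list(genome.features))
    return out, pair


def _harden_pair_flanks(seq: list, pair: RepeatPair, n: int, rng) -> None:
    """Force the 3 alignment columns beyond each end of the pair to mismatch,
    so gapless extension stops exactly at the planted boundary."""
    c1, c2 = pair.copy1, pair.copy2
    for t in range(3):
        if pair.orientation == "direct":
            combos = [
                (c1.start - 1 - t, c2.start - 1 - t, False),
                (c1.end + t, c2.end + t, False),
            ]
        else:
            combos = [
                (c1.start - 1 - t, c2.end + t, True),
                (c1.end + t, c2.start - 1 - t, True),
            ]
        for i, j, inv in combos:
            a = seq[i % n]
            b = seq[j % n]
            bb = _COMPLEMENT.get(b, "?")
            matched = a == (bb if inv else b) and a in "ACGT"
            if matched:
                # mutate the j-side base to break the match
                if inv:
                    bad = _COMPLEMENT.get(a, "N")
                else:
                    bad = a
                choices = [x for x in "ACGT" if x != bad and x != seq[j % n]]
                seq[j % n] = choices[int(rng.integers(0, len(choices)))]


def _realized_pair(seq: str, pair: RepeatPair) -> RepeatPair:
    """Re-derive mismatch columns and identity of a planted pair from the
    current sequence (events shuffle columns between the copies)."""
    n = len(seq)
    c1, c2 = pair.copy1, pair.copy2
    s1 = "".join(seq[p % n] for p in range(c1.start, c1.end))
    s2 = "".join(seq[p % n] for p in range(c2.start, c2.end))
    if pair.orientation == "inverted":
        s2 = reverse_complement(s2)
    cols = tuple(u for u in range(pair.length) if s1[u] != s2[u])
    return replace(
        pair,
        mismatch_positions=cols,
        identity=(pair.length - len(cols)) / pair.length,
    )


# ---------------------------------------------------------------------------
# applying inversions
# ---------------------------------------------------------------------------

def apply_planted_inversion(
    genome: AnnotatedGenome, pair: RepeatPair
) -> tuple[AnnotatedGenome, SequenceInversion]:
    """Recombine the two copies of an inverted-orientation pair: the segment
    between the copy midpoints is reverse-complemented in place; features
    inside flip strand and order.

    Direct-orientation copies are rejected: recombination between direct
    repeats excises the intervening segment as a subcircle (a deletion),
    it cannot produce an inversion.
    """
    if pair.orientation != "inverted":
        raise SynthesisError(
            "recombination between direct-orientation copies deletes the "
            "intervening segment; only inverted-orientation pairs mediate inversions"
        )
    L = pair.length
    b1 = pair.copy1.start + L // 2
    b2 = pair.copy2.start + (L - L // 2)
    if not b1 < b2 <= genome.length:
        raise SynthesisError("inversion segment must not wrap the origin")
    s = genome.sequence
    new_seq = s[:b1] + reverse_complement(s[b1:b2]) + s[b2:]
    feats = []
    for f in genome.features:
        if f.end <= b1 or f.start >= b2:
            feats.append(f)
        elif b1 <= f.start and f.end <= b2:
            ns = b1 + (b2 - f.end)
            feats.append(
                replace(f, start=ns, end=ns + f.length,
                        strand="-" if f.strand == "+" else "+")
            )
        else:
            raise SynthesisError(f"feature {f.name} straddles an inversion breakpoint")
    out = AnnotatedGenome(genome.id, new_seq, genome.topology, feats)
    return out, SequenceInversion(start=b1, end=b2, mediating_repeat=pair.label)


def _track_pair(pair: RepeatPair, ev: SequenceInversion) -> RepeatPair:
    """Propagate a planted pair's coordinates through a sequence inversion."""
    b1, b2 = ev.start, ev.end

    def place(iv: Interval):
        if iv.end <= b1 or iv.start >= b2:
            return iv, False
        if b1 <= iv.start and iv.end <= b2:
            ns = b1 + (b2 - iv.end)
            return Interval(ns, ns + iv.length), True
        # straddles a breakpoint: only the mediating pair does, and the
        # crossover leaves a copy in place at each site
        return iv, None

    c1, f1 = place(pair.copy1)
    c2, f2 = place(pair.copy2)
    orient = pair.orientation
    if f1 is None or f2 is None:  # mediator: orientation and sites preserved
        return pair
    if f1 != f2:
        orient = "inverted" if orient == "direct" else "direct"
    if (c1.start, c1.end) > (c2.start, c2.end):
        c1, c2 = c2, c1
    return replace(pair, copy1=c1, copy2=c2, orientation=orient)


# ---------------------------------------------------------------------------
# the canonical two-event case
# ---------------------------------------------------------------------------

#: decoy pair sizes/mismatches: together with R1 (566/13) and R2 (435/18)
#: the genome carries ten pairs spanning 107–566 bp at ≥90% identity
_DECOYS = [
    (107, 5), (138, 8), (164, 10), (201, 14),
    (242, 17), (287, 20), (333, 24), (389, 28),
]


def _nearest_wide_spacer(spacers, target, min_width, used):
    best = None
    for iv in spacers:
        if iv.end > iv.start and iv.length >= min_width and iv not in used:
            centre = (iv.start + iv.end) // 2
            d = abs(centre - target)
            if best is None or d < best[0]:
                best = (d, iv)
    if best is None:
        raise SynthesisError("no intergenic spacer wide enough")
    return best[1]


def make_two_inversion_case(seed: int = 0):
    """Build the canonical comparison: an ancestral five-region genome and
    the observed genome derived from it by two repeat-mediated inversions.

    Returns (ancestral, observed, truth).  truth.expected_blocks is
    (1, 4, −2, −3, 5); the applied scenario is the R1 inversion of blocks
    3–4 followed by the R2 inversion of blocks 2–3.
    """
    for attempt in range(20):
        try:
            return _build_two_inversion_case(
                seed, np.random.SeedSequence([seed, attempt]), attempt
            )
        except SynthesisError:
            continue
    raise SynthesisError(f"canonical-case construction failed for seed {seed}")


def _build_two_inversion_case(seed: int, ss: np.random.SeedSequence, attempt: int):
    child = ss.generate_state(8)
    sub = [int(x % (2**31 - 1)) for x in child]
    length = 162_574
    base = generate_genome(
        length, n_genes=70, mean_gene_len=900, gc=0.447,
        seed=sub[0], id="mt_ancestral",
    )
    spacers = [iv for iv in intergenic_intervals(base) if iv.end <= length]
    junction_targets = [38_000, 68_000, 98_000, 130_000]
    used = set()
    junctions = []
    for tgt in junction_targets:
        iv = _nearest_wide_spacer(spacers, tgt, 566 + 24, used)
        used.add(iv)
        junctions.append((iv.start + iv.end) // 2)
    p1, p2, p3, p4 = junctions

    g = base
    # R1: inverted pair flanking segment C–D (copies centred on junctions 2, 4)
    g, r1 = plant_repeat_pair(
        g, 566, 13, "inverted",
        Interval(p2 - 283, p2 + 283), Interval(p4 - 283, p4 + 283),
        seed=sub[1], label="R1", per_half_seed_run=True, harden=False,
    )
    # R2: direct pair on junctions 1, 3; the first event re-orients its
    # inner copy, making the second event possible
    g, r2 = plant_repeat_pair(
        g, 435, 18, "direct",
        Interval(p1 - 217, p1 + 218), Interval(p3 - 217, p3 + 218),
        seed=sub[2], label="R2", per_half_seed_run=True, harden=False,
    )
    # decoys in region-internal spacers, well clear of the junctions
    rng = np.random.default_rng(sub[3])
    decoy_pairs = []
    for d, (dlen, dmm) in enumerate(_DECOYS):
        orient = "direct" if d % 2 == 0 else "inverted"
        locs = []
        for _ in range(2):
            cands = [
                iv for iv in spacers
                if iv.length >= dlen + 24 and iv not in used
                and all(abs((iv.start + iv.end) // 2 - p) > 1500 for p in junctions)
            ]
            if not cands:
                raise SynthesisError("ran out of decoy spacers")
            iv = cands[int(rng.integers(0, len(cands)))]
            used.add(iv)
            centre = (iv.start + iv.end) // 2
            locs.append(Interval(centre - dlen // 2, centre - dlen // 2 + dlen))
        locs.sort()
        g, dp = plant_repeat_pair(
            g, dlen, dmm, orient, locs[0], locs[1],
            seed=sub[4] + d, label=f"D{d + 1}", harden=False,
        )
        decoy_pairs.append(dp)

    ancestral = g
    all_pairs = [r1, r2] + decoy_pairs

    # event 1: recombination within R1 inverts [p2, p4) — blocks C and D
    g1, ev1 = apply_planted_inversion(ancestral, r1)
    pairs1 = [_track_pair(p, ev1) for p in all_pairs]
    # event 2: R2 is now inverted; recombination inverts B and (inverted) D
    r2_now = next(p for p in pairs1 if p.label == "R2")
    if r2_now.orientation != "inverted":
        raise SynthesisError("R2 did not re-orient after event 1")
    g2, ev2 = apply_planted_inversion(g1, r2_now)
    pairs2 = [_track_pair(p, ev2) for p in pairs1]
    observed = AnnotatedGenome(
        "mt_observed", g2.sequence, g2.topology, list(g2.features)
    )

    # realize mismatch columns in the observed genome, harden flanks, validate
    seq = list(observed.sequence)
    final_pairs = []
    hrng = np.random.default_rng(sub[5])
    for p in pairs2:
        rp = _realized_pair(observed.sequence, p)
        if len(rp.mismatch_positions) != len(p.mismatch_positions):
            raise SynthesisError(f"{p.label}: mismatch count changed by the events")
        _harden_pair_flanks(seq, rp, observed.length, hrng)
        final_pairs.append(rp)
    observed = AnnotatedGenome("mt_observed", "".join(seq), g2.topology, g2.features)
    for p in final_pairs:
        _validate_recoverable(observed.sequence, p)

    source = identity_permutation(5)
    target = (1, 4, -2, -3, 5)
    scenario = Scenario(
        events=(
            InversionEvent(segment=(3, 4), mediating_repeat="R1"),
            InversionEvent(segment=(2, 3), mediating_repeat="R2"),
        ),
        source=source,
        target=target,
    )
    ancestral_placements = (
        RepeatPlacement("R1", 2, 4, "inverted"),
        RepeatPlacement("R2", 1, 3, "direct"),
    )
    truth = SyntheticTruth(
        planted_repeats=final_pairs,
        applied_scenario=scenario,
        expected_blocks=target,
        seed=seed,
        parameters={
            "length": length,
            "attempt": attempt,
            "junctions": junctions,
            "region_boundaries": [0, p1, p2, p3, p4, length],
            "sequence_events": [
                {"start": ev.start, "end": ev.end, "mediating_repeat": ev.mediating_repeat}
                for ev in (ev1, ev2)
            ],
            "ancestral_placements": [asdict(pl) for pl in ancestral_placements],
            "intermediate_blocks": [1, 2, -4, -3, 5],
        },
    )
    return ancestral, observed, truth


def _validate_recoverable(seq: str, pair: RepeatPair) -> None:
    """Generator invariant: the detector must recover the pair exactly —
    no mismatch run ≥3 inside, a clean ≥21 bp stretch for seeding, and
    hardened (3-mismatch) walls at both ends."""
    rp = _realized_pair(seq, pair)
    cols = rp.mismatch_positions
    if abs(rp.identity - pair.identity) > 1e-9:
        raise SynthesisError(f"{pair.label}: identity drifted")
    run = 1
    for a, b in zip(cols, cols[1:]):
        run = run + 1 if b == a + 1 else 1
        if run >= 3:
            raise SynthesisError(f"{pair.label}: mismatch run of 3 inside the pair")
    pts = [-1] + list(cols) + [pair.length]
    if max(q - p - 1 for p, q in zip(pts, pts[1:])) < 21:
        raise SynthesisError(f"{pair.label}: no seedable exact stretch")
    n = len(seq)
    c1, c2 = pair.copy1, pair.copy2
    for t in range(3):
        if pair.orientation == "direct":
            combos = [(c1.start - 1 - t, c2.start - 1 - t, False),
                      (c1.end + t, c2.end + t, False)]
        else:
            combos = [(c1.start - 1 - t, c2.end + t, True),
                      (c1.end + t, c2.start - 1 - t, True)]
        for i, j, inv in combos:
            a, b = seq[i % n], seq[j % n]
            if inv:
                b = _COMPLEMENT.get(b, "?")
            if a == b and a in "ACGT":
                raise SynthesisError(f"{pair.label}: flank wall not hardened")
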