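"""Detection of large repeat pairs (direct and inverted) on circular genomes.

The repeat model is gapless: a repeat pair is a maximal window along one
diagonal (direct) or antidiagonal (inverted) of the genome's self-comparison
that contains no run of ``MAX_MISMATCH_RUN`` (3) consecutive mismatches, is
trimmed to terminal matches, and passes the length and identity thresholds.
The window is a purely combinatorial object — independent of which seed
k-mer discovered it — which makes the detector reproducible and lets a
brute-force all-diagonal scan serve as an exact oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .genome import AnnotatedGenome, Interval, reverse_complement

#: extension stops when this many consecutive mismatch columns accumulate
MAX_MISMATCH_RUN = 3

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class RepeatError(ValueError):
    pass


@dataclass(frozen=True)
class RepeatPair:
    """Two genomic intervals related by (near-)identity, the recombination substrate.

    ``mismatch_positions`` are alignment columns counted from copy1's start.
    """

    copy1: Interval
    copy2: Interval
    orientation: str  # direct | inverted
    length: int
    identity: float
    mismatch_positions: tuple[int, ...] = ()
    label: str | None = None

    def __post_init__(self) -> None:
        if self.orientation not in ("direct", "inverted"):
            raise RepeatError(f"bad orientation {self.orientation!r}")
        if (self.copy1.start, self.copy1.end) > (self.copy2.start, self.copy2.end):
            raise RepeatError("copy1 must sort before copy2")
        if (self.copy1.start, self.copy1.end) == (self.copy2.start, self.copy2.end):
            raise RepeatError("copies must be distinct intervals")
        expected = (self.length - len(self.mismatch_positions)) / self.length
        if abs(self.identity - expected) > 1e-9:
            raise RepeatError("identity inconsistent with mismatch count")

    @property
    def identity_pct(self) -> float:
        """Identity as a percentage rounded half-up to one decimal (report scale)."""
        return float(
            Decimal(100 * self.identity).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
        )


def pair_identity(copy1_seq: str, copy2_seq: str, orientation: str) -> float:
    """Gapless identity; copy2 is reverse-complemented first when inverted.

    Positions holding ambiguity codes count as mismatches.
    """
    if len(copy1_seq) != len(copy2_seq):
        raise RepeatError("gapless model requires equal-length copies")
    if orientation == "inverted":
        copy2_seq = reverse_complement(copy2_seq)
    elif orientation != "direct":
        raise RepeatError(f"bad orientation {orientation!r}")
    a, b = copy1_seq.upper(), copy2_seq.upper()
    matches = sum(1 for x, y in zip(a, b) if x == y and x in "ACGT")
    return matches / len(a)


# ---------------------------------------------------------------------------
# shared geometry helpers
# ---------------------------------------------------------------------------

def _match(s: str, i: int, j: int, n: int, inverted: bool) -> bool:
    a = s[i % n]
    b = s[j % n]
    if inverted:
        b = _COMPLEMENT.get(b, "?")
    return a == b and a in "ACGT"


def _norm_interval(start: int, length: int, n: int) -> Interval:
    s = start % n
    return Interval(s, s + length)


def _circular_overlap(a: Interval, b: Interval, n: int) -> int:
    pos_a = {p % n for p in range(a.start, a.end)}
    return sum(1 for p in range(b.start, b.end) if p % n in pos_a)


def _diag_key(p: RepeatPair, n: int) -> tuple:
    if p.orientation == "direct":
        return ("direct", (p.copy2.start - p.copy1.start) % n)
    return ("inverted", (p.copy1.start + p.copy2.end - 1) % n)


def _make_pair(orient, i_start, j_start, length, mm, n, min_len, min_identity):
    """Canonicalize a window into a RepeatPair, or None if it fails a filter.

    ``i_start`` is copy1's start; ``j_start`` copy2's (forward-strand) start;
    ``mm`` alignment mismatch columns counted from copy1's start.
    """
    c1 = _norm_interval(i_start, length, n)
    c2 = _norm_interval(j_start, length, n)
    if (c1.start, c1.end) > (c2.start, c2.end):
        c1, c2 = c2, c1
        if orient == "inverted":
            mm = sorted(length - 1 - u for u in mm)
        # direct: columns are offsets in both copies; unchanged under swap
    if (c1.start, c1.end) == (c2.start, c2.end):
        return None
    if _circular_overlap(c1, c2, n) * 2 >= length:
        return None
    identity = (length - len(mm)) / length
    if length < min_len or identity < min_identity:
        return None
    return RepeatPair(
        copy1=c1, copy2=c2, orientation=orient, length=length,
        identity=identity, mismatch_positions=tuple(sorted(mm)),
    )


def _prune(pairs: list[RepeatPair], n: int) -> list[RepeatPair]:
    """Sort by (length desc, copy1) and drop pairs contained in a longer pair
    on the same diagonal."""
    out = sorted(
        pairs, key=lambda p: (-p.length, p.copy1.start, p.copy1.end, p.copy2.start)
    )
    kept: list[RepeatPair] = []
    for p in out:
        contained = any(
            _diag_key(q, n) == _diag_key(p, n)
            and q.copy1.start <= p.copy1.start and p.copy1.end <= q.copy1.end
            and q.copy2.start <= p.copy2.start and p.copy2.end <= q.copy2.end
            for q in kept
        )
        if not contained:
            kept.append(p)
    return kept


# ---------------------------------------------------------------------------
# seed-and-extend finder
# ---------------------------------------------------------------------------

def _extend(s: str, n: int, i0: int, j0: int, k: int, inverted: bool):
    """Grow the run-bounded maximal window around an exact seed.

    Direct: column t compares s[i0+t] with s[j0+t].  Inverted: column t
    compares s[i0+t] with complement(s[j0-t]) — j0 is the *last* forward
    base of the seed on copy2, which grows leftward as copy1 grows right.
    Returns (lo, hi, mismatch-columns-from-lo), trimmed to terminal matches,
    or None when the window would wrap the whole circle (tandem-array
    degeneracy, out of scope here).
    """

    def col(t: int) -> bool:
        if inverted:
            return _match(s, i0 + t, j0 - t, n, True)
        return _match(s, i0 + t, j0 + t, n, False)

    hi = k - 1
    run = 0
    t = k
    while t < n:
        if col(t):
            run = 0
            hi = t
        else:
            run += 1
            if run >= MAX_MISMATCH_RUN:
                break
        t += 1
    else:
        return None
    lo = 0
    run = 0
    t = -1
    while hi - t < n:
        if col(t):
            run = 0
            lo = t
        else:
            run += 1
            if run >= MAX_MISMATCH_RUN:
                break
        t -= 1
    else:
        return None
    mism = [u for u in range(lo, hi + 1) if not col(u)]
    return lo, hi, [m - lo for m in mism]


def find_repeat_pairs(
    genome: AnnotatedGenome,
    min_len: int = 100,
    min_identity: float = 0.90,
    k: int = 21,
) -> list[RepeatPair]:
    """All maximal repeat pairs of the genome against itself, both orientations.

    Exact k-mers (circularly indexed over the forward strand and matched
    against their reverse complements for the inverted orientation) seed the
    gapless extension; windows are deduplicated per diagonal, self-matches
    and palindromic centres discarded, and copies overlapping by ≥50% of the
    pair length rejected.  Sorted by length descending, then copy1 start.
    """
    if k > min_len:
        raise RepeatError(f"seed length k={k} exceeds min_len={min_len}")
    n = genome.length
    s = genome.sequence
    if n < k:
        return []

    index: dict[str, list[int]] = {}
    ext = s + s[: k - 1]
    acgt = set("ACGT")
    for i in range(n):
        kmer = ext[i : i + k]
        if set(kmer) <= acgt:
            index.setdefault(kmer, []).append(i)

    found: list[RepeatPair] = []
    seen_windows: dict[tuple, list[tuple[int, int]]] = {}

    def window_seen(key, col) -> bool:
        return any(lo <= col <= hi for lo, hi in seen_windows.get(key, ()))

    # direct orientation
    for kmer, positions in index.items():
        if len(positions) < 2:
            continue
        for ai in range(len(positions)):
            for bi in range(ai + 1, len(positions)):
                i, j = positions[ai], positions[bi]
                diag = (j - i) % n
                if diag == 0:
                    continue
                key = ("direct", diag)
                if window_seen(key, i):
                    continue
                res = _extend(s, n, i, j, k, inverted=False)
                if res is None:
                    continue
                lo, hi, mm = res
                seen_windows.setdefault(key, []).append((i + lo, i + hi))
                p = _make_pair(
                    "direct", i + lo, j + lo, hi - lo + 1, mm, n, min_len, min_identity
                )
                if p is not None:
                    found.append(p)

    # inverted orientation
    for kmer, positions in index.items():
        partners = index.get(reverse_complement(kmer))
        if not partners:
            continue
        for i in positions:
            for jp in partners:
                if jp % n == i % n:  # palindromic self-seed
                    continue
                j_last = jp + k - 1
                anti = (i + j_last) % n
                key = ("inverted", anti)
                if window_seen(key, i):
                    continue
                res = _extend(s, n, i, j_last, k, inverted=True)
                if res is None:
                    continue
                lo, hi, mm = res
                seen_windows.setdefault(key, []).append((i + lo, i + hi))
                length = hi - lo + 1
                p = _make_pair(
                    "inverted", i + lo, j_last - hi, length, mm, n, min_len, min_identity
                )
                if p is not None:
                    found.append(p)

    # identical windows can be reached from seeds in either copy: dedupe
    uniq = {}
    for p in found:
        uniq[(p.orientation, p.copy1, p.copy2)] = p
    return _prune(list(uniq.values()), n)


# ---------------------------------------------------------------------------
# brute-force oracle (exported for tests and verification)
# ---------------------------------------------------------------------------

def brute_force_repeat_pairs(
    genome: AnnotatedGenome, min_len: int, min_identity: float
) -> list[RepeatPair]:
    """All-diagonal scan implementing the same maximal-window definition.

    No seeding: every diagonal and antidiagonal is split at runs of ≥3
    consecutive mismatches, windows trimmed to terminal matches, thresholds
    applied.  Quadratic — intended for genomes of a few kb.
    """
    n = genome.length
    s = genome.sequence
    results: dict[tuple, RepeatPair] = {}

    def harvest(orient: str, cols: list[tuple[int, int, bool]]):
        # cols: (i, j, matched) along one circular (anti)diagonal, length n
        L = len(cols)
        m = [c[2] for c in cols]
        if True not in m:
            return
        # mark columns inside circular mismatch runs of length >= 3
        z = m.index(True)
        m2 = m[z:] + m[:z]  # starts with a match: runs don't wrap
        blocked2 = [False] * L
        t = 0
        while t < L:
            if not m2[t]:
                u = t
                while u < L and not m2[u]:
                    u += 1
                if u - t >= MAX_MISMATCH_RUN:
                    for v in range(t, u):
                        blocked2[v] = True
                t = u
            else:
                t += 1
        if not any(blocked2):
            return  # full-circle window: tandem degeneracy, out of scope
        # maximal circular runs of unblocked columns, scanned from a blocked col
        zb = blocked2.index(True)
        windows: list[list[int]] = []
        cur: list[int] = []
        for step in range(L):
            t2 = (zb + step) % L
            if blocked2[t2]:
                if cur:
                    windows.append(cur)
                    cur = []
            else:
                cur.append((t2 + z) % L)  # back to original column index
        if cur:
            windows.append(cur)
        for widx in windows:
            w = [cols[t] for t in widx]
            while w and not w[0][2]:
                w.pop(0)
            while w and not w[-1][2]:
                w.pop()
            if len(w) < min_len:
                continue
            length = len(w)
            mm = [u for u in range(length) if not w[u][2]]
            i0 = w[0][0]
            j_start = w[0][1] if orient == "direct" else w[-1][1]
            p = _make_pair(orient, i0, j_start, length, mm, n, min_len, min_identity)
            if p is not None:
                results[(p.orientation, p.copy1, p.copy2)] = p

    for diag in range(1, n):
        harvest(
            "direct",
            [(t, (t + diag) % n, _match(s, t, t + diag, n, False)) for t in range(n)],
        )
    for anti in range(n):
        harvest(
            "inverted",
            [(t, (anti - t) % n, _match(s, t, anti - t, n, True)) for t in range(n)],
        )
    return _prune(list(results.values()), n)


# ---------------------------------------------------------------------------
# cross-genome survey
# ---------------------------------------------------------------------------

def _locate(genome: AnnotatedGenome, iv: Interval) -> str:
    """Describe an interval against the annotation: inside a feature, or in
    the spacer between its flanking genes."""
    if not genome.features:
        return f"{iv.start}-{iv.end}"
    n = genome.length
    mid = (iv.start + iv.end) // 2 % n
    for f in genome.features:
        if f.start <= mid < f.end or (f.end > n and mid < f.end - n):
            return f"within {f.name}"
    prev_f = next_f = None
    for f in genome.features:
        if f.end <= mid:
            prev_f = f
        if f.start > mid and next_f is None:
            next_f = f
    if prev_f is None:
        prev_f = genome.features[-1]
    if next_f is None:
        next_f = genome.features[0]
    return f"between {prev_f.name} and {next_f.name}"


def cross_genome_repeat_survey(
    genomes, min_len: int = 400, min_identity: float = 0.90
) -> "pd.DataFrame":
    """Survey large repeat pairs across genomes and group them by shared
    annotation context into R1/R2/... labels.

    Detection needs both copies present (a deletion of one mate removes the
    pair from the survey); genomes with no qualifying pair contribute zero
    rows.  Unannotated genomes are localized by coordinates only, with a
    warning.
    """
    import warnings

    import pandas as pd

    rows = []
    for g in genomes:
        if not g.features:
            warnings.warn(f"{g.id}: no annotations; localizing by coordinates only")
        for p in find_repeat_pairs(g, min_len=min_len, min_identity=min_identity):
            rows.append(
                {
                    "genome": g.id,
                    "copy1_start": p.copy1.start,
                    "copy1_end": p.copy1.end,
                    "copy2_start": p.copy2.start,
                    "copy2_end": p.copy2.end,
                    "orientation": p.orientation,
                    "length": p.length,
                    "identity_pct": p.identity_pct,
                    "copy1_context": _locate(g, p.copy1),
                    "copy2_context": _locate(g, p.copy2),
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "genome", "copy1_start", "copy1_end", "copy2_start", "copy2_end",
            "orientation", "length", "identity_pct", "copy1_context", "copy2_context",
        ],
    )
    if df.empty:
        df["label"] = pd.Series(dtype=str)
        return df
    context_label: dict[frozenset, str] = {}
    labels = []
    for _, row in df.iterrows():
        ctx = frozenset({row["copy1_context"], row["copy2_context"]})
        if ctx not in context_label:
            context_label[ctx] = f"R{len(context_label) + 1}"
        labels.append(context_label[ctx])
    df["label"] = labels
    return df


def repeats_table(pairs) -> "pd.DataFrame":
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "label": p.label or f"P{i+1}",
                "copy1_start": p.copy1.start,
                "copy1_end": p.copy1.end,
                "copy2_start": p.copy2.start,
                "copy2_end": p.copy2.end,
                "orientation": p.orientation,
                "length": p.length,
                "identity_pct": p.identity_pct,
            }
            for i, p in enumerate(pairs)
        ]
    )
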