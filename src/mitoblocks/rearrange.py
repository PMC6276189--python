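"""Signed-permutation inversion model and repeat-mediated scenario search.

Block orders are linear signed permutations (tuples of non-zero ints whose
absolute values are 1..n); an inversion of segment (i, j) (1-based,
inclusive) reverses the segment and flips every sign.  The scenario search
only allows an inversion when a repeat pair has one copy at the junction
immediately left of i and the other at the junction immediately right of j,
in inverted relative orientation — the homologous-recombination substrate
for an inversion.  Junction index k (0..n) denotes the point between block
positions k and k+1.
"""

from __future__ import annotations

from dataclasses import dataclass

SignedPermutation = tuple[int, ...]

#: state-space guard for the exhaustive searches
MAX_N = 10


class RearrangementError(ValueError):
    pass


def validate_permutation(perm: SignedPermutation) -> None:
    if any(x == 0 for x in perm):
        raise RearrangementError("zero is not a signed block")
    if sorted(abs(x) for x in perm) != list(range(1, len(perm) + 1)):
        raise RearrangementError(f"absolute values of {perm} are not a permutation of 1..n")


def identity_permutation(n: int) -> SignedPermutation:
    return tuple(range(1, n + 1))


def apply_inversion(perm: SignedPermutation, i: int, j: int) -> SignedPermutation:
    """Reverse blocks i..j (1-based, inclusive) and flip their signs."""
    n = len(perm)
    if not 1 <= i <= j <= n:
        raise RearrangementError(f"inversion ({i},{j}) out of range for n={n}")
    seg = tuple(-x for x in reversed(perm[i - 1 : j]))
    return perm[: i - 1] + seg + perm[j:]


def all_inversions(n: int):
    for i in range(1, n + 1):
        for j in range(i, n + 1):
            yield i, j


def inversion_distance_bfs(
    source: SignedPermutation, target: SignedPermutation, max_depth: int = 6
) -> int | None:
    """Minimal number of inversions from source to target by breadth-first
    search over all inversions; None when unreachable within max_depth."""
    validate_permutation(source)
    validate_permutation(target)
    n = len(source)
    if len(target) != n:
        raise RearrangementError("length mismatch")
    if n > MAX_N:
        raise RearrangementError(f"n={n} exceeds the state-space guard ({MAX_N})")
    if source == target:
        return 0
    frontier = {source}
    seen = {source}
    for depth in range(1, max_depth + 1):
        nxt = set()
        for p in frontier:
            for i, j in all_inversions(n):
                q = apply_inversion(p, i, j)
                if q == target:
                    return depth
                if q not in seen:
                    seen.add(q)
                    nxt.add(q)
        frontier = nxt
        if not frontier:
            break
    return None


# ---------------------------------------------------------------------------
# repeat placements on the block order
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RepeatPlacement:
    """One repeat pair seen at the block scale: its copies sit at two
    junctions of the current block order."""

    label: str
    left_junction: int
    right_junction: int
    relative_orientation: str  # direct | inverted

    def __post_init__(self) -> None:
        if self.relative_orientation not in ("direct", "inverted"):
            raise RearrangementError(f"bad orientation {self.relative_orientation!r}")
        if self.left_junction > self.right_junction:
            raise RearrangementError("junctions must be ordered")

    def check(self, n: int) -> None:
        if not 0 <= self.left_junction <= self.right_junction <= n:
            raise RearrangementError(
                f"junctions ({self.left_junction},{self.right_junction}) invalid for n={n}"
            )


@dataclass(frozen=True)
class InversionEvent:
    segment: tuple[int, int]  # (i, j), 1-based inclusive block positions
    mediating_repeat: str | None = None


@dataclass(frozen=True)
class Scenario:
    """An ordered inversion series; replay from source must give target."""

    events: tuple[InversionEvent, ...]
    source: SignedPermutation
    target: SignedPermutation

    def __post_init__(self) -> None:
        p = self.source
        for ev in self.events:
            p = apply_inversion(p, *ev.segment)
        if p != self.target:
            raise RearrangementError("scenario does not replay source -> target")

    def intermediates(self) -> list[SignedPermutation]:
        """Block orders visited, source first, target last."""
        p = self.source
        out = [p]
        for ev in self.events:
            p = apply_inversion(p, *ev.segment)
            out.append(p)
        return out

    def reversed_(self) -> "Scenario":
        """The same walk traversed backwards (inversions are involutions)."""
        return Scenario(
            events=tuple(reversed(self.events)), source=self.target, target=self.source
        )


def track_repeats_through_event(
    placements, event: InversionEvent, n: int
) -> tuple[RepeatPlacement, ...]:
    """Propagate junction placements through one inversion.

    Junctions strictly inside the inverted span (i-1 < k < j) are reflected
    (k -> i-1+j-k); the two boundary junctions are the breakpoints themselves
    and stay in place, as does everything outside.  A pair's relative
    orientation flips iff exactly one copy lies strictly inside the span.
    """
    i, j = event.segment
    if not 1 <= i <= j <= n:
        raise RearrangementError(f"event {event.segment} invalid for n={n}")

    def inside(k: int) -> bool:
        return i - 1 < k < j

    def move(k: int) -> int:
        return (i - 1 + j) - k if inside(k) else k

    out = []
    for pl in placements:
        pl.check(n)
        a, b = move(pl.left_junction), move(pl.right_junction)
        flips = inside(pl.left_junction) != inside(pl.right_junction)
        orient = pl.relative_orientation
        if flips:
            orient = "inverted" if orient == "direct" else "direct"
        out.append(
            RepeatPlacement(pl.label, min(a, b), max(a, b), orient)
        )
    return tuple(out)


def _allowed_events(placements, n: int):
    """Inversions currently licensed by an inverted-orientation repeat pair."""
    for pl in placements:
        if pl.relative_orientation != "inverted":
            continue
        i = pl.left_junction + 1
        j = pl.right_junction
        if i <= j and 1 <= i and j <= n:
            yield InversionEvent(segment=(i, j), mediating_repeat=pl.label)


def find_repeat_mediated_scenarios(
    source: SignedPermutation,
    target: SignedPermutation,
    placements,
    max_events: int = 4,
) -> list[Scenario]:
    """All minimal-length inversion series from source to target in which
    every event is mediated by an inverted-orientation repeat pair whose
    copies flank the inverted segment; placements are re-tracked after each
    event.  Empty list when no scenario exists within max_events.
    """
    validate_permutation(source)
    validate_permutation(target)
    n = len(source)
    if len(target) != n:
        raise RearrangementError("length mismatch")
    if n > MAX_N:
        raise RearrangementError(f"n={n} exceeds the state-space guard ({MAX_N})")
    placements = tuple(placements)
    for pl in placements:
        pl.check(n)

    if source == target:
        return [Scenario(events=(), source=source, target=target)]

    start = (source, placements)
    layer = {start: [()]}  # state -> list of event paths reaching it
    seen_depth = {start: 0}
    for depth in range(1, max_events + 1):
        nxt: dict[tuple, list[tuple]] = {}
        hits: list[tuple] = []
        for (perm, pls), paths in layer.items():
            for ev in _allowed_events(pls, n):
                q = apply_inversion(perm, *ev.segment)
                qpls = track_repeats_through_event(pls, ev, n)
                state = (q, qpls)
                if seen_depth.get(state, depth) < depth:
                    continue  # reached strictly earlier: not on a minimal path
                seen_depth[state] = depth
                new_paths = [path + (ev,) for path in paths]
                if q == target:
                    hits.extend(new_paths)
                else:
                    nxt.setdefault(state, []).extend(new_paths)
        if hits:
            uniq = sorted(set(hits), key=lambda evs: [e.segment for e in evs])
            return [
                Scenario(events=evs, source=source, target=target) for evs in uniq
            ]
        layer = nxt
        if not layer:
            break
    return []


def parse_permutation(text: str) -> SignedPermutation:
    """Comma-separated signed integers -> permutation (with validation)."""
    perm = tuple(int(tok) for tok in text.replace(" ", "").split(",") if tok)
    validate_permutation(perm)
    return perm


def format_permutation(perm: SignedPermutation) -> str:
    return ",".join(str(x) for x in perm)
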