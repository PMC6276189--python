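"""LCB detection: anchors, chaining, permutations, junction association."""

import numpy as np
import pytest

from mitoblocks import lcb, synth
from mitoblocks.genome import AnnotatedGenome, Interval, intergenic_intervals, reverse_complement
from mitoblocks.rearrange import apply_inversion, identity_permutation


def _random_genome(seed, length, id="g"):
    rng = np.random.default_rng(seed)
    return AnnotatedGenome(id, "".join(rng.choice(list("ACGT"), length)))


# ---------------------------------------------------------------------------
# independent helpers (oracles for the property tests)
# ---------------------------------------------------------------------------

def substring_count(hay: str, needle: str) -> int:
    """Brute-force circular substring count, both strands."""
    n = len(hay)
    ext = hay + hay[: len(needle) - 1]
    rc = reverse_complement(hay)
    rcext = rc + rc[: len(needle) - 1]
    return sum(ext[i : i + len(needle)] == needle for i in range(n)) + sum(
        rcext[i : i + len(needle)] == needle for i in range(n)
    )


def merge_collinear(perm):
    """Reduce a signed permutation by merging adjacent entries that are
    consecutive and consistently oriented (they form one collinear block),
    then renumber.  Independent reduction used as truth normalizer."""

    def renumber(p):
        ranks = {a: i + 1 for i, a in enumerate(sorted(abs(x) for x in p))}
        return [(1 if x > 0 else -1) * ranks[abs(x)] for x in p]

    perm = renumber(list(perm))
    changed = True
    while changed:
        changed = False
        for i in range(len(perm) - 1):
            v, w = perm[i], perm[i + 1]
            # (2,3) or (-3,-2): one contiguous, consistently oriented segment
            if w == v + 1:
                perm[i] = min(v, w, key=abs)
                del perm[i + 1]
                perm = renumber(perm)
                changed = True
                break
    return tuple(perm)


def invert_signed(perm):
    inv = [0] * len(perm)
    for i, v in enumerate(perm, 1):
        inv[abs(v) - 1] = i if v > 0 else -i
    return tuple(inv)


def _apply_block_scenario(genome, junctions, events):
    """Realize a block-level inversion scenario at the sequence level.

    junctions: sorted sequence positions partitioning the circle (origin
    fixed); each event (i, j) reverse-complements the span between junction
    i-1 and junction j in the *current* genome, junction positions being
    tracked through each reflection.
    """
    pos = [0] + list(junctions) + [genome.length]
    seq = genome.sequence
    for (i, j) in events:
        a, b = pos[i - 1], pos[j]
        seq = seq[:a] + reverse_complement(seq[a:b]) + seq[b:]
        pos = [a + b - p if a < p < b else p for p in pos]
        pos.sort()
    return AnnotatedGenome("derived", seq)


# ---------------------------------------------------------------------------
# anchors
# ---------------------------------------------------------------------------

class TestFindAnchors:
    def test_identical_genomes_tile_with_same_strand(self):
        g = _random_genome(1, 4000)
        anchors = lcb.find_anchors(g, AnnotatedGenome("b", g.sequence))
        assert anchors
        assert all(a.relative_strand == "same" for a in anchors)
        covered = sum(a.length for a in anchors)
        assert covered >= 0.99 * g.length

    def test_reverse_complement_all_opposite(self):
        g = _random_genome(2, 4000)
        rc = AnnotatedGenome("b", reverse_complement(g.sequence))
        anchors = lcb.find_anchors(g, rc)
        assert anchors
        assert all(a.relative_strand == "opposite" for a in anchors)

    @pytest.mark.parametrize("seed", range(3))
    def test_anchor_uniqueness_bruteforce(self, seed):
        gA = _random_genome(seed, 2500, "A")
        gB = AnnotatedGenome("B", gA.sequence[1200:] + gA.sequence[:1200])
        for a in lcb.find_anchors(gA, gB)[:5]:
            sub = "".join(
                gA.sequence[(a.posA + t) % gA.length] for t in range(a.length)
            )
            assert substring_count(gA.sequence, sub) == 1
            assert substring_count(gB.sequence, sub) == 1


# ---------------------------------------------------------------------------
# chaining and permutations
# ---------------------------------------------------------------------------

class TestChainsAndPermutation:
    def test_identical_genomes_single_block_identity(self):
        g = _random_genome(3, 20_000)
        anchors = lcb.find_anchors(g, AnnotatedGenome("b", g.sequence))
        blocks = lcb.chain_anchors(anchors)
        assert len(blocks) == 1 and blocks[0].sign == 1
        assert lcb.blocks_to_permutation(blocks) == (1,)

    def test_reverse_complement_single_inverted_block(self):
        g = _random_genome(4, 20_000)
        rc = AnnotatedGenome("b", reverse_complement(g.sequence))
        blocks = lcb.chain_anchors(lcb.find_anchors(g, rc))
        assert lcb.blocks_to_permutation(blocks) == (-1,)

    def test_two_inversion_case_five_blocks_two_inverted(self, two_inversion_case):
        anc, obs, truth = two_inversion_case
        blocks = lcb.chain_anchors(lcb.find_anchors(anc, obs))
        assert len(blocks) == 5
        assert sum(1 for b in blocks if b.sign == -1) == 2
        assert lcb.blocks_to_permutation(blocks) == truth.expected_blocks

    def test_block_intervals_disjoint_and_covering(self, two_inversion_case):
        anc, obs, _ = two_inversion_case
        blocks = lcb.chain_anchors(lcb.find_anchors(anc, obs))
        for key in ("intervalA", "intervalB"):
            ivs = sorted(getattr(b, key) for b in blocks)
            for x, y in zip(ivs, ivs[1:]):
                # exact matches may run a few bp past a breakpoint by chance
                assert x.end - y.start <= 50
            assert sum(iv.length for iv in ivs) >= 0.9 * anc.length

    def test_swap_symmetry_gives_inverse_permutation(self, two_inversion_case):
        anc, obs, _ = two_inversion_case
        fwd = lcb.blocks_to_permutation(lcb.chain_anchors(lcb.find_anchors(anc, obs)))
        swp = lcb.blocks_to_permutation(lcb.chain_anchors(lcb.find_anchors(obs, anc)))
        assert swp == invert_signed(fwd)

    @pytest.mark.parametrize("seed", range(10))
    def test_planted_scenario_recovery(self, seed):
        """Any <=3-inversion scenario over >=4 kb segments is read back as
        the truth permutation (after merging still-collinear neighbours)."""
        rng = np.random.default_rng(seed)
        g = synth.generate_genome(40_000, 16, 700, seed=seed + 500, id="anc")
        spacers = [iv for iv in intergenic_intervals(g) if iv.end <= g.length]
        centres = [(iv.start + iv.end) // 2 for iv in spacers]
        # junctions: 3-4 spacer centres at least 4 kb apart
        m = int(rng.integers(3, 5))
        junctions = []
        for c in centres:
            if len(junctions) == m:
                break
            if not junctions or c - junctions[-1] >= 4500:
                if c >= 3000 and g.length - c >= 3000:
                    junctions.append(c)
        assert len(junctions) >= 3
        n_blocks = len(junctions) + 1
        n_events = int(rng.integers(1, 4))
        events = []
        perm = identity_permutation(n_blocks)
        # linear model: first and last blocks stay put (the origin is a
        # fixed linearization point, as in the five-block comparison)
        for _ in range(n_events):
            i = int(rng.integers(2, n_blocks))
            j = int(rng.integers(i, n_blocks))
            events.append((i, j))
            perm = apply_inversion(perm, i, j)
        derived = _apply_block_scenario(g, junctions, events)
        # max_gap scaled to the 40 kb test genome: it must stay below the
        # smallest block displacement (>= 4.5 kb here) or a moved block can
        # be absorbed as a "gap"
        blocks = lcb.chain_anchors(lcb.find_anchors(g, derived), max_gap=1500)
        detected = lcb.blocks_to_permutation(blocks)
        assert merge_collinear(detected) == merge_collinear(perm)


# ---------------------------------------------------------------------------
# junction association
# ---------------------------------------------------------------------------

class TestJunctionAssociation:
    def test_two_inversion_case_r1_r2_each_at_two_junctions(self, two_inversion_report):
        by_label = {}
        for a in two_inversion_report.junctions:
            if a.repeat_label:
                by_label.setdefault(a.repeat_label, set()).add(a.junction)
        # the 566 bp (P1) and 435 bp (P2) pairs each sit on two junctions
        label_of = {p.length: p.label for p in two_inversion_report.repeats}
        assert len(by_label[label_of[566]]) == 2
        assert len(by_label[label_of[435]]) == 2

    def test_all_two_inversion_case_junctions_intergenic(self, two_inversion_report):
        assert two_inversion_report.junctions
        assert all(a.intergenic for a in two_inversion_report.junctions)

    def test_distant_repeats_unassociated(self, two_inversion_case):
        anc, obs, _ = two_inversion_case
        blocks = lcb.chain_anchors(lcb.find_anchors(anc, obs))
        # a fake repeat far from every junction
        from mitoblocks.repeats import RepeatPair

        far = RepeatPair(
            copy1=Interval(5000, 5100), copy2=Interval(15_000, 15_100),
            orientation="direct", length=100, identity=1.0, label="far",
        )
        assocs = lcb.junction_repeat_association(blocks, [far], obs)
        assert all(a.repeat_label is None for a in assocs)
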