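"""Inversion model: involution, distances vs independent oracle, scenarios."""

import heapq
import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mitoblocks import rearrange as rr
from mitoblocks.rearrange import (
    InversionEvent,
    RearrangementError,
    RepeatPlacement,
    Scenario,
    apply_inversion,
    find_repeat_mediated_scenarios,
    identity_permutation,
    inversion_distance_bfs,
    track_repeats_through_event,
)


def dijkstra_distance(source, target, cap=8):
    """Independent uniform-cost search over the inversion graph."""
    pq = [(0, source)]
    dist = {source: 0}
    while pq:
        d, p = heapq.heappop(pq)
        if p == target:
            return d
        if d > dist.get(p, 1e9) or d >= cap:
            continue
        for i in range(1, len(p) + 1):
            for j in range(i, len(p) + 1):
                q = apply_inversion(p, i, j)
                if d + 1 < dist.get(q, 1e9):
                    dist[q] = d + 1
                    heapq.heappush(pq, (d + 1, q))
    return None


def random_signed_perm(rng, n):
    vals = list(rng.permutation(range(1, n + 1)))
    return tuple(int(v) if rng.random() < 0.5 else -int(v) for v in vals)


perm_strategy = st.integers(2, 7).flatmap(
    lambda n: st.permutations(list(range(1, n + 1))).flatmap(
        lambda vals: st.tuples(*[st.sampled_from([v, -v]) for v in vals])
    )
)


class TestApplyInversion:
    def test_fig_model_first_event(self):
        assert apply_inversion((1, 2, 3, 4, 5), 3, 4) == (1, 2, -4, -3, 5)

    def test_fig_model_second_event(self):
        assert apply_inversion((1, 2, -4, -3, 5), 2, 3) == (1, 4, -2, -3, 5)

    @settings(derandomize=True, max_examples=60)
    @given(perm_strategy, st.data())
    def test_involution_and_conservation(self, perm, data):
        n = len(perm)
        i = data.draw(st.integers(1, n))
        j = data.draw(st.integers(i, n))
        q = apply_inversion(perm, i, j)
        assert sorted(abs(x) for x in q) == sorted(abs(x) for x in perm)
        assert apply_inversion(q, i, j) == perm

    def test_out_of_range_rejected(self):
        with pytest.raises(RearrangementError):
            apply_inversion((1, 2, 3), 0, 2)
        with pytest.raises(RearrangementError):
            apply_inversion((1, 2, 3), 2, 4)


class TestInversionDistance:
    def test_observed_order_is_two_steps_and_not_one(self):
        src, tgt = (1, 2, 3, 4, 5), (1, 4, -2, -3, 5)
        assert inversion_distance_bfs(src, tgt) == 2
        # minimality: no single inversion of the identity gives the target
        singles = {
            apply_inversion(src, i, j) for i, j in rr.all_inversions(5)
        }
        assert tgt not in singles

    def test_identity_cases(self):
        assert inversion_distance_bfs((1, 2, 3), (1, 2, 3)) == 0
        assert inversion_distance_bfs((1, 2, 3), (1, -2, 3)) == 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(RearrangementError):
            inversion_distance_bfs((1, 2), (1, 2, 3))

    def test_state_space_guard(self):
        big = identity_permutation(11)
        with pytest.raises(RearrangementError):
            inversion_distance_bfs(big, big)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_independent_dijkstra(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 6))
        p, q = random_signed_perm(rng, n), random_signed_perm(rng, n)
        assert inversion_distance_bfs(p, q, max_depth=8) == dijkstra_distance(p, q)

    @pytest.mark.parametrize("seed", range(6))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(3, 7))
        p, q = random_signed_perm(rng, n), random_signed_perm(rng, n)
        assert inversion_distance_bfs(p, q, 8) == inversion_distance_bfs(q, p, 8)

    @pytest.mark.parametrize("seed", range(5))
    def test_triangle_inequality(self, seed):
        rng = np.random.default_rng(200 + seed)
        n = int(rng.integers(3, 6))
        p, q, r = (random_signed_perm(rng, n) for _ in range(3))
        dpq = inversion_distance_bfs(p, q, 8)
        dqr = inversion_distance_bfs(q, r, 8)
        dpr = inversion_distance_bfs(p, r, 8)
        assert dpr <= dpq + dqr


class TestTrackRepeats:
    def test_event_spanning_neither_copy_unchanged(self):
        pls = (RepeatPlacement("R", 0, 1, "direct"),)
        out = track_repeats_through_event(pls, InversionEvent((3, 4)), 5)
        assert out == pls

    def test_event_spanning_both_copies_keeps_orientation(self):
        pls = (RepeatPlacement("R", 2, 3, "inverted"),)
        out = track_repeats_through_event(pls, InversionEvent((2, 4)), 5)
        assert out[0].relative_orientation == "inverted"

    def test_single_copy_in_span_flips_orientation(self):
        pls = (RepeatPlacement("R2", 1, 3, "direct"),)
        out = track_repeats_through_event(pls, InversionEvent((3, 4)), 5)
        assert out[0].relative_orientation == "inverted"
        assert (out[0].left_junction, out[0].right_junction) == (1, 3)

    def test_two_event_composition_keeps_r2_at_final_junctions(self):
        # hand-propagation through the canonical two-event model: R2 starts
        # at junctions 1,3 (direct); after (3,4) it is inverted at 1,3;
        # after (2,3) it is back to boundaries 1,3, inverted
        pls = (
            RepeatPlacement("R1", 2, 4, "inverted"),
            RepeatPlacement("R2", 1, 3, "direct"),
        )
        after1 = track_repeats_through_event(pls, InversionEvent((3, 4)), 5)
        r1, r2 = after1
        assert (r1.left_junction, r1.right_junction, r1.relative_orientation) == (
            2, 4, "inverted",
        )
        assert (r2.left_junction, r2.right_junction, r2.relative_orientation) == (
            1, 3, "inverted",
        )
        after2 = track_repeats_through_event(after1, InversionEvent((2, 3)), 5)
        r1b, r2b = after2
        assert (r2b.left_junction, r2b.right_junction) == (1, 3)
        # R1 had one copy strictly inside the second span: it re-orients
        assert r1b.relative_orientation == "direct"


class TestScenarioSearch:
    def test_canonical_case_unique_two_event_scenario(self):
        src, tgt = (1, 2, 3, 4, 5), (1, 4, -2, -3, 5)
        pls = [
            RepeatPlacement("R1", 2, 4, "inverted"),
            RepeatPlacement("R2", 1, 3, "direct"),
        ]
        scenarios = find_repeat_mediated_scenarios(src, tgt, pls)
        assert len(scenarios) == 1
        (sc,) = scenarios
        assert [(ev.segment, ev.mediating_repeat) for ev in sc.events] == [
            ((3, 4), "R1"),
            ((2, 3), "R2"),
        ]
        assert sc.intermediates()[1] == (1, 2, -4, -3, 5)

    def test_no_placements_no_scenarios(self):
        assert find_repeat_mediated_scenarios((1, 2, 3), (1, -2, 3), []) == []

    def test_scenarios_replay_on_construction(self):
        with pytest.raises(RearrangementError):
            Scenario(
                events=(InversionEvent((1, 2)),), source=(1, 2), target=(1, 2)
            )

    @pytest.mark.parametrize("seed", range(50))
    def test_constraint_never_shortens_below_bfs(self, seed):
        rng = np.random.default_rng(300 + seed)
        n = int(rng.integers(3, 6))
        src = identity_permutation(n)
        tgt = random_signed_perm(rng, n)
        n_pl = int(rng.integers(0, 4))
        pls = []
        for z in range(n_pl):
            a = int(rng.integers(0, n))
            b = int(rng.integers(a + 1, n + 1))
            pls.append(
                RepeatPlacement(
                    f"P{z}", a, b,
                    "inverted" if rng.random() < 0.5 else "direct",
                )
            )
        scs = find_repeat_mediated_scenarios(src, tgt, pls, max_events=4)
        free = inversion_distance_bfs(src, tgt, max_depth=4)
        if scs:
            assert free is not None
            assert len(scs[0].events) >= free
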