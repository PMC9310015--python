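"""Skeleton reconstruction: classification, corridor, tracing, reattachment."""

from __future__ import annotations

import itertools
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stemtrace.directed_search import (
    SearchConfig,
    Skeleton,
    build_skeleton,
    classify_plant_type,
    filter_in_rect,
    judge_area,
    reattach_branch,
    select_next_node,
    trace_branches,
    trace_main_stem,
)
from stemtrace.errors import InputError
from stemtrace.geometry import Point, Rect, angle_at, canonicalize

CFG = SearchConfig()

COLLINEAR_5 = [Point(400 - 100 * i, 0) for i in range(5)]
# base-up chain with one interleaved off-axis node: the classic
# multi-branched signature
MULTI_5 = [Point(300, 0), Point(200, 0), Point(150, 80), Point(100, 0), Point(0, 0)]


class TestClassifyPlantType:
    def test_collinear_is_single(self):
        assert classify_plant_type(COLLINEAR_5, CFG) == "single"

    def test_interleaved_offaxis_node_is_multi(self):
        cfg = SearchConfig(judge_scope="all")
        # at i=0: consecutive-triplet angle 122.06 deg vs skip-triplet 180
        a1 = angle_at(MULTI_5[0], MULTI_5[1], MULTI_5[2])
        a2 = angle_at(MULTI_5[0], MULTI_5[1], MULTI_5[3])
        # cosine rule by hand: dot((100,0), (-50,80)) / (100 * sqrt(8900))
        expected = math.degrees(math.acos(-5000 / (100 * math.sqrt(8900))))
        assert a1 == pytest.approx(expected, abs=1e-9)
        assert a2 == 180.0
        assert classify_plant_type(MULTI_5, cfg) == "multi"

    def test_three_nodes_single_by_convention(self):
        assert classify_plant_type(
            [Point(100, 0), Point(50, 90), Point(0, 0)], CFG
        ) == "single"

    def test_too_few_nodes_rejected(self):
        with pytest.raises(InputError):
            classify_plant_type([Point(0, 0)], CFG)

    @given(
        dy=st.floats(-1e4, 1e4, allow_nan=False),
        dx=st.floats(-1e4, 1e4, allow_nan=False),
        scale=st.floats(0.01, 100.0),
    )
    @settings(max_examples=100, derandomize=True)
    def test_invariant_under_translation_and_scaling(self, dy, dx, scale):
        def tf(pts):
            return [Point(p.y * scale + dy, p.x * scale + dx) for p in pts]

        cfg = SearchConfig(judge_scope="all")
        for pts in (COLLINEAR_5, MULTI_5):
            assert classify_plant_type(tf(pts), cfg) == classify_plant_type(
                pts, cfg
            )


class TestJudgeArea:
    def test_endpoint_columns_widened(self):
        nodes = [Point(900, 100), Point(500, 120), Point(100, 140)]
        rect = judge_area(nodes, 30, 1000)
        assert rect == Rect(70, 0, 170, 1000)

    def test_symmetric_in_endpoint_order(self):
        a = judge_area([Point(900, 140), Point(100, 100)], 30, 1000)
        b = judge_area([Point(900, 100), Point(100, 140)], 30, 1000)
        assert a == b == Rect(70, 0, 170, 1000)

    def test_zero_expansion(self):
        rect = judge_area([Point(8, 50), Point(2, 50)], 0, 10)
        assert rect == Rect(50, 0, 50, 10)

    def test_bad_height_rejected(self):
        with pytest.raises(InputError):
            judge_area([Point(1, 0), Point(0, 0)], 30, 0)


class TestFilterInRect:
    def test_split_and_boundaries(self):
        rect = Rect(-30, 0, 30, 400)
        inside, outside = filter_in_rect(
            [Point(300, 0), Point(150, 80), Point(100, 30)], rect
        )
        assert inside == [Point(300, 0), Point(100, 30)]  # x == right kept
        assert outside == [Point(150, 80)]

    def test_all_inside(self):
        rect = Rect(0, 0, 100, 100)
        inside, outside = filter_in_rect([Point(50, 50)], rect)
        assert outside == [] and inside == [Point(50, 50)]


class TestSelectNextNode:
    def test_angle_primary_distance_secondary(self):
        """Nearly tied continuation angles resolve by distance to the tip."""
        anchors = (Point(300, 80), Point(250, 80))
        cands = [Point(200, 82), Point(195, 40), Point(140, 84)]
        angles = [angle_at(anchors[0], anchors[1], c) for c in cands]
        assert angles[0] == pytest.approx(177.7088, abs=1e-3)
        assert angles[1] == pytest.approx(143.9726, abs=1e-3)
        assert angles[2] == pytest.approx(177.9172, abs=1e-3)
        # best two angles within alpha; (200, 82) is much nearer
        assert select_next_node(anchors, cands, CFG) == 0

    def test_single_collinear_candidate_chosen(self):
        anchors = (Point(200, 50), Point(100, 50))
        assert select_next_node(anchors, [Point(0, 50)], CFG) == 0

    def test_all_candidates_beyond_gap_cutoff(self):
        anchors = (Point(200, 50), Point(100, 50))
        cands = [Point(-500, 50)]
        assert (
            select_next_node(anchors, cands, CFG, reference_internode=100.0)
            is None
        )

    def test_empty_candidates(self):
        assert select_next_node((Point(1, 0), Point(0, 0)), [], CFG) is None


class TestTraceMainStem:
    def test_collinear_chain_fully_traced(self):
        main, leftovers = trace_main_stem(COLLINEAR_5[:4], CFG)
        assert main == COLLINEAR_5[:4]
        assert leftovers == []

    def test_offaxis_node_skipped(self):
        """A node bending the chain by more than alpha is passed over in
        favour of the collinear continuation."""
        node1 = [Point(300, 0), Point(200, 0), Point(150, 20), Point(100, 0)]
        bend = angle_at(node1[1 - 1], node1[1], node1[2])
        assert bend == pytest.approx(158.1986, abs=1e-3)  # < 180 - alpha
        main, leftovers = trace_main_stem(node1, CFG)
        assert main == [Point(300, 0), Point(200, 0), Point(100, 0)]
        assert leftovers == [Point(150, 20)]

    def test_two_nodes_trivial(self):
        main, leftovers = trace_main_stem([Point(10, 0), Point(0, 0)], CFG)
        assert main == [Point(10, 0), Point(0, 0)]
        assert leftovers == []

    def test_too_few_rejected(self):
        with pytest.raises(InputError):
            trace_main_stem([Point(0, 0)], CFG)


class TestTraceBranches:
    MAIN = [Point(400 - 100 * i, 50) for i in range(5)]
    RECT = Rect(20, 0, 80, 500)

    def test_no_unassigned(self):
        assert trace_branches([], self.MAIN, self.RECT, CFG) == []

    def test_vertical_line_becomes_one_branch(self):
        stray = [Point(300, 200), Point(240, 200), Point(180, 200)]
        chains = trace_branches(stray, self.MAIN, self.RECT, CFG)
        assert chains == [stray]

    def test_singletons_form_no_branch(self):
        stray = [Point(300, 200), Point(100, 600)]
        assert trace_branches(stray, self.MAIN, self.RECT, CFG) == []


class TestReattachBranch:
    MAIN = [Point(300, 50), Point(240, 50), Point(180, 50), Point(120, 50)]

    def test_nearest_eligible_wins(self):
        branch = [Point(180, 120), Point(120, 180)]
        # distances from the branch base to eligible main nodes:
        # 138.9, 92.2, 70.0, 92.2 -> index 2
        assert reattach_branch(branch, self.MAIN, CFG) == 2

    def test_coincident_base(self):
        branch = [Point(240, 50), Point(200, 140)]
        assert reattach_branch(branch, self.MAIN, CFG) == 1

    def test_branch_below_stem_falls_back_to_base(self):
        branch = [Point(500, 300), Point(450, 350)]
        assert reattach_branch(branch, self.MAIN, CFG) == 0


class TestBuildSkeleton:
    def test_collinear_plant_single_chain(self):
        pts = [Point(500 - 100 * i, 40) for i in range(6)]
        skel = build_skeleton(pts, image_height=600)
        assert skel.main_stem == tuple(pts)
        assert skel.branches == () and skel.discarded == ()

    def test_multi_plant_with_two_node_branch(self):
        pts = MULTI_5 + [Point(120, 90)]
        skel = build_skeleton(pts, image_height=400)
        assert skel.main_stem == (
            Point(300, 0), Point(200, 0), Point(100, 0), Point(0, 0),
        )
        assert len(skel.branches) == 1
        branch = skel.branches[0]
        assert branch.chain == (Point(150, 80), Point(120, 90))
        assert branch.attach_index == 1  # nearest eligible, tie to lower node
        assert skel.discarded == ()

    def test_cotyledon_prepended_as_base(self):
        pts = [Point(500 - 100 * i, 40) for i in range(4)]
        cot = Point(560, 41)
        skel = build_skeleton(pts, image_height=600, cotyledon=cot)
        assert skel.main_stem[0] == cot
        assert len(skel.main_stem) == 5

    def test_too_few_nodes(self):
        with pytest.raises(InputError):
            build_skeleton([Point(0, 0)], image_height=10)

    @given(st.data())
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_partition_invariant_on_random_clouds(self, data):
        """Every input node lands in exactly one of main stem, a branch,
        or the discarded set."""
        n = data.draw(st.integers(2, 18))
        ys = data.draw(
            st.lists(
                st.floats(1, 999), min_size=n, max_size=n, unique=True
            )
        )
        xs = data.draw(
            st.lists(st.floats(0, 500), min_size=n, max_size=n)
        )
        pts = [Point(y, x) for y, x in zip(ys, xs)]
        skel = build_skeleton(pts, image_height=1000)
        assert skel.n_points == n
        got = sorted(
            [p for c in skel.chains for p in c] + list(skel.discarded),
            key=lambda p: (p.y, p.x),
        )
        assert got == sorted(pts, key=lambda p: (p.y, p.x))


def _alpha_feasible_chains(pts, alpha):
    """All base-seeded ordered subsequences whose every triplet angle is
    at least 180 - alpha (brute-force oracle for the main-stem trace)."""
    n = len(pts)
    chains = []
    for r in range(2, n + 1):
        for idxs in itertools.combinations(range(2, n), r - 2):
            chain = [pts[0], pts[1]] + [pts[i] for i in idxs]
            ok = all(
                angle_at(chain[i], chain[i + 1], chain[i + 2])
                >= 180.0 - alpha
                for i in range(len(chain) - 2)
            )
            if ok:
                chains.append(chain)
    return chains


def _min_triplet_angle(chain):
    if len(chain) < 3:
        return 180.0
    return min(
        angle_at(chain[i], chain[i + 1], chain[i + 2])
        for i in range(len(chain) - 2)
    )


class TestMainStemOracle:
    """For small corridors, the greedy trace must agree with exhaustive
    search over feasible chains (longest feasible chain, ties by the
    largest minimum triplet angle) whenever that optimum is unique."""

    @pytest.mark.parametrize(
        "pts",
        [
            COLLINEAR_5,
            # straight stem with one decoy that breaks collinearity
            [
                Point(400, 10),
                Point(300, 10),
                Point(250, 45),
                Point(200, 12),
                Point(100, 8),
                Point(0, 10),
            ],
            # gentle smooth bend, fully feasible
            [
                Point(400, 0),
                Point(300, 6),
                Point(200, 16),
                Point(100, 30),
                Point(0, 48),
            ],
        ],
    )
    def test_greedy_matches_exhaustive_optimum(self, pts):
        pts = canonicalize(pts)
        feasible = _alpha_feasible_chains(pts, CFG.alpha_deg)
        assert feasible, "fixture must admit at least one feasible chain"
        best_len = max(len(c) for c in feasible)
        longest = [c for c in feasible if len(c) == best_len]
        best = max(longest, key=_min_triplet_angle)
        # optimum must be unique for the comparison to be meaningful
        ties = [
            c
            for c in longest
            if _min_triplet_angle(c) == _min_triplet_angle(best)
        ]
        assert len(ties) == 1
        main, _ = trace_main_stem(pts, CFG)
        assert set(main) == set(best)
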