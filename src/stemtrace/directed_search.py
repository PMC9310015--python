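"""Greedy angle-guided reconstruction of a plant skeleton from stem nodes.

The input is an unordered set of detected stem-node centers.  Mature soybean
main stems are close to straight: the angle at any node between its two
neighbours is near 180 deg, so a smooth chain can be traced greedily by
always continuing toward the candidate that best preserves collinearity.
The pipeline is:

1. classify the plant as single-stem (one smooth chain) or multi-branched
   by comparing consecutive-triplet and skip-triplet angles;
2. for multi-branched plants, delineate a vertical corridor around the
   main stem (``judge_area``), trace the main stem inside it, then trace
   the left/right branch chains outside it;
3. return every branch to the main stem at its attachment node.

Node candidates are scored with the vertex angle as the primary criterion
and Euclidean distance as the tie-break: when the best and second-best
continuation angles differ by less than the error angle ``alpha``, the
nearer point wins.
"""

from __future__ import annotations

import math
import statistics
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .errors import GeometryError, InputError
from .geometry import Point, Rect, angle_at, canonicalize, distance

__all__ = [
    "SearchConfig",
    "Branch",
    "Skeleton",
    "classify_plant_type",
    "judge_area",
    "filter_in_rect",
    "select_next_node",
    "trace_main_stem",
    "trace_branches",
    "reattach_branch",
    "build_skeleton",
]


@dataclass(frozen=True)
class SearchConfig:
    """Tunable parameters of the directed search.

    alpha_deg
        Error angle in degrees: two angles closer than this are treated as
        equal (tie broken by distance), and the same tolerance drives the
        single/multi classification.  Calibrated on the lower half of the
        stem, 10 deg separates smooth stems from branch junctions.
    expand_pixels
        Half-extension of the main-stem corridor beyond the base/top node
        columns; 30 px keeps all main-stem nodes inside for typical plants.
    judge_scope
        ``"lower_half"`` restricts the single/multi test to the bottom half
        of the node sequence (branches emerge low on the stem, curvature
        concentrates at the top); ``"all"`` uses every triplet.
    max_gap_factor
        A candidate farther than ``max_gap_factor`` reference internode
        lengths from the chain tip is never accepted; this stops chains
        from jumping across the plant.
    branching_angle_mode
        ``"local_direction"`` measures each branching angle against the
        local main-stem direction at the attachment node;
        ``"stem_base"`` measures it against the main stem's second node
        regardless of where the branch attaches.
    """

    alpha_deg: float = 10.0
    expand_pixels: float = 30.0
    judge_scope: str = "lower_half"
    max_gap_factor: float = 2.0
    branching_angle_mode: str = "local_direction"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_deg < 90.0:
            raise InputError(f"alpha_deg {self.alpha_deg} outside (0, 90)")
        if self.expand_pixels < 0:
            raise InputError("expand_pixels must be >= 0")
        if self.judge_scope not in ("lower_half", "all"):
            raise InputError(f"unknown judge_scope {self.judge_scope!r}")
        if self.max_gap_factor <= 0:
            raise InputError("max_gap_factor must be > 0")
        if self.branching_angle_mode not in ("local_direction", "stem_base"):
            raise InputError(
                f"unknown branching_angle_mode {self.branching_angle_mode!r}"
            )


@dataclass(frozen=True)
class Branch:
    """A branch chain (base upward) and the index of its attachment node
    on the main stem."""

    chain: tuple[Point, ...]
    attach_index: int


@dataclass(frozen=True)
class Skeleton:
    """Reconstructed plant topology.

    Every input node belongs to exactly one of ``main_stem``, a branch
    chain, or ``discarded`` (nodes that could not be assigned to any chain
    of length >= 2).
    """

    main_stem: tuple[Point, ...]
    branches: tuple[Branch, ...] = ()
    discarded: tuple[Point, ...] = ()

    @property
    def chains(self) -> list[tuple[Point, ...]]:
        """Main stem first, then each branch chain."""
        return [self.main_stem, *(b.chain for b in self.branches)]

    @property
    def n_points(self) -> int:
        return (
            len(self.main_stem)
            + sum(len(b.chain) for b in self.branches)
            + len(self.discarded)
        )


# ---------------------------------------------------------------------------
# classification


def classify_plant_type(nodes: Sequence[Point], cfg: SearchConfig) -> str:
    """Label a node set ``"single"`` (one smooth chain) or ``"multi"``.

    For each judged index ``i`` the consecutive-triplet angle
    ``(node[i], node[i+1], node[i+2])`` is compared with the skip-triplet
    angle ``(node[i], node[i+1], node[i+3])``; a smooth chain keeps the two
    within the error angle everywhere, while an interleaved branch node
    produces a large discrepancy.  Plants with three or fewer nodes are
    single by convention.
    """
    pts = canonicalize(nodes)
    n = len(pts)
    if n < 2:
        raise InputError("classification needs at least two nodes")
    if n <= 3:
        return "single"
    last = n - 4  # highest i with node[i+3] in range
    if cfg.judge_scope == "lower_half":
        # bottom ceil(n/2) triplets
        idxs = range(0, min(last + 1, math.ceil(n / 2)))
    else:
        idxs = range(0, last + 1)
    for i in idxs:
        a1 = angle_at(pts[i], pts[i + 1], pts[i + 2])
        a2 = angle_at(pts[i], pts[i + 1], pts[i + 3])
        if abs(a1 - a2) >= cfg.alpha_deg:
            return "multi"
    return "single"


# ---------------------------------------------------------------------------
# corridor


def judge_area(
    nodes: Sequence[Point], expand_pixels: float, image_height: float
) -> Rect:
    """Vertical corridor around the main stem.

    Spans the full image height; horizontally it covers the columns of the
    bottom and top nodes widened by ``expand_pixels`` on both sides.
    """
    if image_height <= 0:
        raise InputError(f"image_height {image_height} must be positive")
    pts = canonicalize(nodes)
    if len(pts) < 2:
        raise InputError("corridor needs at least two nodes")
    x0, x1 = pts[0].x, pts[-1].x
    return Rect(
        left=min(x0, x1) - expand_pixels,
        top=0.0,
        right=max(x0, x1) + expand_pixels,
        bottom=float(image_height),
    )


def filter_in_rect(
    nodes: Sequence[Point], rect: Rect
) -> tuple[list[Point], list[Point]]:
    """Split nodes into (inside, outside) a closed rectangle, preserving
    order."""
    inside: list[Point] = []
    outside: list[Point] = []
    for p in nodes:
        (inside if rect.contains(p) else outside).append(p)
    return inside, outside


# ---------------------------------------------------------------------------
# candidate selection


def _median_step(points: Sequence[Point]) -> Optional[float]:
    """Median consecutive distance, the reference internode length."""
    if len(points) < 2:
        return None
    steps = [distance(points[i], points[i + 1]) for i in range(len(points) - 1)]
    return statistics.median(steps)


def select_next_node(
    anchor_pair: tuple[Point, Point],
    candidates: Sequence[Point],
    cfg: SearchConfig,
    reference_internode: Optional[float] = None,
) -> Optional[int]:
    """Pick the next chain node among the first three candidates.

    The continuation angle at the chain tip (between the previous chain
    node and the candidate) is the primary criterion; when the best and
    second-best angles are within ``alpha_deg`` the candidate nearer to the
    tip wins.  Candidates farther than ``max_gap_factor`` reference
    internodes from the tip are ineligible; returns ``None`` when no
    candidate is eligible.
    """
    if not candidates:
        return None
    prev, tip = anchor_pair
    cutoff = (
        None
        if reference_internode is None
        else cfg.max_gap_factor * reference_internode
    )
    scored: list[tuple[int, float, float]] = []
    for i, c in enumerate(candidates[:3]):
        try:
            ang = angle_at(prev, tip, c)
        except GeometryError:
            continue  # coincident with the tip: not a usable continuation
        d = distance(tip, c)
        if cutoff is not None and d > cutoff:
            continue
        scored.append((i, ang, d))
    if not scored:
        return None
    best_angle = max(s[1] for s in scored)
    # every candidate whose angle is indistinguishable from the optimum
    # (within the error angle) competes on distance to the chain tip
    tied = [s for s in scored if best_angle - s[1] < cfg.alpha_deg]
    return min(tied, key=lambda s: (s[2], s[0]))[0]


# ---------------------------------------------------------------------------
# chain tracing


def trace_main_stem(
    node1: Sequence[Point], cfg: SearchConfig
) -> tuple[list[Point], list[Point]]:
    """Trace the main stem through the corridor nodes.

    The two bottom-most nodes seed the chain; the walk repeatedly applies
    :func:`select_next_node` to the remaining nodes in canonical order.
    Nodes passed over by a selection are returned as leftovers (they are
    branch candidates), as are all nodes beyond the point where no
    eligible candidate remains.
    """
    pts = canonicalize(node1)
    if len(pts) < 2:
        raise InputError("main-stem tracing needs at least two corridor nodes")
    chain: list[Point] = [pts[0], pts[1]]
    remaining: list[Point] = list(pts[2:])
    leftovers: list[Point] = []
    # the main stem is not known yet, so the reference internode is the
    # median consecutive spacing over the whole corridor array
    ref = _median_step(pts)
    while remaining:
        idx = select_next_node(
            (chain[-2], chain[-1]), remaining, cfg, reference_internode=ref
        )
        if idx is None:
            leftovers.extend(remaining)
            break
        leftovers.extend(remaining[:idx])
        chain.append(remaining[idx])
        remaining = remaining[idx + 1 :]
    return chain, leftovers


def _nearest_index(points: Sequence[Point], target: Point) -> int:
    return min(range(len(points)), key=lambda i: (distance(points[i], target), i))


def trace_branches(
    unassigned: Sequence[Point],
    main: Sequence[Point],
    rect: Rect,
    cfg: SearchConfig,
) -> list[list[Point]]:
    """Chain the nodes left over after main-stem tracing into branches.

    Nodes are split into a left group (west of the corridor) and a right
    group (east of it); leftovers inside the corridor join the nearer side.
    Within a group, each new chain starts at the bottom-most unassigned
    node, seeds its direction from the nearest main-stem node, and extends
    upward with :func:`select_next_node`.  Chains shorter than two nodes
    are not branches; their nodes are left for the caller to discard.
    """
    pts = canonicalize(unassigned)
    if not pts:
        return []
    ref = _median_step(main) if len(main) >= 2 else _median_step(pts)

    groups: dict[str, list[Point]] = {"left": [], "right": []}
    for p in pts:
        if p.x < rect.left:
            groups["left"].append(p)
        elif p.x > rect.right:
            groups["right"].append(p)
        else:  # corridor leftover: join the nearer side, ties to the left
            if p.x - rect.left <= rect.right - p.x:
                groups["left"].append(p)
            else:
                groups["right"].append(p)

    chains: list[list[Point]] = []
    for side in ("left", "right"):
        remaining = groups[side]
        while remaining:
            start = remaining.pop(0)  # bottom-most unassigned in the group
            chain = [start]
            # Seed anchor: the estimated attachment node on the main stem.
            anchor: Optional[tuple[Point, Point]] = None
            if main:
                est = main[_nearest_index(main, start)]
                if est != start:
                    anchor = (est, start)
            while True:
                above = [
                    (i, p) for i, p in enumerate(remaining) if p.y < chain[-1].y
                ]
                if not above:
                    break
                cand_pts = [p for _, p in above]
                if anchor is None:
                    # degenerate seed: nearest node above, gap-gated
                    j = _nearest_index(cand_pts, chain[-1])
                    if ref is not None and (
                        distance(cand_pts[j], chain[-1])
                        > cfg.max_gap_factor * ref
                    ):
                        break
                else:
                    j = select_next_node(
                        anchor, cand_pts, cfg, reference_internode=ref
                    )
                    if j is None:
                        break
                chain.append(cand_pts[j])
                del remaining[above[j][0]]
                anchor = (chain[-2], chain[-1])
            if len(chain) >= 2:
                chains.append(chain)
    return chains


def reattach_branch(
    branch: Sequence[Point],
    main: Sequence[Point],
    cfg: SearchConfig,
    reference_internode: Optional[float] = None,
) -> int:
    """Index of the main-stem node where a branch attaches.

    Candidates are main-stem nodes at or below the branch's lowest node,
    with one reference internode of vertical slack; among them the node
    nearest to the branch base wins, ties going to the lower index (closer
    to the plant base).  When none is eligible the globally nearest node
    is used.
    """
    if len(branch) < 2 or len(main) < 2:
        raise InputError("reattachment needs a branch chain and a main stem")
    low = canonicalize(branch)[0]
    ref = reference_internode
    if ref is None:
        ref = _median_step(main) or 0.0
    eligible = [i for i, m in enumerate(main) if m.y >= low.y - ref]
    pool = eligible if eligible else list(range(len(main)))
    return min(pool, key=lambda i: (distance(main[i], low), i))


# ---------------------------------------------------------------------------
# orchestration


def build_skeleton(
    nodes: Sequence[Point],
    image_height: float,
    cfg: Optional[SearchConfig] = None,
    cotyledon: Optional[Point] = None,
) -> Skeleton:
    """Reconstruct the full skeleton from an unordered node set.

    Single-stem plants connect all nodes in canonical order; multi-branched
    plants go through corridor delineation, main-stem tracing, branch
    tracing and branch reattachment.  A supplied cotyledon point is
    prepended as the bottom main-stem node before branches are reattached.
    """
    cfg = cfg or SearchConfig()
    pts = canonicalize(nodes)
    if len(pts) < 2:
        raise InputError("skeleton reconstruction needs at least two nodes")

    if classify_plant_type(pts, cfg) == "single":
        main: list[Point] = list(pts)
        chains: list[list[Point]] = []
        unassigned: list[Point] = []
    else:
        rect = judge_area(pts, cfg.expand_pixels, image_height)
        inside, outside = filter_in_rect(pts, rect)
        main, leftovers = trace_main_stem(inside, cfg)
        unassigned = canonicalize(leftovers + outside)
        chains = trace_branches(unassigned, main, rect, cfg)

    if cotyledon is not None:
        main = [cotyledon] + main

    branches = tuple(
        Branch(chain=tuple(c), attach_index=reattach_branch(c, main, cfg))
        for c in chains
    )
    chained = Counter(p for c in chains for p in c)
    discarded: list[Point] = []
    for p in unassigned:
        if chained[p] > 0:
            chained[p] -= 1
        else:
            discarded.append(p)
    return Skeleton(
        main_stem=tuple(main), branches=branches, discarded=tuple(discarded)
    )
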