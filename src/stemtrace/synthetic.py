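"""Ground-truthed synthetic soybean plants for end-to-end testing.

The generator emulates the geometry of mature soybean plants photographed
flat on a white background: a near-straight main stem growing from the
bottom image edge (the cotyledon node is tangent to it), adjacent-triplet
angles tightly concentrated a few degrees below 180, branches attached on
the lower half of the stem and growing outward as their own smooth chains,
and a circular 1-cm scale marker of known pixel diameter.  Every plant
carries its ground-truth skeleton, its phenotype report, and detector-style
bounding boxes, so skeleton reconstruction and phenotype extraction can be
validated without any photographs.

Detector imperfections are emulated separately (:func:`perturb_detections`)
as isotropic Gaussian jitter of the box centers, uniform random misses and
Poisson-distributed spurious boxes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from PIL import Image, ImageDraw
from scipy import optimize, special

from .directed_search import (
    Branch,
    SearchConfig,
    Skeleton,
    classify_plant_type,
    judge_area,
    reattach_branch,
)
from .errors import InfeasiblePlantError, InputError
from .geometry import BBox, Point, Rect, angle_at, canonicalize, distance
from .phenotypes import PhenotypeReport, ScaleCalibration, compute_phenotypes

__all__ = [
    "UniformSpec",
    "TruncatedNormalSpec",
    "PlantParams",
    "NoiseParams",
    "SyntheticPlant",
    "Battery",
    "generate_plant",
    "perturb_detections",
    "render_plant_mask",
    "generate_battery",
    "triplet_angles",
    "topology_matches",
    "match_to_ground_truth",
]

_MAX_SEED = 2**31 - 1


# ---------------------------------------------------------------------------
# distribution specs


@dataclass(frozen=True)
class UniformSpec:
    """Uniform distribution on [low, high] (low == high gives a constant)."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low <= self.high:
            raise InputError(f"uniform bounds reversed: {self}")

    def sample(self, rng: np.random.Generator) -> float:
        if self.low == self.high:
            return self.low
        return float(rng.uniform(self.low, self.high))


@dataclass(frozen=True)
class TruncatedNormalSpec:
    """Normal law truncated to [low, high], parameterized by its *post-
    truncation* mean.

    ``mean`` is the expectation of the truncated distribution itself; the
    location of the underlying normal is solved numerically so that the
    draws actually average to ``mean`` (an asymmetric truncation window
    would otherwise shift it).
    """

    mean: float
    sd: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise InputError("sd must be positive")
        if not self.low < self.mean < self.high:
            raise InputError(f"mean must lie inside the bounds: {self}")

    @property
    def loc(self) -> float:
        """Location of the underlying (untruncated) normal."""
        return _truncnorm_setup(self.mean, self.sd, self.low, self.high)[0]

    def sample(self, rng: np.random.Generator) -> float:
        loc, cdf_lo, cdf_hi = _truncnorm_setup(
            self.mean, self.sd, self.low, self.high
        )
        u = rng.uniform(cdf_lo, cdf_hi)
        return float(loc + self.sd * special.ndtri(u))


@lru_cache(maxsize=64)
def _truncnorm_setup(
    mean: float, sd: float, low: float, high: float
) -> tuple[float, float, float]:
    """Solve the location so the truncated law has the requested mean, and
    precompute the CDF window for inverse-transform sampling."""

    def truncated_mean(mu: float) -> float:
        a = (low - mu) / sd
        b = (high - mu) / sd
        z = special.ndtr(b) - special.ndtr(a)
        if z <= 0:  # window far in a tail; clamp toward the nearer bound
            return low if mu < low else high
        phi = lambda t: math.exp(-0.5 * t * t) / math.sqrt(2.0 * math.pi)
        return mu + sd * (phi(a) - phi(b)) / z

    span = high - low
    loc = float(
        optimize.brentq(
            lambda mu: truncated_mean(mu) - mean,
            low - span,
            high + span,
            xtol=1e-10,
        )
    )
    cdf_lo = float(special.ndtr((low - loc) / sd))
    cdf_hi = float(special.ndtr((high - loc) / sd))
    return loc, cdf_lo, cdf_hi


# ---------------------------------------------------------------------------
# parameters


@dataclass(frozen=True)
class PlantParams:
    """Geometry of a synthetic mature soybean plant.

    Defaults describe a typical single-branch plant: a dozen main-stem
    nodes, internodes of 60-140 px, adjacent-triplet angles averaging
    173.3774 deg (sd 4, truncated to [160, 180]), one branch of four nodes
    attached on the lower half of the stem at 20-80 deg from the stem
    direction, and a 40-px (= 1 cm) circular scale marker.
    """

    n_main_nodes: int = 12
    internode_px: UniformSpec = UniformSpec(60.0, 140.0)
    turn_angle_deg: TruncatedNormalSpec = TruncatedNormalSpec(
        mean=173.3774, sd=4.0, low=160.0, high=180.0
    )
    n_branches: int = 1
    branch_angle_deg: UniformSpec = UniformSpec(20.0, 80.0)
    branch_nodes: int = 4
    attach_zone: float = 0.5
    marker_diameter_px: float = 40.0
    canvas: tuple[int, int] = (2000, 1400)  # (height, width) px
    node_box_px: float = 24.0
    corridor_px: float = 30.0
    max_tilt_deg: float = 15.0
    attach_margin_px: float = 15.0

    def __post_init__(self) -> None:
        if self.n_main_nodes < 3:
            raise InputError("n_main_nodes must be >= 3")
        if self.n_branches < 0:
            raise InputError("n_branches must be >= 0")
        if self.branch_nodes < 2:
            raise InputError("branch_nodes must be >= 2")
        if not 0.0 < self.attach_zone <= 1.0:
            raise InputError("attach_zone must be in (0, 1]")
        if self.marker_diameter_px <= 0:
            raise InputError("marker_diameter_px must be positive")


@dataclass(frozen=True)
class NoiseParams:
    """Detector-noise emulation parameters."""

    jitter_sd_px: float = 0.0
    miss_rate: float = 0.0
    spurious_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.jitter_sd_px < 0:
            raise InputError("jitter_sd_px must be >= 0")
        if not 0.0 <= self.miss_rate < 1.0:
            raise InputError("miss_rate must be in [0, 1)")
        if self.spurious_rate < 0:
            raise InputError("spurious_rate must be >= 0")


@dataclass(frozen=True)
class SyntheticPlant:
    """One generated plant with its complete ground truth."""

    skeleton: Skeleton
    phenotypes: PhenotypeReport
    node_boxes: tuple[BBox, ...]
    marker_box: BBox
    seed: int
    params: PlantParams

    @property
    def canvas(self) -> tuple[int, int]:
        return self.params.canvas

    @property
    def nodes(self) -> list[Point]:
        """All stem-node centers in canonical (base-up) order."""
        return canonicalize(
            [p for chain in self.skeleton.chains for p in chain]
        )

    @property
    def scale(self) -> ScaleCalibration:
        return ScaleCalibration(pixels_per_cm=self.params.marker_diameter_px)


# ---------------------------------------------------------------------------
# growth


def _node_box(p: Point, side: float) -> BBox:
    h = side / 2.0
    return BBox(p.x - h, p.y - h, p.x + h, p.y + h, label="node")


def _grow_chain(
    start: Point,
    tilt_deg: float,
    n_segments: int,
    params: PlantParams,
    rng: np.random.Generator,
    tilt_limit: float,
) -> Optional[list[Point]]:
    """Grow a smooth chain upward from ``start``.

    ``tilt_deg`` is the initial direction measured from vertical (positive
    toward +x).  Each internode draws its length, then the direction turns
    by ``180 - turn_angle`` to a random side; the tilt reflects at
    ``tilt_limit`` so the chain keeps rising.  Returns None when a node
    leaves the canvas.
    """
    height, width = params.canvas
    pts = [start]
    theta = tilt_deg
    for i in range(n_segments):
        length = params.internode_px.sample(rng)
        rad = math.radians(theta)
        p = Point(
            pts[-1].y - length * math.cos(rad), pts[-1].x + length * math.sin(rad)
        )
        if not (0.0 <= p.x < width and 0.0 < p.y < height):
            return None
        if p.y >= pts[-1].y:  # must keep rising
            return None
        pts.append(p)
        if i < n_segments - 1:
            deviation = 180.0 - params.turn_angle_deg.sample(rng)
            sign = 1 if rng.random() < 0.5 else -1
            # keep the tilt bounded by flipping the bend side, never by
            # shrinking the turn: the realized triplet angle must equal
            # 180 - deviation exactly or the angle statistics would drift
            if abs(theta + sign * deviation) > tilt_limit:
                sign = -sign
            theta += sign * deviation
            if abs(theta) > tilt_limit:
                return None
    return pts


def _segment_tilts(chain: Sequence[Point]) -> list[float]:
    """Direction of each segment, degrees from vertical (+x positive)."""
    out = []
    for a, b in zip(chain, chain[1:]):
        out.append(math.degrees(math.atan2(b.x - a.x, a.y - b.y)))
    return out


def _outside_corridor(points: Sequence[Point], rect: Rect) -> bool:
    return all(p.x < rect.left or p.x > rect.right for p in points)


def _try_branches(
    main: list[Point],
    rect: Rect,
    params: PlantParams,
    rng: np.random.Generator,
) -> Optional[list[Branch]]:
    """Attach ``n_branches`` smooth chains on the lower main stem.

    A candidate branch is rejected (and redrawn) unless every node stays in
    the canvas and outside the main-stem corridor, keeps below the stem
    top, rises monotonically, and — so that the ground-truth attachment is
    unambiguous even under a few pixels of detection noise — reattaches to
    its true node under the distance rule used by the reconstruction with a
    margin of at least ``attach_margin_px`` over every competing node.
    """
    if params.n_branches == 0:
        return []
    tilts = _segment_tilts(main)
    top_y = main[-1].y
    zone_hi = max(1, math.floor(params.attach_zone * (len(main) - 1)))
    eligible = list(range(1, zone_hi + 1))
    if len(eligible) < params.n_branches:
        return None
    branches: list[Branch] = []
    used: set[int] = set()
    cfg = SearchConfig()
    for _ in range(params.n_branches):
        for _attempt in range(100):
            k = int(rng.choice([i for i in eligible if i not in used]))
            side = 1 if rng.random() < 0.5 else -1
            phi = params.branch_angle_deg.sample(rng)
            tilt = tilts[k] + side * phi
            if abs(tilt) >= 85.0:
                continue
            chain = _grow_chain(
                main[k], tilt, params.branch_nodes, params, rng, tilt_limit=85.0
            )
            if chain is None:
                continue
            chain = chain[1:]  # the attachment node itself stays on the stem
            if not _outside_corridor(chain, rect):
                continue
            if min(p.y for p in chain) <= top_y:  # stem top must stay topmost
                continue
            if reattach_branch(chain, main, cfg) != k:
                continue  # ambiguous attachment under the distance rule
            d_true = distance(main[k], chain[0])
            others = [
                distance(m, chain[0])
                for i, m in enumerate(main)
                if i != k
            ]
            if min(others) < d_true + params.attach_margin_px:
                continue  # attachment margin too thin for noisy detections
            branches.append(Branch(chain=tuple(chain), attach_index=k))
            used.add(k)
            break
        else:
            return None
    return branches


def generate_plant(params: Optional[PlantParams] = None, seed: int = 0) -> SyntheticPlant:
    """Generate one plant; deterministic given ``(params, seed)``.

    Geometry that exits the canvas or violates the corridor assumptions is
    rejected and redrawn, up to 100 attempts.
    """
    params = params or PlantParams()
    rng = np.random.default_rng(seed)
    height, width = params.canvas

    for _attempt in range(100):
        x0 = width / 2.0 + rng.uniform(-20.0, 20.0)
        base = Point(float(height - 1), x0)
        tilt0 = rng.uniform(-5.0, 5.0)
        main = _grow_chain(
            base,
            tilt0,
            params.n_main_nodes - 1,
            params,
            rng,
            tilt_limit=params.max_tilt_deg,
        )
        if main is None:
            continue
        rect = judge_area(main, params.corridor_px, height)
        if not all(rect.contains(p) for p in main):
            continue
        branches = _try_branches(main, rect, params, rng)
        if branches is None:
            continue

        skeleton = Skeleton(main_stem=tuple(main), branches=tuple(branches))
        scale = ScaleCalibration(pixels_per_cm=params.marker_diameter_px)
        report = compute_phenotypes(skeleton, scale)
        nodes = canonicalize([p for chain in skeleton.chains for p in chain])
        node_boxes = tuple(_node_box(p, params.node_box_px) for p in nodes)
        d = params.marker_diameter_px
        marker = BBox(20.0, 20.0, 20.0 + d, 20.0 + d, label="label")
        return SyntheticPlant(
            skeleton=skeleton,
            phenotypes=report,
            node_boxes=node_boxes,
            marker_box=marker,
            seed=seed,
            params=params,
        )
    raise InfeasiblePlantError(
        f"could not fit a plant in canvas {params.canvas} after 100 attempts"
    )


# ---------------------------------------------------------------------------
# detector noise


def perturb_detections(
    plant: SyntheticPlant, noise: NoiseParams, seed: int = 0
) -> list[BBox]:
    """Noisy detector output for a plant; deterministic given the seed.

    Node box centers receive isotropic Gaussian jitter, each box is dropped
    with ``miss_rate``, and ``Poisson(spurious_rate)`` spurious boxes are
    scattered uniformly over the canvas.  Jittered centers are clamped to
    the canvas, as a detector clips its boxes to the image.  The marker box
    is returned unperturbed.  With all rates zero the output equals the
    ground truth.
    """
    rng = np.random.default_rng(seed)
    height, width = plant.canvas
    side = plant.params.node_box_px
    out: list[BBox] = []
    for box in plant.node_boxes:
        if noise.miss_rate > 0 and rng.random() < noise.miss_rate:
            continue
        if noise.jitter_sd_px > 0:
            dy, dx = rng.normal(0.0, noise.jitter_sd_px, size=2)
            cy = min(max((box.top + box.bottom) / 2.0 + dy, 0.0), height - 1.0)
            cx = min(max((box.left + box.right) / 2.0 + dx, 0.0), width - 1.0)
            dy = cy - (box.top + box.bottom) / 2.0
            dx = cx - (box.left + box.right) / 2.0
        else:
            dy = dx = 0.0
        out.append(
            BBox(
                box.left + dx,
                box.top + dy,
                box.right + dx,
                box.bottom + dy,
                label="node",
            )
        )
    n_spurious = int(rng.poisson(noise.spurious_rate)) if noise.spurious_rate else 0
    for _ in range(n_spurious):
        cy = rng.uniform(side, height - side)
        cx = rng.uniform(side, width - side)
        h = side / 2.0
        out.append(
            BBox(
                cx - h,
                cy - h,
                cx + h,
                cy + h,
                label="node",
                confidence=float(rng.uniform(0.1, 0.9)),
            )
        )
    out.append(plant.marker_box)
    return out


# ---------------------------------------------------------------------------
# rendering


def render_plant_mask(plant: SyntheticPlant, stroke_px: int = 9) -> np.ndarray:
    """Rasterize the skeleton as a dark plant on a light background.

    Polyline strokes at intensity 10 on background 245; the bottom
    main-stem node sits on the bottom image row, so the rendered plant is
    tangent to the bottom edge as the acquisition protocol requires.
    """
    if stroke_px < 1:
        raise InputError("stroke_px must be >= 1")
    height, width = plant.canvas
    skel = plant.skeleton
    for p in skel.main_stem:
        if not (0 <= p.x < width and 0 <= p.y < height):
            raise InputError("skeleton outside canvas")
    img = Image.new("L", (width, height), color=245)
    draw = ImageDraw.Draw(img)
    polylines = [list(skel.main_stem)]
    for b in skel.branches:
        polylines.append([skel.main_stem[b.attach_index], *b.chain])
    for line in polylines:
        xy = [(p.x, p.y) for p in line]
        draw.line(xy, fill=10, width=stroke_px, joint="curve")
    return np.asarray(img)


# ---------------------------------------------------------------------------
# batteries


def triplet_angles(skeleton: Skeleton) -> list[float]:
    """Vertex angles of all adjacent node triplets within each chain."""
    out: list[float] = []
    for chain in skeleton.chains:
        for a, v, b in zip(chain, chain[1:], chain[2:]):
            out.append(angle_at(a, v, b))
    return out


@dataclass(frozen=True)
class Battery:
    """A reproducible collection of synthetic plants plus summary stats."""

    plants: tuple[SyntheticPlant, ...]
    summary: dict


def generate_battery(
    n_plants: int,
    params: Optional[PlantParams] = None,
    seed: int = 0,
) -> Battery:
    """Generate ``n_plants`` plants with per-plant seeds derived from
    ``seed``; deterministic given ``(params, seed)``."""
    if n_plants < 1:
        raise InputError("n_plants must be >= 1")
    params = params or PlantParams()
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, _MAX_SEED, size=n_plants)
    plants = tuple(generate_plant(params, int(s)) for s in child_seeds)

    angles: list[float] = []
    labels: list[str] = []
    cfg = SearchConfig()
    for plant in plants:
        angles.extend(triplet_angles(plant.skeleton))
        labels.append(classify_plant_type(plant.nodes, cfg))
    summary = {
        "n_plants": n_plants,
        "seed": seed,
        "n_triplets": len(angles),
        "mean_triplet_angle_deg": float(np.mean(angles)),
        "min_triplet_angle_deg": float(np.min(angles)),
        "max_triplet_angle_deg": float(np.max(angles)),
        "plant_type_labels": labels,
        "n_single": labels.count("single"),
        "n_multi": labels.count("multi"),
    }
    return Battery(plants=plants, summary=summary)


# ---------------------------------------------------------------------------
# ground-truth comparison


def match_to_ground_truth(
    points: Sequence[Point], plant: SyntheticPlant
) -> Optional[dict[Point, Point]]:
    """Bijective nearest-neighbour map from detected points to true nodes.

    Returns None when the mapping is not one-to-one (e.g. two detections
    collapse onto the same true node).
    """
    truth = plant.nodes
    mapping: dict[Point, Point] = {}
    taken: set[int] = set()
    for p in points:
        j = min(range(len(truth)), key=lambda i: distance(truth[i], p))
        if j in taken:
            return None
        taken.add(j)
        mapping[p] = truth[j]
    return mapping


def topology_matches(
    plant: SyntheticPlant,
    skeleton: Skeleton,
    node_map: Optional[dict[Point, Point]] = None,
) -> bool:
    """True when a reconstruction reproduces the ground-truth topology.

    Checks main-stem membership, the multiset of branch-chain memberships,
    and each branch's attachment node.  ``node_map`` translates detected
    (e.g. jittered) points back to true nodes; identity by default.
    """
    def lift(p: Point) -> Point:
        return node_map[p] if node_map is not None else p

    try:
        got_main = frozenset(lift(p) for p in skeleton.main_stem)
    except KeyError:
        return False
    want = plant.skeleton
    if got_main != frozenset(want.main_stem):
        return False
    if len(skeleton.branches) != len(want.branches):
        return False

    def branch_key(chain: Sequence[Point], attach: Point) -> tuple:
        return (frozenset(chain), attach)

    try:
        got = sorted(
            (
                branch_key(
                    [lift(p) for p in b.chain],
                    lift(skeleton.main_stem[b.attach_index]),
                )
                for b in skeleton.branches
            ),
            key=repr,
        )
    except KeyError:
        return False
    expected = sorted(
        (
            branch_key(b.chain, want.main_stem[b.attach_index])
            for b in want.branches
        ),
        key=repr,
    )
    return got == expected
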