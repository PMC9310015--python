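"""Stem-related phenotypes computed from a reconstructed skeleton.

All lengths are calibrated through the 1-cm circular scale marker placed in
every image: ``pixels_per_cm`` is the mean marker box side divided by the
marker diameter.  The reported phenotypes are

* plant height: straight-line distance between the bottom and top
  main-stem nodes (a vertical drop variant is reported alongside);
* pitch number: node count per chain (internode counts are one less);
* internodal lengths: consecutive node distances per chain;
* branch number and branching angles (angle between each lower branch's
  growth direction and the main stem at the attachment);
* main-stem length: sum of the main-stem internodes;
* stem curvature: plant height over main-stem length, 1 for a perfectly
  erect stem and smaller the more the stem bends (a lodging-resistance
  proxy);
* branch morphology: convergent / semi-open / open by mean branching
  angle (< 30 deg, 30-60 deg, > 60 deg).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from statistics import fmean
from typing import Optional, Sequence

from .directed_search import SearchConfig, Skeleton
from .errors import CalibrationError, InputError, ValidationError
from .geometry import BBox, Point, angle_at, distance

__all__ = [
    "ScaleCalibration",
    "PhenotypeReport",
    "estimate_labelsize",
    "compute_phenotypes",
    "classify_branch_morphology",
]

MARKER_DIAMETER_CM = 1.0


@dataclass(frozen=True)
class ScaleCalibration:
    """Pixel-to-centimeter conversion factor."""

    pixels_per_cm: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.pixels_per_cm) and self.pixels_per_cm > 0):
            raise CalibrationError(
                f"pixels_per_cm must be finite and positive, got {self.pixels_per_cm}"
            )

    def to_cm(self, pixels: float) -> float:
        return pixels / self.pixels_per_cm


def estimate_labelsize(
    marker_boxes: Sequence[BBox],
    marker_diameter_cm: float = MARKER_DIAMETER_CM,
) -> ScaleCalibration:
    """Calibration from the detected scale-marker boxes.

    Each box contributes its mean side length ``(width + height) / 2``;
    the average over boxes divided by the known marker diameter gives
    pixels per centimeter.
    """
    boxes = [b for b in marker_boxes if b.label == "label"]
    if not boxes:
        raise CalibrationError("no scale-marker box found")
    px = fmean((b.width + b.height) / 2.0 for b in boxes)
    return ScaleCalibration(pixels_per_cm=px / marker_diameter_cm)


@dataclass
class PhenotypeReport:
    """Per-plant phenotype record.

    Lengths are in centimeters when a calibration was available, otherwise
    in pixels with ``units == "px"``.  Per-chain sequences list the main
    stem first, then each branch.
    """

    plant_height_cm: float
    vertical_height_cm: float
    node_count_per_chain: list[int]
    internode_count_per_chain: list[int]
    internode_lengths_cm: list[list[float]]
    branch_count: int
    chain_count: int
    branching_angles_deg: list[float]
    main_stem_length_cm: float
    stem_curvature: float
    morphology: str
    units: str = "cm"

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)

    def to_csv_row(self) -> dict:
        """Flat mapping for tabular export; nested lists are JSON-encoded."""
        row = self.to_dict()
        for key in (
            "node_count_per_chain",
            "internode_count_per_chain",
            "internode_lengths_cm",
            "branching_angles_deg",
        ):
            row[key] = json.dumps(row[key])
        return row


def classify_branch_morphology(branching_angles_deg: Sequence[float]) -> str:
    """Morphology class from the mean branching angle.

    Below 30 deg the plant is convergent, above 60 deg open, in between
    semi-open; the boundary values fall in the closed middle interval.
    Plants without branches have no morphology (``"not_applicable"``).
    """
    if not branching_angles_deg:
        return "not_applicable"
    mean = fmean(branching_angles_deg)
    if mean < 30.0:
        return "convergent"
    if mean > 60.0:
        return "open"
    return "semi_open"


def _chain_internodes_px(chain: Sequence[Point]) -> list[float]:
    out = []
    for a, b in zip(chain, chain[1:]):
        d = distance(a, b)
        if d == 0.0:
            raise ValidationError(f"zero-length internode at {a}")
        out.append(d)
    return out


def _branching_angle(
    branch_chain: Sequence[Point],
    main: Sequence[Point],
    attach_index: int,
    mode: str,
) -> float:
    attach = main[attach_index]
    first = branch_chain[0]
    if mode == "stem_base":
        # vertex at the branch base, rays toward the branch's second node
        # and the main stem's second node
        return angle_at(branch_chain[1], first, main[1])
    # local direction: vertex at the attachment node, rays toward the
    # branch base and the next main-stem node above (extrapolated past the
    # stem top if the branch attaches there)
    if attach_index + 1 < len(main):
        ref = main[attach_index + 1]
    else:
        below = main[attach_index - 1]
        ref = Point(2 * attach.y - below.y, 2 * attach.x - below.x)
    return angle_at(first, attach, ref)


def compute_phenotypes(
    skel: Skeleton,
    scale: Optional[ScaleCalibration],
    cfg: Optional[SearchConfig] = None,
) -> PhenotypeReport:
    """All stem-related phenotypes of one plant.

    With ``scale=None`` the report is expressed in raw pixels and flagged
    ``units="px"``.
    """
    cfg = cfg or SearchConfig()
    main = skel.main_stem
    if len(main) < 2:
        raise InputError("phenotypes need a main stem of at least two nodes")

    if scale is None:
        scale = ScaleCalibration(pixels_per_cm=1.0)
        units = "px"
    else:
        units = "cm"

    chains = skel.chains
    internodes_px = [_chain_internodes_px(c) for c in chains]
    internodes_cm = [[scale.to_cm(d) for d in c] for c in internodes_px]

    plant_height = scale.to_cm(distance(main[0], main[-1]))
    vertical_height = scale.to_cm(abs(main[0].y - main[-1].y))
    main_stem_length = sum(internodes_cm[0])
    curvature = plant_height / main_stem_length
    if curvature > 1.0:
        # chord <= path by the triangle inequality; only floating-point
        # round-off can push the ratio past 1
        if curvature > 1.0 + 1e-9:
            raise ValidationError(f"stem curvature {curvature} above 1")
        curvature = 1.0

    angles = [
        _branching_angle(b.chain, main, b.attach_index, cfg.branching_angle_mode)
        for b in skel.branches
    ]

    return PhenotypeReport(
        plant_height_cm=plant_height,
        vertical_height_cm=vertical_height,
        node_count_per_chain=[len(c) for c in chains],
        internode_count_per_chain=[len(c) - 1 for c in chains],
        internode_lengths_cm=internodes_cm,
        branch_count=len(skel.branches),
        chain_count=len(chains),
        branching_angles_deg=angles,
        main_stem_length_cm=main_stem_length,
        stem_curvature=curvature,
        morphology=classify_branch_morphology(angles),
        units=units,
    )
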