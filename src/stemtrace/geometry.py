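"""Planar geometric primitives used throughout the package.

Coordinates follow the raster convention: the origin is the top-left image
corner, ``y`` is the pixel row and increases downward, ``x`` is the pixel
column and increases rightward.  A plant therefore grows toward *smaller*
``y``, and node sequences are canonically ordered from the plant base
upward, i.e. by strictly decreasing ``y``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import GeometryError, InputError

__all__ = [
    "Point",
    "Rect",
    "BBox",
    "canonicalize",
    "distance",
    "angle_at",
    "bbox_center",
    "iou",
]

#: Slack allowed when a floating-point cosine falls outside [-1, 1].
_COS_CLAMP_TOL = 1e-9


@dataclass(frozen=True)
class Point:
    """A continuous pixel coordinate, ``(row, column)``."""

    y: float
    x: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.y) and math.isfinite(self.x)):
            raise GeometryError(f"non-finite point ({self.y}, {self.x})")


@dataclass(frozen=True)
class Rect:
    """An axis-aligned region given by its edge coordinates (closed)."""

    left: float
    top: float
    right: float
    bottom: float

    def __post_init__(self) -> None:
        if self.left > self.right or self.top > self.bottom:
            raise GeometryError(f"degenerate rect {self}")

    def contains(self, p: Point) -> bool:
        return self.left <= p.x <= self.right and self.top <= p.y <= self.bottom


@dataclass(frozen=True)
class BBox:
    """A detector bounding box with a class label and a confidence score.

    ``label`` is ``"node"`` for a stem node and ``"label"`` for the 1-cm
    circular scale marker, mirroring the detector class vocabulary.
    """

    left: float
    top: float
    right: float
    bottom: float
    label: str = "node"
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if not (self.left < self.right and self.top < self.bottom):
            raise GeometryError(f"empty bounding box {self}")
        if not 0.0 <= self.confidence <= 1.0:
            raise InputError(f"confidence {self.confidence} outside [0, 1]")

    @property
    def width(self) -> float:
        return self.right - self.left

    @property
    def height(self) -> float:
        return self.bottom - self.top

    @property
    def area(self) -> float:
        return self.width * self.height


def canonicalize(points: Iterable[Point]) -> list[Point]:
    """Order points from the plant base upward: y strictly descending,
    ties broken by ascending x (a total order keeps every downstream
    routine deterministic)."""
    return sorted(points, key=lambda p: (-p.y, p.x))


def distance(a: Point, b: Point) -> float:
    """Euclidean distance in pixels."""
    return math.hypot(a.y - b.y, a.x - b.x)


def angle_at(a: Point, v: Point, b: Point) -> float:
    """Angle in degrees at vertex ``v`` between rays ``v->a`` and ``v->b``.

    Computed with the cosine rule and clamped to [0, 180].  Raises
    :class:`GeometryError` when either endpoint coincides with the vertex.
    """
    vay, vax = a.y - v.y, a.x - v.x
    vby, vbx = b.y - v.y, b.x - v.x
    na = math.hypot(vay, vax)
    nb = math.hypot(vby, vbx)
    if na == 0.0 or nb == 0.0:
        raise GeometryError("angle vertex coincides with an endpoint")
    c = (vay * vby + vax * vbx) / (na * nb)
    if c > 1.0:
        if c > 1.0 + _COS_CLAMP_TOL:
            raise GeometryError(f"cosine {c} far outside [-1, 1]")
        c = 1.0
    elif c < -1.0:
        if c < -1.0 - _COS_CLAMP_TOL:
            raise GeometryError(f"cosine {c} far outside [-1, 1]")
        c = -1.0
    return math.degrees(math.acos(c))


def bbox_center(b: BBox) -> Point:
    """Center of a bounding box as a :class:`Point`."""
    return Point((b.top + b.bottom) / 2.0, (b.left + b.right) / 2.0)


def iou(b1: BBox, b2: BBox) -> float:
    """Intersection over union of two boxes on continuous coordinates."""
    iw = min(b1.right, b2.right) - max(b1.left, b2.left)
    ih = min(b1.bottom, b2.bottom) - max(b1.top, b2.top)
    if iw <= 0.0 or ih <= 0.0:
        return 0.0
    inter = iw * ih
    union = b1.area + b2.area - inter
    return inter / union
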