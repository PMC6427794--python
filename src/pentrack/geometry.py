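"""Axis-aligned box geometry shared by the detector, tracker and evaluator.

Coordinates are 0-based continuous pixels, ``y`` increasing downward.  A box
``(x, y, w, h)`` covers the half-open region ``[x, x+w) x [y, y+h)``; the
sub-pixel tracker needs real-valued coordinates, so conversion to the 1-based
integer convention of MOT files happens only in the file writer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

__all__ = [
    "Box",
    "Point",
    "jaccard",
    "diag",
    "center_distance",
    "intersection_area",
    "union_box",
]


class Point(NamedTuple):
    """A 2-D point in pixel coordinates (typically a box centre)."""

    cx: float
    cy: float


@dataclass(frozen=True)
class Box:
    """Axis-aligned rectangle ``(x, y, w, h)`` with strictly positive area.

    Degenerate boxes are rejected at construction: every downstream formula
    divides by an area or a diagonal.
    """

    x: float
    y: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if not (self.w > 0 and self.h > 0):
            raise ValueError(f"box must have positive extent, got w={self.w}, h={self.h}")
        if not all(math.isfinite(v) for v in (self.x, self.y, self.w, self.h)):
            raise ValueError("box coordinates must be finite")

    @property
    def area(self) -> float:
        return self.w * self.h

    @property
    def center(self) -> Point:
        return Point(self.x + self.w / 2.0, self.y + self.h / 2.0)

    @property
    def x2(self) -> float:
        return self.x + self.w

    @property
    def y2(self) -> float:
        return self.y + self.h

    def shifted(self, dx: float, dy: float) -> "Box":
        return Box(self.x + dx, self.y + dy, self.w, self.h)

    def contains_point(self, p: Point) -> bool:
        return self.x <= p.cx < self.x2 and self.y <= p.cy < self.y2

    @staticmethod
    def from_center(cx: float, cy: float, w: float, h: float) -> "Box":
        return Box(cx - w / 2.0, cy - h / 2.0, w, h)


def intersection_area(a: Box, b: Box) -> float:
    """Area of the overlap region of two boxes (0 when disjoint)."""
    iw = min(a.x2, b.x2) - max(a.x, b.x)
    ih = min(a.y2, b.y2) - max(a.y, b.y)
    if iw <= 0 or ih <= 0:
        return 0.0
    return iw * ih


def jaccard(a: Box, b: Box) -> float:
    """Intersection-over-union of two boxes, in [0, 1]."""
    inter = intersection_area(a, b)
    return min(inter / (a.area + b.area - inter), 1.0)


def diag(a: Box) -> float:
    """Diagonal length of a box."""
    return math.hypot(a.w, a.h)


def center_distance(a: Box, b: Box) -> float:
    """Euclidean distance between the centre points of two boxes."""
    ca, cb = a.center, b.center
    return math.hypot(ca.cx - cb.cx, ca.cy - cb.cy)


def union_box(a: Box, b: Box) -> Box:
    """Smallest box covering both inputs (used to emulate merged detections)."""
    x1 = min(a.x, b.x)
    y1 = min(a.y, b.y)
    return Box(x1, y1, max(a.x2, b.x2) - x1, max(a.y2, b.y2) - y1)
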