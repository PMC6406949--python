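"""Image-plane geometry primitives shared by the simulator and the analysis stages.

Conventions (used everywhere in this package): coordinates are (row, col),
origin at the top-left pixel, 0-based; rectangles are half-open
``[row0, row1) x [col0, col1)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple

Point = Tuple[float, float]


@dataclass(frozen=True)
class Rect:
    """Half-open axis-aligned rectangle [row0, row1) x [col0, col1)."""

    row0: int
    col0: int
    row1: int
    col1: int

    def __post_init__(self) -> None:
        if not (self.row0 < self.row1 and self.col0 < self.col1):
            raise ValueError(f"degenerate rectangle {self}")

    def contains(self, point: Point) -> bool:
        r, c = point
        return self.row0 <= r < self.row1 and self.col0 <= c < self.col1

    def intersects(self, other: "Rect") -> bool:
        return not (
            self.row1 <= other.row0
            or other.row1 <= self.row0
            or self.col1 <= other.col0
            or other.col1 <= self.col0
        )

    def inside_frame(self, height: int, width: int) -> bool:
        return 0 <= self.row0 and 0 <= self.col0 and self.row1 <= height and self.col1 <= width

    @staticmethod
    def from_sequence(seq) -> "Rect":
        row0, col0, row1, col1 = (int(v) for v in seq)
        return Rect(row0, col0, row1, col1)


@dataclass(frozen=True)
class WeirBand:
    """The weir line segment with a band halfwidth.

    The band is the strip of pixels within ``halfwidth`` (perpendicular
    distance, clamped to the segment) of the line from ``p0`` to ``p1``;
    it is where cell-weir contact, and hence transient deformation, occurs.
    """

    p0: Point
    p1: Point
    halfwidth: float

    def __post_init__(self) -> None:
        if self.halfwidth <= 0:
            raise ValueError("weir band halfwidth must be positive")
        if self.p0 == self.p1:
            raise ValueError("weir segment endpoints coincide")

    @property
    def direction(self) -> Point:
        dr = self.p1[0] - self.p0[0]
        dc = self.p1[1] - self.p0[1]
        norm = math.hypot(dr, dc)
        return (dr / norm, dc / norm)

    def distance(self, point: Point) -> float:
        """Perpendicular distance from ``point`` to the segment."""
        dr, dc = self.direction
        pr = point[0] - self.p0[0]
        pc = point[1] - self.p0[1]
        length = math.hypot(self.p1[0] - self.p0[0], self.p1[1] - self.p0[1])
        t = min(max(pr * dr + pc * dc, 0.0), length)
        fr = self.p0[0] + t * dr
        fc = self.p0[1] + t * dc
        return math.hypot(point[0] - fr, point[1] - fc)

    def contains(self, point: Point) -> bool:
        return self.distance(point) <= self.halfwidth


@dataclass(frozen=True)
class RoiSet:
    """Outlet enumeration regions plus the weir band.

    ``separation`` and ``waste`` are the rectangles at the passages to the
    two outlets where tracked cells are counted; they must be disjoint.
    """

    separation: Rect
    waste: Rect
    weir: WeirBand

    def __post_init__(self) -> None:
        if self.separation.intersects(self.waste):
            raise ValueError("separation and waste ROIs must be disjoint")

    def label_of(self, point: Point) -> str | None:
        if self.separation.contains(point):
            return "separation"
        if self.waste.contains(point):
            return "waste"
        return None
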