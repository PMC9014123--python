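"""Axis-aligned box arithmetic shared by every other module.

Coordinate convention: 0-based, continuous, origin at the top-left corner,
half-open boxes ``[x_min, x_max) x [y_min, y_max)`` so that area equals
``width * height`` and integer-corner boxes tile exactly onto unit pixels.
Annotation files that store ``(x, y, width, height)`` are converted to corner
form at the I/O boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

__all__ = [
    "Category",
    "Box",
    "Point",
    "AffineTransform",
    "area",
    "iou",
    "distance_point_to_box",
    "transform_box",
]


class Category:
    """Box category labels used across the package."""

    HE = "HE"
    OPTIC_DISC = "optic_disc"
    MACULA = "macula"

    ALL = (HE, OPTIC_DISC, MACULA)


@dataclass(frozen=True)
class Box:
    """Axis-aligned rectangle in pixel coordinates.

    ``score`` is an optional detection confidence in [0, 1]; ``category`` is
    one of :class:`Category` (hard exudate, optic disc, macula).
    """

    x_min: float
    y_min: float
    x_max: float
    y_max: float
    score: Optional[float] = None
    category: Optional[str] = None

    def __post_init__(self) -> None:
        if not all(
            math.isfinite(v) for v in (self.x_min, self.y_min, self.x_max, self.y_max)
        ):
            raise ValueError("box coordinates must be finite")
        if self.x_min >= self.x_max or self.y_min >= self.y_max:
            raise ValueError(
                f"degenerate box: ({self.x_min}, {self.y_min}, {self.x_max}, {self.y_max})"
            )
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score must be in [0, 1], got {self.score}")
        if self.category is not None and self.category not in Category.ALL:
            raise ValueError(f"unknown category {self.category!r}")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def center(self) -> "Point":
        return Point((self.x_min + self.x_max) / 2.0, (self.y_min + self.y_max) / 2.0)

    def with_score(self, score: float) -> "Box":
        return replace(self, score=score)

    def geometry_equal(self, other: "Box", tol: float = 0.0) -> bool:
        """Corner-wise equality ignoring score/category."""
        return (
            abs(self.x_min - other.x_min) <= tol
            and abs(self.y_min - other.y_min) <= tol
            and abs(self.x_max - other.x_max) <= tol
            and abs(self.y_max - other.y_max) <= tol
        )


@dataclass(frozen=True)
class Point:
    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError("point coordinates must be finite")


@dataclass(frozen=True)
class AffineTransform:
    """Axis-aligned crop/resize map: ``x -> (x - offset_x) * scale_x`` (same for y)."""

    scale_x: float
    scale_y: float
    offset_x: float = 0.0
    offset_y: float = 0.0

    def __post_init__(self) -> None:
        if self.scale_x <= 0 or self.scale_y <= 0:
            raise ValueError("orientation-inverting or degenerate transform rejected")

    def apply_point(self, p: Point) -> Point:
        return Point((p.x - self.offset_x) * self.scale_x, (p.y - self.offset_y) * self.scale_y)

    def inverse(self) -> "AffineTransform":
        # (x' / scale) + offset == (x' - (-offset*scale)) * (1/scale)
        return AffineTransform(
            scale_x=1.0 / self.scale_x,
            scale_y=1.0 / self.scale_y,
            offset_x=-self.offset_x * self.scale_x,
            offset_y=-self.offset_y * self.scale_y,
        )


def area(b: Box) -> float:
    """Box area in pixels^2; strictly positive for any valid box."""
    return b.width * b.height


def iou(a: Box, b: Box) -> float:
    """Intersection-over-union of two boxes; 0 for disjoint, 1 iff identical.

    Boxes that share only an edge have intersection area 0 and hence IoU 0.
    """
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0.0 or iy <= 0.0:
        return 0.0
    inter = ix * iy
    union = area(a) + area(b) - inter
    return inter / union


def distance_point_to_box(p: Point, b: Box) -> float:
    """Euclidean distance from ``p`` to the nearest point of the closed rectangle.

    Zero when the point lies inside or on the boundary.
    """
    dx = max(b.x_min - p.x, 0.0, p.x - b.x_max)
    dy = max(b.y_min - p.y, 0.0, p.y - b.y_max)
    return math.hypot(dx, dy)


def transform_box(b: Box, t: AffineTransform) -> Box:
    """Map a box through a crop/resize transform; score and category are preserved."""
    return Box(
        x_min=(b.x_min - t.offset_x) * t.scale_x,
        y_min=(b.y_min - t.offset_y) * t.scale_y,
        x_max=(b.x_max - t.offset_x) * t.scale_x,
        y_max=(b.y_max - t.offset_y) * t.scale_y,
        score=b.score,
        category=b.category,
    )
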