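"""Planar geometry primitives for traced contours and marker point pairs.

All coordinates live in the image frame: origin at the top-left corner,
x increasing to the right, y increasing downward, units of pixels.  Angles
are measured with ``atan2(dy, dx)`` in that frame and stored in degrees in
``[-180, 180)``.  Whether an angle reads as clockwise or counterclockwise on
screen is a display concern only; every statistic downstream is relative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from shapely.geometry import Polygon as _ShapelyPolygon

__all__ = [
    "InvalidGeometryError",
    "Point2D",
    "Vector2D",
    "Polygon",
    "polygon_area",
    "polygon_centroid",
    "vector_between",
]

_DEGENERATE_AREA = 1e-12


class InvalidGeometryError(ValueError):
    """Raised for degenerate polygons or undefined vector angles."""


@dataclass(frozen=True)
class Point2D:
    """A point in pixel coordinates (image frame, y down)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise InvalidGeometryError(f"non-finite coordinates ({self.x}, {self.y})")


@dataclass(frozen=True)
class Vector2D:
    """A displacement in pixels; the angle is defined only for non-zero length."""

    dx: float
    dy: float

    @property
    def length(self) -> float:
        return math.hypot(self.dx, self.dy)

    @property
    def is_zero(self) -> bool:
        return self.dx == 0.0 and self.dy == 0.0

    @property
    def angle_deg(self) -> float:
        """Direction in degrees in [-180, 180); undefined for zero vectors."""
        if self.is_zero:
            raise InvalidGeometryError("angle of a zero-length vector is undefined")
        deg = math.degrees(math.atan2(self.dy, self.dx))
        # atan2 returns (-180, 180]; fold +180 onto -180
        return -180.0 if deg == 180.0 else deg


@dataclass(frozen=True)
class Polygon:
    """A closed polygon given by its ordered vertices (the closing edge is implicit)."""

    vertices: tuple[Point2D, ...]

    def __init__(self, vertices: Iterable[Point2D | Sequence[float]]) -> None:
        pts = tuple(
            v if isinstance(v, Point2D) else Point2D(float(v[0]), float(v[1]))
            for v in vertices
        )
        if len(pts) < 3:
            raise InvalidGeometryError(f"polygon needs >= 3 vertices, got {len(pts)}")
        object.__setattr__(self, "vertices", pts)

    def to_shapely(self) -> _ShapelyPolygon:
        return _ShapelyPolygon([(p.x, p.y) for p in self.vertices])

    def coords(self) -> list[list[float]]:
        return [[p.x, p.y] for p in self.vertices]


def polygon_area(p: Polygon) -> float:
    """Absolute (winding-independent) shoelace area, in pixels^2."""
    area = p.to_shapely().area
    if area <= _DEGENERATE_AREA:
        raise InvalidGeometryError("degenerate polygon with zero area")
    return area


def polygon_centroid(p: Polygon) -> Point2D:
    """Area-weighted (shoelace) centroid — not the vertex average."""
    sp = p.to_shapely()
    if sp.area <= _DEGENERATE_AREA:
        raise InvalidGeometryError("centroid of a degenerate polygon is undefined")
    c = sp.centroid
    return Point2D(c.x, c.y)


def vector_between(a: Point2D, b: Point2D) -> Vector2D:
    """The displacement vector from ``a`` to ``b``."""
    return Vector2D(b.x - a.x, b.y - a.y)
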