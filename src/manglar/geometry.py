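"""Planar geometry substrate for habitat patch layers.

All geometry is planar, in a metric projected CRS (the Galápagos workflow
uses EPSG:32715). Patches are simple polygons with optional holes; a layer
is a collection of patches tagged with an epoch year. Measurements follow
standard GIS semantics: holes subtract from area but contribute their ring
length to the perimeter and their vertices to the node count, while the
convex hull is taken over the exterior ring alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np
from shapely.geometry import LineString, MultiLineString, Polygon

__all__ = [
    "InvalidGeometryError",
    "EmptyInputError",
    "PatchPolygon",
    "PatchLayer",
    "CoastlineLayer",
    "area",
    "perimeter",
    "node_count",
    "convex_hull",
    "mmu_filter",
    "DEFAULT_MMU",
]

#: Minimum mapping unit in square metres: the smallest patch retained in a
#: map product. Patches at exactly the MMU are kept (only strictly smaller
#: ones are erased).
DEFAULT_MMU = 10.0


class InvalidGeometryError(ValueError):
    """A ring is degenerate, self-intersecting, or otherwise unusable."""


class EmptyInputError(ValueError):
    """An operation that needs at least one element got none."""


def _dedupe_ring(coords: Sequence[tuple[float, float]]) -> list[tuple[float, float]]:
    """Drop duplicate consecutive vertices (digitization artefacts) and the
    explicit closing vertex.  Returns the open ring."""
    pts = [(float(x), float(y)) for x, y in coords]
    if len(pts) >= 2 and pts[0] == pts[-1]:
        pts = pts[:-1]
    out: list[tuple[float, float]] = []
    for p in pts:
        if not out or p != out[-1]:
            out.append(p)
    if len(out) >= 2 and out[0] == out[-1]:
        out.pop()
    return out


@dataclass(frozen=True)
class PatchPolygon:
    """One habitat patch: an exterior ring plus zero or more holes.

    Coordinates are metres in a planar projected CRS. Rings are stored open
    (the closing vertex is implicit) with consecutive duplicates removed.

    Parameters
    ----------
    exterior
        Vertex ring of the outer boundary.
    holes
        Interior rings lying strictly inside the exterior.
    id
        Opaque identifier (defaults to empty string).
    """

    exterior: tuple[tuple[float, float], ...]
    holes: tuple[tuple[tuple[float, float], ...], ...] = ()
    id: str = ""

    def __post_init__(self) -> None:
        ext = _dedupe_ring(self.exterior)
        if len(ext) < 3:
            raise InvalidGeometryError(
                f"exterior ring needs >= 3 distinct vertices, got {len(ext)}"
            )
        holes = tuple(tuple(_dedupe_ring(h)) for h in self.holes)
        for h in holes:
            if len(h) < 3:
                raise InvalidGeometryError("hole ring needs >= 3 distinct vertices")
        for ring in (ext, *holes):
            for x, y in ring:
                if not (math.isfinite(x) and math.isfinite(y)):
                    raise InvalidGeometryError("non-finite coordinate")
        object.__setattr__(self, "exterior", tuple(ext))
        object.__setattr__(self, "holes", holes)
        shp = self.shapely
        if not shp.is_valid:
            raise InvalidGeometryError("invalid polygon (self-intersection or hole violation)")
        if shp.area <= 0.0:
            raise InvalidGeometryError("polygon has zero area")

    @property
    def shapely(self) -> Polygon:
        """The patch as a :class:`shapely.geometry.Polygon`."""
        return Polygon(self.exterior, [list(h) for h in self.holes])

    @classmethod
    def from_shapely(cls, geom: Polygon, id: str = "") -> "PatchPolygon":
        if geom.geom_type != "Polygon":
            raise InvalidGeometryError(f"expected Polygon, got {geom.geom_type}")
        return cls(
            exterior=tuple(geom.exterior.coords),
            holes=tuple(tuple(r.coords) for r in geom.interiors),
            id=id,
        )

    def translate(self, dx: float, dy: float) -> "PatchPolygon":
        return PatchPolygon(
            exterior=tuple((x + dx, y + dy) for x, y in self.exterior),
            holes=tuple(tuple((x + dx, y + dy) for x, y in h) for h in self.holes),
            id=self.id,
        )


@dataclass(frozen=True)
class PatchLayer:
    """A set of patches with an epoch tag and CRS metadata."""

    patches: tuple[PatchPolygon, ...]
    epoch: int | None = None
    crs: str = "EPSG:32715"
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "patches", tuple(self.patches))

    def __len__(self) -> int:
        return len(self.patches)

    def __iter__(self) -> Iterator[PatchPolygon]:
        return iter(self.patches)

    @property
    def total_area(self) -> float:
        """Total patch area in square metres."""
        return float(sum(area(p) for p in self.patches))

    def translate(self, dx: float, dy: float) -> "PatchLayer":
        return replace(self, patches=tuple(p.translate(dx, dy) for p in self.patches))


@dataclass(frozen=True)
class CoastlineLayer:
    """One or more coastline polylines in a metric CRS."""

    polylines: tuple[tuple[tuple[float, float], ...], ...]
    crs: str = "EPSG:32715"

    def __post_init__(self) -> None:
        lines = tuple(tuple((float(x), float(y)) for x, y in pl) for pl in self.polylines)
        if not lines or all(len(pl) < 2 for pl in lines):
            raise InvalidGeometryError("coastline needs at least one 2-vertex polyline")
        object.__setattr__(self, "polylines", lines)

    @property
    def shapely(self) -> MultiLineString:
        return MultiLineString([LineString(pl) for pl in self.polylines])

    @property
    def total_length(self) -> float:
        """Summed polyline length in metres."""
        return float(self.shapely.length)


def area(p: PatchPolygon) -> float:
    """Patch area in m²: shoelace area of the exterior minus hole areas."""
    return float(p.shapely.area)


def perimeter(p: PatchPolygon) -> float:
    """Total boundary length in metres (exterior plus hole rings)."""
    shp = p.shapely
    return float(shp.exterior.length + sum(r.length for r in shp.interiors))


def node_count(p: PatchPolygon, include_holes: bool = True) -> int:
    """Number of distinct vertices, closing vertex counted once per ring.

    A node is a vertex where the boundary changes direction; digitized
    layers store one vertex per direction change, so we count all stored
    distinct vertices.
    """
    n = len(p.exterior)
    if include_holes:
        n += sum(len(h) for h in p.holes)
    return n


def convex_hull(p: PatchPolygon) -> PatchPolygon:
    """Smallest convex polygon containing the exterior ring's vertices."""
    hull = Polygon(p.exterior).convex_hull
    if hull.geom_type != "Polygon" or hull.area <= 0.0:
        raise InvalidGeometryError("degenerate (collinear) hull")
    return PatchPolygon.from_shapely(hull, id=p.id)


def mmu_filter(layer: PatchLayer, mmu: float = DEFAULT_MMU) -> PatchLayer:
    """Apply the minimum-mapping-unit rule: keep patches with area >= mmu.

    The boundary is inclusive — a patch exactly at the MMU survives.
    """
    if mmu <= 0:
        raise ValueError(f"mmu must be positive, got {mmu}")
    return replace(layer, patches=tuple(p for p in layer.patches if area(p) >= mmu))
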