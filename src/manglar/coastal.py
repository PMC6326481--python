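"""Coast-referenced coverage statistics.

Fringing mangrove hugs the shoreline, so cover is summarized relative to
the coast: cover by distance-from-coastline band (with the d50/d90
distances containing half and 90 % of the cover), the fraction of
coastline fronted by mangrove within a chosen distance, and cover density
(ha per km of coastline) by island or island-age group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from shapely.ops import unary_union

from .geometry import CoastlineLayer, EmptyInputError, PatchLayer

__all__ = [
    "DistanceBandProfile",
    "IslandGroupDensity",
    "distance_band_profile",
    "coastline_protected_fraction",
    "density_by_group",
]


@dataclass(frozen=True)
class DistanceBandProfile:
    """Cumulative cover fraction by distance band from the coastline."""

    edges: tuple[float, ...]            # outer edge of each band, metres
    band_area: tuple[float, ...]        # m² of cover in [e_{i-1}, e_i)
    cumulative_fraction: tuple[float, ...]
    d50: float                          # distance containing 50 % of cover
    d90: float                          # distance containing 90 % of cover


@dataclass(frozen=True)
class IslandGroupDensity:
    """Cover density for one island or island-age group."""

    group: str
    cover_ha: float
    coastline_km: float

    @property
    def density(self) -> float:
        """ha of cover per km of coastline."""
        return self.cover_ha / self.coastline_km


def _quantile_distance(edges: Sequence[float], cum: Sequence[float], q: float) -> float:
    """Distance at which the cumulative cover fraction reaches q, by linear
    interpolation between band edges (distance 0 pairs with fraction 0)."""
    xs = [0.0, *edges]
    ys = [0.0, *cum]
    return float(np.interp(q, ys, xs))


def distance_band_profile(
    layer: PatchLayer,
    coastline: CoastlineLayer,
    edges: Sequence[float] = (100.0, 200.0, 300.0, 400.0, 500.0, 1000.0, 2000.0),
) -> DistanceBandProfile:
    """Cover area within successive coastline buffer rings.

    Bands are half-open intervals [e_{i-1}, e_i) of Euclidean distance
    from the coastline; cover beyond the last edge is appended as a final
    open-ended band so fractions reach 1.
    """
    if layer.crs != coastline.crs:
        raise ValueError(f"CRS mismatch: {layer.crs} != {coastline.crs}")
    edges = tuple(float(e) for e in edges)
    if len(edges) == 0 or any(b <= a for a, b in zip(edges, edges[1:])) or edges[0] <= 0:
        raise ValueError("edges must be strictly increasing and positive")
    if len(layer) == 0:
        raise EmptyInputError("empty patch layer")

    cover = unary_union([p.shapely for p in layer])
    total = cover.area
    coast = coastline.shapely
    band_area: list[float] = []
    prev = None
    for e in edges:
        buf = coast.buffer(e)
        inner_area = cover.intersection(buf).area
        band_area.append(inner_area - (sum(band_area)))
        prev = buf
    beyond = total - sum(band_area)
    all_edges = edges
    if beyond > 1e-9 * max(total, 1.0):
        all_edges = (*edges, float("inf"))
        band_area.append(beyond)
    cum = tuple(float(x) for x in np.cumsum(band_area) / total)
    finite_edges = tuple(e for e in all_edges if np.isfinite(e))
    finite_cum = cum[: len(finite_edges)]
    return DistanceBandProfile(
        edges=all_edges,
        band_area=tuple(band_area),
        cumulative_fraction=cum,
        d50=_quantile_distance(finite_edges, finite_cum, 0.5),
        d90=_quantile_distance(finite_edges, finite_cum, 0.9),
    )


def coastline_protected_fraction(
    layer: PatchLayer,
    coastline: CoastlineLayer,
    fronting_dist: float = 50.0,
) -> float:
    """Percent of coastline arc length fronted by mangrove.

    A stretch of coast counts as protected when it lies within
    ``fronting_dist`` metres of any patch. The choice of fronting
    distance is a reporting convention — state it with the number.
    """
    if fronting_dist <= 0:
        raise ValueError("fronting distance must be positive")
    total = coastline.total_length
    if total <= 0:
        raise ValueError("coastline length must be positive")
    if len(layer) == 0:
        return 0.0
    cover = unary_union([p.shapely for p in layer])
    near = coastline.shapely.intersection(cover.buffer(fronting_dist))
    return 100.0 * near.length / total


def density_by_group(
    cover_ha: Mapping[str, float],
    coastline_km: Mapping[str, float],
    grouping: Mapping[str, str] | None = None,
) -> list[IslandGroupDensity]:
    """Cover density (ha/km) per island, optionally pooled into groups.

    ``grouping`` maps island name -> group label (e.g. geological-age
    class); islands without an entry keep their own name.
    """
    pooled_cover: dict[str, float] = {}
    pooled_coast: dict[str, float] = {}
    for island, ha in cover_ha.items():
        if island not in coastline_km:
            raise ValueError(f"no coastline length for {island!r}")
        g = grouping.get(island, island) if grouping else island
        pooled_cover[g] = pooled_cover.get(g, 0.0) + float(ha)
        pooled_coast[g] = pooled_coast.get(g, 0.0) + float(coastline_km[island])
    out = []
    for g in sorted(pooled_cover):
        if pooled_coast[g] <= 0:
            raise ValueError(f"group {g!r} has zero coastline")
        out.append(IslandGroupDensity(group=g, cover_ha=pooled_cover[g],
                                      coastline_km=pooled_coast[g]))
    return out
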