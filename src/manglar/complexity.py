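"""Polygon shape-complexity metrics for comparing habitat maps.

Three scores quantify how crenulated a digitized patch boundary is —
fringing mangrove patches are sinuous, with many invaginations, so a
faithful map shows *higher* complexity than a coarse one:

* ``complexity1`` — perimeter/area ratio (m⁻¹).
* ``complexity2`` — a convex-hull deficit score,
  ``0.8 · ampl · nodes + 0.2 · conv``, where ``ampl`` is the relative
  boundary-length excess over the hull, ``nodes`` the vertex count
  (a proxy for boundary notch frequency), and ``conv`` the relative
  area deficit against the hull. Zero for convex polygons; unbounded in
  the node count by design.
* ``complexity3`` — layer-level mean node count per polygon.

Layer summaries report the per-study columns used to compare mapping
efforts: patch count, mean patch area (ha), mean scores and total nodes.
"""

from __future__ import annotations

from dataclasses import dataclass

from .geometry import (
    EmptyInputError,
    PatchLayer,
    PatchPolygon,
    area,
    convex_hull,
    node_count,
    perimeter,
)

__all__ = [
    "ComplexityScores",
    "LayerComplexitySummary",
    "complexity1",
    "complexity2",
    "complexity3",
    "patch_scores",
    "summarize_layer",
]

# Weights of the amplitude·nodes and convexity terms in complexity2.
AMPL_WEIGHT = 0.8
CONV_WEIGHT = 0.2


@dataclass(frozen=True)
class ComplexityScores:
    """Per-patch complexity components."""

    c1: float       # perimeter/area, m^-1
    ampl: float     # (perimeter - hull perimeter) / perimeter, in [0, 1)
    nodes: int      # distinct vertex count
    conv: float     # (hull area - area) / hull area, in [0, 1)
    c2: float       # 0.8 * ampl * nodes + 0.2 * conv


@dataclass(frozen=True)
class LayerComplexitySummary:
    """Layer-level complexity columns used for between-study comparison."""

    n_patches: int
    mean_area_ha: float
    mean_c1: float
    mean_c2: float
    mean_nodes: float   # "complexity 3"
    total_nodes: int


def complexity1(p: PatchPolygon) -> float:
    """Perimeter/area ratio in m⁻¹; higher means a more complex outline."""
    return perimeter(p) / area(p)


def patch_scores(p: PatchPolygon, include_hole_nodes: bool = True) -> ComplexityScores:
    """All complexity components of one patch.

    The hull is taken over the exterior ring; ``include_hole_nodes``
    controls whether hole vertices enter the node count (they do by
    default, matching the perimeter convention).
    """
    per = perimeter(p)
    a = area(p)
    hull = convex_hull(p)
    hull_per = perimeter(hull)
    hull_area = area(hull)
    ampl = max(0.0, (per - hull_per) / per)
    conv = max(0.0, (hull_area - a) / hull_area)
    n = node_count(p, include_holes=include_hole_nodes)
    c2 = AMPL_WEIGHT * ampl * n + CONV_WEIGHT * conv
    return ComplexityScores(c1=per / a, ampl=ampl, nodes=n, conv=conv, c2=c2)


def complexity2(p: PatchPolygon, include_hole_nodes: bool = True) -> float:
    """Convex-hull deficit score; 0 for convex polygons."""
    return patch_scores(p, include_hole_nodes=include_hole_nodes).c2


def complexity3(layer: PatchLayer) -> float:
    """Mean node count per polygon over the layer."""
    if len(layer) == 0:
        raise EmptyInputError("complexity3 of an empty layer")
    return sum(node_count(p) for p in layer) / len(layer)


def summarize_layer(layer: PatchLayer) -> LayerComplexitySummary:
    """Between-study comparison columns for one map layer.

    Mean patch area is reported in hectares (1 ha = 10⁴ m²).
    """
    if len(layer) == 0:
        raise EmptyInputError("summary of an empty layer")
    scores = [patch_scores(p) for p in layer]
    n = len(layer)
    total_nodes = sum(s.nodes for s in scores)
    return LayerComplexitySummary(
        n_patches=n,
        mean_area_ha=sum(area(p) for p in layer) / n / 1e4,
        mean_c1=sum(s.c1 for s in scores) / n,
        mean_c2=sum(s.c2 for s in scores) / n,
        mean_nodes=total_nodes / n,
        total_nodes=total_nodes,
    )
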