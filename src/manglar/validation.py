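"""Accuracy assessment of habitat maps.

Ground truth is a set of field sites, each verified for mangrove
presence/absence. A site is buffered (100 m radius, i.e. 3.14 ha) and
random sample points are placed uniformly inside the buffer; each point is
then classified mangrove/non-mangrove by point-in-polygon against the map.
From the resulting 2×2 confusion matrix we report overall accuracy,
Cohen's kappa, and pairwise two-proportion Z-tests between maps
(|Z| >= 1.96 marks a significant accuracy difference at the 5 % level).

The module also carries the digitizer quality-assurance rule (a digitized
polygon counts as accurate when at least half its perimeter coincides with
the reference outline) and standard survey sample-size arithmetic
(Cochran's formula with finite-population correction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from shapely import contains_xy, intersects_xy
from shapely.geometry import Point
from shapely.ops import unary_union

from .geometry import EmptyInputError, PatchLayer, PatchPolygon, perimeter

__all__ = [
    "GroundTruthSite",
    "ConfusionMatrix",
    "ZComparison",
    "QAResult",
    "Z_SIGNIFICANCE",
    "sample_validation_points",
    "confusion",
    "overall_accuracy",
    "cohens_kappa",
    "z_compare",
    "digitizer_qa",
    "qa_error_rate",
    "survey_sample_size",
]

MANGROVE = "mangrove"
NON_MANGROVE = "non-mangrove"
Label = Literal["mangrove", "non-mangrove"]

#: Two-sided 5 % critical value for the accuracy-comparison Z-test.
Z_SIGNIFICANCE = 1.96


class UndefinedKappaError(ZeroDivisionError):
    """Kappa is undefined when chance agreement is exactly 1."""


class DegenerateProportionsError(ZeroDivisionError):
    """The pooled proportion is 0 or 1, so the Z statistic is undefined."""


@dataclass(frozen=True)
class GroundTruthSite:
    """A field-verified presence/absence site with its sampling buffer."""

    x: float
    y: float
    label: Label
    buffer_radius: float = 100.0  # metres; pi * 100^2 = 3.14 ha

    @property
    def buffer_area_ha(self) -> float:
        return math.pi * self.buffer_radius**2 / 1e4


@dataclass(frozen=True)
class ConfusionMatrix:
    """2×2 agreement counts, map class (rows) × truth class (columns).

    Row/column order is (mangrove, non-mangrove).
    """

    mm: int  # map mangrove, truth mangrove
    mn: int  # map mangrove, truth non-mangrove (commission)
    nm: int  # map non-mangrove, truth mangrove (omission)
    nn: int  # both non-mangrove

    @property
    def n(self) -> int:
        return self.mm + self.mn + self.nm + self.nn

    @property
    def correct(self) -> int:
        return self.mm + self.nn

    def as_array(self) -> np.ndarray:
        return np.array([[self.mm, self.mn], [self.nm, self.nn]], dtype=int)


@dataclass(frozen=True)
class ZComparison:
    """Two-proportion Z-test between the accuracies of two maps."""

    x1: float
    n1: int
    x2: float
    n2: int
    rho: float
    z: float

    @property
    def significant(self) -> bool:
        return abs(self.z) >= Z_SIGNIFICANCE


@dataclass(frozen=True)
class QAResult:
    """Digitizer QA verdict for one sampled polygon."""

    coincidence_fraction: float
    accurate: bool


def sample_validation_points(
    site: GroundTruthSite, n_points: int = 500, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Uniform random points in the site's buffer disc.

    Returns an ``(n_points, 2)`` array. Sampling uses the sqrt-radius
    transform so density is uniform over the disc; a fixed seed gives an
    identical point set.
    """
    if site.buffer_radius <= 0:
        raise ValueError("buffer radius must be positive")
    if n_points < 1:
        raise ValueError("need at least one sample point")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    r = site.buffer_radius * np.sqrt(rng.random(n_points))
    theta = rng.random(n_points) * 2.0 * math.pi
    return np.column_stack([site.x + r * np.cos(theta), site.y + r * np.sin(theta)])


def classify_points(map_layer: PatchLayer, points: np.ndarray) -> np.ndarray:
    """Label points by point-in-polygon against the map.

    Returns a boolean array (True = mangrove). Points on a patch boundary
    count as inside.
    """
    pts = np.asarray(points, dtype=float)
    union = unary_union([p.shapely for p in map_layer])
    if union.is_empty:
        return np.zeros(len(pts), dtype=bool)
    # intersects == covers for points: boundary counts as inside
    return intersects_xy(union, pts[:, 0], pts[:, 1])


def confusion(
    map_layer: PatchLayer,
    points: np.ndarray,
    truth_labels: Sequence[bool] | np.ndarray,
) -> ConfusionMatrix:
    """Tally map-vs-truth agreement over labelled sample points.

    ``truth_labels`` is boolean (True = mangrove), aligned with ``points``.
    """
    pts = np.asarray(points, dtype=float)
    truth = np.asarray(truth_labels, dtype=bool)
    if len(pts) == 0:
        raise EmptyInputError("no sample points")
    if len(truth) != len(pts):
        raise ValueError("points and labels differ in length")
    mapped = classify_points(map_layer, pts)
    return ConfusionMatrix(
        mm=int(np.sum(mapped & truth)),
        mn=int(np.sum(mapped & ~truth)),
        nm=int(np.sum(~mapped & truth)),
        nn=int(np.sum(~mapped & ~truth)),
    )


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Percent of sample points on which map and truth agree."""
    if cm.n == 0:
        raise EmptyInputError("empty confusion matrix")
    return 100.0 * cm.correct / cm.n


def cohens_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement, (p_o − p_e)/(1 − p_e), in [−1, 1]."""
    if cm.n == 0:
        raise EmptyInputError("empty confusion matrix")
    n = cm.n
    p_o = cm.correct / n
    row = np.array([cm.mm + cm.mn, cm.nm + cm.nn]) / n
    col = np.array([cm.mm + cm.nm, cm.mn + cm.nn]) / n
    p_e = float(row @ col)
    if math.isclose(p_e, 1.0, abs_tol=1e-12):
        raise UndefinedKappaError("degenerate single-class marginals")
    return (p_o - p_e) / (1.0 - p_e)


def z_compare(x1: float, n1: int, x2: float, n2: int) -> ZComparison:
    """Two-proportion Z-test with pooled standard error.

    ``x_i`` correct points of ``n_i`` sampled (fractional counts are
    accepted so rounded published accuracies can be compared); the
    statistic is
    ``(x1/n1 − x2/n2) / sqrt(ρ(1−ρ)(1/n1 + 1/n2))`` with
    ``ρ = (x1+x2)/(n1+n2)``.
    """
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2) or n1 < 1 or n2 < 1:
        raise ValueError("counts must satisfy 0 <= x_i <= n_i, n_i >= 1")
    rho = (x1 + x2) / (n1 + n2)
    if rho in (0.0, 1.0):
        raise DegenerateProportionsError("pooled proportion is 0 or 1")
    se = math.sqrt(rho * (1.0 - rho) * (1.0 / n1 + 1.0 / n2))
    z = (x1 / n1 - x2 / n2) / se
    return ZComparison(x1=x1, n1=n1, x2=x2, n2=n2, rho=rho, z=z)


def digitizer_qa(
    candidate: PatchPolygon, reference: PatchPolygon, tol: float = 5.0
) -> QAResult:
    """Digitizer quality check: does the candidate outline track the reference?

    The coincidence fraction is the arc length of the candidate's exterior
    lying within ``tol`` metres of the reference's exterior, divided by the
    candidate's exterior length; the polygon passes when the fraction is
    at least one half.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    cand = candidate.shapely.exterior
    ref = reference.shapely.exterior
    near = cand.intersection(ref.buffer(tol))
    frac = float(near.length / cand.length) if not near.is_empty else 0.0
    frac = min(1.0, frac)
    return QAResult(coincidence_fraction=frac, accurate=frac >= 0.5)


def qa_error_rate(n_inaccurate: int, n_sampled: int) -> float:
    """Percent of sampled polygons flagged inaccurate in one stratum."""
    if n_sampled < 1:
        raise EmptyInputError("stratum with no sampled polygons")
    if not 0 <= n_inaccurate <= n_sampled:
        raise ValueError("inaccurate count out of range")
    return 100.0 * n_inaccurate / n_sampled


def survey_sample_size(
    population: int,
    margin: float | None = None,
    z: float = 2.58,
    fraction: float | None = None,
) -> int:
    """Sample size for a polygon-review survey.

    Two modes:

    * Cochran's formula (worst-case p = 0.5) with finite-population
      correction: ``n0 = z²·0.25/margin²``, ``n = n0/(1+(n0−1)/N)``,
      rounded up. ``z`` defaults to 2.58 (99 % confidence).
    * Plain fraction-of-population sampling when ``fraction`` is given
      (e.g. an 8 % stratified sample), rounded to the nearest integer.
    """
    if population < 1:
        raise ValueError("population must be >= 1")
    if fraction is not None:
        if not 0 < fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        return round(population * fraction)
    if margin is None or not 0 < margin < 1:
        raise ValueError("margin must be in (0, 1)")
    n0 = z * z * 0.25 / (margin * margin)
    n = n0 / (1.0 + (n0 - 1.0) / population)
    return math.ceil(n)
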