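"""Seeded generator of synthetic coastal landscapes.

Every pipeline stage — complexity scoring, accuracy assessment, the
classification chains, change analysis and coastal statistics — is
exercised on landscapes produced here, so the whole toolkit is testable
without imagery downloads. The generator emulates the statistical
structure of an arid-archipelago fringing mangrove system:

* a smoothed random-walk coastline with land on one side;
* patches anchored to the coast, log-normal in size (calibrated so
  roughly 85 % of patches are below 0.5 ha) and log-normal in distance
  from shore (calibrated so roughly 90 % of cover lies within 500 m,
  half within ~100 m);
* crenulated star-polygon boundaries (radial noise) whose amplitude is a
  dial between "smooth legacy map" and "faithful digitization";
* a second epoch derived from the first by a scripted ledger of
  expansion / contraction / disappearance / generation events, spaced so
  a boundary-distance grouping at the analysis threshold recovers the
  script exactly;
* a multi-band scene (R, G, B, NIR digital reflectances) whose pixels are
  drawn from per-class Gaussian spectra for the five tonality groups
  (mangrove, deciduous vegetation, lava, sand, water), plus an optional
  sea-surface algae class sharing the mangrove RGB signature — the
  classic confusion that a land/sea-partitioned classifier resolves.

All randomness flows from the single script seed; the same script yields
byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from shapely import contains_xy
from shapely.geometry import Polygon, box
from shapely.ops import unary_union
from shapely.strtree import STRtree

from .classification import GridTransform, SpectralScene, TrainingSet
from .geometry import CoastlineLayer, PatchLayer, PatchPolygon

__all__ = [
    "SpectralClassSpec",
    "ChangeScript",
    "LandscapeScript",
    "GeneratedLandscape",
    "ConfusableScene",
    "generate_landscape",
    "generate_confusable_scene",
    "DEFAULT_SPECTRA",
]

BANDS = ("R", "G", "B", "NIR")

MANGROVE = "mangrove"
DECIDUOUS = "deciduous"
LAVA = "lava"
SAND = "sand"
WATER = "water"
ALGAE = "algae"

LAND_CLASSES = (MANGROVE, DECIDUOUS, LAVA, SAND)
SEA_CLASSES = (WATER, ALGAE)


@dataclass(frozen=True)
class SpectralClassSpec:
    """Gaussian band spectrum of one tonality class (R, G, B, NIR)."""

    mean: tuple[float, float, float, float]
    sigma: float = 0.02


#: Digital reflectances encoding the photo-interpretation tonality groups:
#: mangrove medium green with high NIR; deciduous lighter green, lower NIR;
#: lava brown-black and flat; sand bright; water dark with near-zero NIR.
DEFAULT_SPECTRA: dict[str, SpectralClassSpec] = {
    MANGROVE: SpectralClassSpec((0.12, 0.35, 0.10, 0.60)),
    DECIDUOUS: SpectralClassSpec((0.28, 0.42, 0.22, 0.48)),
    # brown-black basalt reflects slightly less NIR than red: NDVI < 0
    LAVA: SpectralClassSpec((0.12, 0.09, 0.08, 0.08)),
    SAND: SpectralClassSpec((0.55, 0.50, 0.40, 0.45)),
    WATER: SpectralClassSpec((0.10, 0.12, 0.18, 0.02)),
    # sea-surface algae: mangrove RGB, but no NIR plateau (submerged canopy)
    ALGAE: SpectralClassSpec((0.12, 0.35, 0.10, 0.05)),
}


@dataclass(frozen=True)
class ChangeScript:
    """Scripted patch fates between the two epochs.

    Fractions apply to the first-epoch patch census (the remainder stays
    stable); buffers are drawn uniformly from the stated ranges, with
    mitred corners so square test patches stay square. Defaults plant a
    net cover gain of roughly a quarter over the decade, dominated by
    expansion of existing patches, with little generation and very little
    loss — the regime observed in a prograding arid archipelago.
    """

    expand_frac: float = 0.30
    contract_frac: float = 0.12
    disappear_frac: float = 0.04
    generate_frac: float = 0.05
    expand_buffer_m: tuple[float, float] = (4.0, 12.0)
    contract_buffer_m: tuple[float, float] = (2.0, 6.0)


@dataclass(frozen=True)
class LandscapeScript:
    """Full parameterization of one synthetic landscape."""

    seed: int = 0
    # domain and coastline: wide enough that the fringing strip does not
    # saturate at the default census (crowding would push patches inland)
    domain_w: float = 40000.0
    domain_h: float = 5000.0
    coast_y: float = 3000.0
    coast_wiggle: float = 150.0
    coast_step: float = 100.0
    # patch census
    n_patches: int = 300
    median_patch_area_m2: float = 1400.0   # ~85 % of patches < 0.5 ha
    sigma_log_area: float = 1.2
    median_center_dist_m: float = 80.0     # ~half of cover within ~100 m
    sigma_log_dist: float = 1.0            # ~90 % of cover within 500 m
    fringe_depth_m: float = 500.0
    n_vertices: int = 24
    boundary_amplitude: float = 0.35       # 0 = smooth discs
    min_spacing_m: float = 40.0            # > STAMP threshold + buffers
    # epochs
    epoch_t: int = 2004
    epoch_t1: int = 2014
    change: ChangeScript = field(default_factory=ChangeScript)
    # scene
    scene_w: float = 600.0
    scene_h: float = 400.0
    scene_px: float = 2.0
    sand_width_m: float = 8.0
    spectra: Mapping[str, SpectralClassSpec] = field(
        default_factory=lambda: dict(DEFAULT_SPECTRA))
    n_training_px: int = 200
    n_truth_points: int = 400
    crs: str = "EPSG:32715"


@dataclass(frozen=True)
class ChangeLedger:
    """Exact bookkeeping of every planted change event."""

    events: tuple[tuple[str, str, float], ...]  # (patch id, kind, buffer m)
    planted_area: dict[str, float]              # m² per STAMP category

    @property
    def total_t(self) -> float:
        p = self.planted_area
        return p["STB"] + p["CON"] + p["DIS"]

    @property
    def total_t1(self) -> float:
        p = self.planted_area
        return p["STB"] + p["EXP"] + p["GEN"]


@dataclass
class GeneratedLandscape:
    """All mutually consistent artefacts of one generated landscape."""

    script: LandscapeScript
    coastline: CoastlineLayer
    land: Polygon
    layer_t: PatchLayer
    layer_t1: PatchLayer
    ledger: ChangeLedger
    scene: SpectralScene
    truth_grid: np.ndarray               # class-name object array
    training: TrainingSet                # all classes (RGB)
    training_land: TrainingSet
    training_sea: TrainingSet
    truth_points: np.ndarray             # (n, 2)
    truth_labels: np.ndarray             # bool, True = mangrove
    land_point: tuple[float, float]      # reference point on the land side


@dataclass
class ConfusableScene:
    """A scene engineered to reproduce the RGB mangrove confusions."""

    scene: SpectralScene
    truth_grid: np.ndarray
    training: TrainingSet
    training_land: TrainingSet
    training_sea: TrainingSet
    truth_points: np.ndarray
    truth_labels: np.ndarray
    coastline: CoastlineLayer
    land_point: tuple[float, float]
    mangrove_layer: PatchLayer


# ---------------------------------------------------------------------------
# coastline and patches

def _make_coastline(rng: np.random.Generator, s: LandscapeScript):
    xs = np.arange(0.0, s.domain_w + s.coast_step, s.coast_step)
    steps = rng.normal(0.0, 1.0, len(xs))
    walk = np.cumsum(steps)
    kernel = np.ones(7) / 7.0
    smooth = np.convolve(walk, kernel, mode="same")
    smooth -= smooth.mean()
    if smooth.std() > 0:
        smooth *= s.coast_wiggle / smooth.std()
    ys = s.coast_y + smooth
    coast = CoastlineLayer(polylines=(tuple(zip(xs, ys)),), crs=s.crs)
    # land is the region below the coastline
    ring = [(float(x), float(y)) for x, y in zip(xs, ys)]
    ring += [(s.domain_w, 0.0), (0.0, 0.0)]
    land = Polygon(ring).buffer(0)
    return coast, land, xs, ys


def _star_polygon(
    rng: np.random.Generator, cx: float, cy: float, area: float,
    n_vertices: int, amplitude: float,
) -> Polygon:
    """Simple star polygon of the given exact area around (cx, cy)."""
    angles = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    radii = 1.0 + amplitude * rng.uniform(-1.0, 1.0, n_vertices)
    poly = Polygon([(cx + r * math.cos(a), cy + r * math.sin(a))
                    for r, a in zip(radii, angles)])
    scale = math.sqrt(area / poly.area)
    poly = Polygon([(cx + (x - cx) * scale, cy + (y - cy) * scale)
                    for x, y in poly.exterior.coords[:-1]])
    return poly


class _SpacingIndex:
    """Grid-bucket index answering "is anything within d of this polygon"."""

    def __init__(self, spacing: float, cell: float = 500.0) -> None:
        self.spacing = spacing
        self.cell = cell
        self.buckets: dict[tuple[int, int], list[Polygon]] = {}

    def _cells(self, poly: Polygon, pad: float):
        minx, miny, maxx, maxy = poly.bounds
        for ix in range(int((minx - pad) // self.cell), int((maxx + pad) // self.cell) + 1):
            for iy in range(int((miny - pad) // self.cell), int((maxy + pad) // self.cell) + 1):
                yield ix, iy

    def too_close(self, poly: Polygon) -> bool:
        seen: set[int] = set()
        for key in self._cells(poly, self.spacing):
            for g in self.buckets.get(key, ()):
                if id(g) not in seen:
                    seen.add(id(g))
                    if poly.distance(g) < self.spacing:
                        return True
        return False

    def add(self, poly: Polygon) -> None:
        for key in self._cells(poly, 0.0):
            self.buckets.setdefault(key, []).append(poly)


def _place_patches(
    rng: np.random.Generator, s: LandscapeScript, xs: np.ndarray, ys: np.ndarray,
) -> list[PatchPolygon]:
    """Anchor patches to the coast with log-normal size and shore distance.

    The area is drawn once per patch and held fixed while placement is
    retried, so crowding rejections do not bias the size distribution.
    """
    patches: list[PatchPolygon] = []
    index = _SpacingIndex(s.min_spacing_m)
    margin = 50.0
    for i in range(s.n_patches):
        area = rng.lognormal(math.log(s.median_patch_area_m2), s.sigma_log_area)
        area = min(area, 2e5)  # clip monster outliers (20 ha)
        for _ in range(80):
            x = rng.uniform(margin, s.domain_w - margin)
            d = rng.lognormal(math.log(s.median_center_dist_m), s.sigma_log_dist)
            if d > s.domain_h / 2.0:
                continue
            if area > 1e4:
                # extensive stands hug the shoreline; only small pockets sit
                # in inland brackish ponds
                d = min(d, 0.4 * s.fringe_depth_m)
            coast_y = float(np.interp(x, xs, ys))
            cy = coast_y - d
            if cy < margin:
                continue
            poly = _star_polygon(rng, x, cy, area, s.n_vertices, s.boundary_amplitude)
            if not poly.is_valid or poly.area <= 0:
                continue
            if index.too_close(poly):
                continue
            index.add(poly)
            patches.append(PatchPolygon.from_shapely(poly, id=f"p{len(patches):04d}"))
            break
    return patches


def _apply_change(
    rng: np.random.Generator, s: LandscapeScript,
    patches: Sequence[PatchPolygon], xs: np.ndarray, ys: np.ndarray,
) -> tuple[list[PatchPolygon], ChangeLedger]:
    """Produce the second epoch and the exact planted-event ledger."""
    c = s.change
    n = len(patches)
    order = rng.permutation(n)
    n_exp = int(round(c.expand_frac * n))
    n_con = int(round(c.contract_frac * n))
    n_dis = int(round(c.disappear_frac * n))
    fate = {}
    idx = 0
    for count, kind in ((n_exp, "expand"), (n_con, "contract"), (n_dis, "disappear")):
        for i in order[idx: idx + count]:
            fate[int(i)] = kind
        idx += count

    out: list[PatchPolygon] = []
    events: list[tuple[str, str, float]] = []
    planted = {k: 0.0 for k in ("STB", "EXP", "CON", "GEN", "DIS")}
    for i, p in enumerate(patches):
        kind = fate.get(i, "stable")
        g = p.shapely
        if kind == "stable":
            out.append(p)
            planted["STB"] += g.area
            events.append((p.id, "stable", 0.0))
        elif kind == "expand":
            buf = rng.uniform(*c.expand_buffer_m)
            g1 = g.buffer(buf, join_style="mitre")
            out.append(PatchPolygon.from_shapely(g1, id=p.id))
            planted["STB"] += g.area
            planted["EXP"] += g1.area - g.area
            events.append((p.id, "expand", buf))
        elif kind == "contract":
            buf = rng.uniform(*c.contract_buffer_m)
            g1 = g.buffer(-buf, join_style="mitre")
            if g1.is_empty or g1.area <= 0 or g1.geom_type != "Polygon":
                planted["DIS"] += g.area
                events.append((p.id, "disappear", 0.0))
                continue
            out.append(PatchPolygon.from_shapely(g1, id=p.id))
            planted["STB"] += g1.area
            planted["CON"] += g.area - g1.area
            events.append((p.id, "contract", buf))
        else:  # disappear
            planted["DIS"] += g.area
            events.append((p.id, "disappear", 0.0))

    # brand-new patches, kept clear of everything in either epoch
    n_gen = int(round(c.generate_frac * n))
    index = _SpacingIndex(s.min_spacing_m)
    for g in [p.shapely for p in patches] + [p.shapely for p in out]:
        index.add(g)
    attempts, placed = 0, 0
    margin = 50.0
    while placed < n_gen and attempts < n_gen * 100:
        attempts += 1
        x = rng.uniform(margin, s.domain_w - margin)
        d = rng.lognormal(math.log(s.median_center_dist_m), s.sigma_log_dist)
        coast_y = float(np.interp(x, xs, ys))
        cy = coast_y - d
        if cy < margin or d > s.domain_h / 2.0:
            continue
        area = rng.lognormal(math.log(s.median_patch_area_m2), s.sigma_log_area)
        area = min(area, 2e5)
        if area > 1e4 and d > 0.4 * s.fringe_depth_m:
            continue
        poly = _star_polygon(rng, x, cy, area, s.n_vertices, s.boundary_amplitude)
        if index.too_close(poly):
            continue
        pid = f"g{placed:04d}"
        out.append(PatchPolygon.from_shapely(poly, id=pid))
        index.add(poly)
        planted["GEN"] += poly.area
        events.append((pid, "generate", 0.0))
        placed += 1

    ledger = ChangeLedger(events=tuple(events), planted_area=planted)
    return out, ledger


# ---------------------------------------------------------------------------
# scene rasterization

def _paint_truth(
    s: LandscapeScript,
    transform: GridTransform,
    shape: tuple[int, int],
    land: Polygon,
    coastline: CoastlineLayer,
    mangrove_geoms: Sequence[Polygon],
    deciduous_geoms: Sequence[Polygon] = (),
    algae_geoms: Sequence[Polygon] = (),
) -> np.ndarray:
    rows, cols = np.indices(shape)
    x, y = transform.pixel_center(rows.ravel(), cols.ravel())
    truth = np.full(shape, LAVA, dtype=object)
    on_land = contains_xy(land, x, y).reshape(shape)
    truth[~on_land] = WATER
    sand_zone = coastline.shapely.buffer(s.sand_width_m)
    in_sand = contains_xy(sand_zone, x, y).reshape(shape)
    truth[in_sand & on_land] = SAND
    for geoms, label, side in ((algae_geoms, ALGAE, ~on_land),
                               (deciduous_geoms, DECIDUOUS, on_land),
                               (mangrove_geoms, MANGROVE, None)):
        if not geoms:
            continue
        union = unary_union(list(geoms))
        inside = contains_xy(union, x, y).reshape(shape)
        if side is not None:
            inside &= side
        truth[inside] = label
    return truth


def _spectra_scene(
    rng: np.random.Generator,
    truth: np.ndarray,
    transform: GridTransform,
    spectra: Mapping[str, SpectralClassSpec],
    crs: str,
) -> SpectralScene:
    shape = truth.shape
    bands = {b: np.zeros(shape) for b in BANDS}
    for label, spec in spectra.items():
        m = truth == label
        if not m.any():
            continue
        n = int(m.sum())
        for bi, b in enumerate(BANDS):
            bands[b][m] = spec.mean[bi] + rng.normal(0.0, spec.sigma, n)
    for b in BANDS:
        np.clip(bands[b], 0.0, 1.0, out=bands[b])
    return SpectralScene(bands=bands, transform=transform)


def _training_from_truth(
    rng: np.random.Generator,
    scene: SpectralScene,
    truth: np.ndarray,
    classes: Sequence[str],
    n_px: int,
    band_names: Sequence[str] = ("R", "G", "B"),
) -> TrainingSet:
    stack = scene.stack(band_names)
    pixels: dict[str, np.ndarray] = {}
    for label in classes:
        idx = np.flatnonzero((truth == label).ravel())
        if idx.size == 0:
            continue
        take = rng.choice(idx, size=min(n_px, idx.size), replace=False)
        pixels[label] = stack.reshape(-1, len(band_names))[take]
    return TrainingSet(pixels=pixels, band_names=tuple(band_names))


def _scene_window(s: LandscapeScript, xs: np.ndarray, ys: np.ndarray) -> GridTransform:
    """Scene subwindow centred on the coast, ~60 % land / 40 % sea."""
    cx = s.domain_w / 2.0
    coast_y = float(np.interp(cx, xs, ys))
    x0 = cx - s.scene_w / 2.0
    y0 = coast_y + 0.4 * s.scene_h
    return GridTransform(x0=x0, y0=y0, px=s.scene_px)


def generate_landscape(script: LandscapeScript | None = None) -> GeneratedLandscape:
    """Generate a full, mutually consistent synthetic landscape.

    Same script (including seed) -> byte-identical outputs.
    """
    s = script or LandscapeScript()
    rng = np.random.default_rng(s.seed)
    coast, land, xs, ys = _make_coastline(rng, s)
    patches_t = _place_patches(rng, s, xs, ys)
    if not patches_t:
        raise ValueError("infeasible script: no patch fits the domain")
    layer_t = PatchLayer(patches=tuple(patches_t), epoch=s.epoch_t, crs=s.crs)
    patches_t1, ledger = _apply_change(rng, s, patches_t, xs, ys)
    layer_t1 = PatchLayer(patches=tuple(patches_t1), epoch=s.epoch_t1, crs=s.crs)

    transform = _scene_window(s, xs, ys)
    shape = (int(round(s.scene_h / s.scene_px)), int(round(s.scene_w / s.scene_px)))
    mangrove_geoms = [p.shapely for p in patches_t1]
    truth = _paint_truth(s, transform, shape, land, coast, mangrove_geoms)
    scene = _spectra_scene(rng, truth, transform, s.spectra, s.crs)

    training = _training_from_truth(rng, scene, truth, LAND_CLASSES + (WATER,),
                                    s.n_training_px)
    training_land = _training_from_truth(rng, scene, truth, LAND_CLASSES,
                                         s.n_training_px)
    training_sea = _training_from_truth(rng, scene, truth, SEA_CLASSES,
                                        s.n_training_px)

    pts_x = rng.uniform(transform.x0, transform.x0 + s.scene_w, s.n_truth_points)
    pts_y = rng.uniform(transform.y0 - s.scene_h, transform.y0, s.n_truth_points)
    truth_points = np.column_stack([pts_x, pts_y])
    cols = np.clip(((pts_x - transform.x0) / s.scene_px).astype(int), 0, shape[1] - 1)
    rows = np.clip(((transform.y0 - pts_y) / s.scene_px).astype(int), 0, shape[0] - 1)
    truth_labels = truth[rows, cols] == MANGROVE

    land_point = (transform.x0 + s.scene_w / 2.0, transform.y0 - 0.95 * s.scene_h)
    return GeneratedLandscape(
        script=s, coastline=coast, land=land, layer_t=layer_t, layer_t1=layer_t1,
        ledger=ledger, scene=scene, truth_grid=truth, training=training,
        training_land=training_land, training_sea=training_sea,
        truth_points=truth_points, truth_labels=truth_labels,
        land_point=land_point,
    )


def generate_confusable_scene(
    script: LandscapeScript | None = None,
    overlap: float = 0.9,
    algae_cover: float = 0.15,
) -> ConfusableScene:
    """Scene reproducing the RGB confusion failure modes.

    ``overlap`` in (0, 1] pulls the deciduous RGB mean toward the
    mangrove mean (1 = nearly coincident tonality, as in wet-season
    imagery), and deciduous patches are planted contiguous with mangrove
    patches so a vegetation-mask segmentation bridges the two. Sea-surface
    algae mats share the mangrove RGB signature over ``algae_cover`` of
    the sea, so a whole-scene classifier commits them to mangrove while a
    land/sea-partitioned one cannot.
    """
    if not 0.0 <= overlap <= 1.0:
        raise ValueError("overlap must be in [0, 1]")
    s = script or LandscapeScript()
    rng = np.random.default_rng(s.seed + 1)
    coast, land, xs, ys = _make_coastline(rng, s)
    transform = _scene_window(s, xs, ys)
    shape = (int(round(s.scene_h / s.scene_px)), int(round(s.scene_w / s.scene_px)))
    extent = box(transform.x0, transform.y0 - s.scene_h,
                 transform.x0 + s.scene_w, transform.y0)

    # mangrove patches hugging the in-scene coast
    mangrove_geoms: list[Polygon] = []
    deciduous_geoms: list[Polygon] = []
    for _ in range(6):
        x = rng.uniform(transform.x0 + 60.0, transform.x0 + s.scene_w - 60.0)
        coast_y = float(np.interp(x, xs, ys))
        cy = coast_y - rng.uniform(15.0, 45.0)
        g = _star_polygon(rng, x, cy, rng.uniform(1500.0, 4000.0),
                          s.n_vertices, s.boundary_amplitude)
        mangrove_geoms.append(g)
        # a larger deciduous patch planted flush against the mangrove, inland,
        # so the vegetation mask is contiguous across the pair
        minx, miny, maxx, maxy = g.bounds
        dg = _star_polygon(rng, x, miny - 0.3 * (maxy - miny),
                           rng.uniform(4000.0, 8000.0),
                           s.n_vertices, s.boundary_amplitude)
        deciduous_geoms.append(dg)

    # algae mats on the sea side
    algae_geoms: list[Polygon] = []
    sea_area = extent.difference(land).area
    target = algae_cover * sea_area
    got = 0.0
    while got < target:
        x = rng.uniform(transform.x0 + 40.0, transform.x0 + s.scene_w - 40.0)
        coast_y = float(np.interp(x, xs, ys))
        cy = coast_y + rng.uniform(30.0, 0.35 * s.scene_h)
        g = _star_polygon(rng, x, cy, rng.uniform(2000.0, 6000.0), 16, 0.2)
        sea_part = g.difference(land).intersection(extent)
        if sea_part.is_empty:
            continue
        algae_geoms.append(g)
        got += sea_part.area

    spectra = dict(s.spectra)
    m_mean = np.array(spectra[MANGROVE].mean)
    d_mean = np.array(spectra[DECIDUOUS].mean)
    pulled = m_mean + (d_mean - m_mean) * (1.0 - overlap)
    pulled[3] = d_mean[3]  # NIR keeps its contrast: tonality, not phenology
    spectra[DECIDUOUS] = SpectralClassSpec(tuple(pulled), spectra[DECIDUOUS].sigma)

    # paint order: deciduous first, mangrove last, so where the flush pair
    # overlaps the mangrove class wins and the two tile rather than stack
    truth = _paint_truth(s, transform, shape, land, coast,
                         mangrove_geoms, deciduous_geoms, algae_geoms)
    scene = _spectra_scene(rng, truth, transform, spectra, s.crs)

    # the whole-image chain trains the four standard covers only — field
    # workflows have no sea-surface algae class, which is exactly why the
    # unpartitioned classifier commits algae to mangrove
    training = _training_from_truth(
        rng, scene, truth, LAND_CLASSES + (WATER,), s.n_training_px)
    training_land = _training_from_truth(rng, scene, truth, LAND_CLASSES,
                                         s.n_training_px)
    training_sea = _training_from_truth(rng, scene, truth, SEA_CLASSES,
                                        s.n_training_px)

    pts_x = rng.uniform(transform.x0, transform.x0 + s.scene_w, s.n_truth_points)
    pts_y = rng.uniform(transform.y0 - s.scene_h, transform.y0, s.n_truth_points)
    truth_points = np.column_stack([pts_x, pts_y])
    cols = np.clip(((pts_x - transform.x0) / s.scene_px).astype(int), 0, shape[1] - 1)
    rows = np.clip(((transform.y0 - pts_y) / s.scene_px).astype(int), 0, shape[0] - 1)
    truth_labels = truth[rows, cols] == MANGROVE

    mangrove_layer = PatchLayer(
        patches=tuple(PatchPolygon.from_shapely(g, id=f"m{i}")
                      for i, g in enumerate(mangrove_geoms)),
        epoch=s.epoch_t1, crs=s.crs)
    land_point = (transform.x0 + s.scene_w / 2.0, transform.y0 - 0.95 * s.scene_h)
    return ConfusableScene(
        scene=scene, truth_grid=truth, training=training,
        training_land=training_land, training_sea=training_sea,
        truth_points=truth_points, truth_labels=truth_labels,
        coastline=coast, land_point=land_point, mangrove_layer=mangrove_layer,
    )
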