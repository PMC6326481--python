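"""Semi-automatic land-cover classification chains for coastal scenes.

Three chains are provided, mirroring the standard RGB workflows used to
map mangrove from very-high-resolution imagery:

* **MLC1** — plain Gaussian maximum-likelihood classification of the whole
  scene from per-class training pixels.
* **MLC2** — the same classifier applied separately to the land and sea
  sides of the coastline, each side with its own class set. Sea-surface
  features (algae, shallows) that share the mangrove RGB signature can
  then no longer be committed to the mangrove class.
* **HYBRID** — object-based: an NDVI threshold (>= 0.2) masks the scene to
  vegetation, a region-growing segmentation partitions the vegetated area
  into spectrally homogeneous segments, and every segment intersecting the
  MLC2 mangrove class is selected whole.

Classified rasters are converted to patch polygons (4-connected component
tracing in map units) and filtered at the 10 m² minimum mapping unit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from shapely import contains_xy
from shapely.geometry import LineString, Polygon, box
from shapely.ops import unary_union

from .geometry import DEFAULT_MMU, CoastlineLayer, PatchLayer, PatchPolygon, mmu_filter

__all__ = [
    "GridTransform",
    "SpectralScene",
    "TrainingSet",
    "ClassModel",
    "MissingBandError",
    "InsufficientTrainingError",
    "ndvi",
    "vegetation_mask",
    "mlc_train",
    "mlc_classify",
    "land_sea_mask",
    "mlc2_classify",
    "region_grow_segment",
    "hybrid_select",
    "raster_to_patches",
]


class MissingBandError(KeyError):
    """A required spectral band is absent from the scene."""


class InsufficientTrainingError(ValueError):
    """A class has too few training pixels to estimate its covariance."""


@dataclass(frozen=True)
class GridTransform:
    """North-up affine georeference: pixel (row, col) -> map (x, y).

    ``x0, y0`` is the map position of the raster's top-left corner;
    ``px`` is the pixel size in metres (square pixels).
    """

    x0: float
    y0: float
    px: float

    def pixel_center(self, rows: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = self.x0 + (np.asarray(cols) + 0.5) * self.px
        y = self.y0 - (np.asarray(rows) + 0.5) * self.px
        return x, y

    def pixel_box(self, row: int, col: int) -> Polygon:
        x = self.x0 + col * self.px
        y = self.y0 - row * self.px
        return box(x, y - self.px, x + self.px, y)

    @property
    def pixel_area(self) -> float:
        return self.px * self.px


@dataclass
class SpectralScene:
    """A georeferenced multi-band reflectance grid.

    Bands are named 2-D float arrays sharing one shape and transform;
    ``nodata`` marks pixels outside the analysis extent.
    """

    bands: dict[str, np.ndarray]
    transform: GridTransform
    nodata: np.ndarray | None = None  # True where invalid

    def __post_init__(self) -> None:
        shapes = {b.shape for b in self.bands.values()}
        if len(shapes) != 1:
            raise ValueError("all bands must share one shape")
        (self.shape,) = shapes
        if self.nodata is None:
            self.nodata = np.zeros(self.shape, dtype=bool)
        elif self.nodata.shape != self.shape:
            raise ValueError("nodata mask shape mismatch")

    def band(self, name: str) -> np.ndarray:
        try:
            return self.bands[name]
        except KeyError:
            raise MissingBandError(f"scene has no band {name!r}") from None

    def stack(self, names: Sequence[str] | None = None) -> np.ndarray:
        """(rows, cols, n_bands) float stack in the given band order."""
        names = list(names) if names is not None else sorted(self.bands)
        return np.stack([self.band(n) for n in names], axis=-1).astype(float)


@dataclass
class TrainingSet:
    """Per-class training pixel collections (n_i × d arrays)."""

    pixels: dict[str, np.ndarray]
    band_names: tuple[str, ...]

    def __post_init__(self) -> None:
        d = len(self.band_names)
        merged: dict[str, np.ndarray] = {}
        for cls, arr in self.pixels.items():
            arr = np.atleast_2d(np.asarray(arr, dtype=float))
            if arr.shape[1] != d:
                raise ValueError(f"class {cls!r}: expected {d} bands, got {arr.shape[1]}")
            merged[cls] = np.vstack([merged[cls], arr]) if cls in merged else arr
        self.pixels = merged

    @classmethod
    def from_regions(
        cls,
        scene: SpectralScene,
        regions: Mapping[str, Sequence[Polygon]],
        band_names: Sequence[str],
    ) -> "TrainingSet":
        """Extract training pixels whose centres fall inside labelled regions."""
        stack = scene.stack(band_names)
        rows, cols = np.indices(scene.shape)
        x, y = scene.transform.pixel_center(rows.ravel(), cols.ravel())
        pixels: dict[str, np.ndarray] = {}
        for label, polys in regions.items():
            geom = unary_union(list(polys))
            inside = contains_xy(geom, x, y).reshape(scene.shape)
            inside &= ~scene.nodata
            pixels[label] = stack[inside]
        return cls(pixels=pixels, band_names=tuple(band_names))


@dataclass(frozen=True)
class ClassModel:
    """Fitted Gaussian class-conditional model for maximum likelihood."""

    classes: tuple[str, ...]
    means: np.ndarray        # (k, d)
    covariances: np.ndarray  # (k, d, d), regularized SPD
    priors: np.ndarray       # (k,), sums to 1
    band_names: tuple[str, ...]


def ndvi(scene: SpectralScene, nir: str = "NIR", red: str = "R") -> np.ndarray:
    """Normalized difference vegetation index, (NIR − R)/(NIR + R).

    Values lie in [−1, 1]; pixels where NIR + R == 0 (and scene nodata)
    are NaN.
    """
    n = scene.band(nir).astype(float)
    r = scene.band(red).astype(float)
    denom = n + r
    out = np.full(scene.shape, np.nan)
    ok = (denom != 0) & ~scene.nodata
    out[ok] = (n[ok] - r[ok]) / denom[ok]
    return out


def vegetation_mask(ndvi_grid: np.ndarray, threshold: float = 0.2) -> np.ndarray:
    """Vegetated where NDVI >= threshold (inclusive); NaN is non-vegetated."""
    with np.errstate(invalid="ignore"):
        return np.asarray(ndvi_grid) >= threshold


def mlc_train(
    training: TrainingSet,
    priors: Mapping[str, float] | None = None,
    ridge: float = 1e-9,
) -> ClassModel:
    """Fit one Gaussian per class by sample mean and covariance.

    Covariances are ridge-regularized (``ridge`` added to the diagonal,
    scaled by the mean band variance) so nearly constant training regions
    stay invertible. Priors default to equal.
    """
    classes = tuple(sorted(training.pixels))
    if not classes:
        raise InsufficientTrainingError("no training classes")
    d = len(training.band_names)
    means, covs = [], []
    for cls_name in classes:
        arr = training.pixels[cls_name]
        if arr.shape[0] < d + 1:
            raise InsufficientTrainingError(
                f"class {cls_name!r} has {arr.shape[0]} pixels, needs >= {d + 1}"
            )
        mu = arr.mean(axis=0)
        cov = np.cov(arr, rowvar=False).reshape(d, d)
        scale = max(np.trace(cov) / d, 1.0)
        cov = cov + ridge * scale * np.eye(d)
        # bump until SPD (degenerate constant training regions)
        eps = ridge * scale
        while np.linalg.eigvalsh(cov).min() <= 0:
            eps *= 10.0
            cov = cov + eps * np.eye(d)
        means.append(mu)
        covs.append(cov)
    if priors is None:
        pri = np.full(len(classes), 1.0 / len(classes))
    else:
        pri = np.array([priors[c] for c in classes], dtype=float)
        pri = pri / pri.sum()
    return ClassModel(
        classes=classes,
        means=np.array(means),
        covariances=np.array(covs),
        priors=pri,
        band_names=training.band_names,
    )


def _class_log_likelihoods(X: np.ndarray, model: ClassModel) -> np.ndarray:
    """(n, k) Gaussian log density + log prior for flattened pixels."""
    n, d = X.shape
    out = np.empty((n, len(model.classes)))
    for k in range(len(model.classes)):
        mu = model.means[k]
        cov = model.covariances[k]
        L = np.linalg.cholesky(cov)
        diff = X - mu
        sol = np.linalg.solve(L, diff.T)  # (d, n)
        maha = np.sum(sol * sol, axis=0)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        out[:, k] = -0.5 * (maha + logdet + d * math.log(2.0 * math.pi))
        out[:, k] += math.log(model.priors[k]) if model.priors[k] > 0 else -np.inf
    return out


def mlc_classify(
    scene: SpectralScene,
    model: ClassModel,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Per-pixel maximum-likelihood class labels (MLC1 when mask is None).

    Returns an object array of class names, with None outside the mask or
    on nodata. Ties break deterministically by class-name order (argmax
    keeps the first, and classes are sorted).
    """
    valid = ~scene.nodata
    if mask is not None:
        valid = valid & mask
    labels = np.full(scene.shape, None, dtype=object)
    if not valid.any():
        return labels
    X = scene.stack(model.band_names)[valid]
    ll = _class_log_likelihoods(X, model)
    idx = np.argmax(ll, axis=1)
    names = np.array(model.classes, dtype=object)
    labels[valid] = names[idx]
    return labels


def land_sea_mask(
    scene: SpectralScene,
    coastline: CoastlineLayer,
    land_point: tuple[float, float],
) -> np.ndarray:
    """Binary land mask (True = land) by the pixel-centre rule.

    The scene extent is split by the coastline polyline; the pieces
    containing ``land_point`` form the land side. Works for any coastline
    that crosses the scene bounding box.
    """
    from shapely.ops import polygonize

    rows_n, cols_n = scene.shape
    t = scene.transform
    extent = box(t.x0, t.y0 - rows_n * t.px, t.x0 + cols_n * t.px, t.y0)
    pieces = list(polygonize(unary_union([extent.boundary, coastline.shapely])))
    land = [p for p in pieces
            if contains_xy(p, [land_point[0]], [land_point[1]])[0]]
    if not land:
        raise ValueError("land reference point is not inside the scene split")
    land_geom = unary_union(land)
    rows, cols = np.indices(scene.shape)
    x, y = t.pixel_center(rows.ravel(), cols.ravel())
    return contains_xy(land_geom, x, y).reshape(scene.shape)


def mlc2_classify(
    scene: SpectralScene,
    land_model: ClassModel,
    sea_model: ClassModel,
    land_mask: np.ndarray,
) -> np.ndarray:
    """Land/sea-partitioned maximum likelihood (MLC2).

    Each side of the coastline is classified with its own class set, so
    spectra that are ambiguous across the shoreline (e.g. sea-surface
    algae vs mangrove canopy) are resolved by geography.
    """
    land_labels = mlc_classify(scene, land_model, mask=land_mask)
    sea_labels = mlc_classify(scene, sea_model, mask=~land_mask)
    out = np.where(land_mask, land_labels, sea_labels)
    out[scene.nodata] = None
    return out


def region_grow_segment(
    scene: SpectralScene,
    mask: np.ndarray,
    diff_threshold: float = 0.75,
    min_size_px: int = 750,
    band_names: Sequence[str] | None = None,
) -> np.ndarray:
    """Region-growing segmentation of the masked area.

    Pixels join a segment while their Euclidean distance in band space
    (bands min–max normalized to [0, 1] over the mask) from the segment's
    running mean stays <= ``diff_threshold``. Segments smaller than
    ``min_size_px`` are merged into their most spectrally similar
    neighbour. Returns an int grid: segment ids >= 1 inside the mask,
    0 outside. The segmentation partitions the mask.
    """
    if diff_threshold <= 0 or min_size_px <= 0:
        raise ValueError("thresholds must be positive")
    mask = np.asarray(mask, dtype=bool) & ~scene.nodata
    labels = np.zeros(scene.shape, dtype=int)
    if not mask.any():
        return labels
    stack = scene.stack(band_names)
    lo = stack[mask].min(axis=0)
    hi = stack[mask].max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    norm = (stack - lo) / span

    from collections import deque

    nrows, ncols = scene.shape
    next_id = 0
    sums: list[np.ndarray] = [np.zeros(norm.shape[-1])]  # index 0 unused
    counts: list[int] = [0]
    for r0 in range(nrows):
        for c0 in range(ncols):
            if not mask[r0, c0] or labels[r0, c0]:
                continue
            next_id += 1
            seg = next_id
            labels[r0, c0] = seg
            s = norm[r0, c0].copy()
            cnt = 1
            q = deque([(r0, c0)])
            while q:
                r, c = q.popleft()
                for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    rr, cc = r + dr, c + dc
                    if not (0 <= rr < nrows and 0 <= cc < ncols):
                        continue
                    if not mask[rr, cc] or labels[rr, cc]:
                        continue
                    mean = s / cnt
                    if np.linalg.norm(norm[rr, cc] - mean) <= diff_threshold:
                        labels[rr, cc] = seg
                        s += norm[rr, cc]
                        cnt += 1
                        q.append((rr, cc))
            sums.append(s)
            counts.append(cnt)

    labels = _absorb_small_segments(labels, norm, mask, min_size_px)
    return labels


def _absorb_small_segments(
    labels: np.ndarray, norm: np.ndarray, mask: np.ndarray, min_size_px: int
) -> np.ndarray:
    """Merge undersized segments into their most similar touching neighbour.

    Isolated undersized segments (no in-mask neighbour) are kept — there is
    nothing to absorb them into.
    """
    flat = labels[mask]
    if flat.size == 0:
        return labels
    n_ids = int(labels.max()) + 1
    sizes = np.bincount(flat, minlength=n_ids).astype(float)
    d = norm.shape[-1]
    sums = np.zeros((n_ids, d))
    np.add.at(sums, flat, norm[mask])

    # 4-neighbour adjacency between segment ids
    adj: dict[int, set[int]] = {i: set() for i in range(1, n_ids)}
    for a, b in ((labels[:-1, :], labels[1:, :]), (labels[:, :-1], labels[:, 1:])):
        pairs = np.stack([a.ravel(), b.ravel()], axis=1)
        pairs = pairs[(pairs[:, 0] > 0) & (pairs[:, 1] > 0) & (pairs[:, 0] != pairs[:, 1])]
        for i, j in np.unique(pairs, axis=0):
            adj[int(i)].add(int(j))
            adj[int(j)].add(int(i))

    parent = list(range(n_ids))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    import heapq

    heap = [(sizes[i], i) for i in range(1, n_ids) if 0 < sizes[i] < min_size_px]
    heapq.heapify(heap)
    while heap:
        size, sid = heapq.heappop(heap)
        if find(sid) != sid or sizes[sid] != size or sizes[sid] >= min_size_px:
            continue  # stale entry
        neigh = {find(n) for n in adj[sid]} - {sid}
        if not neigh:
            continue
        mean_s = sums[sid] / sizes[sid]
        best = min(neigh, key=lambda n: (float(np.linalg.norm(mean_s - sums[n] / sizes[n])), n))
        parent[sid] = best
        sizes[best] += sizes[sid]
        sums[best] += sums[sid]
        adj[best] |= adj[sid]
        adj[best].discard(best)
        adj[best].discard(sid)
        if sizes[best] < min_size_px:
            heapq.heappush(heap, (sizes[best], best))

    roots = np.array([find(i) for i in range(n_ids)])
    return np.where(mask, roots[labels], 0)


def hybrid_select(segments: np.ndarray, mlc2_mangrove: np.ndarray) -> np.ndarray:
    """Select whole segments that overlap the MLC2 mangrove class anywhere.

    Any single overlapping pixel pulls in the entire segment (any-overlap
    rule). Returns a boolean mangrove grid.
    """
    segments = np.asarray(segments)
    hit = np.unique(segments[(segments > 0) & np.asarray(mlc2_mangrove, dtype=bool)])
    if hit.size == 0:
        return np.zeros(segments.shape, dtype=bool)
    return np.isin(segments, hit)


def raster_to_patches(
    class_grid: np.ndarray,
    target: object,
    transform: GridTransform,
    mmu: float = DEFAULT_MMU,
    epoch: int | None = None,
    crs: str = "EPSG:32715",
) -> PatchLayer:
    """Trace 4-connected components of one class into patch polygons.

    Components are unions of pixel squares in map units; the minimum
    mapping unit filter is applied to the traced layer.
    """
    arr = np.asarray(class_grid)
    hits = arr if arr.dtype == bool else np.asarray(arr == target, dtype=bool)
    comp, n_comp = ndimage.label(hits, structure=np.array(
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool))
    patches: list[PatchPolygon] = []
    for i in range(1, n_comp + 1):
        rows, cols = np.nonzero(comp == i)
        cells = [transform.pixel_box(int(r), int(c)) for r, c in zip(rows, cols)]
        geom = unary_union(cells)
        geoms = [geom] if geom.geom_type == "Polygon" else list(geom.geoms)
        for j, g in enumerate(geoms):
            patches.append(PatchPolygon.from_shapely(g, id=f"seg{i}_{j}"))
    layer = PatchLayer(patches=tuple(patches), epoch=epoch, crs=crs)
    return mmu_filter(layer, mmu)
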