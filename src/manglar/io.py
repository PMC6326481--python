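"""Readers, writers and run configuration.

Vector layers exchange as GeoJSON (RFC 7946) and WKT, with read-only KML
support; rasters as ESRI ASCII grids. All analysis happens in a metric
projected CRS — geographic (degree) inputs are refused with a clear
message rather than silently mis-measured, since no reprojection engine
is bundled.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
from shapely import from_wkt, to_wkt
from shapely.geometry import mapping, shape

from .classification import GridTransform, SpectralScene
from .geometry import CoastlineLayer, PatchLayer, PatchPolygon

__all__ = [
    "FormatError",
    "CRSError",
    "RunConfig",
    "read_patch_layer",
    "write_patch_layer",
    "read_coastline",
    "write_coastline",
    "read_ascii_grid",
    "write_ascii_grid",
    "write_report",
    "read_report",
]


class FormatError(ValueError):
    """The file does not parse as the expected format."""


class CRSError(ValueError):
    """Geographic-CRS input without a projected target."""


_GEOGRAPHIC_HINTS = ("EPSG:4326", "CRS84", "WGS84", "EPSG:4258")


def _check_metric_crs(crs: str) -> None:
    up = crs.upper().replace(" ", "")
    if any(h in up for h in _GEOGRAPHIC_HINTS):
        raise CRSError(
            f"layer CRS {crs!r} is geographic (degrees); reproject to a metric "
            "projected CRS (e.g. the local UTM zone) before analysis"
        )


@dataclass
class RunConfig:
    """Thresholds and paths for a pipeline run; round-trips through JSON."""

    seed: int = 0
    mmu_m2: float = 10.0
    ndvi_threshold: float = 0.2
    stamp_threshold_m: float = 15.0
    fronting_dist_m: float = 50.0
    qa_tolerance_m: float = 5.0
    n_validation_points: int = 500
    out_dir: str = "."
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("mmu_m2", "ndvi_threshold", "stamp_threshold_m",
                     "fronting_dist_m", "qa_tolerance_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# vector I/O

def _geojson_crs(obj: dict, default: str) -> str:
    # RFC 7946 dropped the crs member but we honour it when present
    crs = obj.get("crs")
    if isinstance(crs, dict):
        return str(crs.get("properties", {}).get("name", default))
    return default


def read_patch_layer(
    path: str | Path,
    crs: str | None = None,
    epoch: int | None = None,
) -> PatchLayer:
    """Read a patch layer from GeoJSON, WKT (one geometry per line) or KML.

    Format is chosen by extension (.geojson/.json, .wkt, .kml). ``crs``
    overrides any CRS recorded in the file; geographic CRSs are refused.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".geojson", ".json"):
        geoms, file_crs, props = _read_geojson_geoms(path)
    elif suffix == ".wkt":
        geoms, file_crs, props = _read_wkt_geoms(path)
    elif suffix == ".kml":
        geoms, file_crs, props = _read_kml_geoms(path)
    else:
        raise FormatError(f"unsupported vector format {suffix!r}")
    layer_crs = crs or file_crs
    _check_metric_crs(layer_crs)
    patches = []
    for i, (g, pr) in enumerate(zip(geoms, props)):
        parts = [g] if g.geom_type == "Polygon" else list(getattr(g, "geoms", []))
        for j, part in enumerate(parts):
            if part.geom_type != "Polygon":
                continue
            pid = str(pr.get("id", f"f{i}")) + (f"_{j}" if len(parts) > 1 else "")
            patches.append(PatchPolygon.from_shapely(part, id=pid))
    return PatchLayer(patches=tuple(patches), epoch=epoch, crs=layer_crs)


def _read_geojson_geoms(path: Path):
    try:
        obj = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise FormatError(f"{path}: not valid GeoJSON ({e})") from e
    crs = _geojson_crs(obj, "EPSG:32715")
    if obj.get("type") == "FeatureCollection":
        feats = obj.get("features", [])
        geoms = [shape(f["geometry"]) for f in feats]
        props = [f.get("properties") or {} for f in feats]
    elif obj.get("type") == "Feature":
        geoms = [shape(obj["geometry"])]
        props = [obj.get("properties") or {}]
    elif "type" in obj:
        geoms, props = [shape(obj)], [{}]
    else:
        raise FormatError(f"{path}: no GeoJSON type member")
    return geoms, crs, props


def _read_wkt_geoms(path: Path):
    geoms = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        try:
            geoms.append(from_wkt(line))
        except Exception as e:  # shapely raises GEOSException
            raise FormatError(f"{path}: bad WKT line ({e})") from e
    return geoms, "EPSG:32715", [{} for _ in geoms]


def _read_kml_geoms(path: Path):
    from lxml import etree

    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as e:
        raise FormatError(f"{path}: not valid KML ({e})") from e
    ns = {"k": "http://www.opengis.net/kml/2.2"}
    geoms, props = [], []
    for pm in tree.findall(".//k:Placemark", ns):
        for poly in pm.findall(".//k:Polygon", ns):
            outer = poly.find(".//k:outerBoundaryIs//k:coordinates", ns)
            if outer is None or not outer.text:
                continue
            ext = _parse_kml_coords(outer.text)
            holes = [
                _parse_kml_coords(c.text)
                for c in poly.findall(".//k:innerBoundaryIs//k:coordinates", ns)
                if c.text
            ]
            from shapely.geometry import Polygon

            geoms.append(Polygon(ext, holes))
            name = pm.findtext("k:name", default="", namespaces=ns)
            props.append({"id": name} if name else {})
    # KML is always lon/lat — caller must supply a projected target CRS
    return geoms, "EPSG:4326", props


def _parse_kml_coords(text: str) -> list[tuple[float, float]]:
    out = []
    for token in text.split():
        parts = token.split(",")
        out.append((float(parts[0]), float(parts[1])))
    return out


def write_patch_layer(layer: PatchLayer, path: str | Path) -> None:
    """Write a layer as a GeoJSON FeatureCollection (vertex-exact)."""
    features = [
        {
            "type": "Feature",
            "geometry": mapping(p.shapely),
            "properties": {"id": p.id},
        }
        for p in layer
    ]
    obj: dict[str, Any] = {
        "type": "FeatureCollection",
        "features": features,
        "crs": {"type": "name", "properties": {"name": layer.crs}},
    }
    if layer.epoch is not None:
        obj["epoch"] = layer.epoch
    Path(path).write_text(json.dumps(obj))


def read_coastline(path: str | Path, crs: str | None = None) -> CoastlineLayer:
    """Read coastline polylines from GeoJSON or WKT."""
    path = Path(path)
    if path.suffix.lower() in (".geojson", ".json"):
        geoms, file_crs, _ = _read_geojson_geoms(path)
    elif path.suffix.lower() == ".wkt":
        geoms, file_crs, _ = _read_wkt_geoms(path)
    else:
        raise FormatError(f"unsupported coastline format {path.suffix!r}")
    layer_crs = crs or file_crs
    _check_metric_crs(layer_crs)
    lines = []
    for g in geoms:
        if g.geom_type == "LineString":
            lines.append(tuple(g.coords))
        elif g.geom_type == "MultiLineString":
            lines.extend(tuple(part.coords) for part in g.geoms)
    if not lines:
        raise FormatError(f"{path}: no polylines found")
    return CoastlineLayer(polylines=tuple(lines), crs=layer_crs)


def write_coastline(coast: CoastlineLayer, path: str | Path) -> None:
    obj = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": {"type": "LineString",
                             "coordinates": [list(pt) for pt in pl]},
                "properties": {},
            }
            for pl in coast.polylines
        ],
        "crs": {"type": "name", "properties": {"name": coast.crs}},
    }
    Path(path).write_text(json.dumps(obj))


# ---------------------------------------------------------------------------
# raster I/O (ESRI ASCII grid; one file per band)

def write_ascii_grid(grid: np.ndarray, transform: GridTransform,
                     path: str | Path, nodata: float = -9999.0) -> None:
    """Write one band as an ESRI ASCII grid (plain text)."""
    grid = np.asarray(grid, dtype=float)
    nrows, ncols = grid.shape
    header = (
        f"ncols {ncols}\nnrows {nrows}\n"
        f"xllcorner {transform.x0}\n"
        f"yllcorner {transform.y0 - nrows * transform.px}\n"
        f"cellsize {transform.px}\nNODATA_value {nodata}\n"
    )
    body = "\n".join(" ".join(f"{v:.6g}" for v in row) for row in
                     np.where(np.isnan(grid), nodata, grid))
    Path(path).write_text(header + body + "\n")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridTransform]:
    """Read an ESRI ASCII grid; nodata becomes NaN."""
    lines = Path(path).read_text().splitlines()
    hdr: dict[str, float] = {}
    i = 0
    while i < len(lines) and lines[i].split()[0].lower() in (
        "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
    ):
        k, v = lines[i].split()[:2]
        hdr[k.lower()] = float(v)
        i += 1
    try:
        ncols, nrows = int(hdr["ncols"]), int(hdr["nrows"])
        px = hdr["cellsize"]
        x0 = hdr["xllcorner"]
        y0 = hdr["yllcorner"] + nrows * px
    except KeyError as e:
        raise FormatError(f"{path}: missing ASCII-grid header field {e}") from e
    data = np.loadtxt(lines[i:], dtype=float).reshape(nrows, ncols)
    nodata = hdr.get("nodata_value")
    if nodata is not None:
        data = np.where(data == nodata, np.nan, data)
    return data, GridTransform(x0=x0, y0=y0, px=px)


def write_scene(scene: SpectralScene, out_dir: str | Path, stem: str = "scene") -> list[Path]:
    """Write every band of a scene as ``<stem>_<band>.asc``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, grid in scene.bands.items():
        p = out_dir / f"{stem}_{name}.asc"
        g = np.where(scene.nodata, np.nan, grid)
        write_ascii_grid(g, scene.transform, p)
        paths.append(p)
    return paths


def read_scene(paths: dict[str, str | Path]) -> SpectralScene:
    """Assemble a scene from per-band ASCII grids (band name -> path)."""
    bands, transform = {}, None
    for name, p in paths.items():
        grid, t = read_ascii_grid(p)
        bands[name] = grid
        transform = transform or t
    nodata = np.zeros(next(iter(bands.values())).shape, dtype=bool)
    for g in bands.values():
        nodata |= np.isnan(g)
    return SpectralScene(bands=bands, transform=transform, nodata=nodata)


# ---------------------------------------------------------------------------
# reports

def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(results: dict, path: str | Path,
                 config: RunConfig | None = None) -> None:
    """Write a JSON run report with tool version and config echo."""
    from . import __version__

    payload = {
        "tool": "manglar",
        "version": __version__,
        "config": asdict(config) if config else None,
        "results": _jsonable(results),
    }
    Path(path).write_text(json.dumps(payload, indent=2, ensure_ascii=False))


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
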