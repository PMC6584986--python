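"""Raster and vector I/O plus the pixel<->world coordinate contract.

Rasters are held as :class:`GeoImage` (H x W x 3, bands ordered R,G,B);
georeferencing is a six-coefficient affine in the GDAL layout.  Pixel
coordinates are 0-based ``(col, row)`` and world mapping uses the
pixel-center convention: pixel (0, 0) maps to the world position of its
center, i.e. the affine is evaluated at ``(col + 0.5, row + 0.5)``.

GeoTIFF geo-tags (ModelPixelScale / ModelTiepoint) are read and written
through :mod:`tifffile`; plain PNG/TIFF rasters require an explicit ground
sampling distance.  Vector data uses GeoJSON (shapely geometries) and CSV.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import tifffile
import yaml
from PIL import Image
from shapely.geometry import Point, Polygon, mapping, shape

__all__ = [
    "Affine",
    "GeoImage",
    "PlotMap",
    "PlotPolygon",
    "PointSet",
    "read_orthomosaic",
    "write_orthomosaic",
    "read_plot_map",
    "grid_plot_map",
    "write_plot_map",
    "write_points",
    "read_points",
    "pixel_to_world",
    "world_to_pixel",
]

# GeoTIFF tag ids
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEY_DIRECTORY = 34735


@dataclass(frozen=True)
class Affine:
    """Affine map from edge-based pixel coordinates to world coordinates.

    ``x = a*col + b*row + c`` and ``y = d*col + e*row + f`` where
    ``(col, row)`` are measured from the top-left *corner* of the raster.
    Callers should normally go through :func:`pixel_to_world`, which adds
    the half-pixel offset so that integer pixel indices refer to centers.
    """

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float

    def apply(self, col: float, row: float) -> tuple[float, float]:
        return (
            self.a * col + self.b * row + self.c,
            self.d * col + self.e * row + self.f,
        )

    def inverse(self) -> "Affine":
        det = self.a * self.e - self.b * self.d
        if det == 0:
            raise ValueError("affine transform is singular")
        ia, ib = self.e / det, -self.b / det
        id_, ie = -self.d / det, self.a / det
        ic = -(ia * self.c + ib * self.f)
        if_ = -(id_ * self.c + ie * self.f)
        return Affine(ia, ib, ic, id_, ie, if_)

    @property
    def pixel_size(self) -> float:
        """Mean linear pixel size, sqrt(|det|) of the linear part."""
        return math.sqrt(abs(self.a * self.e - self.b * self.d))

    @staticmethod
    def from_origin(x0: float, y0: float, pixel_size: float) -> "Affine":
        """North-up transform: +x along columns, -y along rows."""
        return Affine(pixel_size, 0.0, x0, 0.0, -pixel_size, y0)


@dataclass
class GeoImage:
    """An RGB raster with optional georeferencing.

    Parameters
    ----------
    pixels:
        H x W x 3 array, bands ordered R, G, B.  Either unsigned 8-bit or
        float in [0, 1]; ``is_8bit`` records which.
    transform:
        Optional affine mapping (col, row) -> (x, y) world coordinates.
    crs_id:
        Opaque coordinate-reference-system identifier (e.g. "EPSG:32754").
    gsd_cm:
        Ground sampling distance in cm/pixel; must agree with the transform's
        pixel size within 1% when both are present.
    """

    pixels: np.ndarray
    gsd_cm: float
    transform: Affine | None = None
    crs_id: str | None = None
    is_8bit: bool = True

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] < 3:
            raise ValueError("GeoImage requires an H x W x 3 array")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("empty raster")
        if not self.gsd_cm > 0:
            raise ValueError("gsd_cm must be > 0")
        if self.transform is not None:
            tr_cm = self.transform.pixel_size * 100.0
            if not math.isclose(tr_cm, self.gsd_cm, rel_tol=0.01):
                raise ValueError(
                    f"gsd_cm={self.gsd_cm} inconsistent with transform pixel "
                    f"size {tr_cm:.6g} cm (>1% off)"
                )
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def band(self, name: str) -> np.ndarray:
        idx = {"red": 0, "green": 1, "blue": 2}[name]
        return self.pixels[:, :, idx]


@dataclass
class PlotPolygon:
    plot_id: str
    polygon: Polygon
    area_m2: float


@dataclass
class PlotMap:
    """Experimental plot polygons in world (or pixel) coordinates."""

    plots: list[PlotPolygon]
    frame: str = "world"  # "world" or "pixel"

    def __post_init__(self) -> None:
        ids = [p.plot_id for p in self.plots]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate plot ids: {dupes}")
        for p in self.plots:
            if not p.polygon.is_valid or p.polygon.area == 0:
                raise ValueError(f"degenerate polygon for plot {p.plot_id!r}")
            if not p.area_m2 > 0:
                raise ValueError(f"non-positive area for plot {p.plot_id!r}")

    def __len__(self) -> int:
        return len(self.plots)

    def ids(self) -> list[str]:
        return [p.plot_id for p in self.plots]


@dataclass
class PointSet:
    """Points in pixel coordinates ``(col, row)`` with optional attributes."""

    points: np.ndarray  # n x 2 float array, columns (col, row)
    label: str = ""
    attributes: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.size == 0:
            pts = pts.reshape(0, 2)
        if pts.shape[1] != 2:
            raise ValueError("points must be n x 2 (col, row)")
        self.points = pts

    def __len__(self) -> int:
        return len(self.points)


# ---------------------------------------------------------------------------
# coordinate mapping


def pixel_to_world(transform: Affine, col: float, row: float):
    """Map pixel (col, row) to world (x, y) at the pixel-center convention.

    Scalar or array inputs are accepted; arrays map element-wise.
    """
    if transform is None:
        raise ValueError("no affine transform present")
    col = np.asarray(col, dtype=float) + 0.5
    row = np.asarray(row, dtype=float) + 0.5
    x = transform.a * col + transform.b * row + transform.c
    y = transform.d * col + transform.e * row + transform.f
    if x.ndim == 0:
        return float(x), float(y)
    return x, y


def world_to_pixel(transform: Affine, x: float, y: float):
    """Inverse of :func:`pixel_to_world` (returns fractional col, row)."""
    inv = transform.inverse()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    col = inv.a * x + inv.b * y + inv.c - 0.5
    row = inv.d * x + inv.e * y + inv.f - 0.5
    if col.ndim == 0:
        return float(col), float(row)
    return col, row


# ---------------------------------------------------------------------------
# rasters


def _geotiff_transform(page: "tifffile.TiffPage") -> Affine | None:
    tags = page.tags
    scale = tags.get(_TAG_MODEL_PIXEL_SCALE)
    tie = tags.get(_TAG_MODEL_TIEPOINT)
    if scale is None or tie is None:
        return None
    sx, sy = float(scale.value[0]), float(scale.value[1])
    i, j, _, x, y, _ = (float(v) for v in tie.value[:6])
    # world position of the tiepoint pixel corner
    return Affine(sx, 0.0, x - i * sx, 0.0, -sy, y + j * sy)


def _geotiff_crs(page: "tifffile.TiffPage") -> str | None:
    keys = page.tags.get(_TAG_GEO_KEY_DIRECTORY)
    if keys is None:
        return None
    vals = list(keys.value)
    # GeoKeyDirectory: header of 4 shorts then (key, loc, count, value) rows
    for k in range(4, len(vals) - 3, 4):
        key_id, loc, _count, value = vals[k : k + 4]
        if key_id in (2048, 3072) and loc == 0 and value not in (0, 32767):
            return f"EPSG:{value}"
    return None


def read_orthomosaic(path: str | Path, gsd_cm: float | None = None) -> GeoImage:
    """Read an RGB orthomosaic from GeoTIFF, plain TIFF, or PNG.

    The affine transform is taken from GeoTIFF tags when present, in which
    case ``gsd_cm`` is derived from the pixel size; otherwise the caller
    must supply ``gsd_cm``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    transform = None
    crs_id = None
    if path.suffix.lower() in {".tif", ".tiff"}:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            data = page.asarray()
            transform = _geotiff_transform(page)
            crs_id = _geotiff_crs(page)
    else:
        data = np.asarray(Image.open(path).convert("RGB"))
    if data.ndim == 2:
        raise ValueError(f"{path}: single-band raster, need >= 3 bands (RGB)")
    if data.shape[2] < 3:
        raise ValueError(f"{path}: {data.shape[2]} bands, need >= 3 (RGB)")
    data = data[:, :, :3]
    if transform is not None:
        derived = transform.pixel_size * 100.0
        if gsd_cm is not None and not math.isclose(derived, gsd_cm, rel_tol=0.01):
            raise ValueError(
                f"supplied gsd_cm={gsd_cm} conflicts with georeferenced "
                f"pixel size {derived:.6g} cm"
            )
        gsd_cm = derived
    if gsd_cm is None:
        raise ValueError(
            f"{path}: no georeferencing tags and no gsd_cm supplied"
        )
    is_8bit = data.dtype == np.uint8
    if not is_8bit:
        data = data.astype(np.float64)
        if data.max() > 1.0:
            raise ValueError("float rasters must be scaled to [0, 1]")
    return GeoImage(
        pixels=data,
        gsd_cm=float(gsd_cm),
        transform=transform,
        crs_id=crs_id,
        is_8bit=is_8bit,
    )


def write_orthomosaic(image: GeoImage, path: str | Path) -> Path:
    """Write a GeoImage as (Geo)TIFF or PNG, preserving geo-tags for TIFF."""
    path = Path(path)
    px = image.pixels
    if not image.is_8bit:
        px = np.clip(np.rint(px * 255.0), 0, 255).astype(np.uint8)
    if path.suffix.lower() in {".tif", ".tiff"}:
        extratags = []
        if image.transform is not None:
            t = image.transform
            extratags = [
                (_TAG_MODEL_PIXEL_SCALE, "d", 3, (t.a, -t.e, 0.0)),
                (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, t.c, t.f, 0.0)),
            ]
        tifffile.imwrite(path, px, extratags=extratags)
    elif path.suffix.lower() == ".png":
        Image.fromarray(px).save(path)
    else:
        raise ValueError(f"unsupported raster format: {path.suffix}")
    return path


# ---------------------------------------------------------------------------
# plot maps


def grid_plot_map(
    rows: int,
    cols: int,
    plot_length_m: float = 5.0,
    plot_width_m: float = 1.0,
    origin: tuple[float, float] = (0.0, 0.0),
    alley_m: float = 0.5,
    id_format: str = "P{:03d}",
) -> PlotMap:
    """Lay out a regular grid of rectangular plots.

    Plots are long along x (length) and narrow along y (width), arranged
    ``rows`` x ``cols`` with ``alley_m`` gaps, row-major ids starting at 1.
    The origin is the top-left corner of plot 1; y decreases down rows
    (north-up world frame).
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    x0, y0 = origin
    plots = []
    n = 0
    for r in range(rows):
        for c in range(cols):
            n += 1
            px = x0 + c * (plot_length_m + alley_m)
            py = y0 - r * (plot_width_m + alley_m)
            poly = Polygon(
                [
                    (px, py),
                    (px + plot_length_m, py),
                    (px + plot_length_m, py - plot_width_m),
                    (px, py - plot_width_m),
                ]
            )
            plots.append(
                PlotPolygon(id_format.format(n), poly, plot_length_m * plot_width_m)
            )
    return PlotMap(plots)


def read_plot_map(source: str | Path | Mapping) -> PlotMap:
    """Read a plot map from GeoJSON, a grid-config YAML/JSON file, or a dict.

    GeoJSON features must carry a ``plot_id`` property (falling back to
    ``id``).  Grid configs have a top-level ``grid`` mapping with keys
    ``rows, cols, plot_length_m, plot_width_m`` and optional
    ``origin, alley_m``.
    """
    if isinstance(source, Mapping):
        cfg = dict(source.get("grid", source))
        return grid_plot_map(
            rows=int(cfg["rows"]),
            cols=int(cfg["cols"]),
            plot_length_m=float(cfg.get("plot_length_m", 5.0)),
            plot_width_m=float(cfg.get("plot_width_m", 1.0)),
            origin=tuple(cfg.get("origin", (0.0, 0.0))),
            alley_m=float(cfg.get("alley_m", 0.5)),
        )
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if path.suffix.lower() in {".yaml", ".yml"}:
        return read_plot_map(yaml.safe_load(text))
    data = json.loads(text)
    if data.get("type") != "FeatureCollection":
        return read_plot_map(data)
    plots = []
    for feat in data["features"]:
        props = feat.get("properties") or {}
        pid = props.get("plot_id", feat.get("id"))
        if pid is None:
            raise ValueError("GeoJSON feature lacks a plot_id property")
        geom = shape(feat["geometry"])
        if geom.geom_type != "Polygon":
            raise ValueError(f"plot {pid!r}: expected Polygon, got {geom.geom_type}")
        if not geom.is_valid:
            raise ValueError(f"plot {pid!r}: self-intersecting polygon")
        area = props.get("area_m2", geom.area)
        plots.append(PlotPolygon(str(pid), geom, float(area)))
    return PlotMap(plots)


def write_plot_map(plot_map: PlotMap, path: str | Path) -> Path:
    path = Path(path)
    features = [
        {
            "type": "Feature",
            "properties": {"plot_id": p.plot_id, "area_m2": p.area_m2},
            "geometry": mapping(p.polygon),
        }
        for p in plot_map.plots
    ]
    path.write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
    )
    return path


# ---------------------------------------------------------------------------
# points


def write_points(
    points: PointSet,
    geo: GeoImage | None,
    path: str | Path,
    format: str = "geojson",
) -> Path:
    """Export points as GeoJSON (world coordinates) or CSV.

    GeoJSON requires a georeferenced image; CSV always carries pixel
    coordinates and adds world coordinates when a transform is available.
    Coordinates are written at full repr precision so that a round-trip
    through :func:`read_points` is exact to well below 1e-6.
    """
    path = Path(path)
    fmt = format.lower()
    cols = points.points[:, 0]
    rows = points.points[:, 1]
    world = None
    if geo is not None and geo.transform is not None:
        world = pixel_to_world(geo.transform, cols, rows)
        if np.ndim(world[0]) == 0 and len(points) == 1:
            world = (np.atleast_1d(world[0]), np.atleast_1d(world[1]))
    if fmt == "geojson":
        if world is None:
            raise ValueError("GeoJSON export requires a georeferenced image")
        feats = []
        for i in range(len(points)):
            props = {"col": float(cols[i]), "row": float(rows[i])}
            for key, vals in points.attributes.items():
                v = vals[i]
                props[key] = v.item() if hasattr(v, "item") else v
            feats.append(
                {
                    "type": "Feature",
                    "properties": props,
                    "geometry": {
                        "type": "Point",
                        "coordinates": [float(world[0][i]), float(world[1][i])],
                    },
                }
            )
        fc = {"type": "FeatureCollection", "features": feats}
        if geo.crs_id:
            fc["crs_id"] = geo.crs_id
        path.write_text(json.dumps(fc, indent=1))
    elif fmt == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            header = ["col", "row"]
            if world is not None:
                header += ["x", "y"]
            header += list(points.attributes)
            writer.writerow(header)
            for i in range(len(points)):
                rec = [repr(float(cols[i])), repr(float(rows[i]))]
                if world is not None:
                    rec += [repr(float(world[0][i])), repr(float(world[1][i]))]
                for key in points.attributes:
                    v = points.attributes[key][i]
                    rec.append(v.item() if hasattr(v, "item") else v)
                writer.writerow(rec)
    else:
        raise ValueError(f"unsupported point format: {format!r} (geojson or csv)")
    return path


def read_points(path: str | Path, geo: GeoImage | None = None) -> PointSet:
    """Read points written by :func:`write_points`.

    GeoJSON points are mapped back to pixel coordinates through the image
    transform (using the stored col/row properties when present).
    """
    path = Path(path)
    if path.suffix.lower() == ".geojson" or path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        pts = []
        attrs: dict[str, list] = {}
        for feat in data["features"]:
            props = feat.get("properties") or {}
            if "col" in props and "row" in props:
                pts.append((props["col"], props["row"]))
            else:
                if geo is None or geo.transform is None:
                    raise ValueError("need a georeferenced image to invert points")
                x, y = feat["geometry"]["coordinates"]
                pts.append(world_to_pixel(geo.transform, x, y))
            for key, val in props.items():
                if key in ("col", "row"):
                    continue
                attrs.setdefault(key, []).append(val)
        return PointSet(
            np.array(pts, dtype=float).reshape(-1, 2),
            attributes={k: np.asarray(v) for k, v in attrs.items()},
        )
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        rows = list(reader)
    pts = [(float(r["col"]), float(r["row"])) for r in rows]
    attrs = {}
    if rows:
        for key in rows[0]:
            if key in ("col", "row", "x", "y"):
                continue
            attrs[key] = np.asarray([_maybe_number(r[key]) for r in rows])
    return PointSet(np.array(pts, dtype=float).reshape(-1, 2), attributes=attrs)


def _maybe_number(s: str):
    for cast in (int, float):
        try:
            return cast(s)
        except (TypeError, ValueError):
            pass
    return s
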