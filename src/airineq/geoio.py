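"""Geospatial and tabular I/O with one internal coordinate convention.

Everything downstream assumes a single equal-area projected coordinate
system with kilometre units: raster cell sizes, polygon coordinates and
areas are all in km / km².  Rasters are single-band GeoTIFF with the
pixel scale, tiepoint and nodata carried in the standard tags; vectors
are GeoJSON FeatureCollections whose coordinates are already projected.
Grids are indexed row-major from the upper-left corner, 0-based, with
half-open extents; a pixel belongs to the county containing its center.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import tifffile
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry
from shapely.strtree import STRtree

__all__ = [
    "GridField",
    "CountyRecord",
    "TractRecord",
    "RegionSet",
    "WeightsMatrix",
    "GeodataError",
    "MultiBandRasterError",
    "MissingGeoreferenceError",
    "OrphanTractError",
    "ZeroAreaError",
    "UndefinedMetricError",
    "read_grid",
    "write_grid",
    "read_regions",
    "write_regions",
    "build_adjacency",
    "grid_adjacency",
    "county_index_grid",
]

# TIFF tag codes used for minimal georeferencing
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


class GeodataError(Exception):
    """Base class for geodata input failures."""


class MultiBandRasterError(GeodataError):
    """Raster has more than one band."""


class MissingGeoreferenceError(GeodataError):
    """Raster lacks pixel-scale/tiepoint tags (unparseable georeferencing)."""


class OrphanTractError(GeodataError):
    """A tract references a county id that does not exist."""


class ZeroAreaError(GeodataError):
    """A polygon has zero (or negative) area."""


class UndefinedMetricError(Exception):
    """A statistic is undefined for the given input (e.g. zero mean)."""


@dataclass
class GridField:
    """A rectangular single-band raster in projected km coordinates.

    ``values`` is a 2-D float array; masked (nodata) cells are stored as
    NaN regardless of the on-disk ``nodata`` sentinel.  ``origin`` is the
    (x, y) of the upper-left *corner*; y decreases with increasing row.
    """

    values: np.ndarray
    cell_size_km: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = float("nan")
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("GridField values must be a non-empty 2-D array")
        if not self.cell_size_km > 0:
            raise ValueError("cell_size_km must be positive")
        valid = self.values[~np.isnan(self.values)]
        if valid.size and valid.min() < 0:
            raise ValueError(f"negative values in field {self.label!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell is nodata."""
        return np.isnan(self.values)

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) center coordinates, each shaped like ``values``."""
        ny, nx = self.values.shape
        ox, oy = self.origin
        x = ox + (np.arange(nx) + 0.5) * self.cell_size_km
        y = oy - (np.arange(ny) + 0.5) * self.cell_size_km
        return np.broadcast_to(x, (ny, nx)), np.broadcast_to(y[:, None], (ny, nx))

    def like(self, values: np.ndarray, label: str | None = None) -> "GridField":
        """New field with the same geometry and different values."""
        return GridField(
            values=values,
            cell_size_km=self.cell_size_km,
            origin=self.origin,
            nodata=self.nodata,
            label=self.label if label is None else label,
        )


@dataclass(frozen=True)
class CountyRecord:
    county_id: str
    polygon: BaseGeometry
    area_km2: float


@dataclass
class TractRecord:
    county_id: str
    tract_id: str
    polygon: BaseGeometry
    area_km2: float
    population: float = 0.0
    low_income_count: float = 0.0


@dataclass
class RegionSet:
    """County polygons, each partitioned into tract polygons."""

    counties: list[CountyRecord] = field(default_factory=list)
    tracts: list[TractRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = {c.county_id for c in self.counties}
        for c in self.counties:
            if not c.area_km2 > 0:
                raise ZeroAreaError(f"county {c.county_id} has non-positive area")
        for t in self.tracts:
            if t.county_id not in ids:
                raise OrphanTractError(
                    f"tract {t.tract_id} references unknown county {t.county_id}"
                )
            if not t.area_km2 > 0:
                raise ZeroAreaError(f"tract {t.tract_id} has non-positive area")
            if not 0 <= t.low_income_count <= t.population:
                raise ValueError(
                    f"tract {t.tract_id}: low_income_count outside [0, population]"
                )

    @property
    def county_ids(self) -> list[str]:
        return [c.county_id for c in self.counties]

    def tracts_of(self, county_id: str) -> list[TractRecord]:
        return [t for t in self.tracts if t.county_id == county_id]


@dataclass
class WeightsMatrix:
    """Binary symmetric spatial adjacency with zero diagonal."""

    w: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.w)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(w, w.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if not np.isin(w, (0, 1)).all():
            raise ValueError("adjacency must be binary")
        self.w = w.astype(np.int8)

    @property
    def n(self) -> int:
        return self.w.shape[0]


# ---------------------------------------------------------------------------
# Raster I/O


def read_grid(path: str | Path, label: str = "") -> GridField:
    """Read a single-band georeferenced GeoTIFF into a :class:`GridField`.

    Raises ``FileNotFoundError`` for a missing file,
    :class:`MultiBandRasterError` for multi-band rasters and
    :class:`MissingGeoreferenceError` when the pixel-scale/tiepoint tags
    are absent.  Nodata cells become NaN.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        arr = page.asarray()
        if arr.ndim != 2:
            raise MultiBandRasterError(f"{path}: expected 1 band, got shape {arr.shape}")
        tags = page.tags
        if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
            raise MissingGeoreferenceError(f"{path}: no pixel scale / tiepoint tags")
        sx, sy = tags[_TAG_PIXEL_SCALE].value[:2]
        tie = tags[_TAG_TIEPOINT].value
        if abs(sx - sy) > 1e-9 * max(sx, sy):
            raise MissingGeoreferenceError(f"{path}: non-square pixels ({sx} x {sy})")
        # tiepoint maps raster (i, j) = (0, 0) to model (x, y)
        origin = (float(tie[3]), float(tie[4]))
        nodata = float("nan")
        if _TAG_GDAL_NODATA in tags:
            try:
                nodata = float(tags[_TAG_GDAL_NODATA].value)
            except ValueError as exc:  # pragma: no cover - malformed tag
                raise MissingGeoreferenceError(f"{path}: bad nodata tag") from exc
    values = np.asarray(arr, dtype=float)
    if np.isfinite(nodata):
        values = np.where(values == nodata, np.nan, values)
    return GridField(values=values, cell_size_km=float(sx), origin=origin,
                     nodata=nodata, label=label or path.stem)


def write_grid(field: GridField, path: str | Path) -> Path:
    """Write a :class:`GridField` as a single-band float GeoTIFF."""
    path = Path(path)
    values = field.values.astype(np.float64)
    nodata = field.nodata
    if np.isfinite(nodata):
        values = np.where(np.isnan(values), nodata, values)
        nodata_ascii = f"{nodata:g}"
    else:
        nodata_ascii = "nan"
    s = float(field.cell_size_km)
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (s, s, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, field.origin[0], field.origin[1], 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, nodata_ascii),
    ]
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, values, extratags=extratags)
    return path


# ---------------------------------------------------------------------------
# Vector I/O


def _feature_collection(features: list[dict]) -> dict:
    return {"type": "FeatureCollection", "features": features}


def write_regions(regions: RegionSet, county_path: str | Path,
                  tract_path: str | Path) -> None:
    """Write counties and tracts as two GeoJSON FeatureCollections."""
    county_feats = [
        {
            "type": "Feature",
            "geometry": mapping(c.polygon),
            "properties": {"county_id": c.county_id},
        }
        for c in regions.counties
    ]
    tract_feats = [
        {
            "type": "Feature",
            "geometry": mapping(t.polygon),
            "properties": {
                "county_id": t.county_id,
                "tract_id": t.tract_id,
                "population": t.population,
                "low_income_count": t.low_income_count,
            },
        }
        for t in regions.tracts
    ]
    Path(county_path).parent.mkdir(parents=True, exist_ok=True)
    Path(county_path).write_text(json.dumps(_feature_collection(county_feats)))
    Path(tract_path).write_text(json.dumps(_feature_collection(tract_feats)))


def read_regions(county_path: str | Path, tract_path: str | Path) -> RegionSet:
    """Read county and tract GeoJSON files into a validated :class:`RegionSet`.

    Areas are recomputed from the polygon geometry (km² under the
    projected-km convention).  Referential integrity and positive areas
    are enforced by :meth:`RegionSet.validate`.
    """
    counties = []
    for feat in json.loads(Path(county_path).read_text())["features"]:
        poly = shape(feat["geometry"])
        counties.append(CountyRecord(
            county_id=str(feat["properties"]["county_id"]),
            polygon=poly,
            area_km2=poly.area,
        ))
    tracts = []
    for feat in json.loads(Path(tract_path).read_text())["features"]:
        poly = shape(feat["geometry"])
        props = feat["properties"]
        tracts.append(TractRecord(
            county_id=str(props["county_id"]),
            tract_id=str(props["tract_id"]),
            polygon=poly,
            area_km2=poly.area,
            population=float(props.get("population", 0.0)),
            low_income_count=float(props.get("low_income_count", 0.0)),
        ))
    return RegionSet(counties=counties, tracts=tracts)


# ---------------------------------------------------------------------------
# Adjacency


def grid_adjacency(shape_: tuple[int, int], rule: str = "rook") -> WeightsMatrix:
    """Adjacency of the cells of an ``(nrows, ncols)`` pixel grid."""
    if rule not in ("rook", "queen"):
        raise ValueError(f"unknown adjacency rule {rule!r}")
    ny, nx = shape_
    n = ny * nx
    w = np.zeros((n, n), dtype=np.int8)
    idx = np.arange(n).reshape(ny, nx)
    offsets = [(0, 1), (1, 0)]
    if rule == "queen":
        offsets += [(1, 1), (1, -1)]
    for di, dj in offsets:
        src = idx[max(0, -di): ny - max(0, di), max(0, -dj): nx - max(0, dj)]
        dst = idx[max(0, di): ny + min(0, di) or None, max(0, dj): nx + min(0, dj) or None]
        w[src.ravel(), dst.ravel()] = 1
        w[dst.ravel(), src.ravel()] = 1
    return WeightsMatrix(w=w)


def build_adjacency(units: Sequence[BaseGeometry] | tuple[int, int],
                    rule: str = "rook") -> WeightsMatrix:
    """Binary adjacency over polygons (or a pixel grid given as a shape tuple).

    Rook: units share a boundary of positive length.  Queen: units touch
    anywhere (shared edge or corner).  A single unit yields the 1x1 zero
    matrix.
    """
    if rule not in ("rook", "queen"):
        raise ValueError(f"unknown adjacency rule {rule!r}")
    if (isinstance(units, tuple) and len(units) == 2
            and all(isinstance(u, (int, np.integer)) for u in units)):
        return grid_adjacency(units, rule)
    geoms = list(units)
    n = len(geoms)
    if n == 0:
        raise ValueError("need at least one unit")
    w = np.zeros((n, n), dtype=np.int8)
    tree = STRtree(geoms)
    for i, g in enumerate(geoms):
        for j in tree.query(g, predicate="intersects"):
            j = int(j)
            if j <= i:
                continue
            inter = g.intersection(geoms[j])
            if inter.is_empty:
                continue
            adjacent = inter.length > 0 if rule == "rook" else True
            if adjacent:
                w[i, j] = w[j, i] = 1
    return WeightsMatrix(w=w)


# ---------------------------------------------------------------------------
# Zonal assignment


def county_index_grid(regions: RegionSet, grid: GridField) -> np.ndarray:
    """Integer array assigning each pixel to the county containing its center.

    Returns indices into ``regions.counties``; -1 where no county contains
    the pixel center.  Ties at shared boundaries go to the first county
    whose (closed) polygon covers the point.
    """
    import shapely

    x, y = grid.cell_centers()
    out = np.full(grid.shape, -1, dtype=np.int64)
    xf, yf = x.ravel(), y.ravel()
    unassigned = np.ones(xf.shape[0], dtype=bool)
    for ci, county in enumerate(regions.counties):
        minx, miny, maxx, maxy = county.polygon.bounds
        cand = unassigned & (xf >= minx) & (xf <= maxx) & (yf >= miny) & (yf <= maxy)
        if not cand.any():
            continue
        hit = shapely.intersects_xy(county.polygon, xf[cand], yf[cand])
        sel = np.flatnonzero(cand)[hit]
        out.ravel()[sel] = ci
        unassigned[sel] = False
    return out
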