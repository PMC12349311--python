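"""Georeferenced raster and field-boundary I/O.

GeoTIFF reading/writing is built on :mod:`tifffile` plus the four GeoTIFF
tags needed for a north-up raster in a projected CRS: ``ModelPixelScale``
(33550), ``ModelTiepoint`` (33922), ``GeoKeyDirectory`` (34735) and GDAL's
nodata tag (42113).  Field boundaries are GeoJSON polygons handled through
shapely.  Only metre-based projected coordinate systems are accepted: every
downstream quantity (pixel area, damage hectares, point spacing) is metric.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
import shapely
import tifffile
from shapely.geometry import MultiPolygon, Polygon, box, mapping, shape
from shapely.ops import unary_union

log = logging.getLogger(__name__)

# GeoTIFF tag codes
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEOKEYS = 34735
_TAG_GDAL_NODATA = 42113

# GeoKey ids
_KEY_MODEL_TYPE = 1024       # 1 = projected, 2 = geographic
_KEY_PROJECTED_CS = 3072     # EPSG code of the projected CRS
_KEY_LINEAR_UNITS = 3076     # 9001 = metre
_METRE = 9001


class CRSError(ValueError):
    """Raised when a raster or vector CRS violates the projected-metre contract."""


class EmptyIntersectionError(ValueError):
    """Raised when a boundary polygon does not overlap the raster extent."""


@dataclass(frozen=True)
class CRS:
    """Minimal projected-CRS descriptor: an EPSG code plus the projected flag."""

    epsg: int | None
    is_projected: bool = True

    def __eq__(self, other):
        if not isinstance(other, CRS):
            return NotImplemented
        return self.epsg == other.epsg and self.is_projected == other.is_projected

    def __hash__(self):
        return hash((self.epsg, self.is_projected))


@dataclass(frozen=True)
class GridTransform:
    """North-up affine georeference.

    Maps pixel indices to projected coordinates: the *outer corner* of pixel
    ``(row=0, col=0)`` sits at ``(x0, y0)``; x grows with columns, y shrinks
    with rows.  Pixel extents are half-open, so a point exactly on a shared
    edge belongs to the pixel down-right of it (and :func:`point_to_rowcol`
    offers the opposite, upper-left convention used for label extraction).
    """

    x0: float
    y0: float
    sx: float  # column step, metres, > 0
    sy: float  # row step, metres, > 0 (applied downward: y = y0 - row*sy)

    def __post_init__(self):
        if self.sx <= 0 or self.sy <= 0:
            raise ValueError("pixel size must be strictly positive")

    def pixel_center(self, row, col):
        """Projected (x, y) of pixel centers; accepts arrays."""
        x = self.x0 + (np.asarray(col) + 0.5) * self.sx
        y = self.y0 - (np.asarray(row) + 0.5) * self.sy
        return x, y

    def point_to_rowcol(self, x, y):
        """Pixel (row, col) containing each point.

        Points exactly on a pixel edge resolve to the upper-left pixel.
        """
        fc = (np.asarray(x, dtype=float) - self.x0) / self.sx
        fr = (self.y0 - np.asarray(y, dtype=float)) / self.sy
        col = np.ceil(fc).astype(int) - 1
        row = np.ceil(fr).astype(int) - 1
        return np.maximum(row, 0), np.maximum(col, 0)

    def extent(self, shape):
        """(minx, miny, maxx, maxy) of a grid with the given (rows, cols)."""
        rows, cols = shape
        return (self.x0, self.y0 - rows * self.sy, self.x0 + cols * self.sx, self.y0)


@dataclass
class RGBOrthomosaic:
    """3-band georeferenced digital-number grid with a validity mask."""

    bands: np.ndarray                  # (3, rows, cols), integer or float dtype
    transform: GridTransform
    crs: CRS
    nodata_mask: np.ndarray            # (rows, cols) bool, True = invalid
    nodata: float | None = None        # declared nodata DN, if any

    def __post_init__(self):
        if self.bands.ndim != 3 or self.bands.shape[0] != 3:
            raise ValueError("bands must have shape (3, rows, cols)")
        if self.nodata_mask.shape != self.bands.shape[1:]:
            raise ValueError("nodata_mask shape must match band shape")
        if not self.crs.is_projected:
            raise CRSError("projected CRS required")

    @property
    def shape(self):
        return self.bands.shape[1:]

    @property
    def pixel_size(self):
        return (self.transform.sx, self.transform.sy)

    @property
    def valid_mask(self):
        return ~self.nodata_mask

    @property
    def bit_depth(self):
        """Bits per sample for integer data; None for float rasters."""
        dt = self.bands.dtype
        if np.issubdtype(dt, np.integer):
            return dt.itemsize * 8
        return None


@dataclass
class FieldBoundary:
    """Cultivated-area polygon(s) in the raster's projected CRS."""

    geometry: Polygon | MultiPolygon
    crs: CRS | None = None

    def __post_init__(self):
        geom = self.geometry
        if not geom.is_valid:
            geom = geom.buffer(0)
        if isinstance(geom, (Polygon, MultiPolygon)):
            # union also deduplicates overlapping members of a MultiPolygon
            geom = unary_union(geom)
        else:
            raise ValueError(f"boundary must be polygonal, got {geom.geom_type}")
        if geom.is_empty or geom.area <= 0:
            raise ValueError("boundary polygon has zero area")
        self.geometry = geom

    @property
    def area_m2(self) -> float:
        return float(self.geometry.area)


# ---------------------------------------------------------------------------
# GeoKey helpers

def _geokeys_for(crs: CRS) -> tuple:
    model = 1 if crs.is_projected else 2
    keys = [(_KEY_MODEL_TYPE, 0, 1, model)]
    if crs.epsg is not None:
        keys.append((_KEY_PROJECTED_CS, 0, 1, int(crs.epsg)))
    keys.append((_KEY_LINEAR_UNITS, 0, 1, _METRE))
    flat = [1, 1, 0, len(keys)]
    for k in keys:
        flat.extend(k)
    return tuple(flat)


def _parse_geokeys(values) -> CRS:
    values = tuple(int(v) for v in values)
    n = values[3]
    entries = {values[4 + 4 * i]: values[7 + 4 * i] for i in range(n)}
    model = entries.get(_KEY_MODEL_TYPE)
    if model == 2:
        raise CRSError("projected CRS required (raster is in a geographic CRS)")
    if model != 1:
        raise CRSError("projected CRS required (raster CRS is unknown)")
    units = entries.get(_KEY_LINEAR_UNITS, _METRE)
    if units != _METRE:
        raise CRSError(f"projected CRS must use metre units (linear unit code {units})")
    return CRS(epsg=entries.get(_KEY_PROJECTED_CS), is_projected=True)


# ---------------------------------------------------------------------------
# Raster I/O

def load_orthomosaic(path: str | os.PathLike) -> RGBOrthomosaic:
    """Read a GeoTIFF orthomosaic as (R, G, B) digital numbers.

    The file must carry at least three bands and a projected, metre-based
    CRS in its GeoKeys.  Bands beyond the third (e.g. an alpha channel) are
    ignored with a warning.  The nodata mask is seeded from the declared
    GDAL nodata value — a pixel is invalid where *all three* bands equal it —
    and is all-false when no nodata value is declared.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        data = page.asarray()
        if data.ndim == 2:
            raise ValueError("expected ≥3 bands, got 1")
        if data.ndim != 3:
            raise ValueError(f"unsupported raster layout with shape {data.shape}")
        # normalize to band-first layout
        if data.shape[0] <= 8 and data.shape[0] < data.shape[-1]:
            pass  # already (bands, rows, cols)
        elif data.shape[-1] <= 8:
            data = np.moveaxis(data, -1, 0)
        nbands = data.shape[0]
        if nbands < 3:
            raise ValueError(f"expected ≥3 bands, got {nbands}")
        if nbands > 3:
            log.warning("ignoring %d extra band(s) beyond RGB", nbands - 3)
        bands = np.ascontiguousarray(data[:3])

        tags = page.tags
        if _TAG_GEOKEYS not in tags:
            raise CRSError("projected CRS required (no GeoKey directory in file)")
        crs = _parse_geokeys(tags[_TAG_GEOKEYS].value)
        if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
            raise ValueError("GeoTIFF georeference (pixel scale + tiepoint) missing")
        sx, sy = tags[_TAG_PIXEL_SCALE].value[:2]
        tp = tags[_TAG_TIEPOINT].value
        # tiepoint maps raster (i, j) to model (x, y); standard upper-left anchor
        x0 = float(tp[3]) - float(tp[0]) * float(sx)
        y0 = float(tp[4]) + float(tp[1]) * float(sy)
        transform = GridTransform(x0=x0, y0=y0, sx=float(sx), sy=float(sy))

        nodata = None
        if _TAG_GDAL_NODATA in tags:
            raw = tags[_TAG_GDAL_NODATA].value
            try:
                nodata = float(str(raw).strip().strip("\x00"))
            except ValueError:
                nodata = None
    if nodata is not None:
        nodata_mask = np.all(bands == np.array(nodata, dtype=bands.dtype), axis=0)
    else:
        nodata_mask = np.zeros(bands.shape[1:], dtype=bool)
    return RGBOrthomosaic(bands=bands, transform=transform, crs=crs,
                          nodata_mask=nodata_mask, nodata=nodata)


def write_orthomosaic(path: str | os.PathLike, ortho: RGBOrthomosaic) -> None:
    """Write a GeoTIFF preserving georeference and declared nodata."""
    t = ortho.transform
    extratags = [
        (_TAG_PIXEL_SCALE, 'd', 3, (t.sx, t.sy, 0.0)),
        (_TAG_TIEPOINT, 'd', 6, (0.0, 0.0, 0.0, t.x0, t.y0, 0.0)),
    ]
    keys = _geokeys_for(ortho.crs)
    extratags.append((_TAG_GEOKEYS, 'H', len(keys), keys))
    if ortho.nodata is not None:
        nd = ortho.nodata
        nd_str = str(int(nd)) if float(nd).is_integer() else repr(float(nd))
        extratags.append((_TAG_GDAL_NODATA, 's', len(nd_str) + 1, nd_str))
    tifffile.imwrite(path, ortho.bands, photometric='rgb',
                     planarconfig='separate', extratags=extratags)


def write_single_band(path: str | os.PathLike, grid: np.ndarray,
                      transform: GridTransform, crs: CRS,
                      nodata: float | None = None,
                      colormap: np.ndarray | None = None) -> None:
    """Write one band with the source georeference (float or integer).

    ``colormap`` (256×3 uint16) turns an 8-bit band into a palette raster,
    used for the vigor-class map.
    """
    extratags = [
        (_TAG_PIXEL_SCALE, 'd', 3, (transform.sx, transform.sy, 0.0)),
        (_TAG_TIEPOINT, 'd', 6, (0.0, 0.0, 0.0, transform.x0, transform.y0, 0.0)),
    ]
    keys = _geokeys_for(crs)
    extratags.append((_TAG_GEOKEYS, 'H', len(keys), keys))
    if nodata is not None:
        nd_str = ('nan' if isinstance(nodata, float) and math.isnan(nodata)
                  else str(int(nodata)) if float(nodata).is_integer()
                  else repr(float(nodata)))
        extratags.append((_TAG_GDAL_NODATA, 's', len(nd_str) + 1, nd_str))
    kwargs = {}
    if colormap is not None:
        kwargs['colormap'] = colormap
    tifffile.imwrite(path, grid, extratags=extratags, **kwargs)


def read_single_band(path: str | os.PathLike) -> tuple[np.ndarray, GridTransform, CRS]:
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        grid = page.asarray()
        tags = page.tags
        crs = _parse_geokeys(tags[_TAG_GEOKEYS].value)
        sx, sy = tags[_TAG_PIXEL_SCALE].value[:2]
        tp = tags[_TAG_TIEPOINT].value
        transform = GridTransform(x0=float(tp[3]), y0=float(tp[4]),
                                  sx=float(sx), sy=float(sy))
    return grid, transform, crs


# ---------------------------------------------------------------------------
# Vector I/O

def load_boundary(path: str | os.PathLike, crs: CRS | None = None) -> FieldBoundary:
    """Read a field boundary from GeoJSON (Polygon/MultiPolygon features).

    GeoJSON carries no projected-CRS metadata by itself; callers pass the
    raster's CRS (the study convention: one CRS for the whole project).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with open(path) as fh:
        gj = json.load(fh)
    geoms = []
    if gj.get("type") == "FeatureCollection":
        for feat in gj["features"]:
            geoms.append(shape(feat["geometry"]))
    elif gj.get("type") == "Feature":
        geoms.append(shape(gj["geometry"]))
    else:
        geoms.append(shape(gj))
    geom = unary_union(geoms)
    file_crs = _geojson_crs(gj)
    return FieldBoundary(geometry=geom, crs=file_crs if file_crs else crs)


def _geojson_crs(gj) -> CRS | None:
    name = (gj.get("crs") or {}).get("properties", {}).get("name", "")
    if "EPSG::" in name:
        try:
            return CRS(epsg=int(name.rsplit("::", 1)[1]))
        except ValueError:
            return None
    return None


def write_boundary(path: str | os.PathLike, boundary: FieldBoundary) -> None:
    gj = {
        "type": "FeatureCollection",
        "features": [{"type": "Feature", "properties": {},
                      "geometry": mapping(boundary.geometry)}],
    }
    if boundary.crs is not None and boundary.crs.epsg is not None:
        gj["crs"] = {"type": "name",
                     "properties": {"name": f"urn:ogc:def:crs:EPSG::{boundary.crs.epsg}"}}
    with open(path, "w") as fh:
        json.dump(gj, fh)


# ---------------------------------------------------------------------------
# Clipping and pixel geometry

def rasterize_boundary(boundary: FieldBoundary, transform: GridTransform,
                       shape: tuple[int, int]) -> np.ndarray:
    """Boolean grid: True where the pixel *center* falls inside the boundary."""
    rows, cols = shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    x, y = transform.pixel_center(rr.ravel(), cc.ravel())
    inside = shapely.contains_xy(boundary.geometry, x, y)
    return inside.reshape(shape)


def clip_to_boundary(ortho: RGBOrthomosaic, boundary: FieldBoundary) -> RGBOrthomosaic:
    """Set pixels whose centers fall outside the boundary to nodata.

    The georeference is untouched (no resampling, no window cropping), so
    clipping is idempotent and area arithmetic stays exact.
    """
    if boundary.crs is not None and boundary.crs != ortho.crs:
        raise CRSError(
            f"boundary CRS (EPSG:{boundary.crs.epsg}) does not match "
            f"raster CRS (EPSG:{ortho.crs.epsg})")
    extent = box(*ortho.transform.extent(ortho.shape))
    if not boundary.geometry.intersects(extent):
        raise EmptyIntersectionError("empty intersection: boundary does not overlap raster extent")
    inside = rasterize_boundary(boundary, ortho.transform, ortho.shape)
    if not inside.any():
        raise EmptyIntersectionError("empty intersection: no pixel center falls inside boundary")
    nodata = ortho.nodata if ortho.nodata is not None else 0
    bands = ortho.bands.copy()
    bands[:, ~inside] = np.array(nodata, dtype=bands.dtype)
    mask = ortho.nodata_mask | ~inside
    return replace(ortho, bands=bands, nodata_mask=mask, nodata=nodata)


def pixel_area_m2(ortho: RGBOrthomosaic) -> float:
    """Ground area of one pixel in square metres (|x_res × y_res|)."""
    sx, sy = ortho.pixel_size
    return abs(sx * sy)
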