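"""Minimal single-band GeoTIFF reader/writer built on tifffile.

Handles the subset of the GeoTIFF tag set needed for north-up, axis-aligned
population rasters: ModelPixelScale (33550), ModelTiepoint (33922),
ModelTransformation (34264), GDAL_NODATA (42113) and the citation entry of
the GeoKey directory (34735/34737) as an opaque CRS label.  Reprojection is
out of scope; grids must already share a georeference.
"""

from __future__ import annotations

import os
from typing import NamedTuple

import numpy as np
import tifffile

__all__ = ["RasterData", "read_raster", "write_raster"]

TAG_MODEL_PIXEL_SCALE = 33550
TAG_MODEL_TIEPOINT = 33922
TAG_MODEL_TRANSFORMATION = 34264
TAG_GEO_KEY_DIRECTORY = 34735
TAG_GEO_ASCII_PARAMS = 34737
TAG_GDAL_NODATA = 42113

_GT_CITATION_KEY = 1026


class RasterData(NamedTuple):
    """Raw contents of a single-band georeferenced raster."""

    values: np.ndarray  # float64, NaN where nodata
    origin_x: float
    origin_y: float
    cell_width: float
    cell_height: float
    crs_label: str


def _tag_value(page: "tifffile.TiffPage", code: int):
    tag = page.tags.get(code)
    return None if tag is None else tag.value


def _parse_georeference(page) -> tuple[float, float, float, float]:
    scale = _tag_value(page, TAG_MODEL_PIXEL_SCALE)
    tiepoint = _tag_value(page, TAG_MODEL_TIEPOINT)
    if scale is not None and tiepoint is not None:
        sx, sy = float(scale[0]), float(scale[1])
        i, j, _, x, y, _ = (float(v) for v in tiepoint[:6])
        # tiepoint maps raster point (i, j) to map point (x, y); shift to (0, 0)
        origin_x = x - i * sx
        origin_y = y + j * sy
        return origin_x, origin_y, sx, sy
    transform = _tag_value(page, TAG_MODEL_TRANSFORMATION)
    if transform is not None:
        t = [float(v) for v in transform]
        if t[1] != 0.0 or t[4] != 0.0:
            raise ValueError("rotated rasters are not supported")
        if t[0] <= 0 or t[5] >= 0:
            raise ValueError("raster must be north-up with positive cell size")
        return t[3], t[7], t[0], -t[5]
    # Ungeoreferenced TIFF: fall back to unit cells anchored at (0, rows).
    return 0.0, float(page.imagelength), 1.0, 1.0


def _parse_crs_label(page) -> str:
    directory = _tag_value(page, TAG_GEO_KEY_DIRECTORY)
    ascii_params = _tag_value(page, TAG_GEO_ASCII_PARAMS)
    if directory is None or ascii_params is None:
        return ""
    keys = np.asarray(directory).ravel()
    for k in range(4, len(keys) - 3, 4):
        key_id, location, count, offset = keys[k : k + 4]
        if key_id == _GT_CITATION_KEY and location == TAG_GEO_ASCII_PARAMS:
            text = ascii_params[offset : offset + count]
            return text.rstrip("|\x00")
    return ""


def read_raster(path: str | os.PathLike, band: int | None = None) -> RasterData:
    """Read a single-band GeoTIFF into a :class:`RasterData`.

    Nodata cells (per the GDAL nodata tag) become NaN.  Non-finite values that
    are *not* the declared nodata raise, since they would silently corrupt
    population totals downstream.
    """
    with tifffile.TiffFile(os.fspath(path)) as tif:
        page = tif.pages[0]
        data = np.asarray(page.asarray())
        if data.ndim == 3:
            if band is None:
                raise ValueError(
                    f"raster has {data.shape[-1] if data.shape[0] > 8 else data.shape[0]}"
                    " bands; pass an explicit band index"
                )
            data = data[band] if data.shape[0] < data.shape[-1] else data[..., band]
        elif band not in (None, 0):
            raise ValueError("band index given for a single-band raster")
        values = data.astype(np.float64)

        nodata_raw = _tag_value(page, TAG_GDAL_NODATA)
        if nodata_raw is not None:
            nodata = float(str(nodata_raw).strip("\x00 "))
            if np.isnan(nodata):
                pass  # NaN already marks missing
            else:
                values[values == nodata] = np.nan
        if not np.all(np.isfinite(values) | np.isnan(values)):
            raise ValueError("raster contains non-finite values other than nodata")

        origin_x, origin_y, cw, ch = _parse_georeference(page)
        crs_label = _parse_crs_label(page)

    return RasterData(values, origin_x, origin_y, cw, ch, crs_label)


def write_raster(
    path: str | os.PathLike,
    values: np.ndarray,
    origin_x: float,
    origin_y: float,
    cell_width: float,
    cell_height: float,
    crs_label: str = "",
    nodata: float = -9999.0,
) -> None:
    """Write a 2-D array as a single-band GeoTIFF; NaN cells become ``nodata``."""
    arr = np.asarray(values, dtype=np.float64).copy()
    arr[np.isnan(arr)] = nodata

    extratags = [
        (TAG_MODEL_PIXEL_SCALE, "d", 3, (float(cell_width), float(cell_height), 0.0)),
        (TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(origin_x), float(origin_y), 0.0)),
        (TAG_GDAL_NODATA, "s", 0, str(nodata)),
    ]
    if crs_label:
        ascii_params = crs_label + "|"
        directory = (1, 1, 0, 1, _GT_CITATION_KEY, TAG_GEO_ASCII_PARAMS, len(ascii_params), 0)
        extratags.append((TAG_GEO_KEY_DIRECTORY, "H", len(directory), directory))
        extratags.append((TAG_GEO_ASCII_PARAMS, "s", 0, ascii_params))

    tifffile.imwrite(os.fspath(path), arr, extratags=extratags)
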