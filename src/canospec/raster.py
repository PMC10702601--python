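"""GeoTIFF read/write for multiband spectral rasters, and pixel arithmetic.

Geo-referencing uses the ModelPixelScale (33550) + ModelTiepoint (33922)
tags with a north-up geotransform; nodata travels in the GDAL_NODATA ASCII
tag (42113). Band *names* are not a GeoTIFF concept, so the band order is
supplied by the caller (default B, G, R, RE, NIR — the five-lens layout of
the survey camera).
"""

from __future__ import annotations

import os

import numpy as np
import tifffile

from .errors import DegenerateInputError, FormatError
from .types import SpectralRaster

DEFAULT_BANDS = ("B", "G", "R", "RE", "NIR")

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


def write_raster(raster: SpectralRaster, path) -> None:
    """Write ``raster`` as a tiled float64 GeoTIFF (bands in dict order)."""
    data = raster.stack()
    if data.shape[-1] == 1:
        data = data[..., 0]
    px = raster.pixel_size
    x0, y0 = raster.origin
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (px, px, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, y0, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(raster.nodata)),
    ]
    tifffile.imwrite(
        path, data, photometric="minisblack",
        planarconfig="contig" if data.ndim == 3 else None,
        extratags=extratags,
    )


def read_raster(path, band_names=DEFAULT_BANDS) -> SpectralRaster:
    """Read a GeoTIFF; band names taken from ``band_names`` in file order."""
    if not os.path.exists(path):
        raise FormatError(f"no such raster: {path}")
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray()
        scale_tag = page.tags.get(_TAG_PIXEL_SCALE)
        tie_tag = page.tags.get(_TAG_TIEPOINT)
        nodata_tag = page.tags.get(_TAG_GDAL_NODATA)
        scale_val = None if scale_tag is None else tuple(scale_tag.value)
        tie_val = None if tie_tag is None else tuple(tie_tag.value)
        nodata_val = None if nodata_tag is None else str(nodata_tag.value)
    if data.ndim == 2:
        data = data[..., None]
    n_bands = data.shape[-1]
    if n_bands != len(band_names):
        raise FormatError(
            f"raster has {n_bands} band(s) but the band mapping names {len(band_names)}"
        )
    if scale_val is None or tie_val is None:
        raise FormatError(f"raster {path} lacks geo-referencing tags")
    px = float(scale_val[0])
    origin = (float(tie_val[3]), float(tie_val[4]))
    nodata = float(nodata_val) if nodata_val is not None else -9999.0
    bands = {name: np.asarray(data[..., i], dtype=np.float64)
             for i, name in enumerate(band_names)}
    return SpectralRaster(bands=bands, origin=origin, pixel_size=px, nodata=nodata)


def map_to_pixel(raster: SpectralRaster, x, y):
    """Map coordinates -> 0-based (row, col) under half-open pixel squares.

    Pixel (0, 0) covers [x0, x0+px) x (y0-px, y0]; rows grow as Y decreases.
    Returns integer arrays; indices may fall outside the raster extent — use
    :func:`in_bounds` to test.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    col = np.floor((x - raster.origin[0]) / raster.pixel_size).astype(np.int64)
    row = np.floor((raster.origin[1] - y) / raster.pixel_size).astype(np.int64)
    return row, col


def in_bounds(raster: SpectralRaster, row, col) -> np.ndarray:
    return (np.asarray(row) >= 0) & (np.asarray(row) < raster.height) \
        & (np.asarray(col) >= 0) & (np.asarray(col) < raster.width)


def sample_band(raster: SpectralRaster, band: str, row, col, method: str = "nearest"):
    """Sample one band at fractional (row, col); integers are cell centers.

    "nearest" returns the stored cell value; "bilinear" the convex
    combination of the four surrounding cell centers. Any nodata neighbor
    makes the bilinear result nodata (nodata propagation).
    """
    grid = raster.band(band)
    row = np.asarray(row, dtype=np.float64)
    col = np.asarray(col, dtype=np.float64)
    if method == "nearest":
        r = np.rint(row).astype(np.int64)
        c = np.rint(col).astype(np.int64)
        if np.any(~in_bounds(raster, r, c)):
            raise DegenerateInputError("nearest sample outside raster extent")
        return grid[r, c]
    if method == "bilinear":
        r0 = np.clip(np.floor(row).astype(np.int64), 0, raster.height - 2)
        c0 = np.clip(np.floor(col).astype(np.int64), 0, raster.width - 2)
        if np.any((row < 0) | (row > raster.height - 1) | (col < 0) | (col > raster.width - 1)):
            raise DegenerateInputError("bilinear sample outside raster interior")
        fr = row - r0
        fc = col - c0
        q = np.stack([grid[r0, c0], grid[r0, c0 + 1], grid[r0 + 1, c0], grid[r0 + 1, c0 + 1]])
        w = np.stack([(1 - fr) * (1 - fc), (1 - fr) * fc, fr * (1 - fc), fr * fc])
        out = np.sum(q * w, axis=0)
        bad = np.any(q == raster.nodata, axis=0)
        return np.where(bad, raster.nodata, out)
    raise DegenerateInputError(f"unknown resampling method {method!r}")
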