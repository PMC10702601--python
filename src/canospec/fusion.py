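"""Point-image fusion: collinearity projection and spectral attachment.

Two modes produce the seven-attribute fused record (X, Y, Z, R, G, B, NIR):

* ``ortho`` (default): the raster is a planimetric orthomosaic, so each
  point is looked up directly at its (X, Y) map position. Orthomosaics have
  no single perspective center, which is why this is the default.
* ``perspective``: the raster is a single camera frame; ground points are
  projected through the collinearity equations
      x = -f * (a1 dX + b1 dY + c1 dZ) / (a3 dX + b3 dY + c3 dZ)
      y = -f * (a2 dX + b2 dY + c2 dZ) / (a3 dX + b3 dY + c3 dZ)
  with (dX, dY, dZ) = P - S and a1..c3 the omega-phi-kappa rotation rows,
  then sampled on the image-plane pixel grid.

Points mapping outside the raster or onto nodata are dropped and counted;
fusion never invents values — every attached NIR equals a raster sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, ProjectionError
from .raster import in_bounds, map_to_pixel
from .types import CameraModel, PointCloud, SpectralRaster, rotation_matrix

__all__ = ["rotation_matrix", "collinearity_project", "fuse", "FuseStats"]

_EPS_DENOM = 1e-12


def collinearity_project(camera: CameraModel, x, y, z):
    """Project ground coordinates to image-plane (x, y) in meters.

    Raises :class:`ProjectionError` when a point lies on or behind the
    perspective plane (denominator >= 0 under the aerial convention of a
    camera z-axis pointing up and the scene below).
    """
    dx = np.asarray(x, dtype=np.float64) - camera.xs
    dy = np.asarray(y, dtype=np.float64) - camera.ys
    dz = np.asarray(z, dtype=np.float64) - camera.zs
    m = camera.rotation
    num_x = m[0, 0] * dx + m[0, 1] * dy + m[0, 2] * dz
    num_y = m[1, 0] * dx + m[1, 1] * dy + m[1, 2] * dz
    den = m[2, 0] * dx + m[2, 1] * dy + m[2, 2] * dz
    if np.any(np.abs(den) < _EPS_DENOM):
        raise ProjectionError("point on the perspective plane of the camera")
    if np.any(den > 0):
        raise ProjectionError("point behind the camera")
    xi = -camera.f * num_x / den - camera.x0
    yi = -camera.f * num_y / den - camera.y0
    return xi, yi


def image_plane_to_pixel(camera: CameraModel, xi, yi):
    """Fractional (row, col) on the camera's pixel grid; integer = cell center.

    The principal point sits at the grid center; image-plane +y points up
    (rows grow downward), +x right.
    """
    col = np.asarray(xi) / camera.pixel_pitch + (camera.width - 1) / 2.0
    row = (camera.height - 1) / 2.0 - np.asarray(yi) / camera.pixel_pitch
    return row, col


@dataclass
class FuseStats:
    n_input: int
    n_fused: int
    n_outside: int
    n_nodata: int


def fuse(
    points: PointCloud,
    raster: SpectralRaster,
    camera: CameraModel | None = None,
    mode: str = "ortho",
    resample: str = "nearest",
    rgb_from_image: bool = False,
    nir_band: str = "NIR",
):
    """Attach spectral values to (visibility-filtered) points.

    Returns ``(fused_cloud, stats)``; raises when no point survives.
    """
    if mode not in ("ortho", "perspective"):
        raise DegenerateInputError(f"unknown fusion mode {mode!r}")
    if mode == "perspective" and camera is None:
        raise DegenerateInputError("perspective fusion requires a camera model")
    n = len(points)
    if n == 0:
        raise DegenerateInputError("empty input cloud")

    if mode == "ortho":
        row, col = map_to_pixel(raster, points.x, points.y)
        rowf, colf = row.astype(np.float64), col.astype(np.float64)
    else:
        xi, yi = collinearity_project(camera, points.x, points.y, points.z)
        rowf, colf = image_plane_to_pixel(camera, xi, yi)
        row = np.rint(rowf).astype(np.int64)
        col = np.rint(colf).astype(np.int64)
        # perspective grid is detached from the raster geotransform: the
        # raster is interpreted as the camera image itself
        row = np.clip(row, -1, raster.height)
        col = np.clip(col, -1, raster.width)

    inside = in_bounds(raster, row, col)
    n_outside = int(np.sum(~inside))

    r_in = row[inside]
    c_in = col[inside]
    grid = raster.band(nir_band)
    if resample == "nearest":
        nir = grid[r_in, c_in]
    elif resample == "bilinear":
        from .raster import sample_band

        rr = np.clip(rowf[inside], 0, raster.height - 1)
        cc = np.clip(colf[inside], 0, raster.width - 1)
        nir = sample_band(raster, nir_band, rr, cc, method="bilinear")
    else:
        raise DegenerateInputError(f"unknown resampling method {resample!r}")

    valid = nir != raster.nodata
    n_nodata = int(np.sum(~valid))
    keep_idx = np.flatnonzero(inside)[valid]
    if keep_idx.size == 0:
        raise DegenerateInputError("fusion retained zero points")

    fused = points.subset(keep_idx).with_(nir=nir[valid])
    if rgb_from_image:
        rk, ck = r_in[valid], c_in[valid]
        fused = fused.with_(
            r=raster.band("R")[rk, ck],
            g=raster.band("G")[rk, ck],
            b=raster.band("B")[rk, ck],
        )
    stats = FuseStats(n_input=n, n_fused=int(keep_idx.size),
                      n_outside=n_outside, n_nodata=n_nodata)
    return fused, stats
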