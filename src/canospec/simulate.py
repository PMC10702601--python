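"""Synthetic three-class forest stands with ground-truth NIR.

The simulator emulates the survey conditions the pipeline was designed for:
a 20 m x 20 m *Pinus*-type plot holding conical tree crowns over a gently
undulating ground, with bare-land and grass regions. Per-point NIR follows
the observed field pattern — canopy NIR decays linearly with 3-D distance
from the tree apex; bare land is a single spectral mode; grass a two-mode
mixture — and RGB is linearly coupled to NIR within each class so that the
color channels carry recoverable spectral signal, as in the field data.

It also renders the matching orthoimage (per-cell max-Z winner) and the
nadir flight-grid viewpoints at survey altitude (80 m).
"""

from __future__ import annotations

import numpy as np

from .errors import DegenerateInputError
from .types import (
    CLASS_GRASS, CLASS_LAND, CLASS_TREE,
    GroundTruthScene, PointCloud, SceneConfig, SpectralRaster,
)

__all__ = ["generate_stand", "render_orthoimage", "flight_grid_viewpoints"]


def _ground_z(cfg: SceneConfig, x, y, rng) -> np.ndarray:
    wx, wy = cfg.plot_size
    base = cfg.ground_amplitude * np.sin(2 * np.pi * x / wx) * np.sin(2 * np.pi * y / wy)
    return base + rng.normal(0.0, cfg.ground_roughness, size=np.shape(x))


def _grass_patches(cfg: SceneConfig, rng):
    wx, wy = cfg.plot_size
    centers = rng.uniform([0, 0], [wx, wy], size=(cfg.n_grass_patches, 2))
    radii = rng.uniform(*cfg.grass_patch_radius, size=cfg.n_grass_patches)
    return centers, radii


def _in_patches(xy, centers, radii) -> np.ndarray:
    d2 = ((xy[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
    return np.any(d2 <= radii[None, :] ** 2, axis=1)


def _sample_region(cfg, rng, n, centers, radii, inside: bool) -> np.ndarray:
    """Rejection-sample n XY points inside (grass) or outside (land) patches."""
    wx, wy = cfg.plot_size
    out = np.empty((0, 2))
    for _ in range(200):
        if len(out) >= n:
            break
        cand = rng.uniform([0, 0], [wx, wy], size=(max(4 * n, 256), 2))
        keep = _in_patches(cand, centers, radii)
        if not inside:
            keep = ~keep
        out = np.vstack([out, cand[keep]])
    if len(out) < n:
        raise DegenerateInputError("grass-patch layout leaves too little area for a class")
    return out[:n]


def _rgb_for(cfg: SceneConfig, class_id: int, nir: np.ndarray, ref: float, rng):
    base = np.asarray(cfg.base_colors[class_id], dtype=np.float64)
    gain = np.asarray(cfg.rgb_nir_gain, dtype=np.float64)
    shift = (nir - ref)[:, None] * gain[None, :]
    noise = rng.normal(0.0, cfg.rgb_noise_sd, size=(nir.size, 3))
    return np.clip(base[None, :] + shift + noise, 0.0, cfg.rgb_max)


def generate_stand(config: SceneConfig | None = None, seed: int = 0) -> GroundTruthScene:
    """Generate a ground-truth stand; bit-identical for a fixed seed.

    Canopy points sample conical crown shells (with a sparse interior
    fraction mimicking sub-canopy laser returns); their NIR is
    ``apex_value - slope * dist3d(point, apex)`` plus Gaussian noise.
    """
    cfg = config or SceneConfig()
    rng = np.random.default_rng(seed)
    n_tree, n_land, n_grass = (int(c) for c in cfg.class_counts)
    wx, wy = cfg.plot_size

    # --- trees ---------------------------------------------------------
    margin = cfg.crown_radius[1]
    apices = rng.uniform([margin, margin], [wx - margin, wy - margin], size=(cfg.n_trees, 2))
    heights = rng.uniform(*cfg.apex_height, size=cfg.n_trees)
    radii = rng.uniform(*cfg.crown_radius, size=cfg.n_trees)
    depths = rng.uniform(*cfg.crown_depth, size=cfg.n_trees)
    trees = [
        {"apex": np.array([apices[i, 0], apices[i, 1], heights[i]]),
         "radius": float(radii[i]), "depth": float(depths[i])}
        for i in range(cfg.n_trees)
    ]
    weights = radii ** 2 / (radii ** 2).sum()
    tree_of = rng.choice(cfg.n_trees, size=n_tree, p=weights)

    t = rng.uniform(0.0, 1.0, size=n_tree)          # 0 = apex, 1 = crown base
    theta = rng.uniform(0.0, 2 * np.pi, size=n_tree)
    interior = rng.uniform(size=n_tree) < cfg.interior_fraction
    radial = np.where(interior, np.sqrt(rng.uniform(size=n_tree)), 1.0)
    r_pt = t * radii[tree_of] * radial
    tx = apices[tree_of, 0] + r_pt * np.cos(theta)
    ty = apices[tree_of, 1] + r_pt * np.sin(theta)
    tz = heights[tree_of] - t * depths[tree_of]
    apex_dist = np.sqrt(
        (tx - apices[tree_of, 0]) ** 2 + (ty - apices[tree_of, 1]) ** 2
        + (tz - heights[tree_of]) ** 2
    )
    tree_nir = (cfg.canopy_nir_apex - cfg.canopy_nir_slope * apex_dist
                + rng.normal(0.0, cfg.nir_noise_sd, size=n_tree))

    # --- ground: grass patches vs bare land ----------------------------
    centers, patch_r = _grass_patches(cfg, rng)
    land_xy = _sample_region(cfg, rng, n_land, centers, patch_r, inside=False)
    grass_xy = _sample_region(cfg, rng, n_grass, centers, patch_r, inside=True)
    land_z = _ground_z(cfg, land_xy[:, 0], land_xy[:, 1], rng)
    grass_z = _ground_z(cfg, grass_xy[:, 0], grass_xy[:, 1], rng) + rng.uniform(
        0.05, 0.35, size=n_grass
    )
    land_nir = rng.normal(cfg.land_nir_mode, cfg.land_nir_sd, size=n_land)
    comp = rng.choice(len(cfg.grass_nir_modes), size=n_grass, p=np.asarray(cfg.grass_nir_weights))
    grass_nir = rng.normal(np.asarray(cfg.grass_nir_modes)[comp], cfg.grass_nir_sd)

    # --- colors --------------------------------------------------------
    canopy_ref = cfg.canopy_nir_apex - cfg.canopy_nir_slope * float(np.mean(apex_dist))
    rgb_tree = _rgb_for(cfg, CLASS_TREE, tree_nir, canopy_ref, rng)
    rgb_land = _rgb_for(cfg, CLASS_LAND, land_nir, cfg.land_nir_mode, rng)
    grass_ref = float(np.dot(cfg.grass_nir_modes, cfg.grass_nir_weights))
    rgb_grass = _rgb_for(cfg, CLASS_GRASS, grass_nir, grass_ref, rng)

    x = np.concatenate([tx, land_xy[:, 0], grass_xy[:, 0]])
    y = np.concatenate([ty, land_xy[:, 1], grass_xy[:, 1]])
    z = np.concatenate([tz, land_z, grass_z])
    nir = np.concatenate([tree_nir, land_nir, grass_nir])
    rgb = np.vstack([rgb_tree, rgb_land, rgb_grass])
    class_id = np.concatenate([
        np.full(n_tree, CLASS_TREE), np.full(n_land, CLASS_LAND), np.full(n_grass, CLASS_GRASS),
    ])
    tree_id = np.concatenate([tree_of + 1, np.zeros(n_land + n_grass, dtype=np.int64)])

    cloud = PointCloud(
        x=x, y=y, z=z, r=rgb[:, 0], g=rgb[:, 1], b=rgb[:, 2],
        nir=nir, class_id=class_id, tree_id=tree_id,
    )
    if len(cloud) == 0:
        raise DegenerateInputError("configuration produced an empty scene")
    return GroundTruthScene(cloud=cloud, trees=trees, config=cfg)


def render_orthoimage(cloud: PointCloud, gsd: float = 0.01,
                      extent=None, nodata: float = -9999.0) -> SpectralRaster:
    """Render the nadir orthoimage: each cell shows its highest point.

    Bands are B, G, R (point colors), RE (0.85 x NIR, a plumbing band) and
    NIR, all taken from the maximum-Z point falling in the cell; empty
    cells hold ``nodata``.
    """
    if gsd <= 0:
        raise DegenerateInputError("gsd must be positive")
    if len(cloud) == 0:
        return SpectralRaster(
            bands={k: np.full((1, 1), nodata) for k in ("B", "G", "R", "RE", "NIR")},
            origin=(0.0, 0.0), pixel_size=gsd, nodata=nodata,
        )
    if extent is None:
        extent = (cloud.x.min(), cloud.y.min(), cloud.x.max(), cloud.y.max())
    xmin, ymin, xmax, ymax = extent
    width = max(int(np.ceil((xmax - xmin) / gsd)), 1)
    height = max(int(np.ceil((ymax - ymin) / gsd)), 1)
    origin = (float(xmin), float(ymin + height * gsd))

    col = np.clip(np.floor((cloud.x - origin[0]) / gsd).astype(np.int64), 0, width - 1)
    row = np.clip(np.floor((origin[1] - cloud.y) / gsd).astype(np.int64), 0, height - 1)
    cell = row * width + col
    order = np.lexsort((cloud.z, cell))          # by cell, then ascending Z
    last = np.ones(len(order), dtype=bool)
    last[:-1] = cell[order][1:] != cell[order][:-1]
    win = order[last]                            # max-Z winner per occupied cell

    bands = {k: np.full((height, width), nodata) for k in ("B", "G", "R", "RE", "NIR")}
    rw, cw = row[win], col[win]
    if cloud.has_rgb:
        bands["B"][rw, cw] = cloud.b[win]
        bands["G"][rw, cw] = cloud.g[win]
        bands["R"][rw, cw] = cloud.r[win]
    if cloud.nir is not None:
        bands["NIR"][rw, cw] = cloud.nir[win]
        bands["RE"][rw, cw] = 0.85 * cloud.nir[win]
    return SpectralRaster(bands=bands, origin=origin, pixel_size=gsd, nodata=nodata)


def flight_grid_viewpoints(extent, spacing: float = 10.0, altitude: float = 80.0) -> np.ndarray:
    """Regular nadir view grid covering ``extent`` at ``altitude`` (m AGL).

    ``extent`` is (xmin, ymin, xmax, ymax); returns an (n, 3) array. A 20 m
    plot with 10 m spacing yields the 3 x 3 grid of simulated UAV stations.
    """
    if spacing <= 0:
        raise DegenerateInputError("spacing must be positive")
    xmin, ymin, xmax, ymax = extent
    xs = np.arange(xmin, xmax + spacing * 1e-9, spacing)
    ys = np.arange(ymin, ymax + spacing * 1e-9, spacing)
    if xs.size == 0 or xs[-1] < xmax - 1e-9:
        xs = np.append(xs, xmax)
    if ys.size == 0 or ys[-1] < ymax - 1e-9:
        ys = np.append(ys, ymax)
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel(), np.full(gx.size, float(altitude))])
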