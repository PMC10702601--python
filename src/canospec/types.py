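"""Core in-memory containers: point clouds, multiband rasters, camera models.

Conventions
-----------
* Coordinates are meters in a projected CRS; Z is height.
* Class ids: 1 = tree (canopy), 2 = bare land, 3 = grass.
* NIR is a grayscale value in raster units (the field data prints ~7-14).
* Pseudo-labels are 1-based ranks of K-means NIR centers, ascending in NIR.
* Angles are radians internally; configs may declare degrees.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace
from typing import Optional, Sequence

import numpy as np

from .errors import DegenerateInputError

CLASS_TREE = 1
CLASS_LAND = 2
CLASS_GRASS = 3
CLASS_NAMES = {CLASS_TREE: "tree", CLASS_LAND: "land", CLASS_GRASS: "grass"}


def _as_f8(a) -> np.ndarray:
    return np.ascontiguousarray(np.asarray(a, dtype=np.float64))


@dataclass
class PointCloud:
    """Columnar point cloud; optional attributes are ``None`` when absent.

    The fused record carries the seven attributes (X, Y, Z, R, G, B, NIR)
    plus optional ground-class id, tree id and NIR pseudo-label.
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    r: Optional[np.ndarray] = None
    g: Optional[np.ndarray] = None
    b: Optional[np.ndarray] = None
    nir: Optional[np.ndarray] = None
    nir_true: Optional[np.ndarray] = None  # simulator ground truth, when known
    class_id: Optional[np.ndarray] = None
    tree_id: Optional[np.ndarray] = None
    label: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.x = _as_f8(self.x)
        self.y = _as_f8(self.y)
        self.z = _as_f8(self.z)
        n = self.x.size
        if self.y.size != n or self.z.size != n:
            raise DegenerateInputError("coordinate arrays have unequal lengths")
        if n and not np.all(np.isfinite(self.z)):
            raise DegenerateInputError("non-finite Z coordinate")
        for name in ("r", "g", "b", "nir", "nir_true"):
            v = getattr(self, name)
            if v is not None:
                v = _as_f8(v)
                if v.size != n:
                    raise DegenerateInputError(f"attribute {name!r} length mismatch")
                setattr(self, name, v)
        for name in ("class_id", "tree_id", "label"):
            v = getattr(self, name)
            if v is not None:
                v = np.ascontiguousarray(np.asarray(v, dtype=np.int64))
                if v.size != n:
                    raise DegenerateInputError(f"attribute {name!r} length mismatch")
                setattr(self, name, v)
        if self.label is not None and self.label.size and self.label.min() < 1:
            raise DegenerateInputError("pseudo-labels must be >= 1")

    def __len__(self) -> int:
        return self.x.size

    @property
    def has_rgb(self) -> bool:
        return self.r is not None and self.g is not None and self.b is not None

    @property
    def xyz(self) -> np.ndarray:
        return np.column_stack([self.x, self.y, self.z])

    def subset(self, idx) -> "PointCloud":
        """New cloud restricted to ``idx`` (indices or boolean mask)."""
        kw = {}
        for f in fields(self):
            v = getattr(self, f.name)
            kw[f.name] = None if v is None else v[idx]
        return PointCloud(**kw)

    def with_(self, **kw) -> "PointCloud":
        return replace(self, **kw)

    def attr(self, name: str) -> np.ndarray:
        v = getattr(self, name)
        if v is None:
            raise DegenerateInputError(f"point cloud has no attribute {name!r}")
        return v


@dataclass
class SpectralRaster:
    """North-up georeferenced multiband raster.

    ``origin`` is the map coordinate of the *top-left corner* of pixel (0, 0);
    rows grow with decreasing Y, columns with increasing X. Pixels are square
    with side ``pixel_size`` meters (0.01 m at full survey scale).
    """

    bands: dict
    origin: tuple
    pixel_size: float
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise DegenerateInputError("pixel size must be positive")
        shapes = {b.shape for b in self.bands.values()}
        if len(shapes) > 1:
            raise DegenerateInputError("bands have differing shapes")
        self.bands = {k: np.asarray(v, dtype=np.float64) for k, v in self.bands.items()}
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    @property
    def band_names(self) -> list:
        return list(self.bands)

    @property
    def shape(self) -> tuple:
        return next(iter(self.bands.values())).shape

    @property
    def height(self) -> int:
        return self.shape[0]

    @property
    def width(self) -> int:
        return self.shape[1]

    @property
    def extent(self) -> tuple:
        """(xmin, ymin, xmax, ymax) in map units."""
        x0, y0 = self.origin
        return (x0, y0 - self.height * self.pixel_size, x0 + self.width * self.pixel_size, y0)

    def band(self, name: str) -> np.ndarray:
        return self.bands[name]

    def stack(self) -> np.ndarray:
        """(H, W, C) array in band order."""
        return np.stack([self.bands[k] for k in self.bands], axis=-1)


def rotation_matrix(omega: float, phi: float, kappa: float) -> np.ndarray:
    """Photogrammetric omega-phi-kappa rotation, R = Rz(kappa) @ Ry(phi) @ Rx(omega).

    Rows are (a1, b1, c1), (a2, b2, c2), (a3, b3, c3): the matrix maps
    ground-frame offsets (P - S) into the camera frame.
    """
    co, so = np.cos(omega), np.sin(omega)
    cp, sp = np.cos(phi), np.sin(phi)
    ck, sk = np.cos(kappa), np.sin(kappa)
    rx = np.array([[1, 0, 0], [0, co, -so], [0, so, co]])
    ry = np.array([[cp, 0, sp], [0, 1, 0], [-sp, 0, cp]])
    rz = np.array([[ck, -sk, 0], [sk, ck, 0], [0, 0, 1]])
    return rz @ ry @ rx


@dataclass
class CameraModel:
    """Interior + exterior orientation of a frame camera.

    f: focal length (m); (xs, ys, zs): projection center (m);
    (omega, phi, kappa): attitude angles (rad); pixel_pitch: m/pixel on the
    image plane; (x0, y0): principal-point offset (m); width/height: pixels.
    """

    f: float
    xs: float
    ys: float
    zs: float
    omega: float = 0.0
    phi: float = 0.0
    kappa: float = 0.0
    pixel_pitch: float = 1e-5
    x0: float = 0.0
    y0: float = 0.0
    width: int = 1000
    height: int = 1000

    def __post_init__(self) -> None:
        if self.f <= 0:
            raise DegenerateInputError("focal length must be positive")

    @property
    def position(self) -> np.ndarray:
        return np.array([self.xs, self.ys, self.zs], dtype=np.float64)

    @property
    def rotation(self) -> np.ndarray:
        return rotation_matrix(self.omega, self.phi, self.kappa)


@dataclass
class ClusterCodebook:
    """Sorted K-means NIR centers with the 1..K ascending pseudo-label map.

    Encoding assigns each NIR value the rank of its nearest center
    (1 = lowest center); an exactly equidistant value takes the lower label.
    Decoding maps a label back to its center, inverting the quantization.
    """

    centers: np.ndarray
    sse_history: Optional[dict] = None

    def __post_init__(self) -> None:
        self.centers = np.sort(np.asarray(self.centers, dtype=np.float64).ravel())
        if self.centers.size == 0:
            raise DegenerateInputError("codebook needs at least one center")
        if self.centers.size > 1 and np.any(np.diff(self.centers) <= 0):
            raise DegenerateInputError("codebook centers must be strictly increasing")

    @property
    def n_clusters(self) -> int:
        return int(self.centers.size)

    def encode(self, values) -> np.ndarray:
        values = np.asarray(values, dtype=np.float64)
        if not np.all(np.isfinite(values)):
            raise DegenerateInputError("cannot encode non-finite NIR")
        mid = (self.centers[:-1] + self.centers[1:]) / 2.0
        # side='left': a value equal to a midpoint falls to the lower label
        return np.searchsorted(mid, values, side="left").astype(np.int64) + 1

    def decode(self, labels) -> np.ndarray:
        labels = np.asarray(labels, dtype=np.int64)
        if labels.size and (labels.min() < 1 or labels.max() > self.n_clusters):
            raise DegenerateInputError("label outside codebook range")
        return self.centers[labels - 1]

    def to_json(self, path) -> None:
        obj = {"centers": self.centers.tolist()}
        if self.sse_history is not None:
            obj["sse_history"] = {str(k): float(v) for k, v in self.sse_history.items()}
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ClusterCodebook":
        with open(path) as fh:
            obj = json.load(fh)
        hist = obj.get("sse_history")
        if hist is not None:
            hist = {int(k): float(v) for k, v in hist.items()}
        return cls(np.asarray(obj["centers"]), hist)


@dataclass
class SceneConfig:
    """Parameters of the synthetic 20 m x 20 m three-class stand.

    Class point counts default to one tenth of the densest field plot
    (tree/land/grass = 108857/75722/83014 -> 10886/7572/8301). Canopy NIR
    decays linearly from each tree apex (apex value minus slope times 3-D
    apex distance, plus Gaussian noise); bare land NIR is unimodal and grass
    NIR a two-component mixture, with modes ordered land < canopy < grass.
    """

    plot_size: tuple = (20.0, 20.0)
    n_trees: int = 7
    class_counts: tuple = (10886, 7572, 8301)  # tree, land, grass
    apex_height: tuple = (6.0, 10.0)
    crown_radius: tuple = (1.5, 2.5)
    crown_depth: tuple = (3.0, 5.0)
    interior_fraction: float = 0.25
    canopy_nir_apex: float = 11.3
    canopy_nir_slope: float = 0.30  # NIR units per meter of apex distance
    nir_noise_sd: float = 0.15
    land_nir_mode: float = 7.96
    land_nir_sd: float = 0.25
    grass_nir_modes: tuple = (12.03, 13.46)
    grass_nir_weights: tuple = (0.55, 0.45)
    grass_nir_sd: float = 0.25
    ground_amplitude: float = 0.3
    ground_roughness: float = 0.03
    n_grass_patches: int = 6
    grass_patch_radius: tuple = (2.0, 4.0)
    base_colors: dict = field(
        default_factory=lambda: {
            CLASS_TREE: (40.0, 90.0, 45.0),
            CLASS_LAND: (150.0, 115.0, 85.0),
            CLASS_GRASS: (95.0, 160.0, 75.0),
        }
    )
    rgb_nir_gain: tuple = (8.0, 12.0, 8.0)  # color shift per NIR unit
    rgb_noise_sd: float = 5.0
    rgb_max: float = 255.0

    def __post_init__(self) -> None:
        if min(self.class_counts) <= 0:
            raise DegenerateInputError("class counts must be positive")
        if self.plot_size[0] <= 0 or self.plot_size[1] <= 0:
            raise DegenerateInputError("plot size must be positive")
        modes = (self.land_nir_mode, self.canopy_nir_apex, *self.grass_nir_modes)
        if not self.land_nir_mode < self.canopy_nir_apex:
            raise DegenerateInputError(f"NIR modes must order land < canopy: {modes}")


@dataclass
class GroundTruthScene:
    """Simulator output: ground-truth cloud plus per-tree geometry.

    ``cloud.nir`` holds the true NIR; ``trees`` is a list of dicts with keys
    apex (3,), radius, depth, giving the generating crown geometry.
    """

    cloud: PointCloud
    trees: list
    config: SceneConfig

    @property
    def extent(self) -> tuple:
        return (
            float(self.cloud.x.min()), float(self.cloud.y.min()),
            float(self.cloud.x.max()), float(self.cloud.y.max()),
        )
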