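"""Containers and file I/O for section stacks, scalar volumes and attributed meshes.

Conventions used throughout the package:

* Volumes are indexed ``(z, y, x)`` with voxel spacing stored in the same
  order, in micrometres.  The world position of voxel ``(k, j, i)`` is
  ``(i * sx, j * sy, k * sz)`` — i.e. the centre of voxel (0, 0, 0) is the
  world origin.
* Mesh vertices are stored as ``(x, y, z)`` columns in micrometres.
* Images keep scanner orientation: row 0 is the top of the slide scan and
  no axis is flipped on read or write.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import imageio.v3 as iio
import tifffile
import trimesh
import yaml

log = logging.getLogger(__name__)

__all__ = [
    "SectionStack",
    "ScalarVolume",
    "SurfaceMesh",
    "PipelineConfig",
    "read_stack",
    "write_volume",
    "read_volume",
    "write_mesh",
    "read_mesh",
    "index_to_world",
    "volume_gigabytes",
]


class DimensionError(ValueError):
    """Raised when slices of a stack disagree in shape."""


@dataclass
class SectionStack:
    """Ordered, registered RGB serial sections with spatial metadata.

    Parameters
    ----------
    slices : list of (H, W, 3) uint8 arrays
        One RGB image per physical section, already registered.
    xy_spacing : float
        In-plane sampling, micrometres per pixel.
    z_spacing : float
        Physical section thickness, micrometres per section.
    names : list of str, optional
        Per-slice identifiers (defaults to zero-padded indices).
    """

    slices: list[np.ndarray]
    xy_spacing: float
    z_spacing: float
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.slices) < 1:
            raise ValueError("a SectionStack needs at least one slice")
        if self.xy_spacing <= 0 or self.z_spacing <= 0:
            raise ValueError("spacings must be positive")
        shape0 = self.slices[0].shape
        for i, s in enumerate(self.slices):
            if s.ndim != 3 or s.shape[2] != 3:
                raise DimensionError(f"slice {i} is not an RGB image: shape {s.shape}")
            if s.shape != shape0:
                raise DimensionError(
                    f"slice {i} shape {s.shape[:2]} differs from slice 0 {shape0[:2]}"
                )
        if not self.names:
            self.names = [f"{i:04d}" for i in range(len(self.slices))]

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of every slice."""
        return self.slices[0].shape[:2]

    def as_array(self) -> np.ndarray:
        """Stack slices into a (z, y, x, 3) array."""
        return np.stack(self.slices, axis=0)


@dataclass
class ScalarVolume:
    """8-bit scalar field on an anisotropic voxel grid, axes (z, y, x)."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3-D (z, y, x)")
        if self.data.dtype != np.uint8:
            if self.data.min() < 0 or self.data.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            self.data = self.data.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive values (z, y, x)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def extent_um(self) -> tuple[float, float, float]:
        """Physical extent (x, y, z) in μm spanned by voxel centres."""
        nz, ny, nx = self.data.shape
        sz, sy, sx = self.spacing
        return ((nx - 1) * sx, (ny - 1) * sy, (nz - 1) * sz)

    def world_bounds(self) -> np.ndarray:
        """(2, 3) array of [min, max] world coordinates (x, y, z) in μm."""
        ex, ey, ez = self.extent_um()
        return np.array([[0.0, 0.0, 0.0], [ex, ey, ez]])


def index_to_world(index: Sequence[float], spacing: Sequence[float]) -> np.ndarray:
    """Map a volume index (k, j, i) to a world position (x, y, z) in μm.

    ``spacing`` is (z, y, x) μm per voxel; the centre of voxel (0, 0, 0)
    is the world origin.
    """
    k, j, i = index
    sz, sy, sx = spacing
    return np.array([i * sx, j * sy, k * sz], dtype=float)


@dataclass
class SurfaceMesh:
    """Triangle mesh in μm coordinates with optional per-vertex attributes.

    ``vertex_attrs`` maps names (``sdf_um``, ``obscurance``, ``distance_um``,
    ``component_id``, ``cut_surface``, ``repaired`` ...) to length-N arrays;
    ``colors`` is an optional (N, 3) uint8 RGB array.
    """

    vertices: np.ndarray
    faces: np.ndarray
    vertex_attrs: dict[str, np.ndarray] = field(default_factory=dict)
    colors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        n = len(self.vertices)
        if n and not np.isfinite(self.vertices).all():
            raise ValueError("mesh vertices contain NaN/inf positions")
        if len(self.faces) and (self.faces.min() < 0 or self.faces.max() >= n):
            raise ValueError("face indices out of range")
        for name, arr in self.vertex_attrs.items():
            arr = np.asarray(arr)
            if len(arr) != n:
                raise ValueError(f"attribute {name!r} has length {len(arr)} != {n}")
            self.vertex_attrs[name] = arr
        if self.colors is not None:
            self.colors = np.asarray(self.colors, dtype=np.uint8).reshape(-1, 3)
            if len(self.colors) != n:
                raise ValueError("colors must be per-vertex RGB")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def is_empty(self) -> bool:
        return len(self.faces) == 0

    def to_trimesh(self) -> trimesh.Trimesh:
        tm = trimesh.Trimesh(
            vertices=self.vertices.copy(), faces=self.faces.copy(), process=False
        )
        if self.colors is not None:
            tm.visual.vertex_colors = np.column_stack(
                [self.colors, np.full(len(self.colors), 255, np.uint8)]
            )
        return tm

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh) -> "SurfaceMesh":
        colors = None
        if tm.visual.kind == "vertex":
            colors = np.asarray(tm.visual.vertex_colors)[:, :3].astype(np.uint8)
        return cls(np.asarray(tm.vertices), np.asarray(tm.faces), colors=colors)

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(
            self.vertices.copy(),
            self.faces.copy(),
            {k: v.copy() for k, v in self.vertex_attrs.items()},
            None if self.colors is None else self.colors.copy(),
        )

    def submesh(self, vertex_mask: np.ndarray) -> "SurfaceMesh":
        """Keep the flagged vertices and every face whose vertices all survive."""
        vertex_mask = np.asarray(vertex_mask, bool)
        remap = -np.ones(self.n_vertices, dtype=np.int64)
        remap[vertex_mask] = np.arange(int(vertex_mask.sum()))
        keep_faces = vertex_mask[self.faces].all(axis=1) if len(self.faces) else np.zeros(0, bool)
        return SurfaceMesh(
            self.vertices[vertex_mask],
            remap[self.faces[keep_faces]] if len(self.faces) else self.faces[:0],
            {k: v[vertex_mask] for k, v in self.vertex_attrs.items()},
            None if self.colors is None else self.colors[vertex_mask],
        )


# filter-chain defaults follow the six-step segmentation sequence:
# Threshold 70, Close 10, Fill hole, Dilate 3, Close 5, Blur 0.33
@dataclass
class FilterChainConfig:
    threshold: int = 70
    close1_r: int = 10
    fill_holes: bool = True
    fill_holes_per_slice: bool = False
    dilate_r: int = 3
    close2_r: int = 5
    blur_sigma: float = 0.33


@dataclass
class PipelineConfig:
    """Every tunable of the reconstruction pipeline, in one YAML-serialisable place.

    All lengths are micrometres.  ``sdf_low``/``sdf_high`` bound the red→green
    caliber gradient (centre ``sdf_center``), ``component_min_diam`` is the
    small-component cutoff (5% of a typical model diagonal), and
    ``small_min``/``small_max`` delimit the red "small structure" band of the
    connectivity models.
    """

    saturation_scale: int = 255
    interp_target_z: float = 1.0
    flow_radius: int = 10
    flow_num_warp: int = 3
    filter_chain: FilterChainConfig = field(default_factory=FilterChainConfig)
    iso_value: float = 127.5
    taubin_iters: int = 10
    taubin_lam: float = 0.5
    taubin_mu: float = -0.53
    sdf_low: float = 12.0
    sdf_high: float = 30.0
    sdf_center: float = 16.5
    sdf_cone_half_angle_deg: float = 20.0
    sdf_n_rays: int = 30
    obscurance_n_samples: int = 24
    obscurance_threshold: float = 0.05
    component_min_diam: float = 70.0
    small_min: float = 7.0
    small_max: float = 28.0
    hausdorff_repair: float = 10.0
    n_large_networks: int = 1
    downsample_xy: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.filter_chain, dict):
            self.filter_chain = FilterChainConfig(**self.filter_chain)
        self.validate()

    def validate(self) -> None:
        if not (self.sdf_low < self.sdf_center < self.sdf_high):
            raise ValueError("require sdf_low < sdf_center < sdf_high")
        if not (self.small_min < self.small_max < self.component_min_diam):
            raise ValueError("require small_min < small_max < component_min_diam")
        for name in (
            "interp_target_z", "sdf_low", "sdf_high", "sdf_center",
            "component_min_diam", "small_min", "small_max", "hausdorff_repair",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_large_networks < 1:
            raise ValueError("n_large_networks must be >= 1")
        if not 0 <= self.saturation_scale <= 255:
            raise ValueError("saturation_scale must be in [0, 255]")
        if self.downsample_xy < 1:
            raise ValueError("downsample_xy must be >= 1")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)


# ---------------------------------------------------------------------------
# stack / volume I/O


def read_stack(
    paths: Sequence[str | Path], xy_spacing: float, z_spacing: float
) -> SectionStack:
    """Read an ordered sequence of RGB section images into a SectionStack.

    Raises ``DimensionError`` if slice shapes differ, ``IOError``/``OSError``
    for unreadable files and ``ValueError`` for an empty path list.
    """
    paths = list(paths)
    if not paths:
        raise ValueError("no input files given")
    slices, names = [], []
    for p in paths:
        p = Path(p)
        if not p.exists():
            raise IOError(f"no such file: {p}")
        img = iio.imread(p)
        if img.ndim == 2:  # grayscale scans are promoted to RGB
            img = np.stack([img] * 3, axis=-1)
        if img.shape[-1] == 4:
            img = img[..., :3]
        slices.append(np.ascontiguousarray(img[..., :3], dtype=np.uint8))
        names.append(p.stem)
    return SectionStack(slices, xy_spacing, z_spacing, names)


def write_stack(stack: SectionStack, directory: str | Path, prefix: str = "section") -> list[Path]:
    """Write each slice as a numbered TIFF; returns the file list."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = []
    for i, s in enumerate(stack.slices):
        p = directory / f"{prefix}_{i:04d}.tif"
        tifffile.imwrite(p, s)
        out.append(p)
    return out


_SPACING_KEY = "vessel3d_spacing_zyx_um"


def write_volume(vol: ScalarVolume, path: str | Path) -> Path:
    """Write a ScalarVolume as a multi-page TIFF with spacing in the description tag."""
    path = Path(path)
    meta = json.dumps({_SPACING_KEY: list(vol.spacing), "provenance": vol.provenance})
    tifffile.imwrite(path, vol.data, description=meta)
    return path


def read_volume(path: str | Path) -> ScalarVolume:
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description or ""
    spacing, provenance = (1.0, 1.0, 1.0), ""
    try:
        meta = json.loads(desc)
        spacing = tuple(meta[_SPACING_KEY])
        provenance = meta.get("provenance", "")
    except (json.JSONDecodeError, KeyError, TypeError):
        log.warning("volume %s lacks spacing metadata; assuming unit voxels", path)
    if data.ndim == 2:
        data = data[None]
    return ScalarVolume(data, spacing, provenance)


# ---------------------------------------------------------------------------
# mesh I/O

_MESH_FORMATS = {".ply": "ply", ".obj": "obj", ".stl": "stl"}


def write_mesh(mesh: SurfaceMesh, path: str | Path, fmt: str | None = None) -> Path:
    """Write a mesh as binary PLY (canonical, carries RGB), OBJ or STL.

    STL cannot carry per-vertex color; a warning is emitted and colors dropped.
    Scalar vertex attributes are preserved only by PLY.
    """
    path = Path(path)
    fmt = (fmt or _MESH_FORMATS.get(path.suffix.lower(), "ply")).lower()
    if fmt not in ("ply", "obj", "stl"):
        raise ValueError(f"unsupported mesh format {fmt!r}")
    if fmt != "ply" and mesh.colors is not None:
        warnings.warn(f"{fmt.upper()} cannot store vertex colors; dropping them")
    if mesh.is_empty and fmt == "stl":
        path.write_bytes(b"\x00" * 80 + (0).to_bytes(4, "little"))
        return path
    tm = mesh.to_trimesh()
    if fmt == "ply":
        for name, arr in mesh.vertex_attrs.items():
            tm.vertex_attributes[name] = np.asarray(arr, dtype=np.float32)
        path.write_bytes(trimesh.exchange.ply.export_ply(tm, encoding="binary_little_endian"))
    else:
        tm.export(path, file_type=fmt)
    return path


def read_mesh(path: str | Path) -> SurfaceMesh:
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    tm = trimesh.load(path, process=False, force="mesh")
    mesh = SurfaceMesh.from_trimesh(tm)
    for name, arr in getattr(tm, "vertex_attributes", {}).items():
        arr = np.asarray(arr)
        if arr.ndim == 1 and len(arr) == mesh.n_vertices:
            mesh.vertex_attrs[name] = arr.astype(np.float64)
    raw = tm.metadata.get("_ply_raw", {}).get("vertex", {})
    if raw:
        skip = {"x", "y", "z", "red", "green", "blue", "alpha", "nx", "ny", "nz"}
        data = raw.get("data")
        if data is not None and getattr(data, "dtype", None) is not None and data.dtype.names:
            for name in data.dtype.names:
                if name not in skip and name not in mesh.vertex_attrs:
                    arr = np.asarray(data[name]).reshape(-1)
                    if len(arr) == mesh.n_vertices:
                        mesh.vertex_attrs[name] = arr.astype(np.float64)
    if len(tm.faces) and not tm.is_watertight:
        log.info("mesh %s is not watertight / possibly non-manifold", path)
    return mesh


def volume_gigabytes(shape_xyz: tuple[int, int, int], channels: int = 1) -> float:
    """Uncompressed size in binary gigabytes (2**30 bytes) of an 8-bit volume."""
    nx, ny, nz = shape_xyz
    return nx * ny * nz * channels / 2**30
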