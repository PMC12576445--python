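"""Core data containers shared across the pipeline.

Coordinates are metres in a z-up local or projected frame everywhere inside
the library; centimetres appear only at the trait/CHM reporting boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

import numpy as np


class Source(str, Enum):
    LIDAR = "lidar"
    DRONE = "drone"
    SYNTHETIC = "synthetic"


class TreeStatus(str, Enum):
    PRESENT = "present"
    GAP = "gap"
    DEAD = "dead"


@dataclass
class PointCloud:
    """N x 3 point set with optional per-point intensity and RGB colour.

    intensity is min-max normalised to [0, 1]; rgb channels are 0-255 ints.
    """

    coords: np.ndarray
    intensity: Optional[np.ndarray] = None
    rgb: Optional[np.ndarray] = None
    crs: Optional[str] = None
    source: Source = Source.SYNTHETIC

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(-1, 3)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("point coordinates must be finite")
        if self.intensity is not None:
            self.intensity = np.asarray(self.intensity, dtype=np.float64).ravel()
            if self.intensity.shape[0] != len(self):
                raise ValueError("intensity length mismatch")
        if self.rgb is not None:
            self.rgb = np.asarray(self.rgb, dtype=np.int64).reshape(-1, 3)
            if self.rgb.shape[0] != len(self):
                raise ValueError("rgb length mismatch")
            if self.rgb.min(initial=0) < 0 or self.rgb.max(initial=0) > 255:
                raise ValueError("rgb channels must lie in [0, 255]")
        if isinstance(self.source, str):
            self.source = Source(self.source)

    def __len__(self) -> int:
        return self.coords.shape[0]

    def select(self, idx) -> "PointCloud":
        """Subset by boolean mask or integer indices, carrying attributes."""
        return PointCloud(
            coords=self.coords[idx],
            intensity=None if self.intensity is None else self.intensity[idx],
            rgb=None if self.rgb is None else self.rgb[idx],
            crs=self.crs,
            source=self.source,
        )

    def with_coords(self, coords: np.ndarray) -> "PointCloud":
        return replace(self, coords=np.asarray(coords, dtype=np.float64))

    @property
    def bbox(self) -> np.ndarray:
        """(2, 3) array: [min_xyz, max_xyz]."""
        return np.vstack([self.coords.min(axis=0), self.coords.max(axis=0)])


NO_DATA = -9999.0


@dataclass
class RasterCHM:
    """Canopy height model raster; heights in centimetres, NO_DATA sentinel."""

    heights: np.ndarray          # R x C, cm
    cell_size: float             # metres
    origin: tuple[float, float]  # (x, y) of the lower-left corner of cell (0, 0)
    crs: Optional[str] = None

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=np.float64)
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        valid = self.heights != NO_DATA
        if np.any(self.heights[valid] < 0):
            raise ValueError("CHM heights must be >= 0 or NO_DATA")

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x0, y0 = self.origin
        return (x0 + (col + 0.5) * self.cell_size, y0 + (row + 0.5) * self.cell_size)


@dataclass
class TreeInstance:
    tree_id: int
    row: int
    col: int
    points: PointCloud
    bbox: np.ndarray                      # (2, 3): [min_xyz, max_xyz]
    centroid_xy: tuple[float, float]
    geo: Optional[tuple[float, float]] = None
    status: TreeStatus = TreeStatus.PRESENT
    point_indices: Optional[np.ndarray] = None  # indices into the source cloud

    def __post_init__(self) -> None:
        if isinstance(self.status, str):
            self.status = TreeStatus(self.status)


@dataclass
class Skeleton:
    """Contracted curve skeleton: nodes, edges and the trunk-base node."""

    nodes: np.ndarray                     # M x 3
    edges: list[tuple[int, int]] = field(default_factory=list)
    source: Source = Source.LIDAR
    base_idx: int = 0
    origin_map: Optional[list[np.ndarray]] = None  # node -> source point indices
    node_intensity: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=np.float64).reshape(-1, 3)
        if isinstance(self.source, str):
            self.source = Source(self.source)
        if len(self.nodes) and self.base_idx == 0:
            self.base_idx = int(np.argmin(self.nodes[:, 2]))

    def __len__(self) -> int:
        return self.nodes.shape[0]


@dataclass
class RigidTransform:
    """Proper rigid motion stored as a 4x4 homogeneous matrix."""

    matrix: np.ndarray
    rmse: Optional[float] = None
    converged: bool = True

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64).reshape(4, 4)
        R = self.matrix[:3, :3]
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation block is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation block must have det = +1 (no reflection)")
        if not np.allclose(self.matrix[3], [0, 0, 0, 1]):
            raise ValueError("bottom row must be [0, 0, 0, 1]")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @classmethod
    def from_rt(cls, R: np.ndarray, t: np.ndarray, **kw) -> "RigidTransform":
        m = np.eye(4)
        m[:3, :3] = R
        m[:3, 3] = np.asarray(t, dtype=np.float64).ravel()
        return cls(m, **kw)

    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=np.float64)
        return pts @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        R = self.rotation
        return RigidTransform.from_rt(R.T, -R.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self ∘ other)(x) = self(other(x))."""
        return RigidTransform(self.matrix @ other.matrix)


@dataclass
class BranchSet:
    trunk_path: list[int]
    branches: list[list[int]]
    r_trunk: float
    skeleton: Optional[Skeleton] = None

    @property
    def num_branch(self) -> int:
        return len(self.branches)


@dataclass
class CanopyTraits:
    height_max: float          # cm
    proj_area_crown: float     # m^2
    volume_crown: float        # m^3
    surfarea_crown: float      # m^2
    diameter_crown: float      # m
    crown_base_z: float        # m
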