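"""Tree positioning on a unified grid.

Trunk centroids from the two survey sources (LiDAR and drone) are computed
by projecting the bottommost trunk points onto the horizontal plane, placed
into a common gridding system, and associated with precise geo-coordinates
by a least-squares similarity transform when the reference table does not
cover every tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import Polygon

from .types import PointCloud, TreeInstance, TreeStatus


def trunk_centroid(tree: TreeInstance | PointCloud,
                   bottom_fraction: float = 0.10,
                   method: str = "mean") -> tuple[float, float]:
    """Overhead projection of the bottom decile of points: the trunk centroid.

    The lowest ``ceil(bottom_fraction * N)`` points by z are projected
    onto the horizontal plane. ``method="mean"`` averages them with equal
    weights; ``method="robust"`` is the density-weighting hook — it
    re-centres iteratively on the dominant cluster of the slice, so a
    trellis post standing in the same height band cannot drag the
    centroid off the trunk axis.
    """
    pc = tree.points if isinstance(tree, TreeInstance) else tree
    n = len(pc)
    if n < 10:
        raise ValueError(f"trunk centroid needs >= 10 points, got {n}")
    m = int(np.ceil(bottom_fraction * n))
    z = pc.coords[:, 2]
    cutoff = np.sort(z, kind="stable")[m - 1]
    sel = z <= cutoff  # ties at the cutoff all belong to the bottom slice
    slab = pc.coords[sel, :2]
    if method == "robust":
        centre = np.median(slab, axis=0)
        for radius in (0.15, 0.12, 0.10, 0.10, 0.10):
            near = np.hypot(*(slab - centre).T) <= radius
            if near.sum() < 5:
                break
            centre = slab[near].mean(axis=0)
        return (float(centre[0]), float(centre[1]))
    xy = slab.mean(axis=0)
    return (float(xy[0]), float(xy[1]))


def canopy_hull_xy(tree: TreeInstance | PointCloud) -> tuple[Polygon, float]:
    """2D convex hull of the overhead projection and its shoelace area (m^2)."""
    pc = tree.points if isinstance(tree, TreeInstance) else tree
    xy = pc.coords[:, :2]
    try:
        hull = ConvexHull(xy)
    except (QhullError, ValueError) as exc:
        raise ValueError(f"degenerate (collinear) projection: {exc}") from exc
    poly = Polygon(xy[hull.vertices])
    return poly, float(poly.area)


@dataclass
class GridCell:
    lidar_centroid: Optional[tuple[float, float]] = None
    drone_centroid: Optional[tuple[float, float]] = None
    geo: Optional[tuple[float, float]] = None
    status: TreeStatus = TreeStatus.PRESENT

    @property
    def offset(self) -> Optional[tuple[float, float]]:
        """Drone minus LiDAR centroid — the fusion QC residual."""
        if self.lidar_centroid is None or self.drone_centroid is None:
            return None
        return (self.drone_centroid[0] - self.lidar_centroid[0],
                self.drone_centroid[1] - self.lidar_centroid[1])


@dataclass
class GridSystem:
    n_rows: int
    n_cols: int
    cell_size: tuple[float, float]          # (dx, dy) metres
    origin: tuple[float, float] = (0.0, 0.0)
    cells: dict = field(default_factory=dict)  # (row, col) -> GridCell
    anomalies: list = field(default_factory=list)

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        return (self.origin[0] + (col + 0.5) * self.cell_size[0],
                self.origin[1] + (row + 0.5) * self.cell_size[1])

    def locate(self, xy) -> Optional[tuple[int, int]]:
        col = int(np.floor((xy[0] - self.origin[0]) / self.cell_size[0]))
        row = int(np.floor((xy[1] - self.origin[1]) / self.cell_size[1]))
        if 0 <= row < self.n_rows and 0 <= col < self.n_cols:
            return (row, col)
        return None


def build_grid(lidar_centroids, drone_centroids, layout) -> GridSystem:
    """Place both centroid sets into a unified gridding system.

    ``layout`` is (n_rows, n_cols, (dx, dy)[, origin]). Centroid sets may be
    dicts keyed by (row, col) or plain sequences of (x, y), in which case
    each centroid lands in the cell containing it; one outside every cell
    is recorded as an anomaly. Per-cell drone-minus-LiDAR offsets are
    available for fusion QC.
    """
    n_rows, n_cols, cell_size = layout[0], layout[1], tuple(layout[2])
    origin = tuple(layout[3]) if len(layout) > 3 else (0.0, 0.0)
    grid = GridSystem(n_rows=n_rows, n_cols=n_cols, cell_size=cell_size,
                      origin=origin)

    def place(centroids, attr):
        items = (centroids.items() if isinstance(centroids, dict)
                 else [(None, c) for c in centroids])
        for key, xy in items:
            if xy is None:
                continue
            rc = key if key is not None else grid.locate(xy)
            if rc is None or not (0 <= rc[0] < n_rows and 0 <= rc[1] < n_cols):
                grid.anomalies.append({"source": attr, "xy": tuple(xy)})
                continue
            cell = grid.cells.setdefault(tuple(rc), GridCell())
            setattr(cell, attr, (float(xy[0]), float(xy[1])))

    place(lidar_centroids, "lidar_centroid")
    place(drone_centroids, "drone_centroid")
    for cell in grid.cells.values():
        if cell.lidar_centroid is None or cell.drone_centroid is None:
            cell.status = TreeStatus.GAP
    return grid


def fit_similarity_2d(src: np.ndarray, dst: np.ndarray):
    """Least-squares 2D similarity transform (scale, rotation, translation).

    Returns (s, R, t) minimising ||s R p + t - q||^2 over pairs (p, q).
    """
    src = np.asarray(src, dtype=np.float64).reshape(-1, 2)
    dst = np.asarray(dst, dtype=np.float64).reshape(-1, 2)
    if len(src) < 2:
        raise ValueError("similarity fit needs >= 2 point pairs")
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    ps, pd = src - mu_s, dst - mu_d
    # complex-number least squares: q = a * p with a = s e^{i theta}
    zs = ps[:, 0] + 1j * ps[:, 1]
    zd = pd[:, 0] + 1j * pd[:, 1]
    denom = np.vdot(zs, zs).real
    if denom == 0:
        raise ValueError("degenerate source configuration")
    a = np.vdot(zs, zd) / denom
    s = abs(a)
    th = np.angle(a)
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    t = mu_d - s * R @ mu_s
    return s, R, t


def assign_geo(grid: GridSystem, reference) -> GridSystem:
    """Attach precise geo-coordinates to every present cell.

    ``reference`` rows are (row, col, x, y). Referenced cells take the
    coordinates verbatim; the rest get geo through a least-squares
    similarity transform fitted from local centroids (or cell centres) to
    the reference frame, which needs at least two reference cells.
    """
    ref = {}
    for row in reference:
        r, c, x, y = int(row[0]), int(row[1]), float(row[2]), float(row[3])
        if (r, c) in ref and not np.allclose(ref[(r, c)], (x, y)):
            raise ValueError(f"inconsistent duplicate reference for cell {(r, c)}")
        ref[(r, c)] = (x, y)

    def local_xy(rc):
        cell = grid.cells.get(rc)
        if cell is not None and cell.lidar_centroid is not None:
            return cell.lidar_centroid
        return grid.cell_center(*rc)

    present = [rc for rc, cell in grid.cells.items()
               if cell.status == TreeStatus.PRESENT]
    uncovered = [rc for rc in present if rc not in ref]
    if uncovered and len(ref) < 2:
        raise ValueError("need >= 2 reference cells to extrapolate geo")

    if uncovered:
        src = np.array([local_xy(rc) for rc in ref])
        dst = np.array([ref[rc] for rc in ref])
        s, R, t = fit_similarity_2d(src, dst)

    for rc in present:
        if rc in ref:
            grid.cells[rc].geo = ref[rc]
        else:
            g = s * R @ np.asarray(local_xy(rc)) + t
            grid.cells[rc].geo = (float(g[0]), float(g[1]))
    return grid
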