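"""Tree-level canopy morphology from (fused) point clouds.

Traits follow orchard-phenotyping convention: maximum height (cm), crown
projection area (m^2, 2D convex hull of the overhead projection), crown
volume and surface area (m^3 / m^2, 3D convex hull) and crown diameter
(m, the larger of the east-west and north-south extents).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from sklearn.cluster import DBSCAN

from .types import CanopyTraits, PointCloud, TreeInstance


def _as_cloud(tree) -> PointCloud:
    return tree.points if isinstance(tree, TreeInstance) else tree


def crown_region(tree, r_trunk: float, eps: float = None, min_pts: int = 10):
    """Split a tree into trunk and crown points.

    DBSCAN finds the density cluster containing the lowest point; members
    within a horizontal radius of 2 x r_trunk of the trunk axis form the
    trunk. Everything above the trunk's tallest tip is crown. Returns
    (trunk_idx, crown_idx, trunk_top_z).
    """
    pc = _as_cloud(tree)
    if len(pc) == 0:
        raise ValueError("empty tree cloud")
    if eps is None:
        eps = 4.0 * r_trunk
    labels = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(pc.coords)
    lowest = int(np.argmin(pc.coords[:, 2]))
    base_z = pc.coords[lowest, 2]
    if labels[lowest] == -1:
        warnings.warn("no density cluster at the base; trunk top fallback")
        trunk_top_z = base_z + 0.3
        trunk_idx = np.zeros(0, dtype=int)
    else:
        member = labels == labels[lowest]
        axis_xy = pc.coords[member & (pc.coords[:, 2] <=
                                      base_z + 0.5), :2].mean(axis=0)
        horiz = np.hypot(pc.coords[:, 0] - axis_xy[0],
                         pc.coords[:, 1] - axis_xy[1])
        trunk = member & (horiz <= 2.0 * r_trunk)
        trunk_idx = np.nonzero(trunk)[0]
        trunk_top_z = float(pc.coords[trunk, 2].max()) if trunk.any() \
            else base_z + 0.3
    crown_idx = np.nonzero(pc.coords[:, 2] > trunk_top_z)[0]
    return trunk_idx, crown_idx, trunk_top_z


def height_max(tree) -> float:
    """Maximum tree height in centimetres: (max z - min z) * 100."""
    pc = _as_cloud(tree)
    if len(pc) < 2:
        raise ValueError("height needs >= 2 points")
    z = pc.coords[:, 2]
    return float((z.max() - z.min()) * 100.0)


def crown_hull_metrics(crown: PointCloud):
    """Convex-hull crown metrics: (volume m^3, surface m^2, proj area m^2,
    diameter m).

    Degenerate geometry (coplanar/collinear inputs) turns only the
    affected metrics into NaN; the rest are still computed. Diameter is
    the larger axis-aligned horizontal extent (east-west vs north-south).
    """
    pts = crown.coords if isinstance(crown, PointCloud) else np.asarray(crown)
    volume = surface = proj_area = np.nan
    if len(pts) >= 4:
        try:
            hull = ConvexHull(pts)
            volume, surface = float(hull.volume), float(hull.area)
        except (QhullError, ValueError):
            pass
    if len(pts) >= 3:
        try:
            h2 = ConvexHull(pts[:, :2])
            proj_area = float(h2.volume)  # 2D hull "volume" is its area
        except (QhullError, ValueError):
            pass
    diameter = np.nan
    if len(pts):
        ext = pts[:, :2].max(axis=0) - pts[:, :2].min(axis=0)
        diameter = float(max(ext))
    return volume, surface, proj_area, diameter


def compute_canopy_traits(tree, r_trunk: float,
                          crown_only_projection: bool = True) -> CanopyTraits:
    """All canopy traits for one tree; see the individual functions."""
    pc = _as_cloud(tree)
    _, crown_idx, trunk_top_z = crown_region(tree, r_trunk)
    crown = pc.select(crown_idx) if len(crown_idx) else pc
    vol, surf, proj, diam = crown_hull_metrics(crown)
    if not crown_only_projection:
        _, _, proj, _ = crown_hull_metrics(pc)
    return CanopyTraits(height_max=height_max(tree), proj_area_crown=proj,
                        volume_crown=vol, surfarea_crown=surf,
                        diameter_crown=diam, crown_base_z=trunk_top_z)
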