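"""Ground-truthed synthetic orchards.

Generates open-centre (vase-form) fruit trees as noisy cylinder assemblies:
a bare trunk up to ``trunk_top``, first-order branches fanning out and up
from the trunk head, optional trellis supports (a vertical post and a
horizontal wire) with distinctly higher LiDAR reflectivity, and blossom
clusters as near-white Gaussian blobs seated on the outer halves of
branches. Every tree is emitted as two views of the same geometry — a
dense "LiDAR" view carrying intensity and a sparser "drone" view carrying
RGB — related by a random rigid transform recorded in the truth record.
Orchard scenes place trees on a (optionally sloped) ground plane in a
regular grid with designated gap slots.

All sampling is deterministic per seed. Default magnitudes (tree height
2.5 m, trunk radius 5 cm, 8 branches, 5000-20000 LiDAR points per tree
with the drone view at 30-60% of that) are desk-scale stand-ins for a
mature pear orchard.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .types import PointCloud, RigidTransform, Source

FOLIAGE_RGB = np.array([60, 120, 50])
BLOSSOM_RGB = np.array([250, 248, 245])
SUPPORT_RGB = np.array([128, 128, 128])
RGB_SIGMA = 10.0
BRANCH_INTENSITY = 0.3
SUPPORT_INTENSITY_OFFSET = 0.6
INTENSITY_SIGMA = 0.05


@dataclass
class SyntheticTreeSpec:
    height: float = 2.5                 # m
    trunk_radius: float = 0.05          # m
    trunk_top: float = 0.8              # m, top of the bare trunk
    n_branches: int = 8
    branch_lengths: Optional[list] = None   # m; default 1.2-1.8
    support: str = "post"               # none | post | post+wire
    support_intensity_offset: float = SUPPORT_INTENSITY_OFFSET
    n_blossom_clusters: int = 10
    cluster_sizes: Optional[list] = None    # default ~80 points each
    touching_pairs: int = 0             # clusters planted as touching pairs
    noise_outlier_frac: float = 0.0
    n_points_lidar: int = 6000
    drone_density: float = 0.4          # fraction of the LiDAR density
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.height, self.trunk_radius, self.trunk_top) <= 0:
            raise ValueError("tree dimensions must be positive")
        if self.trunk_top >= self.height:
            raise ValueError("trunk_top must lie below the tree height")
        if self.touching_pairs > self.n_blossom_clusters // 2:
            raise ValueError("touching_pairs exceeds n_blossom_clusters / 2")


@dataclass
class GroundTruth:
    lidar_labels: np.ndarray            # per LiDAR point: trunk|branch|support|outlier
    drone_labels: np.ndarray            # per drone point: ... |blossom
    height: float
    trunk_top: float
    n_branches: int
    branch_axes: list                   # per branch: (start xyz, end xyz)
    n_blossom_clusters: int             # planted cluster count (pairs merge)
    n_blossom_sites: int                # individual flower blobs planted
    cluster_centroids: np.ndarray       # lidar frame, one per planted cluster
    cluster_branch_ids: np.ndarray      # branch each cluster sits on
    transform: RigidTransform           # maps drone-view coords -> lidar frame
    lidar_branch_ids: np.ndarray = None  # per LiDAR point, -1 off-branch


def _cylinder_points(rng, a, b, radius, n, jitter=0.003):
    """Sample ~n points on the surface of the cylinder from a to b."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    axis = b - a
    length = np.linalg.norm(axis)
    axis = axis / length
    # orthonormal frame around the axis
    ref = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    t = rng.uniform(0, length, n)
    th = rng.uniform(0, 2 * np.pi, n)
    r = radius + rng.normal(0, jitter, n)
    return (a[None, :] + t[:, None] * axis[None, :]
            + r[:, None] * (np.cos(th)[:, None] * u[None, :]
                            + np.sin(th)[:, None] * v[None, :]))


def _tree_geometry(spec: SyntheticTreeSpec, rng):
    """Branch attachment and tip positions for a vase-form scaffold.

    Branches are parametrised by their tips: horizontal tip radius
    0.9-1.4 m (a 2.5 m pear crown stays inside its planting cell) and
    tip height up to the tree height, with one branch reaching ``height``
    exactly. Azimuths spread around the trunk with uneven gaps (no
    artificial rotational symmetry) but never coincide.
    """
    n = spec.n_branches
    az = (2 * np.pi / n) * (np.arange(n) + 0.5 * rng.uniform(-0.5, 0.5, n)) \
        + rng.uniform(0, 2 * np.pi)
    zj = np.linspace(0.5 * spec.trunk_top, spec.trunk_top, n)
    crown_r = min(0.55 * spec.height, 1.4)
    rho = rng.uniform(0.65 * crown_r, crown_r, n)
    zt = rng.uniform(0.6 * spec.height, spec.height, n)
    zt[int(rng.integers(n))] = spec.height  # the leader tip sets the height
    axes, lengths = [], []
    for i in range(n):
        a = np.array([0.0, 0.0, zj[i]])
        b = np.array([rho[i] * np.cos(az[i]), rho[i] * np.sin(az[i]), zt[i]])
        axes.append((a, b))
        lengths.append(float(np.linalg.norm(b - a)))
    lengths = np.asarray(lengths)
    if spec.branch_lengths is not None:
        if len(spec.branch_lengths) != n:
            raise ValueError("branch_lengths length must equal n_branches")
        # honour requested lengths by rescaling each branch about its base
        req = np.asarray(spec.branch_lengths, dtype=float)
        axes = [(a, a + (b - a) * (L / cur))
                for (a, b), L, cur in zip(axes, req, lengths)]
        lengths = req.copy()
    return axes, lengths


def _sample_structure(spec: SyntheticTreeSpec, axes, lengths, rng, n_total):
    """Sample one view of the tree structure; returns coords, labels,
    branch ids."""
    # returns scale with scanned surface area (radius x length)
    r_branch = 0.6 * spec.trunk_radius
    areas = np.concatenate([[spec.trunk_top * spec.trunk_radius],
                            lengths * r_branch])
    weights = areas / areas.sum()
    parts, labels, bids = [], [], []
    n_trunk = max(int(n_total * weights[0]), 60)
    parts.append(_cylinder_points(rng, [0, 0, 0], [0, 0, spec.trunk_top],
                                  spec.trunk_radius, n_trunk))
    labels += ["trunk"] * n_trunk
    bids += [-1] * n_trunk
    for i, ((a, b), L) in enumerate(zip(axes, lengths)):
        nb = max(int(n_total * weights[i + 1]), 20)
        parts.append(_cylinder_points(rng, a, b, r_branch, nb))
        labels += ["branch"] * nb
        bids += [i] * nb
    if spec.support != "none":
        post_a = np.array([0.35, 0.0, 0.0])
        post_b = np.array([0.35, 0.0, 0.9 * spec.height])
        n_post = max(n_total // 12, 40)
        parts.append(_cylinder_points(rng, post_a, post_b, 0.02, n_post))
        labels += ["support"] * n_post
        bids += [-1] * n_post
        if spec.support == "post+wire":
            zw = 0.6 * spec.height
            n_wire = max(n_total // 20, 30)
            parts.append(_cylinder_points(rng, [0.35, -1.0, zw],
                                          [0.35, 1.0, zw], 0.005, n_wire))
            labels += ["support"] * n_wire
            bids += [-1] * n_wire
    coords = np.vstack(parts)
    return coords, np.array(labels), np.array(bids, dtype=int)


def _random_rigid(rng, max_rot_deg=30.0, max_trans=1.0) -> RigidTransform:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    ang = np.deg2rad(rng.uniform(5.0, max_rot_deg))
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    R = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)
    t = rng.uniform(-max_trans, max_trans, 3)
    return RigidTransform.from_rt(R, t)


def generate_tree(spec: SyntheticTreeSpec):
    """One synthetic tree: (lidar_view, drone_view, truth).

    The LiDAR view is dense with intensity (supports reflect brighter by
    ``support_intensity_offset``); the drone view is sparser, coloured,
    and carries the blossom blobs. Drone coordinates are expressed in
    their own frame; ``truth.transform`` maps them back to the LiDAR
    frame. Identical specs (same seed) yield bit-identical clouds.
    """
    rng = np.random.default_rng(spec.seed)
    axes, lengths = _tree_geometry(spec, rng)

    # -------- LiDAR view (bud burst: wood + supports, intensity)
    l_coords, l_labels, l_bids = _sample_structure(
        spec, axes, lengths, rng, spec.n_points_lidar)
    intensity = rng.normal(BRANCH_INTENSITY, INTENSITY_SIGMA, len(l_coords))
    support = l_labels == "support"
    intensity[support] += spec.support_intensity_offset
    intensity = np.clip(intensity, 0.0, 1.0)

    if spec.noise_outlier_frac > 0:
        n_out = int(spec.noise_outlier_frac * len(l_coords))
        lo = l_coords.min(axis=0) - 0.5
        hi = l_coords.max(axis=0) + 0.5
        out = rng.uniform(lo, hi, (n_out, 3))
        l_coords = np.vstack([l_coords, out])
        l_labels = np.concatenate([l_labels, ["outlier"] * n_out])
        l_bids = np.concatenate([l_bids, np.full(n_out, -1, dtype=int)])
        intensity = np.concatenate(
            [intensity, np.clip(rng.normal(BRANCH_INTENSITY, INTENSITY_SIGMA,
                                           n_out), 0, 1)])

    lidar = PointCloud(coords=l_coords, intensity=intensity,
                       source=Source.LIDAR)

    # -------- drone view (bloom: wood + supports + blossoms, RGB)
    n_drone = int(spec.n_points_lidar * spec.drone_density)
    d_coords, d_labels, d_bids = _sample_structure(
        spec, axes, lengths, rng, n_drone)
    rgb = np.where(d_labels[:, None] == "support", SUPPORT_RGB, FOLIAGE_RGB
                   ).astype(float)

    # blossom clusters on the outer halves of branches
    sizes = list(spec.cluster_sizes if spec.cluster_sizes is not None
                 else [80] * spec.n_blossom_clusters)
    if len(sizes) != spec.n_blossom_clusters:
        raise ValueError("cluster_sizes length must equal n_blossom_clusters")
    centroids, cluster_bids = [], []
    blobs, blob_labels = [], []
    n_sites = 0
    branch_choice = rng.integers(0, spec.n_branches, spec.n_blossom_clusters)
    offsets = rng.uniform(0.55, 0.95, spec.n_blossom_clusters)
    for ci in range(spec.n_blossom_clusters):
        a, b = axes[branch_choice[ci]]
        centre = a + offsets[ci] * (b - a)
        # flowers sit on spurs standing off the wood, not on the axis
        axis_dir = (b - a) / np.linalg.norm(b - a)
        perp = np.cross(axis_dir, rng.normal(size=3))
        perp /= np.linalg.norm(perp)
        centre = centre + rng.uniform(0.08, 0.15) * perp
        if ci < spec.touching_pairs:
            # a touching pair: two compact flower blobs 6 cm apart — close
            # enough to merge at the trunk-radius DBSCAN eps, with a real
            # density dip between them for the split stage to find
            sep = rng.normal(size=3)
            sep = 0.06 * sep / np.linalg.norm(sep)
            half = max(sizes[ci], 2 * DBSCAN_PAIR_MIN) // 2
            for sgn in (-0.5, 0.5):
                pts = rng.normal(centre + sgn * sep, 0.008, (half, 3))
                blobs.append(pts)
                n_sites += 1
        else:
            pts = rng.normal(centre, 0.01, (sizes[ci], 3))
            blobs.append(pts)
            n_sites += 1
        centroids.append(centre)
        cluster_bids.append(branch_choice[ci])
    if blobs:
        bl = np.vstack(blobs)
        d_coords = np.vstack([d_coords, bl])
        d_labels = np.concatenate([d_labels, ["blossom"] * len(bl)])
        d_bids = np.concatenate([d_bids, np.full(len(bl), -1, dtype=int)])
        rgb = np.vstack([rgb, np.broadcast_to(BLOSSOM_RGB.astype(float),
                                              (len(bl), 3))])
    rgb = np.clip(rgb + rng.normal(0, RGB_SIGMA, rgb.shape), 0, 255
                  ).astype(np.int64)

    T = _random_rigid(rng)  # drone -> lidar
    drone = PointCloud(coords=T.inverse().apply(d_coords), rgb=rgb,
                       source=Source.DRONE)

    truth = GroundTruth(
        lidar_labels=l_labels, drone_labels=d_labels,
        height=spec.height, trunk_top=spec.trunk_top,
        n_branches=spec.n_branches,
        branch_axes=[(a.copy(), b.copy()) for a, b in axes],
        n_blossom_clusters=spec.n_blossom_clusters,
        n_blossom_sites=n_sites,
        cluster_centroids=np.array(centroids).reshape(-1, 3),
        cluster_branch_ids=np.array(cluster_bids, dtype=int),
        transform=T, lidar_branch_ids=l_bids)
    return lidar, drone, truth


DBSCAN_PAIR_MIN = 150  # per-blob size floor for touching pairs (n >= 50 each)


@dataclass
class OrchardTruth:
    scene_labels: np.ndarray        # per point: ground | tree | outlier
    tree_ids: np.ndarray            # per point, -1 for ground/outliers
    tree_truths: list               # per present tree: GroundTruth
    tree_positions: np.ndarray      # slot centre (x, y) per (row, col), row-major
    present: np.ndarray             # bool per slot, row-major
    layout: tuple                   # (rows, cols, (dx, dy))
    slope_deg: float = 0.0


def generate_orchard(rows: int, cols: int, spacings=(4.0, 3.5),
                     slope_deg: float = 0.0, gap_slots=(), seed: int = 0,
                     tree_spec: Optional[SyntheticTreeSpec] = None,
                     ground_density: float = 25.0):
    """A gridded orchard scene over a sloped ground plane.

    Trees sit at cell centres with a small planting jitter; ``gap_slots``
    (row, col) pairs stay empty. Returns (scene: PointCloud with intensity,
    truth: OrchardTruth). The slope runs along +x.
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    dx, dy = spacings
    rng = np.random.default_rng(seed)
    seeds = np.random.SeedSequence(seed).generate_state(rows * cols + 1) % (2 ** 31)
    gaps = {tuple(g) for g in gap_slots}
    margin = max(dx, dy)
    x0, x1 = -margin, cols * dx + margin
    y0, y1 = -margin, rows * dy + margin
    slope = np.tan(np.deg2rad(slope_deg))

    n_ground = int((x1 - x0) * (y1 - y0) * ground_density)
    gx = rng.uniform(x0, x1, n_ground)
    gy = rng.uniform(y0, y1, n_ground)
    gz = slope * gx + rng.normal(0, 0.01, n_ground)
    coords = [np.column_stack([gx, gy, gz])]
    inten = [np.clip(rng.normal(0.5, 0.1, n_ground), 0, 1)]
    labels = [np.array(["ground"] * n_ground)]
    tree_ids = [np.full(n_ground, -1, dtype=int)]

    tree_truths, positions, present = [], [], []
    tid = 0
    for r in range(rows):
        for c in range(cols):
            cx, cy = (c + 0.5) * dx, (r + 0.5) * dy
            positions.append((cx, cy))
            if (r, c) in gaps:
                present.append(False)
                continue
            present.append(True)
            spec = tree_spec or SyntheticTreeSpec()
            from dataclasses import replace
            spec = replace(spec, seed=int(seeds[tid]))
            lidar, drone, truth = generate_tree(spec)
            jx, jy = rng.uniform(-0.15, 0.15, 2)
            base_z = slope * (cx + jx)
            shift = np.array([cx + jx, cy + jy, base_z])
            coords.append(lidar.coords + shift)
            inten.append(lidar.intensity)
            labels.append(np.where(truth.lidar_labels == "outlier",
                                   "outlier", "tree"))
            tree_ids.append(np.full(len(lidar), tid, dtype=int))
            truth.position = (cx + jx, cy + jy, base_z)
            truth.drone_view = drone
            tree_truths.append(truth)
            tid += 1

    scene = PointCloud(coords=np.vstack(coords),
                       intensity=np.concatenate(inten),
                       source=Source.LIDAR)
    truth = OrchardTruth(scene_labels=np.concatenate(labels),
                         tree_ids=np.concatenate(tree_ids),
                         tree_truths=tree_truths,
                         tree_positions=np.array(positions),
                         present=np.array(present, dtype=bool),
                         layout=(rows, cols, (dx, dy)),
                         slope_deg=slope_deg)
    return scene, truth
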