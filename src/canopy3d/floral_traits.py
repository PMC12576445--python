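"""Blossom extraction, clustering and floral trait quantification.

Flowers are near-white against foliage and wood, so a greyscale Otsu
threshold pulls out candidate blossom points from the coloured (drone)
cloud; residual bright points on branches are removed by proximity to the
bud-burst skeleton. Candidates are grouped into inflorescence clusters by
DBSCAN (radius = trunk radius, floor of 20 points per cluster), classified
into noise (< 50 points), single-flower and multi-flower groups, and
multi-flower groups are split recursively until only singles remain.
Per-cluster volumetrics come from convex hulls plus an auxiliary
voxel-occupancy volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import ConvexHull, QhullError, cKDTree
from sklearn.cluster import DBSCAN, KMeans

from .types import BranchSet, PointCloud, Skeleton

NOISE_MAX_N = 50       # clusters below this many points are noise
DBSCAN_MIN_PTS = 20    # minimum cluster membership at creation


@dataclass
class BlossomCluster:
    point_idx: np.ndarray
    centroid: np.ndarray
    cls: Optional[str] = None            # noise | single | multi
    stratum: Optional[str] = None        # upper | middle | lower
    volume_blossom: float = np.nan       # m^3
    surf_blossom: float = np.nan         # m^2
    projarea_blossom: float = np.nan     # m^2
    voxel_volume: float = np.nan         # auxiliary, m^3
    branch_id: Optional[int] = None
    geo: Optional[tuple[float, float]] = None
    depth_exhausted: bool = False

    @property
    def n(self) -> int:
        return len(self.point_idx)


def blossom_mask(pc: PointCloud) -> np.ndarray:
    """Candidate blossom indices by greyscale adaptive (Otsu) thresholding.

    Greyscale g = 0.299 R + 0.587 G + 0.114 B; points at or above the
    per-tree Otsu threshold are candidates. If all colours are identical
    the threshold degenerates and every point is retained.
    """
    if pc.rgb is None:
        raise ValueError("blossom extraction needs an RGB channel")
    rgb = pc.rgb.astype(np.float64)
    g = 0.299 * rgb[:, 0] + 0.587 * rgb[:, 1] + 0.114 * rgb[:, 2]
    if np.ptp(g) == 0:
        return np.arange(len(pc))
    from skimage.filters import threshold_otsu
    thresh = threshold_otsu(g)
    return np.nonzero(g >= thresh)[0]


def remove_near_skeleton(pc: PointCloud, candidates: np.ndarray,
                         skel: Skeleton, r: float) -> np.ndarray:
    """Drop candidates within ``r`` of the skeleton (branch/trunk surface).

    Distance is measured to the skeleton polyline (its edges) where edges
    exist, so points between two nodes are still recognised as wood; bare
    node sets fall back to node distance.
    """
    candidates = np.asarray(candidates, dtype=int)
    if len(skel) == 0:
        warnings.warn("empty skeleton; R-NN removal skipped")
        return candidates
    pts = pc.coords[candidates]
    d = cKDTree(skel.nodes).query(pts)[0]
    if skel.edges:
        near = d <= r + _max_edge_len(skel)  # only these can touch a segment
        if near.any():
            sub = pts[near]
            dmin = d[near].copy()
            for u, v in skel.edges:
                a, b = skel.nodes[u], skel.nodes[v]
                ab = b - a
                denom = float(ab @ ab)
                if denom == 0:
                    continue
                t = np.clip((sub - a) @ ab / denom, 0.0, 1.0)
                seg_d = np.linalg.norm(sub - (a + t[:, None] * ab), axis=1)
                np.minimum(dmin, seg_d, out=dmin)
            d[near] = dmin
    return candidates[d > r]


def _max_edge_len(skel: Skeleton) -> float:
    return max(float(np.linalg.norm(skel.nodes[u] - skel.nodes[v]))
               for u, v in skel.edges)


def stratify(points: np.ndarray, crown_base_z: float,
             apex_z: float) -> np.ndarray:
    """Label points upper/middle/lower by equal thirds of the crown span.

    A point exactly on a band boundary goes to the lower band of the two.
    """
    if apex_z <= crown_base_z:
        raise ValueError("apex_z must exceed crown_base_z")
    z = np.asarray(points)[:, 2] if np.ndim(points) == 2 else np.asarray(points)
    frac = (z - crown_base_z) / (apex_z - crown_base_z)
    idx = np.clip(np.ceil(frac * 3).astype(int) - 1, 0, 2)
    return np.array(["lower", "middle", "upper"])[idx]


def cluster_blossoms(pc: PointCloud, blossom_idx: np.ndarray, eps: float,
                     min_pts: int = DBSCAN_MIN_PTS) -> list[BlossomCluster]:
    """DBSCAN the blossom points into inflorescence clusters.

    DBSCAN noise points are discarded; every returned cluster has at least
    ``min_pts`` members. ``point_idx`` indexes into the original cloud.
    """
    blossom_idx = np.asarray(blossom_idx, dtype=int)
    if len(blossom_idx) < min_pts:
        return []
    pts = pc.coords[blossom_idx]
    labels = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(pts)
    clusters = []
    for lab in sorted(set(labels) - {-1}):
        members = blossom_idx[labels == lab]
        if len(members) < min_pts:
            continue
        clusters.append(BlossomCluster(
            point_idx=members, centroid=pc.coords[members].mean(axis=0)))
    return clusters


def _cluster_features(pc: PointCloud, cluster: BlossomCluster) -> np.ndarray:
    pts = pc.coords[cluster.point_idx]
    try:
        vol = ConvexHull(pts).volume if len(pts) >= 4 else 0.0
    except (QhullError, ValueError):
        vol = 0.0
    centred = pts - pts.mean(axis=0)
    ext = 2.0 * np.sqrt(np.linalg.eigvalsh(np.cov(centred.T)).max()) \
        if len(pts) > 1 else 0.0
    return np.array([cluster.n, vol, ext])


def classify_clusters(pc: PointCloud, clusters: list[BlossomCluster],
                      k: int = 3, seed: int = 42) -> list[BlossomCluster]:
    """Three-way classification: noise, single-flower, multi-flower.

    Clusters under 50 points are noise by rule. The rest are split by
    K-means (effectively 2 groups) on z-scored features (point count,
    hull volume, max PCA extent); the group with the smaller mean size is
    single-flower. The result is deterministic given the seed and does
    not depend on cluster order.
    """
    if not clusters:
        return clusters
    eligible = []
    for c in clusters:
        if c.n < NOISE_MAX_N:
            c.cls = "noise"
        else:
            eligible.append(c)
    if not eligible:
        warnings.warn("all blossom clusters classified as noise")
        return clusters
    if len(eligible) == 1:
        eligible[0].cls = "single"
        return clusters
    feats = np.array([_cluster_features(pc, c) for c in eligible])
    mu, sd = feats.mean(axis=0), feats.std(axis=0)
    sd[sd == 0] = 1.0
    zs = (feats - mu) / sd
    # canonical order makes labels independent of input permutation
    order = np.lexsort(zs.T[::-1])
    km = KMeans(n_clusters=min(2, len(eligible)), n_init=10,
                random_state=seed).fit(zs[order])
    labels = np.empty(len(eligible), dtype=int)
    labels[order] = km.labels_
    means = [feats[labels == g, 0].mean() for g in range(km.n_clusters)]
    single_group = int(np.argmin(means))
    for c, lab in zip(eligible, labels):
        c.cls = "single" if lab == single_group else "multi"
    return clusters


def split_multiflower(pc: PointCloud, cluster: BlossomCluster, eps: float,
                      max_depth: int = 4,
                      min_pts: int = DBSCAN_MIN_PTS) -> list[BlossomCluster]:
    """Recursively split a multi-flower cluster into single-flower clusters.

    Each level halves the DBSCAN radius and re-clusters; a leaf that no
    longer splits is a single flower, sub-clusters under 50 points are
    noise and dropped, and leaves still splittable at ``max_depth`` are
    forced single with ``depth_exhausted`` set. Output point sets are
    disjoint subsets of the input.
    """
    if cluster.cls != "multi":
        raise ValueError("split_multiflower expects a multi-flower cluster")

    def recurse(idx: np.ndarray, radius: float, depth: int):
        pts = pc.coords[idx]
        labels = DBSCAN(eps=radius, min_samples=min_pts).fit_predict(pts)
        parts = [idx[labels == lab] for lab in sorted(set(labels) - {-1})]
        parts = [p for p in parts if len(p) >= NOISE_MAX_N]
        if len(parts) >= 2:
            if depth >= max_depth:
                warnings.warn("multi-flower split depth exhausted")
                return [BlossomCluster(point_idx=p,
                                       centroid=pc.coords[p].mean(axis=0),
                                       cls="single", depth_exhausted=True)
                        for p in parts]
            out = []
            for p in parts:
                out.extend(recurse(p, radius / 2.0, depth + 1))
            return out
        # no split at this radius: probe finer scales before concluding
        # the cluster is a single flower
        if depth >= max_depth:
            return [BlossomCluster(point_idx=idx,
                                   centroid=pc.coords[idx].mean(axis=0),
                                   cls="single")]
        return recurse(idx, radius / 2.0, depth + 1)

    singles = recurse(np.asarray(cluster.point_idx), eps / 2.0, 1)
    for s in singles:
        s.stratum = cluster.stratum
        s.branch_id = cluster.branch_id
    return singles


def cluster_metrics(pc: PointCloud, cluster: BlossomCluster,
                    voxel: float = 0.01, geo_transform=None) -> BlossomCluster:
    """Convex-hull volumetrics for a cluster (plus voxel-count volume).

    Degenerate clusters keep NaN metrics but still report count and
    centroid. ``geo_transform`` maps the centroid x-y to geo-coordinates.
    """
    pts = pc.coords[cluster.point_idx]
    cluster.centroid = pts.mean(axis=0)
    if len(pts) >= 4:
        try:
            hull = ConvexHull(pts)
            cluster.volume_blossom = float(hull.volume)
            cluster.surf_blossom = float(hull.area)
        except (QhullError, ValueError):
            pass
    if len(pts) >= 3:
        try:
            cluster.projarea_blossom = float(ConvexHull(pts[:, :2]).volume)
        except (QhullError, ValueError):
            pass
    occupied = np.unique(np.floor(pts / voxel).astype(np.int64), axis=0)
    cluster.voxel_volume = float(len(occupied) * voxel ** 3)
    if geo_transform is not None:
        gx, gy = geo_transform(cluster.centroid[0], cluster.centroid[1])
        cluster.geo = (float(gx), float(gy))
    return cluster


def _point_segment_dist(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    ab = b - a
    denom = float(ab @ ab)
    t = 0.0 if denom == 0 else float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
    return float(np.linalg.norm(p - (a + t * ab)))


def assign_to_branches(clusters: list[BlossomCluster], branchset: BranchSet,
                       max_assign_dist: float = 0.5) -> list[BlossomCluster]:
    """Attach each cluster to the nearest branch polyline.

    Ties go to the lower branch index; a centroid farther than
    ``max_assign_dist`` from every branch keeps ``branch_id=None`` and is
    only counted at tree level.
    """
    if branchset.num_branch == 0:
        raise ValueError("branch set is empty")
    skel = branchset.skeleton
    polylines = [skel.nodes[path] for path in branchset.branches]
    for c in clusters:
        best = (np.inf, None)
        for bid, line in enumerate(polylines):
            if len(line) == 1:
                d = float(np.linalg.norm(c.centroid - line[0]))
            else:
                d = min(_point_segment_dist(c.centroid, line[i], line[i + 1])
                        for i in range(len(line) - 1))
            if d < best[0] - 1e-12:
                best = (d, bid)
        c.branch_id = best[1] if best[0] <= max_assign_dist else None
    return clusters
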