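"""Skeleton extraction and multi-source registration.

Each tree cloud is contracted onto a curve skeleton by Laplacian-based
contraction; the sparse skeletons of the two views (LiDAR and drone) are
then aligned by a coarse global stage (FPFH feature correspondences with
RANSAC restarts, keeping the minimum-RMSE transform over up to 50 trials)
followed by fine point-to-point ICP. Registering skeletons rather than the
raw clouds keeps the correspondence problem small. The recovered rigid
transform finally maps the full drone cloud into the LiDAR frame for
fusion.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial import cKDTree

from .types import PointCloud, RigidTransform, Skeleton, Source


# ------------------------------------------------- Laplacian contraction

def _knn_laplacian(coords: np.ndarray, k: int) -> sp.csr_matrix:
    """Combinatorial graph Laplacian L = D - A on the symmetrised kNN graph.

    The unnormalised form amplifies the umbrella vector by the vertex
    degree, which is what drives the radial collapse of tubular clouds.
    """
    n = coords.shape[0]
    tree = cKDTree(coords)
    _, nbr = tree.query(coords, k=k + 1)
    rows = np.repeat(np.arange(n), k)
    cols = nbr[:, 1:].ravel()
    A = sp.coo_matrix((np.ones(n * k), (rows, cols)), shape=(n, n))
    A = ((A + A.T) > 0).astype(np.float64)
    deg = np.asarray(A.sum(axis=1)).ravel()
    return (sp.diags(deg) - A).tocsr()


def laplacian_contract(coords: np.ndarray, iterations: int = 6,
                       attraction: float = 1.0, k: int = 10,
                       contraction: float = 4.0) -> np.ndarray:
    """Contract a point set onto its curve skeleton.

    Each iteration solves the regularised system
        (w_L^2 L^T L + w_H^2 I) X' = w_H^2 X
    where L is the kNN-graph Laplacian, w_L the contraction weight
    (amplified each iteration) and w_H the attraction weight anchoring
    points near their previous positions. Divergence (a point leaving the
    input bounding box by more than 10%) raises with the iteration index.
    """
    X = np.asarray(coords, dtype=np.float64).copy()
    n = X.shape[0]
    bbox_lo, bbox_hi = X.min(axis=0), X.max(axis=0)
    margin = 0.1 * max(float(np.max(bbox_hi - bbox_lo)), 1e-6)
    w_l = contraction
    w_h = attraction
    L = _knn_laplacian(X, k)
    for it in range(iterations):
        A = (w_l ** 2) * (L.T @ L) + (w_h ** 2) * sp.eye(n)
        X = spla.spsolve(A.tocsc(), (w_h ** 2) * X)
        X = np.atleast_2d(X)
        if (np.any(X < bbox_lo - margin) or np.any(X > bbox_hi + margin)
                or not np.all(np.isfinite(X))):
            raise RuntimeError(f"contraction diverged at iteration {it}")
        w_l *= 2.0
        # rebuild the graph so merged strands keep contracting
        L = _knn_laplacian(X, k)
    return X


def extract_skeleton(pc: PointCloud, contraction_iters: int = 5,
                     attraction: float = 1.0, node_spacing: float = 0.05,
                     k: int = 10, source=None) -> Skeleton:
    """Contract a denoised tree cloud and resample it into skeleton nodes.

    Contracted points are grouped into nodes on a ``node_spacing`` voxel
    grid (node position = mean of its contracted points); edges come from
    the Euclidean minimum spanning tree over the nodes, which preserves
    the branching topology of a tree-shaped cloud. The per-node
    ``origin_map`` records which input points each node absorbed.
    """
    n = len(pc)
    if n < 100:
        raise ValueError(f"skeleton extraction needs >= 100 points, got {n}")
    contracted = laplacian_contract(pc.coords, iterations=contraction_iters,
                                    attraction=attraction, k=k)
    # voxel-grid clustering of contracted points into nodes
    key = np.floor(contracted / node_spacing).astype(np.int64)
    _, inverse, counts = np.unique(key, axis=0, return_inverse=True,
                                   return_counts=True)
    m = counts.shape[0]
    nodes = np.zeros((m, 3))
    np.add.at(nodes, inverse, contracted)
    nodes /= counts[:, None]
    origin_map = [np.nonzero(inverse == j)[0] for j in range(m)]

    if m >= 2:
        d = np.linalg.norm(nodes[:, None, :] - nodes[None, :, :], axis=2)
        mst = minimum_spanning_tree(d)
        ii, jj = mst.nonzero()
        edges = [(int(a), int(b)) for a, b in zip(ii, jj)]
    else:
        edges = []
    node_int = None
    if pc.intensity is not None:
        node_int = np.array([pc.intensity[idx].mean() for idx in origin_map])
    return Skeleton(nodes=nodes, edges=edges,
                    source=source or pc.source,
                    base_idx=int(np.argmin(nodes[:, 2])),
                    origin_map=origin_map, node_intensity=node_int)


# ------------------------------------------------------------- features

def _estimate_normals(coords: np.ndarray, radius: float) -> np.ndarray:
    """Local direction field within ``radius`` for the Darboux frames.

    On curve skeletons the surface normal is degenerate, so the dominant
    PCA direction (the local tangent) is used instead, oriented upward
    (trees grow up; near-horizontal tangents are oriented away from the
    centroid to fix the sign).
    """
    tree = cKDTree(coords)
    centroid = coords.mean(axis=0)
    normals = np.zeros_like(coords)
    for i, p in enumerate(coords):
        idx = tree.query_ball_point(p, radius)
        if len(idx) < 3:
            _, idx = tree.query(p, k=min(4, len(coords)))
        q = coords[idx] - coords[idx].mean(axis=0)
        _, _, vt = np.linalg.svd(q, full_matrices=False)
        tang = vt[0]
        if abs(tang[2]) > 0.2:
            if tang[2] < 0:
                tang = -tang
        elif np.dot(tang, p - centroid) < 0:
            tang = -tang
        normals[i] = tang
    return normals


def fpfh_features(coords: np.ndarray, feature_radius: float,
                  normal_radius: float, n_bins: int = 11) -> np.ndarray:
    """Fast point feature histograms (33-D) for every point.

    The simplified point feature histogram (SPFH) bins the three Darboux
    angles between each point and its radius neighbours; the FPFH then
    mixes in the distance-weighted SPFHs of the neighbours.
    """
    n = coords.shape[0]
    normals = _estimate_normals(coords, normal_radius)
    tree = cKDTree(coords)
    neighbours = tree.query_ball_point(coords, feature_radius)
    spfh = np.zeros((n, 3 * n_bins))
    for i in range(n):
        idx = [j for j in neighbours[i] if j != i]
        if not idx:
            continue
        d = coords[idx] - coords[i]
        dist = np.linalg.norm(d, axis=1)
        ok = dist > 1e-12
        if not ok.any():
            continue
        d, dist = d[ok] / dist[ok, None], dist[ok]
        n2 = normals[idx][ok]
        u = normals[i]
        v = np.cross(d, np.broadcast_to(u, d.shape))
        vn = np.linalg.norm(v, axis=1)
        vok = vn > 1e-12
        v[vok] /= vn[vok, None]
        w = np.cross(np.broadcast_to(u, v.shape), v)
        f1 = np.einsum("ij,ij->i", v, n2)                      # in [-1, 1]
        f2 = d @ u                                             # in [-1, 1]
        f3 = np.arctan2(np.einsum("ij,ij->i", w, n2), n2 @ u)  # in [-pi, pi]
        for k_, (f, lo, hi) in enumerate(
                [(f1, -1, 1), (f2, -1, 1), (f3, -np.pi, np.pi)]):
            b = np.clip(((f - lo) / (hi - lo) * n_bins).astype(int), 0,
                        n_bins - 1)
            np.add.at(spfh[i], k_ * n_bins + b, 1.0)
        s = spfh[i].sum()
        if s > 0:
            spfh[i] /= s
    fpfh = spfh.copy()
    for i in range(n):
        idx = [j for j in neighbours[i] if j != i]
        if not idx:
            continue
        dist = np.linalg.norm(coords[idx] - coords[i], axis=1)
        wgt = 1.0 / np.maximum(dist, 1e-9)
        fpfh[i] += (wgt[:, None] * spfh[idx]).sum(axis=0) / wgt.sum()
    return fpfh


def _kabsch(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation + translation mapping src onto dst (least squares)."""
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    H = (src - mu_s).T @ (dst - mu_d)
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    return R, mu_d - R @ mu_s


def _nn_rmse(src: np.ndarray, dst_tree: cKDTree) -> float:
    d, _ = dst_tree.query(src)
    return float(np.sqrt(np.mean(d ** 2)))


def coarse_register(src: Skeleton, dst: Skeleton, max_iters: int = 50,
                    seed: int = 42,
                    max_rotation_deg: float = 60.0) -> RigidTransform:
    """Coarse global registration of src onto dst skeleton nodes.

    FPFH correspondences (top feature matches) feed a RANSAC loop: each
    restart samples three correspondences, gates them on pairwise-length
    compatibility, solves the rigid fit, and scores it by
    nearest-neighbour RMSE; up to ``max_iters`` restarts run and the
    minimum-RMSE transform wins. Candidate rotations beyond
    ``max_rotation_deg`` are rejected: the two surveys of one orchard are
    both coarsely levelled and georeferenced, so the true relative
    rotation is moderate, and the gate stops near-symmetric crowns from
    locking onto a rotated match.
    """
    P, Q = src.nodes, dst.nodes
    if len(P) < 10 or len(Q) < 10:
        raise ValueError("coarse registration needs >= 10 nodes per skeleton")
    spacing = np.mean([np.median(cKDTree(X).query(X, k=2)[0][:, 1])
                       for X in (P, Q)])
    f_src = fpfh_features(P, 5.0 * spacing, 2.5 * spacing)
    f_dst = fpfh_features(Q, 5.0 * spacing, 2.5 * spacing)
    # top-4 feature matches per source node as the candidate pool
    kf = min(4, len(Q))
    _, fwdk = cKDTree(f_dst).query(f_src, k=kf)
    corr_s = np.repeat(np.arange(len(P)), kf)
    corr_d = np.atleast_2d(fwdk).reshape(len(P), kf).ravel()
    if len(corr_s) < 3:
        raise RuntimeError(
            "no reliable feature correspondences; try a larger feature radius")

    rng = np.random.default_rng(seed)
    dst_tree = cKDTree(Q)
    inlier_thresh = 3.0 * spacing
    good_rmse = 1.5 * spacing
    best = (np.inf, None)
    for _ in range(max_iters):
        # one restart: a RANSAC pass over perturbed correspondence samples
        for _ in range(150):
            pick = rng.choice(len(corr_s), size=3, replace=False)
            s3, d3 = P[corr_s[pick]], Q[corr_d[pick]]
            # FGR-style compatibility gate: pairwise lengths must agree
            ds = np.linalg.norm(s3 - np.roll(s3, 1, axis=0), axis=1)
            dd = np.linalg.norm(d3 - np.roll(d3, 1, axis=0), axis=1)
            if np.any(np.abs(ds - dd) > inlier_thresh) or np.any(ds < spacing):
                continue
            try:
                R, t = _kabsch(s3, d3)
            except np.linalg.LinAlgError:
                continue
            ang = np.degrees(np.arccos(np.clip((np.trace(R) - 1) / 2, -1, 1)))
            if ang > max_rotation_deg:
                continue
            rmse = _nn_rmse(P @ R.T + t, dst_tree)
            if rmse < best[0]:
                best = (rmse, (R, t))
        if best[0] < good_rmse:
            break
    if best[1] is None:
        raise RuntimeError("coarse registration found no valid transform")
    R, t = best[1]
    # the minimum-RMSE sample transform is the coarse result; least-squares
    # refinement over dense correspondences is the fine (ICP) stage's job
    return RigidTransform.from_rt(R, t, rmse=best[0])


def fine_register(src: Skeleton, dst: Skeleton, init: RigidTransform,
                  max_corr_dist: float = 0.10, max_iters: int = 100,
                  rel_tol: float = 1e-6) -> RigidTransform:
    """Point-to-point ICP refinement starting from ``init``.

    Correspondences beyond ``max_corr_dist`` are rejected each sweep; the
    objective (correspondence RMSE) is non-increasing, and iteration stops
    on relative improvement below ``rel_tol`` or the iteration cap (the
    best-so-far transform is returned with ``converged=False`` then).
    """
    P, Q = src.nodes, dst.nodes
    dst_tree = cKDTree(Q)
    R, t = init.rotation.copy(), init.translation.copy()
    prev = np.inf
    converged = False
    for _ in range(max_iters):
        moved = P @ R.T + t
        d, j = dst_tree.query(moved)
        keep = d <= max_corr_dist
        if keep.sum() < 3:
            break
        rmse = float(np.sqrt(np.mean(d[keep] ** 2)))
        if np.isfinite(prev) and prev - rmse <= rel_tol * max(prev, 1e-12):
            converged = True
            break
        prev = rmse
        R, t = _kabsch(P[keep], Q[j[keep]])
    rmse = _nn_rmse(P @ R.T + t, dst_tree)
    return RigidTransform.from_rt(R, t, rmse=rmse, converged=converged)


def register(src: Skeleton, dst: Skeleton, max_corr_dist: float = 0.10,
             seed: int = 42) -> RigidTransform:
    """Coarse (FPFH + RANSAC) then fine (ICP) registration, drone -> lidar."""
    coarse = coarse_register(src, dst, seed=seed)
    return fine_register(src, dst, coarse, max_corr_dist=max_corr_dist)


# -------------------------------------------------------------- fusion

def apply_transform(pc: PointCloud, T: RigidTransform) -> PointCloud:
    """Apply a rigid motion to a cloud (pairwise distances preserved)."""
    if not isinstance(T, RigidTransform):
        T = RigidTransform(T)  # validates rigidity
    return pc.with_coords(T.apply(pc.coords))


def fuse_clouds(lidar_pc: PointCloud, drone_pc: PointCloud,
                T: RigidTransform) -> PointCloud:
    """Union of the LiDAR cloud and the transformed drone cloud.

    Colour is carried from the drone points and intensity from the LiDAR
    points (missing channels are NaN-padded / zero-padded); per-point
    provenance is attached as ``fused.provenance`` ("lidar"/"drone").
    """
    if lidar_pc.source == drone_pc.source:
        raise ValueError("fusion expects clouds from two different sources")
    moved = T.apply(drone_pc.coords)
    coords = np.vstack([lidar_pc.coords, moved])
    n_l, n_d = len(lidar_pc), len(drone_pc)
    intensity = None
    if lidar_pc.intensity is not None:
        intensity = np.concatenate([lidar_pc.intensity, np.full(n_d, np.nan)])
    rgb = None
    if drone_pc.rgb is not None:
        pad = np.zeros((n_l, 3), dtype=np.int64)
        rgb = np.vstack([pad, drone_pc.rgb])
    fused = PointCloud(coords=coords, intensity=intensity, rgb=rgb,
                       crs=lidar_pc.crs, source=lidar_pc.source)
    fused.provenance = np.array(["lidar"] * n_l + ["drone"] * n_d)
    return fused
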