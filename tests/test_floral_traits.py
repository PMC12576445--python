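"""Blossom masking, clustering, classification, splitting and metrics."""

import itertools

import numpy as np
import pytest

import canopy3d as c3
from canopy3d import floral_traits as ft
from canopy3d import skeleton_fusion as sf
from canopy3d import skeleton_refinement as sr
from canopy3d.types import Skeleton


# ------------------------------------------------------------ blossom_mask

def test_mask_white_vs_green(rng):
    coords = rng.uniform(0, 1, (200, 3))
    rgb = np.vstack([np.tile([250, 248, 245], (100, 1)),
                     np.tile([60, 120, 50], (100, 1))])
    pc = c3.PointCloud(coords, rgb=rgb)
    idx = ft.blossom_mask(pc)
    assert set(idx) == set(range(100))


def test_mask_identical_colours_all_retained(rng):
    pc = c3.PointCloud(rng.uniform(0, 1, (50, 3)),
                       rgb=np.tile([200, 200, 200], (50, 1)))
    assert len(ft.blossom_mask(pc)) == 50


def test_mask_no_rgb_raises(rng):
    with pytest.raises(ValueError):
        ft.blossom_mask(c3.PointCloud(rng.uniform(0, 1, (10, 3))))


def test_mask_generator_recall_precision(tree_pair):
    _, drone, truth = tree_pair
    idx = ft.blossom_mask(drone)
    lab = truth.drone_labels
    recall = (lab[idx] == "blossom").sum() / (lab == "blossom").sum()
    precision = (lab[idx] == "blossom").mean()
    assert recall >= 0.95
    assert precision >= 0.90


# ----------------------------------------------------- remove_near_skeleton

def test_remove_near_skeleton_trivials(rng):
    skel = Skeleton(np.array([[0, 0, 0.0], [0, 0, 1.0]]), edges=[(0, 1)])
    pc = c3.PointCloud(np.array([[0, 0, 0.5], [0.3, 0, 0.5]]))
    # on the trunk axis -> removed; at 3r from the skeleton -> kept
    kept = ft.remove_near_skeleton(pc, np.array([0, 1]), skel, r=0.1)
    assert list(kept) == [1]


def test_remove_near_skeleton_empty_skeleton_warns(rng):
    pc = c3.PointCloud(rng.uniform(0, 1, (10, 3)))
    skel = Skeleton(np.zeros((0, 3)))
    with pytest.warns(UserWarning):
        kept = ft.remove_near_skeleton(pc, np.arange(10), skel, r=0.1)
    assert len(kept) == 10


def test_remove_near_skeleton_cuts_branch_surface(tree_pair, rng):
    """Bright wood-surface false positives (sun-lit bark) drop by >= 80%
    while blossom recall stays above 95%."""
    lidar, drone, truth = tree_pair
    reg = sf.apply_transform(drone, truth.transform)
    r = sr.estimate_trunk_radius(lidar)
    skel = c3.extract_skeleton(lidar)
    lab = truth.drone_labels
    blossom_idx = np.nonzero(lab == "blossom")[0]
    wood_idx = rng.choice(np.nonzero(lab == "branch")[0], 200, replace=False)
    cand = np.concatenate([blossom_idx, wood_idx])
    kept = set(ft.remove_near_skeleton(reg, cand, skel, r=r).tolist())
    wood_kept = sum(1 for i in wood_idx if i in kept)
    blossom_kept = sum(1 for i in blossom_idx if i in kept)
    assert wood_kept <= 0.2 * len(wood_idx)
    assert blossom_kept >= 0.95 * len(blossom_idx)


# ---------------------------------------------------------------- stratify

def test_stratify_bands():
    z = np.array([0.0, 0.5, 1.0, 1.0 / 3.0])
    labels = ft.stratify(z, crown_base_z=0.0, apex_z=1.0)
    assert labels[0] == "lower"
    assert labels[1] == "middle"
    assert labels[2] == "upper"
    assert labels[3] == "lower"  # boundary goes to the lower band


def test_stratify_requires_positive_span():
    with pytest.raises(ValueError):
        ft.stratify(np.array([0.5]), 1.0, 1.0)


# --------------------------------------------------------- cluster_blossoms

def _blob_cloud(rng, centres, n_each=100, sigma=0.01):
    pts = np.vstack([rng.normal(c, sigma, (n_each, 3)) for c in centres])
    return c3.PointCloud(pts)


def test_cluster_two_separated_blobs(rng):
    pc = _blob_cloud(rng, [[0, 0, 0], [1, 0, 0]])
    clusters = ft.cluster_blossoms(pc, np.arange(len(pc)), eps=0.05)
    assert len(clusters) == 2
    assert sorted(c.n for c in clusters) == [100, 100]


def test_cluster_below_floor_yields_nothing(rng):
    pc = c3.PointCloud(rng.normal(0, 0.01, (15, 3)))
    assert ft.cluster_blossoms(pc, np.arange(15), eps=0.05) == []


def _naive_dbscan(pts, eps, min_pts):
    """Textbook DBSCAN by BFS over the eps-graph (oracle)."""
    n = len(pts)
    d = np.linalg.norm(pts[:, None] - pts[None], axis=2)
    neighbours = [np.nonzero(d[i] <= eps)[0] for i in range(n)]
    core = np.array([len(nb) >= min_pts for nb in neighbours])
    labels = np.full(n, -1)
    cid = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        stack = [i]
        labels[i] = cid
        while stack:
            j = stack.pop()
            if not core[j]:
                continue
            for k in neighbours[j]:
                if labels[k] == -1:
                    labels[k] = cid
                    stack.append(k)
        cid += 1
    return labels


def test_cluster_matches_naive_dbscan_oracle(rng):
    pts = np.vstack([rng.normal([0, 0, 0], 0.02, (80, 3)),
                     rng.normal([0.2, 0, 0], 0.02, (80, 3)),
                     rng.uniform(-0.5, 0.7, (40, 3))])
    pc = c3.PointCloud(pts)
    for eps in [0.03, 0.06, 0.12]:
        mine = ft.cluster_blossoms(pc, np.arange(len(pts)), eps=eps,
                                   min_pts=20)
        oracle = _naive_dbscan(pts, eps, 20)
        ocl = [np.nonzero(oracle == c)[0] for c in range(oracle.max() + 1)
               if (oracle == c).sum() >= 20]
        assert len(mine) == len(ocl)
        mine_sets = {frozenset(c.point_idx.tolist()) for c in mine}
        # label-region agreement up to border-point attachment
        for oc in ocl:
            best = max(len(frozenset(oc.tolist()) & m) / len(oc)
                       for m in mine_sets)
            assert best >= 0.95


# -------------------------------------------------------- classify_clusters

def _made_cluster(pc_list, rng, centre, n, sigma):
    pts = rng.normal(centre, sigma, (n, 3))
    start = sum(len(p) for p in pc_list)
    pc_list.append(pts)
    return np.arange(start, start + n)


def test_classify_small_cluster_is_noise(rng):
    parts = []
    idx1 = _made_cluster(parts, rng, [0, 0, 0], 49, 0.01)
    idx2 = _made_cluster(parts, rng, [1, 0, 0], 80, 0.01)
    idx3 = _made_cluster(parts, rng, [2, 0, 0], 85, 0.01)
    pc = c3.PointCloud(np.vstack(parts))
    clusters = [ft.BlossomCluster(point_idx=i, centroid=pc.coords[i].mean(0))
                for i in (idx1, idx2, idx3)]
    out = ft.classify_clusters(pc, clusters, seed=0)
    assert out[0].cls == "noise"       # n = 49 < 50
    assert out[1].cls in ("single", "multi")  # n = 80 is eligible


def test_classify_two_populations(rng):
    parts = []
    idxs, truth = [], []
    for i in range(8):
        idxs.append(_made_cluster(parts, rng, [i, 0, 0], 80, 0.01))
        truth.append("single")
    for i in range(6):
        idxs.append(_made_cluster(parts, rng, [i, 2, 0], 300, 0.03))
        truth.append("multi")
    pc = c3.PointCloud(np.vstack(parts))
    clusters = [ft.BlossomCluster(point_idx=i, centroid=pc.coords[i].mean(0))
                for i in idxs]
    out = ft.classify_clusters(pc, clusters, seed=0)
    correct = sum(c.cls == t for c, t in zip(out, truth))
    assert correct / len(truth) >= 0.95


def test_classify_order_invariant_and_deterministic(rng):
    parts = []
    idxs = []
    for i in range(5):
        idxs.append(_made_cluster(parts, rng, [i, 0, 0], 80, 0.01))
    for i in range(4):
        idxs.append(_made_cluster(parts, rng, [i, 2, 0], 300, 0.03))
    pc = c3.PointCloud(np.vstack(parts))

    def classify(order):
        clusters = [ft.BlossomCluster(point_idx=idxs[j],
                                      centroid=pc.coords[idxs[j]].mean(0))
                    for j in order]
        out = ft.classify_clusters(pc, clusters, seed=7)
        return {int(c.point_idx[0]): c.cls for c in out}

    a = classify(list(range(9)))
    b = classify(list(reversed(range(9))))
    assert a == b


# --------------------------------------------------------- split_multiflower

def test_split_two_touching_flowers(rng):
    a = rng.normal([0, 0, 0], 0.008, (150, 3))
    b = rng.normal([0.06, 0, 0], 0.008, (150, 3))
    pc = c3.PointCloud(np.vstack([a, b]))
    cluster = ft.BlossomCluster(point_idx=np.arange(300),
                                centroid=pc.coords.mean(0), cls="multi")
    singles = ft.split_multiflower(pc, cluster, eps=0.05)
    assert len(singles) == 2
    union = np.concatenate([s.point_idx for s in singles])
    assert set(union) <= set(range(300))          # conservation
    assert len(union) == len(set(union))          # disjoint


def test_split_rejects_non_multi(rng):
    pc = c3.PointCloud(rng.normal(0, 0.01, (100, 3)))
    cluster = ft.BlossomCluster(point_idx=np.arange(100),
                                centroid=pc.coords.mean(0), cls="single")
    with pytest.raises(ValueError):
        ft.split_multiflower(pc, cluster, eps=0.05)


def test_split_unsplittable_multi_returns_one_single(rng):
    pc = c3.PointCloud(rng.normal(0, 0.01, (200, 3)))
    cluster = ft.BlossomCluster(point_idx=np.arange(200),
                                centroid=pc.coords.mean(0), cls="multi")
    singles = ft.split_multiflower(pc, cluster, eps=0.05)
    assert len(singles) == 1
    assert singles[0].cls == "single"


# ----------------------------------------------------------- cluster_metrics

def test_metrics_unit_cube():
    corners = np.array(list(itertools.product([0.0, 1.0], repeat=3)))
    pc = c3.PointCloud(corners)
    cl = ft.BlossomCluster(point_idx=np.arange(8), centroid=corners.mean(0))
    ft.cluster_metrics(pc, cl)
    assert cl.volume_blossom == pytest.approx(1.0, abs=1e-12)
    assert cl.surf_blossom == pytest.approx(6.0, abs=1e-12)


def test_metrics_spherical_blob(rng):
    v = rng.normal(size=(500, 3))
    v = 0.02 * v / np.linalg.norm(v, axis=1, keepdims=True)
    pc = c3.PointCloud(v)
    cl = ft.BlossomCluster(point_idx=np.arange(500), centroid=v.mean(0))
    ft.cluster_metrics(pc, cl)
    assert cl.volume_blossom == pytest.approx(3.351e-5, rel=0.15)


def test_metrics_centroid_of_symmetric_blob():
    th = np.linspace(0, 2 * np.pi, 64, endpoint=False)
    ring = np.column_stack([np.cos(th), np.sin(th), np.zeros(64)]) + [5, 5, 5]
    pc = c3.PointCloud(ring)
    cl = ft.BlossomCluster(point_idx=np.arange(64), centroid=np.zeros(3))
    ft.cluster_metrics(pc, cl)
    assert np.allclose(cl.centroid, [5, 5, 5], atol=1e-12)


def test_metrics_degenerate_keeps_count_and_centroid(rng):
    line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
    pc = c3.PointCloud(line)
    cl = ft.BlossomCluster(point_idx=np.arange(5), centroid=np.zeros(3))
    ft.cluster_metrics(pc, cl)
    assert np.isnan(cl.volume_blossom)
    assert cl.n == 5
    assert np.allclose(cl.centroid, [2, 0, 0])


# ------------------------------------------------------- assign_to_branches

def _branchset():
    # branch 0 runs along +x and branch 1 along +y, both at z = 1
    nodes = np.array([[0, 0, 0]] +
                     [[0.1 * i, 0, 1.0] for i in range(1, 11)] +
                     [[0, 0.1 * i, 1.0] for i in range(1, 11)], dtype=float)
    skel = Skeleton(nodes)
    return c3.BranchSet(trunk_path=[0],
                        branches=[list(range(1, 11)),
                                  list(range(11, 21))],
                        r_trunk=0.05, skeleton=skel)


def test_assign_cluster_on_branch_midpoint():
    bs = _branchset()
    cl = ft.BlossomCluster(point_idx=np.arange(1),
                           centroid=np.array([0.5, 0.0, 1.0]))
    ft.assign_to_branches([cl], bs)
    assert cl.branch_id == 0


def test_assign_tie_goes_to_lower_branch():
    bs = _branchset()
    # (0.3, 0.3, 1.0) is exactly 0.3 from both polylines
    cl = ft.BlossomCluster(point_idx=np.arange(1),
                           centroid=np.array([0.3, 0.3, 1.0]))
    ft.assign_to_branches([cl], bs)
    assert cl.branch_id == 0


def test_assign_far_cluster_unassigned():
    bs = _branchset()
    cl = ft.BlossomCluster(point_idx=np.arange(1),
                           centroid=np.array([5.0, 5.0, 5.0]))
    ft.assign_to_branches([cl], bs)
    assert cl.branch_id is None


def test_assign_generator_truth(tree_suite):
    """Clusters planted on known branches map to the right detected branch."""
    res = tree_suite[2]
    truth, refined, bs = res["truth"], res["refined"], res["branchset"]
    if bs.num_branch == 0:
        pytest.skip("no branches recovered on this tree")

    def segd(p, a, b):
        ab = b - a
        t = np.clip((p - a) @ ab / (ab @ ab), 0, 1)
        return np.linalg.norm(p - (a + t * ab))

    # map each detected branch to its truth branch by mean axis distance
    det2truth = []
    for path in bs.branches:
        means = [np.mean([segd(refined.nodes[v], a, b) for v in path])
                 for a, b in truth.branch_axes]
        det2truth.append(int(np.argmin(means)))

    clusters = [ft.BlossomCluster(point_idx=np.arange(1), centroid=c)
                for c in truth.cluster_centroids]
    ft.assign_to_branches(clusters, bs)
    ok = sum(1 for cl, tb in zip(clusters, truth.cluster_branch_ids)
             if cl.branch_id is not None and
             det2truth[cl.branch_id] == tb)
    assigned = sum(1 for cl in clusters if cl.branch_id is not None)
    assert assigned >= 0.9 * len(clusters)
    assert ok / max(assigned, 1) >= 0.9
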