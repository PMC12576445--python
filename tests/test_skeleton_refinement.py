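"""Tree graph, support pruning, gap filling, smoothing, branch counting."""

import warnings

import networkx as nx
import numpy as np
import pytest
from scipy.sparse.csgraph import shortest_path

import canopy3d as c3
from canopy3d import skeleton_refinement as sr
from canopy3d.types import Skeleton

from conftest import cylinder, refine_tree


# ----------------------------------------------------- trunk radius

def test_trunk_radius_cylinder(rng):
    pts = cylinder(rng, [0, 0, 0], [0, 0, 1], 0.05, 4000)
    r = sr.estimate_trunk_radius(c3.PointCloud(pts))
    assert r == pytest.approx(0.05, abs=0.002)


def test_trunk_radius_ring_exact():
    """A hollow ring inside the measurement slab gives the radius exactly."""
    th = np.linspace(0, 2 * np.pi, 200, endpoint=False)
    ring = np.column_stack([0.1 * np.cos(th), 0.1 * np.sin(th),
                            np.full(200, 0.3)])
    base = np.array([[0.0, 0.0, 0.0]])  # the trunk base below the slab
    r = sr.estimate_trunk_radius(c3.PointCloud(np.vstack([base, ring])))
    assert r == pytest.approx(0.1, abs=1e-6)


def test_trunk_radius_contaminated_slab(rng):
    trunk = cylinder(rng, [0, 0, 0], [0, 0, 1], 0.05, 3000)
    branch = cylinder(rng, [0, 0, 0.25], [0.5, 0, 0.45], 0.03, 300)
    r = sr.estimate_trunk_radius(c3.PointCloud(np.vstack([trunk, branch])))
    assert abs(r - 0.05) / 0.05 <= 0.20


def test_trunk_radius_sparse_slab_falls_back(rng):
    # a low base plus geometry far above it: the slab just over the base
    # is empty, forcing the bottom-decile fallback
    low = rng.normal([0, 0, 0.0], 0.01, (10, 3))
    high = cylinder(rng, [0, 0, 1.0], [0, 0, 2.0], 0.05, 300)
    with pytest.warns(UserWarning):
        r = sr.estimate_trunk_radius(c3.PointCloud(np.vstack([low, high])))
    assert 0 < r <= 0.5


# ----------------------------------------------------- build_tree_graph

def _skel(nodes):
    return Skeleton(np.asarray(nodes, dtype=float))


def test_graph_three_collinear_small_radius():
    g = sr.build_tree_graph(_skel([[0, 0, 0], [0, 0, 0.05], [0, 0, 0.10]]),
                            radius=0.06, spacing_floor=False)
    assert g.graph.number_of_edges() == 2


def test_graph_three_collinear_large_radius():
    g = sr.build_tree_graph(_skel([[0, 0, 0], [0, 0, 0.05], [0, 0, 0.10]]),
                            radius=0.11, spacing_floor=False)
    assert g.graph.number_of_edges() == 3  # 0.10 <= 0.11 closes the triangle


def test_graph_weights_are_squared_distance():
    g = sr.build_tree_graph(_skel([[0, 0, 0], [0, 0, 0.05], [0, 0, 0.10]]),
                            radius=0.06, spacing_floor=False)
    assert g.graph[0][1]["weight"] == pytest.approx(0.05 ** 2)


def test_graph_base_is_lowest_regardless_of_order():
    g = sr.build_tree_graph(
        _skel([[0, 0, 1.0], [0, 0, -0.5], [0, 0, 0.2]]), radius=2.0,
        spacing_floor=False)
    assert g.base == 1


def test_graph_empty_edge_set_raises():
    with pytest.raises(ValueError):
        sr.build_tree_graph(_skel([[0, 0, 0], [5, 5, 5]]), radius=0.1,
                            spacing_floor=False)


# ------------------------------------------------- graph_prune_supports

def _t_tree_with_post():
    """T-shaped tree plus a parallel post connected only near the ground."""
    trunk = [[0, 0, 0.1 * i] for i in range(11)]           # 0..10
    arm = [[0.1 * i, 0, 1.0] for i in range(1, 6)]          # 11..15
    post = [[0.3, 0, 0.05 + 0.1 * i] for i in range(10)]    # 16..25
    nodes = np.array(trunk + arm + post, dtype=float)
    skel = Skeleton(nodes)
    g = sr.build_tree_graph(skel, radius=0.35, spacing_floor=False)
    return g, len(trunk), len(arm), len(post)


def test_prune_removes_parallel_post():
    g, nt, na, npost = _t_tree_with_post()
    pruned, kept, _ = sr.graph_prune_supports(g)
    post_ids = set(range(nt + na, nt + na + npost))
    # the post survives at most where a shortest path clips its base
    assert len(post_ids & set(kept)) <= 2
    kept_set = set(int(k) for k in kept)
    assert len(set(range(nt)) & kept_set) >= nt - 2   # trunk essentially intact
    assert nt + na - 1 in kept_set                    # arm tip intact


def test_prune_pure_path_graph_identity():
    nodes = [[0, 0, 0.1 * i] for i in range(8)]
    g = sr.build_tree_graph(_skel(nodes), radius=0.15, spacing_floor=False)
    pruned, kept, _ = sr.graph_prune_supports(g)
    assert list(kept) == list(range(8))


def test_prune_shared_trunk_counted_once():
    g, nt, na, _ = _t_tree_with_post()
    pruned, kept, _ = sr.graph_prune_supports(g)
    assert len(kept) == len(set(kept))


def test_prune_matches_brute_force_oracle(rng):
    """Path-union pruning equals an all-pairs shortest-path oracle on a
    small random geometric graph."""
    nodes = rng.uniform(0, 1, (40, 3))
    skel = Skeleton(nodes)
    g = sr.build_tree_graph(skel, radius=0.45, spacing_floor=False)
    _, kept, unreach = sr.graph_prune_supports(g)

    # oracle: dense all-pairs shortest paths with predecessor recovery
    W = np.full((40, 40), np.inf)
    for u, v, data in g.graph.edges(data=True):
        W[u, v] = W[v, u] = data["weight"]
    D, pred = shortest_path(W, method="FW", return_predecessors=True)
    expect = {g.base}
    for tip in g.tips:
        if not np.isfinite(D[g.base, tip]):
            continue
        v = tip
        while v != g.base and v >= 0:
            expect.add(int(v))
            v = pred[g.base, v]
    assert set(kept) == expect


# --------------------------------------------- intensity_prune_supports

def _labelled_fixture(rng):
    """Wood-dominated skeleton with a minority of bright support nodes."""
    branch_pts = cylinder(rng, [0, 0, 0], [0, 0, 2], 0.04, 4000)
    arm_pts = cylinder(rng, [0, 0, 1.0], [1.5, 0, 1.6], 0.03, 2000)
    post_pts = cylinder(rng, [0.5, 0, 0], [0.5, 0, 0.7], 0.03, 600)
    inten = np.concatenate([
        np.clip(rng.normal(0.3, 0.02, 6000), 0, 1),
        np.clip(rng.normal(0.9, 0.02, 600), 0, 1)])
    pc = c3.PointCloud(np.vstack([branch_pts, arm_pts, post_pts]),
                       intensity=inten)
    b_nodes = [[0, 0, 0.1 * i] for i in range(21)] + \
              [[0.1 * i, 0, 1.0 + 0.04 * i] for i in range(1, 16)]
    p_nodes = [[0.5, 0, 0.1 * i] for i in range(8)]
    skel = Skeleton(np.array(b_nodes + p_nodes, dtype=float))
    return pc, skel, len(b_nodes)


def test_intensity_prune_separates_materials(rng):
    pc, skel, nb = _labelled_fixture(rng)
    pruned, kept, removed = sr.intensity_prune_supports(skel, pc, r=0.05,
                                                        alpha=1.0)
    post_nodes = set(range(nb, len(skel)))
    kept_set = set(kept)
    assert len(post_nodes - kept_set) / len(post_nodes) >= 0.95
    assert len(set(range(nb)) - kept_set) / nb <= 0.05


def test_intensity_prune_uniform_no_removal(rng):
    pc, skel, _ = _labelled_fixture(rng)
    pc.intensity = np.full(len(pc), 0.5)
    _, kept, _ = sr.intensity_prune_supports(skel, pc, r=0.05, alpha=1.0)
    assert len(kept) == len(skel)


def test_intensity_prune_alpha_infinity_identity(rng):
    pc, skel, _ = _labelled_fixture(rng)
    _, kept, _ = sr.intensity_prune_supports(skel, pc, r=0.05, alpha=1e9)
    assert len(kept) == len(skel)


def test_intensity_prune_no_channel_warns(rng):
    pc, skel, _ = _labelled_fixture(rng)
    pc.intensity = None
    with pytest.warns(UserWarning):
        out, kept, removed = sr.intensity_prune_supports(skel, pc, r=0.05)
    assert len(kept) == len(skel)


# ------------------------------------------------------------ fill_gaps

def _broken_line_skeleton():
    """A chain with a 10 cm hole in the middle."""
    lo = [[0, 0, 0.02 * i] for i in range(10)]        # z 0 .. 0.18
    hi = [[0, 0, 0.30 + 0.02 * i] for i in range(10)]  # z 0.30 .. 0.48
    nodes = np.array(lo + hi, dtype=float)
    edges = [(i, i + 1) for i in range(9)] + \
            [(10 + i, 11 + i) for i in range(9)]
    return Skeleton(nodes, edges=edges)


def _line_cloud(rng):
    z = rng.uniform(0, 0.5, 3000)
    return c3.PointCloud(np.column_stack(
        [rng.normal(0, 0.004, 3000), rng.normal(0, 0.004, 3000), z]))


def test_fill_bridges_gap_with_few_voxels(rng):
    skel = _broken_line_skeleton()
    pc = _line_cloud(rng)
    filled, info = sr.fill_gaps(skel, pc, voxel=0.02, removed_mask=None)
    g = nx.Graph()
    g.add_nodes_from(range(len(filled)))
    g.add_edges_from(filled.edges)
    assert nx.number_connected_components(g) == 1
    assert info["added"] <= 8


def test_fill_connected_input_is_identity(rng):
    nodes = [[0, 0, 0.05 * i] for i in range(10)]
    skel = Skeleton(np.array(nodes, dtype=float),
                    edges=[(i, i + 1) for i in range(9)])
    filled, info = sr.fill_gaps(skel, _line_cloud(rng), voxel=0.02)
    assert info["added"] == 0
    assert np.allclose(filled.nodes, skel.nodes)


def test_fill_never_bridges_through_removed_supports(rng):
    """The only voxels crossing the gap belong to a removed support: the
    orphan component must be dropped, not reconnected."""
    skel = _broken_line_skeleton()
    z = rng.uniform(0, 0.5, 2000)
    gap = (z > 0.18) & (z < 0.30)
    coords = np.column_stack(
        [rng.normal(0, 0.004, 2000), rng.normal(0, 0.004, 2000), z])
    # the cloud has no wood points inside the hole
    coords = coords[~gap]
    # a support strut is the only geometry crossing the hole
    strut = np.column_stack([np.full(60, 0.0), np.full(60, 0.0),
                             np.linspace(0.18, 0.30, 60)])
    pc = c3.PointCloud(np.vstack([coords, strut]))
    removed_mask = strut[::5]
    filled, info = sr.fill_gaps(skel, pc, voxel=0.02,
                                removed_mask=removed_mask)
    assert info["dropped_components"] == 1
    # no added node may sit near the removed support
    from scipy.spatial import cKDTree
    added = filled.nodes[len(filled) - info["added"]:] if info["added"] \
        else np.zeros((0, 3))
    if len(added):
        assert cKDTree(removed_mask).query(added)[0].min() > 0.04


# ---------------------------------------------------- smooth_interpolate

def test_smooth_straight_path_unchanged(rng):
    nodes = np.array([[0, 0, 0.05 * i] for i in range(20)], dtype=float)
    skel = Skeleton(nodes, edges=[(i, i + 1) for i in range(19)])
    out = sr.smooth_interpolate(skel, window=5)
    d = np.abs(np.hypot(out.nodes[:, 0], out.nodes[:, 1]))
    assert d.max() <= 1e-9  # still on the line after resampling


def test_smooth_reduces_zigzag_deviation(rng):
    t = np.arange(30)
    nodes = np.column_stack([0.02 * (-1.0) ** t, np.zeros(30), 0.05 * t])
    skel = Skeleton(nodes, edges=[(i, i + 1) for i in range(29)])
    out = sr.smooth_interpolate(skel, window=5)
    # interior deviation strictly shrinks (endpoints are fixed anchors)
    assert np.abs(out.nodes[2:, 0]).max() < 0.02


def test_smooth_preserves_junction_count():
    trunk = [[0, 0, 0.1 * i] for i in range(11)]
    arm = [[0.1 * i, 0, 0.5] for i in range(1, 8)]
    nodes = np.array(trunk + arm, dtype=float)
    # the arm hangs off trunk node 5 -> exactly one degree-3 junction
    edges = [(i, i + 1) for i in range(10)] + [(5, 11)] + \
            [(11 + i, 12 + i) for i in range(6)]
    skel = Skeleton(nodes, edges=edges)

    def junctions(s):
        deg = np.zeros(len(s), dtype=int)
        for u, v in s.edges:
            deg[u] += 1
            deg[v] += 1
        return (deg >= 3).sum()

    out = sr.smooth_interpolate(skel, window=5)
    assert junctions(out) == junctions(skel) == 1


def test_smooth_window_clamped_on_short_path():
    nodes = np.array([[0, 0, 0], [0, 0, 0.05], [0, 0, 0.1]], dtype=float)
    skel = Skeleton(nodes, edges=[(0, 1), (1, 2)])
    out = sr.smooth_interpolate(skel, window=99)
    assert len(out) >= 2


# -------------------------------------------------------- count_branches

def test_count_branches_bare_pole():
    nodes = np.array([[0, 0, 0.05 * i] for i in range(20)], dtype=float)
    skel = Skeleton(nodes, edges=[(i, i + 1) for i in range(19)])
    bs = sr.count_branches(skel, r_trunk=0.05)
    assert bs.num_branch == 0


def test_count_branches_generator_truth(tree_suite):
    res = tree_suite[0]
    assert res["branchset"].num_branch == res["truth"].n_branches


def test_count_branches_rigid_motion_invariant(tree_suite, rng):
    from test_skeleton_fusion import rand_rigid
    res = tree_suite[1]
    refined, r = res["refined"], res["r"]
    n0 = sr.count_branches(refined, r_trunk=r).num_branch
    T = rand_rigid(rng, max_deg=20.0)
    # rotate about the base so the trunk-region cylinder stays meaningful
    base = refined.nodes[refined.base_idx]
    Rz = T.rotation
    ang = np.deg2rad(15)
    Rz = np.array([[np.cos(ang), -np.sin(ang), 0],
                   [np.sin(ang), np.cos(ang), 0], [0, 0, 1.0]])
    moved = Skeleton((refined.nodes - base) @ Rz.T + base + [5, 5, 0],
                     edges=refined.edges)
    n1 = sr.count_branches(moved, r_trunk=r).num_branch
    assert n1 == n0
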