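"""Skeleton graph refinement: support removal, gap filling, branch counts.

The skeleton becomes an undirected weighted graph (edges between nodes
within an R-NN radius, weights the squared Euclidean distance). Support
posts and wires are stripped two ways: a graph rule (vertices that lie on
no shortest path from the trunk base to a branch tip are discarded) and an
intensity rule (skeleton nodes whose mean LiDAR reflectivity sits well
above the tree-level average are supports — trellis steel and wire return
brighter than wood). Gaps opened by pruning are bridged with voxel
centroids from the original cloud, screened so removed supports are never
reintroduced, then the paths are smoothed and resampled and first-order
branches are counted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .types import BranchSet, PointCloud, Skeleton, TreeInstance


# ------------------------------------------------------------ trunk radius

def estimate_trunk_radius(tree: TreeInstance | PointCloud,
                          slab: tuple[float, float] = (0.2, 0.4)) -> float:
    """Trunk radius from a horizontal slab just above the base.

    Radius = median horizontal distance of slab points from their x-y
    centroid, clipped to (0, 0.5] m. Falls back to the bottom decile of
    the whole cloud when the slab holds fewer than 30 points.
    """
    pc = tree.points if isinstance(tree, TreeInstance) else tree
    z = pc.coords[:, 2]
    base = z.min()
    sel = (z >= base + slab[0]) & (z <= base + slab[1])
    if sel.sum() < 30:
        warnings.warn("too few slab points; falling back to bottom decile")
        m = max(int(np.ceil(0.1 * len(pc))), 10)
        sel = np.argsort(z, kind="stable")[:m]
    pts = pc.coords[sel, :2]
    # component-wise median centre + one trim pass: robust to a support
    # post sharing the slab with the trunk
    c = np.median(pts, axis=0)
    d = np.hypot(*(pts - c).T)
    r = float(np.median(d))
    near = d <= 4.0 * max(r, 0.01)
    if near.sum() >= 10:
        c = np.median(pts[near], axis=0)
        r = float(np.median(np.hypot(*(pts[near] - c).T)))
    return float(np.clip(r, 1e-4, 0.5))


# ------------------------------------------------------------ tree graph

@dataclass
class TreeGraph:
    graph: nx.Graph
    base: int
    tips: list[int]
    r_nn: float
    skeleton: Skeleton = None


def build_tree_graph(skel: Skeleton, radius: float,
                     spacing_floor: bool = True) -> TreeGraph:
    """R-NN graph over skeleton nodes, edge weight = squared distance.

    The base is the vertex of lowest z; tips are degree-1 vertices plus
    vertices whose shortest-path distance from the base exceeds that of
    all their neighbours (locally outermost). With ``spacing_floor`` the
    radius is floored at 3 x the skeleton's median edge length so a
    sparsely contracted trunk cannot disconnect the graph.
    """
    nodes = skel.nodes
    if len(nodes) < 2:
        raise ValueError("graph building needs >= 2 skeleton nodes")
    if radius <= 0:
        raise ValueError("radius must be positive")
    tree = cKDTree(nodes)
    if spacing_floor:
        nn = tree.query(nodes, k=2)[0][:, 1]
        radius = max(radius, 2.5 * float(np.median(nn)))
    pairs = tree.query_pairs(radius, output_type="ndarray")
    if len(pairs) == 0 and not skel.edges:
        raise ValueError("empty edge set; advise a larger R-NN radius")
    g = nx.Graph()
    g.add_nodes_from(range(len(nodes)))
    if len(pairs):
        d2 = np.sum((nodes[pairs[:, 0]] - nodes[pairs[:, 1]]) ** 2, axis=1)
        g.add_weighted_edges_from(
            (int(u), int(v), float(w)) for (u, v), w in zip(pairs, d2))
    # the skeleton's own edges guard connectivity across sparse stretches
    for u, v in skel.edges:
        if not g.has_edge(u, v):
            g.add_edge(u, v, weight=float(np.sum((nodes[u] - nodes[v]) ** 2)))
    base = int(np.argmin(nodes[:, 2]))
    # tips are the outermost vertices: local maxima of the squared
    # Euclidean distance from the base over R-NN neighbourhoods — a post
    # top flanked by farther tree nodes is not outermost, so the path
    # union never needs to reach into it
    d2base = np.sum((nodes - nodes[base]) ** 2, axis=1)
    tips = []
    for v in g.nodes:
        if v == base:
            continue
        nbrs = tree.query_ball_point(nodes[v], radius)
        others = [u for u in nbrs if u != v]
        if others and all(d2base[u] <= d2base[v] for u in others) and \
                any(d2base[u] < d2base[v] for u in others):
            tips.append(v)
    return TreeGraph(graph=g, base=base, tips=tips, r_nn=radius, skeleton=skel)


def _subset_skeleton(skel: Skeleton, keep: np.ndarray,
                     graph: nx.Graph = None) -> Skeleton:
    """Re-index a skeleton to the kept vertex set (induced edges)."""
    keep = np.asarray(keep)
    if keep.dtype == bool:
        keep = np.nonzero(keep)[0]
    remap = {int(old): new for new, old in enumerate(keep)}
    nodes = skel.nodes[keep]
    if graph is not None:
        edges = [(remap[u], remap[v]) for u, v in graph.edges
                 if u in remap and v in remap]
    else:
        edges = [(remap[u], remap[v]) for u, v in skel.edges
                 if u in remap and v in remap]
    om = None
    if skel.origin_map is not None:
        om = [skel.origin_map[i] for i in keep]
    ni = None if skel.node_intensity is None else skel.node_intensity[keep]
    return Skeleton(nodes=nodes, edges=edges, source=skel.source,
                    base_idx=int(np.argmin(nodes[:, 2])), origin_map=om,
                    node_intensity=ni)


def graph_prune_supports(g: TreeGraph):
    """Keep only vertices on some shortest path base -> tip (Dijkstra).

    Support posts and wires hang off the graph away from every base-to-tip
    route, so the union of shortest paths drops them. Returns the pruned
    skeleton, the kept vertex indices (into the input skeleton) and the
    list of unreachable tips.
    """
    paths = nx.single_source_dijkstra_path(g.graph, g.base)
    keep: set[int] = {g.base}
    path_edges: set[tuple[int, int]] = set()
    unreachable = []
    for tip in g.tips:
        if tip in paths:
            p = paths[tip]
            keep.update(p)
            path_edges.update(zip(p[:-1], p[1:]))
        else:
            unreachable.append(tip)
    kept = np.array(sorted(keep), dtype=int)
    remap = {int(old): new for new, old in enumerate(kept)}
    # the union of shortest paths from one source is a tree; keep exactly
    # those edges so pruning also discards redundant R-NN cross-links
    out = _subset_skeleton(g.skeleton, kept)
    out.edges = sorted({(min(remap[u], remap[v]), max(remap[u], remap[v]))
                        for u, v in path_edges})
    return out, kept, unreachable


def intensity_prune_supports(skel: Skeleton, pc: PointCloud, r: float,
                             alpha: float = 1.0, crown_base_z: float = None,
                             min_excess: float = 0.15):
    """Drop crown skeleton nodes whose LiDAR reflectivity is anomalously high.

    Node intensity = mean intensity of cloud points within ``r`` (the trunk
    radius); a node is a support when its intensity exceeds the tree-level
    mean by more than ``alpha`` standard deviations AND by at least
    ``min_excess`` in absolute terms — the rule targets the large material
    contrast between trellis steel and wood, and the floor keeps the upper
    tail of ordinary wood-reflectivity noise from being clipped on trees
    that carry no supports at all. When ``crown_base_z`` is given, removal
    is restricted to nodes above it (the crown). Returns (pruned skeleton,
    kept indices, removed node positions).
    """
    if pc.intensity is None:
        warnings.warn("cloud has no intensity channel; intensity pruning skipped")
        return skel, np.arange(len(skel)), np.zeros((0, 3))
    tree = cKDTree(pc.coords)
    node_int = np.full(len(skel), np.nan)
    for i, nd in enumerate(skel.nodes):
        idx = tree.query_ball_point(nd, r)
        if idx:
            node_int[i] = pc.intensity[idx].mean()
    valid = np.isfinite(node_int)
    mean = node_int[valid].mean()
    std = node_int[valid].std()
    high = valid & (node_int > mean + alpha * std) \
        & (node_int > mean + min_excess)
    if crown_base_z is not None:
        high &= skel.nodes[:, 2] > crown_base_z
    kept = np.nonzero(~high)[0]
    out = _subset_skeleton(skel, kept)
    out.node_intensity = node_int[kept]
    return out, kept, skel.nodes[high]


# ------------------------------------------------------------ gap filling

def voxel_downsample(pc: PointCloud, voxel: float,
                     return_intensity: bool = False):
    """Voxel-grid downsampling: one centroid per occupied voxel."""
    key = np.floor(pc.coords / voxel).astype(np.int64)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True,
                               return_counts=True)
    cent = np.zeros((counts.shape[0], 3))
    np.add.at(cent, inv, pc.coords)
    cent /= counts[:, None]
    if not return_intensity:
        return cent
    vint = None
    if pc.intensity is not None:
        # max per voxel: one bright (support) return marks the whole voxel
        vint = np.full(counts.shape[0], -np.inf)
        np.maximum.at(vint, inv, pc.intensity)
    return cent, vint


def fill_gaps(pruned: Skeleton, pc: PointCloud, voxel: float = 0.02,
              removed_mask: np.ndarray = None, connect_radius: float = None,
              max_added_per_bridge: int = 200):
    """Bridge disconnected skeleton components through cloud voxels.

    The original cloud is voxel-downsampled and screened two ways so
    removed supports are never reintroduced: voxels within 2 voxels of a
    node listed in ``removed_mask`` (the support nodes the intensity rule
    cut) are excluded, and so are voxels whose own mean LiDAR intensity
    sits more than one standard deviation above the voxel-level mean —
    trellis steel reflects brighter than wood, so support material is
    inadmissible bridge territory even where no skeleton node marked it.
    Components of the pruned skeleton are then reconnected to the base
    component along Dijkstra shortest paths through admissible voxel
    centroids (``connect_radius`` defaults to 3x voxel so surface voxels
    reach axis-contracted skeleton nodes), capped at
    ``max_added_per_bridge`` added nodes per bridge — a bridge may
    legitimately run a while when it detours around a removed support.
    Unbridgeable components are dropped and reported.
    """
    if voxel <= 0:
        raise ValueError("voxel must be positive")
    if connect_radius is None:
        connect_radius = 3.0 * voxel
    g = nx.Graph()
    g.add_nodes_from(range(len(pruned)))
    g.add_edges_from(pruned.edges)
    comps = list(nx.connected_components(g))
    if len(comps) == 1:
        return pruned, {"added": 0, "dropped_components": 0}

    vox, vint = voxel_downsample(pc, voxel, return_intensity=True)
    if vint is not None:
        # a voxel is support territory if its brightest return stands two
        # sigma above the cloud-wide reflectivity
        thr = pc.intensity.mean() + 2.0 * pc.intensity.std()
        vox = vox[vint <= thr]
    if removed_mask is not None and len(removed_mask):
        bad = cKDTree(np.asarray(removed_mask)).query(vox)[0] <= 2.0 * voxel
        vox = vox[~bad]

    all_pts = np.vstack([pruned.nodes, vox])
    n_skel = len(pruned)
    big = nx.Graph()
    big.add_nodes_from(range(len(all_pts)))
    pairs = cKDTree(all_pts).query_pairs(connect_radius, output_type="ndarray")
    if len(pairs):
        d = np.linalg.norm(all_pts[pairs[:, 0]] - all_pts[pairs[:, 1]], axis=1)
        big.add_weighted_edges_from(
            (int(u), int(v), float(w)) for (u, v), w in zip(pairs, d))
    for u, v in pruned.edges:  # keep existing skeleton connectivity
        w = float(np.linalg.norm(pruned.nodes[u] - pruned.nodes[v]))
        big.add_edge(u, v, weight=w)

    base_comp = next(c for c in comps if pruned.base_idx in c)
    new_nodes = list(map(np.asarray, pruned.nodes))
    new_edges = list(pruned.edges)
    keep_vertices = set(base_comp)
    dropped = 0
    added_total = 0
    dist, paths = nx.multi_source_dijkstra(big, set(base_comp))
    for comp in comps:
        if comp is base_comp:
            continue
        best = min(comp, key=lambda v: dist.get(v, np.inf))
        if best not in dist:
            dropped += 1
            continue
        path = paths[best]
        bridge = [p for p in path if p >= n_skel]
        if len(bridge) > max_added_per_bridge:
            dropped += 1
            continue
        idx_map = {}
        for p in bridge:
            idx_map[p] = len(new_nodes)
            new_nodes.append(vox[p - n_skel])
            added_total += 1
        for a, b in zip(path[:-1], path[1:]):
            ia = a if a < n_skel else idx_map[a]
            ib = b if b < n_skel else idx_map[b]
            new_edges.append((ia, ib))
        keep_vertices |= comp
        keep_vertices |= set(idx_map.values())

    keep_sorted = sorted(keep_vertices)
    remap = {old: new for new, old in enumerate(keep_sorted)}
    nodes = np.array([new_nodes[i] for i in keep_sorted])
    edges = [(remap[u], remap[v]) for u, v in new_edges
             if u in remap and v in remap]
    out = Skeleton(nodes=nodes, edges=edges, source=pruned.source,
                   base_idx=int(np.argmin(nodes[:, 2])))
    return out, {"added": added_total, "dropped_components": dropped}


# ------------------------------------------------------------ smoothing

def _decompose_paths(g: nx.Graph) -> list[list[int]]:
    """Split a graph into maximal paths between junction/terminal vertices."""
    anchors = {v for v in g.nodes if g.degree[v] != 2}
    if not anchors and len(g):  # a pure cycle: pick an arbitrary anchor
        anchors = {next(iter(g.nodes))}
    paths = []
    visited_edges = set()
    for a in anchors:
        for nb in g.neighbors(a):
            if (a, nb) in visited_edges:
                continue
            path = [a, nb]
            visited_edges.update({(a, nb), (nb, a)})
            while g.degree[path[-1]] == 2 and path[-1] not in anchors:
                nxt = [x for x in g.neighbors(path[-1]) if x != path[-2]]
                if not nxt:
                    break
                visited_edges.update({(path[-1], nxt[0]), (nxt[0], path[-1])})
                path.append(nxt[0])
            paths.append(path)
    return paths


def smooth_interpolate(skel: Skeleton, window: int = 5,
                       spacing: float = None) -> Skeleton:
    """Moving-average smoothing plus uniform linear resampling per path.

    Junction and terminal vertices stay fixed so the branching topology
    (junction count) is preserved; interior vertices of each path are
    smoothed with a centred window (clamped to the path length) and the
    path is then resampled to uniform node spacing.
    """
    g = nx.Graph()
    g.add_nodes_from(range(len(skel)))
    g.add_edges_from(skel.edges)
    paths = _decompose_paths(g)
    if spacing is None:
        lens = [np.linalg.norm(skel.nodes[u] - skel.nodes[v])
                for u, v in skel.edges]
        spacing = float(np.median(lens)) if lens else 0.05

    anchors = {v for v in g.nodes if g.degree[v] != 2}
    anchor_ids = {a: i for i, a in enumerate(sorted(anchors))}
    new_nodes = [skel.nodes[a] for a in sorted(anchors)]
    new_edges = []
    for path in paths:
        pts = skel.nodes[path]
        w = min(window, len(pts))
        if w >= 3 and len(pts) > 2:
            sm = pts.copy()
            for i in range(1, len(pts) - 1):
                lo = max(0, i - w // 2)
                hi = min(len(pts), i + w // 2 + 1)
                sm[i] = pts[lo:hi].mean(axis=0)
            pts = sm
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        arclen = np.concatenate([[0.0], np.cumsum(seg)])
        total = arclen[-1]
        n_new = max(int(round(total / spacing)), 1)
        ts = np.linspace(0.0, total, n_new + 1)
        resampled = np.column_stack([
            np.interp(ts, arclen, pts[:, k]) for k in range(3)])
        chain = [anchor_ids[path[0]]]
        for p in resampled[1:-1]:
            chain.append(len(new_nodes))
            new_nodes.append(p)
        chain.append(anchor_ids[path[-1]])
        new_edges += list(zip(chain[:-1], chain[1:]))
    nodes = np.array(new_nodes)
    return Skeleton(nodes=nodes, edges=new_edges, source=skel.source,
                    base_idx=int(np.argmin(nodes[:, 2])))


# ------------------------------------------------------------ branches

def count_branches(skel: Skeleton, min_len: float = 0.1,
                   r_trunk: float = None) -> BranchSet:
    """First-order branch extraction from a connected, refined skeleton.

    The trunk is the shortest path from the base to the trunk apex — the
    highest vertex within 2 x r_trunk horizontally of the base (matching
    the trunk definition used for the crown region), or the highest tip
    overall when no trunk radius is known. Each connected component left
    after removing the trunk vertices, hanging off a trunk junction, is
    one branch; its path runs from the junction to the farthest tip of
    the component. Branches shorter than ``min_len`` are discarded.
    """
    g = nx.Graph()
    g.add_nodes_from(range(len(skel)))
    for u, v in skel.edges:
        g.add_edge(u, v, weight=float(np.linalg.norm(skel.nodes[u] -
                                                     skel.nodes[v])))
    base = skel.base_idx
    reach = nx.node_connected_component(g, base)
    if r_trunk is not None:
        axis = skel.nodes[base, :2]
        on_axis = [v for v in reach
                   if np.hypot(*(skel.nodes[v, :2] - axis)) <= 2.0 * r_trunk]
        apex = max(on_axis, key=lambda v: skel.nodes[v][2])
    else:
        apex = max(reach, key=lambda v: skel.nodes[v][2])
    trunk_path = nx.dijkstra_path(g, base, apex)

    # the trunk region is the vertical cylinder around the base axis
    if r_trunk is not None:
        axis = skel.nodes[base, :2]
        horiz = np.hypot(*(skel.nodes[:, :2] - axis).T)
        region = {v for v in reach if horiz[v] <= max(2.0 * r_trunk, 0.1)}
        region |= set(trunk_path)
    else:
        region = set(trunk_path)

    # candidate branch per terminal tip: the base->leaf shortest path
    # truncated at its last trunk-region vertex
    dist_b, paths_b = nx.single_source_dijkstra(g, base)
    cands = []
    for leaf in reach:
        if g.degree[leaf] != 1 or leaf in region:
            continue
        full = paths_b[leaf]
        k = max((i for i, v in enumerate(full) if v in region), default=0)
        path = full[k:]
        length = sum(float(np.linalg.norm(skel.nodes[u] - skel.nodes[v]))
                     for u, v in zip(path[:-1], path[1:]))
        if length >= min_len:
            cands.append((length, path))

    # duplicate-strand suppression: a contraction artefact forks off an
    # existing branch and runs alongside it, so its nodes hug the longer
    # candidate's polyline on average; a real branch diverges
    cands.sort(key=lambda c: -c[0])
    dedup = 0.1
    branches = []
    for length, path in cands:
        nodes_p = skel.nodes[path]
        dup = False
        for kept in branches:
            pts = skel.nodes[kept]
            seg = pts[1:] - pts[:-1]
            denom = np.maximum(np.einsum("ij,ij->i", seg, seg), 1e-12)
            dsum = 0.0
            for p in nodes_p:
                rel = p - pts[:-1]
                t = np.clip(np.einsum("ij,ij->i", rel, seg) / denom, 0, 1)
                dsum += np.linalg.norm(rel - t[:, None] * seg, axis=1).min()
            if dsum / len(nodes_p) < dedup:
                dup = True
                break
        if not dup:
            branches.append(path)
    branches.sort(key=lambda b: skel.nodes[b[0]][2])
    return BranchSet(trunk_path=trunk_path, branches=branches,
                     r_trunk=r_trunk or 0.0, skeleton=skel)
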