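"""Shared fixtures: synthetic trees, orchard scenes and processed stages.

Heavy artefacts (the orchard scene with its preprocessing chain, the
20-tree refinement suite) are session-scoped so the acceptance tests and
the unit tests draw from one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

import canopy3d as c3
from canopy3d import pointcloud_io as pio
from canopy3d import skeleton_refinement as sr
from canopy3d import tree_segmentation as ts
from canopy3d.synthetic_orchard import _cylinder_points


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tree_pair():
    """One synthetic tree: (lidar_view, drone_view, truth)."""
    return c3.generate_tree(c3.SyntheticTreeSpec(seed=5))


@pytest.fixture(scope="session")
def lidar_skeleton(tree_pair):
    lidar, _, _ = tree_pair
    return c3.extract_skeleton(lidar)


def cylinder(rng, a, b, radius, n):
    return _cylinder_points(rng, a, b, radius, n)


@pytest.fixture(scope="session")
def sloped_orchard():
    """4x5 orchard, one gap, 5 degree slope, with per-point truth labels."""
    scene, truth = c3.generate_orchard(4, 5, (4.0, 3.5), slope_deg=5.0,
                                       gap_slots=[(2, 1)], seed=11)
    return scene, truth


@pytest.fixture(scope="session")
def orchard_stages(sloped_orchard):
    """Ground split, CHM, ROIs and cropped instances for the shared scene."""
    scene, truth = sloped_orchard
    ground, above, gmask = pio.csf_ground_filter(scene, 0.5, 0.05,
                                                 return_mask=True)
    chm = pio.build_chm(ground, above, cell_size=0.10)
    from skimage import morphology
    grey = morphology.closing(ts.chm_to_grey(chm), morphology.disk(2))
    rois = ts.detect_tree_rois(grey, open_radius_px=1, min_area_px=25)
    instances = ts.crop_trees(above, rois, chm, mode="box", pad_px=8)
    return {"scene": scene, "truth": truth, "ground": ground, "above": above,
            "gmask": gmask, "chm": chm, "rois": rois, "instances": instances}


def refine_tree(lidar, r=None):
    """The standard per-tree refinement chain used across tests."""
    sk = c3.extract_skeleton(lidar)
    if r is None:
        r = sr.estimate_trunk_radius(lidar)
    g = sr.build_tree_graph(sk, 2 * r)
    pruned, kept, _ = sr.graph_prune_supports(g)
    pruned2, kept2, removed = sr.intensity_prune_supports(pruned, lidar, r=r)
    filled, info = sr.fill_gaps(pruned2, lidar, voxel=0.02,
                                removed_mask=removed)
    refined = sr.smooth_interpolate(filled)
    return {"skeleton": sk, "r": r, "kept": kept, "kept2": kept2,
            "removed": removed, "filled": filled, "refined": refined,
            "fill_info": info,
            "branchset": sr.count_branches(refined, r_trunk=r)}


@pytest.fixture(scope="session")
def tree_suite():
    """20 supported trees run through the refinement chain, with truth."""
    out = []
    for seed in range(20):
        spec = c3.SyntheticTreeSpec(seed=seed, support="post+wire")
        lidar, drone, truth = c3.generate_tree(spec)
        res = refine_tree(lidar)
        node_lab = np.array([
            max(set(truth.lidar_labels[i]),
                key=list(truth.lidar_labels[i]).count)
            for i in res["skeleton"].origin_map])
        out.append({"lidar": lidar, "drone": drone, "truth": truth,
                    "node_labels": node_lab, **res})
    return out
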