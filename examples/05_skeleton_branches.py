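"""Strip trellis supports from a tree skeleton and count its branches.

The skeleton becomes a weighted graph; Dijkstra paths from the trunk base
to the outermost tips discard structures off every path (graph rule), and
nodes whose LiDAR reflectivity stands out from the tree average are cut
as trellis steel (intensity rule). Gaps are re-bridged from screened
cloud voxels, the paths smoothed, and first-order branches counted.
"""

import numpy as np

import canopy3d as c3
from canopy3d import skeleton_refinement as sr

lidar, _, truth = c3.generate_tree(
    c3.SyntheticTreeSpec(seed=2, support="post+wire"))
skeleton = c3.extract_skeleton(lidar)
r_trunk = sr.estimate_trunk_radius(lidar)
print(f"trunk radius estimate: {r_trunk * 100:.1f} cm (planted: 5.0 cm)")

graph = sr.build_tree_graph(skeleton, radius=2 * r_trunk)
pruned, kept, _ = sr.graph_prune_supports(graph)
pruned, _, removed = sr.intensity_prune_supports(pruned, lidar, r=r_trunk)
print(f"pruning: {len(skeleton)} nodes -> {len(pruned)} "
      f"({len(removed)} cut by the intensity rule)")

filled, info = sr.fill_gaps(pruned, lidar, voxel=0.02, removed_mask=removed)
refined = sr.smooth_interpolate(filled)
branches = sr.count_branches(refined, r_trunk=r_trunk)
print(f"gap filling added {info['added']} voxel nodes")
print(f"branches counted: {branches.num_branch} "
      f"(planted: {truth.n_branches})")
for i, path in enumerate(branches.branches):
    length = sum(np.linalg.norm(refined.nodes[u] - refined.nodes[v])
                 for u, v in zip(path[:-1], path[1:]))
    print(f"  branch {i}: {length:.2f} m, {len(path)} nodes")
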