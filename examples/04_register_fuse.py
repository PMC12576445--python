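"""Register the drone view onto the LiDAR view through skeletons.

Both clouds contract to sparse curve skeletons; FPFH-feature RANSAC gives
a coarse global alignment and point-to-point ICP refines it. The
recovered transform then fuses the full clouds so colour (drone) and
reflectivity (LiDAR) live in one frame.
"""

import numpy as np

import canopy3d as c3
from canopy3d import skeleton_fusion as sf

lidar, drone, truth = c3.generate_tree(c3.SyntheticTreeSpec(seed=11))
sk_lidar = c3.extract_skeleton(lidar)
sk_drone = c3.extract_skeleton(drone)
print(f"skeletons: {len(sk_lidar)} LiDAR nodes, {len(sk_drone)} drone nodes "
      f"(from {len(lidar)} / {len(drone)} points)")

coarse = sf.coarse_register(sk_drone, sk_lidar, seed=0)
fine = sf.fine_register(sk_drone, sk_lidar, coarse)
print(f"coarse RMSE {coarse.rmse * 100:.1f} cm -> fine RMSE "
      f"{fine.rmse * 100:.1f} cm")

err = np.degrees(np.arccos(np.clip(
    (np.trace(fine.rotation @ truth.transform.rotation.T) - 1) / 2, -1, 1)))
print(f"rotation error vs the generator's hidden transform: {err:.2f} deg")

fused = sf.fuse_clouds(lidar, drone, fine)
print(f"fused cloud: {len(fused)} points "
      f"({(fused.provenance == 'lidar').sum()} lidar + "
      f"{(fused.provenance == 'drone').sum()} drone)")
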