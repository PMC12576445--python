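"""Ground/canopy separation and the canopy height model on a sloped scene.

The cloth-simulation filter drapes a virtual cloth under the cloud to
estimate the terrain; subtracting the terrain from per-cell canopy tops
yields the CHM in centimetres, which is what tree detection runs on.
"""

import numpy as np

import canopy3d as c3
from canopy3d import pointcloud_io as pio
from canopy3d.types import NO_DATA

scene, truth = c3.generate_orchard(2, 3, slope_deg=5.0, seed=4)
print(f"scene: {len(scene)} points over a 5-degree slope, "
      f"{int(truth.present.sum())} trees")

ground, above = pio.csf_ground_filter(scene, cloth_resolution=0.5,
                                      class_threshold=0.05)
print(f"CSF split: {len(ground)} ground, {len(above)} above-ground")

chm = pio.build_chm(ground, above, cell_size=0.10)
valid = chm.heights[chm.heights != NO_DATA]
print(f"CHM: {chm.shape[0]} x {chm.shape[1]} cells at {chm.cell_size} m")
print(f"max canopy height {valid.max():.0f} cm "
      "(terrain-corrected: the 2.5 m trees read ~250 regardless of slope)")
pio.write_chm_ascii(chm, "chm_example.asc")
print("CHM written to chm_example.asc (ESRI ASCII grid)")
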