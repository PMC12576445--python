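# Methods

This note records the models and procedures behind `canopy3d`, the
parameters that matter, the numerical choices made where the design was
open, and what the synthetic test suite does and does not demonstrate.

## Coordinate conventions and units

All geometry is metres in a z-up frame. Both survey sources must be
expressed in one projected CRS or a local east-north-up frame before
positioning; a least-squares 2D similarity transform (solved in closed
form through complex least squares) reconciles residual frame offsets
between the local frame and surveyed reference coordinates. Geodetic
datum conversion is out of scope. Centimetres appear only at reporting
boundaries: CHM cell values and `Height_Max`. LAS intensity is min-max
normalised to [0, 1] per cloud on read (both 8- and 16-bit dialects are
accepted); the normalisation is idempotent and a constant channel maps
to zero.

## Pre-processing

**SOR.** A point survives statistical outlier removal iff its mean
distance to its k nearest neighbours is at most the global mean plus
`std_ratio` standard deviations of that statistic. Defaults k = 16,
`std_ratio` = 1.0 for homogeneous per-tree clouds. On whole-orchard
scenes the ground is sampled far more sparsely than wood surfaces, and a
global mean + 1σ threshold silently removes sparse-but-valid ground
returns; the orchard pipeline therefore defaults to `std_ratio` = 2.5,
the conservative end of common practice for mixed-density scenes. Both
values sit in the run config.

**CSF.** The ground filter is a simplified cloth simulation written for
this package: a grid of cloth particles (spacing `cloth_resolution`,
default 0.5 m) rises under "gravity" from below the cloud, each particle
freezing when it reaches the lowest return above it, with spring
relaxation toward the four-neighbour mean (rigidness 0.4) so cells whose
lowest return is canopy cannot pull the cloth up into the crown. A point
is ground iff its height above the bilinearly-sampled cloth is at most
`class_threshold` (default 0.05 m). Degenerate clouds narrower than two
cloth cells are rejected.

**CHM.** Per cell (default 0.05 m; the orchard pipeline uses 0.10 m),
canopy height = max above-ground z minus the terrain estimate at the
cell centre, clamped at zero, in cm; empty cells carry a no-data
sentinel. The terrain is interpolated linearly over the Delaunay
triangulation of the ground points with nearest-neighbour fallback
outside their hull. The CHM is terrain-invariant by construction (tested
by adding a planar ramp to both layers).

## Segmentation and positioning

The CHM maps to grey levels 0–255 (linear in height, round-half-down,
no-data → 0). Tree regions come from local-Otsu thresholding (window
65 px, global-Otsu fallback for rasters smaller than the window) plus a
morphological opening (disc, radius 2 px by default; the pipeline uses a
greyscale closing first to consolidate sparse crown projections, then
opening radius 1). Components under `min_area_px` are dropped; boxes
sort row-major. Cropping assigns each point to the region owning its CHM
cell — mask mode cuts exactly at detected boundaries, box mode (the
default in the pipeline, padded 8 px) keeps crown-interior points that
project between branches; overlaps resolve to the nearer region
centroid, ties to the lower tree id. Expected positions on the planting
grid flag unmatched slots as gaps and undersized detections
(< 200 points) as dead; surplus detections near a claimed slot are
reported as anomalies.

The trunk centroid is the overhead projection of the lowest ⌈0.1·N⌉
points (ties at the cutoff height included). The default is the
equal-weights mean, as the plain reading of a "weighted centroid" with
unspecified weights; the density-weighting hook is `method="robust"`,
which re-centres iteratively (radii 0.15 → 0.10 m) on the dominant
cluster of the bottom slice so a trellis post standing in the same
height band cannot drag the centroid off the trunk axis. The pipeline
uses the robust variant; the plain mean remains the API default.

## Skeletonisation

Laplacian-based contraction on the symmetrised 10-NN graph: each
iteration solves `(w_L² LᵀL + w_H² I) X' = w_H² X` with the
*unnormalised* Laplacian `L = D − A` (the degree factor is what drives
the radial collapse of tubular neighbourhoods), contraction weight
`w_L` starting at 4 and doubling per iteration (5 iterations), and
attraction `w_H` = 1 anchoring points to their previous positions. The
graph is rebuilt between iterations so merging strands keep contracting.
Divergence (any point leaving the input bounding box by more than 10%)
raises with the iteration index. Contracted points are grouped on a 5 cm
voxel grid into nodes (node = mean of its points, with an origin map
back to input points and a mean intensity); edges are the Euclidean
minimum spanning tree over the nodes. On noisy cylinders of 5 cm radius
the node-to-axis median distance is ~3 mm.

The per-point semantic labels that a semantic variant of the contraction
would use are carried through as provenance (the origin map) but do not
gate the contraction weights; nothing in the outputs depends on them
beyond bookkeeping.

## Registration

Skeleton-to-skeleton, drone → LiDAR (the LiDAR frame holds the precise
geo-reference). Features are 33-bin FPFH histograms; because the surface
normal of a curve skeleton is degenerate, the Darboux frames are built
on the local *tangent* (dominant PCA direction within 2.5× the node
spacing), oriented upward, with feature radius 5× the node spacing. The
coarse stage draws the top-4 feature matches per node as the
correspondence pool and runs up to 50 restarts of a RANSAC pass (150
samples each): a 3-correspondence sample must pass a pairwise-length
compatibility gate, its rigid fit must rotate by at most 60° — the two
surveys of one orchard are both coarsely levelled and georeferenced, so
the true relative rotation is moderate, and the gate keeps
near-symmetric crowns from locking onto a rotated match — and the
candidate is scored by nearest-neighbour RMSE, keeping the minimum. The
fine stage is point-to-point ICP (correspondence cutoff 0.10 m, ≤ 100
sweeps, relative tolerance 1e-6, monotone objective); all least-squares
refinement deliberately lives here, so the fine stage strictly improves
the coarse result. Fusion concatenates the LiDAR cloud with the
transformed drone cloud, carrying intensity from LiDAR rows, colour from
drone rows and per-point provenance.

## Support pruning, gap filling, branch counting

The R-NN graph over skeleton nodes (radius 2·R_Trunk, floored at 2.5×
the median node spacing so a sparsely contracted trunk cannot disconnect
it; the skeleton's own MST edges are always included) weights edges by
squared Euclidean distance. Tips are the outermost vertices: local
maxima of the squared Euclidean distance from the base over R-NN
neighbourhoods — a post top flanked by farther tree nodes is not
outermost, which is what lets the path rule ignore it. Graph pruning
keeps exactly the union of Dijkstra shortest paths base → tip (a tree,
since single-source shortest paths form one); "not relatively vertically
positioned" is operationalised as this path-union rule.

Intensity pruning assigns each node the mean reflectivity of cloud
points within R_Trunk and removes nodes exceeding the tree-level mean by
more than α·σ (α = 1) **and** by at least 0.15 absolute — the rule
targets the large material contrast between trellis steel and wood, and
the floor keeps the upper tail of ordinary wood-reflectivity noise from
being clipped on trees that carry no supports. Removal can be restricted
to the crown via `crown_base_z`.

Gap filling voxel-downsamples the original cloud (2 cm) and reconnects
skeleton components to the base component along Dijkstra paths through
admissible voxels (connect radius 3× voxel, ≤ 200 added nodes per
bridge). Two screens keep removed supports out: voxels within two
voxels of an intensity-removed node, and voxels whose brightest return
stands two σ above the cloud-wide reflectivity (one bright return marks
the whole voxel). Unbridgeable components are dropped and reported.
Smoothing runs a centred moving average (window 5, clamped) over each
junction-to-junction path with anchors fixed — so the junction count is
preserved — followed by uniform arclength resampling.

Branch counting: the trunk is the shortest path from the base to the
trunk apex, the highest vertex within 2·R_Trunk horizontally of the base
(the same trunk-region definition the crown split uses). Each terminal
tip proposes a branch: its base-to-leaf path truncated at the last
trunk-region vertex, kept if at least `min_len` (0.1 m) long.
Contraction occasionally leaves a duplicate strand running alongside a
real branch; a candidate whose nodes lie on average within 0.1 m of an
already-kept longer path is such a fork artefact and is suppressed. Only
first-order branches are counted; a forked branch counts once through
its longest path.

## Canopy and floral traits

The crown splits from the trunk by DBSCAN (eps 4·R_Trunk, 10 points):
the cluster containing the lowest point, restricted to within 2·R_Trunk
of the axis, is trunk; everything above its top is crown (fallback
base + 0.3 m with a warning if no cluster forms). Hull metrics come from
scipy's convex hulls; degenerate geometry turns only the affected metric
into NaN. Crown projection area uses crown points by default with a flag
for the whole tree.

Blossom extraction thresholds the greyscale (0.299 R + 0.587 G +
0.114 B) by Otsu per tree — the documented stand-in for adaptive
vegetation-index thresholding, adequate because flowers are near-white
against green foliage; identical colours degenerate to all-retained.
Skeleton proximity removal measures distance to the skeleton *polyline*
(not just nodes) so points between nodes register as wood. DBSCAN uses
eps = R_Trunk with a 20-point floor; the noise/single/multi
classification fixes clusters under 50 points as noise by rule and
K-means-partitions the rest (k = 2 on z-scored point count, hull volume
and max PCA extent, 10 restarts, fixed seed, rows fed in a canonical
sort order so labels are independent of input permutation); the group
with the smaller mean size is single-flower. Multi-flower splitting
halves the DBSCAN radius per level (max depth 4), recursing also when a
level fails to split so finer scales are probed before concluding a
cluster is single; sub-clusters under 50 points are dropped as noise and
depth-exhausted leaves are flagged. Strata are equal thirds of the crown
z-span with boundaries belonging to the lower band. Cluster volumetrics
are hull volume/surface plus an auxiliary voxel-occupancy volume
(count × voxel³). Branch assignment takes the nearest branch polyline
(tie → lower index, unassigned beyond 0.5 m).

## The synthetic orchard

The generator emulates a trellised pear/apple planting at desk scale:
vase-form trees (bare trunk to `trunk_top` = 0.8 m, default 8 scaffold
branches parametrised by their tips — horizontal radius 0.9–1.4 m so a
2.5 m crown stays inside a 4.0 × 3.5 m planting cell, one tip realising
the height exactly), cylinders sampled proportionally to surface area
with 3 mm radial noise; a trellis post and optionally a wire with
reflectivity offset +0.6 over wood (N(0.3, 0.05) vs N(0.9, 0.05),
clipped); blossom blobs (σ = 1 cm, ~80 points) seated on spurs 8–15 cm
off the branch axis, RGB near (250, 248, 245) against foliage
(60, 120, 50), σ = 10 per channel; touching pairs as two compact blobs
(σ = 8 mm) 6 cm apart — close enough to merge at the trunk-radius DBSCAN
eps, with a genuine density dip for the split stage. Branch azimuths are
evenly spaced with ±25% jitter and a random global rotation: uneven
enough to avoid artificial rotational symmetry, separated enough that
two scaffolds never grow on top of each other. The LiDAR view carries
6000 points per tree by default with the drone view at 40%, echoing the
order-of-magnitude density ratio of real paired surveys. Orchard scenes
place trees at cell centres with ±0.15 m planting jitter over a sloped
plane (ground sampled at 25 points/m²) with designated gap slots. All
sampling is deterministic per seed; per-tree seeds derive from the scene
seed.

What the generator does *not* emulate: foliage (the bud-burst
assumption — skeletons are extracted from leaf-off wood), occlusion
shadows, multi-return waveforms, georeferencing error beyond a rigid
transform, wind deformation between surveys, and second-order branching.
Passing tests therefore certify the algorithmic chain on clean vase-form
geometry, not performance on leaf-on or heavily occluded field scans.

## Problem sizes and determinism

The test and acceptance runs use 4 × 5 orchards (~140 k points), 20-tree
suites at 6 k points per tree, and per-tree skeletons of 100–300 nodes;
the pipeline subsamples crops to 2500 points before contraction. These
sizes keep the full suite in a few minutes while leaving every stage's
behaviour measurable against ground truth. Every stochastic step
(subsampling, RANSAC, K-means) takes an explicit seed; a pipeline run
writes byte-identical trait tables when repeated with the same seed, and
per-tree failures flag the tree without aborting the orchard.

## Known limitations

- Pure graph pruning cannot remove a support whose own top ranks as an
  outermost tip in pathological geometries; the intensity rule is the
  designed backstop, and clouds without an intensity channel fall back
  to graph pruning alone with a warning.
- The branch definition is first-order only and validated only against
  the synthetic generator; on real trees with strong sub-branching the
  count depends on the minimum-length and dedup thresholds.
- Blossom classification features assume single flowers are compact and
  multi-flower groups larger; heavily overlapping inflorescences beyond
  the touching-pair regime will undercount even after splitting.
- The CSF implementation is a simplified cloth model; extremely steep
  terrain (beyond ~15°) or large overhangs would need the full
  formulation with sloped-cloth post-processing.
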