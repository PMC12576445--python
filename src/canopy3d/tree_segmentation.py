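"""Individual-tree detection and cropping from the CHM.

Two segmentation styles are supported: mask-based detection on the
greyscale CHM (local Otsu threshold + morphological opening, suited to
well-spaced trees) and row-interpolated grid slots for dense plantings
where tree positions follow from row endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from skimage import filters, morphology, measure

from .types import NO_DATA, PointCloud, RasterCHM, TreeInstance, TreeStatus

DEFAULT_MIN_TREE_POINTS = 200


def chm_to_grey(chm: RasterCHM) -> np.ndarray:
    """Map the CHM linearly onto 0-255 grey levels (no-data -> 0).

    Brighter pixels are taller canopy. Half-integers round down
    (round-half-down), so half of the maximum height maps to 127.
    """
    valid = chm.heights != NO_DATA
    if not valid.any():
        raise ValueError("CHM contains no data cells")
    hmax = chm.heights[valid].max()
    grey = np.zeros(chm.shape, dtype=np.uint8)
    if hmax > 0:
        scaled = chm.heights[valid] / hmax * 255.0
        grey[valid] = np.ceil(scaled - 0.5).astype(np.uint8)
    return grey


@dataclass
class TreeROI:
    """A detected tree region: bounding box and binary mask on the CHM grid."""

    bbox: tuple[int, int, int, int]      # min_row, min_col, max_row, max_col
    mask: np.ndarray                     # full-raster boolean
    centroid_rc: tuple[float, float]     # (row, col) in pixels
    area_px: int = 0


def detect_tree_rois(grey: np.ndarray, open_radius_px: int = 2,
                     min_area_px: int = 25, otsu_window_px: int = 65
                     ) -> list[TreeROI]:
    """Detect tree regions of interest in the greyscale CHM.

    Local Otsu thresholding (window ``otsu_window_px``) binarises the
    image, a morphological opening with a disc of ``open_radius_px``
    removes speckle, and connected components below ``min_area_px`` are
    discarded. Boxes come back sorted row-major by centroid.
    """
    grey = np.asarray(grey)
    if grey.std() == 0:
        return []
    if min(grey.shape) < otsu_window_px:
        thresh = filters.threshold_otsu(grey)
        binary = grey > thresh
    else:
        footprint = np.ones((otsu_window_px, otsu_window_px), dtype=bool)
        local = filters.rank.otsu(grey.astype(np.uint8), footprint)
        binary = grey > local
    if open_radius_px > 0:
        binary = morphology.opening(binary, morphology.disk(open_radius_px))
    labels = measure.label(binary, connectivity=2)
    rois: list[TreeROI] = []
    for region in measure.regionprops(labels):
        if region.area < min_area_px:
            continue
        mask = labels == region.label
        rois.append(TreeROI(bbox=tuple(region.bbox[:2]) + tuple(region.bbox[2:]),
                            mask=mask, centroid_rc=region.centroid,
                            area_px=int(region.area)))
    if not rois:
        return []
    # row-major: bin centroid rows by the median box height, then sort by col
    heights = [r.bbox[2] - r.bbox[0] for r in rois]
    bin_h = max(float(np.median(heights)), 1.0)
    rois.sort(key=lambda r: (int(r.centroid_rc[0] // bin_h), r.centroid_rc[1]))
    return rois


def crop_trees(pc: PointCloud, rois: list[TreeROI], chm: RasterCHM,
               min_points: int = DEFAULT_MIN_TREE_POINTS,
               mode: str = "mask", pad_px: int = 0) -> list[TreeInstance]:
    """Assign cloud points to detected tree regions.

    Each point maps to the CHM cell under it; a point inside two regions
    goes to the one with the nearer centroid, ties to the lower tree id.
    Points outside all regions are dropped. An empty region yields a gap
    instance. ``mode="mask"`` uses the detected masks verbatim (canopy
    edges cut exactly); ``mode="box"`` fills each ROI's bounding box,
    which keeps crown-interior points that project between branches.
    """
    nrows, ncols = chm.shape
    x0, y0 = chm.origin
    col = ((pc.coords[:, 0] - x0) / chm.cell_size).astype(int)
    row = ((pc.coords[:, 1] - y0) / chm.cell_size).astype(int)
    in_raster = (row >= 0) & (row < nrows) & (col >= 0) & (col < ncols)

    # per-cell owner, overlap ties resolved by centroid distance then id
    owner = np.full((nrows, ncols), -1, dtype=int)
    best_d2 = np.full((nrows, ncols), np.inf)
    for tid, roi in enumerate(rois):
        if mode == "box":
            r0, c0, r1, c1 = roi.bbox
            m = np.zeros_like(roi.mask)
            m[max(r0 - pad_px, 0):r1 + pad_px,
              max(c0 - pad_px, 0):c1 + pad_px] = True
            rr, cc = np.nonzero(m)
        else:
            rr, cc = np.nonzero(roi.mask)
        d2 = (rr - roi.centroid_rc[0]) ** 2 + (cc - roi.centroid_rc[1]) ** 2
        better = d2 < best_d2[rr, cc]
        owner[rr[better], cc[better]] = tid
        best_d2[rr[better], cc[better]] = d2[better]

    assignment = np.full(len(pc), -1, dtype=int)
    assignment[in_raster] = owner[row[in_raster], col[in_raster]]

    instances: list[TreeInstance] = []
    for tid, roi in enumerate(rois):
        idx = np.nonzero(assignment == tid)[0]
        pts = pc.select(idx)
        if len(pts):
            bbox = pts.bbox
            cen = tuple(pts.coords[:, :2].mean(axis=0))
            status = TreeStatus.PRESENT if len(pts) >= min_points else TreeStatus.DEAD
        else:
            r0, c0, r1, c1 = roi.bbox
            bbox = np.array([[x0 + c0 * chm.cell_size, y0 + r0 * chm.cell_size, 0.0],
                             [x0 + c1 * chm.cell_size, y0 + r1 * chm.cell_size, 0.0]])
            cen = (x0 + (roi.centroid_rc[1] + 0.5) * chm.cell_size,
                   y0 + (roi.centroid_rc[0] + 0.5) * chm.cell_size)
            status = TreeStatus.GAP
        instances.append(TreeInstance(tree_id=tid, row=-1, col=-1, points=pts,
                                      bbox=bbox, centroid_xy=cen, status=status,
                                      point_indices=idx))
    return instances


def interpolate_row(start_xy, end_xy, n_trees: int) -> np.ndarray:
    """Evenly spaced expected tree centroids along a row segment."""
    start = np.asarray(start_xy, dtype=np.float64)
    end = np.asarray(end_xy, dtype=np.float64)
    if n_trees < 2:
        raise ValueError("a row needs at least 2 trees")
    if np.allclose(start, end):
        raise ValueError("row endpoints coincide")
    t = np.linspace(0.0, 1.0, n_trees)[:, None]
    return start[None, :] * (1 - t) + end[None, :] * t


def flag_gaps(expected_centroids: np.ndarray, instances: list[TreeInstance],
              match_radius: float,
              min_points: int = DEFAULT_MIN_TREE_POINTS):
    """Match detections to expected slots; unmatched slots become gaps.

    Returns (statuses, slot_to_instance, anomalies): one status per slot
    (present / gap / dead), the matched instance index per slot (-1 for
    gaps), and detections that lost a two-to-one contest for a slot.
    """
    if match_radius <= 0:
        raise ValueError("match_radius must be positive")
    expected = np.asarray(expected_centroids, dtype=np.float64).reshape(-1, 2)
    detected = np.array([inst.centroid_xy for inst in instances]).reshape(-1, 2)
    statuses: list[TreeStatus] = []
    slot_to_instance = np.full(len(expected), -1, dtype=int)
    anomalies: list[int] = []
    claimed = {}
    for s, exp in enumerate(expected):
        if len(detected) == 0:
            statuses.append(TreeStatus.GAP)
            continue
        d = np.hypot(*(detected - exp).T)
        order = np.argsort(d)
        match = -1
        for j in order:
            if d[j] > match_radius:
                break
            if j not in claimed:
                match = int(j)
                claimed[j] = s
                break
            anomalies.append(int(j))
        if match < 0:
            statuses.append(TreeStatus.GAP)
        else:
            slot_to_instance[s] = match
            n = len(instances[match].points)
            statuses.append(TreeStatus.PRESENT if n >= min_points
                            else TreeStatus.DEAD)
    # detections that lost the contest for a slot but sit within range of one
    if len(detected):
        for j in range(len(detected)):
            if j in claimed or j in anomalies:
                continue
            d = np.hypot(*(expected - detected[j]).T)
            if d.min() <= match_radius:
                anomalies.append(j)
    return statuses, slot_to_instance, sorted(set(anomalies))
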