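"""Point-cloud I/O, denoising, ground/canopy separation and the CHM.

The pre-processing chain mirrors standard airborne-survey practice:
statistical outlier removal (SOR) drops noise returns, a cloth-simulation
filter (CSF) splits the cloud into terrain (DTM) and above-ground (DSM)
points, and their difference on a grid yields the canopy height model
(CHM) in centimetres.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator
from scipy.spatial import cKDTree

from . import _formats
from .types import NO_DATA, PointCloud, RasterCHM, Source


# ---------------------------------------------------------------- I/O

def normalize_intensity(values: np.ndarray) -> np.ndarray:
    """Min-max rescale to [0, 1]; idempotent; constant input maps to 0."""
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size == 0:
        return values
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def read_cloud(path, format: Optional[str] = None, source: Optional[str] = None,
               crs: Optional[str] = None) -> PointCloud:
    """Read a LAS/PLY/CSV point cloud; intensity is min-max normalised.

    Source is inferred from the channels present (RGB -> drone,
    intensity -> lidar) unless given explicitly.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"{path}: no such file")
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "las":
        rec = _formats.read_las(path)
    elif fmt == "ply":
        rec = _formats.read_ply(path)
    elif fmt == "csv":
        rec = _formats.read_csv_cloud(path)
    else:
        raise IOError(f"{path}: unknown point-cloud format '{fmt}'")
    intensity = rec["intensity"]
    if intensity is not None:
        intensity = normalize_intensity(intensity)
    if source is None:
        source = Source.DRONE if rec["rgb"] is not None else Source.LIDAR
    return PointCloud(coords=rec["coords"], intensity=intensity,
                      rgb=rec["rgb"], crs=crs, source=source)


def write_cloud(pc: PointCloud, path, format: Optional[str] = None) -> None:
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "las":
        _formats.write_las(path, pc.coords, pc.intensity, pc.rgb)
    elif fmt == "ply":
        _formats.write_ply(path, pc.coords, pc.intensity, pc.rgb)
    elif fmt == "csv":
        cols = [pc.coords]
        header = "x,y,z"
        if pc.intensity is not None:
            cols.append(pc.intensity.reshape(-1, 1))
            header += ",intensity"
        if pc.rgb is not None:
            cols.append(pc.rgb)
            header += ",r,g,b"
        np.savetxt(path, np.hstack(cols), delimiter=",", header=header,
                   comments="", fmt="%.10g")
    else:
        raise IOError(f"{path}: unknown point-cloud format '{fmt}'")


# ---------------------------------------------------------------- SOR

def sor_denoise(pc: PointCloud, k: int = 16, std_ratio: float = 1.0,
                return_mask: bool = False):
    """Statistical outlier removal.

    A point survives iff its mean distance to its k nearest neighbours is
    at most (global mean + std_ratio * global std) of that statistic.
    Point order is preserved; no point is ever created.
    """
    n = len(pc)
    if n <= k:
        raise ValueError(f"SOR needs more than k={k} points, got {n}")
    tree = cKDTree(pc.coords)
    dists, _ = tree.query(pc.coords, k=k + 1)  # first hit is the point itself
    mean_d = dists[:, 1:].mean(axis=1)
    keep = mean_d <= mean_d.mean() + std_ratio * mean_d.std()
    out = pc.select(keep)
    return (out, keep) if return_mask else out


# ---------------------------------------------------------------- CSF

def _simulate_cloth(pc: PointCloud, cloth_resolution: float,
                    rigidness: float = 0.4, n_iter: int = 300,
                    dz: float = 0.05):
    """Drape a simulated cloth under the cloud to estimate the terrain.

    Working in the original (z-up) frame: the cloth starts below all
    points and rises under "gravity", each particle stopping when it
    reaches the lowest return above it; spring relaxation between
    neighbouring particles keeps the surface smooth so canopy-only cells
    do not pull the cloth up into the crown.
    """
    xy = pc.coords[:, :2]
    z = pc.coords[:, 2]
    lo = xy.min(axis=0)
    hi = xy.max(axis=0)
    extent = hi - lo
    if min(extent) < 2 * cloth_resolution:
        raise ValueError(
            "cloud horizontal extent smaller than 2 x cloth_resolution "
            "(degenerate, e.g. a vertical line)")
    ncols = max(int(np.ceil(extent[0] / cloth_resolution)) + 1, 2)
    nrows = max(int(np.ceil(extent[1] / cloth_resolution)) + 1, 2)

    col = np.clip(((xy[:, 0] - lo[0]) / cloth_resolution).astype(int), 0, ncols - 1)
    row = np.clip(((xy[:, 1] - lo[1]) / cloth_resolution).astype(int), 0, nrows - 1)
    ceil = np.full((nrows, ncols), np.inf)
    np.minimum.at(ceil, (row, col), z)  # lowest return per cell

    h = np.full((nrows, ncols), z.min() - 1.0)
    movable = np.ones_like(h, dtype=bool)
    for _ in range(n_iter):
        h[movable] += dz
        hit = h >= ceil
        h[hit] = ceil[hit]
        movable &= ~hit
        # spring relaxation toward the 4-neighbour mean
        padded = np.pad(h, 1, mode="edge")
        nb = (padded[:-2, 1:-1] + padded[2:, 1:-1] +
              padded[1:-1, :-2] + padded[1:-1, 2:]) / 4.0
        h = np.where(movable, h + rigidness * (nb - h), h)
        over = h > ceil
        h[over] = ceil[over]
        if not movable.any():
            break
    return h, lo, cloth_resolution, (nrows, ncols)


def csf_ground_filter(pc: PointCloud, cloth_resolution: float = 0.5,
                      class_threshold: float = 0.05, return_mask: bool = False):
    """Cloth-simulation ground filter: split into (ground, aboveground).

    A point is ground iff its height above the settled cloth surface is
    at most class_threshold. The two outputs partition the input.
    """
    h, lo, res, (nrows, ncols) = _simulate_cloth(pc, cloth_resolution)
    # bilinear sample of the cloth at each point's x-y
    gx = np.clip((pc.coords[:, 0] - lo[0]) / res, 0, ncols - 1 - 1e-9)
    gy = np.clip((pc.coords[:, 1] - lo[1]) / res, 0, nrows - 1 - 1e-9)
    c0 = gx.astype(int)
    r0 = gy.astype(int)
    fx = gx - c0
    fy = gy - r0
    c1 = np.minimum(c0 + 1, ncols - 1)
    r1 = np.minimum(r0 + 1, nrows - 1)
    cloth_z = (h[r0, c0] * (1 - fx) * (1 - fy) + h[r0, c1] * fx * (1 - fy) +
               h[r1, c0] * (1 - fx) * fy + h[r1, c1] * fx * fy)
    is_ground = pc.coords[:, 2] - cloth_z <= class_threshold
    ground, above = pc.select(is_ground), pc.select(~is_ground)
    return (ground, above, is_ground) if return_mask else (ground, above)


# ---------------------------------------------------------------- CHM

def build_chm(ground: PointCloud, aboveground: PointCloud,
              cell_size: float = 0.05, crs: Optional[str] = None) -> RasterCHM:
    """Canopy height model: per-cell max canopy z minus interpolated DTM.

    Heights are reported in centimetres and clamped at zero; cells with no
    above-ground returns carry the no-data sentinel. DTM interpolation is
    linear barycentric over the ground points with nearest-neighbour
    fallback outside their convex hull.
    """
    if len(ground) == 0 or len(aboveground) == 0:
        raise ValueError("both ground and aboveground clouds must be non-empty")
    g_lo = ground.coords[:, :2].min(axis=0)
    g_hi = ground.coords[:, :2].max(axis=0)
    a_lo = aboveground.coords[:, :2].min(axis=0)
    a_hi = aboveground.coords[:, :2].max(axis=0)
    lo = np.maximum(g_lo, a_lo)
    hi = np.minimum(g_hi, a_hi)
    if np.any(hi < lo):
        raise ValueError("ground and aboveground clouds do not overlap in x-y")

    ncols = max(int(np.ceil((hi[0] - lo[0]) / cell_size)), 1)
    nrows = max(int(np.ceil((hi[1] - lo[1]) / cell_size)), 1)

    xy = aboveground.coords[:, :2]
    z = aboveground.coords[:, 2]
    inside = np.all((xy >= lo) & (xy <= hi), axis=1)
    xy, z = xy[inside], z[inside]
    col = np.clip(((xy[:, 0] - lo[0]) / cell_size).astype(int), 0, ncols - 1)
    row = np.clip(((xy[:, 1] - lo[1]) / cell_size).astype(int), 0, nrows - 1)
    top = np.full((nrows, ncols), -np.inf)
    np.maximum.at(top, (row, col), z)

    # DTM sampled at the centres of occupied cells
    occ_r, occ_c = np.nonzero(np.isfinite(top))
    cx = lo[0] + (occ_c + 0.5) * cell_size
    cy = lo[1] + (occ_r + 0.5) * cell_size
    gxy = ground.coords[:, :2]
    gz = ground.coords[:, 2]
    try:
        lin = LinearNDInterpolator(gxy, gz)
        dtm = lin(np.column_stack([cx, cy]))
    except Exception:  # collinear ground points etc.
        dtm = np.full(cx.shape, np.nan)
    if np.any(np.isnan(dtm)):
        near = NearestNDInterpolator(gxy, gz)
        bad = np.isnan(dtm)
        dtm[bad] = near(np.column_stack([cx[bad], cy[bad]]))

    heights = np.full((nrows, ncols), NO_DATA)
    heights[occ_r, occ_c] = np.maximum(top[occ_r, occ_c] - dtm, 0.0) * 100.0
    return RasterCHM(heights=heights, cell_size=cell_size,
                     origin=(float(lo[0]), float(lo[1])), crs=crs or ground.crs)


def write_chm_ascii(chm: RasterCHM, path) -> None:
    """Export the CHM as an ESRI ASCII grid (plain text)."""
    nrows, ncols = chm.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {chm.origin[0]:.6f}\n")
        fh.write(f"yllcorner {chm.origin[1]:.6f}\n")
        fh.write(f"cellsize {chm.cell_size:.6f}\n")
        fh.write(f"NODATA_value {NO_DATA:g}\n")
        # ESRI grids store the top row first
        np.savetxt(fh, chm.heights[::-1], fmt="%.2f")


def read_chm_ascii(path) -> RasterCHM:
    with open(path) as fh:
        meta = {}
        for _ in range(6):
            key, val = fh.readline().split()
            meta[key.lower()] = float(val)
        heights = np.loadtxt(fh, ndmin=2)[::-1]
    return RasterCHM(heights=heights, cell_size=meta["cellsize"],
                     origin=(meta["xllcorner"], meta["yllcorner"]))
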