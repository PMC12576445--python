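"""End-to-end orchestration: config, parameter derivation, trait tables.

A run goes: scene (synthetic or loaded) -> SOR denoise -> CSF ground split
-> CHM -> tree detection and cropping -> grid positioning -> per-tree
skeletonisation, support pruning, gap filling, smoothing and branch
counting -> canopy traits -> (if a coloured bloom view exists) skeleton
registration and the blossom pipeline. One tree failing flags that tree
and the run continues. All randomness derives from the single config seed,
so a rerun writes byte-identical trait CSVs.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import (canopy_traits, floral_traits, pointcloud_io, skeleton_fusion,
               skeleton_refinement, synthetic_orchard, tree_positioning,
               tree_segmentation)
from .types import PointCloud, Source, TreeStatus


@dataclass
class PipelineConfig:
    seed: int = 42
    out_dir: str = "canopy3d_out"
    # synthetic scene
    rows: int = 4
    cols: int = 5
    tree_spacing: float = 4.0
    row_spacing: float = 3.5
    slope_deg: float = 2.0
    gap_slots: list = field(default_factory=list)
    # pre-processing
    sor_k: int = 16
    sor_std_ratio: float = 1.0
    csf_cloth_resolution: float = 0.5
    csf_class_threshold: float = 0.05
    chm_cell: float = 0.10
    # segmentation
    open_radius_px: int = 1
    close_radius_px: int = 2
    min_area_px: int = 25
    min_tree_points: int = 200
    match_radius: float = 1.2
    crop_mode: str = "box"     # "box" keeps crown-interior points; "mask" cuts edges
    crop_pad_px: int = 8
    # skeleton / pruning
    skeleton_max_points: int = 2500
    contraction_iters: int = 5
    node_spacing: float = 0.05
    prune_alpha: float = 1.0
    voxel: float = 0.02
    branch_min_len: float = 0.1
    # floral
    floral: bool = True
    # explicit parameter overrides (win over derive_parameters)
    overrides: dict = field(default_factory=dict)

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_toml(self, path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, str):
                lines.append(f'{f.name} = "{v}"')
            elif isinstance(v, bool):
                lines.append(f"{f.name} = {str(v).lower()}")
            elif isinstance(v, (int, float)):
                lines.append(f"{f.name} = {v}")
            elif isinstance(v, (list, tuple)):
                lines.append(f"{f.name} = {json.dumps([list(x) if isinstance(x, (list, tuple)) else x for x in v])}")
            elif isinstance(v, dict):
                lines.append(f"{f.name} = {json.dumps(v)}" if not v else
                             "\n".join([f"[{f.name}]"] +
                                       [f"{k} = {json.dumps(val)}" for k, val in v.items()]))
        Path(path).write_text("\n".join(lines) + "\n")


def derive_parameters(r_trunk: float, overrides: dict = None) -> dict:
    """Distance parameters from the trunk radius, by documented multipliers.

    graph_radius = 2 x R_Trunk is the R-NN radius for skeleton graphs;
    blossom DBSCAN eps = R_Trunk; intensity R-NN radius = R_Trunk.
    Explicit overrides always win.
    """
    params = {
        "graph_radius": 2.0 * r_trunk,
        "blossom_eps": r_trunk,
        "intensity_radius": r_trunk,
    }
    if overrides:
        params.update({k: v for k, v in overrides.items() if k in params})
    return params


def _subsample(pc: PointCloud, n_max: int, seed: int) -> PointCloud:
    if len(pc) <= n_max:
        return pc
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(pc), size=n_max, replace=False))
    return pc.select(idx)


def analyse_tree(lidar_pc: PointCloud, cfg: PipelineConfig, seed: int,
                 drone_pc: PointCloud = None) -> dict:
    """Per-tree analysis: skeleton, pruning, branches, canopy + floral traits."""
    out: dict = {}
    r_trunk = skeleton_refinement.estimate_trunk_radius(lidar_pc)
    params = derive_parameters(r_trunk, cfg.overrides)
    out["r_trunk"] = r_trunk

    sub = _subsample(lidar_pc, cfg.skeleton_max_points, seed)
    skel = skeleton_fusion.extract_skeleton(
        sub, contraction_iters=cfg.contraction_iters,
        node_spacing=cfg.node_spacing)
    graph = skeleton_refinement.build_tree_graph(
        skel, max(params["graph_radius"], 2.5 * cfg.node_spacing))
    pruned, kept, _ = skeleton_refinement.graph_prune_supports(graph)
    pruned, _, removed_int = skeleton_refinement.intensity_prune_supports(
        pruned, lidar_pc, r=params["intensity_radius"], alpha=cfg.prune_alpha)
    # the reintroduction screen targets supports: the intensity-removed
    # nodes (plus the voxel intensity screen inside fill_gaps)
    filled, fill_info = skeleton_refinement.fill_gaps(
        pruned, lidar_pc, voxel=cfg.voxel, removed_mask=removed_int)
    refined = skeleton_refinement.smooth_interpolate(filled)
    branchset = skeleton_refinement.count_branches(
        refined, min_len=cfg.branch_min_len, r_trunk=r_trunk)
    branchset.r_trunk = r_trunk
    out["branchset"] = branchset
    out["num_branch"] = branchset.num_branch
    out["skeleton"] = refined
    out["fill_info"] = fill_info

    traits = canopy_traits.compute_canopy_traits(lidar_pc, r_trunk)
    out["canopy"] = traits

    if drone_pc is not None and drone_pc.rgb is not None and cfg.floral:
        d_sub = _subsample(drone_pc, cfg.skeleton_max_points, seed + 1)
        d_skel = skeleton_fusion.extract_skeleton(
            d_sub, contraction_iters=cfg.contraction_iters,
            node_spacing=cfg.node_spacing)
        T = skeleton_fusion.register(d_skel, skel, seed=seed)
        registered = skeleton_fusion.apply_transform(drone_pc, T)
        out["transform"] = T
        cand = floral_traits.blossom_mask(registered)
        cand = floral_traits.remove_near_skeleton(registered, cand, refined,
                                                  r=r_trunk)
        clusters = floral_traits.cluster_blossoms(registered, cand,
                                                  eps=params["blossom_eps"])
        clusters = floral_traits.classify_clusters(registered, clusters,
                                                   seed=seed)
        singles = [c for c in clusters if c.cls == "single"]
        for c in clusters:
            if c.cls == "multi":
                singles.extend(floral_traits.split_multiflower(
                    registered, c, eps=params["blossom_eps"]))
        apex_z = registered.coords[:, 2].max() if len(registered) else 0.0
        base_z = traits.crown_base_z
        if singles and apex_z > base_z:
            strata = floral_traits.stratify(
                np.array([c.centroid for c in singles]), base_z, apex_z)
            for c, s in zip(singles, strata):
                c.stratum = s
        for c in singles:
            floral_traits.cluster_metrics(registered, c, voxel=cfg.voxel)
        if branchset.num_branch:
            floral_traits.assign_to_branches(singles, branchset)
        out["blossom_clusters"] = singles
    return out


def run_pipeline(cfg: PipelineConfig, scene: PointCloud = None,
                 truth=None):
    """Run the full chain and write trait tables under ``cfg.out_dir``.

    Returns a dict with the trait DataFrames, the grid, per-tree results
    and the output paths. Without an input ``scene`` a synthetic orchard
    is generated from the config.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    if scene is None:
        scene, truth = synthetic_orchard.generate_orchard(
            cfg.rows, cfg.cols, (cfg.tree_spacing, cfg.row_spacing),
            slope_deg=cfg.slope_deg, gap_slots=[tuple(g) for g in cfg.gap_slots],
            seed=cfg.seed)
        log.append(f"synth: {len(scene)} points, "
                   f"{int(truth.present.sum())} trees")

    denoised, _ = pointcloud_io.sor_denoise(
        scene, k=cfg.sor_k, std_ratio=cfg.sor_std_ratio, return_mask=True)
    ground, above = pointcloud_io.csf_ground_filter(
        denoised, cloth_resolution=cfg.csf_cloth_resolution,
        class_threshold=cfg.csf_class_threshold)
    chm = pointcloud_io.build_chm(ground, above, cell_size=cfg.chm_cell)
    log.append(f"preprocess: ground={len(ground)} above={len(above)}")

    grey = tree_segmentation.chm_to_grey(chm)
    if cfg.close_radius_px:
        # greyscale closing consolidates sparse crown projections
        from skimage import morphology
        grey = morphology.closing(grey, morphology.disk(cfg.close_radius_px))
    rois = tree_segmentation.detect_tree_rois(
        grey, open_radius_px=cfg.open_radius_px, min_area_px=cfg.min_area_px)
    instances = tree_segmentation.crop_trees(
        above, rois, chm, min_points=cfg.min_tree_points,
        mode=cfg.crop_mode, pad_px=cfg.crop_pad_px)
    log.append(f"segment: {len(instances)} instances")

    # grid positioning from the layout
    layout = (cfg.rows, cfg.cols, (cfg.tree_spacing, cfg.row_spacing))
    expected = np.array([[ (c + 0.5) * cfg.tree_spacing,
                           (r + 0.5) * cfg.row_spacing]
                         for r in range(cfg.rows) for c in range(cfg.cols)])
    statuses, slot_map, anomalies = tree_segmentation.flag_gaps(
        expected, instances, match_radius=cfg.match_radius,
        min_points=cfg.min_tree_points)

    records, floral_rows, branch_json = [], [], {}
    seeds = np.random.SeedSequence(cfg.seed).generate_state(
        cfg.rows * cfg.cols + 1) % (2 ** 31)
    for slot, (status, inst_idx) in enumerate(zip(statuses, slot_map)):
        r, c = slot // cfg.cols, slot % cfg.cols
        rec = {"tree_id": slot, "row": r, "col": c, "status": status.value,
               "geo_x": expected[slot, 0], "geo_y": expected[slot, 1]}
        if status != TreeStatus.PRESENT:
            records.append(rec)
            continue
        inst = instances[inst_idx]
        drone = None
        if truth is not None:
            # match the slot to its synthetic tree's bloom-stage view
            k = int(np.sum(truth.present[:slot]))
            if truth.present[slot]:
                drone = truth.tree_truths[k].drone_view
        try:
            cen = tree_positioning.trunk_centroid(inst, method="robust")
            local = inst.points.with_coords(
                inst.points.coords - np.array([cen[0], cen[1],
                                               inst.points.coords[:, 2].min()]))
            local.intensity = inst.points.intensity
            res = analyse_tree(local, cfg, seed=int(seeds[slot]),
                               drone_pc=drone)
        except Exception as exc:  # noqa: BLE001 — tree isolation contract
            warnings.warn(f"tree {slot} failed: {exc}")
            rec["status"] = "failed"
            records.append(rec)
            continue
        t = res["canopy"]
        rec.update({"centroid_x": cen[0], "centroid_y": cen[1],
                    "n_points": len(inst.points),
                    "height_max_cm": round(t.height_max, 2),
                    "projarea_m2": round(t.proj_area_crown, 4),
                    "volume_m3": round(t.volume_crown, 4),
                    "surfarea_m2": round(t.surfarea_crown, 4),
                    "diameter_m": round(t.diameter_crown, 4),
                    "r_trunk_m": round(res["r_trunk"], 4),
                    "num_branch": res["num_branch"]})
        records.append(rec)
        branch_json[str(slot)] = {
            "num_branch": res["num_branch"],
            "branches": [list(map(int, b)) for b in
                         res["branchset"].branches]}
        for ci, cl in enumerate(res.get("blossom_clusters", [])):
            floral_rows.append({
                "tree_id": slot, "cluster": ci, "stratum": cl.stratum,
                "cls": cl.cls, "n": cl.n,
                "cx": round(float(cl.centroid[0]), 4),
                "cy": round(float(cl.centroid[1]), 4),
                "cz": round(float(cl.centroid[2]), 4),
                "volume_m3": None if np.isnan(cl.volume_blossom)
                else round(cl.volume_blossom, 8),
                "surf_m2": None if np.isnan(cl.surf_blossom)
                else round(cl.surf_blossom, 6),
                "projarea_m2": None if np.isnan(cl.projarea_blossom)
                else round(cl.projarea_blossom, 6),
                "branch_id": cl.branch_id})
        log.append(f"tree {slot}: branches={res['num_branch']} "
                   f"blossoms={len(res.get('blossom_clusters', []))}")

    canopy_df = pd.DataFrame(records)
    floral_df = pd.DataFrame(floral_rows)
    canopy_path = out_dir / "traits_canopy.csv"
    floral_path = out_dir / "traits_floral.csv"
    canopy_df.to_csv(canopy_path, index=False)
    floral_df.to_csv(floral_path, index=False)
    (out_dir / "branches.json").write_text(json.dumps(branch_json, indent=1))
    (out_dir / "run_log.txt").write_text("\n".join(log) + "\n")
    cfg.to_toml(out_dir / "resolved_config.toml")
    return {"canopy": canopy_df, "floral": floral_df,
            "instances": instances, "statuses": statuses,
            "chm": chm, "paths": {"canopy": canopy_path,
                                  "floral": floral_path}}
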