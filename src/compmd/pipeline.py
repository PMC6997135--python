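"""End-to-end comparative analysis of two systems (apo vs complex).

``run_compare`` executes, per system: conformational descriptors
(RMSD/RMSF/Rg/B-factor), RMSD-threshold clustering with a growth curve, a
first-vs-last-frame contact comparison, a hydrogen-bond scan, PCA with a
free-energy landscape and basins, a pore profile, and — when per-frame
component tables are supplied — the binding free-energy ledger.  Stages are
independent: a failing stage is recorded as failed and the rest continue.
Identical config + inputs give an identical report.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import cluster as cluster_mod
from . import contacts as contacts_mod
from . import energetics as energetics_mod
from . import fel as fel_mod
from . import geometry as geometry_mod
from . import interactions as interactions_mod
from . import pore as pore_mod
from .errors import ConfigError, NoHydrogensError
from .traj_io import Trajectory, read_pdb, read_topology_table

logger = logging.getLogger("compmd.pipeline")

__all__ = ["PipelineConfig", "validate_config", "run_compare",
           "StageResult", "Report"]


class PipelineConfig(BaseModel):
    """Validated configuration of the comparative pipeline."""

    model_config = ConfigDict(extra="forbid")

    traj_a: str
    traj_b: str
    label_a: str = "system_a"
    label_b: str = "system_b"
    topology_a: Optional[str] = None
    topology_b: Optional[str] = None
    selection: str = "calpha"
    contact_cutoff: float = Field(4.5, gt=0, le=20)
    neighbor_exclusion: int = Field(2, ge=0)
    cluster_threshold: float = Field(2.4, gt=0)
    cluster_threshold_fine: float = Field(1.5, gt=0)
    cluster_stride: int = Field(1, ge=1)
    cluster_max_frames: int = Field(400, ge=2)
    hbond_distance_max: float = Field(3.5, gt=0)
    hbond_angle_min: float = Field(135.0, ge=0, le=180)
    temperature: float = Field(300.0, gt=0)
    fel_bins: int = Field(50, ge=2)
    basin_depth_cut: float = Field(10.0, gt=0)
    pore_axis: Optional[list] = None   # [[x,y,z],[x,y,z]] or None for auto
    pore_step: float = Field(0.25, gt=0)
    pore_search_radius: float = Field(5.0, gt=0)
    energy_table_a: Optional[str] = None
    energy_table_b: Optional[str] = None
    equilibration_fraction: float = Field(0.1, ge=0, lt=1)
    seed: int = 0
    output_dir: str = "compmd_out"


def validate_config(text: str) -> PipelineConfig:
    """Parse YAML config text; unknown keys and out-of-range values reject.

    Every field left at its default is echoed to the log so the effective
    parameter set is always visible.
    """
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError("config must be a mapping")
    try:
        config = PipelineConfig(**data)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc
    for name, field_info in PipelineConfig.model_fields.items():
        if name not in data:
            logger.info("config default applied: %s = %r",
                        name, getattr(config, name))
    return config


class StageResult(BaseModel):
    status: str                      # "ok" or "failed"
    data: dict[str, Any] = {}
    error: Optional[str] = None


class Report(BaseModel):
    config: dict[str, Any]
    systems: dict[str, dict[str, StageResult]]
    comparison: dict[str, Any]


def _stage(fn):
    try:
        return StageResult(status="ok", data=fn())
    except Exception as exc:  # report the failure, keep the pipeline going
        logger.warning("stage failed: %s", exc)
        return StageResult(status="failed", error=str(exc))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _analyze_system(label: str, traj: Trajectory, config: PipelineConfig,
                    out: Path, energy_table: str | None
                    ) -> dict[str, StageResult]:
    sel = traj.select(config.selection)
    results: dict[str, StageResult] = {}

    def descriptors():
        series = geometry_mod.rmsd_series(
            traj, traj.frame(0), sel,
            equilibration_fraction=config.equilibration_fraction)
        times = (traj.times if traj.times is not None
                 else np.arange(traj.n_frames, dtype=float))
        pd.DataFrame({"frame": np.arange(traj.n_frames), "time_ns": times,
                      "value": series.values}).to_csv(
            out / f"{label}_rmsd.csv", index=False)
        fluct = geometry_mod.rmsf(traj, sel)
        bfac = geometry_mod.bfactor_from_rmsf(fluct)
        pd.DataFrame({"atom_index": sel, "rmsf": fluct,
                      "bfactor": bfac}).to_csv(
            out / f"{label}_rmsf.csv", index=False)
        rg = [geometry_mod.radius_of_gyration(traj.xyz[i], sel)
              for i in (0, traj.n_frames - 1)]
        return {"rmsd_mean": series.mean, "rmsd_sd": series.sd,
                "rmsd_window": list(series.window),
                "rmsf_mean": float(np.mean(fluct)),
                "bfactor_max": float(np.max(bfac)),
                "rg_first": rg[0], "rg_last": rg[1]}

    def clustering():
        stride = max(1, traj.n_frames // config.cluster_max_frames)
        frames = np.arange(0, traj.n_frames, stride)
        sub = Trajectory(topology=traj.topology, xyz=traj.xyz[frames],
                         times=None)
        matrix = cluster_mod.pairwise_rmsd_matrix(sub, sel)
        assignment = cluster_mod.threshold_cluster(
            matrix, config.cluster_threshold)
        prefixes, counts = cluster_mod.cluster_growth(
            sub, sel, threshold=config.cluster_threshold_fine,
            stride=config.cluster_stride, matrix=matrix)
        pd.DataFrame({"frame": frames,
                      "cluster_id": assignment.labels}).to_csv(
            out / f"{label}_clusters.csv", index=False)
        return {"n_clusters": int(assignment.n_clusters),
                "occupancy": assignment.occupancy.tolist(),
                "representatives": frames[
                    assignment.representatives].tolist(),
                "threshold": assignment.threshold,
                "growth_prefix": prefixes.tolist(),
                "growth_count": counts.tolist(),
                "frame_stride": int(stride)}

    def contact_stage():
        first = contacts_mod.contact_map(
            traj, 0, cutoff=config.contact_cutoff,
            neighbor_exclusion=config.neighbor_exclusion)
        last = contacts_mod.contact_map(
            traj, traj.n_frames - 1, cutoff=config.contact_cutoff,
            neighbor_exclusion=config.neighbor_exclusion)
        comparison = contacts_mod.compare_maps(first, last)
        segments = contacts_mod.segment_specific_fraction(first, last)
        first.edge_table().to_csv(out / f"{label}_contacts_first.csv",
                                  index=False)
        last.edge_table().to_csv(out / f"{label}_contacts_last.csv",
                                 index=False)
        segments.to_csv(out / f"{label}_contact_segments.csv", index=False)
        return {"common": comparison.common,
                "specific_first": comparison.specific_first,
                "specific_last": comparison.specific_last,
                "total_first": comparison.total_first,
                "total_last": comparison.total_last,
                "similarity": comparison.similarity,
                "reduction_rate": comparison.reduction_rate}

    def hbond_stage():
        try:
            triples = interactions_mod.find_hbond_candidates(traj)
        except NoHydrogensError:
            return {"n_candidates": 0,
                    "note": "structure has no explicit hydrogens"}
        rows = {}
        for triple in triples:
            stats = interactions_mod.hbond_occupancy(
                traj, triple, distance_max=config.hbond_distance_max,
                angle_min=config.hbond_angle_min)
            rows[triple.label] = {
                "frequency": stats.frequency,
                "mean_distance": stats.mean_distance,
                "mean_angle": stats.mean_angle}
        with open(out / f"{label}_hbonds.json", "w") as fh:
            json.dump(_jsonable(rows), fh, indent=1, sort_keys=True)
        return {"n_candidates": len(triples), "bonds": rows}

    def fel_stage():
        model = fel_mod.pca(traj, sel)
        grid = fel_mod.fel_grid(model.projections[:, :2],
                                temperature=config.temperature,
                                bins=config.fel_bins)
        basins = fel_mod.find_basins(grid, config.basin_depth_cut)
        gaussianity = fel_mod.pc_gaussianity(model.projections[:, 0])
        pd.DataFrame({"frame": np.arange(traj.n_frames),
                      "pc1": model.projections[:, 0],
                      "pc2": model.projections[:, 1]}).to_csv(
            out / f"{label}_pca.csv", index=False)
        total = model.eigenvalues.sum()
        return {"explained_fraction_pc1": float(model.eigenvalues[0] / total),
                "explained_fraction_pc2": float(model.eigenvalues[1] / total),
                "n_basins": len(basins),
                "basin_occupancies": [b.occupancy for b in basins],
                "basin_min_delta_g": [b.min_delta_g for b in basins],
                "pc1_excess_kurtosis": gaussianity.excess_kurtosis,
                "pc1_bimodality": gaussianity.bimodality_coefficient}

    def pore_stage():
        axis = ("auto" if config.pore_axis is None
                else [np.asarray(p, dtype=float) for p in config.pore_axis])
        profile = pore_mod.pore_profile(
            traj, axis=axis, step=config.pore_step,
            search_radius=config.pore_search_radius)
        pd.DataFrame([{
            "z": s.axial_position, "center_x": s.center[0],
            "center_y": s.center[1], "center_z": s.center[2],
            "radius": s.radius, "class": s.classification,
            "nearest_residue": s.nearest_residue[1]}
            for s in profile.stations]).to_csv(
            out / f"{label}_pore.csv", index=False)
        narrowest = profile.min_station()
        return {"min_radius": narrowest.radius,
                "min_position": narrowest.axial_position,
                "min_class": narrowest.classification,
                "n_stations": len(profile.stations)}

    def energy_stage():
        if energy_table is None:
            return {"skipped": "no per-frame component table supplied"}
        series = energetics_mod.load_component_table(
            Path(energy_table).read_text(),
            temperature=config.temperature)
        m = series.mean
        return {"vdw": m.vdw, "ele": m.ele, "polar_solv": m.polar_solv,
                "nonpolar_solv": m.nonpolar_solv,
                "entropy_term": m.entropy_term, "enthalpy": m.enthalpy,
                "binding": m.binding, "polar_total": m.polar_total,
                "nonpolar_total": m.nonpolar_total,
                "sd": series.sd}

    for name, fn in [("descriptors", descriptors), ("cluster", clustering),
                     ("contacts", contact_stage), ("hbonds", hbond_stage),
                     ("fel", fel_stage), ("pore", pore_stage),
                     ("energy", energy_stage)]:
        logger.info("[%s] running stage %s", label, name)
        results[name] = _stage(fn)
    return results


def run_compare(config: PipelineConfig) -> dict:
    """Run the full comparative pipeline; returns (and writes) the report."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    systems = {}
    for label, traj_path, energy_table in [
            (config.label_a, config.traj_a, config.energy_table_a),
            (config.label_b, config.traj_b, config.energy_table_b)]:
        traj = read_pdb(Path(traj_path).read_text())
        systems[label] = _analyze_system(label, traj, config, out,
                                         energy_table)

    comparison: dict[str, Any] = {}
    for stat in ("similarity", "reduction_rate"):
        values = {}
        for label in (config.label_a, config.label_b):
            stage = systems[label]["contacts"]
            if stage.status == "ok":
                values[label] = stage.data[stat]
        comparison[f"contact_{stat}"] = values
    occ = {}
    for label in (config.label_a, config.label_b):
        stage = systems[label]["fel"]
        if stage.status == "ok":
            occ[label] = stage.data["basin_occupancies"]
    comparison["basin_occupancies"] = occ

    report = Report(config=config.model_dump(), systems=systems,
                    comparison=_jsonable(comparison))
    payload = json.loads(report.model_dump_json())
    with open(out / "report.json", "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
    return payload
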