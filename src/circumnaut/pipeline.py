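"""End-to-end orchestration: simulate -> project -> (track) -> triangulate ->
kinematics -> group statistics, from one declarative configuration.

The default experiment mirrors the study design: 8 plants per genotype
(wild type, *rms1-1*, *rms3-1*), support pole 100 mm from the plant, one
stereo frame every 3 minutes.  By default the rendering/tracking stage is
bypassed — ground-truth 3D trajectories are projected to pixel
trajectories with tracking-level noise and triangulated back — which
keeps a full experiment at desk scale; the image path (blob rendering +
KLT tracking) can be switched on and is exercised separately on shorter
sequences.

Every random stage derives its seed deterministically from the top-level
experiment seed, so a configuration reproduces its outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .camera import StereoRig, make_converging_rig
from .errors import InvalidArgumentError
from .kinematics import (
    SegmentationThresholds,
    fill_and_smooth,
    per_cycle_summaries,
    segment_movement,
    summarize,
)
from .reconstruction import reconstruct_trajectory
from .stats import DEFAULT_MEASURES, GroupAnalysisReport, run_group_analysis
from .synthetic import (
    GENOTYPES,
    SceneSpec,
    genotype_preset,
    project_stereo,
    render_marker_sequence,
    simulate_tip_trajectory,
)
from .tracking import TrackerConfig, track_point
from .trajectory import Trajectory2D

__all__ = ["RunConfig", "ExperimentReport", "run_experiment", "run_geometry_only"]

SUMMARY_COLUMNS = [
    "plant_id",
    "genotype",
    "duration_min",
    "mean_vel_mm_min",
    "max_acc_mm_min2",
    "cx",
    "cy",
    "cz",
    "dist_origin_mm",
    "dist_support_mm",
    "n_cycles",
    "outcome",
]


@dataclass(frozen=True)
class RunConfig:
    """Complete, serializable description of one experiment run."""

    genotypes: tuple[str, ...] = GENOTYPES
    n_plants_per_genotype: int = 8
    duration_min: float = 600.0
    seed: int = 0
    pixel_noise_sd: float = 0.2
    use_image_tracking: bool = False
    scene: SceneSpec = field(default_factory=SceneSpec)
    rig: StereoRig = field(default_factory=make_converging_rig)
    tracker: TrackerConfig = field(default_factory=TrackerConfig)
    thresholds: SegmentationThresholds = field(default_factory=SegmentationThresholds)
    smoother_half_width: int = 1
    max_gap: int = 5
    unit: str = "per_cycle"
    posthoc: str = "dunn_holm"
    measures: tuple[str, ...] = DEFAULT_MEASURES

    def __post_init__(self) -> None:
        unknown = [g for g in self.genotypes if g not in GENOTYPES]
        if unknown:
            raise InvalidArgumentError(f"unknown genotype labels: {unknown}")
        if self.n_plants_per_genotype < 1:
            raise InvalidArgumentError("need at least one plant per genotype")
        if self.unit not in ("per_plant", "per_cycle"):
            raise InvalidArgumentError("unit must be 'per_plant' or 'per_cycle'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["rig"] = self.rig.to_dict()
        return d

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=float).encode()
        ).hexdigest()


@dataclass
class ExperimentReport:
    per_plant: pd.DataFrame
    per_cycle: pd.DataFrame
    stats: GroupAnalysisReport
    manifest: dict


def _plant_seeds(base_seed: int, g_idx: int, p_idx: int) -> tuple[int, int]:
    ss = np.random.SeedSequence([base_seed, g_idx, p_idx])
    sim_seed, proj_seed = (int(s) for s in ss.generate_state(2))
    return sim_seed, proj_seed


def _track_via_images(
    traj2d: Trajectory2D, tracker: TrackerConfig, blob_sigma: float = 2.0
) -> Trajectory2D:
    """Render the projected marker into a cropped window and re-track it."""
    ok = traj2d.ok
    if not ok[0]:
        raise InvalidArgumentError("first frame must be visible for tracking")
    pts = traj2d.points[ok]
    # margin large enough that the tracking window fits at every pyramid level
    margin = 2**tracker.pyramid_levels * (tracker.window + 3)
    lo = np.floor(pts.min(axis=0)) - margin
    size = np.ceil(pts.max(axis=0) - lo) + margin
    shifted = Trajectory2D(
        times=traj2d.times.copy(),
        points=traj2d.points - lo,
        status=traj2d.status.copy(),
    )
    stack, _ = render_marker_sequence(
        shifted, image_size=(int(size[0]), int(size[1])), blob_sigma=blob_sigma
    )
    tracked = track_point(
        stack, shifted.points[0], tracker, times=traj2d.times.copy()
    )
    return Trajectory2D(
        times=tracked.times,
        points=tracked.points + lo,
        status=tracked.status,
    )


def process_plant(
    cfg: RunConfig, genotype: str, plant_index: int
) -> tuple[dict, pd.DataFrame]:
    """Run the full measurement chain for one simulated plant.

    Returns the per-plant summary row and the per-cycle observation table.
    """
    g_idx = list(cfg.genotypes).index(genotype)
    sim_seed, proj_seed = _plant_seeds(cfg.seed, g_idx, plant_index)
    preset = genotype_preset(genotype, cfg.duration_min)
    truth = simulate_tip_trajectory(
        preset.params, cfg.scene, cfg.duration_min, seed=sim_seed
    )
    trajL, trajR = project_stereo(
        truth, cfg.rig, pixel_noise_sd=cfg.pixel_noise_sd, seed=proj_seed
    )
    if cfg.use_image_tracking:
        trajL = _track_via_images(trajL, cfg.tracker)
        trajR = _track_via_images(trajR, cfg.tracker)
    traj3d, _ = reconstruct_trajectory(trajL, trajR, cfg.rig)
    smooth = fill_and_smooth(
        traj3d, max_gap=cfg.max_gap, half_width=cfg.smoother_half_width
    )
    epoch = segment_movement(smooth, cfg.scene, cfg.thresholds)
    summary = summarize(smooth, epoch, cfg.scene)
    cycles = per_cycle_summaries(smooth, epoch, cfg.scene)
    plant_id = f"{genotype}_{plant_index:02d}"
    row = {
        "plant_id": plant_id,
        "genotype": genotype,
        "duration_min": summary.duration_min,
        "mean_vel_mm_min": summary.mean_velocity_mm_min,
        "max_acc_mm_min2": summary.max_acceleration_mm_min2,
        "cx": summary.center_mm[0],
        "cy": summary.center_mm[1],
        "cz": summary.center_mm[2],
        "dist_origin_mm": summary.dist_center_origin_mm,
        "dist_support_mm": summary.dist_center_support_mm,
        "n_cycles": summary.n_cycles,
        "outcome": summary.outcome,
    }
    cycles.insert(0, "plant_id", plant_id)
    cycles.insert(1, "genotype", genotype)
    return row, cycles


def run_experiment(cfg: RunConfig, out_dir=None) -> ExperimentReport:
    """Run the genotype-comparison experiment described by ``cfg``.

    Simulates every plant, measures it through the stereo pipeline,
    assembles tidy per-plant and per-cycle tables, and runs the group
    statistics at the configured observational unit.  When ``out_dir`` is
    given, the tables, the statistics report and a provenance manifest
    (config, hash, checksums) are written there.
    """
    rows, cycle_tables = [], []
    for genotype in cfg.genotypes:
        for p in range(cfg.n_plants_per_genotype):
            row, cycles = process_plant(cfg, genotype, p)
            rows.append(row)
            cycle_tables.append(cycles)
    per_plant = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    per_cycle = pd.concat(cycle_tables, ignore_index=True)

    table = per_cycle if cfg.unit == "per_cycle" else per_plant
    stats_report = run_group_analysis(
        table, measures=cfg.measures, unit=cfg.unit, posthoc=cfg.posthoc
    )

    manifest = {
        "package_version": __version__,
        "config": cfg.to_dict(),
        "config_hash": cfg.content_hash(),
        "n_plants": len(per_plant),
        "n_cycle_observations": len(per_cycle),
    }
    report = ExperimentReport(per_plant, per_cycle, stats_report, manifest)
    if out_dir is not None:
        _persist(report, out_dir)
    return report


def _persist(report: ExperimentReport, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {
        "per_plant.csv": lambda p: report.per_plant.to_csv(p, index=False),
        "per_cycle.csv": lambda p: report.per_cycle.to_csv(p, index=False),
        "stats.json": lambda p: Path(p).write_text(
            json.dumps(report.stats.to_dict(), indent=2)
        ),
    }
    checksums = {}
    for name, writer in files.items():
        path = out / name
        writer(path)
        checksums[name] = hashlib.sha256(path.read_bytes()).hexdigest()
    report.manifest["artifact_sha256"] = checksums
    (out / "manifest.json").write_text(json.dumps(report.manifest, indent=2))


def run_geometry_only(cfg: RunConfig) -> dict:
    """Simulate -> project -> triangulate, reporting reconstruction QC only.

    Compares each reconstructed trajectory against its known ground truth
    and aggregates the errors; used to validate the rig and, with
    ``use_image_tracking``, the tracker, without touching kinematics or
    statistics.
    """
    err_3d, reproj, fractions = [], [], []
    for genotype in cfg.genotypes:
        for p in range(cfg.n_plants_per_genotype):
            g_idx = list(cfg.genotypes).index(genotype)
            sim_seed, proj_seed = _plant_seeds(cfg.seed, g_idx, p)
            preset = genotype_preset(genotype, cfg.duration_min)
            truth = simulate_tip_trajectory(
                preset.params, cfg.scene, cfg.duration_min, seed=sim_seed
            )
            trajL, trajR = project_stereo(
                truth, cfg.rig, pixel_noise_sd=cfg.pixel_noise_sd, seed=proj_seed
            )
            if cfg.use_image_tracking:
                trajL = _track_via_images(trajL, cfg.tracker)
                trajR = _track_via_images(trajR, cfg.tracker)
            recon, rep = reconstruct_trajectory(trajL, trajR, cfg.rig)
            valid = recon.valid
            err_3d.extend(
                np.linalg.norm(recon.points[valid] - truth.points[valid], axis=1)
            )
            reproj.extend(rep.reprojection_error_left_px[valid])
            reproj.extend(rep.reprojection_error_right_px[valid])
            fractions.append(rep.fraction_reconstructed)
    err_3d = np.asarray(err_3d)
    reproj = np.asarray(reproj)
    return {
        "n_frames": int(err_3d.size),
        "median_3d_error_mm": float(np.median(err_3d)),
        "max_3d_error_mm": float(np.max(err_3d)),
        "median_reprojection_error_px": float(np.median(reproj)),
        "mean_fraction_reconstructed": float(np.mean(fractions)),
    }
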