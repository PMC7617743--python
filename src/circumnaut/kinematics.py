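"""Movement segmentation and the six circumnutation dependent measures.

From a 3D tendril-tip trajectory and the scene geometry this module
derives, per plant:

* the movement epoch (first visible frame to support contact, fall, or
  cessation of motion) and its outcome (``grasped`` / ``fell`` /
  ``stopped``);
* duration of circumnutation (min);
* mean velocity amplitude (mm/min) — the mean instantaneous 3D speed;
* maximum acceleration amplitude (mm/min^2);
* the gravity center of the circumnutation — the arithmetic mean of tip
  positions over the epoch;
* its 3D distance to the plant origin and its horizontal distance to the
  (vertical, extended) support axis;
* the number of rotation cycles and their direction.

Derivatives are central differences at the native frame interval,
one-sided at the epoch ends, computed on gap-filled and moving-average
smoothed coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    InvalidArgumentError,
    UndefinedRotationError,
    UnfillableGapError,
)
from .synthetic import SceneSpec
from .trajectory import Trajectory3D

__all__ = [
    "MovementEpoch",
    "KinematicSummary",
    "SegmentationThresholds",
    "fill_and_smooth",
    "segment_movement",
    "differentiate",
    "summarize",
    "count_cycles",
    "per_cycle_summaries",
]

OUTCOMES = ("grasped", "fell", "stopped")


@dataclass(frozen=True)
class MovementEpoch:
    start_frame: int
    end_frame: int
    outcome: str
    warning: str | None = None

    def __post_init__(self) -> None:
        if self.start_frame >= self.end_frame:
            raise InvalidArgumentError("epoch must span at least one frame interval")
        if self.outcome not in OUTCOMES:
            raise InvalidArgumentError(f"unknown outcome {self.outcome!r}")


@dataclass(frozen=True)
class SegmentationThresholds:
    """End-of-movement rules; values are analysis choices, logged per run."""

    grasp_margin: float = 2.0  # mm beyond the pole surface that counts as contact
    fall_drop: float = 20.0  # mm of height loss below the running maximum
    stop_speed: float = 0.05  # mm/min below which the plant counts as still
    stop_frames: int = 20  # consecutive still frames for 'stopped'


@dataclass(frozen=True)
class KinematicSummary:
    duration_min: float
    mean_velocity_mm_min: float
    max_acceleration_mm_min2: float
    center_mm: tuple[float, float, float]
    dist_center_origin_mm: float
    dist_center_support_mm: float
    n_cycles: int
    outcome: str

    def __post_init__(self) -> None:
        if self.duration_min <= 0:
            raise InvalidArgumentError("duration must be positive")
        if min(
            self.mean_velocity_mm_min,
            self.max_acceleration_mm_min2,
            self.dist_center_origin_mm,
            self.dist_center_support_mm,
        ) < 0:
            raise InvalidArgumentError("speeds and distances must be >= 0")


# ---------------------------------------------------------------------------
# gap filling and smoothing


def fill_and_smooth(
    traj: Trajectory3D, max_gap: int = 5, half_width: int = 1
) -> Trajectory3D:
    """Fill missing frames by linear interpolation and smooth coordinates.

    Gaps longer than ``max_gap`` frames (or missing frames at either end,
    which cannot be interpolated) raise :class:`UnfillableGapError`.  The
    smoother is a centered moving average of half-width ``half_width``
    frames, with shrinking windows at the endpoints; ``half_width=0``
    disables smoothing.
    """
    valid = traj.valid
    if not valid.any():
        raise UnfillableGapError("trajectory has no valid frames")
    missing = np.flatnonzero(~valid)
    if missing.size:
        if not valid[0] or not valid[-1]:
            raise UnfillableGapError(
                "missing frames at the trajectory boundary cannot be interpolated"
            )
        runs = np.split(missing, np.flatnonzero(np.diff(missing) > 1) + 1)
        too_long = [r for r in runs if len(r) > max_gap]
        if too_long:
            frames = [f"{r[0]}..{r[-1]}" for r in too_long]
            raise UnfillableGapError(
                f"gaps exceed max_gap={max_gap} frames at {', '.join(frames)}"
            )
    pts = traj.points.copy()
    idx = np.arange(len(traj))
    for c in range(3):
        pts[~valid, c] = np.interp(idx[~valid], idx[valid], pts[valid, c])

    if half_width > 0:
        sm = np.empty_like(pts)
        n = len(pts)
        for i in range(n):
            lo = max(0, i - half_width)
            hi = min(n, i + half_width + 1)
            sm[i] = pts[lo:hi].mean(axis=0)
        pts = sm

    meta = dict(traj.metadata)
    meta.update(filled=True, smoothed=half_width > 0, smoother_half_width=half_width)
    return Trajectory3D(
        times=traj.times.copy(),
        points=pts,
        status=np.array(["valid"] * len(traj), dtype=object),
        metadata=meta,
    )


# ---------------------------------------------------------------------------
# differentiation


def differentiate(traj: Trajectory3D) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame speed (mm/min) and acceleration magnitude (mm/min^2).

    Central differences at interior frames, one-sided at the ends;
    magnitudes are Euclidean norms of the 3D derivative vectors.
    """
    if len(traj) < 3:
        raise InvalidArgumentError("need >= 3 frames to differentiate")
    dt = traj.frame_interval  # validates uniformity
    vel = np.gradient(traj.points, dt, axis=0)
    acc = np.gradient(vel, dt, axis=0)
    return np.linalg.norm(vel, axis=1), np.linalg.norm(acc, axis=1)


# ---------------------------------------------------------------------------
# segmentation


def segment_movement(
    traj: Trajectory3D,
    scene: SceneSpec,
    thresholds: SegmentationThresholds | None = None,
) -> MovementEpoch:
    """Locate the movement epoch and classify its outcome.

    The start is the first valid frame.  Scanning forward, the epoch ends
    at the first frame where one of three rules triggers: (a) the tip
    comes within ``grasp_margin`` of the pole surface -> ``grasped``;
    (b) height drops ``fall_drop`` below its running maximum -> ``fell``;
    (c) speed stays below ``stop_speed`` for ``stop_frames`` consecutive
    frame intervals -> ``stopped``.  Ties on the same frame resolve in
    the order grasped > fell > stopped.  If no rule triggers, the epoch
    ends at the last frame as ``stopped`` with a warning flag.
    """
    th = thresholds or SegmentationThresholds()
    start = int(np.argmax(traj.valid))
    if not traj.valid.any():
        raise InvalidArgumentError("trajectory has no valid frames")
    pts = traj.points
    n = len(traj)
    speed, _ = differentiate(traj)
    dist_support = scene.horizontal_distance_to_support(pts)
    grasp_level = scene.support_radius + th.grasp_margin

    running_max_z = pts[start, 2]
    still_run = 0
    for k in range(start + 1, n):
        grasped = dist_support[k] <= grasp_level
        running_max_z = max(running_max_z, pts[k, 2])
        fell = pts[k, 2] <= running_max_z - th.fall_drop
        still_run = still_run + 1 if speed[k] < th.stop_speed else 0
        stopped = still_run >= th.stop_frames
        if grasped:
            return MovementEpoch(start, k, "grasped")
        if fell:
            return MovementEpoch(start, k, "fell")
        if stopped:
            return MovementEpoch(start, k, "stopped")
    return MovementEpoch(
        start, n - 1, "stopped", warning="no end-of-movement rule triggered"
    )


# ---------------------------------------------------------------------------
# cycle counting


def count_cycles(
    traj: Trajectory3D,
    epoch: MovementEpoch,
    min_radius: float = 1e-6,
) -> tuple[int, list[int], int]:
    """Count rotation cycles of the tip about the epoch-mean center.

    The azimuthal angle of the tip around the (horizontal) epoch-mean
    center is unwrapped over time; ``n_cycles`` is the number of full
    2*pi turns, the direction the sign of the total signed angle (viewed
    from above, counterclockwise positive).  Frames with near-zero radius
    are excluded as degenerate; more than 50% degenerate frames raise
    :class:`UndefinedRotationError`.

    Returns ``(n_cycles, cycle_boundary_frames, direction)`` where the
    boundaries are the frames at which each full turn completes.
    """
    sl = slice(epoch.start_frame, epoch.end_frame + 1)
    pts = traj.points[sl]
    frames = np.arange(epoch.start_frame, epoch.end_frame + 1)
    center = pts.mean(axis=0)
    rel = pts[:, :2] - center[:2]
    radius = np.linalg.norm(rel, axis=1)
    good = radius > min_radius
    if good.sum() < max(2, 0.5 * len(pts)):
        raise UndefinedRotationError(
            "more than half of the epoch frames are degenerate (radius ~ 0)"
        )
    angles = np.unwrap(np.arctan2(rel[good, 1], rel[good, 0]))
    total = angles[-1] - angles[0]
    n_cycles = int(np.floor(abs(total) / (2.0 * np.pi)))
    direction = int(np.sign(total)) if total != 0 else 0
    boundaries = []
    for m in range(1, n_cycles + 1):
        hit = np.flatnonzero(np.abs(angles - angles[0]) >= m * 2.0 * np.pi)
        boundaries.append(int(frames[good][hit[0]]))
    return n_cycles, boundaries, direction


# ---------------------------------------------------------------------------
# summary measures


def _center_and_distances(pts: np.ndarray, scene: SceneSpec):
    center = pts.mean(axis=0)
    origin = np.asarray(scene.origin, dtype=float)
    d_origin = float(np.linalg.norm(center - origin))
    d_support = float(scene.horizontal_distance_to_support(center))
    return center, d_origin, d_support


def summarize(
    traj: Trajectory3D, epoch: MovementEpoch, scene: SceneSpec
) -> KinematicSummary:
    """Compute the six dependent measures over the movement epoch."""
    n = len(traj)
    if not (0 <= epoch.start_frame < epoch.end_frame < n):
        raise InvalidArgumentError("epoch outside trajectory")
    sl = slice(epoch.start_frame, epoch.end_frame + 1)
    dt = traj.frame_interval
    speed, acc = differentiate(traj)
    center, d_origin, d_support = _center_and_distances(traj.points[sl], scene)
    try:
        n_cycles, _, _ = count_cycles(traj, epoch)
    except UndefinedRotationError:
        n_cycles = 0
    return KinematicSummary(
        duration_min=(epoch.end_frame - epoch.start_frame) * dt,
        mean_velocity_mm_min=float(np.mean(speed[sl])),
        max_acceleration_mm_min2=float(np.max(acc[sl])),
        center_mm=tuple(float(c) for c in center),
        dist_center_origin_mm=d_origin,
        dist_center_support_mm=d_support,
        n_cycles=n_cycles,
        outcome=epoch.outcome,
    )


def per_cycle_summaries(
    traj: Trajectory3D, epoch: MovementEpoch, scene: SceneSpec
) -> pd.DataFrame:
    """Per-cycle observations: one row per completed rotation cycle.

    Each cycle contributes its own duration, mean speed, maximum
    acceleration, gravity center and the two center distances — the
    finer observational unit used for group comparison.
    """
    n_cycles, boundaries, _ = count_cycles(traj, epoch)
    dt = traj.frame_interval
    speed, acc = differentiate(traj)
    rows = []
    starts = [epoch.start_frame] + boundaries[:-1]
    for c, (a, b) in enumerate(zip(starts, boundaries)):
        sl = slice(a, b + 1)
        center, d_origin, d_support = _center_and_distances(traj.points[sl], scene)
        rows.append(
            {
                "cycle": c,
                "duration_min": (b - a) * dt,
                "mean_vel_mm_min": float(np.mean(speed[sl])),
                "max_acc_mm_min2": float(np.max(acc[sl])),
                "cx": center[0],
                "cy": center[1],
                "cz": center[2],
                "dist_origin_mm": d_origin,
                "dist_support_mm": d_support,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cycle",
            "duration_min",
            "mean_vel_mm_min",
            "max_acc_mm_min2",
            "cx",
            "cy",
            "cz",
            "dist_origin_mm",
            "dist_support_mm",
        ],
    )
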