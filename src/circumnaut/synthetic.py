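"""Synthetic circumnutation scenes with known ground truth.

Circumnutation — the rotatory growth movement of a climbing plant's organ
tip — is modelled here as the simplest kinematic process that exhibits
every feature the downstream measures quantify: an elliptical rotation of
the tendril tip about a slowly moving stem center, vertical elongation,
an optional goal-directed horizontal drift of the stem center toward a
support pole, and an optional collapse ("fall") after which height decays
monotonically.  This is a test surface for the measurement pipeline, not
a biomechanical model.

Three genotype presets emulate the study contrast: a wild-type-like plant
whose rotation center drifts toward the support until its rotation
envelope reaches the pole (so the tip eventually touches and "grasps"),
and two slower mutant-like plants (*rms1-1*, *rms3-1*) with no directed
drift that collapse partway through the recording.

The module also renders marker image sequences (Gaussian blobs on a dark
background, emulating a high-contrast marker against black velvet) and
generates chessboard calibration views, so calibration, tracking,
triangulation and kinematics can each be verified against exact truth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .camera import StereoRig, project_points
from .errors import InvalidArgumentError
from .trajectory import Trajectory2D, Trajectory3D

__all__ = [
    "CircumnutationParams",
    "GenotypePreset",
    "SceneSpec",
    "ChessboardView",
    "GENOTYPES",
    "default_scene",
    "genotype_preset",
    "simulate_tip_trajectory",
    "project_stereo",
    "render_marker_sequence",
    "generate_chessboard_views",
    "first_contact_frame",
]

GENOTYPES = ("wild_type", "rms1_1", "rms3_1")


@dataclass(frozen=True)
class CircumnutationParams:
    """Parameters of one simulated plant's tip movement.

    amplitude_x, amplitude_y
        Semi-axes of the rotation ellipse (mm).
    period
        Nominal duration of one rotation cycle (min) at ``speed_scale`` 1.
    phase
        Initial rotation angle (rad).
    rotation_sign
        +1 counterclockwise (viewed from above), -1 clockwise.
    growth_rate
        Vertical elongation rate (mm/min) at ``speed_scale`` 1.
    drift_gain
        First-order rate (1/min) at which the stem center closes the gap
        to the support axis; 0 disables goal-directed drift.
    speed_scale
        Multiplier on nominal tip speed (scales rotation rate and growth).
    fall_time
        Onset of collapse (min), or ``None`` for no fall.
    fall_speed
        Vertical descent rate after collapse onset (mm/min).
    noise_sd
        Isotropic positional jitter (mm) added per frame.
    """

    amplitude_x: float = 30.0
    amplitude_y: float = 30.0
    period: float = 80.0
    phase: float = 0.0
    rotation_sign: int = 1
    growth_rate: float = 0.15
    drift_gain: float = 0.0
    speed_scale: float = 1.0
    fall_time: float | None = None
    fall_speed: float = 0.8
    noise_sd: float = 0.2

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise InvalidArgumentError("period must be positive")
        if self.amplitude_x < 0 or self.amplitude_y < 0:
            raise InvalidArgumentError("amplitudes must be >= 0")
        if self.speed_scale <= 0:
            raise InvalidArgumentError("speed_scale must be positive")
        if self.drift_gain < 0:
            raise InvalidArgumentError("drift_gain must be >= 0")
        if self.rotation_sign not in (-1, 1):
            raise InvalidArgumentError("rotation_sign must be +1 or -1")
        if self.noise_sd < 0 or self.fall_speed <= 0:
            raise InvalidArgumentError("noise_sd >= 0 and fall_speed > 0 required")


@dataclass(frozen=True)
class GenotypePreset:
    label: str
    params: CircumnutationParams

    def __post_init__(self) -> None:
        if self.label not in GENOTYPES:
            raise InvalidArgumentError(f"unknown genotype label {self.label!r}")


@dataclass(frozen=True)
class SceneSpec:
    """World-coordinate contract shared by all kinematic measures.

    Right-handed, z-up, millimetres; the support pole is a vertical
    cylinder.  Defaults follow the recording setup: pole of 0.5 cm
    diameter, 54 cm above ground, placed 10 cm from the plant; one stereo
    frame every 3 minutes.
    """

    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    internode: tuple[float, float, float] = (0.0, 0.0, 100.0)
    support_axis_base: tuple[float, float, float] = (100.0, 0.0, 0.0)
    support_radius: float = 2.5
    support_height_above_ground: float = 540.0
    frame_interval: float = 3.0
    support_axis_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if self.support_radius <= 0:
            raise InvalidArgumentError("support_radius must be positive")
        if self.frame_interval <= 0:
            raise InvalidArgumentError("frame_interval must be positive")
        d = np.asarray(self.support_axis_direction, dtype=float)
        if np.linalg.norm(d) == 0 or np.linalg.norm(
            d / np.linalg.norm(d) - np.array([0.0, 0.0, 1.0])
        ) > 1e-9:
            raise InvalidArgumentError("support axis must be vertical (z-up)")

    @property
    def frame_frequency_hz(self) -> float:
        """Acquisition frequency in Hz implied by the frame interval."""
        return 1.0 / (self.frame_interval * 60.0)

    def horizontal_distance_to_support(self, points: np.ndarray) -> np.ndarray:
        """Horizontal (xy) distance from points (..., 3) to the pole axis."""
        p = np.asarray(points, dtype=float)
        base = np.asarray(self.support_axis_base[:2])
        return np.linalg.norm(p[..., :2] - base, axis=-1)


def default_scene() -> SceneSpec:
    return SceneSpec()


_PRESET_FIELDS: dict[str, dict] = {
    # Wild type: goal-directed drift toward the support, never falls.
    "wild_type": dict(speed_scale=1.0, drift_gain=0.02, fall_time_fraction=None),
    # SL-synthesis mutant: slowest, undirected, collapses late in the recording.
    "rms1_1": dict(speed_scale=0.5, drift_gain=0.0, fall_time_fraction=0.7),
    # SL-perception mutant: intermediate speed, undirected, also collapses.
    "rms3_1": dict(speed_scale=0.65, drift_gain=0.0, fall_time_fraction=0.7),
}


def genotype_preset(label: str, duration: float) -> GenotypePreset:
    """Default per-genotype movement parameters for a recording of ``duration`` min.

    Mutant presets place collapse onset at 70% of the recording; the
    wild-type preset never falls and drifts toward the support.
    """
    if label not in _PRESET_FIELDS:
        raise InvalidArgumentError(
            f"unknown genotype {label!r}; expected one of {GENOTYPES}"
        )
    fields = _PRESET_FIELDS[label]
    fall_frac = fields["fall_time_fraction"]
    params = CircumnutationParams(
        speed_scale=fields["speed_scale"],
        drift_gain=fields["drift_gain"],
        fall_time=None if fall_frac is None else fall_frac * duration,
    )
    return GenotypePreset(label=label, params=params)


# ---------------------------------------------------------------------------
# tip trajectory


def simulate_tip_trajectory(
    params: CircumnutationParams,
    scene: SceneSpec,
    duration: float,
    seed: int,
) -> Trajectory3D:
    """Simulate the tendril-tip trajectory, sampled every frame interval.

    The tip is ``stem_center(t) + ellipse(t)``: the stem center starts at
    the plant origin, closes the horizontal gap to the support axis at
    first-order rate ``drift_gain`` — saturating when the gap equals the
    rotation envelope, since the tip cannot pass through the pole — and
    elongates vertically at ``growth_rate * speed_scale``.  After
    ``fall_time`` the height decays monotonically at ``fall_speed``
    (clamped at soil level).  Gaussian jitter of sd ``noise_sd`` is added
    to every coordinate; all randomness is fixed by ``seed``.
    """
    if duration < 2.0 * params.period:
        raise InvalidArgumentError(
            "duration must cover at least two nominal periods"
        )
    if params.fall_time is not None and params.fall_time >= duration:
        raise InvalidArgumentError("fall_time must be < duration")

    dt = scene.frame_interval
    n = int(np.floor(duration / dt)) + 1
    t = np.arange(n) * dt

    origin = np.asarray(scene.origin, dtype=float)
    support_xy = np.asarray(scene.support_axis_base[:2], dtype=float)
    gap0 = float(np.linalg.norm(support_xy - origin[:2]))
    envelope = max(params.amplitude_x, params.amplitude_y)

    if params.drift_gain > 0 and gap0 > envelope:
        gap = envelope + (gap0 - envelope) * np.exp(-params.drift_gain * t)
    else:
        gap = np.full(n, gap0)
    if gap0 > 0:
        u = (support_xy - origin[:2]) / gap0
    else:
        u = np.zeros(2)
    center_xy = support_xy[None, :] - gap[:, None] * u[None, :]

    z = origin[2] + params.growth_rate * params.speed_scale * t
    if params.fall_time is not None:
        after = t > params.fall_time
        z_fall = origin[2] + params.growth_rate * params.speed_scale * params.fall_time
        z[after] = z_fall - params.fall_speed * (t[after] - params.fall_time)
        z = np.maximum(z, origin[2])

    omega = params.rotation_sign * 2.0 * np.pi * params.speed_scale / params.period
    theta = params.phase + omega * t
    tip = np.empty((n, 3))
    tip[:, 0] = center_xy[:, 0] + params.amplitude_x * np.cos(theta)
    tip[:, 1] = center_xy[:, 1] + params.amplitude_y * np.sin(theta)
    tip[:, 2] = z

    if params.noise_sd > 0:
        rng = np.random.default_rng(seed)
        tip = tip + rng.normal(0.0, params.noise_sd, size=tip.shape)

    return Trajectory3D(
        times=t,
        points=tip,
        status=np.array(["valid"] * n, dtype=object),
        metadata={"model": "drifting-center ellipse", "seed": seed},
    )


def first_contact_frame(
    traj: Trajectory3D, scene: SceneSpec, margin: float = 2.0
) -> int | None:
    """Ground-truth frame at which the tip first touches the pole surface.

    Contact means horizontal distance to the pole axis at most
    ``support_radius + margin``; returns ``None`` if never reached.
    """
    d = scene.horizontal_distance_to_support(traj.points)
    hits = np.flatnonzero(d <= scene.support_radius + margin)
    return int(hits[0]) if hits.size else None


# ---------------------------------------------------------------------------
# stereo projection


def project_stereo(
    traj: Trajectory3D,
    rig: StereoRig,
    pixel_noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[Trajectory2D, Trajectory2D]:
    """Project a 3D trajectory through both cameras of a rig.

    Each output frame is the distorted pinhole projection of the 3D point
    plus isotropic Gaussian pixel noise; missing input frames, points
    behind a camera and points projecting outside the sensor are flagged
    ``lost`` on that side.
    """
    if pixel_noise_sd < 0:
        raise InvalidArgumentError("pixel_noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for intr, extr in (
        (rig.left_intrinsics, rig.left_extrinsics),
        (rig.right_intrinsics, rig.right_extrinsics),
    ):
        px, in_front = project_points(traj.points, intr, extr)
        if pixel_noise_sd > 0:
            px = px + rng.normal(0.0, pixel_noise_sd, size=px.shape)
        ok = in_front & traj.valid
        if intr.sensor_size is not None:
            w, h = intr.sensor_size
            with np.errstate(invalid="ignore"):
                inside = (
                    (px[:, 0] >= 0) & (px[:, 0] <= w - 1)
                    & (px[:, 1] >= 0) & (px[:, 1] <= h - 1)
                )
            ok = ok & inside
        status = np.where(ok, "tracked", "lost").astype(object)
        px = np.where(ok[:, None], px, np.nan)
        out.append(Trajectory2D(times=traj.times.copy(), points=px, status=status))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# marker rendering


def render_marker_sequence(
    traj2d: Trajectory2D,
    image_size: tuple[int, int] = (128, 128),
    blob_sigma: float = 2.0,
    background: int = 20,
    peak: int = 230,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one 8-bit grayscale frame per trajectory point.

    Each frame contains an isotropic Gaussian blob of sd ``blob_sigma``
    centred at the sub-pixel marker position over a uniform dark
    background.  Markers outside the image (or frames flagged lost)
    produce a uniform background frame.

    Returns ``(stack, status)`` where ``stack`` has shape (n, h, w) and
    ``status`` records ``lost`` for empty frames.
    """
    if blob_sigma < 0.5:
        raise InvalidArgumentError("blob_sigma must be >= 0.5 px")
    w, h = image_size
    n = len(traj2d)
    stack = np.full((n, h, w), background, dtype=np.uint8)
    status = traj2d.status.copy()
    cols = np.arange(w, dtype=float)
    rows = np.arange(h, dtype=float)
    ok = traj2d.ok
    amp = float(peak - background)
    for i in range(n):
        if not ok[i]:
            status[i] = "lost"
            continue
        u, v = traj2d.points[i]
        if not (0 <= u <= w - 1 and 0 <= v <= h - 1):
            status[i] = "lost"
            continue
        gx = np.exp(-((cols - u) ** 2) / (2.0 * blob_sigma**2))
        gy = np.exp(-((rows - v) ** 2) / (2.0 * blob_sigma**2))
        img = background + amp * np.outer(gy, gx)
        stack[i] = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return stack, status


# ---------------------------------------------------------------------------
# chessboard calibration fixtures


@dataclass(frozen=True)
class ChessboardView:
    """One synthetic board pose with exact stereo correspondences.

    ``X_world = rotation_board_to_world @ X_board + translation_board_to_world``.
    """

    object_points: np.ndarray  # (n, 3) board-frame mm, z = 0
    rotation_board_to_world: np.ndarray
    translation_board_to_world: np.ndarray
    pixels_left: np.ndarray  # (n, 2) exact projections
    pixels_right: np.ndarray

    @property
    def world_points(self) -> np.ndarray:
        return (
            self.object_points @ self.rotation_board_to_world.T
            + self.translation_board_to_world
        )


def chessboard_object_points(
    columns: int = 10, rows: int = 7, square_size: float = 18.0
) -> np.ndarray:
    """Inner-corner grid of a board with the given squares: (columns-1)x(rows-1) points."""
    nx, ny = columns - 1, rows - 1
    if nx < 4 or ny < 4:
        raise InvalidArgumentError("board must have >= 4x4 inner corners")
    xs, ys = np.meshgrid(np.arange(nx), np.arange(ny))
    pts = np.column_stack(
        [xs.ravel() * square_size, ys.ravel() * square_size, np.zeros(nx * ny)]
    )
    return pts.astype(float)


def generate_chessboard_views(
    rig: StereoRig,
    columns: int = 10,
    rows: int = 7,
    square_size: float = 18.0,
    n_views: int = 20,
    seed: int = 0,
    depth_range_mm=(500.0, 1000.0),
    max_tilt_deg: float = 45.0,
) -> list[ChessboardView]:
    """Generate randomized board poses fully visible to both cameras.

    The default board (10 columns x 7 rows of 18 mm squares, 20 views)
    matches the calibration target used in the recording protocol.  Poses
    span depth (placed ``depth_range_mm`` along the rig's mean viewing
    axis, so the board covers a substantial part of the field of view, as
    a hand-held calibration target does) and tilt (random rotations up to
    ``max_tilt_deg``).  Correspondences are exact; pixel noise is the
    caller's responsibility.
    """
    if n_views < 3:
        raise InvalidArgumentError(
            "n_views must be >= 3 (planar calibration is underdetermined)"
        )
    obj = chessboard_object_points(columns, rows, square_size)
    obj_centered = obj - obj.mean(axis=0)
    rng = np.random.default_rng(seed)
    # mean viewing axis of the rig: from the midpoint of the camera centers
    # through the average optical-axis direction
    cam_mid = 0.5 * (
        rig.left_extrinsics.camera_center + rig.right_extrinsics.camera_center
    )
    axis = 0.5 * (rig.left_extrinsics.rotation[2] + rig.right_extrinsics.rotation[2])
    axis = axis / np.linalg.norm(axis)
    views: list[ChessboardView] = []
    attempts = 0
    while len(views) < n_views:
        attempts += 1
        if attempts > 500 * n_views:
            raise InvalidArgumentError(
                "could not place requested number of visible board poses"
            )
        depth = rng.uniform(*depth_range_mm)
        lateral = rng.uniform(-0.15, 0.15, size=3) * depth
        center = cam_mid + depth * axis + lateral
        # base orientation: board plane perpendicular to the viewing axis
        normal = -axis
        e1 = np.cross([0.0, 0.0, 1.0], normal)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(normal, e1)
        base = Rotation.from_matrix(np.column_stack([e1, e2, normal]))
        tilt = Rotation.from_rotvec(
            rng.uniform(-1, 1, size=3) * np.deg2rad(max_tilt_deg)
        )
        R_wb = (tilt * base).as_matrix()
        world_pts = obj_centered @ R_wb.T + center
        pxL, okL = project_points(world_pts, rig.left_intrinsics, rig.left_extrinsics)
        pxR, okR = project_points(world_pts, rig.right_intrinsics, rig.right_extrinsics)
        if not (okL.all() and okR.all()):
            continue
        inside = True
        for px, intr in ((pxL, rig.left_intrinsics), (pxR, rig.right_intrinsics)):
            if intr.sensor_size is not None:
                sw, sh = intr.sensor_size
                m = 10.0
                if not (
                    (px[:, 0] > m).all()
                    and (px[:, 0] < sw - m).all()
                    and (px[:, 1] > m).all()
                    and (px[:, 1] < sh - m).all()
                ):
                    inside = False
                    break
        if not inside:
            continue
        t_wb = center - R_wb @ obj.mean(axis=0)
        views.append(
            ChessboardView(
                object_points=obj,
                rotation_board_to_world=R_wb,
                translation_board_to_world=t_wb,
                pixels_left=pxL,
                pixels_right=pxR,
            )
        )
    return views
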