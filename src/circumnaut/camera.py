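"""Pinhole-with-distortion camera model and planar (chessboard) calibration.

The camera model is the standard pinhole with Brown–Conrady distortion:
a world point ``X`` is mapped to the camera frame by a rigid transform
``X_c = R X + t``, perspectively divided, distorted radially
(``k1 r^2 + k2 r^4``) and tangentially (``p1``, ``p2``), and finally
mapped to pixels by the intrinsic matrix (``fx, fy, cx, cy, skew``).

Single-camera calibration follows the classic planar-target approach:
closed-form intrinsics from inter-image homographies of the board,
per-view pose extraction, then joint nonlinear least-squares refinement
of intrinsics, distortion and all poses.  Stereo extrinsics are obtained
by composing per-view board poses seen by both cameras and averaging the
resulting relative poses (rotations via the quaternion eigen-mean).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .errors import (
    BehindCameraError,
    DegenerateGeometryError,
    InvalidArgumentError,
    NumericFailureError,
)

__all__ = [
    "Intrinsics",
    "Extrinsics",
    "StereoRig",
    "project_point",
    "project_points",
    "undistort_point",
    "undistort_points",
    "calibrate_single",
    "calibrate_stereo",
    "make_converging_rig",
    "look_at_extrinsics",
]


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class Intrinsics:
    """Internal projection parameters of one camera.

    ``fx, fy`` focal lengths and ``cx, cy`` principal point are in pixels;
    ``k1, k2`` are radial and ``p1, p2`` tangential distortion coefficients
    acting on normalized image coordinates.
    """

    fx: float
    fy: float
    cx: float
    cy: float
    skew: float = 0.0
    k1: float = 0.0
    k2: float = 0.0
    p1: float = 0.0
    p2: float = 0.0
    sensor_size: tuple[int, int] | None = None  # (width, height) px

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise InvalidArgumentError("focal lengths must be positive")
        if self.sensor_size is not None:
            w, h = self.sensor_size
            if not (0 <= self.cx <= w and 0 <= self.cy <= h):
                raise InvalidArgumentError(
                    "principal point outside sensor bounds"
                )

    @property
    def matrix(self) -> np.ndarray:
        return np.array(
            [
                [self.fx, self.skew, self.cx],
                [0.0, self.fy, self.cy],
                [0.0, 0.0, 1.0],
            ]
        )

    def to_dict(self) -> dict:
        d = {
            "fx_px": self.fx,
            "fy_px": self.fy,
            "cx_px": self.cx,
            "cy_px": self.cy,
            "skew_px": self.skew,
            "k1": self.k1,
            "k2": self.k2,
            "p1": self.p1,
            "p2": self.p2,
        }
        if self.sensor_size is not None:
            d["sensor_size_px"] = list(self.sensor_size)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Intrinsics":
        size = d.get("sensor_size_px")
        return cls(
            fx=d["fx_px"],
            fy=d["fy_px"],
            cx=d["cx_px"],
            cy=d["cy_px"],
            skew=d.get("skew_px", 0.0),
            k1=d.get("k1", 0.0),
            k2=d.get("k2", 0.0),
            p1=d.get("p1", 0.0),
            p2=d.get("p2", 0.0),
            sensor_size=tuple(size) if size is not None else None,
        )


@dataclass(frozen=True)
class Extrinsics:
    """World-to-camera rigid transform: ``X_cam = rotation @ X_world + translation``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise InvalidArgumentError("rotation must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise InvalidArgumentError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise InvalidArgumentError("rotation must be proper (det = +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @property
    def camera_center(self) -> np.ndarray:
        """Camera center in world coordinates."""
        return -self.rotation.T @ self.translation

    def compose_with_inverse(self, other: "Extrinsics") -> "Extrinsics":
        """Relative pose of self w.r.t. ``other``: maps other-frame to self-frame."""
        R = self.rotation @ other.rotation.T
        t = self.translation - R @ other.translation
        return Extrinsics(R, t)

    def to_dict(self) -> dict:
        return {
            "rotation": self.rotation.tolist(),
            "translation_mm": self.translation.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Extrinsics":
        return cls(np.array(d["rotation"]), np.array(d["translation_mm"]))


@dataclass(frozen=True)
class StereoRig:
    """Two calibrated cameras plus the right-with-respect-to-left pose."""

    left_intrinsics: Intrinsics
    left_extrinsics: Extrinsics
    right_intrinsics: Intrinsics
    right_extrinsics: Extrinsics
    relative: Extrinsics = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        rel = self.relative
        derived = self.right_extrinsics.compose_with_inverse(
            self.left_extrinsics
        )
        if rel is None:
            object.__setattr__(self, "relative", derived)
        else:
            if not (
                np.allclose(rel.rotation, derived.rotation, atol=1e-6)
                and np.allclose(rel.translation, derived.translation, atol=1e-3)
            ):
                raise InvalidArgumentError(
                    "relative pose inconsistent with absolute extrinsics"
                )
        if self.baseline_mm <= 0:
            raise DegenerateGeometryError("stereo baseline must be positive")

    @property
    def baseline_mm(self) -> float:
        return float(
            np.linalg.norm(
                self.left_extrinsics.camera_center
                - self.right_extrinsics.camera_center
            )
        )

    def to_dict(self) -> dict:
        return {
            "left": {
                "intrinsics": self.left_intrinsics.to_dict(),
                "extrinsics": self.left_extrinsics.to_dict(),
            },
            "right": {
                "intrinsics": self.right_intrinsics.to_dict(),
                "extrinsics": self.right_extrinsics.to_dict(),
            },
            "relative_right_wrt_left": self.relative.to_dict(),
            "baseline_mm": self.baseline_mm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StereoRig":
        return cls(
            left_intrinsics=Intrinsics.from_dict(d["left"]["intrinsics"]),
            left_extrinsics=Extrinsics.from_dict(d["left"]["extrinsics"]),
            right_intrinsics=Intrinsics.from_dict(d["right"]["intrinsics"]),
            right_extrinsics=Extrinsics.from_dict(d["right"]["extrinsics"]),
            relative=Extrinsics.from_dict(d["relative_right_wrt_left"]),
        )


# ---------------------------------------------------------------------------
# forward / inverse projection


def _distort_normalized(x: np.ndarray, y: np.ndarray, intr: Intrinsics):
    r2 = x * x + y * y
    radial = 1.0 + intr.k1 * r2 + intr.k2 * r2 * r2
    xd = x * radial + 2.0 * intr.p1 * x * y + intr.p2 * (r2 + 2.0 * x * x)
    yd = y * radial + intr.p1 * (r2 + 2.0 * y * y) + 2.0 * intr.p2 * x * y
    return xd, yd


def project_points(
    points: np.ndarray, intr: Intrinsics, extr: Extrinsics
) -> tuple[np.ndarray, np.ndarray]:
    """Project world points (N, 3) mm to pixels (N, 2).

    Returns ``(pixels, in_front)`` where ``in_front`` flags camera-frame
    z > 0; pixels of behind-camera points are NaN rather than raising, so
    callers can mark individual frames missing.
    """
    P = np.atleast_2d(np.asarray(points, dtype=float))
    cam = P @ extr.rotation.T + extr.translation
    z = cam[:, 2]
    in_front = z > 1e-9
    with np.errstate(divide="ignore", invalid="ignore"):
        x = cam[:, 0] / z
        y = cam[:, 1] / z
    xd, yd = _distort_normalized(x, y, intr)
    u = intr.fx * xd + intr.skew * yd + intr.cx
    v = intr.fy * yd + intr.cy
    px = np.column_stack([u, v])
    px[~in_front] = np.nan
    return px, in_front


def project_point(point, intr: Intrinsics, extr: Extrinsics) -> np.ndarray:
    """Project a single world point; raises if it lies behind the camera."""
    px, ok = project_points(np.asarray(point, float).reshape(1, 3), intr, extr)
    if not ok[0]:
        raise BehindCameraError(f"point {point} has camera-frame z <= 0")
    return px[0]


def undistort_points(
    pixels: np.ndarray,
    intr: Intrinsics,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> np.ndarray:
    """Map pixels (N, 2) to ideal normalized coordinates, inverting distortion.

    Fixed-point iteration on the distortion polynomial; raises
    :class:`NumericFailureError` if any pixel fails to converge.
    """
    q = np.atleast_2d(np.asarray(pixels, dtype=float))
    yd = (q[:, 1] - intr.cy) / intr.fy
    xd = (q[:, 0] - intr.cx - intr.skew * yd) / intr.fx
    x, y = xd.copy(), yd.copy()
    for _ in range(max_iter):
        r2 = x * x + y * y
        radial = 1.0 + intr.k1 * r2 + intr.k2 * r2 * r2
        dx = 2.0 * intr.p1 * x * y + intr.p2 * (r2 + 2.0 * x * x)
        dy = intr.p1 * (r2 + 2.0 * y * y) + 2.0 * intr.p2 * x * y
        x_new = (xd - dx) / radial
        y_new = (yd - dy) / radial
        delta = np.max(np.abs(x_new - x) + np.abs(y_new - y))
        x, y = x_new, y_new
        if delta < tol:
            break
    else:
        worst = int(np.argmax(np.abs(_distort_normalized(x, y, intr)[0] - xd)))
        raise NumericFailureError(
            f"undistortion did not converge for pixel {q[worst]}"
        )
    return np.column_stack([x, y])


def undistort_point(pixel, intr: Intrinsics, **kw) -> np.ndarray:
    return undistort_points(np.asarray(pixel, float).reshape(1, 2), intr, **kw)[0]


# ---------------------------------------------------------------------------
# rig construction helpers


def look_at_extrinsics(
    camera_center, target, up=(0.0, 0.0, 1.0)
) -> Extrinsics:
    """World-to-camera pose for a camera at ``camera_center`` looking at ``target``.

    Camera convention: +z optical axis, +x right, +y down (pixel y grows
    downward), so ``up`` in the world maps near -y in the camera.
    """
    c = np.asarray(camera_center, dtype=float)
    fwd = np.asarray(target, dtype=float) - c
    n = np.linalg.norm(fwd)
    if n == 0:
        raise InvalidArgumentError("camera center coincides with target")
    fwd = fwd / n
    upv = np.asarray(up, dtype=float)
    right = np.cross(fwd, upv)
    rn = np.linalg.norm(right)
    if rn < 1e-12:
        raise InvalidArgumentError("up vector parallel to viewing direction")
    right /= rn
    down = np.cross(fwd, right)
    R = np.vstack([right, down, fwd])
    return Extrinsics(R, -R @ c)


def make_converging_rig(
    baseline_mm: float = 450.0,
    camera_height_mm: float = 1100.0,
    standoff_mm: float = 850.0,
    target=(50.0, 0.0, 250.0),
    focal_px: float = 2000.0,
    sensor=(1920, 1080),
    k1: float = -0.08,
    k2: float = 0.015,
    p1: float = 1e-4,
    p2: float = -1e-4,
) -> StereoRig:
    """Default virtual stereo rig.

    Two identical cameras ``baseline_mm`` apart at ``camera_height_mm``
    above the ground plane, offset ``standoff_mm`` horizontally from the
    scene and converging on ``target`` — the published recording layout of
    paired 1080P cameras 45 cm apart, 110 cm above ground, viewing one
    potted plant and its support pole.
    """
    w, h = sensor
    intr = Intrinsics(
        fx=focal_px,
        fy=focal_px,
        cx=w / 2.0,
        cy=h / 2.0,
        k1=k1,
        k2=k2,
        p1=p1,
        p2=p2,
        sensor_size=(w, h),
    )
    left_c = (-baseline_mm / 2.0, -standoff_mm, camera_height_mm)
    right_c = (baseline_mm / 2.0, -standoff_mm, camera_height_mm)
    return StereoRig(
        left_intrinsics=intr,
        left_extrinsics=look_at_extrinsics(left_c, target),
        right_intrinsics=replace(intr),
        right_extrinsics=look_at_extrinsics(right_c, target),
    )


# ---------------------------------------------------------------------------
# planar calibration


def _homography_dlt(obj_xy: np.ndarray, img: np.ndarray) -> np.ndarray:
    """Normalized DLT homography mapping planar board (x, y) to pixels."""

    def normalize(pts):
        mean = pts.mean(axis=0)
        scale = np.sqrt(2.0) / np.mean(np.linalg.norm(pts - mean, axis=1))
        T = np.array(
            [
                [scale, 0, -scale * mean[0]],
                [0, scale, -scale * mean[1]],
                [0, 0, 1],
            ]
        )
        return (pts - mean) * scale, T

    src, Ts = normalize(obj_xy)
    dst, Td = normalize(img)
    n = len(src)
    A = np.zeros((2 * n, 9))
    A[0::2, 0:2] = src
    A[0::2, 2] = 1.0
    A[0::2, 6:8] = -dst[:, 0:1] * src
    A[0::2, 8] = -dst[:, 0]
    A[1::2, 3:5] = src
    A[1::2, 5] = 1.0
    A[1::2, 6:8] = -dst[:, 1:2] * src
    A[1::2, 8] = -dst[:, 1]
    _, _, vt = np.linalg.svd(A)
    H = vt[-1].reshape(3, 3)
    H = np.linalg.inv(Td) @ H @ Ts
    return H / H[2, 2]


def _v_ij(H: np.ndarray, i: int, j: int) -> np.ndarray:
    return np.array(
        [
            H[0, i] * H[0, j],
            H[0, i] * H[1, j] + H[1, i] * H[0, j],
            H[1, i] * H[1, j],
            H[2, i] * H[0, j] + H[0, i] * H[2, j],
            H[2, i] * H[1, j] + H[1, i] * H[2, j],
            H[2, i] * H[2, j],
        ]
    )


def _intrinsics_from_homographies(Hs: list[np.ndarray]) -> Intrinsics:
    V = []
    for H in Hs:
        V.append(_v_ij(H, 0, 1))
        V.append(_v_ij(H, 0, 0) - _v_ij(H, 1, 1))
    V = np.array(V)
    _, s, vt = np.linalg.svd(V)
    if s[-1] > 1e-6 * s[0] and len(Hs) < 3:
        raise InvalidArgumentError("need >= 3 views for full intrinsics")
    b = vt[-1]
    B11, B12, B22, B13, B23, B33 = b
    denom = B11 * B22 - B12 * B12
    if abs(denom) < 1e-18:
        raise DegenerateGeometryError(
            "degenerate view geometry: intrinsic system is rank deficient"
        )
    cy = (B12 * B13 - B11 * B23) / denom
    lam = B33 - (B13 * B13 + cy * (B12 * B13 - B11 * B23)) / B11
    if lam / B11 <= 0:
        raise DegenerateGeometryError(
            "degenerate view geometry (non-positive focal estimate)"
        )
    fx = np.sqrt(lam / B11)
    fy = np.sqrt(lam * B11 / denom)
    skew = -B12 * fx * fx * fy / lam
    cx = skew * cy / fx - B13 * fx * fx / lam
    return Intrinsics(fx=fx, fy=fy, cx=cx, cy=cy, skew=skew)


def _pose_from_homography(H: np.ndarray, K: np.ndarray) -> Extrinsics:
    Kinv = np.linalg.inv(K)
    h1, h2, h3 = H[:, 0], H[:, 1], H[:, 2]
    lam = 1.0 / np.linalg.norm(Kinv @ h1)
    r1 = lam * (Kinv @ h1)
    r2 = lam * (Kinv @ h2)
    t = lam * (Kinv @ h3)
    r3 = np.cross(r1, r2)
    Q = np.column_stack([r1, r2, r3])
    # nearest rotation matrix
    u, _, vt = np.linalg.svd(Q)
    R = u @ vt
    if np.linalg.det(R) < 0:
        R = u @ np.diag([1, 1, -1]) @ vt
    if t[2] < 0:  # board must be in front of the camera
        R = np.column_stack([-R[:, 0], -R[:, 1], R[:, 2]])
        t = -t
    return Extrinsics(R, t)


def _pack(intr: Intrinsics, poses: list[Extrinsics]) -> np.ndarray:
    head = [
        intr.fx,
        intr.fy,
        intr.cx,
        intr.cy,
        intr.skew,
        intr.k1,
        intr.k2,
        intr.p1,
        intr.p2,
    ]
    tail = []
    for e in poses:
        tail.extend(Rotation.from_matrix(e.rotation).as_rotvec())
        tail.extend(e.translation)
    return np.array(head + tail)


def _unpack(x: np.ndarray, n_views: int):
    intr = Intrinsics(
        fx=x[0], fy=x[1], cx=x[2], cy=x[3], skew=x[4],
        k1=x[5], k2=x[6], p1=x[7], p2=x[8],
    )
    poses = []
    for i in range(n_views):
        r = x[9 + 6 * i : 12 + 6 * i]
        t = x[12 + 6 * i : 15 + 6 * i]
        poses.append(Extrinsics(Rotation.from_rotvec(r).as_matrix(), t))
    return intr, poses


def _reprojection_residuals(x, views, n_views):
    intr, poses = _unpack(x, n_views)
    res = []
    for (obj, img), pose in zip(views, poses):
        px, _ = project_points(obj, intr, pose)
        res.append((px - img).ravel())
    return np.concatenate(res)


def calibrate_single(
    views: list[tuple[np.ndarray, np.ndarray]],
) -> tuple[Intrinsics, list[Extrinsics], float]:
    """Calibrate one camera from planar-board views.

    Parameters
    ----------
    views
        List of ``(object_points, image_points)`` pairs; object points are
        (N, 3) board-frame mm with z = 0, image points (N, 2) px.

    Returns
    -------
    (intrinsics, per_view_extrinsics, rms_px)
        Refined intrinsics with distortion, the board pose in each view
        (board frame -> camera frame), and the RMS reprojection error.
    """
    if len(views) < 3:
        raise InvalidArgumentError("calibration requires >= 3 views")
    prepared = []
    for obj, img in views:
        obj = np.asarray(obj, dtype=float)
        img = np.asarray(img, dtype=float)
        if obj.shape[0] < 4 or img.shape[0] != obj.shape[0]:
            raise InvalidArgumentError("each view needs >= 4 matched points")
        if np.max(np.abs(obj[:, 2])) > 1e-9:
            raise InvalidArgumentError("planar calibration requires z = 0 board points")
        prepared.append((obj, img))

    Hs = [_homography_dlt(o[:, :2], i) for o, i in prepared]
    intr0 = _intrinsics_from_homographies(Hs)
    poses0 = [_pose_from_homography(H, intr0.matrix) for H in Hs]

    n = len(prepared)
    # stage 1: refine without distortion (more robust from the linear init)
    x0 = _pack(intr0, poses0)
    fixed_dist = slice(5, 9)

    def residual_nodist(p):
        x = x0.copy()
        mask = np.ones(len(x0), dtype=bool)
        mask[fixed_dist] = False
        x[mask] = p
        x[fixed_dist] = 0.0
        return _reprojection_residuals(x, prepared, n)

    mask = np.ones(len(x0), dtype=bool)
    mask[fixed_dist] = False
    sol1 = least_squares(residual_nodist, x0[mask], method="lm", xtol=1e-12, ftol=1e-12)
    x1 = x0.copy()
    x1[mask] = sol1.x
    x1[fixed_dist] = 0.0

    # stage 2: full refinement including (k1, k2, p1, p2)
    sol2 = least_squares(
        lambda p: _reprojection_residuals(p, prepared, n),
        x1,
        method="lm",
        xtol=1e-14,
        ftol=1e-14,
        max_nfev=200 * len(x1),
    )
    intr, poses = _unpack(sol2.x, n)
    rms = float(np.sqrt(np.mean(sol2.fun**2)))
    return intr, poses, rms


def _refine_pose(obj, img, intr: Intrinsics, pose0: Extrinsics) -> Extrinsics:
    """Pose-only refinement with known intrinsics (used per joint view)."""

    def resid(p):
        e = Extrinsics(Rotation.from_rotvec(p[:3]).as_matrix(), p[3:])
        px, _ = project_points(obj, intr, e)
        return (px - img).ravel()

    p0 = np.concatenate(
        [Rotation.from_matrix(pose0.rotation).as_rotvec(), pose0.translation]
    )
    sol = least_squares(resid, p0, method="lm", xtol=1e-14, ftol=1e-14)
    return Extrinsics(Rotation.from_rotvec(sol.x[:3]).as_matrix(), sol.x[3:])


def _quaternion_mean(rotations: list[np.ndarray]) -> np.ndarray:
    """Chordal-mean rotation: principal eigenvector of the quaternion outer-product sum."""
    A = np.zeros((4, 4))
    for R in rotations:
        q = Rotation.from_matrix(R).as_quat()
        A += np.outer(q, q)
    _, vecs = np.linalg.eigh(A)
    return Rotation.from_quat(vecs[:, -1]).as_matrix()


def calibrate_stereo(
    joint_views: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
    intr_left: Intrinsics,
    intr_right: Intrinsics,
) -> StereoRig:
    """Estimate stereo extrinsics from board views seen by both cameras.

    Parameters
    ----------
    joint_views
        List of ``(object_points, image_points_left, image_points_right)``.
    intr_left, intr_right
        Previously calibrated per-camera intrinsics (with distortion).

    The relative pose is the average over views of
    ``pose_right . pose_left^{-1}`` (quaternion mean for rotation,
    componentwise mean for translation); absolute extrinsics are anchored
    at the first joint view's board frame.
    """
    if len(joint_views) < 1:
        raise InvalidArgumentError("stereo calibration requires >= 1 joint view")
    rels_R, rels_t, posesL = [], [], []
    for obj, imgL, imgR in joint_views:
        obj = np.asarray(obj, dtype=float)
        HL = _homography_dlt(obj[:, :2], np.asarray(imgL, float))
        HR = _homography_dlt(obj[:, :2], np.asarray(imgR, float))
        poseL = _refine_pose(obj, imgL, intr_left, _pose_from_homography(HL, intr_left.matrix))
        poseR = _refine_pose(obj, imgR, intr_right, _pose_from_homography(HR, intr_right.matrix))
        rel = poseR.compose_with_inverse(poseL)
        rels_R.append(rel.rotation)
        rels_t.append(rel.translation)
        posesL.append(poseL)
    R_rel = _quaternion_mean(rels_R) if len(rels_R) > 1 else rels_R[0]
    t_rel = np.mean(rels_t, axis=0)
    rel = Extrinsics(R_rel, t_rel)
    left = posesL[0]
    right = Extrinsics(rel.rotation @ left.rotation, rel.rotation @ left.translation + rel.translation)
    return StereoRig(
        left_intrinsics=intr_left,
        left_extrinsics=left,
        right_intrinsics=intr_right,
        right_extrinsics=right,
        relative=rel,
    )
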