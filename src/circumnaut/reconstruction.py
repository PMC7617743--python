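"""Two-view triangulation of paired 2D trajectories into 3D.

Each stereo frame pair is undistorted to ideal normalized coordinates and
triangulated by the homogeneous direct linear transform (DLT): the
smallest right singular vector of the stacked two-view linear system.
Frames missing in either view are propagated as missing; no temporal
interpolation happens here (gap handling belongs to the kinematics
stage).  A per-frame quality report (reprojection residuals, ray skew
distance) accompanies every reconstructed trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .camera import StereoRig, project_points, undistort_point
from .errors import DegenerateGeometryError, InvalidArgumentError
from .trajectory import Trajectory2D, Trajectory3D

__all__ = [
    "TriangulationResult",
    "TriangulationReport",
    "triangulate_point",
    "triangulate_midpoint",
    "reconstruct_trajectory",
]


@dataclass(frozen=True)
class TriangulationResult:
    point_mm: np.ndarray
    reprojection_error_left_px: float
    reprojection_error_right_px: float
    ray_skew_mm: float
    in_front: bool  # positive depth in both cameras


@dataclass
class TriangulationReport:
    """Per-frame QC of a reconstructed trajectory."""

    reprojection_error_left_px: np.ndarray
    reprojection_error_right_px: np.ndarray
    ray_skew_mm: np.ndarray
    fraction_reconstructed: float

    def to_dict(self) -> dict:
        def clean(a):
            return [None if np.isnan(x) else float(x) for x in a]

        return {
            "reprojection_error_left_px": clean(self.reprojection_error_left_px),
            "reprojection_error_right_px": clean(self.reprojection_error_right_px),
            "ray_skew_mm": clean(self.ray_skew_mm),
            "fraction_reconstructed": self.fraction_reconstructed,
            "median_reprojection_error_px": float(
                np.nanmedian(
                    np.concatenate(
                        [
                            self.reprojection_error_left_px,
                            self.reprojection_error_right_px,
                        ]
                    )
                )
            )
            if np.any(~np.isnan(self.reprojection_error_left_px))
            else None,
        }


def _camera_geometry(rig: StereoRig):
    if rig.baseline_mm <= 1e-9:
        raise DegenerateGeometryError("stereo baseline is zero")
    return (
        (rig.left_intrinsics, rig.left_extrinsics),
        (rig.right_intrinsics, rig.right_extrinsics),
    )


def _dlt_solve(xyL, xyR, extrL, extrR) -> np.ndarray:
    PL = np.hstack([extrL.rotation, extrL.translation[:, None]])
    PR = np.hstack([extrR.rotation, extrR.translation[:, None]])
    A = np.vstack(
        [
            xyL[0] * PL[2] - PL[0],
            xyL[1] * PL[2] - PL[1],
            xyR[0] * PR[2] - PR[0],
            xyR[1] * PR[2] - PR[1],
        ]
    )
    _, _, vt = np.linalg.svd(A)
    Xh = vt[-1]
    if abs(Xh[3]) < 1e-15:
        raise DegenerateGeometryError("triangulated point at infinity")
    return Xh[:3] / Xh[3]


def dlt_algebraic_residual(point_mm, qL, qR, rig: StereoRig) -> float:
    """Norm of the DLT system applied to a candidate point (for QC/tests)."""
    (intrL, extrL), (intrR, extrR) = _camera_geometry(rig)
    xyL = undistort_point(qL, intrL)
    xyR = undistort_point(qR, intrR)
    PL = np.hstack([extrL.rotation, extrL.translation[:, None]])
    PR = np.hstack([extrR.rotation, extrR.translation[:, None]])
    A = np.vstack(
        [
            xyL[0] * PL[2] - PL[0],
            xyL[1] * PL[2] - PL[1],
            xyR[0] * PR[2] - PR[0],
            xyR[1] * PR[2] - PR[1],
        ]
    )
    X = np.append(np.asarray(point_mm, float), 1.0)
    return float(np.linalg.norm(A @ X))


def triangulate_point(qL, qR, rig: StereoRig) -> TriangulationResult:
    """Triangulate one stereo pixel pair into a world point (mm).

    Pixels are undistorted first; the world point is the homogeneous
    least-squares (DLT) solution of the two-view system.  Reprojection
    residuals in both images and the skew distance between the two
    viewing rays are returned for quality control; a point with
    non-positive depth in either camera is flagged (``in_front=False``)
    rather than silently returned as valid.
    """
    (intrL, extrL), (intrR, extrR) = _camera_geometry(rig)
    xyL = undistort_point(qL, intrL)
    xyR = undistort_point(qR, intrR)
    X = _dlt_solve(xyL, xyR, extrL, extrR)

    zL = (extrL.rotation @ X + extrL.translation)[2]
    zR = (extrR.rotation @ X + extrR.translation)[2]
    in_front = bool(zL > 0 and zR > 0)

    if in_front:
        pL, _ = project_points(X[None, :], intrL, extrL)
        pR, _ = project_points(X[None, :], intrR, extrR)
        errL = float(np.linalg.norm(pL[0] - np.asarray(qL, float)))
        errR = float(np.linalg.norm(pR[0] - np.asarray(qR, float)))
    else:
        errL = errR = float("nan")

    skew = _ray_skew_mm(xyL, xyR, extrL, extrR)
    return TriangulationResult(X, errL, errR, skew, in_front)


def _ray_skew_mm(xyL, xyR, extrL, extrR) -> float:
    cL, cR = extrL.camera_center, extrR.camera_center
    dL = extrL.rotation.T @ np.array([xyL[0], xyL[1], 1.0])
    dR = extrR.rotation.T @ np.array([xyR[0], xyR[1], 1.0])
    n = np.cross(dL, dR)
    nn = np.linalg.norm(n)
    if nn < 1e-15:  # parallel rays
        return float(
            np.linalg.norm(np.cross(cR - cL, dL)) / np.linalg.norm(dL)
        )
    return float(abs(np.dot(cR - cL, n)) / nn)


def triangulate_midpoint(qL, qR, rig: StereoRig) -> np.ndarray:
    """Midpoint-of-common-perpendicular triangulation (independent cross-check)."""
    (intrL, extrL), (intrR, extrR) = _camera_geometry(rig)
    xyL = undistort_point(qL, intrL)
    xyR = undistort_point(qR, intrR)
    cL, cR = extrL.camera_center, extrR.camera_center
    dL = extrL.rotation.T @ np.array([xyL[0], xyL[1], 1.0])
    dR = extrR.rotation.T @ np.array([xyR[0], xyR[1], 1.0])
    # solve [dL, -dR] [s, t]^T ~ cR - cL in least squares
    A = np.column_stack([dL, -dR])
    st, *_ = np.linalg.lstsq(A, cR - cL, rcond=None)
    p1 = cL + st[0] * dL
    p2 = cR + st[1] * dR
    return 0.5 * (p1 + p2)


def reconstruct_trajectory(
    trajL: Trajectory2D, trajR: Trajectory2D, rig: StereoRig
) -> tuple[Trajectory3D, TriangulationReport]:
    """Triangulate paired 2D trajectories frame by frame.

    Frames usable in both views are triangulated; frames lost in either
    view (or reconstructed behind a camera) come out ``missing``.
    """
    if len(trajL) != len(trajR) or not np.allclose(trajL.times, trajR.times):
        raise InvalidArgumentError("left/right trajectories have mismatched time bases")
    n = len(trajL)
    pts = np.full((n, 3), np.nan)
    status = np.array(["missing"] * n, dtype=object)
    errL = np.full(n, np.nan)
    errR = np.full(n, np.nan)
    skew = np.full(n, np.nan)
    both_ok = trajL.ok & trajR.ok
    for i in np.flatnonzero(both_ok):
        res = triangulate_point(trajL.points[i], trajR.points[i], rig)
        skew[i] = res.ray_skew_mm
        if not res.in_front:
            continue
        pts[i] = res.point_mm
        status[i] = "valid"
        errL[i] = res.reprojection_error_left_px
        errR[i] = res.reprojection_error_right_px
    report = TriangulationReport(
        reprojection_error_left_px=errL,
        reprojection_error_right_px=errR,
        ray_skew_mm=skew,
        fraction_reconstructed=float(np.mean(status == "valid")),
    )
    traj3d = Trajectory3D(
        times=trajL.times.copy(), points=pts, status=status,
        metadata={"source": "stereo triangulation (DLT)"},
    )
    return traj3d, report
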