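"""Pyramidal Kanade–Lucas–Tomasi point tracking.

A single marker is followed frame to frame by iterative Lucas–Kanade
registration of a square intensity patch, run coarse-to-fine on a
Gaussian image pyramid with bilinear sub-pixel sampling.  A frame is
declared lost when the iteration fails to converge, the patch leaves the
image, the local texture (minimum eigenvalue of the spatial gradient
matrix) falls below threshold, or a forward-backward consistency check
exceeds tolerance.  Lost status is sticky until a manual correction
(supplied as a table of frame/pixel rows) re-seeds the tracker.

Images are converted internally to float in [0, 1]; because the
Lucas–Kanade normal equations scale identically in the gradient matrix
and the mismatch vector, the estimated displacement is invariant to a
constant intensity gain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .errors import InvalidArgumentError, UntrackableStartError
from .trajectory import Trajectory2D

__all__ = ["TrackerConfig", "track_point", "apply_corrections"]


@dataclass(frozen=True)
class TrackerConfig:
    """Numeric settings of the tracker (standard KLT practice)."""

    window: int = 10  # patch half-size, px
    pyramid_levels: int = 3
    max_iters: int = 30  # per pyramid level
    convergence_eps: float = 0.01  # px
    min_texture: float = 1e-4  # min eigenvalue of gradient matrix / pixel
    forward_backward_tol: float = 1.0  # px

    def __post_init__(self) -> None:
        if self.window < 2:
            raise InvalidArgumentError("window half-size must be >= 2 px")
        if self.pyramid_levels < 1:
            raise InvalidArgumentError("pyramid_levels must be >= 1")
        if min(self.max_iters, self.convergence_eps, self.min_texture,
               self.forward_backward_tol) <= 0:
            raise InvalidArgumentError("tracker thresholds must be positive")


def _as_float_stack(images) -> np.ndarray:
    stack = np.asarray(images)
    if stack.ndim != 3:
        raise InvalidArgumentError("images must be a (n, h, w) grayscale stack")
    if stack.dtype == np.uint8:
        return stack.astype(float) / 255.0
    return stack.astype(float)


def _pyramid(img: np.ndarray, levels: int) -> list[np.ndarray]:
    pyr = [img]
    for _ in range(1, levels):
        smoothed = gaussian_filter(pyr[-1], sigma=1.0, mode="nearest")
        pyr.append(smoothed[::2, ::2])
    return pyr


def _patch_coords(center: np.ndarray, half: int) -> np.ndarray:
    offs = np.arange(-half, half + 1, dtype=float)
    du, dv = np.meshgrid(offs, offs)
    # rows (v) first for map_coordinates
    return np.stack([center[1] + dv.ravel(), center[0] + du.ravel()])


def _inside(center: np.ndarray, half: int, shape: tuple[int, int]) -> bool:
    h, w = shape
    return (
        center[0] - half >= 1
        and center[0] + half <= w - 2
        and center[1] - half >= 1
        and center[1] + half <= h - 2
    )


def _sample(img: np.ndarray, coords: np.ndarray) -> np.ndarray:
    return map_coordinates(img, coords, order=1, mode="nearest")


class _FramePyramid:
    """Per-frame cache of the pyramid and its spatial gradients."""

    def __init__(self, img: np.ndarray, levels: int):
        self.levels = _pyramid(img, levels)
        self.grad_x = [np.gradient(L, axis=1) for L in self.levels]
        self.grad_y = [np.gradient(L, axis=0) for L in self.levels]


def _min_eig_per_pixel(gx: np.ndarray, gy: np.ndarray) -> float:
    n = gx.size
    a = float(np.sum(gx * gx)) / n
    b = float(np.sum(gx * gy)) / n
    c = float(np.sum(gy * gy)) / n
    return 0.5 * (a + c - np.hypot(a - c, 2.0 * b))


def _lk_pair(
    prev: _FramePyramid,
    nxt: _FramePyramid,
    pos: np.ndarray,
    cfg: TrackerConfig,
    d0: np.ndarray | None = None,
) -> tuple[np.ndarray | None, str]:
    """Track one point from ``prev`` to ``nxt``; returns (new_pos, reason).

    ``d0`` is an optional displacement prediction (finest-level px), e.g.
    the previous frame's displacement, used to seed the coarsest level.
    """
    half = cfg.window
    n_levels = len(prev.levels)
    d = np.zeros(2) if d0 is None else np.asarray(d0, dtype=float) / 2.0 ** (n_levels - 1)
    for lev in range(n_levels - 1, -1, -1):
        scale = 2.0**lev
        p = pos / scale
        shape = prev.levels[lev].shape
        if not _inside(p, half, shape):
            if lev > 0:  # window does not fit at this coarse level; skip it
                d = d * 2.0
                continue
            return None, "exited"
        coords0 = _patch_coords(p, half)
        patch0 = _sample(prev.levels[lev], coords0)
        gx = _sample(prev.grad_x[lev], coords0)
        gy = _sample(prev.grad_y[lev], coords0)
        # texture is judged at the finest level only: pyramid smoothing
        # dilutes gradient energy at coarse levels even for a good target
        if lev == 0 and _min_eig_per_pixel(gx, gy) < cfg.min_texture:
            return None, "textureless"
        G = np.array(
            [
                [np.sum(gx * gx), np.sum(gx * gy)],
                [np.sum(gx * gy), np.sum(gy * gy)],
            ]
        )
        converged = False
        for _ in range(cfg.max_iters):
            q = p + d
            if not _inside(q, half, nxt.levels[lev].shape):
                if lev > 0:
                    break
                return None, "exited"
            patch1 = _sample(nxt.levels[lev], _patch_coords(q, half))
            err = patch0 - patch1
            b = np.array([np.sum(gx * err), np.sum(gy * err)])
            try:
                step = np.linalg.solve(G, b)
            except np.linalg.LinAlgError:
                if lev > 0:
                    break
                return None, "textureless"
            d = d + step
            if np.linalg.norm(step) < cfg.convergence_eps:
                converged = True
                break
        if lev == 0 and not converged:
            return None, "diverged"
        if lev > 0:
            d = d * 2.0
    new_pos = pos + d
    return new_pos, "ok"


def _track_forward(
    pyramids: list[_FramePyramid],
    start_frame: int,
    start_pos: np.ndarray,
    cfg: TrackerConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Track from ``start_pos`` at ``start_frame`` to the last frame.

    Returns points and status for frames ``start_frame+1 .. n-1``.
    """
    n = len(pyramids)
    m = n - start_frame - 1
    points = np.full((m, 2), np.nan)
    status = np.array(["lost"] * m, dtype=object)
    pos = np.asarray(start_pos, dtype=float)
    last_disp: np.ndarray | None = None  # constant-velocity prediction
    for k, i in enumerate(range(start_frame, n - 1)):
        new_pos, reason = _lk_pair(pyramids[i], pyramids[i + 1], pos, cfg, d0=last_disp)
        if new_pos is None:
            break
        back_pos, back_reason = _lk_pair(
            pyramids[i + 1], pyramids[i], new_pos, cfg, d0=pos - new_pos
        )
        if (
            back_pos is None
            or np.linalg.norm(back_pos - pos) > cfg.forward_backward_tol
        ):
            break
        points[k] = new_pos
        status[k] = "tracked"
        last_disp = new_pos - pos
        pos = new_pos
    return points, status


def track_point(
    images,
    start,
    cfg: TrackerConfig | None = None,
    times: np.ndarray | None = None,
    frame_interval: float = 3.0,
) -> Trajectory2D:
    """Track a single marker through a grayscale image stack.

    Parameters
    ----------
    images
        (n, h, w) stack, uint8 or float.
    start
        Sub-pixel (u, v) position of the marker in frame 0.
    cfg
        Tracker settings; defaults to :class:`TrackerConfig`.
    times
        Frame times in minutes; defaults to a uniform grid at
        ``frame_interval``.
    """
    cfg = cfg or TrackerConfig()
    stack = _as_float_stack(images)
    n, h, w = stack.shape
    pos0 = np.asarray(start, dtype=float)
    if not (0 <= pos0[0] <= w - 1 and 0 <= pos0[1] <= h - 1):
        raise InvalidArgumentError(f"start {tuple(pos0)} outside the image")
    if times is None:
        times = np.arange(n) * frame_interval
    pyramids = [_FramePyramid(f, cfg.pyramid_levels) for f in stack]

    if not _inside(pos0, cfg.window, (h, w)):
        raise UntrackableStartError("start window extends outside frame 0")
    coords = _patch_coords(pos0, cfg.window)
    gx = _sample(pyramids[0].grad_x[0], coords)
    gy = _sample(pyramids[0].grad_y[0], coords)
    if _min_eig_per_pixel(gx, gy) < cfg.min_texture:
        raise UntrackableStartError(
            "start point lies in a textureless region "
            f"(min eigenvalue {_min_eig_per_pixel(gx, gy):.2e} < {cfg.min_texture})"
        )

    points = np.full((n, 2), np.nan)
    status = np.array(["lost"] * n, dtype=object)
    points[0] = pos0
    status[0] = "tracked"
    pts, st = _track_forward(pyramids, 0, pos0, cfg)
    points[1:] = pts
    status[1:] = st
    traj = Trajectory2D(times=np.asarray(times, float), points=points, status=status)
    traj._pyramids = pyramids  # cache for apply_corrections re-tracking
    traj._tracker_cfg = cfg
    return traj


def apply_corrections(
    traj: Trajectory2D,
    corrections,
    images=None,
    cfg: TrackerConfig | None = None,
) -> Trajectory2D:
    """Apply manual corrections and resume tracking from each corrected frame.

    ``corrections`` is an iterable of ``(frame, u_px, v_px)`` rows (or an
    object with ``frame``, ``u_px``, ``v_px`` columns).  Each corrected
    frame takes the supplied coordinates with status ``corrected``; when
    image data is available (passed explicitly, or cached on a trajectory
    produced by :func:`track_point`), tracking resumes automatically from
    each corrected frame up to the next correction.
    """
    rows = _correction_rows(corrections)
    n = len(traj)
    bad = [r for r in rows if not (0 <= r[0] < n)]
    if bad:
        raise InvalidArgumentError(f"correction frames out of range: {bad}")

    points = traj.points.copy()
    status = traj.status.copy()
    if not rows:
        return Trajectory2D(times=traj.times.copy(), points=points, status=status)

    cfg = cfg or getattr(traj, "_tracker_cfg", None) or TrackerConfig()
    pyramids = getattr(traj, "_pyramids", None)
    if images is not None:
        pyramids = [_FramePyramid(f, cfg.pyramid_levels) for f in _as_float_stack(images)]

    rows = sorted(rows, key=lambda r: r[0])
    frames = [r[0] for r in rows]
    for idx, (f, u, v) in enumerate(rows):
        points[f] = (u, v)
        status[f] = "corrected"
        if pyramids is None:
            continue
        stop = frames[idx + 1] if idx + 1 < len(rows) else n
        pts, st = _track_forward(pyramids, f, np.array([u, v], float), cfg)
        span = min(stop, n) - (f + 1)
        points[f + 1 : f + 1 + span] = pts[:span]
        status[f + 1 : f + 1 + span] = st[:span]
    return Trajectory2D(times=traj.times.copy(), points=points, status=status)


def _correction_rows(corrections) -> list[tuple[int, float, float]]:
    if corrections is None:
        return []
    if hasattr(corrections, "itertuples"):  # DataFrame
        return [
            (int(r.frame), float(r.u_px), float(r.v_px))
            for r in corrections.itertuples()
        ]
    return [(int(f), float(u), float(v)) for f, u, v in corrections]
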