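"""Time-stamped point sequences: the data that flows between pipeline stages.

A :class:`Trajectory2D` holds sub-pixel image positions with a per-frame
tracking status (``tracked`` / ``lost`` / ``corrected``); a
:class:`Trajectory3D` holds world positions in mm with status ``valid`` /
``missing``.  Times are minutes on a uniform grid (one stereo frame every
``frame_interval`` minutes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError

STATUS_2D = ("tracked", "lost", "corrected")
STATUS_3D = ("valid", "missing")

OK_2D = frozenset({"tracked", "corrected"})


def _check_times(times: np.ndarray) -> None:
    if times.ndim != 1 or len(times) < 1:
        raise InvalidArgumentError("times must be a non-empty 1D array")
    if len(times) > 1 and np.any(np.diff(times) <= 0):
        raise InvalidArgumentError("times must be strictly increasing")


@dataclass
class Trajectory2D:
    times: np.ndarray  # minutes
    points: np.ndarray  # (n, 2) px
    status: np.ndarray  # str per frame

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.points = np.asarray(self.points, dtype=float)
        self.status = np.asarray(self.status, dtype=object)
        _check_times(self.times)
        n = len(self.times)
        if self.points.shape != (n, 2) or len(self.status) != n:
            raise InvalidArgumentError("times/points/status length mismatch")
        bad = set(self.status) - set(STATUS_2D)
        if bad:
            raise InvalidArgumentError(f"unknown 2D status values: {bad}")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def ok(self) -> np.ndarray:
        """Boolean mask of frames with a usable position."""
        return np.array([s in OK_2D for s in self.status], dtype=bool)


@dataclass
class Trajectory3D:
    times: np.ndarray  # minutes
    points: np.ndarray  # (n, 3) mm
    status: np.ndarray  # str per frame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.points = np.asarray(self.points, dtype=float)
        self.status = np.asarray(self.status, dtype=object)
        _check_times(self.times)
        n = len(self.times)
        if self.points.shape != (n, 3) or len(self.status) != n:
            raise InvalidArgumentError("times/points/status length mismatch")
        bad = set(self.status) - set(STATUS_3D)
        if bad:
            raise InvalidArgumentError(f"unknown 3D status values: {bad}")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def valid(self) -> np.ndarray:
        return np.array([s == "valid" for s in self.status], dtype=bool)

    @property
    def frame_interval(self) -> float:
        if len(self.times) < 2:
            raise InvalidArgumentError("need >= 2 frames for a frame interval")
        steps = np.diff(self.times)
        if np.max(steps) - np.min(steps) > 1e-6 * np.mean(steps):
            raise InvalidArgumentError("non-uniform time base")
        return float(np.mean(steps))
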