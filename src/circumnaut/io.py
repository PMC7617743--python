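"""Readers and writers for the pipeline's on-disk artifacts.

Trajectories travel as CSV (one row per frame), camera rigs as JSON with
explicit field names and units, scenes and genotype presets as YAML, and
image stacks as zero-padded numbered PNG files in one directory per
camera.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .camera import StereoRig
from .errors import InvalidArgumentError
from .synthetic import CircumnutationParams, SceneSpec
from .trajectory import Trajectory2D, Trajectory3D

__all__ = [
    "write_trajectory3d",
    "read_trajectory3d",
    "write_trajectory2d",
    "read_trajectory2d",
    "write_rig",
    "read_rig",
    "write_scene",
    "read_scene",
    "read_params",
    "write_image_stack",
    "read_image_stack",
    "read_corrections",
]


def write_trajectory3d(traj: Trajectory3D, path) -> None:
    df = pd.DataFrame(
        {
            "frame": np.arange(len(traj)),
            "t_min": traj.times,
            "x": traj.points[:, 0],
            "y": traj.points[:, 1],
            "z": traj.points[:, 2],
            "status": traj.status,
        }
    )
    df.to_csv(path, index=False)


def read_trajectory3d(path) -> Trajectory3D:
    df = pd.read_csv(path)
    required = {"frame", "t_min", "x", "y", "z", "status"}
    if not required.issubset(df.columns):
        raise InvalidArgumentError(f"3D trajectory CSV must have columns {sorted(required)}")
    return Trajectory3D(
        times=df["t_min"].to_numpy(float),
        points=df[["x", "y", "z"]].to_numpy(float),
        status=df["status"].to_numpy(object),
    )


def write_trajectory2d(traj: Trajectory2D, path) -> None:
    df = pd.DataFrame(
        {
            "frame": np.arange(len(traj)),
            "t_min": traj.times,
            "u_px": traj.points[:, 0],
            "v_px": traj.points[:, 1],
            "status": traj.status,
        }
    )
    df.to_csv(path, index=False)


def read_trajectory2d(path) -> Trajectory2D:
    df = pd.read_csv(path)
    required = {"frame", "t_min", "u_px", "v_px", "status"}
    if not required.issubset(df.columns):
        raise InvalidArgumentError(f"2D trajectory CSV must have columns {sorted(required)}")
    return Trajectory2D(
        times=df["t_min"].to_numpy(float),
        points=df[["u_px", "v_px"]].to_numpy(float),
        status=df["status"].to_numpy(object),
    )


def write_rig(rig: StereoRig, path) -> None:
    Path(path).write_text(json.dumps(rig.to_dict(), indent=2))


def read_rig(path) -> StereoRig:
    return StereoRig.from_dict(json.loads(Path(path).read_text()))


def write_scene(scene: SceneSpec, path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(scene)))


def _coerce_tuples(d: dict) -> dict:
    return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}


def read_scene(path) -> SceneSpec:
    data = yaml.safe_load(Path(path).read_text())
    return SceneSpec(**_coerce_tuples(data))


def read_params(path) -> CircumnutationParams:
    """Load circumnutation parameters from a YAML mapping."""
    data = yaml.safe_load(Path(path).read_text())
    return CircumnutationParams(**data)


def write_image_stack(stack: np.ndarray, directory) -> list[Path]:
    """Write a (n, h, w) uint8 stack as zero-padded numbered PNGs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    width = max(4, len(str(len(stack) - 1)))
    paths = []
    for i, frame in enumerate(stack):
        p = directory / f"frame_{i:0{width}d}.png"
        iio.imwrite(p, np.asarray(frame, dtype=np.uint8))
        paths.append(p)
    return paths


def read_image_stack(directory) -> np.ndarray:
    files = sorted(Path(directory).glob("*.png"))
    if not files:
        raise InvalidArgumentError(f"no PNG frames found in {directory}")
    return np.stack([iio.imread(f) for f in files])


def read_corrections(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"frame", "u_px", "v_px"}
    if not required.issubset(df.columns):
        raise InvalidArgumentError(f"corrections CSV must have columns {sorted(required)}")
    return df
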