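"""Render a moving marker as a Gaussian blob and re-track it with KLT.

A wild-type circumnutation is projected into the left camera, rendered as
an 8-bit image sequence (bright blob on a dark background, emulating a
high-contrast marker), and tracked frame by frame. The printed RMS error
compares tracked to true sub-pixel positions.
"""

import dataclasses

import numpy as np

from circumnaut import SceneSpec, make_converging_rig, track_point
from circumnaut.synthetic import (
    genotype_preset,
    project_stereo,
    render_marker_sequence,
    simulate_tip_trajectory,
)
from circumnaut.trajectory import Trajectory2D

scene = SceneSpec()
rig = make_converging_rig()
params = dataclasses.replace(genotype_preset("wild_type", 160.0).params, noise_sd=0.0)
truth3d = simulate_tip_trajectory(params, scene, 160.0, seed=0)
left, _ = project_stereo(truth3d, rig)

# crop the sensor region around the trajectory so frames stay small
lo = np.floor(left.points.min(axis=0)) - 104
shifted = Trajectory2D(left.times, left.points - lo, left.status)
size = np.ceil(shifted.points.max(axis=0)) + 104
stack, _ = render_marker_sequence(shifted, (int(size[0]), int(size[1])), blob_sigma=2.0)

tracked = track_point(stack, tuple(shifted.points[0]))
err = np.linalg.norm(tracked.points - shifted.points, axis=1)

print(f"frames: {len(tracked)}, image size: {stack.shape[2]}x{stack.shape[1]} px")
print(f"all frames tracked: {all(s == 'tracked' for s in tracked.status)}")
print(f"RMS tracking error: {np.sqrt(np.nanmean(err**2)):.4f} px")
print(f"max tracking error: {np.nanmax(err):.4f} px")
print("\nSub-0.02 px errors mean tracking noise is negligible against the")
print("pixel scale of the scene (~0.6 mm per px at the plant).")
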