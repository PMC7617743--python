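# circumnaut

3D kinematic analysis of plant circumnutation — the rotatory growth
movement climbing plants such as the garden pea (*Pisum sativum*) use to
find and grasp a support. The package implements the full measurement
chain used in stereo time-lapse studies of tendril behavior:

1. **camera** — pinhole + Brown–Conrady distortion model, planar
   (chessboard) single-camera calibration, and stereo extrinsic
   calibration;
2. **tracking** — pyramidal Kanade–Lucas–Tomasi (KLT) sub-pixel point
   tracking with forward–backward validation and a file-based manual
   correction hook;
3. **reconstruction** — two-view DLT triangulation of paired pixel
   trajectories into millimetre 3D trajectories, with per-frame QC;
4. **kinematics** — movement-epoch segmentation (grasped / fell /
   stopped) and the six dependent measures: duration of circumnutation
   (min), mean velocity amplitude (mm/min), maximum acceleration
   amplitude (mm/min²), the gravity center of the circumnutation and its
   distances to the plant origin (3D, mm) and to the support axis
   (horizontal, mm), plus the number and direction of rotation cycles;
5. **stats** — Shapiro–Wilk screen, robust descriptives, Kruskal–Wallis
   omnibus per measure with tie correction,

   `H = [12/(N(N+1)) · Σ R_g²/n_g − 3(N+1)] / [1 − Σ(t³−t)/(N³−N)]`,

   referred to χ²(k−1), with Dunn–Holm (default) or Tukey-on-ranks post
   hocs;
6. **synthetic** — a scene generator that produces ground-truth
   circumnutation trajectories with genotype-dependent parameters
   (a goal-directed wild type and two slower, undirected mutant-like
   presets, *rms1-1* and *rms3-1*), projects them through a virtual
   calibrated stereo rig, and renders marker image sequences and
   chessboard calibration views — so every stage is testable against
   known truth with no recorded data.

It is a library first (`import circumnaut`), with narrative scripts in
`examples/` and a thin `circumnaut` CLI for shell use.

## Worked example

`python examples/full_experiment.py` simulates the default experiment —
8 plants per genotype, support pole 100 mm from the plant, one stereo
frame every 3 minutes — measures every plant through the stereo pipeline
and compares genotypes:

```
outcomes per genotype:
genotype   outcome
rms1_1     fell       8
rms3_1     fell       8
wild_type  grasped    8

per-plant medians:
           duration_min  mean_vel_mm_min  max_acc_mm_min2  dist_origin_mm  dist_support_mm
genotype
rms1_1            447.0             1.18             0.12           16.09           101.51
rms3_1            447.0             1.52             0.13           21.12           100.94
wild_type         159.0             2.21             0.21           50.43            51.00

group tests (per-cycle observations):
duration_min: H(2) = 43.825, p = 3.045e-10 (n = [16, 24, 9])
mean_vel_mm_min: H(2) = 40.408, p = 1.681e-09 (n = [16, 24, 9])
...
```

Reading: only the wild type reaches and grasps the pole, and it does so
with a shorter movement, higher speed and acceleration, a gravity center
farther from its origin and closer to the support than either mutant —
with the Kruskal–Wallis tests detecting every contrast. The other
examples demonstrate single capabilities: `calibrate_stereo_rig.py`
recovers the focal length to 0.2% and the 450 mm baseline to 0.12% from
20 noisy chessboard views; `track_rendered_marker.py` tracks a rendered
marker with 0.009 px RMS error; `reconstruct_and_measure.py` shows the
stereo noise budget (median 0.47 mm at 0.2 px pixel noise).

## Command line

```sh
circumnaut simulate --genotype wild_type --duration 600 --seed 1 --out sim/
circumnaut reconstruct --left sim/left_2d.csv --right sim/right_2d.csv \
    --rig sim/rig.json --out traj3d.csv
circumnaut kinematics --traj traj3d.csv --scene sim/scene.yaml --out summary.csv
circumnaut run --plants 8 --seed 1 --out experiment/
```

Trajectories travel as CSV (`frame,t_min,x,y,z,status`), rigs as JSON,
scenes as YAML, image stacks as numbered PNGs; see `circumnaut.io`.

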