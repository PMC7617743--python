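# Methods

## Scope and coordinate conventions

The package measures the circumnutation of a single tracked landmark (the
tendril tip) of one plant per recording. World coordinates are
right-handed, z-up, in millimetres; time is in minutes; pixel coordinates
have their origin at the top-left of the sensor, x right, y down. The
scene contract (`SceneSpec`) holds the plant origin at soil level, an
internode reference point, the vertical support-pole axis (base point,
radius 2.5 mm, 540 mm above ground, 100 mm from the plant), and the frame
interval (3 min, i.e. 1/180 s ≈ 0.0056 Hz).

## Synthetic movement model

The generator is a test surface, not a biomechanical model: it is the
simplest kinematic process exhibiting every phenomenon the measures
quantify. The tip is

    tip(t) = stem_center(t) + ellipse(t) + noise,

with `ellipse(t) = (a_x cos θ, a_y sin θ, 0)`,
`θ = phase + sign · 2π · speed_scale · t / period`. The stem center
starts at the plant origin, elongates vertically at
`growth_rate · speed_scale`, and — when `drift_gain > 0` — closes its
horizontal gap to the support axis at first-order rate `drift_gain`,
saturating when the gap equals the rotation envelope
`max(a_x, a_y)` (the tip cannot pass through the pole, so the rotation
center cannot come closer than one amplitude). With the gap pinned at the
amplitude, the tip's distance to the pole surface reaches zero once per
cycle when the rotation phase points at the pole; contact therefore
occurs within a few cycles of the envelope reaching the pole, which is
what ends a wild-type recording. After `fall_time`, height decreases
monotonically at `fall_speed`, clamped at soil level; rotation continues,
which is unphysical after a collapse but irrelevant because segmentation
ends the epoch once the fall is detected.

Positional jitter is isotropic Gaussian (`noise_sd`, default 0.2 mm,
matching the ~0.5 mm 3D uncertainty the stereo pipeline itself
contributes at 0.2 px pixel noise). All randomness is a pure function of
the seed.

### Genotype presets

| preset     | speed_scale | drift_gain (1/min) | fall onset      |
|------------|------------:|-------------------:|-----------------|
| wild_type  | 1.0         | 0.02               | never           |
| rms1_1     | 0.5         | 0                  | 70% of duration |
| rms3_1     | 0.65        | 0                  | 70% of duration |

Shared defaults: semi-axes 30 mm, period 80 min, growth 0.15 mm/min,
fall descent 0.8 mm/min. No quantitative amplitudes or periods are
published for these genotypes; the presets are stand-ins chosen once so
that the three groups reproduce the qualitative ordering of the study
contrast (wild type faster, shorter, goal-directed, grasping; mutants
slower, undirected, falling) — not any published values. Two constraints
fixed the two non-obvious numbers: the growth rate must put the plant
more than one fall-drop threshold (20 mm) above the soil by collapse
onset, or a fall is undetectable; and the fall descent rate must be slow
enough that the collapse's acceleration transient (~`fall_speed/(2Δt)`)
stays below the wild type's centripetal acceleration `(2π/T)²·a ≈ 0.185
mm/min²`, or the acceleration ordering would invert.

### What the generator does and does not emulate

Emulated: three genotype groups with group-level differences in all six
measures; a 3-minute frame interval; mm units; grasp/fall/stop endings;
camera geometry of two converging 1080P cameras 450 mm apart, 1100 mm
above ground; chessboard calibration (10×7 board, 18 mm squares, 20
views); high-contrast marker appearance (Gaussian blob on dark
background).

Not emulated: tendril coiling after contact; stem/leaf posture; occlusion
and appearance change of real markers; lighting drift; non-elliptical or
irregular nutation shapes; within-plant parameter drift. Passing tests
therefore validate the *measurement chain* — geometry, tracking,
differentiation, statistics — on motions of realistic scale and shape,
not the biology of any real recording.

## Camera model and calibration

Projection: rigid transform, perspective division, radial distortion
`(1 + k1 r² + k2 r⁴)` plus tangential `(p1, p2)`, then intrinsics
`(fx, fy, cx, cy, skew)`. Undistortion inverts the polynomial by
fixed-point iteration (cap 50, tolerance 1e-10, error on
non-convergence); round trips close to better than 1e-8 normalized units
across the sensor.

Single-camera calibration is the standard planar-target method:
normalized-DLT homographies per view, closed-form intrinsics from the
absolute-conic constraints, pose extraction, then joint nonlinear least
squares (Levenberg–Marquardt, `scipy.optimize.least_squares`) over
intrinsics + distortion + all poses, staged as (i) no distortion,
(ii) full model, which is robust from the distortion-free linear
initialization. The reported RMS is the refit residual. The distortion
order (k1, k2, p1, p2) is a fixed design choice.

Stereo calibration estimates each camera's board pose per joint view
(pose-only LM with known intrinsics) and averages the per-view relative
poses: chordal quaternion mean for rotation, componentwise mean for
translation. Absolute extrinsics are anchored at the first joint view's
board frame. Synthetic board poses are placed 500–1000 mm along the rig's
mean viewing axis with tilts up to 45°, so the target covers a
substantial part of the field of view — weak, distant poses constrain
focal length poorly.

## Tracking

Pyramidal KLT: per frame pair, iterative Lucas–Kanade on a 3-level
Gaussian pyramid, 21×21 px patch (half-size 10), bilinear sub-pixel
sampling, convergence at 0.01 px, 30 iterations per level. The previous
frame's displacement seeds the coarsest level (constant-velocity
prediction), which keeps the ~12 px/frame circumnutation displacements
well inside the convergence basin. A frame is lost when the finest level
fails to converge, the patch leaves the image, the minimum eigenvalue of
the per-pixel-normalized gradient matrix falls below 1e-4 (judged at the
finest level only, since pyramid smoothing dilutes gradient energy), or a
forward–backward re-track disagrees by more than 1 px. Lost status is
sticky; corrections (`frame,u_px,v_px` rows) re-seed the tracker, which
resumes automatically to the next correction. Because the normal
equations scale identically in gradient matrix and mismatch vector, the
displacement estimate is invariant to constant intensity gain.

All tracker numerics are unstated in the source protocol and follow
standard KLT practice; they are exposed in `TrackerConfig`.

## Triangulation

Pixels are undistorted to ideal normalized coordinates, and the world
point is the homogeneous DLT solution (smallest right singular vector) of
the stacked two-view system — linear, with no per-point nonlinear
refinement. Points with non-positive depth in either camera are flagged
rather than returned silently; frames lost in either view propagate as
missing with no temporal interpolation (gap handling belongs to
kinematics, keeping geometry and smoothing separable). Each trajectory
carries a QC report: per-frame reprojection residuals in both images,
ray-skew distance, and the fraction reconstructed. At the default rig,
0.2 px pixel noise yields ~0.5 mm median 3D error (depth-dominated).

## Kinematics

Gaps up to 5 frames are filled by linear interpolation; coordinates are
then smoothed by a centered moving average of half-width 1 frame
(shrinking at the ends). Derivatives are central differences at the
native 3-min sampling, one-sided at the ends; speed and acceleration are
Euclidean norms of the 3D derivative vectors. At the default period this
finite differencing biases speed by −0.9% and acceleration by −0.5%
(both well inside the tolerances used in tests); no spline fitting is
attempted.

The movement epoch starts at the first valid frame and ends at the first
frame where one of three rules fires: tip within `grasp_margin` (2 mm)
of the pole surface → grasped; height ≥ `fall_drop` (20 mm) below its
running maximum → fell; speed < `stop_speed` (0.05 mm/min) for
`stop_frames` (20) consecutive intervals → stopped. Same-frame ties
resolve grasped > fell > stopped. The thresholds are analysis choices,
configurable and recorded with every run.

The "gravity center of the circumnutation" is operationalized as the
arithmetic mean of tip positions over the epoch — the standard centroid
reading. Its distance to the plant origin is measured in full 3D
(capturing stem inclination); its distance to the support is horizontal,
to the pole *axis*, because the pole is vertical and extended, so a 3D
point-to-point distance would depend arbitrarily on height. "Mean
velocity amplitude" is the mean instantaneous 3D speed over the epoch;
"maximum acceleration amplitude" is the max instantaneous acceleration
magnitude; both are computed on the smoothed trajectory by default.

Cycles are counted by unwrapping the tip's azimuth about the epoch-mean
center: `n_cycles = floor(|total angle| / 2π)`, direction the sign of the
total (counterclockwise positive viewed from above), with near-zero
radius frames (< 1e-6 mm) excluded and an error if more than half the
epoch is degenerate.

## Statistics

The Kruskal–Wallis H is computed from midranks with the standard tie
correction and referred to χ²(k−1); an all-tied sample returns H = 0,
p = 1. An exhaustive-permutation oracle (feasible to total n = 10) serves
as an independent cross-check: at three groups of three, the chi-square
approximation deviates from the exact permutation p by up to ~0.10 in the
middle of the distribution (the documented envelope), while the ranking
of H values always agrees with the ranking of exact p values. Null
calibration at n = 20 per group gives a type-I error of 0.05 ± 0.01 over
2000 replicates.

Post hoc, the default is Dunn's z-statistics on midranks with Holm
adjustment; Tukey's HSD on rank-transformed data is provided as an
alternative because pairing a Tukey post hoc with a Kruskal–Wallis
omnibus, while nonstandard, is common in the applied literature. The
report always names the method used.

Percentiles use linear interpolation between closest ranks. The
observational unit — whole plants or individual circumnutation cycles —
is an explicit parameter, defaults to per-cycle, and is surfaced in every
report, because group H statistics are not comparable across units.

## Experiment orchestration and problem sizes

`run_experiment` derives one seed pair per plant from the experiment seed
via `SeedSequence`, so runs are byte-identical given the configuration;
the manifest records the config hash and artifact checksums. The default
experiment is 8 plants × 3 genotypes over 600 simulated minutes
(201 frames/plant) with direct projection to pixel trajectories at 0.2 px
noise — that keeps a full experiment under ~5 s. Rendering + KLT
tracking of every frame is available (`use_image_tracking`) and is
exercised on shorter sequences in the tests; the image and direct routes
agree to within the tracker's sub-0.02 px error.

## Known limitations

- The tracker follows a single point; multi-marker identity management,
  re-detection, and affine patch deformation are out of scope.
- Triangulation is two-view DLT; no bundle adjustment or n-view support.
- The fall model is a constant-rate descent with continuing rotation;
  only its onset-to-detection window enters the measures.
- Cycle counting assumes rotation about a single center per epoch; it
  will undercount strongly drifting first cycles (the epoch-mean center
  is far from the early rotation center).
- Shapiro–Wilk delegates to the Royston approximation as implemented in
  scipy (3 ≤ n ≤ 5000).
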