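import numpy as np
import pytest

from circumnaut.errors import (
    InvalidArgumentError,
    UndefinedRotationError,
    UnfillableGapError,
)
from circumnaut.kinematics import (
    MovementEpoch,
    SegmentationThresholds,
    count_cycles,
    differentiate,
    fill_and_smooth,
    per_cycle_summaries,
    segment_movement,
    summarize,
)
from circumnaut.synthetic import (
    first_contact_frame,
    genotype_preset,
    simulate_tip_trajectory,
)
from circumnaut.trajectory import Trajectory3D


def make_traj(points, dt=3.0, status=None):
    points = np.asarray(points, dtype=float)
    n = len(points)
    status = status or ["valid"] * n
    return Trajectory3D(np.arange(n) * dt, points, np.array(status, dtype=object))


def circle_traj(R=30.0, T=80.0, dt=3.0, n_periods=10, center=(0.0, 0.0, 0.0)):
    t = np.arange(0, n_periods * T, dt)
    pts = np.column_stack(
        [
            center[0] + R * np.cos(2 * np.pi * t / T),
            center[1] + R * np.sin(2 * np.pi * t / T),
            np.full_like(t, center[2]),
        ]
    )
    return Trajectory3D(t, pts, np.array(["valid"] * len(t), dtype=object))


class TestFillAndSmooth:
    def test_identity_when_no_gap_no_smoothing(self):
        tr = make_traj([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        out = fill_and_smooth(tr, half_width=0)
        assert np.array_equal(out.points, tr.points)

    def test_single_gap_linear_midpoint(self):
        pts = [[0, 0, 0], [np.nan] * 3, [2, 2, 2]]
        tr = make_traj(pts, status=["valid", "missing", "valid"])
        out = fill_and_smooth(tr, half_width=0)
        assert np.allclose(out.points[1], [1, 1, 1])

    def test_long_gap_raises(self):
        pts = [[0, 0, 0]] + [[np.nan] * 3] * 4 + [[5, 5, 5]]
        tr = make_traj(pts, status=["valid"] + ["missing"] * 4 + ["valid"])
        with pytest.raises(UnfillableGapError):
            fill_and_smooth(tr, max_gap=2)

    def test_smoothing_attenuates_white_noise_by_sqrt3(self):
        rng = np.random.default_rng(8)
        sigma = 1.0
        noise = rng.normal(0, sigma, size=(4000, 3))
        tr = make_traj(noise)
        out = fill_and_smooth(tr, half_width=1)
        ratio = out.points[5:-5].std() / sigma
        assert abs(ratio - 1 / np.sqrt(3)) < 0.03


class TestDifferentiate:
    def test_uniform_linear_motion(self):
        pts = [[3.0 * i, 0, 0] for i in range(10)]
        speed, acc = differentiate(make_traj(pts, dt=3.0))
        assert np.allclose(speed, 1.0)
        assert np.allclose(acc[1:-1], 0.0, atol=1e-12)

    def test_circle_closed_form_speed_and_acceleration(self):
        tr = circle_traj(R=30.0, T=80.0, dt=3.0, n_periods=10)
        speed, acc = differentiate(tr)
        v_true = 2 * np.pi * 30.0 / 80.0
        a_true = (2 * np.pi / 80.0) ** 2 * 30.0
        assert abs(np.mean(speed[1:-1]) - v_true) / v_true < 0.02
        assert abs(np.max(acc[1:-1]) - a_true) / a_true < 0.05

    def test_non_uniform_time_base_rejected(self):
        tr = Trajectory3D(
            [0.0, 3.0, 10.0],
            np.zeros((3, 3)),
            np.array(["valid"] * 3, dtype=object),
        )
        with pytest.raises(InvalidArgumentError):
            differentiate(tr)


class TestSegmentMovement:
    def test_wild_type_grasps_at_ground_truth_contact(self, scene):
        preset = genotype_preset("wild_type", 600.0)
        tr = simulate_tip_trajectory(preset.params, scene, 600.0, seed=2)
        sm = fill_and_smooth(tr)
        epoch = segment_movement(sm, scene)
        assert epoch.outcome == "grasped"
        truth_frame = first_contact_frame(tr, scene, margin=2.0)
        assert abs(epoch.end_frame - truth_frame) <= 2  # smoothing tolerance

    @pytest.mark.parametrize("label", ["rms1_1", "rms3_1"])
    def test_mutants_fall(self, scene, label):
        preset = genotype_preset(label, 600.0)
        tr = simulate_tip_trajectory(preset.params, scene, 600.0, seed=3)
        epoch = segment_movement(fill_and_smooth(tr), scene)
        assert epoch.outcome == "fell"
        assert epoch.end_frame * scene.frame_interval > preset.params.fall_time

    def test_constant_position_stops_at_stop_frames(self, scene):
        tr = make_traj([[0.0, 0.0, 50.0]] * 60)
        epoch = segment_movement(tr, scene, SegmentationThresholds(stop_frames=20))
        assert epoch.outcome == "stopped"
        assert epoch.end_frame == 20


class TestCountCycles:
    def test_three_exact_circles_counterclockwise(self):
        tr = circle_traj(n_periods=3.02)
        epoch = MovementEpoch(0, len(tr) - 1, "stopped")
        n, bounds, direction = count_cycles(tr, epoch)
        assert n == 3 and direction == 1
        assert len(bounds) == 3

    def test_time_reversal_flips_direction(self):
        tr = circle_traj(n_periods=3.02)
        rev = Trajectory3D(tr.times, tr.points[::-1], tr.status)
        epoch = MovementEpoch(0, len(tr) - 1, "stopped")
        n, _, direction = count_cycles(rev, epoch)
        assert n == 3 and direction == -1

    def test_wild_type_ten_periods(self, scene):
        preset = genotype_preset("wild_type", 800.0)
        tr = simulate_tip_trajectory(preset.params, scene, 800.0, seed=5)
        epoch = MovementEpoch(0, len(tr) - 1, "stopped")
        n, _, direction = count_cycles(tr, epoch)
        assert abs(n - 10) <= 1
        assert direction == 1

    def test_degenerate_radius_rejected(self):
        tr = make_traj([[0.0, 0.0, float(i)] for i in range(10)])
        with pytest.raises(UndefinedRotationError):
            count_cycles(tr, MovementEpoch(0, 9, "stopped"))


class TestSummarize:
    def test_duration_arithmetic(self):
        tr = circle_traj(n_periods=5)
        epoch = MovementEpoch(0, 100, "stopped")
        s = summarize(tr, epoch, __import__("circumnaut").SceneSpec())
        assert np.isclose(s.duration_min, 300.0)

    def test_circle_center_recovered(self, scene):
        c = (20.0, -10.0, 40.0)
        tr = circle_traj(center=c, n_periods=4)
        # whole cycles only: 4 periods exactly
        epoch = MovementEpoch(0, len(tr) - 1, "stopped")
        s = summarize(tr, epoch, scene)
        # frames cover n_periods less one sample; allow sub-mm closure error
        assert np.allclose(s.center_mm, c, atol=0.5)
        expected = np.hypot(c[0] - 100.0, c[1])
        assert abs(s.dist_center_support_mm - expected) < 0.5

    def test_scaling_invariances(self, scene):
        # time x2 halves speeds and quarters accelerations; space x2 doubles
        # distances and speeds
        tr = circle_traj(n_periods=4)
        epoch = MovementEpoch(0, len(tr) - 1, "stopped")
        s = summarize(tr, epoch, scene)
        slow = Trajectory3D(tr.times * 2.0, tr.points, tr.status)
        s_slow = summarize(slow, MovementEpoch(0, len(tr) - 1, "stopped"), scene)
        assert np.isclose(s_slow.mean_velocity_mm_min, s.mean_velocity_mm_min / 2)
        assert np.isclose(
            s_slow.max_acceleration_mm_min2, s.max_acceleration_mm_min2 / 4
        )
        big = Trajectory3D(tr.times, tr.points * 2.0, tr.status)
        import dataclasses

        scene2 = dataclasses.replace(
            scene,
            support_axis_base=tuple(2 * v for v in scene.support_axis_base),
        )
        s_big = summarize(big, MovementEpoch(0, len(tr) - 1, "stopped"), scene2)
        assert np.isclose(s_big.mean_velocity_mm_min, 2 * s.mean_velocity_mm_min)
        assert np.isclose(s_big.dist_center_support_mm, 2 * s.dist_center_support_mm)

    def test_gravity_center_translation_equivariance(self, scene):
        tr = circle_traj(n_periods=4)
        epoch = MovementEpoch(0, len(tr) - 1, "stopped")
        s1 = summarize(tr, epoch, scene)
        shift = np.array([5.0, -3.0, 7.0])
        tr2 = Trajectory3D(tr.times, tr.points + shift, tr.status)
        s2 = summarize(tr2, epoch, scene)
        assert np.allclose(np.array(s2.center_mm) - np.array(s1.center_mm), shift)
        # center lies inside the convex hull: for a circle, within max radius
        rel = np.linalg.norm(np.array(s1.center_mm)[:2] - tr.points[:, :2].mean(0))
        assert rel < 1e-9

    def test_per_cycle_rows_match_cycle_count(self, scene):
        preset = genotype_preset("rms3_1", 600.0)
        tr = simulate_tip_trajectory(preset.params, scene, 600.0, seed=6)
        sm = fill_and_smooth(tr)
        epoch = segment_movement(sm, scene)
        n, _, _ = count_cycles(sm, epoch)
        table = per_cycle_summaries(sm, epoch, scene)
        assert len(table) == n
        assert (table["duration_min"] > 0).all()
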