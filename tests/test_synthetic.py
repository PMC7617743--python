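import dataclasses

import numpy as np
import pytest

from circumnaut.errors import InvalidArgumentError
from circumnaut.synthetic import (
    CircumnutationParams,
    SceneSpec,
    first_contact_frame,
    generate_chessboard_views,
    genotype_preset,
    project_stereo,
    render_marker_sequence,
    simulate_tip_trajectory,
)
from circumnaut.trajectory import Trajectory2D


def autocorrelation_dominant_period(x: np.ndarray, dt: float) -> float:
    """Independent oracle: lag of the first positive-lag autocorrelation peak."""
    x = x - x.mean()
    ac = np.correlate(x, x, mode="full")[len(x) - 1 :]
    # first local maximum after the zero-lag peak has decayed
    for k in range(1, len(ac) - 1):
        if ac[k] > ac[k - 1] and ac[k] >= ac[k + 1]:
            return k * dt
    raise AssertionError("no autocorrelation peak found")


class TestSimulateTip:
    def test_degenerate_helix_is_a_vertical_line(self, scene):
        p = CircumnutationParams(
            amplitude_x=0, amplitude_y=0, noise_sd=0, drift_gain=0
        )
        tr = simulate_tip_trajectory(p, scene, 400, seed=0)
        assert np.allclose(tr.points[:, :2], np.asarray(scene.origin[:2]))
        assert np.all(np.diff(tr.points[:, 2]) > 0)

    def test_dominant_period_matches_setting(self, scene):
        p = CircumnutationParams(period=80.0, noise_sd=0.0, drift_gain=0.0)
        tr = simulate_tip_trajectory(p, scene, 800, seed=0)
        period = autocorrelation_dominant_period(tr.points[:, 0], scene.frame_interval)
        assert abs(period - 80.0) <= scene.frame_interval

    def test_wild_type_approaches_support(self, scene):
        preset = genotype_preset("wild_type", 2000.0)
        tr = simulate_tip_trajectory(preset.params, scene, 2000.0, seed=4)
        d = scene.horizontal_distance_to_support(tr.points)
        assert d[-1] < d[0]
        assert first_contact_frame(tr, scene) is not None

    def test_determinism_in_seed(self, scene):
        p = genotype_preset("rms1_1", 400.0).params
        a = simulate_tip_trajectory(p, scene, 400.0, seed=9)
        b = simulate_tip_trajectory(p, scene, 400.0, seed=9)
        c = simulate_tip_trajectory(p, scene, 400.0, seed=10)
        assert np.array_equal(a.points, b.points)
        assert not np.array_equal(a.points, c.points)

    def test_tip_center_distance_equals_ellipse_radius(self, scene):
        p = CircumnutationParams(
            amplitude_x=25.0, amplitude_y=25.0, noise_sd=0.0, drift_gain=0.0
        )
        tr = simulate_tip_trajectory(p, scene, 400, seed=0)
        r = np.linalg.norm(tr.points[:, :2] - np.asarray(scene.origin[:2]), axis=1)
        assert np.allclose(r, 25.0, atol=1e-9)

    def test_short_duration_rejected(self, scene):
        p = CircumnutationParams(period=80.0)
        with pytest.raises(InvalidArgumentError):
            simulate_tip_trajectory(p, scene, 100.0, seed=0)

    def test_non_vertical_support_axis_rejected(self):
        with pytest.raises(InvalidArgumentError):
            SceneSpec(support_axis_direction=(0.0, 1.0, 0.0))

    def test_mutant_presets_fall_and_do_not_drift(self):
        wt = genotype_preset("wild_type", 600.0).params
        for label in ("rms1_1", "rms3_1"):
            m = genotype_preset(label, 600.0).params
            assert m.drift_gain == 0.0
            assert m.fall_time is not None and m.fall_time < 600.0
            assert m.speed_scale < wt.speed_scale
        assert wt.drift_gain > 0 and wt.fall_time is None


class TestProjectStereo:
    def test_seed_contract(self, scene, rig):
        p = genotype_preset("wild_type", 400.0).params
        tr = simulate_tip_trajectory(p, scene, 400.0, seed=1)
        l1, r1 = project_stereo(tr, rig, pixel_noise_sd=0.5, seed=1)
        l2, r2 = project_stereo(tr, rig, pixel_noise_sd=0.5, seed=2)
        assert np.array_equal(l1.status, l2.status)
        assert not np.allclose(l1.points, l2.points, equal_nan=True)

    def test_out_of_sensor_flagged_lost(self, rig, scene):
        from circumnaut.trajectory import Trajectory3D

        # one point in the working volume, one far outside the field of view
        tr = Trajectory3D(
            [0.0, 3.0],
            [[50.0, 0.0, 250.0], [50.0, 0.0, 30000.0]],
            np.array(["valid", "valid"], dtype=object),
        )
        left, right = project_stereo(tr, rig)
        assert left.status[0] == "tracked"
        assert left.status[1] == "lost" and right.status[1] == "lost"


class TestRenderMarker:
    @staticmethod
    def _static(n=10, pos=(64.0, 64.0)):
        return Trajectory2D(
            np.arange(n) * 3.0,
            np.tile(pos, (n, 1)),
            np.array(["tracked"] * n, dtype=object),
        )

    def test_static_marker_renders_identically(self):
        stack, status = render_marker_sequence(self._static(), (128, 128), 2.0)
        assert all(np.array_equal(stack[0], f) for f in stack)
        assert all(s == "tracked" for s in status)

    def test_intensity_centroid_matches_subpixel_position(self):
        traj = self._static(1, pos=(64.25, 63.5))
        stack, _ = render_marker_sequence(traj, (128, 128), 2.0)
        img = stack[0].astype(float) - stack[0].min()
        ys, xs = np.mgrid[0:128, 0:128]
        cx = (xs * img).sum() / img.sum()
        cy = (ys * img).sum() / img.sum()
        assert abs(cx - 64.25) < 0.05 and abs(cy - 63.5) < 0.05

    def test_marker_outside_image_gives_background_frame(self):
        traj = self._static(1, pos=(-10.0, -10.0))
        stack, status = render_marker_sequence(traj, (128, 128), 2.0, background=20)
        assert np.all(stack[0] == 20)
        assert status[0] == "lost"

    def test_too_small_blob_rejected(self):
        with pytest.raises(InvalidArgumentError):
            render_marker_sequence(self._static(), (128, 128), blob_sigma=0.2)


class TestChessboardViews:
    def test_reprojection_with_true_rig_is_exact(self, rig):
        views = generate_chessboard_views(rig, n_views=5, seed=11)
        from circumnaut.camera import project_points

        for v in views:
            px, ok = project_points(v.world_points, rig.left_intrinsics, rig.left_extrinsics)
            assert ok.all()
            assert np.allclose(px, v.pixels_left, atol=1e-9)

    def test_underdetermined_view_count_rejected(self, rig):
        with pytest.raises(InvalidArgumentError):
            generate_chessboard_views(rig, n_views=2, seed=0)

    def test_small_board_rejected(self, rig):
        with pytest.raises(InvalidArgumentError):
            generate_chessboard_views(rig, columns=4, rows=4, n_views=3, seed=0)
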