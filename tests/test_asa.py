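"""Average-screw-axis estimation: covariance, direction, ISA lines, frame."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from asakin import (
    AmbiguousAxisError,
    DegenerateMotionError,
    InsufficientMotionError,
    Pose,
    PoseTrajectory,
    ScrewAxisLine,
    SimulationConfig,
    TwistTrajectory,
    angular_covariance,
    asa_direction,
    build_asa_frame,
    instantaneous_screw_axes,
    pseudo_intersection,
    relative_twists,
    simulate_knee,
)
from conftest import random_pose_arrays


def _twists(omega, v=None, frame="fm"):
    omega = np.asarray(omega, dtype=float)
    v = np.zeros_like(omega) if v is None else np.asarray(v, dtype=float)
    t = np.linspace(0.0, 1.0, len(omega))
    return TwistTrajectory(t, omega, v, frame)


class TestAngularCovariance:
    def test_single_direction(self):
        C = angular_covariance(_twists([[0, 0, 2.0]] * 5))
        np.testing.assert_allclose(C.C, np.diag([0.0, 0.0, 4.0]), atol=1e-15)

    def test_hand_summed_two_directions(self):
        # (1,0,0),(0,1,0) and a zero pad: C = diag(1,1,0)/3
        C = angular_covariance(_twists([[1, 0, 0], [0, 1, 0], [0, 0, 0]]))
        np.testing.assert_allclose(C.C, np.diag([1 / 3, 1 / 3, 0.0]), atol=1e-15)

    def test_symmetric_psd_for_random_series(self, rng):
        C = angular_covariance(_twists(rng.normal(size=(40, 3))))
        np.testing.assert_allclose(C.C, C.C.T, atol=1e-15)
        assert np.min(np.linalg.eigvalsh(C.C)) >= -1e-12

    def test_zero_motion_rejected(self):
        with pytest.raises(DegenerateMotionError):
            angular_covariance(_twists(np.zeros((5, 3))))


class TestAsaDirection:
    def test_dominant_axis_with_positive_net_rotation(self):
        tw = _twists([[3, 0, 0], [2.5, 0.3, 0], [2.8, -0.2, 0.1]])
        n = asa_direction(angular_covariance(tw), tw)
        assert n @ [1, 0, 0] > 0.99

    def test_sign_follows_negative_rotations(self):
        tw = _twists([[-3, 0, 0], [-2.5, 0.3, 0], [-2.8, -0.2, 0.1]])
        n = asa_direction(angular_covariance(tw), tw)
        assert n @ [-1, 0, 0] > 0.99

    def test_flex_and_return_sign_from_excursion(self):
        # symmetric oscillation: net rotation ~ 0, excursion decides the sign
        t = np.linspace(0.0, 1.0, 101)
        rate = np.sin(2 * np.pi * t)  # positive first half: excursion > 0
        tw = _twists(np.outer(rate, [0, 0, 1.0]))
        n = asa_direction(angular_covariance(tw), tw)
        np.testing.assert_allclose(n, [0, 0, 1.0], atol=1e-12)
        tw_neg = _twists(np.outer(-rate, [0, 0, 1.0]))
        n_neg = asa_direction(angular_covariance(tw_neg), tw_neg)
        np.testing.assert_allclose(n_neg, [0, 0, -1.0], atol=1e-12)

    def test_oblique_hinge_axis_recovery(self):
        axis = np.array([1.0, 1.0, 1.0]) / np.sqrt(3)
        rate = 1.0 + 0.5 * np.sin(np.linspace(0, 6, 50))
        tw = _twists(np.outer(rate, axis))
        n = asa_direction(angular_covariance(tw), tw)
        assert np.arccos(np.clip(n @ axis, -1, 1)) < 1e-6

    def test_isotropic_motion_is_ambiguous(self):
        tw = _twists([[1, 0, 0], [0, 1, 0], [-1, 0, 0], [0, -1, 0]])
        with pytest.raises(AmbiguousAxisError):
            asa_direction(angular_covariance(tw), tw)


class TestInstantaneousScrewAxes:
    def test_axis_through_origin(self):
        lines = instantaneous_screw_axes(_twists([[0, 0, 1.0]] * 4))
        for ln in lines:
            np.testing.assert_allclose(ln.u, [0, 0, 1.0], atol=1e-15)
            np.testing.assert_allclose(ln.q, 0.0, atol=1e-15)

    def test_offset_axis_hand_cross_product(self):
        # w=(0,0,1), v=(0,1,0): q = w x v / |w|^2 = (-1, 0, 0)
        lines = instantaneous_screw_axes(
            _twists([[0, 0, 1.0]] * 3, [[0, 1.0, 0]] * 3)
        )
        np.testing.assert_allclose(lines[0].q, [-1.0, 0.0, 0.0], atol=1e-15)
        assert abs(lines[0].q @ lines[0].u) < 1e-9

    def test_low_speed_samples_excluded(self):
        omega = [[0, 0, 1.0]] * 4 + [[0, 0, 0.01]] * 3
        lines = instantaneous_screw_axes(_twists(omega), omega_floor=0.10)
        assert len(lines) == 4

    def test_insufficient_samples_above_floor(self):
        with pytest.raises(InsufficientMotionError):
            instantaneous_screw_axes(
                _twists([[0, 0, 1.0], [0, 0, 0.001], [0, 0, 0.001], [0, 0, 0.002]])
            )


def _line(u, q, w=1.0):
    u = np.asarray(u, dtype=float)
    return ScrewAxisLine(u / np.linalg.norm(u), np.asarray(q, dtype=float), w)


class TestPseudoIntersection:
    def test_two_perpendicular_lines_through_origin(self):
        S, diag = pseudo_intersection([_line([1, 0, 0], [0, 0, 0]), _line([0, 1, 0], [0, 0, 0])])
        np.testing.assert_allclose(S, 0.0, atol=1e-12)
        assert not diag["rank_deficient"]

    def test_skew_lines_midpoint(self):
        # x-axis and the y-direction line through (0,0,1): closest point (0,0,0.5)
        S, _ = pseudo_intersection([_line([1, 0, 0], [0, 0, 0]), _line([0, 1, 0], [0, 0, 1.0])])
        np.testing.assert_allclose(S, [0.0, 0.0, 0.5], atol=1e-12)

    def test_three_line_weighted_consistency(self):
        # all three through (0.2, -0.1, 0.3): weights must not move the answer
        p = np.array([0.2, -0.1, 0.3])
        dirs = [[1, 0, 0], [0, 1, 0], [1, 1, 1]]
        for weights in ([1, 1, 1], [4.0, 0.5, 2.0]):
            lines = []
            for u, w in zip(dirs, weights):
                u = np.asarray(u) / np.linalg.norm(u)
                q = p - (p @ u) * u  # closest point to origin on the line
                lines.append(ScrewAxisLine(u, q, np.sqrt(w)))
            S, _ = pseudo_intersection(lines)
            np.testing.assert_allclose(S, p, atol=1e-12)

    def test_parallel_lines_minimum_norm_with_flag(self):
        S, diag = pseudo_intersection(
            [_line([0, 0, 1], [1.0, 0, 0]), _line([0, 0, 1], [-1.0, 0, 0])]
        )
        np.testing.assert_allclose(S, 0.0, atol=1e-12)
        assert diag["rank_deficient"]


class TestBuildAsaFrame:
    def test_hinge_axis_and_origin_recovery(self, pure_hinge_trial):
        fm, tb, truth = pure_hinge_trial
        tw_fm, _ = relative_twists(fm, tb)
        frame = build_asa_frame(tw_fm)
        assert abs(frame.e1 @ truth.true_axis_direction) > 1 - 1e-8
        # origin lies on the true axis (distance measured perpendicular to
        # it); limited by the O(dt^2) differencing error in the linear
        # velocity, ~0.05 mm at 101 samples -- far below marker-noise scale
        delta = frame.origin - truth.true_axis_point
        dist = np.linalg.norm(delta - (delta @ frame.e1) * frame.e1)
        assert dist < 2e-4
        assert frame.axis_parallelism > 1 - 1e-9

    def test_axes_orthonormal_right_handed_eigvec_consistent(self, default_trial):
        fm, tb, _ = default_trial
        tw_fm, tw_tb = relative_twists(fm, tb)
        for tw in (tw_fm, tw_tb):
            frame = build_asa_frame(tw)
            E = np.column_stack([frame.e1, frame.e2, frame.e3])
            np.testing.assert_allclose(E.T @ E, np.eye(3), atol=1e-12)
            assert np.linalg.det(E) == pytest.approx(1.0, abs=1e-12)
            C = angular_covariance(tw).C
            np.testing.assert_allclose(
                C @ frame.e1, frame.eigenvalues[0] * frame.e1, atol=1e-9
            )
            assert np.all(np.diff(frame.eigenvalues) <= 0)
            assert 1 / 3 < frame.axis_parallelism <= 1

    def test_time_reversed_monotonic_rotation_flips_axis(self):
        n = 101
        t = np.linspace(0.0, 1.0, n)
        theta = 1.2 * t**2  # monotonic, net rotation > 0
        Rs = Rotation.from_rotvec(np.outer(theta, [0, 0, 1.0])).as_matrix()
        fw = PoseTrajectory(t, Rs, np.zeros((n, 3)), ("fm", "tb"))
        bw = PoseTrajectory(t, Rs[::-1].copy(), np.zeros((n, 3)), ("fm", "tb"))
        id_traj = PoseTrajectory(
            t, np.tile(np.eye(3), (n, 1, 1)), np.zeros((n, 3)), ("0", "fm")
        )
        e1_fw = build_asa_frame(relative_twists(id_traj, fw)[0]).e1
        e1_bw = build_asa_frame(relative_twists(id_traj, bw)[0]).e1
        np.testing.assert_allclose(e1_fw, [0, 0, 1.0], atol=1e-9)
        np.testing.assert_allclose(e1_bw, [0, 0, -1.0], atol=1e-9)

    def test_equivariance_under_body_frame_change(self, rng, default_trial):
        from asakin import FrameModification, apply_frame_modification

        fm, tb, _ = default_trial
        X = Pose(*random_pose_arrays(rng))
        mod = FrameModification(X_fm=X, X_tb=Pose.identity(), side="body_frame")
        fm2, tb2 = apply_frame_modification(fm, tb, mod)
        f0 = build_asa_frame(relative_twists(fm, tb)[0])
        f1 = build_asa_frame(relative_twists(fm2, tb2)[0])
        Xi = np.linalg.inv(X.matrix)
        expected = Xi @ f0.pose.matrix
        np.testing.assert_allclose(f1.pose.matrix, expected, atol=1e-10)

    def test_floor_choice_does_not_move_noiseless_hinge_axis(self, pure_hinge_trial):
        fm, tb, truth = pure_hinge_trial
        tw, _ = relative_twists(fm, tb)
        for floor in (0.05, 0.10, 0.30):
            frame = build_asa_frame(tw, omega_floor=floor)
            assert abs(frame.e1 @ truth.true_axis_direction) > 1 - 1e-8
            delta = frame.origin - truth.true_axis_point
            dist = np.linalg.norm(delta - (delta @ frame.e1) * frame.e1)
            assert dist < 2e-4

    def test_degenerate_simulation_raises(self):
        cfg = SimulationConfig(flexion_amplitude=0.0, out_of_plane_amplitude=0.0)
        fm, tb, _ = simulate_knee(cfg)
        with pytest.raises(DegenerateMotionError):
            build_asa_frame(relative_twists(fm, tb)[0])
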