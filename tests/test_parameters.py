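"""Parameter series: angle formula, the nine measurements, detectors."""

import numpy as np
import pytest

import gaitlab.skeleton as sk
from gaitlab import (ParameterSeries, Skeleton3D, arm_separation,
                     arm_support_angle, detect_arm_support,
                     detect_stride_lengths, hand_separation, heel_separation,
                     joint_angle, speed_series, stride_signal,
                     trajectory_series, trunk_swing, trunk_tilt,
                     trunk_tilt_mean)
from gaitlab.errors import DegenerateGeometryError

from conftest import make_skeleton


class TestJointAngle:
    A = (0.0, 0.0, 0.0)

    @pytest.mark.parametrize("b,c,expected", [
        ((1, 0, 0), (0, 1, 0), 90.0),
        ((1, 0, 0), (2, 0, 0), 0.0),
        ((1, 0, 0), (-1, 0, 0), 180.0),
        ((1, 0, 0), (1, 1, 0), 45.0),
    ])
    def test_reference_angles(self, b, c, expected):
        assert joint_angle(self.A, b, c) == pytest.approx(expected)

    def test_degenerate_vector_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            joint_angle(self.A, self.A, (1, 0, 0))

    def test_scale_invariance_about_vertex(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            a, b, c = rng.normal(size=(3, 3))
            s = rng.uniform(0.1, 10.0)
            base = joint_angle(a, b, c)
            scaled = joint_angle(a, a + s * (b - a), a + s * (c - a))
            assert scaled == pytest.approx(base, abs=1e-9)


class TestSeriesContracts:
    def test_timestamps_strictly_increasing(self):
        with pytest.raises(ValueError):
            ParameterSeries("stride", "m", [0.0, 0.0], [1.0, 1.0])

    def test_angle_range_enforced(self):
        with pytest.raises(ValueError):
            ParameterSeries("trunk_swing", "degrees", [0.0], [200.0])

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            ParameterSeries("stride", "m", [0.0], [-0.1])

    def test_json_round_trip_preserves_values_exactly(self, tmp_path):
        s = ParameterSeries("stride", "m",
                            [0.0, 1.0 / 3.0, 0.9999999999999],
                            [0.1234567890123456, np.nan, 1e-17])
        path = tmp_path / "s.json"
        s.save(path)
        r = ParameterSeries.load(path)
        np.testing.assert_array_equal(s.t, r.t)
        np.testing.assert_array_equal(s.v, r.v)  # NaN preserved as null


class TestGeometricExamples:
    def test_trunk_swing_hand_computation(self):
        s = make_skeleton({sk.LEFT_SHOULDER: (-0.2, 0.0, 2.0),
                             sk.RIGHT_SHOULDER: (0.2, -0.070, 2.0)})
        expected = np.degrees(np.arctan(0.070 / 0.4))
        assert trunk_swing([s]).v[0] == pytest.approx(expected, abs=1e-9)

    def test_level_shoulders_swing_zero(self):
        s = make_skeleton({sk.LEFT_SHOULDER: (-0.2, 0.1, 2.0),
                             sk.RIGHT_SHOULDER: (0.2, 0.1, 2.0)})
        assert trunk_swing([s]).v[0] == 0.0

    @pytest.mark.parametrize("xl,xr,expected", [
        (0.25, -0.25, 0.5),   # exaggerated stance, half a meter
        (0.05, -0.05, 0.1),   # feet together, ten centimeters
        (0.13, 0.13, 0.0),
    ])
    def test_heel_separation_lateral_distance(self, xl, xr, expected):
        s = make_skeleton({sk.LEFT_ANKLE: (xl, 0.8, 2.0),
                             sk.RIGHT_ANKLE: (xr, 0.8, 2.0)})
        assert heel_separation([s]).v[0] == pytest.approx(expected)

    def test_stride_depth_difference(self):
        s = make_skeleton({sk.LEFT_ANKLE: (0.1, 0.8, 2.0),
                             sk.RIGHT_ANKLE: (-0.1, 0.8, 2.4)})
        assert stride_signal([s]).v[0] == pytest.approx(0.4)
        s2 = make_skeleton({sk.LEFT_ANKLE: (0.1, 0.8, 2.0),
                              sk.RIGHT_ANKLE: (-0.1, 0.8, 2.0)})
        assert stride_signal([s2]).v[0] == 0.0

    def test_hand_separation_euclidean(self):
        s = make_skeleton({sk.LEFT_WRIST: (0.3, 0.0, 2.0),
                             sk.RIGHT_WRIST: (-0.3, 0.0, 2.0)})
        assert hand_separation([s]).v[0] == pytest.approx(0.6)

    def test_arm_hanging_parallel_to_trunk_near_zero(self):
        s = make_skeleton({sk.LEFT_SHOULDER: (0.2, -0.5, 2.0),
                             sk.LEFT_ELBOW: (0.2, -0.2, 2.0),
                             sk.LEFT_HIP: (0.2, 0.0, 2.0)})
        assert arm_separation([s], "left").v[0] == pytest.approx(0.0, abs=1e-6)

    def test_arm_horizontal_ninety_degrees(self):
        s = make_skeleton({sk.LEFT_SHOULDER: (0.2, -0.5, 2.0),
                             sk.LEFT_ELBOW: (0.5, -0.5, 2.0),
                             sk.LEFT_HIP: (0.2, 0.0, 2.0)})
        assert arm_separation([s], "left").v[0] == pytest.approx(90.0)

    def test_extended_arm_support_180(self):
        s = make_skeleton({sk.RIGHT_SHOULDER: (-0.2, -0.5, 2.0),
                             sk.RIGHT_ELBOW: (-0.2, -0.2, 2.0),
                             sk.RIGHT_WRIST: (-0.2, 0.1, 2.0)})
        assert arm_support_angle([s], "right").v[0] == pytest.approx(180.0)

    def test_standing_trunk_tilt_180_and_mean(self):
        kw = {sk.LEFT_SHOULDER: (0.2, -1.0, 2.0),
              sk.LEFT_HIP: (0.2, -0.5, 2.0),
              sk.LEFT_KNEE: (0.2, 0.0, 2.0),
              sk.RIGHT_SHOULDER: (-0.2, -1.0, 2.0),
              sk.RIGHT_HIP: (-0.2, -0.5, 2.0),
              sk.RIGHT_KNEE: (-0.2, -0.25, 2.25)}  # right leg bent 45 deg
        s = make_skeleton(kw)
        assert trunk_tilt([s], "left").v[0] == pytest.approx(180.0)
        assert trunk_tilt([s], "right").v[0] == pytest.approx(135.0)
        assert trunk_tilt_mean([s]).v[0] == pytest.approx(157.5)

    def test_missing_joint_propagates(self):
        s = make_skeleton({sk.LEFT_ANKLE: (np.nan,) * 3})
        assert np.isnan(stride_signal([s]).v[0])
        assert np.isnan(heel_separation([s]).v[0])


class TestSpeedSeries:
    def _static_seq(self, n=31, dt=0.1):
        return [make_skeleton({sk.LEFT_HIP: (0.1, 0.0, 2.0),
                               sk.RIGHT_HIP: (-0.1, 0.0, 2.0)}, t=k * dt)
                for k in range(n)]

    def test_static_speed_zero(self):
        s = speed_series(self._static_seq(), window=1.0)
        assert s.t.size == 21
        np.testing.assert_allclose(s.v, 0.0)

    def test_constant_velocity_recovered(self):
        seq = [make_skeleton({sk.LEFT_HIP: (0.1, 0.0, 4.0 - 0.12 * k),
                              sk.RIGHT_HIP: (-0.1, 0.0, 4.0 - 0.12 * k)},
                             t=k * 0.1)
               for k in range(31)]
        s = speed_series(seq, window=1.0)
        np.testing.assert_allclose(s.v, 1.2, atol=1e-9)

    def test_missing_hip_gap_propagates(self):
        seq = self._static_seq()
        seq[5].joints[sk.LEFT_HIP] = np.nan
        s = speed_series(seq, window=1.0)
        # windows ending at t=0.5+1.0 use the t=0.5 frame as their start
        assert np.isnan(s.v[np.isclose(s.t, 1.5)][0])
        assert np.isfinite(s.v[np.isclose(s.t, 1.6)][0])

    def test_short_sequence_warns_and_empty(self):
        with pytest.warns(UserWarning):
            s = speed_series(self._static_seq(n=5), window=1.0)
        assert s.t.size == 0


class TestTrajectory:
    def test_ground_plane_projection(self):
        seq = [make_skeleton({sk.LEFT_HIP: (0.2, -0.1, 3.0 - 0.1 * k),
                              sk.RIGHT_HIP: (0.0, -0.1, 3.0 - 0.1 * k)},
                             t=k * 0.1)
               for k in range(5)]
        traj = trajectory_series(seq)
        np.testing.assert_allclose(traj.lateral, 0.1)
        assert np.all(np.diff(traj.depth) < 0)  # walking toward the camera


class TestDetectors:
    def test_flat_signal_no_strides(self):
        t = np.arange(50) / 25.0
        sig = ParameterSeries("stride", "m", t, np.zeros(50))
        assert detect_stride_lengths(sig) == []

    def test_two_step_lengths_recovered(self):
        # alternating steps of 0.2 m then 0.4 m
        t = np.arange(0, 8, 1 / 30)
        amp = np.where(t < 4, 0.2, 0.4)
        sig = ParameterSeries("stride", "m", t,
                              amp * np.abs(np.sin(np.pi * 0.75 * t)))
        peaks = detect_stride_lengths(sig)
        early = [v for ts, v in peaks if ts < 4]
        late = [v for ts, v in peaks if ts > 4.4]
        assert early and late
        assert np.allclose(early, 0.2, atol=0.03)
        assert np.allclose(late, 0.4, atol=0.03)

    def test_low_rate_signal_rejected(self):
        t = np.arange(10) / 5.0
        sig = ParameterSeries("stride", "m", t, np.zeros(10))
        with pytest.raises(ValueError):
            detect_stride_lengths(sig)

    def _arm_series(self, t, v):
        return ParameterSeries("arm_support_left", "degrees", t, v)

    def test_no_transition_returns_false(self):
        t = np.arange(0, 5, 1 / 30)
        trunk = ParameterSeries("trunk_tilt_mean", "degrees", t,
                                np.full(t.size, 120.0))
        arms = self._arm_series(t, np.full(t.size, 80.0))  # bent but seated
        res = detect_arm_support(trunk, arms, arms)
        assert res.used is False
        assert res.windows == []

    def test_bend_during_transition_flags_support(self):
        t = np.arange(0, 10, 1 / 30)
        trunk_v = np.interp(t, [0, 4, 6, 10], [120, 120, 175, 175])
        trunk = ParameterSeries("trunk_tilt_mean", "degrees", t, trunk_v)
        bent = 180 - 105 * np.exp(-((t - 5) ** 2) / 0.5)  # dips to 75 at t=5
        extended = np.full(t.size, 178.0)
        res = detect_arm_support(trunk, self._arm_series(t, bent),
                                 self._arm_series(t, extended))
        assert res.used is True
        assert res.min_angle == pytest.approx(75.0, abs=1.0)
        res2 = detect_arm_support(trunk, self._arm_series(t, extended),
                                  self._arm_series(t, extended))
        assert res2.used is False

    def test_bend_outside_window_ignored(self):
        t = np.arange(0, 10, 1 / 30)
        trunk_v = np.interp(t, [0, 4, 6, 10], [120, 120, 175, 175])
        trunk = ParameterSeries("trunk_tilt_mean", "degrees", t, trunk_v)
        early_bend = np.where(t < 1.0, 80.0, 178.0)
        res = detect_arm_support(trunk, self._arm_series(t, early_bend),
                                 self._arm_series(t, early_bend))
        assert res.used is False


class TestOracleEquivalence:
    """The vectorized series must match naive per-frame evaluation exactly."""

    def test_against_brute_force(self, sway_clean):
        seq, _ = sway_clean
        seq = seq[:60]
        computed = {
            "trunk_swing": trunk_swing(seq).v,
            "arm_separation_left": arm_separation(seq, "left").v,
            "arm_support_right": arm_support_angle(seq, "right").v,
            "trunk_tilt_left": trunk_tilt(seq, "left").v,
            "heel_separation": heel_separation(seq).v,
            "stride": stride_signal(seq).v,
            "hand_separation": hand_separation(seq).v,
        }
        for k, s in enumerate(seq):
            J = s.joints
            sv = J[sk.LEFT_SHOULDER] - J[sk.RIGHT_SHOULDER]
            naive = {
                "trunk_swing": np.degrees(np.arctan2(
                    abs(sv[1]), np.sqrt(sv[0] ** 2 + sv[2] ** 2))),
                "arm_separation_left": joint_angle(
                    J[sk.LEFT_SHOULDER], J[sk.LEFT_ELBOW], J[sk.LEFT_HIP]),
                "arm_support_right": joint_angle(
                    J[sk.RIGHT_ELBOW], J[sk.RIGHT_SHOULDER],
                    J[sk.RIGHT_WRIST]),
                "trunk_tilt_left": joint_angle(
                    J[sk.LEFT_HIP], J[sk.LEFT_SHOULDER], J[sk.LEFT_KNEE]),
                "heel_separation": abs(J[sk.LEFT_ANKLE, 0] -
                                       J[sk.RIGHT_ANKLE, 0]),
                "stride": abs(J[sk.LEFT_ANKLE, 2] - J[sk.RIGHT_ANKLE, 2]),
                "hand_separation": float(np.linalg.norm(
                    J[sk.LEFT_WRIST] - J[sk.RIGHT_WRIST])),
            }
            for name, expected in naive.items():
                assert computed[name][k] == pytest.approx(expected,
                                                          abs=1e-12), name


class TestMirrorSymmetry:
    def test_reflection_swaps_sides_and_preserves_symmetric_series(
            self, sway_clean):
        seq, _ = sway_clean
        seq = seq[:40]
        mirrored = [s.mirrored() for s in seq]
        np.testing.assert_allclose(trunk_swing(seq).v,
                                   trunk_swing(mirrored).v, atol=1e-12)
        np.testing.assert_allclose(heel_separation(seq).v,
                                   heel_separation(mirrored).v, atol=1e-12)
        np.testing.assert_allclose(stride_signal(seq).v,
                                   stride_signal(mirrored).v, atol=1e-12)
        np.testing.assert_allclose(hand_separation(seq).v,
                                   hand_separation(mirrored).v, atol=1e-12)
        np.testing.assert_allclose(arm_separation(seq, "left").v,
                                   arm_separation(mirrored, "right").v,
                                   atol=1e-12)
        np.testing.assert_allclose(trunk_tilt(seq, "right").v,
                                   trunk_tilt(mirrored, "left").v,
                                   atol=1e-12)
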