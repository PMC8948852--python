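"""Forward-kinematics simulator: presets, noise injection, cohorts."""

import numpy as np
import pytest

from kinarom import (
    CALIBRATION_PRESETS,
    AcquisitionCondition,
    Anthropometry,
    ArmPoseSpec,
    NoiseModel,
    angle_series,
    condition_noise_params,
    pose_to_skeleton,
    simulate_cohort,
    simulate_measurement_session,
    validate_frame,
)
from kinarom.errors import DomainError


class TestPoseSpec:
    @pytest.mark.parametrize("abd,elb", [(-1, 180), (181, 180), (90, -0.5), (90, 200)])
    def test_out_of_range_angles_rejected(self, abd, elb):
        with pytest.raises(DomainError):
            ArmPoseSpec("right", abd, elb)

    def test_non_positive_lengths_rejected(self):
        with pytest.raises(DomainError):
            Anthropometry(upper_arm_length=0.0)


class TestPoseToSkeleton:
    def test_identity_pose_hangs_straight(self):
        from kinarom import joint_angle
        # arccos near 0/180 is sqrt(eps)-conditioned: 1e-6 deg is floating-point exact here
        frame = pose_to_skeleton(ArmPoseSpec("right", 0.0, 180.0))
        assert joint_angle(frame, "shoulder_abduction", "right").theta == pytest.approx(0.0, abs=1e-6)
        assert joint_angle(frame, "elbow_flexion", "right").theta == pytest.approx(180.0, abs=1e-6)

    def test_right_angle_pose(self):
        from kinarom import joint_angle
        frame = pose_to_skeleton(ArmPoseSpec("right", 90.0, 180.0))
        assert joint_angle(frame, "shoulder_abduction", "right").theta == pytest.approx(90.0, abs=1e-9)

    def test_frame_is_complete_and_valid(self):
        frame = pose_to_skeleton(ArmPoseSpec("left", 120.0, 45.0))
        assert validate_frame(frame) == []

    def test_abduction_moves_arm_laterally(self):
        low = pose_to_skeleton(ArmPoseSpec("right", 10.0))
        high = pose_to_skeleton(ArmPoseSpec("right", 90.0))
        assert high.positions["ElbowRight"][0] > low.positions["ElbowRight"][0]
        mirrored = pose_to_skeleton(ArmPoseSpec("left", 90.0))
        assert mirrored.positions["ElbowLeft"][0] < 0 < high.positions["ElbowRight"][0]

    def test_flexion_brings_hand_forward(self):
        frame = pose_to_skeleton(ArmPoseSpec("right", 90.0, 90.0))
        # the participant's front is -z in camera space
        assert frame.positions["HandRight"][2] < frame.positions["ElbowRight"][2]


class TestCalibrationPresets:
    @pytest.mark.parametrize("distance,lux,bias,sd", [
        (2.0, 73.0, 1.65, 2.06),
        (1.0, 73.0, 21.32, 4.01),
        (2.0, 7.0, -0.26, 2.94),
        (3.0, 7.0, -0.67, 4.77),
    ])
    def test_preset_bias_and_sd(self, distance, lux, bias, sd):
        nm = condition_noise_params(AcquisitionCondition(distance, lux))
        assert nm.angle_bias == pytest.approx(bias, abs=1e-9)
        assert nm.angle_sd == pytest.approx(sd, abs=1e-12)
        assert nm.positional_jitter_sd == 0.0

    def test_six_presets_exist(self):
        assert len(CALIBRATION_PRESETS) == 6

    def test_non_preset_condition_lists_presets(self):
        with pytest.raises(DomainError, match="2 m/7 lx"):
            condition_noise_params(AcquisitionCondition(2.5, 40.0))


class TestSessions:
    def test_zero_noise_constant_pose_measures_exactly(self, clean_stream):
        thetas = angle_series(clean_stream, "shoulder_abduction", "right").thetas
        assert np.allclose(thetas, 90.0, atol=1e-9)

    def test_same_seed_identical_streams(self):
        noise = condition_noise_params(AcquisitionCondition(2.0, 73.0),
                                       positional_jitter_sd=0.003)
        kwargs = dict(trajectory=[ArmPoseSpec("left", 90.0)], noise=noise, seed=1234)
        s1 = simulate_measurement_session(**kwargs)
        s2 = simulate_measurement_session(**kwargs)
        for f1, f2 in zip(s1.frames, s2.frames):
            for n in f1.positions:
                assert np.array_equal(f1.positions[n], f2.positions[n])

    def test_different_seed_differs(self):
        noise = condition_noise_params(AcquisitionCondition(2.0, 73.0))
        s1 = simulate_measurement_session([ArmPoseSpec("left", 90.0)], noise=noise, seed=1)
        s2 = simulate_measurement_session([ArmPoseSpec("left", 90.0)], noise=noise, seed=2)
        assert not np.array_equal(s1.frames[0].positions["ElbowLeft"],
                                  s2.frames[0].positions["ElbowLeft"])

    def test_empty_trajectory_rejected(self):
        with pytest.raises(DomainError):
            simulate_measurement_session([], seed=0)

    def test_trajectory_interpolated_across_frames(self):
        traj = [ArmPoseSpec("right", 0.0), ArmPoseSpec("right", 120.0)]
        stream = simulate_measurement_session(traj, noise=NoiseModel(0, 0, 0),
                                              n_frames=31, seed=0)
        thetas = angle_series(stream, "shoulder_abduction", "right").thetas
        assert thetas[0] == pytest.approx(0.0, abs=1e-6)
        assert thetas[-1] == pytest.approx(120.0, abs=1e-9)
        assert thetas[15] == pytest.approx(60.0, abs=1e-6)

    def test_replicate_sessions_recover_preset_mean(self):
        """(2 m, 73 lx): grand mean over replicates of a true-90 hold ~ 91.65."""
        noise = condition_noise_params(AcquisitionCondition(2.0, 73.0))
        means = []
        for seed in range(60):
            stream = simulate_measurement_session([ArmPoseSpec("right", 90.0)],
                                                  noise=noise, n_frames=30, seed=seed)
            means.append(angle_series(stream, "shoulder_abduction", "right").thetas.mean())
        # 60x30 = 1800 draws; 4-sigma MC band = 4*2.06/sqrt(1800) ~ 0.19 deg
        assert np.mean(means) == pytest.approx(91.65, abs=0.2)


class TestCohorts:
    def test_cohort_counts_and_stream_shapes(self):
        records = simulate_cohort(5, "control", seed=7)
        assert len(records) == 5
        for r in records:
            assert set(r.streams) == {(m, s) for m in ("shoulder_abduction", "elbow_flexion")
                                      for s in ("right", "left")}
            assert all(len(stream) == 30 for stream in r.streams.values())
            assert len(r.manual_items) == 30

    def test_study_abduction_below_control_by_construction(self):
        control = simulate_cohort(15, "control", seed=1)
        study = simulate_cohort(15, "study", seed=2)
        c = np.mean([r.truth[("shoulder_abduction", "right")] for r in control])
        s = np.mean([r.truth[("shoulder_abduction", "right")] for r in study])
        assert s < c

    def test_seed_reproducibility(self):
        a = simulate_cohort(3, "study", seed=11)
        b = simulate_cohort(3, "study", seed=11)
        for ra, rb in zip(a, b):
            assert ra.truth == rb.truth
            assert [i.score for i in ra.manual_items] == [i.score for i in rb.manual_items]

    def test_manual_sheet_consistent_with_target_total(self):
        for r in simulate_cohort(6, "study", seed=3):
            manual_sum = sum(i.score for i in r.manual_items)
            target = r.truth["fma_target_total"]
            assert manual_sum == int(np.clip(target - 6, 0, 60))
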