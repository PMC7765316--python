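"""Generator properties: periodicity, bounds, determinism, IMU consistency."""

import numpy as np
import pytest

from imuheat import (
    ACTIVITY_LABELS,
    GRAVITY,
    ActivitySpec,
    CohortConfig,
    MotionSequence,
    class_trajectory,
    default_activity_specs,
    imu_from_trajectory,
    load_cohort,
    make_cohort,
    save_cohort,
    subject_params,
)
from imuheat.calibration import CalibrationState, reconstruct_trajectory
from imuheat.synthetic import _REST, SubjectParams


def circle_spec(amplitude=0.3, frequency=0.5, aspect=1.0):
    return ActivitySpec("arm_circles", "planar-circle", amplitude, frequency,
                        np.eye(3), np.ones(6), aspect=aspect)


class TestClassTrajectory:
    @pytest.mark.parametrize("spec", default_activity_specs(), ids=lambda s: s.name)
    def test_periodic_families_repeat_after_one_period(self, spec):
        p0 = class_trajectory(spec, 0.0)
        p1 = class_trajectory(spec, 1.0 / spec.frequency)
        np.testing.assert_allclose(p0, p1, atol=1e-9)

    def test_linear_oscillation_stays_within_amplitude_box(self):
        spec = ActivitySpec("arm_raises", "linear-oscillation", 0.25, 0.7,
                            np.eye(3), [1, 1, 0, 0, 0.5, 0])
        t = np.linspace(0, 10, 1500)
        pos = class_trajectory(spec, t)
        for v in range(6):
            offsets = pos[:, v, :] - _REST[v]
            assert np.all(np.abs(offsets) <= spec.amplitude * spec.vertex_weights[v] + 1e-12)

    def test_circle_radius_matches_parametric_form(self):
        # r=0.3 m, f=0.5 Hz, 60 Hz for 2 s: distance to center is the radius
        spec = circle_spec(amplitude=0.3, frequency=0.5)
        t = np.arange(120) / 60.0
        pos = class_trajectory(spec, t)
        d = np.linalg.norm(pos[:, 0, :] - _REST[0], axis=1)
        np.testing.assert_allclose(d, 0.3, atol=1e-9)
        assert abs(d.mean() - 0.3) < 1e-9

    def test_deterministic_given_subject_params(self):
        spec = circle_spec()
        params = SubjectParams(amp_scale=1.1, phase=0.4)
        t = np.linspace(0, 3, 200)
        a = class_trajectory(spec, t, params)
        b = class_trajectory(spec, t, params)
        assert np.array_equal(a, b)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="motion_family"):
            ActivitySpec("arm_circles", "spiral", 0.3, 0.5, np.eye(3), np.ones(6))

    def test_invalid_spec_parameters_rejected(self):
        with pytest.raises(ValueError):
            ActivitySpec("arm_circles", "planar-circle", -0.1, 0.5, np.eye(3), np.ones(6))
        with pytest.raises(ValueError):
            ActivitySpec("arm_circles", "planar-circle", 0.3, 0.5, np.eye(3), np.full(6, 1.5))


class TestMakeCohort:
    def test_sequence_count_and_length(self):
        specs = default_activity_specs()[:3]
        cfg = CohortConfig(n_subjects=2, classes=specs, sampling_rate=60.0,
                           duration_per_class=10.0, seed=3)
        seqs = make_cohort(cfg)
        assert len(seqs) == 6
        assert all(s.n_frames == 600 for s in seqs)
        assert {s.subject_id for s in seqs} == {"s00", "s01"}

    def test_seed_determinism_is_bit_exact(self):
        cfg = CohortConfig(n_subjects=2, classes=default_activity_specs()[:2],
                           duration_per_class=5.0, seed=42)
        a, b = make_cohort(cfg), make_cohort(cfg)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.positions, sb.positions)

    def test_noise_sd_measured_on_positions(self):
        specs = default_activity_specs()[:1]
        base = CohortConfig(n_subjects=2, classes=specs, duration_per_class=30.0,
                            noise_sd=0.0, seed=5)
        noisy = CohortConfig(n_subjects=2, classes=specs, duration_per_class=30.0,
                             noise_sd=0.01, seed=5)
        diffs = np.concatenate([
            (a.positions - b.positions).ravel()
            for a, b in zip(make_cohort(noisy), make_cohort(base))
        ])
        assert diffs.size >= 10_000
        assert abs(diffs.std() - 0.01) < 5e-4

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError, match="n_subjects"):
            CohortConfig(n_subjects=1)

    def test_default_label_set(self):
        assert tuple(s.name for s in default_activity_specs()) == ACTIVITY_LABELS

    def test_roundtrip_through_disk(self, tmp_path, tiny_cohort):
        save_cohort(tiny_cohort, tmp_path)
        loaded = load_cohort(tmp_path)
        assert len(loaded) == len(tiny_cohort)
        for a, b in zip(tiny_cohort, loaded):
            assert np.array_equal(a.positions, b.positions)
            assert (a.subject_id, a.label) == (b.subject_id, b.label)


class TestClassSeparability:
    def test_between_class_distance_exceeds_within_class(self):
        cfg = CohortConfig(n_subjects=3, duration_per_class=10.0, noise_sd=0.0,
                           subject_variation=0.05, seed=9)
        seqs = make_cohort(cfg)
        flat = {}
        for s in seqs:
            flat.setdefault(s.label, []).append(s.positions.ravel())
        labels = list(flat)
        within, between = [], []
        for i, li in enumerate(labels):
            for a in range(len(flat[li])):
                for b in range(a + 1, len(flat[li])):
                    within.append(np.linalg.norm(flat[li][a] - flat[li][b]))
            for lj in labels[i + 1 :]:
                for xa in flat[li]:
                    for xb in flat[lj]:
                        between.append(np.linalg.norm(xa - xb))
        assert np.mean(between) > np.mean(within)


class TestImuFromTrajectory:
    def test_stationary_sensor_reads_gravity(self):
        pos = np.tile(_REST, (50, 1, 1))
        seq = MotionSequence(pos, "s00", "squats", 60.0)
        rec = imu_from_trajectory(seq)
        np.testing.assert_allclose(rec.acc, np.broadcast_to(GRAVITY, rec.acc.shape), atol=1e-9)

    def test_centripetal_magnitude_on_circle(self):
        spec = circle_spec(amplitude=0.3, frequency=0.5)
        t = np.arange(240) / 60.0
        seq = MotionSequence(class_trajectory(spec, t), "s00", "arm_circles", 60.0)
        rec = imu_from_trajectory(seq, gravity=np.zeros(3))
        omega = 2 * np.pi * spec.frequency
        mags = np.linalg.norm(rec.acc[1:-1], axis=2)
        np.testing.assert_allclose(mags, 0.3 * omega**2, rtol=1e-3)

    def test_too_few_frames_rejected(self):
        seq = MotionSequence(np.zeros((2, 6, 3)), "s00", "squats", 60.0)
        with pytest.raises(ValueError, match="3 frames"):
            imu_from_trajectory(seq)

    def test_velocity_tangent_frames_are_rotations(self):
        spec = circle_spec()
        t = np.arange(60) / 60.0
        seq = MotionSequence(class_trajectory(spec, t), "s00", "arm_circles", 60.0)
        rec = imu_from_trajectory(seq, orientation_model="velocity-tangent")
        R = rec.rot.reshape(-1, 3, 3)
        np.testing.assert_allclose(
            R @ R.transpose(0, 2, 1), np.broadcast_to(np.eye(3), R.shape), atol=1e-10
        )
        np.testing.assert_allclose(np.linalg.det(R), 1.0, atol=1e-10)

    @pytest.mark.parametrize("orientation_model", ["identity", "velocity-tangent"])
    def test_round_trip_recovers_noiseless_trajectory(self, orientation_model):
        spec = circle_spec(amplitude=0.3, frequency=0.5)
        t = np.arange(120) / 60.0
        pos = class_trajectory(spec, t)
        seq = MotionSequence(pos, "s00", "arm_circles", 60.0)
        rec = imu_from_trajectory(seq, orientation_model=orientation_model)
        recon = reconstruct_trajectory(rec, sensor=0, calib=CalibrationState(),
                                       x0=pos[0, 0], x1=pos[1, 0])
        err = np.linalg.norm(recon - pos[: recon.shape[0], 0], axis=1).max()
        dt, duration = 1.0 / 60.0, 2.0
        assert err <= 10.0 * dt**2 * duration**2

    def test_round_trip_error_shrinks_quadratically_with_dt(self):
        spec = circle_spec(amplitude=0.3, frequency=0.5)
        errs = []
        for rate in (30.0, 60.0, 120.0):
            t = np.arange(int(2 * rate)) / rate
            pos = class_trajectory(spec, t)
            seq = MotionSequence(pos, "s00", "arm_circles", rate)
            rec = imu_from_trajectory(seq, gravity=np.zeros(3))
            recon = reconstruct_trajectory(rec, sensor=0, calib=CalibrationState(g=np.zeros(3)),
                                           x0=pos[0, 0], x1=pos[1, 0])
            errs.append(np.linalg.norm(recon - pos[: recon.shape[0], 0], axis=1).max())
        for rate, err in zip((30.0, 60.0, 120.0), errs):
            assert err <= 10.0 * (1.0 / rate) ** 2 * 2.0**2
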