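"""Step detection, heading estimation/fusion and the localization bank."""

import numpy as np
import pytest

from imupipe.loc_features import (
    EulerAngles,
    HeadingState,
    LOCFeatureExtractor,
    acceleration_magnitude,
    detect_steps,
    estimate_step_intervals,
    euler_angles,
    extract_loc_features,
    fuse_heading,
    gyroscope_heading_step,
    heading_track,
    magnetometer_heading,
    wrap_angle,
)

FS = 40.0


class TestMagnitude:
    @pytest.mark.parametrize("vec,expected", [
        ((3.0, 4.0, 0.0), 5.0),
        ((0.0, 0.0, 0.0), 0.0),
        ((1.0, 1.0, 1.0), np.sqrt(3.0)),
    ])
    def test_closed_forms(self, vec, expected):
        acc = np.array(vec)[:, None]
        assert acceleration_magnitude(acc)[0] == pytest.approx(expected)

    def test_axis_mismatch_rejected(self):
        with pytest.raises(ValueError):
            acceleration_magnitude(np.ones((2, 10)))


def gait_magnitude(f=2.0, amp=2.0, offset=9.81, duration=10.0, fs=FS):
    t = np.arange(0, duration, 1 / fs)
    return offset + amp * np.sin(2 * np.pi * f * t)


class TestStepDetection:
    def test_two_hz_gait_gives_twenty_steps(self):
        ev = detect_steps(gait_magnitude(), FS)
        assert ev.n_steps == 20

    def test_intervals_are_half_second(self):
        mg = gait_magnitude()
        ev = estimate_step_intervals(mg, detect_steps(mg, FS), FS)
        iv = ev.step_intervals_s
        good = iv[np.isfinite(iv)]
        np.testing.assert_allclose(good, 0.5, atol=1.0 / FS)

    def test_boundary_peak_interval_absent(self):
        mg = gait_magnitude()       # first peak has no left valley
        ev = estimate_step_intervals(mg, detect_steps(mg, FS), FS)
        assert np.isnan(ev.step_intervals_s[0])
        assert np.isfinite(ev.step_intervals_s[1:]).all()

    def test_constant_signal_no_steps(self):
        ev = detect_steps(np.full(400, 9.81), FS)
        assert ev.n_steps == 0

    def test_amplitude_scale_invariance_exact(self):
        mg = gait_magnitude()
        a = detect_steps(mg, FS)
        b = detect_steps(mg * 7.3, FS)
        np.testing.assert_array_equal(a.peak_indices, b.peak_indices)

    def test_single_bump_single_step(self):
        t = np.arange(0, 10, 1 / FS)
        mg = 5.0 + 5.0 * np.exp(-((t - 5.0) ** 2) / (2 * 0.2 ** 2))
        ev = detect_steps(mg, FS)
        assert ev.n_steps == 1
        ev = estimate_step_intervals(mg, ev, FS)
        # valleys of the noiseless bump sit at the flat shoulders
        assert np.isfinite(ev.step_intervals_s[0])

    def test_peaks_strictly_increasing_between_valleys(self):
        mg = gait_magnitude()
        ev = estimate_step_intervals(mg, detect_steps(mg, FS), FS)
        assert np.all(np.diff(ev.peak_indices) > 0)
        for p, (l, r) in zip(ev.peak_indices, ev.valley_pairs):
            if l is not None:
                assert l < p
            if r is not None:
                assert r > p


class TestEulerAngles:
    def test_level_device_north_field(self):
        e = euler_angles((0, 0, 1), (1, 0, 0))
        assert (e.roll, e.pitch, e.yaw) == pytest.approx((0, 0, 0))

    def test_ninety_degree_roll(self):
        e = euler_angles((0, 1, 0), (1, 0, 0))
        assert e.roll == pytest.approx(np.pi / 2)
        assert e.pitch == pytest.approx(0.0)

    def test_level_device_east_field_yaw(self):
        e = euler_angles((0, 0, 1), (0, 1, 0))
        assert e.yaw == pytest.approx(np.pi / 2)

    def test_zero_acceleration_rejected(self):
        with pytest.raises(ValueError):
            euler_angles((0, 0, 0), (1, 0, 0))


class TestMagnetometerHeading:
    def test_north_aligned_zero(self):
        e = euler_angles((0, 0, 1), (1, 0, 0))
        assert magnetometer_heading(e, (1, 0, 0)) == pytest.approx(0.0)

    def test_east_field_quarter_turn(self):
        e = euler_angles((0, 0, 1), (0, 1, 0))
        assert magnetometer_heading(e, (0, 1, 0)) == pytest.approx(np.pi / 2)

    @pytest.mark.parametrize("alpha_deg", [30.0, 120.0, -45.0])
    def test_rotation_equivariance(self, alpha_deg):
        a = np.radians(alpha_deg)
        e = euler_angles((0, 0, 1), (np.cos(a), np.sin(a), 0))
        h = magnetometer_heading(e, (np.cos(a), np.sin(a), 0.0))
        assert h == pytest.approx(a, abs=1e-9)

    def test_vertical_field_flagged(self):
        e = EulerAngles(0.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            magnetometer_heading(e, (0, 0, 50))


class TestGyroHeading:
    def test_zero_rates_keep_identity(self):
        st = gyroscope_heading_step(HeadingState(), (0, 0, 0),
                                    EulerAngles(0, 0, 0), 0.01)
        assert st.h_gyro == pytest.approx(0.0)
        np.testing.assert_allclose(st.q, [1, 0, 0, 0], atol=1e-12)

    def test_constant_yaw_rate_integrates_to_one_radian(self):
        st = HeadingState()
        e = EulerAngles(0, 0, 0)
        for _ in range(1000):                     # 10 s at 100 Hz
            st = gyroscope_heading_step(st, (0, 0, 0.1), e, 0.01)
        assert st.h_gyro == pytest.approx(1.0, abs=0.02)

    @pytest.mark.parametrize("alpha", [np.pi / 6, np.pi / 2])
    def test_quaternion_to_yaw_closed_form(self, alpha):
        q = np.array([np.cos(alpha / 2), 0.0, 0.0, np.sin(alpha / 2)])
        st = gyroscope_heading_step(HeadingState(q=q), (0, 0, 0),
                                    EulerAngles(0, 0, 0), 0.01)
        assert st.h_gyro == pytest.approx(alpha)

    def test_norm_preserved_over_many_steps(self, rng):
        st = HeadingState()
        e = EulerAngles(0.1, 0.05, 0.0)
        for _ in range(10_000):
            st = gyroscope_heading_step(st, rng.normal(0, 0.5, 3), e, 0.01)
        assert abs(np.linalg.norm(st.q) - 1.0) < 1e-9

    def test_non_unit_quaternion_rejected(self):
        with pytest.raises(ValueError):
            HeadingState(q=np.array([1.0, 0.5, 0.0, 0.0]))


class TestFusion:
    def test_identity(self):
        assert fuse_heading(0.4, 0.4) == pytest.approx(0.4)

    def test_small_angle_mean(self):
        h = fuse_heading(np.radians(10), np.radians(20))
        assert np.degrees(h) == pytest.approx(15.0)

    def test_wraparound_mean(self):
        h = fuse_heading(np.radians(350), np.radians(10))
        assert np.degrees(h) == pytest.approx(0.0, abs=1e-9)

    def test_antipodal_falls_back_to_gyro(self):
        assert fuse_heading(0.0, np.pi) == pytest.approx(wrap_angle(np.pi))


class TestHeadingPipelineEquivariance:
    def _world(self, alpha, yaw_rate=0.05, duration=10.0, fs=100.0):
        n = int(duration * fs)
        t = np.arange(n) / fs
        yaw = alpha + yaw_rate * t
        acc = np.vstack([np.zeros(n), np.zeros(n), np.full(n, 9.81)])
        gyr = np.vstack([np.zeros(n), np.zeros(n), np.full(n, yaw_rate)])
        mag = np.vstack([22 * np.cos(yaw), 22 * np.sin(yaw), np.full(n, -42.0)])
        return acc, gyr, mag

    def test_world_rotation_shifts_all_headings(self):
        base = heading_track(*self._world(0.0), fs=100.0)
        alpha = np.radians(70.0)
        rot = heading_track(*self._world(alpha), fs=100.0)
        for key in ("h_mag", "h_gyro", "h_fused"):
            diff = wrap_angle(rot[key] - base[key] - alpha)
            assert np.max(np.abs(diff)) < 1e-3, key


class TestExtraction:
    def test_walking_stack_step_count(self, walking_stacks):
        fv = extract_loc_features(walking_stacks[0])
        vals = dict(zip(fv.layout, fv.values))
        assert vals["steps.count"] == pytest.approx(30, abs=2)
        assert vals["audio.present"] == 1.0
        assert vals["gps.available"] == 1.0

    def test_stationary_stack_no_steps_stable_heading(self, sitting_stacks):
        fv = extract_loc_features(sitting_stacks[0])
        vals = dict(zip(fv.layout, fv.values))
        assert vals["steps.count"] == 0.0
        assert vals["heading.circ_std"] < 0.1
        assert vals["gps.available"] == 0.0

    def test_identical_stacks_identical_vectors(self, walking_stacks):
        ext = LOCFeatureExtractor()
        a = ext.fit_transform([walking_stacks[1]])
        b = ext.fit_transform([walking_stacks[1]])
        np.testing.assert_array_equal(a, b)

    def test_missing_imu_channel_rejected(self, walking_stacks):
        import copy
        stack = copy.deepcopy(walking_stacks[0])
        for w in stack.windows:
            del w.samples["gyr"]
        with pytest.raises(ValueError, match="gyr"):
            LOCFeatureExtractor().fit_transform([stack])

    def test_missing_audio_gives_zeros_and_flag(self, walking_stacks):
        import copy
        stack = copy.deepcopy(walking_stacks[0])
        stack.audio = None
        fv = extract_loc_features(stack)
        vals = dict(zip(fv.layout, fv.values))
        assert vals["audio.present"] == 0.0
        assert all(vals[f"audio.mfcc{i:02d}"] == 0.0 for i in range(13))
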