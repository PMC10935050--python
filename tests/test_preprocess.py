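"""Orientation, ZUPT detection/refinement, stride segmentation, heel strike."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

import footpdr as fp
from footpdr import preprocess as pp
from footpdr._quat import quat_to_rotation, rotation_to_quat
from footpdr.exceptions import CalibrationError, ValidationError

G = 9.80665
DT = 1.0 / 128.0


def stationary_recording(n=512, gyro=(0.0, 0.0, 0.0), accel=None, dt=DT):
    accel = np.tile([0.0, 0.0, G] if accel is None else accel, (n, 1))
    return fp.ImuRecording(
        t=np.arange(n) * dt, accel=accel, gyro=np.tile(gyro, (n, 1)), dt=dt
    )


class TestGyroBias:
    def test_zero_gyro_gives_zero(self):
        rec = stationary_recording()
        np.testing.assert_array_equal(fp.estimate_gyro_bias(rec, (0, 256)), np.zeros(3))

    def test_constant_gyro_recovered_exactly(self):
        w0 = np.array([0.01, -0.02, 0.005])
        rec = stationary_recording(gyro=w0)
        np.testing.assert_allclose(fp.estimate_gyro_bias(rec, (0, 256)), w0, rtol=0, atol=1e-15)

    def test_noisy_gyro_mean_concentrates(self, rng):
        w0 = np.array([0.01, -0.02, 0.005])
        sigma = 0.002
        rec = stationary_recording(n=256)
        rec = fp.ImuRecording(rec.t, rec.accel, w0 + rng.normal(0, sigma, (256, 3)), rec.dt)
        est = fp.estimate_gyro_bias(rec, (0, 256))
        assert np.all(np.abs(est - w0) < 4 * sigma / np.sqrt(256))

    def test_short_window_rejected(self):
        rec = stationary_recording()
        with pytest.raises(CalibrationError):
            fp.estimate_gyro_bias(rec, (0, 64))

    def test_moving_window_rejected(self):
        rec = stationary_recording(gyro=(5.0, 0.0, 0.0))
        with pytest.raises(CalibrationError):
            fp.estimate_gyro_bias(rec, (0, 256))


class TestOrientation:
    def test_stationary_identity(self):
        rec = stationary_recording(n=256)
        ori = fp.estimate_orientation(rec, np.zeros(256, bool), [1, 0, 0, 0])
        np.testing.assert_allclose(ori.q, np.tile([1, 0, 0, 0], (256, 1)), atol=1e-12)

    def test_constant_yaw_rate_closed_form(self):
        # pi/2 rad/s about z for 1 s -> 90 degrees of yaw
        n = 129  # sample 0 plus 128 integration steps of dt
        rec = stationary_recording(n=n, gyro=(0.0, 0.0, np.pi / 2))
        ori = fp.estimate_orientation(rec, np.zeros(n, bool), [1, 0, 0, 0])
        expected = Rotation.from_euler("z", 90, degrees=True)
        err = (quat_to_rotation(ori.q[-1]).inv() * expected).magnitude()
        assert err < 1e-6

    def test_non_unit_q0_rejected(self):
        rec = stationary_recording(n=16)
        with pytest.raises(ValidationError):
            fp.estimate_orientation(rec, np.zeros(16, bool), [1, 1, 0, 0])

    def test_matches_generator_ground_truth(self, clean_single_stride):
        trial = clean_single_stride
        rec = trial.recording
        cfg = fp.PipelineConfig()
        refined = pp.refine_zupt(pp.detect_zupt(rec, cfg.ta, cfg.tw), rec.dt)
        ori = fp.estimate_orientation(rec, refined, trial.trajectory.q[0])
        est = ori.rotations
        true = quat_to_rotation(trial.trajectory.q)
        err = (est.inv() * true).magnitude()
        assert err.max() < 1e-3

    def test_norm_preserved_over_long_integration(self, rng):
        n = 100_000
        gyro = rng.normal(0, 0.5, (n, 3))
        rec = fp.ImuRecording(np.arange(n) * DT, np.tile([0, 0, G], (n, 1)), gyro, DT)
        ori = fp.estimate_orientation(rec, np.zeros(n, bool), [1, 0, 0, 0])
        assert np.abs(np.linalg.norm(ori.q, axis=1) - 1).max() < 1e-9

    def test_tilt_correction_restores_gravity_direction(self):
        # integrate a wrong initial tilt through a stance period: the gravity
        # correction must pull the world-frame mean force back to +z
        n = 512
        rec = stationary_recording(n=n)
        q0 = rotation_to_quat(Rotation.from_euler("y", 5, degrees=True))[0]
        mask = np.zeros(n, bool)
        mask[128:384] = True
        ori = fp.estimate_orientation(rec, mask, q0)
        f_end = quat_to_rotation(ori.q[-1]).apply([0, 0, G])
        assert abs(f_end[0]) < 1e-6 and f_end[2] == pytest.approx(G, rel=1e-9)



class TestDetectZupt:
    def test_stationary_all_true(self):
        rec = stationary_recording()
        assert fp.detect_zupt(rec, 0.4, 0.3).all()

    def test_stationary_true_for_any_positive_thresholds(self):
        rec = stationary_recording()
        for ta, tw in [(1e-6, 1e-6), (0.01, 0.01), (10, 10)]:
            assert fp.detect_zupt(rec, ta, tw).all()

    def test_swing_sample_false(self):
        rec = stationary_recording(gyro=(0.0, 5.0, 0.0))
        assert not fp.detect_zupt(rec, 0.4, 0.3).any()

    def test_matches_per_sample_formula(self, rng):
        n = 200
        accel = rng.normal(0, 5, (n, 3)) + [0, 0, G]
        gyro = rng.normal(0, 0.5, (n, 3))
        rec = fp.ImuRecording(np.arange(n) * DT, accel, gyro, DT)
        mask = fp.detect_zupt(rec, 0.4, 0.3)
        expected = np.array(
            [
                abs(np.linalg.norm(accel[k]) - G) < 0.4 and np.linalg.norm(gyro[k]) < 0.3
                for k in range(n)
            ]
        )
        np.testing.assert_array_equal(mask, expected)


def naive_refine(mask, dt, min_stance, min_swing, frac):
    """Independent reference implementation (pure python run scanning)."""
    m = list(mask)
    n = len(m)

    def runs(val):
        out, k = [], 0
        while k < n:
            if m[k] == val:
                j = k
                while j < n and m[j] == val:
                    j += 1
                out.append((k, j))
                k = j
            else:
                k += 1
        return out

    for a, b in runs(True):
        if (b - a) * dt < min_stance:
            for k in range(a, b):
                m[k] = False
    for a, b in runs(False):
        if a > 0 and b < n and (b - a) * dt < min_swing:
            for k in range(a, b):
                m[k] = True
    if frac < 1.0:
        for a, b in runs(True):
            length = b - a
            keep = max(1, int(np.floor(frac * length + 0.5)))
            drop = length - keep
            front = drop // 2
            for k in range(a, a + front):
                m[k] = False
            for k in range(b - (drop - front), b):
                m[k] = False
    return np.array(m, dtype=bool)


class TestRefineZupt:
    def test_central_80_of_100(self):
        mask = np.zeros(140, bool)
        mask[20:120] = True
        out = fp.refine_zupt(mask, DT, central_frac=0.8)
        expected = np.zeros(140, bool)
        expected[30:110] = True  # drop first 10 and last 10 of the 100-run
        np.testing.assert_array_equal(out, expected)

    def test_all_false_unchanged(self):
        mask = np.zeros(50, bool)
        np.testing.assert_array_equal(fp.refine_zupt(mask, DT), mask)

    def test_two_sample_run_removed(self):
        mask = np.zeros(100, bool)
        mask[40:42] = True
        assert not fp.refine_zupt(mask, DT, min_stance_dur=0.1).any()

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.lists(st.booleans(), min_size=1, max_size=300))
    def test_matches_naive_reference(self, bits):
        mask = np.array(bits, dtype=bool)
        got = fp.refine_zupt(mask, DT, 0.1, 0.2, 0.8)
        want = naive_refine(mask, DT, 0.1, 0.2, 0.8)
        np.testing.assert_array_equal(got, want)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.lists(st.booleans(), min_size=1, max_size=200))
    def test_smoothing_stages_idempotent(self, bits):
        # without the central trim, refinement is a projection
        mask = np.array(bits, dtype=bool)
        once = fp.refine_zupt(mask, DT, 0.1, 0.2, 1.0)
        twice = fp.refine_zupt(once, DT, 0.1, 0.2, 1.0)
        np.testing.assert_array_equal(once, twice)


class TestSegmentStrides:
    def test_single_run_gives_no_strides(self):
        assert fp.segment_strides(np.ones(50, bool)) == []

    def test_midpoint_boundaries(self):
        mask = np.zeros(120, bool)
        mask[0:10] = True
        mask[100:110] = True
        (stride,) = fp.segment_strides(mask)
        assert (stride.start_idx, stride.end_idx) == (5, 105)

    @pytest.mark.parametrize("k", [2, 3, 7])
    def test_k_runs_give_k_minus_1_strides(self, k):
        mask = np.zeros(40 * k, bool)
        for i in range(k):
            mask[40 * i : 40 * i + 12] = True
        strides = fp.segment_strides(mask)
        assert len(strides) == k - 1
        # disjoint, ordered half-open ranges
        for a, b in zip(strides[:-1], strides[1:]):
            assert a.end_idx == b.start_idx and a.start_idx < a.end_idx


class TestHeelStrike:
    @staticmethod
    def _stride(n=128, stance=20):
        mask = np.zeros(n, bool)
        mask[:stance] = True
        mask[-stance:] = True
        return fp.StrideSegment(0, n, zupt_mask=mask)

    def test_smooth_signal_gives_none(self):
        stride = self._stride()
        z = 0.5 * np.sin(np.linspace(0, 2 * np.pi, stride.N))
        assert fp.detect_heel_strike(z, stride) is None

    def test_single_spike_found(self):
        stride = self._stride()
        z = np.zeros(stride.N)
        z[42] = 30.0
        assert fp.detect_heel_strike(z, stride) == 42

    def test_first_of_two_spikes(self):
        stride = self._stride()
        z = np.zeros(stride.N)
        z[42] = 30.0
        z[60] = 40.0
        assert fp.detect_heel_strike(z, stride) == 42

    def test_stance_spikes_ignored(self):
        stride = self._stride()
        z = np.zeros(stride.N)
        z[5] = 50.0  # inside leading stance
        z[70] = 30.0
        assert fp.detect_heel_strike(z, stride) == 70

    def test_generator_impulse_located_exactly(self):
        from conftest import single_level_trial, stride_pieces_with_truth

        trial = single_level_trial(dv=0.2, seed=5)
        seg, aw, *_ = stride_pieces_with_truth(trial)
        khs = fp.detect_heel_strike(aw[:, 2], seg)
        assert khs == trial.khs[0]
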