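"""Accumulator matrices, stride integration and the bias/impulse solves."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import footpdr as fp
from footpdr import error_model as em
from footpdr.exceptions import (
    MissingHeelStrikeError,
    SingularSystemError,
    ValidationError,
)
from conftest import recover_full, single_level_trial, stride_pieces_with_truth

DT = 1.0 / 128.0


def identity_rotations(n):
    return np.tile(np.eye(3), (n, 1, 1))


class TestAccumulateB:
    def test_identity_rotations_closed_form(self):
        n = 10_000
        B = em.accumulate_B(identity_rotations(n))
        k = np.arange(1, n + 1)
        np.testing.assert_allclose(B.Bv, k[:, None, None] * np.eye(3), rtol=0, atol=0)
        np.testing.assert_allclose(B.Bp, (k**2 / 2.0)[:, None, None] * np.eye(3), rtol=0, atol=1e-9)

    def test_first_sample_values(self):
        r = Rotation.random(1, rng=np.random.default_rng(3)).as_matrix()
        B = em.accumulate_B(r)
        np.testing.assert_allclose(B.Bv[0], r[0], atol=0)
        np.testing.assert_allclose(B.Bp[0], 0.5 * r[0], atol=0)

    def test_iterative_equals_direct_sums_on_random_rotations(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 200))
            r = Rotation.random(n, rng=rng).as_matrix()
            B = em.accumulate_B(r)
            # brute-force direct summation oracle
            bv_direct = np.zeros((n, 3, 3))
            bp_direct = np.zeros((n, 3, 3))
            for k in range(n):
                bv_direct[k] = r[: k + 1].sum(axis=0)
                bp_direct[k] = sum(bv_direct[i] - 0.5 * r[i] for i in range(k + 1))
            assert np.abs(B.Bv - bv_direct).max() < 1e-10
            assert np.abs(B.Bp - bp_direct).max() < 1e-10

    def test_non_orthonormal_rejected(self):
        bad = identity_rotations(3)
        bad[1] *= 1.01
        with pytest.raises(ValidationError):
            em.accumulate_B(bad)


class TestIntegrateStride:
    def test_zero_accel_all_zero(self):
        traj, res = em.integrate_stride(np.zeros((50, 3)), DT)
        assert not traj.p.any() and not traj.v.any()
        assert res.h_residual == 0.0 and not res.v_residual.any()

    def test_constant_accel_closed_form(self):
        n = 64
        a = np.tile([1.0, 0.0, 0.0], (n, 1))
        traj, res = em.integrate_stride(a, DT)
        assert res.v_residual[0] == pytest.approx(n * DT, rel=1e-12)
        assert traj.p[-1, 0] == pytest.approx(n**2 / 2.0 * DT**2, rel=1e-12)

    def test_velocity_zero_on_stance_and_residual_at_swing_end(self):
        n = 60
        a = np.tile([0.0, 0.0, 1.0], (n, 1))
        mask = np.zeros(n, bool)
        mask[:10] = True
        mask[-10:] = True
        traj, res = em.integrate_stride(a, DT, mask)
        assert not traj.v[:10].any() and not traj.v[-10:].any()
        assert res.N == 40
        assert res.v_residual[2] == pytest.approx(40 * DT)
        # position frozen through the trailing stance
        np.testing.assert_array_equal(traj.p[-10:], np.tile(traj.p[-11], (10, 1)))

    def test_residuals_match_model_prediction(self):
        # injected bias and impulse produce exactly Bv b dt - (0,0,dv) and the
        # model's height expression
        b = np.array([0.05, -0.1, 0.15])
        dv = 0.25
        trial = single_level_trial(b=b, dv=dv, seed=11)
        _, _, _, res, B, khs_model = stride_pieces_with_truth(trial)
        predicted_v = B.Bv_final @ b * trial.recording.dt - np.array([0, 0, dv])
        np.testing.assert_allclose(res.v_residual, predicted_v, atol=1e-9)
        predicted_h = (
            B.Bp_final[2] @ b * trial.recording.dt**2
            - (res.N - khs_model) * trial.recording.dt * dv
        )
        assert res.h_residual == pytest.approx(predicted_h, abs=1e-9)


class TestSolveFull:
    def test_zero_residuals_zero_solution(self):
        B = em.accumulate_B(identity_rotations(4))
        res = em.StrideResiduals(np.zeros(3), 0.0, 4, khs=3)
        sol = em.solve_full(res, B, 1.0)
        assert not sol.b.any() and sol.dv_hs == 0.0

    def test_worked_identity_example(self):
        # N=4, dt=1, khs=3: vertical rows are 4 b_z - dv = 1 and 8 b_z - dv = 1
        B = em.accumulate_B(identity_rotations(4))
        res = em.StrideResiduals(np.array([0.0, 0.0, 1.0]), 1.0, 4, khs=3)
        sol = em.solve_full(res, B, 1.0)
        np.testing.assert_allclose(sol.b, 0.0, atol=1e-12)
        assert sol.dv_hs == pytest.approx(-1.0, abs=1e-12)

    def test_khs_at_midpoint_is_singular(self):
        B = em.accumulate_B(identity_rotations(4))
        res = em.StrideResiduals(np.array([0.0, 0.0, 1.0]), 1.0, 4, khs=2)
        with pytest.raises(SingularSystemError):
            em.solve_full(res, B, 1.0)

    def test_missing_khs_rejected(self):
        B = em.accumulate_B(identity_rotations(4))
        res = em.StrideResiduals(np.zeros(3), 0.0, 4, khs=None)
        with pytest.raises(MissingHeelStrikeError):
            em.solve_full(res, B, 1.0)

    def test_recovers_injected_parameters(self):
        b = np.array([-0.12, 0.07, 0.18])
        dv = -0.4
        trial = single_level_trial(b=b, dv=dv, seed=21)
        sol = recover_full(trial)
        assert np.linalg.norm(sol.b - b) / np.linalg.norm(b) < 0.01
        assert abs(sol.dv_hs - dv) / abs(dv) < 0.01

    def test_scaling_residuals_by_C_scales_solution(self):
        trial = single_level_trial(b=(0.1, 0.0, -0.05), dv=0.3, seed=31)
        _, _, _, res, B, khs_model = stride_pieces_with_truth(trial)
        res = replace(res, khs=khs_model)
        dt = trial.recording.dt
        full = em.solve_full(res, B, dt)
        half = em.solve_full(res.scaled(0.5), B, dt)
        np.testing.assert_array_equal(half.b, 0.5 * full.b)  # bit-exact for C=1/2
        assert half.dv_hs == 0.5 * full.dv_hs
        zero = em.solve_full(res.scaled(0.0), B, dt)
        assert not zero.b.any() and zero.dv_hs == 0.0


class TestSolveReduced:
    def test_zero_residual_zero_bias(self):
        B = em.accumulate_B(identity_rotations(8))
        sol = em.solve_reduced(em.StrideResiduals(np.zeros(3), 0.0, 8), B, DT)
        assert not sol.b.any() and sol.dv_hs == 0.0 and sol.mode == "reduced"

    def test_identity_rotations_formula(self):
        n = 8
        B = em.accumulate_B(identity_rotations(n))
        v_res = np.array([0.4, -0.2, 0.1])
        sol = em.solve_reduced(em.StrideResiduals(v_res, 0.0, n), B, DT)
        np.testing.assert_allclose(sol.b, v_res / (n * DT), rtol=1e-12)

    def test_recovers_bias_without_impulse(self):
        b = np.array([0.1, -0.15, 0.08])
        trial = single_level_trial(b=b, dv=0.0, seed=41)
        _, _, _, res, B, _ = stride_pieces_with_truth(trial)
        sol = em.solve_reduced(res, B, trial.recording.dt)
        assert np.linalg.norm(sol.b - b) / np.linalg.norm(b) < 1e-6


class TestCorrectStride:
    def test_zero_solution_identical_to_raw(self, rng):
        n = 80
        a = rng.normal(0, 3, (n, 3))
        mask = np.zeros(n, bool)
        mask[:12] = True
        mask[-12:] = True
        raw, _ = em.integrate_stride(a, DT, mask)
        corr = em.correct_stride(
            a, identity_rotations(n), em.ErrorSolution(np.zeros(3), 0.0, "full"), 40, DT, mask
        )
        np.testing.assert_array_equal(corr.p, raw.p)
        np.testing.assert_array_equal(corr.v, raw.v)

    def test_full_solution_zeroes_end_state(self):
        trial = single_level_trial(b=(0.08, -0.1, 0.12), dv=0.35, seed=51)
        seg, aw, rotmats, res, B, khs_model = stride_pieces_with_truth(trial)
        sol = em.solve_full(replace(res, khs=khs_model), B, trial.recording.dt)
        refined_slice = seg.mask_slice()
        khs_local = int(trial.khs[0]) - seg.start_idx
        corr = em.correct_stride(
            aw[seg.slice], rotmats[seg.slice], sol, khs_local, trial.recording.dt, refined_slice
        )
        assert np.linalg.norm(corr.v[-1]) <= 1e-9
        assert abs(corr.p[-1, 2]) <= 1e-9

    def test_velocity_jump_equals_impulse(self):
        n = 60
        a = np.zeros((n, 3))
        sol = em.ErrorSolution(np.zeros(3), 0.5, "full")
        corr = em.correct_stride(a, identity_rotations(n), sol, 30, DT)
        # zero acceleration: the only velocity change is the impulse at khs
        assert corr.v[30, 2] - corr.v[29, 2] == pytest.approx(0.5, abs=0)
        assert not corr.v[:30].any()

    def test_impulse_without_khs_rejected(self):
        sol = em.ErrorSolution(np.zeros(3), 0.2, "full")
        with pytest.raises(MissingHeelStrikeError):
            em.correct_stride(np.zeros((20, 3)), identity_rotations(20), sol, None, DT)


class TestLinearity:
    def test_doubling_bias_doubles_velocity_difference(self, rng):
        r = Rotation.random(100, rng=rng).as_matrix()
        B = em.accumulate_B(r)
        b = np.array([0.03, -0.02, 0.05])
        dv1 = B.Bv_final @ b * DT
        dv2 = B.Bv_final @ (2 * b) * DT
        np.testing.assert_array_equal(dv2, 2 * dv1)

    def test_residual_superposition(self):
        b = np.array([0.06, -0.09, 0.11])
        dv = 0.2
        r_bias = stride_pieces_with_truth(single_level_trial(b=b, dv=0.0, seed=61))[3]
        r_imp = stride_pieces_with_truth(single_level_trial(b=(0, 0, 0), dv=dv, seed=61))[3]
        r_both = stride_pieces_with_truth(single_level_trial(b=b, dv=dv, seed=61))[3]
        np.testing.assert_allclose(
            r_both.v_residual, r_bias.v_residual + r_imp.v_residual, atol=1e-9
        )
        assert r_both.h_residual == pytest.approx(
            r_bias.h_residual + r_imp.h_residual, abs=1e-9
        )
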