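"""Shared fixtures and closed-loop helpers."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

import footpdr as fp
from footpdr import error_model as em
from footpdr import preprocess as pp

GRAVITY = 9.80665


def single_level_trial(
    b=(0.0, 0.0, 0.0),
    dv=0.0,
    seed=0,
    accel_sigma=0.0,
    gyro_sigma=0.0,
    gyro_bias=(0.0, 0.0, 0.0),
) -> fp.TrialData:
    """One level stride with explicit injected errors."""
    spec = fp.SyntheticTrialSpec(
        strides=[fp.level_stride()],
        b_true=np.asarray(b, float),
        gyro_bias_true=np.asarray(gyro_bias, float),
        dv_hs_true=[dv],
        accel_noise_sigma=accel_sigma,
        gyro_noise_sigma=gyro_sigma,
        seed=seed,
    )
    return fp.generate_trial(spec)


def stride_pieces_with_truth(trial: fp.TrialData, stride_index: int = 0):
    """Raw integration pieces of one stride using ground-truth orientation.

    Returns (segment, world_accel, rotation_matrices, residuals,
    accumulators, khs_model) with khs taken from the generator.
    """
    rec = trial.recording
    cfg = fp.PipelineConfig()
    mask = pp.detect_zupt(rec, cfg.ta, cfg.tw, cfg.gravity)
    refined = pp.refine_zupt(mask, rec.dt, cfg.min_stance_dur, cfg.min_swing_dur, cfg.central_frac)
    ori = fp.OrientationSeries(trial.trajectory.q)
    aw = pp.world_accel(rec, ori, None, cfg.gravity)
    seg = pp.segment_strides(refined)[stride_index]
    traj, res = em.integrate_stride(aw[seg.slice], rec.dt, refined[seg.slice])
    rotmats = ori.matrices()
    r_sub = rotmats[seg.start_idx + res.sub_start : seg.start_idx + res.sub_end]
    B = em.accumulate_B(r_sub)
    khs_model = int(trial.khs[stride_index]) - seg.start_idx - res.sub_start + 1
    return seg, aw, rotmats, res, B, khs_model


def recover_full(trial: fp.TrialData):
    """Full-model solution of the first stride with truth orientation/khs."""
    _, _, _, res, B, khs_model = stride_pieces_with_truth(trial)
    return em.solve_full(replace(res, khs=khs_model), B, trial.recording.dt)


@pytest.fixture(scope="session")
def noiseless_mixed():
    """Default mixed route, zero sensor noise, reconstructed once."""
    trial = fp.generate_trial(
        fp.default_mixed_trial(seed=7, accel_noise_sigma=0.0, gyro_noise_sigma=0.0)
    )
    trajectory, reports = fp.reconstruct_trial(trial.recording)
    return trial, trajectory, reports


@pytest.fixture(scope="session")
def clean_single_stride():
    """Single level stride with no corruption at all."""
    return single_level_trial()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
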