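"""End-to-end trial reconstruction.

Pipeline per trial: gyro-bias calibration → orientation estimation (or an
external quaternion stream) → world-frame acceleration → stance detection and
stride segmentation → per-stride raw integration and accumulator build-up →
terrain determination (full solve on every stride) → per-stride final solve
(full on level ground, reduced on ramps/stairs) → corrected re-integration,
chained into one continuous world trajectory.

Strides are mutually independent given the trial-wide orientation and
baseline, so everything after segmentation is a simple per-stride loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np

from . import error_model as em
from . import preprocess as pp
from . import terrain as tr
from ._quat import align_to_z, rotation_to_quat
from .exceptions import ConfigurationError, SingularSystemError, ValidationError
from .io_gait import ImuRecording, PipelineConfig, Trajectory
from .preprocess import OrientationSeries, StrideSegment

__all__ = ["StrideReport", "reconstruct_trial", "stride_geometry"]


@dataclass
class StrideReport:
    """Everything reported about one reconstructed stride."""

    stride_id: int
    segment: StrideSegment
    solution: em.ErrorSolution
    label: tr.TerrainLabel
    residuals: em.StrideResiduals
    stride_length: float
    height_change: float
    max_relative_height: float
    flags: List[str] = field(default_factory=list)

    @property
    def start_idx(self) -> int:
        return self.segment.start_idx

    @property
    def end_idx(self) -> int:
        return self.segment.end_idx

    @property
    def khs_idx(self) -> Optional[int]:
        return self.segment.khs_idx


def stride_geometry(trajectory: Trajectory, stride: StrideSegment) -> Tuple[float, float, float, float]:
    """(stride_length, height_change, max_relative_height, forward_distance).

    Stride length is the horizontal Euclidean start→end distance (also used
    as the forward distance by the terrain cleanup); height change is
    p_z(end) - p_z(start); max relative height is the peak elevation above
    the start.
    """
    if stride.N < 2:
        raise ValidationError("stride needs at least 2 samples")
    p = trajectory.p[stride.slice]
    delta = p[-1] - p[0]
    length = float(np.hypot(delta[0], delta[1]))
    height = float(delta[2])
    max_rel = float(np.max(p[:, 2]) - p[0, 2])
    return length, height, max_rel, length


def _initial_tilt(recording: ImuRecording, window: Optional[Tuple[int, int]]) -> np.ndarray:
    """Initial world-from-sensor quaternion from the lead-in stationary
    window: tilt aligning the mean specific force with +z, heading zero."""
    if window is None:
        return np.array([1.0, 0.0, 0.0, 0.0])
    a, b = window
    f_mean = recording.accel[a:b].mean(axis=0)
    return rotation_to_quat(align_to_z(f_mean))[0]


def _integrate_all(aw, rotmats, strides, dt, refined, hs_threshold):
    """Raw integration, accumulators and heel-strike detection per stride."""
    raw_trajs, residuals, accums = [], [], []
    strides_out = []
    for seg in strides:
        sl = seg.slice
        traj, res = em.integrate_stride(aw[sl], dt, refined[sl])
        B = em.accumulate_B(rotmats[seg.start_idx + res.sub_start : seg.start_idx + res.sub_end])
        khs = pp.detect_heel_strike(aw[:, 2], seg, hs_threshold)
        if khs is not None:
            lo = seg.start_idx + res.sub_start
            hi = seg.start_idx + res.sub_end
            if not lo < khs < hi - 1:
                khs = None  # impact glitch outside the usable swing range
        strides_out.append(replace(seg, khs_idx=khs))
        raw_trajs.append(traj)
        residuals.append(res)
        accums.append(B)
    return strides_out, raw_trajs, residuals, accums


def _model_khs(seg: StrideSegment, res: em.StrideResiduals) -> Optional[int]:
    """Trial-global heel-strike index → 1-based model index in the sub-range."""
    if seg.khs_idx is None:
        return None
    return seg.khs_idx - seg.start_idx - res.sub_start + 1


def _terrain_labels(strides, raw_trajs, residuals, accums, dt, cfg):
    """Algorithm-style terrain determination: full solve on every stride
    (average heel-strike timing substituted where undetected), threshold
    against the trial baseline, then geometry/consecutiveness cleanup."""
    with_khs = tr.assign_default_khs(strides)
    solutions = []
    flags: List[List[str]] = [[] for _ in strides]
    for j, (seg, res, B) in enumerate(zip(with_khs, residuals, accums)):
        khs_model = _model_khs(seg, res)
        khs_model = min(max(khs_model, 1), res.N)
        try:
            solutions.append(em.solve_full(replace(res, khs=khs_model), B, dt))
        except SingularSystemError:
            flags[j].append("terrain_full_singular")
            solutions.append(em.solve_reduced(res, B, dt))
    labels = tr.classify_strides(solutions, cfg)
    geometry = []
    for seg, traj in zip(strides, raw_trajs):
        length, dh, _, fwd = stride_geometry(traj, replace(seg, start_idx=0, end_idx=seg.N, khs_idx=None))
        geometry.append((fwd, dh))
    labels = tr.cleanup_labels(labels, geometry, cfg)
    return labels, flags


def _final_solution(label, seg, res, B, dt, cfg, flags):
    """Per-stride reconstruction solve (Algorithm-2 branch): level strides get
    the full model, ramps/stairs the reduced one; residuals are scaled by C
    first; failures degrade gracefully toward no correction."""
    scaled = res.scaled(cfg.C)
    khs_model = _model_khs(seg, res)
    if label.terrain is tr.Terrain.LEVEL and khs_model is not None:
        try:
            return em.solve_full(replace(scaled, khs=khs_model), B, dt)
        except SingularSystemError:
            flags.append("full_solve_singular")
    elif label.terrain is tr.Terrain.LEVEL:
        flags.append("no_heel_strike_reduced_fallback")
    try:
        return em.solve_reduced(scaled, B, dt)
    except SingularSystemError:
        flags.append("reduced_solve_singular_raw_fallback")
        return em.ErrorSolution(b=np.zeros(3), dv_hs=0.0, mode="raw")


def reconstruct_trial(
    recording: ImuRecording,
    config: Optional[PipelineConfig] = None,
    external_orientation: Optional[np.ndarray] = None,
    no_terrain: bool = False,
) -> Tuple[Trajectory, List[StrideReport]]:
    """Reconstruct a whole trial into a drift-corrected world trajectory.

    Parameters
    ----------
    recording : ImuRecording
    config : PipelineConfig, optional
    external_orientation : (N, 4) array, optional
        Scalar-first world-from-sensor quaternions from any external
        orientation algorithm, bypassing the internal estimator.
    no_terrain : bool
        Skip terrain determination and reconstruct every stride with the
        reduced (bias-only) model.

    Returns
    -------
    trajectory : Trajectory
        Continuous per-sample world path; velocity is zero over refined
        stance samples and each stride starts where the previous one ended.
    reports : list of StrideReport
    """
    cfg = config or PipelineConfig()
    cfg.validate()
    dt = recording.dt

    raw_mask = pp.detect_zupt(recording, cfg.ta, cfg.tw, cfg.gravity)
    window = None
    for a, b in pp.true_runs(raw_mask):
        if (b - a) * dt >= 1.0:
            window = (a, b if (b - a) * dt <= 2.0 else a + int(round(2.0 / dt)))
            break
    if window is not None:
        gyro_bias = pp.estimate_gyro_bias(recording, window, cfg)
        rec = recording.with_gyro_bias_removed(gyro_bias)
    else:
        rec = recording

    mask = pp.detect_zupt(rec, cfg.ta, cfg.tw, cfg.gravity)
    refined = pp.refine_zupt(mask, dt, cfg.min_stance_dur, cfg.min_swing_dur, cfg.central_frac)

    if external_orientation is not None:
        orientation = OrientationSeries(external_orientation)
        if len(orientation) != rec.n:
            raise ValidationError("external orientation must be sample-aligned")
    else:
        q0 = _initial_tilt(rec, window)
        orientation = pp.estimate_orientation(rec, refined, q0, cfg.gravity)

    aw = pp.world_accel(rec, orientation, None, cfg.gravity)
    rotmats = orientation.matrices()
    strides = pp.segment_strides(refined)

    t = recording.t
    if not strides:
        traj = Trajectory(
            t=t,
            p=np.zeros((rec.n, 3)),
            v=np.zeros((rec.n, 3)),
            q=orientation.q,
            stride_id=np.full(rec.n, -1),
        )
        return traj, []

    strides, raw_trajs, residuals, accums = _integrate_all(
        aw, rotmats, strides, dt, refined, cfg.hs_peak_threshold
    )

    if no_terrain:
        labels = None
        terrain_flags: List[List[str]] = [[] for _ in strides]
    else:
        try:
            labels, terrain_flags = _terrain_labels(strides, raw_trajs, residuals, accums, dt, cfg)
        except ConfigurationError:
            # no heel strike anywhere: terrain cannot be determined
            labels = None
            terrain_flags = [["terrain_unavailable"] for _ in strides]

    p_all = np.zeros((rec.n, 3))
    v_all = np.zeros((rec.n, 3))
    sid = np.full(rec.n, -1)
    offset = np.zeros(3)
    reports: List[StrideReport] = []
    for j, (seg, res, B) in enumerate(zip(strides, residuals, accums)):
        flags = list(terrain_flags[j])
        if labels is None:
            # no terrain information: reconstruct conservatively (reduced model)
            label = tr.TerrainLabel.level()
            solution = _final_solution(tr.TerrainLabel.ramp(), seg, res, B, dt, cfg, flags)
        else:
            label = labels[j]
            solution = _final_solution(label, seg, res, B, dt, cfg, flags)
        khs_local = None if seg.khs_idx is None else seg.khs_idx - seg.start_idx
        corrected = em.correct_stride(
            aw[seg.slice], rotmats[seg.slice], solution, khs_local, dt, refined[seg.slice]
        )
        sl = seg.slice
        p_all[sl] = corrected.p + offset
        v_all[sl] = corrected.v
        sid[sl] = j
        offset = p_all[seg.end_idx - 1].copy()
        if seg.end_idx < rec.n:
            p_all[seg.end_idx :] = offset  # carried forward until the next stride overwrites
        reports.append((seg, res, solution, label, flags))

    trajectory = Trajectory(t=t, p=p_all, v=v_all, q=orientation.q, stride_id=sid)

    out: List[StrideReport] = []
    for j, (seg, res, solution, label, flags) in enumerate(reports):
        length, dh, max_rel, _ = stride_geometry(trajectory, seg)
        out.append(
            StrideReport(
                stride_id=j,
                segment=seg,
                solution=solution,
                label=label,
                residuals=res,
                stride_length=length,
                height_change=dh,
                max_relative_height=max_rel,
                flags=flags,
            )
        )
    return trajectory, out
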