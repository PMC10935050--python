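"""Synthetic foot-mounted IMU walking trials with exact discrete ground truth.

The generator emulates the signal structure the reconstruction pipeline
feeds on — foot-flat stance (near-zero motion), swing (large accelerations
and pitch rotation), and a heel-strike impact whose velocity content is
partially lost — on level ground, ramps (default 3.7 deg incline) and stairs
(default 0.15 m risers, two per steady stride).

Ground truth lives on the *discrete* kinematic model: velocity samples are
drawn from smooth quintic swing profiles and positions are defined by the
same forward recursion the reconstruction uses (trapezoidal in velocity),
with the vertical profile rescaled so the discrete end height equals the
commanded height change exactly.  Sensor streams are then synthesised by
inverting the measurement model, so that with zero corruption the pipeline
reproduces the truth to machine precision and every injected error term maps
onto the error model without discretisation leakage.

Corruption terms (all configurable):

* constant sensor-frame acceleration bias ``b_true``,
* per-stride heel-strike vertical velocity loss ``dv_hs`` — realised as an
  acceleration deficit split over samples (khs, khs+1) whose discrete
  end-velocity and end-position effects equal the instantaneous impulse of
  the error model exactly (``impulse_mode="single"`` puts the whole deficit
  on khs, which adds a half-sample position side-effect),
* constant gyroscope bias, and
* white Gaussian accelerometer / gyroscope noise.

By default only level strides carry a heel-strike loss (mean 0.1 m/s): the
reduced model used on ramps and stairs treats the impulse as unobservable,
so the default study conditions keep it out of those strides; set
``dv_hs_ramp``/``dv_hs_stair`` to exercise the mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from ._quat import enforce_sign_continuity, quat_to_rotation
from .evaluation import TerrainSegmentTruth
from .exceptions import StrideSpecError, ValidationError
from .io_gait import ImuRecording, Trajectory
from .terrain import Terrain, TerrainLabel

__all__ = [
    "SyntheticStrideSpec",
    "SyntheticTrialSpec",
    "StrideGroundTruth",
    "TrialData",
    "generate_stride",
    "corrupt_to_imu",
    "generate_trial",
    "level_stride",
    "ramp_stride",
    "stair_stride",
    "mixed_route",
    "default_mixed_trial",
]

GRAVITY = 9.80665


@dataclass(frozen=True)
class SyntheticStrideSpec:
    """Geometry and timing of one synthetic stride.

    ``height_change`` is signed (positive = ascent); ``hs_fraction`` places
    the heel strike at that fraction of the swing; ``clearance`` is the
    mid-swing foot lift above the start height.
    """

    terrain: TerrainLabel
    stride_length: float
    height_change: float
    clearance: float = 0.05
    stance_dur: float = 0.6
    swing_dur: float = 0.5
    hs_fraction: float = 0.92
    pitch_amplitude: float = 0.5  # rad, swing plantar/dorsiflexion excursion

    def __post_init__(self) -> None:
        if self.stance_dur <= 0 or self.swing_dur <= 0:
            raise StrideSpecError("stance and swing durations must be positive")
        if self.stride_length <= 0:
            raise StrideSpecError("stride length must be positive")
        if abs(self.height_change) >= self.stride_length:
            raise StrideSpecError("|height change| must be smaller than the stride length")
        if not 0.0 < self.hs_fraction < 1.0:
            raise StrideSpecError("hs_fraction must lie strictly inside (0, 1)")


def level_stride(stride_length: float = 1.3, **kw) -> SyntheticStrideSpec:
    return SyntheticStrideSpec(TerrainLabel.level(), stride_length, 0.0, **kw)


def ramp_stride(
    stride_length: float = 1.4,
    incline_deg: float = 3.7,
    ascending: bool = True,
    **kw,
) -> SyntheticStrideSpec:
    height = stride_length * np.tan(np.radians(incline_deg))
    return SyntheticStrideSpec(
        TerrainLabel.ramp(ascending), stride_length, height if ascending else -height, **kw
    )


def stair_stride(
    riser: float = 0.15,
    n_risers: int = 2,
    ascending: bool = True,
    stride_length: float = 0.55,
    **kw,
) -> SyntheticStrideSpec:
    height = riser * n_risers
    return SyntheticStrideSpec(
        TerrainLabel.stair(ascending), stride_length, height if ascending else -height, **kw
    )


@dataclass
class SyntheticTrialSpec:
    """A full trial: stride sequence plus the injected sensor error terms."""

    strides: Sequence[SyntheticStrideSpec]
    b_true: np.ndarray = field(default_factory=lambda: np.array([0.04, -0.03, 0.05]))
    gyro_bias_true: np.ndarray = field(default_factory=lambda: np.array([0.002, -0.001, 0.0015]))
    dv_hs_true: Optional[Sequence[float]] = None  # explicit per-stride values, else drawn
    dv_hs_level_mean: float = 0.1
    dv_hs_level_sd: float = 0.02
    dv_hs_ramp: float = 0.0
    dv_hs_stair: float = 0.0
    accel_noise_sigma: float = 0.02
    gyro_noise_sigma: float = 0.002
    fs: float = 128.0
    seed: int = 0
    lead_dur: float = 2.0
    tail_dur: float = 1.0
    impulse_mode: str = "split"  # "split" (model-exact) or "single"

    def __post_init__(self) -> None:
        if not self.strides:
            raise StrideSpecError("trial needs at least one stride")
        if self.fs <= 0:
            raise StrideSpecError("sampling rate must be positive")
        if self.accel_noise_sigma < 0 or self.gyro_noise_sigma < 0:
            raise StrideSpecError("noise sigmas must be non-negative")
        if self.impulse_mode not in ("split", "single"):
            raise StrideSpecError("impulse_mode must be 'split' or 'single'")
        self.b_true = np.asarray(self.b_true, dtype=float).reshape(3)
        self.gyro_bias_true = np.asarray(self.gyro_bias_true, dtype=float).reshape(3)
        if self.dv_hs_true is not None and len(self.dv_hs_true) != len(self.strides):
            raise StrideSpecError("dv_hs_true must give one value per stride")


@dataclass
class StrideGroundTruth:
    """Discrete ground truth of one stride block (stance samples then swing)."""

    spec: SyntheticStrideSpec
    v: np.ndarray  # (n, 3) world velocity
    q: np.ndarray  # (n, 4) scalar-first world-from-sensor quaternions
    p: np.ndarray  # (n, 3) positions by the discrete recursion, start at 0
    khs_rel: int  # heel-strike sample index within the block
    n_stance: int
    n_swing: int


@dataclass
class TrialData:
    """Everything the closed-loop tests need about one generated trial."""

    recording: ImuRecording
    trajectory: Trajectory  # ground-truth world trajectory
    labels: List[TerrainLabel]
    dv_hs: np.ndarray  # injected per-stride impulse, m/s
    khs: np.ndarray  # trial-global heel-strike sample per stride
    b_true: np.ndarray
    gyro_bias_true: np.ndarray
    stride_heights: np.ndarray  # commanded signed height change per stride
    stride_lengths: np.ndarray
    swing_ranges: List[Tuple[int, int]]  # trial-global [start, end) of each swing
    segments: List[TerrainSegmentTruth]
    spec: SyntheticTrialSpec


def _trapz_end(v: np.ndarray, dt: float) -> float:
    """End value of the discrete recursion p(k) = p(k-1) + (v(k)+v(k-1)) dt/2
    starting from rest before the first sample."""
    v_prev = np.concatenate([[0.0], v[:-1]])
    return float(np.sum(0.5 * (v + v_prev)) * dt)


def generate_stride(spec: SyntheticStrideSpec, dt: float) -> StrideGroundTruth:
    """Discrete ground truth for one stride: stance at rest, then swing.

    Swing velocities follow smooth quintic bell profiles (zero value and slope
    at both ends): the forward profile integrates (discretely) to exactly the
    stride length, and the vertical profile is a clearance arc plus a rise
    component rescaled so the discrete end height equals ``height_change``
    exactly.  Foot pitch swings through plantarflexion after toe-off and back
    to dorsiflexion before heel strike, returning to flat for stance.
    """
    n_st = max(1, int(round(spec.stance_dur / dt)))
    n_sw = int(round(spec.swing_dur / dt))
    if n_sw < 8:
        raise StrideSpecError("swing must span at least 8 samples")
    # tau in (0, 1]: the final swing sample has exactly zero velocity, so each
    # block's discrete displacement closes at the block boundary
    tau = np.arange(1, n_sw + 1) / n_sw

    bump = 30.0 * tau**2 * (1.0 - tau) ** 2  # integral 1 over tau in [0,1]
    v_fwd = bump / spec.swing_dur
    v_fwd *= spec.stride_length / _trapz_end(v_fwd, dt)

    # clearance arc: derivative of 64 tau^3 (1-tau)^3 (peak = clearance at
    # mid-swing; cubic edges keep the vertical acceleration continuous at
    # toe-off so the only sharp vertical transient is the heel-strike deficit)
    v_lift = (
        spec.clearance
        * 192.0
        * tau**2
        * (1.0 - tau) ** 2
        * (1.0 - 2.0 * tau)
        / spec.swing_dur
    )
    rise_shape = bump / spec.swing_dur
    alpha = (spec.height_change - _trapz_end(v_lift, dt)) / _trapz_end(rise_shape, dt)
    v_z = v_lift + alpha * rise_shape

    v = np.zeros((n_st + n_sw, 3))
    v[n_st:, 0] = v_fwd
    v[n_st:, 2] = v_z

    # pitch about world y: zero value/slope at swing ends, ~0.8*amplitude peak
    theta = np.zeros(n_st + n_sw)
    theta[n_st:] = -spec.pitch_amplitude * 4.0 * tau * (1.0 - tau) * np.sin(2.0 * np.pi * tau)
    q = np.zeros((n_st + n_sw, 4))
    q[:, 0] = np.cos(theta / 2.0)
    q[:, 2] = np.sin(theta / 2.0)

    v_prev = np.vstack([np.zeros(3), v[:-1]])
    p = np.cumsum(0.5 * (v + v_prev) * dt, axis=0)

    khs_rel = n_st + int(round(spec.hs_fraction * (n_sw - 1)))
    khs_rel = min(max(khs_rel, n_st + 1), n_st + n_sw - 3)
    return StrideGroundTruth(
        spec=spec, v=v, q=q, p=p, khs_rel=khs_rel, n_stance=n_st, n_swing=n_sw
    )


def corrupt_to_imu(
    vel: np.ndarray,
    quat: np.ndarray,
    dt: float,
    b_true: np.ndarray,
    gyro_bias_true: np.ndarray,
    accel_noise_sigma: float,
    gyro_noise_sigma: float,
    impulses: Sequence[Tuple[int, float]],
    rng: np.random.Generator,
    gravity: float = GRAVITY,
    impulse_mode: str = "split",
) -> Tuple[np.ndarray, np.ndarray]:
    """Invert the measurement model: ground-truth kinematics → sensor streams.

    The world acceleration is the exact discrete difference
    a_w(k) = (v(k) - v(k-1))/dt, so raw re-integration reproduces the truth
    bit-for-bit before corruption.  Sensor acceleration is
    R(k)^T (a_w(k) - g) + b + noise; the gyroscope is the exact rotation-vector
    difference of consecutive quaternions over dt, plus bias and noise.  Each
    (khs, dv) impulse removes a vertical-velocity area ``dv`` from the
    acceleration around the heel strike (see module docstring for the split).
    """
    v = np.atleast_2d(np.asarray(vel, dtype=float))
    n = len(v)
    rot = quat_to_rotation(quat)
    g_vec = np.array([0.0, 0.0, -gravity])

    v_prev = np.vstack([np.zeros(3), v[:-1]])
    a_w = (v - v_prev) / dt
    accel = rot.inv().apply(a_w - g_vec) + b_true

    omega = np.zeros((n, 3))
    omega[1:] = (rot[:-1].inv() * rot[1:]).as_rotvec() / dt
    gyro = omega + gyro_bias_true

    for khs, dv in impulses:
        if dv == 0.0:
            continue
        if not 0 < khs < n - 1:
            raise ValidationError("impulse sample must be strictly inside the trial")
        if impulse_mode == "single":
            accel[khs] -= rot[khs].inv().apply([0.0, 0.0, dv / dt])
        else:
            half = np.array([0.0, 0.0, dv / (2.0 * dt)])
            accel[khs] -= rot[khs].inv().apply(half)
            accel[khs + 1] -= rot[khs + 1].inv().apply(half)

    if accel_noise_sigma > 0:
        accel = accel + rng.normal(0.0, accel_noise_sigma, accel.shape)
    if gyro_noise_sigma > 0:
        gyro = gyro + rng.normal(0.0, gyro_noise_sigma, gyro.shape)
    return accel, gyro


def _draw_dv(spec: SyntheticTrialSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.dv_hs_true is not None:
        return np.asarray(spec.dv_hs_true, dtype=float)
    dv = np.empty(len(spec.strides))
    for i, s in enumerate(spec.strides):
        if s.terrain.terrain is Terrain.LEVEL:
            dv[i] = rng.normal(spec.dv_hs_level_mean, spec.dv_hs_level_sd)
        elif s.terrain.terrain is Terrain.RAMP:
            dv[i] = spec.dv_hs_ramp
        else:
            dv[i] = spec.dv_hs_stair
    return dv


def _truth_segments(specs: Sequence[SyntheticStrideSpec]) -> List[TerrainSegmentTruth]:
    segments: List[TerrainSegmentTruth] = []
    run_label, run_height = None, 0.0
    for s in specs:
        if run_label == s.terrain:
            run_height += s.height_change
        else:
            if run_label is not None:
                segments.append(TerrainSegmentTruth(run_label, run_height))
            run_label, run_height = s.terrain, s.height_change
    segments.append(TerrainSegmentTruth(run_label, run_height))
    return segments


def generate_trial(spec: SyntheticTrialSpec) -> TrialData:
    """Assemble a full trial and corrupt it into an IMU recording.

    Layout: a long stationary lead-in (for gyro-bias calibration and initial
    tilt), then for each stride a stance block followed by its swing, and a
    stationary tail.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    dt = 1.0 / spec.fs

    blocks = [generate_stride(s, dt) for s in spec.strides]
    n_lead = int(round(spec.lead_dur / dt))
    n_tail = int(round(spec.tail_dur / dt))

    v_parts = [np.zeros((n_lead, 3))]
    q_parts = [np.tile([1.0, 0.0, 0.0, 0.0], (n_lead, 1))]
    khs_global: List[int] = []
    swing_ranges: List[Tuple[int, int]] = []
    cursor = n_lead
    for blk in blocks:
        khs_global.append(cursor + blk.khs_rel)
        swing_ranges.append((cursor + blk.n_stance, cursor + blk.n_stance + blk.n_swing))
        v_parts.append(blk.v)
        q_parts.append(blk.q)
        cursor += len(blk.v)
    v_parts.append(np.zeros((n_tail, 3)))
    q_parts.append(np.tile([1.0, 0.0, 0.0, 0.0], (n_tail, 1)))

    v = np.vstack(v_parts)
    q = enforce_sign_continuity(np.vstack(q_parts))
    n = len(v)
    t = np.arange(n) * dt
    v_prev = np.vstack([np.zeros(3), v[:-1]])
    p = np.cumsum(0.5 * (v + v_prev) * dt, axis=0)

    dv = _draw_dv(spec, rng)
    accel, gyro = corrupt_to_imu(
        v,
        q,
        dt,
        spec.b_true,
        spec.gyro_bias_true,
        spec.accel_noise_sigma,
        spec.gyro_noise_sigma,
        list(zip(khs_global, dv)),
        rng,
        impulse_mode=spec.impulse_mode,
    )

    recording = ImuRecording(t=t, accel=accel, gyro=gyro, dt=dt)
    trajectory = Trajectory(t=t, p=p, v=v, q=q)
    return TrialData(
        recording=recording,
        trajectory=trajectory,
        labels=[s.terrain for s in spec.strides],
        dv_hs=dv,
        khs=np.asarray(khs_global),
        b_true=spec.b_true.copy(),
        gyro_bias_true=spec.gyro_bias_true.copy(),
        stride_heights=np.array([s.height_change for s in spec.strides]),
        stride_lengths=np.array([s.stride_length for s in spec.strides]),
        swing_ranges=swing_ranges,
        segments=_truth_segments(spec.strides),
        spec=spec,
    )


def mixed_route(
    n_level: int = 20,
    n_ramp: int = 6,
    n_between: int = 5,
    n_stair: int = 10,
    riser: float = 0.15,
    n_risers: int = 2,
    incline_deg: float = 3.7,
) -> List[SyntheticStrideSpec]:
    """Level walking, a ramp up, a staircase up, then the mirrored descent —
    the building-route pattern the method is designed for."""
    return (
        [level_stride()] * n_level
        + [ramp_stride(incline_deg=incline_deg, ascending=True)] * n_ramp
        + [level_stride()] * n_between
        + [stair_stride(riser=riser, n_risers=n_risers, ascending=True)] * n_stair
        + [level_stride()] * n_between
        + [stair_stride(riser=riser, n_risers=n_risers, ascending=False)] * n_stair
        + [level_stride()] * n_between
        + [ramp_stride(incline_deg=incline_deg, ascending=False)] * n_ramp
        + [level_stride()] * n_level
    )


def default_mixed_trial(
    seed: int = 0,
    accel_noise_sigma: float = 0.02,
    gyro_noise_sigma: float = 0.002,
    **overrides,
) -> SyntheticTrialSpec:
    """The default mixed trial: the route of :func:`mixed_route` with the
    default injected bias, level-stride impulses, and the given noise."""
    return SyntheticTrialSpec(
        strides=mixed_route(),
        accel_noise_sigma=accel_noise_sigma,
        gyro_noise_sigma=gyro_noise_sigma,
        seed=seed,
        **overrides,
    )
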