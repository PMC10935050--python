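"""Per-stride error model: bias + heel-strike impulse from integration residuals.

Raw strapdown integration of a stride that truly starts and ends at rest still
leaves a non-zero end velocity ``v_residual`` and end height ``h_residual``.
The model attributes them to two physical error sources:

* a constant sensor-frame acceleration bias ``b = (bx, by, bz)`` whose effect
  on velocity and position is propagated through the rotation-matrix
  accumulators ``Bv(k) = sum_{i<=k} R(i)`` and
  ``Bp(k) = sum_{i<=k} (Bv(i) - R(i)/2)``, and
* an instantaneous world-vertical velocity impulse ``dv_hs`` at the
  heel-strike sample ``khs`` — the velocity information lost when the impact
  exceeds the sensor's bandwidth/range.

Zero residual velocity (3 equations) plus zero height change (1 equation,
valid on level ground) give a 4x4 linear system with a unique solution
(the "full" solve).  On ramps and stairs the zero-height assumption is
invalid, so only the 3x3 velocity system is solved with ``dv_hs = 0``
(the "reduced" solve — a physically grounded ZUPT de-drift).

Stride-local indexing: the model sample index k runs 1..N over the stride's
*integration sub-range* — from the sample after the last leading-stance
sample through the last swing sample.  Velocity is pinned to zero (and
position frozen) over the refined-stance samples bounding the stride, which
is exactly equivalent to integrating only that sub-range; ``N`` and ``khs``
in :class:`StrideResiduals` are sub-range quantities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple, Union

import numpy as np
from scipy.spatial.transform import Rotation

from .exceptions import MissingHeelStrikeError, SingularSystemError, ValidationError
from .io_gait import Trajectory

__all__ = [
    "AccumulatorMatrices",
    "StrideResiduals",
    "ErrorSolution",
    "integrate_stride",
    "accumulate_B",
    "solve_full",
    "solve_reduced",
    "correct_stride",
    "COND_LIMIT",
]

COND_LIMIT = 1e10


@dataclass
class AccumulatorMatrices:
    """Running sums of rotation matrices over one stride's sub-range.

    ``Bv[k]`` and ``Bp[k]`` hold the accumulators after model sample k+1, so
    ``Bv[0] = R(1)`` and ``Bp[0] = R(1)/2``; the final entries map a constant
    sensor-frame bias to end-of-stride velocity (times dt) and position
    (times dt^2) differences.
    """

    Bv: np.ndarray  # (N, 3, 3)
    Bp: np.ndarray  # (N, 3, 3)

    def __len__(self) -> int:
        return len(self.Bv)

    @property
    def Bv_final(self) -> np.ndarray:
        return self.Bv[-1]

    @property
    def Bp_final(self) -> np.ndarray:
        return self.Bp[-1]


@dataclass
class StrideResiduals:
    """End-of-integration residuals of one stride.

    ``N`` is the sub-range sample count; ``khs`` is the 1-based model index of
    the heel strike within the sub-range (None when undetected).
    ``sub_start``/``sub_end`` give the stride-local half-open sub-range.
    """

    v_residual: np.ndarray
    h_residual: float
    N: int
    khs: Optional[int] = None
    sub_start: int = 0
    sub_end: int = 0

    def scaled(self, c: float) -> "StrideResiduals":
        """Residuals scaled by the correction parameter C (linear system ⇒
        the solution scales identically)."""
        return StrideResiduals(
            v_residual=self.v_residual * c,
            h_residual=self.h_residual * c,
            N=self.N,
            khs=self.khs,
            sub_start=self.sub_start,
            sub_end=self.sub_end,
        )


@dataclass
class ErrorSolution:
    """Solved per-stride error parameters.

    ``b`` is the sensor-frame acceleration bias (m/s^2); ``dv_hs`` the
    world-vertical heel-strike velocity error (m/s, zero in reduced mode);
    ``mode`` is "full", "reduced" or "raw" (no correction applied).
    """

    b: np.ndarray
    dv_hs: float
    mode: str = "full"

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.b)) or not np.isfinite(self.dv_hs):
            raise ValidationError("error solution must be finite")
        if self.mode in ("reduced", "raw") and self.dv_hs != 0.0:
            raise ValidationError(f"{self.mode} mode requires dv_hs = 0")


def _subrange(zupt_mask: Optional[np.ndarray], n: int) -> Tuple[int, int]:
    if zupt_mask is None:
        return 0, n
    m = np.asarray(zupt_mask, dtype=bool)
    moving = np.flatnonzero(~m)
    if moving.size == 0:
        return 0, 0
    return int(moving[0]), int(moving[-1]) + 1


def _as_matrices(rotations: Union[np.ndarray, Rotation]) -> np.ndarray:
    if isinstance(rotations, Rotation):
        return rotations.as_matrix()
    r = np.asarray(rotations, dtype=float)
    if r.ndim != 3 or r.shape[1:] != (3, 3):
        raise ValidationError("rotations must be an (N, 3, 3) array")
    return r


def integrate_stride(
    world_accel: np.ndarray,
    dt: float,
    zupt_mask: Optional[np.ndarray] = None,
) -> Tuple[Trajectory, StrideResiduals]:
    """Raw strapdown integration of one stride starting from rest.

    v(k) = v(k-1) + a_w(k) dt and p(k) = p(k-1) + v(k-1) dt + a_w(k) dt^2 / 2
    over the integration sub-range; velocity is held at zero (and position
    frozen) over the bounding refined-stance samples.  Residuals are the
    velocity and vertical position at the last sub-range sample.
    """
    a = np.atleast_2d(np.asarray(world_accel, dtype=float))
    n = len(a)
    t = np.arange(n) * dt
    s, e = _subrange(zupt_mask, n)
    p = np.zeros((n, 3))
    v = np.zeros((n, 3))
    if e - s == 0:
        return Trajectory(t=t, p=p, v=v), StrideResiduals(np.zeros(3), 0.0, 0, None, s, e)
    a_sub = a[s:e]
    v_sub = np.cumsum(a_sub, axis=0) * dt
    v_prev = np.vstack([np.zeros(3), v_sub[:-1]])
    p_sub = np.cumsum(v_prev * dt + 0.5 * a_sub * dt * dt, axis=0)
    v[s:e] = v_sub
    p[s:e] = p_sub
    p[e:] = p_sub[-1]
    residuals = StrideResiduals(
        v_residual=v_sub[-1].copy(),
        h_residual=float(p_sub[-1, 2]),
        N=e - s,
        khs=None,
        sub_start=s,
        sub_end=e,
    )
    return Trajectory(t=t, p=p, v=v), residuals


def accumulate_B(rotations: Union[np.ndarray, Rotation]) -> AccumulatorMatrices:
    """Iterative accumulators Bv(k) = Bv(k-1) + R(k),
    Bp(k) = Bp(k-1) + Bv(k) - R(k)/2, with Bv(0) = Bp(0) = 0.

    These equal the direct sums Bv(k) = sum R(i) and
    Bp(k) = sum (Bv(i) - R(i)/2) by construction; the input matrices must be
    orthonormal.
    """
    r = _as_matrices(rotations)
    if len(r) == 0:
        raise ValidationError("need at least one rotation")
    err = np.einsum("kij,kil->kjl", r, r) - np.eye(3)
    if np.max(np.abs(err)) > 1e-6:
        raise ValidationError("rotation matrices must be orthonormal")
    bv = np.cumsum(r, axis=0)
    bp = np.cumsum(bv - 0.5 * r, axis=0)
    return AccumulatorMatrices(Bv=bv, Bp=bp)


def _check_B(residuals: StrideResiduals, B: AccumulatorMatrices) -> None:
    if len(B) != residuals.N:
        raise ValidationError(
            f"accumulators cover {len(B)} samples but residuals declare N={residuals.N}"
        )


def solve_full(residuals: StrideResiduals, B: AccumulatorMatrices, dt: float) -> ErrorSolution:
    """Solve the 4x4 system for (bx, by, bz, dv_hs) under zero residual
    velocity *and* zero height change.

    Rows 1-3:  Bv(N) b dt - (0, 0, dv_hs)     = v_residual
    Row 4:     Bp(N)_3 b dt^2 - (N - khs) dt dv_hs = h_residual

    Requires a heel-strike index; the system is singular when khs = N/2 with
    isotropic rotations, and a condition-number guard (1e10) rejects
    ill-conditioned strides.
    """
    if residuals.khs is None:
        raise MissingHeelStrikeError("full solve requires a heel-strike index")
    _check_B(residuals, B)
    khs = residuals.khs
    if not 1 <= khs <= residuals.N:
        raise ValidationError(f"khs={khs} outside model range 1..{residuals.N}")
    A = np.zeros((4, 4))
    A[:3, :3] = B.Bv_final * dt
    A[2, 3] = -1.0
    A[3, :3] = B.Bp_final[2] * dt * dt
    A[3, 3] = -(residuals.N - khs) * dt
    rhs = np.array([*residuals.v_residual, residuals.h_residual])
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > COND_LIMIT:
        raise SingularSystemError(f"full system condition number {cond:.3g} exceeds {COND_LIMIT:.0e}")
    x = np.linalg.solve(A, rhs)
    return ErrorSolution(b=x[:3], dv_hs=float(x[3]), mode="full")


def solve_reduced(residuals: StrideResiduals, B: AccumulatorMatrices, dt: float) -> ErrorSolution:
    """Solve Bv(N) b dt = v_residual with dv_hs = 0 (zero residual velocity
    only) — the de-drift used on ramps and stairs where the zero-height
    assumption does not hold."""
    _check_B(residuals, B)
    bv = B.Bv_final
    cond = np.linalg.cond(bv)
    if not np.isfinite(cond) or cond > COND_LIMIT:
        raise SingularSystemError(f"Bv(N) condition number {cond:.3g} exceeds {COND_LIMIT:.0e}")
    b = np.linalg.solve(bv, residuals.v_residual) / dt
    return ErrorSolution(b=b, dv_hs=0.0, mode="reduced")


def correct_stride(
    world_accel: np.ndarray,
    rotations: Union[np.ndarray, Rotation],
    solution: ErrorSolution,
    khs: Optional[int],
    dt: float,
    zupt_mask: Optional[np.ndarray] = None,
) -> Trajectory:
    """Re-integrate one stride with the solved bias removed and the
    heel-strike impulse injected.

    The corrected world acceleration is a_w(k) - R(k) b.  At the heel-strike
    sample the impulse dv_hs is added to the vertical velocity after the
    acceleration update (so it first moves the position one sample later,
    matching the model's (N - khs) dt lever arm).  Velocity is zero and
    position frozen over the bounding stance samples.  ``khs`` is the
    stride-local 0-based sample index.
    """
    a = np.atleast_2d(np.asarray(world_accel, dtype=float))
    r = _as_matrices(rotations)
    if len(r) != len(a):
        raise ValidationError("rotations must align with the acceleration samples")
    if solution.dv_hs != 0.0 and khs is None:
        raise MissingHeelStrikeError("a non-zero impulse requires a heel-strike index")
    n = len(a)
    t = np.arange(n) * dt
    s, e = _subrange(zupt_mask, n)
    p = np.zeros((n, 3))
    v = np.zeros((n, 3))
    if e - s == 0:
        return Trajectory(t=t, p=p, v=v)
    a_corr = a[s:e] - np.einsum("kij,j->ki", r[s:e], solution.b)
    v_sub = np.cumsum(a_corr, axis=0) * dt
    if khs is not None and solution.dv_hs != 0.0:
        if not s <= khs < e:
            raise ValidationError("heel-strike index outside the integration sub-range")
        v_sub[khs - s :, 2] += solution.dv_hs
    v_prev = np.vstack([np.zeros(3), v_sub[:-1]])
    p_sub = np.cumsum(v_prev * dt + 0.5 * a_corr * dt * dt, axis=0)
    v[s:e] = v_sub
    p[s:e] = p_sub
    p[e:] = p_sub[-1]
    return Trajectory(t=t, p=p, v=v)
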