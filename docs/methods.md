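# Methods

## Model

One stride is the sample range between the midpoints of two consecutive
foot-flat (ZUPT) periods. Within a stride, orientation `R(k)` is assumed
known (estimated internally or supplied externally), and the world-frame
acceleration is `a_w(k) = R(k)(a_m(k) − b) + g` with gravity
`g = (0, 0, −9.80665)` m/s² in a right-handed z-up world frame.
Accelerometers report specific force (a resting, level sensor reads
`(0, 0, +9.80665)` in its own frame). The discrete kinematics are

```
v(k) = v(k−1) + a_w(k) Δt
p(k) = p(k−1) + v(k−1) Δt + ½ a_w(k) Δt²
q(k) = q(k−1) ⊗ q(ω(k) Δt)
```

A stride integrated from rest should end at rest; the observed end velocity
`v_residual` and end height `h_residual` are attributed to a constant
sensor-frame acceleration bias `b` and an instantaneous heel-strike vertical
velocity impulse `Δv_hs` in the world frame. Both enter linearly through the
rotation-sum accumulators

```
Bv(k) = Bv(k−1) + R(k)                Bv(0) = 0
Bp(k) = Bp(k−1) + Bv(k) − ½R(k)       Bp(0) = 0
```

which equal the direct sums `Σ R(i)` and `Σ (Bv(i) − ½R(i))`. The bias
contributes `Bv(N)·b·Δt` to the end velocity and `Bp(N)·b·Δt²` to the end
position; the impulse contributes `−Δv_hs` to vertical end velocity (raw
integration *misses* it) and `−(N−k_hs)Δt·Δv_hs` to end height. Setting
residuals to zero gives the full 4×4 system (level ground: zero velocity
*and* zero height change) or, where the height assumption is invalid, the
reduced 3×3 system `Bv(N) b Δt = v_residual` with `Δv_hs = 0`.

Sign conventions: `Δv_hs > 0` means upward velocity was lost at impact. The
corrected stride is re-integrated from `a_m − b` with `Δv_hs` added to `v_z`
at the heel-strike sample *after* the acceleration update, so its first
position effect occurs one sample later — exactly the `(N−k_hs)Δt` lever arm
of the model. Because the correction inverts the same linear map that
produced the residuals, full-mode strides end with machine-zero velocity and
height whatever the data; this is an algebraic identity, not an accuracy
claim.

### Stride-local indexing and ZUPT handling

Velocity is held at zero (and position frozen) throughout the refined ZUPT
periods bounding each stride. This is implemented as integration over the
stride's *sub-range* — from the sample after the last leading-stance sample
through the last swing sample — which is algebraically identical to zeroing
during stance. `N`, `k_hs` and the accumulators are sub-range quantities;
residuals are read at the sub-range's last sample. Interior stance runs
cannot survive mask refinement, so the sub-range is always contiguous.

## Pipeline

1. **Gyro bias**: mean gyroscope output over the first stationary run of at
   least 1 s (capped at 2 s), subtracted everywhere. Without such a run the
   bias is left at zero.
2. **Orientation**: strapdown quaternion integration of the de-biased
   gyroscope, normalised every step. Over every refined stance run, the mean
   measured specific force is rotated into the world frame and the tilt-only
   rotation aligning it with +z is blended in by spherical interpolation
   across the run (no orientation jumps; heading is never corrected). The
   initial tilt comes from the lead-in's mean specific force with zero yaw.
   An externally estimated quaternion stream may replace this entire step.
3. **ZUPT mask**: `| ‖a_m‖ − g | < Ta  and  ‖ω‖ < Tω` per sample, then
   smoothing (stance runs shorter than `min_stance_dur` removed, interior
   swing gaps shorter than `min_swing_dur` filled) and reduction of each run
   to its central `central_frac` portion (default the central 80%, extra
   sample trimmed at the run's end). The trim strictly shrinks runs, so the
   full refinement is a single-application operator; only its smoothing
   stages are idempotent.
4. **Heel strike**: first local maximum of `|Δ a_w,z|` inside the swing above
   a threshold — fixed, or adaptively `max(4 m/s², 6·median |Δa_w,z|)`. The
   magnitude (not the signed difference) is used because a bandwidth-limited
   impact appears in the recorded signal as a glitch of either sign. Absence
   is a valid outcome: strides without a detection receive the trial-average
   heel-strike timing *for terrain determination only* and are reconstructed
   with the reduced model.
5. **Terrain determination**: every stride is solved with the full model;
   the interquartile mean (mean of the sorted middle half, floor-based
   ranks) of `Δv_hs` and of `‖b‖` across the trial is subtracted as the
   level-ground baseline. A stride is STAIR if its `‖b‖` deviation exceeds
   `b_threshold_stair` (1.2 m/s²) or its `|Δv_hs|` deviation exceeds
   `v_threshold_stair` (1.0 m/s); otherwise RAMP if the `|Δv_hs|` deviation
   exceeds `v_threshold_ramp` (0.2 m/s); otherwise LEVEL. Direction is the
   sign of the baseline-subtracted `Δv_hs`. Cleanup: (a) a rectangular
   kinematic boundary (`forward_boundary` 1 m, `height_boundary` 0.3 m, from
   the raw-integration geometry — nothing is re-integrated) flips a
   non-level label only when *both* indicators contradict it; steady
   two-riser stair strides sit exactly on the height boundary, and the
   conservative flip keeps such boundary geometry on the solution-vector
   decision. (b) isolated single strides flanked by one common label adopt
   it; both rules iterate to a fixpoint, making cleanup idempotent.
6. **Reconstruction**: per stride, residuals are scaled by the correction
   parameter `C` (default 1 = attribute everything to the error model),
   solved full (level, heel strike detected) or reduced (ramp/stair, or no
   heel strike), and re-integrated; per-stride solver failures degrade
   gracefully (full → reduced → no correction) and are flagged. Stride
   trajectories chain continuously; samples outside strides hold position.

## Parameters

| parameter | default | unit | role |
|---|---|---|---|
| `gravity` | 9.80665 | m/s² | world gravity magnitude |
| `ta`, `tw` | 0.4, 0.3 | m/s², rad/s | ZUPT thresholds (typical foot-mounted values; stance noise at the default σ is ~20× below, swing ~10× above) |
| `central_frac` | 0.8 | – | stance-run central trim |
| `min_stance_dur`, `min_swing_dur` | 0.1, 0.2 | s | mask smoothing (well under normal gait phase durations) |
| `v_threshold_ramp`, `v_threshold_stair` | 0.2, 1.0 | m/s | Δv_hs deviation thresholds |
| `b_threshold_stair` | 1.2 | m/s² | ‖b‖ deviation threshold |
| `height_boundary`, `forward_boundary` | 0.3, 1.0 | m | ramp/stair kinematic boundary |
| `C` | 1.0 | – | fraction of the residuals corrected (lower for noisier sensors) |
| `hs_peak_threshold` | adaptive | m/s² per sample | heel-strike peak threshold |

The condition-number guard for both solves is 1e10; the full system is
exactly singular at `k_hs = N/2` under isotropic rotations, far from the
physiological heel-strike timing (~0.9 of swing).

## Synthetic data: what it emulates and what it does not

The generator produces stance/swing foot kinematics at 128 Hz: quintic
bell-shaped swing velocity profiles (zero value and slope at both ends) for
forward progression and a cubic-edged clearance arc (default 0.05 m), a
plantarflexion/dorsiflexion pitch excursion (~0.4 rad peak), and geometry
defaults of 1.3 m level strides, 1.4 m strides on a 3.7° ramp, and 0.55 m
strides covering two 0.15 m (or 0.18 m) risers on stairs, with 0.6 s stance
and 0.5 s swing. Ground truth is defined on the *discrete* recursion (the
trapezoidal position update), with the vertical profile rescaled so the
discrete end height equals the commanded height exactly — so oracle
comparisons measure method error, never integration-scheme mismatch.

Corruption: a constant sensor-frame bias (default `(0.04, −0.03, 0.05)`
m/s², modest post-calibration values), a constant gyro bias (default
`(0.002, −0.001, 0.0015)` rad/s), white noise (defaults σ_a = 0.02 m/s²,
σ_ω = 0.002 rad/s, typical consumer MEMS), and a per-stride heel-strike
velocity deficit. The deficit is realised by default as an acceleration
deduction split equally over samples `(k_hs, k_hs+1)`, the discrete
realisation whose end-velocity *and* end-position effects equal the
instantaneous impulse of the error model exactly; `impulse_mode="single"`
concentrates it on one sample, which adds a `½Δv_hs·Δt` position side-effect
(an impulse spread over a short period rather than truly instantaneous).
Level strides draw `Δv_hs ~ N(0.1, 0.02)` m/s; ramp and stair strides
default to zero injected impulse because the reduced model used there treats
the impulse as unobservable — `dv_hs_ramp` / `dv_hs_stair` exercise that
mismatch explicitly.

What passing tests on this generator show: the algebra of the error model,
the exactness of the correction, the separability of the terrain classes
under realistic geometry, bias and noise, and the advantage over linear
de-drifting when impacts dominate. What they do not show: robustness to
soft-tissue artefact, bandwidth roll-off shapes, speed-dependent impact
magnitudes, turning gait, uneven terrain, or transition strides that
straddle two terrains — real recordings contain all of these, and the
fixed thresholds are expected to degrade near terrain transitions.

## Numerical choices

* Quaternions are Hamilton, scalar-first, world-from-sensor, sign-continuity
  enforced; all rotation algebra goes through `scipy.spatial.transform`.
* The interquartile mean uses floor-based rank slicing `[n/4, 3n/4)`; with
  fewer than 4 strides it falls back to the median (warning).
* Stair-before-ramp threshold ordering reproduces the overwrite order of the
  classification rules; `‖b‖` is the Euclidean norm.
* CSV round trips use `%.17g` formatting (lossless for doubles).
* Trajectories freeze position wherever velocity is held zero, so stance
  phases are strictly stationary and strides chain without jumps.

## Known limitations

* Heading is never corrected (no magnetometer): horizontal paths drift in
  yaw over long trials; all accuracy claims concern the vertical channel and
  per-stride geometry.
* The tilt correction uses the biased accelerometer, so a horizontal
  accelerometer bias leaks ~`b_h/g` radians into the orientation; the
  per-stride bias term absorbs most of it, but parameter estimates from the
  internal orientation path are systematically rotated versions of the truth
  (the external-orientation path recovers injected parameters to machine
  precision).
* On ramps and stairs the heel-strike impulse is unobservable and assumed
  zero; any true impulse there biases the reconstructed height by roughly
  `Δv_hs·Δt·(k_hs − N/2)`.
* Strides whose heel strike is missed by the detector fall back to the
  reduced model and keep an impulse-sized height error.
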