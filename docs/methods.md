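# Methods

`myoankle` is a desk-scale model of a continuous proportional myoelectric
impedance controller for a powered (transtibial) ankle prosthesis, together
with the bench power-testing protocol and the offline gait-biomechanics and
EMG analyses used to evaluate such a device. Everything runs on synthetic
signals with known ground truth; no hardware, motion capture, or subject
data is involved.

## Signal chains

Two EMG processing chains are modeled, both built from second-order
Butterworth stages realized as second-order sections (SOS):

* **Control chain** (causal, 450 Hz): high-pass 70 Hz → full-wave
  rectification → low-pass 3 Hz. Realized with streaming direct-form
  state (`StreamingEnvelope`) so the controller can consume one sample
  per tick; the batch function `realtime_envelope` is bit-identical.
* **Analysis chain** (zero-lag): high-pass 50 Hz → rectification →
  low-pass 10 Hz, each stage applied forward-backward (`sosfiltfilt`)
  with reflective edge padding.

The low-pass of a rectified signal can undershoot below zero by a fraction
of a percent; envelope outputs are clamped at 0 (an envelope is a
non-negative amplitude). The causal chain reports a warm-up length of three
low-pass time constants per filter order; envelope values inside it are
returned but flagged.

Useful analytic anchors: for a sinusoidal carrier of amplitude *a* deep in
the pass band, the steady-state envelope is the rectified mean 2a/π; near
the high-pass edge it is |H_hp(f)|·2a/π. Note that a carrier at exactly
fs/3 (150 Hz at 450 Hz) samples the rectified sine at only three phases per
cycle and biases the discrete mean several percent above 2a/π — checks use
carriers whose phase pattern covers the cycle densely (e.g. 155 Hz).

**MVC calibration.** The maximum voluntary contraction is estimated as the
maximum of the real-time envelope over a calibration trial of at least 1 s
(the estimator is not prescribed by the protocol; using the control chain's
own envelope keeps calibration and control consistent). The control signal
is u(t) = clamp(e(t) / (fraction·MVC), 0, 1) with fraction ∈ [0.50, 0.75]
(default 0.75). Offline envelopes are instead normalized by the
passive-walking maximum, without clamping; whether the initial or final
passive session supplies that maximum is a caller choice (no default
preference).

## Controller

The impedance law per tick is τ = k·(θ_set − θ) − b·ω (angles in degrees,
dorsiflexion positive; k in N·m/deg, b in N·m·s/deg). The normalized
control signal drives the set angle linearly: u = 1 commands a 30°
plantarflexion excursion. The excursion is referenced to the +10°
dorsiflexion end of the device's 30° range of motion, so u = 1 commands the
−20° plantarflexion limit; commanded angles are clamped to [−20°, +10°].
This referencing is one consistent reading of "set angle"; it is the one
for which the 30° excursion exactly spans the range of motion.

Below an activation threshold (u < 0.05 by default) the joint holds a
dorsiflexed baseline between 4° and 6° (default 5°, the band midpoint) for
natural roll-over; the return to baseline as activation decays is inherent
to the continuous mapping — there is no state machine.

Stiffness and damping switch between a compliant early/mid-stance pair and
a stiffer push-off pair when the sagittal load-cell moment signals forward
weight shift. The default transition is a logistic blend over a band of
one tenth of the moment threshold (avoids torque discontinuities); a hard
two-level switch is available (`mode="hard"`). The hardware study's gain
values are not public, so the defaults — k 1.5/4.0 N·m/deg, b 0.02/0.05
N·m·s/deg, moment threshold 0.3·(body weight)·(foot length) ≈ 55 N·m for a
75 kg user — are plausible placeholders, all configurable.

## Bench plant and protocol

The bench emulates loaded calf raises off the user: the prosthetic foot
bolted under a hinged beam with mass m stacked at lever arm r, so

    I_eff · θ̈ = τ_act + m·g·r·cos(θ),   I_eff = I₀ + m·r²

in joint coordinates (the beam angle is opposite in sign to the joint
angle: a plantarflexion press raises the load, hence the load moment acts
toward dorsiflexion and PE = −m·g·r·sin θ). Integration is semi-implicit
Euler at the 450 Hz control step — stable for stiff spring-damper torques —
with inelastic hard stops at the range of motion. Defaults: I₀ = 0.05
kg·m², r = 0.12 m (forefoot-lever scale; the true apparatus geometry is not
published), g = 9.81 m/s².

The actuator has two ceilings, a torque limit (140 N·m) and a mechanical
power limit (100 W). These matter: with an ideal actuator the press speed
is set by the EMG-envelope slew rate, which is the same at every load, so
peak press power grows ∝ m and peak power per kg is flat. With a power
ceiling the per-kg peak is min(g·r·ω_set, P_max/m) — non-increasing in
load, which is the observed shape of a powered ankle's bench curve. The
ceilings are properties of the simulated actuator, not calibrated to any
hardware datasheet; absolute W/kg values from this plant are therefore
illustrative, while the trend and the protocol logic are the tested
content.

The protocol runs 10 equally spaced loads from 40.4 to 100.6 kg (step
≈ 6.7 kg; the stated ~6.8 kg increment does not divide the range into an
integer number of steps, so the stated condition count wins). Each
condition feeds a four-burst calf-raise EMG recording through the full
chain (normalized to 75 % MVC of the same trial), simulates the closed
loop, and reports one peak per raise: the maximum plantarflexion-phase
power inside each activation burst (u above half threshold, dilated 0.3 s).
The gravity-assisted return stroke is excluded — it is not power delivered
into the load. A bare local-maxima detector (5 % height, 0.5 s separation)
is the fallback when no control signal accompanies the power trace.
Peak power per kg vs load is summarized by an OLS line with R².

## Gait pipeline

* **Events.** Heel strike = first sample of a vertical-GRF run above 20 N
  sustained ≥ 50 ms; toe off = first sample below after the run. Runs give
  alternation by construction; a GRF that never crosses yields no events.
* **Strides.** Heel-strike to next heel-strike, 0 % at heel strike; the
  last *n* complete cycles (5 for kinetics, 20 for EMG by convention) are
  linearly resampled to a 101-point 0–100 % grid, with toe-off recorded as
  a cycle percentage per stride.
* **Power.** P = M·ω with M mass-normalized (N·m/kg) and ω from the angle
  channel in rad/s by central differences (one-sided at endpoints). In the
  dorsiflexion-positive convention the push-off plantarflexor moment is
  negative and push-off power positive.
* **Deformable-segment power** (sagittal plane): P = F·v_distal + M_y·ω_y,
  the energy flow through a deformable prosthetic foot's distal end plus
  the sagittal couple. The full 6-DOF formulation is out of scope.
* **Work.** Net work per cycle is the moment-angle loop integral ∮M dθ
  (θ in radians, trapezoidal); positive/negative work split by the sign of
  each segment's M·dθ. For smooth strides the grid-resampled loop agrees
  with the raw-sample loop within 1 %, and the time-integral of power
  agrees with the loop integral within discretization error.
* **Peak power.** Per-stride maximum of the power channel, summarized as
  mean ± sample SD across strides.
* An optional zero-lag 10 Hz smoother for angle/moment channels exists but
  is off by default (whether kinetic traces receive extra smoothing before
  work loops is a pipeline choice, not a given).

## Statistics

* **Phase-gated RMS**: RMS of a stride-locked envelope over stance
  (gastrocnemius) or swing (tibialis anterior), averaged across strides and
  normalized by the passive-condition RMS. Stance = grid ≤ toe-off %,
  swing = the complement, so the two windows partition the cycle.
* **Variance-to-signal ratio**: VSR = Σ_t var(e_t) / Σ_t mean(e_t) with
  pointwise across-stride sample (n−1) variance on the 101-point grid (the
  grid choice is ours; the ratio definition fixes only the sums). VSR is 0
  iff strides are identical, scales linearly with a common amplitude
  factor, and is invariant to stride order.
* **Hedges' g** = J·(x̄₁−x̄₂)/s_pooled, J = 1 − 3/(4·df−1), df = n₁+n₂−2
  (independent) or n−1 (paired; the standardizer remains the pooled SD of
  the two condition samples). The 95 % CI is the normal approximation
  g ± 1.96·SE(g) with SE²(d) = (n₁+n₂)/(n₁n₂) + d²/(2df) for independent
  samples and (1/n + d²/2n)·2(1−r) for paired samples (r = sample
  correlation between conditions, Borenstein's approximation). The exact
  CI construction used by commercial meta-analysis software is not
  documented; a noncentral-t inversion would differ in the third decimal
  at these sample sizes.
* **Partial η²** = SS_effect / (SS_effect + SS_error).
* **Preference test**: one-sample t-test of preference scores against the
  declared scale's midpoint (100 mm VAS → 50 mm; 0–10 numeric → 5). The
  caller must declare the scale because VAS instruments are sometimes
  anchored 0–10 while measured in mm; the effect size vs the null is
  J·(x̄−null)/s with df = n−1.

Omnibus repeated-measures ANOVA, Friedman tests, Shapiro-Wilk normality
checks and Bonferroni adjustment are deliberately not reimplemented; use
`statsmodels`/`pingouin` on the long-format tables this package produces.

## Synthetic-data generator

All generators are pure functions of (parameters, seed) — identical inputs
give bit-identical outputs.

* **EMG bursts**: band-limited Gaussian carrier (70–200 Hz at 450 Hz
  sampling — survives the 70 Hz high-pass, respects Nyquist), unit RMS,
  amplitude-modulated by a Gaussian window. Calf-raise traces place four
  such bursts 2 s apart by default. Because the carrier is stochastic, the
  instantaneous envelope wanders on the burst top; burst location is
  recovered by the envelope centroid (within ~2 low-pass time constants),
  not argmax.
* **Gait trials** (defaults: 25 strides of 1.1 ± 0.02 s at 500 Hz, toe off
  62 %, GRF peak 800 N, peak power target 2.0 W/kg — the magnitude scale of
  powered-prosthesis walking; 5 % stride-to-stride EMG amplitude jitter):
  - ankle angle: C1 piecewise-cosine keyframes (heel strike −3°, loading
    −7°, rollover +8°, push-off −15°, swing clearance +2°), continuous
    across stride boundaries;
  - vertical GRF: two raised cosines on a 0.15-of-peak plateau during
    stance, exactly zero in swing. The plateau makes stance onset cross
    the 20 N event threshold at its first sample, so planted events are
    recoverable exactly;
  - ankle moment: plantarflexor (negative) raised-cosine bump over 6–66 %
    of the cycle, scaled per stride so that max(M·ω) on the raw samples
    equals the requested peak power exactly (ω computed with the same
    central-difference operator the pipeline uses);
  - EMG envelopes: gastrocnemius burst centered at 48 % (late stance),
    tibialis anterior at 80 % (swing), with seeded per-stride amplitude
    factors 1 + σ·z clipped at 0.05.

  A trial contains `n_strides` stride onsets; the last stride ends at the
  end of the record, so `n_strides − 1` complete heel-strike-to-heel-strike
  cycles are segmentable. Ground truth records event indices, per-stride
  peak power, per-muscle phase-gated RMS, the per-stride amplitude factors
  and the jitter level.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: motion-capture soft-tissue artifact and
inverse-dynamics error, EMG crosstalk and electrode lift, force-plate
targeting behavior, kinematic consistency between the GRF and the angle
profile beyond phase alignment, and any physiological motor-unit
structure in the EMG. Round-trip recoveries demonstrate pipeline
correctness, not robustness to those real-world effects.

## Numerical choices and degenerate inputs

* Zero-phase filtering uses reflective padding; edge regions (~200 samples)
  are excluded from symmetry comparisons.
* Stride resampling is linear interpolation onto 101 points including both
  heel strikes.
* Sample variance/SD use ddof = 1 throughout; a single stride has SD 0.
* Errors (not silent defaults) for: all-zero MVC trials, zero passive
  normalizers, u outside [0, 1] at the set-angle map, fewer complete
  strides than requested, empty phase windows, zero pooled variance,
  zero-variance preference scores, and infeasible (non-positive) power
  targets.
* Problem sizes in the shipped checks — e.g. 20–30 seeds for jitter
  monotonicity and round-trip sweeps, 21–25-stride trials at 500 Hz — keep
  any single check in the low seconds while leaving Monte-Carlo noise far
  below the tolerances being asserted.

## Known limitations

* The plant is a single rigid body with ideal ceilings: no gearbox or belt
  transmission model (belt slip is a known hardware failure mode), no motor
  electrical/thermal dynamics, no series or structural elasticity.
* Absolute bench W/kg values depend on the placeholder geometry and
  ceilings; only the per-kg trend direction and the protocol/analysis logic
  are claims.
* The impedance gains and weight-shift threshold are placeholders, not the
  study hardware's values.
* The sagittal-plane deformable-power form omits out-of-plane terms.
* The paired Hedges-g CI uses a normal approximation; very small samples
  (n < 5) deserve a noncentral-t or bootstrap interval.
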