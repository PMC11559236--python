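"""Seeded synthetic signals with known ground truth.

Generators for raw EMG bursts (band-limited Gaussian carrier under a
smooth amplitude window), calf-raise and MVC calibration traces, and
multi-stride gait trials whose channels mimic over-ground walking:

* vertical GRF — characteristic double bump during stance (two raised
  cosines on a plateau), exactly zero in swing so gait events are
  unambiguous;
* ankle angle — piecewise-cosine profile (early-stance plantarflexion,
  dorsiflexion rollover, push-off plantarflexion to about -15 deg,
  swing return), dorsiflexion positive;
* ankle moment — plantarflexor (negative) stance bump scaled per stride
  so the power peak M * omega equals the requested target exactly on
  the raw samples;
* EMG envelopes — gastrocnemius burst in late stance, tibialis anterior
  burst in swing, with seeded stride-to-stride amplitude jitter.

Every generator is a pure function of (parameters, seed).  The returned
ground truth records event indices, per-stride peak power, phase-gated
RMS per muscle, and the planted jitter level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .signal_chain import EmgTrace
from .gait_pipeline import GRID_POINTS, GaitTrial

__all__ = [
    "GaitGenParams",
    "GroundTruth",
    "gen_emg_burst",
    "gen_calf_raise_emg",
    "gen_mvc_trial",
    "gen_gait_trial",
]

#: ankle-angle keyframes (cycle fraction, angle deg): heel strike, loading
#: response, dorsiflexion rollover, push-off, swing clearance, return
_ANGLE_KNOTS = ((0.0, -3.0), (0.07, -7.0), (0.45, 8.0), (0.65, -15.0), (0.85, 2.0), (1.0, -3.0))
#: plantarflexor-moment window (cycle fractions)
_MOMENT_SUPPORT = (0.06, 0.66)
#: double-bump GRF shape: (center, half-width, amplitude) per bump, on a
#: 0.15 plateau so stance onset crosses the event threshold immediately
_GRF_BUMPS = ((0.28, 0.28, 1.0), (0.74, 0.28, 0.95))
_GRF_PLATEAU = 0.15

#: EMG burst windows, % of gait cycle: (center, half-width)
DEFAULT_EMG_BURSTS = {
    "gastrocnemius": (48.0, 22.0),
    "tibialis_anterior": (80.0, 16.0),
}


@dataclass
class GaitGenParams:
    """Generator parameters for a multi-stride gait trial.

    Defaults emulate the study's walking conditions: ~1.1 s strides,
    toe off at 62 % of the cycle, a 2.0 W/kg push-off power target
    (the order of the observed powered-prosthesis peaks), and an ~800 N
    GRF peak for an 80 kg walker.
    """

    n_strides: int = 25
    stride_duration_s: float = 1.1
    duration_jitter_sd_s: float = 0.02
    toe_off_percent: float = 62.0
    peak_power_target_wkg: float = 2.0
    grf_peak_n: float = 800.0
    emg_bursts: dict = field(default_factory=lambda: dict(DEFAULT_EMG_BURSTS))
    amplitude_jitter_sd: float = 0.05
    noise_band_hz: tuple = (70.0, 200.0)
    rate_hz: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strides < 1:
            raise ValueError("need at least one stride")
        if self.duration_jitter_sd_s < 0 or self.amplitude_jitter_sd < 0:
            raise ValueError("jitter standard deviations must be non-negative")
        if not (0 < self.toe_off_percent < 100):
            raise ValueError("toe-off percent must lie in (0, 100)")
        lo, hi = self.noise_band_hz
        if not (0 < lo < hi < self.rate_hz / 2):
            raise ValueError("noise band must lie inside (0, Nyquist)")


@dataclass
class GroundTruth:
    """Planted quantities consistent with the emitted channels."""

    heel_strikes: np.ndarray
    toe_offs: np.ndarray
    toe_off_percent: np.ndarray
    peak_power_wkg: np.ndarray  # per stride
    rms: dict  # muscle -> {"phase", "value"} (unnormalized, grid RMS)
    emg_amplitudes: dict  # muscle -> per-stride amplitude factors
    amplitude_jitter_sd: float
    seed: int


def _raised_cosine(x: np.ndarray, center: float, half_width: float) -> np.ndarray:
    z = (x - center) / half_width
    out = np.where(np.abs(z) < 1.0, 0.5 * (1.0 + np.cos(np.pi * z)), 0.0)
    return out


def _cosine_keyframes(phi: np.ndarray, knots) -> np.ndarray:
    """C1 piecewise-cosine interpolation through (phi, value) keyframes."""
    out = np.empty_like(phi)
    for (p0, v0), (p1, v1) in zip(knots[:-1], knots[1:]):
        m = (phi >= p0) & (phi < p1)
        s = (phi[m] - p0) / (p1 - p0)
        out[m] = v0 + (v1 - v0) * 0.5 * (1.0 - np.cos(np.pi * s))
    out[phi >= knots[-1][0]] = knots[-1][1]
    return out


def _band_limited_carrier(n: int, band: tuple, rate: float, rng: np.random.Generator) -> np.ndarray:
    lo, hi = band
    if not (0 < lo < hi < rate / 2):
        raise ValueError("noise band must lie inside (0, Nyquist)")
    white = rng.standard_normal(n)
    sos = sps.butter(4, (lo, hi), btype="bandpass", fs=rate, output="sos")
    x = sps.sosfiltfilt(sos, white)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def gen_emg_burst(
    center_s: float,
    width_s: float,
    amplitude_mv: float,
    noise_band: tuple = (70.0, 200.0),
    rate: float = 450.0,
    seed: int = 0,
    duration_s: float | None = None,
    muscle: str = "gastrocnemius",
    side: str = "residual",
) -> EmgTrace:
    """One EMG burst: unit-RMS band-limited carrier x Gaussian window.

    ``width_s`` is the nominal burst duration (Gaussian sd = width/4);
    the zero-mean carrier survives a 70 Hz high-pass.  Deterministic for
    a given seed.
    """
    if duration_s is None:
        duration_s = center_s + 2.0 * width_s
    n = int(round(duration_s * rate))
    t = np.arange(n) / rate
    rng = np.random.default_rng(seed)
    carrier = _band_limited_carrier(n, noise_band, rate, rng)
    window = np.exp(-0.5 * ((t - center_s) / (width_s / 4.0)) ** 2)
    return EmgTrace(amplitude_mv * window * carrier, rate, muscle, side)


def gen_calf_raise_emg(
    repetitions: int = 4,
    spacing_s: float = 2.0,
    amplitude_mv: float = 1.0,
    burst_width_s: float = 0.8,
    rate: float = 450.0,
    seed: int = 0,
) -> EmgTrace:
    """Calf-raise bench input: well-separated bursts, four by default."""
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    if spacing_s < burst_width_s:
        raise ValueError("burst spacing below burst width: bursts would overlap")
    lead = max(1.0, burst_width_s)
    centers = lead + spacing_s * np.arange(repetitions)
    duration = centers[-1] + lead
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    rng = np.random.default_rng(seed)
    carrier = _band_limited_carrier(n, (70.0, 200.0), rate, rng)
    window = np.zeros(n)
    for c in centers:
        window += np.exp(-0.5 * ((t - c) / (burst_width_s / 4.0)) ** 2)
    return EmgTrace(amplitude_mv * np.clip(window, 0, 1) * carrier, rate)


def gen_mvc_trial(
    amplitude_mv: float = 2.0, rate: float = 450.0, seed: int = 0
) -> EmgTrace:
    """Maximum-voluntary-contraction calibration trial: one strong 3 s burst."""
    return gen_emg_burst(1.5, 1.0, amplitude_mv, rate=rate, seed=seed, duration_s=3.0)


def gen_gait_trial(params: GaitGenParams | None = None) -> tuple[GaitTrial, GroundTruth]:
    """Multi-stride gait trial with planted ground truth.

    The trial contains ``n_strides`` stride onsets (heel strikes); the
    last stride ends at the end of the record, so ``n_strides - 1``
    complete heel-strike-to-heel-strike cycles are segmentable.  The
    moment is scaled per stride so the raw-sample power peak equals the
    target exactly (before grid resampling); EMG amplitude jitter is
    applied per stride from the seeded generator and recorded.
    """
    if params is None:
        params = GaitGenParams()
    if params.peak_power_target_wkg <= 0:
        raise ValueError("peak power target must be positive (plantarflexor push-off)")
    rng = np.random.default_rng(params.seed)
    rate = params.rate_hz
    to_frac = params.toe_off_percent / 100.0

    durations = params.stride_duration_s + rng.normal(
        0.0, params.duration_jitter_sd_s, params.n_strides
    )
    durations = np.clip(durations, 0.5 * params.stride_duration_s, None)
    n_samples = np.maximum(np.round(durations * rate).astype(int), 10)
    muscles = sorted(params.emg_bursts)
    amp_z = rng.standard_normal((params.n_strides, len(muscles)))
    amplitudes = np.clip(1.0 + params.amplitude_jitter_sd * amp_z, 0.05, None)

    starts = np.concatenate([[0], np.cumsum(n_samples)[:-1]])
    total = int(np.sum(n_samples))

    theta = np.empty(total)
    grf = np.zeros(total)
    emg = {m: np.zeros(total) for m in muscles}
    n_stance = np.empty(params.n_strides, dtype=int)
    for i, (s0, ni) in enumerate(zip(starts, n_samples)):
        phi = np.arange(ni) / ni
        theta[s0 : s0 + ni] = _cosine_keyframes(phi, _ANGLE_KNOTS)
        nst = int(round(to_frac * ni))
        nst = min(max(nst, 2), ni - 2)
        n_stance[i] = nst
        s = (np.arange(nst) + 0.5) / nst
        bumps = np.zeros(nst)
        for c, w, a in _GRF_BUMPS:
            bumps += a * _raised_cosine(s, c, w)
        bumps = bumps / np.max(bumps)
        grf[s0 : s0 + nst] = params.grf_peak_n * (_GRF_PLATEAU + (1 - _GRF_PLATEAU) * bumps)
        for j, m in enumerate(muscles):
            c_pct, w_pct = params.emg_bursts[m]
            emg[m][s0 : s0 + ni] = amplitudes[i, j] * _raised_cosine(
                100.0 * phi, c_pct, w_pct
            )

    # plantarflexor moment (negative, dorsiflexion-positive convention),
    # scaled per stride so max(M * omega) on the raw samples hits the
    # target: M_i = -(target / max(-h * omega)) * h over the stride
    omega = np.gradient(np.deg2rad(theta), 1.0 / rate)
    moment = np.zeros(total)
    peak_truth = np.empty(params.n_strides)
    lo, hi = _MOMENT_SUPPORT
    for i, (s0, ni) in enumerate(zip(starts, n_samples)):
        phi = np.arange(ni) / ni
        h = _raised_cosine(phi, 0.5 * (lo + hi), 0.5 * (hi - lo))
        neg_h_omega = -h * omega[s0 : s0 + ni]
        top = float(np.max(neg_h_omega))
        if top <= 0:
            raise ValueError("infeasible power target: no plantarflexion phase under load")
        scale = params.peak_power_target_wkg / top
        moment[s0 : s0 + ni] = -scale * h
        peak_truth[i] = params.peak_power_target_wkg

    time = np.arange(total) / rate
    trial = GaitTrial(time=time, theta=theta, moment=moment, grf_z=grf, rate=rate, emg=emg)

    grid = np.linspace(0.0, 100.0, GRID_POINTS)
    rms_truth = {}
    for j, m in enumerate(muscles):
        c_pct, w_pct = params.emg_bursts[m]
        template = _raised_cosine(grid, c_pct, w_pct)
        phase = "stance" if c_pct <= params.toe_off_percent else "swing"
        mask = grid <= params.toe_off_percent if phase == "stance" else grid > params.toe_off_percent
        per_stride = amplitudes[:, j] * np.sqrt(np.mean(template[mask] ** 2))
        rms_truth[m] = {"phase": phase, "value": float(np.mean(per_stride))}

    truth = GroundTruth(
        heel_strikes=starts.astype(int),
        toe_offs=(starts + n_stance).astype(int),
        toe_off_percent=100.0 * n_stance / n_samples,
        peak_power_wkg=peak_truth,
        rms=rms_truth,
        emg_amplitudes={m: amplitudes[:, j].copy() for j, m in enumerate(muscles)},
        amplitude_jitter_sd=params.amplitude_jitter_sd,
        seed=params.seed,
    )
    return trial, truth
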