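"""EMG processing chains for myoelectric control and offline analysis.

Two Butterworth filter chains operate on raw surface EMG:

* the **control chain** — causal, runs sample-by-sample at the 450 Hz
  controller rate: high-pass 70 Hz (artifact rejection), full-wave
  rectification, low-pass 3 Hz (linear envelope);
* the **analysis chain** — zero-lag (forward-backward), used offline:
  high-pass 50 Hz, rectify, low-pass 10 Hz.

Both are second-order Butterworth stages realized as second-order
sections.  The control envelope is normalized by a fraction (50-75 %)
of the maximum voluntary contraction (MVC) and clamped to [0, 1] to
form the proportional control signal; offline envelopes are normalized
by the passive-walking maximum without clamping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "EmgTrace",
    "ChainConfig",
    "Envelope",
    "ControlSignal",
    "MvcCalibration",
    "design_butterworth",
    "realtime_envelope",
    "offline_envelope",
    "StreamingEnvelope",
    "mvc_from_trial",
    "normalize_control",
    "normalize_offline",
]

MUSCLES = ("gastrocnemius", "tibialis_anterior")
SIDES = ("residual", "intact")

#: default controller sampling rate, Hz
CONTROL_RATE_HZ = 450.0


@dataclass
class EmgTrace:
    """Raw EMG samples with sampling rate and muscle/side labels.

    Parameters
    ----------
    samples : array-like
        Signed amplitude in mV.
    rate : float
        Sampling frequency in Hz (> 0).
    muscle, side : str
        Labels; ``muscle`` in {gastrocnemius, tibialis_anterior},
        ``side`` in {residual, intact}.
    """

    samples: np.ndarray
    rate: float = CONTROL_RATE_HZ
    muscle: str = "gastrocnemius"
    side: str = "residual"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("EMG trace must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("EMG samples must be finite")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.muscle not in MUSCLES:
            raise ValueError(f"unknown muscle {self.muscle!r}")
        if self.side not in SIDES:
            raise ValueError(f"unknown side {self.side!r}")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.rate


@dataclass
class ChainConfig:
    """Filter-chain parameters (cutoffs in Hz, shared Butterworth order)."""

    hp_cutoff: float
    lp_cutoff: float
    order: int = 2
    zero_lag: bool = False

    def __post_init__(self) -> None:
        if self.hp_cutoff <= 0 or self.lp_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        if self.order < 1:
            raise ValueError("filter order must be >= 1")

    @classmethod
    def control(cls) -> "ChainConfig":
        """Causal real-time chain: HP 70 Hz, LP 3 Hz, 2nd order."""
        return cls(hp_cutoff=70.0, lp_cutoff=3.0, order=2, zero_lag=False)

    @classmethod
    def analysis(cls) -> "ChainConfig":
        """Zero-lag offline chain: HP 50 Hz, LP 10 Hz, 2nd order."""
        return cls(hp_cutoff=50.0, lp_cutoff=10.0, order=2, zero_lag=True)

    def validate_rate(self, rate: float) -> None:
        nyq = rate / 2.0
        if not (0 < self.hp_cutoff < nyq and 0 < self.lp_cutoff < nyq):
            raise ValueError(
                f"cutoffs ({self.hp_cutoff}, {self.lp_cutoff}) Hz must lie "
                f"in (0, {nyq}) Hz for rate {rate} Hz"
            )


@dataclass
class Envelope:
    """Non-negative EMG envelope at a given rate.

    ``warmup_samples`` flags the initial region where a causal chain has
    not yet settled (zero for traces processed with the zero-lag chain).
    """

    samples: np.ndarray
    rate: float
    warmup_samples: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if np.any(self.samples < 0):
            raise ValueError("envelope samples must be non-negative")


@dataclass
class ControlSignal:
    """Normalized, clamped control signal u(t) in [0, 1]."""

    u: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        if np.any(self.u < 0) or np.any(self.u > 1):
            raise ValueError("control signal must lie in [0, 1]")


@dataclass
class MvcCalibration:
    """MVC envelope amplitude and the normalization fraction (50-75 %)."""

    mvc_value: float
    fraction: float = 0.75

    def __post_init__(self) -> None:
        if self.mvc_value <= 0:
            raise ValueError("mvc_value must be positive")
        if not (0.50 <= self.fraction <= 0.75):
            raise ValueError("fraction must lie in [0.50, 0.75]")


def design_butterworth(order: int, cutoff_hz: float, rate_hz: float, kind: str) -> np.ndarray:
    """Design a Butterworth stage as second-order sections.

    ``kind`` is ``"highpass"`` or ``"lowpass"``.  The magnitude response
    is -3 dB at the cutoff by construction.  Raises ``ValueError`` when
    the cutoff is at or above Nyquist.
    """
    if kind not in ("highpass", "lowpass"):
        raise ValueError(f"kind must be 'highpass' or 'lowpass', got {kind!r}")
    if order < 1:
        raise ValueError("order must be >= 1")
    if not (0 < cutoff_hz < rate_hz / 2.0):
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must lie strictly inside (0, Nyquist="
            f"{rate_hz / 2.0} Hz)"
        )
    return sps.butter(order, cutoff_hz, btype=kind, fs=rate_hz, output="sos")


def _warmup_samples(cfg: ChainConfig, rate: float, n: int) -> int:
    # settle time dominated by the envelope low-pass: ~3 time constants
    # per order of 1/(2*pi*fc)
    tau = 1.0 / (2.0 * np.pi * cfg.lp_cutoff)
    return int(min(n, round(3.0 * cfg.order * tau * rate)))


def realtime_envelope(emg: EmgTrace, cfg: ChainConfig | None = None) -> Envelope:
    """Causal control-chain envelope: HP -> full-wave rectify -> LP -> clamp.

    Sample *i* of the output depends only on input samples <= *i*.  The
    low-pass of a rectified signal can undershoot slightly below zero;
    outputs are clamped at 0 (envelope semantics).
    """
    if cfg is None:
        cfg = ChainConfig.control()
    if cfg.zero_lag:
        raise ValueError("realtime_envelope requires a causal config (zero_lag=False)")
    cfg.validate_rate(emg.rate)
    sos_hp = design_butterworth(cfg.order, cfg.hp_cutoff, emg.rate, "highpass")
    sos_lp = design_butterworth(cfg.order, cfg.lp_cutoff, emg.rate, "lowpass")
    hp = sps.sosfilt(sos_hp, emg.samples)
    env = sps.sosfilt(sos_lp, np.abs(hp))
    env = np.maximum(env, 0.0)
    return Envelope(env, emg.rate, warmup_samples=_warmup_samples(cfg, emg.rate, env.size))


def offline_envelope(emg: EmgTrace, cfg: ChainConfig | None = None) -> Envelope:
    """Zero-lag analysis-chain envelope (forward-backward filtering).

    Both stages are applied with ``sosfiltfilt`` using reflective edge
    padding, so the chain has zero phase: a symmetric burst yields an
    envelope peaking at the burst center.
    """
    if cfg is None:
        cfg = ChainConfig.analysis()
    cfg.validate_rate(emg.rate)
    sos_hp = design_butterworth(cfg.order, cfg.hp_cutoff, emg.rate, "highpass")
    sos_lp = design_butterworth(cfg.order, cfg.lp_cutoff, emg.rate, "lowpass")
    n = emg.samples.size
    padlen = min(n - 1, 24 * cfg.order)
    hp = sps.sosfiltfilt(sos_hp, emg.samples, padtype="even", padlen=padlen)
    env = sps.sosfiltfilt(sos_lp, np.abs(hp), padtype="even", padlen=padlen)
    return Envelope(np.maximum(env, 0.0), emg.rate, warmup_samples=0)


class StreamingEnvelope:
    """Sample-by-sample causal envelope for the 450 Hz control loop.

    Maintains direct-form filter state so the controller can consume raw
    EMG one sample per tick.  Batch-equivalent to :func:`realtime_envelope`.
    """

    def __init__(self, cfg: ChainConfig | None = None, rate: float = CONTROL_RATE_HZ):
        if cfg is None:
            cfg = ChainConfig.control()
        if cfg.zero_lag:
            raise ValueError("streaming envelope must be causal")
        cfg.validate_rate(rate)
        self.cfg = cfg
        self.rate = rate
        self._sos_hp = design_butterworth(cfg.order, cfg.hp_cutoff, rate, "highpass")
        self._sos_lp = design_butterworth(cfg.order, cfg.lp_cutoff, rate, "lowpass")
        self.reset()

    def reset(self) -> None:
        self._zi_hp = np.zeros((self._sos_hp.shape[0], 2))
        self._zi_lp = np.zeros((self._sos_lp.shape[0], 2))

    def push(self, sample: float) -> float:
        """Process one raw EMG sample; returns the envelope value."""
        hp, self._zi_hp = sps.sosfilt(self._sos_hp, [sample], zi=self._zi_hp)
        env, self._zi_lp = sps.sosfilt(self._sos_lp, np.abs(hp), zi=self._zi_lp)
        return max(float(env[0]), 0.0)


def mvc_from_trial(emg: EmgTrace, cfg: ChainConfig | None = None) -> float:
    """MVC estimate: maximum of the real-time envelope over a calibration trial.

    Raises ``ValueError`` for an all-zero trial (no contraction to calibrate).
    """
    if emg.duration_s < 1.0:
        raise ValueError("MVC trial must be at least 1 s long")
    env = realtime_envelope(emg, cfg)
    mvc = float(np.max(env.samples))
    if mvc <= 0:
        raise ValueError("cannot calibrate MVC from an all-zero trial")
    return mvc


def normalize_control(env: Envelope, cal: MvcCalibration) -> ControlSignal:
    """u(t) = clamp(envelope / (fraction x MVC), 0, 1)."""
    u = np.clip(env.samples / (cal.fraction * cal.mvc_value), 0.0, 1.0)
    return ControlSignal(u, env.rate)


def normalize_offline(env: Envelope, passive_max: float) -> Envelope:
    """Normalize an analysis envelope by the passive-condition maximum.

    No clamping: values may exceed 1 when activity exceeds the passive
    reference.
    """
    if passive_max <= 0:
        raise ValueError("passive_max must be positive")
    return Envelope(env.samples / passive_max, env.rate, env.warmup_samples)
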