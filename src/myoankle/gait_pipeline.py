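"""Offline gait biomechanics: events, stride normalization, power and work.

Gait events come from the vertical ground reaction force (GRF): a heel
strike is a sustained upward crossing of a force threshold, a toe off
the matching sustained drop.  A gait cycle runs heel-strike to next
heel-strike of the same limb (0 % at heel strike); every channel is
linearly resampled onto a 101-point 0-100 % grid.  Ankle power is
P = M * omega (moment assumed mass-normalized, N*m/kg; angular velocity
from the angle channel by central differences), work is the moment-angle
loop integral per cycle, and peak power is the per-stride power maximum.
Sign convention matches the controller: dorsiflexion positive, so a
plantarflexor (push-off) moment is negative and push-off power positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "GaitTrial",
    "StrideSet",
    "WorkLoopResult",
    "detect_events",
    "segment_strides",
    "joint_power",
    "deformable_power",
    "ankle_work",
    "peak_power",
    "GRID_POINTS",
]

#: points on the 0-100 % gait-cycle grid (inclusive)
GRID_POINTS = 101
#: default GRF event threshold (N) and debounce (s)
GRF_THRESHOLD_N = 20.0
GRF_DEBOUNCE_S = 0.05


@dataclass
class GaitTrial:
    """Synchronized trial channels on a common time base.

    theta : ankle angle, deg (dorsiflexion positive)
    moment : ankle moment, N*m/kg (mass-normalized on input)
    grf_z : vertical GRF, N
    emg : optional dict of muscle label -> envelope samples
    heel_strikes / toe_offs : sample indices (filled by event detection)
    """

    time: np.ndarray
    theta: np.ndarray
    moment: np.ndarray
    grf_z: np.ndarray
    rate: float
    emg: dict = field(default_factory=dict)
    heel_strikes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    toe_offs: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in ("theta", "moment", "grf_z"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"channel {name} length differs from time base")
        for m, ch in self.emg.items():
            if len(ch) != n:
                raise ValueError(f"EMG channel {m} length differs from time base")
        if self.rate < 100:
            raise ValueError("analysis requires a sampling rate >= 100 Hz")

    def detect(self, threshold_n: float = GRF_THRESHOLD_N, debounce_s: float = GRF_DEBOUNCE_S) -> "GaitTrial":
        """Detect and attach gait events from the vertical GRF."""
        hs, to = detect_events(self.grf_z, self.rate, threshold_n, debounce_s)
        self.heel_strikes = hs
        self.toe_offs = to
        return self

    def smooth_kinetics(self, cutoff_hz: float = 10.0, order: int = 2) -> "GaitTrial":
        """Optional zero-lag low-pass of angle and moment (off by default)."""
        sos = sps.butter(order, cutoff_hz, btype="lowpass", fs=self.rate, output="sos")
        self.theta = sps.sosfiltfilt(sos, self.theta)
        self.moment = sps.sosfiltfilt(sos, self.moment)
        return self


@dataclass
class StrideSet:
    """Strides time-normalized to the 101-point gait-cycle grid.

    ``channels`` maps channel name -> (n_strides, 101) array.
    """

    channels: dict
    toe_off_percent: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        for name, mat in self.channels.items():
            mat = np.atleast_2d(np.asarray(mat, dtype=float))
            if mat.shape[1] != GRID_POINTS:
                raise ValueError(f"channel {name} rows must have {GRID_POINTS} samples")
            self.channels[name] = mat
        self.toe_off_percent = np.asarray(self.toe_off_percent, dtype=float)
        if np.any(self.toe_off_percent <= 0) or np.any(self.toe_off_percent >= 100):
            raise ValueError("toe-off percent must lie strictly inside (0, 100)")

    @property
    def n_strides(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def grid(self) -> np.ndarray:
        return np.linspace(0.0, 100.0, GRID_POINTS)


@dataclass
class WorkLoopResult:
    """Net/positive/negative work of a moment-angle loop, J/kg."""

    net_work: float
    positive_work: float
    negative_work: float


def detect_events(
    grf_z: np.ndarray,
    rate: float,
    threshold_n: float = GRF_THRESHOLD_N,
    debounce_s: float = GRF_DEBOUNCE_S,
) -> tuple[np.ndarray, np.ndarray]:
    """Threshold-crossing gait events from vertical GRF.

    A heel strike is the first sample of a contiguous above-threshold
    run sustained at least ``debounce_s``; the matching toe off is the
    first below-threshold sample after the run (absent when the run
    extends to the end of the record).  Events alternate by
    construction.  A GRF that never crosses yields empty lists.
    """
    grf = np.asarray(grf_z, dtype=float)
    if not np.all(np.isfinite(grf)):
        raise ValueError("GRF must be finite")
    min_run = max(1, int(round(debounce_s * rate)))
    above = grf > threshold_n
    if not above.any():
        return np.array([], dtype=int), np.array([], dtype=int)
    edges = np.diff(above.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1  # first below-threshold sample
    if above[0]:
        starts = np.r_[0, starts]
    heel_strikes, toe_offs = [], []
    for s in starts:
        e_candidates = ends[ends > s]
        e = int(e_candidates[0]) if e_candidates.size else grf.size
        if e - s >= min_run:
            heel_strikes.append(int(s))
            if e < grf.size:
                toe_offs.append(e)
    return np.array(heel_strikes, dtype=int), np.array(toe_offs, dtype=int)


def segment_strides(trial: GaitTrial, n_last: int, power_channel: bool = True) -> StrideSet:
    """Last ``n_last`` complete heel-strike-to-heel-strike cycles, resampled.

    Each stride is linearly interpolated onto the 101-point grid; the
    toe-off location is recorded per stride as a gait-cycle percentage.
    ``power_channel`` adds an ankle power channel computed on the raw
    samples before resampling.  Raises when fewer complete strides exist.
    """
    hs = trial.heel_strikes
    n_cycles = max(0, hs.size - 1)
    if n_cycles < n_last:
        raise ValueError(
            f"need {n_last} complete strides but only {n_cycles} available "
            f"({hs.size} heel strikes)"
        )
    channels: dict[str, np.ndarray] = {
        "theta": trial.theta,
        "moment": trial.moment,
        "grf_z": trial.grf_z,
    }
    for m, ch in trial.emg.items():
        channels[f"emg_{m}"] = np.asarray(ch, dtype=float)
    if power_channel:
        channels["power"] = joint_power(trial.moment, trial.theta, trial.rate)

    grid = np.linspace(0.0, 1.0, GRID_POINTS)
    out = {name: [] for name in channels}
    toe_off_pct = []
    for i in range(n_cycles - n_last, n_cycles):
        a, b = hs[i], hs[i + 1]
        frac = np.arange(a, b + 1)  # include the closing heel strike
        x = (frac - a) / (b - a)
        for name, ch in channels.items():
            out[name].append(np.interp(grid, x, ch[a : b + 1]))
        tos = trial.toe_offs[(trial.toe_offs > a) & (trial.toe_offs < b)]
        if tos.size == 0:
            raise ValueError(f"no toe off found inside stride starting at sample {a}")
        toe_off_pct.append(100.0 * (tos[0] - a) / (b - a))
    return StrideSet(
        channels={k: np.vstack(v) for k, v in out.items()},
        toe_off_percent=np.array(toe_off_pct),
        rate=trial.rate,
    )


def joint_power(moment: np.ndarray, theta_deg: np.ndarray, rate: float) -> np.ndarray:
    """Ankle power P = M * omega (W/kg for mass-normalized moments).

    Angular velocity from the angle channel (deg -> rad) by central
    differences with one-sided endpoint differences.
    """
    moment = np.asarray(moment, dtype=float)
    theta = np.asarray(theta_deg, dtype=float)
    if moment.shape != theta.shape:
        raise ValueError("moment and angle series must have equal length")
    omega = np.gradient(np.deg2rad(theta), 1.0 / rate)
    return moment * omega


def deformable_power(
    force_2d: np.ndarray,
    moment_y: np.ndarray | float,
    v_distal_2d: np.ndarray,
    omega_y: np.ndarray | float,
) -> np.ndarray:
    """Sagittal-plane deformable-segment power P = F . v_distal + M_y * omega_y.

    The translational term captures energy flow through the distal end
    of a deformable prosthetic foot; the rotational term the sagittal
    couple.  Accepts single samples (shape (2,)) or time series
    (shape (n, 2)).
    """
    f = np.atleast_2d(np.asarray(force_2d, dtype=float))
    v = np.atleast_2d(np.asarray(v_distal_2d, dtype=float))
    if f.shape != v.shape or f.shape[-1] != 2:
        raise ValueError("force and distal velocity must be matching (n, 2) arrays")
    p = np.einsum("ij,ij->i", f, v) + np.asarray(moment_y, dtype=float) * np.asarray(
        omega_y, dtype=float
    )
    return p if p.size > 1 else float(p[0])


def ankle_work(theta_deg: np.ndarray, moment: np.ndarray) -> WorkLoopResult:
    """Work of the moment-angle loop over one gait cycle, J/kg.

    net = loop integral of M dtheta (theta in radians, trapezoidal);
    positive/negative parts split by the sign of each segment's M dtheta.
    """
    theta = np.deg2rad(np.asarray(theta_deg, dtype=float))
    m = np.asarray(moment, dtype=float)
    if theta.shape != m.shape:
        raise ValueError("angle and moment series must have equal length")
    if theta.size < 3:
        raise ValueError("work loop needs at least 3 samples")
    dtheta = np.diff(theta)
    m_mid = 0.5 * (m[:-1] + m[1:])
    dw = m_mid * dtheta
    pos = float(np.sum(dw[dw > 0]))
    neg = float(np.sum(dw[dw < 0]))
    return WorkLoopResult(net_work=pos + neg, positive_work=pos, negative_work=neg)


def peak_power(strides: StrideSet, channel: str = "power") -> dict:
    """Per-stride power maxima with mean and sample standard deviation."""
    if channel not in strides.channels:
        raise KeyError(f"stride set has no channel {channel!r}")
    mat = strides.channels[channel]
    peaks = np.max(mat, axis=1)
    return {
        "per_stride": peaks,
        "mean": float(np.mean(peaks)),
        "sd": float(np.std(peaks, ddof=1)) if peaks.size > 1 else 0.0,
    }
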