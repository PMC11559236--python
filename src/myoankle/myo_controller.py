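"""Continuous proportional myoelectric impedance controller.

The normalized gastrocnemius envelope u in [0, 1] drives the equilibrium
(set) angle of an impedance law

    tau = k * (theta_set - theta) - b * omega

running at 450 Hz.  u = 1 commands a 30 deg plantarflexion excursion,
measured from the 10 deg dorsiflexion end of the device's range of
motion, so full activation commands the -20 deg plantarflexion limit.
Below a small activation threshold the joint holds a 4-6 deg dorsiflexed
baseline for natural roll-over.  Stiffness and damping switch from a
compliant early/mid-stance pair to a stiffer push-off pair when the
sagittal load-cell moment indicates forward weight shift; the default
transition is a smooth logistic blend over a narrow moment band (a hard
switch is available for the idealized two-level behavior).

Sign convention: dorsiflexion positive, plantarflexion negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal_chain import ControlSignal

__all__ = [
    "ImpedanceCommand",
    "JointState",
    "SchedulerConfig",
    "THETA_MIN_DEG",
    "THETA_MAX_DEG",
    "SET_ANGLE_MAX_DEG",
    "CONTROL_RATE_HZ",
    "default_moment_threshold",
    "set_angle_from_control",
    "commanded_joint_angle",
    "schedule_impedance",
    "impedance_torque",
    "controller_step",
    "run_controller",
]

#: device range of motion, deg (dorsiflexion positive)
THETA_MIN_DEG = -20.0
THETA_MAX_DEG = 10.0
#: plantarflexion excursion commanded at u = 1, deg
SET_ANGLE_MAX_DEG = 30.0
#: controller update rate, Hz
CONTROL_RATE_HZ = 450.0

GRAVITY_MS2 = 9.81


def default_moment_threshold(body_mass_kg: float = 75.0, foot_length_m: float = 0.25) -> float:
    """Weight-shift moment threshold proxy: 0.3 x body weight x foot length (N*m)."""
    return 0.3 * body_mass_kg * GRAVITY_MS2 * foot_length_m


@dataclass
class ImpedanceCommand:
    """Per-tick impedance parameters: set angle (deg excursion), k, b."""

    set_angle: float  # plantarflexion excursion from the dorsiflexion stop, deg
    theta_set: float  # commanded joint angle, deg (dorsiflexion positive)
    k: float  # N*m/deg
    b: float  # N*m*s/deg

    def __post_init__(self) -> None:
        if not (0.0 <= self.set_angle <= SET_ANGLE_MAX_DEG):
            raise ValueError("set_angle must lie in [0, 30] deg")
        if self.k <= 0 or self.b < 0:
            raise ValueError("require k > 0 and b >= 0")


@dataclass
class JointState:
    """Joint angle (deg), angular velocity (deg/s), sagittal load-cell moment (N*m)."""

    theta: float
    omega: float = 0.0
    sagittal_moment: float = 0.0

    def __post_init__(self) -> None:
        if not (THETA_MIN_DEG - 1e-9 <= self.theta <= THETA_MAX_DEG + 1e-9):
            raise ValueError(
                f"theta {self.theta} deg outside device range "
                f"[{THETA_MIN_DEG}, {THETA_MAX_DEG}]"
            )


@dataclass
class SchedulerConfig:
    """Baseline hold and loading-dependent impedance schedule.

    ``k_low``/``b_low`` apply in early and mid stance (light loading),
    ``k_high``/``b_high`` during push-off (weight shifted onto the
    forefoot).  The supplement with the study's hardware values is not
    public; the defaults are plausible placeholders for a ~75 kg user.
    """

    baseline_angle: float = 5.0  # deg dorsiflexion, in [4, 6]
    u_threshold: float = 0.05
    moment_threshold: float = field(default_factory=default_moment_threshold)
    k_low: float = 1.5
    b_low: float = 0.02
    k_high: float = 4.0
    b_high: float = 0.05
    mode: str = "smooth"  # "smooth" logistic blend | "hard" two-level switch
    blend_band: float | None = None  # N*m; default moment_threshold / 10

    def __post_init__(self) -> None:
        if not (4.0 <= self.baseline_angle <= 6.0):
            raise ValueError("baseline_angle must lie in [4, 6] deg dorsiflexion")
        if not (0 < self.k_low <= self.k_high):
            raise ValueError("require k_high >= k_low > 0")
        if self.b_low < 0 or self.b_high < 0:
            raise ValueError("damping must be non-negative")
        if self.moment_threshold <= 0:
            raise ValueError("moment_threshold must be positive")
        if self.mode not in ("smooth", "hard"):
            raise ValueError("mode must be 'smooth' or 'hard'")
        if self.blend_band is None:
            self.blend_band = self.moment_threshold / 10.0


def set_angle_from_control(u: float) -> float:
    """Linear proportional map: set_angle = 30 * u (deg of PF excursion)."""
    if not (0.0 <= u <= 1.0):
        raise ValueError(f"control signal u={u} outside [0, 1]; caller must clamp")
    return SET_ANGLE_MAX_DEG * u


def commanded_joint_angle(set_angle: float, cfg: SchedulerConfig, u: float) -> float:
    """Commanded joint angle theta_set (deg, dorsiflexion positive).

    Below the activation threshold the prosthesis holds the dorsiflexed
    baseline; otherwise the set angle is an excursion from the +10 deg
    dorsiflexion end, clamped to the device range of motion.
    """
    if not (0.0 <= set_angle <= SET_ANGLE_MAX_DEG):
        raise ValueError("set_angle must lie in [0, 30] deg")
    if u < cfg.u_threshold:
        return cfg.baseline_angle
    return float(np.clip(THETA_MAX_DEG - set_angle, THETA_MIN_DEG, THETA_MAX_DEG))


def schedule_impedance(
    sagittal_moment: float, in_stance: bool, cfg: SchedulerConfig
) -> tuple[float, float]:
    """(k, b) as a non-decreasing function of the sagittal moment magnitude.

    Off stance the compliant pair always applies.  In smooth mode the
    two levels are blended by a logistic in |moment| centered on the
    threshold (width ``blend_band``), avoiding torque discontinuities.
    """
    if not in_stance:
        return cfg.k_low, cfg.b_low
    m = abs(sagittal_moment)
    if cfg.mode == "hard":
        high = m >= cfg.moment_threshold
        return (cfg.k_high, cfg.b_high) if high else (cfg.k_low, cfg.b_low)
    z = (m - cfg.moment_threshold) / cfg.blend_band
    s = 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))
    k = cfg.k_low + (cfg.k_high - cfg.k_low) * s
    b = cfg.b_low + (cfg.b_high - cfg.b_low) * s
    return float(k), float(b)


def impedance_torque(theta: float, omega: float, theta_set: float, k: float, b: float) -> float:
    """tau = k*(theta_set - theta) - b*omega (N*m; angles deg, omega deg/s)."""
    return k * (theta_set - theta) - b * omega


def controller_step(
    u: float, state: JointState, cfg: SchedulerConfig, in_stance: bool = True
) -> tuple[ImpedanceCommand, float]:
    """One deterministic control tick.

    Composes the proportional set-angle map, baseline hold, impedance
    schedule and spring-damper torque law.
    """
    u = float(u)
    set_angle = set_angle_from_control(u)
    theta_set = commanded_joint_angle(set_angle, cfg, u)
    k, b = schedule_impedance(state.sagittal_moment, in_stance, cfg)
    tau = impedance_torque(state.theta, state.omega, theta_set, k, b)
    return ImpedanceCommand(set_angle, theta_set, k, b), tau


def run_controller(
    control: ControlSignal,
    states: list[JointState] | None,
    cfg: SchedulerConfig,
) -> dict:
    """Run the controller over a control-signal stream.

    ``states`` supplies the measured joint state per tick; when ``None``
    the joint is assumed held at the baseline with zero velocity (useful
    for open-loop command-trajectory inspection).  Returns a dict of
    per-tick arrays: ``theta_set_deg``, ``set_angle_deg``, ``k``, ``b``,
    ``torque_nm`` and ``n_ticks``.
    """
    n = control.u.size
    if states is not None and len(states) != n:
        raise ValueError("states must match control length")
    out = {
        "set_angle_deg": np.empty(n),
        "theta_set_deg": np.empty(n),
        "k": np.empty(n),
        "b": np.empty(n),
        "torque_nm": np.empty(n),
        "n_ticks": n,
    }
    for i in range(n):
        st = states[i] if states is not None else JointState(cfg.baseline_angle)
        cmd, tau = controller_step(control.u[i], st, cfg)
        out["set_angle_deg"][i] = cmd.set_angle
        out["theta_set_deg"][i] = cmd.theta_set
        out["k"][i] = cmd.k
        out["b"][i] = cmd.b
        out["torque_nm"][i] = tau
    return out
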