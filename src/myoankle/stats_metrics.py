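"""EMG summary statistics and effect sizes.

Implements the stride-locked EMG summaries — phase-gated RMS (stance
for the gastrocnemius, swing for the tibialis anterior, normalized to
the passive-walking RMS) and the variance-to-signal ratio

    VSR = sum_t var_strides(e_t) / sum_t mean_strides(e_t)

computed pointwise on the 101-point gait-cycle grid — together with
Hedges' g (Cohen's d with the small-sample correction
J = 1 - 3/(4 df - 1)), partial eta-squared, and the one-sample
preference t-test against the no-preference scale midpoint.

Omnibus models (repeated-measures ANOVA, Friedman, Shapiro-Wilk,
Bonferroni-adjusted post hocs) are deliberately left to standard
statistical packages; only the formulas above are first-class here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sst

from .gait_pipeline import StrideSet

__all__ = [
    "RmsResult",
    "VsrResult",
    "EffectSize",
    "PreferenceResult",
    "rms_phase",
    "vsr",
    "hedges_g",
    "partial_eta_sq",
    "preference_test",
]

PHASES = ("stance", "swing")
#: preference scales: label -> (low, high); null defaults to the midpoint
PREFERENCE_SCALES = {"vas_100mm": (0.0, 100.0), "numeric_0_10": (0.0, 10.0)}


@dataclass
class RmsResult:
    """Phase-gated RMS normalized to the passive-condition RMS."""

    value: float
    phase: str
    muscle: str
    per_stride: np.ndarray


@dataclass
class VsrResult:
    """Variance-to-signal ratio of stride-locked envelopes."""

    vsr: float
    n_strides: int


@dataclass
class EffectSize:
    """Hedges' g with a 95 % confidence interval."""

    g: float
    ci_low: float
    ci_high: float
    eta_p2: float | None = None

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.g <= self.ci_high):
            raise ValueError("CI must bracket g")


@dataclass
class PreferenceResult:
    """One-sample preference test against the no-preference point."""

    t: float
    p: float
    effect: EffectSize
    mean: float
    null_value: float
    n: int


def _phase_mask(grid: np.ndarray, toe_off_pct: float, phase: str) -> np.ndarray:
    # stance and swing partition the cycle: stance = [0, toe-off],
    # swing = (toe-off, 100]
    if phase == "stance":
        return grid <= toe_off_pct
    if phase == "swing":
        return grid > toe_off_pct
    raise ValueError(f"phase must be one of {PHASES}, got {phase!r}")


def rms_phase(
    strides: StrideSet,
    phase: str,
    passive_rms: float,
    channel: str = "emg_gastrocnemius",
    muscle: str | None = None,
) -> RmsResult:
    """Phase-gated RMS of a stride-locked envelope channel.

    RMS over the stance (or swing) window of each stride, averaged
    across strides, divided by the passive-condition RMS.
    """
    if passive_rms <= 0:
        raise ValueError("passive_rms must be positive")
    mat = strides.channels[channel]
    grid = strides.grid
    per_stride = np.empty(mat.shape[0])
    for i in range(mat.shape[0]):
        mask = _phase_mask(grid, strides.toe_off_percent[i], phase)
        if not mask.any():
            raise ValueError(f"empty {phase} window for stride {i}")
        per_stride[i] = np.sqrt(np.mean(mat[i, mask] ** 2))
    if muscle is None:
        muscle = channel.removeprefix("emg_")
    return RmsResult(
        value=float(np.mean(per_stride) / passive_rms),
        phase=phase,
        muscle=muscle,
        per_stride=per_stride,
    )


def vsr(strides: StrideSet | np.ndarray, channel: str = "emg_gastrocnemius") -> VsrResult:
    """Variance-to-signal ratio: sum of pointwise across-stride variance
    over sum of pointwise across-stride mean.

    Sample (n-1) variance on the gait-cycle grid.  Zero iff all strides
    are identical (given a positive mean); scales linearly with a common
    amplitude factor.
    """
    mat = strides.channels[channel] if isinstance(strides, StrideSet) else np.atleast_2d(strides)
    mat = np.asarray(mat, dtype=float)
    if mat.shape[0] < 2:
        raise ValueError("VSR needs at least 2 strides")
    mean_sum = float(np.sum(np.mean(mat, axis=0)))
    if mean_sum <= 0:
        raise ValueError("VSR undefined for a zero-mean envelope")
    var_sum = float(np.sum(np.var(mat, axis=0, ddof=1)))
    return VsrResult(vsr=var_sum / mean_sum, n_strides=mat.shape[0])


def _hedges_j(df: float) -> float:
    return 1.0 - 3.0 / (4.0 * df - 1.0)


def hedges_g(x1, x2, paired: bool = False) -> EffectSize:
    """Hedges' g for two samples, with a 95 % CI.

    g = J * (mean1 - mean2) / s_pooled with J = 1 - 3/(4 df - 1);
    df = n1 + n2 - 2 (independent) or n - 1 (paired).  The standardizer
    is the pooled standard deviation of the two samples in both designs.
    CI: normal approximation g +/- 1.96 SE(g); the paired SE uses the
    sample correlation between conditions (Borenstein).
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    n1, n2 = x1.size, x2.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs at least 2 observations")
    if paired and n1 != n2:
        raise ValueError("paired samples must have equal length")
    v1, v2 = np.var(x1, ddof=1), np.var(x2, ddof=1)
    df = (n1 - 1) if paired else (n1 + n2 - 2)
    s_pooled = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    if s_pooled == 0:
        raise ValueError("zero pooled variance: effect size undefined")
    d = (np.mean(x1) - np.mean(x2)) / s_pooled
    j = _hedges_j(df)
    g = j * d
    if paired:
        r = float(np.corrcoef(x1, x2)[0, 1]) if v1 > 0 and v2 > 0 else 0.0
        var_d = (1.0 / n1 + d**2 / (2.0 * n1)) * 2.0 * (1.0 - r)
    else:
        var_d = (n1 + n2) / (n1 * n2) + d**2 / (2.0 * (n1 + n2 - 2))
    se_g = j * np.sqrt(var_d)
    return EffectSize(g=float(g), ci_low=float(g - 1.96 * se_g), ci_high=float(g + 1.96 * se_g))


def partial_eta_sq(ss_effect: float, ss_error: float) -> float:
    """Partial eta-squared: SS_effect / (SS_effect + SS_error)."""
    if ss_effect < 0 or ss_error < 0:
        raise ValueError("sums of squares must be non-negative")
    if ss_effect == 0 and ss_error == 0:
        raise ValueError("partial eta-squared undefined when both SS are zero")
    return ss_effect / (ss_effect + ss_error)


def preference_test(
    scores,
    scale: str = "vas_100mm",
    null_value: float | None = None,
) -> PreferenceResult:
    """One-sample t-test of preference scores against no preference.

    The caller declares the scale (``vas_100mm`` or ``numeric_0_10``);
    the null defaults to its midpoint (50 mm / 5).  Reports the t
    statistic, two-sided p, and Hedges'-corrected effect size vs the
    null, g = J * (mean - null) / sd with df = n - 1.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    if n < 2:
        raise ValueError("need at least 2 scores")
    if scale not in PREFERENCE_SCALES:
        raise ValueError(f"unknown scale {scale!r}; choose from {sorted(PREFERENCE_SCALES)}")
    lo, hi = PREFERENCE_SCALES[scale]
    if null_value is None:
        null_value = 0.5 * (lo + hi)
    sd = float(np.std(scores, ddof=1))
    if sd == 0:
        raise ValueError("zero variance in preference scores: t-test undefined")
    t, p = sst.ttest_1samp(scores, null_value)
    j = _hedges_j(n - 1)
    d = (float(np.mean(scores)) - null_value) / sd
    g = j * d
    se_g = j * np.sqrt(1.0 / n + d**2 / (2.0 * n))
    effect = EffectSize(g=float(g), ci_low=float(g - 1.96 * se_g), ci_high=float(g + 1.96 * se_g))
    return PreferenceResult(
        t=float(t), p=float(p), effect=effect, mean=float(np.mean(scores)),
        null_value=float(null_value), n=n,
    )
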