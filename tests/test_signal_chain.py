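"""Filter-chain correctness: Butterworth responses, envelopes, normalization."""

import numpy as np
import pytest
from scipy import signal as sps

from myoankle.signal_chain import (
    ChainConfig,
    EmgTrace,
    Envelope,
    MvcCalibration,
    StreamingEnvelope,
    design_butterworth,
    mvc_from_trial,
    normalize_control,
    normalize_offline,
    offline_envelope,
    realtime_envelope,
)

RATE = 450.0


def _mag_db(sos, f, rate):
    w, h = sps.sosfreqz(sos, worN=[f], fs=rate)
    return 20 * np.log10(np.abs(h[0]))


class TestButterworthDesign:
    @pytest.mark.parametrize(
        "order,cutoff,kind",
        [(2, 70.0, "highpass"), (2, 3.0, "lowpass"), (2, 50.0, "highpass"), (2, 10.0, "lowpass")],
    )
    def test_cutoff_is_minus_3_db(self, order, cutoff, kind):
        sos = design_butterworth(order, cutoff, RATE, kind)
        assert _mag_db(sos, cutoff, RATE) == pytest.approx(20 * np.log10(1 / np.sqrt(2)), abs=0.1)

    def test_lowpass_dc_gain_unity(self):
        sos = design_butterworth(2, 3.0, RATE, "lowpass")
        assert np.prod([np.sum(s[:3]) / np.sum(np.r_[1, s[4:]]) for s in sos]) == pytest.approx(1.0)

    @pytest.mark.parametrize("kind", ["highpass", "lowpass"])
    def test_analytic_magnitude_at_probe_frequencies(self, kind):
        """Digital (bilinear-prewarped) response matches |H| of the analog
        Butterworth prototype at 10 probe frequencies within 0.1 dB."""
        cutoff = 70.0 if kind == "highpass" else 3.0
        sos = design_butterworth(2, cutoff, RATE, kind)
        probes = np.geomspace(cutoff / 8, min(cutoff * 8, RATE * 0.45), 10)
        # prewarp both probe and cutoff to compare against the analog prototype
        warp = lambda f: np.tan(np.pi * f / RATE)
        for f in probes:
            ratio = warp(f) / warp(cutoff)
            if kind == "highpass":
                ratio = 1.0 / ratio
            analytic_db = -10 * np.log10(1 + ratio**4)
            assert _mag_db(sos, f, RATE) == pytest.approx(analytic_db, abs=0.1)

    def test_nyquist_violation_raises(self):
        with pytest.raises(ValueError):
            design_butterworth(2, 300.0, RATE, "lowpass")
        with pytest.raises(ValueError):
            design_butterworth(2, 225.0, RATE, "highpass")


class TestRealtimeEnvelope:
    def test_zero_in_zero_out(self):
        env = realtime_envelope(EmgTrace(np.zeros(2000), RATE))
        assert np.all(env.samples == 0)

    def test_dc_rejected(self):
        env = realtime_envelope(EmgTrace(np.ones(9000), RATE))
        assert np.max(env.samples[-1000:]) < 1e-6

    def test_rectified_sine_steady_state_is_2a_over_pi(self):
        """Full-wave-rectified pass-band sine has mean 2a/pi; the 3 Hz
        low-pass recovers that mean within 5 %."""
        a = 1.3
        t = np.arange(int(20 * RATE)) / RATE
        emg = EmgTrace(a * np.sin(2 * np.pi * 155.0 * t), RATE)
        env = realtime_envelope(emg)
        steady = env.samples[int(10 * RATE) :]
        assert np.mean(steady) == pytest.approx(2 * a / np.pi, rel=0.05)

    def test_transition_band_sine_matches_analytic_gain(self):
        """Near the 70 Hz high-pass edge the exact steady state is
        |H_hp(f)| * 2a/pi (the 2a/pi rule holds only deep in the band)."""
        a, f = 1.3, 100.0
        sos = design_butterworth(2, 70.0, RATE, "highpass")
        gain = np.abs(sps.sosfreqz(sos, worN=[f], fs=RATE)[1][0])
        t = np.arange(int(20 * RATE)) / RATE
        env = realtime_envelope(EmgTrace(a * np.sin(2 * np.pi * f * t), RATE))
        steady = np.mean(env.samples[int(10 * RATE) :])
        assert steady == pytest.approx(gain * 2 * a / np.pi, rel=0.01)

    def test_causality_truncation_equivalence(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(3000)
        full = realtime_envelope(EmgTrace(x, RATE)).samples
        cut = realtime_envelope(EmgTrace(x[:1500], RATE)).samples
        np.testing.assert_allclose(full[:1500], cut, atol=1e-12)

    def test_streaming_matches_batch(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal(900)
        batch = realtime_envelope(EmgTrace(x, RATE)).samples
        stream = StreamingEnvelope()
        out = np.array([stream.push(v) for v in x])
        np.testing.assert_allclose(out, batch, atol=1e-12)

    def test_short_trace_flags_warmup(self):
        env = realtime_envelope(EmgTrace(np.ones(50), RATE))
        assert env.warmup_samples == 50  # entire trace inside warm-up

    def test_rejects_zero_lag_config(self):
        with pytest.raises(ValueError):
            realtime_envelope(EmgTrace(np.ones(100), RATE), ChainConfig.analysis())


def _gaussian_burst(center_s, rate, carrier_hz=120.0, sd_s=0.15, n_s=4.0):
    # cosine phase referenced to the center keeps the rectified burst
    # exactly time-symmetric about center_s
    t = np.arange(int(n_s * rate)) / rate
    window = np.exp(-0.5 * ((t - center_s) / sd_s) ** 2)
    return t, window * np.cos(2 * np.pi * carrier_hz * (t - center_s))


class TestOfflineEnvelope:
    def test_zero_in_zero_out(self):
        env = offline_envelope(EmgTrace(np.zeros(2000), RATE))
        assert np.all(env.samples == 0)

    def test_symmetric_burst_envelope_centered(self):
        """Zero phase: a time-symmetric burst yields a time-symmetric
        envelope whose centroid sits at the burst center within 1 sample
        (bare argmax can tie between residual-ripple lobes)."""
        t, x = _gaussian_burst(2.0, RATE)
        env = offline_envelope(EmgTrace(x, RATE)).samples
        centroid = np.sum(t * env) / np.sum(env)
        assert abs(centroid - 2.0) <= 1.0 / RATE
        c = int(2.0 * RATE)
        k = np.arange(1, 200)
        np.testing.assert_allclose(env[c - k], env[c + k], atol=1e-9)
        assert abs(t[np.argmax(env)] - 2.0) <= 5.0 / RATE

    def test_causal_chain_peaks_later(self):
        # group delay of the causal 3 Hz low-pass shifts the peak right
        t, x = _gaussian_burst(2.0, RATE)
        causal = realtime_envelope(EmgTrace(x, RATE)).samples
        zero_lag = offline_envelope(
            EmgTrace(x, RATE), ChainConfig(70.0, 3.0, 2, zero_lag=True)
        ).samples
        assert t[np.argmax(causal)] > t[np.argmax(zero_lag)]

    def test_time_reversal_symmetry(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(4000)
        fwd = offline_envelope(EmgTrace(x, RATE)).samples
        rev = offline_envelope(EmgTrace(x[::-1].copy(), RATE)).samples[::-1]
        interior = slice(200, -200)  # edge padding region excluded
        np.testing.assert_allclose(fwd[interior], rev[interior], atol=1e-8)


class TestMvcAndNormalization:
    def test_mvc_is_envelope_max(self):
        t = np.arange(int(3 * RATE)) / RATE
        x = np.sin(2 * np.pi * 100 * t) * np.minimum(t, 2.0)
        emg = EmgTrace(x, RATE)
        assert mvc_from_trial(emg) == pytest.approx(np.max(realtime_envelope(emg).samples))

    def test_two_bursts_takes_larger(self):
        t = np.arange(int(6 * RATE)) / RATE
        carrier = np.sin(2 * np.pi * 110 * t)
        win = 1.0 * np.exp(-0.5 * ((t - 1.5) / 0.3) ** 2) + 1.6 * np.exp(
            -0.5 * ((t - 4.5) / 0.3) ** 2
        )
        emg = EmgTrace(win * carrier, RATE)
        env = realtime_envelope(emg).samples
        first = np.max(env[: int(3 * RATE)])
        assert mvc_from_trial(emg) > first

    def test_all_zero_trial_raises(self):
        with pytest.raises(ValueError):
            mvc_from_trial(EmgTrace(np.zeros(int(2 * RATE)), RATE))

    def test_too_short_trial_raises(self):
        with pytest.raises(ValueError):
            mvc_from_trial(EmgTrace(np.ones(100), RATE))

    @pytest.mark.parametrize("scale,expected", [(1.0, 1.0), (2.0, 1.0), (0.5, 0.5), (0.0, 0.0)])
    def test_control_normalization_and_clamp(self, scale, expected):
        cal = MvcCalibration(mvc_value=2.0, fraction=0.6)
        env = Envelope(np.full(10, scale * cal.fraction * cal.mvc_value), RATE)
        u = normalize_control(env, cal).u
        assert np.all(u == pytest.approx(expected))

    def test_control_scale_invariance(self):
        rng = np.random.default_rng(5)
        e = rng.uniform(0, 3, 200)
        for c in (0.5, 2.0, 7.0):
            u1 = normalize_control(Envelope(e, RATE), MvcCalibration(2.0, 0.6)).u
            u2 = normalize_control(Envelope(c * e, RATE), MvcCalibration(c * 2.0, 0.6)).u
            np.testing.assert_allclose(u1, u2, atol=1e-14)

    def test_mvc_fraction_bounds(self):
        with pytest.raises(ValueError):
            MvcCalibration(1.0, 0.4)
        with pytest.raises(ValueError):
            MvcCalibration(-1.0, 0.6)

    def test_offline_normalization_unclamped(self):
        env = Envelope(np.array([0.0, 1.3, 2.6]), RATE)
        out = normalize_offline(env, 2.0)
        np.testing.assert_allclose(out.samples, [0.0, 0.65, 1.3])
        with pytest.raises(ValueError):
            normalize_offline(env, 0.0)
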