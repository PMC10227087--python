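"""Band-pass, pulse prominence averaging, oscillogram assembly, screening."""

import numpy as np
import pytest

from bpclip import oscillogram as og
from bpclip.oscillogram import (
    Oscillogram,
    bandpass_ppg,
    build_oscillogram,
    exclude_and_normalize,
    mean_pulse_amplitude,
    screen_subject,
)
from bpclip.protocol import LevelRecord


def sinusoid(freq_hz, seconds=5.0, fs=30.0, amplitude=1.0, phase=0.0, dc=0.0):
    t = np.arange(0, seconds, 1 / fs)
    return t, dc + amplitude * np.sin(2 * np.pi * freq_hz * t + phase)


class TestBandpass:
    def test_dc_rejected(self):
        x = np.full(300, 120.0)
        assert np.max(np.abs(bandpass_ppg(x, 30.0))) < 1e-6

    def test_cardiac_band_preserved(self):
        _, x = sinusoid(1.2, seconds=20.0)
        y = bandpass_ppg(x, 30.0)
        core = y[150:-150]
        assert np.max(np.abs(core)) == pytest.approx(1.0, rel=0.05)

    def test_slow_drift_attenuated(self):
        _, x = sinusoid(0.05, seconds=40.0)
        y = bandpass_ppg(x, 30.0)
        assert np.max(np.abs(y[300:-300])) < 0.1  # > 90 % attenuation

    def test_low_frame_rate_rejected(self):
        with pytest.raises(ValueError):
            bandpass_ppg(np.zeros(100), 15.0)


def oracle_prominence(x, p, sign=1.0):
    """Textbook prominence by direct scan: extend from the extremum on each
    side until a higher point or the window edge; the bases are the interval
    minima and the prominence is the drop to the higher base."""
    y = sign * np.asarray(x, dtype=float)
    bases = []
    for step in (-1, 1):
        i = p + step
        lowest = y[p]
        while 0 <= i < len(y) and y[i] <= y[p]:
            lowest = min(lowest, y[i])
            i += step
        bases.append(lowest)
    return y[p] - max(bases)


def oracle_mean_amplitude(x, min_prominence=0.5):
    """Brute-force check: enumerate strict local extrema by sign changes,
    keep those clearing the prominence floor, pair each interior peak with
    its adjacent troughs explicitly."""
    d = np.sign(np.diff(x))
    peaks = [
        i + 1
        for i in range(len(d) - 1)
        if d[i] > 0 and d[i + 1] < 0
        and oracle_prominence(x, i + 1, +1.0) >= min_prominence
    ]
    troughs = [
        i + 1
        for i in range(len(d) - 1)
        if d[i] < 0 and d[i + 1] > 0
        and oracle_prominence(x, i + 1, -1.0) >= min_prominence
    ]
    amps = []
    for p in peaks:
        left = [t for t in troughs if t < p]
        right = [t for t in troughs if t > p]
        if not left or not right:
            continue
        amps.append(x[p] - 0.5 * (x[left[-1]] + x[right[0]]))
    return (float(np.mean(amps)), len(amps)) if amps else (0.0, 0)


class TestMeanPulseAmplitude:
    def test_constant_is_flagged_zero(self):
        res = mean_pulse_amplitude(np.zeros(150), 30.0)
        assert res.amplitude == 0.0 and res.flagged

    def test_sinusoid_peak_to_trough(self):
        """A 1.2 Hz pulse of peak-to-trough 2A yields ~2A over 5-6 pulses."""
        A = 3.0
        _, x = sinusoid(1.2, seconds=5.0, amplitude=A)
        res = mean_pulse_amplitude(x, 30.0)
        assert res.amplitude == pytest.approx(2 * A, rel=0.05)
        assert 5 <= res.n_pulses <= 6

    @pytest.mark.parametrize("bpm", [36, 48, 60, 72, 84])
    def test_complete_pulse_count_by_heart_rate(self, bpm):
        """Heart rates 36-84 bpm beat 3-7 times in a 5-s window; the
        complete-pulse count equals the beat count, minus at most one pulse
        clipped by the window boundary."""
        beats = bpm / 60.0 * 5.0
        assert 3 <= beats <= 7
        _, x = sinusoid(bpm / 60.0, seconds=5.0, amplitude=2.0)
        res = mean_pulse_amplitude(x, 30.0)
        assert beats - 1 <= res.n_pulses <= beats

    def test_agrees_with_extremum_pairing_oracle(self):
        """On 100 seeded pulse-like signals the implementation matches the
        explicit local-extrema enumeration exactly."""
        fs = 30.0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            f = rng.uniform(0.7, 1.6)
            amp = rng.uniform(1.5, 20.0)
            t = np.arange(0, 5.0, 1 / fs)
            x = amp * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
            x = x + 0.1 * amp * np.sin(2 * np.pi * 0.25 * f * t)
            res = mean_pulse_amplitude(x, fs)
            oracle_amp, oracle_n = oracle_mean_amplitude(x)
            assert res.n_pulses == oracle_n
            assert res.amplitude == pytest.approx(oracle_amp, abs=1e-9)

    def test_sub_prominence_noise_ignored(self):
        rng = np.random.default_rng(0)
        x = 0.05 * rng.normal(size=150)  # well below the 0.5 floor
        res = mean_pulse_amplitude(x, 30.0)
        assert res.flagged and res.amplitude == 0.0


def make_levels(amplitudes, fs=30.0, freq=1.2):
    """Level records carrying pure sinusoidal pulses of given amplitudes."""
    targets = np.linspace(5, 95, len(amplitudes))
    levels = []
    for i, (a, s) in enumerate(zip(amplitudes, targets)):
        t, x = sinusoid(freq, seconds=5.0, fs=fs, amplitude=a / 2.0, dc=150.0)
        levels.append(
            LevelRecord(
                level_index=i,
                target_scale=float(s),
                timestamps=t,
                force_scale=np.full(len(t), float(s)),
                ppg=x,
            )
        )
    return levels


class TestBuildOscillogram:
    def test_one_point_per_level(self):
        amps = np.concatenate([np.linspace(2, 30, 10), np.linspace(28, 2, 10)])
        osc = build_oscillogram(make_levels(amps), frame_rate=30.0)
        assert len(osc) == 20 and osc.n_raw == 20
        assert np.all(np.diff(osc.force_scale) > 0)
        assert np.all(np.diff(osc.pressure_mmhg) > 0)
        assert np.allclose(osc.amplitude, amps, rtol=0.06)

    def test_missing_level_reported(self):
        levels = make_levels(np.linspace(2, 20, 6))
        del levels[2]
        with pytest.raises(ValueError, match=r"\[2\]"):
            build_oscillogram(levels, frame_rate=30.0)

    def test_pulseless_levels_flagged(self):
        levels = make_levels([0.0, 0.0, 0.0, 0.0])
        osc = build_oscillogram(levels, frame_rate=30.0)
        assert np.all(osc.flags) and np.all(osc.amplitude == 0.0)


class TestExcludeAndNormalize:
    def test_twenty_points_become_eighteen(self):
        amps = np.concatenate([np.linspace(2, 30, 10), np.linspace(28, 2, 10)])
        osc = build_oscillogram(make_levels(amps), frame_rate=30.0)
        norm = exclude_and_normalize(osc)
        assert len(norm) == 18
        assert norm.normalized and norm.n_raw == 20
        assert norm.amplitude.min() == 0.0
        assert norm.amplitude.max() == 1.0

    def test_single_spike(self):
        osc = Oscillogram(
            force_scale=np.linspace(5, 95, 7),
            pressure_mmhg=np.linspace(25, 307, 7),
            amplitude=np.array([0.0, 0.0, 0.0, 5.0, 0.0, 0.0, 0.0]),
        )
        norm = exclude_and_normalize(osc)
        assert np.count_nonzero(norm.amplitude == 1.0) == 1
        assert np.count_nonzero(norm.amplitude == 0.0) == len(norm) - 1

    def test_degenerate_rejected(self):
        osc = Oscillogram(
            force_scale=np.array([5.0, 50.0, 95.0]),
            pressure_mmhg=np.array([25.0, 166.0, 307.0]),
            amplitude=np.array([1.0, 1.0, 1.0]),
        )
        with pytest.raises(ValueError, match="degenerate"):
            exclude_and_normalize(osc)

    def test_too_few_points_rejected(self):
        osc = Oscillogram(
            force_scale=np.array([5.0, 95.0]),
            pressure_mmhg=np.array([25.0, 307.0]),
            amplitude=np.array([1.0, 2.0]),
        )
        with pytest.raises(ValueError):
            exclude_and_normalize(osc)

    def test_divide_by_max_variant(self):
        amps = np.concatenate([np.linspace(2, 30, 10), np.linspace(28, 2, 10)])
        osc = build_oscillogram(make_levels(amps), frame_rate=30.0)
        norm = exclude_and_normalize(osc, mode="max")
        assert norm.amplitude.max() == 1.0
        assert norm.amplitude.min() > 0.0  # retained minimum is not zeroed


class TestScreening:
    def raw_osc(self, amplitudes):
        n = len(amplitudes)
        return Oscillogram(
            force_scale=np.linspace(5, 95, n),
            pressure_mmhg=np.linspace(25, 307, n),
            amplitude=np.asarray(amplitudes, dtype=float),
        )

    def test_wide_pulse_pressure_excluded(self):
        res = screen_subject(self.raw_osc([0, 5, 20, 5, 0]), 170.0, 85.0)
        assert not res.retained and res.reason == "pulse_pressure_gt_80"

    def test_normal_subject_retained(self):
        res = screen_subject(self.raw_osc([0, 5, 20, 5, 0]), 120.0, 80.0)
        assert res.retained and res.reason == "ok"

    def test_exactly_80_is_retained(self):
        res = screen_subject(self.raw_osc([0, 5, 20, 5, 0]), 160.0, 80.0)
        assert res.retained  # the rule is "more than 80"

    def test_no_pulse_excluded(self):
        res = screen_subject(self.raw_osc([0.0] * 20), 120.0, 80.0)
        assert not res.retained and res.reason == "no_pulse"

    def test_no_pulse_takes_precedence(self):
        res = screen_subject(self.raw_osc([0.0] * 20), 180.0, 85.0)
        assert res.reason == "no_pulse"

    def test_normalized_oscillogram_rejected(self):
        osc = self.raw_osc([0, 5, 20, 5, 0])
        norm = exclude_and_normalize(osc)
        with pytest.raises(ValueError):
            screen_subject(norm, 120.0, 80.0)
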