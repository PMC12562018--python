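"""Acoustic feature formulas against hand-computed and synthetic oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.signal import lfilter

from dysvoice.audio import AudioSignal
from dysvoice.denoise import StftParams
from dysvoice.features import (FEATURE_NAMES, FeatureConfig, PitchCycles,
                               UnvoicedSignalError, delta_features,
                               extract_cycles, featurize, formants_lpc,
                               hnr_db, jitter_percent, mel_filterbank,
                               mel_spectrogram, mfcc_stack, shimmer_db,
                               shimmer_percent, spectral_descriptors,
                               track_f0, zero_crossing_rate)
from dysvoice.synth import VoiceProfile, synth_vowel


class TestZeroCrossingRate:
    @pytest.mark.parametrize("frame,expected", [
        (np.ones(50), 0.0),
        (np.tile([1.0, -1.0], 25), 1.0),
        (np.array([1.0, -1.0, 1.0, 1.0]), 2.0 / 3.0),
    ])
    def test_hand_cases(self, frame, expected):
        assert zero_crossing_rate(frame) == pytest.approx(expected)

    def test_too_short(self):
        with pytest.raises(ValueError):
            zero_crossing_rate(np.array([1.0]))


class TestSpectralDescriptors:
    def test_two_bin_centroid_and_bandwidth(self):
        freqs = np.array([0.0, 100.0, 200.0, 300.0, 400.0])
        mags = np.array([0.0, 1.0, 0.0, 1.0, 0.0])
        d = spectral_descriptors(mags, freqs)
        assert d.centroid == pytest.approx(200.0)
        assert d.bandwidth == pytest.approx(100.0)

    def test_single_bin_is_pure_tone_limit(self):
        freqs = np.linspace(0, 4000, 129)
        mags = np.zeros(129)
        mags[40] = 2.0
        d = spectral_descriptors(mags, freqs)
        assert d.flatness == 0.0
        assert d.bandwidth == pytest.approx(0.0)
        assert d.centroid == pytest.approx(freqs[40])

    def test_flat_spectrum_is_white_noise_limit(self):
        d = spectral_descriptors(np.full(257, 0.5), np.linspace(0, 4000, 257))
        assert d.flatness == pytest.approx(1.0)

    def test_all_zero_flagged_degenerate(self):
        d = spectral_descriptors(np.zeros(64), np.linspace(0, 4000, 64))
        assert not d.valid
        assert math.isnan(d.centroid)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 9999))
    def test_ranges_on_random_spectra(self, seed):
        rng = np.random.default_rng(seed)
        mags = rng.uniform(0.0, 1.0, 100) + 1e-6
        d = spectral_descriptors(mags, np.linspace(0, 4000, 100))
        assert 0.0 <= d.flatness <= 1.0 + 1e-12
        assert d.bandwidth >= 0.0


class TestTrackF0:
    def test_pure_tone_within_2hz(self, tone_8k):
        track = track_f0(tone_8k)
        voiced = track.f0[track.voicing]
        assert voiced.size > 0
        assert np.all(np.abs(voiced - 200.0) < 2.0)

    def test_white_noise_mostly_unvoiced(self, rng):
        sig = AudioSignal(rng.standard_normal(8000), 8000)
        track = track_f0(sig)
        assert track.n_voiced < 0.5 * track.f0.size

    def test_silence_unvoiced(self):
        track = track_f0(AudioSignal(np.zeros(8000), 8000))
        assert track.n_voiced == 0
        assert np.all(track.f0 == 0.0)

    def test_invalid_range(self, tone_8k):
        with pytest.raises(ValueError):
            track_f0(tone_8k, fmin=500, fmax=100)


class TestExtractCycles:
    def test_periodic_pulse_train_periods_exact(self):
        rate = 8000
        period = 40  # 5 ms
        x = np.zeros(3 * rate)
        x[::period] = 1.0
        x = lfilter([1.0], [1.0, -0.95], x)  # give the pulses a tail
        cycles = extract_cycles(AudioSignal(x / np.abs(x).max(), rate))
        np.testing.assert_allclose(cycles.periods, period / rate,
                                   atol=1.0 / rate)

    def test_amplitude_modulation_recovered_in_amplitudes(self):
        rate = 8000
        t = np.arange(2 * rate) / rate
        envelope = 1.0 + 0.4 * np.sin(2 * np.pi * 2.0 * t)
        x = envelope * np.sin(2 * np.pi * 125 * t)
        cycles = extract_cycles(AudioSignal(x, rate))
        # periods constant, amplitudes track the 2 Hz envelope
        assert np.std(cycles.periods) / np.mean(cycles.periods) < 0.02
        amps = cycles.amplitudes
        assert amps.max() > 1.3 and amps.min() < 0.7

    def test_unvoiced_noise_raises(self, rng):
        with pytest.raises(UnvoicedSignalError):
            extract_cycles(AudioSignal(rng.standard_normal(8000), 8000))


class TestJitterShimmer:
    def test_jitter_printed_example(self):
        cycles = PitchCycles(np.array([10.0, 10.5, 10.0, 10.5]) / 1000,
                             np.ones(5), np.arange(5.0), 8000)
        assert jitter_percent(cycles) == pytest.approx(100 * 0.5 / 10.25,
                                                       rel=1e-9)

    def test_jitter_scale_invariant_and_zero_for_constant(self):
        base = PitchCycles(np.array([8.0, 8.4, 8.1]) / 1000, np.ones(4),
                           np.arange(4.0), 8000)
        doubled = PitchCycles(2 * base.periods, np.ones(4),
                              np.arange(4.0), 8000)
        assert jitter_percent(base) == pytest.approx(jitter_percent(doubled))
        const = PitchCycles(np.full(6, 5e-3), np.ones(7), np.arange(7.0), 8000)
        assert jitter_percent(const) == 0.0

    def test_shimmer_printed_example(self):
        cycles = PitchCycles(np.full(2, 5e-3),
                             np.array([1.0, 0.9, 1.0]), np.arange(3.0), 8000)
        expected = 100 * (0.1 + 0.1) / 2 / ((1.0 + 0.9 + 1.0) / 3)
        assert shimmer_percent(cycles) == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(10.3448, abs=1e-3)

    def test_shimmer_scale_invariant(self):
        a = PitchCycles(np.full(3, 5e-3), np.array([1.0, 1.2, 0.9, 1.1]),
                        np.arange(4.0), 8000)
        b = PitchCycles(np.full(3, 5e-3), 3.0 * a.amplitudes,
                        np.arange(4.0), 8000)
        assert shimmer_percent(a) == pytest.approx(shimmer_percent(b))

    def test_shimmer_db_constant_is_zero(self):
        c = PitchCycles(np.full(3, 5e-3), np.full(4, 0.7),
                        np.arange(4.0), 8000)
        assert shimmer_db(c) == 0.0

    def test_too_few_cycles(self):
        lone = PitchCycles(np.array([5e-3]), np.array([1.0]),
                           np.array([0.0]), 8000)
        with pytest.raises(ValueError):
            jitter_percent(lone)
        with pytest.raises(ValueError):
            shimmer_percent(lone)


class TestHnr:
    def test_known_mixture_recovered(self):
        # harmonic-to-noise power ratio 20 -> 13.01 dB
        profile = VoiceProfile(f0_mean=200.0, f0_sd=1.0, jitter_pct=0.3,
                               shimmer_pct=1.0,
                               hnr_db=10 * math.log10(20.0))
        sig = synth_vowel(profile, seed=5)
        assert hnr_db(sig) == pytest.approx(10 * math.log10(20.0), abs=1.0)

    def test_formula_monotone_in_mixture(self):
        values = []
        for target in (5.0, 15.0):
            profile = VoiceProfile(f0_mean=150.0, hnr_db=target)
            values.append(hnr_db(synth_vowel(profile, seed=2)))
        assert values[0] < values[1]

    def test_unvoiced_raises(self, rng):
        with pytest.raises((UnvoicedSignalError, ValueError)):
            hnr_db(AudioSignal(rng.standard_normal(8000), 8000))


class TestFormants:
    @staticmethod
    def _resonant_noise(rng, freqs, bws, rate=8000, n=4000):
        x = rng.standard_normal(n)
        for f, bw in zip(freqs, bws):
            r = math.exp(-math.pi * bw / rate)
            theta = 2 * math.pi * f / rate
            x = lfilter([1.0 - r], [1.0, -2 * r * math.cos(theta), r * r], x)
        return x

    def test_two_pole_resonators_recovered(self, rng):
        x = self._resonant_noise(rng, (700.0, 1200.0), (60.0, 90.0))
        f1, f2, _ = formants_lpc(x[500:1500], 8000)
        assert f1 == pytest.approx(700.0, abs=50.0)
        assert f2 == pytest.approx(1200.0, abs=50.0)

    def test_pure_sinusoid_single_resonance(self):
        t = np.arange(600) / 8000.0
        f1, _, _ = formants_lpc(np.sin(2 * np.pi * 800 * t), 8000)
        assert f1 == pytest.approx(800.0, abs=30.0)

    def test_white_noise_unreliable(self, rng):
        # no resonance structure: bandwidth filter rejects most roots
        found = []
        for _ in range(5):
            f1, f2, f3 = formants_lpc(rng.standard_normal(600), 8000,
                                      max_bandwidth=80.0)
            found.append(np.isnan([f1, f2, f3]).sum())
        assert np.mean(found) > 1.0

    def test_degenerate_frame_rejected(self):
        with pytest.raises(ValueError):
            formants_lpc(np.zeros(600), 8000)


class TestMfcc:
    def test_matches_direct_summation_oracle(self, tone_8k):
        n_mels, n_coeffs = 24, 10
        mfcc, _, _ = mfcc_stack(tone_8k, n_coeffs, n_mels)
        # independent oracle: explicit filterbank -> log -> cosine sums
        params = StftParams.for_rate(8000)
        from dysvoice.denoise import stft
        power = np.abs(stft(tone_8k, params).values) ** 2
        fb = mel_filterbank(n_mels, params.fft_size, 8000)
        log_e = np.log(np.maximum(power @ fb.T, 1e-10))
        expected = np.empty((log_e.shape[0], n_coeffs))
        for ti in range(log_e.shape[0]):
            for n in range(n_coeffs):
                expected[ti, n] = sum(
                    log_e[ti, m - 1] * math.cos(math.pi * n * (m - 0.5) / n_mels)
                    for m in range(1, n_mels + 1))
        np.testing.assert_allclose(mfcc, expected, rtol=1e-8, atol=1e-8)

    def test_flat_mel_energies_zero_higher_coefficients(self):
        # DCT of a constant log-energy vector vanishes for n >= 1
        n_mels = 16
        m = np.arange(1, n_mels + 1)
        log_e = np.full(n_mels, 3.7)
        for n in range(1, 8):
            coeff = np.sum(log_e * np.cos(np.pi * n * (m - 0.5) / n_mels))
            assert coeff == pytest.approx(0.0, abs=1e-10)

    def test_delta_of_linear_ramp_is_slope(self):
        a = 0.37
        track = a * np.arange(30)[:, None] * np.ones((1, 3))
        delta = delta_features(track, width=2)
        np.testing.assert_allclose(delta[2:-2], a, atol=1e-12)

    def test_delta_of_constant_is_zero(self):
        delta = delta_features(np.full((20, 4), 2.5), width=2)
        np.testing.assert_allclose(delta, 0.0)


class TestMelSpectrogram:
    def test_shape_contract(self, tone_8k):
        grid = mel_spectrogram(tone_8k, n_mels=128, n_frames=40)
        assert grid.shape == (40, 128)

    def test_silence_uniform_floor(self):
        grid = mel_spectrogram(AudioSignal(np.zeros(24000), 8000))
        assert np.all(grid.grid == grid.db_floor)

    def test_tone_peaks_in_correct_mel_band(self):
        t = np.arange(24000) / 8000.0
        sig = AudioSignal(np.sin(2 * np.pi * 1000 * t), 8000)
        grid = mel_spectrogram(sig, n_mels=128, n_frames=40)
        peak_bands = np.argmax(grid.grid, axis=1)
        fb = mel_filterbank(128, 512, 8000)
        freqs = np.arange(257) * 8000 / 512
        centers = fb @ freqs / np.maximum(fb.sum(axis=1), 1e-12)
        assert np.all(np.abs(centers[peak_bands] - 1000.0) < 150.0)

    def test_mel_filterbank_rows_nonzero(self):
        fb = mel_filterbank(128, 256, 8000)
        assert fb.shape == (128, 129)
        assert np.all(fb.sum(axis=1) > 0)


class TestFeaturize:
    def test_fixed_schema_and_determinism(self):
        sig = synth_vowel(VoiceProfile(), seed=3)
        v1 = featurize(sig)
        v2 = featurize(sig)
        assert tuple(v1.values.keys()) == FEATURE_NAMES
        assert v1.values == v2.values  # bit-for-bit deterministic

    def test_unvoiced_input_flags_voice_quality_missing(self, rng):
        sig = AudioSignal(0.3 * rng.standard_normal(8000), 8000)
        vec = featurize(sig)
        assert "jitter_pct" in vec.missing
        assert math.isnan(vec.values["hnr_db"])
        assert tuple(vec.values.keys()) == FEATURE_NAMES  # schema preserved

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            featurize(AudioSignal(np.zeros(1000), 8000))

    def test_amplitude_scale_invariance_of_descriptors(self):
        sig = synth_vowel(VoiceProfile(), seed=9)
        half = AudioSignal(0.5 * sig.samples, sig.rate)
        v1, v2 = featurize(sig), featurize(half)
        for name in ("zcr_mean", "flatness_mean", "contrast_mean",
                     "jitter_pct", "shimmer_pct", "f0_mean_hz"):
            assert v1.values[name] == pytest.approx(v2.values[name],
                                                    rel=1e-6, abs=1e-9)
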