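"""Spectral gating: STFT round trips, noise floor estimation, gain law."""

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st

from dysvoice.audio import AudioSignal
from dysvoice.denoise import (GateParams, NoiseProfile, Spectrogram,
                              SpectralGateDenoiser, StftParams, denoise,
                              estimate_noise_psd, istft, spectral_gate, stft)

PARAMS = StftParams(frame_length=200, hop=80, fft_size=256)


def _tone(freq, rate=8000, seconds=1.0, amp=0.8):
    t = np.arange(int(rate * seconds)) / rate
    return AudioSignal(amp * np.sin(2 * np.pi * freq * t), rate)


class TestStft:
    def test_bin_centered_tone_concentrates_energy(self):
        freq = 1000.0  # bin 32 of a 256-point FFT at 8 kHz
        spec = stft(_tone(freq), PARAMS)
        mags = spec.magnitude
        assert np.all(np.argmax(mags, axis=1) == 32)
        # the mainlobe (3 bins around the tone) carries nearly all energy
        ratio = (mags[:, 31:34] ** 2).sum(axis=1) / (mags ** 2).sum(axis=1)
        assert ratio.min() > 0.9

    def test_zero_signal_gives_zero_grid(self):
        spec = stft(AudioSignal(np.zeros(4000), 8000), PARAMS)
        assert np.all(spec.values == 0)

    def test_perfect_reconstruction_interior(self, rng):
        x = rng.standard_normal(8000)
        spec = stft(AudioSignal(x, 8000), PARAMS)
        back = istft(spec, length=8000).samples
        L = PARAMS.frame_length
        np.testing.assert_allclose(back[L:-L], x[L:-L], atol=1e-9)

    def test_matches_scipy_magnitudes(self, rng):
        # independent oracle: scipy's STFT with identical framing
        from scipy.signal import stft as scipy_stft
        x = rng.standard_normal(4000)
        ours = stft(AudioSignal(x, 8000), PARAMS)
        _, _, Z = scipy_stft(x, fs=8000, window="hann",
                             nperseg=PARAMS.frame_length,
                             noverlap=PARAMS.frame_length - PARAMS.hop,
                             nfft=PARAMS.fft_size, boundary=None,
                             padded=False, scaling="spectrum")
        from scipy.signal import get_window
        win_sum = get_window("hann", PARAMS.frame_length, fftbins=True).sum()
        np.testing.assert_allclose(np.abs(ours.values.T),
                                   np.abs(Z) * win_sum, rtol=1e-6, atol=1e-9)

    def test_too_short_signal_raises(self):
        with pytest.raises(ValueError):
            stft(AudioSignal(np.zeros(100), 8000), PARAMS)


def _spec_from_mags(mags):
    """Build a spectrogram fixture with given magnitudes (zero phase)."""
    frames, bins = mags.shape
    params = StftParams(frame_length=2 * (bins - 1), hop=bins - 1,
                        fft_size=2 * (bins - 1))
    return Spectrogram(mags.astype(complex), params, 8000)


class TestNoisePsd:
    def test_constant_magnitude_gives_squared(self):
        spec = _spec_from_mags(np.full((12, 129), 3.0))
        noise = estimate_noise_psd(spec, 10)
        np.testing.assert_allclose(noise.psd, 9.0)
        assert noise.n_frames_used == 10

    def test_only_leading_frames_used(self):
        mags = np.zeros((20, 129))
        mags[10:] = 100.0  # loud, but after the noise window
        noise = estimate_noise_psd(_spec_from_mags(mags), 10)
        np.testing.assert_allclose(noise.psd, 0.0)

    def test_two_frame_hand_computation(self):
        mags = np.zeros((2, 129))
        mags[0] = 1.0
        mags[1] = 3.0
        noise = estimate_noise_psd(_spec_from_mags(mags), 2)
        np.testing.assert_allclose(noise.psd, (1.0 + 9.0) / 2.0)

    def test_too_few_frames(self):
        with pytest.raises(ValueError):
            estimate_noise_psd(_spec_from_mags(np.ones((3, 129))), 10)


class TestSpectralGate:
    def setup_method(self):
        mags = np.full((5, 129), 10.0)
        mags[:, 7] = 1.0  # one weak bin
        self.spec = _spec_from_mags(mags)
        self.noise = NoiseProfile(np.full(129, 4.0 / 1.5), 10)
        # threshold k*P_N = 4.0 in power -> |X| = 2.0 boundary

    def test_supra_threshold_passes_unchanged(self):
        out = spectral_gate(self.spec, self.noise, GateParams())
        np.testing.assert_array_equal(out.values[:, 20], self.spec.values[:, 20])

    def test_sub_threshold_scaled_by_alpha(self):
        out = spectral_gate(self.spec, self.noise, GateParams(alpha=0.1))
        np.testing.assert_allclose(np.abs(out.values[:, 7]), 0.1)

    def test_alpha_one_is_identity(self):
        out = spectral_gate(self.spec, self.noise, GateParams(alpha=1.0))
        np.testing.assert_array_equal(out.values, self.spec.values)

    def test_phase_preserved(self, rng):
        values = rng.standard_normal((6, 129)) + 1j * rng.standard_normal((6, 129))
        spec = replace(self.spec, values=values)
        out = spectral_gate(spec, self.noise, GateParams())
        nonzero = np.abs(out.values) > 0
        np.testing.assert_allclose(np.angle(out.values)[nonzero],
                                   np.angle(spec.values)[nonzero])

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            spectral_gate(self.spec, NoiseProfile(np.ones(65), 10), GateParams())

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 9999), k=st.floats(0.5, 4.0))
    def test_contraction_and_monotonicity_in_k(self, seed, k):
        rng = np.random.default_rng(seed)
        values = rng.standard_normal((4, 129)) + 1j * rng.standard_normal((4, 129))
        spec = replace(self.spec, values=values)
        noise = NoiseProfile(rng.uniform(0, 2, 129), 10)
        out = spectral_gate(spec, noise, GateParams(k=k))
        assert np.all(np.abs(out.values) <= np.abs(spec.values) + 1e-12)
        harder = spectral_gate(spec, noise, GateParams(k=2 * k))
        assert np.all(np.abs(harder.values) <= np.abs(out.values) + 1e-12)


class TestDenoise:
    @staticmethod
    def _noisy_tone(rng, snr_db=0.0, rate=8000):
        """Tone with stationary white noise and a noise-only lead-in."""
        lead = 10 * 80 + 200  # 10 noise frames + one frame
        n_tone = 2 * rate
        t = np.arange(n_tone) / rate
        clean = np.concatenate([np.zeros(lead),
                                0.7 * np.sin(2 * np.pi * 500 * t)])
        p_sig = 0.49 / 2
        p_noise = p_sig / 10 ** (snr_db / 10)
        noise = rng.standard_normal(clean.size) * np.sqrt(p_noise)
        return clean, AudioSignal(clean + noise, rate), lead

    def test_silence_in_silence_out(self):
        out = denoise(AudioSignal(np.zeros(8000), 8000))
        assert np.allclose(out.samples, 0.0)

    def test_clean_tone_preserved(self, rng):
        clean, noisy, lead = self._noisy_tone(rng, snr_db=60.0)
        out = denoise(noisy)
        seg = slice(lead + 400, lead + 8000)
        corr = np.corrcoef(out.samples[seg], clean[seg])[0, 1]
        assert corr > 0.99

    def test_snr_improves_at_0db(self, rng):
        clean, noisy, lead = self._noisy_tone(rng, snr_db=0.0)
        out = denoise(noisy, renormalize=False)
        seg = slice(lead + 400, lead + 2 * 8000 - 400)
        c = clean[seg]

        def snr(y):
            gain = np.dot(y, c) / np.dot(c, c)
            resid = y - gain * c
            return 10 * np.log10(np.dot(gain * c, gain * c)
                                 / np.dot(resid, resid))
        assert snr(out.samples[seg]) > snr(noisy.samples[seg]) + 3.0

    def test_denoised_correlation_beats_noisy(self, rng):
        clean, noisy, lead = self._noisy_tone(rng, snr_db=0.0)
        out = denoise(noisy, renormalize=False)
        seg = slice(lead + 400, lead + 2 * 8000 - 400)
        c_out = np.corrcoef(out.samples[seg], clean[seg])[0, 1]
        c_in = np.corrcoef(noisy.samples[seg], clean[seg])[0, 1]
        assert c_out >= c_in

    def test_energy_never_grows(self, rng):
        _, noisy, _ = self._noisy_tone(rng, snr_db=5.0)
        out = denoise(noisy, renormalize=False)
        assert np.sum(out.samples ** 2) <= np.sum(noisy.samples ** 2) * (1 + 1e-6)

    def test_output_length_equals_input(self, rng):
        _, noisy, _ = self._noisy_tone(rng)
        assert len(denoise(noisy)) == len(noisy)


def test_denoiser_transformer_roundtrip(rng):
    sigs = [AudioSignal(rng.standard_normal(4000), 8000) for _ in range(2)]
    den = SpectralGateDenoiser(alpha=0.2)
    out = den.fit_transform(sigs)
    assert len(out) == 2 and all(len(o) == 4000 for o in out)
    assert den.get_params()["alpha"] == 0.2
    den.set_params(alpha=0.3)
    assert den.alpha == 0.3
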