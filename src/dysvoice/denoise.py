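"""Spectral-gating noise reduction.

The denoiser follows the classic gate recipe: short-time Fourier
transform, noise power-spectral-density estimate from the leading
(assumed noise-only) frames, a per-bin threshold at ``k`` times the noise
floor, and a binary gain that passes supra-threshold coefficients
unchanged while attenuating sub-threshold ones by ``alpha``; phase is
never altered.  Defaults: k = 1.5, alpha = 0.1, 10 noise frames.

The comparison of a coefficient against the threshold is done in the
power domain by default (``|X|^2 <= k * P_N``); the alternative reading,
comparing the magnitude itself against ``k * P_N``, is available via
``GateParams.domain = "magnitude"``.  The two differ only in effective
aggressiveness; the pass/attenuate semantics are identical.

Frames are taken literally from the head of the signal with no center
padding, so "the first T frames" means exactly the first
``T * hop + frame_length`` samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import get_window

from .audio import AudioSignal, normalize

__all__ = [
    "StftParams",
    "Spectrogram",
    "NoiseProfile",
    "GateParams",
    "stft",
    "istft",
    "estimate_noise_psd",
    "spectral_gate",
    "denoise",
    "SpectralGateDenoiser",
]


@dataclass(frozen=True)
class StftParams:
    """Analysis frame geometry. Defaults are standard speech-analysis
    values (25 ms frames, 10 ms hop, Hann taper) expressed in samples
    for an 8 kHz signal; use :meth:`for_rate` to derive them for any rate."""

    frame_length: int = 200
    hop: int = 80
    window: str = "hann"
    fft_size: int = 256

    def __post_init__(self) -> None:
        if not (0 < self.hop <= self.frame_length <= self.fft_size):
            raise ValueError("need 0 < hop <= frame_length <= fft_size")

    @classmethod
    def for_rate(cls, rate: int, frame_ms: float = 25.0, hop_ms: float = 10.0,
                 window: str = "hann") -> "StftParams":
        frame = int(round(rate * frame_ms / 1000.0))
        hop = int(round(rate * hop_ms / 1000.0))
        fft = 1 << max(1, (frame - 1)).bit_length()
        return cls(frame_length=frame, hop=hop, window=window, fft_size=fft)

    @property
    def n_bins(self) -> int:
        return self.fft_size // 2 + 1

    def taper(self) -> np.ndarray:
        return get_window(self.window, self.frame_length, fftbins=True)


@dataclass(frozen=True)
class Spectrogram:
    """One-sided complex STFT grid, indexed ``values[frame, bin]``."""

    values: np.ndarray
    params: StftParams
    rate: int

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.complex128)
        object.__setattr__(self, "values", values)
        if values.ndim != 2 or values.shape[0] < 1:
            raise ValueError("spectrogram needs at least one frame")
        if values.shape[1] != self.params.n_bins:
            raise ValueError(
                f"bin count {values.shape[1]} != fft_size/2+1 = {self.params.n_bins}")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)


@dataclass(frozen=True)
class NoiseProfile:
    """Per-bin noise power estimated from the leading frames."""

    psd: np.ndarray
    n_frames_used: int

    def __post_init__(self) -> None:
        psd = np.asarray(self.psd, dtype=np.float64)
        object.__setattr__(self, "psd", psd)
        if self.n_frames_used < 1:
            raise ValueError("need at least one noise frame")
        if np.any(psd < 0):
            raise ValueError("noise PSD must be non-negative")


@dataclass(frozen=True)
class GateParams:
    """Gate configuration: threshold multiplier k, sub-threshold gain
    alpha, number of leading noise-only frames, and comparison domain."""

    k: float = 1.5
    alpha: float = 0.1
    noise_frames: int = 10
    domain: str = "power"  # or "magnitude"

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be positive")
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")
        if self.noise_frames < 1:
            raise ValueError("noise_frames must be >= 1")
        if self.domain not in ("power", "magnitude"):
            raise ValueError(f"unknown gate domain {self.domain!r}")


def stft(signal: AudioSignal, params: StftParams | None = None) -> Spectrogram:
    """Short-time Fourier transform.

    Frame ``t`` covers samples ``[t*hop, t*hop + frame_length)`` of the
    input — no centering or boundary padding — and is tapered by the
    analysis window before a one-sided FFT of ``fft_size`` points.
    """
    params = params or StftParams.for_rate(signal.rate)
    x = signal.samples
    if x.size < params.frame_length:
        raise ValueError(
            f"signal of {x.size} samples is shorter than one frame "
            f"({params.frame_length})")
    n_frames = 1 + (x.size - params.frame_length) // params.hop
    idx = (np.arange(params.frame_length)[None, :]
           + params.hop * np.arange(n_frames)[:, None])
    frames = x[idx] * params.taper()[None, :]
    values = np.fft.rfft(frames, n=params.fft_size, axis=1)
    return Spectrogram(values, params, signal.rate)


def istft(spec: Spectrogram, length: int | None = None) -> AudioSignal:
    """Inverse STFT by windowed overlap-add with least-squares envelope
    normalization (synthesis window = analysis window).

    Samples where the squared-window envelope is numerically zero (the
    very edges of a tapered first/last frame) are left at zero.
    """
    p = spec.params
    win = p.taper()
    n = (spec.n_frames - 1) * p.hop + p.frame_length
    out = np.zeros(n)
    env = np.zeros(n)
    frames = np.fft.irfft(spec.values, n=p.fft_size, axis=1)[:, :p.frame_length]
    for t in range(spec.n_frames):
        sl = slice(t * p.hop, t * p.hop + p.frame_length)
        out[sl] += frames[t] * win
        env[sl] += win * win
    # samples under a weakly-covered envelope (the tapered frame edges)
    # are zeroed rather than amplified by a near-zero division
    good = env > 1e-3 * env.max()
    out[good] /= env[good]
    out[~good] = 0.0
    if length is not None:
        if length <= n:
            out = out[:length]
        else:
            out = np.concatenate([out, np.zeros(length - n)])
    return AudioSignal(out, spec.rate)


def estimate_noise_psd(spec: Spectrogram, noise_frames: int = 10) -> NoiseProfile:
    """Noise power per bin: mean squared magnitude of the first
    ``noise_frames`` frames, ``P_N(f) = (1/T) sum_t |X(t,f)|^2``."""
    if spec.n_frames < noise_frames:
        raise ValueError(
            f"need >= {noise_frames} frames to estimate noise, have {spec.n_frames}")
    if noise_frames < 1:
        raise ValueError("noise_frames must be >= 1")
    psd = np.mean(np.abs(spec.values[:noise_frames]) ** 2, axis=0)
    return NoiseProfile(psd, noise_frames)


def spectral_gate(spec: Spectrogram, noise: NoiseProfile,
                  gate: GateParams | None = None) -> Spectrogram:
    """Apply the binary gain: coefficients above the per-bin threshold
    ``T(f) = k * P_N(f)`` pass unchanged, the rest are scaled by alpha.
    The gain is real, so phase is preserved exactly."""
    gate = gate or GateParams()
    if noise.psd.shape[0] != spec.values.shape[1]:
        raise ValueError("noise profile and spectrogram bin grids differ")
    threshold = gate.k * noise.psd[None, :]
    if gate.domain == "power":
        above = np.abs(spec.values) ** 2 > threshold
    else:
        above = np.abs(spec.values) > threshold
    gain = np.where(above, 1.0, gate.alpha)
    return replace(spec, values=spec.values * gain)


def denoise(signal: AudioSignal, stft_params: StftParams | None = None,
            gate: GateParams | None = None, renormalize: bool = True) -> AudioSignal:
    """Full gate chain: STFT -> noise estimate from leading frames ->
    threshold gate -> inverse STFT -> peak normalization.  The output has
    exactly the input's length (tail zero-padded or cropped)."""
    stft_params = stft_params or StftParams.for_rate(signal.rate)
    gate = gate or GateParams()
    spec = stft(signal, stft_params)
    noise = estimate_noise_psd(spec, gate.noise_frames)
    gated = spectral_gate(spec, noise, gate)
    out = istft(gated, length=len(signal))
    out = replace(out, label=signal.label)
    if renormalize and np.any(out.samples):
        out = normalize(out)
    return out


class SpectralGateDenoiser:
    """sklearn-style stateless transformer applying :func:`denoise` to a
    list of :class:`AudioSignal`.

    Parameters mirror :class:`GateParams`; ``fit`` is a no-op so the
    transformer composes with sklearn pipelines.
    """

    def __init__(self, k: float = 1.5, alpha: float = 0.1,
                 noise_frames: int = 10, domain: str = "power",
                 renormalize: bool = True):
        self.k = k
        self.alpha = alpha
        self.noise_frames = noise_frames
        self.domain = domain
        self.renormalize = renormalize

    def get_params(self, deep: bool = True) -> dict:
        return {"k": self.k, "alpha": self.alpha,
                "noise_frames": self.noise_frames, "domain": self.domain,
                "renormalize": self.renormalize}

    def set_params(self, **params) -> "SpectralGateDenoiser":
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X, y=None) -> "SpectralGateDenoiser":
        return self

    def transform(self, X: list[AudioSignal]) -> list[AudioSignal]:
        gate = GateParams(k=self.k, alpha=self.alpha,
                          noise_frames=self.noise_frames, domain=self.domain)
        return [denoise(sig, gate=gate, renormalize=self.renormalize)
                for sig in X]

    def fit_transform(self, X, y=None) -> list[AudioSignal]:
        return self.fit(X, y).transform(X)
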