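"""Audio containers and WAV I/O for sustained-phonation recordings.

Every stage of the screening pipeline consumes and produces
:class:`AudioSignal` — a mono, float-valued waveform with its sample rate
and an optional class tag (``"PD"``, ``"HC"`` or ``None``).  Reading scales
integer PCM to [-1, 1]; writing emits 16-bit PCM.  Fixed-length
segmentation (default 3 s, pad with zeros, truncate from the head) makes
every recording a uniform model input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

__all__ = [
    "AudioSignal",
    "SegmentPolicy",
    "AudioIOError",
    "MissingFileError",
    "UnsupportedEncodingError",
    "EmptyAudioError",
    "load_wav",
    "write_wav",
    "normalize",
    "resample",
    "segment_fixed",
]


class AudioIOError(Exception):
    """Base class for audio ingestion failures."""


class MissingFileError(AudioIOError):
    """The requested WAV file does not exist."""


class UnsupportedEncodingError(AudioIOError):
    """The file is not RIFF/WAVE PCM (or float) audio."""


class EmptyAudioError(AudioIOError):
    """The audio stream contains zero samples."""


@dataclass(frozen=True)
class AudioSignal:
    """A mono waveform.

    Parameters
    ----------
    samples : ndarray of float
        Dimensionless amplitudes; finite.
    rate : int
        Sampling rate in Hz, > 0.
    label : str or None
        Optional class tag, ``"PD"`` or ``"HC"``.
    """

    samples: np.ndarray
    rate: int
    label: str | None = None

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        if samples.ndim != 1:
            raise ValueError("AudioSignal is mono: samples must be 1-D")
        if samples.size and not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")
        if self.label not in (None, "PD", "HC", "unknown"):
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.samples.size / self.rate

    def __len__(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class SegmentPolicy:
    """Fixed-length segmentation: pad short inputs, truncate long ones."""

    target_duration: float = 3.0
    pad_value: float = 0.0
    mode: str = "truncate-head"  # or "truncate-center"

    def __post_init__(self) -> None:
        if self.target_duration <= 0:
            raise ValueError("target_duration must be positive")
        if self.mode not in ("truncate-head", "truncate-center"):
            raise ValueError(f"unknown segmentation mode {self.mode!r}")


_PCM_SCALE = {
    np.dtype(np.int16): 32768.0,
    np.dtype(np.int32): 2147483648.0,
    np.dtype(np.uint8): None,  # offset binary, handled separately
}


def load_wav(path: str | Path, target_rate: int | None = None,
             label: str | None = None) -> AudioSignal:
    """Read a RIFF/WAVE file into an :class:`AudioSignal`.

    Integer PCM is scaled to [-1, 1]; multi-channel audio is averaged to
    mono; if ``target_rate`` is given the signal is resampled.

    Raises
    ------
    MissingFileError, UnsupportedEncodingError, EmptyAudioError
    """
    path = Path(path)
    if not path.exists():
        raise MissingFileError(str(path))
    try:
        rate, data = wavfile.read(str(path))
    except ValueError as exc:  # non-PCM compression, truncated header, ...
        raise UnsupportedEncodingError(f"{path}: {exc}") from exc
    if data.size == 0:
        raise EmptyAudioError(str(path))
    dtype = np.dtype(data.dtype)
    if dtype == np.dtype(np.uint8):
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif dtype in _PCM_SCALE:
        samples = data.astype(np.float64) / _PCM_SCALE[dtype]
    elif dtype.kind == "f":
        samples = data.astype(np.float64)
    else:
        raise UnsupportedEncodingError(f"{path}: unsupported sample dtype {dtype}")
    if samples.ndim == 2:  # average stray stereo to mono (after scaling)
        samples = samples.mean(axis=1)
    sig = AudioSignal(samples, int(rate), label=label)
    if target_rate is not None and target_rate != sig.rate:
        sig = resample(sig, int(target_rate))
    return sig


def write_wav(path: str | Path, signal: AudioSignal) -> None:
    """Write 16-bit PCM. Amplitudes are clipped to [-1, 1] first."""
    clipped = np.clip(signal.samples, -1.0, 32767.0 / 32768.0)
    pcm = np.round(clipped * 32768.0).astype(np.int16)
    wavfile.write(str(path), signal.rate, pcm)


def resample(signal: AudioSignal, target_rate: int) -> AudioSignal:
    """Polyphase resampling (windowed-sinc anti-alias filter at the lower
    Nyquist frequency of the two rates)."""
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if target_rate == signal.rate:
        return signal
    ratio = Fraction(target_rate, signal.rate)
    out = resample_poly(signal.samples, ratio.numerator, ratio.denominator)
    return AudioSignal(out, target_rate, label=signal.label)


def normalize(signal: AudioSignal) -> AudioSignal:
    """Scale to peak amplitude 1 (range [-1, 1]).

    An all-zero signal is returned unchanged — the degenerate case is
    well-defined rather than an error.
    """
    if len(signal) == 0:
        raise EmptyAudioError("cannot normalize an empty signal")
    peak = float(np.max(np.abs(signal.samples)))
    if peak == 0.0:
        return signal
    return replace(signal, samples=signal.samples / peak)


def segment_fixed(signal: AudioSignal, policy: SegmentPolicy | None = None) -> AudioSignal:
    """Force the waveform to exactly ``round(target_duration * rate)``
    samples: zero-pad short inputs at the tail, truncate long ones from
    the head (or symmetrically with mode ``truncate-center``)."""
    policy = policy or SegmentPolicy()
    n_target = round(policy.target_duration * signal.rate)
    x = signal.samples
    if x.size == n_target:
        return signal
    if x.size > n_target:
        if policy.mode == "truncate-head":
            out = x[:n_target]
        else:
            start = (x.size - n_target) // 2
            out = x[start:start + n_target]
    else:
        out = np.full(n_target, policy.pad_value, dtype=np.float64)
        out[:x.size] = x
    return replace(signal, samples=out)
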