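"""Shared fixtures: small deterministic signals and WAV files."""

import numpy as np
import pytest

from dysvoice.audio import AudioSignal, write_wav


@pytest.fixture()
def tone_8k() -> AudioSignal:
    """1 s of a 200 Hz tone at 8 kHz, amplitude 0.8."""
    t = np.arange(8000) / 8000.0
    return AudioSignal(0.8 * np.sin(2 * np.pi * 200 * t), 8000)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture()
def wav_file(tmp_path, tone_8k):
    path = tmp_path / "tone.wav"
    write_wav(path, tone_8k)
    return path
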