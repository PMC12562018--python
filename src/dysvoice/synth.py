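"""Source-filter synthesis of sustained vowels with controllable dysphonia.

A simplified Rosenberg-style glottal pulse train is generated cycle by
cycle: each period is perturbed by an independent Gaussian (jitter) and
each pulse amplitude by another (shimmer); the train is filtered through
second-order formant resonators (vowel /a/ defaults 700/1200/2600 Hz)
and mixed with aspiration noise — white noise shaped by the same vocal
tract — scaled so that the harmonic-to-noise power ratio over the voiced
region equals ``10**(hnr_db/10)``.  Everything is deterministic given a
seed, so downstream feature extractors can be tested against exact
ground truth.

Calibration: the jitter/shimmer statistic used downstream is the mean
absolute *successive* difference over the mean, whose expectation for
i.i.d. Gaussian per-cycle perturbations of sd ``s`` is ``(2/sqrt(pi)) s``.
The per-cycle sd is therefore scaled by ``sqrt(pi)/2`` so that the
*extracted* jitter/shimmer matches the requested percentage.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
from scipy.signal import lfilter

from .audio import AudioSignal

__all__ = [
    "VoiceProfile",
    "LabeledCorpus",
    "synth_vowel",
    "preset_profiles",
    "make_corpus",
    "JITTER_CALIBRATION",
]

#: sd multiplier making E[extracted jitter] equal the requested jitter_pct
JITTER_CALIBRATION = math.sqrt(math.pi) / 2.0

_DEFAULT_FORMANTS = (700.0, 1200.0, 2600.0)
_DEFAULT_BANDWIDTHS = (80.0, 120.0, 200.0)


@dataclass(frozen=True)
class VoiceProfile:
    """Synthesis control parameters for one speaker/recording.

    ``jitter_pct`` and ``shimmer_pct`` are the target values of the
    extracted cycle-to-cycle statistics; ``hnr_db`` is the harmonic to
    aspiration-noise power ratio in dB; ``f0_sd`` controls slow pitch
    drift (reduced in the monotonic parkinsonian presets).
    """

    f0_mean: float = 200.0
    f0_sd: float = 3.0
    jitter_pct: float = 0.3
    shimmer_pct: float = 1.5
    hnr_db: float = 15.0
    formants: tuple[float, float, float] = _DEFAULT_FORMANTS
    bandwidths: tuple[float, float, float] = _DEFAULT_BANDWIDTHS
    duration: float = 3.0
    tremor_rate: float = 0.0
    tremor_depth: float = 0.0
    label: str | None = None

    def __post_init__(self) -> None:
        if not (75.0 <= self.f0_mean <= 500.0):
            raise ValueError("f0_mean must lie in 75-500 Hz")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        for name in ("f0_sd", "jitter_pct", "shimmer_pct", "tremor_rate",
                     "tremor_depth"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class LabeledCorpus:
    """Synthetic recordings plus the manifest that generated them."""

    signals: list[AudioSignal]
    manifest: list[dict]

    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.signals])

    def manifest_json(self) -> str:
        return json.dumps(self.manifest, indent=2)


def _rosenberg_pulse(phase: np.ndarray, open_quotient: float = 0.6,
                     closing_quotient: float = 0.3) -> np.ndarray:
    """Glottal pulse evaluated at continuous cycle phase in [0, 1):
    rising half-cosine over the open phase, sharp cosine fall over the
    closing phase, zero during closure.

    Evaluating the shape as a function of *continuous* phase (rather
    than shifting a precomputed sampled pulse) avoids sample-quantized
    pulse onsets, which would otherwise alias period perturbations into
    a spurious subharmonic.
    """
    oq = open_quotient
    cq = closing_quotient * open_quotient
    out = np.zeros_like(phase)
    rising = phase < oq
    out[rising] = 0.5 * (1.0 - np.cos(np.pi * phase[rising] / oq))
    falling = (phase >= oq) & (phase < oq + cq)
    out[falling] = np.cos(0.5 * np.pi * (phase[falling] - oq) / cq)
    return out


def _formant_filter(x: np.ndarray, rate: int,
                    formants: tuple[float, ...],
                    bandwidths: tuple[float, ...]) -> np.ndarray:
    """Cascade of two-pole resonators at the given center frequencies."""
    out = x
    for f, bw in zip(formants, bandwidths):
        r = math.exp(-math.pi * bw / rate)
        theta = 2.0 * math.pi * f / rate
        b = [1.0 - r]
        a = [1.0, -2.0 * r * math.cos(theta), r * r]
        out = lfilter(b, a, out)
    return out


def synth_vowel(profile: VoiceProfile, rate: int = 8000,
                seed: int = 0) -> AudioSignal:
    """Synthesize one sustained vowel according to ``profile``.

    Deterministic given ``seed``.  The output is peak-normalized to 0.95
    and carries the profile's label.
    """
    rng = np.random.default_rng(seed)
    n = int(round(profile.duration * rate))

    # slow F0 contour: smooth noise with sd = f0_sd (plus optional tremor)
    knots = max(int(profile.duration * 2) + 3, 4)
    contour_knots = rng.standard_normal(knots)
    t_knots = np.linspace(0.0, n, knots)
    contour = np.interp(np.arange(n), t_knots, contour_knots)
    f0_of_n = profile.f0_mean + profile.f0_sd * contour
    if profile.tremor_rate > 0 and profile.tremor_depth > 0:
        phase = rng.uniform(0, 2 * math.pi)
        f0_of_n = f0_of_n * (1.0 + profile.tremor_depth *
                             np.sin(2 * math.pi * profile.tremor_rate *
                                    np.arange(n) / rate + phase))
    f0_of_n = np.clip(f0_of_n, 75.0, 500.0)

    sigma_j = profile.jitter_pct / 100.0 * JITTER_CALIBRATION
    sigma_s = profile.shimmer_pct / 100.0 * JITTER_CALIBRATION

    source = np.zeros(n)
    pos = 0.0
    while True:
        base_period = rate / f0_of_n[min(int(pos), n - 1)]
        period = base_period * (1.0 + sigma_j * rng.standard_normal())
        period = max(period, rate / 500.0)
        amp = max(1.0 + sigma_s * rng.standard_normal(), 0.05)
        if pos + period >= n - 1:
            break
        # The pulse SHAPE spans the unperturbed local period: scaling it
        # with the jittered period would mix adjacent periods into the
        # waveform event times and dilute the effective jitter.
        first = int(math.ceil(pos))
        last = min(int(math.floor(pos + base_period)), n - 1)
        samples = np.arange(first, last + 1)
        phase = (samples - pos) / base_period
        source[samples] += amp * _rosenberg_pulse(phase)
        pos += period

    harmonic = _formant_filter(source, rate, profile.formants,
                               profile.bandwidths)
    noise = _formant_filter(rng.standard_normal(n), rate, profile.formants,
                            profile.bandwidths)

    p_harm = float(np.mean(harmonic ** 2))
    p_noise_raw = float(np.mean(noise ** 2))
    target_ratio = 10.0 ** (profile.hnr_db / 10.0)
    if p_noise_raw > 0 and p_harm > 0:
        noise = noise * math.sqrt(p_harm / (target_ratio * p_noise_raw))
    mix = harmonic + noise
    peak = float(np.max(np.abs(mix)))
    if peak > 0:
        mix = 0.95 * mix / peak
    return AudioSignal(mix, rate, label=profile.label)


def preset_profiles() -> tuple[VoiceProfile, VoiceProfile]:
    """Reference (PD, HC) profiles.

    The healthy preset sits comfortably inside the normal ranges
    (jitter 0.3% <= 0.5%, HNR 15 dB >= 10 dB); the parkinsonian preset
    models dysphonic phonation (jitter 4% in the 3-5% band, HNR 5 dB <=
    7 dB, elevated shimmer, reduced slow F0 variation = monotonicity,
    broadened formant bandwidths = blurred articulation).
    """
    pd_profile = VoiceProfile(
        f0_mean=180.0, f0_sd=0.8, jitter_pct=4.0, shimmer_pct=6.0,
        hnr_db=5.0, bandwidths=(130.0, 180.0, 280.0), label="PD")
    hc_profile = VoiceProfile(
        f0_mean=200.0, f0_sd=3.0, jitter_pct=0.3, shimmer_pct=1.5,
        hnr_db=15.0, label="HC")
    return pd_profile, hc_profile


def _perturbed(base: VoiceProfile, rng: np.random.Generator,
               jitter_spread: float) -> VoiceProfile:
    """Draw an individual speaker profile around a preset."""
    jitter = max(base.jitter_pct + jitter_spread * rng.standard_normal(), 0.05)
    shimmer = max(base.shimmer_pct * (1.0 + 0.15 * rng.standard_normal()), 0.2)
    hnr = base.hnr_db + 1.5 * rng.standard_normal()
    f0 = float(np.clip(base.f0_mean + 15.0 * rng.standard_normal(), 90.0, 400.0))
    f0_sd = max(base.f0_sd * (1.0 + 0.2 * rng.standard_normal()), 0.05)
    formants = tuple(f * (1.0 + 0.04 * rng.standard_normal())
                     for f in base.formants)
    return replace(base, f0_mean=f0, f0_sd=f0_sd, jitter_pct=jitter,
                   shimmer_pct=shimmer, hnr_db=hnr, formants=formants)


def make_corpus(n_pd: int = 40, n_hc: int = 41, jitter_spread: float = 0.4,
                seed: int = 0, rate: int = 8000,
                duration: float = 3.0) -> LabeledCorpus:
    """Generate a labeled synthetic corpus (defaults mirror a 40 PD /
    41 HC study population).

    Speaker profiles are drawn around the presets with the stated jitter
    spread (1 standard deviation, percentage points) plus proportional
    variation of the other dysphonia parameters; ``jitter_spread = 0``
    reproduces the presets exactly.  The manifest records every profile
    and per-item seed, so the corpus is reproducible end to end.
    """
    if n_pd < 1 or n_hc < 1:
        raise ValueError("need at least one item per class")
    master = np.random.default_rng(seed)
    pd_preset, hc_preset = preset_profiles()
    signals: list[AudioSignal] = []
    manifest: list[dict] = []
    for base, count in ((pd_preset, n_pd), (hc_preset, n_hc)):
        for i in range(count):
            if jitter_spread > 0:
                prof = _perturbed(base, master, jitter_spread)
            else:
                prof = base
            prof = replace(prof, duration=duration)
            item_seed = int(master.integers(0, 2 ** 31 - 1))
            signals.append(synth_vowel(prof, rate=rate, seed=item_seed))
            entry = asdict(prof)
            entry.update(seed=item_seed, rate=rate)
            manifest.append(entry)
    return LabeledCorpus(signals, manifest)
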