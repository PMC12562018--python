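# Methods

## Signal model and scope

All analysis operates on mono sustained-vowel phonation, internally at a
canonical 8 kHz sampling rate (the 0–4 kHz band carries F0 and the first
three formants of /a/; telephone-quality corpora are natively 8 kHz and
higher-rate recordings are polyphase-resampled down). Recordings are
peak-normalized to [−1, 1] and cut or zero-padded to a fixed 3 s so
every stage sees a uniform input. Truncation keeps the head of the
recording, where phonation onset is strongest; both the duration and the
truncation mode are configurable.

## Spectral gating

The denoiser assumes the first `T = 10` analysis frames are noise-only;
it makes no attempt to detect silence. Frame geometry is 25 ms / 10 ms
hop with a periodic Hann taper and FFT size the next power of two —
standard speech-analysis values chosen because the gate itself
prescribes none. The per-bin threshold is `k·P_N(f)` with `k = 1.5` and
the sub-threshold gain is `α = 0.1`; the comparison is done in the power
domain (`|X|² ≤ k·P_N`) by default because `P_N` is a power quantity,
with a magnitude-domain reading (`|X| ≤ k·P_N`) available behind
`GateParams.domain` since the gain law is stated ambiguously across
conventions. Gains are real, so phase is never altered. The inverse
STFT uses windowed overlap-add with least-squares envelope
normalization; samples whose window envelope is below 10⁻³ of its
maximum (the extreme tapered edges) are zeroed rather than amplified.

## Voice-quality estimators

**F0.** Framewise normalized autocorrelation over a window of at least
three periods of `fmin` (defaults 75–500 Hz, voicing threshold 0.45 on
the normalized peak), with parabolic lag interpolation. Octave errors
are suppressed with a two-pass scheme: the frame-averaged correlation
picks a recording-level lag (shortest local maximum within 80 % of the
global peak), and each frame then searches only ±30 % around it. This
assumes sustained phonation — F0 drifts but does not jump octaves —
which is exactly the elicitation task the pipeline targets.

**Cycle marks.** Cycle anchors are the 2πk crossings of the
instantaneous (Hilbert) phase of the fundamental band, isolated by a
zero-phase 4th-order Butterworth band-pass. Timing errors induced by
narrow-band noise are strongly correlated across neighboring cycles and
therefore largely cancel in the successive-difference statistic that
jitter measures; this is what makes sub-percent jitter readable at all
at single-digit HNR, where broadband template matching is limited to
roughly one sample of timing noise per cycle. The band is adaptive:
0.45–1.55·F0 passes the full ±F0/2 FM-sideband range that white
per-cycle jitter occupies and is authoritative for pathological jitter;
a 0.70–1.30·F0 band has about one third the noise floor but attenuates
genuine jitter roughly twofold, so its reading is reported only when it
falls below 0.8 % — i.e. when the true jitter is well inside the normal
range and sideband attenuation is immaterial. Marks within two periods
of the signal edges are discarded (filter and Hilbert edge effects),
marks in unvoiced frames are discarded, and periods are sanity-banded
to 0.65–1.5× the median period.

**Jitter and shimmer** are the mean absolute successive differences of
periods and of per-cycle peak amplitudes, normalized by their means, in
percent; shimmer is also exported in dB as the mean |20·log₁₀ ratio| of
successive amplitudes. Per-cycle amplitudes are waveform peaks and thus
noise-inflated at low HNR; shimmer should be read as ordinal at
single-digit HNR.

**HNR.** The harmonic component is reconstructed by pitch-synchronous
source–filter deconvolution: the fractional cycle marks define a
sinc-interpolated impulse train `e`, and a single FIR pulse response `p`
on lags [−T, 2T] is fitted by least squares (Toeplitz normal equations
on the excitation autocorrelation) so that `e ∗ p` matches the
waveform. Because the excitation carries the actual jittered pulse
times, the reconstruction is immune to the period-perturbation
decorrelation that biases autocorrelation- or template-based HNR
estimators downward on jittery voices; a per-cycle least-squares gain
absorbs shimmer. The residual within marked cycles is aperiodic noise,
and `HNR = 10·log₁₀((P_total − P_noise)/P_noise)`, floored at −40 dB and
capped at 80 dB. The ~3T fitted coefficients absorb under 1 % of the
noise power at the corpus scale used here.

**Formants.** LPC by the autocorrelation method (order `2 + rate/1000`,
pre-emphasis 0.97, Hamming window, tiny ridge on the zeroth lag);
formant candidates are polynomial roots inside the unit circle with
bandwidth `−rate/π·ln|r| < 400 Hz`, sorted ascending. Missing formants
are NaN rather than fabricated.

**MFCC.** Triangular mel filterbank (HTK mel scale) with 128 bands — a
deliberately fine resolution shared with the model-input grid — log
floor 10⁻¹⁰, and the cosine projection evaluated exactly as stated
(DCT-II up to scale); deltas by the symmetric regression with half-width
2 and edge replication. Filters narrower than one FFT bin receive unit
weight at their center bin so no band is dead.

**Mel grid.** Power mel spectrogram pooled along time into exactly 40
bins of 128 bands, log-compressed to dB referenced to the grid maximum
and clipped at −80 dB. Silence maps to a uniform floor.

## The synthetic-voice generator

The generator is a simplified source–filter model: a Rosenberg-style
glottal pulse (rising half-cosine open phase, sharp cosine closure)
excited once per cycle, filtered through two-pole resonators at the /a/
formants (700, 1200, 2600 Hz; bandwidths 80/120/200 Hz, broadened for
the parkinsonian preset), plus white aspiration noise passed through the
same resonators and scaled so the harmonic-to-noise power ratio is
exactly `10^(HNR/10)`. Two modeling details matter for fidelity:

* pulses are evaluated as continuous functions of phase at fractional
  onset times — quantizing onsets to samples aliases period
  perturbations into a spurious subharmonic;
* the pulse *shape* spans the unperturbed local period. Scaling the
  shape with the jittered period would shift each cycle's waveform event
  by a mixture of adjacent periods and dilute the realized jitter to
  about half its nominal value.

Per-cycle period and amplitude perturbations are independent Gaussians
whose standard deviation is the requested jitter/shimmer multiplied by
√π/2, so that the *extracted* mean-absolute-difference statistic has the
requested expectation. Slow F0 drift is smooth interpolated noise with
standard deviation `f0_sd`; optional tremor is a slow sinusoidal
modulation. Everything is deterministic given a seed.

Presets: healthy = F0 200 Hz (sd 3 Hz), jitter 0.3 %, shimmer 1.5 %,
HNR 15 dB; parkinsonian = F0 180 Hz (sd 0.8 Hz — monotonic prosody),
jitter 4 %, shimmer 6 %, HNR 5 dB, broadened formant bandwidths. The
default corpus draws 40 PD and 41 HC speakers around these presets
(jitter spread 0.4 pp, ±1.5 dB HNR, ±15 Hz F0, ±4 % formants).

What the generator does **not** emulate: recording-channel variability,
amplitude drift and voice breaks, vowel onset/offset transients,
nonstationary noise, articulation deficits beyond static formant
broadening, and the population overlap of real PD and HC voices. The
synthetic classes are separable by construction — their jitter/HNR
ranges are the disjoint clinical ranges — so classifier accuracies on
this corpus are capacity-and-plumbing checks, not estimates of clinical
performance. In our end-to-end runs both the deep models and the best
classical baselines reach ceiling on the held-out split for exactly this
reason; the real-data regime in which recurrent models dominate
classical ones is driven by noise and variability the generator
deliberately omits.

## Classifiers

The deep stacks operate on the 40 × 128 grid treated as (height, width,
1). The convolutional front ends use 'same' padding and stride-1
kernels with two 2 × 2 max poolings, leaving 10 × 32 × 64 = 20480
activations that reshape exactly into 40 timesteps × 512 features — the
canonical reading of a flatten-then-reshape(40) stage. Recurrence is
LSTM (forget-gate bias 1), GRU (update-gate blend
`h = (1−z)∘h + z∘h̃`), or bidirectional LSTM with concatenated forward
and backward states (width 2×units). Heads are Dense(64, ReLU) with
dropout 0.5 and a single sigmoid unit. Training: Adam at 0.001, binary
cross-entropy, batch 16, stratified 80-20 train/validation split, inputs
standardized by the training-set mean and deviation (stored as fitted
attributes). Published epoch defaults are 50 for CNN+LSTM and 20 for the
others; desk-scale pipeline runs use 12 epochs, which suffices on the
synthetic corpus. Everything runs on a small in-package reverse-mode
autodiff engine over numpy and is bit-reproducible given
`random_state`.

Classical baselines: RBF-kernel SVM and L2 logistic regression on
standardized features, XGBoost on raw features, each tuned by 3-fold
stratified grid-search CV over small default grids.

## Selection and evaluation

Mutual information uses equal-frequency binning with 8 bins (bits;
ties broken by schema order); RFE uses a standardized L2 logistic
scorer, eliminating one column per round to 20 kept by default. The
pipeline applies selection to the classical path only — the deep models
consume the mel grid directly. Metrics follow the confusion-matrix
formulas exactly, with zero-denominator ratios flagged as missing
rather than coerced to 0; ROC uses a threshold sweep with simultaneous
tie crossing and trapezoid AUC; cross-validation is stratified with
pooled out-of-fold confusion as the primary aggregate and per-fold
mean ± sd alongside. The decision threshold is fixed at 0.5.

## Problem sizes

The test suite exercises the estimators on 1–3 s vowels at 8 kHz; the
parameter-recovery grid spans jitter {0, 1, 2, 4} %, HNR {5, 10, 20} dB
and F0 {120, 200} Hz (24 cells, one seed); the end-to-end comparison
uses the 81-speaker synthetic corpus with an 80-20 split and 12-epoch
deep training. The acceptance script runs single 3-s syntheses plus
analytic fixtures and completes in seconds.

## Known limitations

Jitter has a noise floor of roughly 0.5 % at HNR 5 dB (narrow band) —
readings below ~1 % at single-digit HNR are upper bounds, and the
tracker's octave guard assumes monotone-ish sustained phonation.
Shimmer is noise-inflated at low HNR (ordinal, not calibrated, there).
The HNR deconvolution assumes a slowly varying vocal tract; it is not
meant for running speech. The deep models are desk-scale: no
augmentation, early stopping, or GPU-scale capacity.
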