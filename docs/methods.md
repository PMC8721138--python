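# Methods

This note documents the models and procedures implemented in `ffrsws`, the
parameter choices behind them, and what the synthetic-data generator does
and does not emulate.

## Stimuli

Three consonant–vowel tokens ("baw", "boo", "bow"; aliases tok1–tok3) are
defined parametrically: F1 and F2 center-frequency trajectories follow a
raised-cosine transition over the first 120 ms (the consonant–vowel formant
glide) and then hold. F1 spans 310–640 Hz across tokens and carries nearly
all of the between-token contrast; F2 stays within 1,120–1,270 Hz. All
tokens are 335 ms at 44.1 kHz, synthesized as phase-continuous sinusoids
(phase = 2π × cumulative sum of the frequency track / fs), ramped off with
a cosine-squared fall over the final 50 ms (first ramp sample full scale,
final sample exactly zero), and RMS-normalized to a common level (0.05 full
scale by default). The F2 sinusoid amplitude is 0.4 of F1's, reflecting the
lower second-formant energy of natural vowels.

For natural recordings, formant tracks are estimated by autocorrelation
LPC: analysis at 10 kHz (resampled), order 12, 25 ms Hamming windows with
10 ms hop and 0.97 pre-emphasis — conventional speech-analysis values, since
no specific settings are prescribed for this design. Candidate resonances
are LPC-polynomial roots with positive imaginary part; candidates below
90 Hz, with bandwidth ≥ 400 Hz, or with spectral-envelope amplitude under
10% of the strongest candidate (spurious fill-in poles that otherwise land
between the widely spaced resonances of tonal input) are discarded, and the
lowest two remaining are F1 and F2. Unstable or silent frames reuse the
previous frame's estimate and are logged.

## Synthetic sessions

Each sweep's neural response is a delayed sum of components phase-locked to
the stimulus's own frequency tracks — F1, F2, and the F2−F1 difference
track (the quadratic cochlear distortion product, which the auditory system
follows as it would an acoustic input). Defaults:

| parameter | default | meaning |
|---|---|---|
| `delay_ms` | 6 | neural conduction delay (brainstem range 3–10 ms) |
| `rectification_gain` | 0.5 | fraction of half-wave rectification per polarity |
| `f1_gain` / `f2_gain` / `dp_gain` | 0.10 / 0.03 / 0.05 µV | component peak amplitudes (scalp FFRs are ~0.1 µV) |
| `noise_rms` | 2.0 µV | white background level |
| `artifact_gain` | 0 | zero-lag stimulus-artifact contamination |
| `reps_per_polarity` | 1,000 | presentations per token per polarity per phase |
| `iti_ms` | 600 | intertrial interval |
| `training_gain` | 1.0 | post-phase scaling of neural components |
| `transducer_delay_ms` | 1 | insert-earphone acoustic travel time |

Half-wave rectification blends each component with its positive-rectified
version: `(1−g)·x + g·max(x, 0)`, applied after the polarity flip, so the
response amplitude is continuous in `g`. At `g = 0` the two polarities are
exact negations and the added average (A+B)/2 vanishes; at `g = 1` the
added average is `|x|/2` per component, whose leading AC term sits at twice
the track frequency — the frequency-doubling signature of rectifying
(neural) generators. The subtracted average scales as `(1 − g/2)` times the
component, so with the default `g = 0.5` the F1-following subtracted
amplitude is 0.075·`training_gain` µV at unit envelope.

Noise is white in the generator; the 100–2,400 Hz analysis filter shapes it
downstream. 2 µV RMS is an order-of-magnitude choice for in-band scalp
background during passive listening; with it, 40 sweeps per polarity give a
subtracted-average noise floor of ~0.22 µV and the full 1,000-sweep
protocol ~0.045 µV, which reproduces the qualitative regime of real
recordings (clear grand-average cross-correlation peaks; single-condition
decoding above chance but below ceiling). The stationary background never
reaches the ±50 µV rejection bound — that threshold exists for transient
movement artifacts, which the generator does not model by default (tests of
the rejection path construct artifacts explicitly).

Simulated cohorts add two per-participant random effects at the pipeline
level: a shared lognormal amplitude scale (σ = 0.25) and a Gaussian
neural-delay offset (σ = 0.3 ms). Without them nine simulated participants
are statistically identical and cross-participant decoding degenerates to
ceiling in every phase, which no real cohort shows; with them,
between-participant waveform decorrelation limits accuracy the way
individual anatomy does in practice. Sweep-level generation itself is
participant-agnostic.

Not emulated: 1/f EEG background, ocular/muscle artifacts, multi-channel
montages, behavioral learning curves, and amplitude drift within a phase.
Passing tests therefore show that the *analysis chain* recovers known
injected structure under realistic SNR — not that it is robust to every
artifact class of real recordings.

## Preprocessing

Pipeline order is fixed: zero-phase 4th-order Butterworth bandpass
(100–2,400 Hz, forward–backward so FFR latencies are unbiased) → epoching
−50 to 550 ms re acoustic arrival (trigger + 1 ms transducer delay;
half-open windows, exactly 3,000 samples at 5 kHz) → per-epoch linear
detrend over the whole epoch → artifact flagging at ±50 µV (flags, not
deletions, so rejection counts are reportable) → baseline correction by the
mean of [−50, 0) ms. Averages use accepted sweeps only and satisfy
`a_mean = added + subtracted`, `b_mean = added − subtracted` to 1e−12.

## Cross-correlation

Pearson correlation over the overlapping region at every integer-sample lag
within ±20 ms (0.2 ms grid at 5 kHz). The lag maximizing |r| is reported
with the signed r there; |r| handles polarity-inverted montages, and ties
break toward the smallest lag for determinism. Lags in the closed interval
[3, 10] ms gate the response as neural; negative lags are searched but
always gate non-neural. Whether to maximize signed or absolute correlation,
and the boundary inclusivity of the gate, are conventions declared here,
not inferences. The F2−F1 envelope reference is selected per token by
configuration (`ref_override`), mirroring the manual judgment it replaces;
automating that call is out of scope.

## Fourier analyzer

The reference phase is re-integrated from the *smoothed* instantaneous
frequency (analytic-signal phase, unwrapped, differentiated, then a
50-point boxcar moving average applied three times with edge-replication
padding) rather than reusing the raw analytic phase: differentiation acts
as a high-pass and the smoothing exists precisely to remove its
perturbations, so the reference should reflect the smoothed track. The
−6 ms shift advances the response (equivalently delays the reference);
at 5 kHz it is exactly 30 samples. The reference is conjugated, so the
reported phase is response minus reference (`conjugate_reference=False`
flips the convention). A tracked cosine of amplitude A measures A/2.

Noise tracks are the reference shifted by a constant ±5…9 Hz. Because the
offset is constant, the FA product of an on-track response with a noise
track beats at exactly that offset, and the leakage floor over the
T = 0.285 s window is |sinc(Δf·T)| of the on-track amplitude: about 12% at
±9 Hz (and near zero at ±7 Hz, which sits at a sinc null). The presence
rule — amplitude strictly above the mean of the 10 noise-track amplitudes —
is deliberately lenient (≈50% positive rate under pure noise) so that
weak-response participants are retained; it is a floor comparison, not a
significance test. F2 is measured and reported but typically sparse in
subtracted averages; analyses focus on F1 and, where the distortion product
dominates, F2−F1.

## Decoding

Features are the raw 1,900 amplitude-by-time points of each subtracted
average over [0, 380) ms at 5 kHz — no scaling, matching the described
input. Binary classifiers are linear SVMs (C = 1); the one-against-one
layer trains the 3 pairwise classifiers per fold and predicts by voting,
with vote ties resolved toward the class whose pairwise classifiers had the
highest mean training accuracy (a declared interpretation of the ambiguous
"highest accuracy" tie-break). Folds are drawn at the participant level —
all of a participant's observations move together — with remainder
participants distributed round-robin when the count is not divisible by 3.
The iteration accuracy is the mean of the three held-out-fold accuracies;
2,500 iterations at full fidelity, config-scalable (tests and the
acceptance script run 40–500).

`p = (a + 1)/(n + 1)` counts null (or pre-phase) values strictly above the
median of the comparison distribution. Two caveats established by
simulation here: (i) with strongly clustered features, permuted-label CV
sits slightly *below* chance (anti-learning from sampling labels without
replacement), so null medians near 0.26 for 9 participants are expected,
not a defect; (ii) the repeated-CV accuracy of one fixed small cohort
concentrates at that cohort's idiosyncratic level (s.d. ≈ 0.09 across
cohort draws), so chance-level claims are evaluated as means over
independent cohorts. The median-exceedance comparison assumes
non-degenerate distributions; at accuracy ceiling it collapses, which is a
further reason the generator's cohort SNR is kept below ceiling.

## Reproducibility and problem sizes

Every stochastic step takes a seed; the pipeline derives per-stage seeds
from one master seed by stage-name hashing (CRC32, reduced below 2³¹), so
stages can be rerun independently and a rerun reproduces all outputs
bit-exactly (the manifest records seeds, counts, and an MD5 of the
averages). The test suite and acceptance script use reduced problem sizes
chosen to exercise the same code paths at meaningful SNR: 10–200 sweeps per
polarity per session, 9-participant cohorts, 40–500 CV iterations, 3–10
seeded replicates per property; the full-fidelity protocol defaults
(1,000 sweeps per polarity, 2,500 iterations) remain the package defaults.

## Known limitations

- The LPC front end is tuned for two well-separated resonances below
  2 kHz; closely spaced or high formants can merge.
- The F2−F1 "stimulus" is the band-passed analytic envelope; for stimuli
  whose component spacing varies strongly in time the envelope frequency
  and the pointwise track difference can diverge near the transition.
- EDF files are read (via mne, first channel) but not written; synthetic
  sessions are stored as delimited text.
- The FA presence rule inherits the ±9 Hz leakage floor described above;
  absolute noise-floor estimates include that deterministic component in
  addition to stochastic background.
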