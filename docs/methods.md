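# Methods

## Radar forward model

A CW radar transmits `x(t) = sin(ω₀t + φ₀)` at carrier frequency
`f₀ = ω₀/2π = 5.8 GHz`. The chest sits at static distance `d` (default
0.30 m) and moves by `f(t′)`, modelled as a quasi-periodic superposition

    f(t′) = Σ_h A_r κ^{h-1} sin(h·θ_r(t′) + φ_r) + Σ_h A_h κ^{h-1} sin(h·θ_h(t′) + φ_h),

two harmonic series (respiration, heartbeat) with per-harmonic decay `κ`
(default 0.4). The phase difference between transmitted and received signal
is linear in the displacement,

    Φ(t′) = C₀ − (2ω₀/c)·f(t′),    C₀ = (2d/c)·ω₀,

so a single-tone displacement of amplitude `A` produces a phase oscillation
of amplitude `2ω₀A/c` (1.2156 rad for A = 5 mm at 5.8 GHz). `Φ` is
synthesised directly and is continuous; an optional wrapped mode applies the
standard 2π-jump correction that a real arctangent demodulator would need,
recovering the waveform up to a 2π multiple.

### Rate jitter (HRV surrogate)

Each rhythm's base phase `θ(t)` advances 2π per cycle, with the rate of
cycle `k` drawn as `rate·(1 + ε_k)`, `ε_k ~ N(0, rate_jitter_sd)`
(multiplicative, truncated to ±(0.3–3)× the base rate). This
per-cycle instantaneous-frequency perturbation is interpretable as
heart-rate variability, and its cycle boundaries double as ground-truth
beat times: the synthetic ECG draws its R-peak times from the identical
stream, so the two modalities share one beat process per recording and seed.

### Artifacts, noise, ECG

Body-motion artifacts are Poisson-timed raised-cosine bumps (0.5–2 s wide,
configurable amplitude and rate per minute). Phase noise is additive white
Gaussian (radians). The ECG places a PQRST-like template (sum of five
Gaussians; R amplitude 1 mV) at each beat time, plus low-frequency baseline
wander (two random tones near 0.15–0.35 Hz) and white noise; both optional.

### Emotion classes and subjects

Class-conditional parameter distributions are a synthetic convention chosen
to be well separated, not a physiological claim: relax (HR 1.0 Hz, jitter
0.02), scary (2.0 Hz, 0.10), disgust (1.4 Hz, 0.14, fast 0.45 Hz
respiration), joy (1.7 Hz, 0.05, 6 mm respiration amplitude); within-class
sd 0.05 Hz on heart rate. A `separation` knob scales the class-mean
heart-rate gaps. Each subject carries one persistent Gaussian multiplicative
offset (relative sd 0.03) applied to rates and amplitudes across all four
recordings — the subject-identity confound that leave-one-subject-out
evaluation must generalise over. Seeds: one master seed;
`SeedSequence([seed, subject, class])` gives per-recording sub-seeds and
fixed stream indices separate respiration/heart/noise/artifact/ECG draws,
so any recording is independently reproducible.

The default phase-trace rate is 50 Hz — comfortably above twice the highest
modelled harmonic and enough to resolve the 4–8 Hz feature band.

## Preprocessing

RF traces: mean removal (drops C₀), zero-phase Butterworth band-pass
0.1–8 Hz of order 4 (covering respiration, heart harmonics and all feature
bands while removing drift), then per-recording z-scoring (min-max retained
for image scaling). ECG: polyphase resampling to 154 Hz, zero-phase
Butterworth 0.5–45 Hz (the high-pass edge removes baseline wander).
Analysis windows take the final 120 s of each recording, where the evoked
state is assumed strongest. Zero-phase filtering is used so scaleograms and
features are not phase-distorted; polyphase resampling avoids the spectral
leakage of naive interpolation.

## Transforms

* **Scaleogram** (2-D branch input): |CWT| with a complex Morlet wavelet
  (`cmor1.5-1.0` — good frequency localisation for quasi-periodic rhythms)
  on 64 logarithmic scales spanning 0.1–8 Hz; rows ordered by descending
  frequency. The native-resolution magnitude is kept alongside a resized
  (anti-aliased, default 64×64) copy min-max scaled to [0, 1] per image.
* **Boundary handling**: before the CWT the trace is extended on each side
  by a linear-prediction (Yule–Walker AR, order 64, fitted on the nearest
  256 samples) continuation covering the longest wavelet support. Local
  fitting continues the instantaneous rhythm at the boundary; this keeps
  ridge estimates within one scale step of the true instantaneous frequency
  up to the first and last time column, where reflection or zero padding
  bends ridges toward low frequencies.
* **Sequence input** (1-D branch): the z-scored time series resampled to a
  fixed length (default 256) stacked with the unit-norm one-sided FFT
  magnitude interpolated onto the same grid, as two channels. Both raw and
  spectral forms are provided because either alone is an ambiguous summary;
  the fusion default consumes both.

## Feature families

**RF, 7 parameters** (order versioned `rf-7param-v1`): normalized
permutation entropy (m = 3, τ = 1, ties broken by order of occurrence,
normalised by log m! so it is amplitude-free); Welch band powers over
[0.15, 2), [2, 4), [4, 8) Hz (Hann, 30 s segments, 50 % overlap — resolves
0.15 Hz inside a 120 s window; integrated power, half-open bins); population
variance; skewness; non-excess kurtosis (Gaussian → 3, stated to avoid a
silent convention mismatch). Note that after per-recording z-scoring the
variance column is constant by construction; it is retained for pipeline
shape and ignored by scale-invariant learners.

**ECG, 81 IBI features** (catalogue `ibi-27x3-v1`): R peaks from a
derivative → squaring → 150 ms moving-window-integration detector with an
adaptive threshold (fraction of the rolling 95th percentile), 250 ms
refractory period, and refinement to the local ECG maximum; intervals
outside 0.25–2.5 s are discarded as non-physiological. The catalogue applies
27 fixed statistics (location, spread, quantiles, shape, energy, histogram
entropy, mean-crossing rate, linear trend, lag-1 autocorrelation) to each of
the interval series, its first difference and its second difference —
3 × 27 = 81 named features; degenerate statistics map to 0, never NaN.
mRmR selection (MID/difference form: relevance − mean pairwise redundancy,
mutual information on 10-quantile discretized columns, deterministic
lowest-index tie-break) retains 30.

## Models

The fusion classifier is a Y-shaped network: the sequence branch applies two
Conv1D (kernel 7) + MaxPool(2) stages with 32 then 64 feature maps, and an
LSTM cell (hidden 64) consumes the resulting feature sequence, its last
hidden state representing the branch; the image branch applies two Conv2D
(3×3) + MaxPool(2) stages (32, 64 maps) and a dense projection of the
flattened maps. Branch outputs are concatenated into dense(64) → dropout
0.25 → 4-way softmax. The ECG variant omits the LSTM — the selected IBI
features are not a time sequence — and fuses the ECG scaleogram branch with
a dense branch over the 30 features. Training: cross-entropy, Adam
(lr 1e-3), batch 8, default 60 epochs with optional validation-split early
stopping (patience 10); everything is deterministic for a fixed seed. The
engine is plain NumPy (im2col convolutions, BPTT, inverted dropout) and is
verified against central finite differences layer by layer.

Baselines on the 7 features (all standardized, seeded): random forest
(200 trees), RBF SVM (C = 1, γ = 'scale', probability outputs), KNN (k = 5),
decision tree (unlimited depth), LDA (no shrinkage).

## Evaluation

Folds are leave-one-subject-out (the headline, subject-independent
protocol) or leave-one-recording-out (k = N). Models are rebuilt and
retrained per fold with seeds derived from the master seed; predictions are
pooled before computing the confusion matrix (entries sum to N), per-class
one-vs-rest precision/recall/F1 (0/0 → 0), macro means with the inter-class
standard deviation as spread, and one-vs-rest ROC (all distinct scores as
thresholds, trapezoidal AUC; micro = pooled binarized decisions, macro =
mean per-class AUC; classes absent from the truth are flagged NaN).
Probability timelines slide a window across a recording, interpolate the
discrete class probabilities with a monotone cubic, clip and renormalise so
curves sum to one. t-SNE uses perplexity 15 (lowered for tiny samples),
PCA initialisation and a fixed seed.

## Desk-scale benchmark sizes

The package's reference benchmark uses 8 subjects × 4 emotions, 150 s
recordings (120 s analysed), 32×32 scaleogram images, 256-sample sequence
inputs and 60 training epochs; the ECG benchmark uses 10 subjects so
every training fold exceeds the 30 selected features. These are the
package's own desk-scale defaults; larger images (64×64) and longer
training are configurable.

## What the generator does and does not emulate

It emulates quasi-periodic chest displacement with harmonics, HRV-like rate
jitter, class-dependent parameter shifts, between-subject offsets, additive
phase noise, sporadic motion artifacts, and a beat-locked ECG. It does not
model electromagnetic propagation or multipath, antenna patterns, I/Q
receiver imperfections, posture changes, or the psychophysiology linking
emotions to vital signs — class profiles are a labelling convention. Passing
tests therefore demonstrate that the pipeline recovers class structure that
is present in the signals under realistic noise, not that these emotions are
separable in real radar recordings.

## Numerical choices and degenerate inputs

Zero traces: scaleograms are all-zero; z-scoring a constant trace raises a
degenerate-input error; flat-line ECG raises an explicit no-peaks error;
all-zero confusion matrices are rejected. Filtering requires traces longer
than three filter lengths. Argmax ties in prediction resolve to the lowest
class index (alphabetical label order). mRmR skips constant columns with a
warning. The Welch band integration uses half-open bins [low, high) so band
edges are assigned uniquely.

## Known limitations

Single-threaded NumPy training is desk-scale only; the LSTM backward pass is
a Python loop over time steps. The flat-CSV interchange format drops
ground-truth profiles and exact sampling metadata (the `.npz` container is
lossless). Leave-one-recording-out mode is not subject-independent —
it is provided for protocol fidelity, with leave-one-subject-out as the
default headline.
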