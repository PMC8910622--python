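# Methods

This note defines, precisely, what `sleepstage` computes: the signal model,
every feature, the screening rule, the classifiers, the evaluation protocol,
and the synthetic EEG generator. Defaults are stated with units; where a
definition admits more than one reasonable convention, the choice made here
is called out explicitly.

## Signal model and preprocessing

The unit of analysis is a 30-second epoch of a single EEG channel
(Fpz–Cz by default) sampled at 100 Hz, i.e. N = 3000 samples, in microvolts.
Hypnogram intervals are mapped onto the five AASM stages; the older
stage-3/stage-4 labels both map to N3, and movement-time or unscored
intervals are dropped. An epoch is retained only if one hypnogram interval
fully contains it. Class balancing (optional) sub-samples each stage without
replacement using a seeded generator.

Band-pass filtering uses a linear-phase FIR design: 401 Hamming-window taps,
pass band 0.5–45 Hz at fs = 100 Hz, applied with `filtfilt` so the effective
response is zero-phase and the magnitude response is squared. Measured
response: pass-band ripple within ±0.03 dB over 1–40 Hz; ≥ 48 dB attenuation
at DC, 0.1 Hz, and 49 Hz. 401 taps ≈ 4 s of signal keeps the transition band
below 0.5 Hz while remaining far shorter than the epochs being filtered;
filtering requires the signal to be longer than 3× the filter length.

## Features (57 per epoch)

### Time domain, T1–T15

With x(n), n = 1…N, mean μ and population standard deviation s
(all moments are central and divide by N; kurtosis is excess, i.e. −3):

- T1 mean; T2 rectified mean ⟨|x|⟩; T3 peak-to-peak max−min;
  T4 variance s²; T5 skewness; T6 kurtosis; T7 coefficient of variation s/|μ|;
  T8 population SD; T9 mean of |x−μ|.
- T10 zero-crossing rate: the mean is removed first, strict sign changes are
  counted over consecutive samples, and the count is divided by N−1.
- T11 normalised first difference: ⟨|x(n+1)−x(n)|⟩ / s.
- T12 normalised second difference: ⟨|x(n+2)−x(n)|⟩ / s — note the gap
  (two-sample) difference, not the difference of differences.
- T13 Hjorth activity s²; T14 Hjorth mobility s(Δx)/s(x);
  T15 Hjorth complexity (s(Δ²x)/s(Δx)) / (s(Δx)/s(x)), where Δ is the
  first-difference operator and each s is the population SD of the
  corresponding (shorter) sequence.

If s = 0 (constant epoch), the normalised features are reported as 0 and a
`DegenerateEpochWarning` is emitted.

### Frequency domain, F1–F39

The spectrum is the one-sided periodogram |DFT(x)/NFFT|² with NFFT = N = 3000
and no taper. At NFFT = 3000 the bin width is fs/NFFT = 1/30 Hz, so every
band edge below falls on or between bins cleanly; no zero padding is applied
because the features are band integrals, not peak locations. Band powers sum
periodogram bins over half-open intervals [lo, hi):

| band | Hz | power |
|---|---|---|
| total | 0.5–45 | E1 |
| low delta | 0.5–2 | E2 |
| high delta | 1.2–4 | E3 |
| theta | 4–8 | E4 |
| alpha | 8–13 | E5 |
| beta 1 | 13–22 | E6 |
| beta 2 | 22–30 | E7 |
| gamma | 30–45 | E8 |

E9 = E2+…+E8. The two delta bands deliberately overlap (1.2–2 Hz is counted
in both); E9 therefore differs from E1. F1–F6 are E2, E3, E4, E5, E6+E7, E8.
F7–F25 are fixed ratios of these powers (e.g. F7 = E2/E9, F13 = (E2+E3)/E9,
F19 = E5/(E3+E4), F22 = (E6+E7)/E9, F25 = (E2+E6)/E9); the full table is the
`_RATIOS` mapping in `features_freq.py`. A zero denominator yields 0 with a
`DegenerateEpochWarning`.

F26–F39 are the mean power frequency (MPF, the power-weighted mean frequency,
Hz) and frequency variability (FV, the power-weighted variance, Hz²) of seven
ranges: the full 0.5–45 Hz band, low delta, high delta, theta, alpha, a
combined 13–30 Hz beta band, and gamma.

### Nonlinear, N1–N3

- **N1, Higuchi fractal dimension.** k_max = ⌊N/20⌋ (= 150 at N = 3000). For
  each lag k, the k sub-curve lengths are averaged into H̄(k) with the
  standard (N−1)/(⌊(N−m)/k⌋·k²) normalisation, and the FD is the closed-form
  least-squares slope of ln H̄(k) against −ln k. A line scores ≈ 1.0, white
  noise ≈ 2.0.
- **N2, normalised slope indicator.** The epoch is split into m = ⌊0.15·N⌋
  contiguous segments, as equal as possible (the first N mod m segments get
  one extra sample); the NSI is the population SD of the segment means. It is
  translation-invariant and scales with amplitude.
- **N3, sample entropy.** m = 2, tolerance r = 0.2·SD(x), Chebyshev distance,
  self-matches excluded, with N−m templates used for both the length-m and
  length-(m+1) counts; SampEn = −ln(A/B). Neighbour counting uses a k-d tree
  (`cKDTree.count_neighbors`, ≈ 30 ms per 3000-sample epoch) and is verified
  against a brute-force double loop in the tests. If A or B is zero the value
  is NaN with a `DegenerateEpochWarning`.

## Feature screening

An embedded screening rule: fit a 100-tree random forest on the training
features, take its mean-decrease-in-impurity importances, normalise them to
sum to 1, and keep features with weight **strictly greater than** 0.02
(an "above the uniform 1/57 ≈ 0.0175 share, with margin" rule). Strict
inequality matters at the boundary: on the stored published weight table a
feature with weight 0.0201 is retained at threshold 0.02, producing exactly
the 11-feature set {T6, T7, F2, F5, F6, F8, F9, F12, F19, F22, N2}. Selection
order is by descending weight; an empty selection raises an error that
reports the largest available weight.

## Classifiers

All models are scikit-learn pipelines keyed by feature *name*, so prediction
reorders columns to match training. Defaults (seedable everywhere):

- **svm** — standardise, then one-vs-rest RBF SVC with C = 1.3, γ = 0.03.
  One-vs-rest with an RBF kernel was chosen over a linear kernel because a
  kernel width is part of the model definition used throughout.
- **bpnn** — min-max scale to [0, 1], then an MLP with two hidden layers of
  18 units, SGD with learning rate 0.1 and momentum 0.9, early stopping,
  at most 500 iterations.
- **dt** — CART with entropy criterion, max depth 11, min 11 samples/leaf.
- **rf** — 100 trees, Gini, max depth 22, min 5 samples/leaf.

## Evaluation protocol

- Stratified hold-out split, test fraction 0.2 (scikit-learn's per-class
  ceiling rule: the balanced 9696-epoch benchmark set yields exactly 1940
  test epochs), and stratified k-fold CV (default k = 5).
- Per-stage precision, recall, and F1 = TP / (TP + (FN+FP)/2) (algebraically
  the harmonic mean of precision and recall); pooled accuracy; 5×5 confusion
  matrices with fixed stage order; agreement rate between two raters or
  models and Cohen's κ.
- `reference.py` stores the published benchmark: per-stage train/test/correct
  counts and precision/recall for the all-feature SVM (overall accuracy
  81.86 % on 1940 epochs), the 57 published screening weights, and the
  balanced class histogram (W/N1/N2 2029 each, N3 1671, REM 1938). These are
  reference values for validating the metric arithmetic, not training data.

## Synthetic EEG generator

`synthetic.generate_epoch(stage, seed)` draws unit-RMS Gaussian noise,
filters it into the seven bands above (201-tap FIR, zero-phase), and mixes
the bands with stage-specific gains before scaling to a stage-specific RMS
amplitude (µV): W 20, N1 25, N2 35, N3 60, REM 16. The gain profiles encode
the textbook stage signatures: W is alpha-dominant; N1 theta-dominant with
residual alpha; N2 mixed delta/theta **plus transient events** — 13 Hz
spindle bursts (1 s, Hann-windowed, Poisson rate 4 per epoch) and biphasic
K-complexes (rate 1 per epoch); N3 is high-amplitude slow-wave activity
(delta gain 2.2); REM is low-amplitude mixed-frequency with relatively more
beta than N1. Every epoch gets its own seed drawn from a master generator,
so datasets are reproducible epoch-for-epoch and the label histogram is
independent of the seed.

What it does **not** emulate: real inter-subject and within-night
variability, artifacts (EMG, EOG, electrode pops), stage transitions inside
an epoch, 1/f broadband structure, or realistic stage autocorrelation across
the night. Stages are therefore far more separable than in real PSG —
classifiers routinely reach ≈ 100 % on the default recipe. That is by
design: the generator's role is to exercise and validate the pipeline, not
to calibrate expected clinical performance. The `hard=True` recipe averages
the N1 and REM gain profiles toward each other to restore the hardest
real-world confusion.

Default dataset sizes: `generate_dataset()` with no counts reproduces the
balanced benchmark histogram (9696 epochs); tests and the acceptance script
use 200 epochs/stage, which a single CPU processes (generation + features)
in about a minute.

## Numerical and reproducibility notes

- All randomness flows from explicit integer seeds (< 2³¹); repeated runs
  are byte-identical, which the test suite verifies at the file level.
- Moments use population (divide-by-N) conventions throughout; SDs of
  difference sequences use the length of that sequence.
- Band intervals are half-open [lo, hi), so no bin is counted twice within a
  scheme (the two delta bands overlap by construction, not by accident).
- Feature extraction is vectorised (rfft periodogram, `bincount`-based
  Higuchi sums, k-d-tree SampEn) at ≈ 40 ms per epoch; every vectorised
  feature is checked against an independent brute-force oracle.
- Degenerate inputs (constant epochs, empty bands, zero match counts) warn
  via `DegenerateEpochWarning` and return 0 or NaN rather than raising, so a
  single flat epoch cannot abort a whole-night extraction.
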