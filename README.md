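# sleepstage

Automatic sleep-stage classification from a single EEG channel.

`sleepstage` implements a complete feature-based staging pipeline for 30-second
epochs of single-channel EEG (Fpz–Cz, 100 Hz, 3000 samples per epoch):

- **I/O** — read PSG recordings (EDF) and hypnograms (EDF annotations or TSV),
  map R&K / annotation vocabulary onto the five AASM stages
  (W, N1, N2, N3, REM), cut the signal into labelled 30-s epochs, and balance
  classes by random sub-sampling.
- **Preprocessing** — zero-phase 0.5–45 Hz FIR band-pass (401-tap Hamming
  window, applied forward and backward).
- **Features** — a 57-dimensional vector per epoch:
  - *Time domain (T1–T15)*: mean, rectified mean, peak-to-peak, variance,
    skewness, kurtosis, standard deviation, central moments, zero-crossing
    rate, normalised first/second differences, and the three Hjorth
    parameters (activity, mobility, complexity).
  - *Frequency domain (F1–F39)*: absolute and relative powers of seven bands
    (low-δ 0.5–2 Hz, high-δ 1.2–4 Hz, θ 4–8 Hz, α 8–13 Hz, β₁ 13–22 Hz,
    β₂ 22–30 Hz, γ 30–45 Hz), 25 band-power ratios, and mean power frequency /
    frequency variability per band.
  - *Nonlinear (N1–N3)*: Higuchi fractal dimension, normalised slope
    indicator, and sample entropy (m = 2, r = 0.2·SD).
- **Feature screening** — an embedded method: normalised impurity importances
  from a random forest, thresholded at weight > 0.02.
- **Classifiers** — SVM (RBF, one-vs-rest, standardised inputs), BPNN
  (two 18-unit hidden layers, SGD with momentum, min-max scaled inputs),
  decision tree (entropy), and random forest (100 trees), all with fixed
  seeds for reproducibility.
- **Evaluation** — stratified 80/20 split, stratified 5-fold CV, per-stage
  precision/recall/F1, confusion matrices, agreement rate and Cohen's κ,
  plus confusion-matrix and hypnogram plots.
- **Synthetic data** — a seeded, stage-conditioned EEG generator
  (band-limited noise mixtures with stage-specific band gains and amplitudes,
  plus sleep spindles and K-complexes in N2) so the whole pipeline can be
  exercised end-to-end without any recordings.

## Quick start (command line)

Generate a synthetic labelled feature table, screen features, and train and
evaluate a random forest:

```console
$ sleepstage extract --synthetic --epochs-per-stage 40 --seed 42 --out features.csv
retained 200 epochs: {'W': 40, 'N1': 40, 'N2': 40, 'N3': 40, 'REM': 40}
wrote features.csv

$ sleepstage select --features features.csv --threshold 0.02 --seed 42 --out-dir sel
selected 26 features: T4, F6, T13, T14, F9, T15, F19, T3, F15, T10, ...

$ sleepstage evaluate --features features.csv --model rf --test-frac 0.2 --seed 42 --cv --out-dir eval
rf: accuracy 100.00% on 40 test epochs
```

`eval/` then contains `report.json` (accuracy, per-fold CV accuracies),
`report.csv` (per-stage precision/recall/F1), and `confusion.csv`; add
`--plot` for PNG figures. The default synthetic recipe is deliberately
well-separated; pass `--hard` to `extract`/`simulate` to blur the N1/REM
distinction, the hardest pair in real recordings.

Real recordings are staged the same way:

```console
sleepstage extract --psg night1.edf --hypnogram night1-hypnogram.edf \
    --channel "EEG Fpz-Cz" --out night1.csv
sleepstage evaluate --features night1.csv --model svm --out-dir results/
```

Other commands: `sleepstage simulate` writes a synthetic recording as
EDF + TSV hypnogram; `sleepstage train` persists a fitted model;
`sleepstage compare` reproduces the full 4-classifier × {all, screened}
comparison grid. Every command accepts `--config pipeline.yaml` and repeated
`--set key=value` overrides (e.g. `--set models.rf.n_estimators=200`).

## Quick start (Python)

```python
from sleepstage import evaluation, models, selection, synthetic
from sleepstage.features import extract_features, split_table

rec = synthetic.generate_dataset({s: 100 for s in synthetic.STAGES}, seed=7)
x, y = split_table(extract_features(rec))

train, test = evaluation.stratified_split(y, test_frac=0.2, seed=7)
weights = selection.fit_importances(x.iloc[train], y[train], seed=7)
keep = selection.select_by_threshold(weights, threshold=0.02)

model = models.fit(models.ModelSpec("rf", seed=7), x.iloc[train][keep], y[train])
report = evaluation.report(
    evaluation.confusion(y[test], models.predict(model, x.iloc[test][keep]))
)
print(report.per_stage)
```

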