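# mstate

EEG microstate analysis and motor-imagery BCI performance prediction.

The package implements a complete, tested pipeline:

* **Preprocessing** — EDF or plain matrix+sidecar I/O, zero-phase 7–30 Hz
  band-pass, average referencing, pre-trial epoch extraction
  (`mstate.eeg_core`).
* **Microstate segmentation** — global field power (GFP), global map
  dissimilarity (GMD), GFP-peak picking with a 10 ms minimum spacing,
  polarity-invariant modified k-means clustering of peak topographies, and
  backfitting of all samples to template maps (`mstate.microstate`).
* **Cluster-number selection** — global explained variance (GEV), the
  cross-validation criterion, and within-cluster dispersion, scanned over
  K = 2..10 (`mstate.fit_measures`).
* **Feature parameters** — per-class mean duration, occurrence per second,
  time coverage, and the transition probability matrix, with exact pooling
  across epochs (`mstate.parameters`).
* **MI ground truth** — CSP log-variance features, stratified 10-fold
  linear-SVM classification accuracy, and the strict >75 % "high group"
  rule (`mstate.mi_performance`).
* **Prediction** — Pearson correlation screening of all parameters against
  accuracy, a two-feature (MS1 occurrence + MS3 mean duration) LDA
  predictor with per-session leave-one-out CV, ROC/AUC, and a channel-C3
  spectral-entropy baseline (`mstate.predictor`).
* **Synthetic data** — seeded generators with planted microstate maps,
  semi-Markov state dynamics, MI class separability, and a cohort
  (28 subjects × 6 sessions) whose microstate parameters are latently
  correlated with MI accuracy (`mstate.synthetic`, `mstate.pipeline`).

## Command line

```bash
mstate simulate --config cfg.txt --out data/        # synthetic recordings + truth
mstate preprocess --in rec.edf --band 7 30 --out clean.edf
mstate segment --in clean.edf --k 4 --seed 7 --model-out maps.tsv --labels-out labels.txt
mstate scan-k --in clean.edf --k-min 2 --k-max 10 --out scan.tsv
mstate params --labels labels.txt --fs 250 --out params.tsv
mstate accuracy --left left.txt --right right.txt --folds 10 --seed 7
mstate predict --cohort cohort.tsv --out pred.tsv --roc-out roc.tsv
```

## Conventions

Voltages in microvolts, 0-based sample indexing, half-open windows,
durations in milliseconds, 1-based microstate class labels. Default
sampling rate 250 Hz; filter realization is a 4th-order Butterworth applied
forward-backward. Clustering is polarity-invariant; backfitting defaults to
polarity-invariant dissimilarity with a flag for the polarity-sensitive
variant.
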