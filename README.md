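# recline

Lying-posture classification from a single tri-axial accelerometer.

`recline` implements an end-to-end pipeline for detecting the four major
in-bed postures (supine, prone, left lateral, right lateral) from one
body-worn accelerometer:

- **`recline.data`** — episode/dataset containers, magnitude normalization,
  label-based segmentation of continuous recordings, fixed-length
  resegmentation of long recordings, dataset integration with seeded
  subsampling, plain-CSV I/O, and per-(posture, axis) summaries.
- **`recline.features`** — sliding windows (50 % overlap, window length =
  minimum training-episode length) and 48 time-domain features per window,
  averaged into one meta-feature vector per episode.
- **`recline.classical`** — a bagged ensemble of 100 decision trees with
  random feature subsets and majority voting, MSE-based feature importance,
  and two linear baselines (LDA and linear SVM on per-axis episode means).
- **`recline.adalstm`** — a bidirectional LSTM sequence classifier
  (10 hidden units, three fully connected layers, softmax) trained with
  Adam and a decaying learning-rate schedule against a length-weighted
  cross-entropy. Implemented in pure NumPy with analytic backpropagation
  (finite-difference-verified); a constant-schedule variant provides the
  fixed-learning-rate LSTM baseline.
- **`recline.evaluation`** — leave-one-subject-out (LOSO) cross-validation,
  confusion-matrix metrics (macro one-vs-rest accuracy, macro
  precision/recall, F1, balanced accuracy), coefficient of variation over
  folds, and a Kruskal–Wallis comparison helper.
- **`recline.synthetic`** — a seeded simulator of labeled in-bed
  accelerometer episodes built on gravity projection: per-(site, posture)
  orientation vectors, per-subject mounting rotations, jitter, and
  raised-cosine movement bursts whose rate is elevated at arm/wrist sites.

## CLI

One executable with subcommands (see `recline --help`):

```sh
# generate a synthetic chest dataset (manifest + episode CSVs + latents.json)
recline simulate --out data/ --seed 7 --subjects 8 --site chest

# 48-column meta-feature table
recline extract-features --manifest data/manifest.csv --out features.csv

# LOSO evaluation of a model at one site
recline evaluate-loso --manifest data/manifest.csv --model ensemble \
    --site chest --seed 7 --out results/

# train on the full dataset and archive the model
recline train --manifest data/manifest.csv --model adalstm --seed 7 \
    --out model

# summarize one or more LOSO runs
recline report --results results/
```

Models: `ensemble`, `adalstm`, `lda`, `svm`, `lstm-fixed`. All stochastic
commands require `--seed` and are deterministic given it.

## Data formats

- Episode CSV: columns `t,ax,ay,az` (time optional; accelerations in g).
- Manifest CSV: columns `file,subject,site,posture,rate_hz`.
- Body sites: `chest`, `thigh_L/R`, `ankle_L/R`, `arm_L/R`, `wrist_L/R`.
- `read_dataset(..., scale=...)` rescales datasets recorded in other units.
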