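# trialcv

Quantifying how within-trial temporal correlation biases k-fold
cross-validation in single-subject classification of trial-structured
physiological time series — and how trial-level ("block-wise")
cross-validation behaves instead.

## The problem

In passive brain–computer-interface studies (mental workload, fatigue,
emotion), data are recorded in relatively long trials of one mental state
and cut into short epochs that serve as classification samples. Epochs from
the same trial are more correlated with each other than with epochs from
other trials of the same class. Ordinary k-fold CV randomly partitions
*samples*, so epochs of one trial land on both sides of every train/test
split: the classifier can exploit trial identity rather than mental state,
and the accuracy estimate inflates. Block-wise (trial-wise) CV partitions
*trials*, keeping every epoch of a trial on one side of the split.

`trialcv` provides the full machinery to measure this effect under
controlled conditions:

- a **synthetic session generator**: binary-class sessions of `n`-second
  trials of multichannel band-limited signal, with a separability knob
  `δ` (per-class band-amplitude contrast) and a correlation knob `τ` (a
  per-trial multiplicative gain `g ~ N(1, τ²)` shared by all epochs of a
  trial);
- EEG-style **per-epoch features**: band power in the δ/θ/α/β/γ bands,
  differential entropy `½ ln(2πe·P)`, delta-band spectral entropy,
  broadband RMS and variance;
- **in-fold mRMR** feature selection (greedy relevance-minus-redundancy on
  3-bin discretized features) and three classifier contracts (LDA, linear
  SVM, KNN);
- a **CV engine** with sample-level k-fold and trial-level block-wise
  partitions, repeated runs, and the two label-randomization diagnostics:
  *trial-level* (relabel half of each class's trials wholesale — masks the
  class effect, keeps within-trial label structure) and *sample-level*
  (relabel half of each class's epochs — destroys both);
- **t-test reporting**: paired tests of each CV mode against the
  ground-truth condition (1 epoch/trial, randomized order), one-sample
  tests of randomized-label accuracies against chance (50%), assembled into
  a scenario grid;
- a **Monte-Carlo Bayes-rate oracle** giving the best achievable
  single-epoch accuracy under the generator, used to check that CV is
  calibrated when no leakage channel exists.

Accuracy under trial-randomized labels with k-fold CV is the headline
diagnostic: the class effect is gone, so anything above 50% is leakage.

## Worked example

Six replicate synthetic participants in the low-separability,
high-correlation regime (6 min/class of 60-s trials → 12 five-second
epochs per trial; δ = 0.035, τ = 0.5; band-power features, linear SVM,
6-fold/6-block CV × 5 runs):

```python
from trialcv import run_condition_battery
from trialcv.experiment import DELTA_LOW, TAU_HIGH
import numpy as np

conds = [
    dict(name="true_kfold", trial_duration_s=60, tau=TAU_HIGH, delta=DELTA_LOW,
         cv_mode="sample_kfold", rand_level="none"),
    dict(name="true_blockwise", trial_duration_s=60, tau=TAU_HIGH, delta=DELTA_LOW,
         cv_mode="trial_blockwise", rand_level="none"),
    dict(name="trialrand_kfold", trial_duration_s=60, tau=TAU_HIGH, delta=DELTA_LOW,
         cv_mode="sample_kfold", rand_level="trial"),
    dict(name="trialrand_blockwise", trial_duration_s=60, tau=TAU_HIGH, delta=DELTA_LOW,
         cv_mode="trial_blockwise", rand_level="trial"),
]
battery = run_condition_battery(conds, n_replicates=6, master_seed=7,
                                feature_set="bandpower", classifier="svm")
for name, vals in battery.items():
    print(f"{name:22s} {np.mean(vals):5.1f}%  (replicate sd {np.std(vals, ddof=1):.1f})")
```

which prints:

```
true_kfold              57.9%  (replicate sd 9.0)
true_blockwise          51.4%  (replicate sd 13.0)
trialrand_kfold         59.5%  (replicate sd 4.0)
trialrand_blockwise     52.1%  (replicate sd 4.2)
```

Read it like this: with the class labels *randomized at trial level* there
is nothing real to classify, yet k-fold CV still reports 59.5% — that whole
margin above 50% is leakage through within-trial correlation, and it is as
large as the true-label k-fold estimate itself. Block-wise CV under the
same randomization sits at chance, and its true-label estimate (51.4%) is
the honest — if noisier — picture of how little signal this regime
actually contains.

## Command line

```bash
trialcv simulate --config cfg.yaml --out data/ --seed 1   # one session → CSV dataset
trialcv features --dataset data/ --feature-set bandpower --out feats.csv
trialcv run --features feats.csv --scheme kfold --k 6 --runs 5 \
            --rand trial --clf svm --select 30 --seed 0 --out cv.json
trialcv study --smoke --out results/                      # reduced end-to-end study
trialcv report --in results/ --alpha 0.05 --out report.csv
```

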