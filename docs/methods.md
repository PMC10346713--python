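# Methods

## The generative model

A session consists of `2 × minutes_per_class × 60 / trial_duration_s`
trials, presented in uniformly random order, each belonging to one of two
classes. Trial `i` of class `c` produces an `n_channels × (fs ·
trial_duration_s)` signal

```
x_ch(t) = Σ_b  G[c, b, ch] · g_i · η_b,ch(t)  +  σ · w_ch(t)
```

where `η_b,ch` is unit-variance Gaussian noise exactly confined to band
`b` (delta 1–4, theta 4–8, alpha 8–12, beta 12–30, gamma 30–50 Hz by
default), `w_ch` is white noise with SD `σ` (`noise_sd`, default 1), `G`
is the per-class, per-band, per-channel amplitude gain, and `g_i ~
Normal(1, τ²)` is a gain drawn once per trial, shared by every band and
channel, and truncated below at 0.05 so it can never flip sign or zero out
the power.

Two scalar knobs summarize the design space:

- **δ (separability)** — `gain_profile(delta, n_channels)` builds `G`
  with unit gain everywhere except class 1's alpha band, which gets
  `1 + δ`. δ = 0 gives exchangeable classes (chance-level Bayes rate).
- **τ (`trial_gain_sd`, within-trial correlation)** — with τ > 0, all
  epochs cut from one trial share the same power scale `g_i`, so their
  band-power features co-fluctuate. This is the leakage channel: a
  sample-level partition lets a classifier match a test epoch to its
  same-trial siblings in the training set through `g_i`, independent of
  the class effect. With τ = 0 epochs are i.i.d. across trials.

Band-limited noise is synthesized by zeroing rFFT bins outside the band
(DC and Nyquist always excluded) and scaling by the analytic factor
`sqrt(N / (2·m_b))` (`m_b` = in-band bin count), which makes the process
variance exactly 1 while keeping the in-band spectrum flat and Gaussian.
The analytic scale (rather than per-realization standardization) is what
makes the oracle below exact.

The session plan and the signal noise are drawn from two independent seed
streams, so tests can vary the trial ordering while holding waveforms
fixed.

### What the generator does and does not emulate

It reproduces the statistical skeleton that matters for cross-validation
behaviour: balanced binary designs, randomized trial order, configurable
epochs-per-trial, band-limited spectra, class effects localized in a band,
and within-trial correlation of adjustable strength. It does **not**
attempt realistic electrophysiology: no 1/f background, no spatial mixing
or volume conduction (channels are independent), no artifacts (blinks,
EMG, line noise), no non-stationarity beyond the per-trial gain, and the
within-trial correlation is a single multiplicative factor rather than an
empirically fitted autocorrelation process. Passing the property suite
therefore shows that the *pipeline* behaves correctly under a controlled
correlation structure; it does not certify effect sizes on real
recordings, where the correlation structure is richer.

## The Bayes-rate oracle

Conditional on `g`, the in-band rFFT energies of a single epoch are
independent Gamma variates: shape `m_b`, scale `(G[c,b,ch]·g)²·N/(2·m_b) +
σ²` (common factors dropped). Those energies are sufficient for the class
because in-band spectra are flat and phases carry no information.
`bayes_rate_oracle` simulates `n_mc` balanced single epochs directly from
this sampling distribution and classifies each with the likelihood-ratio
rule, marginalizing `g` by quadrature over its truncated normal
distribution (201-point grid, with the truncated lower tail's mass placed
on the 0.05 atom, matching the generator). The returned accuracy carries a
binomial standard error. With δ = 0 the rule degenerates and the estimate
is exactly the class balance (0.5).

## Features

- Epochs are contiguous, non-overlapping, fixed-length (default 5 s)
  segments; a trailing remainder is discarded with a warning.
- **PSD estimator**: Welch with 1-s windows and 50% overlap by default —
  the conventional choice for EEG band power. A `psd_method="periodogram"`
  option computes the single full-epoch rectangular-window periodogram
  instead; its in-band integral is exactly the epoch's in-band energy, the
  generator's sufficient statistic. The Hann window of the Welch estimator
  leaks a few percent of the power of an exactly band-confined process out
  of its band, which matters only for closed-form checks and for the
  ground-truth-recovery comparison below.
- Band power integrates the PSD over `[low, high)` (rectangle rule at bin
  resolution). Differential entropy is the Gaussian closed form
  `½ ln(2πe·P_band)` in nats. Spectral entropy is the Shannon entropy of
  the normalized in-band PSD divided by `ln(#bins)`. RMS and variance use
  the population (`n`) denominator so `RMS² = var + mean²` holds exactly.
- **Preprocessing** (optional; the pipeline runs on raw synthetic signals
  by default because they are generated band-limited at the target rate):
  anti-aliased decimation, zero-phase bandpass, common-average reference.
  The bandpass is a 6th-order elliptic design (0.1 dB ripple, 20 dB
  stopband) applied forward–backward. An all-pole 4th-order design was
  rejected because the transition from a 55 Hz passband edge to 60 Hz
  mains is only 0.13 octave: a 4th-order Butterworth attenuates 60 Hz by
  ~12 dB double-pass, while the elliptic design is flat to ±0.2 dB through
  54 Hz and below −50 dB at 60 Hz.
- **Fold-safe z-scoring**: `train_fitted` scales the test fold by the
  training fold's means/SDs; `separate` scales each side by its own
  statistics (both variants exist in the literature this package serves;
  `train_fitted` is the default and every report records the mode used).
  Zero-variance columns are centered with scale pinned to 1.

## Selection and classifiers

mRMR uses the classic discrete scheme: z-score, cut at ±0.5 SD into three
bins, mutual information (nats) from contingency tables, greedy MID
(relevance minus mean redundancy with the selected set), ties to the
lowest column index. `m ≥ n_features` returns all features in relevance
order. The default `m = 30` matches the dimensionality the field commonly
reduces to; with the synthetic montages (≤ 40 features) selection is often
the identity, which is intentional — the contract, not the compression, is
what the engine exercises.

Classifiers are scikit-learn estimators behind a thin contract: LDA
(SVD solver; optional shrinkage via lsqr), SVC with a linear kernel
(C = 1), KNeighbors (k = 5, odd to avoid binary voting ties). Fixed
defaults replace automatic hyperparameter search so every result is
reproducible from its seed; an optional small inner 3-fold grid
(`inner_tuning="small_grid"`) exists for sensitivity checks. A
single-class training fold raises rather than degrading silently.

## The CV engine

`run_cv` repeats, per run: re-randomize labels (fresh sub-seed),
partition, then per fold z-score → mRMR on the training rows only → fit →
score. Sub-seeds (randomization, partition) are drawn per run from the
scheme's master seed and recorded in the result, so any fold replays
exactly. Partition counts must divide evenly (the balanced designs used
here are exactly divisible; silent near-balance would weaken the
invariant tests). The reported estimate is the unweighted mean of the
runs × folds accuracy grid — fold sizes are equal by construction.

Label randomization preserves class totals exactly: trial-level flips all
samples of a random half of each class's trials (requires even per-class
trial counts); sample-level flips a random half of each class's samples.
Original labels are kept in a `true_label` column for audit.

## Statistics and the report grid

True-label accuracies are compared to the ground-truth condition by
two-sided paired t-tests across replicates; randomized-label accuracies to
chance (50%) by two-sided one-sample t-tests. Zero-variance, zero-mean
differences take `t = 0, p = 1`. Sidedness is pinned to two-sided as the
conservative default. No multiple-testing correction is applied by default
(each scenario is reported as an individual test); a Holm option exists.
Replicate synthetic sessions play the role of participants; the default
replicate count is 12.

## Study conditions and problem sizes

The factorial study crosses 2 separability levels × 4 feature sets
(band power, delta spectral entropy, RMS, variance) × 3 classifiers = 24
scenarios, each with 12 CV tests across the three trial-length sections
(2 for the 5-s section, where k-fold and block-wise coincide, 5 each for
the 15-s and 60-s sections), i.e. 288 tests per participant.

δ is calibrated once against the oracle at the study conditions
(8 channels, 5-s epochs, 250 Hz, σ = 1, τ = 0.5): `DELTA_LOW = 0.035`
(Bayes rate 64.5%) and `DELTA_HIGH = 0.15` (92.6%), matching the low and
high separability regimes the design targets. `TAU_HIGH = 0.5` makes the
per-trial gain the dominant source of feature variance, a deliberately
strong but not degenerate correlation level.

The property suite and the acceptance script run the leakage battery at
full design size (6 min/class, 144 epochs per section, 6-fold × 5 runs,
12 replicates) but with an 8-channel montage and a reduced factor set
(band power + SVM for the leakage battery), keeping the whole suite
around ten minutes on one CPU; montage width affects absolute accuracy
but not the presence or ordering of the leakage effects being tested.

## Ground-truth recovery and known biases

Two calibration facts shape how the pipeline's correctness is checked:

1. **Finite-sample classifier penalty.** A trained linear classifier does
   not attain the Bayes rate at the study's default dimensions (40
   features vs 120 training samples costs roughly 7 points at
   mid-separability; Welch leakage costs ~2 more; marginalizing the
   trial gain adds a structural nonlinearity worth ~5 points at τ = 0.5).
   The check that both CV modes agree with the oracle is therefore run in
   a regime where the attainability premise demonstrably holds: one
   channel (5 DE features), 12 min/class (240 training samples), τ = 0,
   periodogram features — there the trained pipeline sits within ~1
   combined SE of the oracle. At wider montages the CV estimate is an
   unbiased estimate of the *trained classifier's* accuracy, which is
   genuinely below the Bayes bound; that gap is a property of the
   classifier, not of cross-validation.

2. **Pessimistic bias under balanced permutation.** Sample-randomized
   k-fold accuracy averages slightly below 50% (about −1.2 points at the
   study sizes): with exactly half of each class relabeled, train and
   test labels are negatively dependent through the balance constraint,
   and a classifier that overfits training noise is systematically
   slightly anti-correlated with the held-out labels. This bias is
   conservative (it cannot masquerade as signal) and is visible in the
   acceptance output; calibration checks therefore assess whether the
   replicate accuracy distribution (mean ± 1.96 SD) covers chance.

## Numerical conventions

- All accuracies are reported in percent; internal fold scores are
  fractions.
- Tie-breaks: mRMR → lowest column index; KNN → odd k avoids binary ties.
- Degenerate inputs: constant features are centered (scale 1, warning);
  constant signals give zero band power; zero band power is an error for
  differential entropy (log of zero) and spectral entropy.
- Seed hierarchy: master seed → per-run seeds → (randomization,
  partition) sub-seeds, all recorded; dataset generation separates plan
  and noise streams. Every seed stays below 2³¹.

## Limitations

- The correlation model is a single per-trial gain; real within-trial
  dependence also includes slow drifts and band-specific dynamics, so
  absolute inflation sizes here do not transfer to real data.
- Channels are statistically independent; common-average referencing on
  such data slightly mixes rather than denoises, so preprocessing is off
  by default for synthetic runs.
- Only balanced binary designs are supported; multiclass and unbalanced
  partitions raise errors by design.
- Block-wise CV with few trials per class (e.g. 6, as in the 60-s
  section) has large replicate variance; conclusions at that design size
  need the replicate averaging the study driver provides.
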