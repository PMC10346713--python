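"""Sample-level k-fold CV, trial-level block-wise CV and label randomization.

The engine implements the two partitioning strategies whose contrast is the
point of this package:

* **k-fold**: samples (epochs) are randomly divided into ``k`` equal,
  class-balanced subsets.  Epochs from one trial end up on both sides of
  each split, so within-trial temporal correlation can leak into the test
  fold and inflate the accuracy estimate.
* **block-wise**: trials are randomly divided into ``b`` equal subsets and
  every epoch follows its trial, so no trial ever spans the train/test
  boundary.

Two label-randomization diagnostics quantify the leakage: *trial-level*
randomization relabels half of each class's trials wholesale (masking the
class effect but keeping labels homogeneous within trials), while
*sample-level* randomization relabels half of each class's epochs
independently of the trial structure.  Under trial randomization, any
accuracy above chance in k-fold CV is attributable purely to within-trial
correlation.

``run_cv`` repeats the full procedure (re-randomize labels, partition,
z-score in-fold, mRMR on the training fold only, fit, score) over several
runs and reports the unweighted mean of the runs-by-folds accuracy grid.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .features import FeatureTable, zscore_fit_apply
from .selection import ClassifierSpec, mrmr_select, train_eval

__all__ = [
    "CVSchemeSpec",
    "LabelRandomization",
    "CVResult",
    "kfold_partition",
    "blockwise_partition",
    "randomize_labels",
    "evaluate_folds",
    "run_cv",
]


@dataclasses.dataclass(frozen=True)
class CVSchemeSpec:
    """Declarative description of one cross-validation test."""

    mode: str = "sample_kfold"  # or "trial_blockwise"
    k: int = 6
    runs: int = 5
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("sample_kfold", "trial_blockwise"):
            raise ValueError(f"unknown CV mode {self.mode!r}")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.runs < 1:
            raise ValueError("runs must be >= 1")


@dataclasses.dataclass(frozen=True)
class LabelRandomization:
    """Label-shuffling diagnostic: none, trial-level, or sample-level."""

    level: str = "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.level not in ("none", "trial", "sample"):
            raise ValueError(f"unknown randomization level {self.level!r}")


def _split_even(ids: np.ndarray, k: int, what: str) -> list[np.ndarray]:
    if len(ids) % k:
        raise ValueError(f"{what} count {len(ids)} is not divisible by k={k}")
    return np.split(ids, k)


def kfold_partition(
    table: FeatureTable, k: int, stratified: bool = True, seed: int = 0
) -> list[np.ndarray]:
    """Randomly divide sample ids into ``k`` disjoint equal subsets.

    With ``stratified`` each subset carries equal per-class counts; counts
    that do not divide by ``k`` raise (the balanced designs targeted here
    are exactly divisible).  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    ids = table.sample_ids
    if stratified:
        parts: list[list[np.ndarray]] = [[] for _ in range(k)]
        labels = table.y
        for c in np.unique(labels):
            class_ids = rng.permutation(ids[labels == c])
            for fold, chunk in enumerate(_split_even(class_ids, k, f"class {c} sample")):
                parts[fold].append(chunk)
        return [np.concatenate(p) for p in parts]
    return _split_even(rng.permutation(ids), k, "sample")


def blockwise_partition(
    table: FeatureTable, b: int, stratified: bool = True, seed: int = 0
) -> list[np.ndarray]:
    """Randomly divide trials into ``b`` subsets; samples follow their trial.

    No trial id ever spans two subsets.  With ``stratified`` the per-class
    trial counts are equal across subsets (counts must divide by ``b``).
    """
    rng = np.random.default_rng(seed)
    frame = table.frame
    trial_label = frame.groupby("trial_id", sort=True)["class_label"].first()
    trial_ids = trial_label.index.to_numpy()
    folds_of_trials: list[list] = [[] for _ in range(b)]
    if stratified:
        for c in np.unique(trial_label.to_numpy()):
            class_trials = rng.permutation(trial_ids[trial_label.to_numpy() == c])
            for fold, chunk in enumerate(_split_even(class_trials, b, f"class {c} trial")):
                folds_of_trials[fold].extend(chunk)
    else:
        for fold, chunk in enumerate(_split_even(rng.permutation(trial_ids), b, "trial")):
            folds_of_trials[fold].extend(chunk)
    sample_folds = []
    for trials in folds_of_trials:
        mask = frame["trial_id"].isin(set(trials))
        sample_folds.append(frame.loc[mask, "sample_id"].to_numpy())
    return sample_folds


def randomize_labels(table: FeatureTable, spec: LabelRandomization) -> FeatureTable:
    """Mask class differences by relabeling half of each class.

    Trial level: half of each class's trials are selected and all their
    samples relabeled as the other class, so labels stay constant within
    trials and the temporal structure stays label-aligned.  Sample level:
    half of each class's samples are relabeled independently of trials.
    Overall class counts are preserved exactly; per-class counts must be
    even (no silent floor).  The original labels are kept in the
    ``true_label`` metadata column.
    """
    if spec.level == "none":
        return table.with_labels(table.y.copy())
    classes = np.unique(table.y)
    if classes.size != 2:
        raise ValueError("label randomization requires binary labels")
    rng = np.random.default_rng(spec.seed)
    labels = table.y.copy()
    other = {classes[0]: classes[1], classes[1]: classes[0]}

    if spec.level == "trial":
        frame = table.frame
        trial_label = frame.groupby("trial_id", sort=True)["class_label"].first()
        for c in classes:
            class_trials = trial_label.index.to_numpy()[trial_label.to_numpy() == c]
            if len(class_trials) % 2:
                raise ValueError(
                    f"trial-level randomization needs an even trial count per class; "
                    f"class {c} has {len(class_trials)}"
                )
            flip = rng.choice(class_trials, size=len(class_trials) // 2, replace=False)
            mask = frame["trial_id"].isin(set(flip)).to_numpy()
            labels[mask] = other[c]
    else:  # sample level
        for c in classes:
            idx = np.flatnonzero(table.y == c)
            if len(idx) % 2:
                raise ValueError(
                    f"sample-level randomization needs an even sample count per class; "
                    f"class {c} has {len(idx)}"
                )
            flip = rng.choice(idx, size=len(idx) // 2, replace=False)
            labels[flip] = other[c]
    return table.with_labels(labels)


def evaluate_folds(
    table: FeatureTable,
    folds: Sequence[np.ndarray],
    sel_m: int,
    clf: ClassifierSpec,
    norm_mode: str = "train_fitted",
) -> list[float]:
    """Score every fold of one partition; returns accuracies in [0, 1].

    Per fold: z-score with ``norm_mode``, run mRMR on the (normalized)
    training rows only, restrict both sides to the selected columns, fit
    and score.  The test rows are never read before scoring.
    """
    all_ids = set(table.sample_ids)
    accs = []
    for test_ids in folds:
        train_ids = all_ids - set(test_ids)
        train = table.subset_samples(train_ids)
        test = table.subset_samples(test_ids)
        train_n, test_n = zscore_fit_apply(train, test, norm_mode)
        sel = mrmr_select(train_n, sel_m)
        train_s = train_n.select_features(sel.selected_indices)
        test_s = test_n.select_features(sel.selected_indices)
        accs.append(train_eval(clf, train_s, test_s))
    return accs


@dataclasses.dataclass
class CVResult:
    """Per-run, per-fold accuracies of one cross-validation test.

    Accuracies are stored in percent.  ``mean_accuracy`` is the unweighted
    arithmetic mean over the full runs-by-folds grid (fold sizes are equal
    by construction).
    """

    scheme: CVSchemeSpec
    randomization: LabelRandomization
    accuracies: np.ndarray  # runs x k, percent
    n_test_per_fold: list[int]
    run_seeds: list[dict]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sd(self) -> float:
        return float(np.std(self.accuracies, ddof=1)) if self.accuracies.size > 1 else 0.0

    def to_frame(self) -> pd.DataFrame:
        runs, k = self.accuracies.shape
        return pd.DataFrame(
            {
                "run": np.repeat(np.arange(runs), k),
                "fold": np.tile(np.arange(k), runs),
                "accuracy_pct": self.accuracies.ravel(),
            }
        )

    def to_dict(self) -> dict:
        return {
            "scheme": dataclasses.asdict(self.scheme),
            "randomization": dataclasses.asdict(self.randomization),
            "accuracies_pct": self.accuracies.tolist(),
            "n_test_per_fold": list(self.n_test_per_fold),
            "run_seeds": self.run_seeds,
            "mean_accuracy_pct": self.mean_accuracy,
            "sd_pct": self.sd,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "CVResult":
        return cls(
            scheme=CVSchemeSpec(**d["scheme"]),
            randomization=LabelRandomization(**d["randomization"]),
            accuracies=np.asarray(d["accuracies_pct"], dtype=float),
            n_test_per_fold=list(d["n_test_per_fold"]),
            run_seeds=list(d["run_seeds"]),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CVResult":
        return cls.from_dict(json.loads(Path(path).read_text()))


def run_cv(
    table: FeatureTable,
    scheme: CVSchemeSpec,
    rand: LabelRandomization = LabelRandomization(),
    sel_m: int = 30,
    clf: ClassifierSpec = ClassifierSpec(),
    norm_mode: str = "train_fitted",
) -> CVResult:
    """Execute one full cross-validation test.

    Per run, with sub-seeds derived from the scheme's master seed: labels
    are freshly re-randomized (when a level is set), the table is
    partitioned (sample k-fold or trial block-wise), and every fold is
    scored by :func:`evaluate_folds`.  The (randomization, partition)
    sub-seeds of every run are recorded in the result so any single fold
    can be replayed exactly.
    """
    master = np.random.default_rng(scheme.seed)
    grid = np.empty((scheme.runs, scheme.k))
    run_seeds = []
    n_test = None
    for r in range(scheme.runs):
        rand_seed, part_seed = (int(s) for s in master.integers(2**31, size=2))
        run_seeds.append({"run": r, "rand_seed": rand_seed, "part_seed": part_seed})
        table_r = randomize_labels(table, dataclasses.replace(rand, seed=rand_seed))
        if scheme.mode == "sample_kfold":
            folds = kfold_partition(table_r, scheme.k, scheme.stratified, part_seed)
        else:
            folds = blockwise_partition(table_r, scheme.k, scheme.stratified, part_seed)
        try:
            accs = evaluate_folds(table_r, folds, sel_m, clf, norm_mode)
        except ValueError as err:
            raise ValueError(f"run {r}: {err}") from err
        grid[r] = accs
        if n_test is None:
            n_test = [len(f) for f in folds]
    return CVResult(
        scheme=scheme,
        randomization=rand,
        accuracies=grid * 100.0,
        n_test_per_fold=n_test or [],
        run_seeds=run_seeds,
    )
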