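"""In-fold mRMR feature selection and the classifier contracts.

The selector is the classic discrete minimum-redundancy maximum-relevance
greedy: features are z-scored and discretized into three bins at +/- 0.5 SD,
relevance and redundancy are mutual information between the discretized
columns (and the labels), and features are added one at a time maximizing
``relevance - mean redundancy with the already-selected set`` (the MID,
difference, criterion).  Ties break to the lowest column index, so the
selection is deterministic given the column order.

Three classifier kinds are supported -- LDA, linear-kernel SVM and KNN --
delegated to scikit-learn with fixed default hyperparameters (SVM C = 1,
KNN k = 5, LDA shrinkage 0) or an optional small inner-CV grid.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import GridSearchCV
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .features import FeatureTable

__all__ = ["SelectionResult", "ClassifierSpec", "mrmr_select", "train_eval", "build_estimator"]


@dataclasses.dataclass
class SelectionResult:
    """Ordered greedy selection with the criterion value at each step."""

    selected_indices: list[int]
    scores: list[float]
    m: int

    def __post_init__(self) -> None:
        if len(set(self.selected_indices)) != len(self.selected_indices):
            raise ValueError("selected indices must be unique")


def _discretize(x: np.ndarray) -> np.ndarray:
    """Z-score each column (population SD) and cut at +/- 0.5 SD into 3 bins."""
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    z = (x - mu) / sd
    return np.digitize(z, [-0.5, 0.5])  # 0, 1, 2


def _mutual_information(a: np.ndarray, b: np.ndarray, n_a: int, n_b: int) -> float:
    """MI in nats between two small-alphabet integer codes of equal length."""
    joint = np.bincount(a * n_b + b, minlength=n_a * n_b).reshape(n_a, n_b)
    joint = joint / joint.sum()
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log(joint[nz] / (pa @ pb)[nz])))


def mrmr_select(train: FeatureTable, m: int) -> SelectionResult:
    """Greedy mRMR (MID) selection of ``m`` features from the training fold.

    The first pick is the feature with maximal mutual information with the
    class label; each later pick maximizes relevance minus the mean MI with
    the features already selected.  If ``m`` is at least the number of
    features, all features are returned in relevance order (with a warning
    when ``m`` strictly exceeds it).  Constant features have zero relevance
    and are never preferred over informative ones.
    """
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    y = train.y
    if len(np.unique(y)) < 2:
        raise ValueError("mRMR requires a labeled training set with >= 2 classes")
    x = _discretize(train.X)
    n_features = x.shape[1]
    _, y_codes = np.unique(y, return_inverse=True)
    n_y = int(y_codes.max()) + 1

    relevance = np.array(
        [_mutual_information(y_codes, x[:, j], n_y, 3) for j in range(n_features)]
    )

    if m >= n_features:
        if m > n_features:
            warnings.warn(
                f"m={m} exceeds the {n_features} available features; selecting all",
                stacklevel=2,
            )
        order = np.argsort(-relevance, kind="stable")
        return SelectionResult(
            selected_indices=[int(j) for j in order],
            scores=[float(relevance[j]) for j in order],
            m=m,
        )

    redundancy = np.full((n_features, n_features), np.nan)

    def red(i: int, j: int) -> float:
        if np.isnan(redundancy[i, j]):
            mi = _mutual_information(x[:, i], x[:, j], 3, 3)
            redundancy[i, j] = redundancy[j, i] = mi
        return redundancy[i, j]

    selected = [int(np.argmax(relevance))]
    scores = [float(relevance[selected[0]])]
    remaining = [j for j in range(n_features) if j != selected[0]]
    while len(selected) < m:
        crit = np.array(
            [relevance[j] - np.mean([red(j, s) for s in selected]) for j in remaining]
        )
        best = int(np.argmax(crit))  # ties break to the lowest index
        scores.append(float(crit[best]))
        selected.append(remaining.pop(best))
    return SelectionResult(selected_indices=selected, scores=scores, m=m)


@dataclasses.dataclass(frozen=True)
class ClassifierSpec:
    """Declarative classifier choice with fixed default hyperparameters.

    ``kind`` is one of ``lda`` (shrinkage in [0, 1], default 0), ``svm``
    (linear kernel, cost C, default 1) or ``knn`` (k neighbors, default 5,
    odd to avoid binary voting ties).  ``inner_tuning='small_grid'`` swaps
    the fixed values for a small inner 3-fold grid search.
    """

    kind: str = "lda"
    svm_c: float = 1.0
    knn_k: int = 5
    knn_metric: str = "minkowski"
    lda_shrinkage: float = 0.0
    inner_tuning: str = "off"

    def __post_init__(self) -> None:
        if self.kind not in ("lda", "svm", "knn"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if self.svm_c <= 0:
            raise ValueError("svm_c must be positive")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")
        if not 0.0 <= self.lda_shrinkage <= 1.0:
            raise ValueError("lda_shrinkage must lie in [0, 1]")
        if self.inner_tuning not in ("off", "small_grid"):
            raise ValueError(f"unknown inner_tuning mode {self.inner_tuning!r}")


_SMALL_GRIDS = {
    "svm": {"C": [0.1, 1.0, 10.0]},
    "knn": {"n_neighbors": [3, 5, 7]},
    "lda": {"shrinkage": [0.0, 0.25, 0.5]},
}


def build_estimator(spec: ClassifierSpec):
    """Instantiate the scikit-learn estimator for a spec."""
    if spec.kind == "lda":
        if spec.lda_shrinkage > 0 or spec.inner_tuning == "small_grid":
            est = LinearDiscriminantAnalysis(
                solver="lsqr", shrinkage=spec.lda_shrinkage if spec.inner_tuning == "off" else 0.0
            )
        else:
            est = LinearDiscriminantAnalysis(solver="svd")
    elif spec.kind == "svm":
        est = SVC(kernel="linear", C=spec.svm_c)
    else:
        est = KNeighborsClassifier(n_neighbors=spec.knn_k, metric=spec.knn_metric)
    if spec.inner_tuning == "small_grid":
        est = GridSearchCV(est, _SMALL_GRIDS[spec.kind], cv=3, n_jobs=1)
    return est


def train_eval(spec: ClassifierSpec, train: FeatureTable, test: FeatureTable) -> float:
    """Fit on the training fold and return the test accuracy in [0, 1].

    A single-class training fold is a degenerate split and raises.
    """
    classes = np.unique(train.y)
    if classes.size < 2:
        raise ValueError("degenerate fold: training set contains a single class")
    est = build_estimator(spec)
    est.fit(train.X, train.y)
    return float(np.mean(est.predict(test.X) == test.y))
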