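"""Linear classifiers and cross-validation schemes.

Two classifiers are provided:

* ``paper_lda`` — the mean-difference classifier analysed by the theory
  module: project onto the axis joining the empirical class means and
  threshold at their midpoint.  Implemented from scratch so that it matches
  the analytic model exactly.
* ``linear_svm`` — a soft-margin linear support vector machine (scikit-learn
  ``SVC(kernel="linear")``) with configurable cost.

Two cross-validation schemes:

* ``stratified_kfold_trialwise`` — class-stratified k-fold (2-fold by
  default) assigning *trials* to folds, so members of the same subclass end
  up on both sides of the split.  This is the common practice whose accuracy
  is inflated by nested subclasses.
* ``leave_one_subclass_out`` — one whole subclass per class held out per
  fold, which prevents subclass structure from leaking into the test set.

CCRs (correct classification rates) are pooled over held-out trials, not
averaged over folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .simulate import LabeledDataset

__all__ = [
    "CVScheme",
    "CCRResult",
    "LinearRule",
    "fit_paper_lda",
    "fit_linear_svm",
    "make_folds",
    "cross_validate",
    "CLASSIFIERS",
]

TRIALWISE = "stratified_kfold_trialwise"
LOSO = "leave_one_subclass_out"
_KIND_ALIASES = {
    "2fold": TRIALWISE,
    "trialwise": TRIALWISE,
    TRIALWISE: TRIALWISE,
    "loso": LOSO,
    LOSO: LOSO,
}

CLASSIFIERS = ("paper_lda", "linear_svm")


@dataclass(frozen=True)
class CVScheme:
    """Cross-validation specification.

    ``n_folds`` applies to the trial-wise scheme (default 2, the split-half
    CV recommended for permutation testing); leave-one-subclass-out always
    uses K folds, one per subclass pair.
    """

    kind: str = TRIALWISE
    n_folds: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KIND_ALIASES:
            raise ValueError(f"unknown CV kind {self.kind!r}")
        object.__setattr__(self, "kind", _KIND_ALIASES[self.kind])
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")

    def replace(self, **kwargs) -> "CVScheme":
        return replace(self, **kwargs)


@dataclass
class CCRResult:
    """Outcome of one cross-validated classification."""

    ccr: float
    per_fold_ccr: list[float]
    classifier_id: str
    cv: CVScheme
    n_test_trials: int
    fold_assignment: np.ndarray = field(repr=False, default=None)


@dataclass
class LinearRule:
    """Linear decision rule: label_pos if w.x >= b else label_neg.

    Points exactly on the threshold go to ``label_pos`` (the first class in
    sorted label order); this tie-break is measure-zero for continuous data
    but reachable in constructed tests.
    """

    weights: np.ndarray
    bias: float
    label_pos: object
    label_neg: object

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X @ self.weights - self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        score = self.decision_function(X)
        return np.where(score >= 0, self.label_pos, self.label_neg)


def _check_two_classes(train: LabeledDataset) -> np.ndarray:
    classes = np.unique(train.class_labels)
    if len(classes) != 2:
        raise ValueError("training data must contain exactly two classes")
    return classes


def fit_paper_lda(train: LabeledDataset) -> LinearRule:
    """Mean-difference / midpoint classifier.

    Projects onto w = mean(class 1) - mean(class 2) and thresholds at the
    midpoint theta = (mean_1 + mean_2) / 2, i.e. assigns a point to the
    class whose empirical mean is nearer along the projection axis.  This is
    LDA with an isotropic (identity) covariance model.
    """
    classes = _check_two_classes(train)
    m1 = train.features[train.class_labels == classes[0]].mean(axis=0)
    m2 = train.features[train.class_labels == classes[1]].mean(axis=0)
    w = m1 - m2
    bias = float(w @ (m1 + m2) / 2.0)
    return LinearRule(weights=w, bias=bias, label_pos=classes[0], label_neg=classes[1])


def fit_linear_svm(train: LabeledDataset, cost: float = 1.0):
    """Soft-margin linear SVM with cost parameter ``cost`` (libsvm)."""
    from sklearn.svm import SVC

    if cost <= 0:
        raise ValueError("cost must be positive")
    _check_two_classes(train)
    model = SVC(kernel="linear", C=cost)
    model.fit(train.features, train.class_labels)
    return model


def _fit(classifier_id: str, train: LabeledDataset, cost: float):
    if classifier_id == "paper_lda":
        return fit_paper_lda(train)
    if classifier_id == "linear_svm":
        return fit_linear_svm(train, cost=cost)
    raise ValueError(f"unknown classifier {classifier_id!r}; choose from {CLASSIFIERS}")


def make_folds(data: LabeledDataset, cv: CVScheme) -> np.ndarray:
    """Per-trial fold indices for a CV scheme.

    Trial-wise: trials of each class are shuffled (scheme seed) and dealt
    round-robin into ``n_folds`` folds, so class counts are balanced to
    within one trial per fold.  Subclass membership is deliberately ignored.

    Leave-one-subclass-out: subclasses of the two classes are paired in
    sorted-label order; fold f holds out pair f.  Requires equal subclass
    counts per class.
    """
    if cv.kind == TRIALWISE:
        rng = np.random.default_rng(cv.seed)
        folds = np.empty(data.n_trials, dtype=np.intp)
        for c in data.classes():
            idx = rng.permutation(np.flatnonzero(data.class_labels == c))
            for f in range(cv.n_folds):
                folds[idx[f::cv.n_folds]] = f
        return folds
    # leave-one-subclass-out
    c1, c2 = data.classes()
    subs1 = data.subclasses_of(c1)
    subs2 = data.subclasses_of(c2)
    if len(subs1) != len(subs2):
        raise ValueError(
            "leave-one-subclass-out requires equal subclass counts per class"
        )
    if len(subs1) < 2:
        raise ValueError("leave-one-subclass-out requires at least 2 subclasses")
    fold_of = {}
    for f, (a, b) in enumerate(zip(subs1, subs2)):
        fold_of[a] = f
        fold_of[b] = f
    return np.array([fold_of[s] for s in data.subclass_labels], dtype=np.intp)


def cross_validate(
    data: LabeledDataset,
    classifier_id: str = "paper_lda",
    cv: CVScheme | None = None,
    cost: float = 1.0,
) -> CCRResult:
    """Cross-validated correct classification rate.

    Every trial is tested exactly once; the CCR is the number of correctly
    classified held-out trials divided by the total trial count (pooled over
    folds).  Per-fold CCRs are reported alongside.
    """
    cv = cv or CVScheme()
    folds = make_folds(data, cv)
    n_folds = int(folds.max()) + 1
    correct = 0
    per_fold = []
    for f in range(n_folds):
        test_mask = folds == f
        train = LabeledDataset(
            data.features[~test_mask],
            data.class_labels[~test_mask],
            data.subclass_labels[~test_mask],
        )
        model = _fit(classifier_id, train, cost)
        pred = model.predict(data.features[test_mask])
        hits = int((pred == data.class_labels[test_mask]).sum())
        correct += hits
        per_fold.append(hits / int(test_mask.sum()))
    return CCRResult(
        ccr=correct / data.n_trials,
        per_fold_ccr=per_fold,
        classifier_id=classifier_id,
        cv=cv,
        n_test_trials=data.n_trials,
        fold_assignment=folds,
    )
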