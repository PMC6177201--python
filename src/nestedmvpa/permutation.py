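"""Permutation null distributions for cross-validated accuracy.

Two relabeling schemes:

* ``trial_wise`` — class labels are shuffled over individual trials.  This
  destroys class structure *and* subclass structure, so the null is centred
  at chance (50%) even when the data contain subclasses — which makes it
  anti-conservative for such data.
* ``subclass_wise_balanced`` — whole subclasses are reassigned to two new
  classes, each receiving exactly K/2 subclasses from each original class.
  Within-subclass dependence is preserved while class information is
  removed, so the null inherits the subclass-induced accuracy inflation and
  the test stays calibrated.

For K subclasses per class there are C(K, K/2)^2 / 2 distinct balanced
assignments (the factor 1/2 removes class-label-swap duplicates).  Small
designs are enumerated exhaustively; large ones are sampled uniformly
without replacement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .classify import CVScheme, cross_validate
from .simulate import LabeledDataset

__all__ = [
    "NullDistribution",
    "BalancedAssignment",
    "count_balanced_assignments",
    "enumerate_balanced_assignments",
    "sample_balanced_assignments",
    "block_permutation_null",
    "trial_permutation_null",
    "p_value",
    "group_null",
]

TRIAL_WISE = "trial_wise"
BLOCK_WISE = "subclass_wise_balanced"

#: Largest balanced-assignment count that will be enumerated rather than
#: sampled (K=16 gives ~82.8e6; K=12 gives 427'350 — still enumerable).
ENUMERATION_CAP = 2_000_000


@dataclass
class NullDistribution:
    """A set of CCRs obtained under a relabeling scheme."""

    ccrs: np.ndarray
    scheme: str
    n_draws: int
    exhaustive: bool
    seed: int | None = None

    def __post_init__(self) -> None:
        self.ccrs = np.asarray(self.ccrs, dtype=float)
        if self.ccrs.size == 0:
            raise ValueError("null distribution must be non-empty")
        if self.ccrs.min() < 0 or self.ccrs.max() > 1:
            raise ValueError("CCRs must lie in [0, 1]")
        if self.n_draws != self.ccrs.size:
            raise ValueError("n_draws must equal the number of stored CCRs")


@dataclass(frozen=True)
class BalancedAssignment:
    """One balanced reassignment of the 2K subclasses into two new classes.

    Each new class holds exactly K/2 subclasses from each original class.
    Canonical form: ``class1_subclasses`` contains the designated reference
    subclass (the first subclass of original class A), which removes the
    label-swap duplicate constructively.
    """

    class1_subclasses: frozenset
    class2_subclasses: frozenset

    def labels_for(self, subclass_labels: np.ndarray) -> np.ndarray:
        """New class labels (1/2) for a vector of subclass ids."""
        in_c1 = np.isin(subclass_labels, list(self.class1_subclasses))
        return np.where(in_c1, 1, 2)


def _require_even(K: int) -> None:
    if K < 2 or K % 2 != 0:
        raise ValueError(
            f"balanced assignment undefined for K={K}: need an even number "
            "of subclasses per class (each new class takes K/2 from each)"
        )


def count_balanced_assignments(K: int) -> int:
    """Number of distinct balanced assignments: C(K, K/2)^2 / 2.

    The square counts ordered choices of K/2 subclasses from each original
    class for new class 1; halving removes the duplicate obtained by
    swapping the two new class labels.
    """
    _require_even(K)
    return math.comb(K, K // 2) ** 2 // 2


def enumerate_balanced_assignments(
    K: int,
    class_a: Sequence | None = None,
    class_b: Sequence | None = None,
) -> Iterator[BalancedAssignment]:
    """Yield every distinct balanced assignment exactly once.

    ``class_a``/``class_b`` give the subclass identifiers of the two
    original classes (defaults: 0..K-1 and K..2K-1).  Label-swap duplicates
    are removed by requiring new class 1 to contain ``class_a[0]``.
    """
    from itertools import combinations

    _require_even(K)
    total = count_balanced_assignments(K)
    if total > ENUMERATION_CAP:
        raise ValueError(
            f"{total} balanced assignments exceed the enumeration cap "
            f"({ENUMERATION_CAP}); use sample_balanced_assignments instead"
        )
    class_a = list(class_a) if class_a is not None else list(range(K))
    class_b = list(class_b) if class_b is not None else list(range(K, 2 * K))
    if len(class_a) != K or len(class_b) != K:
        raise ValueError("class_a and class_b must each contain K subclass ids")
    ref, rest_a = class_a[0], class_a[1:]
    half = K // 2
    all_subs = frozenset(class_a) | frozenset(class_b)
    for a_part in combinations(rest_a, half - 1):
        for b_part in combinations(class_b, half):
            c1 = frozenset((ref, *a_part, *b_part))
            yield BalancedAssignment(c1, all_subs - c1)


def sample_balanced_assignments(
    K: int,
    n: int,
    rng: np.random.Generator,
    class_a: Sequence | None = None,
    class_b: Sequence | None = None,
) -> list[BalancedAssignment]:
    """Draw ``n`` distinct balanced assignments uniformly without replacement."""
    _require_even(K)
    total = count_balanced_assignments(K)
    if n > total:
        raise ValueError(f"cannot draw {n} distinct assignments from {total}")
    class_a = list(class_a) if class_a is not None else list(range(K))
    class_b = list(class_b) if class_b is not None else list(range(K, 2 * K))
    ref = class_a[0]
    half = K // 2
    all_subs = frozenset(class_a) | frozenset(class_b)
    seen: set[frozenset] = set()
    out: list[BalancedAssignment] = []
    arr_a = np.array(class_a, dtype=object)
    arr_b = np.array(class_b, dtype=object)
    while len(out) < n:
        pick_a = arr_a[rng.choice(K, size=half, replace=False)]
        pick_b = arr_b[rng.choice(K, size=half, replace=False)]
        c1 = frozenset(pick_a) | frozenset(pick_b)
        if ref not in c1:  # canonicalize under label swap
            c1 = all_subs - c1
        if c1 in seen:
            continue
        seen.add(c1)
        out.append(BalancedAssignment(c1, all_subs - c1))
    return out


def _subclasses_by_class(data: LabeledDataset):
    c1, c2 = data.classes()
    subs_a = data.subclasses_of(c1)
    subs_b = data.subclasses_of(c2)
    if len(subs_a) != len(subs_b):
        raise ValueError(
            "block permutation is only valid for an equal number of "
            f"subclasses per class (got {len(subs_a)} vs {len(subs_b)})"
        )
    return subs_a, subs_b


def block_permutation_null(
    data: LabeledDataset,
    classifier_id: str = "paper_lda",
    cv: CVScheme | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    cost: float = 1.0,
) -> NullDistribution:
    """Null distribution from balanced subclass-wise relabelings.

    If the number of distinct balanced assignments is at most ``n_perm`` the
    enumeration is used exhaustively; otherwise ``n_perm`` assignments are
    sampled uniformly without replacement.  Each draw re-runs the full
    cross-validation with a fresh fold split seeded from ``seed``, so fold
    artefacts do not correlate across draws.  Subclass membership is never
    broken: after relabeling every subclass still belongs to one class.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    cv = cv or CVScheme()
    subs_a, subs_b = _subclasses_by_class(data)
    K = len(subs_a)
    _require_even(K)
    total = count_balanced_assignments(K)
    rng = np.random.default_rng(seed)
    if total <= n_perm:
        assignments = list(enumerate_balanced_assignments(K, subs_a, subs_b))
        exhaustive = True
    else:
        assignments = sample_balanced_assignments(K, n_perm, rng, subs_a, subs_b)
        exhaustive = False
    ccrs = np.empty(len(assignments))
    for i, assignment in enumerate(assignments):
        permuted = data.relabeled(assignment.labels_for(data.subclass_labels))
        fold_seed = int(rng.integers(2**31))
        result = cross_validate(
            permuted, classifier_id, cv.replace(seed=fold_seed), cost=cost
        )
        ccrs[i] = result.ccr
    return NullDistribution(ccrs, BLOCK_WISE, len(assignments), exhaustive, seed)


def trial_permutation_null(
    data: LabeledDataset,
    classifier_id: str = "paper_lda",
    cv: CVScheme | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    cost: float = 1.0,
) -> NullDistribution:
    """Null distribution from trial-wise label shuffles.

    Class labels are permuted over all trials (class sizes preserved).
    Because shuffled labels cut across subclasses, the permuted data are
    treated as subclass-free (every trial its own block) — exactly the
    independence assumption this scheme encodes.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    cv = cv or CVScheme()
    rng = np.random.default_rng(seed)
    singleton_subs = np.arange(data.n_trials)
    ccrs = np.empty(n_perm)
    for i in range(n_perm):
        labels = rng.permutation(data.class_labels)
        permuted = LabeledDataset(data.features, labels, singleton_subs)
        fold_seed = int(rng.integers(2**31))
        result = cross_validate(
            permuted, classifier_id, cv.replace(seed=fold_seed), cost=cost
        )
        ccrs[i] = result.ccr
    return NullDistribution(ccrs, TRIAL_WISE, n_perm, False, seed)


def p_value(observed: float, null: NullDistribution) -> float:
    """Permutation p-value for an observed CCR against a null.

    Sampled nulls use the add-one estimator (1 + #{null >= observed}) /
    (1 + n), which can never return zero.  Exhaustive nulls count the
    observed arrangement as one outcome: max(#{null >= observed}, 1) / n.
    """
    ge = int((null.ccrs >= observed).sum())
    if null.exhaustive:
        return max(ge, 1) / null.n_draws
    return (1 + ge) / (1 + null.n_draws)


def group_null(
    per_subject_nulls: Sequence[NullDistribution],
    observed_ccrs: Sequence[float],
    n_resample: int = 10_000,
    seed: int = 0,
) -> tuple[float, NullDistribution]:
    """Group-level test of the mean CCR across subjects.

    The group statistic is the mean of the subjects' observed CCRs; the
    group null is built by repeatedly averaging one CCR drawn uniformly from
    each subject's null distribution.  Returns (p-value, group null).
    Useful when single subjects have too few subclasses for fine-grained
    per-subject p-values.
    """
    if len(per_subject_nulls) == 0 or len(observed_ccrs) == 0:
        raise ValueError("need at least one subject")
    if len(per_subject_nulls) != len(observed_ccrs):
        raise ValueError("one observed CCR per subject null is required")
    if n_resample < 1:
        raise ValueError("n_resample must be >= 1")
    rng = np.random.default_rng(seed)
    draws = np.empty((n_resample, len(per_subject_nulls)))
    for j, null in enumerate(per_subject_nulls):
        idx = rng.integers(null.n_draws, size=n_resample)
        draws[:, j] = null.ccrs[idx]
    means = draws.mean(axis=1)
    group = NullDistribution(means, "group_mean", n_resample, False, seed)
    observed_mean = float(np.mean(observed_ccrs))
    return p_value(observed_mean, group), group
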