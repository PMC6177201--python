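"""Multilevel Gaussian simulator for two-class data with nested subclasses.

Trials follow the variance-components model

    y_ijk = C_i + S_ij + eps_ijk,

where ``C_i`` is the centroid of class ``i`` (i = 1, 2), ``S_ij`` the offset
of the j-th subclass nested in class ``i``, and ``eps_ijk`` per-trial noise.
All three effects are isotropic Gaussians in ``d`` dimensions with standard
deviations ``sigma_C``, ``sigma_S`` and ``sigma_W``.  Subclasses are *nested*:
every subclass belongs to exactly one class, so subclass identity carries
class-unrelated structure that a classifier can exploit.  The intraclass
correlation ICC = sigma_S^2 / (sigma_S^2 + sigma_W^2) quantifies how much of
the non-class variance is subclass-borne.

The generator is the single source of synthetic data for the whole package:
classifier calibration, permutation nulls and the analytic expected-accuracy
theory are all exercised against datasets produced here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimParams",
    "LabeledDataset",
    "generate_dataset",
    "generate_dataset_two_level",
    "icc",
    "collapse_levels",
    "estimate_icc",
    "estimate_variance_components",
    "toy_subclass_dataset",
]

CLASS_LABELS = (1, 2)


@dataclass(frozen=True)
class SimParams:
    """Generative parameters of the multilevel Gaussian model.

    Parameters
    ----------
    d : int
        Feature-space dimensionality.
    K : int
        Number of subclasses nested in each class.
    N : int
        Trials per subclass; each class contributes ``K * N`` trials.
    sigma_C : float
        Standard deviation of the class centroids (per dimension).
    sigma_S : float
        Standard deviation of subclass centroids around their class centroid.
    sigma_W : float
        Within-subclass (trial noise) standard deviation.
    seed : int
        Seed of the dataset's private RNG; identical parameters give
        bit-identical datasets.
    """

    d: int
    K: int
    N: int
    sigma_C: float
    sigma_S: float
    sigma_W: float
    seed: int = 0
    n_classes: int = 2

    def __post_init__(self) -> None:
        if self.d < 1 or self.K < 1 or self.N < 1:
            raise ValueError("d, K and N must all be >= 1")
        for name in ("sigma_C", "sigma_S", "sigma_W"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_classes != 2:
            raise ValueError("only two-class designs are supported")

    @property
    def trials_per_class(self) -> int:
        return self.K * self.N

    def to_dict(self) -> dict:
        return {
            "d": self.d,
            "K": self.K,
            "N": self.N,
            "sigma_C": self.sigma_C,
            "sigma_S": self.sigma_S,
            "sigma_W": self.sigma_W,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, mapping: Mapping) -> "SimParams":
        known = {"d", "K", "N", "sigma_C", "sigma_S", "sigma_W", "seed"}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown simulate keys: {sorted(unknown)}")
        return cls(**{k: mapping[k] for k in mapping})

    def replace(self, **kwargs) -> "SimParams":
        return replace(self, **kwargs)


@dataclass
class LabeledDataset:
    """Trials-by-features matrix with parallel class and subclass labels.

    ``subclass_labels`` are globally unique: a subclass identifier never
    occurs in more than one class (the nesting invariant, validated on
    construction and on load).
    """

    features: np.ndarray
    class_labels: np.ndarray
    subclass_labels: np.ndarray
    provenance: SimParams | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.class_labels = np.asarray(self.class_labels)
        self.subclass_labels = np.asarray(self.subclass_labels)
        self.validate()

    # -- invariants ------------------------------------------------------

    def validate(self) -> None:
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D trials x features matrix")
        n = self.features.shape[0]
        if len(self.class_labels) != n or len(self.subclass_labels) != n:
            raise ValueError("label vectors must match the feature row count")
        classes = np.unique(self.class_labels)
        if len(classes) != 2:
            raise ValueError(f"expected exactly 2 classes, found {len(classes)}")
        # nesting: each subclass maps to exactly one class
        for sc in np.unique(self.subclass_labels):
            owners = np.unique(self.class_labels[self.subclass_labels == sc])
            if len(owners) != 1:
                raise ValueError(
                    f"subclass {sc!r} spans classes {owners.tolist()}: "
                    "subclasses must be nested within a single class"
                )

    # -- convenience -----------------------------------------------------

    @property
    def n_trials(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def classes(self) -> np.ndarray:
        return np.unique(self.class_labels)

    def subclasses_of(self, class_label) -> np.ndarray:
        return np.unique(self.subclass_labels[self.class_labels == class_label])

    def relabeled(self, class_labels: np.ndarray) -> "LabeledDataset":
        """Same features/subclasses under a new class labeling."""
        return LabeledDataset(
            self.features, np.asarray(class_labels), self.subclass_labels
        )

    # -- IO --------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        cols = {f"f{j + 1}": self.features[:, j] for j in range(self.n_features)}
        return pd.DataFrame(
            {
                "trial_id": np.arange(self.n_trials),
                "class": self.class_labels,
                "subclass": self.subclass_labels,
                **cols,
            }
        )

    def to_csv(self, path: str | Path, sep: str = ",") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "LabeledDataset":
        required = {"trial_id", "class", "subclass"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"missing required columns: {sorted(missing)}")
        feat_cols = [c for c in frame.columns if c.startswith("f") and c[1:].isdigit()]
        if not feat_cols:
            raise ValueError("no feature columns f1..fd found")
        feat_cols.sort(key=lambda c: int(c[1:]))
        return cls(
            frame[feat_cols].to_numpy(dtype=float),
            frame["class"].to_numpy(),
            frame["subclass"].to_numpy(),
        )

    @classmethod
    def from_csv(cls, path: str | Path, sep: str | None = None) -> "LabeledDataset":
        frame = pd.read_csv(path, sep=sep, engine="python")
        return cls.from_frame(frame)


def generate_dataset(params: SimParams) -> LabeledDataset:
    """Draw one dataset from the multilevel model.

    Draw order is fixed so seeds are portable across versions: class
    centroids (class 1 then 2), then all subclass centroids (class 1's K
    subclasses, then class 2's), then trial noise in trial order.  Trials are
    ordered class 1 subclass 1..K, then class 2; subclass labels are
    ``1..K`` for class 1 and ``K+1..2K`` for class 2.
    """
    rng = np.random.default_rng(params.seed)
    d, K, N = params.d, params.K, params.N
    centroids = rng.normal(0.0, params.sigma_C, size=(2, d))
    sub_centroids = rng.normal(0.0, params.sigma_S, size=(2, K, d))
    noise = rng.normal(0.0, params.sigma_W, size=(2, K, N, d))

    means = centroids[:, None, None, :] + sub_centroids[:, :, None, :]
    features = (means + noise).reshape(2 * K * N, d)
    class_labels = np.repeat([1, 2], K * N)
    subclass_labels = np.repeat(np.arange(1, 2 * K + 1), N)
    return LabeledDataset(features, class_labels, subclass_labels, provenance=params)


def generate_dataset_two_level(
    params: SimParams, sigma_S_inner: float, K_inner: int
) -> LabeledDataset:
    """Dataset with two nested subclass levels, flattened to one level.

    Each class has ``params.K`` outer subclasses (spread ``params.sigma_S``),
    each containing ``K_inner`` inner subclasses (spread ``sigma_S_inner``)
    of ``params.N`` trials.  The returned subclass labels identify the inner
    subclasses, i.e. the model y = C_i + S_ij + S_ijk + eps collapsed to
    y = C_i + S_ij' + eps with Var(S_ij') = sigma_S^2 + sigma_S_inner^2
    (see :func:`collapse_levels`).
    """
    if sigma_S_inner < 0:
        raise ValueError("sigma_S_inner must be non-negative")
    if K_inner < 1:
        raise ValueError("K_inner must be >= 1")
    rng = np.random.default_rng(params.seed)
    d, K, N = params.d, params.K, params.N
    centroids = rng.normal(0.0, params.sigma_C, size=(2, d))
    outer = rng.normal(0.0, params.sigma_S, size=(2, K, d))
    inner = rng.normal(0.0, sigma_S_inner, size=(2, K, K_inner, d))
    noise = rng.normal(0.0, params.sigma_W, size=(2, K, K_inner, N, d))

    means = (
        centroids[:, None, None, None, :]
        + outer[:, :, None, None, :]
        + inner[:, :, :, None, :]
    )
    features = (means + noise).reshape(2 * K * K_inner * N, d)
    n_sub = K * K_inner
    class_labels = np.repeat([1, 2], n_sub * N)
    subclass_labels = np.repeat(np.arange(1, 2 * n_sub + 1), N)
    return LabeledDataset(features, class_labels, subclass_labels)


def icc(sigma_S: float, sigma_W: float) -> float:
    """Intraclass correlation sigma_S^2 / (sigma_S^2 + sigma_W^2)."""
    if sigma_S < 0 or sigma_W < 0:
        raise ValueError("standard deviations must be non-negative")
    if sigma_S == 0 and sigma_W == 0:
        raise ValueError("ICC is undefined when both variance components are zero")
    s2 = sigma_S**2
    return s2 / (s2 + sigma_W**2)


def collapse_levels(sigma_level1: float, sigma_level2: float) -> float:
    """Collapse two nested subclass levels into one standard deviation.

    Because Gaussians add in variance, a design with two nested subclass
    levels is distributionally equivalent to a single level with
    sigma' = sqrt(sigma_level1^2 + sigma_level2^2).
    """
    if sigma_level1 < 0 or sigma_level2 < 0:
        raise ValueError("standard deviations must be non-negative")
    return float(np.hypot(sigma_level1, sigma_level2))


def _anova_components(data: LabeledDataset):
    """Per-class, per-dimension one-way random-effects mean squares.

    Returns pooled (sigma_W^2, sigma_S^2) estimates via the method of
    moments: sigma_W^2 = MSW, sigma_S^2 = (MSB - MSW) / n0 with n0 the
    (balanced-design) subclass size correction.
    """
    msw_parts = []
    msb_parts = []
    n0s = []
    for c in data.classes():
        mask = data.class_labels == c
        X = data.features[mask]
        subs = data.subclass_labels[mask]
        uniq, inv = np.unique(subs, return_inverse=True)
        J = len(uniq)
        if J < 2:
            raise ValueError("need at least 2 subclasses per class")
        counts = np.bincount(inv)
        if counts.min() < 2:
            raise ValueError("need at least 2 trials per subclass")
        n_tot = X.shape[0]
        # subclass means, per dimension
        sums = np.zeros((J, X.shape[1]))
        np.add.at(sums, inv, X)
        means = sums / counts[:, None]
        grand = X.mean(axis=0)
        ssw = ((X - means[inv]) ** 2).sum(axis=0)
        ssb = (counts[:, None] * (means - grand) ** 2).sum(axis=0)
        msw_parts.append(ssw / (n_tot - J))
        msb_parts.append(ssb / (J - 1))
        n0s.append((n_tot - (counts**2).sum() / n_tot) / (J - 1))
    msw = np.mean(np.concatenate(msw_parts))
    msb = np.mean(np.concatenate(msb_parts))
    n0 = float(np.mean(n0s))
    sigma_w2 = float(msw)
    sigma_s2 = max(float((msb - msw) / n0), 0.0)
    return sigma_w2, sigma_s2


def estimate_icc(data: LabeledDataset) -> float:
    """Moment estimate of the ICC from one dataset.

    One-way random-effects decomposition (between- vs within-subclass mean
    squares) per class and dimension, pooled, then mapped to
    sigma_S^2 / (sigma_S^2 + sigma_W^2) and clipped to [0, 1].
    """
    sigma_w2, sigma_s2 = _anova_components(data)
    if sigma_w2 == 0 and sigma_s2 == 0:
        raise ValueError("ICC is undefined: no variance in the data")
    return float(np.clip(sigma_s2 / (sigma_s2 + sigma_w2), 0.0, 1.0))


def estimate_variance_components(datasets: Iterable[LabeledDataset]) -> dict:
    """Pooled moment estimates of sigma_C^2, sigma_S^2, sigma_W^2.

    Within-dataset ANOVA supplies the subclass and trial components; the
    class component uses E[(xbar_1 - xbar_2)^2]/2 = sigma_C^2 + sigma_S^2/K
    + sigma_W^2/(K N) per dimension, pooled over datasets.  Intended for
    generator validation over many replicate datasets.
    """
    w2s, s2s, c2s = [], [], []
    for data in datasets:
        sigma_w2, sigma_s2 = _anova_components(data)
        w2s.append(sigma_w2)
        s2s.append(sigma_s2)
        c1, c2 = data.classes()
        m1 = data.features[data.class_labels == c1].mean(axis=0)
        m2 = data.features[data.class_labels == c2].mean(axis=0)
        K = len(data.subclasses_of(c1))
        n_per_class = int((data.class_labels == c1).sum())
        half_sq = ((m1 - m2) ** 2).mean() / 2.0
        c2s.append(half_sq - sigma_s2 / K - sigma_w2 / n_per_class)
    if not w2s:
        raise ValueError("need at least one dataset")
    return {
        "sigma2_C": max(float(np.mean(c2s)), 0.0),
        "sigma2_S": float(np.mean(s2s)),
        "sigma2_W": float(np.mean(w2s)),
    }


def toy_subclass_dataset(
    seed: int = 7, K: int = 4, N: int = 25, sigma_S: float = 1.0, sigma_W: float = 0.25
) -> LabeledDataset:
    """Small 2-D demo dataset: identical class centroids, visible subclasses.

    Two classes with ``K`` well-separated subclasses each and no class
    effect (sigma_C = 0).  Useful for demos and machinery tests; any
    above-chance cross-validated accuracy on it is pure subclass bias.
    """
    params = SimParams(
        d=2, K=K, N=N, sigma_C=0.0, sigma_S=sigma_S, sigma_W=sigma_W, seed=seed
    )
    return generate_dataset(params)
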