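"""Simulation experiments: accuracy surfaces, theory validation, bias maps.

Three orchestrated studies, all over the multilevel generator:

* :func:`run_ccr_surface` — mean cross-validated CCR over a grid of class
  (sigma_C) and subclass (sigma_S) effect sizes, at fixed K and d.
* :func:`run_theory_validation` — closed-form expected CCR vs Monte-Carlo
  simulation over an ICC grid for several subclass counts.
* :func:`run_significance_bias` — proportion of significant permutation
  tests per (sigma_C, sigma_S) cell and the significance bias
  SB = P(sigma_S) - P(sigma_S = 0), for trial-wise and block-wise schemes.

Defaults are desk-scale (hundreds of repetitions per cell); the full-scale
protocols (thousands of repetitions) are reached by raising ``n_reps`` /
``n_perm`` in the spec or config file.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import CVScheme, cross_validate
from .permutation import (
    BLOCK_WISE,
    TRIAL_WISE,
    block_permutation_null,
    trial_permutation_null,
    p_value,
)
from .simulate import SimParams, generate_dataset
from .theory import corollary_ccr, mc_ccr_oracle

__all__ = [
    "SweepSpec",
    "SBResult",
    "run_ccr_surface",
    "run_theory_validation",
    "run_significance_bias",
    "write_manifest",
]

log = logging.getLogger("nestedmvpa")

DEFAULT_GRID = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6)


@dataclass(frozen=True)
class SweepSpec:
    """Parameters of a simulation sweep.

    ``trials_per_class`` must be divisible by ``K``; the per-subclass trial
    count N = trials_per_class / K.  ``n_reps`` datasets are generated per
    grid cell.
    """

    sigma_C_grid: tuple = DEFAULT_GRID
    sigma_S_grid: tuple = DEFAULT_GRID
    d: int = 100
    K: int = 10
    trials_per_class: int = 120
    sigma_W: float = 1.0
    n_reps: int = 500
    alpha: float = 0.05
    classifier_id: str = "linear_svm"
    cost: float = 1.0
    cv_kind: str = "stratified_kfold_trialwise"
    n_folds: int = 2
    n_perm: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.sigma_C_grid) or any(
            v < 0 for v in self.sigma_S_grid
        ):
            raise ValueError("grid values must be non-negative")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.trials_per_class % self.K != 0:
            raise ValueError("trials_per_class must be divisible by K")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @property
    def N(self) -> int:
        return self.trials_per_class // self.K

    def base_params(self, sigma_C: float, sigma_S: float, seed: int) -> SimParams:
        return SimParams(
            d=self.d,
            K=self.K,
            N=self.N,
            sigma_C=sigma_C,
            sigma_S=sigma_S,
            sigma_W=self.sigma_W,
            seed=seed,
        )

    @classmethod
    def from_config(cls, cfg: dict) -> "SweepSpec":
        """Build from a config mapping with sections simulate/classify/permute/sweep."""
        kwargs: dict = {}
        sim = cfg.get("simulate", {})
        for key in ("d", "K", "trials_per_class", "sigma_W"):
            if key in sim:
                kwargs[key] = sim[key]
        clf = cfg.get("classify", {})
        if "classifier" in clf:
            kwargs["classifier_id"] = _classifier_name(clf["classifier"])
        for src, dst in (("cost", "cost"), ("cv", "cv_kind"), ("n_folds", "n_folds")):
            if src in clf:
                kwargs[dst] = clf[src]
        perm = cfg.get("permute", {})
        if "n_perm" in perm:
            kwargs["n_perm"] = perm["n_perm"]
        sweep = cfg.get("sweep", {})
        for key in ("sigma_C_grid", "sigma_S_grid"):
            if key in sweep:
                kwargs[key] = tuple(sweep[key])
        for key in ("n_reps", "alpha", "seed"):
            if key in sweep:
                kwargs[key] = sweep[key]
        return cls(**kwargs)


def _classifier_name(name: str) -> str:
    aliases = {"lda": "paper_lda", "svm": "linear_svm"}
    return aliases.get(name, name)


@dataclass
class SBResult:
    """Significance-bias map for one permutation scheme.

    ``table`` has one row per (sigma_C, sigma_S) cell with the proportion of
    significant datasets ``prop_significant`` and the significance bias
    ``sb`` relative to the matched sigma_S = 0 cell.  SB > 0 means the
    scheme declares significance more often than it would on subclass-free
    data with the same class effect (liberal); SB < 0 means conservative.
    """

    table: pd.DataFrame
    scheme: str
    alpha: float
    null_mode: str


def _cell_ccrs(spec: SweepSpec, sigma_C: float, sigma_S: float, rng) -> np.ndarray:
    ccrs = np.empty(spec.n_reps)
    for i in range(spec.n_reps):
        params = spec.base_params(sigma_C, sigma_S, int(rng.integers(2**31)))
        data = generate_dataset(params)
        cv = CVScheme(spec.cv_kind, spec.n_folds, seed=int(rng.integers(2**31)))
        ccrs[i] = cross_validate(data, spec.classifier_id, cv, cost=spec.cost).ccr
    return ccrs


def run_ccr_surface(spec: SweepSpec) -> pd.DataFrame:
    """Mean and SD of the cross-validated CCR per (sigma_C, sigma_S) cell.

    Reproducible bit-for-bit for a given (spec, seed): every dataset and
    fold split draws its seed from one master RNG in grid order.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for sc in spec.sigma_C_grid:
        for ss in spec.sigma_S_grid:
            ccrs = _cell_ccrs(spec, sc, ss, rng)
            rows.append(
                {
                    "sigma_C": sc,
                    "sigma_S": ss,
                    "mean_ccr": ccrs.mean(),
                    "sd_ccr": ccrs.std(ddof=1),
                    "n_reps": spec.n_reps,
                }
            )
            log.info(
                "surface cell sigma_C=%.2f sigma_S=%.2f mean CCR=%.3f", sc, ss, ccrs.mean()
            )
    return pd.DataFrame(rows)


def run_theory_validation(
    total_subclasses: Sequence[int] = (4, 8, 16),
    icc_grid: Sequence[float] = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7),
    n_reps: int = 2000,
    seed: int = 0,
    N: int = 100,
    d: int = 1,
) -> pd.DataFrame:
    """Closed-form vs Monte-Carlo expected CCR at zero class effect.

    ``total_subclasses`` counts subclasses over both classes (K per class is
    half).  Per cell: closed form, MC mean, MC standard error, |difference|.
    """
    from .theory import TheoryParams

    rng = np.random.default_rng(seed)
    rows = []
    for total in total_subclasses:
        if total % 2 != 0:
            raise ValueError("total subclass counts must be even (K per class)")
        K = total // 2
        for icc_val in icc_grid:
            closed = corollary_ccr(K, icc_val)
            mc_mean, mc_se = mc_ccr_oracle(
                TheoryParams(K=K, icc=icc_val),
                N=N,
                d=d,
                n_reps=n_reps,
                seed=int(rng.integers(2**31)),
            )
            rows.append(
                {
                    "total_subclasses": total,
                    "K": K,
                    "icc": icc_val,
                    "ccr_closed_form": closed,
                    "mc_mean": mc_mean,
                    "mc_stderr": mc_se,
                    "abs_diff": abs(closed - mc_mean),
                }
            )
            log.info(
                "theory cell K=%d icc=%.2f closed=%.4f mc=%.4f", K, icc_val, closed, mc_mean
            )
    return pd.DataFrame(rows)


def run_significance_bias(
    spec: SweepSpec,
    scheme: str = BLOCK_WISE,
    null_mode: str = "per_dataset",
) -> SBResult:
    """Proportion of significant results and significance bias per cell.

    ``null_mode="per_dataset"`` (default) runs the actual permutation test
    on every simulated dataset (``spec.n_perm`` draws each) — the procedure
    usable on real data.  ``null_mode="population"`` instead pools the CCRs
    of ``spec.n_reps`` independent null datasets into one reference null per
    sigma_S (sigma_C = 0; additionally sigma_S = 0 for the trial-wise
    scheme, which assumes no subclass structure), mirroring large-scale
    simulation studies of the schemes.
    """
    if scheme not in (TRIAL_WISE, BLOCK_WISE):
        raise ValueError(f"unknown scheme {scheme!r}")
    if null_mode not in ("per_dataset", "population"):
        raise ValueError(f"unknown null_mode {null_mode!r}")
    if 0.0 not in spec.sigma_S_grid:
        raise ValueError("sigma_S grid must contain 0 to define the bias baseline")
    rng = np.random.default_rng(spec.seed)

    pop_nulls: dict[float, np.ndarray] = {}
    if null_mode == "population":
        if scheme == TRIAL_WISE:
            null_ccrs = _cell_ccrs(spec, 0.0, 0.0, rng)
            pop_nulls = {ss: null_ccrs for ss in spec.sigma_S_grid}
        else:
            pop_nulls = {
                ss: _cell_ccrs(spec, 0.0, ss, rng) for ss in spec.sigma_S_grid
            }

    rows = []
    for sc in spec.sigma_C_grid:
        for ss in spec.sigma_S_grid:
            significant = 0
            for _ in range(spec.n_reps):
                params = spec.base_params(sc, ss, int(rng.integers(2**31)))
                data = generate_dataset(params)
                cv = CVScheme(spec.cv_kind, spec.n_folds, seed=int(rng.integers(2**31)))
                ccr = cross_validate(data, spec.classifier_id, cv, cost=spec.cost).ccr
                if null_mode == "population":
                    null = pop_nulls[ss]
                    p = (1 + int((null >= ccr).sum())) / (1 + len(null))
                else:
                    perm_seed = int(rng.integers(2**31))
                    if scheme == TRIAL_WISE:
                        null_dist = trial_permutation_null(
                            data, spec.classifier_id, cv, spec.n_perm, perm_seed,
                            cost=spec.cost,
                        )
                    else:
                        null_dist = block_permutation_null(
                            data, spec.classifier_id, cv, spec.n_perm, perm_seed,
                            cost=spec.cost,
                        )
                    p = p_value(ccr, null_dist)
                significant += p <= spec.alpha
            rows.append(
                {
                    "sigma_C": sc,
                    "sigma_S": ss,
                    "prop_significant": significant / spec.n_reps,
                    "n_reps": spec.n_reps,
                }
            )
            log.info(
                "SB cell scheme=%s sigma_C=%.2f sigma_S=%.2f P=%.3f",
                scheme, sc, ss, rows[-1]["prop_significant"],
            )
    table = pd.DataFrame(rows)
    baseline = table[table.sigma_S == 0.0].set_index("sigma_C")["prop_significant"]
    table["sb"] = table.apply(
        lambda r: r["prop_significant"] - baseline.loc[r["sigma_C"]], axis=1
    )
    return SBResult(table=table, scheme=scheme, alpha=spec.alpha, null_mode=null_mode)


def plot_ccr_surface(table: pd.DataFrame, ax=None, value: str = "mean_ccr"):
    """Heatmap of a :func:`run_ccr_surface` table (requires matplotlib).

    Convenience only — the tabular output is the tested surface.
    """
    import matplotlib.pyplot as plt

    pivot = table.pivot(index="sigma_S", columns="sigma_C", values=value)
    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(pivot.to_numpy(), origin="lower", aspect="auto",
                   vmin=0.5, vmax=1.0, cmap="viridis")
    ax.set_xticks(range(len(pivot.columns)), [f"{v:g}" for v in pivot.columns])
    ax.set_yticks(range(len(pivot.index)), [f"{v:g}" for v in pivot.index])
    ax.set_xlabel("sigma_C")
    ax.set_ylabel("sigma_S")
    ax.figure.colorbar(im, ax=ax, label=value)
    return ax


def write_manifest(path: str | Path, spec: SweepSpec, extra: dict | None = None) -> None:
    """JSON run manifest: all sweep parameters, seed and package version."""
    from . import __version__

    manifest = {"spec": asdict(spec), "version": __version__}
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, default=float))
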