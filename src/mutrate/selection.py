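"""Forward model selection by cross-validated deviance loss.

The workflow mirrors genome-scale practice: selection runs on a random
subsample of 1 kb windows (a few percent of the genome); candidate variables
are added one at a time to a base model (sample intercepts + neighbor
context); each candidate is scored by k-fold cross-validated deviance, with
folds assigned at the window level so spatial correlation stays within folds;
the best candidate enters the model and the procedure iterates until the
improvement levels off.  Count tables are rebuilt per candidate, so no table
ever contains more variables than its model needs.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import glm
from .glm import FitError, ModelSpec, Term
from .tabulate import build_count_table

logger = logging.getLogger(__name__)


class SelectionError(ValueError):
    pass


@dataclass
class SelectionData:
    """Inputs to selection: per-site covariates, annotated mutations, samples."""

    sites: pd.DataFrame
    mutations: pd.DataFrame
    samples: pd.DataFrame
    chrom_lengths: dict[str, int]

    @classmethod
    def from_dataset(cls, ds) -> "SelectionData":
        return cls(ds.sites, ds.annotated_mutations(), ds.samples,
                   ds.chrom_lengths)


@dataclass(frozen=True)
class SelectionConfig:
    base_spec: ModelSpec = field(
        default_factory=lambda: ModelSpec(outcome="multinomial",
                                          intercept_scope="per_sample",
                                          context=True))
    candidates: tuple[Term, ...] = ()
    k_folds: int = 5
    n_windows: int = 60
    window_size: int = 1000
    seed: int = 0
    max_steps: int = 3
    min_relative_improvement: float = 1e-4
    min_cancer_mutations: int = 0
    fit_method: str = "binary"
    pseudo_counts: bool = True

    def __post_init__(self):
        if self.k_folds < 2:
            raise SelectionError("k_folds must be >= 2")
        if self.window_size < 1:
            raise SelectionError("window_size must be >= 1")


@dataclass
class SelectionStep:
    variable: str
    cv_deviance: float
    fold_deviances: tuple[float, ...]
    candidate_deviances: dict[str, float]
    failed_candidates: tuple[str, ...] = ()
    train_r2: float | None = None


@dataclass
class SelectionPath:
    """Ordered record of a forward-selection run."""

    config: SelectionConfig
    base_deviance: float
    base_fold_deviances: tuple[float, ...]
    steps: list[SelectionStep]
    windows: list[tuple]
    excluded_cancer_types: tuple[str, ...] = ()

    def selected_variables(self) -> list[str]:
        return [s.variable for s in self.steps]

    def deviances(self) -> list[float]:
        return [self.base_deviance] + [s.cv_deviance for s in self.steps]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"step": 0, "variable": "(base)",
                 "cv_deviance": self.base_deviance,
                 **{f"fold{i}": d
                    for i, d in enumerate(self.base_fold_deviances)}}]
        for i, s in enumerate(self.steps, start=1):
            rows.append({"step": i, "variable": s.variable,
                         "cv_deviance": s.cv_deviance,
                         **{f"fold{j}": d
                            for j, d in enumerate(s.fold_deviances)}})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# window subsampling and folds
# ---------------------------------------------------------------------------

def sample_windows(chrom_lengths: Mapping[str, int], n_windows: int,
                   window_size: int, seed=0) -> list[tuple]:
    """Uniformly sample non-overlapping, grid-aligned windows from the genome."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) \
        else seed
    grid = [(chrom, w * window_size, (w + 1) * window_size)
            for chrom in sorted(chrom_lengths)
            for w in range(chrom_lengths[chrom] // window_size)]
    if n_windows > len(grid):
        raise SelectionError(
            f"cannot draw {n_windows} windows of {window_size} bases from "
            f"{len(grid)} available")
    idx = np.sort(rng.choice(len(grid), size=n_windows, replace=False))
    return [grid[i] for i in idx]


def make_cv_folds(windows: Sequence, k: int, seed=0) -> np.ndarray:
    """Random fold label per window; fold sizes differ by at most one."""
    if k > len(windows):
        raise SelectionError("more folds than windows")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) \
        else seed
    perm = rng.permutation(len(windows))
    folds = np.empty(len(windows), dtype=int)
    folds[perm] = np.arange(len(windows)) % k
    return folds


def assign_site_folds(sites: pd.DataFrame, windows: Sequence[tuple],
                      folds: np.ndarray) -> np.ndarray:
    """Fold id per site (-1 for sites outside every sampled window)."""
    out = np.full(len(sites), -1, dtype=int)
    chrom = sites["chrom"].astype(str).to_numpy()
    pos = sites["pos"].to_numpy()
    for (c, start, end), f in zip(windows, folds):
        out[(chrom == c) & (pos >= start) & (pos < end)] = f
    return out


# ---------------------------------------------------------------------------
# cross-validated deviance
# ---------------------------------------------------------------------------

def _spec_table(sites: pd.DataFrame, mutations: pd.DataFrame,
                samples: pd.DataFrame, spec: ModelSpec):
    covs = [t.name for t in spec.terms]
    return build_count_table(sites, mutations, samples, covariates=covs,
                             context=spec.context)


def cv_deviance(data: SelectionData, spec: ModelSpec, site_folds: np.ndarray,
                k: int, fit_method: str = "binary",
                pseudo_counts: bool = True):
    """Sum over folds of the held-out deviance: fit on k-1 folds, evaluate the
    deviance loss on the remaining one.  Tables are rebuilt per model."""
    fold_devs = []
    for f in range(k):
        train = data.sites[(site_folds >= 0) & (site_folds != f)]
        valid = data.sites[site_folds == f]
        train_tab = _spec_table(train, data.mutations, data.samples, spec)
        valid_tab = _spec_table(valid, data.mutations, data.samples, spec)
        if pseudo_counts:
            train_tab = glm.add_pseudo_counts(train_tab)
        fit = glm.fit_multinomial(train_tab, spec, method=fit_method,
                                  compute_vcov=False)
        if not fit.converged:
            raise glm.NonConvergenceError(
                f"fold {f} fit did not converge for terms "
                f"{[t.name for t in spec.terms]}")
        d, _ = glm.deviance_loss(fit, valid_tab)
        fold_devs.append(d)
    return float(sum(fold_devs)), tuple(fold_devs)


# ---------------------------------------------------------------------------
# forward selection
# ---------------------------------------------------------------------------

def forward_select(config: SelectionConfig, data: SelectionData) -> SelectionPath:
    """Greedy forward selection over the candidate variables.

    At each step every remaining candidate is scored by :func:`cv_deviance`;
    the argmin enters the model (ties broken by candidate declaration order).
    The search stops at ``max_steps``, when every candidate fails to converge,
    or when the deviance improvement drops below
    ``min_relative_improvement x base deviance``.
    """
    excluded = ()
    samples = data.samples
    mutations = data.mutations
    if config.min_cancer_mutations > 0:
        per_cancer = mutations.groupby("cancer_type", observed=True).size()
        excluded = tuple(sorted(
            c for c in samples["cancer_type"].unique()
            if per_cancer.get(c, 0) < config.min_cancer_mutations))
        if excluded:
            logger.info("excluding low-mutation cancer types: %s", excluded)
            samples = samples[~samples["cancer_type"].isin(excluded)]
            mutations = mutations[~mutations["cancer_type"].isin(excluded)]
    data = SelectionData(data.sites, mutations, samples.reset_index(drop=True),
                         data.chrom_lengths)

    windows = sample_windows(data.chrom_lengths, config.n_windows,
                             config.window_size,
                             np.random.default_rng([config.seed, 0]))
    folds = make_cv_folds(windows, config.k_folds,
                          np.random.default_rng([config.seed, 1]))
    site_folds = assign_site_folds(data.sites, windows, folds)

    base_dev, base_fold = cv_deviance(data, config.base_spec, site_folds,
                                      config.k_folds, config.fit_method,
                                      config.pseudo_counts)
    threshold = config.min_relative_improvement * base_dev
    steps: list[SelectionStep] = []
    spec = config.base_spec
    remaining = list(config.candidates)
    prev_dev = base_dev
    while remaining and len(steps) < config.max_steps:
        cand_devs: dict[str, float] = {}
        cand_folds: dict[str, tuple] = {}
        failed = []
        for cand in remaining:
            try:
                d, fd = cv_deviance(data, spec.with_terms(cand), site_folds,
                                    config.k_folds, config.fit_method,
                                    config.pseudo_counts)
            except FitError as exc:
                logger.warning("candidate %s failed: %s", cand.name, exc)
                failed.append(cand.name)
                cand_devs[cand.name] = math.inf
                continue
            cand_devs[cand.name] = d
            cand_folds[cand.name] = fd
        best = None
        for cand in remaining:  # declaration order breaks ties
            if best is None or cand_devs[cand.name] < cand_devs[best.name]:
                best = cand
        if not math.isfinite(cand_devs[best.name]):
            steps.append(SelectionStep("(all candidates failed)", math.inf,
                                       (), cand_devs, tuple(failed)))
            break
        if prev_dev - cand_devs[best.name] < threshold:
            logger.info("improvement below threshold; stopping after %d steps",
                        len(steps))
            break
        steps.append(SelectionStep(best.name, cand_devs[best.name],
                                   cand_folds[best.name], cand_devs,
                                   tuple(failed)))
        spec = spec.with_terms(best)
        prev_dev = cand_devs[best.name]
        remaining = [c for c in remaining if c.name != best.name]
    return SelectionPath(config, base_dev, base_fold, steps, windows, excluded)
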