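"""Regression models on collapsed count data.

Three granularities of the somatic mutation-rate model:

* **Poisson count regression** on region summaries, log link with a
  log-exposure offset: ``log lambda_r,sam = mu_sam + sum_j beta_j,can x_r,j``.
* **Site-specific binomial logistic regression** on collapsed site counts:
  ``logit p_i,sam = mu_sam + sum_j beta_j,can x_i,j``.
* **Site-specific multinomial logistic regression** over the strand-symmetric
  mutation types: three logits per strand class against the no-mutation
  reference, e.g. ``log(p^{C>A}/p^{C>C}) = mu_sam^{C>A} + sum_j
  beta_j,can^{C>A} x_i,j``.

Because every term carries mutation-type-specific coefficients, the
multinomial likelihood factorizes exactly into the C-site and the T-site
block; the two 4-category blocks are fitted separately and reported jointly.
Fractional counts (after pseudo-count adjustment) are handled as observation
weights throughout.

The default estimation path fits each mutation type versus the no-mutation
reference in a separate weighted binary logistic regression (fast, and nearly
exact in the rare-event regime); the exact multinomial Newton solver is
available as ``method="exact"``.  The variance-covariance matrix is always
that of the full multinomial likelihood evaluated at the combined estimates.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg
import statsmodels.api as sm

from .annotate import MUTATION_TYPES
from .tabulate import COUNT_COLS, CountTable, aggregate_to_cancer, _ref_column_indices

logger = logging.getLogger(__name__)

#: per strand class: the three substitution outcomes and the no-mutation reference
BLOCK_OUTCOMES = {"C": ("C>A", "C>G", "C>T"), "T": ("T>A", "T>C", "T>G")}
BLOCK_REF = {"C": "C>C", "T": "T>T"}
_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


class FitError(ValueError):
    pass


class NonConvergenceError(FitError):
    pass


class UnknownLevelError(FitError):
    pass


# ---------------------------------------------------------------------------
# model specification and parameter accounting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Term:
    """One explanatory variable of a :class:`ModelSpec`.

    ``kind`` is ``continuous``, ``dummy`` or ``categorical``; ``per_cancer``
    stratifies the coefficient by cancer type.  ``n_levels`` is required for
    categorical terms in the nominal parameter accounting.
    """

    name: str
    kind: str = "continuous"
    per_cancer: bool = True
    n_levels: int | None = None

    def __post_init__(self):
        if self.kind not in ("continuous", "dummy", "categorical"):
            raise FitError(f"unknown term kind {self.kind!r}")


@dataclass(frozen=True)
class ModelSpec:
    """Structure of a mutation-rate regression model.

    ``intercept_scope`` is ``global``, ``per_cancer`` or ``per_sample`` (a
    per-sample intercept subsumes per-cancer intercepts, so only one scope is
    allowed).  ``context`` adds the trinucleotide-neighbor term (left x right
    interaction, stratified per cancer type by default).  ``outcome`` selects
    the model family: ``multinomial``, ``binomial`` or ``poisson``.
    """

    outcome: str = "multinomial"
    intercept_scope: str = "per_sample"
    context: bool = True
    context_per_cancer: bool = True
    terms: tuple[Term, ...] = ()

    def __post_init__(self):
        if self.outcome not in ("multinomial", "binomial", "poisson"):
            raise FitError(f"unknown outcome {self.outcome!r}")
        if self.intercept_scope not in ("global", "per_cancer", "per_sample"):
            raise FitError(f"unknown intercept scope {self.intercept_scope!r}")

    def with_terms(self, *terms: Term) -> "ModelSpec":
        return ModelSpec(self.outcome, self.intercept_scope, self.context,
                         self.context_per_cancer, tuple(self.terms) + tuple(terms))


def count_parameters(spec: ModelSpec, n_samples: int, n_cancer_types: int) -> int:
    """Nominal parameter count of a model (the published accounting).

    Per-sample intercepts contribute ``6 * n_samples`` for the multinomial
    model; the neighbor-context term contributes ``4 * 4 * 6`` per cancer type
    (full dummy coding); each continuous or dummy term contributes 6 per
    cancer type.  Fitted designs use treatment coding and therefore have
    slightly fewer free coefficients.
    """
    k = 6 if spec.outcome == "multinomial" else 1
    total = {"global": k, "per_cancer": k * n_cancer_types,
             "per_sample": k * n_samples}[spec.intercept_scope]
    if spec.context:
        total += 4 * 4 * k * (n_cancer_types if spec.context_per_cancer else 1)
    for t in spec.terms:
        if t.kind == "categorical":
            if t.n_levels is None:
                raise FitError(f"categorical term {t.name!r} needs n_levels")
            units = t.n_levels
        else:
            units = 1
        total += units * k * (n_cancer_types if t.per_cancer else 1)
    return total


def count_observations(n_samples: int, n_positions: float) -> float:
    """Total observations of the site-level design: positions x samples."""
    return n_samples * n_positions


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

@dataclass
class DesignInfo:
    """Frozen layout of a design matrix, reused for prediction."""

    columns: list[str]
    intercept_scope: str
    samples: tuple[str, ...]
    cancers: tuple[str, ...]
    levels: dict[str, tuple[str, ...]]  # categorical term -> levels (first = reference)
    terms: tuple[Term, ...]
    context: bool
    context_per_cancer: bool
    block: str | None


def _context_values(df: pd.DataFrame, block: str | None) -> np.ndarray:
    lr = df["left"].astype(str).to_numpy() + df["right"].astype(str).to_numpy()
    if block is None:
        return df["strand_class"].astype(str).to_numpy() + lr
    return lr


def build_design(df: pd.DataFrame, spec: ModelSpec, block: str | None = None,
                 info: DesignInfo | None = None):
    """Assemble the design matrix for collapsed-table rows.

    Treatment coding: for categorical terms the alphabetically first level is
    the reference.  With ``info`` given (prediction / validation), the
    training layout is reused and unknown samples, cancer types or levels
    raise :class:`UnknownLevelError`.
    """
    sample = df["sample"].astype(str).to_numpy()
    cancer = df["cancer_type"].astype(str).to_numpy()
    cat_vals: dict[str, np.ndarray] = {}
    terms = list(spec.terms)
    if spec.context:
        cat_vals["context"] = _context_values(df, block)
        terms = [Term("context", "categorical",
                      per_cancer=spec.context_per_cancer)] + terms
    for t in spec.terms:
        if t.kind == "categorical":
            cat_vals[t.name] = df[t.name].astype(str).to_numpy()

    if info is None:
        info = DesignInfo(
            columns=[], intercept_scope=spec.intercept_scope,
            samples=tuple(sorted(np.unique(sample))),
            cancers=tuple(sorted(np.unique(cancer))),
            levels={name: tuple(sorted(np.unique(v)))
                    for name, v in cat_vals.items()},
            terms=tuple(terms), context=spec.context,
            context_per_cancer=spec.context_per_cancer, block=block)
        fresh = True
    else:
        fresh = False
        unknown = set(np.unique(sample)) - set(info.samples)
        if spec.intercept_scope == "per_sample" and unknown:
            raise UnknownLevelError(f"unknown samples: {sorted(unknown)}")
        unknown = set(np.unique(cancer)) - set(info.cancers)
        if unknown:
            raise UnknownLevelError(f"unknown cancer types: {sorted(unknown)}")
        for name, v in cat_vals.items():
            unknown = set(np.unique(v)) - set(info.levels[name])
            if unknown:
                raise UnknownLevelError(
                    f"unknown levels of {name!r}: {sorted(unknown)}")

    names: list[str] = []
    arrs: list[np.ndarray] = []
    if spec.intercept_scope == "global":
        names.append("mu")
        arrs.append(np.ones(len(df)))
    elif spec.intercept_scope == "per_cancer":
        for c in info.cancers:
            names.append(f"mu[{c}]")
            arrs.append((cancer == c).astype(float))
    else:
        for s in info.samples:
            names.append(f"mu[{s}]")
            arrs.append((sample == s).astype(float))
    for t in terms:
        if t.kind == "categorical":
            vals = cat_vals[t.name]
            lvls = info.levels[t.name][1:]  # first level = reference
            if t.per_cancer:
                for c in info.cancers:
                    in_c = cancer == c
                    for lv in lvls:
                        names.append(f"b[{t.name}|{c}|{lv}]")
                        arrs.append((in_c & (vals == lv)).astype(float))
            else:
                for lv in lvls:
                    names.append(f"b[{t.name}|{lv}]")
                    arrs.append((vals == lv).astype(float))
        else:
            x = df[t.name].to_numpy(float)
            if t.per_cancer:
                for c in info.cancers:
                    names.append(f"b[{t.name}|{c}]")
                    arrs.append(x * (cancer == c))
            else:
                names.append(f"b[{t.name}]")
                arrs.append(x)
    X = np.column_stack(arrs) if arrs else np.empty((len(df), 0))
    if fresh:
        info.columns = names
    return X, info


# ---------------------------------------------------------------------------
# weighted multinomial Newton solver
# ---------------------------------------------------------------------------

def _eta_probs(X: np.ndarray, B: np.ndarray):
    """Stable softmax of the K non-reference logits against reference eta=0."""
    Eta = X @ B.T  # n x K
    m = np.maximum(Eta.max(axis=1), 0.0)
    Z = np.exp(-m) + np.exp(Eta - m[:, None]).sum(axis=1)
    logZ = np.log(Z) + m
    P = np.exp(Eta - logZ[:, None])
    return Eta, P, logZ


def multinomial_information(X: np.ndarray, P: np.ndarray, N: np.ndarray) -> np.ndarray:
    """Fisher information of the collapsed multinomial likelihood.

    Block (k,l) is ``X' diag(N (p_k d_kl - p_k p_l)) X`` over the K
    non-reference outcomes; symmetric positive semidefinite.
    """
    n, p = X.shape
    K = P.shape[1]
    H = np.empty((K * p, K * p))
    for k in range(K):
        for l in range(k, K):
            if k == l:
                w = N * P[:, k] * (1.0 - P[:, k])
            else:
                w = -N * P[:, k] * P[:, l]
            Hkl = X.T @ (w[:, None] * X)
            H[k * p:(k + 1) * p, l * p:(l + 1) * p] = Hkl
            if l != k:
                H[l * p:(l + 1) * p, k * p:(k + 1) * p] = Hkl.T
    return H


def _solve_spd(H: np.ndarray, g: np.ndarray):
    try:
        c, low = linalg.cho_factor(H)
        return linalg.cho_solve((c, low), g), False
    except linalg.LinAlgError:
        warnings.warn("singular information matrix; using pseudo-inverse")
        return np.linalg.pinv(H) @ g, True


def _multinomial_newton(X: np.ndarray, Y: np.ndarray, tol: float = 1e-9,
                        max_iter: int = 100):
    """Newton-Raphson with step-halving for the weighted multinomial logit.

    ``Y`` has the K non-reference outcome counts in the first K columns and
    the reference count last; counts may be fractional.
    """
    n, p = X.shape
    K = Y.shape[1] - 1
    N = Y.sum(axis=1)
    B = np.zeros((K, p))
    Eta, P, logZ = _eta_probs(X, B)
    ll = float((Y[:, :K] * Eta).sum() - (N * logZ).sum())
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        G = np.empty((K, p))
        for k in range(K):
            G[k] = X.T @ (Y[:, k] - N * P[:, k])
        H = multinomial_information(X, P, N)
        step, _ = _solve_spd(H, G.ravel())
        step = step.reshape(K, p)
        scale = 1.0
        for _ in range(40):
            Bn = B + scale * step
            Eta_n, P_n, logZ_n = _eta_probs(X, Bn)
            ll_n = float((Y[:, :K] * Eta_n).sum() - (N * logZ_n).sum())
            if np.isfinite(ll_n) and ll_n >= ll - 1e-10:
                break
            scale /= 2.0
        delta = ll_n - ll
        B, Eta, P, logZ, ll = Bn, Eta_n, P_n, logZ_n, ll_n
        if abs(delta) <= tol * (abs(ll) + 1.0):
            converged = True
            break
    if np.abs(B).max() > 50:
        converged = False
    return B, ll, P, N, it, converged


# ---------------------------------------------------------------------------
# fit results
# ---------------------------------------------------------------------------

@dataclass
class BlockFit:
    info: DesignInfo
    outcomes: tuple[str, ...]
    ref_outcome: str
    params: np.ndarray            # K x p, NaN for aliased columns
    used: np.ndarray              # bool mask of non-aliased columns
    vcov: np.ndarray | None       # (K * p_used)^2, column-major by outcome
    loglik: float
    n_iter: int
    converged: bool


@dataclass
class FitResult:
    """Fitted mutation-rate model (multinomial, binomial or null single-rate)."""

    kind: str
    spec: ModelSpec | None
    method: str
    blocks: dict
    loglik: float
    converged: bool
    coefficients: pd.DataFrame
    sample_map: dict = field(default_factory=dict)
    null_rate: float | None = None  # shared per-type probability of the null model

    # -- prediction ---------------------------------------------------------
    def predict_type_probs(self, df: pd.DataFrame) -> np.ndarray:
        """Per-row probabilities in count-column order (n_A, n_C, n_G, n_T).

        The slot of the strand base holds the no-mutation probability; the
        other three slots the substitution probabilities.  Rows sum to 1.
        """
        out = np.empty((len(df), 4))
        strand = df["strand_class"].astype(str).to_numpy()
        ref_idx = np.where(strand == "C", 1, 3)
        if self.kind == "null":
            q = self.null_rate
            out.fill(q)
            out[np.arange(len(df)), ref_idx] = 1.0 - 3.0 * q
            return out
        if self.kind == "binomial":
            p = self.predict_mut_prob(df)
            out[:] = (p / 3.0)[:, None]
            out[np.arange(len(df)), ref_idx] = 1.0 - p
            return out
        for block, bf in self.blocks.items():
            rows = np.nonzero(strand == block)[0]
            if rows.size == 0:
                continue
            sub = df.iloc[rows]
            X, _ = build_design(sub, self.spec, block=block, info=bf.info)
            _, P, _ = _eta_probs(X[:, bf.used], bf.params[:, bf.used])
            probs = np.empty((len(sub), 4))
            probs[:, _BASE_IDX[block]] = 1.0 - P.sum(axis=1)
            for k, outc in enumerate(bf.outcomes):
                probs[:, _BASE_IDX[outc[-1]]] = P[:, k]
            out[rows] = probs
        return out

    def predict_mut_prob(self, df: pd.DataFrame) -> np.ndarray:
        """Total per-site-sample mutation probability (1 - no-mutation prob)."""
        if self.kind == "binomial":
            bf = self.blocks[None]
            X, _ = build_design(df, self.spec, block=None, info=bf.info)
            eta = X[:, bf.used] @ bf.params[0, bf.used]
            return 1.0 / (1.0 + np.exp(-eta))
        P = self.predict_type_probs(df)
        strand = df["strand_class"].astype(str).to_numpy()
        ref_idx = np.where(strand == "C", 1, 3)
        return 1.0 - P[np.arange(len(df)), ref_idx]


def predict_probs(fit: FitResult, covariates: pd.DataFrame, sample: str) -> pd.DataFrame:
    """Mutation-type probabilities at sites for one sample.

    ``covariates`` holds site rows (``strand_class``, ``left``, ``right`` and
    the model's covariates); the sample's cancer type is looked up from the
    training data.  Returns the four probabilities per row in count-column
    order; each row sums to 1.
    """
    if sample not in fit.sample_map:
        raise UnknownLevelError(f"unknown sample {sample!r}")
    df = covariates.copy()
    df["sample"] = sample
    df["cancer_type"] = fit.sample_map[sample]
    probs = fit.predict_type_probs(df)
    return pd.DataFrame(probs, columns=[f"p_{c[-1]}" for c in COUNT_COLS],
                        index=covariates.index)


def _block_counts(df: pd.DataFrame, block: str) -> np.ndarray:
    """Counts as n x 4: the three substitutions of the block, then the reference."""
    alt_cols = [f"n_{o[-1]}" for o in BLOCK_OUTCOMES[block]]
    ref_col = f"n_{block}"
    return df[alt_cols + [ref_col]].to_numpy(float)


def _coef_frame(blocks: dict) -> pd.DataFrame:
    rows = []
    for bf in blocks.values():
        p_used = int(bf.used.sum())
        for k, outc in enumerate(bf.outcomes):
            se_used = None
            if bf.vcov is not None:
                diag = np.diag(bf.vcov)
                se_used = np.sqrt(np.maximum(diag[k * p_used:(k + 1) * p_used], 0.0))
            j_used = 0
            for j, col in enumerate(bf.info.columns):
                if bf.used[j]:
                    se = float(se_used[j_used]) if se_used is not None else np.nan
                    rows.append((outc, col, float(bf.params[k, j]), se, False))
                    j_used += 1
                else:
                    rows.append((outc, col, np.nan, np.nan, True))
    return pd.DataFrame(rows, columns=["outcome", "term", "estimate", "se", "aliased"])


def _check_outcome_counts(Y: np.ndarray, outcomes, block):
    for k, outc in enumerate(list(outcomes) + ["reference"]):
        if Y[:, k].sum() <= 0:
            raise FitError(
                f"no observed counts for outcome {outc} in {block}-site block; "
                "consider pseudo-count adjustment")


def fit_multinomial(table: CountTable, spec: ModelSpec, method: str = "binary",
                    compute_vcov: bool = True, tol: float = 1e-9,
                    max_iter: int = 100) -> FitResult:
    """Fit the strand-symmetric site multinomial model on a collapsed table.

    ``method="binary"`` (default) estimates each mutation type versus the
    no-mutation reference in a separate weighted binary logistic regression;
    ``method="exact"`` maximizes the joint multinomial likelihood by Newton-
    Raphson.  Either way the reported log-likelihood and variance-covariance
    matrix are those of the full multinomial model at the final estimates.
    """
    if spec.outcome != "multinomial":
        raise FitError("spec.outcome must be 'multinomial'")
    data = table.data
    blocks = {}
    total_ll = 0.0
    all_converged = True
    for block in ("C", "T"):
        sub = data[data["strand_class"].astype(str) == block]
        if len(sub) == 0:
            continue
        X, info = build_design(sub, spec, block=block)
        Y = _block_counts(sub, block)
        _check_outcome_counts(Y, BLOCK_OUTCOMES[block], block)
        used = (X != 0).any(axis=0)
        Xu = X[:, used]
        K = 3
        if method == "exact":
            Bu, ll, P, N, it, conv = _multinomial_newton(Xu, Y, tol, max_iter)
        elif method == "binary":
            Bu = np.empty((K, Xu.shape[1]))
            it = 0
            conv = True
            for k in range(K):
                endog = np.column_stack([Y[:, k], Y[:, 3]])
                keep = endog.sum(axis=1) > 0
                res = sm.GLM(endog[keep], Xu[keep],
                             family=sm.families.Binomial()).fit(
                                 maxiter=max_iter, tol=1e-10)
                Bu[k] = res.params
                it = max(it, int(res.fit_history["iteration"]))
                conv = conv and getattr(res, "converged", True) \
                    and np.abs(res.params).max() < 50
            _, P, logZ = _eta_probs(Xu, Bu)
            N = Y.sum(axis=1)
            Eta = Xu @ Bu.T
            ll = float((Y[:, :K] * Eta).sum() - (N * logZ).sum())
        else:
            raise FitError(f"unknown method {method!r}")
        vcov = None
        if compute_vcov:
            H = multinomial_information(Xu, P, N)
            try:
                c, low = linalg.cho_factor(H)
                vcov = linalg.cho_solve((c, low), np.eye(H.shape[0]))
            except linalg.LinAlgError:
                warnings.warn(f"singular information in {block} block; pseudo-inverse")
                vcov = np.linalg.pinv(H)
        params = np.full((K, X.shape[1]), np.nan)
        params[:, used] = Bu
        blocks[block] = BlockFit(info, BLOCK_OUTCOMES[block], BLOCK_REF[block],
                                 params, used, vcov, ll, it, conv)
        total_ll += ll
        all_converged = all_converged and conv
    sample_map = dict(zip(data["sample"].astype(str),
                          data["cancer_type"].astype(str)))
    return FitResult("multinomial", spec,
                     "multinomial-newton" if method == "exact" else "binary-logit",
                     blocks, total_ll, all_converged, _coef_frame(blocks),
                     sample_map)


def fit_multinomial_via_binary(table: CountTable, spec: ModelSpec,
                               **kwargs) -> FitResult:
    """Three separate binary logits against the no-mutation reference (the
    memory-saving estimation route); see :func:`fit_multinomial`."""
    return fit_multinomial(table, spec, method="binary", **kwargs)


def fit_binomial(table: CountTable, spec: ModelSpec,
                 max_iter: int = 100) -> FitResult:
    """Weighted binary logistic regression of mutated versus not."""
    if spec.outcome != "binomial":
        raise FitError("spec.outcome must be 'binomial'")
    data = table.data
    counts = data[list(COUNT_COLS)].to_numpy(float)
    ref_idx = _ref_column_indices(data)
    ref = counts[np.arange(len(data)), ref_idx]
    mut = counts.sum(axis=1) - ref
    if mut.sum() <= 0:
        raise FitError("no observed mutations")
    X, info = build_design(data, spec, block=None)
    used = (X != 0).any(axis=0)
    endog = np.column_stack([mut, ref])
    keep = endog.sum(axis=1) > 0
    res = sm.GLM(endog[keep], X[keep][:, used],
                 family=sm.families.Binomial()).fit(maxiter=max_iter, tol=1e-10)
    conv = getattr(res, "converged", True) and np.abs(res.params).max() < 50
    if not conv:
        warnings.warn("binomial fit did not converge (possible separation)")
    eta = X[:, used] @ res.params
    p = 1.0 / (1.0 + np.exp(-eta))
    ll = float(np.sum(mut * np.log(p) + ref * np.log1p(-p)))
    params = np.full((1, X.shape[1]), np.nan)
    params[0, used] = res.params
    vcov = np.asarray(res.cov_params())
    bf = BlockFit(info, ("mut",), "ref", params, used, vcov, ll,
                  int(res.fit_history["iteration"]), conv)
    sample_map = dict(zip(data["sample"].astype(str),
                          data["cancer_type"].astype(str)))
    return FitResult("binomial", spec, "binomial-irls", {None: bf}, ll, conv,
                     _coef_frame({None: bf}), sample_map)


# ---------------------------------------------------------------------------
# Poisson region model
# ---------------------------------------------------------------------------

def build_region_design(df: pd.DataFrame, spec: ModelSpec,
                        info: DesignInfo | None = None):
    """Design matrix for region summaries.

    Continuous terms use the region means; categorical terms use the level
    proportion columns ``p_<name>:<level>`` (first level dropped).
    """
    sample = df["sample"].astype(str).to_numpy()
    cancer = df["cancer_type"].astype(str).to_numpy()
    if info is None:
        levels = {}
        for t in spec.terms:
            if t.kind == "categorical":
                prefix = f"p_{t.name}:"
                lv = sorted(c[len(prefix):] for c in df.columns
                            if c.startswith(prefix))
                if not lv:
                    raise FitError(f"no proportion columns for {t.name!r}")
                levels[t.name] = tuple(lv)
        info = DesignInfo([], spec.intercept_scope,
                          tuple(sorted(np.unique(sample))),
                          tuple(sorted(np.unique(cancer))),
                          levels, tuple(spec.terms), False, False, None)
        fresh = True
    else:
        fresh = False
        if spec.intercept_scope == "per_sample" and \
                set(np.unique(sample)) - set(info.samples):
            raise UnknownLevelError("unknown samples in region design")
    names, arrs = [], []
    if spec.intercept_scope == "global":
        names.append("mu")
        arrs.append(np.ones(len(df)))
    elif spec.intercept_scope == "per_cancer":
        for c in info.cancers:
            names.append(f"mu[{c}]")
            arrs.append((cancer == c).astype(float))
    else:
        for s in info.samples:
            names.append(f"mu[{s}]")
            arrs.append((sample == s).astype(float))
    for t in spec.terms:
        if t.kind == "categorical":
            for_cancers = info.cancers if t.per_cancer else [None]
            for c in for_cancers:
                w = (cancer == c).astype(float) if c is not None else 1.0
                for lv in info.levels[t.name][1:]:
                    col = df[f"p_{t.name}:{lv}"].to_numpy(float)
                    names.append(f"b[{t.name}|{c}|{lv}]" if c is not None
                                 else f"b[{t.name}|{lv}]")
                    arrs.append(col * w)
        else:
            x = df[t.name].to_numpy(float)
            if t.per_cancer:
                for c in info.cancers:
                    names.append(f"b[{t.name}|{c}]")
                    arrs.append(x * (cancer == c))
            else:
                names.append(f"b[{t.name}]")
                arrs.append(x)
    X = np.column_stack(arrs) if arrs else np.empty((len(df), 0))
    if fresh:
        info.columns = names
    return X, info


@dataclass
class PoissonFit:
    """Poisson region regression with log link and log-exposure offset."""

    spec: ModelSpec
    info: DesignInfo
    params: np.ndarray
    used: np.ndarray
    vcov: np.ndarray
    loglik: float
    converged: bool
    coefficients: pd.DataFrame
    kind: str = "poisson"

    def predict_rate(self, regions: pd.DataFrame) -> np.ndarray:
        """Expected mutation count lambda-hat per region row."""
        X, _ = build_region_design(regions, self.spec, info=self.info)
        length = regions["length"].to_numpy(float)
        if (length <= 0).any():
            raise FitError("zero-length region")
        return np.exp(X[:, self.used] @ self.params + np.log(length))


def fit_poisson(regions: pd.DataFrame, spec: ModelSpec,
                max_iter: int = 100) -> PoissonFit:
    """Poisson MLE of per-region mutation counts with log(L_r) offset."""
    if spec.outcome != "poisson":
        raise FitError("spec.outcome must be 'poisson'")
    length = regions["length"].to_numpy(float)
    if (length <= 0).any():
        raise FitError("zero-length region")
    X, info = build_region_design(regions, spec)
    used = (X != 0).any(axis=0)
    endog = regions["count"].to_numpy(float)
    res = sm.GLM(endog, X[:, used], family=sm.families.Poisson(),
                 offset=np.log(length)).fit(maxiter=max_iter, tol=1e-10)
    conv = getattr(res, "converged", True)
    params = np.full(X.shape[1], np.nan)
    params[used] = res.params
    lam = np.exp(X[:, used] @ res.params + np.log(length))
    ll = float(np.sum(endog * np.log(lam) - lam))
    rows = []
    se = np.sqrt(np.maximum(np.diag(np.asarray(res.cov_params())), 0.0))
    j_used = 0
    for j, col in enumerate(info.columns):
        if used[j]:
            rows.append(("rate", col, float(res.params[j_used]),
                         float(se[j_used]), False))
            j_used += 1
        else:
            rows.append(("rate", col, np.nan, np.nan, True))
    coef = pd.DataFrame(rows, columns=["outcome", "term", "estimate", "se", "aliased"])
    return PoissonFit(spec, info, params[used], used,
                      np.asarray(res.cov_params()), ll, conv, coef)


# ---------------------------------------------------------------------------
# pseudo counts
# ---------------------------------------------------------------------------

def add_pseudo_counts(table: CountTable) -> CountTable:
    """Dirichlet-prior pseudo-count adjustment of zero cells.

    For every row with at least one zero substitution count, the count vector
    (including the no-mutation component) is replaced by
    ``0.5 * n_K,sam + (N_K,sam / (2 N_K,can)) * n_K,can`` where ``n_K,can`` is
    the componentwise sum over all samples of the row's cancer type.  The
    per-sample row total is preserved exactly; rows whose substitution counts
    are all positive are untouched.  Adjusted counts may be fractional.
    """
    df = table.data.copy()
    agg = aggregate_to_cancer(table)
    agg = agg.rename(columns={c: f"can_{c}" for c in COUNT_COLS})
    merged = df.merge(agg, on=table.key_cols + ["cancer_type"], how="left")
    counts = merged[list(COUNT_COLS)].to_numpy(float)
    can_counts = merged[[f"can_{c}" for c in COUNT_COLS]].to_numpy(float)
    ref_idx = _ref_column_indices(merged)
    alt_mask = np.ones_like(counts, dtype=bool)
    alt_mask[np.arange(len(counts)), ref_idx] = False
    needs = ((counts == 0) & alt_mask).any(axis=1)
    n_sam = counts.sum(axis=1)
    n_can = can_counts.sum(axis=1)
    fallback = needs & (n_can <= 0)
    adjust = needs & (n_can > 0)
    new = counts.copy()
    if adjust.any():
        f = (n_sam[adjust] / (2.0 * n_can[adjust]))[:, None]
        new[adjust] = 0.5 * counts[adjust] + f * can_counts[adjust]
    if fallback.any():
        logger.warning("pseudo-count fallback (+0.5 per outcome) on %d rows "
                       "with empty cancer aggregate", int(fallback.sum()))
        new[fallback] = counts[fallback] + 0.5
    out = table.data.copy()
    out[list(COUNT_COLS)] = new
    logger.info("pseudo counts added to %d of %d rows", int(needs.sum()), len(out))
    return CountTable(out, list(table.key_cols))


# ---------------------------------------------------------------------------
# deviance, null model, McFadden's pseudo R^2
# ---------------------------------------------------------------------------

def deviance_loss(fit, table: CountTable, floor: float = 1e-12):
    """Total deviance loss ``D = -2 sum n log p-hat`` over the four outcomes,
    weighted by the collapsed counts, plus the per-row contributions.

    Probabilities below ``floor`` for observed outcomes are floored (logged)
    to guard against infinite deviance on held-out data.
    """
    probs = fit.predict_type_probs(table.data)
    counts = table.data[list(COUNT_COLS)].to_numpy(float)
    if ((probs < floor) & (counts > 0)).any():
        logger.warning("deviance probability floor %g triggered", floor)
    logp = np.log(np.clip(probs, floor, 1.0))
    per_row = -2.0 * (counts * logp).sum(axis=1)
    return float(per_row.sum()), per_row


def binary_deviance_loss(fit, table: CountTable, floor: float = 1e-12):
    """Deviance of the collapsed mutated/not-mutated outcome (type-blind)."""
    p = np.clip(fit.predict_mut_prob(table.data), floor, 1.0 - floor)
    counts = table.data[list(COUNT_COLS)].to_numpy(float)
    ref_idx = _ref_column_indices(table.data)
    ref = counts[np.arange(len(counts)), ref_idx]
    mut = counts.sum(axis=1) - ref
    per_row = -2.0 * (mut * np.log(p) + ref * np.log1p(-p))
    return float(per_row.sum()), per_row


def null_loglik(table: CountTable, null: str = "shared") -> float:
    """Log-likelihood of the no-predictor model.

    ``null="shared"`` uses one probability q for every mutation type (the
    single-genome-wide-rate reference model; q-hat = M/(3N)).  ``null="per-type"``
    estimates one pooled probability per mutation type instead.
    """
    counts = table.data[list(COUNT_COLS)].to_numpy(float)
    ref_idx = _ref_column_indices(table.data)
    ref = counts[np.arange(len(counts)), ref_idx]
    totals = counts.sum(axis=1)
    mut = totals - ref
    M, R = mut.sum(), ref.sum()
    N = M + R
    if null == "shared":
        q = M / (3.0 * N)
        return float(M * np.log(q) + R * np.log1p(-3.0 * q))
    if null == "per-type":
        ll = 0.0
        strand = table.data["strand_class"].astype(str).to_numpy()
        for block in ("C", "T"):
            rows = strand == block
            if not rows.any():
                continue
            Y = _block_counts(table.data[rows], block)
            n_block = Y.sum()
            p = Y.sum(axis=0) / n_block
            ll += float((Y.sum(axis=0)[p > 0] * np.log(p[p > 0])).sum())
        return ll
    raise FitError(f"unknown null model {null!r}")


def fit_null_single_rate(table: CountTable) -> FitResult:
    """The reference model: one genome-wide rate, no predictors, uniform over
    the three mutation types.  Its McFadden pseudo R^2 against itself is 0."""
    counts = table.data[list(COUNT_COLS)].to_numpy(float)
    ref_idx = _ref_column_indices(table.data)
    ref = counts[np.arange(len(counts)), ref_idx]
    mut = counts.sum(axis=1) - ref
    q = mut.sum() / (3.0 * counts.sum())
    ll = null_loglik(table, "shared")
    sample_map = dict(zip(table.data["sample"].astype(str),
                          table.data["cancer_type"].astype(str)))
    return FitResult("null", None, "single-rate", {}, ll, True,
                     pd.DataFrame([("any", "rate", q, np.nan, False)],
                                  columns=["outcome", "term", "estimate",
                                           "se", "aliased"]),
                     sample_map, null_rate=q)


def mcfadden_r2(fit, table: CountTable, null: str = "shared") -> float:
    """McFadden's pseudo R^2 = 1 - logL_M / logL_0 against the no-predictor null."""
    l0 = null_loglik(table, null)
    lm = fit.loglik
    if l0 == 0.0:
        raise FitError("null log-likelihood is zero")
    if lm == l0:
        return 0.0
    return 1.0 - lm / l0


def mcfadden_r2_from_loglik(loglik_model: float, loglik_null: float) -> float:
    if loglik_null == 0.0:
        raise FitError("null log-likelihood is zero")
    return 1.0 - loglik_model / loglik_null


def expected_type_totals(fit: FitResult, table: CountTable) -> pd.DataFrame:
    """Fitted and observed per-sample totals of each mutation type.

    For a converged canonical-link fit with per-sample intercepts these agree
    (score equations)."""
    probs = fit.predict_type_probs(table.data)
    counts = table.data[list(COUNT_COLS)].to_numpy(float)
    totals = counts.sum(axis=1)
    strand = table.data["strand_class"].astype(str).to_numpy()
    recs = []
    for block in ("C", "T"):
        rows = strand == block
        if not rows.any():
            continue
        for outc in BLOCK_OUTCOMES[block]:
            col = _BASE_IDX[outc[-1]]
            d = pd.DataFrame({
                "sample": table.data.loc[rows, "sample"].astype(str).to_numpy(),
                "expected": totals[rows] * probs[rows, col],
                "observed": counts[rows, col]})
            g = d.groupby("sample").sum().reset_index()
            g["outcome"] = outc
            recs.append(g)
    return pd.concat(recs, ignore_index=True)
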