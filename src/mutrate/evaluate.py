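"""Predicted-versus-observed evaluation at several granularities.

Region models and site models are compared the way whole-genome studies do
it: expected versus observed mutation counts in large (e.g. 100 kb) windows,
where all granularities look similar, and held-out deviance on a small random
set of individual sites, where site-specific models shine.  A region-trained
Poisson model assigns probability to a single site as its region's rate
density lambda-hat / L spread uniformly over the region's retained sites (a
documented modelling choice; region models carry no finer information).
Type-blind models split the total mutation probability uniformly over the
three substitution types when scored on the type-resolved outcome.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import glm
from .tabulate import (COUNT_COLS, CountTable, build_count_table,
                       summarize_regions, _ref_column_indices)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# window-level predictions
# ---------------------------------------------------------------------------

def predict_window_counts(fit, sites: pd.DataFrame, mutations: pd.DataFrame,
                          windows: Sequence[tuple], samples: pd.DataFrame,
                          ) -> pd.DataFrame:
    """Expected and observed mutation counts per window and sample.

    For site models the expectation is the sum over retained sites and
    samples of the per-site mutation probability; for the Poisson region
    model it is lambda-hat.  Fully masked windows get expected 0 and a flag.
    """
    if getattr(fit, "kind", None) == "poisson":
        covs = [t.name for t in fit.spec.terms]
        regions = summarize_regions(sites, mutations, windows, samples,
                                    covariates=covs)
        regions = regions.copy()
        regions["expected"] = fit.predict_rate(regions)
        regions["observed"] = regions["count"]
        regions["masked"] = False
        return regions[["region", "chrom", "start", "end", "sample",
                        "cancer_type", "expected", "observed", "masked"]]
    covs = [t.name for t in fit.spec.terms] if fit.spec is not None else []
    context = fit.spec.context if fit.spec is not None else True
    chrom_arr = sites["chrom"].astype(str).to_numpy()
    pos_arr = sites["pos"].to_numpy()
    recs = []
    for rid, (chrom, start, end) in enumerate(windows):
        in_win = sites[(chrom_arr == chrom) & (pos_arr >= start)
                       & (pos_arr < end)]
        if len(in_win) == 0:
            for rec in samples.itertuples(index=False):
                recs.append((rid, chrom, start, end, rec.sample,
                             rec.cancer_type, 0.0, 0, True))
            continue
        tab = build_count_table(in_win, mutations, samples, covariates=covs,
                                context=context)
        p = fit.predict_mut_prob(tab.data)
        totals = tab.row_totals()
        muts = tab.mutation_counts()
        d = pd.DataFrame({"sample": tab.data["sample"].astype(str),
                          "cancer_type": tab.data["cancer_type"].astype(str),
                          "expected": totals * p, "observed": muts})
        g = d.groupby(["sample", "cancer_type"]).sum().reset_index()
        for rec in g.itertuples(index=False):
            recs.append((rid, chrom, start, end, rec.sample, rec.cancer_type,
                         float(rec.expected), int(rec.observed), False))
    return pd.DataFrame(recs, columns=["region", "chrom", "start", "end",
                                       "sample", "cancer_type", "expected",
                                       "observed", "masked"])


# ---------------------------------------------------------------------------
# Poisson fit as a site-level model
# ---------------------------------------------------------------------------

@dataclass
class PoissonSiteAdapter:
    """Site-level probabilities from a region-trained Poisson model.

    The per-site mutation probability is the region's fitted rate density
    lambda-hat / L (L = retained sites), uniform over the region, and split
    uniformly over the three substitution types.  Site rows must carry a
    ``region`` column mapping them to the training regions.
    """

    rates: pd.DataFrame  # columns: region, sample, p
    kind: str = "poisson-site"

    def _lookup(self, df: pd.DataFrame) -> np.ndarray:
        key = df[["region", "sample"]].copy()
        key["region"] = key["region"].astype(int)
        key["sample"] = key["sample"].astype(str)
        merged = key.merge(self.rates, on=["region", "sample"], how="left")
        p = merged["p"].to_numpy(float)
        if np.isnan(p).any():
            raise glm.UnknownLevelError("site outside every training region")
        return p

    def predict_mut_prob(self, df: pd.DataFrame) -> np.ndarray:
        return self._lookup(df)

    def predict_type_probs(self, df: pd.DataFrame) -> np.ndarray:
        p = self._lookup(df)
        out = np.empty((len(df), 4))
        out[:] = (p / 3.0)[:, None]
        strand = df["strand_class"].astype(str).to_numpy()
        ref_idx = np.where(strand == "C", 1, 3)
        out[np.arange(len(df)), ref_idx] = 1.0 - p
        return out


def poisson_site_adapter(fit, regions: pd.DataFrame,
                         p_max: float = 0.999) -> PoissonSiteAdapter:
    lam = fit.predict_rate(regions)
    p = np.clip(lam / regions["length"].to_numpy(float), 1e-300, p_max)
    rates = pd.DataFrame({"region": regions["region"].astype(int),
                          "sample": regions["sample"].astype(str), "p": p})
    return PoissonSiteAdapter(rates)


# ---------------------------------------------------------------------------
# random-site evaluation
# ---------------------------------------------------------------------------

def random_site_evaluation(fits: Mapping[str, object], sites: pd.DataFrame,
                           mutations: pd.DataFrame, samples: pd.DataFrame,
                           n_sites: int = 1000, seed: int = 0,
                           site_regions: np.ndarray | None = None):
    """Held-out deviance of several models on a random sample of sites.

    Every model is evaluated on the identical site x sample outcomes.
    Returns ``(summary, per_type)``: the summary has the type-resolved and
    the binary (mutated / not) deviance per model; ``per_type`` the expected
    and observed counts per mutation type per model.  ``site_regions`` maps
    each site to its Poisson training region (required when a
    :class:`PoissonSiteAdapter` is among the fits).
    """
    rng = np.random.default_rng(seed)
    if n_sites > len(sites):
        raise ValueError("fewer retained sites than requested")
    chosen = np.sort(rng.choice(len(sites), size=n_sites, replace=False))
    picked = sites.iloc[chosen].copy()
    if site_regions is not None:
        picked["region"] = np.asarray(site_regions)[chosen]
        if (picked["region"] < 0).any():
            n_bad = int((picked["region"] < 0).sum())
            logger.info("excluding %d sampled sites outside training regions",
                        n_bad)
            picked = picked[picked["region"] >= 0]
    covs = sorted({t.name for f in fits.values()
                   for t in (getattr(f, "spec", None).terms
                             if getattr(f, "spec", None) is not None else ())})
    if site_regions is not None:
        covs.append("region")
    table = build_count_table(picked, mutations, samples, covariates=covs,
                              context=True)
    summary_rows = []
    type_rows = []
    counts = table.data[list(COUNT_COLS)].to_numpy(float)
    totals = counts.sum(axis=1)
    ref_idx = _ref_column_indices(table.data)
    strand = table.data["strand_class"].astype(str).to_numpy()
    for name, fit in fits.items():
        d_type, _ = glm.deviance_loss(fit, table)
        d_bin, _ = glm.binary_deviance_loss(fit, table)
        summary_rows.append((name, d_type, d_bin, int(totals.sum())))
        probs = fit.predict_type_probs(table.data)
        for block in ("C", "T"):
            rows = strand == block
            if not rows.any():
                continue
            for outc in glm.BLOCK_OUTCOMES[block]:
                col = glm._BASE_IDX[outc[-1]]
                type_rows.append((name, outc,
                                  float((totals[rows] * probs[rows, col]).sum()),
                                  float(counts[rows, col].sum())))
    summary = pd.DataFrame(summary_rows, columns=["model", "type_deviance",
                                                  "binary_deviance",
                                                  "n_site_samples"])
    per_type = pd.DataFrame(type_rows, columns=["model", "mutation_type",
                                                "expected", "observed"])
    return summary, per_type


# ---------------------------------------------------------------------------
# heterogeneity summaries
# ---------------------------------------------------------------------------

def context_proportions(mutations: pd.DataFrame) -> pd.DataFrame:
    """Relative proportion of mutations in each of the 32 trinucleotide
    context classes (2 strand classes x 4 left x 4 right), per cancer type;
    columns sum to 1."""
    m = mutations.copy()
    m["strand_class"] = m["strand_class"].astype(str)
    m["left"] = m["left"].astype(str)
    m["right"] = m["right"].astype(str)
    idx = pd.MultiIndex.from_product(
        [["C", "T"], list("ACGT"), list("ACGT")],
        names=["strand_class", "left", "right"])
    counts = (m.groupby(["strand_class", "left", "right", "cancer_type"],
                        observed=True).size().unstack("cancer_type",
                                                      fill_value=0))
    counts = counts.reindex(idx, fill_value=0)
    totals = counts.sum(axis=0)
    props = counts / totals.replace(0, np.nan)
    return props.fillna(0.0)


def stratified_rates(mutations: pd.DataFrame, sites: pd.DataFrame,
                     samples: pd.DataFrame, column: str) -> pd.DataFrame:
    """Mutations per at-risk site-sample, stratified by one site covariate
    (element label or 0/1 dummy) and cancer type.  Empty strata report rate 0
    together with their at-risk count."""
    at_risk = sites.groupby(column, observed=False).size().rename("at_risk")
    n_per_cancer = samples.groupby("cancer_type", observed=True).size()
    mut = (mutations.merge(sites[["chrom", "pos", column]],
                           left_on=["chrom", "pos0"], right_on=["chrom", "pos"])
           .groupby([column, "cancer_type"], observed=False).size()
           .rename("n_mut"))
    rows = []
    for level in at_risk.index:
        for can in n_per_cancer.index:
            n = int(mut.get((level, can), 0))
            ar = int(at_risk.loc[level]) * int(n_per_cancer.loc[can])
            rows.append((level, can, n, ar, n / ar if ar else 0.0))
    return pd.DataFrame(rows, columns=[column, "cancer_type", "n_mut",
                                       "at_risk", "rate"])


def heterogeneity_summary(mutations: pd.DataFrame, sites: pd.DataFrame,
                          samples: pd.DataFrame,
                          strata: Sequence[str] = ()) -> dict[str, pd.DataFrame]:
    """Stratified mutation-rate tables: the 32-class context proportions plus a
    per-level rate table for every requested site covariate."""
    out = {"context": context_proportions(mutations)}
    for col in strata:
        out[col] = stratified_rates(mutations, sites, samples, col)
    return out


def fold_change(fit, outcome: str, term_column: str, delta_x: float = 1.0) -> float:
    """Multiplicative mutation-rate change exp(beta * delta_x) for a contrast
    of ``delta_x`` in a covariate (e.g. conserved vs. neutral)."""
    coef = fit.coefficients
    row = coef[(coef["outcome"] == outcome) & (coef["term"] == term_column)]
    if len(row) != 1:
        raise KeyError(f"no unique coefficient for {outcome}/{term_column}")
    return float(np.exp(row["estimate"].iloc[0] * delta_x))
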