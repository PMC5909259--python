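"""Collapsing per-site data into analytical count tables and region summaries.

A :class:`CountTable` row holds, for one covariate combination *K* and one
sample, the counts of the three possible substitutions of the strand class and
the no-mutation count.  Collapsing makes genome-scale GLM fitting tractable:
the table size is bounded by (covariate-level combinations) x (samples),
independent of genome length.

Count-column layout: ``n_A, n_C, n_G, n_T`` are indexed by the *alternative*
base on the pyrimidine strand; the slot of the strand base itself (``n_C`` on
C-site rows, ``n_T`` on T-site rows) holds the no-mutation count.  A C-site
row therefore reads (C>A, no-mutation, C>G, C>T) across the four columns.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COUNT_COLS = ("n_A", "n_C", "n_G", "n_T")
CONTEXT_COLS = ("strand_class", "left", "right")


class TabulationError(ValueError):
    pass


@dataclass
class CountTable:
    """Collapsed (covariate combination x sample) outcome counts.

    ``data`` columns: ``key_cols`` + ``sample`` + ``cancer_type`` + the four
    count columns.  ``key_cols`` always includes ``strand_class`` and includes
    ``left``/``right`` when trinucleotide context is part of the combination.
    Counts may be fractional after pseudo-count adjustment.
    """

    data: pd.DataFrame
    key_cols: list[str]

    @property
    def samples(self) -> pd.DataFrame:
        return (self.data[["sample", "cancer_type"]]
                .drop_duplicates().reset_index(drop=True))

    def row_totals(self) -> np.ndarray:
        return self.data[list(COUNT_COLS)].to_numpy(float).sum(axis=1)

    def mutation_counts(self) -> np.ndarray:
        """Per-row total substitution count (row total minus the no-mutation slot)."""
        counts = self.data[list(COUNT_COLS)].to_numpy(float)
        ref_idx = _ref_column_indices(self.data)
        totals = counts.sum(axis=1)
        return totals - counts[np.arange(len(counts)), ref_idx]

    def copy(self) -> "CountTable":
        return CountTable(self.data.copy(), list(self.key_cols))

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "CountTable":
        df = pd.read_csv(path, sep="\t", dtype={"sample": str, "cancer_type": str})
        key_cols = [c for c in df.columns
                    if c not in COUNT_COLS and c not in ("sample", "cancer_type")]
        return cls(df, key_cols)


def _ref_column_indices(df: pd.DataFrame) -> np.ndarray:
    """Index into COUNT_COLS of the no-mutation slot per row (the strand base)."""
    strand = df["strand_class"].astype(str).to_numpy()
    return np.where(strand == "C", 1, 3)


def _alt_base(mutation_type: pd.Series) -> pd.Series:
    return mutation_type.astype(str).str[-1]


def build_count_table(sites: pd.DataFrame, mutations: pd.DataFrame,
                      samples: pd.DataFrame, covariates: Sequence[str] = (),
                      context: bool = True,
                      chunk_size: int | None = None) -> CountTable:
    """Collapse sites and mutations into a :class:`CountTable`.

    ``sites`` is the per-site covariate table (see ``annotate.build_site_table``),
    ``mutations`` the annotated mutation records, ``samples`` a table with
    columns ``sample`` and ``cancer_type``.  Only the requested ``covariates``
    (plus strand class, and the neighbor context when ``context=True``) enter
    the combination key.  Mutations at sites absent from ``sites`` (masked or
    excluded) are dropped with a logged count.  ``chunk_size`` bounds memory by
    streaming the site table in chunks; the output is independent of chunking.
    """
    key_cols = ["strand_class"] + (["left", "right"] if context else []) + list(covariates)
    for c in key_cols:
        if c not in sites.columns:
            raise TabulationError(f"covariate {c!r} missing from site table")

    if chunk_size:
        parts = [sites.iloc[i:i + chunk_size]
                 for i in range(0, len(sites), chunk_size)]
    else:
        parts = [sites]
    at_risk = None
    for part in parts:
        g = part.groupby(key_cols, observed=True, sort=True).size()
        at_risk = g if at_risk is None else at_risk.add(g, fill_value=0)
    at_risk = at_risk.astype(np.int64).rename("n_sites").reset_index()

    # attach site covariates to each mutation by genomic position
    site_cov = sites[["chrom", "pos"] + [c for c in key_cols if c != "strand_class"]
                     + ["strand_class"]]
    muts = mutations.copy()
    muts["pos"] = muts["pos0"] if "pos0" in muts.columns else muts["pos"] - 1
    merged = muts.merge(site_cov, on=["chrom", "pos"], how="inner",
                        suffixes=("_rec", ""))
    n_dropped = len(muts) - len(merged)
    if n_dropped:
        logger.info("dropped %d mutations at masked/excluded sites", n_dropped)
    if "strand_class_rec" in merged.columns:
        bad = merged["strand_class_rec"].astype(str) != merged["strand_class"].astype(str)
        if bad.any():
            raise TabulationError("mutation strand class conflicts with site strand class")
    merged["alt_pyr"] = _alt_base(merged["mutation_type"])

    tally = (merged.groupby(key_cols + ["sample"], observed=True)["alt_pyr"]
             .value_counts().unstack(fill_value=0))
    tally.columns = [f"n_{b}" for b in tally.columns]
    tally = tally.reset_index()

    rows = at_risk.merge(samples, how="cross")
    rows = rows.merge(tally, on=key_cols + ["sample"], how="left")
    for col in COUNT_COLS:
        if col not in rows.columns:
            rows[col] = 0.0
        rows[col] = rows[col].fillna(0).astype(float)

    counts = rows[list(COUNT_COLS)].to_numpy(float)
    ref_idx = _ref_column_indices(rows)
    n_mut = counts.sum(axis=1)
    ref_count = rows["n_sites"].to_numpy(float) - n_mut
    if (ref_count < 0).any():
        raise TabulationError("more mutations than at-risk sites in a combination")
    counts[np.arange(len(rows)), ref_idx] = ref_count
    rows[list(COUNT_COLS)] = counts
    rows = rows.drop(columns=["n_sites"])
    order = key_cols + ["sample", "cancer_type"] + list(COUNT_COLS)
    return CountTable(rows[order].reset_index(drop=True), key_cols)


def aggregate_to_cancer(table: CountTable) -> pd.DataFrame:
    """Componentwise cancer-type aggregates n_K,can of the sample counts."""
    return (table.data.groupby(table.key_cols + ["cancer_type"], observed=True)
            [list(COUNT_COLS)].sum().reset_index())


def expand_table(table: CountTable) -> pd.DataFrame:
    """One observation per counted unit (testing oracle; integer counts only).

    Returns rows of key columns + ``sample`` + ``cancer_type`` + ``outcome``
    (the alt base, or the strand base for no-mutation observations).  The
    multiset of observations equals the pre-collapse data.
    """
    counts = table.data[list(COUNT_COLS)].to_numpy(float)
    if not np.allclose(counts, np.round(counts), atol=1e-9):
        raise TabulationError("non-integer counts cannot be expanded")
    long = table.data.melt(
        id_vars=table.key_cols + ["sample", "cancer_type"],
        value_vars=list(COUNT_COLS), var_name="outcome", value_name="n")
    long["outcome"] = long["outcome"].str[-1]
    long["n"] = long["n"].round().astype(int)
    long = long[long["n"] > 0]
    obs = long.loc[long.index.repeat(long["n"])].drop(columns="n")
    return obs.reset_index(drop=True)


def table_from_observations(obs: pd.DataFrame, key_cols: Sequence[str]) -> CountTable:
    """Rebuild a :class:`CountTable` from a per-observation stream (round-trip oracle)."""
    tally = (obs.groupby(list(key_cols) + ["sample", "cancer_type"], observed=True)
             ["outcome"].value_counts().unstack(fill_value=0))
    tally.columns = [f"n_{b}" for b in tally.columns]
    tally = tally.reset_index()
    for col in COUNT_COLS:
        if col not in tally.columns:
            tally[col] = 0.0
        tally[col] = tally[col].astype(float)
    order = list(key_cols) + ["sample", "cancer_type"] + list(COUNT_COLS)
    return CountTable(tally[order], list(key_cols))


def summarize_regions(sites: pd.DataFrame, mutations: pd.DataFrame,
                      regions: Sequence[tuple], samples: pd.DataFrame,
                      covariates: Sequence[str] = ()) -> pd.DataFrame:
    """Per-region, per-sample summaries for Poisson count regression.

    ``regions`` holds disjoint ``(chrom, start, end)`` intervals.  Continuous
    covariates are averaged over the retained sites of the region; categorical
    covariates become per-level proportion columns ``p_<name>:<level>``.  The
    exposure ``length`` is the number of retained sites (the at-risk length).
    Regions without retained sites are dropped with a warning.
    """
    recs = []
    mut_pos = mutations.copy()
    if "pos0" in mut_pos.columns:
        mut_pos["p0"] = mut_pos["pos0"]
    else:
        mut_pos["p0"] = mut_pos["pos"] - 1
    for rid, (chrom, start, end) in enumerate(regions):
        in_region = sites[(sites["chrom"].astype(str) == chrom)
                          & (sites["pos"] >= start) & (sites["pos"] < end)]
        if len(in_region) == 0:
            logger.warning("region %s:%d-%d has no retained sites; dropped",
                           chrom, start, end)
            continue
        summary = {"region": rid, "chrom": chrom, "start": start, "end": end,
                   "length": len(in_region)}
        for cov in covariates:
            col = in_region[cov]
            if pd.api.types.is_numeric_dtype(col):
                summary[cov] = float(col.mean())
            else:
                props = col.astype(str).value_counts(normalize=True)
                levels = (col.cat.categories if hasattr(col, "cat")
                          else sorted(col.astype(str).unique()))
                for level in levels:
                    summary[f"p_{cov}:{level}"] = float(props.get(level, 0.0))
        m = mut_pos[(mut_pos["chrom"].astype(str) == chrom)
                    & (mut_pos["p0"] >= start) & (mut_pos["p0"] < end)]
        per_sample = m.groupby("sample", observed=True).size()
        for rec in samples.itertuples(index=False):
            row = dict(summary)
            row["sample"] = rec.sample
            row["cancer_type"] = rec.cancer_type
            row["count"] = int(per_sample.get(rec.sample, 0))
            recs.append(row)
    if not recs:
        raise TabulationError("no region retained any sites")
    return pd.DataFrame(recs)
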