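"""Readers and writers for the standard genomic text formats used here.

FASTA via pyfaidx; BED / bedGraph / TSV via pandas.  All coordinates follow
the conventions in :mod:`mutrate.annotate` (1-based mutation positions,
0-based half-open intervals).
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from pyfaidx import Fasta

from .annotate import ContinuousTrack, ElementTrack, IntervalTrack, BinningScheme
from .glm import ModelSpec, Term

MUTATION_COLUMNS = ["chrom", "pos", "ref", "alt", "sample", "cancer_type"]


def read_fasta(path) -> dict[str, str]:
    with Fasta(str(path), as_raw=True, sequence_always_upper=True) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(path, reference: Mapping[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(reference):
            fh.write(f">{chrom}\n")
            seq = reference[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_mutations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str,
                                            "sample": str, "cancer_type": str})
    missing = set(MUTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"mutation table missing columns {sorted(missing)}")
    return df


def write_mutations(path, mutations: pd.DataFrame) -> None:
    mutations[MUTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_samples(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def write_samples(path, samples: pd.DataFrame) -> None:
    samples.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# tracks
# ---------------------------------------------------------------------------

def write_bedgraph(path, track: ContinuousTrack) -> None:
    """Run-length-collapsed bedGraph of a per-base track."""
    with open(path, "w") as fh:
        for chrom in sorted(track.values):
            v = np.asarray(track.values[chrom], dtype=float)
            if v.size == 0:
                continue
            change = np.nonzero(np.diff(v) != 0)[0]
            starts = np.concatenate([[0], change + 1])
            ends = np.concatenate([change + 1, [v.size]])
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\t{v[s]:.6g}\n")


def read_bedgraph(path, chrom_lengths: Mapping[str, int]) -> ContinuousTrack:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"],
                     dtype={"chrom": str})
    values = {c: np.full(n, np.nan) for c, n in chrom_lengths.items()}
    for rec in df.itertuples(index=False):
        if rec.chrom in values:
            values[rec.chrom][rec.start:rec.end] = rec.value
    return ContinuousTrack(values)


def write_bed(path, intervals: Sequence[tuple]) -> None:
    with open(path, "w") as fh:
        for t in sorted(intervals):
            fh.write("\t".join(str(x) for x in t) + "\n")


def read_bed(path, typed: bool = False):
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            if typed and len(parts) >= 4:
                rows.append((parts[0], int(parts[1]), int(parts[2]), parts[3]))
            else:
                rows.append((parts[0], int(parts[1]), int(parts[2])))
    return rows


# ---------------------------------------------------------------------------
# model specs and fits
# ---------------------------------------------------------------------------

def read_model_spec(path) -> ModelSpec:
    """Model YAML: outcome, intercept_scope, context, and a term list of
    ``{name, kind, per_cancer}`` mappings."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    terms = tuple(Term(t["name"], t.get("kind", "continuous"),
                       t.get("per_cancer", True), t.get("n_levels"))
                  for t in raw.get("terms", []))
    return ModelSpec(outcome=raw.get("outcome", "multinomial"),
                     intercept_scope=raw.get("intercept_scope", "per_sample"),
                     context=raw.get("context", True),
                     context_per_cancer=raw.get("context_per_cancer", True),
                     terms=terms)


def write_fit(prefix, fit) -> None:
    """Coefficient TSV plus a JSON with log-likelihood and convergence info."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    fit.coefficients.to_csv(f"{prefix}.coefficients.tsv", sep="\t", index=False)
    meta = {"kind": fit.kind, "method": getattr(fit, "method", ""),
            "loglik": fit.loglik, "converged": bool(fit.converged)}
    with open(f"{prefix}.meta.json", "w") as fh:
        json.dump(meta, fh, indent=2)


def read_track_config(path):
    """Track YAML: list of ``{name, kind, path, bins, zero_threshold}``."""
    with open(path) as fh:
        return yaml.safe_load(fh)
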