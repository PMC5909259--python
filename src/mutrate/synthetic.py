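"""Synthetic genomes, annotation tracks and mutations under a known model.

Everything downstream (annotation, tabulation, fitting, selection,
evaluation) is testable against ground truth generated here: a reference
sequence with a chosen GC fraction, kilobase-scale smooth covariates
(replication-timing/expression-like), per-base covariates (conservation-like),
interval dummies (CpG-island/repeat-like), a six-label element partition, and
mutations drawn site-by-site from the strand-symmetric multinomial logistic
model with sample intercepts and cancer-type-stratified coefficients.

The generative logits use the *binned* covariate representatives — the same
values the downstream regression sees — so the fitted model family contains
the truth and parameter recovery can be checked exactly up to sampling noise.
All randomness derives from ``SyntheticConfig.seed``; a fixed seed fixes every
byte of output.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import annotate
from .annotate import (BASES, COMPLEMENT, ELEMENT_TYPES, MUTATION_TYPES,
                       BinningScheme, ContinuousTrack, ElementTrack,
                       IntervalTrack, PYRIMIDINES)
from .glm import BLOCK_OUTCOMES

logger = logging.getLogger(__name__)

_TYPE_IDX = {t: i for i, t in enumerate(MUTATION_TYPES)}


class ConfigurationError(ValueError):
    pass


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class TrackSpec:
    """Recipe for one synthetic annotation track.

    ``kind`` is one of ``continuous-smooth`` (moving average of white noise,
    varying on the kilobase scale set by ``window``), ``continuous-sitewise``
    (iid per base), ``interval-dummy`` (non-overlapping intervals covering
    roughly ``fraction`` of the genome) or ``element-partition`` (consecutive
    blocks labelled with the six genomic element types).  ``bounds`` rescales
    a smooth track to a fixed range, e.g. (0, 1) for replication timing.
    """

    name: str
    kind: str
    window: int = 10_000
    scale: float = 1.0
    bounds: tuple[float, float] | None = None
    fraction: float = 0.05
    mean_length: int = 1000
    proportions: tuple[float, ...] | None = None


def default_track_specs() -> tuple[TrackSpec, ...]:
    return (
        TrackSpec("replication_timing", "continuous-smooth", window=10_000,
                  bounds=(0.0, 1.0)),
        TrackSpec("expression", "continuous-smooth", window=10_000,
                  bounds=(0.0, 8.0)),
        TrackSpec("conservation", "continuous-sitewise", scale=1.0),
        TrackSpec("cpg_island", "interval-dummy", fraction=0.02, mean_length=500),
        TrackSpec("simple_repeat", "interval-dummy", fraction=0.05, mean_length=300),
        TrackSpec("element", "element-partition", mean_length=2000,
                  proportions=(0.05, 0.01, 0.02, 0.07, 0.35, 0.50)),
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of a synthetic dataset.

    Defaults give a 200 kb single-chromosome genome, 3 cancer types with 17
    samples each and a per-type baseline mutation probability of 1e-3 per
    site and sample — a desk-scale analogue of whole-genome cohorts (the
    real-data per-site rate would leave almost no mutations at this genome
    size).
    """

    genome_length: int = 200_000
    n_chromosomes: int = 1
    n_cancer_types: int = 3
    samples_per_cancer_type: int = 17
    seed: int = 0
    gc_fraction: float = 0.41
    track_specs: tuple[TrackSpec, ...] = field(default_factory=default_track_specs)
    base_rate: float = 1e-3

    def __post_init__(self):
        if self.genome_length < 1:
            raise ConfigurationError("genome_length must be positive")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ConfigurationError("gc_fraction must be in [0, 1]")
        if self.n_chromosomes < 1 or self.n_cancer_types < 1 \
                or self.samples_per_cancer_type < 1:
            raise ConfigurationError("counts must be positive")
        if not 0.0 < self.base_rate < 1.0 / 3.0:
            raise ConfigurationError("base_rate must be in (0, 1/3)")


@dataclass
class TrueModel:
    """Generative parameters on the log-odds scale (vs. the no-mutation reference).

    ``sample_intercepts``: one row per sample, one column per mutation type.
    ``context_effects``: MultiIndex (cancer_type, context) where context is the
    left+right neighbor pair on the pyrimidine strand; the reference level
    ``"AA"`` must be 0 (treatment coding, matching the fitted design).
    ``covariate_effects``: MultiIndex (cancer_type, variable).  A ``-inf``
    sample intercept is the zero-rate sentinel.
    """

    sample_intercepts: pd.DataFrame
    context_effects: pd.DataFrame | None = None
    covariate_effects: pd.DataFrame | None = None

    def __post_init__(self):
        for df in (self.context_effects, self.covariate_effects):
            if df is not None and not np.isfinite(df.to_numpy(float)).all():
                raise ConfigurationError("non-finite coefficient in true model")

    def variables(self) -> tuple[str, ...]:
        if self.covariate_effects is None:
            return ()
        return tuple(self.covariate_effects.index.get_level_values(1).unique())

    def true_value(self, outcome: str, column: str) -> float:
        """Generative value of a fitted design coefficient (0 when unset)."""
        if column.startswith("mu["):
            return float(self.sample_intercepts.loc[column[3:-1], outcome])
        inner = column[2:-1].split("|")
        if inner[0] == "context":
            _, cancer, level = inner
            if self.context_effects is None:
                return 0.0
            try:
                return float(self.context_effects.loc[(cancer, level), outcome])
            except KeyError:
                return 0.0
        name, cancer = inner
        if self.covariate_effects is None:
            return 0.0
        try:
            return float(self.covariate_effects.loc[(cancer, name), outcome])
        except KeyError:
            return 0.0


# ---------------------------------------------------------------------------
# reference and tracks
# ---------------------------------------------------------------------------

def simulate_reference(config: SyntheticConfig) -> dict[str, str]:
    """IID reference sequence with expected G:C fraction ``config.gc_fraction``."""
    gc = config.gc_fraction
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    byte_lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    reference = {}
    for i in range(config.n_chromosomes):
        rng = np.random.default_rng([config.seed, 0, i])
        codes = rng.choice(4, size=config.genome_length, p=p)
        reference[f"chr{i + 1}"] = byte_lut[codes].tobytes().decode("ascii")
    return reference


def _smooth_noise(rng, length: int, window: int) -> np.ndarray:
    noise = rng.standard_normal(length + window)
    cum = np.concatenate([[0.0], np.cumsum(noise)])
    return (cum[window:length + window] - cum[:length]) / window


def _random_intervals(rng, length: int, fraction: float, mean_length: int):
    n = max(1, int(round(fraction * length / mean_length)))
    starts = np.sort(rng.choice(max(1, length - mean_length), size=n, replace=False))
    out = []
    prev_end = -1
    for s in starts:
        if s >= prev_end:
            e = min(int(s) + mean_length, length)
            out.append((int(s), e))
            prev_end = e
    return out


def simulate_tracks(config: SyntheticConfig, reference: Mapping[str, str]):
    """Annotation tracks per :class:`TrackSpec`; deterministic given the seed."""
    tracks: dict[str, object] = {}
    for t_idx, spec in enumerate(config.track_specs):
        if spec.kind == "continuous-smooth":
            values = {}
            for c_idx, chrom in enumerate(sorted(reference)):
                rng = np.random.default_rng([config.seed, 1, t_idx, c_idx])
                v = _smooth_noise(rng, len(reference[chrom]), spec.window)
                if spec.bounds is not None:
                    lo, hi = spec.bounds
                    vmin, vmax = v.min(), v.max()
                    v = lo + (hi - lo) * (v - vmin) / (vmax - vmin)
                else:
                    v = v * spec.scale
                values[chrom] = v
            tracks[spec.name] = ContinuousTrack(values)
        elif spec.kind == "continuous-sitewise":
            values = {}
            for c_idx, chrom in enumerate(sorted(reference)):
                rng = np.random.default_rng([config.seed, 1, t_idx, c_idx])
                values[chrom] = rng.standard_normal(len(reference[chrom])) * spec.scale
            tracks[spec.name] = ContinuousTrack(values)
        elif spec.kind == "interval-dummy":
            ivs = []
            for c_idx, chrom in enumerate(sorted(reference)):
                rng = np.random.default_rng([config.seed, 1, t_idx, c_idx])
                ivs.extend((chrom, s, e) for s, e in _random_intervals(
                    rng, len(reference[chrom]), spec.fraction, spec.mean_length))
            tracks[spec.name] = IntervalTrack(ivs)
        elif spec.kind == "element-partition":
            props = spec.proportions or tuple([1 / 6] * 6)
            ivs = []
            for c_idx, chrom in enumerate(sorted(reference)):
                rng = np.random.default_rng([config.seed, 1, t_idx, c_idx])
                length = len(reference[chrom])
                pos = 0
                while pos < length:
                    block = int(rng.geometric(1.0 / spec.mean_length))
                    label = ELEMENT_TYPES[rng.choice(6, p=np.asarray(props))]
                    end = min(pos + block, length)
                    if label != "intergenic":
                        ivs.append((chrom, pos, end, label))
                    pos = end
            tracks[spec.name] = ElementTrack(ivs)
        else:
            raise ConfigurationError(f"unknown track kind {spec.kind!r}")
    return tracks


def default_schemes(tracks: Mapping[str, object]) -> dict[str, BinningScheme]:
    """Quantile binning for the continuous tracks: quintiles everywhere, except
    quartiles with the <10% zero rule for GC content."""
    schemes = {}
    for name, track in tracks.items():
        if not isinstance(track, ContinuousTrack):
            continue
        values = np.concatenate([np.asarray(v, float)
                                 for v in track.values.values()])
        if name == "gc":
            schemes[name] = annotate.fit_binning(
                values, 4, special_zero_threshold=0.10, name=name)
        else:
            schemes[name] = annotate.fit_binning(values, 5, name=name)
    return schemes


# ---------------------------------------------------------------------------
# samples and the generative model
# ---------------------------------------------------------------------------

def make_samples(config: SyntheticConfig) -> pd.DataFrame:
    rows = [(f"C{c + 1}_s{s + 1:02d}", f"C{c + 1}")
            for c in range(config.n_cancer_types)
            for s in range(config.samples_per_cancer_type)]
    return pd.DataFrame(rows, columns=["sample", "cancer_type"])


def default_true_model(config: SyntheticConfig, samples: pd.DataFrame,
                       rng: np.random.Generator | None = None,
                       covariates: Sequence[str] = ("conservation",
                                                    "replication_timing"),
                       ) -> TrueModel:
    """Study-condition generative model.

    Baseline per-type log-odds from ``config.base_rate``; a transition bias
    (C>T, T>C elevated); cancer-type shifts (SD 0.3) and sample-level rate
    spread (SD 0.5, shared across types); neighbor-context effects (SD 0.3)
    with a CpG C>T deamination boost (+1); conservation effect -0.4 and
    replication-timing effect +0.8 on every type (late-replicating, less
    conserved sites mutate more), jittered per cancer type (SD 0.1).
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 3])
    base = np.log(config.base_rate / (1.0 - 3.0 * config.base_rate))
    type_bias = pd.Series([0.0, 0.0, 0.7, 0.0, 0.3, 0.0], index=MUTATION_TYPES)
    cancers = sorted(samples["cancer_type"].unique())
    cancer_shift = pd.DataFrame(rng.normal(0.0, 0.3, (len(cancers), 6)),
                                index=cancers, columns=MUTATION_TYPES)
    mu = pd.DataFrame(index=samples["sample"], columns=MUTATION_TYPES, dtype=float)
    for rec in samples.itertuples(index=False):
        shift = rng.normal(0.0, 0.5)
        mu.loc[rec.sample] = (base + type_bias
                              + cancer_shift.loc[rec.cancer_type] + shift)
    contexts = [l + r for l in BASES for r in BASES]
    ctx_rows = []
    for can in cancers:
        for ctx in contexts:
            if ctx == "AA":  # treatment-coding reference level
                eff = np.zeros(6)
            else:
                eff = rng.normal(0.0, 0.3, 6)
                if ctx[1] == "G":  # CpG deamination boost on C>T
                    eff[_TYPE_IDX["C>T"]] += 1.0
            ctx_rows.append((can, ctx, *eff))
    context_effects = pd.DataFrame(
        ctx_rows, columns=["cancer_type", "context", *MUTATION_TYPES]
    ).set_index(["cancer_type", "context"])
    base_beta = {"conservation": -0.4, "replication_timing": 0.8,
                 "expression": -0.15, "gc": 0.3}
    cov_rows = []
    for can in cancers:
        for var in covariates:
            eff = base_beta.get(var, 0.0) + rng.normal(0.0, 0.1, 6)
            cov_rows.append((can, var, *eff))
    covariate_effects = pd.DataFrame(
        cov_rows, columns=["cancer_type", "variable", *MUTATION_TYPES]
    ).set_index(["cancer_type", "variable"]) if cov_rows else None
    return TrueModel(mu, context_effects, covariate_effects)


# ---------------------------------------------------------------------------
# mutation sampling
# ---------------------------------------------------------------------------

def _site_base_logits(sites: pd.DataFrame, true_model: TrueModel,
                      cancers: Sequence[str]):
    """Per-cancer, per-strand-block covariate+context logits (n_block x 3)."""
    strand = sites["strand_class"].astype(str).to_numpy()
    ctx = sites["left"].astype(str).to_numpy() + sites["right"].astype(str).to_numpy()
    contexts = sorted({l + r for l in BASES for r in BASES})
    ctx_code = pd.Categorical(ctx, categories=contexts).codes
    out = {}
    for block in ("C", "T"):
        rows = np.nonzero(strand == block)[0]
        type_cols = [_TYPE_IDX[t] for t in BLOCK_OUTCOMES[block]]
        per_cancer = {}
        for can in cancers:
            eta = np.zeros((rows.size, 3))
            if true_model.context_effects is not None:
                lut = np.zeros((len(contexts), 3))
                for i, c in enumerate(contexts):
                    try:
                        row = true_model.context_effects.loc[(can, c)]
                        lut[i] = row.to_numpy(float)[type_cols]
                    except KeyError:
                        pass
                eta += lut[ctx_code[rows]]
            if true_model.covariate_effects is not None:
                for (c2, var), row in true_model.covariate_effects.iterrows():
                    if c2 != can:
                        continue
                    x = sites[var].to_numpy(float)[rows]
                    eta += np.outer(x, row.to_numpy(float)[type_cols])
            if np.isposinf(eta).any():
                bad = int(rows[np.isposinf(eta).any(axis=1)][0])
                raise SimulationError(
                    f"overflowing logit at site index {bad}")
            per_cancer[can] = eta
        out[block] = (rows, per_cancer)
    return out


def simulate_mutations(reference: Mapping[str, str], tracks, true_model: TrueModel,
                       config: SyntheticConfig, *, samples: pd.DataFrame | None = None,
                       sites: pd.DataFrame | None = None,
                       schemes: Mapping[str, BinningScheme] | None = None,
                       rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw mutation records from the multinomial model, site by site and
    sample by sample.

    For each site the outcome is drawn from the softmax of the three type
    logits against the no-mutation reference; the strand class follows the
    pyrimidine base; only mutated outcomes are emitted.  Returns a
    mutation-record frame with 1-based positions and reference-strand
    ref/alt bases.
    """
    if samples is None:
        samples = make_samples(config)
    if sites is None:
        if schemes is None:
            schemes = default_schemes(tracks)
        sites = annotate.build_site_table(reference, tracks, schemes)
    if rng is None:
        rng = np.random.default_rng([config.seed, 2])
    cancers = sorted(samples["cancer_type"].unique())
    base = _site_base_logits(sites, true_model, cancers)
    chrom_arr = sites["chrom"].astype(str).to_numpy()
    pos_arr = sites["pos"].to_numpy()
    recs = []
    for rec in samples.itertuples(index=False):
        mu_row = true_model.sample_intercepts.loc[rec.sample]
        for block in ("C", "T"):
            rows, per_cancer = base[block]
            if rows.size == 0:
                continue
            mu = mu_row.to_numpy(float)[[_TYPE_IDX[t]
                                         for t in BLOCK_OUTCOMES[block]]]
            with np.errstate(invalid="ignore"):
                eta = per_cancer[rec.cancer_type] + mu
            m = np.maximum(eta.max(axis=1), 0.0)
            with np.errstate(invalid="ignore"):
                z = np.exp(-m) + np.exp(eta - m[:, None]).sum(axis=1)
            p = np.exp(eta - (np.log(z) + m)[:, None])
            if np.isnan(p).any():
                bad = int(rows[np.isnan(p).any(axis=1)][0])
                raise SimulationError(
                    f"mutation probabilities fail to normalize at site {bad}")
            u = rng.random(rows.size)
            cum = np.cumsum(p, axis=1)
            k = (u[:, None] >= cum).sum(axis=1)  # 0..2 types, 3 = no mutation
            hit = np.nonzero(k < 3)[0]
            for h in hit:
                site_row = rows[h]
                chrom = chrom_arr[site_row]
                pos0 = int(pos_arr[site_row])
                seq_base = reference[chrom][pos0].upper()
                mut_type = BLOCK_OUTCOMES[block][k[h]]
                alt_pyr = mut_type[-1]
                alt = alt_pyr if seq_base in PYRIMIDINES else COMPLEMENT[alt_pyr]
                recs.append((chrom, pos0 + 1, seq_base, alt,
                             rec.sample, rec.cancer_type))
    out = pd.DataFrame(recs, columns=["chrom", "pos", "ref", "alt",
                                      "sample", "cancer_type"])
    return out.sort_values(["chrom", "pos", "sample"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# one-shot dataset
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """Everything one simulated study produces, with ground truth attached."""

    config: SyntheticConfig
    reference: dict[str, str]
    tracks: dict[str, object]
    schemes: dict[str, BinningScheme]
    sites: pd.DataFrame
    samples: pd.DataFrame
    mutations: pd.DataFrame
    true_model: TrueModel

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.reference.items()}

    def annotated_mutations(self) -> pd.DataFrame:
        return annotate.annotate_mutations(self.mutations, self.reference)


def synthesize(config: SyntheticConfig,
               true_model: TrueModel | None = None,
               with_gc: bool = True) -> SyntheticDataset:
    """Generate a full dataset: reference, tracks (plus a GC-content track
    computed from the reference), binned site covariates, samples, generative
    model and mutation records."""
    reference = simulate_reference(config)
    tracks = simulate_tracks(config, reference)
    n_gc_windows = sum(int(np.ceil(len(s) / 1000)) for s in reference.values())
    if with_gc and n_gc_windows >= 8:
        tracks["gc"] = annotate.gc_track(reference)
    elif with_gc:
        logger.info("genome too short for GC quartile binning; GC track skipped")
    schemes = default_schemes(tracks)
    sites = annotate.build_site_table(reference, tracks, schemes)
    samples = make_samples(config)
    if true_model is None:
        true_model = default_true_model(config, samples)
    mutations = simulate_mutations(reference, tracks, true_model, config,
                                   samples=samples, sites=sites, schemes=schemes)
    return SyntheticDataset(config, reference, tracks, schemes, sites, samples,
                            mutations, true_model)
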