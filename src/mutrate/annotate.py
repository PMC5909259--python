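"""Per-site covariate construction.

Turns raw genomic inputs (reference sequence, continuous tracks, interval
annotations, expression tables) into the per-site covariates used by the
regression models: strand-collapsed trinucleotide context, quantile-binned
continuous annotations, 0/1 dummies, genomic element labels and masking.

Coordinate conventions (followed bit-exactly throughout the package):

* mutation positions are 1-based (VCF convention);
* all intervals are 0-based half-open (BED convention);
* internal site indices are 0-based.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")
_CODE = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
PYRIMIDINES = frozenset("CT")

#: the six strand-symmetric substitution classes, reported on the pyrimidine strand
MUTATION_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: genomic element labels in decreasing precedence (used for overlapping annotations)
ELEMENT_TYPES = ("coding", "5utr", "3utr", "ncRNA", "intron", "intergenic")


class AnnotationError(ValueError):
    """Raised for invalid bases, malformed intervals or degenerate binning input."""


# ---------------------------------------------------------------------------
# strand collapsing
# ---------------------------------------------------------------------------

def collapse_strand(ref: str, left: str, right: str, alt: str | None = None):
    """Collapse a site (and optionally a substitution) onto the pyrimidine strand.

    Sites are reported on the strand carrying the C or T nucleotide, so e.g.
    A[G>A]T becomes A[C>T]T and an A>C substitution becomes T>G.

    Returns ``(strand_class, left', right', mutation_type)`` where
    ``strand_class`` is ``"C"`` or ``"T"``, the neighbors are the 5' and 3'
    bases on the pyrimidine strand and ``mutation_type`` is one of the six
    strand-symmetric classes (or ``None`` when no ``alt`` is given).
    """
    for b in (ref, left, right):
        if b not in _CODE:
            raise AnnotationError(f"invalid base {b!r}")
    if alt is not None:
        if alt not in _CODE:
            raise AnnotationError(f"invalid base {alt!r}")
        if alt == ref:
            raise AnnotationError("alt equals ref")
    if ref in PYRIMIDINES:
        mut = f"{ref}>{alt}" if alt is not None else None
        return ref, left, right, mut
    rc_ref = COMPLEMENT[ref]
    mut = f"{rc_ref}>{COMPLEMENT[alt]}" if alt is not None else None
    return rc_ref, COMPLEMENT[right], COMPLEMENT[left], mut


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes A,C,G,T -> 0..3; other letters -> 255."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 255, dtype=np.uint8)
    for base, code in _CODE.items():
        out[arr == ord(base)] = code
    return out


def collapse_strand_codes(ref_c: np.ndarray, left_c: np.ndarray, right_c: np.ndarray):
    """Vectorized :func:`collapse_strand` on base codes (complement code = 3 - code)."""
    pyr = (ref_c == 1) | (ref_c == 3)
    strand = np.where(pyr, ref_c, 3 - ref_c)
    left = np.where(pyr, left_c, 3 - right_c)
    right = np.where(pyr, right_c, 3 - left_c)
    return strand.astype(np.uint8), left.astype(np.uint8), right.astype(np.uint8)


# ---------------------------------------------------------------------------
# quantile binning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BinningScheme:
    """Quantile discretization of a continuous annotation.

    ``boundaries`` are the interior cut points; bin *k* is the right-closed
    interval ``(b[k-1], b[k]]`` (values at a boundary go to the lower bin,
    values outside the range are clamped).  Each bin is represented by the
    mean value within the bin.  ``special_zero_threshold`` implements the
    GC-content rule: values strictly below the threshold map to an extra
    representative 0.
    """

    name: str
    boundaries: tuple[float, ...]
    representatives: tuple[float, ...]
    special_zero_threshold: float | None = None

    @property
    def n_bins(self) -> int:
        return len(self.boundaries) + 1


def fit_binning(values, n_bins: int,
                special_zero_threshold: float | None = None,
                name: str = "") -> BinningScheme:
    """Fit a quantile :class:`BinningScheme` (quartiles ``n_bins=4``, quintiles 5)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if special_zero_threshold is not None:
        v = v[v >= special_zero_threshold]
    if v.size == 0 or np.unique(v).size < n_bins:
        raise AnnotationError(
            f"cannot fit {n_bins} bins for {name!r}: too few distinct values")
    qs = np.arange(1, n_bins) / n_bins
    boundaries = np.quantile(v, qs)
    if np.unique(boundaries).size < boundaries.size:
        raise AnnotationError(f"degenerate binning for {name!r}: tied quantiles")
    idx = np.searchsorted(boundaries, v, side="left")
    reps = np.empty(n_bins)
    for k in range(n_bins):
        member = v[idx == k]
        if member.size == 0:
            raise AnnotationError(f"empty bin {k} for {name!r}")
        reps[k] = member.mean()
    return BinningScheme(name=name, boundaries=tuple(boundaries),
                         representatives=tuple(reps),
                         special_zero_threshold=special_zero_threshold)


def apply_binning(scheme: BinningScheme, values):
    """Map values to their bin representatives (scalar or array)."""
    scalar = np.isscalar(values)
    v = np.atleast_1d(np.asarray(values, dtype=float))
    boundaries = np.asarray(scheme.boundaries)
    reps = np.asarray(scheme.representatives)
    idx = np.searchsorted(boundaries, v, side="left")
    out = reps[idx]
    if scheme.special_zero_threshold is not None:
        out = np.where(v < scheme.special_zero_threshold, 0.0, out)
    out = np.where(np.isnan(v), np.nan, out)
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# tracks
# ---------------------------------------------------------------------------

@dataclass
class ContinuousTrack:
    """A per-base continuous annotation, one float array per chromosome."""

    values: dict[str, np.ndarray]

    def per_base(self, chrom: str, length: int) -> np.ndarray:
        v = np.asarray(self.values[chrom], dtype=float)
        if v.shape[0] != length:
            raise AnnotationError(
                f"track length {v.shape[0]} != chromosome length {length}")
        return v


@dataclass
class IntervalTrack:
    """Half-open intervals ``(chrom, start, end[, score])``.

    Expanded per base as 0/1 (dummy) or as the interval score with 0 off-interval
    (DNase-peak style).
    """

    intervals: list[tuple]
    scored: bool = False

    def sorted_intervals(self, chrom: str):
        ivs = sorted(t for t in self.intervals if t[0] == chrom)
        return ivs

    def per_base(self, chrom: str, length: int) -> np.ndarray:
        out = np.zeros(length)
        for t in self.sorted_intervals(chrom):
            start, end = int(t[1]), int(t[2])
            if not 0 <= start < end:
                raise AnnotationError(f"malformed interval {t}")
            val = float(t[3]) if (self.scored and len(t) > 3) else 1.0
            out[start:min(end, length)] = val
        return out


@dataclass
class ElementTrack:
    """Typed genomic intervals ``(chrom, start, end, label)`` over the six element types."""

    intervals: list[tuple]

    def per_base(self, chrom: str, length: int) -> np.ndarray:
        """Label array resolving overlaps by precedence (coding highest)."""
        codes = np.full(length, ELEMENT_TYPES.index("intergenic"), dtype=np.int8)
        # paint from lowest to highest precedence so the highest wins
        for label in reversed(ELEMENT_TYPES[:-1]):
            code = ELEMENT_TYPES.index(label)
            for t in self.intervals:
                if t[0] != chrom or t[3] != label:
                    continue
                start, end = int(t[1]), int(t[2])
                if not 0 <= start < end:
                    raise AnnotationError(f"malformed interval {t}")
                codes[start:min(end, length)] = code
        return codes


def classify_element(position: int, typed_intervals: Iterable[tuple]) -> str:
    """Element label of a single position, resolving overlaps by precedence.

    ``typed_intervals`` holds ``(start, end, label)`` or ``(chrom, start, end, label)``
    half-open intervals; positions outside every interval are intergenic.
    """
    best = len(ELEMENT_TYPES) - 1  # intergenic
    for t in typed_intervals:
        if len(t) == 4:
            _, start, end, label = t
        else:
            start, end, label = t
        if label not in ELEMENT_TYPES:
            raise AnnotationError(f"unknown element label {label!r}")
        if int(start) <= position < int(end):
            best = min(best, ELEMENT_TYPES.index(label))
    return ELEMENT_TYPES[best]


# ---------------------------------------------------------------------------
# GC content
# ---------------------------------------------------------------------------

def gc_content_windows(seq: str, window: int = 1000) -> np.ndarray:
    """G:C fraction per non-overlapping window (last partial window uses its actual length)."""
    if window < 1:
        raise AnnotationError("window must be positive")
    codes = encode_sequence(seq)
    is_gc = ((codes == 1) | (codes == 2)).astype(float)
    valid = (codes != 255).astype(float)
    n_win = int(np.ceil(len(seq) / window))
    out = np.empty(n_win)
    for w in range(n_win):
        sl = slice(w * window, min((w + 1) * window, len(seq)))
        denom = valid[sl].sum()
        out[w] = is_gc[sl].sum() / denom if denom else np.nan
    return out


def gc_track(reference: Mapping[str, str], window: int = 1000) -> ContinuousTrack:
    """Per-base expansion of :func:`gc_content_windows` over every chromosome."""
    values = {}
    for chrom, seq in reference.items():
        per_window = gc_content_windows(seq, window)
        values[chrom] = np.repeat(per_window, window)[: len(seq)]
    return ContinuousTrack(values)


# ---------------------------------------------------------------------------
# interval arithmetic: flanked merging, masking
# ---------------------------------------------------------------------------

def merge_with_flanks(intervals: Sequence[tuple], flank: int, merge_distance: int,
                      chrom_lengths: Mapping[str, int] | None = None):
    """Extend each interval by ``flank`` on both sides, then merge intervals whose
    gap is strictly less than ``merge_distance`` (the exclusion-region rule)."""
    if flank < 0:
        raise AnnotationError("negative flank")
    by_chrom: dict[str, list[list[int]]] = {}
    for chrom, start, end in intervals:
        lo = max(0, int(start) - flank)
        hi = int(end) + flank
        if chrom_lengths is not None and chrom in chrom_lengths:
            hi = min(hi, chrom_lengths[chrom])
        by_chrom.setdefault(chrom, []).append([lo, hi])
    out = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom])
        merged = [ivs[0]]
        for lo, hi in ivs[1:]:
            if lo - merged[-1][1] < merge_distance:
                merged[-1][1] = max(merged[-1][1], hi)
            else:
                merged.append([lo, hi])
        out.extend((chrom, lo, hi) for lo, hi in merged)
    return out


def apply_masks(positions, intervals: Sequence[tuple]) -> np.ndarray:
    """Retain the 0-based positions covered by no exclusion interval.

    ``intervals`` holds half-open ``(start, end)`` pairs on the same chromosome.
    """
    pos = np.asarray(positions)
    if len(intervals) == 0:
        return pos
    keep = np.ones(pos.shape, dtype=bool)
    for start, end in intervals:
        keep &= ~((pos >= int(start)) & (pos < int(end)))
    return pos[keep]


def mask_array(length: int, intervals: Sequence[tuple]) -> np.ndarray:
    """Boolean exclusion array over ``[0, length)`` from ``(start, end)`` intervals."""
    excluded = np.zeros(length, dtype=bool)
    for t in intervals:
        start, end = (int(t[-2]), int(t[-1])) if len(t) == 3 else (int(t[0]), int(t[1]))
        excluded[max(0, start):min(end, length)] = True
    return excluded


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def expression_covariate(expression: pd.DataFrame, gene_intervals: Sequence[tuple],
                         cancer_type: str, chrom_lengths: Mapping[str, int]):
    """Per-site expression track and gene-body dummy for one cancer type.

    ``expression`` is a tidy table with columns ``gene``, ``cancer_type`` and
    ``expression`` (raw values; replicates allowed).  Per gene the median
    log2(x+1)-transformed value of the cancer type is used; a site covered by
    several genes gets the cumulative sum.  ``gene_intervals`` holds
    ``(chrom, start, end, gene)``; when a gene has multiple annotations the
    longest one is used.  Genes missing from the table raise a warning and
    contribute expression 0 (but still count as gene body).
    """
    sub = expression[expression["cancer_type"] == cancer_type]
    levels = (
        np.log2(sub["expression"].astype(float) + 1.0)
        .groupby(sub["gene"]).median()
    )
    # longest annotation per gene
    best: dict[str, tuple] = {}
    for chrom, start, end, gene in gene_intervals:
        cur = best.get(gene)
        if cur is None or (end - start) > (cur[2] - cur[1]):
            best[gene] = (chrom, int(start), int(end), gene)
    values = {c: np.zeros(n) for c, n in chrom_lengths.items()}
    body = []
    for chrom, start, end, gene in best.values():
        end = min(end, chrom_lengths[chrom])
        body.append((chrom, start, end))
        if gene in levels.index:
            values[chrom][start:end] += levels.loc[gene]
        else:
            warnings.warn(f"gene {gene!r} absent from expression table; "
                          "treated as expression 0 within its gene body")
    return ContinuousTrack(values), IntervalTrack(sorted(body))


# ---------------------------------------------------------------------------
# site table and mutation annotation
# ---------------------------------------------------------------------------

_STRAND_CAT = pd.CategoricalDtype(["C", "T"])
_BASE_CAT = pd.CategoricalDtype(list(BASES))


def build_site_table(reference: Mapping[str, str],
                     tracks: Mapping[str, object] | None = None,
                     schemes: Mapping[str, BinningScheme] | None = None,
                     mask_intervals: Sequence[tuple] | None = None) -> pd.DataFrame:
    """Assemble the per-site covariate table for the retained genome.

    One row per retained site with columns ``chrom``, ``pos`` (0-based),
    ``strand_class``, ``left``, ``right`` plus one column per track (binned
    representatives where a :class:`BinningScheme` is supplied, element labels
    for :class:`ElementTrack`, raw values otherwise).  Excluded are chromosome
    ends (no neighbor), non-ACGT bases, masked sites and sites with a missing
    continuous annotation.
    """
    tracks = tracks or {}
    schemes = schemes or {}
    frames = []
    for chrom in sorted(reference):
        seq = reference[chrom]
        length = len(seq)
        if length < 3:
            continue
        codes = encode_sequence(seq)
        keep = np.ones(length, dtype=bool)
        keep[0] = keep[-1] = False
        keep &= codes != 255
        keep[1:] &= codes[:-1] != 255
        keep[:-1] &= codes[1:] != 255
        if mask_intervals:
            ivs = [t for t in mask_intervals if len(t) != 3 or t[0] == chrom]
            keep &= ~mask_array(length, ivs)
        col_values = {}
        for name, track in tracks.items():
            arr = track.per_base(chrom, length)
            if isinstance(track, ElementTrack):
                col_values[name] = arr
            else:
                if name in schemes:
                    arr = apply_binning(schemes[name], arr)
                keep &= np.isfinite(np.asarray(arr, dtype=float))
                col_values[name] = arr
        pos = np.nonzero(keep)[0]
        strand, left, right = collapse_strand_codes(
            codes[pos], codes[pos - 1], codes[pos + 1])
        base_lookup = np.array(BASES)
        df = pd.DataFrame({
            "chrom": pd.Categorical([chrom] * len(pos)),
            "pos": pos,
            "strand_class": pd.Categorical(base_lookup[strand], dtype=_STRAND_CAT),
            "left": pd.Categorical(base_lookup[left], dtype=_BASE_CAT),
            "right": pd.Categorical(base_lookup[right], dtype=_BASE_CAT),
        })
        for name, arr in col_values.items():
            if isinstance(tracks[name], ElementTrack):
                df[name] = pd.Categorical(
                    np.asarray(ELEMENT_TYPES)[arr[pos].astype(int)],
                    categories=list(ELEMENT_TYPES))
            else:
                df[name] = np.asarray(arr, dtype=float)[pos]
        frames.append(df)
    if not frames:
        raise AnnotationError("no retained sites")
    out = pd.concat(frames, ignore_index=True)
    return out


def annotate_mutations(mutations: pd.DataFrame, reference: Mapping[str, str]) -> pd.DataFrame:
    """Validate mutation records against the reference and collapse them onto the
    pyrimidine strand.

    ``mutations`` needs columns ``chrom, pos`` (1-based), ``ref, alt, sample,
    cancer_type``.  Adds ``pos0``, ``strand_class``, ``left``, ``right`` and
    ``mutation_type``.  Records at chromosome ends (no trinucleotide context)
    are dropped with a log message.
    """
    rows = []
    n_dropped = 0
    for rec in mutations.itertuples(index=False):
        seq = reference[rec.chrom]
        pos0 = int(rec.pos) - 1
        if not 0 <= pos0 < len(seq):
            raise AnnotationError(f"position {rec.pos} outside {rec.chrom}")
        if seq[pos0].upper() != rec.ref:
            raise AnnotationError(
                f"ref mismatch at {rec.chrom}:{rec.pos}: expected "
                f"{seq[pos0].upper()}, record says {rec.ref}")
        if pos0 == 0 or pos0 == len(seq) - 1:
            n_dropped += 1
            continue
        left, right = seq[pos0 - 1].upper(), seq[pos0 + 1].upper()
        if any(b not in _CODE for b in (rec.ref, rec.alt, left, right)):
            n_dropped += 1
            continue
        strand, l, r, mut = collapse_strand(rec.ref, left, right, rec.alt)
        rows.append((rec.chrom, int(rec.pos), pos0, rec.ref, rec.alt,
                     rec.sample, rec.cancer_type, strand, l, r, mut))
    if n_dropped:
        logger.info("dropped %d mutations without full trinucleotide context", n_dropped)
    return pd.DataFrame(rows, columns=[
        "chrom", "pos", "pos0", "ref", "alt", "sample", "cancer_type",
        "strand_class", "left", "right", "mutation_type"])
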