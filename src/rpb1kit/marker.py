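"""Barcoding-marker evaluation on an aligned, species-labelled reference set.

Distances are Kimura two-parameter (K2P): transitions (P) and transversions
(Q) counted over comparable sites, with

    d = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)]

Columns where either sequence carries a gap or N are excluded pairwise
(pairwise deletion, not complete deletion: the reference mixes full-length
and shorter fragments).  Where the logarithm's argument is non-positive or
no comparable sites remain, the distance is undefined and reported as NaN;
downstream minima/maxima skip it rather than treating it as infinite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import RegionAnnotation, SeqRecord, TaxonomyLineage

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
#: purines (A, G) map to class 0, pyrimidines (C, T) to class 1
_CLASS = np.array([0, 1, 0, 1])


def encode(seq: str) -> np.ndarray:
    """Encode DNA into int8: A=0 C=1 G=2 T=3, gap/N/other = -1."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, code in _CODE.items():
        out[arr == ord(base)] = code
    return out


@dataclass
class ReferenceSet:
    """Aligned marker references with species labels and lineages."""

    records: list[SeqRecord]
    species: dict[str, str]
    lineages: dict[str, TaxonomyLineage] = field(default_factory=dict)
    isolates: dict[str, str] = field(default_factory=dict)
    annotation: RegionAnnotation | None = None

    def __post_init__(self):
        lengths = {len(r.seq) for r in self.records}
        if len(lengths) > 1:
            raise ValueError(f"reference sequences of unequal length: {sorted(lengths)}")
        for r in self.records:
            if r.id not in self.species:
                raise ValueError(f"reference {r.id!r} has no species label")
        if self.annotation is not None and self.records:
            if self.annotation.length != len(self.records[0].seq):
                raise ValueError(
                    "annotation length does not match alignment length"
                )

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def alignment_length(self) -> int:
        return len(self.records[0].seq) if self.records else 0

    def matrix(self) -> np.ndarray:
        return np.vstack([encode(r.seq) for r in self.records])

    def species_of(self, seq_id: str) -> str:
        return self.species[seq_id]


# ---------------------------------------------------------------------------
# K2P


def _k2p_from_counts(ts, tv, comp, min_sites=1):
    """Vectorised K2P from per-pair transition/transversion/site counts."""
    ts = np.asarray(ts, dtype=float)
    tv = np.asarray(tv, dtype=float)
    comp = np.asarray(comp, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        P = ts / comp
        Q = tv / comp
        w1 = 1.0 - 2.0 * P - Q
        w2 = 1.0 - 2.0 * Q
        d = -0.5 * np.log(w1 * np.sqrt(np.where(w2 > 0, w2, np.nan)))
    valid = (comp >= min_sites) & (w1 > 0) & (w2 > 0)
    return np.where(valid, d, np.nan)


def _pair_site_classes(a: np.ndarray, b: np.ndarray):
    """Boolean per-column masks: comparable, transition, transversion."""
    comp = (a >= 0) & (b >= 0)
    diff = comp & (a != b)
    same_class = _CLASS[np.where(a >= 0, a, 0)] == _CLASS[np.where(b >= 0, b, 0)]
    ts = diff & same_class
    tv = diff & ~same_class
    return comp, ts, tv


def k2p(seq_a: str, seq_b: str) -> float:
    """K2P distance between two aligned equal-length sequences (NaN if undefined)."""
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"k2p requires equal-length aligned sequences ({len(seq_a)} vs {len(seq_b)})"
        )
    a, b = encode(seq_a), encode(seq_b)
    comp, ts, tv = _pair_site_classes(a, b)
    return float(_k2p_from_counts(ts.sum(), tv.sum(), comp.sum()))


def p_distance(seq_a: str, seq_b: str) -> float:
    """Uncorrected proportion of differing comparable sites (NaN if none)."""
    a, b = encode(seq_a), encode(seq_b)
    comp = (a >= 0) & (b >= 0)
    n = comp.sum()
    if n == 0:
        return float("nan")
    return float(((a != b) & comp).sum() / n)


def pairwise_k2p(ref: ReferenceSet | list[SeqRecord]) -> pd.DataFrame:
    """Full symmetric K2P matrix; undefined entries are NaN, never dropped."""
    records = ref.records if isinstance(ref, ReferenceSet) else ref
    ids = [r.id for r in records]
    mat = np.vstack([encode(r.seq) for r in records])
    n = len(records)
    out = np.zeros((n, n))
    for i in range(n):
        ai = mat[i]
        comp, ts, tv = _pair_site_classes(ai[None, :], mat[i + 1 :])
        d = _k2p_from_counts(ts.sum(axis=1), tv.sum(axis=1), comp.sum(axis=1))
        out[i, i + 1 :] = d
        out[i + 1 :, i] = d
    return pd.DataFrame(out, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# Sliding windows


@dataclass(frozen=True)
class WindowProfile:
    start: int
    length: int
    mean_k2p: float  # NaN when no pair is defined in the window
    diagnostic_sum: int


def _window_sums(x: np.ndarray, window: int, step: int) -> np.ndarray:
    """Sliding-window sums along the last axis via cumulative sums."""
    c = np.cumsum(x, axis=-1, dtype=np.int64)
    c = np.concatenate([np.zeros(c.shape[:-1] + (1,), dtype=np.int64), c], axis=-1)
    L = x.shape[-1]
    starts = np.arange(0, L - window + 1, step)
    return c[..., starts + window] - c[..., starts]


def sliding_window_profile(
    ref: ReferenceSet, window: int = 50, step: int = 1, min_pair_sites: int = 10
) -> list[WindowProfile]:
    """Mean pairwise K2P and diagnostic-nucleotide sum per window.

    Pairs with fewer than ``min_pair_sites`` comparable columns inside a
    window are treated as undefined for that window.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    L = ref.alignment_length
    if window > L:
        raise ValueError(f"window {window} exceeds alignment length {L}")
    mat = ref.matrix()
    n = len(ref.records)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    comp = np.empty((len(pairs), L), dtype=bool)
    ts = np.empty_like(comp)
    tv = np.empty_like(comp)
    for k, (i, j) in enumerate(pairs):
        comp[k], ts[k], tv[k] = _pair_site_classes(mat[i], mat[j])

    comp_w = _window_sums(comp, window, step)
    ts_w = _window_sums(ts, window, step)
    tv_w = _window_sums(tv, window, step)
    d = _k2p_from_counts(ts_w, tv_w, comp_w, min_sites=min_pair_sites)
    with np.errstate(invalid="ignore"):
        mean_k2p = np.nanmean(d, axis=0) if len(pairs) else np.full(comp_w.shape[-1], np.nan)

    diag_col = _diagnostic_columns(ref)
    diag_w = _window_sums(diag_col[None, :], window, step)[0]

    starts = range(0, L - window + 1, step)
    return [
        WindowProfile(s, window, float(mean_k2p[k]), int(diag_w[k]))
        for k, s in enumerate(starts)
    ]


def _diagnostic_columns(ref: ReferenceSet) -> np.ndarray:
    """Per-column count of species for which the column is diagnostic.

    A column is diagnostic for species S iff every member of S carries the
    same unambiguous base there and no non-member carries that base.
    """
    mat = ref.matrix()
    species_labels = [ref.species[r.id] for r in ref.records]
    uniq = sorted(set(species_labels))
    if len(uniq) < 2:
        return np.zeros(mat.shape[1], dtype=np.int64)
    counts = np.zeros(mat.shape[1], dtype=np.int64)
    for sp in uniq:
        members = np.array([s == sp for s in species_labels])
        sub = mat[members]
        rest = mat[~members]
        fixed = (sub[0] >= 0) & (sub == sub[0]).all(axis=0)
        shared_base = sub[0]
        present_elsewhere = (rest == shared_base[None, :]).any(axis=0)
        counts += (fixed & ~present_elsewhere).astype(np.int64)
    return counts


def diagnostic_nucleotides(
    ref: ReferenceSet, window: int = 50, step: int = 1
) -> list[tuple[int, int]]:
    """Per-window (start, sum of diagnostic nucleotides over species)."""
    if len(set(ref.species.values())) < 2:
        pass  # single-species sets yield all-zero sums, not an error
    diag = _diagnostic_columns(ref)
    L = ref.alignment_length
    w = _window_sums(diag[None, :], window, step)[0]
    return [(s, int(w[k])) for k, s in enumerate(range(0, L - window + 1, step))]


# ---------------------------------------------------------------------------
# Barcode gap


@dataclass(frozen=True)
class BarcodeGapRecord:
    seq_id: str
    species: str
    max_intraspecific: float  # 0.0 for single-sequence species
    min_interspecific: float  # NaN when no interspecific distance defined
    flagged: bool  # True when all interspecific distances undefined

    @property
    def gap(self) -> float:
        return self.min_interspecific - self.max_intraspecific


def barcode_gap(
    dm: pd.DataFrame, species: dict[str, str]
) -> list[BarcodeGapRecord]:
    """Per sequence: max distance to conspecifics, min to heterospecifics.

    Undefined (NaN) distances are excluded from both extrema.  Sequences for
    which every interspecific distance is undefined are flagged and excluded
    from threshold derivation downstream.
    """
    ids = list(dm.index)
    labels = np.array([species[i] for i in ids])
    if len(set(labels)) < 2:
        raise ValueError("barcode gap needs at least two species")
    d = dm.values
    out = []
    for i, sid in enumerate(ids):
        same = (labels == labels[i]) & (np.arange(len(ids)) != i)
        other = labels != labels[i]
        intra = d[i, same]
        inter = d[i, other]
        intra = intra[~np.isnan(intra)]
        inter = inter[~np.isnan(inter)]
        max_intra = float(intra.max()) if intra.size else 0.0
        if inter.size:
            out.append(BarcodeGapRecord(sid, labels[i], max_intra, float(inter.min()), False))
        else:
            out.append(BarcodeGapRecord(sid, labels[i], max_intra, float("nan"), True))
    return out


@dataclass(frozen=True)
class ThresholdWarning:
    message: str
    max_intraspecific: float
    threshold: float


def derive_otu_threshold(
    records: list[BarcodeGapRecord],
    excluded_taxa: set[str] | frozenset[str] = frozenset(),
    resolution: float = 0.001,
) -> tuple[float, ThresholdWarning | None]:
    """OTU distance threshold from the barcode gap.

    The minimum gap over non-excluded, non-flagged records is floored to
    ``resolution`` and one resolution step is subtracted (a 0.9 % minimum
    gap yields a 0.8 % threshold).  If the result falls below the largest
    intraspecific distance among the same records, a warning is returned
    alongside rather than silently accepting an over-splitting threshold.
    """
    usable = [r for r in records if not r.flagged and r.species not in excluded_taxa]
    if not usable:
        raise ValueError("no usable barcode-gap records after exclusions")
    min_gap = min(r.gap for r in usable)
    if not math.isfinite(min_gap) or min_gap <= resolution:
        raise ValueError(
            f"no usable barcode gap: minimum gap {min_gap!r} <= resolution {resolution}"
        )
    steps = math.floor(min_gap / resolution + 1e-9)
    threshold = round((steps - 1) * resolution, 12)
    max_intra = max(r.max_intraspecific for r in usable)
    warning = None
    if threshold < max_intra:
        warning = ThresholdWarning(
            f"derived threshold {threshold} is below the maximum intraspecific "
            f"distance {max_intra:.4f}; conspecific sequences may split",
            max_intra,
            threshold,
        )
    return threshold, warning


def barcode_gap_table(records: list[BarcodeGapRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.seq_id, r.species, r.max_intraspecific, r.min_interspecific, r.gap, r.flagged)
            for r in records
        ],
        columns=["seq_id", "species", "max_intraspecific", "min_interspecific", "gap", "flagged"],
    )
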