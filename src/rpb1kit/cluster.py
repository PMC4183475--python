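"""Deterministic greedy abundance-sorted centroid clustering.

The same engine serves both the 99.7 % pre-clustering step and OTU picking
at the barcode-gap-derived distance threshold; only the distance metric and
the threshold differ.  Determinism: input sequences are processed in
descending abundance, ties broken by longer sequence first, then
lexicographic id — re-running on the same input reproduces the same
clusters byte for byte.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable

import math

import numpy as np

from ._align import glocal_identity, k2p_unaligned
from .marker import encode


class _TetramerIndex:
    """Candidate prescreen by cosine similarity of 4-mer count vectors.

    Scoring is a single matrix-vector product against all current
    centroids, so the cost per query stays flat as centroids accumulate;
    ties are broken by insertion order (stable sort) for determinism.
    """

    DIM = 256

    def __init__(self, capacity: int = 1024):
        self._mat = np.zeros((capacity, self.DIM), dtype=np.float32)
        self.n = 0

    @classmethod
    def vector(cls, seq: str) -> np.ndarray:
        c = encode(seq).astype(np.int64)
        if c.size < 4:
            return np.zeros(cls.DIM, dtype=np.float32)
        idx = c[:-3] * 64 + c[1:-2] * 16 + c[2:-1] * 4 + c[3:]
        ok = (c[:-3] >= 0) & (c[1:-2] >= 0) & (c[2:-1] >= 0) & (c[3:] >= 0)
        v = np.bincount(idx[ok], minlength=cls.DIM).astype(np.float32)
        norm = np.linalg.norm(v)
        return v / norm if norm > 0 else v

    def add(self, seq: str) -> int:
        if self.n == self._mat.shape[0]:
            self._mat = np.vstack([self._mat, np.zeros_like(self._mat)])
        self._mat[self.n] = self.vector(seq)
        self.n += 1
        return self.n - 1

    def candidates(self, seq: str, top: int = 16) -> list[int]:
        if self.n == 0:
            return []
        scores = self._mat[: self.n] @ self.vector(seq)
        order = np.argsort(-scores, kind="stable")[:top]
        return [int(i) for i in order if scores[i] > 0]


@dataclass
class Cluster:
    """A centroid with its members and per-sample abundance.

    ``longest_seq`` is the longest member sequence (within the clustering
    threshold of the centroid by construction); greedy clustering visits
    abundant-but-short sequences first, so the centroid itself often
    truncates information that longer members still carry.
    """

    centroid_id: str
    centroid_seq: str
    member_ids: list[str] = field(default_factory=list)
    sample_counts: Counter = field(default_factory=Counter)
    longest_seq: str = ""

    def __post_init__(self):
        if not self.longest_seq:
            self.longest_seq = self.centroid_seq

    @property
    def total(self) -> int:
        return sum(self.sample_counts.values())


def identity_distance(a: str, b: str) -> float:
    """1 - glocal identity of the shorter sequence aligned into the longer."""
    if len(a) > len(b):
        a, b = b, a
    return 1.0 - glocal_identity(a, b)


def k2p_distance(a: str, b: str) -> float:
    return k2p_unaligned(a, b)


@dataclass(frozen=True)
class SeqItem:
    """A unique sequence with aggregated per-sample abundance.

    ``read_ids`` lists every read carrying the sequence, so cluster
    membership stays traceable to individual reads.
    """

    seq_id: str
    seq: str
    sample_counts: tuple[tuple[str, int], ...]
    read_ids: tuple[str, ...] = ()

    @property
    def total(self) -> int:
        return sum(c for _, c in self.sample_counts)

    @property
    def members(self) -> tuple[str, ...]:
        return self.read_ids if self.read_ids else (self.seq_id,)


def aggregate_unique(
    entries: Iterable[tuple[str, str, str]]
) -> list[SeqItem]:
    """Collapse exact duplicate sequences.

    ``entries`` are (read_id, sample_id, seq); the id of the first read
    carrying a sequence (input order) names the unique sequence.
    """
    order: dict[str, int] = {}
    first_id: dict[str, str] = {}
    counts: dict[str, Counter] = {}
    readers: dict[str, list[str]] = {}
    for read_id, sample_id, seq in entries:
        if seq not in order:
            order[seq] = len(order)
            first_id[seq] = read_id
            counts[seq] = Counter()
            readers[seq] = []
        counts[seq][sample_id] += 1
        readers[seq].append(read_id)
    items = [
        SeqItem(first_id[seq], seq, tuple(sorted(counts[seq].items())), tuple(readers[seq]))
        for seq in order
    ]
    return items


def greedy_cluster(
    items: list[SeqItem],
    threshold: float,
    metric: Callable[[str, str], float] = identity_distance,
    prescreen_top: int = 16,
) -> list[Cluster]:
    """Greedy centroid clustering at the given distance threshold.

    Sequences are visited in descending abundance (ties: longer first, then
    id); each joins the first centroid, in k-mer-similarity order, within
    ``threshold`` distance, else founds a new centroid.  Abundance is
    conserved: the summed sample counts over clusters equal the input.
    """
    ordered = sorted(items, key=lambda it: (-it.total, -len(it.seq), it.seq_id))
    clusters: list[Cluster] = []
    index = _TetramerIndex()
    for it in ordered:
        placed = None
        for ci in index.candidates(it.seq, top=prescreen_top):
            d = metric(it.seq, clusters[ci].centroid_seq)
            if not math.isnan(d) and d <= threshold:
                placed = clusters[ci]
                break
        if placed is None:
            placed = Cluster(centroid_id=it.seq_id, centroid_seq=it.seq)
            clusters.append(placed)
            index.add(it.seq)
        placed.member_ids.extend(it.members)
        if len(it.seq) > len(placed.longest_seq):
            placed.longest_seq = it.seq
        for sample, c in it.sample_counts:
            placed.sample_counts[sample] += c
    return clusters
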