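"""The read filter cascade for barcoded protein-coding amplicons.

Stage order is fixed: demultiplex -> length/ambiguity -> alignment screen
-> pre-cluster -> de novo chimera detection -> homopolymer frame
correction.  Each stage's input count equals the previous stage's output
count; the funnel table records the accounting.

The chimera detector is a two-parent single-crossover scorer: for each
query centroid (ascending abundance) it seeks a pair of more abundant
centroids whose prefix+suffix explains the query almost perfectly while
neither parent alone does.  Frame correction exploits the coding exons:
single-base length discrepancies of reference homopolymer runs (length
>= 3) that shift the reading frame are repaired, and sequences whose exon
translation still frameshifts or contains a stop codon are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._align import (
    _align,
    glocal_identity,
    match_profile,
    parse_cigar,
)
from .cluster import Cluster, SeqItem, aggregate_unique, greedy_cluster, identity_distance
from .io import RegionAnnotation, SampleMap, SeqRecord, hamming
from .marker import ReferenceSet

STAGES = ("demux", "length", "ambiguity", "align-screen", "precluster", "chimera", "frame")

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class ProcessedRead:
    read_id: str
    sample_id: str | None
    seq: str  # trimmed (barcode/linker/primer removed)
    raw_length: int  # original read length including barcode and primer
    stages: dict[str, bool] = field(default_factory=dict)
    fail_stage: str | None = None
    best_ref: str | None = None
    best_identity: float = float("nan")

    def passed(self, stage: str) -> "ProcessedRead":
        self.stages[stage] = True
        return self

    def failed(self, stage: str) -> "ProcessedRead":
        self.stages[stage] = False
        self.fail_stage = stage
        return self


# ---------------------------------------------------------------------------
# Demultiplexing


def demultiplex(
    reads: list[SeqRecord],
    sample_map: SampleMap,
    primer: str,
    linker: str = "",
    max_barcode_mismatch: int = 1,
) -> tuple[list[ProcessedRead], list[ProcessedRead]]:
    """Assign reads to samples by barcode; trim barcode+linker+primer.

    Reads whose leading bases match no barcode within
    ``max_barcode_mismatch`` (or that are shorter than the prefix) go to the
    unassigned bin.  The >=4-mismatch barcode design guarantees a unique
    nearest barcode at one mismatch.
    """
    bc_len = sample_map.barcode_length
    prefix_len = bc_len + len(linker) + len(primer)
    assigned: list[ProcessedRead] = []
    unassigned: list[ProcessedRead] = []
    barcodes = [(s.sample_id, s.barcode) for s in sample_map]
    for rec in reads:
        if len(rec.seq) <= prefix_len:
            unassigned.append(
                ProcessedRead(rec.id, None, rec.seq, len(rec.seq)).failed("demux")
            )
            continue
        observed = rec.seq[:bc_len]
        best_sample, best_d = None, bc_len + 1
        for sid, bc in barcodes:
            d = hamming(observed, bc)
            if d < best_d:
                best_sample, best_d = sid, d
        if best_d <= max_barcode_mismatch:
            pr = ProcessedRead(
                rec.id, best_sample, rec.seq[prefix_len:], len(rec.seq)
            ).passed("demux")
            assigned.append(pr)
        else:
            unassigned.append(
                ProcessedRead(rec.id, None, rec.seq, len(rec.seq)).failed("demux")
            )
    return assigned, unassigned


# ---------------------------------------------------------------------------
# Length / ambiguity filter


def length_ambiguity_filter(
    reads: list[ProcessedRead],
    min_len: int = 200,
    include_prefix_in_length: bool = True,
) -> tuple[list[ProcessedRead], list[ProcessedRead]]:
    """Drop reads shorter than ``min_len`` or containing an ambiguous base.

    By default the length criterion applies to the raw read including
    barcode, linker and primer; set ``include_prefix_in_length=False`` to
    measure the trimmed sequence instead.
    """
    kept, removed = [], []
    for r in reads:
        length = r.raw_length if include_prefix_in_length else len(r.seq)
        if length < min_len:
            removed.append(r.failed("length"))
        elif "N" in r.seq:
            removed.append(r.failed("ambiguity"))
        else:
            kept.append(r.passed("length").passed("ambiguity"))
    return kept, removed


# ---------------------------------------------------------------------------
# 60 % alignment screen


def alignment_screen(
    reads: list[ProcessedRead],
    reference: ReferenceSet | list[SeqRecord],
    min_similarity: float = 0.60,
) -> tuple[list[ProcessedRead], list[ProcessedRead]]:
    """Keep reads aligning to some reference at >= ``min_similarity``.

    Each read is glocally aligned (free reference end gaps) against every
    ungapped reference; identity excludes terminal gaps.  The best-scoring
    reference is recorded for downstream frame correction.  Results are
    memoised per unique read sequence.
    """
    records = reference.records if isinstance(reference, ReferenceSet) else reference
    refs = [(r.id, r.ungapped) for r in records]
    if not refs:
        raise ValueError("alignment screen requires a non-empty reference set")
    cache: dict[str, tuple[str, float]] = {}
    kept, removed = [], []
    for r in reads:
        if r.seq not in cache:
            best_id, best_ident = None, -1.0
            for rid, rseq in refs:
                ident = glocal_identity(r.seq, rseq)
                if ident > best_ident:
                    best_id, best_ident = rid, ident
            cache[r.seq] = (best_id, best_ident)
        r.best_ref, r.best_identity = cache[r.seq]
        if r.best_identity >= min_similarity:
            kept.append(r.passed("align-screen"))
        else:
            removed.append(r.failed("align-screen"))
    return kept, removed


# ---------------------------------------------------------------------------
# Pre-clustering


def precluster(
    reads: list[ProcessedRead], similarity: float = 0.997
) -> list[Cluster]:
    """Greedy centroid clustering at ``1 - similarity`` distance.

    Exact duplicates are collapsed first; per-sample abundances are summed
    onto centroids and conserved overall.
    """
    items = aggregate_unique((r.read_id, r.sample_id, r.seq) for r in reads)
    return greedy_cluster(items, threshold=1.0 - similarity, metric=identity_distance)


# ---------------------------------------------------------------------------
# Chimera detection


@dataclass(frozen=True)
class ChimeraVerdict:
    centroid_id: str
    is_chimera: bool
    parent_a: str | None = None
    parent_b: str | None = None
    crossover: int | None = None  # query position where parents switch
    model_identity: float = float("nan")
    best_single_identity: float = float("nan")


def detect_chimeras(
    clusters: list[Cluster],
    skew: float = 2.0,
    min_model_identity: float = 0.99,
    min_margin: float = 0.01,
    min_parent_contrib: int = 30,
    min_diffs: int = 3,
    max_parents: int = 30,
    max_candidates: int = 30,
) -> dict[str, ChimeraVerdict]:
    """Flag centroids explained by a two-parent single crossover.

    Queries are visited in ascending abundance; candidate parents must be
    at least ``skew`` times more abundant than the query.  For each parent
    pair, scoring is restricted to the query span covered by both parents
    (reads vary widely in length, so an uncovered tail says nothing about
    chimerism).  A query is chimeric iff some crossover model reaches
    ``min_model_identity`` over that span, beats the better single parent
    by ``min_margin`` and by at least ``min_diffs`` crossover-supporting
    bases, and each parent contributes at least ``min_parent_contrib``
    bases.
    """
    order = sorted(range(len(clusters)), key=lambda i: (clusters[i].total, clusters[i].centroid_id))
    by_abundance = sorted(
        range(len(clusters)), key=lambda i: (-clusters[i].total, clusters[i].centroid_id)
    )
    verdicts: dict[str, ChimeraVerdict] = {}
    for qi in order:
        q = clusters[qi]
        L = len(q.centroid_seq)
        parents = [
            i for i in by_abundance
            if i != qi and clusters[i].total >= skew * q.total
        ][:max_candidates]
        if len(parents) < 2 or L < 2 * min_parent_contrib:
            verdicts[q.centroid_id] = ChimeraVerdict(q.centroid_id, False)
            continue
        profiles = []
        for pi in parents:
            prof, qs, qe = match_profile(q.centroid_seq, clusters[pi].longest_seq)
            pref = np.concatenate([[0], np.cumsum(prof)])
            profiles.append((pi, pref, qs, qe, int(prof.sum())))
        profiles.sort(key=lambda t: (-t[4], clusters[t[0]].centroid_id))
        profiles = profiles[:max_parents]

        best = None  # (qualifies, margin, model_id, pa, pb, crossover)
        for ai, (pa, pref_a, qsa, qea, _) in enumerate(profiles):
            for bi, (pb, pref_b, qsb, qeb, _) in enumerate(profiles):
                if ai == bi:
                    continue
                rs, re = max(qsa, qsb), min(qea, qeb)
                span = re - rs
                if span < 2 * min_parent_contrib:
                    continue
                lo, hi = rs + min_parent_contrib, re - min_parent_contrib
                left = pref_a[lo : hi + 1] - pref_a[rs]
                right = pref_b[re] - pref_b[lo : hi + 1]
                scores = left + right
                k = int(np.argmax(scores))
                single_m = max(pref_a[re] - pref_a[rs], pref_b[re] - pref_b[rs])
                model_id = scores[k] / span
                margin = (scores[k] - single_m) / span
                qualifies = (
                    model_id >= min_model_identity
                    and margin >= min_margin
                    and scores[k] - single_m >= min_diffs
                )
                cand = (qualifies, margin, model_id, pa, pb, lo + k)
                if best is None or cand[:3] > best[:3]:
                    best = cand
        if best is None:
            verdicts[q.centroid_id] = ChimeraVerdict(q.centroid_id, False)
            continue
        qualifies, margin, model_identity, pa, pb, crossover = best
        verdicts[q.centroid_id] = ChimeraVerdict(
            q.centroid_id,
            qualifies,
            clusters[pa].centroid_id,
            clusters[pb].centroid_id,
            crossover,
            model_identity,
            model_identity - margin,
        )
    return verdicts


def remove_chimeras(
    clusters: list[Cluster], verdicts: dict[str, ChimeraVerdict]
) -> tuple[list[Cluster], list[Cluster]]:
    kept = [c for c in clusters if not verdicts[c.centroid_id].is_chimera]
    flagged = [c for c in clusters if verdicts[c.centroid_id].is_chimera]
    return kept, flagged


# ---------------------------------------------------------------------------
# Homopolymer frame correction


@dataclass
class ReferenceFrames:
    """Per-reference ungapped exon/intron labels, codon phases and runs."""

    seqs: dict[str, str]
    labels: dict[str, np.ndarray]  # 1 = exon, 0 = intron, per ungapped position
    phases: dict[str, np.ndarray]  # codon phase per position (-1 outside exons)
    run_len: dict[str, np.ndarray]  # homopolymer run length at each position

    @classmethod
    def from_reference(cls, ref: ReferenceSet) -> "ReferenceFrames":
        if ref.annotation is None:
            raise ValueError("frame correction requires a region annotation")
        col_labels = ref.annotation.labels()
        col_phase = ref.annotation.codon_phase()
        seqs, labels, phases, runs = {}, {}, {}, {}
        for rec in ref.records:
            ung = []
            lab = []
            ph = []
            for col, base in enumerate(rec.seq):
                if base == "-":
                    continue
                ung.append(base)
                lab.append(1 if col_labels[col] == "exon" else 0)
                ph.append(col_phase.get(col, -1))
            seq = "".join(ung)
            seqs[rec.id] = seq
            labels[rec.id] = np.array(lab, dtype=np.int8)
            phases[rec.id] = np.array(ph, dtype=np.int8)
            runs[rec.id] = _run_lengths(seq)
        return cls(seqs, labels, phases, runs)


def _run_lengths(seq: str) -> np.ndarray:
    """Length of the homopolymer run covering each position."""
    n = len(seq)
    out = np.empty(n, dtype=np.int32)
    i = 0
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        out[i:j] = j - i
        i = j
    return out


@dataclass(frozen=True)
class FrameResult:
    centroid_id: str
    seq: str  # corrected sequence (equal to input when nothing was edited)
    status: str  # "ok" | "no-exon" | "frameshift" | "stop-codon"
    insertions: int = 0
    deletions: int = 0


def frame_correct(
    clusters: list[Cluster],
    best_ref: dict[str, str],
    frames: ReferenceFrames,
    min_run: int = 3,
    min_exon_overlap: int = 30,
) -> list[FrameResult]:
    """Repair single-base homopolymer indels in exons; validate translation.

    A read indel is corrected only when it is a single base, lies in an
    exon, and sits inside a reference homopolymer run of length >=
    ``min_run`` (the dominant pyrosequencing error mode).  Intron columns
    are never edited.  After correction the exon translation in the
    annotated frame must be stop-free and frame-consistent, else the
    sequence is discarded with a named status.
    """
    results = []
    for c in clusters:
        rid = best_ref.get(c.centroid_id)
        if rid is None:
            raise ValueError(f"centroid {c.centroid_id!r} has no screened reference")
        results.append(
            _frame_correct_one(
                c.centroid_id,
                c.centroid_seq,
                frames.seqs[rid],
                frames.labels[rid],
                frames.phases[rid],
                frames.run_len[rid],
                min_run,
                min_exon_overlap,
            )
        )
    return results


def _frame_correct_one(
    cid, seq, ref, labels, phases, run_len, min_run, min_exon_overlap
) -> FrameResult:
    res = _align(seq, ref, mode="HW")
    t0 = res["locations"][0][0]
    corrected: list[str] = []
    ins = dels = 0
    t, q = t0, 0
    for n, op in parse_cigar(res["cigar"]):
        if op in ("=", "X"):
            corrected.append(seq[q : q + n])
            q += n
            t += n
        elif op == "I":  # extra base(s) in the read
            base = seq[q : q + n]
            in_exon = labels[min(t, len(labels) - 1)] == 1 if t > 0 else labels[0] == 1
            in_run = False
            if n == 1:
                if t < len(ref) and ref[t] == base and run_len[t] >= min_run:
                    in_run = True
                elif t > 0 and ref[t - 1] == base and run_len[t - 1] >= min_run:
                    in_run = True
            if n == 1 and in_exon and in_run:
                dels += 1  # drop the surplus base
            else:
                corrected.append(base)
            q += n
        elif op == "D":  # base(s) missing from the read
            for j in range(n):
                pos = t + j
                if (
                    n == 1
                    and labels[pos] == 1
                    and run_len[pos] >= min_run
                ):
                    corrected.append(ref[pos])
                    ins += 1
            t += n
    fixed = "".join(corrected)

    # Validate: realign and inspect the exon portion.
    res2 = _align(fixed, ref, mode="HW")
    t = res2["locations"][0][0]
    q = 0
    exon_pairs: list[tuple[int, str]] = []  # (ref position, read base or '-')
    exon_indel = 0
    for n, op in parse_cigar(res2["cigar"]):
        if op in ("=", "X"):
            for j in range(n):
                if labels[t + j] == 1:
                    exon_pairs.append((t + j, fixed[q + j]))
            q += n
            t += n
        elif op == "I":
            boundary = min(t, len(labels) - 1)
            if labels[boundary] == 1:
                exon_indel += n
            q += n
        elif op == "D":
            for j in range(n):
                if labels[t + j] == 1:
                    exon_pairs.append((t + j, "-"))
                    exon_indel += 1
            t += n

    aligned_exon = [p for p in exon_pairs if p[1] != "-"]
    if len(aligned_exon) < min_exon_overlap:
        return FrameResult(cid, fixed, "no-exon", ins, dels)
    gaps_inside = sum(1 for _, b in exon_pairs if b == "-")
    if (exon_indel % 3) != 0:
        return FrameResult(cid, fixed, "frameshift", ins, dels)
    if gaps_inside:  # in-frame deletion relative to reference: tolerate
        exon_pairs = aligned_exon
    # Translate from the first complete codon.
    bases = [(phases[pos], b) for pos, b in exon_pairs]
    start = next((k for k, (ph, _) in enumerate(bases) if ph == 0), None)
    if start is not None:
        codon_seq = "".join(b for _, b in bases[start:])
        for k in range(0, len(codon_seq) - 2, 3):
            if codon_seq[k : k + 3] in STOP_CODONS:
                return FrameResult(cid, fixed, "stop-codon", ins, dels)
    return FrameResult(cid, fixed, "ok", ins, dels)


def apply_frame_results(
    clusters: list[Cluster], results: list[FrameResult]
) -> tuple[list[Cluster], dict[str, int]]:
    """Replace centroid sequences with corrected ones; drop failed centroids."""
    by_id = {r.centroid_id: r for r in results}
    kept: list[Cluster] = []
    reasons: dict[str, int] = {"frameshift": 0, "stop-codon": 0}
    for c in clusters:
        r = by_id[c.centroid_id]
        if r.status in ("ok", "no-exon"):
            c.centroid_seq = r.seq
            kept.append(c)
        else:
            reasons[r.status] += 1
    return kept, reasons


# ---------------------------------------------------------------------------
# Funnel accounting


def funnel_table(rows: list[tuple[str, int, int]]) -> pd.DataFrame:
    """Per-stage (stage, reads in, reads out); monotone non-increasing."""
    df = pd.DataFrame(rows, columns=["stage", "reads_in", "reads_out"])
    return df
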