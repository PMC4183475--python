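"""Pairwise alignment utilities (edlib-backed) and a k-mer prescreen index.

Reads are partial-length fragments, so identities are computed over the
aligned span with free terminal gaps on the longer sequence ("glocal"
alignment): identity = matched columns / all aligned columns of the read.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict

import numpy as np
import edlib

from .marker import k2p

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


def _align(query: str, target: str, mode: str = "HW"):
    res = edlib.align(query, target, mode=mode, task="path")
    if res["editDistance"] < 0 or res["cigar"] is None:
        raise RuntimeError("alignment failed")
    return res


def glocal_identity(query: str, target: str) -> float:
    """Identity of query aligned into target with free target end gaps.

    Terminal target-only columns cost nothing and are excluded; the
    denominator is the number of aligned columns spanned by the query.
    """
    res = _align(query, target, mode="HW")
    ops = parse_cigar(res["cigar"])
    matches = sum(n for n, op in ops if op == "=")
    columns = sum(n for n, _ in ops)
    return matches / columns if columns else 0.0


def glocal_alignment(query: str, target: str) -> tuple[str, str, int]:
    """Gapped (query_aligned, target_aligned) strings plus target start.

    Covers only the aligned span: free terminal target gaps are trimmed.
    """
    res = _align(query, target, mode="HW")
    t0, _ = res["locations"][0]
    nice = edlib.getNiceAlignment(res, query, target)
    return nice["query_aligned"], nice["target_aligned"], t0


def k2p_unaligned(a: str, b: str) -> float:
    """K2P distance after on-the-fly glocal alignment (shorter into longer)."""
    if len(a) > len(b):
        a, b = b, a
    qa, ta, _ = glocal_alignment(a, b)
    return k2p(qa, ta)


def match_profile(query: str, target: str) -> tuple[np.ndarray, int, int]:
    """Per-query-position match booleans plus the covered query span.

    The shorter sequence is always the one aligned into the longer with
    free end gaps, so a target shorter than the query yields an honest
    coverage window instead of a forced garbage tail.  Positions outside
    [qstart, qend) are uncovered and say nothing about the target.
    """
    out = np.zeros(len(query), dtype=bool)
    if len(target) >= len(query):
        res = _align(query, target, mode="HW")
        q = 0
        ops = parse_cigar(res["cigar"])
        for n, op in ops:
            if op == "=":
                out[q : q + n] = True
                q += n
            elif op in ("X", "I"):
                q += n
            # 'D' consumes only the target
        qstart = ops[0][0] if ops and ops[0][1] == "I" else 0
        qend = len(query) - (ops[-1][0] if ops and ops[-1][1] == "I" else 0)
        return out, qstart, qend
    # target shorter: align it into the query and map back
    res = _align(target, query, mode="HW")
    q0, q1 = res["locations"][0]
    q = q0
    for n, op in parse_cigar(res["cigar"]):
        if op == "=":
            out[q : q + n] = True
            q += n
        elif op in ("X", "D"):  # 'D' here consumes the query
            q += n
        # 'I' consumes only the (shorter) target
    return out, q0, q1 + 1


def kmer_set(seq: str, k: int = 8) -> set[int]:
    """Hashed k-mer presence set (positions ignored)."""
    if len(seq) < k:
        return set()
    return {hash(seq[i : i + k]) for i in range(len(seq) - k + 1)}


class KmerIndex:
    """Inverted k-mer index over centroids for candidate prescreening.

    Candidates are returned by descending shared-k-mer count with ties
    broken by insertion order, which keeps greedy clustering deterministic.
    """

    def __init__(self, k: int = 8):
        self.k = k
        self._index: dict[int, list[int]] = defaultdict(list)
        self.n = 0

    def add(self, seq: str) -> int:
        idx = self.n
        for km in kmer_set(seq, self.k):
            self._index[km].append(idx)
        self.n += 1
        return idx

    def candidates(self, seq: str, top: int = 16) -> list[int]:
        counts: Counter[int] = Counter()
        for km in kmer_set(seq, self.k):
            for idx in self._index.get(km, ()):
                counts[idx] += 1
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return [idx for idx, _ in ranked[:top]]
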