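"""OTU picking, three-way taxonomy, consensus, and molecular taxa (MTs).

Denoised centroids are clustered into OTUs at the barcode-gap-derived K2P
threshold.  Each OTU representative is then assigned a lineage by three
independent routes — a naive-Bayes k-mer classifier with bootstrap
confidence, parsimony insertion into the reference tree (a deterministic
stand-in for likelihood-based evolutionary placement, same decision
structure), and a bootstrapped neighbour-joining tree on K2P distances —
and the three are merged by a fixed precedence: tree methods outrank the
classifier, placement outranks NJ, and any residual disagreement truncates
the lineage to the deepest rank on which all non-empty assignments agree.
OTUs sharing a consensus lineage collapse into one molecular taxon.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj

from ._align import glocal_alignment, glocal_identity, kmer_set
from .cluster import Cluster, SeqItem, greedy_cluster, k2p_distance
from .io import TaxonomyLineage, RANKS
from .marker import ReferenceSet, encode, _pair_site_classes, _k2p_from_counts


@dataclass
class OTU:
    otu_id: str
    representative: str  # sequence of the most abundant member
    rep_read_id: str
    sample_counts: Counter
    member_ids: list[str]

    @property
    def total(self) -> int:
        return sum(self.sample_counts.values())


@dataclass(frozen=True)
class TaxAssignment:
    method: str  # "classifier" | "placement" | "nj"
    lineage: TaxonomyLineage
    confidence: float


@dataclass(frozen=True)
class MolecularTaxon:
    name: str
    member_otu_ids: tuple[str, ...]
    rank: str  # rank at which the MT is named


# ---------------------------------------------------------------------------
# OTU picking


def cluster_otus(
    clusters: list[Cluster], distance_threshold: float = 0.008
) -> list[OTU]:
    """Greedy abundance-sorted centroid clustering at a K2P threshold."""
    if not clusters:
        return []
    items = [
        SeqItem(
            c.centroid_id,
            c.centroid_seq,
            tuple(sorted(c.sample_counts.items())),
            tuple(c.member_ids),
        )
        for c in clusters
    ]
    merged = greedy_cluster(items, threshold=distance_threshold, metric=k2p_distance)
    otus = []
    for i, m in enumerate(merged):
        otus.append(
            OTU(
                otu_id=f"OTU_{i + 1:04d}",
                representative=m.centroid_seq,
                rep_read_id=m.centroid_id,
                sample_counts=m.sample_counts,
                member_ids=m.member_ids,
            )
        )
    return otus


def remove_singletons_and_offtarget(
    otus: list[OTU],
    consensus: dict[str, TaxonomyLineage],
    target_phylum: str = "Glomeromycota",
) -> tuple[list[OTU], dict]:
    """Drop single-read OTUs and OTUs assigned outside the target phylum.

    The report counts removals per reason and the off-target read total;
    specificity is later computed against the length-filter read count.
    """
    kept: list[OTU] = []
    report = {
        "singleton_otus": 0,
        "offtarget_otus": 0,
        "singleton_reads": 0,
        "offtarget_reads": 0,
    }
    for o in otus:
        lineage = consensus.get(o.otu_id, TaxonomyLineage())
        if o.total < 2:
            report["singleton_otus"] += 1
            report["singleton_reads"] += o.total
        elif lineage and lineage.at("phylum") != target_phylum:
            report["offtarget_otus"] += 1
            report["offtarget_reads"] += o.total
        else:
            kept.append(o)
    return kept, report


# ---------------------------------------------------------------------------
# Query-to-alignment projection (shared by placement and NJ)


def project_to_alignment(query: str, ref: ReferenceSet) -> tuple[str, str]:
    """Thread an unaligned query onto the reference alignment columns.

    The query is glocally aligned to its most similar reference; matched
    bases inherit that reference's columns, everything else becomes a gap.
    Returns (aligned query row, best reference id).
    """
    best_id, best_ident = None, -1.0
    for rec in ref.records:
        ident = glocal_identity(query, rec.ungapped)
        if ident > best_ident:
            best_id, best_ident = rec.id, ident
    rec = next(r for r in ref.records if r.id == best_id)
    # ungapped position -> alignment column for the best reference
    cols = [i for i, b in enumerate(rec.seq) if b != "-"]
    qa, ta, t0 = glocal_alignment(query, rec.ungapped)
    row = ["-"] * ref.alignment_length
    t = t0
    for qb, tb in zip(qa, ta):
        if tb == "-":
            continue  # query insertion relative to the reference: no column
        if qb != "-":
            row[cols[t]] = qb
        t += 1
    return "".join(row), best_id


# ---------------------------------------------------------------------------
# Naive-Bayes k-mer classifier with bootstrap confidence


class KmerBayesClassifier:
    """Per-species k-mer presence model with bootstrap confidence.

    P(kmer | species) is the smoothed fraction of the species' reference
    sequences containing the k-mer; a query is scored by the summed log
    probabilities of its k-mers.  Confidence per rank is the fraction of
    bootstrap subsamples (1/8 of the query k-mers each) whose winning
    species agrees at that rank.
    """

    def __init__(self, ref: ReferenceSet, k: int = 8):
        self.k = k
        self.species: list[str] = []
        self.lineages: dict[str, TaxonomyLineage] = {}
        seqs_by_species: dict[str, list[str]] = {}
        for rec in ref.records:
            sp = ref.species[rec.id]
            seqs_by_species.setdefault(sp, []).append(rec.ungapped)
            self.lineages[sp] = ref.lineages.get(rec.id, TaxonomyLineage())
        self.species = sorted(seqs_by_species)
        self._kmer_ids: dict[int, int] = {}
        rows = []
        for sp in self.species:
            seqs = seqs_by_species[sp]
            counts: Counter[int] = Counter()
            for s in seqs:
                for km in kmer_set(s, k):
                    counts[km] += 1
            rows.append((counts, len(seqs)))
        vocab = set()
        for counts, _ in rows:
            vocab.update(counts)
        self._kmer_ids = {km: i for i, km in enumerate(sorted(vocab))}
        self.logp = np.empty((len(self.species), len(vocab)))
        for si, (counts, n) in enumerate(rows):
            p = np.full(len(vocab), 0.5 / (n + 1.0))
            for km, c in counts.items():
                p[self._kmer_ids[km]] = (c + 0.5) / (n + 1.0)
            self.logp[si] = np.log(p)
        # penalty for k-mers never seen in any reference
        self.default_logp = np.log(0.5 / (max(n for _, n in rows) + 1.0))

    def _score(self, kmer_idx: np.ndarray, n_unseen: int) -> int:
        scores = self.logp[:, kmer_idx].sum(axis=1) + n_unseen * self.default_logp
        return int(np.argmax(scores))

    def classify(
        self,
        query: str,
        bootstraps: int = 100,
        min_conf: float = 0.80,
        seed: int = 0,
    ) -> TaxAssignment:
        kms = kmer_set(query, self.k)
        if not kms:
            return TaxAssignment("classifier", TaxonomyLineage(), 0.0)
        known = np.array(
            [self._kmer_ids[km] for km in kms if km in self._kmer_ids], dtype=int
        )
        n_unseen = len(kms) - known.size
        if known.size == 0:
            return TaxAssignment("classifier", TaxonomyLineage(), 0.0)
        winner = self.species[self._score(known, n_unseen)]
        lineage = self.lineages[winner]
        rng = np.random.default_rng(seed)
        m = max(1, len(kms) // 8)
        agree = np.zeros(lineage.depth)
        all_idx = np.concatenate([known, np.full(n_unseen, -1, dtype=int)])
        for _ in range(bootstraps):
            pick = all_idx[rng.integers(0, all_idx.size, m)]
            sub_known = pick[pick >= 0]
            sub_unseen = int((pick < 0).sum())
            w = self.lineages[self.species[self._score(sub_known, sub_unseen)]]
            for r in range(min(lineage.depth, w.depth)):
                if w.names[r] == lineage.names[r]:
                    agree[r] += 1
                else:
                    break
        conf = agree / bootstraps
        depth = 0
        for r in range(lineage.depth):
            if conf[r] >= min_conf:
                depth = r + 1
            else:
                break
        if depth == 0:
            return TaxAssignment("classifier", TaxonomyLineage(), float(conf[0]) if lineage.depth else 0.0)
        return TaxAssignment("classifier", lineage.truncate(depth), float(conf[depth - 1]))


def classify_kmer_bayes(
    query: str,
    ref: ReferenceSet,
    k: int = 8,
    bootstraps: int = 100,
    min_conf: float = 0.80,
    seed: int = 0,
) -> TaxAssignment:
    return KmerBayesClassifier(ref, k=k).classify(query, bootstraps, min_conf, seed)


# ---------------------------------------------------------------------------
# Parsimony placement on the reference tree

_MASK = {"A": 1, "C": 2, "G": 4, "T": 8}


def _mask_row(seq: str) -> np.ndarray:
    out = np.full(len(seq), 15, dtype=np.uint8)  # gap/N: any state
    for base, m in _MASK.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        out[arr == ord(base)] = m
    return out


def _popcount_zero(x: np.ndarray) -> np.ndarray:
    return x == 0


def assign_by_placement(
    query: str,
    tree: TreeNode,
    ref: ReferenceSet,
    min_columns: int = 50,
) -> TaxAssignment:
    """Attach the query to the edge minimising added parsimony score.

    The query is threaded onto the alignment, every edge of the reference
    tree is tried by full Fitch re-scoring, and the winner set is narrowed
    by (1) smallest p-distance between query and subtree, (2) smallest
    subtree.  The assignment is the shared lineage of the remaining
    subtree(s); the confidence is 1 - (ties - 1)/edges over the
    equally-parsimonious edges.
    """
    row, _ = project_to_alignment(query, ref)
    qmask_full = _mask_row(row)
    use = qmask_full != 15
    if int(use.sum()) < min_columns:
        return TaxAssignment("placement", TaxonomyLineage(), 0.0)
    cols = np.where(use)[0]
    qmask = qmask_full[cols]

    leaf_masks = {r.id: _mask_row(r.seq)[cols] for r in ref.records}
    tree_leaves = {t.name for t in tree.tips()}
    missing = tree_leaves - set(leaf_masks)
    if missing:
        raise ValueError(f"tree leaves missing from reference alignment: {sorted(missing)}")

    nodes = list(tree.traverse(include_self=True))
    edges = [n for n in nodes if n.parent is not None]

    def fitch(node, target):
        """(state set array, cost) of the subtree, with the query inserted
        on the edge above ``target`` when encountered."""
        if node.is_tip():
            s, c = leaf_masks[node.name], 0
        else:
            s = None
            c = 0
            for child in node.children:
                cs, cc = fitch(child, target)
                c += cc
                if s is None:
                    s = cs
                else:
                    inter = s & cs
                    zero = inter == 0
                    c += int(zero.sum())
                    s = np.where(zero, s | cs, inter)
        if node is target:
            inter = s & qmask
            zero = inter == 0
            c += int(zero.sum())
            s = np.where(zero, s | qmask, inter)
        return s, c

    costs = np.array([fitch(tree, e)[1] for e in edges])
    best = costs.min()
    tied = [e for e, c in zip(edges, costs) if c == best]

    # narrow by query-to-subtree p-distance, then by subtree size
    def min_pdist(node) -> float:
        dists = []
        for t in node.tips(include_self=True):
            lm = leaf_masks[t.name]
            comp = lm != 15
            n = int(comp.sum())
            if n == 0:
                continue
            dists.append(int(((lm & qmask) == 0)[comp].sum()) / n)
        return min(dists) if dists else 1.0

    pd_vals = [min_pdist(e) for e in tied]
    best_pd = min(pd_vals)
    narrowed = [e for e, v in zip(tied, pd_vals) if v <= best_pd + 1e-12]
    sizes = [sum(1 for _ in e.tips(include_self=True)) for e in narrowed]
    smallest = min(sizes)
    final = [e for e, s in zip(narrowed, sizes) if s == smallest]

    lineage = None
    for e in final:
        sub = _shared_lineage([t.name for t in e.tips(include_self=True)], ref)
        lineage = sub if lineage is None else lineage.common_prefix(sub)
    confidence = 1.0 - (len(tied) - 1) / len(edges)
    return TaxAssignment("placement", lineage or TaxonomyLineage(), max(confidence, 0.0))


def _shared_lineage(leaf_ids: list[str], ref: ReferenceSet) -> TaxonomyLineage:
    lineage = None
    for lid in leaf_ids:
        lin = ref.lineages.get(lid, TaxonomyLineage())
        lineage = lin if lineage is None else lineage.common_prefix(lin)
    return lineage or TaxonomyLineage()


# ---------------------------------------------------------------------------
# Bootstrapped neighbour joining


def k2p_matrix(mat: np.ndarray) -> np.ndarray:
    """Pairwise K2P over the rows of an encoded character matrix."""
    n = mat.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        comp, ts, tv = _pair_site_classes(mat[i][None, :], mat[i + 1 :])
        d = _k2p_from_counts(ts.sum(axis=1), tv.sum(axis=1), comp.sum(axis=1))
        out[i, i + 1 :] = d
        out[i + 1 :, i] = d
    return out


def _nj_tree(dm: np.ndarray, ids: list[str]) -> TreeNode | None:
    d = dm.copy()
    finite = np.isfinite(d)
    if not finite.all():
        if not finite.any():
            return None
        fill = np.nanmax(d[finite]) * 2.0
        d[~finite] = fill
    np.fill_diagonal(d, 0.0)
    d = np.maximum(d, d.T)  # symmetrise against float jitter
    return _skbio_nj(DistanceMatrix(d, ids))


def _bipartitions_without(tree: TreeNode, query_id: str) -> set[frozenset]:
    """Edge bipartitions, each keyed by the side not containing the query."""
    all_tips = frozenset(t.name for t in tree.tips())
    out = set()
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            continue
        side = frozenset(t.name for t in node.tips())
        if query_id in side:
            side = all_tips - side
        if 0 < len(side) < len(all_tips) - 1:
            out.add(side)
    return out


def assign_by_nj(
    query: str,
    ref: ReferenceSet,
    bootstraps: int = 100,
    min_support: float = 0.70,
    seed: int = 0,
) -> TaxAssignment:
    """Neighbour joining on K2P distances with clade bootstrap support.

    The assignment is the shared lineage of the smallest clade containing
    the query whose bootstrap support reaches ``min_support``.
    """
    if len(ref.records) < 4:
        raise ValueError("NJ assignment needs at least 4 reference sequences")
    row, _ = project_to_alignment(query, ref)
    ids = ref.ids + ["__query__"]
    mat = np.vstack([ref.matrix(), encode(row)])
    dm = k2p_matrix(mat)
    if np.all(~np.isfinite(dm[-1, :-1])):
        return TaxAssignment("nj", TaxonomyLineage(), 0.0)
    tree = _nj_tree(dm, ids)
    if tree is None:
        return TaxAssignment("nj", TaxonomyLineage(), 0.0)

    # nested clades containing the query, smallest first
    qtip = tree.find("__query__")
    clades = []
    node = qtip.parent
    all_tips = frozenset(ids)
    while node is not None:
        members = frozenset(t.name for t in node.tips())
        if len(members) < len(ids):
            clades.append(members)
        node = node.parent
    # sister-side key for support lookup
    rng = np.random.default_rng(seed)
    n_cols = mat.shape[1]
    support: Counter[frozenset] = Counter()
    for _ in range(bootstraps):
        pick = rng.integers(0, n_cols, n_cols)
        bdm = k2p_matrix(mat[:, pick])
        btree = _nj_tree(bdm, ids)
        if btree is None:
            continue
        bip = _bipartitions_without(btree, "__query__")
        for members in clades:
            key = all_tips - members
            if key in bip:
                support[key] += 1

    for members in clades:  # smallest first by construction
        refs_in = [m for m in members if m != "__query__"]
        if not refs_in:
            continue
        s = support[all_tips - members] / bootstraps
        if s >= min_support:
            return TaxAssignment("nj", _shared_lineage(refs_in, ref), s)
    return TaxAssignment("nj", TaxonomyLineage(), 0.0)


# ---------------------------------------------------------------------------
# Consensus


def consensus_assignment(
    a_classifier: TaxAssignment | None,
    a_placement: TaxAssignment | None,
    a_nj: TaxAssignment | None,
) -> tuple[TaxonomyLineage, str]:
    """Merge the three assignments; returns (lineage, rule fired).

    Tree-based methods outrank the classifier and placement outranks NJ,
    but the result is never allowed to contradict a non-empty assignment
    at a rank it reports: any genuine disagreement truncates the lineage
    to the deepest commonly agreed rank.
    """
    cls = a_classifier.lineage if a_classifier else TaxonomyLineage()
    plc = a_placement.lineage if a_placement else TaxonomyLineage()
    njl = a_nj.lineage if a_nj else TaxonomyLineage()
    nonempty = [l for l in (cls, plc, njl) if l]
    if not nonempty:
        return TaxonomyLineage(), "all-empty"

    if plc and njl:
        if plc.is_prefix_of(njl) or njl.is_prefix_of(plc):
            tree_lin = plc if plc.depth >= njl.depth else njl
            rule = "tree-agree"
        else:
            tree_lin = plc.common_prefix(njl)  # placement preferred, but never
            rule = "tree-disagree-lca"  # contradicting the NJ assignment
    elif plc or njl:
        tree_lin = plc if plc else njl
        rule = "single-tree"
    else:
        return cls, "classifier-only"

    if not cls or cls.is_prefix_of(tree_lin):
        out = tree_lin
        rule = rule + ("+refined" if cls and cls.depth < tree_lin.depth else "")
    elif tree_lin.is_prefix_of(cls):
        out = cls
        rule = rule + "+classifier-deeper"
    else:
        # classifier contradicts the preferred tree lineage: common sublevel
        out = tree_lin.common_prefix(cls)
        rule = "disagreement-lca"
    # never contradict a non-empty assignment at a rank the result reports
    for lin in nonempty:
        out = out.common_prefix(lin) if not out.is_prefix_of(lin) and not lin.is_prefix_of(out) else out
    return out, rule


# ---------------------------------------------------------------------------
# Molecular taxa


def aggregate_to_mts(
    otus: list[OTU],
    consensus: dict[str, TaxonomyLineage],
    aliases: dict[frozenset, str] | None = None,
) -> list[MolecularTaxon]:
    """Merge OTUs sharing their deepest-named lineage into one MT.

    Species-level MTs carry the species name; shallower ones are named
    "<deepest taxon> sp.".  ``aliases`` maps frozensets of species names to
    a merged MT name for sibling species indistinguishable on short reads.
    """
    aliases = aliases or {}
    groups: dict[tuple, list[str]] = {}
    for o in otus:
        lin = consensus.get(o.otu_id, TaxonomyLineage())
        groups.setdefault(lin.names, []).append(o.otu_id)

    def mt_name(names: tuple) -> tuple[str, str]:
        if not names:
            return ("unassigned sp.", "unranked")
        rank = RANKS[len(names) - 1]
        if rank == "species":
            for key, merged in aliases.items():
                if names[-1] in key:
                    return (merged, "species")
            return (names[-1], "species")
        return (f"{names[-1]} sp.", rank)

    merged: dict[str, tuple[str, list[str]]] = {}
    for names, otu_ids in groups.items():
        name, rank = mt_name(names)
        if name in merged:
            merged[name][1].extend(otu_ids)
        else:
            merged[name] = (rank, list(otu_ids))
    out = [
        MolecularTaxon(name, tuple(sorted(otu_ids)), rank)
        for name, (rank, otu_ids) in sorted(merged.items())
    ]
    return out


def assignment_audit(
    otu_ids: list[str],
    assignments: dict[str, tuple[TaxAssignment, TaxAssignment, TaxAssignment]],
    consensus: dict[str, TaxonomyLineage],
    rules: dict[str, str],
) -> pd.DataFrame:
    rows = []
    for oid in otu_ids:
        c, p, n = assignments[oid]
        rows.append(
            (
                oid,
                c.lineage.to_string(),
                c.confidence,
                p.lineage.to_string(),
                p.confidence,
                n.lineage.to_string(),
                n.confidence,
                consensus[oid].to_string(),
                rules[oid],
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "otu_id",
            "classifier",
            "classifier_conf",
            "placement",
            "placement_conf",
            "nj",
            "nj_conf",
            "consensus",
            "rule",
        ],
    )
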