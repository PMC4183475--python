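"""Community diversity statistics on the OTU table and OTU tree.

Tables are oriented samples x OTUs (one row per sample).  UniFrac distances
are computed with scikit-bio on the neighbour-joining tree of OTU
representatives; ANOSIM is a rank-based permutation test with mid-ranks for
ties and an explicit seed (the permutation p-value is
(#{permuted R >= observed} + 1) / (permutations + 1)); PCoA is classical
scaling that reports negative eigenvalues instead of discarding them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.stats import rankdata
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity
from skbio.tree import nj as _skbio_nj

from .io import SampleMap
from .marker import encode
from .otus import OTU, k2p_matrix


def to_sample_matrix(otu_counts: pd.DataFrame) -> pd.DataFrame:
    """Transpose an OTU x sample count table into samples x OTUs."""
    return otu_counts.T


def otu_table_from_otus(otus: list[OTU], sample_ids: list[str]) -> pd.DataFrame:
    """Samples x OTUs integer count table from clustered OTUs."""
    data = {
        o.otu_id: [o.sample_counts.get(s, 0) for s in sample_ids] for o in otus
    }
    return pd.DataFrame(data, index=sample_ids, dtype=int)


# ---------------------------------------------------------------------------
# Rarefaction


def rarefy(table: pd.DataFrame, depth: int = 1400, seed: int = 0) -> pd.DataFrame:
    """Subsample every sample to ``depth`` reads without replacement.

    Samples already at exactly ``depth`` are returned unchanged; samples
    below it are dropped with a warning.  Deterministic given ``seed``.
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be positive, got {depth}")
    rng = np.random.default_rng(seed)
    rows = {}
    for sample, row in table.iterrows():
        total = int(row.sum())
        if total < depth:
            warnings.warn(
                f"sample {sample!r} has {total} < {depth} reads; dropped from rarefaction"
            )
            continue
        if total == depth:
            rows[sample] = row.to_numpy(dtype=int)
        else:
            rows[sample] = rng.multivariate_hypergeometric(
                row.to_numpy(dtype=int), depth
            )
    return pd.DataFrame.from_dict(rows, orient="index", columns=table.columns).astype(int)


def rarefaction_curves(
    table: pd.DataFrame, depths: list[int], reps: int = 10, seed: int = 0
) -> pd.DataFrame:
    """Mean observed OTU richness per (sample, depth) over ``reps`` draws.

    Depths at or above a sample's total return the observed richness.
    """
    if any(b < a for a, b in zip(depths, depths[1:])):
        raise ValueError("depth grid must be ascending")
    rng = np.random.default_rng(seed)
    out = np.zeros((len(table.index), len(depths)))
    for si, (_, row) in enumerate(table.iterrows()):
        counts = row.to_numpy(dtype=int)
        total = counts.sum()
        observed = int((counts > 0).sum())
        for di, depth in enumerate(depths):
            if depth >= total:
                out[si, di] = observed
                continue
            rich = [
                int((rng.multivariate_hypergeometric(counts, depth) > 0).sum())
                for _ in range(reps)
            ]
            out[si, di] = float(np.mean(rich))
    return pd.DataFrame(out, index=table.index, columns=depths)


# ---------------------------------------------------------------------------
# UniFrac


def build_otu_tree(otus: list[OTU]) -> TreeNode:
    """Neighbour-joining tree of OTU representatives on K2P distances.

    Negative NJ branch lengths are clamped to zero (UniFrac requires
    non-negative branch lengths).
    """
    if len(otus) < 3:
        raise ValueError("OTU tree needs at least 3 OTUs")
    from ._align import glocal_alignment

    # thread all representatives onto the longest one so rows are comparable
    anchor = max(otus, key=lambda o: len(o.representative))
    rows = []
    for o in otus:
        if o is anchor:
            rows.append(anchor.representative)
            continue
        qa, ta, t0 = glocal_alignment(o.representative, anchor.representative)
        row = ["-"] * len(anchor.representative)
        t = t0
        for qb, tb in zip(qa, ta):
            if tb == "-":
                continue
            if qb != "-":
                row[t] = qb
            t += 1
        rows.append("".join(row))
    mat = np.vstack([encode(r) for r in rows])
    dm = k2p_matrix(mat)
    if not np.isfinite(dm).all():
        fill = np.nanmax(dm[np.isfinite(dm)]) * 2.0
        dm[~np.isfinite(dm)] = fill
        np.fill_diagonal(dm, 0.0)
    dm = np.maximum(dm, dm.T)
    tree = _skbio_nj(DistanceMatrix(dm, [o.otu_id for o in otus]))
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    try:
        tree = tree.root_at_midpoint()
    except Exception:  # zero-length degenerate trees: root on the first edge
        tree = tree.root_at(tree.children[0])
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def unifrac(
    table: pd.DataFrame,
    tree: TreeNode,
    weighted: bool = True,
    normalized: bool = True,
) -> DistanceMatrix:
    """UniFrac distance matrix between samples.

    Unweighted: fraction of branch length unique to one of the two
    communities.  Weighted: branch lengths weighted by the difference in
    relative abundance below them; the normalized variant is bounded [0, 1].
    """
    tips = {t.name for t in tree.tips()}
    for otu in table.columns:
        if otu not in tips:
            raise ValueError(f"OTU {otu!r} missing from the OTU tree")
    counts = table.to_numpy(dtype=int)
    kwargs = {}
    if weighted:
        metric = "weighted_unifrac"
        kwargs["normalized"] = normalized
    else:
        metric = "unweighted_unifrac"
    return beta_diversity(
        metric,
        counts,
        ids=list(table.index),
        taxa=list(table.columns),
        tree=tree,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# PCoA


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame  # samples x axes, scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray  # descending; negatives reported, not dropped
    proportion_explained: np.ndarray  # relative to the positive eigenvalue sum


def pcoa(dm: DistanceMatrix | pd.DataFrame | np.ndarray, ids=None) -> PcoaResult:
    """Classical scaling (Gower double-centring + eigendecomposition)."""
    if isinstance(dm, DistanceMatrix):
        d, ids = dm.data, list(dm.ids)
    elif isinstance(dm, pd.DataFrame):
        d, ids = dm.to_numpy(dtype=float), list(dm.index)
    else:
        d = np.asarray(dm, dtype=float)
        ids = ids or [str(i) for i in range(d.shape[0])]
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("PCoA requires a symmetric distance matrix")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise ValueError("PCoA requires a zero diagonal")
    n = d.shape[0]
    a = -0.5 * d**2
    centre = np.eye(n) - np.ones((n, n)) / n
    g = centre @ a @ centre
    eigvals, eigvecs = scipy.linalg.eigh(g)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    coords = np.zeros_like(eigvecs)
    pos = eigvals > 0
    coords[:, pos] = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    pos_sum = eigvals[pos].sum()
    prop = np.where(pos, eigvals / pos_sum, 0.0) if pos_sum > 0 else np.zeros(n)
    axes = [f"PC{i + 1}" for i in range(n)]
    return PcoaResult(
        coordinates=pd.DataFrame(coords, index=ids, columns=axes),
        eigenvalues=eigvals,
        proportion_explained=prop,
    )


# ---------------------------------------------------------------------------
# ANOSIM


@dataclass(frozen=True)
class AnosimResult:
    R: float
    p: float
    permutations: int
    grouping: str


def anosim(
    dm: DistanceMatrix | pd.DataFrame,
    grouping: dict[str, str] | pd.Series,
    permutations: int = 2000,
    seed: int = 0,
) -> AnosimResult:
    """Analysis of similarities: R in [-1, 1] with a permutation p-value.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2, ranks (mid-ranks for ties) taken over all pairwise
    distances.  Group labels are permuted ``permutations`` times.
    """
    if isinstance(dm, DistanceMatrix):
        d, ids = dm.data, list(dm.ids)
    else:
        d, ids = dm.to_numpy(dtype=float), list(dm.index)
    labels = np.array([grouping[i] for i in ids])
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("ANOSIM needs at least two groups")
    if (counts < 2).any():
        small = uniq[counts < 2][0]
        raise ValueError(f"group {small!r} has fewer than 2 members")
    n = len(ids)
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(d[iu])
    m = n * (n - 1) / 2

    def stat(lab):
        within = lab[iu[0]] == lab[iu[1]]
        return (ranks[~within].mean() - ranks[within].mean()) / (m / 2.0)

    observed = stat(labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        if stat(rng.permutation(labels)) >= observed:
            hits += 1
    p = (hits + 1) / (permutations + 1)
    return AnosimResult(
        R=float(observed),
        p=float(p),
        permutations=permutations,
        grouping=" vs ".join(map(str, uniq)),
    )


# ---------------------------------------------------------------------------
# Composition summaries


def composition_summary(
    table: pd.DataFrame,
    otu_to_mt: dict[str, str],
    sample_map: SampleMap,
) -> dict[str, pd.DataFrame]:
    """Relative MT abundances per sample (plot) and per treatment.

    Rows of both relative tables sum to one; ``presence`` counts in how
    many samples of each treatment an MT occurs.
    """
    missing = [c for c in table.columns if c not in otu_to_mt]
    if missing:
        raise ValueError(f"OTUs without an MT mapping: {missing[:5]}")
    mt = table.T.groupby(lambda otu: otu_to_mt[otu]).sum().T
    per_sample = mt.div(mt.sum(axis=1), axis=0)
    treatments = pd.Series(
        {s.sample_id: s.treatment for s in sample_map}, name="treatment"
    )
    by_treatment = mt.groupby(treatments.reindex(mt.index)).sum()
    per_treatment = by_treatment.div(by_treatment.sum(axis=1), axis=0)
    presence = (mt > 0).groupby(treatments.reindex(mt.index)).sum()
    return {
        "mt_counts": mt,
        "per_sample": per_sample,
        "per_treatment": per_treatment,
        "presence": presence,
    }
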