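"""Synthetic reference sets and amplicon communities with ground truth.

The generator emulates the statistical structure the analysis assumes:

* a random species tree with sequences evolved under a Kimura
  two-parameter substitution process, introns evolving at a configurable
  multiple of the exon rate (so the intron/exon variability contrast holds
  by construction) and conserved primer sites at both marker ends;
* coding exons that translate without stop codons in the declared frame
  (codons mutating into stops revert to the parental codon);
* intra-specific isolates at a bounded distance from the species sequence;
* treatment x block community compositions (Dirichlet means per treatment,
  one draw per plot, multinomial reads per sample);
* pyrosequencing-style read errors: random substitutions plus homopolymer
  indels whose probability grows with run length, and single-crossover
  PCR chimeras between two reads of the same sample.

Every emitted read has exactly one ground-truth row.  Identical seed and
configuration give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skbio import TreeNode

from .io import (
    Region,
    RegionAnnotation,
    SampleInfo,
    SampleMap,
    SeqRecord,
    TaxonomyLineage,
)
from .marker import ReferenceSet, encode, k2p

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
#: transition partner of each encoded base (A<->G, C<->T)
_TS_MAP = np.array([2, 3, 0, 1])

TREATMENTS = ("no-tillage", "chisel", "tillage")

DEFAULT_LAYOUT = (
    Region(0, 150, "exon"),
    Region(150, 231, "intron"),
    Region(231, 441, "exon"),
    Region(441, 516, "intron"),
    Region(516, 756, "exon"),
)


def default_treatment_means(n_species: int, effect: float = 4.0) -> dict[str, tuple[float, ...]]:
    """Per-treatment Dirichlet mean compositions with a block effect.

    Each treatment enriches one third of the species by ``effect``-fold
    over a flat baseline; the blocks are disjoint, giving a designed
    between-treatment separation tunable through ``effect``.
    """
    means = {}
    block = max(1, n_species // 3)
    for t_idx, name in enumerate(TREATMENTS):
        w = np.ones(n_species)
        lo = t_idx * block
        hi = n_species if t_idx == len(TREATMENTS) - 1 else (t_idx + 1) * block
        w[lo:hi] *= effect
        means[name] = tuple(w / w.sum())
    return means


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults define the study conditions."""

    n_species: int = 8
    isolates_per_species: int = 2
    layout: tuple[Region, ...] = DEFAULT_LAYOUT
    frame: int = 0
    intron_rate_multiplier: float = 4.0
    kappa: float = 2.0
    target_inter_species_divergence: float = 0.05
    min_inter_species_divergence: float = 0.02
    intra_species_divergence: float = 0.002
    substitution_error_rate: float = 0.002
    homopolymer_indel_base_rate: float = 0.002
    chimera_rate: float = 0.05
    chimera_min_segment: int = 50
    chimera_parents_distinct_species: bool = True
    read_length: tuple[int, int, int] = (145, 254, 515)  # min, mode, max
    primer_length: int = 20
    treatments: dict[str, tuple[float, ...]] | None = None
    dirichlet_concentration: float = 50.0
    plots_per_treatment: int = 4
    reads_per_sample: int = 1800
    poisson_depth: bool = False
    include_offtarget: bool = True
    offtarget_divergence: float = 0.35
    offtarget_read_fraction: float = 0.0006
    barcode_length: int = 9
    seed: int = 0

    def __post_init__(self):
        for name in (
            "intra_species_divergence",
            "substitution_error_rate",
            "homopolymer_indel_base_rate",
            "chimera_rate",
            "offtarget_read_fraction",
            "target_inter_species_divergence",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        lo, mode, hi = self.read_length
        if not lo <= mode <= hi:
            raise ValueError(f"read lengths must satisfy min <= mode <= max: {self.read_length}")
        if self.n_species < 2:
            raise ValueError("need at least two species")
        if self.treatments is None:
            self.treatments = default_treatment_means(self.n_species)
        for name, mean in self.treatments.items():
            if len(mean) != self.n_species:
                raise ValueError(f"treatment {name!r}: composition length != n_species")
            if abs(sum(mean) - 1.0) > 1e-9:
                raise ValueError(f"treatment {name!r}: composition does not sum to 1")

    @property
    def annotation(self) -> RegionAnnotation:
        return RegionAnnotation(list(self.layout), frame=self.frame)


OUTGROUP_SPECIES = "Fusarium sp."
OUTGROUP_LINEAGE = TaxonomyLineage(
    ("Ascomycota", "Sordariomycetes", "Hypocreales", "Nectriaceae", "Fusarium", OUTGROUP_SPECIES)
)
TARGET_PHYLUM = "Glomeromycota"


def species_lineage(index: int) -> TaxonomyLineage:
    """Synthetic rank-complete lineage; two species per genus, two genera per family."""
    genus = index // 2 + 1
    family = index // 4 + 1
    return TaxonomyLineage(
        (
            TARGET_PHYLUM,
            "Glomeromycetes",
            "Glomerales",
            f"Family{family:02d}",
            f"Genus{genus:02d}",
            f"Species{index + 1:02d}",
        )
    )


# ---------------------------------------------------------------------------
# K2P sequence evolution


def _k2p_site_probs(d: np.ndarray, kappa: float):
    """Transition and per-branch transversion probabilities at distance d."""
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e_tv = np.exp(-4.0 * beta * d)
    e_ts = np.exp(-2.0 * (alpha + beta) * d)
    p_ts = 0.25 + 0.25 * e_tv - 0.5 * e_ts
    p_tv = 0.5 - 0.5 * e_tv  # both transversion targets together
    return p_ts, p_tv


def _mutate(codes: np.ndarray, d: np.ndarray, kappa: float, rng) -> np.ndarray:
    """One branch of K2P evolution over per-site distances ``d``."""
    p_ts, p_tv = _k2p_site_probs(d, kappa)
    u = rng.random(codes.size)
    out = codes.copy()
    ts = u < p_ts
    tv = (~ts) & (u < p_ts + p_tv)
    out[ts] = _TS_MAP[codes[ts]]
    pick = rng.integers(0, 2, codes.size)
    purine = np.isin(codes, (0, 2))
    tv_target = np.where(purine, np.where(pick == 0, 1, 3), np.where(pick == 0, 0, 2))
    out[tv] = tv_target[tv]
    return out


def _decode(codes: np.ndarray) -> str:
    return "".join(_BASES[c] for c in codes)


def _codon_spans(annotation: RegionAnnotation) -> list[tuple[int, int, int]]:
    """Alignment-column triples forming complete exon codons."""
    cols = annotation.exon_columns()
    lead = (3 - annotation.frame) % 3
    cols = cols[lead:]
    return [tuple(cols[i : i + 3]) for i in range(0, len(cols) - 2, 3)]


def _repair_stops(child: np.ndarray, parent: np.ndarray, codons) -> np.ndarray:
    """Revert codons that mutated into stops back to the parental codon."""
    out = child.copy()
    for c0, c1, c2 in codons:
        tri = _BASES[out[c0]] + _BASES[out[c1]] + _BASES[out[c2]]
        if tri in _STOPS:
            out[[c0, c1, c2]] = parent[[c0, c1, c2]]
    return out


def _random_root(annotation: RegionAnnotation, rng) -> np.ndarray:
    """Random marker sequence whose exon codons avoid stops."""
    L = annotation.length
    codes = rng.integers(0, 4, L)
    codons = _codon_spans(annotation)
    for c0, c1, c2 in codons:
        while _BASES[codes[c0]] + _BASES[codes[c1]] + _BASES[codes[c2]] in _STOPS:
            codes[[c0, c1, c2]] = rng.integers(0, 4, 3)
    return codes


# ---------------------------------------------------------------------------
# Species tree


def _random_tree(names: list[str], rng) -> tuple[TreeNode, dict[int, float]]:
    """Random coalescent-style ultrametric topology with unit-scale heights."""
    nodes = [TreeNode(name=n) for n in names]
    heights = {id(n): 0.0 for n in nodes}
    h = 0.0
    k = len(nodes)
    while len(nodes) > 1:
        h += rng.exponential(1.0 / k)
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        parent = TreeNode(children=[a, b])
        heights[id(parent)] = h
        nodes = [n for t, n in enumerate(nodes) if t not in (i, j)] + [parent]
    return nodes[0], heights


def _set_lengths(tree: TreeNode, heights: dict, scale: float, floor: float) -> None:
    """Branch lengths from scaled node heights with a minimum-split floor.

    Internal-node heights are shifted up as a block so that the shallowest
    split sits at least ``floor`` above the tips, bounding the closest
    species pair away from zero.
    """
    internals = [n for n in tree.traverse(include_self=True) if not n.is_tip()]
    scaled = {id(n): heights[id(n)] * scale for n in internals}
    shift = max(0.0, floor - min(scaled.values()))

    def h(node):
        return 0.0 if node.is_tip() else scaled[id(node)] + shift

    for node in tree.traverse(include_self=True):
        for child in node.children:
            child.length = h(node) - h(child)


def _mean_tip_distance(tree: TreeNode) -> float:
    tips = list(tree.tips())
    total, n = 0.0, 0
    for i in range(len(tips)):
        for j in range(i + 1, len(tips)):
            total += tips[i].distance(tips[j])
            n += 1
    return total / n


def simulate_reference_set(config: SimulationConfig) -> tuple[ReferenceSet, TreeNode]:
    """Simulate species sequences on a random tree plus isolate replicates.

    Returns the (trivially aligned) reference set and the reference tree
    whose leaves are the isolate ids.  Branch lengths are calibrated so the
    realised mean pairwise exon K2P distance between species matches the
    configured target; introns evolve ``intron_rate_multiplier`` times
    faster and the terminal primer sites are held invariant.
    """
    ann = config.annotation
    if not ann.is_frame_consistent():
        raise ValueError(
            f"exon layout is not frame-consistent: {ann.exon_length()} exon columns "
            f"at frame {ann.frame}"
        )
    rng = np.random.default_rng(config.seed)
    L = ann.length
    labels = np.array([1 if lab == "exon" else 0 for lab in ann.labels()], dtype=np.int8)
    site_mult = np.where(labels == 1, 1.0, config.intron_rate_multiplier)
    site_mult[: config.primer_length] = 0.0
    site_mult[L - config.primer_length :] = 0.0
    codons = _codon_spans(ann)

    species_names = [f"sp{i + 1:02d}" for i in range(config.n_species)]
    tree, heights = _random_tree(species_names, rng)
    floor = config.min_inter_species_divergence / 2.0
    _set_lengths(tree, heights, 1.0, 0.0)
    scale = config.target_inter_species_divergence / _mean_tip_distance(tree) / 2.0

    root_codes = _random_root(ann, rng)

    # Calibrate the tree scale against realised exon K2P (stop-codon repair
    # and invariant primer sites depress divergence below the nominal scale).
    exon_cols = np.array(ann.exon_columns())
    for _ in range(4):
        _set_lengths(tree, heights, scale, floor)
        species_codes = _evolve(tree, root_codes, site_mult, codons, config.kappa,
                                np.random.default_rng(config.seed + 1))
        mean_d = _mean_exon_k2p(species_codes, species_names, exon_cols)
        ratio = config.target_inter_species_divergence / mean_d
        if abs(ratio - 1.0) < 0.05:
            break
        scale *= ratio

    # Off-target outgroup on a long branch, attached above the ingroup root.
    if config.include_offtarget:
        out_codes = _mutate(root_codes, config.offtarget_divergence * site_mult,
                            config.kappa, rng)
        out_codes = _repair_stops(out_codes, root_codes, codons)
        species_codes["outgroup"] = out_codes

    # Isolates: bounded divergence from the species sequence, stop-free exons.
    records: list[SeqRecord] = []
    species_of: dict[str, str] = {}
    lineages: dict[str, TaxonomyLineage] = {}
    isolates: dict[str, str] = {}
    mutable = np.where(site_mult > 0)[0]
    n_iso_mut = int(np.floor(config.intra_species_divergence / 2.0 * mutable.size))
    tip_children: dict[str, list[tuple[str, float]]] = {}
    all_names = species_names + (["outgroup"] if config.include_offtarget else [])
    for idx, sp in enumerate(all_names):
        lineage = OUTGROUP_LINEAGE if sp == "outgroup" else species_lineage(idx)
        label = lineage.deepest_name
        n_iso = 1 if sp == "outgroup" else config.isolates_per_species
        tip_children[sp] = []
        for k in range(n_iso):
            iso_id = f"{sp}_iso{k + 1}"
            codes = species_codes[sp].copy()
            if n_iso_mut > 0 and sp != "outgroup":
                sites = rng.choice(mutable, size=n_iso_mut, replace=False)
                sub = _mutate_selected(codes, sites, config.kappa, rng)
                codes = _repair_stops(sub, species_codes[sp], codons)
            records.append(SeqRecord(iso_id, _decode(codes)))
            species_of[iso_id] = label
            lineages[iso_id] = lineage
            isolates[iso_id] = iso_id
            tip_children[sp].append((iso_id, config.intra_species_divergence / 2.0))

    ref_tree = _expand_tips(tree, tip_children, config)
    ref = ReferenceSet(records, species_of, lineages, isolates, annotation=ann)
    return ref, ref_tree


def _mutate_selected(codes: np.ndarray, sites: np.ndarray, kappa: float, rng) -> np.ndarray:
    """Force exactly one substitution at each selected site."""
    out = codes.copy()
    p_ts = kappa / (kappa + 2.0)
    for pos in sites:
        if rng.random() < p_ts:
            out[pos] = _TS_MAP[out[pos]]
        else:
            pick = rng.integers(0, 2)
            out[pos] = (1, 3)[pick] if out[pos] in (0, 2) else (0, 2)[pick]
    return out


def _evolve(tree, root_codes, site_mult, codons, kappa, rng) -> dict[str, np.ndarray]:
    """Recursive K2P evolution; returns tip name -> encoded sequence."""
    out: dict[str, np.ndarray] = {}

    def walk(node, codes):
        for child in node.children:
            mutated = _mutate(codes, child.length * site_mult, kappa, rng)
            mutated = _repair_stops(mutated, codes, codons)
            if child.is_tip():
                out[child.name] = mutated
            else:
                walk(child, mutated)

    walk(tree, root_codes)
    return out


def _mean_exon_k2p(species_codes, species_names, exon_cols) -> float:
    seqs = {sp: _decode(species_codes[sp][exon_cols]) for sp in species_names}
    vals = []
    for i, a in enumerate(species_names):
        for b in species_names[i + 1 :]:
            vals.append(k2p(seqs[a], seqs[b]))
    return float(np.nanmean(vals))


def _expand_tips(tree: TreeNode, tip_children, config) -> TreeNode:
    """Reference tree with isolate leaves (and the outgroup above the root)."""
    new = tree.copy()
    for tip in list(new.tips()):
        kids = tip_children[tip.name]
        if len(kids) == 1:
            tip.name = kids[0][0]
        else:
            tip.name = None
            for iso_id, length in kids:
                tip.append(TreeNode(name=iso_id, length=length))
    if config.include_offtarget:
        root = TreeNode(children=[new])
        new.length = 0.02
        og = tip_children["outgroup"][0]
        root.append(TreeNode(name=og[0], length=config.offtarget_divergence))
        new = root
    return new


# ---------------------------------------------------------------------------
# Community reads


def make_barcodes(n: int, length: int, min_distance: int, rng) -> list[str]:
    """Random barcodes with pairwise Hamming distance >= ``min_distance``."""
    out: list[str] = []
    attempts = 0
    while len(out) < n:
        cand = "".join(_BASES[c] for c in rng.integers(0, 4, length))
        if all(sum(a != b for a, b in zip(cand, prev)) >= min_distance for prev in out):
            out.append(cand)
        attempts += 1
        if attempts > 100000:
            raise RuntimeError("could not satisfy barcode distance constraint")
    return out


def _homopolymer_runs(seq: str) -> list[tuple[int, int]]:
    """(start, length) of every homopolymer run of length >= 2."""
    runs = []
    i = 0
    n = len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= 2:
            runs.append((i, j - i))
        i = j
    return runs


def _apply_errors(seq: str, sub_rate: float, hp_rate: float, rng) -> tuple[str, int, int]:
    """Substitutions plus homopolymer +/-1 indels; returns (seq, n_subs, n_indels)."""
    codes = encode(seq).copy()
    n_subs = 0
    if sub_rate > 0:
        hits = np.where(rng.random(codes.size) < sub_rate)[0]
        for pos in hits:
            codes[pos] = (codes[pos] + rng.integers(1, 4)) % 4
        n_subs = len(hits)
    out = _decode(codes)
    n_indels = 0
    if hp_rate > 0:
        edited = []
        cursor = 0
        for start, run in _homopolymer_runs(out):
            p = min(hp_rate * (run - 1), 0.5)
            if rng.random() < p:
                edited.append(out[cursor:start])
                base = out[start]
                if rng.random() < 0.5:
                    edited.append(base * (run + 1))  # insertion
                else:
                    edited.append(base * (run - 1))  # deletion
                n_indels += 1
                cursor = start + run
        edited.append(out[cursor:])
        out = "".join(edited)
    return out, n_subs, n_indels


def simulate_community_reads(
    config: SimulationConfig, reference: ReferenceSet
) -> tuple[list[SeqRecord], SampleMap, pd.DataFrame]:
    """Barcoded raw reads for every sample, with per-read ground truth.

    Each read is ``barcode + forward primer + amplicon prefix`` where the
    amplicon is the primer-bounded marker of a randomly drawn isolate and
    the prefix length follows a triangular distribution.  Chimeras are
    single crossovers between the templates of two earlier reads of the
    same sample; errors are applied after chimera formation.
    """
    rng = np.random.default_rng(config.seed + 10_000)
    ann = config.annotation
    by_species: dict[str, list[tuple[str, str]]] = {}
    for rec in reference.records:
        sp = reference.species[rec.id]
        by_species.setdefault(sp, []).append((rec.id, rec.ungapped))
    target_species = [species_lineage(i).deepest_name for i in range(config.n_species)]
    for sp in target_species:
        if sp not in by_species:
            raise ValueError(f"reference set lacks species {sp!r}")
    primer = by_species[target_species[0]][0][1][: config.primer_length]
    for sp, recs in by_species.items():
        for iso_id, seq in recs:
            if primer not in seq[: config.primer_length]:
                raise ValueError(f"forward primer not found in reference of {sp!r} ({iso_id})")

    barcodes = make_barcodes(
        len(config.treatments) * config.plots_per_treatment,
        config.barcode_length,
        4,
        rng,
    )
    samples = []
    b = 0
    for treatment in config.treatments:
        for plot in range(1, config.plots_per_treatment + 1):
            samples.append(
                SampleInfo(f"{treatment}-P{plot}", barcodes[b], treatment, f"P{plot}")
            )
            b += 1
    sample_map = SampleMap(samples)

    lo, mode, hi = config.read_length
    reads: list[SeqRecord] = []
    truth_rows = []
    for s in samples:
        mean = np.asarray(config.treatments[s.treatment])
        p_plot = rng.dirichlet(mean * config.dirichlet_concentration)
        depth = (
            rng.poisson(config.reads_per_sample)
            if config.poisson_depth
            else config.reads_per_sample
        )
        # (read_id, species, template) of this sample, for chimera parents
        templates: list[tuple[str, str, str]] = []
        for i in range(depth):
            read_id = f"{s.sample_id}_r{i:05d}"
            length = int(round(rng.triangular(lo, mode, hi))) if hi > lo else lo
            is_chimera = (
                config.chimera_rate > 0
                and len(templates) >= 2
                and rng.random() < config.chimera_rate
            )
            if not is_chimera:
                if (
                    config.include_offtarget
                    and rng.random() < config.offtarget_read_fraction
                ):
                    sp = OUTGROUP_SPECIES
                else:
                    sp = target_species[rng.choice(len(target_species), p=p_plot)]
                iso_id, marker = by_species[sp][rng.integers(0, len(by_species[sp]))]
                template = marker[: min(length, len(marker))]
                templates.append((read_id, sp, template))
                parent_a = parent_b = None
                crossover = None
            else:
                sp, iso_id = "", ""
                parent_a, parent_b, crossover, template = _make_chimera(
                    templates, config, rng
                )
                if template is None:  # no eligible parent pair; plain read instead
                    is_chimera = False
                    sp = target_species[rng.choice(len(target_species), p=p_plot)]
                    iso_id, marker = by_species[sp][rng.integers(0, len(by_species[sp]))]
                    template = marker[: min(length, len(marker))]
                    templates.append((read_id, sp, template))
                    parent_a = parent_b = crossover = None
            seq, n_subs, n_indels = _apply_errors(
                template,
                config.substitution_error_rate,
                config.homopolymer_indel_base_rate,
                rng,
            )
            reads.append(SeqRecord(read_id, s.barcode + seq))
            truth_rows.append(
                (
                    read_id,
                    s.sample_id,
                    sp,
                    iso_id,
                    is_chimera,
                    parent_a,
                    parent_b,
                    crossover,
                    len(template),
                    n_subs,
                    n_indels,
                )
            )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "read_id",
            "sample_id",
            "species",
            "isolate",
            "is_chimera",
            "parent_a",
            "parent_b",
            "crossover",
            "template_len",
            "n_subs",
            "n_indels",
        ],
    )
    return reads, sample_map, truth


def _make_chimera(templates, config: SimulationConfig, rng):
    """Single crossover between two earlier templates of the sample.

    The crossover position is uniform over positions leaving at least
    ``chimera_min_segment`` bases from each parent (shorter homologous
    stretches do not recombine appreciably during PCR).
    """
    min_seg = config.chimera_min_segment
    for _ in range(50):
        i, j = rng.choice(len(templates), size=2, replace=False)
        ra, sa, ta = templates[i]
        rb, sb, tb = templates[j]
        if config.chimera_parents_distinct_species and sa == sb:
            continue
        overlap = min(len(ta), len(tb))
        if overlap < 2 * min_seg:
            continue
        x = int(rng.integers(min_seg, overlap - min_seg + 1))
        return ra, rb, x, ta[:x] + tb[x:]
    return None, None, None, None


def write_ground_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_ground_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
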