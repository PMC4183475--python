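"""End-to-end orchestration: raw reads to community statistics.

Stage order is fixed: demultiplex -> length/ambiguity filter -> 60 %
alignment screen -> 99.7 % pre-clustering -> de novo chimera removal ->
homopolymer frame correction -> OTU picking at the barcode-gap threshold
-> three-way taxonomy + consensus -> singleton/off-target removal -> MT
aggregation -> rarefaction, UniFrac, PCoA, ANOSIM.  Identical inputs,
parameters and seed reproduce identical artifacts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from . import community as comm
from . import io as rio
from . import marker, otus as otum, reads as rp
from .io import SampleMap, SeqRecord, TaxonomyLineage
from .marker import ReferenceSet
from .otus import KmerBayesClassifier, TaxAssignment


@dataclass
class PipelineParams:
    """All tunable thresholds, with their field-standard defaults."""

    max_barcode_mismatch: int = 1
    min_length: int = 200
    length_includes_prefix: bool = True
    min_alignment_similarity: float = 0.60
    precluster_similarity: float = 0.997
    otu_threshold: float | None = None  # None: derive from the barcode gap
    threshold_resolution: float = 0.001
    excluded_taxa: tuple[str, ...] = ()
    chimera_skew: float = 2.0
    chimera_min_model_identity: float = 0.99
    chimera_min_margin: float = 0.01
    chimera_min_parent_contrib: int = 30
    chimera_min_diffs: int = 3
    classifier_k: int = 8
    classifier_bootstraps: int = 100
    classifier_min_conf: float = 0.80
    nj_bootstraps: int = 100
    nj_min_support: float = 0.70
    target_phylum: str = "Glomeromycota"
    rarefaction_depth: int = 1400
    anosim_permutations: int = 2000
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def specificity_report(offtarget_reads: int, length_passing_reads: int) -> dict:
    """Primer specificity as printed percentages (two decimals).

    specificity = 100 * (1 - off-target / reads passing the length filter).
    """
    if length_passing_reads <= 0:
        return {"specificity_percent": float("nan"), "offtarget_percent": float("nan")}
    off = 100.0 * offtarget_reads / length_passing_reads
    return {
        "specificity_percent": round(100.0 - off, 2),
        "offtarget_percent": round(off, 2),
    }


@dataclass
class RunReport:
    funnel: list[tuple[str, int, int]] = field(default_factory=list)
    params: dict = field(default_factory=dict)
    seed: int = 0
    otu_threshold: float = float("nan")
    threshold_warning: str | None = None
    otu_count: int = 0
    otu_count_retained: int = 0
    mt_count: int = 0
    retained_reads: int = 0
    length_passing_reads: int = 0
    offtarget_reads: int = 0
    specificity_percent: float = float("nan")
    offtarget_percent: float = float("nan")
    removal_report: dict = field(default_factory=dict)
    anosim: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["funnel"] = [
            {"stage": s, "reads_in": a, "reads_out": b} for s, a, b in self.funnel
        ]
        return d

    def to_json(self, path: str | Path) -> None:
        def default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(type(o))

        Path(path).write_text(json.dumps(self.to_dict(), indent=2, default=default))


@dataclass
class PipelineResult:
    report: RunReport
    otus: list
    mts: list
    otu_table: pd.DataFrame | None
    rarefied: pd.DataFrame | None
    consensus: dict
    audit: pd.DataFrame | None
    unifrac: dict
    pcoa: object | None
    composition: dict | None
    screened_read_ids: frozenset = frozenset()
    chimera_flagged_read_ids: frozenset = frozenset()


def derive_threshold_from_reference(
    reference: ReferenceSet, params: PipelineParams
) -> tuple[float, str | None]:
    dm = marker.pairwise_k2p(reference)
    gaps = marker.barcode_gap(dm, {r.id: reference.species[r.id] for r in reference.records})
    threshold, warning = marker.derive_otu_threshold(
        gaps, set(params.excluded_taxa), params.threshold_resolution
    )
    return threshold, (warning.message if warning else None)


def run_pipeline(
    raw_reads: list[SeqRecord],
    sample_map: SampleMap,
    reference: ReferenceSet,
    reference_tree: TreeNode,
    primer: str,
    params: PipelineParams | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    params = params or PipelineParams()
    report = RunReport(params=params.to_dict(), seed=params.seed)
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    n_raw = len(raw_reads)
    assigned, _ = rp.demultiplex(
        raw_reads, sample_map, primer, max_barcode_mismatch=params.max_barcode_mismatch
    )
    report.funnel.append(("demux", n_raw, len(assigned)))

    kept, _ = rp.length_ambiguity_filter(
        assigned,
        min_len=params.min_length,
        include_prefix_in_length=params.length_includes_prefix,
    )
    report.funnel.append(("length-ambiguity", len(assigned), len(kept)))
    report.length_passing_reads = len(kept)

    if kept:
        screened, _ = rp.alignment_screen(
            kept, reference, min_similarity=params.min_alignment_similarity
        )
    else:
        screened = []
    report.funnel.append(("align-screen", len(kept), len(screened)))

    clusters = rp.precluster(screened, similarity=params.precluster_similarity)
    n_preclustered = sum(c.total for c in clusters)
    report.funnel.append(("precluster", len(screened), n_preclustered))

    if clusters:
        verdicts = rp.detect_chimeras(
            clusters,
            skew=params.chimera_skew,
            min_model_identity=params.chimera_min_model_identity,
            min_margin=params.chimera_min_margin,
            min_parent_contrib=params.chimera_min_parent_contrib,
            min_diffs=params.chimera_min_diffs,
        )
        clusters, flagged = rp.remove_chimeras(clusters, verdicts)
    else:
        verdicts, flagged = {}, []
    n_after_chimera = sum(c.total for c in clusters)
    report.funnel.append(("chimera", n_preclustered, n_after_chimera))

    if clusters:
        frames = rp.ReferenceFrames.from_reference(reference)
        ref_by_read = {r.read_id: r.best_ref for r in screened}
        best_ref = {c.centroid_id: ref_by_read[c.centroid_id] for c in clusters}
        frame_results = rp.frame_correct(clusters, best_ref, frames)
        clusters, _ = rp.apply_frame_results(clusters, frame_results)
    n_after_frame = sum(c.total for c in clusters)
    report.funnel.append(("frame", n_after_chimera, n_after_frame))

    # --- OTU threshold
    if params.otu_threshold is not None:
        threshold = params.otu_threshold
    else:
        threshold, warn = derive_threshold_from_reference(reference, params)
        report.threshold_warning = warn
    report.otu_threshold = threshold

    # --- OTU picking
    otu_list = otum.cluster_otus(clusters, distance_threshold=threshold)
    report.otu_count = len(otu_list)
    report.funnel.append(("otu", n_after_frame, sum(o.total for o in otu_list)))

    # --- taxonomy (non-singleton OTUs only; singletons are removed regardless)
    consensus: dict[str, TaxonomyLineage] = {}
    rules: dict[str, str] = {}
    assignments: dict[str, tuple] = {}
    to_assign = [o for o in otu_list if o.total >= 2]
    if to_assign:
        classifier = KmerBayesClassifier(reference, k=params.classifier_k)
        for o in to_assign:
            a_cls = classifier.classify(
                o.representative,
                bootstraps=params.classifier_bootstraps,
                min_conf=params.classifier_min_conf,
                seed=params.seed,
            )
            a_plc = otum.assign_by_placement(o.representative, reference_tree, reference)
            a_nj = otum.assign_by_nj(
                o.representative,
                reference,
                bootstraps=params.nj_bootstraps,
                min_support=params.nj_min_support,
                seed=params.seed,
            )
            lineage, rule = otum.consensus_assignment(a_cls, a_plc, a_nj)
            consensus[o.otu_id] = lineage
            rules[o.otu_id] = rule
            assignments[o.otu_id] = (a_cls, a_plc, a_nj)

    retained, removal = otum.remove_singletons_and_offtarget(
        otu_list, consensus, target_phylum=params.target_phylum
    )
    report.removal_report = removal
    report.otu_count_retained = len(retained)
    report.retained_reads = sum(o.total for o in retained)
    report.offtarget_reads = removal["offtarget_reads"]
    spec = specificity_report(report.offtarget_reads, report.length_passing_reads)
    report.specificity_percent = spec["specificity_percent"]
    report.offtarget_percent = spec["offtarget_percent"]
    report.funnel.append(
        ("singleton-offtarget", sum(o.total for o in otu_list), report.retained_reads)
    )

    mts = otum.aggregate_to_mts(retained, consensus)
    report.mt_count = len(mts)

    audit = (
        otum.assignment_audit(
            [o.otu_id for o in to_assign], assignments, consensus, rules
        )
        if to_assign
        else None
    )

    # --- community statistics
    otu_table = rarefied = pcoa_result = composition = None
    unifrac_out: dict = {}
    if len(retained) >= 3 and len(sample_map) >= 4:
        otu_table = comm.otu_table_from_otus(retained, sample_map.sample_ids)
        rarefied = comm.rarefy(
            otu_table, depth=params.rarefaction_depth, seed=params.seed
        )
        rarefied = rarefied.loc[:, (rarefied > 0).any(axis=0)]
        if rarefied.shape[0] >= 4 and rarefied.shape[1] >= 3:
            tree = comm.build_otu_tree([o for o in retained if o.otu_id in rarefied.columns])
            grouping = {s.sample_id: s.treatment for s in sample_map}
            grouping = {k: v for k, v in grouping.items() if k in rarefied.index}
            for name, kwargs in (
                ("weighted", {"weighted": True, "normalized": True}),
                ("unweighted", {"weighted": False}),
            ):
                dm = comm.unifrac(rarefied, tree, **kwargs)
                unifrac_out[name] = dm
                if len(set(grouping.values())) >= 2:
                    res = comm.anosim(
                        dm,
                        grouping,
                        permutations=params.anosim_permutations,
                        seed=params.seed,
                    )
                    report.anosim[name] = {
                        "R": res.R,
                        "p": res.p,
                        "permutations": res.permutations,
                    }
            if "weighted" in unifrac_out:
                pcoa_result = comm.pcoa(unifrac_out["weighted"])
            otu_to_mt = {
                oid: mt.name for mt in mts for oid in mt.member_otu_ids
            }
            composition = comm.composition_summary(
                rarefied, {o: otu_to_mt[o] for o in rarefied.columns}, sample_map
            )

    if out is not None:
        _write_artifacts(
            out, report, retained, mts, consensus, audit, otu_table, rarefied,
            unifrac_out, pcoa_result, composition, clusters,
        )

    return PipelineResult(
        report=report,
        otus=retained,
        mts=mts,
        otu_table=otu_table,
        rarefied=rarefied,
        consensus=consensus,
        audit=audit,
        unifrac=unifrac_out,
        pcoa=pcoa_result,
        composition=composition,
        screened_read_ids=frozenset(r.read_id for r in screened),
        chimera_flagged_read_ids=frozenset(
            rid for c in flagged for rid in c.member_ids
        ),
    )


def _write_artifacts(
    out, report, retained, mts, consensus, audit, otu_table, rarefied,
    unifrac_out, pcoa_result, composition, clusters,
):
    manifest = {}

    funnel_path = out / "funnel.tsv"
    rp.funnel_table(report.funnel).to_csv(funnel_path, sep="\t", index=False)
    manifest["funnel"] = funnel_path.name

    denoised = out / "denoised.fasta"
    rio.write_fasta(
        [
            SeqRecord(rio.annotate_abundance(c.centroid_id, c.total), c.centroid_seq)
            for c in clusters
        ],
        denoised,
    )
    counts = pd.DataFrame(
        [
            {"centroid_id": c.centroid_id, **dict(c.sample_counts)}
            for c in clusters
        ]
    ).fillna(0)
    counts.to_csv(out / "denoised_counts.tsv", sep="\t", index=False)
    manifest["denoised"] = denoised.name

    if otu_table is not None:
        tax = pd.Series({oid: lin.to_string() for oid, lin in consensus.items()})
        rio.write_otu_table(otu_table.T, out / "otu_table.tsv", taxonomy=tax)
        manifest["otu_table"] = "otu_table.tsv"
    if rarefied is not None:
        rarefied.to_csv(out / "otu_table_rarefied.tsv", sep="\t")
        manifest["otu_table_rarefied"] = "otu_table_rarefied.tsv"
    if audit is not None:
        audit.to_csv(out / "assignment_audit.tsv", sep="\t", index=False)
        manifest["assignment_audit"] = "assignment_audit.tsv"

    mt_rows = [
        {"mt_name": m.name, "rank": m.rank, "n_otus": len(m.member_otu_ids),
         "otu_ids": ",".join(m.member_otu_ids)}
        for m in mts
    ]
    pd.DataFrame(mt_rows).to_csv(out / "mt_table.tsv", sep="\t", index=False)
    manifest["mt_table"] = "mt_table.tsv"

    for name, dm in unifrac_out.items():
        path = out / f"unifrac_{name}.tsv"
        pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(path, sep="\t")
        manifest[f"unifrac_{name}"] = path.name
    if pcoa_result is not None:
        pcoa_result.coordinates.to_csv(out / "pcoa_coordinates.tsv", sep="\t")
        manifest["pcoa"] = "pcoa_coordinates.tsv"
    if composition is not None:
        composition["per_treatment"].to_csv(out / "composition_per_treatment.tsv", sep="\t")
        manifest["composition"] = "composition_per_treatment.tsv"

    report.manifest = manifest
    report.to_json(out / "report.json")
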