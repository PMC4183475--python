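from collections import Counter

import numpy as np
import pytest

from rpb1kit.cluster import Cluster, aggregate_unique, greedy_cluster, identity_distance
from rpb1kit.io import SampleInfo, SampleMap, SeqRecord
from rpb1kit.reads import (
    ProcessedRead,
    ReferenceFrames,
    alignment_screen,
    demultiplex,
    detect_chimeras,
    frame_correct,
    length_ambiguity_filter,
    precluster,
    remove_chimeras,
)

from conftest import random_dna


@pytest.fixture
def two_sample_map():
    return SampleMap(
        [
            SampleInfo("s1", "AAAAAAAAA", "no-tillage", "P1"),
            SampleInfo("s2", "TTTTAAAAA", "tillage", "P1"),
        ]
    )


PRIMER = "ACGTACGTACGTACGTACGT"


class TestDemultiplex:
    def _read(self, barcode, insert="GGGGCCCCGGGGCCCC"):
        return SeqRecord("r1", barcode + PRIMER + insert)

    def test_exact_barcode_assigned_and_trimmed(self, two_sample_map):
        assigned, unassigned = demultiplex(
            [self._read("AAAAAAAAA")], two_sample_map, PRIMER
        )
        assert len(assigned) == 1 and not unassigned
        assert assigned[0].sample_id == "s1"
        assert assigned[0].seq == "GGGGCCCCGGGGCCCC"

    def test_one_mismatch_still_assigned(self, two_sample_map):
        assigned, _ = demultiplex([self._read("AAAAAAAAC")], two_sample_map, PRIMER)
        assert assigned and assigned[0].sample_id == "s1"

    def test_two_mismatches_unassigned(self, two_sample_map):
        assigned, unassigned = demultiplex(
            [self._read("AAAAAAACC")], two_sample_map, PRIMER
        )
        assert not assigned and len(unassigned) == 1
        assert unassigned[0].fail_stage == "demux"

    def test_read_shorter_than_prefix_unassigned(self, two_sample_map):
        short = SeqRecord("r1", "AAAA")
        assigned, unassigned = demultiplex([short], two_sample_map, PRIMER)
        assert not assigned and len(unassigned) == 1


class TestLengthAmbiguityFilter:
    def _pr(self, seq, raw_length):
        return ProcessedRead("r", "s1", seq, raw_length)

    def test_199bp_read_removed_at_boundary(self):
        kept, removed = length_ambiguity_filter([self._pr("A" * 170, 199)])
        assert not kept and removed[0].fail_stage == "length"

    def test_200bp_read_kept(self):
        kept, _ = length_ambiguity_filter([self._pr("A" * 171, 200)])
        assert len(kept) == 1

    def test_clean_250bp_read_kept(self):
        kept, _ = length_ambiguity_filter([self._pr("A" * 221, 250)])
        assert len(kept) == 1

    def test_single_ambiguous_base_removes_read(self):
        seq = "A" * 100 + "N" + "A" * 120
        _, removed = length_ambiguity_filter([self._pr(seq, 250)])
        assert removed[0].fail_stage == "ambiguity"

    def test_trimmed_length_mode(self):
        # 199 raw but 185 trimmed: kept only when the prefix counts
        kept, _ = length_ambiguity_filter(
            [self._pr("A" * 185, 214)], min_len=200, include_prefix_in_length=True
        )
        assert len(kept) == 1
        kept2, _ = length_ambiguity_filter(
            [self._pr("A" * 185, 214)], min_len=200, include_prefix_in_length=False
        )
        assert not kept2


class TestAlignmentScreen:
    def test_identical_read_kept_with_identity_one(self, clean_reference):
        ref, _ = clean_reference
        read = ProcessedRead("r", "s1", ref.records[0].ungapped[20:280], 269)
        kept, _ = alignment_screen([read], ref)
        assert kept and kept[0].best_identity == pytest.approx(1.0)
        assert kept[0].best_ref == ref.records[0].id

    def test_random_dna_never_passes(self, clean_reference, rng):
        ref, _ = clean_reference
        reads = [
            ProcessedRead(f"r{i}", "s1", random_dna(rng, 260), 289) for i in range(100)
        ]
        kept, removed = alignment_screen(reads, ref)
        assert not kept and len(removed) == 100

    def test_read_with_five_percent_errors_kept(self, clean_reference, rng):
        ref, _ = clean_reference
        base = ref.records[0].ungapped[20:320]
        noisy = "".join(
            "ACGT"[rng.integers(0, 4)] if rng.random() < 0.05 else c for c in base
        )
        kept, _ = alignment_screen([ProcessedRead("r", "s1", noisy, 329)], ref)
        assert len(kept) == 1

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            alignment_screen([], [])


class TestPrecluster:
    def _reads(self, seqs, sample="s1"):
        return [ProcessedRead(f"r{i}", sample, s, len(s) + 29) for i, s in enumerate(seqs)]

    def test_identical_reads_collapse_to_one_centroid(self, rng):
        seq = random_dna(rng, 300)
        clusters = precluster(self._reads([seq] * 7))
        assert len(clusters) == 1
        assert clusters[0].total == 7

    def test_one_percent_divergent_reads_stay_separate(self, rng):
        a = random_dna(rng, 300)
        pos = rng.choice(300, size=3, replace=False)
        b = list(a)
        for p in pos:
            b[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[p]]
        clusters = precluster(self._reads([a, "".join(b)]))
        assert len(clusters) == 2

    def test_abundance_conservation(self, rng):
        seqs = [random_dna(rng, 250) for _ in range(5)] * 3
        clusters = precluster(self._reads(seqs))
        assert sum(c.total for c in clusters) == 15

    def test_longest_member_tracked(self, rng):
        long = random_dna(rng, 400)
        short = long[:250]
        reads = self._reads([short, short, long])
        clusters = precluster(reads)
        assert len(clusters) == 1
        assert clusters[0].longest_seq == long
        assert len(clusters[0].centroid_seq) == 250  # most abundant stays centroid


def _diverge(seq, every=33):
    """Deterministically substitute every ``every``-th base (~3 % divergence)."""
    out = list(seq)
    for i in range(0, len(out), every):
        out[i] = "ACGT"[("ACGT".index(out[i]) + 2) % 4]
    return "".join(out)


class TestChimeraDetection:
    def test_no_recombinants_no_flags(self, rng):
        parents = [random_dna(rng, 300) for _ in range(4)]
        clusters = [
            Cluster(f"p{i}", s, [f"p{i}"], Counter({"s1": 50})) for i, s in enumerate(parents)
        ]
        verdicts = detect_chimeras(clusters)
        assert not any(v.is_chimera for v in verdicts.values())

    def test_perfect_chimera_of_divergent_parents_flagged(self, rng):
        a = random_dna(rng, 300)
        b = _diverge(a)
        chimera = a[:150] + b[150:]
        clusters = [
            Cluster("pa", a, ["pa"], Counter({"s1": 100})),
            Cluster("pb", b, ["pb"], Counter({"s1": 80})),
            Cluster("q", chimera, ["q"], Counter({"s1": 1})),
        ]
        verdicts = detect_chimeras(clusters)
        v = verdicts["q"]
        assert v.is_chimera
        assert {v.parent_a, v.parent_b} == {"pa", "pb"}
        # the breakpoint is only identifiable between the flanking
        # diagnostic sites (here every 33rd base)
        assert 150 - 33 <= v.crossover <= 150 + 33

    def test_chimera_with_absent_parents_not_flagged(self, rng):
        a = random_dna(rng, 300)
        b = _diverge(a)
        chimera = a[:150] + b[150:]
        others = [random_dna(rng, 300) for _ in range(3)]
        clusters = [
            Cluster(f"o{i}", s, [f"o{i}"], Counter({"s1": 60})) for i, s in enumerate(others)
        ] + [Cluster("q", chimera, ["q"], Counter({"s1": 1}))]
        verdicts = detect_chimeras(clusters)
        assert not verdicts["q"].is_chimera

    def test_abundance_skew_respected(self, rng):
        # parents not >= 2x the query abundance: nothing to test against
        a = random_dna(rng, 300)
        b = _diverge(a)
        chimera = a[:150] + b[150:]
        clusters = [
            Cluster("pa", a, ["pa"], Counter({"s1": 10})),
            Cluster("pb", b, ["pb"], Counter({"s1": 10})),
            Cluster("q", chimera, ["q"], Counter({"s1": 9})),
        ]
        verdicts = detect_chimeras(clusters)
        assert not verdicts["q"].is_chimera

    def test_remove_chimeras_partition(self, rng):
        a = random_dna(rng, 300)
        b = _diverge(a)
        clusters = [
            Cluster("pa", a, ["pa"], Counter({"s1": 100})),
            Cluster("pb", b, ["pb"], Counter({"s1": 80})),
            Cluster("q", a[:150] + b[150:], ["q"], Counter({"s1": 1})),
        ]
        verdicts = detect_chimeras(clusters)
        kept, flagged = remove_chimeras(clusters, verdicts)
        assert len(kept) + len(flagged) == 3
        assert {c.centroid_id for c in flagged} == {"q"}


class TestFrameCorrection:
    @pytest.fixture
    def frames(self, clean_reference):
        ref, _ = clean_reference
        return ref, ReferenceFrames.from_reference(ref)

    def _find_exon_run(self, frames_obj, rid, min_run=3):
        labels = frames_obj.labels[rid]
        runs = frames_obj.run_len[rid]
        for pos in range(60, len(labels) - 60):
            if labels[pos] == 1 and runs[pos] >= min_run:
                return pos
        raise AssertionError("no exon homopolymer run found")

    def test_error_free_read_unmodified(self, frames):
        ref, fr = frames
        rid = ref.records[0].id
        read = fr.seqs[rid][20:320]
        cluster = Cluster("c1", read, ["c1"], Counter({"s1": 3}))
        results = frame_correct([cluster], {"c1": rid}, fr)
        assert results[0].status == "ok"
        assert results[0].seq == read
        assert results[0].insertions == results[0].deletions == 0

    def test_homopolymer_deletion_repaired(self, frames):
        ref, fr = frames
        rid = ref.records[0].id
        pos = self._find_exon_run(fr, rid)
        full = fr.seqs[rid]
        read = full[20:380]
        p = pos - 20
        damaged = read[:p] + read[p + 1 :]  # delete one base of the run
        cluster = Cluster("c1", damaged, ["c1"], Counter({"s1": 3}))
        res = frame_correct([cluster], {"c1": rid}, fr)[0]
        assert res.status == "ok"
        assert res.insertions == 1
        assert len(res.seq) == len(read)

    def test_homopolymer_insertion_repaired(self, frames):
        ref, fr = frames
        rid = ref.records[0].id
        pos = self._find_exon_run(fr, rid)
        full = fr.seqs[rid]
        read = full[20:380]
        p = pos - 20
        damaged = read[:p] + read[p] + read[p:]  # duplicate one run base
        cluster = Cluster("c1", damaged, ["c1"], Counter({"s1": 3}))
        res = frame_correct([cluster], {"c1": rid}, fr)[0]
        assert res.status == "ok"
        assert res.deletions == 1
        assert res.seq == read

    def test_substitution_creating_stop_codon_discarded(self, frames):
        ref, fr = frames
        rid = ref.records[0].id
        labels, phases = fr.labels[rid], fr.phases[rid]
        full = fr.seqs[rid]
        # single substitution turning a codon starting with ?AA into TAA
        for pos in range(60, len(full) - 63):
            if (
                labels[pos] == 1
                and phases[pos] == 0
                and labels[pos + 2] == 1
                and full[pos] != "T"
                and full[pos + 1 : pos + 3] == "AA"
            ):
                break
        else:
            pytest.skip("no suitable codon in this reference")
        damaged = full[:pos] + "T" + full[pos + 1 :]
        read = damaged[20:380]
        cluster = Cluster("c1", read, ["c1"], Counter({"s1": 3}))
        res = frame_correct([cluster], {"c1": rid}, fr)[0]
        assert res.status == "stop-codon"

    def test_non_homopolymer_frameshift_discarded(self, frames):
        ref, fr = frames
        rid = ref.records[0].id
        labels = fr.labels[rid]
        runs = fr.run_len[rid]
        full = fr.seqs[rid]
        # exon position outside any run of >= 2
        for pos in range(80, len(full) - 80):
            if labels[pos] == 1 and runs[pos] == 1:
                break
        read = full[20:380]
        p = pos - 20
        damaged = read[:p] + read[p + 1 :]
        cluster = Cluster("c1", damaged, ["c1"], Counter({"s1": 3}))
        res = frame_correct([cluster], {"c1": rid}, fr)[0]
        assert res.status == "frameshift"

    def test_intron_indel_never_edited(self, frames):
        ref, fr = frames
        rid = ref.records[0].id
        labels = fr.labels[rid]
        runs = fr.run_len[rid]
        full = fr.seqs[rid]
        for pos in range(60, len(full) - 80):
            if labels[pos] == 0 and runs[pos] >= 3:
                break
        else:
            pytest.skip("no intron homopolymer in this reference")
        read = full[20:440]
        p = pos - 20
        damaged = read[:p] + read[p + 1 :]
        cluster = Cluster("c1", damaged, ["c1"], Counter({"s1": 3}))
        res = frame_correct([cluster], {"c1": rid}, fr)[0]
        # the deletion sits in an intron: no edit, no frameshift, read passes
        assert res.status == "ok"
        assert res.insertions == 0 and res.deletions == 0
        assert res.seq == damaged


class TestGreedyClustering:
    def test_deterministic_order_with_ties(self, rng):
        seqs = [random_dna(rng, 200) for _ in range(6)]
        items = aggregate_unique((f"r{i}", "s1", s) for i, s in enumerate(seqs))
        a = greedy_cluster(items, 0.03, identity_distance)
        b = greedy_cluster(list(reversed(items)), 0.03, identity_distance)
        assert [c.centroid_id for c in a] == [c.centroid_id for c in b]

    def test_aggregate_unique_tracks_reads(self):
        items = aggregate_unique(
            [("r1", "s1", "ACGT"), ("r2", "s2", "ACGT"), ("r3", "s1", "TTTT")]
        )
        assert len(items) == 2
        first = items[0]
        assert first.members == ("r1", "r2")
        assert dict(first.sample_counts) == {"s1": 1, "s2": 1}
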