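from collections import Counter

import numpy as np
import pytest
from skbio import TreeNode

from rpb1kit.cluster import Cluster
from rpb1kit.io import SeqRecord, TaxonomyLineage
from rpb1kit.marker import ReferenceSet
from rpb1kit.otus import (
    KmerBayesClassifier,
    TaxAssignment,
    aggregate_to_mts,
    assign_by_nj,
    assign_by_placement,
    cluster_otus,
    consensus_assignment,
    remove_singletons_and_offtarget,
    OTU,
)
from rpb1kit.simulate import SimulationConfig, simulate_reference_set

from conftest import random_dna


def _cluster(cid, seq, counts):
    return Cluster(cid, seq, [cid], Counter(counts))


def _lineage(*names):
    return TaxonomyLineage(tuple(names))


class TestClusterOtus:
    def test_all_identical_reads_one_otu(self, rng):
        seq = random_dna(rng, 300)
        clusters = [_cluster(f"c{i}", seq, {"s1": 5}) for i in range(3)]
        otus = cluster_otus(clusters, 0.008)
        assert len(otus) == 1
        assert otus[0].total == 15

    def test_two_divergent_species_two_otus(self, clean_reference):
        ref, _ = clean_reference
        a = ref.records[0].ungapped[20:320]
        b = ref.records[1].ungapped[20:320]
        clusters = [_cluster("a", a, {"s1": 10}), _cluster("b", b, {"s1": 8})]
        assert len(cluster_otus(clusters, 0.008)) == 2

    def test_count_conservation(self, rng):
        clusters = [
            _cluster(f"c{i}", random_dna(rng, 250), {"s1": i + 1, "s2": 2})
            for i in range(6)
        ]
        otus = cluster_otus(clusters, 0.01)
        assert sum(o.total for o in otus) == sum(c.total for c in clusters)

    def test_empty_input_empty_output(self):
        assert cluster_otus([], 0.008) == []

    def test_nearby_variants_absorbed_into_species_otu(self, clean_reference):
        ref, _ = clean_reference
        base = ref.records[0].ungapped[20:320]
        variant = "T" + base[1:] if base[0] != "T" else "A" + base[1:]
        clusters = [
            _cluster("main", base, {"s1": 50}),
            _cluster("var", variant, {"s1": 1}),
        ]
        assert len(cluster_otus(clusters, 0.008)) == 1


@pytest.fixture(scope="module")
def assignment_reference():
    cfg = SimulationConfig(
        n_species=6,
        isolates_per_species=2,
        intra_species_divergence=0.004,
        include_offtarget=True,
        seed=13,
    )
    return simulate_reference_set(cfg)


class TestKmerBayesClassifier:
    def test_reference_sequence_classified_to_own_species(self, assignment_reference):
        ref, _ = assignment_reference
        clf = KmerBayesClassifier(ref)
        rec = ref.records[0]
        a = clf.classify(rec.ungapped, seed=1)
        assert a.lineage == ref.lineages[rec.id]
        assert a.confidence == pytest.approx(1.0)

    def test_random_dna_unassigned(self, assignment_reference, rng):
        ref, _ = assignment_reference
        clf = KmerBayesClassifier(ref)
        a = clf.classify(random_dna(rng, 300), seed=1)
        assert a.lineage.depth == 0

    def test_query_shorter_than_k_unassigned(self, assignment_reference):
        ref, _ = assignment_reference
        a = KmerBayesClassifier(ref).classify("ACGT", seed=1)
        assert not a.lineage

    def test_between_genera_mosaic_not_species_deep(self, assignment_reference):
        # a half-and-half mosaic of two congeneric species should not be
        # confidently assigned at species rank
        ref, _ = assignment_reference
        clf = KmerBayesClassifier(ref)
        pairs = {}
        for rec in ref.records:
            lin = ref.lineages[rec.id]
            if lin.at("genus"):
                pairs.setdefault(lin.at("genus"), []).append(rec)
        genus, members = next(
            (g, m) for g, m in pairs.items()
            if len({ref.species[r.id] for r in m}) == 2
        )
        sp = sorted({ref.species[r.id] for r in members})
        a_seq = next(r.ungapped for r in members if ref.species[r.id] == sp[0])
        b_seq = next(r.ungapped for r in members if ref.species[r.id] == sp[1])
        half = len(a_seq) // 2
        mosaic = a_seq[:half] + b_seq[half:]
        a = clf.classify(mosaic, seed=1)
        assert a.lineage.at("genus") in (None, genus)
        if a.lineage.at("species"):
            assert a.confidence >= 0.8  # deep only when the bootstrap is sure


class TestPlacement:
    def test_query_identical_to_leaf_gets_species(self, assignment_reference):
        ref, tree = assignment_reference
        rec = ref.records[2]
        a = assign_by_placement(rec.ungapped, tree, ref)
        assert a.lineage == ref.lineages[rec.id]

    def test_short_query_unassigned(self, assignment_reference):
        ref, tree = assignment_reference
        a = assign_by_placement(ref.records[0].ungapped[:40], tree, ref)
        assert not a.lineage

    def test_midway_between_congeners_gives_genus(self):
        # hand-built 4-leaf case: two congeneric species A1, A2 and two
        # outgroup species; the query is an even mosaic of A1 and A2.
        # Divergence sites of the three contrasts are kept disjoint so the
        # case is exactly symmetric between A1 and A2.
        rng = np.random.default_rng(3)
        base = random_dna(rng, 400)

        def diverge(seq, sites, rot=1):
            out = list(seq)
            for i in sites:
                out[i] = "ACGT"[("ACGT".index(out[i]) + rot) % 4]
            return "".join(out)

        sites_a = list(range(5, 400, 40))   # = 5, 13 mod 16: disjoint below
        sites_b = list(range(8, 400, 16))   # = 8 mod 16
        sites_c = list(range(2, 400, 16))   # = 2 mod 16
        # both congeners are derived (differently) at the contrast sites, so
        # the outgroup state favours neither and the case is symmetric
        a1 = diverge(base, sites_a, rot=1)
        a2 = diverge(base, sites_a, rot=2)
        b = diverge(base, sites_b)
        c = diverge(b, sites_c)
        records = [
            SeqRecord("A1", a1), SeqRecord("A2", a2),
            SeqRecord("B", b), SeqRecord("C", c),
        ]
        lineages = {
            "A1": _lineage("P", "Cl", "O", "F", "GenusA", "a-one"),
            "A2": _lineage("P", "Cl", "O", "F", "GenusA", "a-two"),
            "B": _lineage("P", "Cl", "O", "F2", "GenusB", "b-one"),
            "C": _lineage("P", "Cl", "O", "F2", "GenusC", "c-one"),
        }
        species = {k: v.deepest_name for k, v in lineages.items()}
        ref = ReferenceSet(records, species, lineages)
        tree = TreeNode.read(["((A1:0.01,A2:0.01):0.05,(B:0.03,C:0.03):0.05);"])
        # query: takes A1's state at half the A sites, A2's at the other half
        q = list(base)
        for k, i in enumerate(sites_a):
            q[i] = a2[i] if k % 2 else a1[i]
        a = assign_by_placement("".join(q), tree, ref)
        assert a.lineage.at("genus") == "GenusA"
        assert a.lineage.at("species") is None


class TestNjAssignment:
    def test_query_identical_to_reference_species_assigned(self, assignment_reference):
        # with two near-identical isolates per species, bootstrap columns
        # occasionally swap the cherry partner, so support is high but not 1
        ref, _ = assignment_reference
        rec = ref.records[1]
        a = assign_by_nj(rec.ungapped, ref, bootstraps=50, seed=3)
        assert a.lineage == ref.lineages[rec.id]
        assert a.confidence >= 0.7

    def test_identical_query_in_distinct_species_panel_full_support(self, rng):
        base = random_dna(rng, 400)

        def diverge(seq, sites):
            out = list(seq)
            for i in sites:
                out[i] = "ACGT"[("ACGT".index(out[i]) + 1) % 4]
            return "".join(out)

        seqs = {
            "w": base,
            "x": diverge(base, range(3, 400, 10)),
            "y": diverge(base, range(5, 400, 9)),
            "z": diverge(base, range(7, 400, 11)),
        }
        records = [SeqRecord(k, s) for k, s in seqs.items()]
        lineages = {
            k: TaxonomyLineage(("P", "C", "O", "F", f"G{k}", f"sp-{k}"))
            for k in seqs
        }
        ref = ReferenceSet(records, {k: f"sp-{k}" for k in seqs}, lineages)
        a = assign_by_nj(seqs["x"], ref, bootstraps=50, seed=3)
        assert a.lineage == lineages["x"]
        assert a.confidence == pytest.approx(1.0)

    def test_random_query_unassigned(self, assignment_reference, rng):
        ref, _ = assignment_reference
        a = assign_by_nj(random_dna(rng, 400), ref, bootstraps=30, seed=3)
        assert a.lineage.depth <= 1

    def test_too_few_references_rejected(self):
        records = [SeqRecord(f"r{i}", "ACGTACGTAC") for i in range(3)]
        ref = ReferenceSet(records, {r.id: "x" for r in records})
        with pytest.raises(ValueError):
            assign_by_nj("ACGTACGTAC", ref)


class TestNjTopology:
    def test_nj_recovers_additive_four_taxon_tree(self):
        """NJ on an additive matrix matches the generating quartet topology,
        verified against the four-point condition over all three pairings."""
        from rpb1kit.otus import _nj_tree

        # tree ((a,b),(c,d)) with internal branch 0.06
        d = {
            ("a", "b"): 0.02 + 0.03,
            ("a", "c"): 0.02 + 0.06 + 0.04,
            ("a", "d"): 0.02 + 0.06 + 0.05,
            ("b", "c"): 0.03 + 0.06 + 0.04,
            ("b", "d"): 0.03 + 0.06 + 0.05,
            ("c", "d"): 0.04 + 0.05,
        }
        ids = ["a", "b", "c", "d"]
        mat = np.zeros((4, 4))
        for i, x in enumerate(ids):
            for j, y in enumerate(ids):
                if i != j:
                    mat[i, j] = d[tuple(sorted((x, y)))]
        # four-point condition oracle: the true split minimises the sum
        sums = {
            ("ab", "cd"): d[("a", "b")] + d[("c", "d")],
            ("ac", "bd"): d[("a", "c")] + d[("b", "d")],
            ("ad", "bc"): d[("a", "d")] + d[("b", "c")],
        }
        assert min(sums, key=sums.get) == ("ab", "cd")
        tree = _nj_tree(mat, ids)
        # the tree must contain the {a,b} (equivalently {c,d}) bipartition
        splits = set()
        for node in tree.traverse(include_self=False):
            if not node.is_tip():
                splits.add(frozenset(t.name for t in node.tips()))
        assert frozenset({"a", "b"}) in splits or frozenset({"c", "d"}) in splits


class TestConsensus:
    C = staticmethod(lambda lin, conf=0.9: TaxAssignment("classifier", lin, conf))
    P = staticmethod(lambda lin, conf=0.9: TaxAssignment("placement", lin, conf))
    N = staticmethod(lambda lin, conf=0.9: TaxAssignment("nj", lin, conf))

    def test_unanimous_species_lineage_kept(self):
        lin = _lineage("P", "C", "O", "F", "G", "S")
        out, rule = consensus_assignment(self.C(lin), self.P(lin), self.N(lin))
        assert out == lin

    def test_classifier_refined_by_tree_methods(self):
        fam = _lineage("P", "C", "O", "F")
        spec = _lineage("P", "C", "O", "F", "G", "S")
        out, rule = consensus_assignment(self.C(fam), self.P(spec), self.N(spec))
        assert out == spec
        assert "refined" in rule

    def test_three_way_genus_disagreement_falls_back_to_family(self):
        a = _lineage("P", "C", "O", "F", "G1", "S1")
        b = _lineage("P", "C", "O", "F", "G2", "S2")
        c = _lineage("P", "C", "O", "F", "G3", "S3")
        out, _ = consensus_assignment(self.C(a), self.P(b), self.N(c))
        assert out == _lineage("P", "C", "O", "F")

    def test_all_empty_is_unassigned(self):
        empty = TaxonomyLineage(())
        out, rule = consensus_assignment(self.C(empty), self.P(empty), self.N(empty))
        assert not out and rule == "all-empty"

    def test_never_deeper_than_deepest_input(self):
        rng = np.random.default_rng(0)
        names = ["P", "C", "O", "F", "G", "S"]
        for _ in range(50):
            lins = [
                _lineage(*names[: rng.integers(0, 7)]) for _ in range(3)
            ]
            out, _ = consensus_assignment(
                self.C(lins[0]), self.P(lins[1]), self.N(lins[2])
            )
            assert out.depth <= max(l.depth for l in lins)

    def test_never_contradicts_any_nonempty_input(self):
        a = _lineage("P", "C", "O", "F", "G1")
        b = _lineage("P", "C", "O", "F", "G2", "S2")
        out, _ = consensus_assignment(self.C(TaxonomyLineage(())), self.P(a), self.N(b))
        for lin in (a, b):
            for r in range(min(out.depth, lin.depth)):
                assert out.names[r] == lin.names[r]


class TestRemovalAndMts:
    def _otu(self, oid, total, per_sample=None):
        counts = per_sample or {"s1": total}
        return OTU(oid, "ACGT" * 50, oid, Counter(counts), [oid])

    def test_singleton_removed(self):
        lin = _lineage("Glomeromycota", "Glomeromycetes")
        kept, report = remove_singletons_and_offtarget(
            [self._otu("o1", 1), self._otu("o2", 5)], {"o1": lin, "o2": lin}
        )
        assert [o.otu_id for o in kept] == ["o2"]
        assert report["singleton_otus"] == 1

    def test_offtarget_phylum_removed_and_counted(self):
        glo = _lineage("Glomeromycota", "Glomeromycetes")
        asco = _lineage("Ascomycota", "Sordariomycetes")
        kept, report = remove_singletons_and_offtarget(
            [self._otu("o1", 20), self._otu("o2", 15)], {"o1": glo, "o2": asco}
        )
        assert [o.otu_id for o in kept] == ["o1"]
        assert report["offtarget_reads"] == 15

    def test_fourteen_otus_one_species_one_mt(self):
        lin = _lineage("P", "C", "O", "F", "G", "Rh. irregularis")
        otus = [self._otu(f"o{i}", 5) for i in range(14)]
        mts = aggregate_to_mts(otus, {o.otu_id: lin for o in otus})
        assert len(mts) == 1
        assert mts[0].name == "Rh. irregularis"
        assert len(mts[0].member_otu_ids) == 14

    def test_family_level_mt_named_sp(self):
        fam = _lineage("P", "C", "O", "Glomeraceae")
        otus = [self._otu("o1", 5)]
        mts = aggregate_to_mts(otus, {"o1": fam})
        assert mts[0].name == "Glomeraceae sp."
        assert mts[0].rank == "family"

    def test_alias_merges_sibling_species(self):
        l1 = _lineage("P", "C", "O", "F", "Cl", "Cl. etunicatum")
        l2 = _lineage("P", "C", "O", "F", "Cl", "Cl. claroideum")
        otus = [self._otu("o1", 5), self._otu("o2", 5)]
        aliases = {
            frozenset({"Cl. etunicatum", "Cl. claroideum"}): "Cl. etunicatum/Cl. claroideum"
        }
        mts = aggregate_to_mts(otus, {"o1": l1, "o2": l2}, aliases)
        assert len(mts) == 1
        assert mts[0].name == "Cl. etunicatum/Cl. claroideum"

    def test_mts_partition_otus(self):
        lins = [
            _lineage("P", "C", "O", "F", "G", f"S{i % 3}") for i in range(9)
        ]
        otus = [self._otu(f"o{i}", 4) for i in range(9)]
        mts = aggregate_to_mts(otus, {f"o{i}": lins[i] for i in range(9)})
        seen = [oid for m in mts for oid in m.member_otu_ids]
        assert sorted(seen) == sorted(o.otu_id for o in otus)

    def test_simulated_clean_data_k_species_k_mts(self, clean_reference, clean_config):
        ref, tree = clean_reference
        reps = {}
        for rec in ref.records:
            reps.setdefault(ref.species[rec.id], rec.ungapped[20:320])
        otus = [
            _cluster(f"c{i}", seq, {"s1": 10}) for i, seq in enumerate(reps.values())
        ]
        otu_list = cluster_otus(otus, 0.008)
        lins = {}
        for o in otu_list:
            a = assign_by_placement(o.representative, tree, ref)
            lins[o.otu_id] = a.lineage
        mts = aggregate_to_mts(otu_list, lins)
        assert len(mts) == clean_config.n_species
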