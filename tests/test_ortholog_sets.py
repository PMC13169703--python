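"""Orthology-graph construction, validation and set assembly."""

import numpy as np
import pytest

from helpers import brute_force_local_score
from trnapanel.annotations_io import LiftoverRecord, TRNALocus
from trnapanel.ortholog_sets import (
    OrthologSet,
    OrthologyGraph,
    ProjectedInterval,
    assemble_sets,
    classify_absence,
    enforce_bidirectional,
    local_align,
    project_orthologs,
    validate_edge,
)


def _locus(genome, lid, start, end, chrom="c", strand="+"):
    return TRNALocus(lid, genome, chrom, start, end, strand, "Gly", "GCC", 70.0)


def _rec(sg, ss, se, dg, ds, de, strand="+", chrom="c"):
    return LiftoverRecord(sg, chrom, ss, se, dg, chrom, ds, de, strand)


class TestProjectOrthologs:
    def test_fragments_with_small_gap_merge_and_link(self):
        loci = {
            "A": [_locus("A", "a1", 500, 570)],
            "B": [_locus("B", "b1", 100, 160)],
        }
        records = [
            _rec("A", 480, 540, "B", 100, 130),
            _rec("A", 545, 590, "B", 132, 160),
        ]
        og = project_orthologs(records, loci, min_len=50, merge_gap=10)
        assert og.projections[(("A", "a1"), "B")] == [
            ProjectedInterval("c", 100, 160, "+")
        ]
        assert og.graph.has_edge(("A", "a1"), ("B", "b1"))

    def test_short_merged_interval_creates_no_edge_but_is_recorded(self):
        loci = {
            "A": [_locus("A", "a1", 500, 570)],
            "B": [_locus("B", "b1", 100, 140)],
        }
        og = project_orthologs(
            [_rec("A", 480, 540, "B", 100, 140)], loci, min_len=50
        )
        assert og.graph.number_of_edges() == 0
        assert og.projections[(("A", "a1"), "B")][0].length == 40

    def test_duplicate_records_collapse_to_one_edge(self):
        loci = {
            "A": [_locus("A", "a1", 500, 570)],
            "B": [_locus("B", "b1", 100, 160)],
        }
        rec = _rec("A", 480, 590, "B", 100, 160)
        og = project_orthologs([rec, rec, rec], loci, min_len=50)
        assert og.graph.number_of_edges() == 1
        assert len(og.projections[(("A", "a1"), "B")]) == 1

    def test_unknown_genome_errors(self):
        with pytest.raises(ValueError, match="unknown genome"):
            project_orthologs(
                [_rec("A", 0, 100, "Z", 0, 100)],
                {"A": [_locus("A", "a1", 0, 70)]},
            )


class TestEnforceBidirectional:
    def test_one_way_edges_removed_two_way_kept(self):
        og = OrthologyGraph()
        og.graph.add_edge(
            ("A", "a1"), ("B", "b1"), directions={("A", "B"), ("B", "A")}
        )
        og.graph.add_edge(("A", "a2"), ("B", "b2"), directions={("A", "B")})
        out = enforce_bidirectional(og)
        assert out.graph.has_edge(("A", "a1"), ("B", "b1"))
        assert not out.graph.has_edge(("A", "a2"), ("B", "b2"))

    def test_empty_graph_stays_empty(self):
        assert enforce_bidirectional(OrthologyGraph()).graph.number_of_edges() == 0


class TestLocalAlign:
    def test_identity(self):
        res = local_align("ACGTACGT", "ACGTACGT")
        assert (res.score, res.aligned_length) == (8, 8)

    def test_all_mismatches_is_no_alignment(self):
        assert local_align("AAAA", "TTTT").aligned_length == 0

    def test_worked_example(self):
        # optimal local alignment of ACGT vs AGT is "GT" (score 2), beating
        # the gapped A-GT alignment (score 1)
        res = local_align("ACGT", "AGT")
        assert (res.score, res.aligned_length) == (2, 2)

    def test_empty_string(self):
        assert local_align("", "ACGT") == local_align("ACGT", "")
        assert local_align("", "ACGT").score == 0

    def test_matches_brute_force_on_random_short_pairs(self):
        rng = np.random.default_rng(11)
        for _ in range(40):
            a = "".join("ACGT"[i] for i in rng.integers(0, 4, rng.integers(1, 8)))
            b = "".join("ACGT"[i] for i in rng.integers(0, 4, rng.integers(1, 8)))
            assert local_align(a, b).score == brute_force_local_score(a, b)


class TestValidateEdge:
    def test_identical_flanked_sequences_pass(self):
        rng = np.random.default_rng(5)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 270))
        assert validate_edge(seq, seq, 0.5)

    def test_identical_bodies_in_unrelated_flanks_fail(self):
        # the safeguard the flank requirement exists for: two copies of the
        # same 70 bp gene placed at unrelated 100 bp flanking contexts
        rng = np.random.default_rng(6)
        body = "".join("ACGT"[i] for i in rng.integers(0, 4, 70))
        f = lambda: "".join("ACGT"[i] for i in rng.integers(0, 4, 100))
        assert not validate_edge(f() + body + f(), f() + body + f(), 0.5)

    def test_empty_sequence_fails(self):
        assert not validate_edge("", "ACGT" * 70, 0.5)


class TestAssembleSets:
    def _graph(self, edges):
        og = OrthologyGraph()
        for u, v in edges:
            og.graph.add_edge(u, v, directions=set())
        return og

    def test_triangle_becomes_one_set(self):
        og = self._graph(
            [(("A", "a1"), ("B", "b1")), (("B", "b1"), ("C", "c1")), (("A", "a1"), ("C", "c1"))]
        )
        (s,) = assemble_sets(og)
        assert s.members == {"A": "a1", "B": "b1", "C": "c1"}

    def test_path_resolved_by_lowest_degree_lexicographic_removal(self):
        # path a1-b1-c1: degrees 1,2,1; a1 removed first (lexicographic),
        # leaving the clique {b1,c1}; a1 re-enters as a singleton set
        og = self._graph([(("A", "a1"), ("B", "b1")), (("B", "b1"), ("C", "c1"))])
        sets = {frozenset(s.members.items()) for s in assemble_sets(og)}
        assert sets == {
            frozenset({("B", "b1"), ("C", "c1")}),
            frozenset({("A", "a1")}),
        }

    def test_two_loci_of_same_genome_resolved(self):
        og = self._graph([(("A", "a1"), ("B", "b1")), (("A", "a2"), ("B", "b1"))])
        sets = assemble_sets(og)
        genomes_per_set = [list(s.members) for s in sets]
        assert all(len(g) == len(set(g)) for g in genomes_per_set)
        all_nodes = [n for s in sets for n in s.nodes]
        assert len(all_nodes) == len(set(all_nodes)) == 3

    def test_set_named_after_reference_member_when_present(self):
        og = self._graph([(("A", "a1"), ("B", "b1"))])
        (s,) = assemble_sets(og, reference="B")
        assert s.set_id == "B|b1"

    def test_loci_disjoint_across_sets_on_full_panel(self, default_analysis):
        seen = set()
        for s in default_analysis.sets:
            for node in s.nodes:
                assert node not in seen
                seen.add(node)


class TestClassifyAbsence:
    def _setup(self, projections):
        og = OrthologyGraph(projections=projections)
        oset = OrthologSet("A|a1", {"A": "a1", "B": "b1"})
        annotated = [_locus("C", "c1", 0, 70)]
        return og, oset, annotated

    def test_no_projection_is_missing(self):
        og, oset, ann = self._setup({})
        assert classify_absence(oset, "C", og, ann) == "missing"

    def test_projection_without_scan_hit_is_pseudo(self):
        og, oset, ann = self._setup(
            {(("A", "a1"), "C"): [ProjectedInterval("c", 1000, 1100, "+")]}
        )
        assert classify_absence(oset, "C", og, ann) == "pseudo"

    def test_projection_onto_annotated_locus_is_conflict(self):
        og, oset, ann = self._setup(
            {(("A", "a1"), "C"): [ProjectedInterval("c", 10, 90, "+")]}
        )
        assert classify_absence(oset, "C", og, ann) == "conflict"

    def test_member_genome_rejected(self):
        og, oset, ann = self._setup({})
        with pytest.raises(ValueError):
            classify_absence(oset, "A", og, ann)
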