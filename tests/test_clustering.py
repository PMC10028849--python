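import numpy as np
import pytest

from netflow3d.clustering import (
    C1,
    C2,
    C3,
    C4,
    Cluster3D,
    dedupe_predicted,
    expand_to_residues,
    inter_clusters,
    interface_clusters,
    intra_clusters,
)
from netflow3d.io_preprocess import IN_FRAME, LOF, MutationRecord
from netflow3d.structurome import (
    ContactGraph,
    INTRA_EXPERIMENTAL,
    INTRA_PREDICTED,
    INTER_EXPERIMENTAL,
    InterfaceAnnotation,
)

from conftest import brute_force_components


def record(protein, start, end=None, term="missense_variant", sample="S1",
           cls=IN_FRAME):
    return MutationRecord(
        sample_id=sample, cancer_type="T", gene_id=protein, protein_id=protein,
        residue_start=start, residue_end=end or start,
        consequence_term=term, consequence_class=cls,
    )


def graph_from_edges(edges, kind=INTRA_PREDICTED, vertices=(), cutoff=6.0):
    g = ContactGraph(kind, cutoff)
    for u, v in edges:
        g.add_contact(u, v, 5.0)
    for v in vertices:
        g.add_vertex(v)
    return g


class TestExpandToResidues:
    def test_footprints(self):
        mutated = expand_to_residues(
            [
                record("P1", 42),
                record("P1", 10, 12, term="inframe_deletion"),
                record("P1", 99, term="inframe_insertion"),
            ],
            {"P1": 100},
        )
        assert mutated.residues_of("P1") == {42, 10, 11, 12, 99}

    def test_out_of_range_dropped(self):
        mutated = expand_to_residues([record("P1", 999)], {"P1": 500})
        assert mutated.residues_of("P1") == set()

    def test_unknown_length_skipped_and_lof_ignored(self):
        mutated = expand_to_residues(
            [record("P_unknown", 5),
             record("P1", 7, term="stop_gained", cls=LOF)],
            {"P1": 100},
        )
        assert mutated.by_residue == {}


class TestIntraClusters:
    def test_edge_joins_two_residues(self):
        g = graph_from_edges([(("P1", 5), ("P1", 40))])
        mutated = expand_to_residues([record("P1", 5), record("P1", 40)],
                                     {"P1": 100})
        clusters = intra_clusters(g, mutated)
        assert len(clusters) == 1
        assert clusters[0].residues["P1"] == frozenset({5, 40})
        assert clusters[0].source == C3

    def test_isolated_vertices_are_singletons(self):
        g = graph_from_edges([], vertices=[("P1", i) for i in range(1, 11)])
        mutated = expand_to_residues([record("P1", 2), record("P1", 8)],
                                     {"P1": 100})
        clusters = intra_clusters(g, mutated)
        assert sorted(c.residues["P1"] for c in clusters) == [
            frozenset({2}), frozenset({8})
        ]

    def test_residue_outside_graph_excluded(self):
        g = graph_from_edges([], vertices=[("P1", 1)],
                             kind=INTRA_EXPERIMENTAL)
        mutated = expand_to_residues([record("P1", 1), record("P1", 50)],
                                     {"P1": 100})
        clusters = intra_clusters(g, mutated)
        assert len(clusters) == 1 and clusters[0].residues["P1"] == frozenset({1})
        assert clusters[0].source == C1

    def test_observed_counts_events_not_residues(self):
        g = graph_from_edges([(("P1", 5), ("P1", 6))])
        mutated = expand_to_residues(
            [record("P1", 5, sample="S1"), record("P1", 5, sample="S2"),
             record("P1", 6, sample="S3")],
            {"P1": 100},
        )
        (cluster,) = intra_clusters(g, mutated)
        assert cluster.observed == 3
        assert cluster.k == 2

    def test_deletion_spanning_cluster_counts_once(self):
        g = graph_from_edges([(("P1", 10), ("P1", 11))])
        mutated = expand_to_residues(
            [record("P1", 10, 12, term="inframe_deletion")], {"P1": 100}
        )
        (cluster,) = intra_clusters(g, mutated)
        assert cluster.observed == 1

    def test_input_order_invariance(self):
        edges = [(("P1", i), ("P1", i + 1)) for i in range(1, 6)]
        recs = [record("P1", i, sample=f"S{i}") for i in (1, 3, 4, 6)]
        a = intra_clusters(graph_from_edges(edges),
                           expand_to_residues(recs, {"P1": 100}))
        b = intra_clusters(graph_from_edges(list(reversed(edges))),
                           expand_to_residues(list(reversed(recs)), {"P1": 100}))
        assert [c.residue_set() for c in a] == [c.residue_set() for c in b]

    def test_components_match_brute_force_oracle(self, rng):
        for trial in range(200):
            n = int(rng.integers(2, 50))
            nodes = [("P1", i + 1) for i in range(n)]
            p_edge = rng.uniform(0.01, 0.15)
            edges = [
                (nodes[i], nodes[j])
                for i in range(n) for j in range(i + 1, n)
                if rng.random() < p_edge
            ]
            g = graph_from_edges(edges, vertices=nodes)
            mut_idx = rng.random(n) < 0.5
            recs = [record("P1", i + 1) for i in range(n) if mut_idx[i]]
            if not recs:
                continue
            mutated = expand_to_residues(recs, {"P1": n})
            clusters = intra_clusters(g, mutated)
            mut_nodes = {("P1", i + 1) for i in range(n) if mut_idx[i]}
            induced = [(u, v) for u, v in edges
                       if u in mut_nodes and v in mut_nodes]
            oracle = brute_force_components(mut_nodes, induced)
            assert {c.residue_set() for c in clusters} == oracle
            # disjoint cover of the eligible mutated vertex set
            union = set()
            for c in clusters:
                assert not (c.residue_set() & union)
                union |= c.residue_set()
            assert union == mut_nodes


class TestInterClusters:
    def setup_graphs(self):
        g1 = graph_from_edges(
            [(("A", 10), ("A", 11))], kind=INTRA_EXPERIMENTAL,
            vertices=[("A", 10), ("A", 11), ("B", 20), ("B", 21)],
        )
        g2 = ContactGraph(INTER_EXPERIMENTAL, 9.0)
        g2.add_contact(("A", 11), ("B", 20), 8.0)
        return g1, g2

    def test_requires_inter_edge(self):
        g1, g2 = self.setup_graphs()
        mutated = expand_to_residues(
            [record("A", 10), record("A", 11)], {"A": 100, "B": 100}
        )
        assert inter_clusters(g1, g2, mutated, [("A", "B")]) == []

    def test_single_inter_edge_cluster(self):
        g1, g2 = self.setup_graphs()
        mutated = expand_to_residues(
            [record("A", 11), record("B", 20)], {"A": 100, "B": 100}
        )
        (cluster,) = inter_clusters(g1, g2, mutated, [("A", "B")])
        assert cluster.residue_set() == {("A", 11), ("B", 20)}
        assert cluster.source == C2 and cluster.ppi == frozenset("AB")

    def test_merged_component_includes_intra_neighbors(self):
        g1, g2 = self.setup_graphs()
        mutated = expand_to_residues(
            [record("A", 10), record("A", 11), record("B", 20)],
            {"A": 100, "B": 100},
        )
        (cluster,) = inter_clusters(g1, g2, mutated, [("A", "B")])
        assert cluster.residue_set() == {("A", 10), ("A", 11), ("B", 20)}
        # oracle on the merged graph
        oracle = brute_force_components(
            cluster.residue_set(),
            [(("A", 10), ("A", 11)), (("A", 11), ("B", 20))],
        )
        assert cluster.residue_set() in oracle

    def test_restricted_to_supplied_ppis(self):
        g1, g2 = self.setup_graphs()
        mutated = expand_to_residues(
            [record("A", 11), record("B", 20)], {"A": 100, "B": 100}
        )
        assert inter_clusters(g1, g2, mutated, [("A", "C")]) == []

    def test_deleting_inter_edges_splits_across_proteins(self):
        g1, g2 = self.setup_graphs()
        mutated = expand_to_residues(
            [record("A", 10), record("A", 11), record("B", 20)],
            {"A": 100, "B": 100},
        )
        (cluster,) = inter_clusters(g1, g2, mutated, [("A", "B")])
        intra_only = brute_force_components(
            cluster.residue_set(), [(("A", 10), ("A", 11))]
        )
        for piece in intra_only:
            assert len({p for p, _ in piece}) == 1


class TestInterfaceClusters:
    def make_annotation(self):
        ann = InterfaceAnnotation()
        for r in (10, 20):
            ann.add("A", "B", "A", r)
        ann.add("A", "B", "B", 5)
        return ann

    def test_definitional_union(self):
        mutated = expand_to_residues(
            [record("A", 10), record("B", 5)], {"A": 100, "B": 100}
        )
        (cluster,) = interface_clusters(self.make_annotation(), mutated,
                                        [("A", "B")])
        assert cluster.residue_set() == {("A", 10), ("B", 5)}
        assert cluster.source == C4

    def test_no_mutated_interface_residue_no_cluster(self):
        mutated = expand_to_residues([record("A", 99)], {"A": 100})
        assert interface_clusters(self.make_annotation(), mutated,
                                  [("A", "B")]) == []

    def test_fully_mutated_interface(self):
        mutated = expand_to_residues(
            [record("A", 10), record("A", 20), record("B", 5)],
            {"A": 100, "B": 100},
        )
        (cluster,) = interface_clusters(self.make_annotation(), mutated)
        assert cluster.residue_set() == {("A", 10), ("A", 20), ("B", 5)}


class TestDedupePredicted:
    def c(self, source, protein, residues, observed=1):
        return Cluster3D(
            cluster_id=f"{source}:{protein}:{min(residues)}",
            source=source, proteins=(protein,),
            residues={protein: frozenset(residues)},
            mutations=[record(protein, min(residues))], observed=observed,
        )

    def test_overlap_with_c1_removed_disjoint_kept(self):
        c1 = [self.c(C1, "P1", {5, 6})]
        c3 = [self.c(C3, "P1", {6, 7}), self.c(C3, "P1", {50})]
        kept = dedupe_predicted(c3, c1)
        assert [k.residues["P1"] for k in kept] == [frozenset({50})]

    def test_redundancy_rule_consults_c1_only(self):
        # a C3 cluster overlapping a C2 cluster (but no C1 cluster) stays:
        # the redundancy rule compares against the experimental intra family
        c3 = [self.c(C3, "P1", {6, 7})]
        assert dedupe_predicted(c3, []) == c3
        disjoint_c1 = [self.c(C1, "P1", {90})]
        assert dedupe_predicted(c3, disjoint_c1) == c3
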