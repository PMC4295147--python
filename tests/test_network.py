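import random

import networkx as nx
import pytest

from plasnet.network import (
    ComponentSummary,
    SweepConfig,
    build_network,
    classify_edges,
    connected_components,
    connectivity_rows,
    connectivity_table,
    identity_histogram,
    largest_component,
    paralog_class_counts,
    threshold_sweep,
)
from plasnet.seq_io import ProteinRecord, Replicon, RepliconSet
from plasnet.similarity import HomologyEdge


def tiny_rset():
    reps = [
        Replicon("P1", "plasmid"),
        Replicon("P2", "plasmid"),
        Replicon("CHR", "chromosome"),
    ]
    prots = [
        ProteinRecord(pid, rid, "MKVL")
        for pid, rid in [
            ("A", "P1"), ("B", "P1"), ("C", "P2"), ("D", "P2"), ("E", "CHR"),
        ]
    ]
    return RepliconSet(replicons=reps, proteins=prots)


def bfs_partition(nodes, adj):
    """Brute-force breadth-first component oracle."""
    seen, parts = set(), []
    for start in nodes:
        if start in seen:
            continue
        queue, comp = [start], set()
        while queue:
            n = queue.pop()
            if n in comp:
                continue
            comp.add(n)
            queue.extend(adj.get(n, ()))
        seen |= comp
        parts.append(frozenset(comp))
    return {p for p in parts if len(p) > 1}


class TestClassification:
    def test_edge_classes(self):
        rset = tiny_rset()
        edges = classify_edges(
            [
                HomologyEdge("A", "B", 50, 1e-5),
                HomologyEdge("A", "C", 50, 1e-5),
                HomologyEdge("A", "E", 50, 1e-5),
            ],
            rset,
        )
        assert [e.edge_class for e in edges] == [
            "in_paralog", "out_paralog", "plasmid_chromosome",
        ]
        counts = paralog_class_counts(edges, rset)
        assert counts == {"in_paralog": 1, "out_paralog": 1, "plasmid_chromosome": 1}
        assert sum(counts.values()) == len(edges)


class TestBuildNetwork:
    def make_edges(self):
        return classify_edges(
            [HomologyEdge("A", "B", 45, 1e-5), HomologyEdge("A", "C", 80, 1e-9)],
            tiny_rset(),
        )

    def test_threshold_filter_at_plasmidome_level(self):
        g = build_network(self.make_edges(), tiny_rset(), "plasmidome", 50)
        assert g.number_of_edges() == 1
        assert g.has_edge("A", "C")
        assert "E" not in g  # chromosome proteins not eligible

    def test_class_filter_at_plasmid_vs_chromosome_level(self):
        g = build_network(self.make_edges(), tiny_rset(), "plasmid_vs_chromosome", 40)
        assert g.number_of_edges() == 0
        assert set(g.nodes) == {"A", "B", "C", "D", "E"}

    def test_top_threshold_keeps_only_full_identity(self):
        edges = classify_edges(
            [HomologyEdge("A", "B", 100.0, 0.0), HomologyEdge("C", "D", 99.9, 0.0)],
            tiny_rset(),
        )
        g = build_network(edges, tiny_rset(), "genome", 100)
        assert list(g.edges) == [("A", "B")]

    def test_intra_requires_named_replicon(self):
        with pytest.raises(ValueError, match="named replicon"):
            build_network(self.make_edges(), tiny_rset(), "intra", 40)

    def test_isolated_nodes_present(self):
        g = build_network(self.make_edges(), tiny_rset(), "genome", 40)
        assert g.degree("D") == 0 and "D" in g


class TestConnectedComponents:
    def test_path_plus_isolate(self):
        g = nx.Graph()
        g.add_nodes_from("ABCD", replicon="P1")
        g.add_edges_from([("A", "B"), ("B", "C")], edge_class="in_paralog")
        comps = connected_components(g)
        assert [c.members for c in comps] == [frozenset("ABC")]

    def test_sorting_and_tie_break_by_smallest_member(self):
        g = nx.Graph()
        g.add_nodes_from("ABXYZM", replicon="P1")
        g.add_edges_from([("X", "Y"), ("M", "B")])
        comps = connected_components(g)
        assert [c.min_member for c in comps] == ["B", "X"]
        assert largest_component(comps).members == frozenset({"B", "M"})

    def test_empty_graph_has_no_largest_component(self):
        with pytest.raises(ValueError):
            largest_component(connected_components(nx.Graph()))

    @pytest.mark.parametrize("seed", range(25))
    def test_partition_matches_bfs_oracle(self, seed):
        rng = random.Random(seed)
        n = rng.randint(2, 12)
        g = nx.gnp_random_graph(n, rng.random(), seed=seed)
        nx.set_node_attributes(g, "P1", "replicon")
        adj = {u: set(g.neighbors(u)) for u in g}
        expected = bfs_partition(list(g.nodes), adj)
        assert {c.members for c in connected_components(g)} == expected


class TestConnectivityTable:
    def test_half_up_rounding_at_two_and_one_decimals(self):
        totals, conn = {"R": 1748}, {"R": 244}
        assert connectivity_rows(totals, conn, 2).percent_connected[0] == 13.96
        assert connectivity_rows(totals, conn, 1).percent_connected[0] == 14.0

    @pytest.mark.parametrize("total,conn,expect", [(10, 0, 0.0), (125, 125, 100.0)])
    def test_edge_percentages(self, total, conn, expect):
        df = connectivity_rows({"R": total}, {"R": conn})
        assert df.percent_connected[0] == expect
        assert df.unconnected[0] + df.connected[0] == df.total[0]

    def test_scope_counts_from_components(self):
        rset = tiny_rset()
        edges = classify_edges(
            [HomologyEdge("A", "C", 80, 1e-9), HomologyEdge("A", "E", 80, 1e-9)], rset
        )
        g = build_network(edges, rset, "genome", 40)
        comps = connected_components(g)
        df = connectivity_table(comps, rset, scope="genome")
        row = df.set_index("replicon_id")
        assert row.loc["P1", "connected"] == 1  # only A
        assert row.loc["CHR", "connected"] == 1
        # sum over components of per-replicon counts equals table totals
        per_rep: dict[str, int] = {}
        for c in comps:
            for rid, k in c.per_replicon.items():
                per_rep[rid] = per_rep.get(rid, 0) + k
        for rid in row.index:
            assert per_rep.get(rid, 0) == row.loc[rid, "connected"]


class TestSweepAndHistogram:
    def edges_at(self, idents):
        rset = tiny_rset()
        pairs = [("A", "B"), ("A", "C"), ("B", "C"), ("C", "D"), ("A", "D")]
        return classify_edges(
            [HomologyEdge(u, v, i, 1e-9) for (u, v), i in zip(pairs, idents)], rset
        ), rset

    def test_stated_enumeration(self):
        edges, rset = self.edges_at([45, 55, 100])
        df = threshold_sweep(edges, rset, "genome")
        assert list(df.edges) == [3, 2, 1, 1, 1, 1, 1]

    def test_empty_edges_all_zero(self):
        df = threshold_sweep([], tiny_rset(), "genome")
        assert list(df.edges) == [0] * 7
        assert list(df.connected_nodes) == [0] * 7

    @pytest.mark.parametrize("seed", range(10))
    def test_counts_non_increasing_on_random_inputs(self, seed):
        rng = random.Random(seed)
        idents = [rng.uniform(40, 100) for _ in range(5)]
        edges, rset = self.edges_at(idents)
        df = threshold_sweep(edges, rset, "genome")
        assert all(a >= b for a, b in zip(df.edges, df.edges[1:]))
        assert all(a >= b for a, b in zip(df.connected_nodes, df.connected_nodes[1:]))
        # brute-force recount at each threshold
        for t, count in zip(df.threshold, df.edges):
            assert count == sum(1 for i in idents if i >= t)

    @pytest.mark.parametrize(
        "ident,label",
        [(91.0, "91-99"), (100.0, "100"), (50.4, "40-50"), (50.6, "51-60"),
         (99.4, "91-99")],
    )
    def test_bin_assignment_by_rounded_identity(self, ident, label):
        edges, _ = self.edges_at([ident])
        df = identity_histogram(edges[:1])
        assert df.set_index("bin").edges[label] == 1
        assert df.edges.sum() == 1

    def test_identity_outside_range_errors(self):
        edges, _ = self.edges_at([39.0])
        with pytest.raises(ValueError, match="outside"):
            identity_histogram(edges[:1])

    def test_bins_must_be_contiguous(self):
        with pytest.raises(ValueError):
            SweepConfig(bins=((40, 50), (52, 60)))

    def test_thresholds_strictly_increasing(self):
        with pytest.raises(ValueError):
            SweepConfig(thresholds=(40, 40, 60))


class TestComponentSummaryInvariants:
    def test_size_must_match_per_replicon_sum(self):
        with pytest.raises(ValueError):
            ComponentSummary(frozenset("AB"), {"P1": 3}, {})
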