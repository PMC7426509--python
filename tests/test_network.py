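"""Unit tests for interactome assembly and minimalist network condensation."""

import networkx as nx
import numpy as np
import pytest

import trioweave as tw
from trioweave.network import NetworkError

from oracles import min_set_cover_size


def graph_from_edges(edges):
    return tw.assemble_interactome(ppi_edges=edges)


class TestAssemble:
    def test_duplicate_edge_merges_provenance(self):
        g = tw.assemble_interactome(ppi_edges=[("a", "b")], tf_edges=[("a", "b")])
        assert g.number_of_edges() == 1
        assert g["a"]["b"]["provenance"] == {"PPI", "TF"}

    def test_self_loop_dropped_and_counted(self):
        g = tw.assemble_interactome(ppi_edges=[("a", "a"), ("a", "b")])
        assert g.number_of_edges() == 1
        assert g.graph["self_loops_dropped"] == 1

    def test_disjoint_lists_sum(self):
        g = tw.assemble_interactome(
            ppi_edges=[("a", "b"), ("b", "c"), ("c", "d")],
            tf_edges=[("e", "f"), ("f", "g"), ("g", "h"), ("h", "i")],
        )
        assert g.number_of_edges() == 7

    def test_empty_union_rejected(self):
        with pytest.raises(NetworkError):
            tw.assemble_interactome()


class TestNeighborsWithin:
    def test_path_distance_two(self):
        g = graph_from_edges([("A", "B"), ("B", "C"), ("C", "D")])
        assert tw.neighbors_within(g, ["A"], k=2) == {"A", "B", "C"}

    def test_isolated_seed(self):
        g = graph_from_edges([("x", "y")])
        g.add_node("S")
        assert tw.neighbors_within(g, ["S"], k=2) == {"S"}

    def test_k1_direct_neighbors_only(self):
        g = graph_from_edges([("A", "B"), ("B", "C")])
        assert tw.neighbors_within(g, ["A"], k=1) == {"A", "B"}


class TestSelectInterconnectedSeeds:
    def test_distance_three_pair_dropped(self):
        g = graph_from_edges([("A", "x"), ("x", "y"), ("y", "B")])
        retained, report = tw.select_interconnected_seeds(g, ["A", "B"])
        assert retained == set()
        assert sorted(report["seed"]) == ["A", "B"]
        assert (report["nearest_seed_distance"] == 3).all()

    def test_distance_two_pair_retained(self):
        g = graph_from_edges([("A", "B"), ("B", "C")])
        retained, _ = tw.select_interconnected_seeds(g, ["A", "C"])
        assert retained == {"A", "C"}

    def test_isolated_seed_dropped(self):
        g = graph_from_edges([("A", "B"), ("C", "B")])
        g.add_node("Z")
        retained, report = tw.select_interconnected_seeds(g, ["A", "C", "Z"])
        assert retained == {"A", "C"}
        assert list(report["seed"]) == ["Z"]


class TestCondenseMinimal:
    def test_forced_connector_on_path(self):
        g = graph_from_edges([("A", "B"), ("B", "C")])
        minimal = tw.condense_minimal(g, ["A", "C"])
        assert minimal.nodes == {"A", "B", "C"}
        assert set(map(frozenset, minimal.graph.edges)) == {
            frozenset({"A", "B"}),
            frozenset({"B", "C"}),
        }
        assert minimal.connectors == ["B"]

    def test_adjacent_seeds_no_connector(self):
        g = graph_from_edges([("A", "B"), ("B", "Q")])
        minimal = tw.condense_minimal(g, ["A", "B"])
        assert minimal.connectors == []
        assert minimal.nodes == {"A", "B"}

    def test_diamond_lexicographic_tie_break(self):
        g = graph_from_edges([("A", "X"), ("X", "C"), ("A", "Y"), ("Y", "C")])
        minimal = tw.condense_minimal(g, ["A", "C"])
        assert minimal.connectors == ["X"]
        assert "Y" not in minimal.nodes

    def test_hub_beats_private_connectors(self):
        edges = []
        for s in ("S1", "S2", "S3"):
            edges.append(("H", s))
        edges += [("P12", "S1"), ("P12", "S2"), ("P13", "S1"), ("P13", "S3"),
                  ("P23", "S2"), ("P23", "S3")]
        g = graph_from_edges(edges)
        minimal = tw.condense_minimal(g, ["S1", "S2", "S3"])
        assert minimal.connectors == ["H"]

    def test_seed_never_a_connector(self):
        g = graph_from_edges([("A", "B"), ("B", "C"), ("A", "C")])
        minimal = tw.condense_minimal(g, ["A", "B", "C"])
        assert minimal.connectors == []
        assert minimal.seeds == {"A", "B", "C"}

    def test_decorations_attached(self):
        g = graph_from_edges([("A", "B"), ("B", "C")])
        minimal = tw.condense_minimal(
            g, ["A", "C"], decorations={"A": {"snp_ids": "rs1", "de": True}}
        )
        payload = minimal.to_json_dict()
        node_a = next(n for n in payload["nodes"] if n["id"] == "A")
        assert node_a["snp_ids"] == "rs1" and node_a["role"] == "seed"


def check_invariants(net, seeds):
    retained, _ = tw.select_interconnected_seeds(net, seeds)
    if not retained:
        return
    minimal = tw.condense_minimal(net, retained)
    # subgraph containment
    for u, v in minimal.graph.edges:
        assert net.has_edge(u, v)
    # all retained seeds present, connectors are non-seeds
    assert retained <= minimal.nodes
    assert not (set(minimal.connectors) & retained)
    # coverage: seed pairs at distance exactly 2 through a shared non-seed
    # neighbour are connected at length <= 2 in the output
    from itertools import combinations

    candidates = {}
    for s in retained:
        for v in net.neighbors(s):
            if v not in retained:
                candidates.setdefault(v, set()).add(s)
    cover_map = {}
    coverable = set()
    for u, v in combinations(sorted(retained), 2):
        if net.has_edge(u, v):
            continue
        for c, adj in candidates.items():
            if u in adj and v in adj:
                coverable.add((u, v))
                cover_map.setdefault(c, set()).add((u, v))
    for u, v in coverable:
        assert nx.has_path(minimal.graph, u, v)
        assert nx.shortest_path_length(minimal.graph, u, v) <= 2
    # irredundancy
    for conn in minimal.connectors:
        mine = cover_map.get(conn, set())
        others = set().union(
            *(cover_map.get(c, set()) for c in minimal.connectors if c != conn)
        ) if len(minimal.connectors) > 1 else set()
        direct = {
            p for p in mine
            if minimal.graph.has_edge(conn, p[0]) and minimal.graph.has_edge(conn, p[1])
        }
        assert direct - others, f"connector {conn} is redundant"
    # greedy within (1 + ln P) of the exhaustive optimum on small instances
    if 0 < len(coverable) <= 12 and len(candidates) <= 10:
        opt = min_set_cover_size(sorted(coverable), candidates)
        if opt:
            assert len(minimal.connectors) <= (1 + np.log(len(coverable))) * opt


class TestInvariantsRandom:
    def test_random_graphs(self, rng):
        for trial in range(60):
            n = int(rng.integers(8, 20))
            g = nx.gnp_random_graph(n, 0.2, seed=int(rng.integers(0, 2**31)))
            g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
            if g.number_of_edges() == 0:
                continue
            net = tw.assemble_interactome(ppi_edges=list(g.edges))
            nodes = sorted(net.nodes)
            seeds = list(rng.choice(nodes, size=min(5, len(nodes)), replace=False))
            check_invariants(net, seeds)


class TestCommonTfReport:
    def test_maximal_overlap_tf_top_ranked(self):
        g = graph_from_edges([("A", "B"), ("B", "C")])
        minimal = tw.condense_minimal(g, ["A", "C"])
        universe = {"A", "B", "C"} | {f"u{i}" for i in range(20)}
        annot = tw.AnnotationMap(
            terms={
                "TF_all": {"A", "B", "C"},
                "TF_one": {"A", "u1", "u2", "u3"},
                "TF_bg": {f"u{i}" for i in range(10)},
            },
            universe=universe,
        )
        report = tw.common_tf_report(minimal, annot)
        assert report["term_id"].iloc[0] == "TF_all"
        one = report[report["term_id"] == "TF_one"]
        assert one["p_value"].iloc[0] == 1.0  # k=1 under EASE
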