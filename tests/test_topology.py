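"""PPI edge filtering, the three centralities and consensus hub selection.

Hand-computed cases pin the definitional conventions (unnormalized
betweenness over unordered pairs, bridging coefficient as inverse-degree
ratio, centroid over the component excluding both probe nodes); random
small graphs are checked against independent brute-force enumeration.
"""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from conftest import random_connected_graph
from evmirnet import topology
from oracles import brute_betweenness, brute_bridging_coef, brute_centroid


def edge_table(rows):
    return pd.DataFrame(rows, columns=["protein_a", "protein_b", "experiments", "databases"])


class TestFilterEdges:
    def test_union_semantics_one_channel_enough(self):
        edges = edge_table([("a", "b", 0.5, 0.0)])
        assert len(topology.filter_ppi_edges(edges)) == 1

    def test_boundary_scores_dropped(self):
        # strict inequality: exactly at both thresholds fails
        edges = edge_table([("a", "b", 0.0031, 0.36)])
        assert topology.filter_ppi_edges(edges).empty

    def test_intersection_mode(self):
        edges = edge_table([("a", "b", 0.5, 0.0), ("a", "c", 0.5, 0.5)])
        kept = topology.filter_ppi_edges(edges, mode="intersection")
        assert kept["protein_b"].tolist() == ["c"]

    def test_canonicalization_and_loops(self):
        edges = edge_table([("b", "a", 0.9, 0.9), ("a", "b", 0.9, 0.9), ("c", "c", 0.9, 0.9)])
        kept = topology.filter_ppi_edges(edges)
        assert len(kept) == 1
        assert kept.iloc[0]["protein_a"] == "a"

    def test_unknown_channel_rejected(self):
        edges = edge_table([("a", "b", 0.5, 0.5)])
        with pytest.raises(ValueError, match="textmining.*databases|available"):
            topology.filter_ppi_edges(edges, {"textmining": 0.1})

    def test_random_table_matches_predicate(self, rng):
        rows = [
            (f"p{rng.integers(10)}", f"p{rng.integers(10)}", rng.random(), rng.random())
            for _ in range(60)
        ]
        edges = edge_table(rows)
        kept = topology.filter_ppi_edges(edges)
        expected = set()
        for a, b, e, d in rows:
            if a == b:
                continue
            if e > 0.0031 or d > 0.36:
                expected.add(tuple(sorted((a, b))))
        assert set(zip(kept["protein_a"], kept["protein_b"])) == expected


class TestHandCases:
    def test_path_p3(self):
        g = nx.path_graph(["a", "c", "b"])  # a - c - b
        cb = topology.betweenness(g)
        assert cb == {"a": 0.0, "c": 1.0, "b": 0.0}
        cc = topology.centroid(g)
        assert cc == {"a": -1.0, "c": 1.0, "b": -1.0}

    def test_star_four_leaves(self):
        g = nx.star_graph(4)  # center 0
        cb = topology.betweenness(g)
        assert cb[0] == pytest.approx(6.0)  # C(4,2) leaf pairs
        bcoef, brc = topology.bridging(g, cb)
        assert bcoef[0] == pytest.approx(1 / 16)
        assert brc[0] == pytest.approx(0.375)
        assert all(brc[v] == 0.0 for v in range(1, 5))
        cc = topology.centroid(g)
        assert cc[0] == pytest.approx(3.0)  # n - 2

    def test_cycle_four(self):
        g = nx.cycle_graph(4)
        cb = topology.betweenness(g)
        assert all(v == pytest.approx(0.5) for v in cb.values())
        bcoef, brc = topology.bridging(g, cb)
        assert all(b == pytest.approx(0.5) for b in bcoef.values())
        assert all(v == pytest.approx(0.25) for v in brc.values())

    @pytest.mark.parametrize("n", [3, 4, 6])
    def test_complete_graph_all_zero(self, n):
        g = nx.complete_graph(n)
        assert all(v == 0.0 for v in topology.betweenness(g).values())
        assert all(v == 0.0 for v in topology.centroid(g).values())


class TestOracleEquivalence:
    def test_random_graphs_match_brute_force(self, rng):
        for _ in range(60):
            g = random_connected_graph(rng)
            nodes, edges = list(g.nodes), list(g.edges)
            cb = topology.betweenness(g)
            bf_cb = brute_betweenness(nodes, edges)
            for v in nodes:
                assert cb[v] == pytest.approx(bf_cb[v], abs=1e-9)
            bcoef, _ = topology.bridging(g, cb)
            bf_bc = brute_bridging_coef(nodes, edges)
            for v in nodes:
                assert bcoef[v] == pytest.approx(bf_bc[v], abs=1e-9)
            cc = topology.centroid(g)
            bf_cc = brute_centroid(nodes, edges)
            for v in nodes:
                assert cc[v] == pytest.approx(bf_cc[v], abs=1e-9)

    def test_disconnected_components_handled(self):
        g = nx.union(nx.path_graph(3), nx.path_graph([10, 11, 12, 13]))
        cc = topology.centroid(g)
        bf = brute_centroid(list(g.nodes), list(g.edges))
        assert cc == pytest.approx(bf)
        assert topology.centroid(nx.empty_graph(2)) == {0: 0.0, 1: 0.0}


class TestProperties:
    def test_permutation_equivariance(self, rng):
        g = random_connected_graph(rng, n_min=6, n_max=7)
        perm = {v: f"x{v}" for v in g.nodes}
        h = nx.relabel_nodes(g, perm)
        rep_g = topology.centrality_report(g)
        rep_h = topology.centrality_report(h)
        for v in g.nodes:
            for col in rep_g.columns:
                assert rep_g.loc[v, col] == pytest.approx(rep_h.loc[f"x{v}", col])

    def test_pendant_leaf_never_decreases_betweenness(self, rng):
        for _ in range(20):
            g = random_connected_graph(rng)
            v = list(g.nodes)[int(rng.integers(g.number_of_nodes()))]
            before = topology.betweenness(g)[v]
            g2 = g.copy()
            g2.add_edge(v, "pendant")
            after = topology.betweenness(g2)[v]
            assert after >= before - 1e-12


class TestHubs:
    def test_identical_values_no_hubs(self):
        g = nx.complete_graph(5)
        hubs = topology.select_hubs(topology.centrality_report(g))
        assert hubs.hubs == []

    def test_star_center_unique_hub(self):
        g = nx.star_graph(4)
        hubs = topology.select_hubs(topology.centrality_report(g))
        assert hubs.hubs == [0]

    def test_all_subset_of_any(self, rng):
        g = random_connected_graph(rng, n_min=6, n_max=7)
        rep = topology.centrality_report(g)
        strict = topology.select_hubs(rep, mode="all")
        loose = topology.select_hubs(rep, mode="any")
        assert set(strict.hubs) <= set(loose.hubs)

    def test_crosslink_counts(self):
        g = nx.star_graph(4)
        hubs = topology.select_hubs(topology.centrality_report(g))
        bip = nx.Graph()
        bip.add_nodes_from(["m1", "m2"], bipartite=0)
        bip.add_node(0, bipartite=1)
        bip.add_edges_from([("m1", 0), ("m2", 0)])
        hubs = topology.crosslink_hubs(hubs, bip)
        assert hubs.crosslink == {0: 2}

    def test_crosslink_absent_node_zero(self):
        g = nx.star_graph(4)
        hubs = topology.select_hubs(topology.centrality_report(g))
        hubs = topology.crosslink_hubs(hubs, nx.Graph())
        assert hubs.crosslink == {0: 0}
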