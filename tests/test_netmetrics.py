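"""Condition-network extraction, betweenness, CTS and hub ranking."""

from __future__ import annotations

import math
import random

import networkx as nx
import pytest

from comonet.netmetrics import (
    ConditionLookupError,
    betweenness_centrality,
    compute_node_metrics,
    cross_talk_specificity,
    extract_condition_network,
    metrics_table,
    rank_nodes,
)
from comonet.synthetic import generate_global_network, plant_condition_links

from conftest import bfs_betweenness_oracle, build_kb


class TestExtraction:
    def test_members_are_exactly_condition_linked_genes(self, path_kb):
        net = extract_condition_network(path_kb, "c")
        assert net.members == {"g1", "g2"}
        assert net.gene_gene_edges == {("g1", "g2")}  # g3 never linked to c

    def test_single_gene_network_has_no_edges(self):
        kb = build_kb(condition_links=[("c", "g1", "ASSOCIATION", "to_condition")])
        net = extract_condition_network(kb, "c")
        assert net.members == {"g1"} and not net.gene_gene_edges

    def test_unknown_condition_raises(self, path_kb):
        with pytest.raises(ConditionLookupError):
            extract_condition_network(path_kb, "nosuch")
        with pytest.raises(ConditionLookupError):
            extract_condition_network(path_kb, "g1")  # wrong entity type

    def test_zero_gene_condition_yields_empty_network_with_flag(self):
        kb = build_kb(gene_edges=[("a", "b")])
        from comonet.kb import Entity

        kb.add_entity(Entity("c", "c", "condition"))
        net = extract_condition_network(kb, "c")
        assert net.empty and net.members == set()

    def test_parallel_links_tracked_in_multiplicity(self):
        kb = build_kb(
            gene_edges=[("a", "b", "PPI"), ("a", "b", "UPREGULATES"), ("b", "a", "PPI")],
            condition_links=[
                ("c", "a", "ASSOCIATION", "to_condition"),
                ("c", "b", "ASSOCIATION", "to_condition"),
                ("c", "b", "CAUSES", "to_condition"),
            ],
        )
        net = extract_condition_network(kb, "c")
        assert net.link_multiplicity[("a", "b")] == 3
        assert net.gene_condition_links == {"a": 1, "b": 2}

    def test_planted_module_is_recovered(self):
        from comonet.synthetic import SyntheticSpec, generate_bundle

        spec = SyntheticSpec(
            n_genes=200, m=2, condition_names=("c0",), module_sizes=(30,),
            planted_core_size=0, planted_pairwise_overlaps={}, seed=11,
        )
        kb, _, truth = generate_bundle(spec)
        net = extract_condition_network(kb, "c0")
        assert net.members >= set(truth.modules["c0"])


class TestBetweenness:
    def test_path_graph(self):
        kb = build_kb(
            gene_edges=[("A", "B"), ("B", "C")],
            condition_links=[("c", g, "ASSOCIATION", "to_condition") for g in "ABC"],
        )
        bc = betweenness_centrality(extract_condition_network(kb, "c"))
        assert bc == {"A": 0.0, "B": 1.0, "C": 0.0}

    def test_star_center_covers_all_leaf_pairs(self):
        leaves = ["l1", "l2", "l3", "l4"]
        kb = build_kb(
            gene_edges=[("hub", l) for l in leaves],
            condition_links=[
                ("c", g, "ASSOCIATION", "to_condition") for g in ["hub"] + leaves
            ],
        )
        bc = betweenness_centrality(extract_condition_network(kb, "c"))
        assert bc["hub"] == 6.0  # C(4,2) leaf pairs
        assert all(bc[l] == 0.0 for l in leaves)

    def test_four_cycle_splits_credit(self):
        kb = build_kb(
            gene_edges=[("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")],
            condition_links=[("c", g, "ASSOCIATION", "to_condition") for g in "ABCD"],
        )
        bc = betweenness_centrality(extract_condition_network(kb, "c"))
        # opposite corners have two tied shortest paths, each interior node
        # gets half a credit: brute-force enumeration gives 0.5 everywhere
        assert bc == pytest.approx({g: 0.5 for g in "ABCD"})

    @pytest.mark.parametrize("trial", range(60))
    def test_matches_both_oracles_on_random_small_graphs(self, trial):
        rnd = random.Random(trial)
        n = rnd.randint(2, 8)
        nodes = [f"n{i}" for i in range(n)]
        adj = {v: set() for v in nodes}
        for a in nodes:
            for b in nodes:
                if a < b and rnd.random() < 0.4:
                    adj[a].add(b)
                    adj[b].add(a)
        kb = build_kb(
            gene_edges=[(a, b) for a in adj for b in adj[a] if a < b],
            condition_links=[("c", g, "ASSOCIATION", "to_condition") for g in nodes],
        )
        bc = betweenness_centrality(extract_condition_network(kb, "c"))
        oracle = bfs_betweenness_oracle(adj)
        assert bc == pytest.approx(oracle, abs=1e-9)
        G = nx.Graph((a, b) for a in adj for b in adj[a])
        G.add_nodes_from(nodes)
        nx_bc = nx.betweenness_centrality(G, normalized=False)
        assert bc == pytest.approx(nx_bc, abs=1e-9)

    def test_credit_conservation(self):
        # total betweenness equals the summed (pair, interior) credits of
        # the enumeration oracle — conservation of shortest-path credit
        rnd = random.Random(99)
        nodes = [f"n{i}" for i in range(8)]
        edges = [(a, b) for a in nodes for b in nodes if a < b and rnd.random() < 0.35]
        adj = {v: set() for v in nodes}
        for a, b in edges:
            adj[a].add(b)
            adj[b].add(a)
        kb = build_kb(
            gene_edges=edges,
            condition_links=[("c", g, "ASSOCIATION", "to_condition") for g in nodes],
        )
        bc = betweenness_centrality(extract_condition_network(kb, "c"))
        oracle = bfs_betweenness_oracle(adj)
        assert sum(bc.values()) == pytest.approx(sum(oracle.values()), abs=1e-9)


class TestCrossTalkSpecificity:
    def test_fully_embedded_gene_scores_one(self):
        kb = build_kb(
            gene_edges=[("a", "b")],
            condition_links=[
                ("c", "a", "ASSOCIATION", "to_condition"),
                ("c", "b", "ASSOCIATION", "to_condition"),
            ],
        )
        cts = cross_talk_specificity(extract_condition_network(kb, "c"), kb)
        assert cts["a"] == (2, 2, 1.0)

    def test_direct_formula(self):
        # gene "a": 3 in-network links + condition link = K 4; 6 external = M 10
        inside = [("a", "x1"), ("a", "x2"), ("a", "x3")]
        outside = [("a", f"o{i}") for i in range(6)]
        kb = build_kb(
            gene_edges=inside + outside,
            condition_links=[
                ("c", g, "ASSOCIATION", "to_condition")
                for g in ["a", "x1", "x2", "x3"]
            ],
        )
        k, m, cts = cross_talk_specificity(extract_condition_network(kb, "c"), kb)["a"]
        assert (k, m, cts) == (4, 10, 0.4)

    def test_parallel_links_counted_in_k_and_m(self):
        kb = build_kb(
            gene_edges=[("a", "b", "PPI"), ("a", "b", "UPREGULATES"), ("a", "z")],
            condition_links=[
                ("c", "a", "ASSOCIATION", "to_condition"),
                ("c", "b", "ASSOCIATION", "to_condition"),
            ],
        )
        k, m, _ = cross_talk_specificity(extract_condition_network(kb, "c"), kb)["a"]
        assert (k, m) == (3, 4)

    def test_invariant_under_kb_duplication(self):
        kb = build_kb(
            gene_edges=[("a", "b"), ("a", "z")],
            condition_links=[
                ("c", "a", "ASSOCIATION", "to_condition"),
                ("c", "b", "ASSOCIATION", "to_condition"),
            ],
        )
        before = cross_talk_specificity(extract_condition_network(kb, "c"), kb)
        from comonet.kb import Interaction

        for i in list(kb.interactions):
            kb.add_interaction(Interaction(i.source, i.target, i.rtype, i.pmids))
        after = cross_talk_specificity(extract_condition_network(kb, "c"), kb)
        for g in before:
            assert after[g][2] == pytest.approx(before[g][2])
            assert after[g][0] == 2 * before[g][0]

    def test_cts_bounds(self):
        kb = generate_global_network(150, 2, seed=5)
        members = sorted(kb.gene_ids())[:40]
        plant_condition_links(kb, "c", {g: ["OTHER"] for g in members})
        cts = cross_talk_specificity(extract_condition_network(kb, "c"), kb)
        assert all(0.0 < v <= 1.0 for _, _, v in cts.values())


class TestRanking:
    METRICS = None

    def _metrics(self, pairs):
        from comonet.netmetrics import NodeMetrics

        return {
            g: NodeMetrics(K=k, neighbor_degree=k, betweenness=float(k), M=k, cts=1.0)
            for g, k in pairs
        }

    def test_top_by_key(self):
        assert rank_nodes(self._metrics([("A", 3), ("B", 5)]), "K", 1) == ["B"]

    def test_lexicographic_tie_break(self):
        assert rank_nodes(self._metrics([("B", 2), ("A", 2)]), "K", 2) == ["A", "B"]

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="unknown ranking key"):
            rank_nodes(self._metrics([("A", 1)]), "degree", 1)

    def test_planted_hub_ranks_first_by_k_and_betweenness(self):
        leaves = [f"l{i:02d}" for i in range(50)]
        chain = [(f"l{i:02d}", f"l{i + 1:02d}") for i in range(0, 8)]
        kb = build_kb(
            gene_edges=[("hub", l) for l in leaves] + chain,
            condition_links=[
                ("c", g, "ASSOCIATION", "to_condition") for g in ["hub"] + leaves
            ],
        )
        net = extract_condition_network(kb, "c")
        metrics = compute_node_metrics(net, kb)
        assert rank_nodes(metrics, "K", 1) == ["hub"]
        assert rank_nodes(metrics, "B", 1) == ["hub"]
        oracle = bfs_betweenness_oracle(net.neighbors())
        assert metrics["hub"].betweenness == pytest.approx(oracle["hub"])


def test_pipeline_deterministic(path_kb):
    first = compute_node_metrics(extract_condition_network(path_kb, "c"), path_kb)
    second = compute_node_metrics(extract_condition_network(path_kb, "c"), path_kb)
    assert first == second


def test_metrics_table_sorted_by_cts():
    kb = build_kb(
        gene_edges=[("a", "b"), ("a", "ext1"), ("a", "ext2")],
        condition_links=[
            ("c", "a", "ASSOCIATION", "to_condition"),
            ("c", "b", "ASSOCIATION", "to_condition"),
        ],
    )
    df = metrics_table(compute_node_metrics(extract_condition_network(kb, "c"), kb))
    assert list(df.columns) == ["gene", "K", "neighbor_degree", "betweenness", "M", "CTS"]
    assert list(df["CTS"]) == sorted(df["CTS"], reverse=True)
    assert math.isclose(df.iloc[0]["CTS"], 1.0)  # gene b fully embedded
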