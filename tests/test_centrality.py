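"""Hub-centrality indices against hand cases, brute force and networkx."""

import math

import networkx as nx
import numpy as np
import pytest

from hormonet.centrality import (
    INDEX_COLUMNS,
    CentralityParams,
    compute_bottleneck,
    compute_centrality_table,
    compute_epc,
    compute_local_indices,
    compute_neighborhood_indices,
    compute_path_indices,
    rank_and_select_hubs,
)

from _oracles import (
    all_shortest_paths_stats,
    mcc_bruteforce,
    neighborhood_component_bruteforce,
    random_graph,
)


def path_graph(n):
    return nx.path_graph([chr(ord("a") + i) for i in range(n)])


class TestLocalIndices:
    def test_star_center(self):
        star = nx.star_graph(5)
        out = compute_local_indices(star)
        assert out["degree"][0] == 5
        assert out["clustering_coefficient"][0] == 0.0

    def test_triangle_node(self):
        tri = nx.complete_graph(3)
        out = compute_local_indices(tri)
        assert out["degree"][0] == 2
        assert out["clustering_coefficient"][0] == 1.0

    def test_random_matches_triangle_counting(self, rng):
        for _ in range(10):
            graph = random_graph(rng)
            ours = compute_local_indices(graph)["clustering_coefficient"]
            ref = nx.clustering(graph)
            for v in graph:
                assert ours[v] == pytest.approx(ref[v])


class TestPathIndices:
    def test_three_node_path_stress_and_betweenness(self):
        out = compute_path_indices(path_graph(3))
        assert out["stress"]["b"] == 1
        assert out["betweenness"]["b"] == 1

    def test_tree_leaf_has_zero_betweenness(self, rng):
        tree = nx.random_labeled_tree(9, seed=5)
        out = compute_path_indices(tree)
        for v in tree:
            if tree.degree(v) == 1:
                assert out["betweenness"][v] == 0.0

    def test_matches_exhaustive_enumeration_on_small_graphs(self, rng):
        for _ in range(25):
            graph = random_graph(rng, n_max=8)
            ours = compute_path_indices(graph)
            ref = all_shortest_paths_stats(graph)
            for key in ref:
                for v in graph:
                    assert ours[key][v] == pytest.approx(ref[key][v]), (key, v)

    def test_betweenness_agrees_with_networkx(self, rng):
        for _ in range(10):
            graph = random_graph(rng, n_max=8)
            ours = compute_path_indices(graph)["betweenness"]
            ref = nx.betweenness_centrality(graph, normalized=False)
            for v in graph:
                assert ours[v] == pytest.approx(ref[v])

    def test_closeness_agrees_with_networkx_harmonic(self, rng):
        for _ in range(10):
            graph = random_graph(rng, n_max=8)
            ours = compute_path_indices(graph)["closeness"]
            ref = nx.harmonic_centrality(graph)
            for v in graph:
                assert ours[v] == pytest.approx(ref[v])


class TestNeighborhoodIndices:
    def test_triangle_mcc(self):
        out = compute_neighborhood_indices(nx.complete_graph(3))
        assert out["mcc"][0] == 2.0  # one maximal clique of size 3, (3-1)! = 2

    def test_star_center_mcc_equals_degree(self):
        star = nx.star_graph(6)
        out = compute_neighborhood_indices(star)
        assert out["mcc"][0] == star.degree(0)

    def test_isolated_node_scores_zero(self):
        graph = nx.Graph()
        graph.add_node("x")
        out = compute_neighborhood_indices(graph)
        assert out["mcc"]["x"] == out["mnc"]["x"] == out["dmnc"]["x"] == 0.0

    def test_matches_bruteforce_cliques_and_components(self, rng):
        for _ in range(20):
            graph = random_graph(rng, n_max=8)
            out = compute_neighborhood_indices(graph)
            mcc_ref = mcc_bruteforce(graph)
            mnc_ref, dmnc_ref = neighborhood_component_bruteforce(graph)
            for v in graph:
                assert out["mcc"][v] == pytest.approx(mcc_ref[v])
                assert out["mnc"][v] == pytest.approx(mnc_ref[v])
                assert out["dmnc"][v] == pytest.approx(dmnc_ref[v])

    def test_node_guard_aborts_on_large_graphs(self):
        graph = nx.path_graph(10)
        with pytest.raises(ValueError, match="guard"):
            compute_neighborhood_indices(graph, CentralityParams(mcc_max_nodes=5))


class TestBottleneck:
    def test_three_node_path_center(self):
        out = compute_bottleneck(path_graph(3))
        assert out["bottleneck"]["b"] == 2.0  # bottleneck for sources a and c

    def test_complete_graph_all_zero(self):
        out = compute_bottleneck(nx.complete_graph(4))
        assert all(v == 0.0 for v in out["bottleneck"].values())

    def test_random_trees_match_subtree_size_count(self, rng):
        for seed in range(8):
            tree = nx.random_labeled_tree(8, seed=seed)
            out = compute_bottleneck(tree)["bottleneck"]
            # independent count: on a tree the shortest-path tree is the tree
            expected = {v: 0.0 for v in tree}
            n = tree.number_of_nodes()
            for s in tree:
                sizes = {}

                def subtree(v, parent):
                    total = 1
                    for w in tree.neighbors(v):
                        if w != parent:
                            total += subtree(w, v)
                    sizes[v] = total
                    return total

                subtree(s, None)
                for v in tree:
                    if v != s and sizes[v] > 0.25 * n:
                        expected[v] += 1.0
            assert out == expected


class TestEpc:
    def test_keep_probability_one_is_component_fraction(self):
        graph = nx.disjoint_union(nx.complete_graph(3), nx.path_graph(2))
        out = compute_epc(graph, CentralityParams(epc_keep_probability=1.0, epc_realizations=3))
        n = graph.number_of_nodes()
        for comp in nx.connected_components(graph):
            for v in comp:
                assert out["epc"][v] == pytest.approx(len(comp) / n)

    def test_isolated_node_scores_one_over_n(self):
        graph = nx.Graph()
        graph.add_nodes_from(["a", "b", "c"])
        graph.add_edge("a", "b")
        out = compute_epc(graph, CentralityParams(epc_realizations=50, epc_seed=1))
        assert out["epc"]["c"] == pytest.approx(1 / 3)

    def test_reproducible_for_fixed_seed(self):
        graph = nx.path_graph(5)
        p = CentralityParams(epc_seed=42, epc_realizations=200)
        assert compute_epc(graph, p) == compute_epc(graph, p)

    def test_monotone_in_keep_probability(self):
        graph = nx.path_graph(6)
        means = []
        for keep in (0.2, 0.5, 0.8, 1.0):
            p = CentralityParams(epc_keep_probability=keep, epc_seed=7, epc_realizations=400)
            out = compute_epc(graph, p)["epc"]
            means.append(sum(out.values()) / len(out))
        assert means == sorted(means)

    def test_zero_realizations_rejected(self):
        with pytest.raises(ValueError):
            compute_epc(nx.path_graph(3), CentralityParams(epc_realizations=0))


class TestTableAndHubs:
    def test_table_has_twelve_score_columns(self, rng):
        graph = random_graph(rng)
        table = compute_centrality_table(graph, CentralityParams(epc_realizations=20))
        assert [c for c in table.columns if not c.startswith("rank_")] == list(INDEX_COLUMNS)
        assert len(INDEX_COLUMNS) == 12
        assert not table[list(INDEX_COLUMNS)].isna().any().any()
        assert (table[list(INDEX_COLUMNS)] >= 0).all().all()

    def test_label_invariance(self, rng):
        graph = random_graph(rng, n_max=7)
        mapping = {v: f"z{v}" for v in graph}
        relabeled = nx.relabel_nodes(graph, mapping)
        p = CentralityParams(epc_keep_probability=1.0, epc_realizations=1)
        t1 = compute_centrality_table(graph, p)
        t2 = compute_centrality_table(relabeled, p)
        for v in graph:
            for col in INDEX_COLUMNS:
                assert t1.at[v, col] == pytest.approx(t2.at[mapping[v], col])

    # odd cycle: BFS shortest-path trees have no parent ties, so even the
    # deterministic bottleneck tie-break preserves the symmetry
    @pytest.mark.parametrize("graph", [nx.cycle_graph(5), nx.complete_graph(5)])
    def test_vertex_transitive_graphs_score_uniformly(self, graph):
        p = CentralityParams(epc_keep_probability=1.0, epc_realizations=1)
        table = compute_centrality_table(graph, p)
        for col in INDEX_COLUMNS:
            assert table[col].nunique() == 1

    def test_dense_ranking_shares_ranks(self):
        graph = nx.star_graph(4)
        table = compute_centrality_table(graph, CentralityParams(epc_realizations=5))
        assert table.at[0, "rank_degree"] == 1
        leaves = [v for v in graph if v != 0]
        assert {table.at[v, "rank_degree"] for v in leaves} == {2}

    def test_star_center_is_sole_hub_with_all_indices(self):
        star = nx.relabel_nodes(nx.star_graph(5), {i: f"v{i}" for i in range(6)})
        table = compute_centrality_table(star, CentralityParams(epc_realizations=50, epc_seed=3))
        assert rank_and_select_hubs(table, k=1, m=12) == ["v0"]

    def test_m_one_k_n_selects_all_nodes(self, rng):
        graph = random_graph(rng)
        table = compute_centrality_table(graph, CentralityParams(epc_realizations=5))
        assert rank_and_select_hubs(table, k=len(table), m=1) == sorted(map(str, graph))

    def test_matches_bruteforce_filter(self, rng):
        graph = random_graph(rng, n_max=8)
        table = compute_centrality_table(graph, CentralityParams(epc_realizations=20, epc_seed=2))
        k, m = 3, 4
        hubs = rank_and_select_hubs(table, k=k, m=m)
        expected = []
        for v in table.index:
            count = 0
            for col in INDEX_COLUMNS:
                ordered = sorted(table.index, key=lambda u: (-table.at[u, col], str(u)))
                if v in ordered[:k]:
                    count += 1
            if count >= m:
                expected.append(str(v))
        assert hubs == sorted(expected)

    def test_invalid_parameters_rejected(self, rng):
        table = compute_centrality_table(random_graph(rng), CentralityParams(epc_realizations=5))
        with pytest.raises(ValueError):
            rank_and_select_hubs(table, k=0, m=1)
        with pytest.raises(ValueError):
            rank_and_select_hubs(table, k=1, m=13)
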