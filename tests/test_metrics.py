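"""Global attributes, centralities and divisive clustering."""

import networkx as nx
import numpy as np
import pytest

from conftest import random_graph
from oracles import oracle_closeness, oracle_edge_betweenness, oracle_node_betweenness
from planknet.metrics import (
    communities,
    edge_betweenness,
    fragmentation_after_removal,
    global_attributes,
    node_centralities,
)


def star(leaves: int) -> nx.Graph:
    g = nx.star_graph(leaves)
    return g


class TestGlobalAttributes:
    def test_complete_graph_limits(self):
        a = global_attributes(nx.complete_graph(4))
        assert a.density == pytest.approx(1.0)
        assert a.clustering_coefficient == pytest.approx(1.0)
        assert a.network_centralization == pytest.approx(0.0)
        assert a.heterogeneity == pytest.approx(0.0)
        assert a.characteristic_path_length == pytest.approx(1.0)

    def test_star_centralization_is_one(self):
        a = global_attributes(star(3))
        assert a.network_centralization == pytest.approx(1.0)
        assert a.clustering_coefficient == pytest.approx(0.0)

    @pytest.mark.parametrize("n,expected", [(27, 702), (28, 756), (22, 462)])
    def test_connected_network_ordered_pair_count(self, n, expected):
        g = nx.connected_watts_strogatz_graph(n, 4, 0.2, seed=1)
        a = global_attributes(g)
        assert a.shortest_paths_count == expected  # n(n-1)
        assert a.connected_pair_fraction == pytest.approx(1.0)

    def test_density_equals_mean_neighbors_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            g = random_graph(rng)
            n = g.number_of_nodes()
            a = global_attributes(g)
            assert a.density == pytest.approx(a.mean_neighbors / (n - 1))

    def test_isolated_node_policy_changes_density(self):
        g = nx.complete_graph(4)
        g.add_node("iso")
        with_iso = global_attributes(g, include_isolated=True)
        without = global_attributes(g, include_isolated=False)
        assert with_iso.n_nodes == 5 and without.n_nodes == 4
        assert without.density == pytest.approx(1.0)
        assert with_iso.density == pytest.approx(0.6)

    def test_disconnected_path_statistics(self):
        g = nx.Graph([("a", "b"), ("c", "d")])
        a = global_attributes(g)
        assert a.shortest_paths_count == 4
        assert a.connected_pair_fraction == pytest.approx(4 / 12)
        assert a.characteristic_path_length == pytest.approx(1.0)

    def test_heterogeneity_zero_iff_regular(self):
        assert global_attributes(nx.cycle_graph(6)).heterogeneity == 0.0
        assert global_attributes(star(3)).heterogeneity > 0

    def test_clustering_exclusion_convention(self):
        g = nx.complete_graph(3)
        g.add_edge(0, "pendant")
        zero = global_attributes(g, clustering_degree_lt2="zero")
        excl = global_attributes(g, clustering_degree_lt2="exclude")
        assert excl.clustering_coefficient > zero.clustering_coefficient

    def test_too_small_network_rejected(self):
        g = nx.Graph()
        g.add_node("only")
        with pytest.raises(ValueError):
            global_attributes(g)

    def test_centralization_missing_below_three_nodes(self):
        a = global_attributes(nx.Graph([("a", "b")]))
        assert a.network_centralization is None


class TestNodeCentralities:
    def test_path_graph_values(self):
        g = nx.path_graph(["a", "b", "c"])
        table = node_centralities(g).nodes.set_index("taxon")
        assert table.loc["b", "ncc"] == pytest.approx(1.0)
        assert table.loc["a", "ncc"] == pytest.approx(2 / 3)
        assert table.loc["b", "nbc"] == pytest.approx(1.0)
        assert table.loc["a", "nbc"] == pytest.approx(0.0)

    def test_star_hub(self):
        table = node_centralities(star(5)).nodes.set_index("taxon")
        assert table.loc[0, "nbc"] == pytest.approx(1.0)
        for leaf in range(1, 6):
            assert table.loc[leaf, "nbc"] == pytest.approx(0.0)

    def test_isolated_node_closeness_zero(self):
        g = nx.Graph([("a", "b")])
        g.add_node("iso")
        table = node_centralities(g).nodes.set_index("taxon")
        assert table.loc["iso", "ncc"] == 0.0
        assert table.loc["iso", "ndc"] == 0

    def test_oracle_equivalence_random_graphs(self):
        """NDC/NCC/NBC match exhaustive geodesic enumeration on 50 small graphs."""
        rng = np.random.default_rng(123)
        for _ in range(50):
            g = random_graph(rng)
            n = g.number_of_nodes()
            A = nx.to_numpy_array(g, nodelist=range(n))
            table = node_centralities(g).nodes.set_index("taxon")
            np.testing.assert_allclose(
                table["ncc"].loc[list(range(n))], oracle_closeness(A), atol=1e-12
            )
            np.testing.assert_allclose(
                table["nbc"].loc[list(range(n))],
                oracle_node_betweenness(A, normalized=n > 2),
                atol=1e-12,
            )
            np.testing.assert_allclose(
                table["ndc"].loc[list(range(n))], A.sum(axis=0), atol=0
            )


class TestEdgeBetweenness:
    def test_single_edge(self):
        table = edge_betweenness(nx.Graph([("a", "b")])).edges
        assert table["ebc"].iloc[0] == pytest.approx(1.0)

    def test_star_edges(self):
        # 3 leaves: each edge carries its endpoint pair plus 2 leaf-leaf paths
        table = edge_betweenness(star(3)).edges
        assert np.allclose(table["ebc"], 3.0)

    def test_bridge_between_triangles(self):
        g = nx.Graph()
        g.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)])
        table = edge_betweenness(g).edges
        bridge = table[(table["source"] == 2) & (table["target"] == 3)]["ebc"].iloc[0]
        A = nx.to_numpy_array(g, nodelist=range(6))
        assert bridge == pytest.approx(oracle_edge_betweenness(A)[(2, 3)])
        assert bridge == pytest.approx(9.0)  # all 3x3 cross pairs route through it

    def test_oracle_equivalence_random_graphs(self):
        rng = np.random.default_rng(321)
        for _ in range(50):
            g = random_graph(rng)
            n = g.number_of_nodes()
            A = nx.to_numpy_array(g, nodelist=range(n))
            expected = oracle_edge_betweenness(A)
            table = edge_betweenness(g).edges
            got = {
                (min(r.source, r.target), max(r.source, r.target)): r.ebc
                for r in table.itertuples()
            }
            assert set(got) == set(expected)
            for e, v in expected.items():
                assert got[e] == pytest.approx(v, abs=1e-12)

    def test_tree_ebc_sum_equals_connected_pairs(self):
        g = nx.random_labeled_tree(9, seed=4)
        table = edge_betweenness(g).edges
        # on a tree every unordered pair crosses each of its path edges once
        assert table["ebc"].sum() == pytest.approx(
            sum(nx.shortest_path_length(g, s, t) for s in g for t in g if s < t)
        )


class TestCommunities:
    def test_two_disjoint_triangles(self):
        g = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        parts = communities(g, k=2)
        assert sorted(map(sorted, parts)) == [[0, 1, 2], [3, 4, 5]]

    def test_bridge_removed_first(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        g.add_edge(0, 5)
        parts = communities(g, k=2)
        assert sorted(map(sorted, parts)) == [[0, 1, 2, 3, 4], [5, 6, 7, 8, 9]]

    def test_k_one_returns_everything(self):
        g = nx.complete_graph(5)
        parts = communities(g, k=1)
        assert parts == [frozenset(range(5))]

    def test_k_exceeding_nodes_rejected(self):
        with pytest.raises(ValueError):
            communities(nx.complete_graph(3), k=4)

    def test_edgeless_network_rejected(self):
        g = nx.Graph()
        g.add_nodes_from("ab")
        with pytest.raises(ValueError):
            communities(g)

    def test_modularity_stop_finds_planted_blocks(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        g.add_edge(0, 4)
        parts = communities(g)
        assert sorted(map(sorted, parts)) == [[0, 1, 2, 3], [4, 5, 6, 7]]

    def test_deterministic(self):
        g = nx.karate_club_graph()
        assert communities(g, k=3) == communities(g, k=3)


def test_removing_max_nbc_node_never_increases_connectivity():
    rng = np.random.default_rng(99)
    for _ in range(20):
        g = random_graph(rng)
        if g.number_of_edges() == 0:
            continue
        table = node_centralities(g).nodes
        hub = table.sort_values(["nbc", "taxon"], ascending=[False, True])["taxon"].iloc[0]
        before = global_attributes(g).shortest_paths_count if g.number_of_nodes() >= 2 else 0
        after = fragmentation_after_removal(g, hub)
        # deleting the top broker loses at least its own 2*(degree>0 reachable) pairs
        assert after <= before
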