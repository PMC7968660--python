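import networkx as nx
import numpy as np
import pytest

from soilconet import (
    classify_role,
    er_random_network,
    null_summary,
    node_role_table,
    participation_coefficient,
    within_module_degree_z,
)


def two_module_fixture():
    """10 nodes: a 5-node hub-and-spoke module and a 5-node clique module.

    In module 0, node 0 links to every other member (within-degree 4) while
    the spokes have within-degree 1, the Zi example vector (4,1,1,1,1).
    """
    g = nx.Graph()
    for v in range(1, 5):
        g.add_edge(0, v)
    for u in range(5, 10):
        for v in range(u + 1, 10):
            g.add_edge(u, v)
    g.add_edge(1, 5)  # one inter-module link
    partition = {v: 0 if v < 5 else 1 for v in g}
    return g, partition


class TestWithinModuleDegreeZ:
    def test_clique_module_all_zero(self):
        g = nx.complete_graph(4)
        z = within_module_degree_z(g, {v: 0 for v in g})
        assert all(v == 0.0 for v in z.values())

    def test_hub_zscore_matches_direct_mean_sd(self):
        g, part = two_module_fixture()
        z = within_module_degree_z(g, part)
        # kappa = (4,1,1,1,1): mean 1.6, population sd 1.2 -> hub z = 2.0
        assert z[0] == pytest.approx((4 - 1.6) / 1.2)
        assert z[0] == pytest.approx(2.0)
        assert z[1] == pytest.approx((1 - 1.6) / 1.2)

    def test_zscores_sum_to_zero_within_module(self):
        g, part = two_module_fixture()
        z = within_module_degree_z(g, part)
        assert sum(z[v] for v in range(5)) == pytest.approx(0.0, abs=1e-12)

    def test_missing_node_rejected(self):
        g = nx.path_graph(3)
        with pytest.raises(ValueError):
            within_module_degree_z(g, {0: 0, 1: 0})


class TestParticipationCoefficient:
    def test_all_internal_links(self):
        g = nx.complete_graph(4)
        p = participation_coefficient(g, {v: 0 for v in g})
        assert all(v == 0.0 for v in p.values())

    def test_even_split_two_modules(self):
        g = nx.Graph([("x", "a"), ("x", "b")])
        p = participation_coefficient(g, {"x": 0, "a": 0, "b": 1})
        assert p["x"] == pytest.approx(0.5)

    def test_degree_four_split_2_1_1(self):
        g = nx.Graph([("x", "a"), ("x", "b"), ("x", "c"), ("x", "d")])
        part = {"x": 0, "a": 0, "b": 0, "c": 1, "d": 2}
        p = participation_coefficient(g, part)
        assert p["x"] == pytest.approx(1 - (4 + 1 + 1) / 16)
        assert p["x"] == pytest.approx(0.625)

    def test_isolated_node_rejected(self):
        g = nx.Graph([(0, 1)])
        g.add_node(2)
        with pytest.raises(ValueError, match="2"):
            participation_coefficient(g, {0: 0, 1: 0, 2: 1})

    def test_matches_edge_count_oracle_on_random_graphs(self):
        rng = np.random.default_rng(37)
        for _ in range(20):
            g = nx.gnp_random_graph(10, 0.4, seed=int(rng.integers(2**31)))
            g.remove_nodes_from(list(nx.isolates(g)))
            if g.number_of_edges() == 0:
                continue
            part = {v: int(rng.integers(0, 3)) for v in g}
            z = within_module_degree_z(g, part)
            p = participation_coefficient(g, part)
            for v in g:
                kappa = {v2: sum(1 for nb in g[v2] if part[nb] == part[v2]) for v2 in g}
                members = [u for u in g if part[u] == part[v]]
                vals = [kappa[u] for u in members]
                mean = sum(vals) / len(vals)
                sd = (sum((x - mean) ** 2 for x in vals) / len(vals)) ** 0.5
                expect_z = 0.0 if sd == 0 else (kappa[v] - mean) / sd
                assert z[v] == pytest.approx(expect_z, abs=1e-12)
                k = g.degree(v)
                by_mod = {}
                for nb in g[v]:
                    by_mod[part[nb]] = by_mod.get(part[nb], 0) + 1
                assert p[v] == pytest.approx(
                    1 - sum((kt / k) ** 2 for kt in by_mod.values()), abs=1e-12
                )


class TestClassifyRole:
    @pytest.mark.parametrize(
        "zi, pi, role",
        [
            (0.0, 0.0, "peripheral"),
            (1.0, 0.70, "connector"),
            (3.0, 0.10, "module_hub"),
            (3.0, 0.70, "network_hub"),
            # boundary values: hubs include Zi = 2.5, connectors exclude Pi = 0.62
            (2.5, 0.62, "module_hub"),
            (2.4999, 0.62, "peripheral"),
            (2.5, 0.6201, "network_hub"),
            (0.0, 0.6201, "connector"),
        ],
    )
    def test_four_regions_with_boundaries(self, zi, pi, role):
        assert classify_role(zi, pi) == role


class TestErRandomNetwork:
    def test_exact_link_count(self):
        for seed in range(10):
            g = er_random_network(27, 306, seed)
            assert g.number_of_edges() == 306
            assert g.number_of_nodes() == 27

    def test_three_nodes_three_links_is_triangle(self):
        for seed in range(5):
            g = er_random_network(3, 3, seed)
            assert sorted(map(tuple, map(sorted, g.edges()))) == [(0, 1), (0, 2), (1, 2)]

    def test_deterministic(self):
        a = er_random_network(12, 20, 99)
        b = er_random_network(12, 20, 99)
        assert sorted(a.edges()) == sorted(b.edges())

    def test_too_many_links_rejected(self):
        with pytest.raises(ValueError):
            er_random_network(4, 7, 0)


class TestNullSummary:
    def test_complete_graph_parameters(self):
        s = null_summary(5, 10, n_reps=5, seed=0)
        assert s.mean_avg_path_distance == 1.0
        assert s.mean_avg_clustering == 1.0

    def test_requires_two_replicates(self):
        with pytest.raises(ValueError):
            null_summary(10, 5, n_reps=1, seed=0)

    def test_seed_invariance_up_to_monte_carlo_error(self):
        a = null_summary(15, 40, n_reps=60, seed=1)
        b = null_summary(15, 40, n_reps=60, seed=2)
        se = a.sd_avg_clustering / np.sqrt(60)
        assert abs(a.mean_avg_clustering - b.mean_avg_clustering) < 6 * se + 1e-9


def test_node_role_table_covers_all_nodes():
    g, part = two_module_fixture()
    table = node_role_table(g, part)
    assert set(table["node"]) == set(g)
    assert set(table["category"]) <= {
        "peripheral", "connector", "module_hub", "network_hub"
    }
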