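import networkx as nx
import numpy as np
import pytest

from soilconet import (
    SimilarityMatrix,
    avg_clustering,
    avg_connectivity,
    avg_path_distance,
    build_network,
    detect_modules,
    link_sign_fractions,
    network_report,
    spearman_matrix,
)

import oracles


def sim_from(rho: np.ndarray) -> SimilarityMatrix:
    return SimilarityMatrix([f"t{i}" for i in range(len(rho))], rho)


class TestSpearmanMatrix:
    def test_identity_and_antitone(self):
        x = np.array([[1.0, 2, 3], [3, 2, 1]])
        sim = spearman_matrix(x)
        assert sim.rho[0, 0] == 1.0
        assert sim.rho[0, 1] == pytest.approx(-1.0)

    def test_tied_data_matches_brute_force(self):
        x = np.array([[1.0, 2, 2, 4], [1, 3, 2, 4]])
        sim = spearman_matrix(x)
        assert sim.rho[0, 1] == pytest.approx(
            oracles.spearman([1, 2, 2, 4], [1, 3, 2, 4]), abs=1e-12
        )

    def test_constant_row_gets_zero(self):
        x = np.array([[1.0, 2, 3, 4], [5, 5, 5, 5]])
        sim = spearman_matrix(x)
        assert sim.rho[0, 1] == 0.0
        assert sim.rho[1, 1] == 1.0

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            spearman_matrix(np.ones((3, 2)))

    def test_invariant_under_monotone_transforms(self):
        """Rank-based similarity ignores any strictly monotone rescaling."""
        rng = np.random.default_rng(9)
        x = rng.normal(size=(5, 12))
        y = np.exp(2 * x) + 7  # strictly increasing transform, row-wise
        assert np.allclose(spearman_matrix(x).rho, spearman_matrix(y).rho, atol=1e-12)


class TestBuildNetwork:
    def rho3(self, r01, r02=0.0, r12=0.0):
        rho = np.eye(3)
        rho[0, 1] = rho[1, 0] = r01
        rho[0, 2] = rho[2, 0] = r02
        rho[1, 2] = rho[2, 1] = r12
        return sim_from(rho)

    def test_edge_signs_and_strict_threshold(self):
        net = build_network(self.rho3(0.7, -0.65, 0.6), st=0.6)
        assert net.graph["t0"]["t1"]["sign"] == "+"
        assert net.graph["t0"]["t2"]["sign"] == "-"
        assert not net.graph.has_edge("t1", "t2")  # rho == St exactly: no edge

    def test_isolated_nodes_removed(self):
        net = build_network(self.rho3(0.9), st=0.6)
        assert set(net.graph) == {"t0", "t1"}

    def test_raising_st_never_adds_edges(self):
        rng = np.random.default_rng(13)
        a = rng.normal(size=(8, 10))
        sim = spearman_matrix(a)
        prev = None
        for st in (0.3, 0.5, 0.7, 0.9):
            edges = set(map(frozenset, build_network(sim, st).graph.edges()))
            if prev is not None:
                assert edges <= prev
            prev = edges
        hi = float(np.abs(sim.rho - np.eye(8)).max())
        if hi < 0.999:
            assert build_network(sim, max(hi, 1e-6)).graph.number_of_edges() == 0


class TestMetrics:
    def test_triangle(self):
        g = nx.complete_graph(3)
        assert avg_connectivity(g) == 2.0
        assert avg_path_distance(g) == 1.0
        assert avg_clustering(g) == 1.0

    def test_star_and_path(self):
        star = nx.star_graph(4)  # 5 nodes, 4 edges
        assert avg_connectivity(star) == pytest.approx(1.6)
        assert avg_clustering(star) == 0.0
        path = nx.path_graph(3)
        assert avg_path_distance(path) == pytest.approx(4 / 3)

    def test_sign_fractions(self):
        g = nx.Graph()
        for i in range(3):
            g.add_edge(i, i + 10, sign="+")
        g.add_edge(0, 1, sign="-")
        assert link_sign_fractions(g) == (75.0, 25.0)
        with pytest.raises(ValueError):
            link_sign_fractions(nx.Graph())

    def test_metrics_match_enumeration_oracles(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            n = int(rng.integers(3, 9))
            g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(2**31)))
            if g.number_of_edges() == 0:
                continue
            adj = oracles.adjacency(g)
            assert avg_connectivity(g) == pytest.approx(
                sum(len(adj[u]) for u in adj) / n
            )
            assert avg_path_distance(g) == pytest.approx(oracles.avg_path_distance(adj))
            assert avg_clustering(g) == pytest.approx(oracles.avg_clustering(adj))


class TestDetectModules:
    def test_single_clique_one_module(self):
        part, q = detect_modules(nx.complete_graph(5))
        assert len(set(part.values())) == 1
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_two_triangle_bridge(self):
        g = nx.Graph([(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5), (2, 3)])
        part, q = detect_modules(g)
        assert q == pytest.approx(5 / 14, abs=1e-12)
        assert part[0] == part[1] == part[2]
        assert part[3] == part[4] == part[5]
        assert part[0] != part[3]

    def test_q_never_below_trivial_partition(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            g = nx.gnp_random_graph(7, 0.4, seed=int(rng.integers(2**31)))
            if g.number_of_edges() == 0:
                continue
            _, q = detect_modules(g)
            assert q >= -1e-12

    def test_no_edges_rejected(self):
        with pytest.raises(ValueError):
            detect_modules(nx.empty_graph(4))


def test_network_report_internal_consistency():
    rng = np.random.default_rng(31)
    x = rng.normal(size=(10, 15))
    x[:4] += 3 * rng.normal(size=15)  # planted correlated block
    net = build_network(spearman_matrix(x), st=0.5)
    rep = network_report(net)
    assert rep.pct_positive_links + rep.pct_negative_links == pytest.approx(100.0)
    assert rep.avg_connectivity == pytest.approx(
        2 * rep.total_links / rep.total_nodes
    )
    assert -0.5 <= rep.modularity <= 1.0
    assert set(rep.module_partition) == set(net.graph)
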