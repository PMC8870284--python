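"""Seven graph measures: closed forms, brute-force oracles, networkx
cross-checks, and structural properties."""

import numpy as np
import networkx as nx
import pytest

from eeggraph import (
    assortativity,
    betweenness_centrality,
    characteristic_path,
    clustering_coefficient,
    compute_metrics,
    global_efficiency,
    local_efficiency,
    node_strength,
    shortest_paths,
)
from eeggraph.connectivity import Network

from _oracles import (
    oracle_assortativity,
    oracle_betweenness,
    oracle_char_path,
    oracle_clustering,
    oracle_global_efficiency,
    oracle_local_efficiency,
    oracle_strength,
)
from conftest import binary_network, weighted_network


def _complete(n):
    return binary_network(np.ones((n, n)) - np.eye(n))


def _cycle(n):
    a = np.zeros((n, n))
    for i in range(n):
        a[i, (i + 1) % n] = a[(i + 1) % n, i] = 1
    return binary_network(a)


class TestShortestPaths:
    def test_path_graph_hops_and_counts(self, path3):
        d, s = shortest_paths(path3)
        assert d[0, 2] == 2
        assert s[0, 2] == 1

    def test_complete_graph_unit_distances(self, k4):
        d, _ = shortest_paths(k4)
        off = ~np.eye(4, dtype=bool)
        assert np.all(d[off] == 1)

    def test_weighted_triangle_inverse_weight_lengths(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.5
        w[1, 2] = w[2, 1] = 0.5
        w[0, 2] = w[2, 0] = 0.2
        d, s = shortest_paths(weighted_network(w))
        assert d[0, 2] == pytest.approx(4.0)  # via b: 1/0.5 + 1/0.5 < 1/0.2
        assert s[0, 2] == 1

    def test_disconnected_pair_infinite(self):
        d, s = shortest_paths(binary_network(np.zeros((2, 2))))
        assert np.isinf(d[0, 1]) and s[0, 1] == 0

    def test_parallel_shortest_paths_counted(self):
        d, s = shortest_paths(_cycle(4))
        assert d[0, 2] == 2
        assert s[0, 2] == 2  # both ways around


class TestClosedForms:
    def test_complete_graph_unit_measures(self):
        for n in (3, 4, 5):
            net = _complete(n)
            assert global_efficiency(net)[1] == pytest.approx(1.0)
            assert clustering_coefficient(net)[1] == pytest.approx(1.0)
            assert local_efficiency(net)[1] == pytest.approx(1.0)
            assert characteristic_path(net)[1] == pytest.approx(1.0)
            assert np.allclose(betweenness_centrality(net), 0.0)
            assert np.all(node_strength(net) == n - 1)

    def test_path3(self, path3):
        assert global_efficiency(path3)[1] == pytest.approx(5 / 6)
        assert characteristic_path(path3)[1] == pytest.approx(4 / 3)
        np.testing.assert_allclose(betweenness_centrality(path3), [0, 1, 0])
        assert local_efficiency(path3)[1] == pytest.approx(0.0)

    def test_star5(self, star5):
        assert assortativity(star5) == pytest.approx(-1.0)
        nb = betweenness_centrality(star5)
        assert nb[0] == pytest.approx(6.0)  # C(4,2) leaf pairs via center
        assert np.allclose(nb[1:], 0.0)
        assert clustering_coefficient(star5)[1] == pytest.approx(0.0)

    def test_cycle4(self):
        assert characteristic_path(_cycle(4))[1] == pytest.approx(4 / 3)
        assert np.isnan(assortativity(_cycle(4)))  # degree-regular: 0/0

    def test_two_isolated_nodes(self):
        net = binary_network(np.zeros((2, 2)))
        assert global_efficiency(net)[1] == 0.0
        assert np.all(node_strength(net) == 0.0)
        with pytest.raises(ValueError, match="no edges"):
            assortativity(net)

    def test_weighted_triangle_strength(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.9
        w[1, 2] = w[2, 1] = 0.8
        w[0, 2] = w[2, 0] = 0.7
        np.testing.assert_allclose(
            node_strength(weighted_network(w)), [1.6, 1.7, 1.5]
        )


def _random_binary(rng, n, p=0.45):
    a = (rng.random((n, n)) < p).astype(float)
    a = np.triu(a, 1)
    return binary_network(a + a.T)


def _random_weighted(rng, n, p=0.5):
    w = rng.uniform(0.1, 1.0, (n, n)) * (rng.random((n, n)) < p)
    w = np.triu(w, 1)
    return weighted_network(w + w.T)


@pytest.mark.parametrize("mode", ["binary", "weighted"])
def test_random_graphs_match_oracles(rng, mode):
    """Implementation vs independent brute force (Floyd-Warshall, simple-path
    enumeration, triangle counting) on random 6-node graphs, both modes."""
    for _ in range(15):
        net = _random_binary(rng, 6) if mode == "binary" else _random_weighted(rng, 6)
        w = net.w
        binary = mode == "binary"
        per, tot = global_efficiency(net)
        o_per, o_tot = oracle_global_efficiency(w, binary)
        np.testing.assert_allclose(per, o_per, atol=1e-10)
        assert tot == pytest.approx(o_tot, abs=1e-10)

        per, tot = local_efficiency(net)
        o_per, o_tot = oracle_local_efficiency(w, binary)
        np.testing.assert_allclose(per, o_per, atol=1e-10)

        per, tot = clustering_coefficient(net)
        o_per, o_tot = oracle_clustering(w)
        np.testing.assert_allclose(per, o_per, atol=1e-10)

        np.testing.assert_allclose(
            betweenness_centrality(net), oracle_betweenness(w, binary), atol=1e-8
        )
        np.testing.assert_allclose(node_strength(net), oracle_strength(w), atol=1e-12)

        per, cp, unreach = characteristic_path(net)
        o_per, o_cp, o_unreach = oracle_char_path(w, binary)
        np.testing.assert_allclose(per, o_per, atol=1e-10)
        assert cp == pytest.approx(o_cp, abs=1e-10)
        assert unreach == o_unreach

        if net.n_edges:
            ours = assortativity(net)
            theirs = oracle_assortativity(w, binary)
            assert (np.isnan(ours) and np.isnan(theirs)) or ours == pytest.approx(
                theirs, abs=1e-10
            )


def test_networkx_cross_checks(rng):
    """Independent library check on binary graphs: unnormalized betweenness,
    clustering, global efficiency, degree assortativity."""
    for _ in range(10):
        net = _random_binary(rng, 7)
        g = nx.from_numpy_array(net.w)
        nb_nx = nx.betweenness_centrality(g, normalized=False)
        np.testing.assert_allclose(
            betweenness_centrality(net), [nb_nx[i] for i in range(7)], atol=1e-9
        )
        cc_nx = nx.clustering(g)
        np.testing.assert_allclose(
            clustering_coefficient(net)[0], [cc_nx[i] for i in range(7)], atol=1e-9
        )
        assert global_efficiency(net)[1] == pytest.approx(
            nx.global_efficiency(g), abs=1e-9
        )
        degs = net.degrees()
        if net.n_edges and degs.std() > 0:
            r_nx = nx.degree_assortativity_coefficient(g)
            ours = assortativity(net)
            if not (np.isnan(ours) or np.isnan(r_nx)):
                assert ours == pytest.approx(r_nx, abs=1e-8)


class TestProperties:
    def test_permutation_equivariance(self, rng):
        net = _random_weighted(rng, 7)
        perm = rng.permutation(7)
        permuted = Network(
            w=net.w[np.ix_(perm, perm)], density=net.density, mode=net.mode
        )
        ms = compute_metrics(net)
        ms_p = compute_metrics(permuted)
        np.testing.assert_allclose(ms.strength_node[perm], ms_p.strength_node, atol=1e-12)
        np.testing.assert_allclose(ms.loc_eff_node[perm], ms_p.loc_eff_node, atol=1e-10)
        np.testing.assert_allclose(
            ms.betweenness_node[perm], ms_p.betweenness_node, atol=1e-9
        )
        assert ms.glob_eff == pytest.approx(ms_p.glob_eff, abs=1e-12)
        assert ms.char_path == pytest.approx(ms_p.char_path, abs=1e-12)
        if not np.isnan(ms.assortativity):
            assert ms.assortativity == pytest.approx(ms_p.assortativity, abs=1e-10)

    def test_edge_addition_monotone(self, rng):
        """On connected binary graphs, adding an edge never decreases global
        efficiency and never increases the characteristic path length."""
        for _ in range(10):
            net = _random_binary(rng, 6)
            if not nx.is_connected(nx.from_numpy_array(net.w)):
                continue
            missing = [
                (i, j)
                for i in range(6)
                for j in range(i + 1, 6)
                if net.w[i, j] == 0
            ]
            if not missing:
                continue
            i, j = missing[0]
            w2 = net.w.copy()
            w2[i, j] = w2[j, i] = 1.0
            bigger = binary_network(w2)
            assert global_efficiency(bigger)[1] >= global_efficiency(net)[1] - 1e-12
            assert characteristic_path(bigger)[1] <= characteristic_path(net)[1] + 1e-12

    def test_bounds(self, rng):
        for _ in range(10):
            net = _random_binary(rng, 6)
            assert 0.0 <= global_efficiency(net)[1] <= 1.0
            assert 0.0 <= local_efficiency(net)[1] <= 1.0
            assert 0.0 <= clustering_coefficient(net)[1] <= 1.0
            if net.n_edges:
                r = assortativity(net)
                assert np.isnan(r) or -1.0 - 1e-9 <= r <= 1.0 + 1e-9
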