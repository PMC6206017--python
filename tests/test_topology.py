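import numpy as np
import pytest

import oracles
from conftest import net_from_adjacency, net_from_edges
from metnet.topology import (
    DegenerateNetworkError,
    betweenness,
    degrees,
    eigencentrality,
    global_efficiency,
    hits_scores,
    local_clustering,
    local_efficiency,
    powerlaw_exponents,
    powerlaw_mle,
    shortest_distances,
    compute_node_metrics,
    METRIC_NAMES,
)

RNG = np.random.default_rng(421)
RANDOM_GRAPHS = [oracles.random_digraph(RNG) for _ in range(60)]


def _vec(d: dict, n: int) -> np.ndarray:
    return np.array([d[f"n{i:02d}"] for i in range(n)])


class TestWorkedExamples:
    def test_three_cycle_degrees(self):
        net = net_from_edges([("A", "B"), ("B", "C"), ("C", "A")])
        k, k_in, k_out, mean_k = degrees(net)
        assert all(k[v] == 2 and k_in[v] == 1 and k_out[v] == 1 for v in "ABC")
        assert mean_k == 1.0

    def test_fan_in_degrees(self):
        net = net_from_edges([("A", "C"), ("B", "C")])
        k, k_in, k_out, _ = degrees(net)
        assert k_out["A"] == 1 and k_in["C"] == 2 and k["C"] == 2

    def test_path_distances_and_length(self):
        # A->B->C: reachable pairs contribute 1+2+1; unreachable are zero
        net = net_from_edges([("A", "B"), ("B", "C")])
        d, length = shortest_distances(net)
        assert d[0, 2] == 2 and d[2, 0] == 0
        assert length == pytest.approx(4 / 6)

    def test_cycle_length(self):
        net = net_from_edges([("A", "B"), ("B", "C"), ("C", "A")])
        _, length = shortest_distances(net)
        assert length == pytest.approx(1.5)

    def test_edgeless_graph_has_zero_length(self):
        net = net_from_edges([], extra_nodes=["A", "B", "C"])
        _, length = shortest_distances(net)
        assert length == 0.0

    def test_leaf_node_clustering_zero(self):
        net = net_from_edges([("A", "B")])
        assert local_clustering(net)["A"] == 0.0

    def test_bidirectional_triangle_clustering(self):
        edges = [(u, v) for u in "ABC" for v in "ABC" if u != v]
        net = net_from_edges(edges)
        c = local_clustering(net)
        # k=4, two ordered connected neighbor pairs -> 2/12
        assert all(c[v] == pytest.approx(1 / 6) for v in "ABC")

    def test_star_with_chord_clustering(self):
        net = net_from_edges([("A", "B"), ("A", "C"), ("A", "D"), ("B", "C")])
        c = local_clustering(net)
        assert c["A"] == pytest.approx(1 / 6)

    def test_fan_in_hits_exact(self):
        net = net_from_edges([("A", "C"), ("B", "C")])
        h, a = hits_scores(net)
        assert h["A"] == pytest.approx(1 / np.sqrt(2))
        assert h["B"] == pytest.approx(1 / np.sqrt(2))
        assert h["C"] == pytest.approx(0.0, abs=1e-12)
        assert a["C"] == pytest.approx(1.0)

    def test_cycle_hits_symmetric(self):
        net = net_from_edges([("A", "B"), ("B", "C"), ("C", "A")])
        h, a = hits_scores(net)
        assert np.ptp(list(h.values())) < 1e-8
        assert np.ptp(list(a.values())) < 1e-8

    def test_path_betweenness(self):
        net = net_from_edges([("A", "B"), ("B", "C")])
        b = betweenness(net)
        assert b["B"] == pytest.approx(0.5)
        assert b["A"] == b["C"] == 0.0

    def test_cycle_betweenness(self):
        net = net_from_edges([("A", "B"), ("B", "C"), ("C", "A")])
        b = betweenness(net)
        assert all(v == pytest.approx(0.5) for v in b.values())

    def test_undirected_path_eigencentrality_closed_form(self):
        net = net_from_edges([("a", "b"), ("b", "a"), ("b", "c"), ("c", "b")])
        e, lam = eigencentrality(net)
        assert lam == pytest.approx(np.sqrt(2), abs=1e-8)
        expected = np.array([1.0, np.sqrt(2), 1.0])
        expected /= np.linalg.norm(expected)
        got = np.array([e["a"], e["b"], e["c"]])
        assert np.allclose(got, expected, atol=1e-8)

    def test_complete_graph_eigencentrality_uniform(self):
        edges = [(u, v) for u in "ABC" for v in "ABC" if u != v]
        e, _ = eigencentrality(net_from_edges(edges))
        assert np.ptp(list(e.values())) < 1e-10

    def test_disconnected_neighbors_efficiency_zero(self):
        net = net_from_edges([("A", "B"), ("A", "C")])
        assert local_efficiency(net)["A"] == 0.0

    def test_bidirectional_triangle_efficiency_one(self):
        edges = [(u, v) for u in "ABC" for v in "ABC" if u != v]
        f = local_efficiency(net_from_edges(edges))
        assert all(v == pytest.approx(1.0) for v in f.values())

    def test_degenerate_inputs_raise(self):
        one = net_from_edges([], extra_nodes=["A"])
        with pytest.raises(DegenerateNetworkError):
            shortest_distances(one)
        with pytest.raises(DegenerateNetworkError):
            hits_scores(one)
        with pytest.raises(DegenerateNetworkError):
            betweenness(net_from_edges([("A", "B")]))


@pytest.mark.parametrize("a", RANDOM_GRAPHS, ids=lambda a: f"n{a.shape[0]}e{a.sum()}")
class TestOracleAgreement:
    """Each metric equals an independent brute-force oracle on random digraphs."""

    def test_degrees(self, a):
        net = net_from_adjacency(a)
        k, k_in, k_out, mean_k = degrees(net)
        ok, oin, oout = oracles.degrees(a)
        n = a.shape[0]
        assert np.array_equal(_vec(k, n), ok)
        assert np.array_equal(_vec(k_in, n), oin)
        assert np.array_equal(_vec(k_out, n), oout)
        # the three expressions for the mean degree agree
        assert mean_k == pytest.approx(oin.mean()) == pytest.approx(oout.mean())
        assert mean_k == pytest.approx(a.sum() / n)

    def test_distances_and_length(self, a):
        net = net_from_adjacency(a)
        d, length = shortest_distances(net)
        od = oracles.bfs_distances(a)
        assert np.array_equal(d, od)
        assert length == pytest.approx(oracles.avg_path_length(a))

    def test_clustering(self, a):
        net = net_from_adjacency(a)
        c = _vec(local_clustering(net), a.shape[0])
        assert np.allclose(c, oracles.clustering(a), atol=1e-12)
        assert np.all((c >= 0) & (c <= 1))

    def test_betweenness(self, a):
        if a.shape[0] < 3:
            pytest.skip("betweenness needs 3 nodes")
        b = _vec(betweenness(net_from_adjacency(a)), a.shape[0])
        assert np.allclose(b, oracles.betweenness(a), atol=1e-12)
        assert np.all((b >= 0) & (b <= 1))

    def test_hits_fixed_point(self, a):
        n = a.shape[0]
        h, auth = hits_scores(net_from_adjacency(a))
        hv, av = _vec(h, n), _vec(auth, n)
        assert np.all(hv >= -1e-12) and np.all(av >= -1e-12)
        assert np.linalg.norm(hv) == pytest.approx(1.0)
        # eigen-residuals against dense decomposition of A A^T / A^T A
        _, _, lam = oracles.hits_eig(a.astype(float))
        assert np.linalg.norm(a @ a.T @ hv - lam * hv) < 1e-6
        assert np.linalg.norm(a.T @ a @ av - lam * av) < 1e-6

    def test_eigencentrality(self, a):
        n = a.shape[0]
        e, lam = eigencentrality(net_from_adjacency(a))
        ev = _vec(e, n)
        ov, olam, spectrum = oracles.sym_eigencentrality(a.astype(float))
        assert lam == pytest.approx(olam, abs=1e-7)
        s = ((a + a.T) > 0).astype(float)
        assert np.linalg.norm(s @ ev - lam * ev) < 1e-6
        if len(spectrum) > 1 and spectrum[-1] - spectrum[-2] > 1e-6:
            assert np.allclose(ev, ov, atol=1e-6)

    def test_local_efficiency(self, a):
        f = _vec(local_efficiency(net_from_adjacency(a)), a.shape[0])
        assert np.allclose(f, oracles.local_efficiency(a), atol=1e-12)
        assert np.all((f >= 0) & (f <= 1))
        assert global_efficiency(net_from_adjacency(a)) == pytest.approx(
            oracles.efficiency(a)
        )


class TestPermutationEquivariance:
    def test_metrics_follow_node_relabeling(self):
        rng = np.random.default_rng(7)
        a = oracles.random_digraph(rng, n_max=6)
        n = a.shape[0]
        perm = rng.permutation(n)
        ap = a[np.ix_(perm, perm)]
        ta = compute_node_metrics(net_from_adjacency(a))
        tb = compute_node_metrics(net_from_adjacency(ap))
        for col in METRIC_NAMES:
            assert np.allclose(
                ta[col].to_numpy()[perm], tb[col].to_numpy(), atol=1e-7
            ), col

    def test_symmetric_graph_hub_equals_authority(self):
        rng = np.random.default_rng(11)
        a = oracles.random_digraph(rng, n_max=6)
        sym = ((a + a.T) > 0).astype(np.int8)
        np.fill_diagonal(sym, 0)
        h, auth = hits_scores(net_from_adjacency(sym))
        assert np.allclose(list(h.values()), list(auth.values()), atol=1e-7)


class TestPowerLaw:
    def test_mle_recovers_exponent(self):
        rng = np.random.default_rng(99)
        sample = rng.zipf(2.5, size=10000)
        gamma = powerlaw_mle(sample)
        assert 2.4 <= gamma <= 2.6

    def test_degenerate_sample_flagged(self):
        assert powerlaw_mle(np.full(100, 3)) is None
        assert powerlaw_mle(np.array([1, 2, 3])) is None  # too small

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(5)
        a = (rng.random((40, 40)) < 0.12).astype(np.int8)
        np.fill_diagonal(a, 0)
        perm = rng.permutation(40)
        g1 = powerlaw_exponents(net_from_adjacency(a))
        g2 = powerlaw_exponents(net_from_adjacency(a[np.ix_(perm, perm)]))
        assert g1 == g2
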