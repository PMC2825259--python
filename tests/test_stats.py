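"""Bow-tie decomposition, betweenness, efficiency, degree profile."""

from __future__ import annotations

import numpy as np
import pytest

from mesoconn import betweenness, bow_tie, degree_profile, efficiency

from conftest import make_net


# ---------------------------------------------------------------------------
# independent oracles (no networkx): dense reachability and path counting
# ---------------------------------------------------------------------------


def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    d = np.full((n, n), np.inf)
    d[adj > 0] = 1
    np.fill_diagonal(d, 0)
    for k in range(n):
        d = np.minimum(d, d[:, [k]] + d[[k], :])
    return d


def brute_betweenness(adj: np.ndarray) -> np.ndarray:
    """Count shortest paths by dynamic programming over distances."""
    n = adj.shape[0]
    d = floyd_warshall(adj)
    sigma = np.zeros((n, n))
    for s in range(n):
        sigma[s, s] = 1
        finite = sorted(
            (t for t in range(n) if t != s and np.isfinite(d[s, t])),
            key=lambda t: d[s, t],
        )
        for t in finite:
            sigma[s, t] = sum(
                sigma[s, u] for u in range(n) if adj[u, t] and d[s, u] + 1 == d[s, t]
            )
    bc = np.zeros(n)
    for v in range(n):
        for s in range(n):
            for t in range(n):
                if len({s, t, v}) < 3 or not np.isfinite(d[s, t]):
                    continue
                if d[s, v] + d[v, t] == d[s, t] and sigma[s, t] > 0:
                    bc[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    return bc


def brute_bowtie(adj: np.ndarray):
    n = adj.shape[0]
    reach = np.isfinite(floyd_warshall(adj))
    mutual = reach & reach.T
    comps = []
    seen = set()
    for i in range(n):
        if i in seen:
            continue
        comp = {j for j in range(n) if mutual[i, j]}
        seen |= comp
        comps.append(comp)
    scc = max(comps, key=lambda c: (len(c), sorted(c)))
    rep = min(scc)
    in_ = {i for i in range(n) if reach[i, rep]} - scc
    out = {i for i in range(n) if reach[rep, i]} - scc
    rest = set(range(n)) - scc - in_ - out
    return scc, in_, out, rest


def _random_digraph(seed: int):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 11))
    adj = (rng.random((n, n)) < 0.3).astype(int)
    np.fill_diagonal(adj, 0)
    names = [f"n{i}" for i in range(n)]
    edges = [
        (names[i], names[j], 1) for i in range(n) for j in range(n) if adj[i, j]
    ]
    return adj, names, make_net(directed_edges=edges, extra_nodes=names)


class TestBowTie:
    def test_directed_cycle_all_scc(self):
        net = make_net(directed_edges=[("a", "b", 1), ("b", "c", 1), ("c", "a", 1)])
        bt = bow_tie(net)
        assert bt.scc == {"a", "b", "c"} and not bt.in_ and not bt.out

    def test_chain_with_back_edge(self):
        net = make_net(
            directed_edges=[("a", "b", 1), ("b", "c", 1), ("c", "b", 1)]
        )
        bt = bow_tie(net)
        assert bt.scc == {"b", "c"} and bt.in_ == {"a"} and bt.out == set()

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_reachability_oracle(self, seed):
        adj, names, net = _random_digraph(seed)
        bt = bow_tie(net)
        scc, in_, out, rest = brute_bowtie(adj)
        as_names = lambda ix: {names[i] for i in ix}  # noqa: E731
        assert bt.scc == as_names(scc)
        assert bt.in_ == as_names(in_)
        assert bt.out == as_names(out)
        assert bt.disconnected == as_names(rest)

    @pytest.mark.parametrize("seed", [100, 101, 102])
    def test_disjoint_and_exhaustive(self, seed):
        _, names, net = _random_digraph(seed)
        bt = bow_tie(net)
        parts = [bt.scc, bt.in_, bt.out, bt.disconnected]
        assert sum(len(p) for p in parts) == len(names)
        assert set().union(*parts) == set(names)


class TestBetweenness:
    def test_star_center(self):
        net = make_net(
            undirected_edges=[("hub", leaf, 1) for leaf in "abcd"]
        )
        bc = betweenness(net, directed=False)
        assert bc["hub"] == pytest.approx(6.0)
        assert all(bc[leaf] == 0 for leaf in "abcd")

    def test_path_graph(self):
        net = make_net(
            undirected_edges=[("a", "b", 1), ("b", "c", 1), ("c", "d", 1)]
        )
        bc = betweenness(net, directed=False)
        assert bc["b"] == pytest.approx(2.0) and bc["c"] == pytest.approx(2.0)
        assert bc["a"] == 0 and bc["d"] == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_enumeration_oracle(self, seed):
        adj, names, net = _random_digraph(seed)
        bc = betweenness(net, directed=True)
        expected = brute_betweenness(adj)
        for i, n in enumerate(names):
            assert bc[n] == pytest.approx(expected[i], abs=1e-9)

    def test_total_betweenness_conservation(self):
        # summed BC = total (fractional) intermediate visits over all paths
        adj, names, net = _random_digraph(7)
        expected = brute_betweenness(adj)
        assert betweenness(net).sum() == pytest.approx(expected.sum(), abs=1e-9)


class TestEfficiency:
    def test_complete_graph(self):
        edges = [(a, b, 1) for a in "abcd" for b in "abcd" if a < b]
        assert efficiency(make_net(undirected_edges=edges)) == pytest.approx(1.0)

    def test_directed_three_cycle(self):
        net = make_net(directed_edges=[("a", "b", 1), ("b", "c", 1), ("c", "a", 1)])
        assert efficiency(net) == pytest.approx(0.75)

    def test_isolated_nodes(self):
        assert efficiency(make_net(extra_nodes=["a", "b"])) == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_monotone_under_edge_addition(self, seed):
        rng = np.random.default_rng(seed)
        names = [f"n{i}" for i in range(8)]
        all_pairs = [(a, b) for a in names for b in names if a != b]
        rng.shuffle(all_pairs)
        edges = []
        prev = 0.0
        for a, b in all_pairs[:20]:
            edges.append((a, b, 1))
            e = efficiency(make_net(directed_edges=edges, extra_nodes=names))
            assert e >= prev - 1e-12
            prev = e


class TestDegreeProfile:
    def test_star_perfectly_disassortative(self):
        net = make_net(undirected_edges=[("hub", leaf, 1) for leaf in "abcd"])
        assert degree_profile(net).assortativity == pytest.approx(-1.0)

    def test_ring_knn_constant(self):
        names = [f"n{i}" for i in range(6)]
        edges = [(names[i], names[(i + 1) % 6], 1) for i in range(6)]
        prof = degree_profile(make_net(undirected_edges=edges))
        # every node has total degree 4 (mirrored ring), neighbors likewise
        assert len(prof.knn) == 1
        assert prof.knn["knn_mean"].iloc[0] == pytest.approx(
            prof.knn["k"].iloc[0]
        )

    def test_hand_built_assortativity(self):
        # path a-b-c plus pendant d on b, undirected
        net = make_net(
            undirected_edges=[("a", "b", 1), ("b", "c", 1), ("b", "d", 1)]
        )
        # mirrored edges: six ordered pairs with k in {1,3}
        ks = np.array([[1, 3], [3, 1], [1, 3], [3, 1], [1, 3], [3, 1]])
        expected = np.corrcoef(ks[:, 0], ks[:, 1])[0, 1]
        assert degree_profile(net).assortativity == pytest.approx(expected)

    def test_ccdf_starts_at_one(self, synth_bundle):
        prof = degree_profile(synth_bundle["net"])
        for df in (prof.degree_ccdf, prof.strength_in_ccdf, prof.strength_out_ccdf):
            assert df["ccdf"].iloc[0] == pytest.approx(1.0)
            assert (df["ccdf"].diff().dropna() <= 0).all()
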