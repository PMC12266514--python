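"""Centralities, size metrics and communities vs brute-force graph oracles."""

import itertools

import numpy as np
import pytest

from coexnet.network_analysis import (dense_rank_descending,
                                      detect_communities,
                                      network_size_metrics, node_centralities)
from coexnet.network_inference import CoexpressionNetwork


def _net(edges, genes=None):
    if genes is None:
        genes = sorted({v for e in edges for v in e})
    return CoexpressionNetwork(list(genes), {tuple(sorted(e)): 1.0 for e in edges})


def brute_force_betweenness(net):
    """Pair-by-pair shortest-path enumeration (BFS layers + path counting)."""
    genes = list(net.genes)
    index = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    adj = [[] for _ in range(n)]
    for (a, b) in net.edges:
        adj[index[a]].append(index[b])
        adj[index[b]].append(index[a])

    def bfs(src):
        dist = [-1] * n
        sigma = [0] * n
        dist[src], sigma[src] = 0, 1
        queue = [src]
        for u in queue:
            for v in adj[u]:
                if dist[v] == -1:
                    dist[v] = dist[u] + 1
                    queue.append(v)
                if dist[v] == dist[u] + 1:
                    sigma[v] += sigma[u]
        return dist, sigma

    dists, sigmas = zip(*(bfs(s) for s in range(n)))
    bet = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        if dists[s][t] == -1 or sigmas[s][t] == 0:
            continue
        for v in range(n):
            if v in (s, t):
                continue
            if dists[s][v] + dists[v][t] == dists[s][t]:
                bet[v] += sigmas[s][v] * sigmas[v][t] / sigmas[s][t]
    norm = (n - 1) * (n - 2) / 2
    return {genes[v]: bet[v] / norm for v in range(n)} if norm else \
        {g: 0.0 for g in genes}


def count_triangles_triads(net):
    genes = list(net.genes)
    index = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    a = np.zeros((n, n), dtype=bool)
    for (x, y) in net.edges:
        a[index[x], index[y]] = a[index[y], index[x]] = True
    triangles = triads = 0
    local = np.zeros(n)
    for i, j, k in itertools.combinations(range(n), 3):
        if a[i, j] and a[j, k] and a[i, k]:
            triangles += 1
    deg = a.sum(1)
    triads = int(sum(d * (d - 1) // 2 for d in deg))
    for v in range(n):
        neigh = np.flatnonzero(a[v])
        if neigh.size < 2:
            continue
        links = sum(1 for x, y in itertools.combinations(neigh, 2) if a[x, y])
        local[v] = links / (neigh.size * (neigh.size - 1) / 2)
    return triangles, triads, local.mean()


class TestCentralities:
    def test_path_graph(self):
        net = _net([("a", "b"), ("b", "c")])
        table = node_centralities(net).table
        assert table.loc["b", "degree"] == 2
        assert table.loc["b", "betweenness"] == pytest.approx(1.0)
        assert table.loc["b", "closeness"] == pytest.approx(1.0)
        assert table.loc["b", "degree_rank"] == 1

    def test_star_center(self):
        net = _net([("hub", leaf) for leaf in "wxyz"])
        table = node_centralities(net).table
        assert table.loc["hub", "betweenness"] == pytest.approx(1.0)
        assert table.loc["hub", "closeness"] == pytest.approx(1.0)

    def test_betweenness_matches_brute_force(self, rng):
        for trial in range(3):
            genes = [f"g{i}" for i in range(30)]
            edges = {tuple(sorted((genes[i], genes[j])))
                     for i, j in itertools.combinations(range(30), 2)
                     if rng.random() < 0.12}
            net = _net(edges, genes)
            table = node_centralities(net).table
            oracle = brute_force_betweenness(net)
            for g in genes:
                assert table.loc[g, "betweenness"] == pytest.approx(
                    oracle[g], abs=1e-9)

    def test_relabeling_invariance(self, rng):
        genes = [f"g{i}" for i in range(15)]
        edges = {tuple(sorted((genes[i], genes[j])))
                 for i, j in itertools.combinations(range(15), 2)
                 if rng.random() < 0.3}
        net = _net(edges, genes)
        mapping = {g: f"x{14 - i}" for i, g in enumerate(genes)}
        renamed = _net({tuple(sorted((mapping[a], mapping[b])))
                        for a, b in edges}, sorted(mapping.values()))
        t1 = node_centralities(net).table
        t2 = node_centralities(renamed).table
        for g in genes:
            for metric in ("degree", "betweenness", "closeness"):
                assert t1.loc[g, metric] == pytest.approx(
                    t2.loc[mapping[g], metric], abs=1e-12)

    def test_empty_edge_set_all_zero(self):
        net = _net([], genes=["a", "b", "c"])
        table = node_centralities(net).table
        assert (table[["degree", "betweenness", "closeness"]] == 0).all().all()


class TestSizeMetrics:
    def test_triangle(self):
        metrics = network_size_metrics(_net([("a", "b"), ("b", "c"), ("a", "c")]))
        assert metrics.density == 1.0
        assert metrics.transitivity == 1.0
        assert metrics.average_clustering == 1.0

    def test_star(self):
        metrics = network_size_metrics(_net([("hub", l) for l in "wxyz"]))
        assert metrics.transitivity == 0.0
        assert metrics.average_clustering == 0.0
        assert metrics.density == pytest.approx(0.4)

    def test_random_graph_matches_enumeration(self, rng):
        genes = [f"g{i}" for i in range(25)]
        edges = {tuple(sorted((genes[i], genes[j])))
                 for i, j in itertools.combinations(range(25), 2)
                 if rng.random() < 0.2}
        net = _net(edges, genes)
        metrics = network_size_metrics(net)
        triangles, triads, avg_local = count_triangles_triads(net)
        assert metrics.transitivity == pytest.approx(
            3 * triangles / triads if triads else 0.0, abs=1e-12)
        assert metrics.average_clustering == pytest.approx(avg_local, abs=1e-12)
        n, m = 25, len(edges)
        assert metrics.density == pytest.approx(2 * m / (n * (n - 1)))

    def test_complete_graph_property(self):
        for n in (3, 5, 8):
            genes = [f"g{i}" for i in range(n)]
            net = _net(set(itertools.combinations(genes, 2)), genes)
            metrics = network_size_metrics(net)
            assert metrics.density == 1.0 and metrics.transitivity == 1.0


class TestCommunities:
    def _two_cliques(self):
        left = [f"l{i}" for i in range(5)]
        right = [f"r{i}" for i in range(5)]
        edges = set(itertools.combinations(left, 2)) | \
            set(itertools.combinations(right, 2)) | {("l0", "r0")}
        return _net(edges, left + right), left, right

    def test_two_cliques_split(self):
        net, left, right = self._two_cliques()
        part = detect_communities(net, seed=0)
        left_ids = {part.membership[v] for v in left}
        right_ids = {part.membership[v] for v in right}
        assert len(left_ids) == len(right_ids) == 1
        assert left_ids != right_ids
        # oracle: the 2-partition into the cliques maximizes modularity
        # over all 2-partitions of the 10 nodes
        import networkx as nx

        g = net.to_networkx()
        best = -1.0
        nodes = list(g)
        for bits in range(1, 2 ** 9):  # fix node 0's side; enumerate rest
            side = {nodes[0]}
            for b in range(9):
                if bits >> b & 1:
                    side.add(nodes[b + 1])
            other = set(nodes) - side
            if not other:
                continue
            best = max(best, nx.community.modularity(g, [side, other]))
        got = nx.community.modularity(
            g, [set(left), set(right)])
        assert got == pytest.approx(best, abs=1e-12)

    def test_single_clique_one_community(self):
        genes = [f"g{i}" for i in range(6)]
        net = _net(set(itertools.combinations(genes, 2)), genes)
        part = detect_communities(net, seed=0)
        assert len(set(part.membership.values())) == 1

    def test_deterministic_given_seed(self):
        net, _, _ = self._two_cliques()
        a = detect_communities(net, seed=7)
        b = detect_communities(net, seed=7)
        assert a.membership == b.membership

    def test_edgeless_network_singletons(self):
        net = _net([], genes=["a", "b"])
        with pytest.warns(UserWarning, match="edgeless"):
            part = detect_communities(net, seed=0)
        assert len(set(part.membership.values())) == 2

    def test_partition_beats_trivial_modularity(self, rng):
        import networkx as nx

        genes = [f"g{i}" for i in range(20)]
        edges = {tuple(sorted((genes[i], genes[j])))
                 for i, j in itertools.combinations(range(20), 2)
                 if rng.random() < 0.2}
        net = _net(edges, genes)
        part = detect_communities(net, seed=1)
        g = net.to_networkx()
        groups = {}
        for v, c in part.membership.items():
            groups.setdefault(c, set()).add(v)
        assert nx.community.modularity(g, groups.values()) >= \
            nx.community.modularity(g, [set(genes)]) - 1e-12


def test_dense_rank_descending():
    ranks = dense_rank_descending(np.array([3.0, 1.0, 3.0, 2.0]))
    assert ranks.tolist() == [1, 3, 1, 2]
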