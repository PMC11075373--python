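"""Centralities, modularity and path statistics against closed forms and
exhaustive oracles."""

import itertools
import math
from collections import deque

import networkx as nx
import numpy as np
import pytest

import narcoscreen as ns
from narcoscreen import ValidationError


def weighted(edges):
    G = nx.Graph()
    for u, v, w in edges:
        G.add_edge(u, v, weight=w)
    return G


# --------------------------------------------------------------------------
# Independent oracles
# --------------------------------------------------------------------------

def brute_betweenness(G):
    """Exhaustive all-shortest-paths enumeration (BFS + backward DFS)."""
    bc = {n: 0.0 for n in G}
    for s, t in itertools.combinations(list(G), 2):
        dist = {s: 0}
        queue = deque([s])
        while queue:
            u = queue.popleft()
            for v in G[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    queue.append(v)
        if t not in dist:
            continue
        paths = []

        def extend(path):
            u = path[-1]
            if u == t:
                paths.append(list(path))
                return
            for v in G[u]:
                if dist.get(v) == dist[u] + 1 and dist[v] <= dist[t]:
                    extend(path + [v])

        extend([s])
        sigma = len(paths)
        for p in paths:
            for v in p[1:-1]:
                bc[v] += 1.0 / sigma
    return bc


def dense_eigenvector(G):
    """Dense eigendecomposition per component, global max-normalization."""
    values = {n: 0.0 for n in G}
    for comp in nx.connected_components(G):
        if len(comp) == 1:
            continue
        nodes = sorted(comp)
        A = np.zeros((len(nodes), len(nodes)))
        index = {n: i for i, n in enumerate(nodes)}
        for u, v, d in G.subgraph(comp).edges(data=True):
            w = d.get("weight", 1)
            A[index[u], index[v]] = A[index[v], index[u]] = w
        eigvals, eigvecs = np.linalg.eigh(A)
        vec = eigvecs[:, -1]
        if vec.sum() < 0:
            vec = -vec
        for n in nodes:
            values[n] = float(vec[index[n]])
    peak = max(values.values())
    return {n: v / peak for n, v in values.items()}


def modularity_double_sum(G, partition):
    """Q by the elementwise double sum over node pairs."""
    nodes = list(G)
    A = nx.to_numpy_array(G, nodelist=nodes, weight="weight")
    k = A.sum(axis=1)
    two_m = A.sum()
    q = 0.0
    for i, u in enumerate(nodes):
        for j, v in enumerate(nodes):
            if partition[u] == partition[v]:
                q += A[i, j] - k[i] * k[j] / two_m
    return q / two_m


def set_partitions(items):
    """All set partitions (restricted-growth enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i, block in enumerate(smaller):
            yield smaller[:i] + [[first] + block] + smaller[i + 1:]
        yield [[first]] + smaller


# --------------------------------------------------------------------------
# Degree / weighted degree
# --------------------------------------------------------------------------

class TestDegrees:
    def test_example_two_mode_counts(self, make_record):
        G = ns.build_two_mode([
            make_record(pid="P-01", hid="H-01"),
            make_record(pid="P-01", hid="H-02", date="2020-02-01"),
            make_record(pid="P-02", hid="H-01", date="2020-03-01"),
        ])
        dw = ns.degree_and_weighted_degree(G)
        assert dw.loc["H-01", "degree"] == 2
        assert dw.loc["H-01", "weighted_degree"] == 2
        assert dw.loc["P-01", "degree"] == 2

    def test_isolated_node_scores_zero(self):
        G = nx.Graph()
        G.add_node("A")
        dw = ns.degree_and_weighted_degree(G)
        assert dw.loc["A"].tolist() == [0, 0.0]

    def test_weighted_triangle_handshake(self):
        G = weighted([("A", "B", 1), ("B", "C", 2), ("A", "C", 3)])
        dw = ns.degree_and_weighted_degree(G)
        assert sorted(dw["weighted_degree"]) == [3.0, 4.0, 5.0]
        assert dw["weighted_degree"].sum() == 2 * (1 + 2 + 3)


# --------------------------------------------------------------------------
# Betweenness
# --------------------------------------------------------------------------

class TestBetweenness:
    def test_path_center_scores_one(self):
        G = nx.path_graph(["A", "B", "C"])
        assert ns.betweenness(G) == {"A": 0.0, "B": 1.0, "C": 0.0}

    def test_complete_graph_all_zero(self):
        G = nx.complete_graph(4)
        assert all(v == 0.0 for v in ns.betweenness(G).values())

    def test_random_graphs_match_path_enumeration(self):
        for seed in (11, 12, 13):
            G = nx.gnp_random_graph(8, 0.35, seed=seed)
            got = ns.betweenness(G)
            want = brute_betweenness(G)
            for n in G:
                assert got[n] == pytest.approx(want[n], abs=1e-10)

    def test_unweighted_paths_ignore_edge_weights(self):
        G = weighted([("A", "B", 1), ("B", "C", 100), ("A", "D", 1),
                      ("D", "C", 1)])
        scaled = nx.Graph()
        for u, v, d in G.edges(data=True):
            scaled.add_edge(u, v, weight=d["weight"] * 7)
        assert ns.betweenness(G) == ns.betweenness(scaled)

    def test_leaf_scores_zero(self):
        G = nx.star_graph(4)
        bc = ns.betweenness(G)
        assert all(bc[leaf] == 0.0 for leaf in range(1, 5))


# --------------------------------------------------------------------------
# Eigenvector
# --------------------------------------------------------------------------

class TestEigenvector:
    def test_star_closed_form(self):
        G = nx.star_graph(5)  # center 0, 5 leaves
        eig = ns.eigenvector(G)
        assert eig[0] == pytest.approx(1.0)
        for leaf in range(1, 6):
            assert eig[leaf] == pytest.approx(1 / math.sqrt(5), abs=1e-8)

    def test_triangle_symmetry(self):
        eig = ns.eigenvector(nx.complete_graph(3))
        assert all(v == pytest.approx(1.0, abs=1e-8) for v in eig.values())

    def test_three_node_path(self):
        eig = ns.eigenvector(nx.path_graph(3))
        assert eig[1] == pytest.approx(1.0)
        assert eig[0] == pytest.approx(math.sqrt(0.5), abs=1e-8)
        assert eig[2] == pytest.approx(math.sqrt(0.5), abs=1e-8)

    def test_random_graphs_match_dense_eigendecomposition(self):
        rng = np.random.default_rng(21)
        for seed in range(30):
            G = nx.gnp_random_graph(int(rng.integers(3, 9)), 0.4,
                                    seed=int(rng.integers(10000)))
            if G.number_of_edges() == 0:
                continue
            for u, v in G.edges:
                G[u][v]["weight"] = int(rng.integers(1, 5))
            got = ns.eigenvector(G)
            want = dense_eigenvector(G)
            for n in G:
                assert got[n] == pytest.approx(want[n], abs=1e-8)

    def test_isolated_nodes_score_zero_and_positive_within_components(self):
        G = weighted([("A", "B", 2), ("B", "C", 1)])
        G.add_node("Z")
        eig = ns.eigenvector(G)
        assert eig["Z"] == 0.0
        assert all(eig[n] > 0 for n in "ABC")  # Perron-Frobenius

    def test_edgeless_network_rejected(self):
        G = nx.Graph()
        G.add_node("A")
        with pytest.raises(ValidationError):
            ns.eigenvector(G)

    def test_near_degenerate_component_finished_by_fallback(self):
        """Two almost identical heavy stars sharing one bridge node:
        the leading eigenvalues nearly coincide, so power iteration
        cannot separate them; the Lanczos fallback must still match the
        dense solution (and the no-fallback path must say so)."""
        G = nx.Graph()
        for leaf in range(12):
            G.add_edge("A", f"a{leaf}", weight=40)
            G.add_edge("B", f"b{leaf}", weight=40)
        G.add_edge("a0", "B", weight=1)
        got = ns.eigenvector(G)
        want = dense_eigenvector(G)
        for n in G:
            assert got[n] == pytest.approx(want[n], abs=1e-7)
        with pytest.raises(ns.ConvergenceError, match="did not converge"):
            ns.eigenvector(G, fallback=None)
        again = ns.eigenvector(G)
        assert again == got  # deterministic fallback

    def test_bipartite_component_converges(self, make_record):
        # bipartite spectra are symmetric; the shifted iteration must
        # still converge
        recs = [make_record(pid=f"P-{i}", hid=f"H-{j}", date="2020-01-01")
                for i in range(4) for j in range(3)]
        G = ns.build_two_mode(recs)
        eig = ns.eigenvector(G)
        assert max(eig.values()) == pytest.approx(1.0)


# --------------------------------------------------------------------------
# Modularity / Louvain
# --------------------------------------------------------------------------

class TestModularity:
    def test_two_disjoint_cliques_give_half(self):
        G = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        partition = {n: 0 if n < 4 else 1 for n in G}
        assert ns.modularity(G, partition) == pytest.approx(0.5)
        louv = ns.communities_louvain(G, seed=0)
        assert louv.n_communities == 2
        assert louv.modularity == pytest.approx(0.5)

    def test_single_edge_one_community_zero(self):
        G = nx.Graph([("A", "B")])
        assert ns.modularity(G, {"A": 0, "B": 0}) == pytest.approx(0.0)

    def test_all_in_one_partition_of_connected_network_is_zero(self):
        G = nx.gnp_random_graph(10, 0.4, seed=2)
        assert ns.modularity(G, {n: 0 for n in G}) == pytest.approx(0.0)

    def test_formula_matches_double_sum(self):
        G = nx.gnp_random_graph(10, 0.4, seed=4)
        for u, v in G.edges:
            G[u][v]["weight"] = (u + v) % 3 + 1
        partition = {n: n % 3 for n in G}
        assert ns.modularity(G, partition) == pytest.approx(
            modularity_double_sum(G, partition), abs=1e-12
        )

    def test_louvain_attains_exhaustive_optimum_on_planted_cliques(self):
        # two K4 cliques joined by a single bridge edge; 4140 partitions
        G = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        G.add_edge(3, 4)
        best = max(
            (
                ns.modularity(G, {n: i for i, block in enumerate(p)
                                  for n in block})
                for p in set_partitions(list(G))
            )
        )
        louv = ns.communities_louvain(G, seed=1)
        assert louv.modularity == pytest.approx(best, abs=1e-9)

    def test_empty_network_rejected(self):
        with pytest.raises(ValidationError):
            ns.communities_louvain(nx.Graph())

    def test_seeded_partition_is_reproducible(self):
        G = nx.gnp_random_graph(30, 0.2, seed=9)
        a = ns.communities_louvain(G, seed=7)
        b = ns.communities_louvain(G, seed=7)
        assert a.partition == b.partition and a.modularity == b.modularity


# --------------------------------------------------------------------------
# Path statistics
# --------------------------------------------------------------------------

class TestPathStatistics:
    def test_four_node_path(self):
        stats = ns.path_statistics(nx.path_graph(4))
        assert stats.diameter == 3
        assert stats.average_path_length == pytest.approx(10 / 6)
        assert stats.connected_pair_fraction == 1.0

    def test_complete_graph(self):
        stats = ns.path_statistics(nx.complete_graph(5))
        assert stats.diameter == 1
        assert stats.average_path_length == 1.0

    def test_two_disjoint_edges(self):
        G = nx.Graph([("A", "B"), ("C", "D")])
        stats = ns.path_statistics(G)
        assert stats.diameter == 1
        assert stats.average_path_length == 1.0
        assert stats.connected_pair_fraction == pytest.approx(2 / 6)

    def test_edgeless_network_rejected(self):
        G = nx.Graph()
        G.add_nodes_from("AB")
        with pytest.raises(ValidationError):
            ns.path_statistics(G)


# --------------------------------------------------------------------------
# Summary assembly
# --------------------------------------------------------------------------

class TestSummary:
    def test_example_average_degree(self, make_record):
        G = ns.build_two_mode([
            make_record(pid="P-01", hid="H-01"),
            make_record(pid="P-01", hid="H-02", date="2020-02-01"),
            make_record(pid="P-02", hid="H-01", date="2020-03-01"),
        ])
        summary = ns.summarize_network(G, seed=0)
        assert summary.average_degree == pytest.approx(6 / 4)

    def test_ring_average_degree_exactly_two(self):
        summary = ns.summarize_network(nx.cycle_graph(9), seed=0)
        assert summary.average_degree == 2.0
        assert summary.average_weighted_degree == 2.0

    def test_generated_fixture_matches_export_recompute(
        self, tmp_path, small_zolpidem_dataset
    ):
        """Every summary field equals recomputation from the exported
        GraphML through an independent second path (networkx built-ins)."""
        records, _ = small_zolpidem_dataset
        G = ns.build_two_mode(records)
        louv = ns.communities_louvain(G, seed=5)
        summary = ns.summarize_network(G, louvain=louv)

        path = tmp_path / "g.graphml"
        ns.write_graphml(G, path)
        back = ns.read_graphml(path)

        degrees = [d for _, d in back.degree()]
        wdegrees = [d for _, d in back.degree(weight="weight")]
        assert summary.n_nodes == back.number_of_nodes()
        assert summary.n_edges == back.number_of_edges()
        assert summary.average_degree == pytest.approx(np.mean(degrees))
        assert summary.average_weighted_degree == pytest.approx(np.mean(wdegrees))
        comms = [
            {n for n in back if louv.partition[n] == c}
            for c in set(louv.partition.values())
        ]
        assert summary.modularity == pytest.approx(
            nx.community.modularity(back, comms, weight="weight"), abs=1e-12
        )
        diam = 0
        total = n_pairs = 0
        for comp in nx.connected_components(back):
            if len(comp) < 2:
                continue
            sub = back.subgraph(comp)
            diam = max(diam, nx.diameter(sub))
            total += sum(
                d for lengths in dict(nx.all_pairs_shortest_path_length(sub)).values()
                for d in lengths.values()
            )
            n = len(comp)
            n_pairs += n * (n - 1)
        assert summary.diameter == diam
        assert summary.average_path_length == pytest.approx(total / n_pairs)

    def test_centrality_table_columns_and_categories(self, make_record):
        G = ns.build_two_mode([make_record()])
        table = ns.centrality_table(G, seed=0)
        assert list(table.columns) == [
            "category", "degree", "weighted_degree", "betweenness",
            "eigenvector", "community_id",
        ]
        hosp = ns.hospital_table(table)
        assert list(hosp.index) == ["H-1"]
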