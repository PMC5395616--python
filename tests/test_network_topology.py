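"""Induced subnetworks, path lengths, power-law fits and the resampling null."""

from collections import deque

import networkx as nx
import numpy as np
import pytest

from regionppi.network_topology import (
    avg_path_length,
    find_orphans,
    fit_power_law,
    induce_subgraph,
    resample_null,
    topology_report,
)
from regionppi.synthetic_data import SyntheticSpec, gen_background_graph, sample_power_law


def bfs_avg_path_length(g: nx.Graph) -> float | None:
    """Independent all-pairs BFS oracle (no networkx shortest-path calls)."""
    nodes = list(g.nodes)
    adj = {n: set(g.neighbors(n)) for n in nodes}
    total, pairs = 0, 0
    for i, src in enumerate(nodes):
        dist = {src: 0}
        queue = deque([src])
        while queue:
            u = queue.popleft()
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    queue.append(v)
        for tgt in nodes[i + 1 :]:
            if tgt in dist:
                total += dist[tgt]
                pairs += 1
    return total / pairs if pairs else None


class TestInduceSubgraph:
    def test_missing_proteins_become_orphans(self):
        background = nx.Graph([("A", "B")])
        g = induce_subgraph({"A", "B", "C"}, background)
        assert set(g.nodes) == {"A", "B", "C"}
        assert set(map(frozenset, g.edges)) == {frozenset({"A", "B"})}
        assert find_orphans(g) == {"C"}

    def test_full_query_reproduces_background(self, small_background):
        g = induce_subgraph(set(small_background.nodes), small_background)
        assert g.number_of_nodes() == small_background.number_of_nodes()
        assert g.number_of_edges() == small_background.number_of_edges()

    def test_edges_match_brute_force_scan(self, small_background):
        rng = np.random.default_rng(1)
        nodes = sorted(small_background.nodes)
        edges = [frozenset(e) for e in small_background.edges]
        for _ in range(5):
            query = set(rng.choice(nodes, size=40, replace=False).tolist())
            g = induce_subgraph(query, small_background)
            expected = {e for e in edges if e <= query}
            assert set(map(frozenset, g.edges)) == expected

    def test_monotone_in_query(self, small_background):
        nodes = sorted(small_background.nodes)
        small = induce_subgraph(set(nodes[:30]), small_background)
        large = induce_subgraph(set(nodes[:60]), small_background)
        assert set(map(frozenset, small.edges)) <= set(map(frozenset, large.edges))

    def test_empty_query_gives_empty_graph(self, small_background):
        g = induce_subgraph(set(), small_background)
        assert g.number_of_nodes() == 0


class TestOrphans:
    def test_path_graph_has_no_orphans(self):
        assert find_orphans(nx.path_graph(5)) == set()

    def test_isolated_node_is_orphan(self):
        g = nx.Graph([("A", "B")])
        g.add_node("LONER")
        assert find_orphans(g) == {"LONER"}

    def test_planted_isolates_counted(self, small_background):
        """A 47-protein set with 10 members absent from the background:
        10 orphans, 37 connected-component candidates remain."""
        nodes = sorted(small_background.nodes)
        # take a connected neighborhood so the 37 in-background nodes have edges
        seed_node = max(small_background.degree, key=lambda kv: kv[1])[0]
        neighborhood = [seed_node] + sorted(small_background.neighbors(seed_node))[:36]
        query = set(neighborhood) | {f"MISSING{i:02d}" for i in range(10)}
        assert len(query) == 47
        g = induce_subgraph(query, small_background)
        orphans = find_orphans(g)
        assert {f"MISSING{i:02d}" for i in range(10)} <= orphans
        report = topology_report(g)
        assert report.n_nodes == 47
        assert report.n_orphans == len(orphans)
        assert sum(report.degree_histogram.values()) == 47 - report.n_orphans


class TestAvgPathLength:
    def test_path_graph_p3(self):
        assert avg_path_length(nx.path_graph(3)) == pytest.approx(4 / 3)

    @pytest.mark.parametrize("n", [2, 3, 5, 8])
    def test_complete_graph_is_one(self, n):
        assert avg_path_length(nx.complete_graph(n)) == 1.0

    @pytest.mark.parametrize("n", [2, 4, 7, 10])
    def test_path_graph_closed_form(self, n):
        assert avg_path_length(nx.path_graph(n)) == pytest.approx((n + 1) / 3)

    def test_orphans_and_components_excluded_not_penalized(self):
        g = nx.path_graph(3)
        g.add_node("X")  # orphan contributes no pairs
        assert avg_path_length(g) == pytest.approx(4 / 3)
        g.add_edge("Y", "Z")  # second component: pairs within it only
        assert avg_path_length(g) == pytest.approx((1 + 1 + 2 + 1) / 4)

    def test_no_connected_pair_returns_none(self):
        g = nx.empty_graph(4)
        assert avg_path_length(g) is None

    def test_matches_bfs_oracle_on_random_graphs(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(2, 50))
            g = nx.gnp_random_graph(n, float(rng.uniform(0.05, 0.5)), seed=int(rng.integers(1e6)))
            assert avg_path_length(g) == pytest.approx(bfs_avg_path_length(g))


class TestPowerLawFit:
    def test_parameter_recovery(self):
        draws = sample_power_law(2.5, 5000, seed=3)
        assert fit_power_law(draws) == pytest.approx(2.5, abs=0.15)

    def test_degenerate_sample_absent(self):
        assert fit_power_law([1] * 50) is None

    def test_too_few_points_absent(self):
        assert fit_power_law([1, 2, 3]) is None

    def test_preferential_attachment_exponent_near_three(self):
        spec = SyntheticSpec(graph_nodes=5000, graph_attach=5, seed=2)
        g = gen_background_graph(spec)
        alpha = fit_power_law([d for _, d in g.degree], x_min=spec.graph_attach)
        assert alpha == pytest.approx(3.0, abs=0.3)


class TestResampleNull:
    def test_seed_reproducibility(self, small_background):
        query = set(sorted(small_background.nodes)[:25])
        a = resample_null(query, small_background, n_resamples=50, seed=5)
        b = resample_null(query, small_background, n_resamples=50, seed=5)
        assert a == b
        c = resample_null(query, small_background, n_resamples=50, seed=6)
        assert a.samples != c.samples

    def test_empirical_p_on_resolution_grid(self, small_background):
        query = set(sorted(small_background.nodes)[:25])
        null = resample_null(query, small_background, n_resamples=40, seed=1)
        assert null.empirical_p in {i / 40 for i in range(41)}
        assert len(null.samples) == 40
        assert null.n_smaller <= 40

    def test_observed_smaller_than_every_sample_gives_zero(self):
        # a clique query inside a sparse background: observed APL = 1, unbeatable
        background = nx.barabasi_albert_graph(200, 2, seed=3)
        clique = list(range(200, 208))
        background.add_edges_from(
            (u, v) for i, u in enumerate(clique) for v in clique[i + 1 :]
        )
        null = resample_null(set(clique), background, n_resamples=100, seed=9)
        assert null.observed_stat == 1.0
        assert null.empirical_p == 0.0

    def test_planted_dense_community_is_significant(self):
        """A densely wired community sits closer than ≥95% of random sets.

        The background is dense (as a brain interactome is), so random
        same-size node sets induce well-connected subgraphs with path
        lengths near 2, while the planted community interacts at distance 1.
        """
        g = gen_background_graph(SyntheticSpec(graph_nodes=300, graph_attach=20, seed=4))
        members = [f"HUB{i:02d}" for i in range(25)]
        anchors = sorted(g.nodes)[:25]
        rng = np.random.default_rng(13)
        for i, m in enumerate(members):
            g.add_edge(m, anchors[i])
            for j in range(i + 1, len(members)):
                if rng.random() < 0.8:
                    g.add_edge(m, members[j])
        null = resample_null(set(members), g, n_resamples=200, seed=21)
        assert null.empirical_p <= 0.05

    def test_query_larger_than_background_rejected(self, small_background):
        too_big = {f"Q{i}" for i in range(small_background.number_of_nodes() + 1)}
        with pytest.raises(ValueError, match="exceeds background"):
            resample_null(too_big, small_background, n_resamples=5, seed=0)
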