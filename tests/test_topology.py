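"""Topology statistics: closed forms, conventions and brute-force oracles."""

import math
import random

import networkx as nx
import pytest

from litmesh.medline import MeshEntity
from litmesh.topology import (
    TopologyReport,
    centralization_from,
    characteristic_path_length,
    clustering_coefficients,
    degree_centralization,
    density_from,
    edge_betweenness,
    mean_neighbors_from,
    network_density,
    node_degrees,
    reports_table,
    topology_report,
)

from oracles import (
    clustering_oracle,
    degrees_oracle,
    edge_betweenness_oracle,
    path_length_oracle,
)


class TestClosedForms:
    """The analytic identities k=2M/N, ρ=2M/(N(N−1)), Freeman centralization."""

    def test_mean_degree_from_published_raw_counts(self):
        assert round(mean_neighbors_from(1229, 18451), 3) == 30.026

    def test_density_from_published_who_counts(self):
        assert round(density_from(32, 197), 3) == 0.397

    def test_centralization_from_published_who_counts(self):
        assert round(centralization_from(32, 197, 31), 3) == 0.643

    def test_degenerate_sizes_rejected(self):
        with pytest.raises(ValueError):
            mean_neighbors_from(0, 0)
        with pytest.raises(ValueError):
            density_from(1, 0)
        with pytest.raises(ValueError):
            centralization_from(2, 1, 1)


class TestNodeDegrees:
    def test_cycle_is_2_regular(self):
        degs, mean, kmax = node_degrees(nx.cycle_graph(5))
        assert set(degs.values()) == {2}
        assert mean == 2.0
        assert kmax == 2

    def test_empty_graph_reports_absent(self):
        degs, mean, kmax = node_degrees(nx.Graph())
        assert (degs, mean, kmax) == ({}, None, None)

    def test_matches_edge_list_recount(self):
        g = nx.gnp_random_graph(25, 0.2, seed=1)
        degs, _, _ = node_degrees(g)
        assert degs == degrees_oracle(list(g.nodes), list(g.edges))


class TestDensity:
    def test_complete_graph(self):
        assert network_density(nx.complete_graph(5)) == 1.0

    def test_edgeless_graph(self):
        g = nx.empty_graph(6)
        assert network_density(g) == 0.0

    def test_single_node_absent(self):
        assert network_density(nx.empty_graph(1)) is None


class TestClustering:
    def test_triangle_all_one(self):
        local, mean = clustering_coefficients(nx.complete_graph(3))
        assert set(local.values()) == {1.0}
        assert mean == 1.0

    def test_star_all_zero(self):
        local, mean = clustering_coefficients(nx.star_graph(4))
        assert set(local.values()) == {0.0}
        assert mean == 0.0

    def test_four_clique_minus_edge(self):
        g = nx.complete_graph(4)
        g.remove_edge(0, 1)
        _, mean = clustering_coefficients(g)
        assert math.isclose(mean, 5 / 6)

    def test_k_lt_2_convention_and_flag(self):
        # path 0-1 plus triangle 2-3-4: endpoints of the path have k=1
        g = nx.Graph([(0, 1), (2, 3), (3, 4), (2, 4)])
        _, mean_all = clustering_coefficients(g)
        _, mean_k2 = clustering_coefficients(g, only_k_ge2=True)
        assert math.isclose(mean_all, 3 / 5)
        assert mean_k2 == 1.0


class TestPathLength:
    def test_complete_graph_is_one(self):
        value, reduced = characteristic_path_length(nx.complete_graph(6))
        assert value == 1.0 and not reduced

    def test_star_closed_form(self):
        # star on N nodes: 2(N−1)/N mean distance
        value, _ = characteristic_path_length(nx.star_graph(4))  # N=5
        assert math.isclose(value, 1.6)

    def test_disconnected_uses_largest_component_and_flags(self):
        g = nx.Graph([(0, 1), (1, 2), (3, 4)])
        value, reduced = characteristic_path_length(g)
        assert reduced
        assert math.isclose(value, (1 + 1 + 2) / 3)


class TestCentralization:
    def test_star_is_one(self):
        for n in (4, 7, 15):
            assert math.isclose(degree_centralization(nx.star_graph(n - 1)), 1.0)

    def test_regular_graphs_are_zero(self):
        assert degree_centralization(nx.cycle_graph(9)) == 0.0
        assert degree_centralization(nx.complete_graph(6)) == 0.0

    def test_monotone_in_max_degree(self):
        values = [centralization_from(50, 100, k) for k in range(4, 50)]
        assert all(a < b for a, b in zip(values, values[1:]))

    def test_too_small_graph_absent(self):
        assert degree_centralization(nx.complete_graph(2)) is None


class TestEdgeBetweenness:
    def test_path_raw_counts(self):
        g = nx.path_graph(3)
        eb = edge_betweenness(g)
        assert eb[(0, 1)] == 2.0
        assert eb[(1, 2)] == 2.0

    def test_triangle_symmetry(self):
        eb = edge_betweenness(nx.complete_graph(3))
        assert len(set(eb.values())) == 1

    def test_matches_path_enumeration_oracle(self):
        g = nx.gnp_random_graph(20, 0.2, seed=9)
        eb = edge_betweenness(g)
        oracle = edge_betweenness_oracle(list(g.nodes), list(g.edges))
        for (a, b), value in eb.items():
            assert math.isclose(value, oracle[frozenset((a, b))], abs_tol=1e-9)


class TestReport:
    def test_identities_hold(self):
        g = nx.gnp_random_graph(30, 0.15, seed=3)
        report = topology_report(g, "test")
        assert math.isclose(
            report.mean_neighbors * report.n_nodes, 2 * report.n_edges, rel_tol=1e-12
        )
        assert math.isclose(
            report.density,
            2 * report.n_edges / (report.n_nodes * (report.n_nodes - 1)),
            rel_tol=1e-12,
        )

    def test_report_table_rounding_and_columns(self):
        g = nx.complete_graph(5)
        table = reports_table([topology_report(g, "k5")])
        assert list(table.columns) == [
            "Network", "N", "M", "CC", "l", "Centralization", "k", "rho",
        ]
        row = table.iloc[0]
        assert row["CC"] == 1.0 and row["rho"] == 1.0 and row["k"] == 4.0

    def test_out_of_range_fraction_rejected(self):
        with pytest.raises(AssertionError):
            TopologyReport(
                name="bad", n_nodes=3, n_edges=2, mean_clustering=1.5,
                char_path_length=1.0, centralization=0.5, mean_neighbors=4 / 3,
                density=2 / 3, max_degree=2, n_components=1,
            )

    def test_fields_match_independent_recount(self):
        rng = random.Random(77)
        g = nx.gnp_random_graph(24, 0.18, seed=rng.randint(0, 10**6))
        report = topology_report(g)
        nodes, edges = list(g.nodes), list(g.edges)
        degs = degrees_oracle(nodes, edges)
        assert report.n_nodes == len(nodes)
        assert report.n_edges == len(edges)
        assert report.max_degree == max(degs.values())
        assert math.isclose(
            report.mean_clustering,
            sum(clustering_oracle(nodes, edges).values()) / len(nodes),
            abs_tol=1e-12,
        )


class TestEgoDegreeContract:
    def test_focal_degree_is_n_minus_one_on_random_graphs(self):
        """First-neighbor subnetworks satisfy k_focal = N − 1."""
        from litmesh.network import ego_subnetwork

        rng = random.Random(55)
        for trial in range(10):
            raw = nx.gnp_random_graph(30, rng.uniform(0.1, 0.3), seed=trial)
            g = nx.relabel_nodes(raw, {i: MeshEntity(f"T{i:02d}") for i in raw.nodes})
            focal = max(g.nodes, key=g.degree)
            sub = ego_subnetwork(g, focal)
            assert sub.degree(focal) == sub.number_of_nodes() - 1
            # and when the focal node dominates, it is the report's max degree
            report = topology_report(sub)
            assert report.max_degree >= sub.degree(focal)
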