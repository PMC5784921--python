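"""Network topology statistics with the conventions used throughout.

One report row per network: node count N, edge count M, mean local
clustering coefficient ⟨CC⟩, characteristic path length ℓ, Freeman degree
centralization, mean number of neighbors ⟨k⟩ = 2M/N and density
ρ = 2M/(N(N−1)).  Conventions:

* clustering of a node with degree < 2 is 0, and the network value averages
  over *all* nodes by default (``only_k_ge2`` switches to averaging over
  nodes with at least two neighbors);
* ℓ is the mean shortest-path hop count over unordered distinct pairs,
  computed on the largest component (and flagged) when the graph is
  disconnected — edge weights never enter path lengths;
* edge betweenness is raw (unnormalized) shortest-path betweenness with
  each pair's contribution split equally among its shortest paths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import pandas as pd


# -- closed forms on (N, M, k_max): usable directly on published tables ----


def mean_neighbors_from(n_nodes: int, n_edges: int) -> float:
    """Mean degree ⟨k⟩ = 2M/N."""
    if n_nodes <= 0:
        raise ValueError("mean degree undefined for empty graph")
    return 2.0 * n_edges / n_nodes


def density_from(n_nodes: int, n_edges: int) -> float:
    """Density ρ = 2M/(N(N−1))."""
    if n_nodes < 2:
        raise ValueError("density undefined for N < 2")
    return 2.0 * n_edges / (n_nodes * (n_nodes - 1))


def centralization_from(n_nodes: int, n_edges: int, max_degree: int) -> float:
    """Freeman degree centralization (N·k_max − 2M)/((N−1)(N−2)).

    1 for a star, 0 for any regular graph.
    """
    if n_nodes < 3:
        raise ValueError("centralization undefined for N < 3")
    return (n_nodes * max_degree - 2.0 * n_edges) / ((n_nodes - 1) * (n_nodes - 2))


# -- per-graph statistics ---------------------------------------------------


def node_degrees(graph: nx.Graph):
    """Unweighted degrees; returns (per-node map, mean, max).

    Mean and max are None for the empty graph.
    """
    degrees = dict(graph.degree())
    if not degrees:
        return degrees, None, None
    return degrees, mean_neighbors_from(len(degrees), graph.number_of_edges()), max(
        degrees.values()
    )


def network_density(graph: nx.Graph) -> float | None:
    if graph.number_of_nodes() < 2:
        return None
    return density_from(graph.number_of_nodes(), graph.number_of_edges())


def clustering_coefficients(graph: nx.Graph, only_k_ge2: bool = False):
    """Local clustering per node plus the network mean.

    Local coefficient: 2·(links among neighbors)/(k(k−1)) for k ≥ 2, else 0.
    """
    local = nx.clustering(graph)
    if not local:
        return local, None
    if only_k_ge2:
        eligible = [c for n, c in local.items() if graph.degree(n) >= 2]
        mean = sum(eligible) / len(eligible) if eligible else None
    else:
        mean = sum(local.values()) / len(local)
    return local, mean


def characteristic_path_length(graph: nx.Graph) -> tuple[float | None, bool]:
    """Mean hop distance over unordered connected pairs.

    Returns (value, on_largest_component): a disconnected graph is reduced
    to its largest component and flagged.  None for graphs with < 2 nodes.
    """
    if graph.number_of_nodes() < 2:
        return None, False
    reduced = False
    if not nx.is_connected(graph):
        component = max(nx.connected_components(graph), key=len)
        graph = graph.subgraph(component)
        reduced = True
        if graph.number_of_nodes() < 2:
            return None, True
    return nx.average_shortest_path_length(graph), reduced


def degree_centralization(graph: nx.Graph) -> float | None:
    if graph.number_of_nodes() < 3:
        return None
    _, _, k_max = node_degrees(graph)
    return centralization_from(
        graph.number_of_nodes(), graph.number_of_edges(), k_max
    )


def edge_betweenness(graph: nx.Graph, normalized: bool = False):
    """Shortest-path edge betweenness (Brandes), raw counts by default."""
    return nx.edge_betweenness_centrality(graph, normalized=normalized)


@dataclass
class TopologyReport:
    """One table row of topology statistics for a named network."""

    name: str
    n_nodes: int
    n_edges: int
    mean_clustering: float | None
    char_path_length: float | None
    centralization: float | None
    mean_neighbors: float | None
    density: float | None
    max_degree: int | None
    n_components: int
    path_on_largest_component: bool = False

    def __post_init__(self) -> None:
        for frac in (self.mean_clustering, self.centralization, self.density):
            if frac is not None and not (-1e-12 <= frac <= 1 + 1e-12):
                raise AssertionError(f"fraction out of range in report: {frac}")
        if self.n_nodes > 0 and self.mean_neighbors is not None:
            if not math.isclose(
                self.mean_neighbors * self.n_nodes, 2.0 * self.n_edges, rel_tol=1e-12
            ):
                raise AssertionError("mean_neighbors × N != 2M")

    def to_row(self, ndigits: int = 3) -> dict:
        """Table-style row with fractions rounded for output."""

        def r(x):
            return None if x is None else round(x, ndigits)

        return {
            "Network": self.name,
            "N": self.n_nodes,
            "M": self.n_edges,
            "CC": r(self.mean_clustering),
            "l": r(self.char_path_length),
            "Centralization": r(self.centralization),
            "k": r(self.mean_neighbors),
            "rho": r(self.density),
        }


def topology_report(
    graph: nx.Graph, name: str | None = None, only_k_ge2: bool = False
) -> TopologyReport:
    """Assemble the full statistic set for one graph."""
    n = graph.number_of_nodes()
    m = graph.number_of_edges()
    _, mean_k, k_max = node_degrees(graph)
    _, mean_cc = clustering_coefficients(graph, only_k_ge2=only_k_ge2)
    path_length, reduced = characteristic_path_length(graph)
    return TopologyReport(
        name=name or graph.graph.get("name", "graph"),
        n_nodes=n,
        n_edges=m,
        mean_clustering=mean_cc,
        char_path_length=path_length,
        centralization=degree_centralization(graph),
        mean_neighbors=mean_k,
        density=network_density(graph),
        max_degree=k_max,
        n_components=nx.number_connected_components(graph) if n else 0,
        path_on_largest_component=reduced,
    )


def reports_table(reports: list[TopologyReport], ndigits: int = 3) -> pd.DataFrame:
    """Combined table, one row per network, fractions rounded to 3 decimals."""
    return pd.DataFrame([r.to_row(ndigits) for r in reports])
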