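"""Weighted MeSH co-occurrence networks and first-neighbor subnetworks.

Nodes are MeSH entities (descriptor + major-topic flag); an undirected edge
links two entities whenever at least one article is indexed with both, its
weight being the number of such articles and its ``pmids`` attribute the
sorted list of their identifiers.  Each article therefore contributes a
clique over its retained (non-stop-listed) entities: the more articles share
a pair of terms, the stronger the link.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import pandas as pd

from .codebook import CodeBook, categorize_terms, edge_class
from .medline import Corpus, MeshEntity


def build_network(
    corpus: Corpus,
    codebook: CodeBook | None = None,
    min_weight: int = 1,
    name: str = "global",
) -> nx.Graph:
    """Build the term co-occurrence graph from a filtered corpus.

    Stop-listed entities are removed per record; every unordered pair of the
    remaining entities gains an edge (weight incremented, pmid appended).
    Records with fewer than two retained entities contribute nothing.
    An optional minimum edge weight drops weaker links after construction.
    """
    graph = nx.Graph(name=name)
    for record in corpus.records:
        entities = [
            e
            for e in record.mesh
            if codebook is None or not codebook.is_stoplisted(e)
        ]
        for a, b in combinations(sorted(set(entities)), 2):
            if graph.has_edge(a, b):
                graph[a][b]["weight"] += 1
                graph[a][b]["pmids"].append(record.pmid)
            else:
                graph.add_edge(a, b, weight=1, pmids=[record.pmid])
    if min_weight > 1:
        weak = [
            (a, b) for a, b, w in graph.edges(data="weight") if w < min_weight
        ]
        graph.remove_edges_from(weak)
        graph.remove_nodes_from(list(nx.isolates(graph)))
    for _, _, data in graph.edges(data=True):
        data["pmids"] = sorted(data["pmids"])
    _annotate_categories(graph, codebook)
    return graph


def _annotate_categories(graph: nx.Graph, codebook: CodeBook | None) -> None:
    if codebook is None:
        cats = {n: "uncategorized" for n in graph.nodes}
    else:
        cats = categorize_terms(graph.nodes, codebook)
    nx.set_node_attributes(graph, cats, "category")
    for a, b, data in graph.edges(data=True):
        data["edge_class"] = edge_class(cats[a], cats[b])


def _resolve(graph: nx.Graph, focal: MeshEntity | str) -> MeshEntity:
    if isinstance(focal, MeshEntity):
        if focal in graph:
            return focal
        raise KeyError(f"term not in graph: {focal.label!r}")
    # string: match by label, else by descriptor preferring non-major form
    for node in graph.nodes:
        if node.label == focal:
            return node
    candidates = sorted(
        (n for n in graph.nodes if n.descriptor.casefold() == focal.casefold()),
        key=lambda n: n.major_topic,
    )
    if candidates:
        return candidates[0]
    raise KeyError(f"term not in graph: {focal!r}")


def ego_subnetwork(graph: nx.Graph, focal: MeshEntity | str) -> nx.Graph:
    """Induced subgraph on a focal term and all its first neighbors.

    All parent-graph edges among the retained nodes are kept with their
    weights and supporting pmids, so the focal term's degree in the
    subnetwork equals (node count − 1).
    """
    node = _resolve(graph, focal)
    members = {node} | set(graph.neighbors(node))
    sub = graph.subgraph(members).copy()
    sub.graph["name"] = node.descriptor
    sub.graph["focal"] = node.label
    return sub


def largest_component(graph: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest connected component.

    Size ties are broken by the lexicographically smallest member label;
    an empty graph is returned unchanged.
    """
    if graph.number_of_nodes() == 0:
        return graph.copy()
    components = sorted(
        nx.connected_components(graph),
        key=lambda c: (-len(c), min(n.label for n in c)),
    )
    sub = graph.subgraph(components[0]).copy()
    sub.graph["name"] = graph.graph.get("name", "graph")
    return sub


# ---------------------------------------------------------------------------
# import / export


def node_table(graph: nx.Graph) -> pd.DataFrame:
    """Node attribute table: term, major_topic, degree, category, local_clustering."""
    clustering = nx.clustering(graph)
    rows = [
        {
            "term": n.label,
            "major_topic": n.major_topic,
            "degree": graph.degree(n),
            "category": graph.nodes[n].get("category", "uncategorized"),
            "local_clustering": clustering[n],
        }
        for n in sorted(graph.nodes, key=lambda n: n.label)
    ]
    return pd.DataFrame(
        rows, columns=["term", "major_topic", "degree", "category", "local_clustering"]
    )


def edge_table(graph: nx.Graph) -> pd.DataFrame:
    """Edge attribute table with raw shortest-path edge betweenness."""
    betweenness = nx.edge_betweenness_centrality(graph, normalized=False)
    rows = []
    for a, b, data in graph.edges(data=True):
        a, b = sorted((a, b), key=lambda n: n.label)
        rows.append(
            {
                "source": a.label,
                "target": b.label,
                "weight": data.get("weight", 1),
                "pmids": ";".join(data.get("pmids", [])),
                "edge_class": data.get("edge_class", "mixed"),
                "betweenness": betweenness.get((a, b), betweenness.get((b, a), 0.0)),
            }
        )
    rows.sort(key=lambda r: (r["source"], r["target"]))
    return pd.DataFrame(
        rows, columns=["source", "target", "weight", "pmids", "edge_class", "betweenness"]
    )


def export_graph(graph: nx.Graph, path, format: str = "graphml") -> None:
    """Write the graph as attributed GraphML or as an edge/node CSV table."""
    if format == "graphml":
        out = nx.Graph(name=graph.graph.get("name", "graph"))
        for n, data in graph.nodes(data=True):
            out.add_node(
                n.label,
                major_topic=n.major_topic,
                category=data.get("category", "uncategorized"),
                degree=graph.degree(n),
            )
        for a, b, data in graph.edges(data=True):
            out.add_edge(
                a.label,
                b.label,
                weight=data.get("weight", 1),
                pmids=";".join(data.get("pmids", [])),
                edge_class=data.get("edge_class", "mixed"),
            )
        nx.write_graphml(out, path)
    elif format == "edge-csv":
        edge_table(graph).to_csv(path, index=False)
    elif format == "node-csv":
        node_table(graph).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown export format: {format!r}")


def import_graphml(path) -> nx.Graph:
    """Re-load a GraphML export, reconstructing MeshEntity nodes and pmid lists."""
    raw = nx.read_graphml(path)
    graph = nx.Graph(name=raw.graph.get("name", "graph"))
    mapping = {label: MeshEntity.from_label(label) for label in raw.nodes}
    for label, data in raw.nodes(data=True):
        graph.add_node(mapping[label], category=data.get("category", "uncategorized"))
    for a, b, data in raw.edges(data=True):
        graph.add_edge(
            mapping[a],
            mapping[b],
            weight=int(data.get("weight", 1)),
            pmids=data.get("pmids", "").split(";") if data.get("pmids") else [],
            edge_class=data.get("edge_class", "mixed"),
        )
    return graph
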