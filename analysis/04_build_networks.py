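"""Build the global MeSH co-occurrence network and the focal subnetworks.

Constructs the weighted term co-occurrence graph from the curated corpus
(stop-listed terms removed, one clique per article), keeps its largest
connected component, and extracts the five first-neighbor subnetworks
around the standard focal terms.  Exports GraphML plus edge/node CSV tables
for downstream rendering.
"""

from pathlib import Path

from litmesh.codebook import load_codebook
from litmesh.gazetteer import load_gazetteer
from litmesh.medline import parse_medline
from litmesh.network import (
    build_network,
    ego_subnetwork,
    export_graph,
    largest_component,
)
from litmesh.pipeline import DEFAULT_FOCAL_TERMS

OUTDIR = Path(__file__).resolve().parent.parent / "results" / "analysis"


def main() -> None:
    gazetteer = load_gazetteer()
    codebook = load_codebook(None, gazetteer)
    with open(OUTDIR / "corpus_curated.medline", encoding="utf-8") as fh:
        corpus = parse_medline(fh, gazetteer)

    graph = largest_component(build_network(corpus, codebook, name="global"))
    export_graph(graph, OUTDIR / "global.graphml", "graphml")
    export_graph(graph, OUTDIR / "global_edges.csv", "edge-csv")
    export_graph(graph, OUTDIR / "global_nodes.csv", "node-csv")
    print(
        f"global network: {graph.number_of_nodes()} nodes, "
        f"{graph.number_of_edges()} edges (largest component)"
    )
    hubs = sorted(graph.degree, key=lambda kv: -kv[1])[:5]
    print("hub terms:", ", ".join(f"{n.label} (k={k})" for n, k in hubs))

    for term in DEFAULT_FOCAL_TERMS:
        try:
            sub = ego_subnetwork(graph, term)
        except KeyError:
            print(f"  focal term not in network, skipped: {term}")
            continue
        stem = term.lower().replace(" ", "_").replace(",", "")
        export_graph(sub, OUTDIR / f"subnet_{stem}.graphml", "graphml")
        export_graph(sub, OUTDIR / f"subnet_{stem}_edges.csv", "edge-csv")
        focal = [n for n in sub.nodes if n.descriptor == term or n.label == term]
        k = sub.degree(focal[0]) if focal else "?"
        print(
            f"  {term}: {sub.number_of_nodes()} nodes, "
            f"{sub.number_of_edges()} edges, focal degree {k} = N-1"
        )


if __name__ == "__main__":
    main()
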