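"""End-to-end orchestration: corpus → curated corpus → trends → networks → tables.

Mirrors the analysis workflow: (optionally) generate a synthetic corpus,
parse and deduplicate the MEDLINE text, screen it with the codebook, build
the year × country trend matrix, construct the global co-occurrence network
(largest connected component), extract the configured first-neighbor
subnetworks, and emit one combined topology table with a row per network.
All outputs are plain text (CSV / GraphML / MEDLINE) and deterministic for
a fixed seed and configuration: no timestamps, sorted orderings throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import medline, network, topology, trends
from .codebook import load_codebook
from .gazetteer import load_gazetteer
from .synthetic import GeneratorConfig, generate_corpus

logger = logging.getLogger(__name__)

#: The five focal terms whose first-neighbor subnetworks are analyzed.
DEFAULT_FOCAL_TERMS = (
    "Social Determinants of Health",
    "Health Status Disparities",
    "Health Policy",
    "World Health Organization",
    "Global Health",
)


@dataclass
class PipelineConfig:
    input_path: str | None = None  # MEDLINE text; None → generate synthetically
    codebook_path: str | None = None  # None → packaged default
    gazetteer_path: str | None = None
    year_range: tuple[int, int] = trends.DEFAULT_YEAR_RANGE
    focal_terms: tuple[str, ...] = DEFAULT_FOCAL_TERMS
    output_dir: str = "results/pipeline"
    seed: int = 0
    n_records: int = 1000
    min_edge_weight: int = 1
    clustering_only_k_ge2: bool = False

    def __post_init__(self) -> None:
        if not self.focal_terms:
            raise ValueError("focal_terms must be non-empty")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, write the artifact bundle, return a summary dict."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    gazetteer = load_gazetteer(config.gazetteer_path)
    codebook = load_codebook(config.codebook_path, gazetteer)

    # -- corpus ----------------------------------------------------------
    if config.input_path is None:
        gen = GeneratorConfig(n_records=config.n_records, seed=config.seed)
        text, truth = generate_corpus(gen)
        corpus_path = outdir / "corpus.medline"
        corpus_path.write_text(text, encoding="utf-8")
        with open(outdir / "ground_truth.csv", "w", encoding="utf-8") as fh:
            truth.to_csv(fh)
        log(f"generate: {gen.n_records} synthetic records (seed={config.seed})")
    else:
        corpus_path = Path(config.input_path)

    with open(corpus_path, encoding="utf-8", errors="replace") as fh:
        corpus = medline.parse_medline(fh, gazetteer)
    log(f"parse: {corpus.provenance['parse']['before']} records read, "
        f"{len(corpus)} retained")

    corpus = medline.deduplicate(corpus)
    log(f"deduplicate: {corpus.provenance['deduplicate']['after']} unique PMIDs")

    corpus, report = apply_filters(corpus, codebook)
    report.to_frame().to_csv(outdir / "filter_report.csv", index=False)
    log(
        f"filter: {report.retrieved} retrieved, "
        + ", ".join(f"{k}={v}" for k, v in report.per_rule.items())
        + f", {report.assessed} assessed"
    )

    # -- trends ----------------------------------------------------------
    matrix = trends.year_country_matrix(corpus, config.year_range)
    matrix.to_csv(outdir / "trend_matrix.csv")
    matrix.country_marginals().to_csv(outdir / "trend_country_totals.csv", header=["count"])
    counts, undated = trends.yearly_counts(corpus)
    with open(outdir / "yearly_counts.csv", "w", encoding="utf-8") as fh:
        fh.write("year,count\n")
        for year, count in counts.items():
            fh.write(f"{year},{count}\n")
    log(
        f"trends: {matrix.total} records in matrix "
        f"({matrix.unknown_country} unknown-country, {undated} undated, "
        f"{matrix.out_of_range} out-of-range)"
    )

    # -- networks --------------------------------------------------------
    graph = network.build_network(
        corpus, codebook, min_weight=config.min_edge_weight, name="global"
    )
    graph = network.largest_component(graph)
    network.export_graph(graph, outdir / "global.graphml", "graphml")
    network.export_graph(graph, outdir / "global_edges.csv", "edge-csv")
    network.export_graph(graph, outdir / "global_nodes.csv", "node-csv")
    log(
        f"network: global component with {graph.number_of_nodes()} nodes, "
        f"{graph.number_of_edges()} edges"
    )

    reports = [
        topology.topology_report(graph, "global", config.clustering_only_k_ge2)
    ]
    skipped: list[str] = []
    for term in config.focal_terms:
        try:
            sub = network.ego_subnetwork(graph, term)
        except KeyError:
            logger.warning("focal term not in graph, skipping subnetwork: %r", term)
            skipped.append(term)
            continue
        stem = term.lower().replace(" ", "_").replace(",", "")
        network.export_graph(sub, outdir / f"subnet_{stem}.graphml", "graphml")
        network.export_graph(sub, outdir / f"subnet_{stem}_edges.csv", "edge-csv")
        reports.append(
            topology.topology_report(sub, term, config.clustering_only_k_ge2)
        )
        log(
            f"subnet {term!r}: {sub.number_of_nodes()} nodes, "
            f"{sub.number_of_edges()} edges"
        )
    if skipped:
        log(f"subnets skipped (not in graph): {len(skipped)} {skipped}")

    table = topology.reports_table(reports)
    table.to_csv(outdir / "topology_table.csv", index=False)
    log(f"topology: {len(reports)} networks reported")

    (outdir / "pipeline_log.txt").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    return {
        "output_dir": str(outdir),
        "n_assessed": report.assessed,
        "n_nodes": graph.number_of_nodes(),
        "n_edges": graph.number_of_edges(),
        "n_networks": len(reports),
        "skipped_subnets": skipped,
        "filter_report": report,
        "topology_table": table,
    }


def apply_filters(corpus, codebook):
    """Codebook screening step shared by pipeline and CLI."""
    from .codebook import apply_inclusion_exclusion

    return apply_inclusion_exclusion(corpus, codebook)
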