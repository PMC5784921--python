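"""Co-occurrence network construction, ego extraction and import/export."""

import io
import random

import networkx as nx
import pytest

from litmesh.codebook import apply_inclusion_exclusion
from litmesh.medline import Corpus, MedlineRecord, MeshEntity, parse_medline
from litmesh.network import (
    build_network,
    edge_table,
    ego_subnetwork,
    export_graph,
    import_graphml,
    largest_component,
    node_table,
)
from litmesh.synthetic import GeneratorConfig, generate_corpus

from oracles import components_oracle

X, Y, Z, W = (MeshEntity(d) for d in "XYZW")


def corpus_of(*mesh_lists):
    return Corpus(
        records=[
            MedlineRecord(pmid=str(i), mesh=tuple(ms))
            for i, ms in enumerate(mesh_lists, 1)
        ]
    )


class TestBuildNetwork:
    def test_clique_per_article(self):
        g = build_network(corpus_of([X, Y, Z], [Y, Z, W]))
        assert set(g.nodes) == {X, Y, Z, W}
        assert g.number_of_edges() == 5
        assert g[Y][Z]["weight"] == 2
        assert g[Y][Z]["pmids"] == ["1", "2"]
        assert all(
            g[a][b]["weight"] == 1 for a, b in g.edges if {a, b} != {Y, Z}
        )

    def test_single_entity_record_contributes_nothing(self):
        g = build_network(corpus_of([X], [Y, Z]))
        assert X not in g
        assert set(g.nodes) == {Y, Z}

    def test_stoplisted_terms_removed(self, codebook):
        humans = MeshEntity("Humans")
        g = build_network(corpus_of([X, Y, humans]), codebook)
        assert humans not in g
        assert g.number_of_edges() == 1

    def test_min_weight_threshold(self):
        g = build_network(corpus_of([X, Y, Z], [Y, Z, W]), min_weight=2)
        assert list(g.edges) == [(Y, Z)]

    def test_handshake_lemma(self):
        g = build_network(corpus_of([X, Y, Z], [Y, Z, W], [X, W]))
        assert sum(d for _, d in g.degree) == 2 * g.number_of_edges()

    def test_permutation_invariance(self):
        records = [
            MedlineRecord(pmid=p, mesh=tuple(ms))
            for p, ms in [("1", [X, Y, Z]), ("2", [Y, Z, W]), ("3", [X, W]), ("4", [Z, W])]
        ]
        g1 = build_network(Corpus(records=records))
        g2 = build_network(Corpus(records=list(reversed(records))))
        assert set(map(frozenset, g1.edges)) == set(map(frozenset, g2.edges))
        for a, b in g1.edges:
            assert g1[a][b]["weight"] == g2[a][b]["weight"]
            assert g1[a][b]["pmids"] == g2[a][b]["pmids"]  # stored sorted

    def test_total_weight_equals_pair_count_oracle(self, codebook, gazetteer):
        """Σ edge weights = Σ_a C(m_a, 2) from the generator's bookkeeping."""
        text, truth = generate_corpus(GeneratorConfig(n_records=1000, seed=31))
        corpus = parse_medline(io.StringIO(text), gazetteer)
        filtered, _ = apply_inclusion_exclusion(corpus, codebook)
        g = build_network(filtered, codebook)
        total = sum(w for _, _, w in g.edges(data="weight"))
        assert total == truth.pair_weight_total()

    def test_edge_classes_follow_categories(self, codebook):
        sef = MeshEntity("Socioeconomic Factors")
        pov = MeshEntity("Poverty")
        ls = MeshEntity("Life Style")
        g = build_network(corpus_of([sef, pov, ls]), codebook)
        assert g[sef][pov]["edge_class"] == "structural"
        assert g[sef][ls]["edge_class"] == "mixed"


class TestEgoSubnetwork:
    def test_full_neighborhood_retained(self, example_graph):
        sub = ego_subnetwork(example_graph, Y)
        assert set(sub.nodes) == {X, Y, Z, W}
        assert sub.number_of_edges() == 5
        assert sub.degree(Y) == sub.number_of_nodes() - 1

    def test_isolated_pair(self):
        g = build_network(corpus_of([X, Y]))
        sub = ego_subnetwork(g, X)
        assert sub.number_of_nodes() == 2
        assert sub.number_of_edges() == 1

    def test_weights_and_pmids_preserved(self, example_graph):
        sub = ego_subnetwork(example_graph, Z)
        assert sub[Y][Z]["weight"] == 2
        assert sub[Y][Z]["pmids"] == ["a1", "a2"]

    def test_subgraph_inclusion_property(self, example_graph):
        for focal in example_graph.nodes:
            sub = ego_subnetwork(example_graph, focal)
            assert set(sub.edges) <= set(example_graph.edges) or all(
                example_graph.has_edge(a, b) for a, b in sub.edges
            )
            assert set(example_graph.neighbors(focal)) <= set(sub.nodes)
            assert sub.degree(focal) == sub.number_of_nodes() - 1

    def test_missing_focal_raises_named_error(self, example_graph):
        with pytest.raises(KeyError, match="Nonexistent"):
            ego_subnetwork(example_graph, "Nonexistent Term")

    def test_string_lookup_by_label(self, example_graph):
        sub = ego_subnetwork(example_graph, "Y")
        assert sub.graph["focal"] == "Y"


class TestLargestComponent:
    def test_connected_graph_is_identity(self, example_graph):
        out = largest_component(example_graph)
        assert set(out.nodes) == set(example_graph.nodes)
        assert set(out.edges) == set(example_graph.edges)

    def test_larger_component_wins(self):
        a = [MeshEntity(f"A{i}") for i in range(5)]
        b = [MeshEntity(f"B{i}") for i in range(3)]
        g = nx.Graph()
        nx.add_path(g, a)
        nx.add_path(g, b)
        assert set(largest_component(g).nodes) == set(a)

    def test_empty_graph(self):
        assert largest_component(nx.Graph()).number_of_nodes() == 0

    def test_component_membership_matches_bfs_oracle(self):
        rng = random.Random(41)
        for trial in range(20):
            n = rng.randint(2, 30)
            from conftest import random_entity_graph

            g = random_entity_graph(n, rng.uniform(0.02, 0.15), seed=100 + trial)
            comps = components_oracle(list(g.nodes), list(g.edges))
            biggest_size = max(len(c) for c in comps)
            candidates = [c for c in comps if len(c) == biggest_size]
            out = largest_component(g)
            assert len(out) == biggest_size
            if len(candidates) == 1:
                assert set(out.nodes) == set(candidates[0])
            else:
                # tie broken by lexicographically smallest member label
                winner = min(candidates, key=lambda c: min(n.label for n in c))
                assert set(out.nodes) == set(winner)


class TestExport:
    def test_edge_csv_row_count(self, example_graph, tmp_path):
        path = tmp_path / "edges.csv"
        export_graph(example_graph, path, "edge-csv")
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1 + example_graph.number_of_edges()
        assert lines[0] == "source,target,weight,pmids,edge_class,betweenness"

    def test_node_table_columns(self, example_graph):
        table = node_table(example_graph)
        assert list(table.columns) == [
            "term",
            "major_topic",
            "degree",
            "category",
            "local_clustering",
        ]
        assert len(table) == 4

    def test_graphml_round_trip(self, codebook, tmp_path):
        corpus = corpus_of(
            [MeshEntity("Poverty"), MeshEntity("Smoking", True), MeshEntity("Life Style")],
            [MeshEntity("Poverty"), MeshEntity("Smoking", True)],
        )
        g = build_network(corpus, codebook)
        path = tmp_path / "g.graphml"
        export_graph(g, path, "graphml")
        back = import_graphml(path)
        assert set(back.nodes) == set(g.nodes)
        assert set(map(frozenset, back.edges)) == set(map(frozenset, g.edges))
        for a, b in g.edges:
            assert back[a][b]["weight"] == g[a][b]["weight"]
            assert back[a][b]["pmids"] == g[a][b]["pmids"]
            assert back[a][b]["edge_class"] == g[a][b]["edge_class"]
        for n in g.nodes:
            assert back.nodes[n]["category"] == g.nodes[n]["category"]

    def test_unknown_format_rejected(self, example_graph, tmp_path):
        with pytest.raises(ValueError):
            export_graph(example_graph, tmp_path / "x", "gexf")

    def test_synthetic_export_counts(self, codebook, gazetteer, tmp_path):
        text, _ = generate_corpus(GeneratorConfig(n_records=300, seed=43))
        corpus = parse_medline(io.StringIO(text), gazetteer)
        filtered, _ = apply_inclusion_exclusion(corpus, codebook)
        g = build_network(filtered, codebook)
        export_graph(g, tmp_path / "n.csv", "node-csv")
        export_graph(g, tmp_path / "e.csv", "edge-csv")
        n_rows = len((tmp_path / "n.csv").read_text().strip().splitlines()) - 1
        e_rows = len((tmp_path / "e.csv").read_text().strip().splitlines()) - 1
        assert n_rows == g.number_of_nodes()
        assert e_rows == g.number_of_edges()
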