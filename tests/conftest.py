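import io

import pytest

from litmesh.codebook import load_codebook
from litmesh.gazetteer import load_gazetteer
from litmesh.medline import MeshEntity, parse_medline


@pytest.fixture(scope="session")
def gazetteer():
    return load_gazetteer()


@pytest.fixture(scope="session")
def codebook():
    return load_codebook()


SAMPLE_MEDLINE = """\
PMID- 100001
TI  - Socioeconomic position and infarction risk in two
      population cohorts.
AB  - A synthetic abstract.
DP  - 1996 Jul-Aug
MH  - *Myocardial Infarction/epidemiology
MH  - Socioeconomic Factors
MH  - Social Class/*economics
MH  - Humans
AD  - Dept. of Cardiology, London, UK.

PMID- 100002
TI  - Health policy and heart disease.
DP  - Winter 2010
MH  - Heart Diseases
MH  - Health Policy
MH  - Socioeconomic Factors
MH  - Humans
AD  - School of Public Health, Springfield University, USA.

PMID- 100003
TI  - An undated report without headings.
DP  - n.d.
"""


@pytest.fixture
def sample_corpus(gazetteer):
    return parse_medline(io.StringIO(SAMPLE_MEDLINE), gazetteer)


@pytest.fixture
def example_graph():
    """Two articles A1={X,Y,Z}, A2={Y,Z,W} → 4 nodes, 5 edges, w(YZ)=2."""
    import networkx as nx

    x, y, z, w = (MeshEntity(d) for d in "XYZW")
    g = nx.Graph(name="example")
    g.add_edge(x, y, weight=1, pmids=["a1"])
    g.add_edge(x, z, weight=1, pmids=["a1"])
    g.add_edge(y, z, weight=2, pmids=["a1", "a2"])
    g.add_edge(y, w, weight=1, pmids=["a2"])
    g.add_edge(z, w, weight=1, pmids=["a2"])
    return g


def random_entity_graph(n, p, seed):
    """G(n, p) with MeshEntity node labels."""
    import networkx as nx

    raw = nx.gnp_random_graph(n, p, seed=seed)
    mapping = {i: MeshEntity(f"Term {i:03d}") for i in raw.nodes}
    return nx.relabel_nodes(raw, mapping)
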