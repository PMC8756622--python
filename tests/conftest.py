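import pytest

from kgap.graph_core import (
    CellNode,
    ConceptNode,
    DrugNode,
    DrugSignatureEdge,
    GeneNode,
    IndicationEdge,
    KnowledgeGraph,
    SignatureGeneEdge,
    SignatureNode,
)


def make_toy_graph(z_values=None):
    """2 drugs / 3 signatures / 4 genes / 1 cell / 1 concept.

    d1 perturbs s1, s2; d2 perturbs s3.  Each signature carries z-scores
    for a couple of genes; default values straddle the |z| > 3 cutoff.
    """
    if z_values is None:
        z_values = {
            ("s1", "g1"): 4.2,
            ("s1", "g2"): -3.5,
            ("s2", "g2"): 1.0,
            ("s2", "g3"): 3.0,   # exactly at the default threshold
            ("s3", "g4"): -6.0,
        }
    drugs = [DrugNode("d1", "alphadrug", 11, frozenset({"N04AA"})),
             DrugNode("d2", "betadrug", 22, frozenset({"C01AB"}))]
    genes = [GeneNode(f"g{i}", f"GENE{i}") for i in range(1, 5)]
    cells = [CellNode("c1", "toy cell")]
    sigs = [SignatureNode(s, "c1") for s in ("s1", "s2", "s3")]
    concepts = [ConceptNode("omop:1", "Toy syndrome")]
    sg = [SignatureGeneEdge(s, g, z) for (s, g), z in z_values.items()]
    ds = [DrugSignatureEdge("d1", "s1"), DrugSignatureEdge("d1", "s2"),
          DrugSignatureEdge("d2", "s3")]
    ind = [IndicationEdge("d1", "omop:1"), IndicationEdge("d2", "omop:1")]
    return KnowledgeGraph(drugs, genes, sigs, cells, concepts, sg, ds, ind)


@pytest.fixture
def toy_graph():
    return make_toy_graph()


@pytest.fixture(scope="session")
def table4():
    from kgap.synthetic import table4_fixture

    return table4_fixture()


@pytest.fixture(scope="session")
def planted():
    """Default-parameter synthetic graph with planted signal, fixed seed."""
    from kgap.synthetic import SyntheticSpec, generate

    return generate(SyntheticSpec(seed=7))
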