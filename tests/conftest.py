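import networkx as nx
import pytest

from cencam import fixtures
from cencam.model import validate


@pytest.fixture(scope="session")
def index():
    return fixtures.builtin_ontology()


@pytest.fixture()
def worked(index):
    """All twelve worked-example models, built fresh (models are mutable)."""
    return fixtures.all_worked_examples(index)


def errors_of(model, index):
    return [v for v in validate(model, index) if v.severity == "error"]


def labeled_isomorphic(m1, m2) -> bool:
    """Graph isomorphism respecting class labels on nodes and relation
    labels on edges."""
    nm = nx.algorithms.isomorphism.categorical_node_match("class_curie", None)
    em = nx.algorithms.isomorphism.categorical_multiedge_match("relation", None)
    return nx.is_isomorphic(m1.graph(), m2.graph(), node_match=nm, edge_match=em)
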