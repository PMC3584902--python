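import pytest

from gopred.fixtures import FixtureSpec, make_toy_corpus, make_toy_dag
from gopred.ontology import GoDag


@pytest.fixture
def chain_dag() -> GoDag:
    """Three-term MF chain: leaf -> mid -> root."""
    return GoDag(
        namespace={"GO:1000000": "MF", "GO:1000001": "MF", "GO:1000002": "MF"},
        is_a_edges=[("GO:1000001", "GO:1000000"), ("GO:1000002", "GO:1000001")],
    )


@pytest.fixture
def diamond_dag() -> GoDag:
    """Six-term MF DAG: root; a, b below it; c below both; d below c;
    e a second child of a (sibling branch)."""
    r, a, b, c, d, e = (f"GO:100000{i}" for i in range(6))
    return GoDag(
        namespace={t: "MF" for t in (r, a, b, c, d, e)},
        is_a_edges=[(a, r), (b, r), (c, a), (c, b), (d, c), (e, a)],
    )


@pytest.fixture(scope="session")
def toy_spec() -> FixtureSpec:
    return FixtureSpec(seed=11)


@pytest.fixture(scope="session")
def toy_dag(toy_spec):
    return make_toy_dag(toy_spec)


@pytest.fixture(scope="session")
def toy_corpus(toy_spec, toy_dag):
    corpus, bookkeeping = make_toy_corpus(toy_dag, toy_spec)
    return corpus, bookkeeping
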