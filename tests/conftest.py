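import pytest

from pxpn import synthdata as sd
from pxpn.pathways import Pathway, PathwayCollection


@pytest.fixture(scope="session")
def scenario():
    """Default planted scenario: params, pair plan, truth, collection."""
    params, plan, truth = sd.default_scenario()
    collection = sd.make_collection(params, plan, seed=1)
    return params, plan, truth, collection


@pytest.fixture(scope="session")
def scenario_expr(scenario):
    params, _, truth, collection = scenario
    return sd.simulate_expression(collection, truth, params, seed=11)


@pytest.fixture
def tiny_collection():
    """Three pathways: P1-P2 share g3, P3 disjoint."""
    return PathwayCollection(
        [
            Pathway("P1", "first", frozenset({"g1", "g2", "g3"})),
            Pathway("P2", "second", frozenset({"g3", "g4"})),
            Pathway("P3", "third", frozenset({"g5", "g6"})),
        ]
    )
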