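import pytest

from mirdisnet import EdgeEvidence, build_graph
from mirdisnet.synth import worked_example_fixture


def edge(m, d, w):
    return (m, d, EdgeEvidence(weight=w))


@pytest.fixture
def worked_example():
    """Five-edge demonstration network: m1-d1=20, m1-d2=30, m2-d3=2,
    m3-d3=16, m3-d4=10."""
    return worked_example_fixture()


@pytest.fixture
def star_graph():
    """One miRNA regulating three diseases."""
    return build_graph([edge("m1", d, 1) for d in ("d1", "d2", "d3")])


@pytest.fixture
def four_cycle():
    """K_{2,2}: two miRNAs sharing two diseases (one square motif)."""
    return build_graph(
        [edge("m1", "d1", 1), edge("m1", "d2", 1), edge("m2", "d1", 1), edge("m2", "d2", 1)]
    )


@pytest.fixture
def single_edge():
    return build_graph([edge("m1", "d1", 5)])
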