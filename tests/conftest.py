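import networkx as nx
import pytest

from regionppi.synthetic_data import SyntheticSpec, gen_background_graph


@pytest.fixture(scope="session")
def small_background() -> nx.Graph:
    """500-node preferential-attachment background PPI graph."""
    return gen_background_graph(SyntheticSpec(graph_nodes=500, graph_attach=5, seed=11))


@pytest.fixture()
def study_sets() -> tuple[set[str], set[str]]:
    """Two interactomes with the published composition: |A|=211, |B|=255, |A∩B|=47."""
    common = {f"C{i:03d}" for i in range(47)}
    a = common | {f"A{i:03d}" for i in range(164)}
    b = common | {f"B{i:03d}" for i in range(208)}
    return a, b
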