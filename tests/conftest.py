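import networkx as nx
import numpy as np
import pytest

from pinmod import synthetic


@pytest.fixture(scope="session")
def small_scenario():
    """A desk-sized synthetic scenario shared by read-only tests."""
    return synthetic.generate_scenario(
        11, n_nodes=400, edges_per_new_node=3, module_size=15,
        n_mirnas=40, n_pathways=20, set_size_range=(5, 20), enriched_sets=3,
    )


@pytest.fixture()
def path_graph():
    g = nx.path_graph(5)
    return nx.relabel_nodes(g, {i: f"N{i}" for i in g.nodes})


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
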