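import numpy as np
import pandas as pd
import pytest

from planknet.io import BiomassMatrix
from planknet.synthetic import make_study_fixture, study_fixture_specs


@pytest.fixture(scope="session")
def study_fixture():
    """Three-class synthetic study datasets, one fixed seed for the session."""
    return make_study_fixture(0)


@pytest.fixture(scope="session")
def study_specs():
    return study_fixture_specs(0)


@pytest.fixture
def toy_matrix():
    """3 samples x 2 taxa biomass table."""
    values = pd.DataFrame(
        {"Daphnia cucullata": [0.1, 0.2, 0.3], "Keratella valga": [1.0, 0.5, 0.2]},
        index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
    )
    meta = pd.DataFrame(
        {"turbidity_ntu": [31.83, 18.5, 12.58]},
        index=values.index,
    )
    return BiomassMatrix(values, meta)


def random_graph(rng: np.random.Generator, n_max: int = 8):
    """Small random undirected graph for oracle comparisons."""
    import networkx as nx

    n = int(rng.integers(2, n_max + 1))
    p = float(rng.uniform(0.2, 0.9))
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(i, j)
    return g
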