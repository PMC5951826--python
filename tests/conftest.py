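import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from modseeker import datasets

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def shared_table():
    return datasets.load_shared_knockdown_table()


@pytest.fixture(scope="session")
def pathway_sets():
    return datasets.load_pathway_sets()


@pytest.fixture()
def path_graph():
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c"), ("c", "d")])
    return g


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def two_group_expression(rng):
    """60 null genes, 4 samples (2 vs 2), heterogeneous per-gene variance."""
    genes = [f"g{i:03d}" for i in range(60)]
    samples = ["c1", "c2", "t1", "t2"]
    sd = rng.uniform(0.1, 0.5, size=len(genes))
    matrix = rng.normal(7.0, 1.0, size=(len(genes), 1)) + rng.normal(
        0.0, 1.0, size=(len(genes), len(samples))
    ) * sd[:, None]
    expr = pd.DataFrame(matrix, index=genes, columns=samples)
    groups = pd.Series(["control", "control", "treated", "treated"], index=samples)
    return expr, groups
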