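import networkx as nx
import numpy as np
import pandas as pd
import pytest

import netprox as npx


def table_from_graph(g: nx.Graph, score: float = 0.95) -> pd.DataFrame:
    """Edge list of a graph as a scored interaction table."""
    rows = sorted((min(u, v), max(u, v), score) for u, v in g.edges)
    return pd.DataFrame(rows, columns=["protein1", "protein2", "combined_score"])


def named_gnp(n: int, p: float, seed: int) -> nx.Graph:
    g = nx.gnp_random_graph(n, p, seed=seed)
    return nx.relabel_nodes(g, {i: f"N{i:04d}" for i in g})


@pytest.fixture
def path_network():
    """A 4-node path a-b-c-d wrapped as an InteractionNetwork."""
    g = nx.path_graph(["a", "b", "c", "d"])
    return npx.build_network(table_from_graph(g), {"a", "b", "c", "d"}, {})


@pytest.fixture
def sbm_truth():
    """The standard easy-regime planted interactome: 10 blocks x 25 nodes."""
    return npx.gen_interactome(10, 25, p_in=0.25, p_out=0.01, seed=42)
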