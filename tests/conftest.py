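import networkx as nx
import numpy as np
import pandas as pd
import pytest

from netmods.network import PPINetwork
from netmods.scoring import GeneScoreTable


@pytest.fixture
def path_graph() -> PPINetwork:
    """A–B–C–D path."""
    return PPINetwork.from_edges([("A", "B"), ("B", "C"), ("C", "D")])


@pytest.fixture
def abc_path() -> PPINetwork:
    """A–B–C path used by the hand-traced greedy example."""
    return PPINetwork.from_edges([("A", "B"), ("B", "C")])


@pytest.fixture
def abc_scores() -> GeneScoreTable:
    """z = {A: 2, B: 0.5, C: 3} expressed through p-values."""
    from scipy.stats import norm

    z = {"A": 2.0, "B": 0.5, "C": 3.0}
    return GeneScoreTable.from_pvalues(pd.Series({g: norm.sf(v) for g, v in z.items()}))


@pytest.fixture
def triangle() -> PPINetwork:
    return PPINetwork.from_edges([("A", "B"), ("B", "C"), ("A", "C")])


def scores_from_z(z: dict[str, float]) -> GeneScoreTable:
    """Build a score table whose z column equals the given z-scores."""
    from scipy.stats import norm

    return GeneScoreTable.from_pvalues(pd.Series({g: norm.sf(v) for g, v in z.items()}))


def random_scored_graph(seed: int, n_max: int = 30):
    """Random connected-ish test graph plus node z-scores (oracle fodder)."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, n_max + 1))
    g = nx.gnp_random_graph(n, min(1.0, 2.5 / n), seed=int(rng.integers(2**31)))
    g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in range(n)})
    z = {node: float(rng.normal()) for node in g.nodes}
    return PPINetwork(g), z
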