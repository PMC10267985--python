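import networkx as nx
import numpy as np
import pandas as pd
import pytest

from netscreen import ExpressionStudy, SimConfig, TargetSet


@pytest.fixture
def small_cfg():
    """Desk-scale config used by fast unit tests."""
    return SimConfig(
        seed=11,
        n_genes=400,
        n_interactome_nodes=300,
        attachment_edges=3,
        de_fraction=0.05,
        n_herbs=3,
        ingredients_per_herb=2,
        targets_per_ingredient=10,
        n_distinct_drug_targets=30,
        n_genesets=20,
        geneset_size=15,
        n_planted_enriched=3,
        surv_n_per_arm=20,
    )


@pytest.fixture
def path_graph():
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("B", "C"), ("C", "D")])
    return g


@pytest.fixture
def tiny_study():
    """3 tumour vs 3 normal samples, one strong DE gene, one flat gene."""
    values = pd.DataFrame(
        {
            "T1": [5.0, 2.0],
            "T2": [5.1, 2.1],
            "T3": [4.9, 1.9],
            "N1": [2.0, 2.0],
            "N2": [2.1, 2.1],
            "N3": [1.9, 1.9],
        },
        index=["UPGENE", "FLAT"],
    )
    groups = pd.Series(
        ["tumor"] * 3 + ["normal"] * 3, index=values.columns, name="group"
    )
    return ExpressionStudy("tiny", values, groups)


def random_connected_graph(rng: np.random.Generator, n_max: int = 8) -> nx.Graph:
    """Small random connected graph: spanning tree plus random extra edges."""
    n = int(rng.integers(3, n_max + 1))
    g = nx.Graph()
    nodes = [f"N{i}" for i in range(n)]
    g.add_nodes_from(nodes)
    for i in range(1, n):
        g.add_edge(nodes[i], nodes[int(rng.integers(0, i))])
    n_extra = int(rng.integers(0, n))
    for _ in range(n_extra):
        u, v = rng.choice(n, size=2, replace=False)
        g.add_edge(nodes[u], nodes[v])
    return g


@pytest.fixture
def targets_abc():
    return TargetSet("seeds", {"A", "C"}, provenance="drug")
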