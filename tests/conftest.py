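import networkx as nx
import numpy as np
import pandas as pd
import pytest

from coessnet.netconstruct import EssentialityMatrix, build_coessentiality_network
from coessnet.synthdata import (
    simulate_drivers,
    simulate_drug_table,
    simulate_essentiality,
)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def path_graph():
    """Unit-weight path a-b-c."""
    g = nx.Graph()
    g.add_weighted_edges_from([("a", "b", 1.0), ("b", "c", 1.0)])
    return g


@pytest.fixture
def small_matrix(rng):
    vals = pd.DataFrame(
        rng.standard_normal((6, 8)),
        index=[f"g{i}" for i in range(6)],
        columns=[f"c{i}" for i in range(8)],
    )
    return EssentialityMatrix(vals)


def random_weighted_graph(n_nodes, p_edge, rng, connected=True):
    """Random weighted graph used across property tests."""
    g = nx.Graph()
    nodes = [f"n{i:03d}" for i in range(n_nodes)]
    g.add_nodes_from(nodes)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                g.add_edge(nodes[i], nodes[j], weight=float(rng.uniform(0.1, 3.0)))
    if connected:
        comps = list(nx.connected_components(g))
        for a, b in zip(comps, comps[1:]):
            g.add_edge(min(a), min(b), weight=1.0)
    return g


@pytest.fixture(scope="session")
def planted_dataset():
    """Small planted-module dataset shared by module-recovery tests.

    Sized down from the full recovery conditions so the whole suite stays
    fast; the full-scale run lives in the acceptance tests.
    """
    matrix, truth = simulate_essentiality(
        n_genes=400,
        n_cells=60,
        n_modules=3,
        module_size=25,
        beta=1.0,
        sigma=0.5,
        missing_rate=0.0,
        seed=0,
    )
    net = build_coessentiality_network(matrix)
    drivers = simulate_drivers(truth, "cancer_0", n_drivers=8, seed=1)
    return {"matrix": matrix, "truth": truth, "net": net, "drivers": drivers}


@pytest.fixture(scope="session")
def recovery_dataset():
    """Full-scale planted dataset at the stated recovery conditions."""
    matrix, truth = simulate_essentiality(
        n_genes=2000,
        n_cells=80,
        n_modules=5,
        module_size=40,
        beta=1.0,
        sigma=0.5,
        seed=0,
    )
    net = build_coessentiality_network(matrix)
    drivers = simulate_drivers(truth, "cancer_0", n_drivers=10, seed=1)
    drug_table, effective = simulate_drug_table(
        truth, "cancer_0", n_effective=5, n_null=45, dags_per_drug=5, seed=2
    )
    return {
        "matrix": matrix,
        "truth": truth,
        "net": net,
        "drivers": [g for g in drivers if g in net],
        "drug_table": drug_table,
        "effective": effective,
    }
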