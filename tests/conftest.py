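"""Shared fixtures: the seed-7 synthetic bundle and its downstream products.

The expensive end-to-end objects are session-scoped so the recovery and
acceptance tests share one computation.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from drugrepo import (
    SyntheticBundleConfig,
    WkdaConfig,
    compute_paired_de,
    generate_bundle,
    run_network_dr,
    run_overlap_dr,
    run_wkda,
    select_degs,
)
from drugrepo.wkda import key_drivers

BUNDLE_SEED = 7


@pytest.fixture(scope="session")
def bundle7():
    """Full synthetic input bundle at the reference seed."""
    return generate_bundle(SyntheticBundleConfig(seed=BUNDLE_SEED))


@pytest.fixture(scope="session")
def de7(bundle7):
    study, _, _, _ = bundle7
    table = compute_paired_de(study)
    return table, select_degs(table)


@pytest.fixture(scope="session")
def wkda7(bundle7, de7):
    _, network, _, _ = bundle7
    _, degs = de7
    table = run_wkda(network, set(degs.index), WkdaConfig(seed=11))
    return table, key_drivers(table)


@pytest.fixture(scope="session")
def arms7(bundle7, wkda7):
    _, network, library, _ = bundle7
    _, kdgs = wkda7
    ov = run_overlap_dr(kdgs, library, set(network.nodes()))
    nd = run_network_dr(kdgs, library, network, n_null=1000, seed=13)
    return ov, nd


@pytest.fixture(scope="session")
def small_weighted_graph():
    """A 100-node scale-free graph with continuous edge weights."""
    rng = np.random.default_rng(42)
    graph = nx.barabasi_albert_graph(100, 3, seed=42)
    for u, v in graph.edges():
        graph.edges[u, v]["weight"] = float(rng.uniform(0.25, 1.0))
    return nx.relabel_nodes(graph, {i: f"g{i}" for i in graph.nodes()})
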