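"""Weighted key-driver analysis (wKDA).

Every network gene is scored for enrichment of a disease gene set in its
local edge-weighted neighborhood. The per-hub statistic compares the observed
disease weight O in the neighborhood with its expectation E under random
placement of the disease set, as (O - E) / sqrt(E); significance comes from a
permutation null that relabels the disease set over the network's nodes, with
BH control across hubs. ``edge_factor`` exponentiates edge weights, so 0.0
reproduces the unweighted analysis and 1.0 uses the raw weights. A greedy
redundancy filter discards hubs whose neighborhoods overlap an already-kept
hub's neighborhood by more than ``min_hub_overlap`` (Jaccard).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse

from .diffexpr import adjust_bh


@dataclass
class WkdaConfig:
    depth: int = 1
    min_hub_overlap: float = 0.33
    edge_factor: float = 0.0
    fdr_cut: float = 0.05
    n_perm: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0 <= self.min_hub_overlap <= 1:
            raise ValueError("min_hub_overlap must lie in [0, 1]")


def extract_neighborhood(
    network: nx.Graph, hub, depth: int = 1, edge_factor: float = 0.0
) -> dict:
    """Nodes within ``depth`` edges of ``hub`` (hub excluded), each weighted by
    (heaviest path product)^edge_factor, so edge_factor = 0 gives weight 1."""
    if hub not in network:
        raise KeyError(f"hub {hub!r} not in network")
    # best product over paths of exactly k hops, maximized over k <= depth
    frontier = {hub: 1.0}
    best: dict = {}
    for _ in range(depth):
        nxt: dict = {}
        for node, prod in frontier.items():
            for nbr in network.neighbors(node):
                cand = prod * network.edges[node, nbr].get("weight", 1.0)
                if cand > nxt.get(nbr, -np.inf):
                    nxt[nbr] = cand
        for node, prod in nxt.items():
            if node != hub and prod > best.get(node, -np.inf):
                best[node] = prod
        frontier = nxt
    return {node: prod**edge_factor for node, prod in best.items()}


def kd_statistic(
    neighborhood: dict,
    disease_genes: set,
    universe: set,
    null_observed: np.ndarray | None = None,
) -> tuple[float, float]:
    """Enrichment statistic (O - E)/sqrt(E) for one weighted neighborhood.

    O sums the weights of disease genes in the neighborhood; E scales the total
    neighborhood weight by the disease fraction of the universe. The p-value is
    the upper tail of ``null_observed`` (permutation draws of O produced by
    :func:`run_wkda`); without a null it is undefined (nan) since E alone does
    not determine the spread.
    """
    if not neighborhood:
        raise ValueError("neighborhood is empty")
    total = sum(neighborhood.values())
    observed = sum(w for g, w in neighborhood.items() if g in disease_genes)
    frac = len(disease_genes & universe) / len(universe)
    expected = total * frac
    if expected == 0:
        warnings.warn("expected disease weight is 0; statistic undefined", stacklevel=2)
        return float("nan"), 1.0
    stat = (observed - expected) / np.sqrt(expected)
    if null_observed is None:
        return float(stat), float("nan")
    null_observed = np.asarray(null_observed, dtype=float)
    p = np.sum(null_observed >= observed) / null_observed.size
    return float(stat), float(p)


def _neighborhood_matrix(network: nx.Graph, nodes: list, config: WkdaConfig):
    """Sparse hubs x nodes matrix of neighborhood weights (rows follow
    ``nodes``; nodes of degree 0 get empty rows)."""
    index = {g: i for i, g in enumerate(nodes)}
    rows, cols, vals = [], [], []
    for i, hub in enumerate(nodes):
        if network.degree(hub) == 0:
            continue
        for nbr, w in extract_neighborhood(network, hub, config.depth, config.edge_factor).items():
            rows.append(i)
            cols.append(index[nbr])
            vals.append(w)
    return sparse.csr_matrix((vals, (rows, cols)), shape=(len(nodes), len(nodes)))


def run_wkda(network: nx.Graph, disease_genes: set, config: WkdaConfig) -> pd.DataFrame:
    """Score every connected node; permutation p, BH FDR, redundancy filter.

    Returns a DataFrame sorted by statistic descending with columns ``hub``,
    ``size``, ``observed``, ``expected``, ``statistic``, ``p``, ``fdr``,
    ``is_key_driver`` (fdr < fdr_cut) and ``kept`` (survives the hub-overlap
    filter among key drivers).
    """
    nodes = sorted(network.nodes())
    disease = set(disease_genes) & set(nodes)
    if not disease:
        raise ValueError("disease set does not intersect the network")
    scored = [g for g in nodes if network.degree(g) > 0]
    W = _neighborhood_matrix(network, nodes, config)
    ind = np.fromiter((g in disease for g in nodes), dtype=float, count=len(nodes))
    observed = np.asarray(W @ ind).ravel()
    totals = np.asarray(W.sum(axis=1)).ravel()
    frac = len(disease) / len(nodes)
    expected = totals * frac

    rng = np.random.default_rng(config.seed)
    keys = rng.random((config.n_perm, len(nodes)))
    picks = np.argpartition(keys, len(disease) - 1, axis=1)[:, : len(disease)]
    B = np.zeros((len(nodes), config.n_perm))
    B[picks.T, np.arange(config.n_perm)[None, :].repeat(len(disease), axis=0)] = 1.0
    null_obs = np.asarray(W @ B)  # hubs x n_perm

    # plain Monte-Carlo fraction (resolution 1/n_perm): with thousands of
    # hubs under BH, an add-one floor of 1/(n_perm+1) would make the default
    # n_perm unable to certify any hub
    exceed = (null_obs >= observed[:, None]).sum(axis=1)
    p = exceed / config.n_perm
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = (observed - expected) / np.sqrt(expected)
    degenerate = expected == 0
    stat[degenerate] = np.nan
    p[degenerate] = 1.0

    idx = [i for i, g in enumerate(nodes) if g in set(scored)]
    table = pd.DataFrame(
        {
            "hub": [nodes[i] for i in idx],
            "size": np.asarray((W != 0).sum(axis=1)).ravel()[idx].astype(int),
            "observed": observed[idx],
            "expected": expected[idx],
            "statistic": stat[idx],
            "p": p[idx],
        }
    )
    table["fdr"] = adjust_bh(table["p"].to_numpy())
    table["is_key_driver"] = table["fdr"] < config.fdr_cut
    table = table.sort_values(
        ["statistic", "hub"], ascending=[False, True], kind="stable", ignore_index=True, na_position="last"
    )
    kept = hub_overlap_filter(table[table["is_key_driver"]], network, config.min_hub_overlap, config)
    table["kept"] = table["hub"].isin(set(kept["hub"])) & table["is_key_driver"]
    return table


def hub_overlap_filter(
    results: pd.DataFrame, network: nx.Graph, min_hub_overlap: float, config: WkdaConfig | None = None
) -> pd.DataFrame:
    """Greedy redundancy filter on results sorted by statistic descending:
    discard a hub whose neighborhood Jaccard-overlaps an already-kept hub's
    neighborhood by more than ``min_hub_overlap``."""
    config = config or WkdaConfig()
    kept_rows = []
    kept_sets: list[set] = []
    for _, row in results.iterrows():
        nbhd = set(extract_neighborhood(network, row["hub"], config.depth, config.edge_factor))
        redundant = any(
            len(nbhd & other) / len(nbhd | other) > min_hub_overlap for other in kept_sets if nbhd | other
        )
        if not redundant:
            kept_rows.append(row)
            kept_sets.append(nbhd)
    return pd.DataFrame(kept_rows, columns=results.columns).reset_index(drop=True)


def key_drivers(table: pd.DataFrame) -> set:
    """The kept key-driver gene set from a run_wkda table."""
    return set(table.loc[table["kept"], "hub"])
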