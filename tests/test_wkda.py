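"""Weighted key-driver analysis: neighborhoods, statistic, nulls, filters."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from drugrepo import WkdaConfig, extract_neighborhood, hub_overlap_filter, kd_statistic, run_wkda
from drugrepo.wkda import key_drivers


def weighted(edges):
    g = nx.Graph()
    for u, v, w in edges:
        g.add_edge(u, v, weight=w)
    return g


class TestExtractNeighborhood:
    def test_star_center_depth_one(self):
        g = nx.star_graph(5)
        nbhd = extract_neighborhood(g, 0, depth=1, edge_factor=0.0)
        assert nbhd == {i: 1.0 for i in range(1, 6)}

    def test_path_depths(self):
        g = nx.path_graph(["a", "b", "c"])
        assert set(extract_neighborhood(g, "a", depth=1)) == {"b"}
        assert set(extract_neighborhood(g, "a", depth=2)) == {"b", "c"}

    def test_weighted_triangle_edge_factor_one(self):
        g = weighted([("a", "b", 0.5), ("b", "c", 0.8), ("a", "c", 0.9)])
        nbhd = extract_neighborhood(g, "a", depth=1, edge_factor=1.0)
        assert nbhd == pytest.approx({"b": 0.5, "c": 0.9})

    def test_heaviest_path_wins_at_depth_two(self):
        # two routes a->c: direct 0.1 vs via b 0.9*0.9 = 0.81
        g = weighted([("a", "b", 0.9), ("b", "c", 0.9), ("a", "c", 0.1)])
        nbhd = extract_neighborhood(g, "a", depth=2, edge_factor=1.0)
        assert nbhd["c"] == pytest.approx(0.81)

    def test_isolated_hub_empty(self):
        g = nx.Graph()
        g.add_node("x")
        assert extract_neighborhood(g, "x") == {}


class TestKdStatistic:
    def test_null_case_zero(self):
        nbhd = {f"g{i}": 1.0 for i in range(10)}
        universe = {f"g{i}" for i in range(100)}
        disease = {f"g{i}" for i in range(10, 19)} | {"g0"}  # one in the neighborhood
        stat, _ = kd_statistic(nbhd, disease, universe)
        assert stat == pytest.approx(0.0)

    def test_fully_diseased_neighborhood(self):
        nbhd = {f"g{i}": 1.0 for i in range(10)}
        universe = {f"g{i}" for i in range(100)}
        disease = {f"g{i}" for i in range(10)}
        stat, _ = kd_statistic(nbhd, disease, universe)
        assert stat == pytest.approx((10 - 1) / 1.0)

    def test_no_expected_weight_warns(self):
        with pytest.warns(UserWarning, match="undefined"):
            stat, p = kd_statistic({"a": 1.0}, set(), {"a", "b"})
        assert math.isnan(stat) and p == 1.0

    def test_p_from_supplied_null(self):
        nbhd = {"a": 1.0, "b": 1.0}
        stat, p = kd_statistic(nbhd, {"a"}, {"a", "b", "c", "d"}, null_observed=[0, 0, 1, 2])
        assert p == pytest.approx(2 / 4)


class TestRunWkda:
    def test_empty_disease_intersection_rejected(self):
        g = nx.path_graph(["a", "b", "c"])
        with pytest.raises(ValueError, match="intersect"):
            run_wkda(g, {"zz"}, WkdaConfig(n_perm=50, seed=0))

    def test_permutation_p_matches_hypergeometric_small_graph(self):
        """Unweighted depth-1: the permutation null is hypergeometric."""
        g = nx.barabasi_albert_graph(18, 2, seed=1)
        g = nx.relabel_nodes(g, {i: f"g{i}" for i in g.nodes()})
        disease = {f"g{i}" for i in (0, 3, 5, 7, 11)}
        cfg = WkdaConfig(n_perm=4000, seed=9)
        table = run_wkda(g, disease, cfg).set_index("hub")
        for hub in ["g0", "g1", "g2"]:
            nbrs = set(g.neighbors(hub))
            obs = len(nbrs & disease)
            exact = stats.hypergeom.sf(obs - 1, 18, len(disease), len(nbrs))
            p_hat = table.loc[hub, "p"]
            tol = 3 * np.sqrt(exact * (1 - exact) / cfg.n_perm)
            assert abs(p_hat - exact) <= tol + 1e-9

    def test_matches_exhaustive_placement_oracle(self):
        """On a tiny graph, compare against enumerating every disease-set
        placement exactly."""
        g = nx.relabel_nodes(nx.barabasi_albert_graph(12, 2, seed=3), lambda i: f"n{i}")
        nodes = sorted(g.nodes())
        disease = {"n0", "n2", "n9"}
        cfg = WkdaConfig(n_perm=3000, seed=4)
        table = run_wkda(g, disease, cfg).set_index("hub")
        for hub in nodes[:5]:
            nbrs = set(g.neighbors(hub))
            obs = len(nbrs & disease)
            hits = sum(
                len(nbrs & set(combo)) >= obs
                for combo in itertools.combinations(nodes, len(disease))
            )
            exact = hits / math.comb(len(nodes), len(disease))
            tol = 3 * np.sqrt(exact * (1 - exact) / cfg.n_perm)
            assert abs(table.loc[hub, "p"] - exact) <= tol + 1e-9

    def test_edge_factor_zero_invariant_to_weight_rescaling(self, small_weighted_graph):
        g1 = small_weighted_graph
        g2 = g1.copy()
        for u, v in g2.edges():
            g2.edges[u, v]["weight"] *= 7.3
        disease = {f"g{i}" for i in range(0, 40, 3)}
        cfg = WkdaConfig(edge_factor=0.0, n_perm=300, seed=5)
        t1 = run_wkda(g1, disease, cfg)
        t2 = run_wkda(g2, disease, cfg)
        pd.testing.assert_frame_equal(t1, t2)

    def test_null_p_values_uniform(self, small_weighted_graph):
        """Permutation p at a high-degree hub under random disease sets is
        uniform (weighted statistic, so ties are negligible)."""
        g = small_weighted_graph
        hub = max(g.nodes(), key=lambda n: g.degree(n))
        rng = np.random.default_rng(17)
        ps = []
        for seed in range(50):
            disease = set(rng.choice(sorted(g.nodes()), 25, replace=False))
            cfg = WkdaConfig(edge_factor=1.0, n_perm=400, seed=seed)
            table = run_wkda(g, disease, cfg).set_index("hub")
            ps.append(table.loc[hub, "p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_planted_hubs_recovered(self, bundle7, wkda7):
        _, _, _, truth = bundle7
        table, kdgs = wkda7
        significant = set(table.loc[table["is_key_driver"], "hub"])
        assert truth.key_driver_ids <= significant
        top = set(table.head(2 * len(truth.key_driver_ids))["hub"])
        assert truth.key_driver_ids <= top


class TestHubOverlapFilter:
    @staticmethod
    def results_for(hubs, stats_):
        return pd.DataFrame({"hub": hubs, "statistic": stats_}).sort_values(
            "statistic", ascending=False, ignore_index=True
        )

    def test_identical_neighborhoods_keep_stronger(self):
        g = nx.Graph()
        for leaf in ("x", "y", "z"):
            g.add_edge("a", leaf)
            g.add_edge("b", leaf)
        kept = hub_overlap_filter(self.results_for(["a", "b"], [5.0, 3.0]), g, 0.33)
        assert list(kept["hub"]) == ["a"]

    def test_disjoint_neighborhoods_all_kept(self):
        g = nx.Graph()
        g.add_edges_from([("a", "x"), ("a", "y"), ("b", "u"), ("b", "v")])
        kept = hub_overlap_filter(self.results_for(["a", "b"], [5.0, 3.0]), g, 0.33)
        assert list(kept["hub"]) == ["a", "b"]

    def test_nine_node_toy_with_known_overlaps(self):
        """J(a,b)=0.5 > 0.33 so b falls to a; J(a,c)=J(b,c)=0.2 so c stays."""
        g = nx.Graph()
        g.add_edges_from([("a", 1), ("a", 2), ("a", 3)])
        g.add_edges_from([("b", 2), ("b", 3), ("b", 4)])
        g.add_edges_from([("c", 3), ("c", 8), ("c", 9)])
        kept = hub_overlap_filter(self.results_for(["a", "b", "c"], [5.0, 4.0, 3.0]), g, 0.33)
        assert list(kept["hub"]) == ["a", "c"]


def test_wkda_false_positive_rate_controlled(small_weighted_graph):
    """Random disease sets: mean fraction of FDR-significant hubs stays at or
    below the nominal level plus two binomial SDs."""
    g = small_weighted_graph
    n_hubs = sum(1 for n in g.nodes() if g.degree(n) > 0)
    rng = np.random.default_rng(23)
    fractions = []
    for seed in range(50):
        disease = set(rng.choice(sorted(g.nodes()), 20, replace=False))
        table = run_wkda(g, disease, WkdaConfig(n_perm=300, seed=seed))
        fractions.append(table["is_key_driver"].mean())
    level = 0.05
    bound = level + 2 * np.sqrt(level * (1 - level) / (50 * n_hubs))
    assert np.mean(fractions) <= bound


def test_key_drivers_helper(bundle7, wkda7):
    table, kdgs = wkda7
    assert kdgs == set(table.loc[table["kept"], "hub"])
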