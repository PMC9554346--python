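"""Paired differential expression: identities, BH, moderation, recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drugrepo import (
    PairedExpressionStudy,
    SyntheticStudyConfig,
    adjust_bh,
    compute_paired_de,
    generate_paired_expression,
    select_degs,
)


def make_study(diffs: np.ndarray, base: np.ndarray | None = None) -> PairedExpressionStudy:
    """Study with the given genes x pairs difference matrix (tumour - normal)."""
    n_genes, n_pairs = diffs.shape
    base = base if base is not None else np.full((n_genes, n_pairs), 8.0)
    cols, data, meta = [], [], []
    for p in range(n_pairs):
        cols += [f"P{p}_N", f"P{p}_T"]
        data += [base[:, p], base[:, p] + diffs[:, p]]
        meta += [{"pair_id": f"P{p}", "condition": "normal"}, {"pair_id": f"P{p}", "condition": "tumour"}]
    values = pd.DataFrame(np.column_stack(data), index=[f"g{i}" for i in range(n_genes)], columns=cols)
    return PairedExpressionStudy(values=values, samples=pd.DataFrame(meta, index=cols))


class TestComputePairedDe:
    def test_identical_conditions_give_null_result(self):
        with pytest.warns(UserWarning, match="constant"):
            table = compute_paired_de(make_study(np.zeros((5, 4))), moderation=False)
        assert np.allclose(table["logFC"], 0)
        assert np.allclose(table["p"], 1)

    def test_consistent_shift_with_tiny_jitter_is_significant(self):
        diffs = np.array([[1.0, 1.0001, 0.9999]])
        table = compute_paired_de(make_study(diffs), moderation=False)
        assert table["logFC"].iloc[0] == pytest.approx(1.0, abs=1e-3)
        assert abs(table["t"].iloc[0]) > 1e3
        assert table["p"].iloc[0] < 1e-6

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError, match="2 complete pairs"):
            compute_paired_de(make_study(np.ones((3, 1))))

    def test_label_swap_negates_logfc_and_keeps_p(self):
        rng = np.random.default_rng(0)
        diffs = rng.normal(0, 1, size=(50, 6))
        fwd = compute_paired_de(make_study(diffs))
        rev = compute_paired_de(make_study(-diffs))
        assert np.allclose(fwd["logFC"], -rev["logFC"])
        assert np.allclose(fwd["p"], rev["p"])

    def test_planted_logfc_within_three_se(self, bundle7):
        """Estimated logFC for planted genes is within 3 SE of truth for >=95%
        of them; the generator fixes SE = noise_sd / sqrt(n_pairs)."""
        study, _, _, truth = bundle7
        table = compute_paired_de(study)
        cfg = SyntheticStudyConfig()
        se = cfg.noise_sd / np.sqrt(cfg.n_pairs)
        planted = sorted(truth.de_gene_ids)
        err = np.abs(table.loc[planted, "logFC"].to_numpy() - np.array([truth.true_logfc[g] for g in planted]))
        assert np.mean(err <= 3 * se) >= 0.95

    def test_moderated_matches_limma_oracle(self, tmp_path):
        """The empirical-Bayes moderated t reproduces the reference R
        implementation (limma on the paired-difference matrix) to 4 digits."""
        import subprocess

        rng = np.random.default_rng(3)
        diffs = rng.normal(0, rng.uniform(0.3, 1.5, size=(120, 1)), size=(120, 6))
        diffs[:20] += 1.0
        table = compute_paired_de(make_study(diffs), moderation=True)
        dpath, opath = tmp_path / "d.tsv", tmp_path / "limma.tsv"
        pd.DataFrame(diffs).to_csv(dpath, sep="\t", index=False)
        script = f"""
        suppressMessages(library(limma))
        d <- as.matrix(read.delim("{dpath}"))
        fit <- eBayes(lmFit(d, rep(1, ncol(d))))
        write.table(data.frame(logFC=fit$coefficients[,1], t=fit$t[,1], p=fit$p.value[,1]),
                    "{opath}", sep="\t", row.names=FALSE)
        """
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        ref = pd.read_csv(opath, sep="\t")
        assert np.allclose(table["logFC"], ref["logFC"], rtol=1e-6)
        assert np.allclose(table["t"], ref["t"], rtol=1e-4)
        assert np.allclose(table["p"], ref["p"], rtol=1e-3)


class TestAdjustBh:
    def test_worked_examples(self):
        assert np.allclose(adjust_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        assert np.allclose(adjust_bh([1.0, 1.0, 1.0]), 1.0)
        assert adjust_bh([0.2]) == pytest.approx([0.2])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.5])
        with pytest.raises(ValueError):
            adjust_bh([-0.1])

    def test_matches_stepup_definition_on_random_vectors(self):
        """Literal step-up oracle: adj_p(i) = min_{j: p_j >= p_i} min(1, p_j*n/rank_j)."""

        def stepup(p):
            n = len(p)
            order = sorted(range(n), key=lambda i: p[i])
            out = [0.0] * n
            running = 1.0
            for rank in range(n, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * n / rank)
                out[i] = min(1.0, running)
            return out

        rng = np.random.default_rng(1)
        for _ in range(1000):
            p = rng.uniform(0, 1, size=rng.integers(1, 40))
            assert np.allclose(adjust_bh(p), stepup(list(p)))

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(2)
        p = rng.uniform(0, 1, size=500)
        assert np.allclose(adjust_bh(p), multipletests(p, method="fdr_bh")[1])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(deadline=None, max_examples=100)
    def test_monotone_and_dominating(self, p):
        adj = adjust_bh(p)
        assert np.all(adj >= np.asarray(p) - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestSelectDegs:
    def test_boundary_logfc_excluded(self):
        table = pd.DataFrame(
            {"logFC": [1.5, 1.6], "t": [5, 5], "p": [1e-6, 1e-6], "adj_p": [1e-5, 1e-5], "direction": "ns"},
            index=["at_cut", "above_cut"],
        )
        kept = select_degs(table)
        assert list(kept.index) == ["above_cut"]

    def test_strongly_upregulated_gene_included(self):
        # the magnitudes reported for MMP1 in the ESCC cohort
        table = pd.DataFrame(
            {"logFC": [4.443], "t": [15.0], "p": [1e-30], "adj_p": [8.65e-29], "direction": "ns"},
            index=["MMP1"],
        )
        kept = select_degs(table)
        assert list(kept.index) == ["MMP1"]
        assert kept["direction"].iloc[0] == "up"

    def test_planted_gene_recovery(self, bundle7, de7):
        _, _, _, truth = bundle7
        _, degs = de7
        recovered = set(degs.index)
        precision = len(recovered & truth.de_gene_ids) / len(recovered)
        recall = len(recovered & truth.de_gene_ids) / len(truth.de_gene_ids)
        assert precision >= 0.9
        assert recall >= 0.9

    def test_null_data_selects_at_most_nominal_fraction(self):
        """BH at 0.01 on pure-noise studies: mean selected fraction <= 1%."""
        fractions = []
        for seed in range(50):
            cfg = SyntheticStudyConfig(n_genes=400, n_pairs=15, n_de_genes=0, seed=seed)
            study, _ = generate_paired_expression(cfg)
            table = compute_paired_de(study)
            fractions.append(len(select_degs(table, logfc_cut=0.0)) / cfg.n_genes)
        assert np.mean(fractions) <= 0.01


class TestStudyContainer:
    def test_unbalanced_pairs_rejected(self):
        values = pd.DataFrame(np.zeros((2, 2)), index=["a", "b"], columns=["s1", "s2"])
        samples = pd.DataFrame(
            {"pair_id": ["P0", "P0"], "condition": ["tumour", "tumour"]}, index=["s1", "s2"]
        )
        with pytest.raises(ValueError, match="exactly once"):
            PairedExpressionStudy(values=values, samples=samples)

    def test_missing_values_dropped(self, caplog):
        study = make_study(np.ones((3, 3)))
        study.values.iloc[0, 0] = np.nan
        relaoded = PairedExpressionStudy(values=study.values, samples=study.samples)
        assert len(relaoded.gene_ids) == 2
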