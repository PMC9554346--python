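"""Stage functions binding the pipeline together, plus the run manifest.

Each stage reads its inputs from a run directory, computes through the
library modules, writes TSV/JSON outputs back into the run directory, and
records what it did (inputs, parameters, seed) in ``manifest.json``. The
``run_all`` driver chains the stages in analysis order: simulate -> de ->
enrich -> wkda -> overlap -> netdr -> select.
"""

from __future__ import annotations

import datetime
import logging
from pathlib import Path

import pandas as pd

from . import __version__, diffexpr, enrichment, io, overlap, proximity, selection, synthetic, wkda
from .config import PipelineConfig

logger = logging.getLogger(__name__)

STAGES = ("simulate", "de", "enrich", "wkda", "overlap", "netdr", "select")


def _record(run_dir: Path, stage: str, config: PipelineConfig, inputs: list[str], outputs: list[str]) -> None:
    path = run_dir / "manifest.json"
    manifest = io.read_json(path) if path.exists() else {"version": __version__, "stages": {}}
    manifest["stages"][stage] = {
        "inputs": inputs,
        "outputs": outputs,
        "seed": config.stage_seed(stage),
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "parameters": {
            k: v for k, v in vars(config).items() if not isinstance(v, dict)
        },
    }
    io.write_json(manifest, path)


def stage_simulate(config: PipelineConfig, run_dir: Path) -> None:
    """Generate the full synthetic input bundle (with truth) into run_dir."""
    run_dir.mkdir(parents=True, exist_ok=True)
    bundle_cfg = synthetic.SyntheticBundleConfig(
        study=synthetic.SyntheticStudyConfig(
            n_genes=config.n_genes,
            n_pairs=config.n_pairs,
            n_de_genes=config.n_de_genes,
            de_logfc_mean=config.de_logfc_mean,
            de_logfc_sd=config.de_logfc_sd,
            noise_sd=config.noise_sd,
        ),
        n_drugs=config.n_drugs,
        reversal_drugs=config.reversal_drugs,
        partial_drugs=config.partial_drugs,
        seed=config.stage_seed("simulate"),
    )
    study, network, library, truth = synthetic.generate_bundle(bundle_cfg)
    io.write_expression(study, run_dir / config.expression, run_dir / config.samples)
    io.write_network(network, run_dir / config.network)
    io.write_drug_library(library, run_dir / config.drug_library)
    _write_synthetic_gene_sets(study, truth, config, run_dir)
    io.write_json(
        {
            "de_gene_ids": truth.de_gene_ids,
            "true_logfc": truth.true_logfc,
            "key_driver_ids": truth.key_driver_ids,
            "reversal_drug_ids": truth.reversal_drug_ids,
        },
        run_dir / "truth.json",
    )
    _record(run_dir, "simulate", config, [], [config.expression, config.samples, config.network, config.drug_library, config.gene_sets, "truth.json"])


def _write_synthetic_gene_sets(study, truth, config: PipelineConfig, run_dir: Path) -> None:
    """Small GO/KEGG stand-in collection: random sets plus two planted sets
    drawn from the DE genes, so the enrichment stage has signal to find."""
    import numpy as np

    rng = np.random.default_rng(config.stage_seed("simulate") + 1)
    genes = list(study.gene_ids)
    de = sorted(truth.de_gene_ids)
    sets: dict[str, set[str]] = {}
    for i in range(18):
        size = int(rng.integers(15, 60))
        sets[f"random_set_{i + 1:02d}"] = {genes[j] for j in rng.choice(len(genes), size, replace=False)}
    for name, frac in (("planted_disease_module_a", 0.8), ("planted_disease_module_b", 0.6)):
        size = int(rng.integers(25, 50))
        n_de = min(int(frac * size), len(de))
        members = {de[j] for j in rng.choice(len(de), n_de, replace=False)}
        members |= {genes[j] for j in rng.choice(len(genes), size - n_de, replace=False)}
        sets[name] = members
    io.write_gmt(sets, run_dir / config.gene_sets)


def stage_de(config: PipelineConfig, run_dir: Path) -> pd.DataFrame:
    study = io.read_expression(run_dir / config.expression, run_dir / config.samples)
    table = diffexpr.compute_paired_de(study, moderation=config.moderation)
    degs = diffexpr.select_degs(table, logfc_cut=config.logfc_cut, adjp_cut=config.de_adjp_cut)
    io.write_results(table, run_dir / "de_table.tsv", {"stage": "de"}, index=True)
    io.write_results(degs, run_dir / "degs.tsv", {"stage": "de"}, index=True)
    (run_dir / config.disease_genes).write_text("".join(f"{g}\n" for g in degs.index))
    logger.info("de: %d DEGs (%d up / %d down)", len(degs), (degs["direction"] == "up").sum(), (degs["direction"] == "down").sum())
    _record(run_dir, "de", config, [config.expression, config.samples], ["de_table.tsv", "degs.tsv", config.disease_genes])
    return degs


def stage_enrich(config: PipelineConfig, run_dir: Path) -> pd.DataFrame:
    table = io.read_results(run_dir / "de_table.tsv", index_col="gene")
    degs = [g.strip() for g in (run_dir / config.disease_genes).read_text().splitlines() if g.strip()]
    sets = io.read_gmt(run_dir / config.gene_sets)
    collection = enrichment.GeneSetCollection(sets=sets, universe=set(table.index))
    ora = enrichment.ora_test(set(degs), collection)
    ranked = table["t"].astype(float)
    gsea = enrichment.gsea_preranked(
        ranked, collection, n_perm=config.gsea_n_perm, seed=config.stage_seed("enrich")
    )
    io.write_results(ora, run_dir / "enrichment_ora.tsv", {"stage": "enrich"})
    io.write_results(gsea, run_dir / "enrichment_gsea.tsv", {"stage": "enrich"})
    _record(run_dir, "enrich", config, ["de_table.tsv", config.disease_genes, config.gene_sets], ["enrichment_ora.tsv", "enrichment_gsea.tsv"])
    return ora


def stage_wkda(config: PipelineConfig, run_dir: Path) -> pd.DataFrame:
    network = io.read_network(run_dir / config.network)
    degs = {g.strip() for g in (run_dir / config.disease_genes).read_text().splitlines() if g.strip()}
    cfg = wkda.WkdaConfig(
        depth=config.depth,
        min_hub_overlap=config.min_hub_overlap,
        edge_factor=config.edge_factor,
        fdr_cut=config.kd_fdr_cut,
        n_perm=config.wkda_n_perm,
        seed=config.stage_seed("wkda"),
    )
    table = wkda.run_wkda(network, degs, cfg)
    kdgs = wkda.key_drivers(table)
    io.write_results(table, run_dir / "wkda.tsv", {"stage": "wkda"})
    (run_dir / "kdgs.txt").write_text("".join(f"{g}\n" for g in sorted(kdgs)))
    logger.info("wkda: %d significant hubs, %d kept after overlap filter", int(table["is_key_driver"].sum()), len(kdgs))
    _record(run_dir, "wkda", config, [config.network, config.disease_genes], ["wkda.tsv", "kdgs.txt"])
    return table


def _read_kdgs(run_dir: Path) -> set:
    return {g.strip() for g in (run_dir / "kdgs.txt").read_text().splitlines() if g.strip()}


def stage_overlap(config: PipelineConfig, run_dir: Path) -> pd.DataFrame:
    network = io.read_network(run_dir / config.network)
    library = io.read_drug_library(run_dir / config.drug_library)
    result = overlap.run_overlap_dr(_read_kdgs(run_dir), library, set(network.nodes()))
    io.write_results(result, run_dir / "overlap_dr.tsv", {"stage": "overlap"})
    _record(run_dir, "overlap", config, ["kdgs.txt", config.drug_library, config.network], ["overlap_dr.tsv"])
    return result


def stage_netdr(config: PipelineConfig, run_dir: Path) -> pd.DataFrame:
    network = io.read_network(run_dir / config.network)
    library = io.read_drug_library(run_dir / config.drug_library)
    result = proximity.run_network_dr(
        _read_kdgs(run_dir),
        library,
        network,
        n_null=config.netdr_n_null,
        seed=config.stage_seed("netdr"),
    )
    io.write_results(result, run_dir / "network_dr.tsv", {"stage": "netdr"})
    _record(run_dir, "netdr", config, ["kdgs.txt", config.drug_library, config.network], ["network_dr.tsv"])
    return result


def stage_select(config: PipelineConfig, run_dir: Path, prefiltered: bool = False) -> pd.DataFrame:
    """Arm filtering + intersection. With ``prefiltered`` the arm tables are
    taken as already filtered and deduplicated (e.g. a published candidate
    table split into its arm projections) and only intersect-and-rank runs:
    the mean-Jaccard cut is calibrated against the full arm output and is not
    idempotent, so re-applying it to its own survivors would drop rows."""
    ov = io.read_results(run_dir / "overlap_dr.tsv")
    nd = io.read_results(run_dir / "network_dr.tsv")
    if prefiltered:
        final = selection.intersect_and_rank(ov, nd)
    else:
        final = selection.intersect_and_rank(
            selection.filter_overlap_arm(ov), selection.filter_network_arm(nd)
        )
    io.write_results(final, run_dir / "final_table.tsv", {"stage": "select"})
    io.write_json(final.to_dict(orient="records"), run_dir / "final_table.json")
    logger.info("select: %d repositioned drug(s)", len(final))
    _record(run_dir, "select", config, ["overlap_dr.tsv", "network_dr.tsv"], ["final_table.tsv", "final_table.json"])
    return final


_STAGE_FN = {
    "simulate": stage_simulate,
    "de": stage_de,
    "enrich": stage_enrich,
    "wkda": stage_wkda,
    "overlap": stage_overlap,
    "netdr": stage_netdr,
    "select": stage_select,
}


def run_stage(stage: str, config: PipelineConfig, run_dir: Path):
    if stage not in _STAGE_FN:
        raise KeyError(f"unknown stage {stage!r}")
    return _STAGE_FN[stage](config, Path(run_dir))


def run_all(config: PipelineConfig, run_dir: Path) -> pd.DataFrame:
    """Chain every stage in analysis order; returns the final drug table."""
    run_dir = Path(run_dir)
    for stage in STAGES:
        logger.info("running stage %s", stage)
        result = _STAGE_FN[stage](config, run_dir)
    return result
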