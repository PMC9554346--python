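"""Synthetic pipeline inputs with planted, recoverable truth.

Three generators emulate the pipeline's real inputs:

* paired tumour/normal log2 expression with a chosen number of differential
  genes (tumour = normal + planted log2 fold change + noise);
* a scale-free (preferential-attachment) weighted gene network in which a few
  high-degree hubs are rewired so their depth-1 neighborhoods are enriched for
  disease genes — the planted key drivers;
* a drug-signature library in which most drugs draw genes uniformly from the
  network while a few planted "reversal" drugs draw a stated fraction of their
  genes from the disease module — the disease genes and the neighbor nodes
  most strongly connected to them (sampling probability proportional to the
  square of a node's disease connectivity, which concentrates reversal
  signatures on the module's hub regulators).

Every generator also returns the planted truth so downstream stages have a
parameter-recovery oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .diffexpr import NORMAL, TUMOUR, PairedExpressionStudy
from .io import DrugLibrary, DrugSignature

HUMAN = "Homo sapiens"


@dataclass(frozen=True)
class SyntheticStudyConfig:
    """Paired-expression generator settings.

    Defaults emulate a 53-pair microarray cohort on a reduced 2000-gene
    universe; all values are on the log2-expression scale.
    """

    n_genes: int = 2000
    n_pairs: int = 53
    n_de_genes: int = 150
    de_logfc_mean: float = 2.5
    de_logfc_sd: float = 0.5
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_de_genes > self.n_genes:
            raise ValueError("n_de_genes cannot exceed n_genes")
        if self.de_logfc_sd <= 0 or self.noise_sd <= 0:
            raise ValueError("sd parameters must be positive")


@dataclass(frozen=True)
class SyntheticNetworkConfig:
    """Scale-free network generator settings (preferential attachment with
    ``attachment_parameter`` edges per new node, then hub planting)."""

    n_nodes: int = 2000
    attachment_parameter: int = 3
    n_planted_hubs: int = 5
    planted_neighborhood_disease_fraction: float = 0.8
    weight_distribution: tuple = ("uniform", 0.25, 1.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_planted_hubs < 0:
            raise ValueError("n_planted_hubs must be >= 0")
        if not 0 <= self.planted_neighborhood_disease_fraction <= 1:
            raise ValueError("disease fraction must lie in [0, 1]")


@dataclass
class PlantedTruth:
    """What the generators planted; the downstream recovery oracle."""

    de_gene_ids: set = field(default_factory=set)
    true_logfc: dict = field(default_factory=dict)
    key_driver_ids: set = field(default_factory=set)
    reversal_drug_ids: set = field(default_factory=set)

    def merged_with(self, other: "PlantedTruth") -> "PlantedTruth":
        return PlantedTruth(
            de_gene_ids=self.de_gene_ids | other.de_gene_ids,
            true_logfc={**self.true_logfc, **other.true_logfc},
            key_driver_ids=self.key_driver_ids | other.key_driver_ids,
            reversal_drug_ids=self.reversal_drug_ids | other.reversal_drug_ids,
        )


def gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def generate_paired_expression(config: SyntheticStudyConfig) -> tuple[PairedExpressionStudy, PlantedTruth]:
    """Paired log2 expression; tumour = normal + true_logfc + noise.

    Planted genes get |logFC| ~ Normal(de_logfc_mean, de_logfc_sd) (truncated
    at 0) with a random sign; all other genes have true_logfc = 0.
    """
    rng = np.random.default_rng(config.seed)
    genes = gene_ids(config.n_genes)
    baseline = rng.uniform(4.0, 12.0, size=config.n_genes)

    logfc = np.zeros(config.n_genes)
    de_idx = rng.choice(config.n_genes, size=config.n_de_genes, replace=False)
    magnitude = np.abs(rng.normal(config.de_logfc_mean, config.de_logfc_sd, size=config.n_de_genes))
    sign = rng.choice([-1.0, 1.0], size=config.n_de_genes)
    logfc[de_idx] = magnitude * sign

    normal = baseline[:, None] + rng.normal(0.0, config.noise_sd, size=(config.n_genes, config.n_pairs))
    tumour = normal + logfc[:, None] + rng.normal(0.0, config.noise_sd, size=(config.n_genes, config.n_pairs))

    columns, data, meta = [], [], []
    for p in range(config.n_pairs):
        for cond, mat in ((NORMAL, normal), (TUMOUR, tumour)):
            columns.append(f"P{p:02d}_{'N' if cond == NORMAL else 'T'}")
            data.append(mat[:, p])
            meta.append({"pair_id": f"P{p:02d}", "condition": cond})
    values = pd.DataFrame(np.column_stack(data), index=pd.Index(genes, name="gene"), columns=columns)
    samples = pd.DataFrame(meta, index=pd.Index(columns, name="sample"))
    study = PairedExpressionStudy(values=values, samples=samples)

    truth = PlantedTruth(
        de_gene_ids={genes[i] for i in de_idx},
        true_logfc={genes[i]: float(logfc[i]) for i in range(config.n_genes)},
    )
    return study, truth


def _draw_weights(rng, dist: tuple, size: int) -> np.ndarray:
    name, *params = dist
    if name == "uniform":
        return rng.uniform(params[0], params[1], size=size)
    if name == "lognormal":
        return rng.lognormal(params[0], params[1], size=size)
    raise ValueError(f"unknown weight distribution {name!r}")


def generate_network(
    config: SyntheticNetworkConfig, disease_genes: set, node_ids: list[str] | None = None
) -> tuple[nx.Graph, PlantedTruth]:
    """Preferential-attachment network with planted disease-enriched hubs.

    Planted hubs are drawn from the highest-degree non-disease nodes; each has
    its neighborhood rewired (degree-preserving where possible) until the
    configured fraction of its neighbors are disease genes. Edge weights are
    drawn from ``weight_distribution`` after rewiring.
    """
    node_ids = node_ids if node_ids is not None else gene_ids(config.n_nodes)
    if len(node_ids) != config.n_nodes:
        raise ValueError("node_ids length must equal n_nodes")
    disease = set(disease_genes)
    if not disease <= set(node_ids):
        raise ValueError("disease set must be a subset of the node set")
    rng = np.random.default_rng(config.seed)

    backbone = nx.barabasi_albert_graph(config.n_nodes, config.attachment_parameter, seed=int(rng.integers(2**31)))
    graph = nx.relabel_nodes(backbone, dict(enumerate(node_ids)))

    frac = config.planted_neighborhood_disease_fraction
    by_degree = sorted(graph.nodes(), key=lambda g: (-graph.degree(g), g))
    candidates = [g for g in by_degree if g not in disease]
    if config.n_planted_hubs > len(candidates):
        raise ValueError("not enough non-disease nodes for the requested hubs")
    pool = candidates[: max(4 * config.n_planted_hubs, config.n_planted_hubs)]
    hubs = [pool[i] for i in rng.choice(len(pool), size=config.n_planted_hubs, replace=False)]

    for hub in hubs:
        neighbors = set(graph.neighbors(hub))
        want = math.ceil(frac * len(neighbors))
        have = len(neighbors & disease)
        addable = sorted(disease - neighbors - {hub})
        removable = sorted(g for g in neighbors if g not in disease)
        rng.shuffle(addable)
        rng.shuffle(removable)
        for _ in range(want - have):
            if not addable:
                break
            new = addable.pop()
            graph.add_edge(hub, new)
            if removable:  # keep hub degree constant while pool lasts
                graph.remove_edge(hub, removable.pop())

    order = sorted(graph.edges())
    for (u, v), w in zip(order, _draw_weights(rng, config.weight_distribution, len(order))):
        graph.edges[u, v]["weight"] = float(w)

    return graph, PlantedTruth(key_driver_ids=set(hubs))


def _regulator_pool(network: nx.Graph, disease: set) -> tuple[list[str], np.ndarray]:
    """Non-disease neighbors of disease genes, weighted by the square of
    their disease connectivity so the module's hub regulators dominate."""
    conn: dict[str, float] = {}
    for d in disease:
        if d not in network:
            continue
        for nbr in network.neighbors(d):
            if nbr not in disease:
                conn[nbr] = conn.get(nbr, 0.0) + 1.0
    nodes = sorted(conn)
    w = np.array([conn[g] ** 2 for g in nodes])
    return nodes, w / w.sum()


def generate_drug_library(
    n_drugs: int = 100,
    signature_size_range: tuple[int, int] = (30, 80),
    reversal_drugs: int = 5,
    disease_genes: set = frozenset(),
    network: nx.Graph = None,
    seed: int = 0,
    reversal_fraction: float = 0.5,
    partial_drugs: int = 20,
    partial_fraction: float = 0.1,
) -> tuple[DrugLibrary, PlantedTruth]:
    """Drug-signature library with planted reversal drugs.

    Three tiers emulate a real signature library:

    * reversal drugs (the planted positives; always human, two study-tagged
      signatures each to exercise deduplication) draw ``reversal_fraction``
      of their genes from the disease module, split evenly between the
      disease genes themselves and the regulator pool — their non-disease
      network neighbors weighted by squared disease connectivity;
    * partial mimics touch the module's regulators (``partial_fraction`` of
      their genes from the regulator pool) without reversing it broadly, the
      way a targeted inhibitor hits one hub — they populate the moderate
      overlap range that real libraries always contain;
    * background drugs draw genes uniformly from the network's node set
      (about a fifth tagged as non-human to exercise the species filter, the
      first few duplicated across study tags).
    """
    if reversal_drugs > n_drugs:
        raise ValueError("reversal_drugs cannot exceed n_drugs")
    if reversal_drugs + partial_drugs > n_drugs:
        partial_drugs = n_drugs - reversal_drugs
    disease = set(disease_genes)
    if reversal_drugs > 0 and not disease:
        raise ValueError("reversal drugs require a non-empty disease set")
    rng = np.random.default_rng(seed)
    nodes = sorted(network.nodes())
    disease_list = sorted(disease & set(nodes))
    lo, hi = signature_size_range
    tissues = ["esophagus", "liver", "blood", "lung"]

    pool_nodes, pool_p = (
        _regulator_pool(network, disease) if (reversal_drugs or partial_drugs) else ([], None)
    )

    def fill_uniform(genes: set, size: int) -> frozenset:
        rest = [g for g in nodes if g not in genes]
        extra = rng.choice(len(rest), size=size - len(genes), replace=False)
        return frozenset(genes | {rest[i] for i in extra})

    def background_draw(size: int) -> frozenset:
        return frozenset(nodes[i] for i in rng.choice(len(nodes), size=size, replace=False))

    def reversal_draw(size: int) -> frozenset:
        # the module draw covers the disease genes first and spills into the
        # regulator pool, so a full-fraction draw of |disease| genes is the
        # disease set itself; below that it splits 60/40 disease/regulators
        n_rev = min(round(reversal_fraction * size), len(pool_nodes) + len(disease_list))
        if n_rev >= len(disease_list):
            n_dis = len(disease_list)
            n_reg = min(n_rev - n_dis, len(pool_nodes))
        else:
            n_reg = min(round(0.4 * n_rev), len(pool_nodes))
            n_dis = n_rev - n_reg
        genes = {disease_list[i] for i in rng.choice(len(disease_list), n_dis, replace=False)}
        if n_reg:
            genes |= {pool_nodes[i] for i in rng.choice(len(pool_nodes), n_reg, replace=False, p=pool_p)}
        return fill_uniform(genes, size)

    def partial_draw(size: int) -> frozenset:
        n_reg = min(round(partial_fraction * size), len(pool_nodes))
        genes = {pool_nodes[i] for i in rng.choice(len(pool_nodes), n_reg, replace=False, p=pool_p)}
        return fill_uniform(genes, size)

    signatures: list[DrugSignature] = []
    reversal_ids = set()
    for r in range(reversal_drugs):
        drug = f"reversadol-{r + 1:02d}"
        reversal_ids.add(drug)
        tissue = tissues[int(rng.integers(len(tissues)))]
        for study in ("in_vitro", "meta"):  # deliberate duplicate across studies
            size = int(rng.integers(lo, hi + 1))
            signatures.append(DrugSignature(drug, HUMAN, tissue, study, reversal_draw(size)))

    for m in range(partial_drugs):
        drug = f"mimicine-{m + 1:02d}"
        tissue = tissues[int(rng.integers(len(tissues)))]
        size = int(rng.integers(max(lo, (lo + hi) // 2), hi + 1))
        signatures.append(DrugSignature(drug, HUMAN, tissue, "in_vitro", partial_draw(size)))

    n_background = n_drugs - reversal_drugs - partial_drugs
    for b in range(n_background):
        drug = f"drug-{b + 1:03d}"
        species = HUMAN if rng.random() > 0.2 else "Mus musculus"
        tissue = tissues[int(rng.integers(len(tissues)))]
        size = int(rng.integers(lo, hi + 1))
        signatures.append(DrugSignature(drug, species, tissue, "in_vitro", background_draw(size)))
        if b < 10:  # duplicated study context for the dedup step
            size = int(rng.integers(lo, hi + 1))
            signatures.append(DrugSignature(drug, species, tissue, "meta", background_draw(size)))

    return DrugLibrary(signatures), PlantedTruth(reversal_drug_ids=reversal_ids)


@dataclass(frozen=True)
class SyntheticBundleConfig:
    """One knob set for a full, internally consistent input bundle."""

    study: SyntheticStudyConfig = SyntheticStudyConfig()
    network: SyntheticNetworkConfig = SyntheticNetworkConfig()
    n_drugs: int = 100
    reversal_drugs: int = 5
    partial_drugs: int = 20
    signature_size_range: tuple[int, int] = (30, 80)
    reversal_fraction: float = 0.5
    partial_fraction: float = 0.1
    seed: int = 0


def generate_bundle(config: SyntheticBundleConfig):
    """Expression, network, drug library and merged truth on one gene
    universe. The network's disease set is the planted DE gene set, so each
    stage's recovery target is consistent with the one before it."""
    rng = np.random.default_rng(config.seed)
    s1, s2, s3 = (int(x) for x in rng.integers(2**31, size=3))
    study, truth_e = generate_paired_expression(replace(config.study, seed=s1))
    net_cfg = replace(config.network, n_nodes=config.study.n_genes, seed=s2)
    network, truth_n = generate_network(net_cfg, truth_e.de_gene_ids, node_ids=list(study.gene_ids))
    library, truth_d = generate_drug_library(
        n_drugs=config.n_drugs,
        signature_size_range=config.signature_size_range,
        reversal_drugs=config.reversal_drugs,
        disease_genes=truth_e.de_gene_ids,
        network=network,
        seed=s3,
        reversal_fraction=config.reversal_fraction,
        partial_drugs=config.partial_drugs,
        partial_fraction=config.partial_fraction,
    )
    truth = truth_e.merged_with(truth_n).merged_with(truth_d)
    return study, network, library, truth
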