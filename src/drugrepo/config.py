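"""Pipeline configuration: thresholds, permutation counts, paths, seeding.

Defaults reproduce the published cut-offs (|logFC| > 1.5, DE adj p < 0.01,
key-driver FDR < 0.05, arm adj p < 0.05). One master seed deterministically
derives a per-stage seed by hashing the stage name, so any stage can be
re-run in isolation and reproduce its part of a full run.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # input paths (filled by the simulate stage or by the user)
    expression: str = "expression.tsv"
    samples: str = "samples.tsv"
    network: str = "network.tsv"
    drug_library: str = "drug_library.gmtx"
    gene_sets: str = "gene_sets.gmt"
    disease_genes: str = "degs.txt"

    # stage thresholds (published defaults)
    logfc_cut: float = 1.5
    de_adjp_cut: float = 0.01
    moderation: bool = True
    kd_fdr_cut: float = 0.05
    min_hub_overlap: float = 0.33
    edge_factor: float = 0.0
    depth: int = 1
    arm_adjp_cut: float = 0.05
    enrich_adjp_cut: float = 0.05

    # permutation counts
    wkda_n_perm: int = 1000
    netdr_n_null: int = 1000
    gsea_n_perm: int = 200

    # synthetic-bundle sizes (simulate stage)
    n_genes: int = 2000
    n_pairs: int = 53
    n_de_genes: int = 150
    de_logfc_mean: float = 2.5
    de_logfc_sd: float = 0.5
    noise_sd: float = 0.5
    n_drugs: int = 100
    reversal_drugs: int = 5
    partial_drugs: int = 20

    seed: int = 0
    extras: dict = field(default_factory=dict)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed (< 2**31) from the master seed."""
        return (zlib.crc32(stage.encode()) ^ (self.seed * 2654435761)) % (2**31)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)
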