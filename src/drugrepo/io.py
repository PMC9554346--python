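"""Readers and writers for the plain-text formats the pipeline uses.

Formats: expression TSV (genes x samples) with a sample-metadata sidecar,
edge-list TSV for gene networks, GMT and GMT-extended gene-set files, results
TSV with a ``#``-prefixed metadata header, and JSON for planted truth /
manifests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import networkx as nx
import pandas as pd

from .diffexpr import PairedExpressionStudy


# ---------------------------------------------------------------- expression

def write_expression(study: PairedExpressionStudy, values_path, samples_path) -> None:
    study.values.to_csv(values_path, sep="\t", index_label="gene")
    study.samples.to_csv(samples_path, sep="\t", index_label="sample")


def read_expression(values_path, samples_path) -> PairedExpressionStudy:
    values = pd.read_csv(values_path, sep="\t", index_col="gene")
    samples = pd.read_csv(samples_path, sep="\t", index_col="sample")
    return PairedExpressionStudy(values=values, samples=samples)


# ------------------------------------------------------------------- network

def write_network(graph: nx.Graph, path) -> None:
    rows = [(u, v, graph.edges[u, v].get("weight", 1.0)) for u, v in sorted(graph.edges())]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"]).to_csv(path, sep="\t", index=False)


def read_network(path) -> nx.Graph:
    df = pd.read_csv(path, sep="\t")
    if "weight" not in df.columns:
        df["weight"] = 1.0
    df["weight"] = df["weight"].fillna(1.0)
    if (df["weight"] < 0).any():
        raise ValueError("edge weights must be non-negative")
    graph = nx.Graph()
    for a, b, w in df[["gene_a", "gene_b", "weight"]].itertuples(index=False):
        if a == b:
            continue  # undirected, no self-loops
        graph.add_edge(str(a), str(b), weight=float(w))
    return graph


# ------------------------------------------------------------ gene sets (GMT)

def write_gmt(sets: dict[str, set[str]], path, descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name in sets:
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{descriptions.get(name, name)}\t{members}\n")


def read_gmt(path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(parts[2:])
    return sets


# ------------------------------------------------------------- drug library

@dataclass(frozen=True)
class DrugSignature:
    """A drug's perturbed gene set in one species/tissue/study context."""

    drug_id: str
    species: str
    tissue: str
    study: str
    genes: frozenset = field(repr=False)

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"empty signature for {self.drug_id}")

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.drug_id, self.species, self.tissue, self.study)


@dataclass
class DrugLibrary:
    signatures: list[DrugSignature]

    def __post_init__(self):
        keys = [s.key for s in self.signatures]
        if len(keys) != len(set(keys)):
            raise ValueError("(drug, species, tissue, study) tuples must be unique")

    def __len__(self) -> int:
        return len(self.signatures)

    def __iter__(self):
        return iter(self.signatures)


def write_drug_library(library: DrugLibrary, path) -> None:
    """GMT-extended: drug_id <tab> species|tissue|study <tab> gene1 ..."""
    with open(path, "w") as fh:
        for sig in library.signatures:
            meta = f"{sig.species}|{sig.tissue}|{sig.study}"
            fh.write("\t".join([sig.drug_id, meta, *sorted(sig.genes)]) + "\n")


def read_drug_library(path) -> DrugLibrary:
    sigs = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            species, tissue, study = parts[1].split("|")
            sigs.append(
                DrugSignature(parts[0], species, tissue, study, frozenset(parts[2:]))
            )
    return DrugLibrary(sigs)


# ------------------------------------------------------------------- results

def write_results(df: pd.DataFrame, path, metadata: dict | None = None, index: bool = False) -> None:
    """Results TSV with a '#'-prefixed key=value metadata block."""
    with open(path, "w") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_results(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def _jsonify(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if hasattr(obj, "item"):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


# ---------------------------------------------------------------- reference

def load_escc_reference_table() -> pd.DataFrame:
    """The published 25-row ESCC repositioned-drug table shipped with the
    package (drug, study, z_score, jaccard, odds_ratio, adj_p,
    within_species_rank)."""
    with resources.files("drugrepo.data").joinpath("escc_repositioned_drugs.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
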