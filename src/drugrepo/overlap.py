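"""Overlap arm of drug repositioning.

Each drug signature is scored against the key-driver gene set by direct gene
overlap: Jaccard similarity, fold enrichment as the Fisher odds ratio of the
2x2 overlap table, and the one-sided (enrichment) exact test p-value, with BH
adjustment across all signatures and a within-species percentile rank of the
Jaccard score.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import adjust_bh
from .io import DrugLibrary


def jaccard(a: set, b: set) -> float:
    a, b = set(a), set(b)
    if not a and not b:
        raise ValueError("Jaccard undefined for two empty sets")
    return len(a & b) / len(a | b)


def overlap_fisher(query: set, signature: set, universe: set) -> tuple[float, float]:
    """Odds ratio and one-sided enrichment p for the 2x2 overlap table.

    Cells: a = |query & signature|, b = query only, c = signature only,
    d = neither. The odds ratio is (a*d)/(b*c), with a 0.5 Haldane correction
    applied only when some cell is zero; p is the hypergeometric upper tail
    (identical to Fisher's one-sided 'greater' exact test).
    """
    query, signature, universe = set(query), set(signature), set(universe)
    if not (query <= universe and signature <= universe):
        raise ValueError("query and signature must be subsets of the universe")
    a = len(query & signature)
    b = len(query - signature)
    c = len(signature - query)
    d = len(universe) - a - b - c
    if b == 0 and c == 0 and d == 0:
        warnings.warn("degenerate 2x2 table: query = signature = universe", stacklevel=2)
    p = float(stats.hypergeom.sf(a - 1, len(universe), len(signature), len(query)))
    # Haldane 0.5 only where the plain ratio is undefined; a zero numerator
    # stays an odds ratio of 0
    if b == 0 or c == 0:
        odds = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    else:
        odds = a * d / (b * c)
    return float(odds), p


def within_species_rank(jaccards: np.ndarray) -> np.ndarray:
    """Percentile rank in (0, 1], 1 = best Jaccard, average-rank ties:
    1 - (rank_desc - 1)/N."""
    ranks = stats.rankdata(-np.asarray(jaccards, dtype=float), method="average")
    return 1.0 - (ranks - 1.0) / len(ranks)


def run_overlap_dr(kdgs: set, library: DrugLibrary, universe: set) -> pd.DataFrame:
    """Score every signature in the library against the key-driver set.

    Returns one row per signature with jaccard, overlap count, odds_ratio,
    fisher_p, BH adj_p across all signatures, and within_species_rank computed
    among signatures of the same species.
    """
    kdgs = set(kdgs) & set(universe)
    if not kdgs:
        raise ValueError("key-driver set is empty (after universe restriction)")
    if len(library) == 0:
        raise ValueError("drug library is empty")
    rows = []
    for sig in library:
        genes = set(sig.genes) & set(universe)
        odds, p = overlap_fisher(kdgs, genes, universe)
        rows.append(
            {
                "drug": sig.drug_id,
                "species": sig.species,
                "tissue": sig.tissue,
                "study": sig.study,
                "signature_size": len(genes),
                "overlap": len(kdgs & genes),
                "jaccard": jaccard(kdgs, genes) if (kdgs or genes) else 0.0,
                "odds_ratio": odds,
                "fisher_p": p,
            }
        )
    out = pd.DataFrame(rows)
    out["adj_p"] = adjust_bh(out["fisher_p"].to_numpy())
    out["within_species_rank"] = np.nan
    for _, idx in out.groupby("species").groups.items():
        out.loc[idx, "within_species_rank"] = within_species_rank(out.loc[idx, "jaccard"].to_numpy())
    return out.sort_values(["fisher_p", "drug"], kind="stable", ignore_index=True)
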