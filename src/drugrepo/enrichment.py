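"""Over-representation and preranked gene-set enrichment.

Collections are plain named gene sets over a stated universe (GO/KEGG-style
GMT files supply them in practice). ORA uses the hypergeometric upper tail;
preranked GSEA uses the weighted Kolmogorov-Smirnov running sum with a
gene-label permutation null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import adjust_bh


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to a stated universe."""

    sets: dict[str, set[str]]
    universe: set[str]
    category: str = "custom"

    def __post_init__(self):
        self.sets = {name: set(members) & self.universe for name, members in self.sets.items()}

    def __len__(self) -> int:
        return len(self.sets)


def ora_test(query: set[str], collection: GeneSetCollection, universe: set[str] | None = None) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each set.

    p = P(overlap >= observed) drawing |query| genes from the universe;
    BH-adjusted across sets; ``significant`` at adj_p < 0.05.
    """
    universe = set(universe) if universe is not None else collection.universe
    if not universe:
        raise ValueError("empty universe")
    query = set(query) & universe
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    M, N = len(universe), len(query)
    rows = []
    for name, members in collection.sets.items():
        members = members & universe
        n = len(members)
        k = len(query & members)
        degenerate = n == M and N == M
        p = 1.0 if degenerate else float(stats.hypergeom.sf(k - 1, M, n, N))
        rows.append(
            {
                "set": name,
                "size": n,
                "overlap": k,
                "expected": N * n / M,
                "p": p,
                "degenerate": degenerate,
            }
        )
    out = pd.DataFrame(rows)
    out["adj_p"] = adjust_bh(out["p"].to_numpy()) if len(out) else []
    out["significant"] = out["adj_p"] < 0.05
    return out.sort_values("p", kind="stable", ignore_index=True)


def enrichment_score(ranked_genes: list[str], scores: np.ndarray, members: set[str], weight_exponent: float = 1.0) -> float:
    """Weighted KS running-sum enrichment score for one set.

    Hit steps are proportional to |score|^weight_exponent, miss steps uniform;
    the ES is the running sum's maximum deviation from zero (signed).
    """
    hit = np.fromiter((g in members for g in ranked_genes), dtype=bool, count=len(ranked_genes))
    n_hit = int(hit.sum())
    if n_hit == 0 or n_hit == len(ranked_genes):
        return 0.0
    w = np.abs(scores) ** weight_exponent
    hit_w = np.where(hit, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:  # all-zero scores inside the set: fall back to unweighted
        hit_w = hit.astype(float)
        denom = hit_w.sum()
    steps = hit_w / denom - (~hit) / (len(ranked_genes) - n_hit)
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


def gsea_preranked(
    ranked: pd.Series,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    weight_exponent: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Preranked GSEA against every set in the collection.

    ``ranked`` maps gene -> signed score (e.g. a DE t-statistic); genes are
    ordered by decreasing score. The null shuffles gene labels (equivalently,
    draws random same-size sets); p is one-sided in the sign of the observed
    ES and NES divides by the mean |null ES| of that sign.
    """
    if ranked.index.has_duplicates:
        raise ValueError("ranked list must have unique genes")
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    ranked = ranked.sort_values(ascending=False)
    genes = list(ranked.index)
    scores = ranked.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)

    rows = []
    for name, members in collection.sets.items():
        in_list = members & set(genes)
        if len(in_list) < 2:
            warnings.warn(f"set {name!r} has <2 genes in the ranked list; skipped", stacklevel=2)
            continue
        es = enrichment_score(genes, scores, in_list, weight_exponent)
        null = np.empty(n_perm)
        size = len(in_list)
        for b in range(n_perm):
            perm = set(rng.choice(len(genes), size=size, replace=False))
            null[b] = enrichment_score(genes, scores, {genes[i] for i in perm}, weight_exponent)
        if es >= 0:
            p = (1 + np.sum(null >= es)) / (n_perm + 1)
            side = null[null > 0]
        else:
            p = (1 + np.sum(null <= es)) / (n_perm + 1)
            side = null[null < 0]
        nes = es / np.mean(np.abs(side)) if side.size else 0.0
        rows.append({"set": name, "size": size, "es": es, "nes": nes, "p": float(p)})
    out = pd.DataFrame(rows)
    if len(out):
        out["adj_p"] = adjust_bh(out["p"].to_numpy())
        out = out.sort_values("p", kind="stable", ignore_index=True)
    return out
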