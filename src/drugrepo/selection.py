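"""Candidate selection: arm filtering, deduplication, intersection, ranking.

The overlap arm keeps human signatures with adj_p < 0.05 and a positive
within-species rank, removes signatures whose Jaccard falls below the mean of
those survivors, and collapses each drug to its highest-ranking signature.
The network arm keeps signatures with adj_p < 0.05 and collapses each drug to
its best (lowest) proximity rank. Drugs surviving both arms form the final
table, sorted by ascending proximity z-score (most strongly reversing first).
"""

from __future__ import annotations

import warnings

import pandas as pd

HUMAN = "Homo sapiens"

FINAL_COLUMNS = ["drug", "study", "z_score", "jaccard", "odds_ratio", "adj_p", "within_species_rank"]


def normalize_drug_name(name: str, synonyms: dict[str, str] | None = None) -> str:
    """Join key: lowercase, trimmed; optional synonym map applied after."""
    key = str(name).strip().lower()
    return (synonyms or {}).get(key, key)


def split_arm_projections(final_table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a final candidate table back into its two arm projections.

    The overlap projection carries the overlap-arm fields (study, Jaccard,
    odds ratio, adjusted p, within-species rank; species is human by
    construction of the overlap filter); the network projection carries the
    z-score with ranks re-derived by ascending z. Both are already filtered
    and deduplicated, so they recombine through :func:`intersect_and_rank`.
    """
    ov = final_table[["drug", "study", "jaccard", "odds_ratio", "adj_p", "within_species_rank"]].copy()
    ov["species"] = HUMAN
    nd = final_table[["drug", "z_score"]].copy()
    nd["adj_p"] = 0.0
    nd = nd.sort_values("z_score", kind="stable", ignore_index=True)
    nd["rank"] = range(1, len(nd) + 1)
    return ov, nd


def filter_overlap_arm(results: pd.DataFrame) -> pd.DataFrame:
    """Keep-filters, mean-Jaccard cut, then per-drug dedup (best rank kept).

    The mean Jaccard is computed over the keep-filter survivors, before
    deduplication; signatures strictly below it are dropped.
    """
    if results.empty:
        warnings.warn("overlap arm: empty input", stacklevel=2)
        return results.copy()
    kept = results[
        (results["adj_p"] < 0.05)
        & (results["species"] == HUMAN)
        & (results["within_species_rank"] > 0)
    ].copy()
    if kept.empty:
        warnings.warn("overlap arm: nothing survives the keep-filters", stacklevel=2)
        return kept
    mean_jaccard = kept["jaccard"].mean()
    kept = kept[kept["jaccard"] >= mean_jaccard - 1e-12]  # strict removal below the mean
    p_col = "fisher_p" if "fisher_p" in kept.columns else "adj_p"
    kept = kept.sort_values(
        ["drug", "within_species_rank", "jaccard", p_col],
        ascending=[True, False, False, True],
        kind="stable",
    )
    kept["_key"] = kept["drug"].map(normalize_drug_name)
    kept = kept.drop_duplicates("_key", keep="first").drop(columns="_key")
    return kept.reset_index(drop=True)


def filter_network_arm(results: pd.DataFrame) -> pd.DataFrame:
    """adj_p < 0.05 filter, then per-drug dedup keeping the best (lowest)
    proximity rank."""
    if results.empty:
        warnings.warn("network arm: empty input", stacklevel=2)
        return results.copy()
    kept = results[results["adj_p"] < 0.05].copy()
    if kept.empty:
        warnings.warn("network arm: nothing passes adj_p < 0.05", stacklevel=2)
        return kept
    kept = kept.sort_values(["drug", "rank"], ascending=[True, True], kind="stable")
    kept["_key"] = kept["drug"].map(normalize_drug_name)
    kept = kept.drop_duplicates("_key", keep="first").drop(columns="_key")
    return kept.reset_index(drop=True)


def intersect_and_rank(overlap_kept: pd.DataFrame, network_kept: pd.DataFrame) -> pd.DataFrame:
    """Inner-join the deduplicated arms on the normalized drug name and sort
    by ascending z-score. Overlap-arm fields (study, jaccard, odds ratio,
    adj_p, within-species rank) and the network-arm z populate each record."""
    if overlap_kept.empty or network_kept.empty:
        warnings.warn("empty arm input: final table is empty", stacklevel=2)
        return pd.DataFrame(columns=FINAL_COLUMNS)
    left = overlap_kept.copy()
    right = network_kept.copy()
    left["_key"] = left["drug"].map(normalize_drug_name)
    right["_key"] = right["drug"].map(normalize_drug_name)
    merged = left.merge(
        right[["_key", "z_score"]], on="_key", how="inner", validate="one_to_one"
    )
    if merged.empty:
        warnings.warn("no drug common to both arms", stacklevel=2)
        return pd.DataFrame(columns=FINAL_COLUMNS)
    final = merged[FINAL_COLUMNS].sort_values(
        ["z_score", "drug"], kind="stable", ignore_index=True
    )
    assert final["drug"].map(normalize_drug_name).is_unique
    return final
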