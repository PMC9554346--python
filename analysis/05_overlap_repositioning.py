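"""Overlap arm: direct gene overlap between drug signatures and key drivers.

Jaccard score, Fisher odds ratio and one-sided exact p per signature, BH
across the library, within-species percentile ranks. The planted reversal
drugs should dominate the significant end.
"""

from _util import shared

from drugrepo.io import read_json
from drugrepo.pipeline import stage_overlap


def main() -> None:
    cfg_mod = shared()
    run_dir = cfg_mod.setup()
    res = stage_overlap(cfg_mod.CONFIG, run_dir)
    rev = set(read_json(run_dir / "truth.json")["reversal_drug_ids"])
    sig = res[res["adj_p"] < 0.05]
    print(f"{len(sig)} of {len(res)} signatures significant at adj_p < 0.05")
    print(f"reversal signatures among them: {sig['drug'].isin(rev).sum()}")
    print(sig.head(10)[["drug", "study", "overlap", "jaccard", "odds_ratio", "adj_p", "within_species_rank"]].to_string(index=False))


if __name__ == "__main__":
    main()
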