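"""Candidate selection: arm filters, intersection, final ranking.

Overlap arm: adj_p < 0.05, human, positive within-species rank, mean-Jaccard
cut, per-drug dedup. Network arm: adj_p < 0.05, per-drug best rank. Drugs in
both arms form the final table sorted by ascending z. With planted truth the
table should be exactly the reversal drugs, strongest reverser first.
"""

from _util import shared

from drugrepo.io import read_json
from drugrepo.pipeline import stage_select


def main() -> None:
    cfg_mod = shared()
    run_dir = cfg_mod.setup()
    final = stage_select(cfg_mod.CONFIG, run_dir)
    rev = set(read_json(run_dir / "truth.json")["reversal_drug_ids"])
    print(f"{len(final)} repositioned drug(s); planted reversal drugs recovered: "
          f"{final['drug'].isin(rev).sum()}/{len(rev)}")
    print(final.to_string(index=False))


if __name__ == "__main__":
    main()
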