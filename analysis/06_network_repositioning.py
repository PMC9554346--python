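"""Network arm: degree-aware proximity between drug signatures and key
drivers.

Closest distance on the network, 1000 degree-preserving null samples per
signature, z-score and lower-tail empirical p. Reversal drugs should sit at
strongly negative z.
"""

from _util import shared

from drugrepo.io import read_json
from drugrepo.pipeline import stage_netdr


def main() -> None:
    cfg_mod = shared()
    run_dir = cfg_mod.setup()
    res = stage_netdr(cfg_mod.CONFIG, run_dir)
    rev = set(read_json(run_dir / "truth.json")["reversal_drug_ids"])
    print(f"{len(res)} signatures scored; z range [{res['z_score'].min():.2f}, {res['z_score'].max():.2f}]")
    top = res.head(10)
    print(f"reversal signatures in the top 10 by z: {top['drug'].isin(rev).sum()}")
    print(top[["drug", "study", "observed_distance", "null_mean", "null_sd", "z_score", "adj_p", "rank"]].to_string(index=False))


if __name__ == "__main__":
    main()
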