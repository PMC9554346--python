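"""Paired differential expression with the published thresholds.

Moderated paired t on tumour-minus-normal log2 differences, BH adjustment,
selection at |logFC| > 1.5 and adjusted p < 0.01. Reports recovery of the
planted differential genes and the top hits by fold change.
"""

from _util import shared

from drugrepo.io import read_json
from drugrepo.pipeline import stage_de


def main() -> None:
    cfg_mod = shared()
    run_dir = cfg_mod.setup()
    degs = stage_de(cfg_mod.CONFIG, run_dir)
    planted = set(read_json(run_dir / "truth.json")["de_gene_ids"])
    recovered = set(degs.index)
    up = (degs["direction"] == "up").sum()
    print(f"{len(degs)} DEGs selected ({up} up / {len(degs) - up} down)")
    print(f"precision {len(recovered & planted) / len(recovered):.3f}, "
          f"recall {len(recovered & planted) / len(planted):.3f} against planted truth")
    print("top 5 by |logFC|:")
    print(degs.reindex(degs["logFC"].abs().sort_values(ascending=False).index).head(5)[["logFC", "adj_p", "direction"]])


if __name__ == "__main__":
    main()
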