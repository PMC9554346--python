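"""Functional enrichment of the differential genes.

Over-representation (hypergeometric) of the selected DEGs and preranked GSEA
on the moderated-t ranking, both against the generated GO/KEGG stand-in
collection; the two planted disease-module sets should surface.
"""

from _util import shared

from drugrepo.pipeline import stage_enrich


def main() -> None:
    cfg_mod = shared()
    run_dir = cfg_mod.setup()
    ora = stage_enrich(cfg_mod.CONFIG, run_dir)
    hits = ora[ora["significant"]]
    print(f"{len(hits)} of {len(ora)} gene sets enriched at adj_p < 0.05:")
    print(hits[["set", "size", "overlap", "expected", "adj_p"]].to_string(index=False))


if __name__ == "__main__":
    main()
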