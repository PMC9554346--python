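"""Generate the synthetic study inputs with planted truth.

Emulates the real analysis' four inputs on a 2000-gene universe: a 53-pair
tumour/normal log2 expression matrix with 150 planted differential genes, a
scale-free weighted gene network with 5 disease-enriched hubs, a 100-drug
signature library with 5 planted reversal drugs, and a GO/KEGG stand-in
gene-set collection. Writes everything plus truth.json into results/seed7.
"""

from _util import shared

from drugrepo.io import read_json
from drugrepo.pipeline import stage_simulate


def main() -> None:
    cfg_mod = shared()
    run_dir = cfg_mod.setup()
    stage_simulate(cfg_mod.CONFIG, run_dir)
    truth = read_json(run_dir / "truth.json")
    print(f"wrote inputs to {run_dir}")
    print(f"planted: {len(truth['de_gene_ids'])} DE genes, "
          f"{len(truth['key_driver_ids'])} key-driver hubs, "
          f"{len(truth['reversal_drug_ids'])} reversal drugs")


if __name__ == "__main__":
    main()
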