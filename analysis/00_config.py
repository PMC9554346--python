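"""Shared settings for the numbered analysis drivers.

Every driver operates on the same run directory (results/seed7) with the
study-condition defaults and master seed 7; run them in order, or run
``drugrepo run-all --run-dir results/seed7 --seed 7`` to do it in one go.
"""

from pathlib import Path

from drugrepo import PipelineConfig

RUN_DIR = Path(__file__).resolve().parent.parent / "results" / "seed7"
CONFIG = PipelineConfig(seed=7)


def setup() -> Path:
    RUN_DIR.mkdir(parents=True, exist_ok=True)
    CONFIG.to_yaml(RUN_DIR / "config.yaml")
    return RUN_DIR
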