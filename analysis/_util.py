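"""Loader for the numbered-driver shared config (module names start with digits)."""

import importlib.util
from pathlib import Path


def shared():
    spec = importlib.util.spec_from_file_location(
        "analysis_config", Path(__file__).resolve().parent / "00_config.py"
    )
    mod = importlib.util.module_from_spec(spec)
    spec.loader.exec_module(mod)
    return mod
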