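"""Shared paths and the study seed for the numbered analysis drivers."""

from pathlib import Path

SEED = 20260923
RESULTS = Path(__file__).resolve().parent.parent / "results"
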