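"""Shared locations for the analysis scripts (importable as a module)."""

from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results" / "cohort"
RAW = RESULTS / "raw"
PHENOTYPED = RESULTS / "phenotyped"
REGIONS = RESULTS / "regions"
TABLES = RESULTS / "tables"

SEED = 1
N_SAMPLES = 20
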