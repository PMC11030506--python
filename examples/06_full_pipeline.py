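"""Run the whole pipeline (simulate -> differential accessibility -> CRD ->
TRD -> ABC -> enrichment -> report) and print the report.

Equivalent shell command:  sexregulome run --seed 1 --out run_out
"""

import tempfile
from pathlib import Path

from sexregulome.pipeline import run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    out = Path(tmp) / "demo_run"
    manifest = run_pipeline({"outdir": str(out), "seed": 1})
    print((out / "report.md").read_text())
    print(f"{len(manifest.files)} output files, config hash {manifest.config_hash[:12]}")
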