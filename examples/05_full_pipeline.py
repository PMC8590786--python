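"""Run every stage end to end with one config and inspect the manifest.

Equivalent shell command:  coexqtl all --outdir run --seed 1
"""

import json
import logging
from pathlib import Path

from coexqtl.config import RunConfig
from coexqtl.pipeline import run_pipeline

logging.basicConfig(level=logging.INFO, format="%(levelname)s %(message)s")

config = RunConfig(outdir="run_example", seed=1)
art = run_pipeline(config)

manifest = json.loads((Path(config.outdir) / "manifest.json").read_text())
print("\nstage outputs and row counts:")
for stage, entry in manifest["stages"].items():
    print(f"  {stage}: {entry['counts']}")
print("\nRe-running with the same config and seed reproduces every output "
      "byte-identically (checksums are recorded in the manifest).")
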