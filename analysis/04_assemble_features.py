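"""Assemble and scale the model matrix from the five source tables."""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _config import RUN_DIR, config

from geopharm.pipeline import run_stage

run_stage("features", config())
man = json.loads((RUN_DIR / "matrix_manifest.json").read_text())
print(f"matrix: {man['n_rows']} rows x {man['n_features']} features")
print(f"block widths: {man['block_widths']}")
print(f"imputation: {man['impute']}; dropped rows (no chemistry): "
      f"{man['n_dropped_rows']}")
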