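"""Tree-SHAP attributions: global ranking, stability, dependence exports."""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _config import RUN_DIR, config

from geopharm.pipeline import run_stage

run_stage("explain", config())
ranking = pd.read_csv(RUN_DIR / "shap_ranking.csv")
print("top 12 features by mean |SHAP|:")
print(ranking.head(12).to_string(index=False))
stab = pd.read_csv(RUN_DIR / "shap_stability.csv")
print(f"\nbootstrap stability: median Spearman rho = "
      f"{stab.spearman_rho.median():.3f} over {len(stab)} resamples")
manifest = json.loads((RUN_DIR / "manifest.json").read_text())
explain = next(e for e in manifest if e["stage"] == "explain")
print(f"top-10 order-consistent resamples: "
      f"{explain['counts']['top10_order_consistent']}/100; "
      f"set-consistent: {explain['counts']['top10_set_consistent']}/100")
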