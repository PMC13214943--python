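"""Mass univariate signature x drug screen with p < 0.01 atlas filter."""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _config import RUN_DIR, config

from geopharm.pipeline import run_stage

run_stage("screen", config())
atlas = pd.read_csv(RUN_DIR / "interaction_atlas.csv")
sig = atlas[atlas.significant]
print(f"tested {len(atlas)} (signature, drug) pairs; "
      f"{len(sig)} significant at p < 0.01")
print("\nstrongest associations:")
print(atlas.head(8).to_string(index=False))
planted = sig[sig.signature.isin(['SBS4', 'SBS18', 'SBS7a'])]
print(f"\nplanted aetiology signatures among hits: "
      f"{sorted(planted.signature.unique())} "
      f"({len(planted)} pairs; SBS4 slopes should be positive, SBS18 negative)")
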