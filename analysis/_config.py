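"""Shared run configuration for the numbered analysis drivers.

Every driver operates on the same run directory (results/run) with the
desk-scale profile, so the sequence 01..07 reproduces the full pipeline:
simulated inputs -> raster -> zones -> features -> model -> attributions
-> interaction screen.
"""

from pathlib import Path

from geopharm.model import BoosterConfig
from geopharm.pipeline import PipelineConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"
RUN_DIR = RESULTS / "run"


def config(seed: int = 1) -> PipelineConfig:
    return PipelineConfig(outdir=RUN_DIR, seed=seed, profile="fast",
                          booster=BoosterConfig.fast(), cv_k=5,
                          attribution_rows=1000)
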