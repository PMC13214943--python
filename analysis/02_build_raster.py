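"""Interpolate the scattered UV / PM2.5 points onto the 1-degree raster.

Linear (Delaunay barycentric) interpolation inside each network's convex
hull, nearest-neighbour fill outside it; writes results/run/raster.csv.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _config import RUN_DIR, config

from geopharm.pipeline import run_stage

run_stage("raster", config())
raster = pd.read_csv(RUN_DIR / "raster.csv")
print(f"raster: {len(raster)} cells")
print(f"UV_Annual range [{raster.UV_Annual.min():.2f}, {raster.UV_Annual.max():.2f}] UVI; "
      f"PM25 range [{raster.PM25_ug_m3.min():.2f}, {raster.PM25_ug_m3.max():.2f}] ug/m3")
eq = raster[raster.lat.abs() < 5].UV_Annual.mean()
hi = raster[raster.lat.abs() > 65].UV_Annual.mean()
print(f"mean UV near equator {eq:.2f} vs high latitude {hi:.2f} "
      "(expected: strong equatorial peak)")
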