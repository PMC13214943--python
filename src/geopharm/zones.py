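"""Cancer-type aetiology zones and ecological exposure assignment.

Each TCGA cancer code is mapped to a geographic bounding box representing
its dominant environmental exposure region (e.g. cutaneous melanoma -> the
tropical UV belt, lung adenocarcinoma -> the East Asian industrial belt).
Zone_UV and Zone_PM25 for a code are the arithmetic means of the raster
cells whose centers fall inside the box; every cell line of that code
inherits the same pair of values (ecological assignment).  Codes without a
box fall back to the global median over all raster cells.

"N"/"E" box suffixes from the published table are normalised to signed
degrees.  No land mask is applied: all cells inside a box, ocean included,
enter the mean.  Boxes may not cross the antimeridian.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .env_raster import EnvironmentalRaster
from .errors import EmptyZoneError, InvalidConfigError, InvalidInputError

__all__ = ["AetiologyZone", "ZoneExposure", "load_zone_table", "zone_means",
           "assign_zones", "DEFAULT_ZONE_ROWS"]


@dataclass(frozen=True)
class AetiologyZone:
    """A TCGA code's exposure bounding box; ``lon_min``/``lon_max`` of None
    means the box spans all longitudes."""

    tcga_code: str
    lat_min: float
    lat_max: float
    lon_min: float | None = None
    lon_max: float | None = None
    rationale: str = ""

    def __post_init__(self):
        if not self.lat_min < self.lat_max:
            raise InvalidConfigError(
                f"{self.tcga_code}: lat_min must be < lat_max")
        if (self.lon_min is None) != (self.lon_max is None):
            raise InvalidConfigError(
                f"{self.tcga_code}: lon bounds must both be set or both None")
        if self.lon_min is not None and self.lon_min > self.lon_max:
            raise InvalidConfigError(
                f"{self.tcga_code}: antimeridian-crossing boxes are not supported")

    @property
    def all_longitudes(self) -> bool:
        return self.lon_min is None


@dataclass(frozen=True)
class ZoneExposure:
    tcga_code: str
    zone_uv: float
    zone_pm25: float
    n_cells: int


# The published aetiology table, in signed degrees.
DEFAULT_ZONE_ROWS: tuple[tuple, ...] = (
    ("SKCM",   -35.0, 35.0, None, None,    "Tropical UV belt"),
    ("LUAD",    20.0, 55.0, 70.0, 130.0,   "E. Asian industrial"),
    ("LUSC",    20.0, 55.0, 70.0, 130.0,   "E. Asian industrial"),
    ("ESCA",     5.0, 40.0, 25.0, 80.0,    "E. Africa/C. Asia"),
    ("HNSC",   -25.0, 30.0, None, None,    "Tropical UV/tobacco"),
    ("STAD",    20.0, 50.0, 90.0, 140.0,   "E. Asian industrial"),
    ("LIHC",   -20.0, 30.0, 0.0, 120.0,    "Tropical industrial"),
    ("BRCA",    30.0, 60.0, None, None,    "Mid-Lat N. Hemisphere"),
    ("COREAD",  30.0, 55.0, None, None,    "Mid-Lat N. Hemisphere"),
    ("BLCA",    30.0, 55.0, None, None,    "Mid-Lat N. Hemisphere"),
    ("UCEC",    30.0, 60.0, -100.0, 50.0,  "N. Hemisphere mixed"),
)


def _zone_from_mapping(row: Mapping) -> AetiologyZone:
    lon_min, lon_max = row.get("lon_min"), row.get("lon_max")
    if str(row.get("lon", "")).lower() == "all":
        lon_min = lon_max = None
    return AetiologyZone(
        tcga_code=row["tcga_code"],
        lat_min=float(row["lat_min"]), lat_max=float(row["lat_max"]),
        lon_min=None if lon_min is None else float(lon_min),
        lon_max=None if lon_max is None else float(lon_max),
        rationale=row.get("rationale", ""),
    )


def load_zone_table(config: str | Path | Sequence[Mapping] | None = None,
                    ) -> list[AetiologyZone]:
    """The default 11-row aetiology table, optionally extended/overridden.

    ``config`` may be a YAML path or a sequence of mappings with keys
    tcga_code, lat_min, lat_max and either lon_min/lon_max or ``lon: all``.
    A config row whose code matches a default replaces it; new codes are
    appended.  Duplicate codes within the config itself are rejected.
    """
    zones = {r[0]: AetiologyZone(*r) for r in DEFAULT_ZONE_ROWS}
    if config is None:
        return list(zones.values())
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            rows = yaml.safe_load(fh)
        if isinstance(rows, Mapping):
            rows = rows.get("zones", [])
    else:
        rows = list(config)
    seen: set[str] = set()
    for row in rows:
        z = _zone_from_mapping(row)
        if z.tcga_code in seen:
            raise InvalidConfigError(f"duplicate tcga_code {z.tcga_code!r} in config")
        seen.add(z.tcga_code)
        zones[z.tcga_code] = z
    return list(zones.values())


def _box_mask(raster: EnvironmentalRaster, zone: AetiologyZone) -> np.ndarray:
    lat = raster.grid.lat_centers
    lon = raster.grid.lon_centers
    m_lat = (lat >= zone.lat_min) & (lat <= zone.lat_max)
    if zone.all_longitudes:
        m_lon = np.ones(len(lon), dtype=bool)
    else:
        m_lon = (lon >= zone.lon_min) & (lon <= zone.lon_max)
    return np.outer(m_lat, m_lon)


def zone_means(raster: EnvironmentalRaster, zone: AetiologyZone) -> ZoneExposure:
    """Mean UV and PM2.5 over the raster cells whose centers fall inside the
    zone's bounding box (bounds inclusive)."""
    mask = _box_mask(raster, zone)
    n = int(mask.sum())
    if n == 0:
        raise EmptyZoneError(
            f"{zone.tcga_code}: bounding box contains no raster cell centers")
    return ZoneExposure(
        tcga_code=zone.tcga_code,
        zone_uv=float(raster.uv_annual[mask].mean()),
        zone_pm25=float(raster.pm25_ug_m3[mask].mean()),
        n_cells=n,
    )


def exposure_table(raster: EnvironmentalRaster,
                   zone_table: Iterable[AetiologyZone]) -> pd.DataFrame:
    """Per-code exposure table (TCGA_DESC, Zone_UV, Zone_PM25, n_cells)."""
    rows = [zone_means(raster, z) for z in zone_table]
    return pd.DataFrame(
        [(e.tcga_code, e.zone_uv, e.zone_pm25, e.n_cells) for e in rows],
        columns=["TCGA_DESC", "Zone_UV", "Zone_PM25", "n_cells"],
    )


def assign_zones(cell_lines: pd.DataFrame,
                 zone_table: Iterable[AetiologyZone],
                 raster: EnvironmentalRaster,
                 fallback: str = "median") -> pd.DataFrame:
    """Attach Zone_UV / Zone_PM25 to each cell line via its TCGA code.

    Codes present in the zone table receive that zone's raster means; any
    other code receives the fallback summary over *all* raster cells
    (default: global median, matching how unlisted cancer types are
    handled).  Assignment is a pure function of the code, so all lines of
    one code share identical values.
    """
    if "TCGA_DESC" not in cell_lines.columns:
        raise InvalidInputError("cell-line table lacks a TCGA_DESC column")
    codes = cell_lines["TCGA_DESC"]
    if codes.isna().any() or (codes.astype(str).str.len() == 0).any():
        raise InvalidInputError("every cell line must carry a TCGA code")

    if fallback == "median":
        fb = (float(np.median(raster.uv_annual)),
              float(np.median(raster.pm25_ug_m3)))
    elif fallback == "mean":
        fb = (float(raster.uv_annual.mean()), float(raster.pm25_ug_m3.mean()))
    else:
        raise InvalidInputError(f"unknown fallback {fallback!r}")

    lookup = {z.tcga_code: zone_means(raster, z) for z in zone_table}
    uv = codes.map(lambda c: lookup[c].zone_uv if c in lookup else fb[0])
    pm = codes.map(lambda c: lookup[c].zone_pm25 if c in lookup else fb[1])
    out = cell_lines.copy()
    out["Zone_UV"] = uv.astype(float)
    out["Zone_PM25"] = pm.astype(float)
    return out
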