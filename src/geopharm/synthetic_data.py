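"""Synthetic pipeline inputs with known ground truth.

Every downstream stage (raster interpolation, zone assignment, feature
assembly, boosted-tree modelling, attribution, interaction screen) is
exercised against data generated here, so each generator records exactly
what it planted:

* environmental fields are closed-form functions of (lat, lon), and the
  scattered measurement points carry the field value *noiselessly*, so any
  raster error is attributable to interpolation alone;
* the drug-response surface is an additive model over named features with
  stored per-feature contributions and the stored noise draw, so
  ``intercept + sum(contributions) + noise == LN_IC50`` holds exactly;
* the default response profile is moment-calibrated to the GDSC2 LN_IC50
  marginals (mean 2.81, SD 2.76 log-uM).

All generators are deterministic given a seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError, JoinError

__all__ = [
    "SIGNATURE_NAMES",
    "DESCRIPTOR_NAMES",
    "DEFAULT_TCGA_CODES",
    "PlantedEffect",
    "GroundTruthSpec",
    "gen_measurement_points",
    "gen_cell_lines",
    "gen_drugs",
    "gen_zone_exposures",
    "gen_responses",
    "gen_correlated_pair",
    "simulate_inputs",
    "FAST_PROFILE",
    "COHORT_PROFILE",
]

# The 40 COSMIC v3-style single-base-substitution signatures retained for
# modelling (the germline-polymorphism artefact column SBS_SNP is excluded
# upstream by feature selection, never generated here).
SIGNATURE_NAMES: tuple[str, ...] = (
    "SBS1", "SBS2", "SBS3", "SBS4", "SBS5", "SBS6",
    "SBS7a", "SBS7b", "SBS7c", "SBS7d", "SBS8", "SBS9",
    "SBS10a", "SBS10b", "SBS11", "SBS12", "SBS13", "SBS14",
    "SBS15", "SBS16", "SBS17a", "SBS17b", "SBS18", "SBS19",
    "SBS20", "SBS21", "SBS22", "SBS23", "SBS24", "SBS25",
    "SBS26", "SBS28", "SBS29", "SBS30", "SBS31", "SBS32",
    "SBS33", "SBS34", "SBS35", "SBS36",
)
assert len(SIGNATURE_NAMES) == 40

# RDKit-style molecular descriptors consumed as tabulated input.
DESCRIPTOR_NAMES: tuple[str, ...] = (
    "TPSA", "MolWt", "MolLogP", "NumRotatableBonds",
    "NumHDonors", "NumHAcceptors", "RingCount", "FractionCSP3",
)
_INTEGER_DESCRIPTORS = {"NumRotatableBonds", "NumHDonors", "NumHAcceptors", "RingCount"}

DEFAULT_TCGA_CODES: tuple[str, ...] = (
    "SKCM", "LUAD", "LUSC", "ESCA", "HNSC", "STAD",
    "LIHC", "BRCA", "COREAD", "BLCA", "UCEC",
)

# Per (TCGA code, signature) activity multipliers emulating aetiology-driven
# signature enrichment (melanoma/UV, lung/tobacco, gastric-oesophageal/ROS).
DEFAULT_ENRICHMENT: dict[tuple[str, str], float] = {
    ("SKCM", "SBS7a"): 30.0,
    ("SKCM", "SBS7b"): 12.0,
    ("SKCM", "SBS7c"): 5.0,
    ("SKCM", "SBS7d"): 4.0,
    ("LUAD", "SBS4"): 18.0,
    ("LUSC", "SBS4"): 22.0,
    ("HNSC", "SBS4"): 6.0,
    ("ESCA", "SBS18"): 6.0,
    ("STAD", "SBS18"): 5.0,
    ("COREAD", "SBS18"): 4.0,
    ("BRCA", "SBS2"): 5.0,
    ("BRCA", "SBS13"): 5.0,
    ("BLCA", "SBS2"): 4.0,
    ("BLCA", "SBS13"): 4.0,
}

# Clock-like signatures are present in essentially every cell line.
_UBIQUITOUS = {"SBS1", "SBS5"}


def _default_uv_field(lat, lon):
    """Annual-mean UV index: cosine-of-latitude profile, peak ~8 UVI at the
    equator, small longitudinal harmonic; clipped at zero near the poles."""
    lat_r = np.deg2rad(np.asarray(lat, dtype=float))
    lon_r = np.deg2rad(np.asarray(lon, dtype=float))
    c = np.cos(lat_r)
    out = 8.0 * np.clip(c, 0.0, None) ** 3 + 0.3 * c * np.sin(2.0 * lon_r)
    return np.maximum(out, 0.0)


_PM25_HOTSPOTS = (
    # (lat, lon, amplitude ug/m3, sd degrees) — East Asia, South Asia,
    # North Africa/Middle East, and a milder North American plume.
    (32.0, 112.0, 48.0, 14.0),
    (26.0, 80.0, 40.0, 11.0),
    (22.0, 12.0, 28.0, 16.0),
    (41.0, -88.0, 9.0, 12.0),
)


def _default_pm25_field(lat, lon):
    """PM2.5 ground concentration: low oceanic/boreal baseline plus Gaussian
    industrial hotspots."""
    lat_a = np.asarray(lat, dtype=float)
    lon_a = np.asarray(lon, dtype=float)
    out = np.full(np.broadcast(lat_a, lon_a).shape, 4.0)
    for hlat, hlon, amp, sd in _PM25_HOTSPOTS:
        d2 = (lat_a - hlat) ** 2 + (lon_a - hlon) ** 2
        out = out + amp * np.exp(-d2 / (2.0 * sd * sd))
    return out


@dataclass(frozen=True)
class PlantedEffect:
    """One planted feature effect on LN_IC50.

    ``shape`` is evaluated on the feature min-max normalised to [0, 1]
    within the generated cohort:

    * ``linear``      -> coef * x
    * ``threshold``   -> coef * 1[x > threshold]
    * ``u-shape``     -> coef * 4 * (x - 0.5)**2   (extremes high, middle low)
    """

    feature: str
    shape: str
    coef: float
    threshold: float = 0.6

    def __post_init__(self):
        if self.shape not in ("linear", "threshold", "u-shape"):
            raise InvalidInputError(f"unknown effect shape {self.shape!r}")
        if not math.isfinite(self.coef):
            raise InvalidInputError("effect coefficient must be finite")

    def apply(self, x_norm: np.ndarray) -> np.ndarray:
        if self.shape == "linear":
            return self.coef * x_norm
        if self.shape == "threshold":
            return self.coef * (x_norm > self.threshold).astype(float)
        return self.coef * 4.0 * (x_norm - 0.5) ** 2


def default_effect_table() -> list[PlantedEffect]:
    """Planted effects emulating the qualitative dependence structure the
    model is expected to recover: polar-surface-area U-shape, pollution and
    tobacco-signature resistance, oxidative-stress sensitivity, a melanoma
    UV-signature resistance threshold, and a mild clock-signature trend."""
    return [
        PlantedEffect("TPSA", "u-shape", 3.0),
        PlantedEffect("MolWt", "linear", 1.2),
        PlantedEffect("MolLogP", "linear", -0.8),
        PlantedEffect("Zone_PM25", "linear", 1.5),
        PlantedEffect("Zone_UV", "linear", 0.6),
        PlantedEffect("SBS4", "linear", 2.0),
        PlantedEffect("SBS18", "linear", -1.0),
        PlantedEffect("SBS7a", "threshold", 2.0, threshold=0.8),
        PlantedEffect("SBS1", "linear", -0.5),
    ]


@dataclass
class GroundTruthSpec:
    """Deterministic description of everything the generators plant."""

    uv_field: Callable = field(default=_default_uv_field)
    pm25_field: Callable = field(default=_default_pm25_field)
    effect_table: list[PlantedEffect] = field(default_factory=default_effect_table)
    #: SD of additive Gaussian noise on LN_IC50; None = calibrate the planted
    #: coefficients and the noise so the marginal SD matches ``target_sd``
    #: with ``signal_fraction`` of the variance attributable to the effects.
    noise_sd: float | None = None
    seed: int = 0
    target_mean: float = 2.81
    target_sd: float = 2.76
    #: share of LN_IC50 variance carried by the planted effects under the
    #: calibrated default; 0.7 emulates a strongly predictable response
    #: (residual noise SD ~1.5 log-uM at SD 2.76).
    signal_fraction: float = 0.7

    def field_fn(self, which: str) -> Callable:
        if which.upper() == "UV":
            return self.uv_field
        if which.upper() in ("PM25", "PM2.5"):
            return self.pm25_field
        raise InvalidInputError(f"unknown field {which!r}")

    def to_dict(self) -> dict:
        return {
            "effect_table": [
                {"feature": e.feature, "shape": e.shape, "coef": e.coef,
                 "threshold": e.threshold}
                for e in self.effect_table
            ],
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "target_mean": self.target_mean,
            "target_sd": self.target_sd,
        }


def _rng_stable(seed: int, tag_index: int) -> np.random.Generator:
    # independent, reproducible stream per generator stage
    return np.random.default_rng([int(seed), int(tag_index)])


# stable integer tags, one stream per stage
_TAGS = {"UV": 11, "PM25": 13, "cells": 17, "drugs": 19, "responses": 23,
         "pair": 29, "missing": 31}


def gen_measurement_points(
    n: int,
    which: str,
    lat_range: tuple[float, float],
    truth: GroundTruthSpec,
) -> pd.DataFrame:
    """Scattered measurement points for one environmental field.

    Points are uniform over ``lat_range`` x [-180, 180) and carry the
    ground-truth field value exactly (noiseless), so interpolation error
    downstream is a pure property of the interpolator.
    """
    if n < 3:
        raise InvalidInputError("need at least 3 measurement points")
    lo, hi = lat_range
    if not (-90.0 <= lo < hi <= 90.0):
        raise InvalidInputError(f"lat_range {lat_range} outside [-90, 90]")
    rng = _rng_stable(truth.seed, _TAGS[which.upper().replace(".", "")])
    lat = rng.uniform(lo, hi, size=n)
    lon = rng.uniform(-180.0, 180.0, size=n)
    value = np.asarray(truth.field_fn(which)(lat, lon), dtype=float)
    return pd.DataFrame({"lat": lat, "lon": lon, "value": value})


def gen_cell_lines(
    n_lines: int,
    tcga_codes: Sequence[str] = DEFAULT_TCGA_CODES,
    n_proteomic: int = 64,
    seed: int = 0,
    *,
    missing_frac: float = 0.3,
    enrichment: dict[tuple[str, str], float] | None = None,
    names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Cell-line table: name, TCGA code, 40 sparse non-negative SBS
    activities with code-specific enrichment, and a proteomic block.

    SBS activities follow a zero-inflated gamma (NMF exposures are sparse
    and non-negative); (code, signature) enrichment multipliers raise both
    the expected activity and the detection probability, e.g. melanoma-coded
    lines get elevated SBS7a and lung-coded lines elevated SBS4.
    ``missing_frac`` of proteomic entries are set missing (NaN) to emulate
    incomplete multi-omic coverage.
    """
    if n_lines < 1:
        raise InvalidInputError("n_lines must be >= 1")
    if not tcga_codes:
        raise InvalidInputError("tcga_codes must be non-empty")
    if n_proteomic < 0:
        raise InvalidInputError("n_proteomic must be >= 0")
    if not 0.0 <= missing_frac <= 1.0:
        raise InvalidInputError("missing_frac must be in [0, 1]")
    if names is not None:
        if len(names) != n_lines:
            raise InvalidInputError("len(names) must equal n_lines")
        if len(set(names)) != len(names):
            raise InvalidInputError("duplicate cell-line names requested")
    else:
        names = [f"CL{i:04d}" for i in range(n_lines)]
    if enrichment is None:
        enrichment = DEFAULT_ENRICHMENT

    rng = _rng_stable(seed, _TAGS["cells"])
    codes = np.asarray(tcga_codes)[rng.integers(0, len(tcga_codes), size=n_lines)]

    out = pd.DataFrame({"CELL_LINE_NAME": list(names), "TCGA_DESC": codes})
    for sig in SIGNATURE_NAMES:
        mult = np.array([enrichment.get((c, sig), 1.0) for c in codes])
        p_detect = np.where(mult > 1.0, 0.95, 0.05 if sig not in _UBIQUITOUS else 1.0)
        if sig in _UBIQUITOUS:
            p_detect = np.ones(n_lines)
        elif sig not in {s for (_, s) in enrichment}:
            p_detect = np.full(n_lines, 0.45)
        detected = rng.random(n_lines) < p_detect
        base_scale = 400.0 if sig in _UBIQUITOUS else 80.0
        activity = rng.gamma(shape=1.2, scale=base_scale, size=n_lines) * mult
        out[sig] = np.where(detected, activity, 0.0)

    if n_proteomic:
        prot = rng.normal(0.0, 1.0, size=(n_lines, n_proteomic))
        if missing_frac > 0:
            mask = rng.random(prot.shape) < missing_frac
            prot = np.where(mask, np.nan, prot)
        prot_df = pd.DataFrame(
            prot, columns=[f"PROT_{j:04d}" for j in range(n_proteomic)]
        )
        out = pd.concat([out, prot_df], axis=1)
    return out


def gen_drugs(n_drugs: int = 36, seed: int = 0) -> pd.DataFrame:
    """Drug table with the eight tabulated molecular descriptors, drawn from
    drug-like ranges; count descriptors are non-negative integers and
    FractionCSP3 lies in [0, 1]."""
    if n_drugs < 1:
        raise InvalidInputError("n_drugs must be >= 1")
    rng = _rng_stable(seed, _TAGS["drugs"])
    df = pd.DataFrame({"DRUG_NAME": [f"DRUG{i:03d}" for i in range(n_drugs)]})
    df["TPSA"] = np.clip(rng.lognormal(mean=4.4, sigma=0.5, size=n_drugs), 3.0, 280.0)
    df["MolWt"] = rng.uniform(160.0, 720.0, size=n_drugs)
    df["MolLogP"] = rng.normal(2.5, 1.5, size=n_drugs)
    df["NumRotatableBonds"] = rng.poisson(6.0, size=n_drugs)
    df["NumHDonors"] = rng.poisson(2.0, size=n_drugs)
    df["NumHAcceptors"] = rng.poisson(5.0, size=n_drugs)
    df["RingCount"] = 1 + rng.poisson(2.0, size=n_drugs)
    df["FractionCSP3"] = rng.beta(2.0, 2.0, size=n_drugs)
    return df


def gen_zone_exposures(
    tcga_codes: Sequence[str],
    truth: GroundTruthSpec,
    resolution: float = 1.0,
) -> pd.DataFrame:
    """Ground-truth zone exposures: the mean of each closed-form field over
    each code's aetiology bounding box, evaluated directly on the raster
    cell centers (no interpolation).

    This is the reference the raster->zone pipeline should approach; it is
    also what :func:`gen_responses` uses to plant Zone_* effects.
    """
    from .zones import load_zone_table  # local import to avoid a cycle

    zones = {z.tcga_code: z for z in load_zone_table()}
    nlat = int(round(180.0 / resolution))
    nlon = int(round(360.0 / resolution))
    lat_c = -90.0 + (np.arange(nlat) + 0.5) * resolution
    lon_c = -180.0 + (np.arange(nlon) + 0.5) * resolution
    lon_g, lat_g = np.meshgrid(lon_c, lat_c)
    uv = np.asarray(truth.uv_field(lat_g, lon_g), dtype=float)
    pm = np.asarray(truth.pm25_field(lat_g, lon_g), dtype=float)

    rows = []
    for code in tcga_codes:
        z = zones.get(code)
        if z is None:
            # fallback mirrors the assignment rule: global median
            rows.append((code, float(np.median(uv)), float(np.median(pm))))
            continue
        m_lat = (lat_g >= z.lat_min) & (lat_g <= z.lat_max)
        if z.all_longitudes:
            m = m_lat
        else:
            m = m_lat & (lon_g >= z.lon_min) & (lon_g <= z.lon_max)
        rows.append((code, float(uv[m].mean()), float(pm[m].mean())))
    return pd.DataFrame(rows, columns=["TCGA_DESC", "Zone_UV", "Zone_PM25"])


def _minmax_norm(x: np.ndarray) -> tuple[np.ndarray, float, float]:
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        return np.zeros_like(x, dtype=float), lo, hi
    return (x - lo) / (hi - lo), lo, hi


def gen_responses(
    cells: pd.DataFrame,
    drugs: pd.DataFrame,
    zones: pd.DataFrame,
    truth: GroundTruthSpec,
) -> tuple[pd.DataFrame, dict]:
    """Master interaction table: one row per (cell line, drug) pair with

        LN_IC50 = intercept + sum(planted contributions) + N(0, noise_sd^2)

    Planted contributions are stored alongside as ``GT_<feature>`` columns
    and the noise draw as ``GT_NOISE``, so the decomposition can be
    reconstructed exactly.  The intercept is set so the marginal mean equals
    ``truth.target_mean``; when ``truth.noise_sd`` is None the noise SD is
    set so the marginal SD matches ``truth.target_sd`` (the GDSC2-calibrated
    default: mean 2.81, SD 2.76 log-uM).

    Returns ``(master, sidecar)`` where the sidecar dict records the
    intercept, resolved noise SD, per-feature normalisation bounds and the
    effect table.
    """
    for col in ("CELL_LINE_NAME", "TCGA_DESC"):
        if col not in cells.columns:
            raise JoinError(f"cells table missing {col}")
    if "DRUG_NAME" not in drugs.columns:
        raise JoinError("drugs table missing DRUG_NAME")
    unknown = set(cells["TCGA_DESC"]) - set(zones["TCGA_DESC"])
    if unknown:
        raise JoinError(f"zone exposures missing for TCGA codes {sorted(unknown)}")

    cell_feat = cells.merge(zones, on="TCGA_DESC", how="left", validate="m:1")

    n_c, n_d = len(cells), len(drugs)
    ci = np.repeat(np.arange(n_c), n_d)
    di = np.tile(np.arange(n_d), n_c)
    master = pd.DataFrame({
        "CELL_LINE_NAME": cell_feat["CELL_LINE_NAME"].to_numpy()[ci],
        "TCGA_DESC": cell_feat["TCGA_DESC"].to_numpy()[ci],
        "DRUG_NAME": drugs["DRUG_NAME"].to_numpy()[di],
    })

    norm_bounds: dict[str, tuple[float, float]] = {}
    gt_cols = []
    for eff in truth.effect_table:
        if eff.feature in cell_feat.columns:
            raw = cell_feat[eff.feature].to_numpy(dtype=float)
            x, lo, hi = _minmax_norm(raw)
            contrib = eff.apply(x)[ci]
        elif eff.feature in drugs.columns:
            raw = drugs[eff.feature].to_numpy(dtype=float)
            x, lo, hi = _minmax_norm(raw)
            contrib = eff.apply(x)[di]
        else:
            raise JoinError(f"planted feature {eff.feature!r} found in no table")
        norm_bounds[eff.feature] = (lo, hi)
        col = f"GT_{eff.feature}"
        master[col] = contrib
        gt_cols.append(col)

    det = master[gt_cols].sum(axis=1).to_numpy()
    scale = 1.0
    if truth.noise_sd is None:
        # calibrated default: rescale the planted contributions so they carry
        # signal_fraction of the target variance, and let noise make up the rest
        det_var = float(det.var())
        if det_var > 0:
            scale = math.sqrt(truth.signal_fraction * truth.target_sd**2 / det_var)
            for col in gt_cols:
                master[col] = master[col] * scale
            det = master[gt_cols].sum(axis=1).to_numpy()
        noise_sd = math.sqrt((1.0 - truth.signal_fraction)) * truth.target_sd
    else:
        noise_sd = float(truth.noise_sd)
    intercept = truth.target_mean - float(det.mean())

    rng = _rng_stable(truth.seed, _TAGS["responses"])
    noise = noise_sd * rng.standard_normal(len(master)) if noise_sd > 0 \
        else np.zeros(len(master))
    master["GT_NOISE"] = noise
    master["LN_IC50"] = intercept + master[gt_cols + ["GT_NOISE"]].sum(axis=1)

    front = ["CELL_LINE_NAME", "TCGA_DESC", "DRUG_NAME", "LN_IC50"]
    master = master[front + gt_cols + ["GT_NOISE"]]
    sidecar = {
        **truth.to_dict(),
        "intercept": intercept,
        "noise_sd": noise_sd,
        "coefficient_scale": scale,
        "normalisation_bounds": norm_bounds,
    }
    return master, sidecar


def gen_correlated_pair(
    n: int,
    rho: float,
    seed: int = 0,
    signature: str = "SBS18",
    drug: str = "DRUG_PAIR",
    mean_ic50: float = 2.81,
    sd_ic50: float = 2.76,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One (signature, drug) pair whose activity and LN_IC50 are bivariate
    normal with population Pearson correlation ``rho`` — the planted-effect
    fixture for screen effect-size recovery.

    Returns (master, signatures) tables shaped for :func:`geopharm.screen.screen`.
    Activities are shifted well away from zero so non-negativity holds
    without distorting the correlation.
    """
    if not -1.0 < rho < 1.0:
        raise InvalidInputError("rho must be in (-1, 1)")
    if n < 3:
        raise InvalidInputError("need n >= 3")
    rng = _rng_stable(seed, _TAGS["pair"])
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    activity = 8.0 + z1  # P(activity < 0) ~ 6e-16
    ln_ic50 = mean_ic50 + sd_ic50 * (rho * z1 + math.sqrt(1 - rho * rho) * z2)
    names = [f"CL{i:04d}" for i in range(n)]
    master = pd.DataFrame({
        "CELL_LINE_NAME": names,
        "TCGA_DESC": "PAN",
        "DRUG_NAME": drug,
        "LN_IC50": ln_ic50,
    })
    signatures = pd.DataFrame({"CELL_LINE_NAME": names, signature: activity})
    return master, signatures


# Scale profiles.  "fast" is the desk-scale CI profile; "cohort" matches
# the source cohort dimensions (948 lines x 36 drugs x 1215 proteomic
# features, 1872 UV / 19,605 PM2.5 measurement points).
FAST_PROFILE = {
    "n_lines": 200, "n_drugs": 36, "n_proteomic": 64,
    "n_uv_points": 400, "n_pm25_points": 900,
}
COHORT_PROFILE = {
    "n_lines": 948, "n_drugs": 36, "n_proteomic": 1215,
    "n_uv_points": 1872, "n_pm25_points": 19605,
}

UV_LAT_RANGE = (-55.0, 70.0)   # satellite/station UV coverage band
PM25_LAT_RANGE = (-60.0, 80.0)  # near-global; polar caps are NN-filled


def simulate_inputs(
    profile: str | dict = "fast",
    seed: int = 0,
    truth: GroundTruthSpec | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Generate the five pipeline input tables plus the ground-truth sidecar.

    Returns a dict with keys ``master, signatures, chemistry, proteomics,
    uv_points, pm25_points, zone_exposures, sidecar``; when ``outdir`` is
    given, also writes the CSV files and a JSON sidecar there.
    """
    if isinstance(profile, str):
        try:
            profile = {"fast": FAST_PROFILE, "cohort": COHORT_PROFILE}[profile]
        except KeyError:
            raise InvalidInputError(f"unknown profile {profile!r}") from None
    if truth is None:
        truth = GroundTruthSpec(seed=seed)

    cells = gen_cell_lines(
        profile["n_lines"], n_proteomic=profile["n_proteomic"], seed=seed
    )
    drugs = gen_drugs(profile["n_drugs"], seed=seed)
    zones = gen_zone_exposures(sorted(set(cells["TCGA_DESC"])), truth)
    master, sidecar = gen_responses(cells, drugs, zones, truth)
    uv_points = gen_measurement_points(
        profile["n_uv_points"], "UV", UV_LAT_RANGE, truth
    )
    pm25_points = gen_measurement_points(
        profile["n_pm25_points"], "PM25", PM25_LAT_RANGE, truth
    )

    sig_cols = ["CELL_LINE_NAME"] + list(SIGNATURE_NAMES)
    prot_cols = ["CELL_LINE_NAME"] + [
        c for c in cells.columns if c.startswith("PROT_")
    ]
    out = {
        "master": master,
        "signatures": cells[sig_cols].copy(),
        "chemistry": drugs,
        "proteomics": cells[prot_cols].copy(),
        "uv_points": uv_points,
        "pm25_points": pm25_points,
        "zone_exposures": zones,
        "sidecar": sidecar,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        master_cols = ["CELL_LINE_NAME", "TCGA_DESC", "DRUG_NAME", "LN_IC50"]
        master[master_cols].to_csv(outdir / "master.csv", index=False)
        master.to_csv(outdir / "master_with_ground_truth.csv", index=False)
        out["signatures"].to_csv(outdir / "signatures.csv", index=False)
        drugs.to_csv(outdir / "chemistry.csv", index=False)
        out["proteomics"].to_csv(outdir / "proteomics.csv", index=False)
        uv_points.to_csv(outdir / "uv_points.csv", index=False)
        pm25_points.to_csv(outdir / "pm25_points.csv", index=False)
        zones.to_csv(outdir / "zone_exposures_truth.csv", index=False)
        with open(outdir / "ground_truth.json", "w") as fh:
            json.dump(sidecar, fh, indent=2, default=str)
    return out
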