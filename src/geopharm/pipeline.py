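"""End-to-end stage orchestration with a reproducibility manifest.

Stages (in dependency order): simulate -> raster -> zones -> features ->
train -> explain; screen depends only on simulate.  Each stage reads its
inputs from and writes its outputs to a run directory, and appends a
manifest entry recording parameters, seeds, input checksums, and row
counts, so a run directory alone suffices to reproduce any stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import attribution, env_raster, features, model, screen as screen_mod, zones
from .errors import DependencyError, InvalidConfigError
from .synthetic_data import GroundTruthSpec, simulate_inputs

__all__ = ["PipelineConfig", "run_stage", "STAGES"]

log = logging.getLogger(__name__)

STAGES = ("simulate", "raster", "zones", "features", "train", "explain",
          "screen", "all")

_DEPS = {
    "raster": ["uv_points.csv", "pm25_points.csv"],
    "zones": ["raster.csv", "master.csv"],
    "features": ["master.csv", "signatures.csv", "chemistry.csv",
                 "proteomics.csv", "zone_exposures.csv"],
    "train": ["matrix_X.parquet"],
    "explain": ["model.ubj", "matrix_X.parquet"],
    "screen": ["master.csv", "signatures.csv"],
}


@dataclass
class PipelineConfig:
    """Validated parameters for a pipeline run."""

    outdir: Path = Path("run")
    seed: int = 0
    profile: str = "fast"              # fast | cohort
    resolution: float = 1.0
    zone_config: str | None = None     # YAML path extending the zone table
    impute: str = "zero"
    booster: model.BoosterConfig = field(default_factory=model.BoosterConfig.fast)
    holdout_fraction: float = 0.2
    holdout_seed: int = 42
    cv_k: int = 5
    attribution_rows: int = 6000
    screen_alpha: float = 0.01
    screen_min_n: int = 20

    def __post_init__(self):
        self.outdir = Path(self.outdir)
        if self.profile not in ("fast", "cohort"):
            raise InvalidConfigError(f"unknown profile {self.profile!r}")
        if not 0.0 < self.holdout_fraction < 1.0:
            raise InvalidConfigError("holdout_fraction must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        booster = raw.pop("booster", None)
        cfg = cls(**raw)
        if booster:
            cfg.booster = model.BoosterConfig(**booster)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _manifest_append(cfg: PipelineConfig, stage: str, params: dict,
                     inputs: list[Path], outputs: list[Path],
                     counts: dict) -> None:
    path = cfg.outdir / "manifest.json"
    entries = json.loads(path.read_text()) if path.exists() else []
    entries.append({
        "stage": stage,
        "params": params,
        "inputs": {p.name: _sha256(p) for p in inputs if p.exists()},
        "outputs": {p.name: _sha256(p) for p in outputs if p.exists()},
        "counts": counts,
    })
    path.write_text(json.dumps(entries, indent=2, default=str))


def _need(cfg: PipelineConfig, stage: str) -> list[Path]:
    paths = [cfg.outdir / f for f in _DEPS.get(stage, [])]
    missing = [p for p in paths if not p.exists()]
    if missing:
        raise DependencyError(
            f"stage {stage!r} requires missing artefacts: "
            + ", ".join(str(p) for p in missing))
    return paths


def _stage_simulate(cfg: PipelineConfig) -> None:
    truth = GroundTruthSpec(seed=cfg.seed)
    out = simulate_inputs(cfg.profile, seed=cfg.seed, truth=truth,
                          outdir=cfg.outdir)
    _manifest_append(
        cfg, "simulate",
        {"profile": cfg.profile, "seed": cfg.seed},
        [], [cfg.outdir / f for f in
             ("master.csv", "signatures.csv", "chemistry.csv",
              "proteomics.csv", "uv_points.csv", "pm25_points.csv")],
        {"master_rows": len(out["master"]),
         "cell_lines": out["master"]["CELL_LINE_NAME"].nunique(),
         "drugs": out["master"]["DRUG_NAME"].nunique()},
    )


def _stage_raster(cfg: PipelineConfig) -> None:
    inputs = _need(cfg, "raster")
    uv = pd.read_csv(inputs[0])
    pm = pd.read_csv(inputs[1])
    raster = env_raster.build_raster(uv, pm, resolution=cfg.resolution,
                                     out_csv=cfg.outdir / "raster.csv")
    _manifest_append(
        cfg, "raster", {"resolution": cfg.resolution},
        inputs, [cfg.outdir / "raster.csv"],
        {"cells": raster.grid.n_cells,
         "uv_nn_filled": int(raster.uv_nearest.sum()),
         "pm25_nn_filled": int(raster.pm25_nearest.sum())},
    )


def _load_raster(cfg: PipelineConfig) -> env_raster.EnvironmentalRaster:
    df = pd.read_csv(cfg.outdir / "raster.csv")
    grid = env_raster.build_grid(cfg.resolution)
    shape = grid.shape
    return env_raster.EnvironmentalRaster(
        grid=grid,
        uv_annual=df["UV_Annual"].to_numpy().reshape(shape),
        pm25_ug_m3=df["PM25_ug_m3"].to_numpy().reshape(shape),
        uv_nearest=np.zeros(shape, dtype=bool),
        pm25_nearest=np.zeros(shape, dtype=bool),
    )


def _stage_zones(cfg: PipelineConfig) -> None:
    inputs = _need(cfg, "zones")
    raster = _load_raster(cfg)
    table = zones.load_zone_table(cfg.zone_config)
    master = pd.read_csv(cfg.outdir / "master.csv")
    codes = master[["TCGA_DESC"]].drop_duplicates().reset_index(drop=True)
    assigned = zones.assign_zones(codes, table, raster)
    out_path = cfg.outdir / "zone_exposures.csv"
    assigned.rename(columns={"TCGA_DESC": "TCGA_DESC"}).to_csv(out_path, index=False)
    _manifest_append(cfg, "zones", {"zone_config": cfg.zone_config},
                     inputs, [out_path], {"codes": len(assigned)})


def _stage_features(cfg: PipelineConfig) -> features.FeatureMatrix:
    inputs = _need(cfg, "features")
    master = pd.read_csv(cfg.outdir / "master.csv")
    sigs = pd.read_csv(cfg.outdir / "signatures.csv")
    chem = pd.read_csv(cfg.outdir / "chemistry.csv")
    prot = pd.read_csv(cfg.outdir / "proteomics.csv")
    zexp = pd.read_csv(cfg.outdir / "zone_exposures.csv")
    fm = features.assemble(master, sigs, chem, prot, zexp, impute=cfg.impute)
    fm = features.scale_minmax(fm)
    fm.X.to_parquet(cfg.outdir / "matrix_X.parquet")
    pd.DataFrame({"LN_IC50": fm.y, "CELL_LINE_NAME": fm.groups}).to_parquet(
        cfg.outdir / "matrix_meta.parquet")
    (cfg.outdir / "matrix_manifest.json").write_text(json.dumps({
        "block_widths": fm.block_widths,
        "n_rows": fm.n_rows, "n_features": fm.n_features,
        "dropped_drugs": fm.dropped_drugs,
        "n_dropped_rows": fm.n_dropped_rows,
        "impute": fm.impute,
    }, indent=2))
    _manifest_append(cfg, "features", {"impute": cfg.impute}, inputs,
                     [cfg.outdir / "matrix_X.parquet"],
                     {"rows": fm.n_rows, "features": fm.n_features,
                      "dropped_rows": fm.n_dropped_rows})
    return fm


def _load_matrix(cfg: PipelineConfig) -> features.FeatureMatrix:
    X = pd.read_parquet(cfg.outdir / "matrix_X.parquet")
    meta = pd.read_parquet(cfg.outdir / "matrix_meta.parquet")
    man = json.loads((cfg.outdir / "matrix_manifest.json").read_text())
    return features.FeatureMatrix(X=X, y=meta["LN_IC50"],
                                  groups=meta["CELL_LINE_NAME"],
                                  block_widths=man["block_widths"],
                                  impute=man["impute"])


def _stage_train(cfg: PipelineConfig) -> None:
    inputs = _need(cfg, "train")
    fm = _load_matrix(cfg)
    train_m, test_m = features.split_holdout(fm, cfg.holdout_fraction,
                                             cfg.holdout_seed)
    fitted = model.train(train_m, cfg.booster)
    holdout = model.evaluate(fitted, test_m)
    cv = model.cross_validate(fm, cfg.cv_k, cfg.booster, seed=cfg.holdout_seed)
    fitted.get_booster().save_model(cfg.outdir / "model.ubj")
    report = {
        "holdout": {"r2": holdout.r2, "rmse": holdout.rmse,
                    "mae": holdout.mae, "n": holdout.n},
        "grouped_cv": {"mean_r2": cv.mean_r2, "sd_r2": cv.sd_r2,
                       "mean_rmse": cv.mean_rmse, "mean_mae": cv.mean_mae,
                       "k": cfg.cv_k,
                       "per_fold_r2": [m.r2 for m in cv.per_fold]},
        "booster": model.config_dict(cfg.booster),
    }
    (cfg.outdir / "metrics.json").write_text(json.dumps(report, indent=2))
    pd.DataFrame([{"fold": i, "r2": m.r2, "rmse": m.rmse, "mae": m.mae,
                   "n": m.n} for i, m in enumerate(cv.per_fold)]).to_csv(
        cfg.outdir / "cv_report.csv", index=False)
    _manifest_append(cfg, "train", report["booster"], inputs,
                     [cfg.outdir / "model.ubj", cfg.outdir / "metrics.json"],
                     {"train_rows": train_m.n_rows, "test_rows": test_m.n_rows})


def _stage_explain(cfg: PipelineConfig) -> None:
    import xgboost as xgb

    inputs = _need(cfg, "explain")
    fm = _load_matrix(cfg)
    _, test_m = features.split_holdout(fm, cfg.holdout_fraction, cfg.holdout_seed)
    booster = xgb.Booster()
    booster.load_model(cfg.outdir / "model.ubj")
    attr = attribution.attribute(booster, test_m, max_rows=cfg.attribution_rows,
                                 seed=cfg.seed)
    summary = attribution.rank_features(attr)
    summary.to_csv(cfg.outdir / "shap_ranking.csv", index=False)
    stab = attribution.bootstrap_stability(attr, n_boot=100, k_top=10,
                                           seed=cfg.seed)
    pd.DataFrame({"resample": np.arange(stab.n_boot),
                  "spearman_rho": stab.spearman_rhos}).to_csv(
        cfg.outdir / "shap_stability.csv", index=False)
    for feat in attribution.DEFAULT_COLOUR_PAIRS:
        if feat in attr.phi.columns:
            attribution.dependence_data(attr, feat).to_csv(
                cfg.outdir / f"dependence_{feat}.csv", index=False)
    _manifest_append(cfg, "explain",
                     {"rows": len(attr.phi), "n_boot": stab.n_boot},
                     inputs, [cfg.outdir / "shap_ranking.csv"],
                     {"median_rho": stab.median_rho,
                      "top10_order_consistent": stab.topk_order_consistent,
                      "top10_set_consistent": stab.topk_set_consistent})


def _stage_screen(cfg: PipelineConfig) -> None:
    inputs = _need(cfg, "screen")
    master = pd.read_csv(cfg.outdir / "master.csv")
    sigs = pd.read_csv(cfg.outdir / "signatures.csv")
    results = screen_mod.screen(master, sigs, alpha=cfg.screen_alpha,
                                min_n=cfg.screen_min_n)
    results = screen_mod.adjust_fdr(results)
    paths = screen_mod.atlas_export(results, cfg.outdir)
    _manifest_append(cfg, "screen",
                     {"alpha": cfg.screen_alpha, "min_n": cfg.screen_min_n},
                     inputs, list(paths.values()),
                     {"pairs": len(results),
                      "significant": int(results["significant"].sum())})


_RUNNERS = {
    "simulate": _stage_simulate,
    "raster": _stage_raster,
    "zones": _stage_zones,
    "features": _stage_features,
    "train": _stage_train,
    "explain": _stage_explain,
    "screen": _stage_screen,
}


def run_stage(name: str, cfg: PipelineConfig) -> None:
    """Run one pipeline stage (or ``all`` in dependency order)."""
    if name not in STAGES:
        raise InvalidConfigError(f"unknown stage {name!r}; choose from {STAGES}")
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    if name == "all":
        for stage in ("simulate", "raster", "zones", "features", "train",
                      "explain", "screen"):
            log.info("running stage %s", stage)
            _RUNNERS[stage](cfg)
    else:
        _RUNNERS[name](cfg)
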