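"""Model-matrix assembly: joins, imputation, scaling, and leakage-safe splits.

The matrix is built from five tables keyed on cell line and drug:

* master interaction records (cell line, TCGA code, drug, LN_IC50);
* per-cell-line SBS signature activities (the artefact column SBS_SNP, when
  present, is dropped before assembly);
* per-drug molecular descriptors — master rows without a descriptor entry
  are removed by an inner join, and every dropped drug key is logged;
* per-cell-line proteomic/epigenetic features;
* per-TCGA-code environmental zone exposures (Zone_UV, Zone_PM25).

Remaining missing entries are imputed (zero by default; feature-mean for
the sensitivity variant), then every column is min-max scaled to [0, 1].
At source-cohort scale the block widths are 40 + 8 + 1215 + 2 = 1265.

Two split procedures are provided: a plain row-level holdout (the headline
evaluation) and cell-line-grouped folds in which all records of a cell line
fall in exactly one test fold (the leakage-safe generalisation estimate).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyOutputError, InvalidInputError, SchemaError
from .synthetic_data import DESCRIPTOR_NAMES

__all__ = [
    "FeatureMatrix", "ScalerState", "select_sbs_columns", "assemble",
    "scale_minmax", "split_holdout", "grouped_folds",
]

log = logging.getLogger(__name__)

#: Artefact signature column excluded from the feature set (germline
#: polymorphism artefact, not an exposure process).
EXCLUDED_SIGNATURES = ("SBS_SNP",)

ENV_FEATURES = ("Zone_UV", "Zone_PM25")


def select_sbs_columns(signatures: pd.DataFrame) -> list[str]:
    """Signature feature columns: everything except the key column and the
    excluded artefact signatures."""
    return [c for c in signatures.columns
            if c != "CELL_LINE_NAME" and c not in EXCLUDED_SIGNATURES]


@dataclass
class ScalerState:
    """Per-column (min, max) fitted by :func:`scale_minmax`."""

    col_min: pd.Series
    col_max: pd.Series

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        rng = (self.col_max - self.col_min).replace(0.0, np.nan)
        out = (X - self.col_min) / rng
        return out.fillna(0.0)  # constant columns map to 0

    def inverse_transform(self, X_scaled: pd.DataFrame) -> pd.DataFrame:
        rng = self.col_max - self.col_min
        return X_scaled * rng + self.col_min


@dataclass
class FeatureMatrix:
    """Assembled interaction-record matrix with group bookkeeping."""

    X: pd.DataFrame                 # rows x features
    y: pd.Series                    # LN_IC50
    groups: pd.Series               # cell line per row
    block_widths: dict = field(default_factory=dict)
    dropped_drugs: list = field(default_factory=list)
    n_dropped_rows: int = 0
    impute: str = "zero"
    scaler: ScalerState | None = None

    @property
    def n_rows(self) -> int:
        return len(self.X)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def take(self, idx: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            X=self.X.iloc[idx].reset_index(drop=True),
            y=self.y.iloc[idx].reset_index(drop=True),
            groups=self.groups.iloc[idx].reset_index(drop=True),
            block_widths=self.block_widths,
            dropped_drugs=self.dropped_drugs,
            n_dropped_rows=self.n_dropped_rows,
            impute=self.impute,
            scaler=self.scaler,
        )


def _require(df: pd.DataFrame, cols, name: str):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} table missing columns {missing}")


def assemble(master: pd.DataFrame,
             signatures: pd.DataFrame,
             chemistry: pd.DataFrame,
             proteomics: pd.DataFrame,
             zone_exposures: pd.DataFrame,
             impute: str = "zero") -> FeatureMatrix:
    """Join the five source tables into the unscaled model matrix.

    Master rows whose drug lacks a chemistry entry are dropped (inner
    join); the signature, proteomic and zone blocks are left-joined on cell
    line / TCGA code and remaining gaps imputed by ``impute`` ("zero", the
    default, or "feature-mean").  Column order is signatures, chemistry
    descriptors, proteomics, then (Zone_UV, Zone_PM25).
    """
    _require(master, ["CELL_LINE_NAME", "TCGA_DESC", "DRUG_NAME", "LN_IC50"], "master")
    _require(signatures, ["CELL_LINE_NAME"], "signatures")
    _require(chemistry, ["DRUG_NAME"], "chemistry")
    _require(proteomics, ["CELL_LINE_NAME"], "proteomics")
    _require(zone_exposures, ["TCGA_DESC", *ENV_FEATURES], "zone_exposures")
    if impute not in ("zero", "feature-mean"):
        raise InvalidInputError(f"unknown imputation mode {impute!r}")

    sbs_cols = select_sbs_columns(signatures)
    chem_cols = [c for c in chemistry.columns if c != "DRUG_NAME"]
    prot_cols = [c for c in proteomics.columns if c != "CELL_LINE_NAME"]

    known_drugs = set(chemistry["DRUG_NAME"])
    drop_mask = ~master["DRUG_NAME"].isin(known_drugs)
    dropped_drugs = sorted(set(master.loc[drop_mask, "DRUG_NAME"]))
    n_dropped = int(drop_mask.sum())
    if dropped_drugs:
        log.info("inner join dropped %d rows for %d drugs without chemistry: %s",
                 n_dropped, len(dropped_drugs), dropped_drugs)

    rec = master.loc[~drop_mask].reset_index(drop=True)
    if rec.empty:
        raise EmptyOutputError("no master rows survive the chemistry inner join")

    rec = rec.merge(chemistry[["DRUG_NAME"] + chem_cols], on="DRUG_NAME",
                    how="left", validate="m:1")
    rec = rec.merge(signatures[["CELL_LINE_NAME"] + sbs_cols], on="CELL_LINE_NAME",
                    how="left", validate="m:1")
    rec = rec.merge(proteomics[["CELL_LINE_NAME"] + prot_cols], on="CELL_LINE_NAME",
                    how="left", validate="m:1")
    rec = rec.merge(zone_exposures[["TCGA_DESC", *ENV_FEATURES]], on="TCGA_DESC",
                    how="left", validate="m:1")

    feat_cols = sbs_cols + chem_cols + prot_cols + list(ENV_FEATURES)
    X = rec[feat_cols].astype(float)
    if impute == "zero":
        X = X.fillna(0.0)
    else:
        X = X.fillna(X.mean()).fillna(0.0)  # all-NaN columns fall back to 0

    return FeatureMatrix(
        X=X,
        y=rec["LN_IC50"].astype(float),
        groups=rec["CELL_LINE_NAME"],
        block_widths={
            "signatures": len(sbs_cols),
            "chemistry": len(chem_cols),
            "proteomics": len(prot_cols),
            "environment": len(ENV_FEATURES),
        },
        dropped_drugs=dropped_drugs,
        n_dropped_rows=n_dropped,
        impute=impute,
    )


def scale_minmax(matrix: FeatureMatrix) -> FeatureMatrix:
    """Min-max scale every column to [0, 1]; constant columns map to 0.

    The fitted per-column (min, max) is stored on the returned matrix for
    inverse transforms and for scaling unseen rows.
    """
    if matrix.n_rows == 0:
        raise InvalidInputError("cannot scale an empty matrix")
    state = ScalerState(col_min=matrix.X.min(), col_max=matrix.X.max())
    out = matrix.take(np.arange(matrix.n_rows))
    out.X = state.transform(matrix.X)
    out.scaler = state
    return out


def split_holdout(matrix: FeatureMatrix, test_fraction: float = 0.2,
                  seed: int = 42) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Row-level random holdout split; |test| = round(n * test_fraction)."""
    if not 0.0 < test_fraction < 1.0:
        raise InvalidInputError("test_fraction must be in (0, 1)")
    n = matrix.n_rows
    if n < 2:
        raise InvalidInputError("need at least 2 rows to split")
    n_test = int(round(n * test_fraction))
    n_test = min(max(n_test, 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    return matrix.take(np.sort(perm[n_test:])), matrix.take(np.sort(perm[:n_test]))


def grouped_folds(matrix: FeatureMatrix, k: int, seed: int = 42) -> np.ndarray:
    """Cell-line-grouped fold assignment: per-row test-fold index in
    [0, k), with every cell line's rows in exactly one test fold and fold
    sizes balanced by group count."""
    if k < 2:
        raise InvalidInputError("k must be >= 2")
    lines = matrix.groups.unique()
    if len(lines) < k:
        raise InvalidInputError(f"only {len(lines)} cell lines for k={k} folds")
    order = np.random.default_rng(seed).permutation(len(lines))
    fold_of_line = {lines[j]: i % k for i, j in enumerate(order)}
    return matrix.groups.map(fold_of_line).to_numpy()
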