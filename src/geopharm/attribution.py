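"""Tree-SHAP attribution, global importance rankings, and rank stability.

Per-prediction additive attributions are computed with the exact
tree-traversal Shapley algorithm (TreeSHAP) built into XGBoost
(``pred_contribs=True``), so the local-accuracy identity

    base_value + sum_j phi_j = model prediction

holds to floating-point tolerance for every row, and features never used
by any tree receive exactly zero attribution.

Global importance is the mean absolute attribution over a holdout sample
(6000 rows by default), ranked descending; stability is assessed by
bootstrap-resampling the attribution rows, re-ranking, and comparing each
resample's ordering to the full-sample ordering (Spearman rho and top-k
consistency, both as exact-order and as set identity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy import stats

from . import _treeshap
from .errors import InvalidInputError, SchemaError
from .features import FeatureMatrix

__all__ = [
    "AttributionMatrix", "AttributionSummary", "StabilityReport",
    "attribute", "rank_features", "dependence_data", "bootstrap_stability",
    "compare_rankings", "DEFAULT_COLOUR_PAIRS",
]

#: Default dependence-plot colour pairings (feature -> interaction feature).
DEFAULT_COLOUR_PAIRS = {
    "Zone_PM25": "MolLogP",
    "TPSA": "Zone_PM25",
    "SBS4": "SBS5",
    "SBS18": "SBS4",
}


@dataclass
class AttributionMatrix:
    """Per-row, per-feature attributions over a sampled set of records."""

    phi: pd.DataFrame          # rows x features, log-uM contributions
    base_values: np.ndarray    # expected model output per row
    rows: pd.DataFrame         # the (scaled) feature values attributed
    predictions: np.ndarray    # model output per row

    @property
    def features(self) -> list[str]:
        return list(self.phi.columns)


@dataclass
class StabilityReport:
    n_boot: int
    k_top: int
    spearman_rhos: np.ndarray          # per-resample rho vs full ranking
    topk_order_consistent: int         # resamples with identical top-k order
    topk_set_consistent: int           # resamples with identical top-k set

    @property
    def median_rho(self) -> float:
        return float(np.median(self.spearman_rhos))


#: AttributionSummary: a DataFrame with columns Feature, mean_abs_shap,
#: rank (1-based, descending mean |phi|, ties broken lexicographically).
AttributionSummary = pd.DataFrame


def attribute(model: xgb.XGBRegressor, sample: FeatureMatrix,
              max_rows: int = 6000, seed: int = 0,
              engine: str = "exact") -> AttributionMatrix:
    """Exact TreeSHAP attributions for up to ``max_rows`` rows sampled
    (without replacement, seeded) from the supplied holdout matrix.

    ``engine="exact"`` (default) runs the in-repo float64 path-dependent
    TreeSHAP, for which the local-accuracy identity holds to float64
    round-off; ``engine="xgboost"`` uses the library's native float32
    ``pred_contribs`` (same algorithm class, faster on huge ensembles).
    ``model`` may be a fitted ``XGBRegressor`` or a raw ``Booster``.
    """
    booster = model.get_booster() if hasattr(model, "get_booster") else model
    names = booster.feature_names
    if names is not None and list(sample.X.columns) != list(names):
        raise SchemaError("attribution columns do not match training columns")
    n = sample.n_rows
    if n == 0:
        raise InvalidInputError("no rows to attribute")
    if n > max_rows:
        idx = np.sort(np.random.default_rng(seed).choice(n, max_rows, replace=False))
        sample = sample.take(idx)
    cols = list(sample.X.columns)
    if engine == "exact":
        trees = _treeshap.parse_booster(booster)
        phi_arr, base_value, preds = _treeshap.shap_values(
            trees, sample.X.to_numpy())
        phi = pd.DataFrame(phi_arr, columns=cols)
        base = np.full(len(phi), base_value)
    elif engine == "xgboost":
        dm = xgb.DMatrix(sample.X)
        contribs = booster.predict(dm, pred_contribs=True).astype(np.float64)
        phi = pd.DataFrame(contribs[:, :-1], columns=cols)
        base = contribs[:, -1]
        preds = booster.predict(dm).astype(np.float64)
    else:
        raise InvalidInputError(f"unknown attribution engine {engine!r}")
    return AttributionMatrix(phi=phi, base_values=base, rows=sample.X.copy(),
                             predictions=preds)


def rank_features(attr: AttributionMatrix) -> AttributionSummary:
    """Global importance: mean |phi| per feature, descending rank; ties are
    broken by feature name (lexicographic)."""
    if len(attr.phi) == 0:
        raise InvalidInputError("empty attribution matrix")
    mean_abs = attr.phi.abs().mean(axis=0)
    out = (pd.DataFrame({"Feature": mean_abs.index, "mean_abs_shap": mean_abs.values})
           .sort_values(["mean_abs_shap", "Feature"], ascending=[False, True])
           .reset_index(drop=True))
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def dependence_data(attr: AttributionMatrix, feature: str,
                    colour_feature: str | None = None) -> pd.DataFrame:
    """Tidy per-row (feature value, phi, colour value) triples for a
    dependence plot.  Feature values are the (scaled) model inputs as
    attributed.  The colour feature defaults to the conventional pairing
    where one exists, else the feature itself."""
    if feature not in attr.phi.columns:
        raise SchemaError(f"unknown feature {feature!r}")
    if colour_feature is None:
        colour_feature = DEFAULT_COLOUR_PAIRS.get(feature, feature)
    if colour_feature not in attr.rows.columns:
        raise SchemaError(f"unknown colour feature {colour_feature!r}")
    return pd.DataFrame({
        "feature": feature,
        "value": attr.rows[feature].to_numpy(),
        "phi": attr.phi[feature].to_numpy(),
        "colour_feature": colour_feature,
        "colour_value": attr.rows[colour_feature].to_numpy(),
    })


def _ranking_series(summary: AttributionSummary) -> pd.Series:
    return summary.set_index("Feature")["rank"]


def bootstrap_stability(attr: AttributionMatrix, n_boot: int = 100,
                        k_top: int = 10, seed: int = 0) -> StabilityReport:
    """Bootstrap the attribution rows (with replacement), re-rank, and
    compare each resample's mean-|phi| ordering to the full-sample one."""
    if n_boot < 2:
        raise InvalidInputError("n_boot must be >= 2")
    full = rank_features(attr)
    full_ranks = _ranking_series(full)
    top_full = list(full["Feature"].head(k_top))
    rng = np.random.default_rng(seed)
    n = len(attr.phi)
    abs_phi = attr.phi.abs().to_numpy()
    cols = list(attr.phi.columns)

    rhos = np.empty(n_boot)
    order_hits = 0
    set_hits = 0
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        mean_abs = abs_phi[idx].mean(axis=0)
        boot = (pd.DataFrame({"Feature": cols, "mean_abs_shap": mean_abs})
                .sort_values(["mean_abs_shap", "Feature"], ascending=[False, True]))
        boot_rank = pd.Series(np.arange(1, len(cols) + 1), index=boot["Feature"])
        rho = stats.spearmanr(full_ranks.to_numpy(),
                              boot_rank.reindex(full_ranks.index).to_numpy()).statistic
        rhos[b] = rho
        top_boot = list(boot["Feature"].head(k_top))
        if top_boot == top_full:
            order_hits += 1
        if set(top_boot) == set(top_full):
            set_hits += 1
    return StabilityReport(n_boot=n_boot, k_top=k_top, spearman_rhos=rhos,
                           topk_order_consistent=order_hits,
                           topk_set_consistent=set_hits)


def compare_rankings(summary_a: AttributionSummary,
                     summary_b: AttributionSummary
                     ) -> tuple[float, pd.DataFrame]:
    """Spearman rho between two importance orderings over the same feature
    set, plus per-feature rank deltas (rank_b - rank_a)."""
    ra, rb = _ranking_series(summary_a), _ranking_series(summary_b)
    if set(ra.index) != set(rb.index):
        raise SchemaError("rankings cover different feature sets")
    rb = rb.reindex(ra.index)
    rho = float(stats.spearmanr(ra.to_numpy(), rb.to_numpy()).statistic)
    deltas = pd.DataFrame({"Feature": ra.index, "rank_a": ra.to_numpy(),
                           "rank_b": rb.to_numpy(),
                           "delta": (rb - ra).to_numpy()}).reset_index(drop=True)
    return rho, deltas
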