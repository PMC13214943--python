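"""Gradient-boosted drug-response regression and its evaluation.

The learner is an XGBoost regressor with squared-error loss and the fixed
hyperparameter set used throughout (600 trees, depth 7, learning rate
0.025, 80% row and column subsampling, histogram tree method).  Training
defaults to single-threaded CPU so results are reproducible; no early
stopping is used (the round count is fixed).

Evaluation metrics are implemented from their definitions —
R^2 = 1 - SS_res/SS_tot, RMSE, MAE — and cross-validation uses the
cell-line-grouped folds from :mod:`geopharm.features` so no cell line ever
appears on both sides of a fold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import xgboost as xgb

from .errors import InvalidInputError, UndefinedR2Error
from .features import FeatureMatrix, grouped_folds

__all__ = ["BoosterConfig", "ModelMetrics", "CvReport", "train", "evaluate",
           "cross_validate"]


@dataclass(frozen=True)
class BoosterConfig:
    """Hyperparameters of the gradient-boosted regressor."""

    n_estimators: int = 600
    max_depth: int = 7
    learning_rate: float = 0.025
    subsample: float = 0.80
    colsample_bytree: float = 0.80
    seed: int = 42
    tree_method: str = "hist"
    device: str = "cpu"
    n_jobs: int = 1

    def __post_init__(self):
        if self.n_estimators <= 0 or self.max_depth <= 0 or self.learning_rate <= 0:
            raise InvalidInputError("booster sizes and learning rate must be positive")
        if not (0.0 < self.subsample <= 1.0 and 0.0 < self.colsample_bytree <= 1.0):
            raise InvalidInputError("subsample fractions must lie in (0, 1]")

    @classmethod
    def fast(cls, seed: int = 42) -> "BoosterConfig":
        """Desk-scale profile for tests and quick runs: fewer, shallower
        trees with a larger step so small synthetic cohorts still converge."""
        return cls(n_estimators=300, max_depth=5, learning_rate=0.1,
                   subsample=0.9, colsample_bytree=0.9, seed=seed)


@dataclass(frozen=True)
class ModelMetrics:
    r2: float
    rmse: float
    mae: float
    n: int


@dataclass
class CvReport:
    per_fold: list[ModelMetrics]
    mean_r2: float = field(init=False)
    sd_r2: float = field(init=False)
    mean_rmse: float = field(init=False)
    mean_mae: float = field(init=False)

    def __post_init__(self):
        r2s = np.array([m.r2 for m in self.per_fold])
        self.mean_r2 = float(r2s.mean())
        self.sd_r2 = float(r2s.std(ddof=1)) if len(r2s) > 1 else 0.0
        self.mean_rmse = float(np.mean([m.rmse for m in self.per_fold]))
        self.mean_mae = float(np.mean([m.mae for m in self.per_fold]))


def train(matrix: FeatureMatrix, config: BoosterConfig | None = None) -> xgb.XGBRegressor:
    """Fit the boosted regressor on a (scaled) feature matrix."""
    if config is None:
        config = BoosterConfig()
    if matrix.n_rows == 0:
        raise InvalidInputError("empty training matrix")
    if not np.isfinite(matrix.X.to_numpy()).all():
        raise InvalidInputError("training features contain non-finite values")
    if not np.isfinite(matrix.y.to_numpy()).all():
        raise InvalidInputError("training target contains non-finite values")
    model = xgb.XGBRegressor(
        objective="reg:squarederror",
        n_estimators=config.n_estimators,
        max_depth=config.max_depth,
        learning_rate=config.learning_rate,
        subsample=config.subsample,
        colsample_bytree=config.colsample_bytree,
        tree_method=config.tree_method,
        device=config.device,
        n_jobs=config.n_jobs,
        random_state=config.seed,
    )
    model.fit(matrix.X, matrix.y)
    return model


def compute_metrics(y: np.ndarray, yhat: np.ndarray) -> ModelMetrics:
    """R^2, RMSE, MAE from their definitions."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    resid = y - yhat
    rmse = float(math.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise UndefinedR2Error("target has zero variance; R^2 undefined",
                               rmse=rmse, mae=mae, n=len(y))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return ModelMetrics(r2=r2, rmse=rmse, mae=mae, n=len(y))


def evaluate(model: xgb.XGBRegressor, matrix: FeatureMatrix) -> ModelMetrics:
    """Holdout metrics; the evaluation matrix must share the training columns."""
    booster_names = model.get_booster().feature_names
    if booster_names is not None and list(matrix.X.columns) != list(booster_names):
        raise InvalidInputError("evaluation columns do not match training columns")
    yhat = model.predict(matrix.X)
    return compute_metrics(matrix.y.to_numpy(), yhat)


def cross_validate(matrix: FeatureMatrix, k: int = 5,
                   config: BoosterConfig | None = None,
                   seed: int = 42) -> CvReport:
    """k-fold cell-line-grouped cross-validation (leakage-safe)."""
    folds = grouped_folds(matrix, k, seed=seed)
    per_fold = []
    for f in range(k):
        test_idx = np.flatnonzero(folds == f)
        train_idx = np.flatnonzero(folds != f)
        model = train(matrix.take(train_idx), config)
        per_fold.append(evaluate(model, matrix.take(test_idx)))
    return CvReport(per_fold=per_fold)


def config_dict(config: BoosterConfig) -> dict:
    return asdict(config)
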