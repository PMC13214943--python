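"""Shared fixtures: one fast synthetic cohort and one fitted model, built
once per session so model-dependent tests stay cheap."""

import numpy as np
import pandas as pd
import pytest

import geopharm as gp
from geopharm import features, model
from geopharm.synthetic_data import GroundTruthSpec


@pytest.fixture(scope="session")
def sim():
    """Fast-profile synthetic cohort (200 lines x 36 drugs x 64 proteomic)."""
    return gp.simulate_inputs("fast", seed=7)


@pytest.fixture(scope="session")
def truth():
    return GroundTruthSpec(seed=7)


@pytest.fixture(scope="session")
def matrix(sim):
    """Assembled + scaled feature matrix for the fast cohort."""
    fm = gp.assemble(sim["master"], sim["signatures"], sim["chemistry"],
                     sim["proteomics"], sim["zone_exposures"])
    return gp.scale_minmax(fm)


@pytest.fixture(scope="session")
def split(matrix):
    return gp.split_holdout(matrix, 0.2, seed=42)


@pytest.fixture(scope="session")
def fitted(split):
    train_m, _ = split
    return gp.train(train_m, model.BoosterConfig.fast())


def small_matrix(X: np.ndarray, y: np.ndarray, cols=None,
                 groups=None) -> features.FeatureMatrix:
    """Wrap raw arrays as a FeatureMatrix for targeted unit tests."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    cols = cols or [f"f{i}" for i in range(X.shape[1])]
    if groups is None:
        groups = [f"g{i}" for i in range(len(X))]
    return features.FeatureMatrix(
        X=pd.DataFrame(X, columns=cols),
        y=pd.Series(np.asarray(y, dtype=float), name="LN_IC50"),
        groups=pd.Series(groups),
    )
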