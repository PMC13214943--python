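"""Attribution contracts: exact local accuracy, null features, planted
importance and direction recovery, ranking and stability bookkeeping."""

import numpy as np
import pandas as pd
import pytest
import xgboost as xgb
from scipy import stats

import functools

import geopharm as gp
from geopharm import _treeshap, attribution as at, model as md
from geopharm.errors import SchemaError
from conftest import small_matrix


@pytest.fixture(scope="module")
def attr(fitted, split):
    _, test = split
    return at.attribute(fitted, test, max_rows=400, seed=0)


class TestLocalAccuracy:
    def test_identity_holds_per_row(self, attr):
        err = np.abs(attr.base_values + attr.phi.sum(axis=1).to_numpy()
                     - attr.predictions)
        assert err.max() < 1e-6

    def test_own_predictions_match_xgboost(self, fitted, attr):
        direct = fitted.predict(attr.rows).astype(float)
        np.testing.assert_allclose(attr.predictions, direct, atol=2e-5)

    def test_agrees_with_library_treeshap(self, fitted, split):
        """Independent route: xgboost's native pred_contribs (same
        algorithm, float32) must agree with the in-repo float64 version."""
        _, test = split
        sub = test.take(np.arange(50))
        ours = at.attribute(fitted, sub, max_rows=50, engine="exact")
        lib = at.attribute(fitted, sub, max_rows=50, engine="xgboost")
        np.testing.assert_allclose(ours.phi.to_numpy(), lib.phi.to_numpy(),
                                   atol=5e-4)
        np.testing.assert_allclose(ours.base_values, lib.base_values, atol=5e-4)

    def test_brute_force_shapley_oracle_on_tiny_ensemble(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.random((80, 4)), columns=list("abcd"))
        y = 2 * X.a - X.b + (X.c > 0.4) * 0.7 + rng.normal(0, 0.05, 80)
        mdl = xgb.XGBRegressor(n_estimators=4, max_depth=3, learning_rate=0.6,
                               n_jobs=1, random_state=0)
        mdl.fit(X, y)
        trees = _treeshap.parse_booster(mdl.get_booster())
        phi, base, preds = _treeshap.shap_values(trees, X.to_numpy()[:8])
        for i in range(8):
            expect = _treeshap.brute_force_shap(trees, X.to_numpy()[i])
            np.testing.assert_allclose(phi[i], expect, atol=1e-10)
        # base value is the cover-weighted no-information expectation
        assert base == pytest.approx(
            _treeshap.expected_value_subset(trees, X.to_numpy()[0], frozenset()))


class TestNullFeatures:
    def test_stump_attributes_only_its_split_feature(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.random((200, 3)), columns=list("abc"))
        y = (X.a > 0.5).astype(float)
        mdl = xgb.XGBRegressor(n_estimators=1, max_depth=1, learning_rate=1.0,
                               n_jobs=1, random_state=0)
        mdl.fit(X, y)
        fm = small_matrix(X.to_numpy(), y.to_numpy(), cols=list("abc"))
        attr = at.attribute(mdl, fm, max_rows=200)
        assert (attr.phi.b == 0).all() and (attr.phi.c == 0).all()
        assert attr.phi.a.abs().max() > 0

    def test_constant_model_has_zero_attributions(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.random((50, 3)), columns=list("abc"))
        y = np.full(50, 1.5)
        mdl = xgb.XGBRegressor(n_estimators=5, max_depth=2, n_jobs=1,
                               random_state=0)
        mdl.fit(X, y)
        fm = small_matrix(X.to_numpy(), y, cols=list("abc"))
        attr = at.attribute(mdl, fm, max_rows=50)
        assert np.abs(attr.phi.to_numpy()).max() < 1e-9
        np.testing.assert_allclose(attr.base_values, 1.5, atol=1e-6)


class TestRanking:
    def make_attr(self, phi: dict):
        df = pd.DataFrame(phi)
        return at.AttributionMatrix(phi=df, base_values=np.zeros(len(df)),
                                    rows=df * 0, predictions=np.zeros(len(df)))

    def test_mean_abs_ordering(self):
        attr = self.make_attr({"A": [1.0, 3.0], "B": [0.5, 0.5]})
        summary = at.rank_features(attr)
        assert summary.Feature.tolist() == ["A", "B"]
        assert summary.mean_abs_shap.tolist() == [2.0, 0.5]
        assert summary["rank"].tolist() == [1, 2]

    def test_all_zero_ties_break_lexicographically(self):
        attr = self.make_attr({"b": [0.0], "a": [0.0], "c": [0.0]})
        summary = at.rank_features(attr)
        assert summary.Feature.tolist() == ["a", "b", "c"]

    def test_mean_abs_nonincreasing_in_rank(self, attr):
        summary = at.rank_features(attr)
        assert (np.diff(summary.mean_abs_shap.to_numpy()) <= 1e-15).all()
        assert sorted(summary["rank"]) == list(range(1, len(summary) + 1))


class TestPlantedRecovery:
    @staticmethod
    @functools.lru_cache(maxsize=None)
    def _run_seed(seed):
        """Train on 4 planted features + 50 pure-noise decoys; return the
        ranking and the attribution matrix."""
        rng = np.random.default_rng(seed)
        n = 1500
        planted = {
            "Zone_PM25": (1.5, "linear"), "TPSA": (3.0, "u"),
            "SBS4": (2.0, "linear"), "SBS18": (-1.0, "linear"),
        }
        cols, data, contrib = [], {}, np.zeros(n)
        for name, (coef, shape) in planted.items():
            x = rng.random(n)
            data[name] = x
            contrib += coef * (4 * (x - 0.5) ** 2 if shape == "u" else x)
            cols.append(name)
        for j in range(50):
            data[f"NOISE_{j:02d}"] = rng.random(n)
        y = contrib + rng.normal(0, 0.3, n)
        X = pd.DataFrame(data)
        fm = small_matrix(X.to_numpy(), y, cols=list(X.columns))
        mdl = gp.train(fm, md.BoosterConfig(n_estimators=150, max_depth=4,
                                            learning_rate=0.1, subsample=0.9,
                                            colsample_bytree=0.9, seed=seed))
        attr = at.attribute(mdl, fm, max_rows=300, seed=seed)
        return at.rank_features(attr), attr

    def test_planted_features_outrank_noise_block(self):
        """All four planted features beat the best decoy in >= 9/10 seeds."""
        wins = 0
        for seed in range(10):
            summary, _ = self._run_seed(seed)
            ranks = summary.set_index("Feature")["rank"]
            best_noise = min(ranks[f] for f in ranks.index if f.startswith("NOISE"))
            if all(ranks[f] < best_noise
                   for f in ("Zone_PM25", "TPSA", "SBS4", "SBS18")):
                wins += 1
        assert wins >= 9

    def test_sign_recovery_in_upper_quartile(self):
        _, attr = self._run_seed(0)
        for feat, positive in (("Zone_PM25", True), ("SBS18", False)):
            x = attr.rows[feat]
            upper = attr.phi[feat][x >= x.quantile(0.75)]
            assert (upper.mean() > 0) == positive


class TestDependence:
    def test_positive_linear_effect_yields_positive_phi_trend(self):
        _, attr = TestPlantedRecovery._run_seed(1)
        dep = at.dependence_data(attr, "Zone_PM25", colour_feature="TPSA")
        rho = stats.spearmanr(dep.value, dep.phi).statistic
        assert rho > 0.8

    def test_negative_effect_yields_negative_trend(self):
        _, attr = TestPlantedRecovery._run_seed(1)
        dep = at.dependence_data(attr, "SBS18")
        assert stats.spearmanr(dep.value, dep.phi).statistic < -0.8
        assert (dep.colour_feature == "SBS4").all()  # conventional pairing

    def test_colour_column_is_the_raw_row_value(self, attr):
        dep = at.dependence_data(attr, "Zone_PM25", colour_feature="MolLogP")
        np.testing.assert_array_equal(dep.colour_value.to_numpy(),
                                      attr.rows.MolLogP.to_numpy())

    def test_unknown_feature_rejected(self, attr):
        with pytest.raises(SchemaError):
            at.dependence_data(attr, "NOT_A_FEATURE")


class TestStability:
    def test_degenerate_identical_rows_give_rho_one(self):
        phi = pd.DataFrame({"A": [3.0] * 20, "B": [1.0] * 20, "C": [0.1] * 20})
        attr = at.AttributionMatrix(phi=phi, base_values=np.zeros(20),
                                    rows=phi * 0, predictions=np.zeros(20))
        rep = at.bootstrap_stability(attr, n_boot=25, k_top=2, seed=0)
        assert np.allclose(rep.spearman_rhos, 1.0)
        assert rep.topk_order_consistent == 25
        assert rep.topk_set_consistent == 25

    def test_default_resample_count_is_100(self, attr):
        rep = at.bootstrap_stability(attr, seed=1)
        assert rep.n_boot == 100 and len(rep.spearman_rhos) == 100
        assert rep.k_top == 10
        assert np.all(np.abs(rep.spearman_rhos) <= 1.0)
        assert rep.topk_order_consistent <= rep.topk_set_consistent <= 100


class TestCompareRankings:
    def make_summary(self, order):
        return pd.DataFrame({"Feature": order,
                             "mean_abs_shap": np.linspace(1, 0.1, len(order)),
                             "rank": np.arange(1, len(order) + 1)})

    def test_identical_orderings_give_rho_one(self):
        s = self.make_summary(list("abcd"))
        rho, deltas = at.compare_rankings(s, s)
        assert rho == 1.0 and (deltas.delta == 0).all()

    def test_reversed_orderings_give_rho_minus_one(self):
        a = self.make_summary(list("abcd"))
        b = self.make_summary(list("dcba"))
        assert at.compare_rankings(a, b)[0] == -1.0

    def test_matches_pearson_on_ranks(self):
        rng = np.random.default_rng(7)
        feats = [f"f{i}" for i in range(12)]
        a = self.make_summary(list(rng.permutation(feats)))
        b = self.make_summary(list(rng.permutation(feats)))
        rho, _ = at.compare_rankings(a, b)
        ra = a.set_index("Feature")["rank"]
        rb = b.set_index("Feature")["rank"].reindex(ra.index)
        expect = np.corrcoef(ra, rb)[0, 1]
        assert rho == pytest.approx(expect, abs=1e-12)

    def test_feature_set_mismatch_rejected(self):
        with pytest.raises(SchemaError):
            at.compare_rankings(self.make_summary(list("abc")),
                                self.make_summary(list("abd")))
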