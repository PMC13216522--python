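"""Feature assembly, tuned gradient boosting, Shapley attributions."""

import numpy as np
import pandas as pd
import pytest
import xgboost as xgb

import screenscape as ss
from screenscape.determinants import (AGE_SHARE_COLS, FEATURES, build_features,
                                      shap_explain, tune_fit)


def synthetic_features(n=400, rng_seed=0, noise=1.0, signal=True):
    """Feature table with a known deterministic outcome surface."""
    rng = np.random.default_rng(rng_seed)
    df = pd.DataFrame({"neighborhood_id": np.arange(n)})
    df["deprivation"] = rng.random(n)
    df["access"] = rng.random(n) * 3
    shares = rng.dirichlet(np.ones(5), size=n)
    for j, c in enumerate(AGE_SHARE_COLS):
        df[c] = shares[:, j]
    df["x"] = rng.random(n) * 1e4
    df["y"] = rng.random(n) * 1e4
    mu = 40 + (15 * df["deprivation"] - 4 * df["access"] if signal else 0.0)
    df["outcome"] = mu + rng.normal(0, noise, n)
    return df


@pytest.fixture(scope="module")
def fitted():
    feats = synthetic_features(n=600, rng_seed=1)
    model, report = tune_fit(feats, n_evals=6, rng_seed=0)
    return feats, model, report


class TestBuildFeatures:
    def test_age_shares_from_final_period_invitations(self, small_canton,
                                                      small_panel, small_spec):
        acc = ss.access_panel(
            small_canton.neighborhoods[["neighborhood_id", "x", "y"]],
            small_canton.centers, small_canton.network,
            small_spec.period_labels)
        feats = build_features(small_panel, acc, small_canton.neighborhoods,
                               small_canton.invitations)
        assert feats.attrs["period"] == max(small_spec.period_labels)
        shares = feats[list(AGE_SHARE_COLS)].to_numpy()
        np.testing.assert_allclose(shares.sum(axis=1), 1.0, atol=1e-9)
        # row count = neighborhoods invited in the final period
        final = small_panel[small_panel["period"]
                            == max(small_spec.period_labels)]
        assert len(feats) == len(final)

    def test_single_band_neighborhood_gets_unit_share(self):
        panel = pd.DataFrame({"neighborhood_id": [0], "period": [2020],
                              "n": [10], "o": [4], "raw_rate": [40.0],
                              "sebs_rate": [40.0]})
        acc = pd.DataFrame({"neighborhood_id": [0], "period": [2020],
                            "access": [1.0]})
        nb = pd.DataFrame({"neighborhood_id": [0], "x": [0.0], "y": [0.0],
                           "deprivation": [0.5]})
        inv = pd.DataFrame({"neighborhood_id": [0] * 10, "period": [2020] * 10,
                            "age_group": ["50-54"] * 10})
        feats = build_features(panel, acc, nb, inv)
        assert feats.loc[0, "share_50_54"] == 1.0
        assert feats[list(AGE_SHARE_COLS)[1:]].iloc[0].sum() == 0.0

    def test_orphan_ids_raise(self):
        panel = pd.DataFrame({"neighborhood_id": [0, 99], "period": 2020,
                              "n": 5, "o": 2, "raw_rate": 40.0,
                              "sebs_rate": 40.0})
        acc = pd.DataFrame({"neighborhood_id": [0], "period": [2020],
                            "access": [1.0]})
        nb = pd.DataFrame({"neighborhood_id": [0], "x": [0.0], "y": [0.0],
                           "deprivation": [0.5]})
        inv = pd.DataFrame({"neighborhood_id": [0], "period": [2020],
                            "age_group": ["50-54"]})
        with pytest.raises(ValueError, match="99"):
            build_features(panel, acc, nb, inv)


class TestTuneFit:
    def test_recovers_deterministic_surface(self, fitted):
        _, _, report = fitted
        assert report.test_r2 >= 0.9
        assert report.n_train == 480 and report.n_test == 120

    def test_pure_noise_has_no_skill(self):
        feats = synthetic_features(n=300, rng_seed=2, signal=False, noise=5.0)
        _, report = tune_fit(feats, n_evals=4, rng_seed=0)
        assert report.test_r2 <= 0.1

    def test_deterministic_given_seed(self):
        feats = synthetic_features(n=200, rng_seed=3)
        _, r1 = tune_fit(feats, n_evals=4, rng_seed=5)
        _, r2 = tune_fit(feats, n_evals=4, rng_seed=5)
        assert r1.best_params == r2.best_params
        assert r1.test_rmse == r2.test_rmse
        np.testing.assert_array_equal(r1.test_index, r2.test_index)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="100"):
            tune_fit(synthetic_features(n=50))

    def test_constant_outcome_rejected(self):
        feats = synthetic_features(n=200, rng_seed=4)
        feats["outcome"] = 3.0
        with pytest.raises(ValueError, match="variance"):
            tune_fit(feats)


class TestShap:
    def test_local_accuracy(self, fitted):
        feats, model, report = fitted
        expl = shap_explain(model, feats, interactions=False)
        pred = model.predict(
            xgb.DMatrix(feats[list(FEATURES)].to_numpy(),
                        feature_names=list(FEATURES)))
        total = expl["values"].sum(axis=1) + expl["base_value"]
        np.testing.assert_allclose(total, pred, atol=1e-4)

    def test_dominant_planted_effect_ranks_first(self, fitted):
        feats, model, _ = fitted
        expl = shap_explain(model, feats, interactions=False)
        imp = expl["importance"]
        assert imp.index[0] == "deprivation"
        assert all(imp["deprivation"] > imp[c] for c in AGE_SHARE_COLS)
        assert all(imp["access"] > imp[c] for c in AGE_SHARE_COLS)

    def test_directional_attributions(self, fitted):
        """Planted +deprivation and −access signs must show up as rank
        correlations between feature value and attribution."""
        from scipy.stats import spearmanr
        feats, model, _ = fitted
        expl = shap_explain(model, feats, interactions=False)
        rho_dep = spearmanr(feats["deprivation"],
                            expl["values"]["deprivation"]).statistic
        rho_acc = spearmanr(feats["access"], expl["values"]["access"]).statistic
        assert rho_dep > 0.9
        assert rho_acc < -0.9

    def test_single_split_stump_attributes_only_to_split_feature(self):
        feats = synthetic_features(n=300, rng_seed=6, noise=0.0)
        X = feats[list(FEATURES)].to_numpy()
        y = (feats["deprivation"] > 0.5).astype(float).to_numpy()
        dm = xgb.DMatrix(X, label=y, feature_names=list(FEATURES))
        booster = xgb.train({"max_depth": 1, "eta": 1.0, "nthread": 1},
                            dm, num_boost_round=1)
        expl = shap_explain(booster, feats, interactions=False)
        nonzero = expl["values"].abs().sum()
        assert nonzero["deprivation"] > 0
        assert nonzero.drop("deprivation").max() == pytest.approx(0.0, abs=1e-7)

    def test_interaction_matrix_shape_and_symmetry(self, fitted):
        feats, model, _ = fitted
        expl = shap_explain(model, feats.head(50), interactions=True)
        mat = expl["interaction_importance"]
        assert mat.shape == (len(FEATURES), len(FEATURES))
        np.testing.assert_allclose(mat.to_numpy(), mat.to_numpy().T, atol=1e-6)

    def test_non_tree_model_rejected(self):
        with pytest.raises(TypeError, match="tree"):
            shap_explain(object(), synthetic_features(n=120))
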