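import numpy as np
import pandas as pd
import pytest

from funsurf import MFPCA, SimulationConfig, simulate_cohort
from funsurf.forest import (
    FeatureEncoder,
    FeatureSchemaError,
    SurvivalForest,
    build_feature_matrix,
    variable_importance,
)


def _ph_data(n=500, beta=0.0, seed=0, n_features=5):
    """Weibull proportional-hazards data with signal on the first feature."""
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.normal(size=(n, n_features)),
        columns=[f"x{j}" for j in range(n_features)],
    )
    eta = beta * X["x0"].to_numpy()
    t = 20.0 * (rng.exponential(size=n) * np.exp(-eta)) ** (1 / 1.3)
    censor = rng.uniform(10, 80, n)
    return X, np.minimum(t, censor), t <= censor


class TestBuildFeatureMatrix:
    def test_variant_a_has_all_baseline_covariates(self, small_cohort):
        cohort, _ = small_cohort
        frame = build_feature_matrix(cohort, variant="A")
        assert frame.shape == (len(cohort), 18)

    def test_variant_b_adds_one_preop_column_per_marker(self, small_cohort):
        cohort, _ = small_cohort
        a = build_feature_matrix(cohort, variant="A")
        b = build_feature_matrix(cohort, variant="B")
        assert b.shape[1] == a.shape[1] + len(cohort.marker_names)
        assert all(f"preop_{m}" in b.columns for m in cohort.marker_names)

    def test_variant_c_requires_scores(self, small_cohort):
        cohort, _ = small_cohort
        with pytest.raises(ValueError, match="requires MFPC scores"):
            build_feature_matrix(cohort, variant="C")

    def test_variant_c_appends_score_columns(self, small_cohort):
        cohort, _ = small_cohort
        scores = MFPCA().fit(cohort).transform(cohort)
        frame = build_feature_matrix(cohort, scores, variant="C")
        assert "mfpc_1" in frame.columns
        assert "sparse_flag" not in frame.columns


class TestFeatureEncoder:
    def test_unseen_category_maps_to_zero_row_with_warning(self):
        train = pd.DataFrame({"site": ["colon", "rectum", "colon"], "age": [60, 55, 70]})
        enc = FeatureEncoder().fit(train)
        new = pd.DataFrame({"site": ["appendix"], "age": [50]})
        with pytest.warns(UserWarning, match="unseen"):
            out = enc.transform(new)
        assert out[["site=colon", "site=rectum"]].to_numpy().sum() == 0

    def test_missing_values_imputed_with_training_median(self):
        train = pd.DataFrame({"age": [50.0, 60.0, 70.0]})
        enc = FeatureEncoder().fit(train)
        out = enc.transform(pd.DataFrame({"age": [np.nan]}))
        assert out["age"].iloc[0] == 60.0

    def test_schema_mismatch_rejected(self):
        enc = FeatureEncoder().fit(pd.DataFrame({"a": [1.0]}))
        with pytest.raises(FeatureSchemaError):
            enc.transform(pd.DataFrame({"b": [1.0]}))


class TestSurvivalForest:
    def test_null_features_give_chance_level_oob(self):
        X, t, e = _ph_data(n=500, beta=0.0, seed=1)
        f = SurvivalForest(n_trees=200, random_state=0).fit(X, t, e)
        assert 0.45 <= f.oob_cindex_ <= 0.55

    def test_strong_signal_gives_high_oob(self):
        X, t, e = _ph_data(n=500, beta=1.2, seed=2)
        f = SurvivalForest(n_trees=200, random_state=0).fit(X, t, e)
        assert f.oob_cindex_ >= 0.7

    def test_same_seed_identical_predictions(self):
        X, t, e = _ph_data(n=200, beta=0.5, seed=3)
        grid = np.array([6.0, 12.0, 24.0])
        a = SurvivalForest(n_trees=50, random_state=7).fit(X, t, e)
        b = SurvivalForest(n_trees=50, random_state=7).fit(X, t, e)
        np.testing.assert_array_equal(
            a.predict_survival(X, grid), b.predict_survival(X, grid)
        )

    def test_survival_curves_monotone_in_unit_interval(self):
        X, t, e = _ph_data(n=200, beta=0.5, seed=4)
        f = SurvivalForest(n_trees=50, random_state=0).fit(X, t, e)
        grid = np.linspace(0, 60, 40)
        S = f.predict_survival(X, grid)
        assert np.all(S >= 0) and np.all(S <= 1)
        assert np.all(np.diff(S, axis=1) <= 1e-12)
        assert np.allclose(S[:, 0], 1.0)  # S(0) = 1

    def test_duplicated_rows_get_identical_curves(self):
        X, t, e = _ph_data(n=100, beta=0.5, seed=5)
        f = SurvivalForest(n_trees=50, random_state=0).fit(X, t, e)
        dup = pd.concat([X.iloc[[3]], X.iloc[[3]]])
        S = f.predict_survival(dup, np.array([6.0, 24.0]))
        np.testing.assert_array_equal(S[0], S[1])

    def test_degenerate_forest_reproduces_km_and_na_of_training_sample(self):
        """A single root-only tree on the full sample is the training-sample
        Kaplan-Meier (survival) / Nelson-Aalen (cumulative hazard)."""
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        e = np.array([True, True, False, True, False])
        X = pd.DataFrame({"x": np.zeros(5)})
        f = SurvivalForest(
            n_trees=1, bootstrap=False, min_samples_leaf=5, random_state=0
        ).fit(X, t, e)
        S = f.predict_survival(X.iloc[[0]], t)[0]
        km = np.array([4 / 5, 4 / 5 * 3 / 4, 4 / 5 * 3 / 4,
                       4 / 5 * 3 / 4 * 1 / 2, 4 / 5 * 3 / 4 * 1 / 2])
        np.testing.assert_allclose(S, km, atol=1e-10)
        chf = f.model_.predict_cumulative_hazard_function(
            X.to_numpy()[:1], return_array=True
        )[0]
        na = np.array([1 / 5, 1 / 5 + 1 / 4, 1 / 5 + 1 / 4,
                       1 / 5 + 1 / 4 + 1 / 2, 1 / 5 + 1 / 4 + 1 / 2])
        np.testing.assert_allclose(chf, na, atol=1e-10)

    def test_all_censored_outcome_rejected(self):
        X, t, _ = _ph_data(n=50, seed=6)
        with pytest.raises(ValueError, match="all-censored"):
            SurvivalForest(n_trees=10).fit(X, t, np.zeros(50, dtype=bool))

    def test_schema_mismatch_lists_columns(self):
        X, t, e = _ph_data(n=60, seed=7)
        f = SurvivalForest(n_trees=10, random_state=0).fit(X, t, e)
        bad = X.rename(columns={"x0": "z0"})
        with pytest.raises(FeatureSchemaError, match="x0"):
            f.predict_survival(bad, np.array([6.0]))


@pytest.fixture(scope="module")
def signal_fit():
    X, t, e = _ph_data(n=400, beta=1.2, seed=8)
    X["constant"] = 0.0  # never split on
    f = SurvivalForest(n_trees=200, random_state=0).fit(X, t, e)
    return f, X, t, e


class TestVariableImportance:
    def test_signal_feature_ranks_first(self, signal_fit):
        f, X, t, e = signal_fit
        table = variable_importance(f, X, t, e, n_permutations=3, seed=0)
        assert table.iloc[0]["feature"] == "x0"
        assert table.iloc[0]["vimp"] > 0

    def test_never_split_feature_has_exactly_zero_vimp(self, signal_fit):
        f, X, t, e = signal_fit
        table = variable_importance(f, X, t, e, n_permutations=2, seed=0)
        assert table.set_index("feature").loc["constant", "vimp"] == 0.0

    def test_noise_features_near_zero(self, signal_fit):
        f, X, t, e = signal_fit
        table = variable_importance(f, X, t, e, n_permutations=5, seed=1)
        noise = table.set_index("feature").loc[["x3", "x4"], "vimp"]
        assert (noise.abs() < 0.05).all()

    def test_grouped_importance(self, signal_fit):
        f, X, t, e = signal_fit
        groups = {"signal": ["x0"], "rest": ["x1", "x2", "x3", "x4", "constant"]}
        table = variable_importance(f, X, t, e, n_permutations=3, seed=0,
                                    groups=groups)
        assert set(table["feature"]) == {"signal", "rest"}
        assert table.iloc[0]["feature"] == "signal"

    def test_invalid_permutation_count_rejected(self, signal_fit):
        f, X, t, e = signal_fit
        with pytest.raises(ValueError):
            variable_importance(f, X, t, e, n_permutations=0)
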