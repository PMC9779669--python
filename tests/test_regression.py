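"""Standardization, repeated-split scoring, selection and ranking."""

import itertools

import numpy as np
import pandas as pd
import pytest

from tfnoise.regression import (
    NoiseRegression,
    _aic,
    filter_features,
    multi_feature_model,
    rank_features,
    select_features,
    single_feature_model,
    standardize,
    stepwise_aic,
)
from tfnoise.synthetic import SyntheticFeatureSpec, gen_feature_table


class TestStandardize:
    def test_hand_computed_column(self):
        X = pd.DataFrame({"f": [1.0, 2.0, 3.0]})
        out, stats = standardize(X)
        assert np.allclose(out["f"], [-1, 0, 1])  # sample sd of {1,2,3} is 1

    def test_constant_column_dropped_with_warning(self):
        X = pd.DataFrame({"f": [1.0, 2.0, 3.0], "const": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="constant"):
            out, _ = standardize(X)
        assert list(out.columns) == ["f"]

    def test_idempotent(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(50, 3)), columns=list("abc"))
        once, _ = standardize(X)
        twice, _ = standardize(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_training_stats_reapplied_to_test_split(self):
        X = pd.DataFrame({"f": [0.0, 2.0, 4.0]})
        _, stats = standardize(X)
        test = pd.DataFrame({"f": [6.0]})
        out, _ = standardize(test, stats_from=stats)
        assert out.loc[0, "f"] == pytest.approx((6.0 - 2.0) / 2.0)


class TestRepeatedSplits:
    def test_exact_linear_relation_scores_one(self):
        x = np.random.default_rng(1).normal(size=100)
        X = pd.DataFrame({"f": x})
        y = pd.Series(3 * x)
        rep = single_feature_model(X, y, "f", n_repeats=20, seed=0)
        assert rep.fraction_variation_explained == pytest.approx(1.0)
        assert rep.predicted_r2 == pytest.approx(1.0)
        assert rep.coefficients["f"] == pytest.approx(3.0)

    def test_null_feature_predicted_r2_near_zero(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"f": rng.normal(size=500)})
        y = pd.Series(rng.normal(size=500))
        rep = single_feature_model(X, y, "f", n_repeats=200, seed=0)
        assert abs(rep.predicted_r2) < 0.05
        # training R2 >= predicted R2 in expectation on nulls (overfitting direction)
        assert rep.fraction_variation_explained > rep.predicted_r2

    def test_bit_reproducible_given_seed(self, feature_data):
        X, y, _ = feature_data
        a = multi_feature_model(X, y, list(X.columns[:3]), n_repeats=25, seed=42)
        b = multi_feature_model(X, y, list(X.columns[:3]), n_repeats=25, seed=42)
        assert a.fraction_variation_explained == b.fraction_variation_explained
        assert a.predicted_r2 == b.predicted_r2

    def test_two_orthogonal_features_add_their_variance(self):
        spec = SyntheticFeatureSpec(
            n_genes=4000, n_features=2, orthogonalize=True, seed=3,
            true_coefficients=np.array([1.0, 1.0]),
        )
        # signal variance 2, noise variance 3: each feature explains 1/5 = 0.2
        spec.noise_sd = np.sqrt(3.0)
        X, y, _ = gen_feature_table(spec)
        single = single_feature_model(X, y, "f000", n_repeats=50, seed=0)
        both = multi_feature_model(X, y, ["f000", "f001"], n_repeats=50, seed=0)
        assert single.fraction_variation_explained == pytest.approx(0.2, abs=0.03)
        assert both.fraction_variation_explained == pytest.approx(0.4, abs=0.03)

    def test_random_forest_engine_reports_same_statistics(self, feature_data):
        X, y, _ = feature_data
        rep = multi_feature_model(
            X, y, list(X.columns[:3]), n_repeats=3, engine="random_forest",
            seed=0, rf_kwargs={"n_estimators": 20},
        )
        assert rep.engine == "random_forest"
        assert np.isfinite(rep.predicted_r2)

    def test_too_few_cases_rejected(self):
        X = pd.DataFrame({"f": np.arange(10.0)})
        y = pd.Series(np.arange(10.0))
        with pytest.raises(ValueError):
            single_feature_model(X, y, "f")


class TestSelection:
    def test_lasso_keeps_true_support(self):
        spec = SyntheticFeatureSpec(n_genes=1000, n_features=30, seed=4, orthogonalize=True)
        spec.noise_sd = spec.noise_sd_for_r2(0.5)
        X, y, beta = gen_feature_table(spec)
        selected = select_features(X, y, method="lasso", seed=0)
        assert set(X.columns[beta != 0]) <= set(selected)

    def test_collinear_duplicate_not_both_selected(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=500)
        X = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=500)})
        y = pd.Series(x + rng.normal(0, 0.5, size=500))
        selected = select_features(X, y, method="lasso", seed=0)
        assert not {"a", "b"} <= set(selected)

    def test_ridge_significance_selection(self):
        spec = SyntheticFeatureSpec(n_genes=800, n_features=20, seed=6)
        spec.noise_sd = spec.noise_sd_for_r2(0.5)
        X, y, beta = gen_feature_table(spec)
        selected = select_features(X, y, method="ridge", seed=0)
        assert set(X.columns[beta != 0]) <= set(selected)
        assert len(selected) <= 12  # nulls mostly rejected


class TestStepwiseAIC:
    def test_single_true_feature_recovered_noiselessly(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.normal(size=(200, 5)), columns=[f"f{i}" for i in range(5)])
        y = pd.Series(2.0 * X["f2"])
        assert stepwise_aic(X, y, list(X.columns)) == ["f2"]

    def test_returned_model_beats_full_model_aic(self, feature_data):
        X, y, _ = feature_data
        chosen = stepwise_aic(X, y, list(X.columns))
        assert _aic(X, y, tuple(sorted(chosen))) <= _aic(X, y, tuple(sorted(X.columns))) + 1e-9

    def test_matches_exhaustive_best_subset(self):
        spec = SyntheticFeatureSpec(
            n_genes=250, n_features=7, seed=8,
            true_coefficients=np.array([1.0, 0.7, 0, 0, 0, 0, 0]), noise_sd=1.0,
        )
        X, y, _ = gen_feature_table(spec)
        got = tuple(stepwise_aic(X, y, list(X.columns)))
        best = min(
            (_aic(X, y, tuple(sorted(s))), tuple(sorted(s)))
            for r in range(8)
            for s in itertools.combinations(X.columns, r)
        )[1]
        assert got == best


class TestFilters:
    def test_null_feature_removed_planted_feature_kept(self):
        spec = SyntheticFeatureSpec(
            n_genes=3000, n_features=2, seed=9,
            true_coefficients=np.array([1.0, 0.0]),
        )
        spec.noise_sd = spec.noise_sd_for_r2(0.1)
        X, y, _ = gen_feature_table(spec)
        kept = filter_features(X, y, mode="correlation")
        assert list(kept.columns) == ["f000"]
        kept = filter_features(X, y, mode="impact", n_repeats=30, seed=0)
        assert list(kept.columns) == ["f000"]

    def test_impact_threshold_defaults(self):
        import inspect

        sig = inspect.signature(filter_features)
        assert sig.parameters["min_fraction"].default == 0.05
        assert sig.parameters["min_predicted_r2"].default == 0.05


class TestRanking:
    def test_identical_responses_have_rank_correlation_one(self, feature_data):
        X, y, _ = feature_data
        out = rank_features(X.iloc[:, :5], y, y, n_repeats=10, seed=0)
        assert out["rank_correlation"] == pytest.approx(1.0)

    def test_shared_generative_features_give_positive_rank_correlation(self):
        spec = SyntheticFeatureSpec(n_genes=1500, n_features=8, seed=10)
        spec.noise_sd = spec.noise_sd_for_r2(0.4)
        X, y1, beta = gen_feature_table(spec)
        rng = np.random.default_rng(11)
        y2 = pd.Series(
            X.to_numpy() @ beta + rng.normal(0, spec.noise_sd, size=len(y1)), index=y1.index
        )
        out = rank_features(X, y1, y2, n_repeats=20, seed=0)
        assert out["rank_correlation"] > 0.5


class TestNoiseRegressionModel:
    def test_full_protocol_recovers_planted_r2(self):
        spec = SyntheticFeatureSpec(n_genes=1500, n_features=40, seed=12, orthogonalize=True)
        spec.noise_sd = spec.noise_sd_for_r2(0.3)
        X, y, beta = gen_feature_table(spec)
        results = NoiseRegression(X, y).fit(select="lasso", stepwise=True, n_repeats=50, seed=0)
        assert set(X.columns[beta != 0]) <= set(results.selected)
        assert results.fraction_variation_explained == pytest.approx(0.3, abs=0.05)
        assert "fraction of variation explained" in results.summary()
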