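"""Regression, thresholding, splitting, stepwise selection, tree and forest."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from footstrike import (
    PUBLISHED_MR,
    ClassThresholds,
    classify_fsp,
    fit_ctree,
    fit_forest,
    fit_stepwise_mr,
    predict_class,
    split_dataset,
)
from footstrike.errors import ConfigError, InputError
from footstrike.features import FEATURE_COLUMNS

from _reference import CLASS_FEATURE_STATS


def feature_frame(rows: dict | list[dict]) -> pd.DataFrame:
    if isinstance(rows, dict):
        rows = [rows]
    return pd.DataFrame(rows)


class TestPublishedMR:
    def test_intercept_at_origin(self):
        """With every predictor at zero the prediction is the intercept."""
        zeros = feature_frame({c: 0.0 for c in PUBLISHED_MR.predictors})
        assert PUBLISHED_MR.predict(zeros)[0] == pytest.approx(-89.2)

    @settings(max_examples=25, derandomize=True)
    @given(lam=st.floats(min_value=0.0, max_value=1.0))
    def test_affinity(self, lam):
        """eval(lam*a + (1-lam)*b) == lam*eval(a) + (1-lam)*eval(b)."""
        rng = np.random.default_rng(0)
        a = {c: rng.uniform(0, 1) for c in PUBLISHED_MR.predictors}
        b = {c: rng.uniform(0, 1) for c in PUBLISHED_MR.predictors}
        mix = {c: lam * a[c] + (1 - lam) * b[c] for c in a}
        ya, yb, ym = (PUBLISHED_MR.predict(feature_frame(d))[0] for d in (a, b, mix))
        assert ym == pytest.approx(lam * ya + (1 - lam) * yb, abs=1e-9)

    def test_rearfoot_feature_vector_classifies_rf(self):
        """A heavily aft-loaded step maps through the equation to RF."""
        means = {k: v[0] for k, v in CLASS_FEATURE_STATS["RF"].items()}
        means["ir_aft"] = 0.9
        pred = PUBLISHED_MR.predict(feature_frame(means))[0]
        assert classify_fsp(pred) == "RF"

    def test_missing_feature_rejected(self):
        with pytest.raises(InputError):
            PUBLISHED_MR.predict(feature_frame({"ir_aft": 0.5}))


class TestClassifyFsp:
    @pytest.mark.parametrize(
        "fsa,expected",
        [(-1.6, "MF"), (8.0, "MF"), (-1.6000001, "FF"), (8.000001, "RF"),
         (24.9, "RF"), (-10.2, "FF"), (3.0, "MF")],
    )
    def test_boundaries(self, fsa, expected):
        assert classify_fsp(fsa) == expected

    @settings(max_examples=100, derandomize=True)
    @given(fsa=st.floats(min_value=-90, max_value=90, allow_nan=False))
    def test_partitions_the_line(self, fsa):
        """Every finite angle belongs to exactly one class."""
        assert classify_fsp(fsa) in ("FF", "MF", "RF")

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ConfigError):
            ClassThresholds(ff_upper=9.0, rf_lower=8.0)


class TestSplitDataset:
    def test_published_sizes(self):
        """3489 records at 70% -> 2442 train / 1047 test."""
        df = pd.DataFrame({"x": np.arange(3489)})
        train, test = split_dataset(df, 0.7, seed=0)
        assert (len(train), len(test)) == (2442, 1047)

    def test_small_split(self):
        train, test = split_dataset(list(range(10)), 0.7, seed=3)
        assert (len(train), len(test)) == (7, 3)

    def test_partition_is_disjoint_and_exhaustive(self):
        df = pd.DataFrame({"x": np.arange(101)})
        train, test = split_dataset(df, 0.7, seed=5)
        combined = sorted(train["x"].tolist() + test["x"].tolist())
        assert combined == list(range(101))

    def test_seeded_determinism(self):
        df = pd.DataFrame({"x": np.arange(50)})
        a1, b1 = split_dataset(df, 0.7, seed=9)
        a2, b2 = split_dataset(df, 0.7, seed=9)
        assert a1["x"].tolist() == a2["x"].tolist()
        assert b1["x"].tolist() == b2["x"].tolist()


def synthetic_regression(rng, n, coefs: dict, sigma: float) -> pd.DataFrame:
    """Feature table with independent predictors and a known linear response."""
    cols = {}
    for c in FEATURE_COLUMNS:
        lo, hi = (1.0, 4.5) if c.startswith("ln_") else (0.0, 1.0)
        cols[c] = rng.uniform(lo, hi, n)
    df = pd.DataFrame(cols)
    y = np.zeros(n)
    for c, beta in coefs.items():
        y += beta * df[c].to_numpy()
    df["true_fsa_deg"] = y + sigma * rng.standard_normal(n)
    return df


class TestStepwiseMR:
    def test_recovers_a_planted_three_predictor_model(self, rng):
        coefs = {"ir_aft": 40.0, "pf_fore": -25.0, "rfd_aft": 15.0}
        df = synthetic_regression(rng, 2000, coefs, sigma=1.0)
        fit = fit_stepwise_mr(df)
        assert sorted(fit.selected) == sorted(coefs)
        for c, beta in coefs.items():
            assert fit.coefficients[c] == pytest.approx(beta, rel=0.05)

    def test_null_response_selects_little(self):
        """Forward entry at p<=0.05 over 10 candidates admits a noise variable
        in a minority of replicates (P(all p>0.05) ~ 0.95**10 ~ 0.60); the
        empty model is the majority outcome and selections stay rare."""
        rng = np.random.default_rng(11)
        n_empty, n_selected = 0, []
        for _ in range(20):
            df = synthetic_regression(rng, 2000, {}, sigma=5.0)
            fit = fit_stepwise_mr(df)
            n_empty += not fit.selected
            n_selected.append(len(fit.selected))
        assert n_empty >= 10
        assert np.mean(n_selected) < 1.0

    def test_noiseless_linear_response_is_exact(self, rng):
        df = synthetic_regression(rng, 500, {"ir_aft": 30.0, "pf_aft": -8.0},
                                  sigma=0.0)
        fit = fit_stepwise_mr(df)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)
        assert fit.resid_se == pytest.approx(0.0, abs=1e-6)

    def test_collinear_candidate_is_dropped(self, rng):
        """Of two perfectly complementary shares, exactly one can enter; the
        other is reported as collinear rather than crashing the fit."""
        df = synthetic_regression(rng, 500, {"ir_aft": 30.0}, sigma=1.0)
        df["ir_fore"] = 1.0 - df["ir_aft"]  # exact complement
        fit = fit_stepwise_mr(df)
        pair = {"ir_aft", "ir_fore"}
        assert len(pair & set(fit.selected)) == 1
        assert len(pair & set(fit.dropped_collinear)) == 1

    def test_fit_statistics_are_consistent(self, rng):
        df = synthetic_regression(rng, 800, {"ir_aft": 40.0, "rfd_aft": 12.0},
                                  sigma=2.0)
        fit = fit_stepwise_mr(df)
        assert 0 <= fit.adj_r2 <= fit.r2 <= 1
        assert fit.df_resid == fit.n - (len(fit.selected) + 1)
        assert fit.bic > fit.aic  # ln(800) > 2 penalizes harder


class TestConditionalInferenceTree:
    def test_separable_clusters_yield_single_root_split(self):
        """Two well-separated response clusters on one feature: depth-1 tree
        with the cut inside the gap."""
        n = 60
        x = np.concatenate([np.linspace(0.0, 0.3, n), np.linspace(0.7, 1.0, n)])
        df = pd.DataFrame({c: 0.5 for c in FEATURE_COLUMNS}, index=range(2 * n))
        df["rfd_aft"] = x
        df["true_fsa_deg"] = np.where(x < 0.5, -10.0, 25.0)
        tree = fit_ctree(df, task="predict")
        assert tree.depth == 1
        assert tree.first_split_feature == "rfd_aft"
        assert 0.3 < tree.root.threshold < 0.7

    def test_pure_noise_rarely_splits(self):
        """The Bonferroni-adjusted alpha=0.01 gate keeps noise roots as leaves."""
        rng = np.random.default_rng(5)
        roots_are_leaves = 0
        for _ in range(20):
            df = pd.DataFrame(rng.uniform(0, 1, (200, 10)), columns=FEATURE_COLUMNS)
            df["true_fsa_deg"] = rng.normal(0, 5, 200)
            tree = fit_ctree(df, task="predict")
            roots_are_leaves += tree.root.is_leaf
        assert roots_are_leaves >= 19

    def test_depth_caps_and_significant_splits(self, feature_table):
        pred = fit_ctree(feature_table, task="predict")
        clf = fit_ctree(feature_table, task="classify")
        assert pred.depth <= 8
        assert clf.depth <= 6

        def check(node):
            if not node.is_leaf:
                assert node.p_adjusted <= 0.01
                check(node.left)
                check(node.right)

        check(pred.root)
        check(clf.root)

    def test_first_split_is_a_class_separating_share(self, feature_table):
        """The classification root splits on one of the fore/aft share
        features (the published first splitter is the aft loading-rate share;
        the winner among these near-interchangeable shares is recorded, not
        enforced)."""
        clf = fit_ctree(feature_table, task="classify")
        assert not clf.root.is_leaf
        separating = {"ir_fore", "ir_aft", "ir_fore_0_33", "ir_aft_0_33",
                      "pf_fore", "pf_aft", "rfd_fore", "rfd_aft"}
        assert clf.first_split_feature in separating

    def test_classification_leaves_predict_majority(self, feature_table):
        clf = fit_ctree(feature_table, task="classify")
        preds = clf.predict(feature_table)
        assert set(preds) <= {"RF", "MF", "FF"}
        agree = np.mean(preds == feature_table["true_class"].to_numpy())
        assert agree > 0.9  # classes are well separated in feature space

    def test_json_round_trip(self, feature_table):
        from footstrike.ctree import TreeModel

        tree = fit_ctree(feature_table, task="predict")
        clone = TreeModel.from_dict(tree.to_dict())
        np.testing.assert_allclose(clone.predict(feature_table),
                                   tree.predict(feature_table))


class TestRandomForest:
    def test_oob_error_tracks_holdout(self, feature_table):
        """OOB misclassification is within 3 points of held-out error."""
        train, test = split_dataset(feature_table, 0.7, seed=2)
        forest = fit_forest(train, task="classify", n_trees=200,
                            candidate_grid=(3,), seed=0)
        holdout = 1.0 - np.mean(forest.predict(test) == test["true_class"].to_numpy())
        assert abs(forest.oob_error - holdout) <= 0.03

    def test_single_informative_feature_dominates_importance(self, rng):
        df = pd.DataFrame(rng.uniform(0, 1, (400, 10)), columns=FEATURE_COLUMNS)
        df["true_fsa_deg"] = 30 * df["pf_aft"] + 0.5 * rng.standard_normal(400)
        forest = fit_forest(df, task="predict", n_trees=100, candidate_grid=(3,),
                            seed=1)
        assert forest.importances.idxmax() == "pf_aft"

    def test_regression_forest_averages_its_trees(self, feature_table):
        forest = fit_forest(feature_table, task="predict", n_trees=3,
                            candidate_grid=(3,), seed=4)
        X = feature_table[list(forest.features)].to_numpy()
        per_tree = np.column_stack([t.predict(X) for t in forest.estimator.estimators_])
        np.testing.assert_allclose(forest.predict(feature_table),
                                   per_tree.mean(axis=1), rtol=1e-9)

    def test_predict_class_routes_through_thresholds(self, feature_table):
        forest = fit_forest(feature_table, task="predict", n_trees=50,
                            candidate_grid=(3,), seed=6)
        labels = predict_class(forest, feature_table)
        fsa = forest.predict(feature_table)
        np.testing.assert_array_equal(labels, classify_fsp(fsa))
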