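"""Segmentation, features, evaluation metrics and classifier training."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import cohen_kappa_score

from cahow.classify import (
    FEATURE_NAMES,
    ClassifierConfig,
    cohens_kappa,
    evaluate,
    featurize,
    features_table,
    segment,
    train_classifier,
    variable_importance,
)
from cahow.signal_metrics import compute_metrics
from cahow.synthetic import gen_accel, gen_training_segments
from cahow.taxonomy import collapse_modes

SMALL_CONFIG = ClassifierConfig(
    cv_folds=3, cv_repeats=1, grid_size=4, rfe_sizes=(8, 14, 36),
    n_estimators=50, seed=0,
)


def metric_frame(n, rate=25.0, start="2023-02-01"):
    idx = pd.date_range(start, periods=n, freq=pd.Timedelta(seconds=1 / rate))
    rng = np.random.default_rng(0)
    df = pd.DataFrame(
        {c: rng.normal(0, 1, n) for c in
         ("surge", "sway", "heave", "dyn_surge", "dyn_sway", "dyn_heave",
          "pitch", "roll", "vedba", "vesba", "temp_c")},
        index=idx,
    )
    df["wingbeat"] = False
    return df


class TestSegment:
    def test_exact_multiple_of_window(self):
        assert len(segment(metric_frame(150 * 25))) == 10

    def test_trailing_partial_window_dropped(self):
        assert len(segment(metric_frame(155 * 25))) == 10

    def test_windows_never_straddle_gaps(self):
        a = metric_frame(20 * 25)
        b = metric_frame(20 * 25, start="2023-02-01 01:00:00")
        segs = segment(pd.concat([a, b]))
        assert len(segs) == 2
        for s in segs:
            dt = np.diff(s.index.to_numpy()).astype("timedelta64[ms]").astype(int)
            assert np.all(dt == 40)

    def test_too_short_block_rejected(self):
        with pytest.raises(ValueError):
            segment(metric_frame(100))


class TestFeaturize:
    def test_exactly_36_named_features(self):
        feats = featurize(metric_frame(375))
        assert len(feats) == 36
        assert set(feats) == set(FEATURE_NAMES)
        # the five headline importance variables must exist by name
        for name in ("vedba_mean", "vedba_q90", "dyn_sway_mean",
                     "dyn_heave_mean", "heave_iqr"):
            assert name in feats

    def test_constant_channels(self):
        df = metric_frame(375)
        for c in df.columns:
            if c != "wingbeat":
                df[c] = 0.7
        feats = featurize(df)
        assert feats["vedba_iqr"] == 0.0
        assert feats["vedba_mean"] == pytest.approx(0.7)

    def test_wingbeat_sum_counts_flags(self):
        df = metric_frame(375)
        df["wingbeat"] = False
        df.iloc[:12, df.columns.get_loc("wingbeat")] = True
        assert featurize(df)["wingbeat_sum"] == 12

    def test_quantiles_match_sort_oracle(self):
        df = metric_frame(375)
        x = np.sort(df["vedba"].to_numpy())
        # brute-force linear-interpolation quantile
        def q(p):
            h = (len(x) - 1) * p
            lo = int(np.floor(h))
            return x[lo] + (h - lo) * (x[min(lo + 1, len(x) - 1)] - x[lo])
        feats = featurize(df)
        assert feats["vedba_q10"] == pytest.approx(q(0.10), abs=1e-9)
        assert feats["vedba_q90"] == pytest.approx(q(0.90), abs=1e-9)

    def test_missing_channel_rejected(self):
        with pytest.raises(ValueError):
            featurize(metric_frame(375).drop(columns=["vedba"]))


class TestKappa:
    def test_hand_worked_two_class_matrix(self):
        # confusion [[45, 5], [15, 35]]: p_o = 0.8, p_e = 0.5
        y_true = ["a"] * 50 + ["b"] * 50
        y_pred = ["a"] * 45 + ["b"] * 5 + ["a"] * 15 + ["b"] * 35
        rep = evaluate(y_true, y_pred)
        assert rep.accuracy == pytest.approx(0.80)
        assert rep.kappa == pytest.approx(0.60)

    def test_perfect_predictions(self):
        rep = evaluate(["a", "b", "c"] * 10, ["a", "b", "c"] * 10)
        assert rep.accuracy == 1.0
        assert rep.kappa == 1.0
        assert np.all(rep.per_class["balanced_accuracy"] == 1.0)

    def test_single_class_predictions_are_chance(self):
        y_true = ["a"] * 50 + ["b"] * 50
        rep = evaluate(y_true, ["a"] * 100)
        assert rep.accuracy == pytest.approx(0.5)
        assert rep.kappa == pytest.approx(0.0)

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 10_000))
    def test_matches_sklearn_on_random_labelings(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(10, 200)
        k = rng.integers(2, 6)
        y_true = rng.integers(0, k, n)
        y_pred = rng.integers(0, k, n)
        if len(np.unique(y_true)) < 2:
            return
        assert cohens_kappa(y_true, y_pred) == pytest.approx(
            cohen_kappa_score(y_true, y_pred), abs=1e-12
        )

    def test_balanced_accuracy_matches_brute_force(self, rng):
        y_true = rng.integers(0, 3, 300)
        y_pred = rng.integers(0, 3, 300)
        rep = evaluate(y_true, y_pred)
        for lab in (0, 1, 2):
            tp = np.sum((y_true == lab) & (y_pred == lab))
            fn = np.sum((y_true == lab) & (y_pred != lab))
            fp = np.sum((y_true != lab) & (y_pred == lab))
            tn = np.sum((y_true != lab) & (y_pred != lab))
            want = 0.5 * (tp / (tp + fn) + tn / (tn + fp))
            assert rep.per_class.loc[lab, "balanced_accuracy"] == pytest.approx(want)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            evaluate(["a", "b"], ["a", "z"], labels=["a", "b"])


class TestCollapseModes:
    def test_class_to_mode_mapping(self):
        assert collapse_modes("flying-flap-glide") == "flying"
        assert collapse_modes("water-inactive") == "water"
        assert collapse_modes("burrow-still") == "burrow"

    def test_mode_accuracy_never_below_class_accuracy(self, rng):
        classes = ["burrow-still", "burrow-active", "water-active",
                   "water-inactive", "flying-flap-glide",
                   "flying-dynamic-soaring"]
        y_true = rng.choice(classes, 400)
        y_pred = rng.choice(classes, 400)
        class_acc = evaluate(y_true, y_pred).accuracy
        mode_acc = evaluate(collapse_modes(y_true), collapse_modes(y_pred)).accuracy
        assert mode_acc >= class_acc

    def test_within_mode_confusions_collapse_to_agreement(self):
        y_true = ["flying-flap-glide"] * 50 + ["water-active"] * 50
        y_pred = ["flying-dynamic-soaring"] * 50 + ["water-inactive"] * 50
        assert evaluate(y_true, y_pred).accuracy == 0.0
        assert evaluate(collapse_modes(y_true), collapse_modes(y_pred)).accuracy == 1.0


@pytest.fixture(scope="module")
def small_table():
    return gen_training_segments(n_per_bird=36, n_birds=4, seed=21)


class TestTraining:
    def test_separable_classes_classified_accurately(self, small_table):
        res = train_classifier(small_table, SMALL_CONFIG)
        assert res.report.accuracy >= 0.90
        assert res.mode_report.accuracy >= res.report.accuracy

    def test_training_is_deterministic(self, small_table):
        r1 = train_classifier(small_table, SMALL_CONFIG)
        r2 = train_classifier(small_table, SMALL_CONFIG)
        assert r1.model.selected_features_ == r2.model.selected_features_
        feat_cols = [c for c in small_table.columns
                     if c not in ("label", "bird", "start")]
        assert np.array_equal(
            r1.model.predict(small_table[feat_cols]),
            r2.model.predict(small_table[feat_cols]),
        )

    def test_split_has_no_train_validation_overlap(self, small_table):
        res = train_classifier(small_table, SMALL_CONFIG)
        assert len(np.intersect1d(res.train_index, res.valid_index)) == 0
        assert len(res.train_index) + len(res.valid_index) == len(small_table)

    def test_prediction_invariant_to_column_order(self, small_table):
        res = train_classifier(small_table, SMALL_CONFIG)
        feat_cols = [c for c in small_table.columns
                     if c not in ("label", "bird", "start")]
        X = small_table[feat_cols]
        shuffled = X[list(reversed(feat_cols))]
        assert np.array_equal(res.model.predict(X), res.model.predict(shuffled))

    def test_indistinguishable_classes_score_near_chance(self, rng):
        # identical feature distributions for two labels: kappa ~ 0
        X = pd.DataFrame(rng.normal(0, 1, (200, 6)),
                         columns=[f"f{i}" for i in range(6)])
        y = np.array(["a", "b"] * 100)
        df = X.copy()
        df["label"] = y
        cfg = ClassifierConfig(cv_folds=3, cv_repeats=1, grid_size=2,
                               rfe_sizes=(3, 6), n_estimators=30, seed=1)
        res = train_classifier(df, cfg)
        assert abs(res.report.kappa) < 0.35

    def test_single_class_input_rejected(self):
        df = pd.DataFrame({"f0": np.arange(10.0), "label": ["a"] * 10})
        with pytest.raises(ValueError):
            train_classifier(df, SMALL_CONFIG)


class TestVariableImportance:
    def test_informative_feature_ranks_first(self, rng):
        n = 300
        X = pd.DataFrame(rng.normal(0, 1, (n, 5)),
                         columns=[f"f{i}" for i in range(5)])
        y = (X["f2"] > 0).map({True: "a", False: "b"}).to_numpy()
        df = X.copy()
        df["label"] = y
        cfg = ClassifierConfig(cv_folds=3, cv_repeats=1, grid_size=2,
                               rfe_sizes=(5,), n_estimators=50, seed=2)
        res = train_classifier(df, cfg)
        imp = variable_importance(res.model, X, y)
        assert imp.index[0] == "f2"
        assert imp.iloc[0] == pytest.approx(100.0)
        assert np.all(imp >= 0)

    def test_duplicated_feature_no_crash(self, rng):
        n = 200
        X = pd.DataFrame(rng.normal(0, 1, (n, 3)), columns=["f0", "f1", "f2"])
        X["f3"] = X["f2"]
        y = (X["f2"] > 0).map({True: "a", False: "b"}).to_numpy()
        df = X.copy()
        df["label"] = y
        cfg = ClassifierConfig(cv_folds=3, cv_repeats=1, grid_size=2,
                               rfe_sizes=(4,), n_estimators=50, seed=3)
        res = train_classifier(df, cfg)
        imp = variable_importance(res.model, X, y)
        assert {"f2", "f3"} <= set(imp.index[:3])
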