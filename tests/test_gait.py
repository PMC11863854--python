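"""Window labeling, threshold calibration, LOSO hygiene, voting, segmentation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from armswing.gait import (
    CalibratedClassifier,
    calibrate_threshold_balanced_accuracy,
    calibrate_threshold_specificity,
    categorize_duration,
    fit_classifier,
    label_windows,
    predict_timestamps,
    segment_gait,
    select_model,
    train_loso,
)
from armswing.recording import ACTIVITY_LAYER, AnnotationTrack, ImuRecording, Interval
from oracles import majority_vote_oracle, segments_oracle

FS = 100.0


def make_block(n=2000):
    t = np.arange(n) / FS
    return ImuRecording(t, np.zeros((n, 3)), np.zeros((n, 3)), FS)


class TestLabelWindows:
    def test_fully_inside_gait(self):
        block = make_block(1000)
        ann = AnnotationTrack([Interval(0, 10, ACTIVITY_LAYER, "gait")])
        assert label_windows(block, ann, np.array([0.0, 2.0]), 6.0).tolist() == [True, True]

    def test_minority_gait_is_non_gait(self):
        block = make_block(1000)
        ann = AnnotationTrack(
            [Interval(0, 2, ACTIVITY_LAYER, "gait"), Interval(2, 10, ACTIVITY_LAYER, "sitting")]
        )
        assert label_windows(block, ann, np.array([0.0]), 6.0).tolist() == [False]

    def test_unannotated_window_errors(self):
        block = make_block(1000)
        ann = AnnotationTrack([Interval(0, 4, ACTIVITY_LAYER, "gait")])
        with pytest.raises(ValueError, match="unannotated"):
            label_windows(block, ann, np.array([0.0]), 6.0)

    @given(st.lists(st.sampled_from(["gait", "sitting"]), min_size=5, max_size=12))
    def test_random_timeline_matches_counting_oracle(self, seq):
        block = make_block(len(seq) * 100)
        ivs = [Interval(i, i + 1, ACTIVITY_LAYER, lab) for i, lab in enumerate(seq)]
        ann = AnnotationTrack(ivs)
        starts = np.arange(0.0, len(seq) - 3.0 + 1e-9, 1.0)
        got = label_windows(block, ann, starts, 3.0)
        labels = ann.labels_at(block.time_s)
        for s, g in zip(starts, got):
            in_win = (block.time_s >= s - 1e-9) & (block.time_s < s + 3.0 - 1e-9)
            n_gait = int(np.sum(labels[in_win] == "gait"))
            n_tot = int(np.sum(in_win))
            assert g == (2 * n_gait > n_tot)


class TestSpecificityThreshold:
    def test_perfect_scores(self):
        p = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
        y = np.array([0, 0, 0, 1, 1, 1], dtype=bool)
        # the smallest grid value attaining specificity 0.95 is the positive score
        assert calibrate_threshold_specificity(p, y) == 1.0

    def test_sweep_oracle_on_overlapping_scores(self, rng):
        p = np.concatenate([rng.beta(2, 5, 200), rng.beta(5, 2, 200)])
        y = np.concatenate([np.zeros(200, bool), np.ones(200, bool)])
        t = calibrate_threshold_specificity(p, y, 0.95)
        neg = p[~y]
        spec = np.mean(neg < t)
        assert spec >= 0.95
        # every strictly smaller candidate violates the constraint
        for cand in np.unique(p):
            if cand < t:
                assert np.mean(neg < cand) < 0.95

    def test_single_outlier_negative(self):
        neg = np.linspace(0.01, 0.4, 10)
        pos = np.linspace(0.6, 0.99, 30)
        p = np.concatenate([neg, [0.7], pos])
        y = np.concatenate([np.zeros(10, bool), [False], np.ones(30, bool)])
        t = calibrate_threshold_specificity(p, y, 0.95)
        # threshold lands just above the 0.7 outlier (10/11 < 0.95 below it)
        assert t > 0.7
        assert t == np.min(pos[pos > 0.7])

    def test_unattainable_specificity_errors(self):
        p = np.ones(10)
        y = np.array([0, 1] * 5, dtype=bool)
        with pytest.raises(ValueError):
            calibrate_threshold_specificity(p, y, 0.95)

    def test_threshold_monotonicity(self, rng):
        """Raising the threshold never increases sensitivity and never
        decreases specificity."""
        p = rng.uniform(size=300)
        y = rng.uniform(size=300) < 0.4
        last_sens, last_spec = 2.0, -1.0
        for t in np.linspace(0, 1.001, 50):
            pred = p >= t
            sens = np.mean(pred[y])
            spec = np.mean(~pred[~y])
            assert sens <= last_sens + 1e-12
            assert spec >= last_spec - 1e-12
            last_sens, last_spec = sens, spec


class TestBalancedAccuracyThreshold:
    def test_separated_classes(self):
        p = np.array([0.1, 0.2, 0.8, 0.9])
        y = np.array([0, 0, 1, 1], dtype=bool)
        t = calibrate_threshold_balanced_accuracy(p, y)
        pred = p >= t
        assert np.mean(pred[y]) == 1.0 and np.mean(~pred[~y]) == 1.0

    def test_sweep_oracle_crossing(self, rng):
        p = np.concatenate([rng.normal(0.35, 0.1, 300), rng.normal(0.65, 0.1, 300)]).clip(0, 1)
        y = np.concatenate([np.zeros(300, bool), np.ones(300, bool)])
        t = calibrate_threshold_balanced_accuracy(p, y)

        def ba(thr):
            pred = p >= thr
            return (np.mean(pred[y]) + np.mean(~pred[~y])) / 2

        best = max(ba(c) for c in np.unique(p))
        assert ba(t) == pytest.approx(best)
        assert 0.4 < t < 0.6  # near the crossing of the two distributions


class TestPredictTimestamps:
    def test_unanimous_gait(self):
        t = np.arange(0, 10, 0.01)
        out = predict_timestamps(t, np.array([0.0, 1.0, 2.0]), 6.0, np.array([1, 1, 1], bool))
        assert out[(t >= 2.0) & (t < 6.0)].all()

    def test_tie_is_non_gait(self):
        t = np.arange(0, 12, 0.01)
        starts = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        preds = np.array([1, 1, 1, 0, 0, 0], bool)
        out = predict_timestamps(t, starts, 6.0, preds)
        # samples in [5, 6) are covered by all six windows: 3 vs 3 -> non-gait
        assert not out[(t >= 5.0) & (t < 6.0)].any()

    def test_uncovered_is_non_gait(self):
        t = np.arange(0, 10, 0.01)
        out = predict_timestamps(t, np.array([0.0]), 3.0, np.array([1], bool))
        assert not out[t >= 3.0].any()

    @given(st.integers(0, 2**31 - 1))
    def test_matches_vote_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        t = np.arange(0, 20, 0.1)
        starts = np.sort(rng.choice(np.arange(0, 15, 0.5), size=8, replace=False))
        preds = rng.uniform(size=8) < 0.5
        got = predict_timestamps(t, starts, 4.0, preds)
        assert np.array_equal(got, majority_vote_oracle(t, starts, 4.0, preds))


class TestSegmentGait:
    def test_short_segment(self):
        t = np.arange(0, 30, 0.01)
        segs = segment_gait(t, (t >= 0) & (t < 4.0))
        assert len(segs) == 1
        assert segs[0].category == "short"

    def test_small_gap_merges(self):
        t = np.arange(0, 30, 0.01)
        gait = ((t >= 0) & (t <= 10)) | ((t >= 11) & (t <= 20))
        segs = segment_gait(t, gait)
        assert len(segs) == 1
        assert segs[0].duration_s == pytest.approx(20.0, abs=0.02)
        assert segs[0].category == "very_long"

    def test_large_gap_splits(self):
        t = np.arange(0, 30, 0.01)
        gait = ((t >= 0) & (t <= 10)) | ((t >= 12) & (t <= 20))
        segs = segment_gait(t, gait)
        assert len(segs) == 2
        assert segs[0].category == "long"  # duration exactly 10 s
        assert segs[1].category == "moderately_long"

    @pytest.mark.parametrize(
        "duration,category",
        [(4.99, "short"), (5.0, "moderately_long"), (9.99, "moderately_long"),
         (10.0, "long"), (19.99, "long"), (20.0, "very_long")],
    )
    def test_duration_categories(self, duration, category):
        assert categorize_duration(duration) == category

    @given(st.integers(0, 2**31 - 1))
    def test_matches_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        t = np.arange(0, 60, 0.5)
        gait = rng.uniform(size=len(t)) < 0.3
        segs = segment_gait(t, gait)
        oracle = segments_oracle(t, gait)
        assert [(s.start_s, s.end_s) for s in segs] == oracle


def synthetic_feature_frame(n_subjects=6, n_per=60, separation=3.0, seed=0):
    """Gaussian two-class feature set with subject structure (no IMU involved)."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        for _ in range(n_per):
            label = rng.uniform() < 0.5
            x = rng.standard_normal(5) + (separation if label else 0.0)
            rows.append({"subject": f"s{s}", "label": label, **{f"f{i}": v for i, v in enumerate(x)}})
    return pd.DataFrame(rows)


FEATS = tuple(f"f{i}" for i in range(5))


class TestTrainLoso:
    def test_fold_structure(self):
        df = synthetic_feature_frame()
        res = train_loso(df, "logistic_lasso", FEATS, grid={"clf__C": [1.0]})
        assert len(res.folds) == 6
        held = {f.classifier.metadata["held_out_subject"] for f in res.folds}
        assert held == set(df["subject"].unique())
        for f in res.folds:
            assert np.all(df.iloc[f.oof_index]["subject"] == f.subject)

    def test_separable_features_high_balanced_accuracy(self):
        df = synthetic_feature_frame(separation=3.0, seed=1)
        res = train_loso(df, "logistic_lasso", FEATS, grid={"clf__C": [1.0]})
        assert res.balanced_accuracy > 0.95

    def test_permuted_labels_near_chance(self):
        """Out-of-fold balanced accuracy under label permutation stays near 0.5
        (no leakage across folds)."""
        bas = []
        for seed in range(3):
            df = synthetic_feature_frame(separation=3.0, seed=seed)
            rng = np.random.default_rng(seed)
            df["label"] = rng.permutation(df["label"].to_numpy())
            res = train_loso(df, "logistic_lasso", FEATS, grid={"clf__C": [1.0]},
                             threshold_rule="balanced_accuracy")
            bas.append(res.balanced_accuracy)
        assert abs(np.mean(bas) - 0.5) <= 0.1

    def test_row_order_does_not_change_oof_predictions(self):
        df = synthetic_feature_frame(seed=3)
        res1 = train_loso(df, "logistic_lasso", FEATS, grid={"clf__C": [1.0]})
        shuffled = df.sample(frac=1.0, random_state=9).reset_index(drop=True)
        res2 = train_loso(shuffled, "logistic_lasso", FEATS, grid={"clf__C": [1.0]})
        a = res1.oof.sort_values(["subject", "p"]).reset_index(drop=True)
        b = res2.oof.sort_values(["subject", "p"]).reset_index(drop=True)
        assert np.allclose(a["p"], b["p"])

    def test_too_few_subjects_rejected(self):
        df = synthetic_feature_frame(n_subjects=2)
        with pytest.raises(ValueError):
            train_loso(df, "logistic_lasso", FEATS)

    def test_single_class_fold_rejected(self):
        df = synthetic_feature_frame(n_subjects=3)
        df.loc[df.subject != "s0", "label"] = True
        with pytest.raises(ValueError, match="single class"):
            train_loso(df, "logistic_lasso", FEATS)


def test_select_model_prefers_lr_on_tie():
    df = synthetic_feature_frame(seed=4)
    res = train_loso(df, "logistic_lasso", FEATS, grid={"clf__C": [1.0]})
    import copy

    res_rf = copy.deepcopy(res)
    res_rf.model_kind = "random_forest"
    assert select_model(res_rf, res).model_kind == "logistic_lasso"
    assert select_model(res, res_rf).model_kind == "logistic_lasso"


def test_classifier_roundtrip(tmp_path):
    df = synthetic_feature_frame(seed=5)
    clf = fit_classifier(df, "logistic_lasso", FEATS, threshold_rule="balanced_accuracy")
    path = tmp_path / "model.joblib"
    clf.save(path)
    loaded = CalibratedClassifier.load(path)
    assert loaded.threshold == clf.threshold
    assert loaded.feature_names == clf.feature_names
    X = df[list(FEATS)]
    assert np.array_equal(loaded.predict_proba(X), clf.predict_proba(X))
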