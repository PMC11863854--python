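"""Gait vs non-gait classification.

Windows are labeled by per-sample majority vote against the annotation
track; classifiers (LASSO-regularized logistic regression or random forest)
are trained with nested leave-one-subject-out cross-validation, the inner
loop grid-searching hyperparameters by balanced accuracy.  The decision
threshold is calibrated on a designated training subset to guarantee a
minimum specificity of 0.95 (false-positive gait would contaminate the
downstream arm-swing estimate).  Per-sample predictions come from uniform
majority voting over the overlapping windows covering each timestamp, and
gait samples are merged into segments using a 1.5-s gap rule with four
duration categories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import GridSearchCV, LeaveOneGroupOut
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .recording import ACTIVITY_LAYER, AnnotationTrack, ImuRecording

GAP_S = 1.5
MIN_SPECIFICITY = 0.95

DEFAULT_GRIDS = {
    "logistic_lasso": {"clf__C": [0.05, 0.5, 5.0]},
    "random_forest": {"clf__n_estimators": [50], "clf__max_depth": [3, None]},
}

_CATEGORY_EDGES = ((0.0, 5.0, "short"), (5.0, 10.0, "moderately_long"), (10.0, 20.0, "long"))


def categorize_duration(duration_s: float) -> str:
    """short < 5 s; moderately_long 5-10 s; long 10-20 s; very_long >= 20 s."""
    for lo, hi, name in _CATEGORY_EDGES:
        if lo <= duration_s < hi:
            return name
    return "very_long"


@dataclass(frozen=True)
class GaitSegment:
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def category(self) -> str:
        return categorize_duration(self.duration_s)


def make_estimator(model_kind: str, seed: int = 0, **params) -> Pipeline:
    """Classifier pipeline; logistic regression gets in-pipeline standardization
    so per-fold training statistics never leak across folds."""
    if model_kind == "logistic_lasso":
        clf = LogisticRegression(l1_ratio=1.0, solver="liblinear", C=1.0, max_iter=300, random_state=seed)
        steps = [("scaler", StandardScaler()), ("clf", clf)]
    elif model_kind == "random_forest":
        clf = RandomForestClassifier(n_estimators=50, random_state=seed)
        steps = [("clf", clf)]
    else:
        raise ValueError(f"unknown model kind {model_kind!r}")
    pipe = Pipeline(steps)
    if params:
        pipe.set_params(**params)
    return pipe


@dataclass
class CalibratedClassifier:
    """A fitted classifier plus its calibrated decision threshold.

    Predicts the positive class when the predicted probability is >= the
    threshold.  The feature name registry travels with the model so feature
    order is stable across save/load.
    """

    model_kind: str
    estimator: Pipeline
    threshold: float
    feature_names: tuple[str, ...]
    metadata: dict = field(default_factory=dict)

    def predict_proba(self, X) -> np.ndarray:
        X = self._matrix(X)
        return self.estimator.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X) >= self.threshold

    def _matrix(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            return X[list(self.feature_names)].to_numpy()
        return np.asarray(X)

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path: str | Path) -> "CalibratedClassifier":
        obj = joblib.load(path)
        if not isinstance(obj, CalibratedClassifier):
            raise TypeError("file does not contain a CalibratedClassifier")
        return obj


# ---------------------------------------------------------------------------
# window labeling


def window_majority_vote(values: np.ndarray, starts: np.ndarray, wlen: int, tie_value: bool = False) -> np.ndarray:
    """Majority of a boolean per-sample series within each window.

    ``tie_value`` is returned on exact ties.
    """
    values = np.asarray(values, dtype=bool)
    csum = np.concatenate([[0], np.cumsum(values)])
    out = np.empty(len(starts), dtype=bool)
    for k, i0 in enumerate(starts):
        pos = csum[i0 + wlen] - csum[i0]
        if 2 * pos == wlen:
            out[k] = tie_value
        else:
            out[k] = 2 * pos > wlen
    return out


def label_windows(block: ImuRecording, ann: AnnotationTrack, starts_s: np.ndarray, length_s: float) -> np.ndarray:
    """Gait / non-gait window labels by per-sample majority vote (tie -> non-gait).

    Raises if any window overlaps unannotated time (such samples should have
    been removed upstream).
    """
    labels = ann.labels_at(block.time_s, layer=ACTIVITY_LAYER)
    wlen = int(round(length_s * block.sample_rate_hz))
    idx0 = np.searchsorted(block.time_s, np.asarray(starts_s) - 1e-9, side="left")
    for i0 in idx0:
        if i0 + wlen > len(block):
            raise ValueError("window extends past the block")
        if np.any(labels[i0 : i0 + wlen] == ""):
            raise ValueError("window overlaps unannotated time")
    return window_majority_vote(labels == "gait", idx0, wlen, tie_value=False)


# ---------------------------------------------------------------------------
# threshold calibration


def calibrate_threshold_specificity(p: np.ndarray, y: np.ndarray, min_specificity: float = MIN_SPECIFICITY) -> float:
    """Smallest threshold (from the sorted unique scores) whose specificity on
    (p, y) is >= ``min_specificity``; maximizes sensitivity subject to the
    specificity constraint.  Decision rule: positive iff p >= threshold."""
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=bool)
    neg = p[~y]
    if neg.size == 0:
        raise ValueError("calibration set contains no negative examples")
    for t in np.unique(p):
        if np.mean(neg < t) >= min_specificity:
            return float(t)
    raise ValueError(f"no threshold attains specificity {min_specificity}")


def calibrate_threshold_balanced_accuracy(p: np.ndarray, y: np.ndarray) -> float:
    """Threshold maximizing balanced accuracy on (p, y); ties -> lower threshold."""
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=bool)
    if not y.any() or y.all():
        raise ValueError("calibration set must contain both classes")
    best_t, best_ba = None, -np.inf
    for t in np.unique(p):
        pred = p >= t
        sens = np.mean(pred[y])
        spec = np.mean(~pred[~y])
        ba = (sens + spec) / 2
        if ba > best_ba + 1e-12:
            best_ba, best_t = ba, float(t)
    return best_t


# ---------------------------------------------------------------------------
# nested LOSO training


@dataclass
class FoldResult:
    subject: str
    classifier: CalibratedClassifier
    oof_index: np.ndarray  # row positions of the held-out windows


@dataclass
class LosoResult:
    model_kind: str
    folds: list[FoldResult]
    oof: pd.DataFrame  # subject, label, p, pred per window (out of fold)

    @property
    def balanced_accuracy(self) -> float:
        return float(balanced_accuracy_score(self.oof["label"], self.oof["pred"]))

    def per_subject_balanced_accuracy(self) -> pd.Series:
        return self.oof.groupby("subject").apply(
            lambda d: balanced_accuracy_score(d["label"], d["pred"]), include_groups=False
        )


def train_loso(
    dataset: pd.DataFrame,
    model_kind: str,
    feature_names: tuple[str, ...],
    grid: dict | None = None,
    calibration_mask: np.ndarray | None = None,
    threshold_rule: str = "specificity",
    min_specificity: float = MIN_SPECIFICITY,
    seed: int = 0,
) -> LosoResult:
    """Nested leave-one-subject-out training.

    ``dataset`` needs columns ``subject`` and ``label`` (bool: positive
    class) plus the feature columns.  The inner loop grid-searches
    hyperparameters by balanced accuracy with leave-one-subject-out over the
    training subjects; the refit model's threshold is calibrated on the
    training rows selected by ``calibration_mask`` (default: all training
    rows; pass e.g. a PD-group mask to mirror calibration on the PD sample).
    ``threshold_rule`` is "specificity" (gait detection) or
    "balanced_accuracy" (arm-activity filtering).
    """
    subjects = pd.unique(dataset["subject"])
    if len(subjects) < 3:
        raise ValueError("nested LOSO needs at least 3 subjects")
    grid = DEFAULT_GRIDS[model_kind] if grid is None else grid
    X = dataset[list(feature_names)].to_numpy()
    y = dataset["label"].to_numpy(dtype=bool)
    groups = dataset["subject"].to_numpy()
    if calibration_mask is None:
        calibration_mask = np.ones(len(dataset), dtype=bool)
    calibration_mask = np.asarray(calibration_mask, dtype=bool)

    folds: list[FoldResult] = []
    oof_p = np.full(len(dataset), np.nan)
    for subj in subjects:
        test_mask = groups == subj
        train_mask = ~test_mask
        ytr = y[train_mask]
        if ytr.all() or not ytr.any():
            raise ValueError(f"training fold for held-out subject {subj!r} has a single class")
        est = _fit_inner(X[train_mask], ytr, groups[train_mask], model_kind, grid, seed)
        cal = train_mask & calibration_mask
        if not cal.any():
            cal = train_mask
        p_cal = est.predict_proba(X[cal])[:, 1]
        if threshold_rule == "specificity":
            thr = calibrate_threshold_specificity(p_cal, y[cal], min_specificity)
        elif threshold_rule == "balanced_accuracy":
            thr = calibrate_threshold_balanced_accuracy(p_cal, y[cal])
        else:
            raise ValueError(f"unknown threshold rule {threshold_rule!r}")
        clf = CalibratedClassifier(
            model_kind=model_kind,
            estimator=est,
            threshold=thr,
            feature_names=tuple(feature_names),
            metadata={"held_out_subject": str(subj), "grid": grid, "seed": seed, "threshold_rule": threshold_rule},
        )
        oof_p[test_mask] = est.predict_proba(X[test_mask])[:, 1]
        # out-of-fold hard predictions use this fold's calibrated threshold
        folds.append(FoldResult(subject=str(subj), classifier=clf, oof_index=np.flatnonzero(test_mask)))

    pred = np.zeros(len(dataset), dtype=bool)
    for fr in folds:
        pred[fr.oof_index] = oof_p[fr.oof_index] >= fr.classifier.threshold
    oof = pd.DataFrame({"subject": groups, "label": y, "p": oof_p, "pred": pred})
    return LosoResult(model_kind=model_kind, folds=folds, oof=oof)


def _fit_inner(Xtr, ytr, gtr, model_kind, grid, seed):
    n_combos = int(np.prod([len(v) for v in grid.values()])) if grid else 1
    base = make_estimator(model_kind, seed=seed)
    if n_combos <= 1 or len(np.unique(gtr)) < 2:
        if grid:
            base.set_params(**{k: v[0] for k, v in grid.items()})
        base.fit(Xtr, ytr)
        return base
    gs = GridSearchCV(base, grid, cv=LeaveOneGroupOut(), scoring="balanced_accuracy", n_jobs=1, refit=True)
    with warnings.catch_warnings():
        # inner folds whose held-out subject happens to be single-class are fine
        warnings.filterwarnings("ignore", message="A single label was found", category=UserWarning)
        gs.fit(Xtr, ytr, groups=gtr)
    return gs.best_estimator_


def fit_classifier(
    dataset: pd.DataFrame,
    model_kind: str,
    feature_names: tuple[str, ...],
    calibration_mask: np.ndarray | None = None,
    threshold_rule: str = "specificity",
    min_specificity: float = MIN_SPECIFICITY,
    seed: int = 0,
    **params,
) -> CalibratedClassifier:
    """Fit one classifier on the full dataset and calibrate its threshold
    (no cross-validation; used for a final deployable model)."""
    X = dataset[list(feature_names)].to_numpy()
    y = dataset["label"].to_numpy(dtype=bool)
    est = make_estimator(model_kind, seed=seed, **params)
    est.fit(X, y)
    if calibration_mask is None:
        calibration_mask = np.ones(len(dataset), dtype=bool)
    p_cal = est.predict_proba(X[calibration_mask])[:, 1]
    if threshold_rule == "specificity":
        thr = calibrate_threshold_specificity(p_cal, y[calibration_mask], min_specificity)
    else:
        thr = calibrate_threshold_balanced_accuracy(p_cal, y[calibration_mask])
    return CalibratedClassifier(
        model_kind=model_kind,
        estimator=est,
        threshold=thr,
        feature_names=tuple(feature_names),
        metadata={"seed": seed, "threshold_rule": threshold_rule},
    )


def select_model(result_a: LosoResult, result_b: LosoResult) -> LosoResult:
    """Higher out-of-fold balanced accuracy wins; on a tie the logistic
    regression is preferred for its simplicity."""
    ba_a, ba_b = result_a.balanced_accuracy, result_b.balanced_accuracy
    if abs(ba_a - ba_b) < 1e-12:
        if result_a.model_kind == "logistic_lasso":
            return result_a
        if result_b.model_kind == "logistic_lasso":
            return result_b
    return result_a if ba_a >= ba_b else result_b


# ---------------------------------------------------------------------------
# timestamp-level prediction and segmentation


def predict_timestamps(
    times: np.ndarray,
    window_starts_s: np.ndarray,
    window_length_s: float,
    window_pred: np.ndarray,
) -> np.ndarray:
    """Per-sample prediction by uniform majority voting over the thresholded
    decisions of all windows covering each timestamp.

    Ties and samples covered by zero windows resolve to the negative class.
    """
    times = np.asarray(times, dtype=float)
    n = len(times)
    pos = np.zeros(n + 1)
    tot = np.zeros(n + 1)
    for start, pred in zip(np.asarray(window_starts_s, dtype=float), np.asarray(window_pred, dtype=bool)):
        i0 = int(np.searchsorted(times, start - 1e-9, side="left"))
        i1 = int(np.searchsorted(times, start + window_length_s - 1e-9, side="left"))
        tot[i0] += 1
        tot[i1] -= 1
        if pred:
            pos[i0] += 1
            pos[i1] -= 1
    pos = np.cumsum(pos[:-1])
    tot = np.cumsum(tot[:-1])
    return 2 * pos > tot


def segment_gait(times: np.ndarray, is_gait: np.ndarray, gap_s: float = GAP_S) -> list[GaitSegment]:
    """Maximal runs of gait timestamps; a gap > ``gap_s`` between consecutive
    gait timestamps starts a new segment (gaps <= gap_s are bridged)."""
    times = np.asarray(times, dtype=float)
    gait_times = times[np.asarray(is_gait, dtype=bool)]
    if gait_times.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(gait_times) > gap_s + 1e-9)
    starts = np.concatenate([[0], breaks + 1])
    stops = np.concatenate([breaks, [gait_times.size - 1]])
    return [GaitSegment(float(gait_times[i]), float(gait_times[j])) for i, j in zip(starts, stops)]


def segment_mask(times: np.ndarray, segments: list[GaitSegment]) -> np.ndarray:
    """Boolean per-sample mask of membership in any segment (closed intervals)."""
    times = np.asarray(times, dtype=float)
    out = np.zeros(times.shape, dtype=bool)
    for seg in segments:
        out |= (times >= seg.start_s - 1e-9) & (times <= seg.end_s + 1e-9)
    return out
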