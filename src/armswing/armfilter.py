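"""Detection of gait with vs without other arm activities ("filtering gait").

Within predicted gait segments only, 3-s Hann windows with 75% overlap are
classified as "gait with other arm activities" (positive class) vs "gait
without other arm activities" using the 46-feature set (34 accelerometer
features plus 12 gyroscope-norm MFCCs).  The decision threshold optimizes
balanced accuracy on the training set: here false positives and false
negatives are equally undesirable.  Filtered gait is the subset of predicted
gait samples additionally predicted to carry no other arm activity,
re-segmented with the same 1.5-s gap rule.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .features import ARM_WINDOWING, ARMFILTER_FEATURE_NAMES, WindowingSpec, extract_feature_table
from .gait import GaitSegment, GAP_S, LosoResult, segment_gait, train_loso, window_majority_vote
from .recording import ARM_LAYER, AnnotationTrack, ImuRecording


def window_predicted_gait(
    block: ImuRecording,
    segments: list[GaitSegment],
    spec: WindowingSpec = ARM_WINDOWING,
) -> np.ndarray:
    """Window start times fully contained in a predicted gait segment.

    Windows align to each segment's start (window 0 starts at the segment
    start); segments shorter than one window yield none; windows never span
    two segments.
    """
    t0, t1 = (float(block.time_s[0]), float(block.time_s[-1])) if len(block) else (0.0, 0.0)
    starts: list[float] = []
    for seg in segments:
        lo = max(seg.start_s, t0)
        hi = min(seg.end_s, t1 + 1.0 / block.sample_rate_hz)
        if lo > seg.start_s + 1e-9:
            continue  # segment does not start in this block
        k = 0
        while True:
            s = seg.start_s + k * spec.step_s
            if s + spec.length_s > min(seg.end_s, hi) + 1e-9:
                break
            starts.append(s)
            k += 1
    return np.asarray(starts, dtype=float)


def arm_feature_table(
    block: ImuRecording,
    segments: list[GaitSegment],
    spec: WindowingSpec = ARM_WINDOWING,
) -> pd.DataFrame:
    """46-feature table for the arm-activity task over predicted gait windows."""
    from .features import armfilter_feature_vector

    if block.acc_dynamic is None or block.acc_gravity is None:
        raise ValueError("block must carry a gravity decomposition")
    starts = window_predicted_gait(block, segments, spec)
    fs = block.sample_rate_hz
    wlen = int(round(spec.length_s * fs))
    rows, times = [], []
    for s in starts:
        i0 = int(np.searchsorted(block.time_s, s - 1e-9, side="left"))
        if i0 + wlen > len(block):
            continue
        rows.append(
            armfilter_feature_vector(
                block.acc_dynamic[i0 : i0 + wlen],
                block.acc_gravity[i0 : i0 + wlen],
                block.gyr[i0 : i0 + wlen],
                fs,
            )
        )
        times.append(s)
    df = pd.DataFrame(rows, columns=list(ARMFILTER_FEATURE_NAMES))
    df.insert(0, "start_s", times)
    return df


def label_arm_windows(
    block: ImuRecording,
    ann: AnnotationTrack,
    starts_s: np.ndarray,
    length_s: float = ARM_WINDOWING.length_s,
    arm: str | None = None,
) -> np.ndarray:
    """True = "gait with other arm activities", by per-sample majority vote of
    arm-activity presence; exact ties label as *with* (conservative: prefer
    excluding possibly contaminated windows)."""
    if ARM_LAYER not in ann.layers:
        raise ValueError("annotation track has no arm-activity layer")
    arm = arm or block.side
    active = ann.covered_mask(block.time_s, layer=ARM_LAYER, arm=arm)
    wlen = int(round(length_s * block.sample_rate_hz))
    idx0 = np.searchsorted(block.time_s, np.asarray(starts_s, dtype=float) - 1e-9, side="left")
    for i0 in idx0:
        if i0 + wlen > len(block):
            raise ValueError("window extends past the block")
    return window_majority_vote(active, idx0, wlen, tie_value=True)


def train_arm_filter(
    dataset: pd.DataFrame,
    model_kind: str = "logistic_lasso",
    grid: dict | None = None,
    calibration_mask: np.ndarray | None = None,
    seed: int = 0,
) -> LosoResult:
    """Nested LOSO training of the arm-activity classifier; the threshold
    maximizes training-set balanced accuracy (ties -> lower threshold)."""
    return train_loso(
        dataset,
        model_kind,
        ARMFILTER_FEATURE_NAMES,
        grid=grid,
        calibration_mask=calibration_mask,
        threshold_rule="balanced_accuracy",
        seed=seed,
    )


def filter_gait(
    times: np.ndarray,
    gait_pred: np.ndarray,
    arm_activity_pred: np.ndarray,
    gap_s: float = GAP_S,
) -> list[GaitSegment]:
    """Filtered gait: samples predicted gait AND predicted to have no other
    arm activity, re-segmented with the gap rule."""
    keep = np.asarray(gait_pred, dtype=bool) & ~np.asarray(arm_activity_pred, dtype=bool)
    return segment_gait(times, keep, gap_s=gap_s)
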