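"""End-to-end orchestration: dataset assembly and per-subject application of
the gait-detection -> arm-activity-filtering -> RoM-quantification chain.

These helpers glue the stage modules together for cohort-level experiments;
each stage remains individually usable.  Ground-truth bypass flags let the
RoM stage be evaluated in isolation from classifier errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .armfilter import arm_feature_table, filter_gait, label_arm_windows, window_predicted_gait
from .features import ARM_WINDOWING, GAIT_WINDOWING, extract_feature_table
from .gait import (
    CalibratedClassifier,
    GaitSegment,
    label_windows,
    predict_timestamps,
    segment_gait,
    segment_mask,
)
from .preprocess import EDGE_EXCLUSION_S, preprocess_recording, valid_time_span
from .recording import ACTIVITY_LAYER, AnnotationTrack, ImuRecording
from .rom import ArmSwingAggregates, RomSeries, quantify_arm_swing
from .synthetic import SubjectRecording


def truth_gait_segments(rec: ImuRecording, ann: AnnotationTrack, gap_s: float = 1.5) -> list[GaitSegment]:
    """Gait segments straight from the annotated activity layer."""
    labels = ann.labels_at(rec.time_s, layer=ACTIVITY_LAYER)
    return segment_gait(rec.time_s, labels == "gait", gap_s=gap_s)


def build_gait_dataset(subjects: list[SubjectRecording], edge_s: float = EDGE_EXCLUSION_S) -> pd.DataFrame:
    """Labeled 34-feature windows pooled over subjects (gait-detection task).

    Columns: subject, group, state, label (True = gait) + features.
    """
    frames = []
    for subj in subjects:
        span = valid_time_span(subj.recording, edge_s)
        blocks = preprocess_recording(subj.recording, subj.annotations)
        for block in blocks:
            feats = extract_feature_table(block, GAIT_WINDOWING, valid_span=span)
            if feats.empty:
                continue
            labels = label_windows(block, subj.annotations, feats["start_s"].to_numpy(), GAIT_WINDOWING.length_s)
            feats.insert(0, "label", labels)
            feats.insert(0, "state", subj.state)
            feats.insert(0, "group", subj.group)
            feats.insert(0, "subject", subj.subject_id)
            frames.append(feats)
    if not frames:
        raise ValueError("no windows extracted from the cohort")
    return pd.concat(frames, ignore_index=True)


def build_arm_dataset(
    subjects: list[SubjectRecording],
    segments_by_subject: dict[str, list[GaitSegment]] | None = None,
    edge_s: float = EDGE_EXCLUSION_S,
) -> pd.DataFrame:
    """Labeled 46-feature windows within gait segments (arm-filter task).

    ``segments_by_subject`` supplies predicted gait segments per subject;
    when omitted, ground-truth gait segments are used (bypassing step 1).
    Columns: subject, group, state, label (True = gait WITH other arm
    activities) + features.
    """
    frames = []
    for subj in subjects:
        if segments_by_subject is not None:
            segments = segments_by_subject[subj.subject_id]
        else:
            segments = truth_gait_segments(subj.recording, subj.annotations)
        span = valid_time_span(subj.recording, edge_s)
        segments = [s for s in segments if s.start_s >= span[0] and s.end_s <= span[1]]
        blocks = preprocess_recording(subj.recording, subj.annotations)
        for block in blocks:
            feats = arm_feature_table(block, segments, ARM_WINDOWING)
            if feats.empty:
                continue
            labels = label_arm_windows(
                block, subj.annotations, feats["start_s"].to_numpy(), ARM_WINDOWING.length_s, arm=subj.recording.side
            )
            feats.insert(0, "label", labels)
            feats.insert(0, "state", subj.state)
            feats.insert(0, "group", subj.group)
            feats.insert(0, "subject", subj.subject_id)
            frames.append(feats)
    if not frames:
        raise ValueError("no arm-task windows extracted")
    return pd.concat(frames, ignore_index=True)


@dataclass
class PipelineResult:
    times: np.ndarray
    gait_pred: np.ndarray  # per-sample, after majority voting
    arm_activity_pred: np.ndarray  # per-sample, True = other arm activity
    gait_segments: list[GaitSegment]
    filtered_segments: list[GaitSegment]
    rom: RomSeries
    aggregates: ArmSwingAggregates


def apply_pipeline(
    rec: ImuRecording,
    ann: AnnotationTrack,
    gait_classifier: CalibratedClassifier | None = None,
    arm_classifier: CalibratedClassifier | None = None,
    edge_s: float = EDGE_EXCLUSION_S,
) -> PipelineResult:
    """Run the three-stage chain on one recording.

    Passing ``None`` for a classifier bypasses that stage with ground truth
    (annotated gait / annotated arm activities), which isolates the RoM
    stage for validation.
    """
    span = valid_time_span(rec, edge_s)
    blocks = preprocess_recording(rec, ann)
    times = np.concatenate([b.time_s for b in blocks]) if blocks else np.array([])

    # stage 1: per-sample gait
    if gait_classifier is None:
        gait_pred = ann.labels_at(times, layer=ACTIVITY_LAYER) == "gait"
    else:
        parts = []
        for block in blocks:
            feats = extract_feature_table(block, GAIT_WINDOWING, valid_span=span)
            if feats.empty:
                parts.append(np.zeros(len(block), dtype=bool))
                continue
            wpred = gait_classifier.predict(feats)
            parts.append(predict_timestamps(block.time_s, feats["start_s"].to_numpy(), GAIT_WINDOWING.length_s, wpred))
        gait_pred = np.concatenate(parts) if parts else np.array([], dtype=bool)
    gait_segments = segment_gait(times, gait_pred)

    # stage 2: per-sample other-arm-activity within predicted gait
    if arm_classifier is None:
        arm_pred = ann.covered_mask(times, layer="arm_activity", arm=rec.side)
    else:
        parts = []
        for block in blocks:
            feats = arm_feature_table(block, gait_segments, ARM_WINDOWING)
            if feats.empty:
                parts.append(np.zeros(len(block), dtype=bool))
                continue
            wpred = arm_classifier.predict(feats)
            parts.append(predict_timestamps(block.time_s, feats["start_s"].to_numpy(), ARM_WINDOWING.length_s, wpred))
        arm_pred = np.concatenate(parts) if parts else np.array([], dtype=bool)

    filtered = filter_gait(times, segment_mask(times, gait_segments), arm_pred)

    rom, aggregates = quantify_arm_swing(blocks, filtered)
    return PipelineResult(
        times=times,
        gait_pred=gait_pred,
        arm_activity_pred=np.asarray(arm_pred, dtype=bool),
        gait_segments=gait_segments,
        filtered_segments=filtered,
        rom=rom,
        aggregates=aggregates,
    )
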