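"""Preprocessing: orientation harmonization, decimation to the working rate,
gravity/dynamic decomposition, and removal of unannotated data.

The accelerometer is split into a gravitational (wrist orientation) and a
dynamic (movement) component with a 4th-order Butterworth high-pass at
0.2 Hz, applied forward-backward so the two components stay phase-aligned.
Recordings are decimated from their native rate (nominally 200 Hz) to a
100 Hz working rate after an anti-alias low-pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .recording import ACTIVITY_LAYER, AnnotationTrack, ImuRecording

#: canonical-frame sign flip for orientation "B" (180 deg rotation about z)
ORIENTATION_SIGN_MAP = np.array([-1.0, -1.0, 1.0])

DEFAULT_CUTOFF_HZ = 0.2
DEFAULT_FILTER_ORDER = 4
DEFAULT_TARGET_RATE_HZ = 100.0
#: seconds at each recording edge excluded from feature windows (filter edge)
EDGE_EXCLUSION_S = 5.0


@dataclass
class GravityDecomposition:
    """High-pass (dynamic) and complementary low-pass (gravity) acceleration."""

    gravity: np.ndarray  # (n, 3), g
    dynamic: np.ndarray  # (n, 3), g


def harmonize_orientation(rec: ImuRecording) -> ImuRecording:
    """Map a recording into the canonical axis frame.

    Orientation "A" is canonical (identity); orientation "B" recordings have
    x and y of both sensors sign-flipped.  Applying the operation to a
    harmonized recording whose orientation field has been toggled back to "B"
    restores the original signal (the sign map is an involution).
    """
    if rec.orientation == "A":
        return rec
    if rec.orientation != "B":
        raise ValueError(f"unknown orientation {rec.orientation!r}")
    return ImuRecording(
        time_s=rec.time_s.copy(),
        acc=rec.acc * ORIENTATION_SIGN_MAP,
        gyr=rec.gyr * ORIENTATION_SIGN_MAP,
        sample_rate_hz=rec.sample_rate_hz,
        side=rec.side,
        orientation="A",
    )


def resample_to_working_rate(rec: ImuRecording, target_hz: float = DEFAULT_TARGET_RATE_HZ) -> ImuRecording:
    """Decimate to the working rate (integer ratio only).

    An 8th-order Butterworth low-pass at 0.4x the target rate is applied
    forward-backward before sample dropping; output length is ceil(n/ratio).
    """
    ratio = rec.sample_rate_hz / target_hz
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(f"sample rate {rec.sample_rate_hz} is not an integer multiple of {target_hz}")
    ratio = int(round(ratio))
    if ratio == 1:
        return rec
    sos = signal.butter(8, 0.4 * target_hz, btype="lowpass", fs=rec.sample_rate_hz, output="sos")
    acc = signal.sosfiltfilt(sos, rec.acc, axis=0)
    gyr = signal.sosfiltfilt(sos, rec.gyr, axis=0)
    return ImuRecording(
        time_s=rec.time_s[::ratio],
        acc=acc[::ratio],
        gyr=gyr[::ratio],
        sample_rate_hz=target_hz,
        side=rec.side,
        orientation=rec.orientation,
    )


def _highpass_sos(sample_rate_hz: float, cutoff_hz: float, order: int) -> np.ndarray:
    return signal.butter(order, cutoff_hz, btype="highpass", fs=sample_rate_hz, output="sos")


def decompose_gravity(
    acc: np.ndarray,
    sample_rate_hz: float,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_FILTER_ORDER,
) -> GravityDecomposition:
    """Split acceleration into dynamic (high-pass) and gravity components.

    ``gravity + dynamic`` reconstructs the input exactly by construction.
    Signals shorter than three times the filter's settling length are
    rejected.
    """
    acc = np.atleast_2d(np.asarray(acc, dtype=float))
    if acc.shape[0] == 1 and acc.shape[1] > 3:
        acc = acc.T
    if not np.all(np.isfinite(acc)):
        raise ValueError("acceleration must be finite")
    sos = _highpass_sos(sample_rate_hz, cutoff_hz, order)
    # a 0.2 Hz high-pass settles over ~1/cutoff seconds; reflect-pad 3x that
    settle = int(sample_rate_hz / cutoff_hz)
    if acc.shape[0] <= 3 * settle:
        raise ValueError(f"signal too short for gravity decomposition (need > {3 * settle} samples)")
    dynamic = signal.sosfiltfilt(sos, acc, axis=0, padlen=min(acc.shape[0] - 1, 3 * settle))
    gravity = acc - dynamic
    return GravityDecomposition(gravity=gravity, dynamic=dynamic)


def attach_gravity(rec: ImuRecording, cutoff_hz: float = DEFAULT_CUTOFF_HZ, order: int = DEFAULT_FILTER_ORDER) -> ImuRecording:
    """Return a copy of the recording carrying its gravity decomposition."""
    dec = decompose_gravity(rec.acc, rec.sample_rate_hz, cutoff_hz, order)
    return ImuRecording(
        time_s=rec.time_s,
        acc=rec.acc,
        gyr=rec.gyr,
        sample_rate_hz=rec.sample_rate_hz,
        side=rec.side,
        orientation=rec.orientation,
        acc_gravity=dec.gravity,
        acc_dynamic=dec.dynamic,
    )


def discard_unannotated(rec: ImuRecording, ann: AnnotationTrack) -> list[ImuRecording]:
    """Drop samples outside any activity-layer interval.

    Returns the retained data as contiguous blocks so downstream windowing
    never spans a removed region.  An empty overlap yields an empty list (with
    a warning-free no-op semantics left to the caller).
    """
    mask = ann.covered_mask(rec.time_s, layer=ACTIVITY_LAYER)
    if not mask.any():
        return []
    edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
    starts = [0] if mask[0] else []
    starts += [int(e) + 1 for e in edges if mask[int(e) + 1]]
    stops = [int(e) + 1 for e in edges if mask[int(e)]]
    if mask[-1]:
        stops.append(len(mask))
    return [rec.slice(i0, i1) for i0, i1 in zip(starts, stops)]


def preprocess_recording(
    rec: ImuRecording,
    ann: AnnotationTrack | None = None,
    target_hz: float = DEFAULT_TARGET_RATE_HZ,
) -> list[ImuRecording]:
    """Full preprocessing chain: harmonize, decimate, decompose, discard.

    The gravity decomposition is computed on the continuous decimated
    recording before unannotated data are removed, so filter transients do
    not restart at block boundaries.  Returns annotated contiguous blocks
    each carrying ``acc_gravity`` / ``acc_dynamic``.
    """
    rec = harmonize_orientation(rec)
    if rec.sample_rate_hz != target_hz:
        rec = resample_to_working_rate(rec, target_hz)
    rec = attach_gravity(rec)
    if ann is None:
        return [rec]
    return discard_unannotated(rec, ann)


def valid_time_span(rec: ImuRecording, edge_s: float = EDGE_EXCLUSION_S) -> tuple[float, float]:
    """Time range of a recording with filter-edge samples excluded."""
    if len(rec) == 0:
        return (0.0, 0.0)
    return (float(rec.time_s[0] + edge_s), float(rec.time_s[-1] - edge_s))
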