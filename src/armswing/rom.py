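"""Arm-swing range-of-motion (RoM) quantification.

Within filtered gait segments, a single PCA over the pooled gyroscope y/z
samples of one participant-side isolates the angular velocity along the arm
swing direction; the first principal component is integrated (trapezoidal)
to an angle, detrended with a centered 1-s moving average, and alternating
angle extrema are selected under two rules: same-type successors collapse to
the largest absolute value, and peaks closer than 1/1.8 s to the previously
kept peak are discarded.  RoM values are absolute differences between
consecutive peaks; participant-level summaries are the median (general
performance) and 95th percentile (capacity), computed only when at least one
minute of filtered gait is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .gait import GaitSegment
from .recording import ImuRecording

#: minimum time between kept peaks: first gait harmonic stays below 1.8 Hz
MIN_PEAK_SPACING_S = 1.0 / 1.8
MIN_FILTERED_MINUTES = 1.0


@dataclass
class AngleSeries:
    time_s: np.ndarray
    theta_deg: np.ndarray


@dataclass
class Peaks:
    times_s: np.ndarray
    values_deg: np.ndarray
    is_max: np.ndarray


@dataclass
class RomSeries:
    peak_times_s: np.ndarray  # time of the later peak of each pair
    rom_deg: np.ndarray

    def __len__(self) -> int:
        return len(self.rom_deg)


@dataclass
class ArmSwingAggregates:
    median_rom_deg: float | None
    p95_rom_deg: float | None
    filtered_gait_minutes: float
    n_swings: int
    excluded: bool = False


def pca_swing_axis(segments_yz: list[np.ndarray]) -> tuple[list[np.ndarray], np.ndarray]:
    """First principal component of pooled gyroscope (y, z) samples.

    Fitted once over all filtered segments of one participant-side, then
    applied per segment.  The component sign is chosen so the loading with
    the larger magnitude is positive, making angles comparable across runs.
    Returns (per-segment 1-D score series, loading vector).
    """
    if not segments_yz:
        raise ValueError("no segments provided")
    pooled = np.vstack([np.asarray(s, dtype=float) for s in segments_yz])
    if pooled.shape[0] < 2 or pooled.shape[1] != 2:
        raise ValueError("need at least 2 pooled samples of shape (n, 2)")
    mean = pooled.mean(axis=0)
    cov = np.cov(pooled - mean, rowvar=False)
    if not np.any(cov > 1e-15):
        raise ValueError("zero-variance gyroscope input")
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, int(np.argmax(evals))]
    if v[int(np.argmax(np.abs(v)))] < 0:
        v = -v
    return [(np.asarray(s, dtype=float) - mean) @ v for s in segments_yz], v


def integrate_angle(omega_deg_s: np.ndarray, sample_rate_hz: float, t0: float = 0.0) -> AngleSeries:
    """Cumulative trapezoidal integration of angular velocity; angle starts at 0."""
    omega = np.asarray(omega_deg_s, dtype=float)
    theta = cumulative_trapezoid(omega, dx=1.0 / sample_rate_hz, initial=0.0)
    return AngleSeries(time_s=t0 + np.arange(len(omega)) / sample_rate_hz, theta_deg=theta)


def remove_drift(angle: AngleSeries, sample_rate_hz: float, window_s: float = 1.0) -> AngleSeries:
    """Subtract a centered 1-s moving average (integration drift removal).

    The average is a symmetric trapezoid-weighted mean spanning exactly
    ``window_s`` (half-weight endpoints), so linear drift cancels exactly in
    the interior and a component periodic at 1/window_s passes unchanged;
    edge windows shrink.
    """
    half = max(int(round(window_s * sample_rate_hz / 2)), 1)
    kernel = np.ones(2 * half + 1)
    kernel[0] = kernel[-1] = 0.5
    theta = np.asarray(angle.theta_deg, dtype=float)
    num = np.convolve(theta, kernel, mode="same")
    den = np.convolve(np.ones_like(theta), kernel, mode="same")
    return AngleSeries(time_s=angle.time_s, theta_deg=theta - num / den)


def _raw_extrema(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices and types of local extrema; plateaus resolve to their midpoint."""
    d = np.diff(theta)
    nz = np.flatnonzero(d != 0)
    if nz.size < 2:
        return np.array([], dtype=int), np.array([], dtype=bool)
    signs = np.sign(d[nz])
    idx, is_max = [], []
    for k in range(len(nz) - 1):
        if signs[k] != signs[k + 1]:
            # extremum lies on the (possibly flat) stretch between the slopes
            i = (nz[k] + 1 + nz[k + 1]) // 2
            idx.append(int(i))
            is_max.append(signs[k] > 0)
    return np.asarray(idx, dtype=int), np.asarray(is_max, dtype=bool)


def apply_peak_rules(peaks: Peaks, min_spacing_s: float = MIN_PEAK_SPACING_S) -> Peaks:
    """The two peak-selection rules, applied to a candidate extrema sequence.

    Rule 1: a minimum may not be succeeded by another minimum, nor a maximum
    by another maximum; successive same-type extrema collapse to the one
    with the largest absolute value.  Rule 2: scanning left to right, a peak
    closer than ``min_spacing_s`` to the previously kept peak is discarded
    (the later peak goes).
    """
    t = np.asarray(peaks.times_s, dtype=float)
    v = np.asarray(peaks.values_deg, dtype=float)
    im = np.asarray(peaks.is_max, dtype=bool)
    # rule 1: enforce min/max alternation
    kept: list[int] = []
    for k in range(len(t)):
        if kept and im[kept[-1]] == im[k]:
            if abs(v[k]) > abs(v[kept[-1]]):
                kept[-1] = k
        else:
            kept.append(k)
    # rule 2: minimum spacing, discarding the later peak
    final: list[int] = []
    for k in kept:
        if final and t[k] - t[final[-1]] < min_spacing_s - 1e-9:
            continue
        final.append(k)
    fi = np.asarray(final, dtype=int)
    return Peaks(times_s=t[fi], values_deg=v[fi], is_max=im[fi])


def detect_peaks(angle: AngleSeries, min_spacing_s: float = MIN_PEAK_SPACING_S) -> Peaks:
    """Angle extrema under the two selection rules (see
    :func:`apply_peak_rules`).  Candidate extrema come from sign changes of
    the first difference, with plateaus resolved to their midpoint; a
    monotone series yields no peaks.
    """
    theta = np.asarray(angle.theta_deg, dtype=float)
    t = np.asarray(angle.time_s, dtype=float)
    idx, is_max = _raw_extrema(theta)
    raw = Peaks(times_s=t[idx], values_deg=theta[idx], is_max=is_max)
    return apply_peak_rules(raw, min_spacing_s)


def compute_rom(peaks: Peaks) -> RomSeries:
    """Absolute differences of the angle between consecutive peaks (degrees)."""
    if len(peaks.values_deg) < 2:
        return RomSeries(peak_times_s=np.array([]), rom_deg=np.array([]))
    rom = np.abs(np.diff(peaks.values_deg))
    return RomSeries(peak_times_s=peaks.times_s[1:], rom_deg=rom)


def aggregate_rom(
    rom: RomSeries,
    filtered_gait_minutes: float,
    min_minutes: float = MIN_FILTERED_MINUTES,
) -> ArmSwingAggregates:
    """Median and 95th-percentile RoM (linear percentile interpolation).

    Participant-sides with less than ``min_minutes`` of filtered gait are
    flagged excluded and yield no aggregates.
    """
    if filtered_gait_minutes < min_minutes:
        return ArmSwingAggregates(None, None, filtered_gait_minutes, len(rom), excluded=True)
    if len(rom) == 0:
        raise ValueError("no RoM values despite sufficient filtered gait")
    return ArmSwingAggregates(
        median_rom_deg=float(np.median(rom.rom_deg)),
        p95_rom_deg=float(np.percentile(rom.rom_deg, 95)),
        filtered_gait_minutes=filtered_gait_minutes,
        n_swings=len(rom),
    )


def quantify_arm_swing(
    blocks: list[ImuRecording],
    segments: list[GaitSegment],
    min_segment_s: float = 1.0,
) -> tuple[RomSeries, ArmSwingAggregates]:
    """Full RoM chain for one participant-side.

    Pools gyroscope y/z over all filtered segments for the PCA, then per
    segment integrates, detrends, detects peaks and computes RoM; returns the
    pooled RoM series and the participant-level aggregates.  Segments shorter
    than ``min_segment_s`` contribute no RoM (too short for detrending).
    """
    seg_data: list[np.ndarray] = []
    seg_meta: list[tuple[float, float]] = []  # (t0, fs)
    minutes = sum(s.duration_s for s in segments) / 60.0
    for seg in segments:
        for block in blocks:
            if len(block) == 0:
                continue
            i0 = int(np.searchsorted(block.time_s, seg.start_s - 1e-9, side="left"))
            i1 = int(np.searchsorted(block.time_s, seg.end_s + 1e-9, side="right"))
            if i1 - i0 < 2:
                continue
            if seg.duration_s < min_segment_s:
                continue
            seg_data.append(block.gyr[i0:i1, 1:3])
            seg_meta.append((float(block.time_s[i0]), block.sample_rate_hz))
            break
    if not seg_data:
        return RomSeries(np.array([]), np.array([])), aggregate_rom(
            RomSeries(np.array([]), np.array([])), 0.0
        )
    scores, _ = pca_swing_axis(seg_data)
    all_times, all_rom = [], []
    for pc, (t0, fs) in zip(scores, seg_meta):
        angle = integrate_angle(pc, fs, t0=t0)
        angle = remove_drift(angle, fs)
        rom = compute_rom(detect_peaks(angle))
        all_times.append(rom.peak_times_s)
        all_rom.append(rom.rom_deg)
    rom_series = RomSeries(np.concatenate(all_times), np.concatenate(all_rom))
    return rom_series, aggregate_rom(rom_series, minutes)
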