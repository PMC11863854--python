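"""Sliding-window spectral and temporal features.

Two tasks share one feature vocabulary: gait detection uses 6-s Hann windows
with 1-s steps and 34 accelerometer features (temporal SD of the dynamic
norm, 12 MFCCs of the dynamic norm, per-axis dominant frequency, per-axis
log band powers in four bands, per-axis gravity mean/SD); arm-activity
filtering uses 3-s windows with 0.75-s steps and adds 12 MFCCs of the
gyroscope norm (46 features).

Spectral conventions (fixed here so feature values are reproducible):
single-segment Hann-tapered one-sided periodogram normalized so that the
bin sum approximates signal power; band bins assigned half-open [lo, hi);
log floors at ``EPS``; MFCCs use 15 triangular mel filterbanks over
0-25 Hz, an orthonormal DCT-II, and exclude the 0th (energy) coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import fft as sp_fft
from scipy import signal

from .recording import ImuRecording

EPS = 1e-10

#: frequency bands (Hz), half-open [lo, hi)
BANDS: dict[str, tuple[float, float]] = {
    "below_gait": (0.0, 0.7),
    "gait": (0.7, 3.5),
    "tremor": (3.5, 8.0),
    "above_tremor": (8.0, 25.0),
}
_BAND_ORDER = ("below_gait", "gait", "tremor", "above_tremor")
_AXES = ("x", "y", "z")


@dataclass(frozen=True)
class WindowingSpec:
    length_s: float
    step_s: float
    taper: str = "hann"

    def __post_init__(self) -> None:
        if not (0 < self.step_s <= self.length_s):
            raise ValueError("need 0 < step_s <= length_s")
        if self.taper != "hann":
            raise ValueError("only the Hann taper is supported")


GAIT_WINDOWING = WindowingSpec(length_s=6.0, step_s=1.0)  # 6 s, 5 s overlap
ARM_WINDOWING = WindowingSpec(length_s=3.0, step_s=0.75)  # 3 s, 75% overlap


@dataclass(frozen=True)
class MfccSpec:
    n_coefficients: int = 12
    n_filterbanks: int = 15
    f_min: float = 0.0
    f_max: float = 25.0

    def __post_init__(self) -> None:
        if self.n_coefficients > self.n_filterbanks:
            raise ValueError("n_coefficients must be <= n_filterbanks")


DEFAULT_MFCC = MfccSpec()


def make_windows(n_samples: int, sample_rate_hz: float, spec: WindowingSpec) -> tuple[np.ndarray, int]:
    """Window start indices (multiples of the step) and the window length.

    The trailing remainder shorter than one window is dropped; a block
    shorter than one window yields no windows.
    """
    wlen = int(round(spec.length_s * sample_rate_hz))
    step = int(round(spec.step_s * sample_rate_hz))
    if n_samples < wlen:
        return np.array([], dtype=int), wlen
    return np.arange(0, n_samples - wlen + 1, step, dtype=int), wlen


def hann_periodogram(x: np.ndarray, sample_rate_hz: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Hann-tapered periodogram as power per frequency bin.

    Normalized so that the sum over all bins approximates the signal power
    (mean square) of the window.
    """
    x = np.asarray(x, dtype=float)
    freqs, psd = signal.periodogram(x, fs=sample_rate_hz, window="hann", detrend=False)
    return freqs, psd * (sample_rate_hz / len(x))


def band_log_power(x: np.ndarray, sample_rate_hz: float, band: tuple[float, float]) -> float:
    """log(EPS + total periodogram power in the half-open band [lo, hi))."""
    lo, hi = band
    if lo >= hi:
        raise ValueError("degenerate band: need lo < hi")
    if hi > sample_rate_hz / 2 + 1e-9:
        raise ValueError("band exceeds the Nyquist frequency")
    freqs, p = hann_periodogram(x, sample_rate_hz)
    mask = (freqs >= lo) & (freqs < hi)
    return float(np.log(EPS + p[mask].sum()))


def dominant_frequency(x: np.ndarray, sample_rate_hz: float, f_max: float = 25.0) -> float:
    """Frequency (Hz) with the highest periodogram power in [0, f_max].

    Ties break toward the lower frequency.
    """
    freqs, p = hann_periodogram(x, sample_rate_hz)
    mask = freqs <= f_max
    return float(freqs[mask][int(np.argmax(p[mask]))])


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(freqs: np.ndarray, spec: MfccSpec = DEFAULT_MFCC) -> np.ndarray:
    """(n_filterbanks, n_freqs) triangular mel-spaced filters over [f_min, f_max]."""
    mel_pts = np.linspace(_hz_to_mel(spec.f_min), _hz_to_mel(spec.f_max), spec.n_filterbanks + 2)
    hz_pts = _mel_to_hz(mel_pts)
    fb = np.zeros((spec.n_filterbanks, freqs.shape[0]))
    for j in range(spec.n_filterbanks):
        left, center, right = hz_pts[j], hz_pts[j + 1], hz_pts[j + 2]
        up = (freqs - left) / max(center - left, 1e-12)
        down = (right - freqs) / max(right - center, 1e-12)
        fb[j] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def mfcc(x: np.ndarray, sample_rate_hz: float, spec: MfccSpec = DEFAULT_MFCC) -> np.ndarray:
    """Mel-frequency cepstral coefficients 1..n of a (norm) signal window.

    Power spectrum -> triangular mel filterbank energies -> log (EPS floor)
    -> orthonormal DCT-II; the 0th coefficient is excluded, so a silent
    window yields exactly zero for every returned coefficient.
    """
    freqs, p = hann_periodogram(x, sample_rate_hz)
    mask = freqs <= spec.f_max
    energies = mel_filterbank(freqs[mask], spec) @ p[mask]
    log_e = np.log(EPS + energies)
    coeffs = sp_fft.dct(log_e, type=2, norm="ortho")
    return coeffs[1 : spec.n_coefficients + 1]


def gravity_window_stats(gravity: np.ndarray) -> np.ndarray:
    """Per-axis mean then per-axis population SD of a gravity window: 6 values."""
    gravity = np.asarray(gravity, dtype=float)
    return np.concatenate([gravity.mean(axis=0), gravity.std(axis=0)])


def temporal_std_norm(dynamic: np.ndarray) -> float:
    """Population SD of the Euclidean norm of the 3-axis dynamic signal."""
    return float(np.linalg.norm(np.asarray(dynamic, dtype=float), axis=1).std())


def _feature_names(include_gyro: bool) -> list[str]:
    names = ["std_norm_acc"]
    names += [f"mfcc_acc_{i}" for i in range(1, 13)]
    names += [f"dom_freq_{a}" for a in _AXES]
    names += [f"power_{b}_{a}" for a in _AXES for b in _BAND_ORDER]
    names += [f"grav_mean_{a}" for a in _AXES] + [f"grav_std_{a}" for a in _AXES]
    if include_gyro:
        names += [f"mfcc_gyr_{i}" for i in range(1, 13)]
    return names


GAIT_FEATURE_NAMES: tuple[str, ...] = tuple(_feature_names(include_gyro=False))  # 34
ARMFILTER_FEATURE_NAMES: tuple[str, ...] = tuple(_feature_names(include_gyro=True))  # 46


def _accel_features(dynamic: np.ndarray, gravity: np.ndarray, fs: float, mfcc_spec: MfccSpec) -> list[float]:
    vals: list[float] = [temporal_std_norm(dynamic)]
    norm_dyn = np.linalg.norm(dynamic, axis=1)
    vals += list(mfcc(norm_dyn, fs, mfcc_spec))
    for ax in range(3):
        vals.append(dominant_frequency(dynamic[:, ax], fs))
    for ax in range(3):
        for band in _BAND_ORDER:
            vals.append(band_log_power(dynamic[:, ax], fs, BANDS[band]))
    vals += list(gravity_window_stats(gravity))
    return vals


def _check_finite(values: np.ndarray, names: tuple[str, ...]) -> None:
    bad = np.flatnonzero(~np.isfinite(values))
    if bad.size:
        raise ValueError(f"non-finite feature value: {names[bad[0]]}")


def gait_feature_vector(
    dynamic: np.ndarray,
    gravity: np.ndarray,
    sample_rate_hz: float,
    mfcc_spec: MfccSpec = DEFAULT_MFCC,
) -> np.ndarray:
    """The 34 gait-detection features of one accelerometer window."""
    vals = np.asarray(_accel_features(dynamic, gravity, sample_rate_hz, mfcc_spec))
    _check_finite(vals, GAIT_FEATURE_NAMES)
    return vals


def armfilter_feature_vector(
    dynamic: np.ndarray,
    gravity: np.ndarray,
    gyr: np.ndarray,
    sample_rate_hz: float,
    mfcc_spec: MfccSpec = DEFAULT_MFCC,
) -> np.ndarray:
    """The 46 arm-activity-filter features: 34 accelerometer + 12 gyro MFCCs."""
    vals = _accel_features(dynamic, gravity, sample_rate_hz, mfcc_spec)
    vals += list(mfcc(np.linalg.norm(np.asarray(gyr, dtype=float), axis=1), sample_rate_hz, mfcc_spec))
    vals = np.asarray(vals)
    _check_finite(vals, ARMFILTER_FEATURE_NAMES)
    return vals


def extract_feature_table(
    block: ImuRecording,
    spec: WindowingSpec = GAIT_WINDOWING,
    include_gyro: bool = False,
    valid_span: tuple[float, float] | None = None,
    mfcc_spec: MfccSpec = DEFAULT_MFCC,
) -> pd.DataFrame:
    """Feature table of one contiguous preprocessed block.

    The block must carry its gravity decomposition (see
    :func:`armswing.preprocess.attach_gravity`).  ``valid_span`` optionally
    restricts windows to a time range (used to exclude filter-edge samples).
    Columns: ``start_s`` plus one column per named feature.
    """
    if block.acc_dynamic is None or block.acc_gravity is None:
        raise ValueError("block must carry a gravity decomposition")
    fs = block.sample_rate_hz
    starts, wlen = make_windows(len(block), fs, spec)
    names = ARMFILTER_FEATURE_NAMES if include_gyro else GAIT_FEATURE_NAMES
    rows, times = [], []
    for i0 in starts:
        t0 = float(block.time_s[i0])
        if valid_span is not None and not (t0 >= valid_span[0] and t0 + spec.length_s <= valid_span[1] + 1e-9):
            continue
        dyn = block.acc_dynamic[i0 : i0 + wlen]
        grav = block.acc_gravity[i0 : i0 + wlen]
        if include_gyro:
            rows.append(armfilter_feature_vector(dyn, grav, block.gyr[i0 : i0 + wlen], fs, mfcc_spec))
        else:
            rows.append(gait_feature_vector(dyn, grav, fs, mfcc_spec))
        times.append(t0)
    df = pd.DataFrame(rows, columns=list(names))
    df.insert(0, "start_s", times)
    return df
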