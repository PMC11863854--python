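"""Independent brute-force oracles used across the test suite.

Everything here is deliberately written from first principles (explicit DFT
sums, per-sample loops, closed-form expressions) rather than reusing any
code path from the package under test.
"""

from __future__ import annotations

import numpy as np


def periodic_hann(n: int) -> np.ndarray:
    return 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(n) / n)


def dft_power_spectrum(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Hann-tapered power-per-bin spectrum by explicit DFT sum.

    Normalized so the bin sum equals sum((w*x)^2)/sum(w^2): power of the
    tapered window.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    w = periodic_hann(n)
    xw = x * w
    k = np.arange(n // 2 + 1)
    basis = np.exp(-2j * np.pi * np.outer(k, np.arange(n)) / n)
    X = basis @ xw
    p = 2.0 * np.abs(X) ** 2 / (n * np.sum(w**2))
    p[0] /= 2.0
    if n % 2 == 0:
        p[-1] /= 2.0
    return k * fs / n, p


def band_power_oracle(x: np.ndarray, fs: float, lo: float, hi: float) -> float:
    freqs, p = dft_power_spectrum(x, fs)
    return float(p[(freqs >= lo) & (freqs < hi)].sum())


def dominant_frequency_oracle(x: np.ndarray, fs: float, f_max: float = 25.0) -> float:
    freqs, p = dft_power_spectrum(x, fs)
    m = freqs <= f_max
    fm, pm = freqs[m], p[m]
    return float(fm[int(np.argmax(pm))])


def mel_hz(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def hz_mel(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mfcc_oracle(
    x: np.ndarray,
    fs: float,
    n_coeff: int = 12,
    n_banks: int = 15,
    f_min: float = 0.0,
    f_max: float = 25.0,
    eps: float = 1e-10,
) -> np.ndarray:
    """Second MFCC implementation: explicit DFT, triangles, and DCT-II matrix."""
    freqs, p = dft_power_spectrum(x, fs)
    m = freqs <= f_max
    freqs, p = freqs[m], p[m]
    pts = hz_mel(np.linspace(mel_hz(f_min), mel_hz(f_max), n_banks + 2))
    energies = np.zeros(n_banks)
    for j in range(n_banks):
        left, center, right = pts[j], pts[j + 1], pts[j + 2]
        wts = np.minimum((freqs - left) / max(center - left, 1e-12), (right - freqs) / max(right - center, 1e-12))
        energies[j] = np.sum(np.clip(wts, 0, None) * p)
    log_e = np.log(eps + energies)
    # explicit orthonormal DCT-II
    n = n_banks
    coeffs = np.zeros(n)
    for k in range(n):
        c = np.sum(log_e * np.cos(np.pi * (np.arange(n) + 0.5) * k / n))
        coeffs[k] = c * (np.sqrt(1.0 / n) if k == 0 else np.sqrt(2.0 / n))
    return coeffs[1 : n_coeff + 1]


def majority_vote_oracle(
    times: np.ndarray,
    window_starts: np.ndarray,
    window_length: float,
    window_pred: np.ndarray,
) -> np.ndarray:
    """Per-sample vote counting by explicit loop over windows and samples."""
    out = np.zeros(len(times), dtype=bool)
    for i, t in enumerate(times):
        pos = tot = 0
        for s, pred in zip(window_starts, window_pred):
            if s - 1e-9 <= t < s + window_length - 1e-9:
                tot += 1
                pos += bool(pred)
        out[i] = pos * 2 > tot
    return out


def segments_oracle(times: np.ndarray, is_gait: np.ndarray, gap_s: float = 1.5) -> list[tuple[float, float]]:
    """Segment boundaries by a per-sample scan."""
    segs = []
    cur = None
    last = None
    for t, g in zip(times, is_gait):
        if not g:
            continue
        if cur is None:
            cur, last = t, t
        elif t - last > gap_s + 1e-9:
            segs.append((cur, last))
            cur, last = t, t
        else:
            last = t
    if cur is not None:
        segs.append((cur, last))
    return segs


def icc2_oracle(a: np.ndarray, b: np.ndarray) -> float:
    """ICC(2,1) via the two-way ANOVA mean squares (absolute agreement)."""
    x = np.column_stack([np.asarray(a, float), np.asarray(b, float)])
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
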