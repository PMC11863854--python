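"""Core containers: synchronized wrist IMU recordings and interval annotations.

An :class:`ImuRecording` holds a uniformly sampled triaxial accelerometer
(units g) and gyroscope (units deg/s) stream for one wrist.  An
:class:`AnnotationTrack` holds labeled, per-layer non-overlapping time
intervals: an ``activity`` layer (gait / sitting / standing / ...) and an
``arm_activity`` layer (per arm: holding_object / gesturing / ...), mirroring
video-annotation ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ACTIVITY_LAYER = "activity"
ARM_LAYER = "arm_activity"

ACTIVITY_LABELS = ("gait", "sitting", "standing", "turning", "stairs", "cycling", "other")
ARM_ACTIVITY_LABELS = ("holding_object", "hand_in_pocket", "gesturing", "pushing", "other")

IMU_COLUMNS = ["time_s", "acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z"]


@dataclass
class ImuRecording:
    """Synchronized triaxial accelerometer + gyroscope time series.

    Parameters
    ----------
    time_s : (n,) array
        Uniformly spaced timestamps in seconds (strictly increasing).
    acc : (n, 3) array
        Acceleration in g, canonical axis order (x, y, z).
    gyr : (n, 3) array
        Angular velocity in deg/s.
    sample_rate_hz : float
        Sampling rate; ``time_s`` must advance by ``1/sample_rate_hz``.
    side : {"left", "right"}
    orientation : {"A", "B"}
        Watch-strap orientation; "A" is the canonical frame.
    acc_gravity, acc_dynamic : optional (n, 3) arrays
        Filled by :func:`armswing.preprocess.attach_gravity`.
    """

    time_s: np.ndarray
    acc: np.ndarray
    gyr: np.ndarray
    sample_rate_hz: float
    side: str = "right"
    orientation: str = "A"
    acc_gravity: np.ndarray | None = None
    acc_dynamic: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyr = np.asarray(self.gyr, dtype=float)
        n = self.time_s.shape[0]
        if self.acc.shape != (n, 3) or self.gyr.shape != (n, 3):
            raise ValueError("acc and gyr must both have shape (n, 3) matching time_s")
        if self.side not in ("left", "right"):
            raise ValueError(f"unknown side {self.side!r}")
        if n >= 2:
            dt = np.diff(self.time_s)
            if np.any(dt <= 0):
                raise ValueError("time_s must be strictly increasing")
            if not np.allclose(dt, 1.0 / self.sample_rate_hz, rtol=1e-6, atol=1e-9):
                raise ValueError("time_s must be uniform with step 1/sample_rate_hz")

    def __len__(self) -> int:
        return self.time_s.shape[0]

    @property
    def duration_s(self) -> float:
        if len(self) == 0:
            return 0.0
        return float(len(self) / self.sample_rate_hz)

    def slice(self, start_idx: int, stop_idx: int) -> "ImuRecording":
        """Contiguous sub-recording by sample index (half-open)."""
        kw = {}
        for name in ("acc_gravity", "acc_dynamic"):
            arr = getattr(self, name)
            kw[name] = None if arr is None else arr[start_idx:stop_idx]
        return ImuRecording(
            time_s=self.time_s[start_idx:stop_idx],
            acc=self.acc[start_idx:stop_idx],
            gyr=self.gyr[start_idx:stop_idx],
            sample_rate_hz=self.sample_rate_hz,
            side=self.side,
            orientation=self.orientation,
            **kw,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "acc_x": self.acc[:, 0],
                "acc_y": self.acc[:, 1],
                "acc_z": self.acc[:, 2],
                "gyr_x": self.gyr[:, 0],
                "gyr_y": self.gyr[:, 1],
                "gyr_z": self.gyr[:, 2],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        sample_rate_hz: float | None = None,
        side: str = "right",
        orientation: str = "A",
    ) -> "ImuRecording":
        missing = [c for c in IMU_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        t = df["time_s"].to_numpy(dtype=float)
        if sample_rate_hz is None:
            if len(t) < 2:
                raise ValueError("cannot infer sample rate from fewer than 2 samples")
            sample_rate_hz = float(round(1.0 / np.median(np.diff(t))))
        return cls(
            time_s=t,
            acc=df[["acc_x", "acc_y", "acc_z"]].to_numpy(dtype=float),
            gyr=df[["gyr_x", "gyr_y", "gyr_z"]].to_numpy(dtype=float),
            sample_rate_hz=sample_rate_hz,
            side=side,
            orientation=orientation,
        )

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        sample_rate_hz: float | None = None,
        side: str = "right",
        orientation: str = "A",
    ) -> "ImuRecording":
        return cls.from_frame(pd.read_csv(path), sample_rate_hz, side, orientation)


@dataclass(frozen=True)
class Interval:
    start_s: float
    end_s: float
    layer: str
    label: str
    arm: str | None = None  # side for the arm_activity layer

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValueError(f"interval end ({self.end_s}) must exceed start ({self.start_s})")


class AnnotationTrack:
    """Labeled time intervals in named layers, non-overlapping per layer.

    The ``activity`` layer labels whole-body activity; the ``arm_activity``
    layer labels per-arm concurrent activities (intervals carry ``arm``).
    Time not covered by the activity layer is treated as unannotated.
    """

    def __init__(self, intervals: Iterable[Interval] = (), layers: Sequence[str] = (ACTIVITY_LAYER, ARM_LAYER)):
        self.layers = tuple(layers)
        self.intervals: list[Interval] = sorted(intervals, key=lambda iv: (iv.layer, iv.arm or "", iv.start_s))
        self._check_overlap()

    def _check_overlap(self) -> None:
        groups: dict[tuple[str, str | None], list[Interval]] = {}
        for iv in self.intervals:
            key = (iv.layer, iv.arm if iv.layer == ARM_LAYER else None)
            groups.setdefault(key, []).append(iv)
        for key, ivs in groups.items():
            ivs = sorted(ivs, key=lambda iv: iv.start_s)
            for a, b in zip(ivs, ivs[1:]):
                if b.start_s < a.end_s - 1e-12:
                    raise ValueError(f"overlapping intervals in layer {key}: {a} / {b}")

    def __len__(self) -> int:
        return len(self.intervals)

    def select(self, layer: str, arm: str | None = None) -> list[Interval]:
        out = [iv for iv in self.intervals if iv.layer == layer]
        if arm is not None:
            out = [iv for iv in out if iv.arm == arm]
        return out

    def labels_at(self, times: np.ndarray, layer: str = ACTIVITY_LAYER, arm: str | None = None) -> np.ndarray:
        """Per-sample label array; empty string where no interval covers.

        Intervals are half-open ``[start_s, end_s)``.
        """
        times = np.asarray(times, dtype=float)
        out = np.full(times.shape, "", dtype=object)
        for iv in self.select(layer, arm):
            mask = (times >= iv.start_s - 1e-9) & (times < iv.end_s - 1e-9)
            out[mask] = iv.label
        return out

    def covered_mask(self, times: np.ndarray, layer: str = ACTIVITY_LAYER, arm: str | None = None) -> np.ndarray:
        return self.labels_at(times, layer, arm) != ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"start_s": iv.start_s, "end_s": iv.end_s, "layer": iv.layer, "label": iv.label, "arm": iv.arm or ""}
                for iv in self.intervals
            ],
            columns=["start_s", "end_s", "layer", "label", "arm"],
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AnnotationTrack":
        ivs = []
        for row in df.itertuples(index=False):
            arm = getattr(row, "arm", "") or None
            if isinstance(arm, float) and np.isnan(arm):
                arm = None
            ivs.append(Interval(float(row.start_s), float(row.end_s), str(row.layer), str(row.label), arm))
        return cls(ivs)

    @classmethod
    def from_csv(cls, path: str | Path) -> "AnnotationTrack":
        return cls.from_frame(pd.read_csv(path, keep_default_na=False))
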