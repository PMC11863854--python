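"""Synthetic annotated wrist-IMU recordings with known ground truth.

The generator emulates the structure of a video-annotated free-living visit:
a timeline of activity bouts (gait, sitting, standing, turning, ...), arm
swing during gait modeled as a fundamental-plus-first-harmonic angular
oscillation carried by the gyroscope y/z axes, step-band accelerometer energy
near twice the swing frequency, optional rest-tremor-band (3.5-8 Hz)
acceleration during non-gait, and per-arm "other arm activity" sub-intervals
that damp the swing and add broadband gyroscope noise.  Every draw flows from
a single integer seed, so identical configurations reproduce byte-identical
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .recording import (
    ACTIVITY_LABELS,
    ACTIVITY_LAYER,
    ARM_ACTIVITY_LABELS,
    ARM_LAYER,
    AnnotationTrack,
    ImuRecording,
    Interval,
)

#: gravity unit vectors of canonical wrist poses (arm hanging, palm up, etc.)
CANONICAL_POSES: tuple[tuple[float, float, float], ...] = (
    (0.0, 0.0, 1.0),
    (0.0, 0.0, -1.0),
    (0.0, 1.0, 0.0),
    (0.707, 0.0, 0.707),
    (0.0, 0.707, 0.707),
)
#: pose during gait: arm hanging alongside the body, slight forearm rotation
GAIT_POSE = (0.0, 0.17, 0.985)

#: fixed unit direction of arm swing angular velocity in the gyro (y, z) plane
SWING_AXIS_YZ = (0.866, 0.5)

#: per non-gait activity: (band-pass limits in Hz or None for white, acc noise sd in g)
ACTIVITY_DYNAMICS: dict[str, tuple[tuple[float, float] | None, float]] = {
    "sitting": (None, 0.005),
    "standing": (None, 0.008),
    "turning": ((0.3, 1.5), 0.06),
    "stairs": ((1.2, 3.0), 0.08),
    "cycling": ((0.8, 2.5), 0.05),
    "other": ((0.3, 3.0), 0.04),
}

#: multiplicative swing-amplitude damping during other arm activities
ARM_ACTIVITY_DAMPING = 0.2
#: broadband gyroscope noise added during other arm activities (deg/s)
ARM_ACTIVITY_GYR_NOISE = 25.0
#: extra accelerometer noise during other arm activities (g)
ARM_ACTIVITY_ACC_NOISE = 0.02


@dataclass(frozen=True)
class ArmActivitySpec:
    """Sub-interval of a gait bout during which another arm activity occurs."""

    start_s: float
    end_s: float
    label: str = "holding_object"

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValueError("arm activity end must exceed start")
        if self.label not in ARM_ACTIVITY_LABELS:
            raise ValueError(f"unknown arm activity label {self.label!r}")


@dataclass(frozen=True)
class BoutSpec:
    """One activity bout on the timeline.

    Swing parameters are only meaningful for ``activity_label == "gait"``.
    ``swing_freq_hz`` must lie in (0, 0.9] so that angle extrema remain at
    least 1/1.8 s apart (the peak-spacing rule downstream).
    """

    start_s: float
    end_s: float
    activity_label: str = "gait"
    swing_amplitude_deg: float = 30.0
    swing_freq_hz: float = 0.5
    harmonic_fraction: float = 0.05
    arm_activity: ArmActivitySpec | None = None

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValueError("bout end must exceed start")
        if self.activity_label not in ACTIVITY_LABELS:
            raise ValueError(f"unknown activity label {self.activity_label!r}")
        if self.activity_label == "gait":
            if not (0.0 < self.swing_freq_hz <= 0.9):
                raise ValueError("swing_freq_hz must be in (0, 0.9]")
            if self.swing_amplitude_deg < 0:
                raise ValueError("swing_amplitude_deg must be >= 0")
        if self.arm_activity is not None:
            if self.arm_activity.start_s < self.start_s - 1e-9 or self.arm_activity.end_s > self.end_s + 1e-9:
                raise ValueError("arm activity sub-interval must lie within its bout")


@dataclass
class ScenarioConfig:
    """Full description of one synthetic recording; the seed fixes all noise."""

    duration_s: float
    sample_rate_hz: float = 100.0
    bouts: list[BoutSpec] = field(default_factory=list)
    tremor_band_power: float = 0.0  # sd (g) of the 3.5-8 Hz tremor component
    noise_sd_acc: float = 0.02  # white accelerometer measurement noise, g
    noise_sd_gyr: float = 2.0  # white gyroscope measurement noise, deg/s
    seed: int = 0
    side: str = "right"
    orientation: str = "A"

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be > 0")
        ivs = sorted(self.bouts, key=lambda b: b.start_s)
        for b in ivs:
            if b.start_s < -1e-9 or b.end_s > self.duration_s + 1e-9:
                raise ValueError("bout intervals must lie within [0, duration_s]")
        for a, b in zip(ivs, ivs[1:]):
            if b.start_s < a.end_s - 1e-9:
                raise ValueError(f"overlapping bouts: [{a.start_s}, {a.end_s}) and [{b.start_s}, {b.end_s})")


def _band_noise(rng: np.random.Generator, n: int, fs: float, band: tuple[float, float] | None, sd: float) -> np.ndarray:
    """White noise, optionally band-passed, rescaled to the target sd."""
    x = rng.standard_normal(n)
    if sd == 0.0 or n == 0:
        return np.zeros(n)
    if band is not None and n > 30:
        lo = max(band[0], 0.01)
        hi = min(band[1], 0.999 * fs / 2)
        sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
        padlen = min(3 * (2 * sos.shape[0] + 1), n - 1)
        x = signal.sosfiltfilt(sos, x, padlen=padlen)
    s = x.std()
    if s > 0:
        x = x * (sd / s)
    return x


def simulate_recording(config: ScenarioConfig) -> tuple[ImuRecording, AnnotationTrack]:
    """Synthesize one annotated recording from a scenario description.

    Returns the recording (canonical orientation unless ``config.orientation``
    is "B", in which case the stored axes are sign-flipped the way the
    alternate strap orientation would record them) and the exactly matching
    annotation track.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = config.sample_rate_hz
    n = int(round(config.duration_s * fs))
    t = np.arange(n) / fs

    acc = np.zeros((n, 3))
    gyr = np.zeros((n, 3))
    covered = np.zeros(n, dtype=bool)
    intervals: list[Interval] = []

    for bout in sorted(config.bouts, key=lambda b: b.start_s):
        i0 = int(np.searchsorted(t, bout.start_s - 1e-9, side="left"))
        i1 = int(np.searchsorted(t, bout.end_s - 1e-9, side="left"))
        if i1 <= i0:
            continue
        idx = slice(i0, i1)
        m = i1 - i0
        tb = t[idx]
        covered[idx] = True
        intervals.append(Interval(bout.start_s, bout.end_s, ACTIVITY_LAYER, bout.activity_label))

        if bout.activity_label == "gait":
            A = bout.swing_amplitude_deg
            f = bout.swing_freq_hz
            h = bout.harmonic_fraction
            phase = rng.uniform(0, 2 * math.pi)
            # omega = d/dt [A sin(2pi f t + phase) + h A sin(4pi f t + 2 phase)]
            omega = A * 2 * math.pi * f * np.cos(2 * math.pi * f * tb + phase)
            omega = omega + h * A * 4 * math.pi * f * np.cos(4 * math.pi * f * tb + 2 * phase)
            damping = np.ones(m)
            if bout.arm_activity is not None:
                aa = bout.arm_activity
                aa_mask = (tb >= aa.start_s - 1e-9) & (tb < aa.end_s - 1e-9)
                damping[aa_mask] = ARM_ACTIVITY_DAMPING
                intervals.append(Interval(aa.start_s, aa.end_s, ARM_LAYER, aa.label, arm=config.side))
            omega = omega * damping
            gyr[idx, 1] += SWING_AXIS_YZ[0] * omega
            gyr[idx, 2] += SWING_AXIS_YZ[1] * omega

            acc[idx] += np.asarray(GAIT_POSE)
            # step impacts concentrate near twice the swing frequency
            step_band = (max(0.3, 2 * f - 0.6), 2 * f + 0.6)
            for ax in range(3):
                acc[i0:i1, ax] += _band_noise(rng, m, fs, step_band, 0.12)
            if bout.arm_activity is not None:
                aa_mask = (tb >= bout.arm_activity.start_s - 1e-9) & (tb < bout.arm_activity.end_s - 1e-9)
                for ax in range(3):
                    extra_g = rng.standard_normal(m) * ARM_ACTIVITY_GYR_NOISE
                    gyr[i0:i1, ax] += np.where(aa_mask, extra_g, 0.0)
                    extra_a = rng.standard_normal(m) * ARM_ACTIVITY_ACC_NOISE
                    acc[i0:i1, ax] += np.where(aa_mask, extra_a, 0.0)
        else:
            pose = CANONICAL_POSES[int(rng.integers(len(CANONICAL_POSES)))]
            acc[idx] += np.asarray(pose)
            band, sd = ACTIVITY_DYNAMICS.get(bout.activity_label, (None, 0.01))
            for ax in range(3):
                acc[i0:i1, ax] += _band_noise(rng, m, fs, band, sd)
            if bout.activity_label in ("turning", "cycling", "stairs"):
                for ax in range(3):
                    gyr[i0:i1, ax] += _band_noise(rng, m, fs, (0.3, 2.0), 20.0)
            if config.tremor_band_power > 0:
                for ax in range(3):
                    acc[i0:i1, ax] += _band_noise(rng, m, fs, (3.5, 8.0), config.tremor_band_power)

    # unannotated time: wrist at rest, gravity only
    acc[~covered] += np.asarray([0.0, 0.0, 1.0])

    if config.noise_sd_acc > 0:
        acc += rng.standard_normal((n, 3)) * config.noise_sd_acc
    if config.noise_sd_gyr > 0:
        gyr += rng.standard_normal((n, 3)) * config.noise_sd_gyr

    if config.orientation == "B":
        from .preprocess import ORIENTATION_SIGN_MAP

        acc = acc * ORIENTATION_SIGN_MAP
        gyr = gyr * ORIENTATION_SIGN_MAP
    elif config.orientation != "A":
        raise ValueError(f"unknown orientation {config.orientation!r}")

    rec = ImuRecording(
        time_s=t, acc=acc, gyr=gyr, sample_rate_hz=fs, side=config.side, orientation=config.orientation
    )
    return rec, AnnotationTrack(intervals)


# ---------------------------------------------------------------------------
# cohort-level generation


@dataclass
class SubjectRecording:
    """One simulated subject visit with its ground truth."""

    subject_id: str
    group: str  # "pd" or "control"
    state: str  # "pre", "post" or "na"
    config: ScenarioConfig
    recording: ImuRecording
    annotations: AnnotationTrack
    swing_amplitude_deg: float
    swing_freq_hz: float


_GAIT_DURATION_BINS = ((3.0, 5.0), (5.0, 10.0), (10.0, 20.0), (20.0, 45.0))
_GAIT_DURATION_PROBS = (0.15, 0.2, 0.15, 0.5)
_NONGAIT_LABELS = ("sitting", "standing", "turning", "stairs", "cycling", "other")
_NONGAIT_PROBS = (0.45, 0.3, 0.1, 0.05, 0.05, 0.05)


def random_scenario(
    duration_s: float,
    seed: int,
    *,
    swing_amplitude_deg: float = 30.0,
    swing_freq_hz: float = 0.6,
    harmonic_fraction: float = 0.05,
    gait_prob: float = 0.6,
    arm_activity_prob: float = 0.5,
    tremor_band_power: float = 0.0,
    noise_sd_acc: float = 0.02,
    noise_sd_gyr: float = 2.0,
    side: str = "right",
) -> ScenarioConfig:
    """Random but reproducible visit timeline: non-gait bouts interleaved with
    gait bouts whose durations follow the four duration categories, and whose
    swing may be perturbed by one other-arm-activity sub-interval."""
    rng = np.random.default_rng(seed)
    bouts: list[BoutSpec] = []
    tcur = 0.0
    while tcur < duration_s - 5.0:
        label = _NONGAIT_LABELS[rng.choice(len(_NONGAIT_LABELS), p=_NONGAIT_PROBS)]
        dur = rng.uniform(15.0, 45.0)
        end = min(tcur + dur, duration_s)
        bouts.append(BoutSpec(tcur, end, activity_label=label))
        tcur = end
        if tcur >= duration_s - 5.0:
            break
        if rng.uniform() < gait_prob:
            lo, hi = _GAIT_DURATION_BINS[rng.choice(4, p=_GAIT_DURATION_PROBS)]
            gdur = rng.uniform(lo, hi)
            gend = min(tcur + gdur, duration_s)
            aa = None
            if rng.uniform() < arm_activity_prob and gend - tcur > 3.0:
                frac = rng.uniform(0.3, 0.9)
                adur = frac * (gend - tcur)
                a0 = tcur + rng.uniform(0, (gend - tcur) - adur)
                aa = ArmActivitySpec(a0, a0 + adur, ARM_ACTIVITY_LABELS[int(rng.integers(len(ARM_ACTIVITY_LABELS)))])
            bouts.append(
                BoutSpec(
                    tcur,
                    gend,
                    activity_label="gait",
                    swing_amplitude_deg=swing_amplitude_deg,
                    swing_freq_hz=swing_freq_hz,
                    harmonic_fraction=harmonic_fraction,
                    arm_activity=aa,
                )
            )
            tcur = gend
    return ScenarioConfig(
        duration_s=duration_s,
        bouts=bouts,
        tremor_band_power=tremor_band_power,
        noise_sd_acc=noise_sd_acc,
        noise_sd_gyr=noise_sd_gyr,
        seed=int(rng.integers(2**31)),
        side=side,
    )


def simulate_subject(
    subject_id: str,
    seed: int,
    *,
    group: str = "pd",
    state: str = "pre",
    duration_s: float = 300.0,
    swing_amplitude_deg: float | None = None,
    swing_freq_hz: float | None = None,
    arm_activity_prob: float = 0.5,
    tremor_band_power: float = 0.0,
    noise_sd_acc: float = 0.02,
    noise_sd_gyr: float = 2.0,
) -> SubjectRecording:
    """Simulate one visit; subject-level swing parameters drawn by group.

    Controls swing larger (~35 deg) than PD pre-medication (~18 deg); the
    post-medication state adds ~10 deg, matching the direction of reported
    group and medication effects.
    """
    rng = np.random.default_rng(seed)
    if swing_amplitude_deg is None:
        if group == "control":
            swing_amplitude_deg = float(np.clip(rng.normal(35.0, 8.0), 15.0, 60.0))
        else:
            base = float(np.clip(rng.normal(18.0, 6.0), 5.0, 40.0))
            swing_amplitude_deg = base + (float(np.clip(rng.normal(10.0, 3.0), 2.0, 20.0)) if state == "post" else 0.0)
    if swing_freq_hz is None:
        swing_freq_hz = float(rng.uniform(0.4, 0.85))
    cfg = random_scenario(
        duration_s,
        seed=int(rng.integers(2**31)),
        swing_amplitude_deg=swing_amplitude_deg,
        swing_freq_hz=swing_freq_hz,
        arm_activity_prob=arm_activity_prob,
        tremor_band_power=tremor_band_power,
        noise_sd_acc=noise_sd_acc,
        noise_sd_gyr=noise_sd_gyr,
    )
    rec, ann = simulate_recording(cfg)
    return SubjectRecording(
        subject_id=subject_id,
        group=group,
        state=state,
        config=cfg,
        recording=rec,
        annotations=ann,
        swing_amplitude_deg=swing_amplitude_deg,
        swing_freq_hz=swing_freq_hz,
    )


def simulate_cohort(
    n_subjects: int,
    seed: int,
    *,
    group: str = "pd",
    state: str = "pre",
    duration_s: float = 300.0,
    **kwargs,
) -> list[SubjectRecording]:
    """Independent subjects with per-subject seeds derived from ``seed``."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_subjects):
        out.append(
            simulate_subject(
                f"{group}{i:02d}",
                seed=int(rng.integers(2**31)),
                group=group,
                state=state,
                duration_s=duration_s,
                **kwargs,
            )
        )
    return out
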