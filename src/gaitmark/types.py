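"""Core domain types shared across the gait pipeline.

All times are seconds, lengths meters, angular velocity rad/s and
acceleration m/s^2 unless a field says otherwise.  Types are plain
dataclasses with invariant checks in ``__post_init__`` so that malformed
objects fail loudly at construction time rather than deep inside a
detection routine.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

Foot = Literal["left", "right"]
EventKind = Literal["HS", "TO"]
Placement = Literal["left_foot", "right_foot", "lumbar"]
Modality = Literal["foot_imu", "lumbar_imu", "kinect", "reference"]


def _other(foot: Foot) -> Foot:
    return "left" if foot == "right" else "right"


# ---------------------------------------------------------------------------
# Simulation profile and ground truth
# ---------------------------------------------------------------------------

@dataclass
class GaitProfile:
    """Construction parameters for a synthetic walking trial.

    ``stance_fraction`` and ``double_support_fraction`` are fractions of
    the stride time; the initial double-support of each stride is
    ``double_support_fraction/2 x stride``.  Together with per-foot
    alternation these force the contralateral step time to
    ``(1 + ds/2 - stance) x stride``; the defaults are chosen
    self-consistent (``ds = 2*stance - 1``) which yields symmetric step
    times of half a stride.
    """

    stride_time_mean: float = 1.08
    stride_time_sd: float = 0.04
    stance_fraction: float = 0.657
    double_support_fraction: float = 0.314
    step_length_mean: float = 0.63
    step_length_sd: float = 0.02
    path_length: float = 7.0
    n_passes: int = 2
    asymmetry_ratio: float = 1.0  # left/right step-length ratio

    def __post_init__(self) -> None:
        if not (0.0 < self.double_support_fraction < self.stance_fraction < 1.0):
            raise ValueError(
                "require 0 < double_support_fraction < stance_fraction < 1"
            )
        if self.stride_time_mean <= 0 or self.step_length_mean <= 0:
            raise ValueError("stride_time_mean and step_length_mean must be > 0")
        if self.path_length <= 0 or self.n_passes < 1:
            raise ValueError("path_length > 0 and n_passes >= 1 required")
        if self.asymmetry_ratio <= 0:
            raise ValueError("asymmetry_ratio must be > 0")
        # ordering HS_F < TO_C < HS_C < TO_F < HS_F' inside each stride
        step_frac = 1.0 + self.double_support_fraction / 2.0 - self.stance_fraction
        if not (self.double_support_fraction / 2.0 < step_frac < self.stance_fraction):
            raise ValueError(
                "stance/double-support fractions do not admit a valid event order"
            )

    @property
    def step_time_fraction(self) -> float:
        """Contralateral step time as a fraction of stride time."""
        return 1.0 + self.double_support_fraction / 2.0 - self.stance_fraction


@dataclass(frozen=True)
class GaitEvent:
    time: float
    foot: Foot
    kind: EventKind
    pass_index: int


@dataclass
class GroundTruthEvents:
    """Timestamped, side-labelled HS/TO trains plus per-step lengths.

    ``step_lengths`` maps the index (into ``events``) of each heel strike
    to the length of the step ending at that heel strike.  ``positions``
    carries the signed along-path coordinate of the landing foot at each
    HS (used by the skeleton synthesizer); it mirrors ``step_lengths``.
    """

    events: list[GaitEvent]
    step_lengths: list[tuple[int, float]] = field(default_factory=list)
    positions: list[tuple[int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        by_pass: dict[int, list[GaitEvent]] = {}
        for ev in self.events:
            by_pass.setdefault(ev.pass_index, []).append(ev)
        for evs in by_pass.values():
            times = [e.time for e in evs]
            if any(b <= a for a, b in zip(times, times[1:])):
                raise ValueError("events within a pass must strictly increase in time")
        for foot in ("left", "right"):
            kinds = [e.kind for e in self.events if e.foot == foot]
            if any(a == b for a, b in zip(kinds, kinds[1:])):
                raise ValueError(f"{foot}-foot events must alternate HS/TO")

    def times(self, foot: Foot, kind: EventKind) -> np.ndarray:
        return np.array(
            [e.time for e in self.events if e.foot == foot and e.kind == kind]
        )

    @property
    def t_end(self) -> float:
        return self.events[-1].time if self.events else 0.0

    def shifted(self, dt: float) -> "GroundTruthEvents":
        evs = [replace(e, time=e.time + dt) for e in self.events]
        return GroundTruthEvents(evs, list(self.step_lengths), list(self.positions))


@dataclass
class SensorNoise:
    """Additive Gaussian noise plus a slow sinusoidal drift."""

    gaussian_sd: float = 0.0
    drift_amplitude: float = 0.0
    drift_period: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gaussian_sd < 0 or self.drift_amplitude < 0:
            raise ValueError("noise magnitudes must be >= 0")
        if self.drift_period <= 0:
            raise ValueError("drift_period must be > 0")


# ---------------------------------------------------------------------------
# Sensor streams
# ---------------------------------------------------------------------------

@dataclass
class ImuRecording:
    """Uniformly sampled 6-axis inertial recording."""

    fs: float
    t: np.ndarray
    gyro_xyz: np.ndarray   # shape (n, 3)
    accel_xyz: np.ndarray  # shape (n, 3)
    placement: Placement
    axis_convention: str = "y outward from skin; z toward ground (right-hand rule)"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.gyro_xyz = np.asarray(self.gyro_xyz, dtype=float)
        self.accel_xyz = np.asarray(self.accel_xyz, dtype=float)
        n = len(self.t)
        if self.gyro_xyz.shape != (n, 3) or self.accel_xyz.shape != (n, 3):
            raise ValueError("gyro/accel must be (n, 3) matching the time grid")
        if n > 1:
            dt = np.diff(self.t)
            if np.max(np.abs(dt - 1.0 / self.fs)) >= 1e-9:
                raise ValueError("time grid must be uniform at 1/fs")

    @property
    def n(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class SkeletonFrame:
    time: float
    body_id: int
    joints: dict[str, tuple[float, float, float]]  # name -> (x, y, z) meters


@dataclass
class SkeletonRecording:
    """Per-frame, per-body joint positions in camera coordinates.

    x is lateral, y vertical, z depth (distance from the camera).
    """

    frames: list[SkeletonFrame]

    def __post_init__(self) -> None:
        seen: set[tuple[float, int]] = set()
        last_t = -np.inf
        for fr in self.frames:
            if fr.time < last_t:
                raise ValueError("frame times must be non-decreasing")
            last_t = fr.time
            key = (fr.time, fr.body_id)
            if key in seen:
                raise ValueError("duplicate (time, body_id) frame")
            seen.add(key)

    def body_ids(self) -> list[int]:
        return sorted({fr.body_id for fr in self.frames})

    def frame_times(self) -> np.ndarray:
        return np.unique([fr.time for fr in self.frames])

    def body_frames(self, body_id: int) -> list[SkeletonFrame]:
        return [fr for fr in self.frames if fr.body_id == body_id]


@dataclass
class SyncSignal:
    """Two-level TTL trigger: 5 V idle, 0 V during active tasks."""

    fs: float
    level: np.ndarray  # volts per sample, values in {0, 5}

    def __post_init__(self) -> None:
        self.level = np.asarray(self.level, dtype=float)
        if not np.all(np.isin(self.level, (0.0, 5.0))):
            raise ValueError("trigger levels must be exactly 0 or 5 volts")

    @property
    def t(self) -> np.ndarray:
        return np.arange(len(self.level)) / self.fs


# ---------------------------------------------------------------------------
# Detection outputs
# ---------------------------------------------------------------------------

@dataclass
class EventSeries:
    """Detected HS/TO times for one foot from one modality."""

    foot: Foot
    hs_times: np.ndarray
    to_times: np.ndarray
    modality: Modality
    empty_warning: bool = False

    def __post_init__(self) -> None:
        self.hs_times = np.asarray(self.hs_times, dtype=float)
        self.to_times = np.asarray(self.to_times, dtype=float)
        for arr in (self.hs_times, self.to_times):
            if arr.size > 1 and np.any(np.diff(arr) <= 0):
                raise ValueError("event times must strictly increase")
        merged = sorted(
            [(t, "HS") for t in self.hs_times] + [(t, "TO") for t in self.to_times]
        )
        kinds = [k for _, k in merged]
        if any(a == b for a, b in zip(kinds, kinds[1:])):
            raise ValueError("per-foot HS/TO sequence must alternate")

    @property
    def n_events(self) -> int:
        return self.hs_times.size + self.to_times.size


@dataclass
class PeakParams:
    """Thresholds handed to peak detection (heights in signal units)."""

    min_height: float = 0.0
    min_prominence: float = 0.0
    min_distance: float = 0.0  # seconds

    def __post_init__(self) -> None:
        if min(self.min_height, self.min_prominence, self.min_distance) < 0:
            raise ValueError("peak parameters must be >= 0")


@dataclass
class CwtConfig:
    """Wavelet-differentiation settings for the lumbar pipeline."""

    wavelet: str = "gaus1"
    scale: float = 14.0  # samples
    scale_rule: Literal["fixed", "from_step_frequency"] = "fixed"
    sign: float = -1.0  # fixed so HS appear as minima (see lumbar_imu docs)

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be > 0")


@dataclass
class ParticipantTrack:
    """The single tracked body identified as the walking participant."""

    body_id: int
    frames: list[SkeletonFrame]
    coverage: float

    def __post_init__(self) -> None:
        if not (0.0 < self.coverage <= 1.0):
            raise ValueError("coverage must be in (0, 1]")


# ---------------------------------------------------------------------------
# Sync / segmentation
# ---------------------------------------------------------------------------

@dataclass
class TaskWindow:
    label: str  # practice | single_task | dual_task | extra_k
    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("window start must precede end")

    @property
    def duration(self) -> float:
        return self.end - self.start


# ---------------------------------------------------------------------------
# Markers and agreement
# ---------------------------------------------------------------------------

@dataclass
class StrideRecord:
    """All temporal (and, when available, spatial) markers of one stride."""

    foot: Foot
    step_time: float
    stride_time: float
    stance_time: float
    swing_time: float
    single_support: float
    ds_initial: float
    ds_terminal: float
    ds_total: float
    step_length: float | None = None
    stride_length: float | None = None
    stride_velocity: float | None = None
    start_time: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "step_time", "stride_time", "stance_time", "swing_time",
            "single_support", "ds_initial", "ds_terminal", "ds_total",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class TrialSummary:
    """Per-marker mean and SD over the retained strides of one trial."""

    task: str
    n_strides: int
    means: dict[str, float]
    sds: dict[str, float]

    def __post_init__(self) -> None:
        if self.n_strides < 1:
            raise ValueError("a summary needs at least one retained stride")


@dataclass
class WeinbergParams:
    """Calibration for the quarter-power step-length estimator."""

    K: float
    pitch_source: str = "medial-lateral gyro integrated per segment, drift reset"

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError("K must be > 0")


@dataclass
class PairedMarkerSample:
    marker: str
    units: str
    ref_values: np.ndarray
    test_values: np.ndarray

    def __post_init__(self) -> None:
        self.ref_values = np.asarray(self.ref_values, dtype=float)
        self.test_values = np.asarray(self.test_values, dtype=float)
        if self.ref_values.shape != self.test_values.shape:
            raise ValueError("ref/test must be aligned")
        if self.ref_values.size < 2:
            raise ValueError("need at least two paired observations")

    @property
    def n(self) -> int:
        return self.ref_values.size


@dataclass
class AgreementResult:
    marker: str
    units: str
    mae_mean: float
    mae_sd: float
    maep: float | None
    r: float | None
    p_value: float | None
    bias: float
    loa_low: float
    loa_high: float

    def __post_init__(self) -> None:
        if not (self.loa_low - 1e-12 <= self.bias <= self.loa_high + 1e-12):
            raise ValueError("bias must lie within the limits of agreement")
        if self.r is not None and abs(self.r) > 1 + 1e-12:
            raise ValueError("|r| must be <= 1")
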