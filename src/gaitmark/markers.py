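"""Spatiotemporal gait markers from heel-strike / toe-off event trains.

Temporal markers are computed per foot and per stride.  For a stride of
foot F running HS_F(i) -> HS_F(i+1), with the contralateral foot C:

======================  =================================================
step time               HS_F(i) - preceding HS_C
stride time             HS_F(i+1) - HS_F(i)
stance time             next TO_F after HS_F(i), minus HS_F(i)
swing time              stride - stance
initial double support  first TO_C after HS_F(i), minus HS_F(i)
terminal double support own TO_F minus the HS_C inside the stride
single support          HS_C - TO_C inside the stride (contralateral swing)
double support          initial + terminal
======================  =================================================

These satisfy stance = single support + total double support and
stride = stance + swing identically.  Strides that are not fully inside
the supplied walking mask - including the preceding contralateral heel
strike used for step time - are dropped, mirroring how a pressure
walkway excludes partial or off-mat steps at the turn.

Spatial markers are modality-specific and attached afterwards: the
quarter-power (Weinberg) range estimator for foot sensors, the inverted
pendulum model for the lumbar sensor, and ankle-depth differences for
the depth camera.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.signal import detrend

from .types import EventSeries, Foot, ImuRecording, StrideRecord, TrialSummary

G = 9.81

MARKER_NAMES = (
    "velocity", "cadence", "step_time", "stride_time", "stance_time",
    "swing_time", "single_support", "double_support",
    "step_length", "stride_length", "stride_velocity",
)

#: units per marker, in the scale conventionally reported (cm, s, cm/s)
MARKER_UNITS = {
    "velocity": "cm/s", "cadence": "steps/min", "step_time": "s",
    "stride_time": "s", "stance_time": "s", "swing_time": "s",
    "single_support": "s", "double_support": "s",
    "step_length": "cm", "stride_length": "cm", "stride_velocity": "cm/s",
}


def _in_mask(mask: list[tuple[float, float]] | None, *times: float) -> bool:
    if mask is None:
        return True
    return any(all(a - 1e-9 <= t <= b + 1e-9 for t in times) for a, b in mask)


def temporal_markers(
    events_left: EventSeries,
    events_right: EventSeries,
    mask: list[tuple[float, float]] | None = None,
) -> list[StrideRecord]:
    """Per-stride temporal markers for both feet.

    ``mask`` is a list of retained walking intervals; a stride is kept
    only when every event it uses falls inside one interval.  Strides
    with missing interleaved events are dropped.
    """
    series = {"left": events_left, "right": events_right}
    records: list[StrideRecord] = []
    for foot in ("left", "right"):
        own, contra = series[foot], series["left" if foot == "right" else "right"]
        for i in range(len(own.hs_times) - 1):
            a, b = own.hs_times[i], own.hs_times[i + 1]
            prev_c = contra.hs_times[contra.hs_times < a]
            to_c_in = contra.to_times[(contra.to_times > a) & (contra.to_times < b)]
            hs_c_in = contra.hs_times[(contra.hs_times > a) & (contra.hs_times < b)]
            to_own = own.to_times[(own.to_times > a) & (own.to_times < b)]
            if not (len(prev_c) and len(to_c_in) and len(hs_c_in) and len(to_own)):
                continue
            step_prev = prev_c[-1]
            to_c, hs_c, to_f = to_c_in[0], hs_c_in[0], to_own[0]
            if not _in_mask(mask, step_prev, a, to_c, hs_c, to_f, b):
                continue
            if not (a < to_c < hs_c < to_f < b):
                continue  # malformed interleaving
            if a - step_prev >= b - a:
                continue  # preceding contralateral HS missed: step > stride
            stride = b - a
            stance = to_f - a
            rec = StrideRecord(
                foot=foot,  # type: ignore[arg-type]
                step_time=a - step_prev,
                stride_time=stride,
                stance_time=stance,
                swing_time=stride - stance,
                single_support=hs_c - to_c,
                ds_initial=to_c - a,
                ds_terminal=to_f - hs_c,
                ds_total=(to_c - a) + (to_f - hs_c),
                start_time=a,
            )
            records.append(rec)
    records.sort(key=lambda r: r.start_time)
    return records


# ---------------------------------------------------------------------------
# Foot-sensor step length (quarter-power range estimator)
# ---------------------------------------------------------------------------

def vertical_acceleration_series(rec: ImuRecording, segment: tuple[float, float]) -> np.ndarray:
    """Gravity-free vertical acceleration over a segment of a foot IMU.

    aZ = ax*sin(theta) + az*cos(theta) - g, with the pitch angle theta
    obtained by integrating the medial-lateral angular velocity over the
    segment (linear drift reset per segment).
    """
    t0, t1 = segment
    sel = (rec.t >= t0) & (rec.t < t1)
    if sel.sum() < 3:
        raise ValueError("segment too short")
    gy = rec.gyro_xyz[sel, 1]
    theta = detrend(cumulative_trapezoid(gy, dx=1.0 / rec.fs, initial=0.0), type="linear")
    ax = rec.accel_xyz[sel, 0]
    az = rec.accel_xyz[sel, 2]
    return ax * np.sin(theta) + az * np.cos(theta) - G


def weinberg_length(aZ_segment: np.ndarray, K: float) -> float:
    """Step (or stride) length ``K * (max(aZ) - min(aZ))**(1/4)``.

    A flat segment yields 0 (degenerate but not an error).
    """
    aZ_segment = np.asarray(aZ_segment, dtype=float)
    rng = float(aZ_segment.max() - aZ_segment.min())
    return K * rng ** 0.25


def calibrate_K(range_roots: list[float] | np.ndarray, true_total_distance: float) -> float:
    """Subject-specific constant from a calibration walk of known length.

    ``range_roots`` are the per-step (amax - amin)**(1/4) values; the
    returned K makes the summed estimated lengths match the walked
    distance exactly (zero mean bias on the calibration pass).
    """
    roots = np.asarray(range_roots, dtype=float)
    if roots.size < 3:
        raise ValueError("need at least 3 steps to calibrate")
    if true_total_distance <= 0:
        raise ValueError("distance must be > 0")
    s = roots.sum()
    if s <= 0:
        raise ValueError("zero total range root: cannot calibrate")
    return float(true_total_distance / s)


# ---------------------------------------------------------------------------
# Lumbar step length (inverted pendulum)
# ---------------------------------------------------------------------------

def pendulum_step_length(h: float, l: float) -> float:
    """``SL = 2*sqrt(2*l*h - h^2)`` - chord of a pendulum of length l
    whose bob rises by h during the step.  Requires 0 <= h < 2l."""
    if not 0 <= h < 2 * l:
        raise ValueError("require 0 <= h < 2*l for a real solution")
    return 2.0 * np.sqrt(2.0 * l * h - h * h)


# ---------------------------------------------------------------------------
# Trial aggregation
# ---------------------------------------------------------------------------

def macro_and_spatiotemporal(strides: list[StrideRecord]) -> TrialSummary:
    """Mean +- SD per marker over the retained strides, plus macro markers.

    cadence  = 2 * n_strides / sum(stride times) * 60   [steps/min]
    velocity = sum(stride lengths) / sum(stride times)  [cm/s]

    Length-sum over time-sum (rather than distance over wall-clock time)
    matches walkway-style velocity computed on retained footfalls only.
    """
    if not strides:
        raise ValueError("no retained strides")
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    per_stride = {
        "step_time": [s.step_time for s in strides],
        "stride_time": [s.stride_time for s in strides],
        "stance_time": [s.stance_time for s in strides],
        "swing_time": [s.swing_time for s in strides],
        "single_support": [s.single_support for s in strides],
        "double_support": [s.ds_total for s in strides],
        "step_length": [s.step_length * 100 for s in strides if s.step_length is not None],
        "stride_length": [s.stride_length * 100 for s in strides if s.stride_length is not None],
        "stride_velocity": [
            s.stride_length / s.stride_time * 100
            for s in strides
            if s.stride_length is not None and s.stride_time > 0
        ],
    }
    for name, vals in per_stride.items():
        if vals:
            arr = np.asarray(vals, dtype=float)
            means[name] = float(arr.mean())
            sds[name] = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    total_time = float(sum(s.stride_time for s in strides))
    means["cadence"] = 2.0 * len(strides) / total_time * 60.0
    sds["cadence"] = 0.0
    lengths = [s.stride_length for s in strides if s.stride_length is not None]
    if lengths and total_time > 0:
        covered = [s.stride_time for s in strides if s.stride_length is not None]
        means["velocity"] = float(sum(lengths) / sum(covered)) * 100.0
        sds["velocity"] = 0.0
    return TrialSummary(task="", n_strides=len(strides), means=means, sds=sds)


def attach_lengths(
    strides: list[StrideRecord],
    step_lengths: list[tuple[float, float]],
    stride_lengths: list[tuple[float, float]] | None = None,
    tol: float = 0.25,
) -> None:
    """Attach step/stride lengths to stride records in place.

    ``step_lengths`` holds (HS time, step length in meters) pairs; the
    step length of a stride is the one ending at its terminal HS.  When
    ``stride_lengths`` (terminal HS time, length) is given it is used
    directly (foot-sensor and camera pipelines measure strides
    themselves); otherwise the stride length is the sum of the two step
    lengths inside the stride.  Records with no length within ``tol``
    seconds keep None.
    """
    if not step_lengths and not stride_lengths:
        return
    times = np.array([t for t, _ in step_lengths])
    vals = np.array([v for _, v in step_lengths])

    def lookup(ts: np.ndarray, vs: np.ndarray, t: float) -> float | None:
        if not ts.size:
            return None
        i = int(np.argmin(np.abs(ts - t)))
        return float(vs[i]) if abs(ts[i] - t) <= tol else None

    st_times = np.array([t for t, _ in (stride_lengths or [])])
    st_vals = np.array([v for _, v in (stride_lengths or [])])

    for rec in strides:
        end = rec.start_time + rec.stride_time
        own = lookup(times, vals, end)
        rec.step_length = own
        if stride_lengths is not None:
            rec.stride_length = lookup(st_times, st_vals, end)
        else:
            # the contralateral step ends strictly inside the stride
            inside = vals[(times > rec.start_time + 1e-6) & (times < end - 1e-6)]
            if own is not None and inside.size:
                rec.stride_length = float(own + inside[-1])
        if rec.stride_length is not None and rec.stride_time > 0:
            rec.stride_velocity = rec.stride_length / rec.stride_time
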