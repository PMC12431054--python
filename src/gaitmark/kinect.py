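"""Participant selection and gait events from depth-camera skeletons.

A clinic scene contains bystanders whose tracker ids come and go; the
participant is the body that is present throughout, stays inside the
walkway's lateral gate and travels the path.  Ankle depth (z) signals
are resampled to a uniform grid, low-passed (6th-order Butterworth,
3 Hz, zero-phase), twice differentiated, and the extrema of the
direction-normalized ankle acceleration give heel strikes and toe-offs.

Direction convention: ``direction_sign`` is +1 when the subject walks
toward the camera (depth decreasing) and -1 when walking away; it
equals ``-sign(mean dz/dt)`` over a pass.  On a toward-camera pass the
terminal-swing deceleration makes the raw depth acceleration positive
at heel strike, so after multiplying by ``direction_sign`` heel strikes
are local maxima and toe-offs local minima on every pass.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .foot_imu import repair_alternation
from .types import EventSeries, Foot, ParticipantTrack, PeakParams, SkeletonRecording

BUTTER_ORDER = 6
BUTTER_CUTOFF = 3.0   # Hz
RESAMPLE_FPS = 30.0
DEFAULT_GATE = (-0.5, 0.5)  # m, lateral extent of the walkway


# ---------------------------------------------------------------------------
# Participant selection
# ---------------------------------------------------------------------------

def select_participant(
    rec: SkeletonRecording,
    walkway_gate: tuple[float, float] = DEFAULT_GATE,
    min_gate_fraction: float = 0.10,
) -> ParticipantTrack:
    """Pick the body that covers the recording and walks the path.

    Score = coverage x fraction-of-frames-inside-gate (pelvis x within
    the gate); ties broken by the larger total depth range travelled.
    Raises if no body is inside the gate in >= ``min_gate_fraction`` of
    its frames.
    """
    if not rec.frames:
        raise ValueError("empty recording")
    n_times = len(rec.frame_times())
    best: tuple[float, float, int] | None = None
    for bid in rec.body_ids():
        frames = rec.body_frames(bid)
        coverage = len(frames) / n_times
        xs = np.array([fr.joints.get("pelvis", (np.nan,) * 3)[0] for fr in frames])
        in_gate = np.mean((xs >= walkway_gate[0]) & (xs <= walkway_gate[1]))
        if in_gate < min_gate_fraction:
            continue
        zs = np.array([fr.joints["pelvis"][2] for fr in frames])
        z_range = float(zs.max() - zs.min()) if zs.size else 0.0
        score = coverage * in_gate
        cand = (score, z_range, bid)
        if best is None or cand[:2] > best[:2]:
            best = cand
    if best is None:
        raise ValueError("no participant found inside the walkway gate")
    bid = best[2]
    frames = rec.body_frames(bid)
    return ParticipantTrack(body_id=bid, frames=frames,
                            coverage=len(frames) / n_times)


# ---------------------------------------------------------------------------
# Joint signal processing
# ---------------------------------------------------------------------------

def resample_joint(
    track: ParticipantTrack, joint: str, axis: int, fps: float = RESAMPLE_FPS
) -> tuple[np.ndarray, np.ndarray]:
    """Linearly resample one joint coordinate onto a uniform grid.

    Camera frame timing jitters below the nominal rate; Butterworth
    filtering needs uniform sampling.  Returns ``(t, x)``.
    """
    ts = np.array([fr.time for fr in track.frames])
    xs = np.array([fr.joints[joint][axis] for fr in track.frames])
    t = np.arange(ts[0], ts[-1], 1.0 / fps)
    return t, np.interp(t, ts, xs)


def filter_joint_signal(x: np.ndarray, fps: float) -> np.ndarray:
    """Zero-phase 6th-order Butterworth low-pass at 3 Hz."""
    if fps < 7:
        raise ValueError("fps too low for a 3 Hz cutoff")
    x = np.asarray(x, dtype=float)
    sos = sps.butter(BUTTER_ORDER, BUTTER_CUTOFF, btype="lowpass", fs=fps, output="sos")
    return sps.sosfiltfilt(sos, x)


def ankle_acceleration(position: np.ndarray, fps: float) -> np.ndarray:
    """Discrete second derivative of a position signal, in m/s^2.

    Compact central second difference (x[i-1] - 2 x[i] + x[i+1]) * fps^2
    in the interior, replicated at the edges.  The compact stencil keeps
    the response within 5% of the analytic second derivative up to 2 Hz
    at 30 fps (the wider double-gradient stencil attenuates ~6%).
    """
    position = np.asarray(position, dtype=float)
    if position.size < 5:
        raise ValueError("need at least 5 samples")
    a = np.empty_like(position)
    a[1:-1] = (position[:-2] - 2 * position[1:-1] + position[2:]) * fps ** 2
    a[0] = a[1]
    a[-1] = a[-2]
    return a


# ---------------------------------------------------------------------------
# Event detection
# ---------------------------------------------------------------------------

def pass_direction_sign(z: np.ndarray) -> int:
    """+1 toward the camera (depth decreasing), -1 away."""
    dz = np.diff(z)
    return 1 if dz.mean() < 0 else -1


def default_peak_params(accel: np.ndarray, fps: float) -> PeakParams:
    mad = np.median(np.abs(accel - np.median(accel)))
    peak_amp = np.percentile(np.abs(accel), 99)
    # gait-initiation and turn-entry swings are much shorter than steady
    # swings, so the gate sits well below the steady lobe amplitude
    return PeakParams(
        min_height=0.20 * peak_amp,
        min_prominence=0.5 * 1.4826 * mad,
        min_distance=0.5,  # s; well under a stride, above within-stride ringing
    )


def _detect_one_foot(
    accel: np.ndarray, fps: float, direction_sign: int,
    params: PeakParams | None, foot: Foot, t0: float,
) -> EventSeries:
    a = direction_sign * np.asarray(accel, dtype=float)
    if params is None:
        params = default_peak_params(a, fps)
    kwargs: dict = {}
    if params.min_height > 0:
        kwargs["height"] = params.min_height
    if params.min_prominence > 0:
        kwargs["prominence"] = params.min_prominence
    if params.min_distance > 0:
        kwargs["distance"] = max(1, int(round(params.min_distance * fps)))
    hs_idx, _ = sps.find_peaks(a, **kwargs)   # maxima -> HS
    to_idx, _ = sps.find_peaks(-a, **kwargs)  # minima -> TO
    if hs_idx.size == 0 and to_idx.size == 0:
        return EventSeries(foot=foot, hs_times=np.array([]), to_times=np.array([]),
                           modality="kinect", empty_warning=True)

    def value(i: int, kind: str) -> float:
        return a[i] if kind == "HS" else -a[i]

    hs_idx, to_idx = repair_alternation(hs_idx, to_idx, value)
    return EventSeries(foot=foot, hs_times=t0 + hs_idx / fps,
                       to_times=t0 + to_idx / fps, modality="kinect")


def detect_kinect_events(
    accel_left: np.ndarray,
    accel_right: np.ndarray,
    fps: float,
    direction_sign: int,
    params: PeakParams | None = None,
    t0: float = 0.0,
) -> tuple[EventSeries, EventSeries]:
    """HS/TO per foot from direction-normalized ankle depth acceleration."""
    left = _detect_one_foot(accel_left, fps, direction_sign, params, "left", t0)
    right = _detect_one_foot(accel_right, fps, direction_sign, params, "right", t0)
    return left, right


def split_passes(
    pelvis_z: np.ndarray, fps: float, min_duration: float = 2.0,
    min_speed: float = 0.25,
) -> list[tuple[int, int, int]]:
    """Straight-walking segments from the sign of the pelvis depth velocity.

    Returns ``(start_idx, end_idx, direction_sign)`` per pass; standing
    and turning intervals (|v| < min_speed) separate passes.  The depth
    trend is smoothed at 0.4 Hz first so the step-phasic velocity
    modulation (which dips to zero each double support) does not
    fragment a pass.
    """
    z = np.asarray(pelvis_z, dtype=float)
    sos = sps.butter(2, 0.4, btype="lowpass", fs=fps, output="sos")
    z = sps.sosfiltfilt(sos, z)
    v = np.gradient(z) * fps
    moving = np.abs(v) > min_speed
    out: list[tuple[int, int, int]] = []
    i = 0
    n = len(v)
    while i < n:
        if not moving[i]:
            i += 1
            continue
        j = i
        while j < n and moving[j] and np.sign(v[j]) == np.sign(v[i]):
            j += 1
        if (j - i) / fps >= min_duration:
            out.append((i, j, 1 if v[i] < 0 else -1))
        i = j
    return out


# ---------------------------------------------------------------------------
# Spatial markers
# ---------------------------------------------------------------------------

def _z_at(track_t: np.ndarray, track_z: np.ndarray, time: float) -> float:
    """Depth one frame after the event.

    At the frame nearest a heel strike the ankle can still carry most of
    its swing momentum (the deceleration completes within half a frame
    period), so that read may catch the foot mid-landing.  One frame
    later the foot has settled onto its stance plateau, where it stays
    for the remainder of stance, so the read is stable.
    """
    i = int(np.argmin(np.abs(track_t - time)))
    return float(track_z[min(i + 1, len(track_z) - 1)])


def kinect_lengths(
    t_grid: np.ndarray,
    z_left: np.ndarray,
    z_right: np.ndarray,
    events_left: EventSeries,
    events_right: EventSeries,
) -> tuple[list[tuple[float, float]], list[tuple[float, float]]]:
    """Step and stride lengths from ankle depths at heel strikes.

    Step length = |z of one ankle at its HS - z of the other ankle at
    its preceding HS|; stride length = |z of the same ankle at
    consecutive HS|.  Events outside the grid span are skipped.
    Returns ``(steps, strides)`` as lists of (HS time, length).
    """
    z = {"left": z_left, "right": z_right}
    span = (t_grid[0], t_grid[-1])
    merged = sorted(
        [(t, "left") for t in events_left.hs_times]
        + [(t, "right") for t in events_right.hs_times]
    )
    merged = [(t, f) for (t, f) in merged if span[0] <= t <= span[1]]
    steps: list[tuple[float, float]] = []
    strides: list[tuple[float, float]] = []
    for (t_prev, f_prev), (t_cur, f_cur) in zip(merged, merged[1:]):
        if f_prev == f_cur:
            continue
        sl = abs(_z_at(t_grid, z[f_cur], t_cur) - _z_at(t_grid, z[f_prev], t_prev))
        steps.append((t_cur, sl))
    for foot in ("left", "right"):
        hs = [t for (t, f) in merged if f == foot]
        for t_a, t_b in zip(hs, hs[1:]):
            strides.append(
                (t_b, abs(_z_at(t_grid, z[foot], t_b) - _z_at(t_grid, z[foot], t_a)))
            )
    strides.sort()
    return steps, strides
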