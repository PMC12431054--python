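"""Synthetic three-modality gait recordings with known ground truth.

The generator emulates the study conditions the pipeline is built for:
straight back-and-forth walking over a ~7 m path with a turn between
passes, recorded simultaneously by foot-mounted gyroscopes (128 Hz), a
lumbar accelerometer (128 Hz), a depth-camera skeleton stream (<= 30 fps,
with bystander clutter and changing body ids) and a TTL trigger channel.

Event geometry
--------------
Within a stride of duration ``T`` starting at a left heel strike the
event order is ``HS_L, TO_R, HS_R, TO_L, HS_L'`` with

* ``TO_R`` at ``ds/2 * T``          (initial double support),
* ``HS_R`` at ``(1 + ds/2 - stance) * T``  (forced by requiring the
  contralateral stance to also equal ``stance * T``),
* ``TO_L`` at ``stance * T``.

Each pass ends with an extra half-cycle (``TO_R, HS_R, TO_L``) stepping
into an event-free turn interval, so the per-foot HS/TO alternation
chains across passes and strides that straddle the turn can be excluded
downstream exactly like off-mat steps on a pressure walkway.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from .types import (
    Foot,
    GaitEvent,
    GaitProfile,
    GroundTruthEvents,
    ImuRecording,
    SensorNoise,
    SkeletonFrame,
    SkeletonRecording,
    SyncSignal,
)

G = 9.81  # m/s^2

#: depth (m) of the path start from the camera; the camera sits past the
#: turn line, so depth decreases on the outbound pass (cf. a camera placed
#: at the far end of the walkway).
CAMERA_DEPTH_AT_START = 8.5

TURN_DURATION = 2.0      # s, event-free interval between passes
TURN_BACKSTEP = 0.75     # m, repositioning past the turn point while turning
FOOT_LOBE_WIDTH = 0.12   # s, full width (+-3 sigma) of gyro event lobes
LUMBAR_LOBE_SD = 0.025   # s, sigma of lumbar AP event lobes
WEINBERG_K0 = 0.45       # baseline constant embedded in the foot accel
ANKLE_HEIGHT = 0.10      # m, ankle marker height during stance
SWING_CLEARANCE = 0.05   # m, vertical ankle bump during swing


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Normal draws truncated at +-3 SD (re-draw rejection)."""
    if sd == 0:
        return np.full(n, mean)
    out = rng.normal(mean, sd, n)
    for _ in range(100):
        bad = np.abs(out - mean) > 3 * sd
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
    return np.clip(out, mean - 3 * sd, mean + 3 * sd)


# ---------------------------------------------------------------------------
# Ground-truth event trains
# ---------------------------------------------------------------------------

def generate_event_sequence(profile: GaitProfile, seed: int) -> GroundTruthEvents:
    """Generate side-labelled HS/TO trains for ``profile.n_passes`` passes.

    Stride times are Normal(mean, sd) truncated at +-3 SD; per-pass
    cumulative step lengths never exceed ``path_length``.  Deterministic
    for a fixed seed.  Raises ``ValueError`` when a single stride cannot
    fit on the path.
    """
    r = profile.asymmetry_ratio
    left_mean = profile.step_length_mean * 2 * r / (1 + r)
    right_mean = profile.step_length_mean * 2 / (1 + r)
    worst_stride = (left_mean + right_mean) + 6 * profile.step_length_sd
    if worst_stride > profile.path_length:
        raise ValueError("a single stride exceeds path_length: unusable geometry")

    rng = np.random.default_rng(seed)
    ds = profile.double_support_fraction
    stance = profile.stance_fraction
    sf = profile.step_time_fraction

    events: list[GaitEvent] = []
    step_lengths: list[tuple[int, float]] = []
    positions: list[tuple[int, float]] = []
    turn_intervals: list[tuple[float, float]] = []

    t = 0.0          # current time
    pos = 0.0        # signed along-path coordinate of the walker
    direction = 1.0

    def emit(time: float, foot: Foot, kind: str, p: int) -> int:
        events.append(GaitEvent(time, foot, kind, p))  # type: ignore[arg-type]
        return len(events) - 1

    for p in range(profile.n_passes):
        # draw generously; the distance budget ends the pass
        max_strides = int(np.ceil(profile.path_length / max(worst_stride / 4, 1e-6))) + 2
        stride_times = _truncnorm(
            rng, profile.stride_time_mean, profile.stride_time_sd, max_strides
        )
        right_steps = _truncnorm(rng, right_mean, profile.step_length_sd, max_strides)
        left_steps = _truncnorm(rng, left_mean, profile.step_length_sd, max_strides)

        # gait initiation: the left foot lifts and swings onto the start
        # position, so the first heel strike has a kinematic signature in
        # every stream (and the per-foot chain alternates across passes)
        emit(t, "left", "TO", p)
        t += (1.0 - stance) * stride_times[0]
        idx = emit(t, "left", "HS", p)
        positions.append((idx, pos))

        cum = 0.0
        k = 0
        while cum + right_steps[k] + left_steps[k] <= profile.path_length:
            T = stride_times[k]
            emit(t + ds / 2 * T, "right", "TO", p)
            cum += right_steps[k]
            pos += direction * right_steps[k]
            idx = emit(t + sf * T, "right", "HS", p)
            step_lengths.append((idx, right_steps[k]))
            positions.append((idx, pos))
            emit(t + stance * T, "left", "TO", p)
            cum += left_steps[k]
            pos += direction * left_steps[k]
            t += T
            idx = emit(t, "left", "HS", p)
            step_lengths.append((idx, left_steps[k]))
            positions.append((idx, pos))
            k += 1
            if k >= max_strides:
                break

        # half-cycle tail: the right foot steps into the turn (the left
        # foot's next event is the initiation TO of the following pass)
        T = stride_times[min(k, max_strides - 1)]
        turn_step = min(0.5 * profile.step_length_mean, profile.path_length - cum)
        emit(t + ds / 2 * T, "right", "TO", p)
        pos += direction * turn_step
        idx = emit(t + sf * T, "right", "HS", p)
        step_lengths.append((idx, turn_step))
        positions.append((idx, pos))

        turn_start = t + sf * T
        t = turn_start + TURN_DURATION
        if p < profile.n_passes - 1:
            turn_intervals.append((turn_start, t))
        direction = -direction
        # turning, the walker steps back past the turn point so the next
        # initiation swing moves in the new travel direction
        pos += direction * TURN_BACKSTEP

    truth = GroundTruthEvents(events, step_lengths, positions)
    truth.turn_intervals = turn_intervals  # type: ignore[attr-defined]
    return truth


def walking_intervals(truth: GroundTruthEvents) -> list[tuple[float, float]]:
    """Steady straight-walking intervals: first to last left HS of each pass.

    The half-cycle tail stepping into the turn falls outside, so strides
    touching it are excluded by downstream masking.
    """
    out: list[tuple[float, float]] = []
    passes = sorted({e.pass_index for e in truth.events})
    for p in passes:
        left_hs = [e.time for e in truth.events
                   if e.pass_index == p and e.foot == "left" and e.kind == "HS"]
        if len(left_hs) >= 2:
            out.append((left_hs[0], left_hs[-1]))
    return out


# ---------------------------------------------------------------------------
# Foot-mounted gyroscope (+ accelerometer for step length)
# ---------------------------------------------------------------------------

def _gauss_lobes(t: np.ndarray, centers: np.ndarray, amp: float, sigma: float) -> np.ndarray:
    out = np.zeros_like(t)
    for c in centers:
        lo = np.searchsorted(t, c - 5 * sigma)
        hi = np.searchsorted(t, c + 5 * sigma)
        out[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - c) / sigma) ** 2)
    return out


def _apply_noise(rng: np.random.Generator, x: np.ndarray, t: np.ndarray,
                 noise: SensorNoise) -> np.ndarray:
    out = x + rng.normal(0.0, noise.gaussian_sd, x.shape) if noise.gaussian_sd else x.copy()
    if noise.drift_amplitude:
        out = out + noise.drift_amplitude * np.sin(2 * np.pi * t / noise.drift_period)
    return out


def synthesize_foot_gyro(
    events: GroundTruthEvents,
    foot: Foot,
    fs: float,
    noise: SensorNoise,
    duration: float | None = None,
    hs_amplitude: float = 2.5,
    to_amplitude: float = 2.0,
    lobe_width: float = FOOT_LOBE_WIDTH,
    weinberg_k0: float = WEINBERG_K0,
) -> ImuRecording:
    """Foot IMU stream for one foot.

    The medial-lateral angular-velocity channel (gyro y) carries a
    dominant negative Gaussian lobe at each of that foot's heel strikes
    and a positive lobe at each toe-off.  The accelerometer z channel
    carries gravity plus a swing oscillation whose within-step range
    equals ``(step_length / weinberg_k0)**4`` so that the quarter-power
    step-length estimator is exact at the baseline constant.
    """
    if fs < 64:
        raise ValueError("fs must be >= 64 Hz")
    if duration is None:
        duration = events.t_end + 1.5
    rng = np.random.default_rng(noise.seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    sigma = lobe_width / 6.0

    hs = events.times(foot, "HS")
    to = events.times(foot, "TO")
    gy = _gauss_lobes(t, hs, -hs_amplitude, sigma) + _gauss_lobes(t, to, to_amplitude, sigma)

    # swing oscillation in accel z, one full sine per swing (TO_F -> HS_F)
    az = np.full(n, G)
    length_by_idx = dict(events.step_lengths)
    foot_events = [(i, e) for i, e in enumerate(events.events) if e.foot == foot]
    for (i, ev), (j, nxt) in zip(foot_events, foot_events[1:]):
        if ev.kind == "TO" and nxt.kind == "HS" and j in length_by_idx:
            sl = length_by_idx[j]
            if sl <= 0:
                continue
            rng_az = (sl / weinberg_k0) ** 4
            sel = (t >= ev.time) & (t < nxt.time)
            u = (t[sel] - ev.time) / (nxt.time - ev.time)
            az[sel] += 0.5 * rng_az * np.sin(2 * np.pi * u)

    gyro = np.zeros((n, 3))
    accel = np.zeros((n, 3))
    gyro[:, 1] = _apply_noise(rng, gy, t, noise)
    gyro[:, 0] = rng.normal(0.0, noise.gaussian_sd, n) if noise.gaussian_sd else 0.0
    gyro[:, 2] = rng.normal(0.0, noise.gaussian_sd, n) if noise.gaussian_sd else 0.0
    accel[:, 2] = _apply_noise(rng, az, t, noise)
    accel[:, 0] = rng.normal(0.0, noise.gaussian_sd, n) if noise.gaussian_sd else 0.0
    accel[:, 1] = rng.normal(0.0, noise.gaussian_sd, n) if noise.gaussian_sd else 0.0

    placement = "left_foot" if foot == "left" else "right_foot"
    return ImuRecording(fs=fs, t=t, gyro_xyz=gyro, accel_xyz=accel, placement=placement)


# ---------------------------------------------------------------------------
# Lumbar accelerometer
# ---------------------------------------------------------------------------

def invert_pendulum(step_length: float, pendulum_length: float) -> float:
    """Vertical COM excursion h solving ``2*sqrt(2*l*h - h^2) = SL``.

    Uses the smaller quadratic root (physical excursions are small
    relative to the pendulum length).  Raises when ``SL >= 2*l``.
    """
    if step_length == 0:
        return 0.0
    if step_length >= 2 * pendulum_length:
        raise ValueError("step length >= 2*pendulum_length: no real solution")
    l = pendulum_length
    return l - np.sqrt(l * l - step_length ** 2 / 4.0)


def _vertical_chain_gain(n: int = 512) -> float:
    """Excursion recovered by the double-integration drift-reset chain
    from the unit-amplitude per-step waveform.

    The per-step vertical acceleration is a single-cycle cosine; the
    downstream chain (integrate, linear detrend, integrate, linear
    detrend) is linear, so its gain on this fixed shape is a constant
    (independent of step duration and amplitude).  The synthesizer
    divides by it so the recovered excursion equals the intended h.
    """
    from scipy import signal as _sig
    from scipy.integrate import cumulative_trapezoid as _ct

    u = np.arange(n) / n
    a = 0.5 * (2 * np.pi) ** 2 * np.cos(2 * np.pi * u)  # h = 1, D = 1
    v = _sig.detrend(_ct(a, dx=1.0 / n, initial=0.0), type="linear")
    p = _sig.detrend(_ct(v, dx=1.0 / n, initial=0.0), type="linear")
    return float(p.max() - p.min())


_VERT_GAIN = _vertical_chain_gain()


def synthesize_lumbar_accel(
    events: GroundTruthEvents,
    fs: float,
    noise: SensorNoise,
    pendulum_length: float,
    duration: float | None = None,
    ap_amplitude: float = 1.5,
    lobe_sd: float = LUMBAR_LOBE_SD,
    ap_jitter_sd: float = 0.0,
    vertical_attenuation: float = 1.0,
) -> ImuRecording:
    """Lumbar IMU stream.

    The anterior-posterior channel (accel z in the lumbar sensor's axis
    convention) carries a negative Gaussian lobe at every heel
    strike of either foot and a positive lobe at every toe-off, so the
    detrend / low-pass / integrate / wavelet-differentiate chain - which
    amounts to zero-lag Gaussian smoothing - keeps minima at HS and
    maxima at TO.  The vertical channel (accel x) embeds, per step, a
    single-cycle cosine whose doubly-integrated excursion equals the h
    obtained by inverting the pendulum relation for the true step length.

    Two fidelity parameters emulate what a trunk sensor actually
    observes rather than an ideal event encoder: ``ap_jitter_sd``
    randomly displaces each AP event lobe (trunk dynamics transmit foot
    contacts with tens of milliseconds of variability), and
    ``vertical_attenuation`` scales the embedded COM excursion below its
    pendulum value (soft tissue and pelvic list attenuate the vertical
    displacement seen at L5, which is why uncorrected pendulum step
    lengths underestimate).  Both default to the ideal values (0, 1) so
    the noiseless recovery contracts hold; the cohort simulation sets
    realistic ones.
    """
    if pendulum_length <= 0:
        raise ValueError("pendulum_length must be > 0")
    if duration is None:
        duration = events.t_end + 1.5
    rng = np.random.default_rng(noise.seed + 1)
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    hs_all = np.sort(np.concatenate([events.times("left", "HS"),
                                     events.times("right", "HS")]))
    to_all = np.sort(np.concatenate([events.times("left", "TO"),
                                     events.times("right", "TO")]))
    if ap_jitter_sd > 0:
        hs_all = np.sort(hs_all + rng.normal(0.0, ap_jitter_sd, hs_all.shape))
        to_all = np.sort(to_all + rng.normal(0.0, ap_jitter_sd, to_all.shape))
    ap = (_gauss_lobes(t, hs_all, -ap_amplitude, lobe_sd)
          + _gauss_lobes(t, to_all, ap_amplitude, lobe_sd))

    vert = np.full(n, G)
    length_by_idx = dict(events.step_lengths)
    hs_indexed = [(i, e) for i, e in enumerate(events.events) if e.kind == "HS"]
    for (_, prev), (j, cur) in zip(hs_indexed, hs_indexed[1:]):
        if j not in length_by_idx:
            continue
        sl = length_by_idx[j]
        h = vertical_attenuation * invert_pendulum(sl, pendulum_length)
        if h == 0:
            continue
        d = cur.time - prev.time
        sel = (t >= prev.time) & (t < cur.time)
        u = (t[sel] - prev.time) / d
        # single-cycle cosine, pre-scaled so the drift-reset double
        # integration downstream recovers exactly h (see _vertical_chain_gain)
        amp = h / _VERT_GAIN
        vert[sel] += (amp / 2.0) * (2 * np.pi / d) ** 2 * np.cos(2 * np.pi * u)

    gyro = np.zeros((n, 3))
    accel = np.zeros((n, 3))
    accel[:, 2] = _apply_noise(rng, ap, t, noise)
    accel[:, 0] = _apply_noise(rng, vert, t, noise)
    accel[:, 1] = rng.normal(0.0, noise.gaussian_sd, n) if noise.gaussian_sd else 0.0
    if noise.gaussian_sd:
        gyro += rng.normal(0.0, noise.gaussian_sd, (n, 3))
    return ImuRecording(fs=fs, t=t, gyro_xyz=gyro, accel_xyz=accel, placement="lumbar")


# ---------------------------------------------------------------------------
# Depth-camera skeleton
# ---------------------------------------------------------------------------

PARTICIPANT_BODY_ID = 1
CLUTTER_MIN_OFFSET = 0.8  # m lateral offset of bystanders from the walkway


SWING_EDGE_SD = 0.014    # s, width of the TO/HS acceleration transients
SWING_EDGE_LEAD = 0.014  # s, ankle transients lead the contact events


def _norm_cdf(u: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + erf(u / np.sqrt(2.0)))


def _cdf_integral(u: np.ndarray) -> np.ndarray:
    """Antiderivative of the standard normal CDF: u*Phi(u) + phi(u)."""
    return u * _norm_cdf(u) + np.exp(-0.5 * u ** 2) / np.sqrt(2 * np.pi)


def _foot_depth_trajectory(
    tgrid: np.ndarray,
    hs_times: np.ndarray,
    hs_pos: np.ndarray,
    to_times: np.ndarray,
    edge_sd: float | None = None,
    edge_lead: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Ankle progression: hold during stance, smoothed-ramp advance
    during swing.

    The swing velocity is a plateau bounded by Gaussian edges, so the
    progression *acceleration* is a symmetric positive lobe near toe-off
    and a symmetric negative lobe near heel strike; any zero-phase
    symmetric filter leaves those extrema in place.  Both edges lead the
    contact events by ``edge_lead``: the ankle rolls forward during
    pre-swing before the toes leave the ground, and its deceleration
    completes just before heel contact, so the foot is nearly stationary
    when it lands (nearest-frame depth reads at heel strike are then
    on the stance plateau).  A uniform lead shifts every detected event
    equally and cancels out of all between-event marker differences.
    Returns (along-path s, swing phase in [0,1] or nan during stance).
    """
    if edge_sd is None:
        edge_sd = SWING_EDGE_SD
    if edge_lead is None:
        edge_lead = SWING_EDGE_LEAD
    s = np.full_like(tgrid, hs_pos[0] if len(hs_pos) else 0.0)
    u_swing = np.full_like(tgrid, np.nan)
    for k in range(len(hs_times) - 1):
        start, end = hs_times[k], hs_times[k + 1]
        tos = to_times[(to_times > start) & (to_times < end)]
        if not len(tos):
            continue
        a, b = tos[0] - edge_lead, end - edge_lead
        dL = hs_pos[k + 1] - hs_pos[k]
        # integral of (Phi((t-a)/sd) - Phi((t-b)/sd)) equals (b-a) as
        # t -> inf, so the total advance is exactly dL
        adv = (dL / (b - a)) * edge_sd * (
            _cdf_integral((tgrid - a) / edge_sd) - _cdf_integral((tgrid - b) / edge_sd)
        )
        s = s + adv
        sel = (tgrid >= a) & (tgrid < b)
        u_swing[sel] = (tgrid[sel] - a) / (b - a)
    return s, u_swing


def synthesize_skeleton(
    events: GroundTruthEvents,
    fps: float,
    clutter: int,
    noise: SensorNoise,
    duration: float | None = None,
) -> SkeletonRecording:
    """Skeleton stream: one persistent participant body plus ``clutter``
    bystanders that appear/disappear with changing body ids at >= 0.8 m
    lateral offset.  Ankle depth decreases on the outbound pass and
    increases on the return (camera past the turn line)."""
    if fps > 30:
        raise ValueError("fps must be <= 30")
    if clutter < 0:
        raise ValueError("clutter must be >= 0")
    if duration is None:
        duration = events.t_end + 1.5
    rng = np.random.default_rng(noise.seed + 2)
    tgrid = np.arange(0.0, duration, 1.0 / fps)

    pos_by_idx = dict(events.positions)
    joints_series: dict[str, np.ndarray] = {}
    lateral = {"left": -0.10, "right": 0.10}
    s_feet = {}
    length_by_idx = dict(events.step_lengths)
    for foot in ("left", "right"):
        hs_times, hs_pos = [], []
        first_hs_idx = None
        for i, e in enumerate(events.events):
            if e.foot == foot and e.kind == "HS" and i in pos_by_idx:
                if first_hs_idx is None:
                    first_hs_idx = i
                hs_times.append(e.time)
                hs_pos.append(pos_by_idx[i])
        to_times = events.times(foot, "TO")
        # a TO precedes the first HS (gait initiation): the foot starts
        # one step behind its first landing spot so that heel strike also
        # has a visible swing
        if len(to_times) and len(hs_times) and to_times[0] < hs_times[0]:
            d0 = np.sign(hs_pos[1] - hs_pos[0]) if len(hs_pos) > 1 else 1.0
            step0 = length_by_idx.get(first_hs_idx, 0.45)
            hs_times.insert(0, to_times[0] - 0.3)
            hs_pos.insert(0, hs_pos[0] - max(step0, 0.05) * (d0 or 1.0))
        s, u = _foot_depth_trajectory(tgrid, np.array(hs_times), np.array(hs_pos), to_times)
        s_feet[foot] = s
        z = CAMERA_DEPTH_AT_START - s
        y = np.full_like(tgrid, ANKLE_HEIGHT)
        swing = ~np.isnan(u)
        y[swing] += SWING_CLEARANCE * np.sin(np.pi * u[swing])
        x = np.full_like(tgrid, lateral[foot])
        joints_series[f"{foot}_ankle"] = np.column_stack([x, y, z])
        joints_series[f"{foot}_foot"] = np.column_stack([x, y - 0.06, z + 0.05])
    pelvis_z = 0.5 * (joints_series["left_ankle"][:, 2] + joints_series["right_ankle"][:, 2])
    joints_series["pelvis"] = np.column_stack(
        [np.zeros_like(tgrid), np.full_like(tgrid, 0.95), pelvis_z]
    )

    frames: list[SkeletonFrame] = []
    jitter = noise.gaussian_sd

    def noisy(p: np.ndarray) -> tuple[float, float, float]:
        if jitter:
            p = p + rng.normal(0.0, jitter, 3)
        return (float(p[0]), float(p[1]), float(p[2]))

    # bystander episodes: each person re-enters 2-3 times with a NEW id
    episodes: list[tuple[float, float, int, float, float]] = []
    next_id = 100
    for _ in range(clutter):
        side = rng.choice([-1.0, 1.0])
        x_off = side * (CLUTTER_MIN_OFFSET + rng.uniform(0.0, 0.7))
        for _ in range(int(rng.integers(2, 4))):
            start = rng.uniform(0.0, max(duration - 1.0, 0.1))
            ep_dur = rng.uniform(1.0, min(5.0, duration - start))
            z0 = rng.uniform(1.5, CAMERA_DEPTH_AT_START)
            episodes.append((start, start + ep_dur, next_id, x_off, z0))
            next_id += 1

    for fi, tf in enumerate(tgrid):
        joints = {name: noisy(series[fi]) for name, series in joints_series.items()}
        frames.append(SkeletonFrame(time=float(tf), body_id=PARTICIPANT_BODY_ID, joints=joints))
        for (t0, t1, bid, x_off, z0) in episodes:
            if t0 <= tf < t1:
                wob = 0.05 * np.sin(2 * np.pi * 0.3 * (tf - t0))
                j = {
                    "left_ankle": noisy(np.array([x_off - 0.1, ANKLE_HEIGHT, z0 + wob])),
                    "right_ankle": noisy(np.array([x_off + 0.1, ANKLE_HEIGHT, z0 - wob])),
                    "left_foot": noisy(np.array([x_off - 0.1, 0.04, z0 + wob])),
                    "right_foot": noisy(np.array([x_off + 0.1, 0.04, z0 - wob])),
                    "pelvis": noisy(np.array([x_off, 0.95, z0])),
                }
                frames.append(SkeletonFrame(time=float(tf), body_id=bid, joints=j))
    return SkeletonRecording(frames)


# ---------------------------------------------------------------------------
# Trigger channel
# ---------------------------------------------------------------------------

def synthesize_trigger(
    task_windows: list[tuple[float, float]],
    fs: float,
    total_duration: float,
) -> SyncSignal:
    """5 V outside the task windows, 0 V inside (sample-exact at
    ``floor(start*fs)`` / ``ceil(end*fs)``).  Overlapping windows are
    rejected."""
    ordered = sorted(task_windows)
    for (a0, a1), (b0, b1) in zip(ordered, ordered[1:]):
        if b0 < a1:
            raise ValueError("task windows must not overlap")
    for (a, b) in ordered:
        if a < 0 or b > total_duration or a >= b:
            raise ValueError("windows must lie within [0, total_duration]")
    n = int(round(total_duration * fs))
    level = np.full(n, 5.0)
    for (a, b) in ordered:
        lo = int(np.floor(a * fs))
        hi = min(int(np.ceil(b * fs)), n)
        level[lo:hi] = 0.0
    return SyncSignal(fs=fs, level=level)


# ---------------------------------------------------------------------------
# Whole-trial convenience bundle
# ---------------------------------------------------------------------------

@dataclass
class TrialStreams:
    """All synchronized streams of one walking trial plus its truth."""

    truth: GroundTruthEvents
    imu_left: ImuRecording
    imu_right: ImuRecording
    imu_lumbar: ImuRecording
    skeleton: SkeletonRecording
    pendulum_length: float
    walking_intervals: list[tuple[float, float]] = field(default_factory=list)


def simulate_trial(
    profile: GaitProfile,
    seed: int,
    noise: SensorNoise | None = None,
    fs_imu: float = 128.0,
    fps: float = 30.0,
    clutter: int = 0,
    pendulum_length: float = 0.94,
    lead_in: float = 3.0,
    lumbar_ap_jitter_sd: float = 0.0,
    lumbar_vertical_attenuation: float = 1.0,
) -> TrialStreams:
    """Generate one trial: truth events and all three sensor streams.

    ``lead_in`` seconds of quiet signal precede the first event (and pad
    the end) so zero-phase filters see no edge transients near events.
    """
    if noise is None:
        noise = SensorNoise(seed=seed)
    noise = SensorNoise(noise.gaussian_sd, noise.drift_amplitude,
                        noise.drift_period, seed)
    truth0 = generate_event_sequence(profile, seed)
    truth = truth0.shifted(lead_in)
    truth.turn_intervals = [  # type: ignore[attr-defined]
        (a + lead_in, b + lead_in)
        for (a, b) in getattr(truth0, "turn_intervals", [])
    ]
    dur = truth.t_end + lead_in
    return TrialStreams(
        truth=truth,
        imu_left=synthesize_foot_gyro(truth, "left", fs_imu, noise, duration=dur),
        imu_right=synthesize_foot_gyro(truth, "right", fs_imu, noise, duration=dur),
        imu_lumbar=synthesize_lumbar_accel(
            truth, fs_imu, noise, pendulum_length, duration=dur,
            ap_jitter_sd=lumbar_ap_jitter_sd,
            vertical_attenuation=lumbar_vertical_attenuation,
        ),
        skeleton=synthesize_skeleton(truth, fps, clutter, noise, duration=dur),
        pendulum_length=pendulum_length,
        walking_intervals=walking_intervals(truth),
    )
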