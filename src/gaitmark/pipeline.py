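"""End-to-end orchestration: simulate -> segment -> detect -> markers -> compare.

A simulated *session* mirrors the study protocol: one continuous
recording per subject containing a practice walk, a single-task walk and
a dual-task walk, separated by idle gaps, with a TTL trigger marking the
active windows.  The dual-task profile is slower (longer stride time,
shorter steps), as a concurrent cognitive load produces.

``simulate_dataset`` writes one directory per subject (IMU CSVs +
sidecars, skeleton CSV, trigger CSV, per-task ground-truth event CSVs,
manifest).  ``run_dataset`` reads it back knowing nothing but the CSV
dialects, segments tasks from the trigger, runs the three detection
pipelines plus the reference path, computes the 11 markers per task, and
assembles cross-subject agreement reports per task.

The per-subject Weinberg constants are calibrated on the practice walk
against the reference system's walked distance, then applied unchanged
to both tasks.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import agreement as agr
from . import foot_imu, io, kinect, lumbar_imu, markers, sync
from .synthdata import (
    TrialStreams,
    simulate_trial,
    synthesize_trigger,
    walking_intervals,
)
from .types import (
    EventSeries,
    GaitProfile,
    GroundTruthEvents,
    ImuRecording,
    PairedMarkerSample,
    SensorNoise,
    SkeletonFrame,
    SkeletonRecording,
    SyncSignal,
    TaskWindow,
    TrialSummary,
)

log = logging.getLogger("gaitmark")

TASKS = ("practice", "single_task", "dual_task")

DEFAULT_CONFIG: dict = {
    "cohort": {
        "n_subjects": 18,
        # cohort-mean walking parameters per task; single- vs dual-task
        # means follow the slower, shorter-stepped dual-task pattern
        "single_task": {"stride_time_mean": 1.08, "step_length_mean": 0.666},
        "dual_task": {"stride_time_mean": 1.16, "step_length_mean": 0.621},
        "between_subject_sd": {"stride_time": 0.07, "step_length": 0.06},
        "within_subject_sd": {"stride_time": 0.03, "step_length": 0.02},
        "stance_fraction": 0.657,
        "double_support_fraction": 0.314,
        "path_length": 7.0,
        "n_passes": 2,
    },
    "noise": {
        "imu_gaussian_sd": 0.05,
        "imu_drift_amplitude": 0.3,
        "imu_drift_period": 30.0,
        "skeleton_gaussian_sd": 0.005,
        # trunk-transmission fidelity of the lumbar stream: foot contacts
        # reach L5 with timing variability, and soft tissue attenuates
        # the vertical COM excursion (hence the pendulum model's known
        # underestimation of step length when uncorrected)
        "lumbar_event_jitter_sd": 0.03,
        "lumbar_vertical_attenuation": 0.8,
    },
    "sensors": {"fs_imu": 128.0, "fps": 30.0, "fs_trigger": 120.0, "clutter": 2},
    "pendulum_length": 0.94,
    "idle_gap": 4.0,
    "seed": 0,
}


def merge_config(overrides: dict | None = None) -> dict:
    cfg = copy.deepcopy(DEFAULT_CONFIG)

    def rec(dst: dict, src: dict) -> None:
        for k, v in src.items():
            if isinstance(v, dict) and isinstance(dst.get(k), dict):
                rec(dst[k], v)
            else:
                dst[k] = v

    if overrides:
        rec(cfg, overrides)
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha1(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:8]


# ---------------------------------------------------------------------------
# Subject profiles
# ---------------------------------------------------------------------------

def subject_profiles(cfg: dict, subject_seed: int) -> dict[str, GaitProfile]:
    """Per-subject task profiles: cohort means plus a subject random
    effect shared across tasks (slower walkers are slower in both)."""
    c = cfg["cohort"]
    rng = np.random.default_rng(subject_seed)
    dt_stride = rng.normal(0.0, c["between_subject_sd"]["stride_time"])
    dt_step = rng.normal(0.0, c["between_subject_sd"]["step_length"])
    out = {}
    for task in TASKS:
        base = c["single_task"] if task != "dual_task" else c["dual_task"]
        out[task] = GaitProfile(
            stride_time_mean=max(base["stride_time_mean"] + dt_stride, 0.7),
            stride_time_sd=c["within_subject_sd"]["stride_time"],
            stance_fraction=c["stance_fraction"],
            double_support_fraction=c["double_support_fraction"],
            step_length_mean=float(np.clip(base["step_length_mean"] + dt_step, 0.35, 0.95)),
            step_length_sd=c["within_subject_sd"]["step_length"],
            path_length=c["path_length"],
            n_passes=c["n_passes"],
        )
    return out


# ---------------------------------------------------------------------------
# Session assembly
# ---------------------------------------------------------------------------

@dataclass
class SubjectSession:
    """One continuous multi-stream recording with per-task ground truth."""

    imu_left: ImuRecording
    imu_right: ImuRecording
    imu_lumbar: ImuRecording
    skeleton: SkeletonRecording
    trigger: SyncSignal
    truths: dict[str, GroundTruthEvents]
    windows: list[TaskWindow] = field(default_factory=list)
    pendulum_length: float = 0.94


def _concat_imu(trials: list[tuple[float, ImuRecording]], fs: float,
                total: float, idle_accel: np.ndarray,
                rng: np.random.Generator, noise_sd: float,
                placement: str) -> ImuRecording:
    n = int(round(total * fs))
    gyro = rng.normal(0.0, noise_sd, (n, 3)) if noise_sd else np.zeros((n, 3))
    accel = (rng.normal(0.0, noise_sd, (n, 3)) if noise_sd else np.zeros((n, 3))) + idle_accel
    for off, rec in trials:
        i0 = int(round(off * fs))
        i1 = i0 + rec.n
        gyro[i0:i1] = rec.gyro_xyz
        accel[i0:i1] = rec.accel_xyz
    return ImuRecording(fs=fs, t=np.arange(n) / fs, gyro_xyz=gyro,
                        accel_xyz=accel, placement=placement)


def simulate_subject(cfg: dict, subject_seed: int) -> SubjectSession:
    profiles = subject_profiles(cfg, subject_seed)
    s = cfg["sensors"]
    nz = cfg["noise"]
    gap = float(cfg["idle_gap"])
    imu_noise = SensorNoise(nz["imu_gaussian_sd"], nz["imu_drift_amplitude"],
                            nz["imu_drift_period"], subject_seed)
    skel_noise = SensorNoise(nz["skeleton_gaussian_sd"], 0.0, 30.0, subject_seed)

    trials: dict[str, TrialStreams] = {}
    offsets: dict[str, float] = {}
    t_cursor = gap
    for k, task in enumerate(TASKS):
        tr = simulate_trial(
            profiles[task], seed=subject_seed * 7 + k, noise=imu_noise,
            fs_imu=s["fs_imu"], fps=s["fps"], clutter=s["clutter"],
            pendulum_length=cfg["pendulum_length"],
            lumbar_ap_jitter_sd=nz.get("lumbar_event_jitter_sd", 0.0),
            lumbar_vertical_attenuation=nz.get("lumbar_vertical_attenuation", 1.0),
        )
        # skeleton noise differs from IMU noise in units; regenerate stream
        from .synthdata import synthesize_skeleton
        skl_noise = SensorNoise(nz["skeleton_gaussian_sd"], 0.0, 30.0,
                                subject_seed * 7 + k)
        tr.skeleton = synthesize_skeleton(tr.truth, s["fps"], s["clutter"],
                                          skl_noise, duration=tr.imu_left.t[-1] + 1 / s["fps"])
        trials[task] = tr
        # snap offsets onto the IMU sample grid
        offsets[task] = round(t_cursor * s["fs_imu"]) / s["fs_imu"]
        t_cursor = offsets[task] + tr.imu_left.t[-1] + 1.0 / s["fs_imu"] + gap
    total = t_cursor

    rng = np.random.default_rng(subject_seed + 10_000)
    g = 9.81
    sessions = {}
    for name, idle in (("left", np.array([0.0, 0.0, g])),
                       ("right", np.array([0.0, 0.0, g])),
                       ("lumbar", np.array([g, 0.0, 0.0]))):
        attr = {"left": "imu_left", "right": "imu_right", "lumbar": "imu_lumbar"}[name]
        placement = {"left": "left_foot", "right": "right_foot", "lumbar": "lumbar"}[name]
        sessions[attr] = _concat_imu(
            [(offsets[t], getattr(trials[t], attr)) for t in TASKS],
            s["fs_imu"], total, idle, rng, nz["imu_gaussian_sd"], placement,
        )

    frames: list[SkeletonFrame] = []
    for task in TASKS:
        off = offsets[task]
        for fr in trials[task].skeleton.frames:
            frames.append(SkeletonFrame(time=fr.time + off, body_id=fr.body_id,
                                        joints=fr.joints))
    skeleton = SkeletonRecording(frames)

    window_bounds = [
        (offsets[t], offsets[t] + trials[t].imu_left.t[-1]) for t in TASKS
    ]
    trigger = synthesize_trigger(window_bounds, s["fs_trigger"], total)

    truths = {t: trials[t].truth.shifted(offsets[t]) for t in TASKS}
    for t in TASKS:
        truths[t].turn_intervals = [  # type: ignore[attr-defined]
            (a + offsets[t], b + offsets[t])
            for a, b in getattr(trials[t].truth, "turn_intervals", [])
        ]
    windows = [TaskWindow(label=t, start=a, end=b)
               for t, (a, b) in zip(TASKS, window_bounds)]
    return SubjectSession(
        imu_left=sessions["imu_left"], imu_right=sessions["imu_right"],
        imu_lumbar=sessions["imu_lumbar"], skeleton=skeleton, trigger=trigger,
        truths=truths, windows=windows, pendulum_length=cfg["pendulum_length"],
    )


def simulate_dataset(cfg: dict, out_dir: str | Path) -> Path:
    """Write the full cohort dataset; returns the dataset directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io.save_config(cfg, out / "config.json")
    manifest = {"config_hash": config_hash(cfg), "subjects": []}
    for si in range(cfg["cohort"]["n_subjects"]):
        subject_seed = int(cfg["seed"]) * 1000 + si
        sess = simulate_subject(cfg, subject_seed)
        sdir = out / f"subject_{si:02d}"
        sdir.mkdir(exist_ok=True)
        io.write_imu(sess.imu_left, sdir / "imu_lfoot.csv")
        io.write_imu(sess.imu_right, sdir / "imu_rfoot.csv")
        io.write_imu(sess.imu_lumbar, sdir / "imu_lumbar.csv")
        io.write_skeleton(sess.skeleton, sdir / "skeleton.csv")
        io.write_trigger(sess.trigger, sdir / "trigger.csv")
        for task in TASKS:
            io.write_truth(sess.truths[task], sdir / f"truth_{task}.csv")
        manifest["subjects"].append(sdir.name)
        log.info("simulated %s (seed %d)", sdir.name, subject_seed)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


# ---------------------------------------------------------------------------
# Per-modality marker pipelines (operate on one task window)
# ---------------------------------------------------------------------------

def _series_from_times(foot: str, hs: list[float], to: list[float],
                       modality: str) -> EventSeries:
    """Sorted, deduplicated, alternation-repaired series (keep-first)."""
    merged: list[tuple[float, str]] = sorted(
        [(t, "HS") for t in hs] + [(t, "TO") for t in to]
    )
    kept: list[tuple[float, str]] = []
    for t, k in merged:
        if kept and abs(t - kept[-1][0]) < 0.1 and k == kept[-1][1]:
            continue  # duplicate from overlapping segments
        if kept and kept[-1][1] == k:
            continue  # alternation repair: keep first
        kept.append((t, k))
    return EventSeries(
        foot=foot,  # type: ignore[arg-type]
        hs_times=np.array([t for t, k in kept if k == "HS"]),
        to_times=np.array([t for t, k in kept if k == "TO"]),
        modality=modality,  # type: ignore[arg-type]
    )


def reference_series(truth: GroundTruthEvents) -> tuple[EventSeries, EventSeries]:
    return (
        EventSeries("left", truth.times("left", "HS"), truth.times("left", "TO"),
                    "reference"),
        EventSeries("right", truth.times("right", "HS"), truth.times("right", "TO"),
                    "reference"),
    )


def detect_foot(imu: ImuRecording, foot: str) -> EventSeries:
    y = foot_imu.preprocess_foot_gyro(imu.gyro_xyz[:, 1], imu.fs)
    return foot_imu.detect_foot_events(y, imu.fs, foot=foot, t0=imu.t[0])


def detect_lumbar(imu: ImuRecording, first_side: str) -> tuple[EventSeries, EventSeries]:
    ap = lumbar_imu.preprocess_lumbar(imu.accel_xyz[:, 2], imu.fs)
    d = lumbar_imu.integrate_then_cwt_differentiate(ap, imu.fs)
    return lumbar_imu.detect_lumbar_events(d, imu.fs, first_side=first_side,
                                           t0=imu.t[0])


def detect_kinect(skel: SkeletonRecording, fps: float,
                  pad: float = 0.8) -> tuple[EventSeries, EventSeries, dict]:
    """Events plus the resampled ankle grids (for length computation)."""
    track = kinect.select_participant(skel)
    t, zl = kinect.resample_joint(track, "left_ankle", 2, fps)
    _, zr = kinect.resample_joint(track, "right_ankle", 2, fps)
    _, zp = kinect.resample_joint(track, "pelvis", 2, fps)
    fzl = kinect.filter_joint_signal(zl, fps)
    fzr = kinect.filter_joint_signal(zr, fps)
    passes = kinect.split_passes(zp, fps)
    npad = int(pad * fps)
    det: dict[tuple[str, str], list[float]] = {
        (f, k): [] for f in ("left", "right") for k in ("HS", "TO")
    }
    for (a, b, d) in passes:
        a2, b2 = max(0, a - npad), min(len(t), b + npad)
        el, er = kinect.detect_kinect_events(
            kinect.ankle_acceleration(fzl[a2:b2], fps),
            kinect.ankle_acceleration(fzr[a2:b2], fps),
            fps, d, t0=t[a2],
        )
        for es, foot in ((el, "left"), (er, "right")):
            det[(foot, "HS")].extend(es.hs_times)
            det[(foot, "TO")].extend(es.to_times)
    left = _series_from_times("left", det[("left", "HS")], det[("left", "TO")], "kinect")
    right = _series_from_times("right", det[("right", "HS")], det[("right", "TO")], "kinect")
    # length readout uses the raw resampled depth: the low-pass filter is
    # for event detection and smears the landing corner of the stance
    # plateau by its kernel width
    grids = {"t": t, "z_left": zl, "z_right": zr}
    return left, right, grids


def foot_step_roots(
    imu_by_foot: dict[str, ImuRecording],
    left: EventSeries, right: EventSeries,
    mask: list[tuple[float, float]] | None,
) -> tuple[list[tuple[float, float]], list[tuple[float, float]]]:
    """(HS time, (amax-amin)^(1/4)) per step and per stride.

    The step root comes from the landing foot's sensor over the window
    from the preceding contralateral HS to the landing HS; the stride
    root spans consecutive same-foot HS.
    """
    merged = sorted([(t, "left") for t in left.hs_times]
                    + [(t, "right") for t in right.hs_times])
    steps: list[tuple[float, float]] = []
    for (t0, f0), (t1, f1) in zip(merged, merged[1:]):
        if f0 == f1 or not markers._in_mask(mask, t0, t1):
            continue
        aZ = markers.vertical_acceleration_series(imu_by_foot[f1], (t0, t1))
        steps.append((t1, float((aZ.max() - aZ.min()) ** 0.25)))
    strides: list[tuple[float, float]] = []
    for foot, es in (("left", left), ("right", right)):
        for t0, t1 in zip(es.hs_times, es.hs_times[1:]):
            if not markers._in_mask(mask, t0, t1):
                continue
            aZ = markers.vertical_acceleration_series(imu_by_foot[foot], (t0, t1))
            strides.append((t1, float((aZ.max() - aZ.min()) ** 0.25)))
    strides.sort()
    return steps, strides


def lumbar_step_lengths(
    imu: ImuRecording, left: EventSeries, right: EventSeries,
    pendulum_length: float, mask: list[tuple[float, float]] | None,
) -> list[tuple[float, float]]:
    """(HS time, pendulum step length) per step between detected HS."""
    merged = sorted([(t, "left") for t in left.hs_times]
                    + [(t, "right") for t in right.hs_times])
    out: list[tuple[float, float]] = []
    for (t0, f0), (t1, f1) in zip(merged, merged[1:]):
        if f0 == f1 or not markers._in_mask(mask, t0, t1):
            continue
        try:
            h = lumbar_imu.step_vertical_displacement(
                imu.accel_xyz[:, 0], imu.fs, (t0, t1), t0=imu.t[0]
            )
            h = min(h, 2 * pendulum_length - 1e-9)
            out.append((t1, markers.pendulum_step_length(h, pendulum_length)))
        except ValueError:
            continue
    return out


# ---------------------------------------------------------------------------
# Task-level runs
# ---------------------------------------------------------------------------


def _add_summary(summaries: dict, modality: str, strides: list) -> None:
    try:
        summaries[modality] = markers.macro_and_spatiotemporal(strides)
    except ValueError:
        log.warning("%s: no retained strides; summary omitted", modality)

@dataclass
class TaskResult:
    task: str
    summaries: dict[str, TrialSummary]          # modality -> summary
    events: dict[str, list[EventSeries]] = field(default_factory=dict)
    strides: dict[str, list] = field(default_factory=dict)


def run_task(
    session_streams: dict,
    truth: GroundTruthEvents,
    window: TaskWindow,
    pendulum_length: float,
    weinberg_constants: tuple[float, float] | None,
    modalities: tuple[str, ...] = ("foot_imu", "lumbar_imu", "kinect"),
) -> TaskResult:
    """Detect events and compute markers for one task window."""
    mask = walking_intervals(truth)
    ref_l, ref_r = reference_series(truth)
    true_lengths = [(truth.events[i].time, l) for i, l in truth.step_lengths]

    summaries: dict[str, TrialSummary] = {}
    all_events: dict[str, list[EventSeries]] = {}
    all_strides: dict[str, list] = {}

    ref_strides = markers.temporal_markers(ref_l, ref_r, mask)
    markers.attach_lengths(ref_strides, true_lengths)
    summaries["reference"] = markers.macro_and_spatiotemporal(ref_strides)
    all_events["reference"] = [ref_l, ref_r]
    all_strides["reference"] = ref_strides

    if "foot_imu" in modalities:
        il = sync.slice_recording(session_streams["imu_left"], window)
        ir = sync.slice_recording(session_streams["imu_right"], window)
        fl = detect_foot(il, "left")
        fr = detect_foot(ir, "right")
        strides = markers.temporal_markers(fl, fr, mask)
        if weinberg_constants is not None:
            k_step, k_stride = weinberg_constants
            roots_step, roots_stride = foot_step_roots(
                {"left": il, "right": ir}, fl, fr, mask
            )
            markers.attach_lengths(
                strides,
                [(t, k_step * r) for t, r in roots_step],
                [(t, k_stride * r) for t, r in roots_stride],
            )
        _add_summary(summaries, "foot_imu", strides)
        all_events["foot_imu"] = [fl, fr]
        all_strides["foot_imu"] = strides

    if "lumbar_imu" in modalities:
        ilum = sync.slice_recording(session_streams["imu_lumbar"], window)
        first_side = truth.events[0].foot if truth.events else "right"
        ll, lr = detect_lumbar(ilum, first_side)
        strides = markers.temporal_markers(ll, lr, mask)
        markers.attach_lengths(
            strides, lumbar_step_lengths(ilum, ll, lr, pendulum_length, mask)
        )
        _add_summary(summaries, "lumbar_imu", strides)
        all_events["lumbar_imu"] = [ll, lr]
        all_strides["lumbar_imu"] = strides

    if "kinect" in modalities:
        skel = sync.slice_recording(session_streams["skeleton"], window)
        kl, kr, grids = detect_kinect(skel, session_streams["fps"])
        strides = markers.temporal_markers(kl, kr, mask)
        steps, strd = kinect.kinect_lengths(
            grids["t"], grids["z_left"], grids["z_right"], kl, kr
        )
        steps = [(t, v) for t, v in steps if markers._in_mask(mask, t)]
        strd = [(t, v) for t, v in strd if markers._in_mask(mask, t)]
        markers.attach_lengths(strides, steps, strd)
        _add_summary(summaries, "kinect", strides)
        all_events["kinect"] = [kl, kr]
        all_strides["kinect"] = strides

    return TaskResult(task=window.label, summaries=summaries,
                      events=all_events, strides=all_strides)


def calibrate_weinberg(
    session_streams: dict, truth: GroundTruthEvents, window: TaskWindow
) -> tuple[float, float]:
    """K_step and K_stride from the practice walk vs. reference distance."""
    mask = walking_intervals(truth)
    il = sync.slice_recording(session_streams["imu_left"], window)
    ir = sync.slice_recording(session_streams["imu_right"], window)
    fl = detect_foot(il, "left")
    fr = detect_foot(ir, "right")
    roots_step, roots_stride = foot_step_roots({"left": il, "right": ir}, fl, fr, mask)
    true_lengths = {truth.events[i].time: l for i, l in truth.step_lengths}
    t_hs = np.array(sorted(true_lengths))

    def ref_distance(times: list[float]) -> float:
        total = 0.0
        for t, _ in times:
            i = int(np.argmin(np.abs(t_hs - t)))
            if abs(t_hs[i] - t) < 0.25:
                total += true_lengths[t_hs[i]]
        return total

    k_step = markers.calibrate_K([r for _, r in roots_step],
                                 ref_distance(roots_step))
    # a stride covers two steps: its reference length is the sum of the
    # step ending at the stride's terminal HS and the one before it
    stride_dist = 0.0
    for t, _ in roots_stride:
        i = int(np.argmin(np.abs(t_hs - t)))
        if abs(t_hs[i] - t) < 0.25 and i >= 1:
            stride_dist += true_lengths[t_hs[i]] + true_lengths[t_hs[i - 1]]
    k_stride = markers.calibrate_K([r for _, r in roots_stride], stride_dist)
    return k_step, k_stride


# ---------------------------------------------------------------------------
# Dataset-level run
# ---------------------------------------------------------------------------

def run_subject_dir(sdir: Path, cfg: dict,
                    modalities: tuple[str, ...] = ("foot_imu", "lumbar_imu", "kinect"),
                    ) -> dict[str, TaskResult]:
    streams = {
        "imu_left": io.read_imu(sdir / "imu_lfoot.csv"),
        "imu_right": io.read_imu(sdir / "imu_rfoot.csv"),
        "imu_lumbar": io.read_imu(sdir / "imu_lumbar.csv"),
        "fps": cfg["sensors"]["fps"],
    }
    skeleton_path = sdir / "skeleton.csv"
    mods = tuple(modalities)
    if skeleton_path.exists():
        streams["skeleton"] = io.read_skeleton(skeleton_path)
    elif "kinect" in mods:
        log.warning("%s: skeleton.csv missing; kinect modality skipped", sdir.name)
        mods = tuple(m for m in mods if m != "kinect")

    windows = sync.detect_task_windows(io.read_trigger(sdir / "trigger.csv"))
    by_label = {w.label: w for w in windows}
    truths = {task: io.read_truth(sdir / f"truth_{task}.csv") for task in TASKS
              if (sdir / f"truth_{task}.csv").exists()}

    weinberg = None
    if "practice" in by_label and "practice" in truths and "foot_imu" in mods:
        weinberg = calibrate_weinberg(streams, truths["practice"], by_label["practice"])
        log.info("%s: Weinberg K_step=%.3f K_stride=%.3f", sdir.name, *weinberg)

    results = {}
    for task in ("single_task", "dual_task"):
        if task not in by_label or task not in truths:
            continue
        results[task] = run_task(
            streams, truths[task], by_label[task], cfg["pendulum_length"],
            weinberg, mods,
        )
        log.info("%s/%s: %s", sdir.name, task,
                 {m: s.n_strides for m, s in results[task].summaries.items()})
    return results


def aggregate_agreement(
    all_results: list[dict[str, TaskResult]],
) -> dict[str, agr.AgreementReport]:
    """Cross-subject paired agreement per task, marker and modality."""
    reports: dict[str, agr.AgreementReport] = {}
    for task in ("single_task", "dual_task"):
        subject_results = [r[task] for r in all_results if task in r]
        if not subject_results:
            continue
        report = agr.AgreementReport(task=task)
        mods = sorted({m for r in subject_results for m in r.summaries if m != "reference"})
        for modality in mods:
            for marker in markers.MARKER_NAMES:
                ref_vals, test_vals = [], []
                for r in subject_results:
                    if modality not in r.summaries:
                        continue
                    rv = r.summaries["reference"].means.get(marker)
                    tv = r.summaries[modality].means.get(marker)
                    if rv is not None and tv is not None:
                        ref_vals.append(rv)
                        test_vals.append(tv)
                if len(ref_vals) >= 2:
                    report.add(modality, PairedMarkerSample(
                        marker=marker, units=markers.MARKER_UNITS[marker],
                        ref_values=np.array(ref_vals),
                        test_values=np.array(test_vals),
                    ))
        reports[task] = report
    return reports


def run_dataset(dataset_dir: str | Path, out_dir: str | Path | None = None,
                modalities: tuple[str, ...] = ("foot_imu", "lumbar_imu", "kinect"),
                make_plots: bool = True) -> dict[str, agr.AgreementReport]:
    """Run the full pipeline over a simulated (or compatible) dataset."""
    dataset_dir = Path(dataset_dir)
    cfg = merge_config(io.load_config(dataset_dir / "config.json"))
    manifest = json.loads((dataset_dir / "manifest.json").read_text())
    all_results = []
    for sname in manifest["subjects"]:
        sdir = dataset_dir / sname
        all_results.append(run_subject_dir(sdir, cfg, modalities))
        if out_dir is not None:
            rdir = Path(out_dir) / sname
            rdir.mkdir(parents=True, exist_ok=True)
            for task, res in all_results[-1].items():
                for modality, strides in res.strides.items():
                    io.write_strides(strides, rdir / f"strides_{task}_{modality}.csv")
                io.write_events(
                    [es for ser in res.events.values() for es in ser],
                    rdir / f"events_{task}.csv",
                )
                for modality, summ in res.summaries.items():
                    io.write_summary(summ, rdir / f"summary_{task}_{modality}.csv")
    reports = aggregate_agreement(all_results)
    if out_dir is not None:
        for task, report in reports.items():
            agr.build_report(report, Path(out_dir) / "agreement", make_plots=make_plots)
    return reports
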