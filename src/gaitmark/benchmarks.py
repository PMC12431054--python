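"""Standard validation suites for the whole pipeline.

Each function runs a self-contained experiment on synthetic data with
known ground truth and returns plain numbers: event-recovery rates per
modality, temporal-marker identity checks against an independent
pattern-matching calculator, closed-form spot checks, parameter
recovery at zero variance, and the cross-modality accuracy ordering on
noisy cohorts.  The test suite asserts on these numbers and the
acceptance script reports them.
"""

from __future__ import annotations

import numpy as np

from . import agreement as agr
from . import foot_imu, lumbar_imu, markers, pipeline as pl
from . import synthdata as sd
from .types import GaitProfile, PairedMarkerSample, SensorNoise

ZERO_VARIANCE_PROFILE = dict(
    stride_time_mean=1.08, stride_time_sd=0.0,
    stance_fraction=0.657, double_support_fraction=0.314,
    step_length_mean=0.6245, step_length_sd=0.0,
)

TEMPORAL_MARKERS = ("step_time", "stride_time", "stance_time", "swing_time",
                    "single_support", "double_support")


def _in(t: float, intervals) -> bool:
    return any(a - 1e-9 <= t <= b + 1e-9 for a, b in intervals)


def _recovery(true_times, detected, tol):
    true_times = np.asarray(true_times, dtype=float)
    detected = np.asarray(detected, dtype=float)
    if true_times.size == 0:
        return 0, 0
    if detected.size == 0:
        return 0, len(true_times)
    errs = np.array([np.min(np.abs(detected - t)) for t in true_times])
    return int(np.sum(errs <= tol)), len(true_times)


# ---------------------------------------------------------------------------
# Event recovery on noiseless data
# ---------------------------------------------------------------------------

def event_recovery_suite(n_seeds: int = 20, n_subjects: int = 18,
                         seed0: int = 0) -> dict[str, float]:
    """Noiseless recovery per modality over seeds x subjects.

    Tolerances: foot +-15 ms, lumbar +-30 ms, depth camera +-1.5 frames.
    Subjects vary by a between-subject random effect on stride time and
    step length; every stream is noise-free.
    """
    hits = {"foot_imu": 0, "lumbar_imu": 0, "kinect": 0}
    totals = {"foot_imu": 0, "lumbar_imu": 0, "kinect": 0}
    rng = np.random.default_rng(seed0)
    for s in range(n_seeds):
        for subj in range(n_subjects):
            prof = GaitProfile(
                stride_time_mean=float(np.clip(rng.normal(1.08, 0.07), 0.85, 1.4)),
                stride_time_sd=0.03,
                step_length_mean=float(np.clip(rng.normal(0.666, 0.06), 0.45, 0.9)),
                step_length_sd=0.02,
            )
            trial_seed = (seed0 * 100_003 + s * 1000 + subj) % (2 ** 31 - 1)
            tr = sd.simulate_trial(prof, seed=trial_seed, clutter=2,
                                   noise=SensorNoise())
            truth, wi = tr.truth, tr.walking_intervals

            for foot, rec in (("left", tr.imu_left), ("right", tr.imu_right)):
                es = pl.detect_foot(rec, foot)
                for kind, det in (("HS", es.hs_times), ("TO", es.to_times)):
                    true = [t for t in truth.times(foot, kind) if _in(t, wi)]
                    h, n = _recovery(true, det, 0.015)
                    hits["foot_imu"] += h
                    totals["foot_imu"] += n

            ll, lr = pl.detect_lumbar(tr.imu_lumbar, truth.events[0].foot)
            for kind in ("HS", "TO"):
                true = [t for t in np.concatenate(
                    [truth.times("left", kind), truth.times("right", kind)])
                    if _in(t, wi)]
                det = np.sort(np.concatenate([
                    getattr(ll, kind.lower() + "_times"),
                    getattr(lr, kind.lower() + "_times")]))
                h, n = _recovery(true, det, 0.030)
                hits["lumbar_imu"] += h
                totals["lumbar_imu"] += n

            kl, kr, _ = pl.detect_kinect(tr.skeleton, 30.0)
            for foot, es in (("left", kl), ("right", kr)):
                for kind, det in (("HS", es.hs_times), ("TO", es.to_times)):
                    true = [t for t in truth.times(foot, kind) if _in(t, wi)]
                    h, n = _recovery(true, det, 1.5 / 30.0)
                    hits["kinect"] += h
                    totals["kinect"] += n
    return {m: hits[m] / totals[m] for m in hits}


# ---------------------------------------------------------------------------
# Temporal-marker identities vs. an independent calculator
# ---------------------------------------------------------------------------

def _pattern_match_markers(events):
    """Independent brute-force interval calculator on the merged
    chronological event list (pattern HS_F, TO_C, HS_C, TO_F, HS_F)."""
    out = []
    for i, (t0, f, k) in enumerate(events):
        if k != "HS" or i + 4 >= len(events) + 1:
            continue
        window = events[i + 1: i + 5]
        if len(window) < 4:
            continue
        (t1, f1, k1), (t2, f2, k2), (t3, f3, k3), (t4, f4, k4) = window
        c = "left" if f == "right" else "right"
        if (f1, k1) == (c, "TO") and (f2, k2) == (c, "HS") \
                and (f3, k3) == (f, "TO") and (f4, k4) == (f, "HS"):
            out.append((round(t0, 9), {
                "stride_time": t4 - t0, "stance_time": t3 - t0,
                "swing_time": t4 - t3, "single_support": t2 - t1,
                "ds_initial": t1 - t0, "ds_terminal": t3 - t2,
            }))
    return dict(out)


def marker_identity_suite(n_trains: int = 1000, seed0: int = 0,
                          sample_period: float = 1 / 128) -> dict[str, float]:
    """Conservation identities and oracle agreement over random trains.

    Per retained stride: stance + swing = stride, ds_total = ds_initial
    + ds_terminal, stance = single_support + ds_total (all to <= 2
    sample periods), and every interval equals the independent
    calculator's value.
    """
    rng = np.random.default_rng(seed0)
    n_strides = 0
    max_violation = 0.0
    mismatches = 0
    for k in range(n_trains):
        stance = rng.uniform(0.58, 0.72)
        ds = float(min(rng.uniform(0.3, 1.2) * (2 * stance - 1), stance - 0.02))
        if ds <= 0.02:
            continue
        try:
            prof = GaitProfile(
                stride_time_mean=rng.uniform(0.9, 1.4),
                stride_time_sd=rng.uniform(0.0, 0.06),
                stance_fraction=stance, double_support_fraction=ds,
                n_passes=1,
            )
        except ValueError:
            continue
        truth = sd.generate_event_sequence(prof, seed=(seed0 * 7919 + k) % (2 ** 31 - 1))
        left = pl.reference_series(truth)[0]
        right = pl.reference_series(truth)[1]
        recs = markers.temporal_markers(left, right)
        oracle = _pattern_match_markers(
            sorted((e.time, e.foot, e.kind) for e in truth.events))
        for r in recs:
            n_strides += 1
            max_violation = max(
                max_violation,
                abs(r.stance_time + r.swing_time - r.stride_time),
                abs(r.ds_total - (r.ds_initial + r.ds_terminal)),
                abs(r.stance_time - (r.single_support + r.ds_total)),
            )
            o = oracle.get(round(r.start_time, 9))
            if o is None:
                mismatches += 1
                continue
            for name, v in o.items():
                if abs(getattr(r, name) - v) > 1e-9:
                    mismatches += 1
                    break
    return {
        "n_strides": float(n_strides),
        "max_identity_violation_s": max_violation,
        "identity_tolerance_s": 2 * sample_period,
        "oracle_mismatches": float(mismatches),
    }


# ---------------------------------------------------------------------------
# Closed-form spot checks
# ---------------------------------------------------------------------------

def closed_form_checks(seed: int = 0) -> dict[str, float]:
    rng = np.random.default_rng(seed)
    out: dict[str, float] = {}
    out["weinberg_16_range_K05"] = markers.weinberg_length(
        np.array([0.0, 16.0]), 0.5)
    out["pendulum_l1_h005"] = markers.pendulum_step_length(0.05, 1.0)

    ref = rng.normal(10, 2, 50)
    ba = agr.bland_altman(PairedMarkerSample("m", "u", ref, ref + 5.0))
    out["bland_altman_offset_bias"] = ba["bias"]
    out["bland_altman_offset_loa_width"] = ba["loa_high"] - ba["loa_low"]

    x = rng.normal(0, 1, 30)
    r_affine, _ = agr.pearson(PairedMarkerSample("m", "u", x, 2 * x + 1))
    out["pearson_affine_r"] = r_affine

    # sampling distribution of r at n=20, rho=0.9 (1000 replicates)
    rho = 0.9
    rs = []
    for _ in range(1000):
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=20)
        r, _ = agr.pearson(PairedMarkerSample("m", "u", z[:, 0], z[:, 1]))
        rs.append(r)
    out["pearson_mc_mean_r_n20_rho09"] = float(np.mean(rs))

    z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=10_000)
    r_big, _ = agr.pearson(PairedMarkerSample("m", "u", z[:, 0], z[:, 1]))
    out["pearson_large_sample_r_rho09"] = r_big
    return out


# ---------------------------------------------------------------------------
# Parameter recovery at zero variance
# ---------------------------------------------------------------------------

def parameter_recovery(seed: int = 0) -> dict[str, float]:
    """Zero-variance, noise-free session through the full pipeline.

    Reports per-modality deviations of the trial-mean markers from the
    construction values (times in s, lengths in m).
    """
    zv = ZERO_VARIANCE_PROFILE
    cfg = pl.merge_config({
        "cohort": {
            "n_subjects": 1,
            "single_task": {"stride_time_mean": zv["stride_time_mean"],
                            "step_length_mean": zv["step_length_mean"]},
            "dual_task": {"stride_time_mean": zv["stride_time_mean"],
                          "step_length_mean": zv["step_length_mean"]},
            "between_subject_sd": {"stride_time": 0.0, "step_length": 0.0},
            "within_subject_sd": {"stride_time": 0.0, "step_length": 0.0},
        },
        "noise": {"imu_gaussian_sd": 0.0, "imu_drift_amplitude": 0.0,
                  "skeleton_gaussian_sd": 0.0,
                  "lumbar_event_jitter_sd": 0.0,
                  "lumbar_vertical_attenuation": 1.0},
        "seed": seed,
    })
    sess = pl.simulate_subject(cfg, seed)
    streams = {"imu_left": sess.imu_left, "imu_right": sess.imu_right,
               "imu_lumbar": sess.imu_lumbar, "skeleton": sess.skeleton,
               "fps": 30.0}
    by_label = {w.label: w for w in sess.windows}
    weinberg = pl.calibrate_weinberg(streams, sess.truths["practice"],
                                     by_label["practice"])
    res = pl.run_task(streams, sess.truths["single_task"],
                      by_label["single_task"], cfg["pendulum_length"], weinberg)

    T = zv["stride_time_mean"]
    expected = {
        "stride_time": T, "step_time": T / 2,
        "stance_time": zv["stance_fraction"] * T,
        "swing_time": (1 - zv["stance_fraction"]) * T,
        "single_support": (1 - zv["stance_fraction"]) * T,
        "double_support": (2 * zv["stance_fraction"] - 1) * T,
    }
    out: dict[str, float] = {"grid_resolution_s": 2 / 128}
    for mod in ("reference", "foot_imu"):
        summ = res.summaries[mod]
        out[f"{mod}_max_temporal_dev_s"] = max(
            abs(summ.means[m] - v) for m, v in expected.items()
        )
    sl_cm = zv["step_length_mean"] * 100
    out["foot_imu_step_length_dev_cm"] = abs(
        res.summaries["foot_imu"].means["step_length"] - sl_cm)
    out["lumbar_step_length_rel_err"] = abs(
        res.summaries["lumbar_imu"].means["step_length"] - sl_cm) / sl_cm
    out["lumbar_stride_length_rel_err"] = abs(
        res.summaries["lumbar_imu"].means["stride_length"] - 2 * sl_cm) / (2 * sl_cm)
    out["kinect_step_length_dev_m"] = abs(
        res.summaries["kinect"].means["step_length"] - sl_cm) / 100
    out["kinect_stride_length_dev_m"] = abs(
        res.summaries["kinect"].means["stride_length"] - 2 * sl_cm) / 100
    return out


# ---------------------------------------------------------------------------
# Modality accuracy ordering on noisy cohorts
# ---------------------------------------------------------------------------

def modality_ordering(n_cohorts: int = 20, n_subjects: int = 18,
                      seed0: int = 0) -> dict[str, float]:
    """Mean MAEP over temporal markers per modality for each cohort at
    the default noise; counts how often foot <= kinect <= lumbar."""
    ordered = 0
    maeps = {"foot_imu": [], "kinect": [], "lumbar_imu": []}
    for c in range(n_cohorts):
        cfg = pl.merge_config({"cohort": {"n_subjects": n_subjects},
                               "seed": seed0 * 1000 + c})
        results = []
        for subj in range(n_subjects):
            subject_seed = int(cfg["seed"]) * 1000 + subj
            sess = pl.simulate_subject(cfg, subject_seed)
            streams = {"imu_left": sess.imu_left, "imu_right": sess.imu_right,
                       "imu_lumbar": sess.imu_lumbar, "skeleton": sess.skeleton,
                       "fps": 30.0}
            by_label = {w.label: w for w in sess.windows}
            weinberg = pl.calibrate_weinberg(
                streams, sess.truths["practice"], by_label["practice"])
            per_task = {}
            for task in ("single_task", "dual_task"):
                per_task[task] = pl.run_task(
                    streams, sess.truths[task], by_label[task],
                    cfg["pendulum_length"], weinberg)
            results.append(per_task)
        reports = pl.aggregate_agreement(results)
        cohort_maep = {}
        for mod in maeps:
            vals = []
            for task, rep in reports.items():
                vals += [rep.results[(m, mod)].maep for m in TEMPORAL_MARKERS
                         if (m, mod) in rep.results
                         and rep.results[(m, mod)].maep is not None]
            cohort_maep[mod] = float(np.mean(vals))
            maeps[mod].append(cohort_maep[mod])
        if cohort_maep["foot_imu"] <= cohort_maep["kinect"] <= cohort_maep["lumbar_imu"]:
            ordered += 1
    out = {f"mean_temporal_maep_{m}": float(np.mean(v)) for m, v in maeps.items()}
    out["cohorts_with_expected_ordering"] = float(ordered)
    out["n_cohorts"] = float(n_cohorts)
    return out


# ---------------------------------------------------------------------------
# Round trips
# ---------------------------------------------------------------------------

def round_trip_checks(seed: int = 0, tmp_dir=None) -> dict[str, float]:
    import hashlib
    import tempfile
    from pathlib import Path

    from . import sync
    from .synthdata import synthesize_trigger

    rng = np.random.default_rng(seed)
    out: dict[str, float] = {}

    # trigger windows round trip
    fs, total = 120.0, 200.0
    cursor, windows = 0.0, []
    for _ in range(4):
        a = cursor + rng.uniform(3, 8)
        b = a + rng.uniform(5, 30)
        if b > total:
            break
        windows.append((a, b))
        cursor = b
    ws = sync.detect_task_windows(synthesize_trigger(windows, fs, total))
    out["trigger_max_edge_error_s"] = max(
        max(abs(w.start - a), abs(w.end - b))
        for w, (a, b) in zip(ws, windows)
    )
    out["trigger_windows_recovered"] = float(len(ws) == len(windows))

    # noiseless synthetic -> detected -> event times round trip (foot)
    prof = GaitProfile(**ZERO_VARIANCE_PROFILE)
    tr = sd.simulate_trial(prof, seed=seed, noise=SensorNoise())
    es = pl.detect_foot(tr.imu_left, "left")
    true = [t for t in tr.truth.times("left", "HS")
            if _in(t, tr.walking_intervals)]
    h, n = _recovery(true, es.hs_times, 0.015)
    out["foot_event_round_trip_fraction"] = h / n

    # config-hash determinism: identical dataset bytes on rerun
    cfg = pl.merge_config({"cohort": {"n_subjects": 1}, "seed": seed})
    base = Path(tmp_dir) if tmp_dir else Path(tempfile.mkdtemp())

    def dataset_digest(path: Path) -> str:
        h = hashlib.sha1()
        for p in sorted(path.rglob("*")):
            if p.is_file():
                h.update(p.read_bytes())
        return h.hexdigest()

    d1, d2 = base / "rt_a", base / "rt_b"
    pl.simulate_dataset(cfg, d1)
    pl.simulate_dataset(cfg, d2)
    out["dataset_rerun_identical"] = float(dataset_digest(d1) == dataset_digest(d2))
    return out
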