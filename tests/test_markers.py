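"""Temporal-marker extraction, length estimators and trial aggregation."""

import numpy as np
import pytest

from conftest import ZERO_VARIANCE
from gaitmark import markers as mk
from gaitmark import synthdata as sd
from gaitmark.types import EventSeries, GaitProfile


def series_from_truth(truth, foot):
    return EventSeries(foot, truth.times(foot, "HS"), truth.times(foot, "TO"),
                       "reference")


def brute_force_markers(events):
    """Independent oracle: pattern-match HS_F, TO_C, HS_C, TO_F, HS_F
    directly on the merged chronological (time, foot, kind) list."""
    out = []
    for i in range(len(events)):
        t0, f, k = events[i]
        if k != "HS":
            continue
        window = events[i + 1: i + 5]
        if len(window) < 4:
            continue
        (t1, f1, k1), (t2, f2, k2), (t3, f3, k3), (t4, f4, k4) = window
        c = "left" if f == "right" else "right"
        if (f1, k1) == (c, "TO") and (f2, k2) == (c, "HS") \
                and (f3, k3) == (f, "TO") and (f4, k4) == (f, "HS"):
            prev_hs_c = [t for t, ff, kk in events[:i] if ff == c and kk == "HS"]
            if not prev_hs_c:
                continue
            out.append({
                "foot": f, "start": t0,
                "step_time": t0 - prev_hs_c[-1],
                "stride_time": t4 - t0,
                "stance_time": t3 - t0,
                "swing_time": (t4 - t0) - (t3 - t0),
                "single_support": t2 - t1,
                "ds_initial": t1 - t0,
                "ds_terminal": t3 - t2,
            })
    return out


class TestTemporalMarkers:
    def test_worked_example(self):
        left = EventSeries("left", [0.00, 1.08], [0.66], "reference")
        right = EventSeries("right", [0.54, 1.62], [0.12, 1.20], "reference")
        recs = mk.temporal_markers(left, right)
        r = [x for x in recs if x.foot == "right"][0]
        assert r.step_time == pytest.approx(0.54)
        assert r.stride_time == pytest.approx(1.08)
        assert r.stance_time == pytest.approx(0.66)
        assert r.swing_time == pytest.approx(0.42)
        assert r.ds_initial == pytest.approx(0.12)
        assert r.ds_terminal == pytest.approx(0.12)
        assert r.ds_total == pytest.approx(0.24)
        assert r.single_support == pytest.approx(0.42)

    def test_symmetric_gait_gives_identical_sides(self, zero_variance_profile):
        truth = sd.generate_event_sequence(zero_variance_profile, seed=0)
        recs = mk.temporal_markers(series_from_truth(truth, "left"),
                                   series_from_truth(truth, "right"),
                                   mask=sd.walking_intervals(truth))
        for name in ("step_time", "stride_time", "stance_time", "swing_time"):
            left = [getattr(r, name) for r in recs if r.foot == "left"]
            right = [getattr(r, name) for r in recs if r.foot == "right"]
            assert np.mean(left) == pytest.approx(np.mean(right), abs=1e-12)

    def test_single_hs_pair_yields_no_strides(self):
        """A lone stride with no interleaved contralateral events is
        dropped (insufficient events)."""
        left = EventSeries("left", [0.0, 1.08], [0.7], "reference")
        right = EventSeries("right", [], [], "reference")
        assert mk.temporal_markers(left, right) == []

    def test_matches_brute_force_oracle_on_random_trains(self):
        """Conservation identities and value-level agreement against the
        pattern-matching oracle on many random valid event trains."""
        rng = np.random.default_rng(99)
        for trial in range(60):
            stance = rng.uniform(0.58, 0.72)
            ds = min(rng.uniform(0.3, 1.2) * (2 * stance - 1), stance - 0.02)
            if ds <= 0.02:
                continue
            try:
                prof = GaitProfile(
                    stride_time_mean=rng.uniform(0.9, 1.4),
                    stride_time_sd=rng.uniform(0, 0.06),
                    stance_fraction=stance, double_support_fraction=ds,
                    n_passes=1,
                )
            except ValueError:
                continue
            truth = sd.generate_event_sequence(prof, seed=trial)
            recs = mk.temporal_markers(series_from_truth(truth, "left"),
                                       series_from_truth(truth, "right"))
            merged = sorted((e.time, e.foot, e.kind) for e in truth.events)
            oracle = brute_force_markers(merged)
            by_start = {round(o["start"], 9): o for o in oracle}
            matched = 0
            for r in recs:
                o = by_start.get(round(r.start_time, 9))
                if o is None:
                    continue
                matched += 1
                for name in ("step_time", "stride_time", "stance_time",
                             "swing_time", "single_support", "ds_initial",
                             "ds_terminal"):
                    assert getattr(r, name) == pytest.approx(o[name], abs=1e-9)
                # conservation identities
                assert r.stance_time + r.swing_time == pytest.approx(
                    r.stride_time, abs=1e-9)
                assert r.ds_total == pytest.approx(
                    r.ds_initial + r.ds_terminal, abs=1e-12)
                assert r.stance_time == pytest.approx(
                    r.single_support + r.ds_total, abs=1e-9)
            assert matched >= max(1, len(recs) - 2)

    def test_zero_variance_round_trip_to_profile(self):
        """Markers from reference events reproduce construction values."""
        prof = GaitProfile(**ZERO_VARIANCE)
        truth = sd.generate_event_sequence(prof, seed=1)
        recs = mk.temporal_markers(series_from_truth(truth, "left"),
                                   series_from_truth(truth, "right"),
                                   mask=sd.walking_intervals(truth))
        lengths = [(truth.events[i].time, l) for i, l in truth.step_lengths]
        mk.attach_lengths(recs, lengths)
        summ = mk.macro_and_spatiotemporal(recs)
        T = prof.stride_time_mean
        assert summ.means["stride_time"] == pytest.approx(T, abs=1e-12)
        assert summ.means["stance_time"] == pytest.approx(0.657 * T, abs=1e-12)
        assert summ.means["swing_time"] == pytest.approx(0.343 * T, abs=1e-12)
        assert summ.means["step_length"] == pytest.approx(62.45, abs=1e-9)
        assert summ.means["stride_length"] == pytest.approx(124.9, abs=1e-9)
        assert summ.means["cadence"] == pytest.approx(2 / T * 60, abs=1e-9)


class TestWeinberg:
    def test_quarter_power_exact_case(self):
        # 16^(1/4) = 2 exactly
        assert mk.weinberg_length(np.array([0.0, 16.0]), K=0.5) == 1.0

    def test_flat_segment_gives_zero(self):
        assert mk.weinberg_length(np.full(10, 3.3), K=0.5) == 0.0

    def test_calibration_arithmetic(self):
        assert mk.calibrate_K([2.0, 2.0, 2.0], 3.0) == pytest.approx(0.5)

    def test_calibration_rejects_too_few_steps(self):
        with pytest.raises(ValueError):
            mk.calibrate_K([2.0], 1.0)

    def test_calibrated_on_one_pass_transfers_to_another(self, noiseless_trial):
        """K from pass 1 reproduces pass-2 step lengths within 8%."""
        truth = noiseless_trial.truth
        rec = noiseless_trial.imu_right
        lengths = dict(truth.step_lengths)
        hs = [(i, e) for i, e in enumerate(truth.events)
              if e.kind == "HS" and lengths.get(i, 0) > 0.3]
        turn = truth.turn_intervals[0][0]
        def roots_for(pred):
            out = []
            for (i, prev), (j, cur) in zip(hs, hs[1:]):
                if cur.foot != "right" or not pred(cur.time):
                    continue
                if cur.time - prev.time > 1.0:
                    continue
                aZ = mk.vertical_acceleration_series(rec, (prev.time, cur.time))
                out.append(((aZ.max() - aZ.min()) ** 0.25, lengths[j]))
            return out
        cal = roots_for(lambda t: t < turn)
        test = roots_for(lambda t: t > turn)
        K = mk.calibrate_K([r for r, _ in cal], sum(l for _, l in cal))
        for root, true_len in test:
            assert K * root == pytest.approx(true_len, rel=0.08)


class TestPendulum:
    def test_closed_form_value(self):
        assert mk.pendulum_step_length(0.05, 1.0) == pytest.approx(0.6245, abs=5e-5)

    def test_zero_excursion(self):
        assert mk.pendulum_step_length(0.0, 1.0) == 0.0

    def test_boundary_behavior(self):
        """The chord length is maximal (= 2l) at h = l and collapses to
        zero as h approaches the 2l limit."""
        assert mk.pendulum_step_length(0.5, 0.5) == pytest.approx(1.0, rel=1e-12)
        assert mk.pendulum_step_length(1.0 - 1e-9, 0.5) == pytest.approx(0.0, abs=1e-4)

    def test_imaginary_root_rejected(self):
        with pytest.raises(ValueError):
            mk.pendulum_step_length(1.1, 0.5)


class TestTrialSummary:
    def _uniform_strides(self, n=10, stride_time=1.08, stride_length=1.2960):
        from gaitmark.types import StrideRecord
        return [
            StrideRecord(foot="left" if i % 2 else "right",
                         step_time=stride_time / 2, stride_time=stride_time,
                         stance_time=0.7 * stride_time,
                         swing_time=0.3 * stride_time,
                         single_support=0.3 * stride_time,
                         ds_initial=0.2 * stride_time,
                         ds_terminal=0.2 * stride_time,
                         ds_total=0.4 * stride_time,
                         stride_length=stride_length,
                         step_length=stride_length / 2,
                         start_time=i * stride_time)
            for i in range(n)
        ]

    def test_cadence_and_velocity_arithmetic(self):
        summ = mk.macro_and_spatiotemporal(self._uniform_strides())
        assert summ.means["cadence"] == pytest.approx(111.1111, abs=1e-3)
        assert summ.means["velocity"] == pytest.approx(120.0, abs=1e-9)
        assert summ.means["stride_velocity"] == pytest.approx(120.0, abs=1e-9)

    def test_single_stride_has_zero_sds(self):
        summ = mk.macro_and_spatiotemporal(self._uniform_strides(n=1))
        assert summ.n_strides == 1
        assert all(v == 0.0 for v in summ.sds.values())

    def test_halving_times_doubles_rates(self):
        s1 = mk.macro_and_spatiotemporal(self._uniform_strides(stride_time=1.0))
        s2 = mk.macro_and_spatiotemporal(self._uniform_strides(stride_time=0.5))
        assert s2.means["velocity"] == pytest.approx(2 * s1.means["velocity"])
        assert s2.means["cadence"] == pytest.approx(2 * s1.means["cadence"])

    def test_empty_strides_rejected(self):
        with pytest.raises(ValueError):
            mk.macro_and_spatiotemporal([])
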