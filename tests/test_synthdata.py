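"""Generator contracts: event geometry, stream construction, determinism."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import ZERO_VARIANCE, event_recovery, in_intervals
from gaitmark import synthdata as sd
from gaitmark.types import GaitProfile, SensorNoise


class TestEventSequence:
    def test_zero_variance_strides_are_exact(self, zero_variance_profile):
        truth = sd.generate_event_sequence(zero_variance_profile, seed=0)
        for foot in ("left", "right"):
            hs = truth.times(foot, "HS")
            steady = [b - a for a, b in zip(hs, hs[1:]) if b - a < 2.0]
            assert steady and np.allclose(steady, 1.08, atol=1e-12)

    def test_stance_and_swing_follow_construction(self, zero_variance_profile):
        truth = sd.generate_event_sequence(zero_variance_profile, seed=0)
        # steady-state stance: own HS to next own TO within a pass
        for foot in ("left", "right"):
            hs = truth.times(foot, "HS")
            to = truth.times(foot, "TO")
            stances = []
            for h in hs:
                later = to[to > h]
                if later.size and later[0] - h < 1.0:
                    stances.append(later[0] - h)
            assert np.allclose(np.median(stances), 0.657 * 1.08, atol=1e-9)
            assert np.isclose(1.08 - np.median(stances), 0.37044, atol=1e-9)

    def test_same_seed_identical_different_seed_differs(self):
        prof = GaitProfile()
        a = sd.generate_event_sequence(prof, seed=42)
        b = sd.generate_event_sequence(prof, seed=42)
        c = sd.generate_event_sequence(prof, seed=43)
        assert [(e.time, e.foot, e.kind) for e in a.events] == \
               [(e.time, e.foot, e.kind) for e in b.events]
        assert [e.time for e in a.events] != [e.time for e in c.events]

    def test_single_stride_exceeding_path_rejected(self):
        with pytest.raises(ValueError, match="stride exceeds"):
            sd.generate_event_sequence(
                GaitProfile(step_length_mean=1.2, path_length=2.0), seed=0
            )

    def test_cumulative_step_lengths_within_path(self):
        prof = GaitProfile(n_passes=3)
        truth = sd.generate_event_sequence(prof, seed=5)
        by_pass: dict[int, float] = {}
        for i, l in truth.step_lengths:
            by_pass[truth.events[i].pass_index] = by_pass.get(
                truth.events[i].pass_index, 0.0) + l
        for total in by_pass.values():
            assert total <= prof.path_length + 1e-9

    @given(
        stride=st.floats(0.8, 1.6),
        stance=st.floats(0.55, 0.75),
        ds_scale=st.floats(0.3, 1.2),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=40, deadline=None)
    def test_invariants_hold_across_profiles(self, stride, stance, ds_scale, seed):
        ds = min((2 * stance - 1) * ds_scale, stance - 0.01)
        if ds <= 0:
            return
        try:
            prof = GaitProfile(
                stride_time_mean=stride, stride_time_sd=0.05 * stride,
                stance_fraction=stance, double_support_fraction=ds,
            )
        except ValueError:
            return  # fractions do not admit a valid event order
        truth = sd.generate_event_sequence(prof, seed=seed)
        # validate() (in the constructor) asserts strict per-pass time
        # order and per-foot HS/TO alternation; check the global cycle:
        # each HS is followed by the opposite foot's TO
        evs = truth.events
        for a, b in zip(evs, evs[1:]):
            if a.kind == "HS" and b.pass_index == a.pass_index:
                assert b.kind == "TO" and b.foot != a.foot


class TestFootGyro:
    def test_sample_count(self, zero_variance_profile):
        truth = sd.generate_event_sequence(zero_variance_profile, seed=0)
        rec = sd.synthesize_foot_gyro(truth, "left", 128.0, SensorNoise(),
                                      duration=10.0)
        assert rec.n == 1280
        assert rec.gyro_xyz.shape == (1280, 3)

    def test_noiseless_extrema_at_events(self, noiseless_trial):
        """Per-foot minima/maxima of the raw ML channel sit within one
        sample of each true HS/TO."""
        truth = noiseless_trial.truth
        for foot, rec in (("left", noiseless_trial.imu_left),
                          ("right", noiseless_trial.imu_right)):
            gy = rec.gyro_xyz[:, 1]
            for kind, sign in (("HS", -1), ("TO", 1)):
                for t_ev in truth.times(foot, kind):
                    i = int(round(t_ev * rec.fs))
                    w = gy[i - 10: i + 11] * sign
                    assert abs(int(np.argmax(w)) - 10) <= 1

    def test_lobe_width_bounded(self):
        assert sd.FOOT_LOBE_WIDTH <= 0.25 * 1.08

    def test_fixed_seed_bit_identical(self, zero_variance_profile):
        t1 = sd.simulate_trial(zero_variance_profile, seed=3)
        t2 = sd.simulate_trial(zero_variance_profile, seed=3)
        assert np.array_equal(t1.imu_left.gyro_xyz, t2.imu_left.gyro_xyz)
        assert np.array_equal(t1.imu_lumbar.accel_xyz, t2.imu_lumbar.accel_xyz)
        assert t1.skeleton.frames[50].joints == t2.skeleton.frames[50].joints


class TestLumbar:
    def test_pendulum_inversion_example(self):
        # 2*sqrt(2*1*0.05 - 0.05^2) = 0.6245, so the inverse of 0.6245 is 0.05
        assert sd.invert_pendulum(2 * np.sqrt(2 * 1.0 * 0.05 - 0.05 ** 2), 1.0) == \
            pytest.approx(0.05, abs=1e-12)
        assert sd.invert_pendulum(0.0, 1.0) == 0.0

    def test_pendulum_inversion_rejects_impossible_step(self):
        with pytest.raises(ValueError):
            sd.invert_pendulum(2.1, 1.0)

    def test_vertical_channel_flat_for_zero_length_step(self):
        prof = GaitProfile(**ZERO_VARIANCE)
        truth = sd.generate_event_sequence(prof, seed=0)
        truth.step_lengths = [(i, 0.0) for i, _ in truth.step_lengths]
        rec = sd.synthesize_lumbar_accel(truth, 128.0, SensorNoise(), 1.0)
        assert np.allclose(rec.accel_xyz[:, 0], sd.G)

    def test_noiseless_lumbar_recovers_events(self, noiseless_trial):
        from gaitmark import lumbar_imu as li

        truth = noiseless_trial.truth
        rec = noiseless_trial.imu_lumbar
        ap = li.preprocess_lumbar(rec.accel_xyz[:, 2], rec.fs)
        d = li.integrate_then_cwt_differentiate(ap, rec.fs)
        left, right = li.detect_lumbar_events(d, rec.fs, first_side="left")
        hs_det = np.sort(np.concatenate([left.hs_times, right.hs_times]))
        hs_true = np.sort(np.concatenate(
            [truth.times("left", "HS"), truth.times("right", "HS")]
        ))
        sens, _, _ = event_recovery(hs_true, hs_det, tol=0.030)
        assert sens >= 0.95


class TestSkeleton:
    def test_clutter_body_ids(self, zero_variance_profile):
        truth = sd.generate_event_sequence(zero_variance_profile, seed=1)
        rec0 = sd.synthesize_skeleton(truth, 30.0, 0, SensorNoise())
        assert rec0.body_ids() == [sd.PARTICIPANT_BODY_ID]
        rec2 = sd.synthesize_skeleton(truth, 30.0, 2, SensorNoise())
        ids = rec2.body_ids()
        assert len(ids) >= 3
        times = rec2.frame_times()
        cover = {
            bid: len(rec2.body_frames(bid)) / len(times) for bid in ids
        }
        full = [bid for bid, c in cover.items() if c >= 0.95]
        assert full == [sd.PARTICIPANT_BODY_ID]

    def test_right_hs_depth_steps_by_stride_length(self, noiseless_trial):
        truth = noiseless_trial.truth
        skel = noiseless_trial.skeleton
        tgrid = skel.frame_times()
        z = {round(fr.time, 6): fr.joints["right_ankle"][2]
             for fr in skel.frames if fr.body_id == sd.PARTICIPANT_BODY_ID}
        zs = np.array([z[round(t, 6)] for t in tgrid])
        hs = [t for t in truth.times("right", "HS")
              if in_intervals(t, noiseless_trial.walking_intervals)]
        # consecutive right heel strikes on the outbound pass: depth drops
        # by one stride length
        outbound = [t for t in hs if t < truth.turn_intervals[0][0]]
        for a, b in zip(outbound, outbound[1:]):
            za = zs[np.argmin(np.abs(tgrid - a))]
            zb = zs[np.argmin(np.abs(tgrid - b))]
            assert zb - za == pytest.approx(-2 * 0.6245, abs=0.01)

    def test_fps_cap_enforced(self, zero_variance_profile):
        truth = sd.generate_event_sequence(zero_variance_profile, seed=0)
        with pytest.raises(ValueError):
            sd.synthesize_skeleton(truth, 31.0, 0, SensorNoise())


class TestTrigger:
    def test_low_sample_count(self):
        sig = sd.synthesize_trigger([(10.0, 20.0)], 120.0, 30.0)
        assert abs(int(np.sum(sig.level == 0.0)) - 1200) <= 1

    def test_no_windows_all_high(self):
        sig = sd.synthesize_trigger([], 120.0, 5.0)
        assert np.all(sig.level == 5.0)

    def test_full_window_all_low(self):
        sig = sd.synthesize_trigger([(0.0, 30.0)], 120.0, 30.0)
        assert np.all(sig.level == 0.0)

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            sd.synthesize_trigger([(0.0, 10.0), (5.0, 15.0)], 120.0, 30.0)
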