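"""Participant selection, joint filtering and depth-based event detection."""

import numpy as np
import pytest

from conftest import event_recovery, in_intervals
from gaitmark import kinect as kn
from gaitmark import pipeline as pl
from gaitmark import synthdata as sd
from gaitmark.types import GaitProfile, SensorNoise, SkeletonFrame, SkeletonRecording

FPS = 30.0


def _sine(freq: float, duration: float = 20.0, fps: float = FPS) -> np.ndarray:
    t = np.arange(int(duration * fps)) / fps
    return np.sin(2 * np.pi * freq * t)


class TestSelectParticipant:
    def test_cluttered_scene_returns_constructed_participant(self, noiseless_trial):
        track = kn.select_participant(noiseless_trial.skeleton)
        assert track.body_id == sd.PARTICIPANT_BODY_ID
        assert track.coverage == 1.0

    def test_single_body_recording(self, zero_variance_profile):
        truth = sd.generate_event_sequence(zero_variance_profile, seed=0)
        rec = sd.synthesize_skeleton(truth, FPS, 0, SensorNoise())
        track = kn.select_participant(rec)
        assert track.body_id == sd.PARTICIPANT_BODY_ID

    def test_empty_recording_errors(self):
        with pytest.raises(ValueError):
            kn.select_participant(SkeletonRecording([]))

    def test_invariant_to_permuting_clutter_ids(self, noiseless_trial):
        rec = noiseless_trial.skeleton
        clutter_ids = [b for b in rec.body_ids() if b != sd.PARTICIPANT_BODY_ID]
        perm = {b: clutter_ids[(i + 1) % len(clutter_ids)]
                for i, b in enumerate(clutter_ids)}
        perm[sd.PARTICIPANT_BODY_ID] = sd.PARTICIPANT_BODY_ID
        permuted = SkeletonRecording([
            SkeletonFrame(fr.time, perm[fr.body_id], fr.joints)
            for fr in rec.frames
        ])
        assert kn.select_participant(permuted).body_id == sd.PARTICIPANT_BODY_ID


class TestJointFilter:
    def test_6hz_strongly_attenuated(self):
        y = kn.filter_joint_signal(_sine(6.0), FPS)
        mid = slice(int(5 * FPS), int(15 * FPS))
        assert np.abs(y[mid]).max() <= 0.02

    def test_passband_preserved(self):
        y = kn.filter_joint_signal(_sine(0.5), FPS)
        mid = slice(int(5 * FPS), int(15 * FPS))
        assert np.abs(y[mid]).max() == pytest.approx(1.0, rel=0.02)

    def test_constant_unchanged(self):
        y = kn.filter_joint_signal(np.full(300, 2.5), FPS)
        assert np.allclose(y, 2.5)

    def test_low_fps_rejected(self):
        with pytest.raises(ValueError):
            kn.filter_joint_signal(np.zeros(100), 6.0)


class TestAnkleAcceleration:
    def test_constant_acceleration_recovered(self):
        t = np.arange(300) / FPS
        pos = 0.5 * 1.7 * t ** 2
        a = kn.ankle_acceleration(pos, FPS)
        assert np.allclose(a[2:-2], 1.7, rtol=1e-9)

    def test_linear_position_gives_zero(self):
        t = np.arange(300) / FPS
        a = kn.ankle_acceleration(3.0 + 0.4 * t, FPS)
        assert np.abs(a[2:-2]).max() < 1e-9

    def test_sinusoid_second_derivative(self):
        f = 2.0
        x = _sine(f)
        a = kn.ankle_acceleration(x, FPS)
        expected = -((2 * np.pi * f) ** 2) * x
        mid = slice(int(2 * FPS), int(18 * FPS))
        assert np.allclose(a[mid], expected[mid],
                           atol=0.05 * np.abs(expected).max())

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            kn.ankle_acceleration(np.zeros(4), FPS)


class TestDetect:
    def test_constant_position_gives_empty_series(self):
        a = np.zeros(300)
        left, right = kn.detect_kinect_events(a, a, FPS, 1)
        assert left.n_events == 0 and right.n_events == 0

    def test_direction_flip_swaps_labels(self, noiseless_trial):
        track = kn.select_participant(noiseless_trial.skeleton)
        t, zl = kn.resample_joint(track, "left_ankle", 2)
        fzl = kn.filter_joint_signal(zl, FPS)
        passes = kn.split_passes(
            kn.resample_joint(track, "pelvis", 2)[1], FPS)
        a, b, d = passes[0]
        acc = kn.ankle_acceleration(fzl[a:b], FPS)
        e1, _ = kn.detect_kinect_events(acc, acc, FPS, d, t0=t[a])
        e2, _ = kn.detect_kinect_events(acc, acc, FPS, -d, t0=t[a])
        assert np.allclose(e1.hs_times, e2.to_times)
        assert np.allclose(e1.to_times, e2.hs_times)

    def test_noiseless_recovery_within_1_5_frames(self, noiseless_trial):
        truth = noiseless_trial.truth
        left, right, _ = pl.detect_kinect(noiseless_trial.skeleton, FPS)
        for foot, es in (("left", left), ("right", right)):
            for kind, det in (("HS", es.hs_times), ("TO", es.to_times)):
                true = [t for t in truth.times(foot, kind)
                        if in_intervals(t, noiseless_trial.walking_intervals)]
                sens, _, _ = event_recovery(true, det, tol=1.5 / FPS)
                assert sens >= 0.90

    def test_recovery_with_position_noise(self):
        """HS sensitivity stays >= 0.85 with 1 cm joint position noise."""
        prof = GaitProfile()
        sens_all = []
        for seed in range(8):
            tr = sd.simulate_trial(prof, seed=seed, clutter=2,
                                   noise=SensorNoise(gaussian_sd=0.0))
            skel = sd.synthesize_skeleton(tr.truth, FPS, 2,
                                          SensorNoise(gaussian_sd=0.01, seed=seed))
            left, right, _ = pl.detect_kinect(skel, FPS)
            for foot, es in (("left", left), ("right", right)):
                true = [t for t in tr.truth.times(foot, "HS")
                        if in_intervals(t, tr.walking_intervals)]
                sens, _, _ = event_recovery(true, es.hs_times, tol=1.5 / FPS)
                sens_all.append(sens)
        assert np.mean(sens_all) >= 0.85


class TestLengths:
    def test_step_length_is_depth_difference(self):
        t = np.arange(10) / FPS
        zl = np.full(10, 3.72)
        zr = np.full(10, 3.10)
        from gaitmark.types import EventSeries
        el = EventSeries("left", [t[2]], [], "kinect")
        er = EventSeries("right", [t[5]], [], "kinect")
        steps, _ = kn.kinect_lengths(t, zl, zr, el, er)
        assert len(steps) == 1
        assert steps[0][1] == pytest.approx(0.62, abs=1e-9)

    def test_stride_length_same_foot_consecutive_hs(self):
        t = np.arange(40) / FPS
        zr = np.concatenate([np.full(20, 3.10), np.full(20, 1.86)])
        from gaitmark.types import EventSeries
        er = EventSeries("right", [t[10], t[30]], [t[20]], "kinect")
        el = EventSeries("left", [], [], "kinect")
        _, strides = kn.kinect_lengths(t, np.zeros(40), zr, el, er)
        assert len(strides) == 1
        assert strides[0][1] == pytest.approx(1.24, abs=1e-9)

    def test_noiseless_stride_lengths_match_truth(self, noiseless_trial):
        from gaitmark import markers as mk

        left, right, grids = pl.detect_kinect(noiseless_trial.skeleton, FPS)
        strides = mk.temporal_markers(left, right,
                                      noiseless_trial.walking_intervals)
        steps, strd = kn.kinect_lengths(
            grids["t"], grids["z_left"], grids["z_right"], left, right)
        mk.attach_lengths(strides, steps, strd)
        checked = 0
        for s in strides:
            if s.stride_length is not None:
                assert s.stride_length == pytest.approx(2 * 0.6245, abs=0.02)
                checked += 1
        assert checked >= 8

    def test_direction_invariance_of_lengths(self, noiseless_trial):
        """Outbound and return passes yield indistinguishable stride
        lengths on symmetric gait (turn-straddling strides masked)."""
        from gaitmark import markers as mk

        left, right, grids = pl.detect_kinect(noiseless_trial.skeleton, FPS)
        strides = mk.temporal_markers(left, right,
                                      noiseless_trial.walking_intervals)
        steps, strd = kn.kinect_lengths(
            grids["t"], grids["z_left"], grids["z_right"], left, right)
        mk.attach_lengths(strides, steps, strd)
        turn = noiseless_trial.truth.turn_intervals[0][0]
        out = [s.stride_length for s in strides
               if s.stride_length is not None and s.start_time < turn]
        back = [s.stride_length for s in strides
                if s.stride_length is not None and s.start_time > turn]
        assert out and back
        assert abs(np.mean(out) - np.mean(back)) < 0.01


class TestPassSplitting:
    def test_two_passes_with_opposite_directions(self, noiseless_trial):
        track = kn.select_participant(noiseless_trial.skeleton)
        _, zp = kn.resample_joint(track, "pelvis", 2)
        passes = kn.split_passes(zp, FPS)
        assert len(passes) == 2
        assert passes[0][2] == 1 and passes[1][2] == -1
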