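"""Task segmentation from the TTL trigger channel.

The trigger sits at 5 V while the devices idle and drops to 0 V during
an active task, so each maximal low-level run is one task window.  The
first three runs are the practice, single-task and dual-task trials;
any further runs are kept with ``extra_k`` labels.  Windows are
half-open ``[start, end)`` and edge times are the time of the first
sample at the new level (sample resolution is the best the data
supports).
"""

from __future__ import annotations

import numpy as np

from .types import ImuRecording, SkeletonFrame, SkeletonRecording, SyncSignal, TaskWindow

_POSITIONAL_LABELS = ("practice", "single_task", "dual_task")

#: low runs shorter than this are treated as glitches and discarded
MIN_TASK_DURATION = 2.0


def detect_task_windows(
    sync: SyncSignal, min_duration: float = MIN_TASK_DURATION
) -> list[TaskWindow]:
    """One window per maximal low-level run, in temporal order."""
    low = sync.level == 0.0
    if not low.any():
        return []
    edges = np.diff(low.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if low[0]:
        starts.insert(0, 0)
    if low[-1]:
        ends.append(len(low))
    windows: list[TaskWindow] = []
    k = 0
    for s, e in zip(starts, ends):
        t0, t1 = s / sync.fs, e / sync.fs
        if t1 - t0 < min_duration:
            continue  # glitch
        label = _POSITIONAL_LABELS[k] if k < len(_POSITIONAL_LABELS) else f"extra_{k - 2}"
        windows.append(TaskWindow(label=label, start=t0, end=t1))
        k += 1
    return windows


def slice_recording(
    recording: ImuRecording | SkeletonRecording, window: TaskWindow
) -> ImuRecording | SkeletonRecording:
    """Samples/frames with ``window.start <= t < window.end``.

    Raises ``ValueError`` on an empty slice (window/recording mismatch).
    """
    if isinstance(recording, ImuRecording):
        sel = (recording.t >= window.start) & (recording.t < window.end)
        if not sel.any():
            raise ValueError("window does not overlap the recording")
        out = ImuRecording(
            fs=recording.fs,
            t=recording.t[sel],
            gyro_xyz=recording.gyro_xyz[sel],
            accel_xyz=recording.accel_xyz[sel],
            placement=recording.placement,
            axis_convention=recording.axis_convention,
        )
        return out
    frames = [
        fr for fr in recording.frames if window.start <= fr.time < window.end
    ]
    if not frames:
        raise ValueError("window does not overlap the recording")
    return SkeletonRecording(frames)
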