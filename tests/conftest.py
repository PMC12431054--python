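import numpy as np
import pytest

from gaitmark import synthdata as sd
from gaitmark.types import GaitProfile, SensorNoise


ZERO_VARIANCE = dict(
    stride_time_mean=1.08,
    stride_time_sd=0.0,
    stance_fraction=0.657,
    double_support_fraction=0.314,
    step_length_mean=0.6245,
    step_length_sd=0.0,
)


@pytest.fixture(scope="session")
def zero_variance_profile() -> GaitProfile:
    return GaitProfile(**ZERO_VARIANCE)


@pytest.fixture(scope="session")
def noiseless_trial(zero_variance_profile):
    """One deterministic, noise-free trial with all three streams."""
    return sd.simulate_trial(
        zero_variance_profile, seed=7, noise=SensorNoise(), clutter=2,
        pendulum_length=1.0,
    )


def event_recovery(true_times: np.ndarray, detected: np.ndarray, tol: float):
    """(sensitivity, precision, matched |errors|) at tolerance ``tol``."""
    true_times = np.asarray(true_times, dtype=float)
    detected = np.asarray(detected, dtype=float)
    if true_times.size == 0:
        return 1.0, 1.0, np.array([])
    if detected.size == 0:
        return 0.0, 1.0, np.array([])
    errs = np.array([np.min(np.abs(detected - t)) for t in true_times])
    sens = float(np.mean(errs <= tol))
    d_errs = np.array([np.min(np.abs(true_times - d)) for d in detected])
    prec = float(np.mean(d_errs <= tol))
    return sens, prec, errs[errs <= tol]


def in_intervals(t: float, intervals) -> bool:
    return any(a - 1e-9 <= t <= b + 1e-9 for a, b in intervals)
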