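"""Gait events and per-step vertical displacement from a lumbar IMU.

The anterior-posterior trunk acceleration is detrended, low-passed at
10 Hz (2nd-order Butterworth, zero-phase), integrated (cumulative
trapezoid) and then differentiated with a continuous wavelet transform
using a first-derivative-of-Gaussian ('gaus1') wavelet.  Because the
integral and the derivative wavelet cancel, the chain acts as zero-lag
Gaussian smoothing of the acceleration (smoothing std = scale/sqrt(2)
samples): heel strikes appear as minima and toe-offs as maxima of the
output.  pywt's 'gaus1' convolution returns the *negative* of the
smoothed signal, so a sign factor (default -1) fixes the convention;
flip it for sensors with the opposite axis polarity.

A single lumbar sensor cannot observe laterality, so detected events are
assigned to alternating feet starting from a configurable first side.

Step length uses the inverted-pendulum relation: the vertical channel is
doubly integrated over each step (with a linear drift reset after each
integration stage) to obtain the COM excursion h, and
``SL = 2*sqrt(2*l*h - h^2)``.
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy import signal as sps
from scipy.integrate import cumulative_trapezoid

from .foot_imu import repair_alternation
from .types import CwtConfig, EventSeries, Foot, PeakParams

LOWPASS_ORDER = 2
LOWPASS_CUTOFF = 10.0  # Hz
STEP_FREQ_BAND = (1.4, 2.6)  # Hz, physiological step-frequency search band


def preprocess_lumbar(ap_signal: np.ndarray, fs: float) -> np.ndarray:
    """Linear detrend + zero-phase 2nd-order Butterworth low-pass (10 Hz)."""
    x = np.asarray(ap_signal, dtype=float)
    if x.size < 2 * fs:
        raise ValueError("need at least 2 s of signal")
    y = sps.detrend(x, type="linear")
    sos = sps.butter(LOWPASS_ORDER, LOWPASS_CUTOFF, btype="lowpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, y)


def estimate_step_frequency(x: np.ndarray, fs: float) -> float:
    """Dominant spectral peak inside the physiological step band."""
    x = np.asarray(x, dtype=float) - np.mean(x)
    f, p = sps.periodogram(x, fs=fs)
    band = (f >= STEP_FREQ_BAND[0]) & (f <= STEP_FREQ_BAND[1])
    if not band.any() or not np.any(p[band] > 0):
        return 1.85  # fall back to a typical adult step rate
    return float(f[band][np.argmax(p[band])])


def scale_for(cfg: CwtConfig, signal: np.ndarray, fs: float) -> float:
    """Resolve the wavelet scale.

    ``from_step_frequency`` centers the wavelet's passband on the step
    frequency: scale = fc * fs / f_step with fc the wavelet center
    frequency (0.2 for 'gaus1'), ~14 samples at 128 Hz for a 1.85 Hz
    step rate — which matches the fixed default.
    """
    if cfg.scale_rule == "fixed":
        return cfg.scale
    fc = pywt.central_frequency(cfg.wavelet)
    return fc * fs / estimate_step_frequency(signal, fs)


def integrate_then_cwt_differentiate(
    x: np.ndarray, fs: float, cfg: CwtConfig | None = None
) -> np.ndarray:
    """Cumulative-trapezoid integral followed by CWT differentiation.

    Acts as a smoothed identity of the input (length preserved).
    Raises when the scale is >= length/4 (kernel would not fit).
    """
    if cfg is None:
        cfg = CwtConfig()
    x = np.asarray(x, dtype=float)
    scale = scale_for(cfg, x, fs)
    if scale >= x.size / 4:
        raise ValueError("wavelet scale too large for the signal length")
    integ = cumulative_trapezoid(x, dx=1.0 / fs, initial=0.0)
    coef, _ = pywt.cwt(integ, [scale], cfg.wavelet)
    return cfg.sign * coef[0]


def default_peak_params(diff_signal: np.ndarray, fs: float) -> PeakParams:
    mad = np.median(np.abs(diff_signal - np.median(diff_signal)))
    f_step = estimate_step_frequency(diff_signal, fs)
    return PeakParams(
        min_height=0.0,
        min_prominence=0.5 * 1.4826 * mad,
        min_distance=0.5 / f_step,
    )


def detect_lumbar_events(
    diff_signal: np.ndarray,
    fs: float,
    params: PeakParams | None = None,
    first_side: Foot = "right",
    t0: float = 0.0,
) -> tuple[EventSeries, EventSeries]:
    """Minima -> HS, maxima -> TO; sides assigned alternately.

    Successive heel strikes alternate feet starting with ``first_side``;
    each toe-off is attributed to the foot opposite the most recent heel
    strike (in steady gait the contralateral foot lifts just after a
    heel strike).  Returns ``(left_series, right_series)``.
    """
    x = np.asarray(diff_signal, dtype=float)
    if params is None:
        params = default_peak_params(x, fs)
    kwargs: dict = {}
    if params.min_prominence > 0:
        kwargs["prominence"] = params.min_prominence
    if params.min_distance > 0:
        kwargs["distance"] = max(1, int(round(params.min_distance * fs)))
    hs_idx, _ = sps.find_peaks(-x, **kwargs)
    to_idx, _ = sps.find_peaks(x, **kwargs)

    def value(i: int, kind: str) -> float:
        return -x[i] if kind == "HS" else x[i]

    # enforce global HS/TO alternation before side assignment
    hs_idx, to_idx = repair_alternation(hs_idx, to_idx, value)
    merged = sorted([(int(i), "HS") for i in hs_idx] + [(int(i), "TO") for i in to_idx])

    times: dict[tuple[Foot, str], list[float]] = {
        ("left", "HS"): [], ("left", "TO"): [],
        ("right", "HS"): [], ("right", "TO"): [],
    }
    hs_side: Foot = first_side
    last_hs_side: Foot | None = None
    for idx, kind in merged:
        t = t0 + idx / fs
        if kind == "HS":
            times[(hs_side, "HS")].append(t)
            last_hs_side = hs_side
            hs_side = "left" if hs_side == "right" else "right"
        else:
            if last_hs_side is None:
                continue  # leading TO before any HS: side unknowable
            side: Foot = "left" if last_hs_side == "right" else "right"
            times[(side, "TO")].append(t)

    def series(foot: Foot) -> EventSeries:
        hs = np.array(times[(foot, "HS")])
        to = np.array(times[(foot, "TO")])
        return EventSeries(foot=foot, hs_times=hs, to_times=to,
                           modality="lumbar_imu",
                           empty_warning=(hs.size + to.size == 0))

    return series("left"), series("right")


def step_vertical_displacement(
    vert_signal: np.ndarray, fs: float, step_bounds: tuple[float, float],
    t0: float = 0.0,
) -> float:
    """COM vertical excursion over one step.

    Double cumulative-trapezoid integration of the vertical acceleration
    over ``[t_start, t_end)``, removing the linear trend after each
    integration stage (drift reset); returns max - min of the position
    trace (>= 0).
    """
    a, b = step_bounds
    if not a < b:
        raise ValueError("step bounds must satisfy t0 < t1")
    i0 = int(round((a - t0) * fs))
    i1 = int(round((b - t0) * fs))
    x = np.asarray(vert_signal, dtype=float)
    if i0 < 0 or i1 > x.size:
        raise ValueError("step bounds outside the signal span")
    seg = x[i0:i1]
    if seg.size < 3:
        raise ValueError("step shorter than 3 samples")
    v = sps.detrend(cumulative_trapezoid(seg, dx=1.0 / fs, initial=0.0), type="linear")
    p = sps.detrend(cumulative_trapezoid(v, dx=1.0 / fs, initial=0.0), type="linear")
    return float(p.max() - p.min())
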