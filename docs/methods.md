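# Methods

This note documents the models and numerical choices behind `gaitmark`:
what the synthetic-data generator emulates, how each detection pipeline
works, how the eleven gait markers are defined, and where design
decisions were genuinely open.

## 1. Gait event geometry

A walking trial is modeled as strides of duration `T` drawn from
Normal(μ_T, σ_T) truncated at ±3 SD. Within a stride beginning at a
left heel strike (HS_L), the event order is

```
HS_L    at 0
TO_R    at (ds/2)·T                    initial double support
HS_R    at (1 + ds/2 − stance)·T
TO_L    at stance·T
HS_L'   at T
```

with `stance` the stance fraction and `ds` the total double-support
fraction. Requiring both feet to have stance time `stance·T` fixes the
contralateral heel strike at `(1 + ds/2 − stance)·T`; as a consequence
`ds = 2·stance − 1` must hold for symmetric step times of `T/2`, and
the defaults are chosen on that manifold (`stance = 0.657`,
`ds = 0.314`), which reproduces typical older-adult values (stride
≈ 1.08 s single-task / 1.16 s dual-task, stance ≈ 0.71 s, swing and
single support ≈ 0.37 s, double support ≈ 0.34 s).

Each ~7 m pass begins with a gait-initiation toe-off (the leading foot
swings onto the start position) and ends with a half-cycle "tail"
stepping into an event-free 2 s turn; this keeps the per-foot HS/TO
alternation chained across passes and creates turn-straddling strides
that downstream masking must exclude — the analogue of off-mat steps on
a pressure walkway. Step lengths are truncated-normal draws whose
per-pass cumulative sum never exceeds the path length; an asymmetry
ratio can skew left/right step lengths.

## 2. What the generator emulates (and what it does not)

Per trial the generator emits, on one clock:

* two foot IMU streams (128 Hz): the medial–lateral gyro carries a
  negative Gaussian lobe (width 120 ms) at each of that foot's heel
  strikes and a positive lobe at each toe-off; the accelerometer's z
  channel carries gravity plus a per-swing oscillation whose range is
  `(step_length / K₀)⁴` with `K₀ = 0.45`, so the quarter-power length
  estimator is exact at the baseline constant;
* a lumbar IMU stream (128 Hz): AP channel = ±Gaussian lobes (σ 25 ms)
  at every HS (−) and TO (+); vertical channel = gravity plus a
  single-cycle cosine per step whose doubly-integrated excursion equals
  the pendulum inversion `h = l − √(l² − SL²/4)` of the true step
  length (the waveform is pre-scaled by the measured gain of the
  drift-reset double-integration chain, which is < 1 because one cosine
  cycle is not orthogonal to a linear trend);
* a skeleton stream (≤30 fps): ankle depth holds during stance and
  advances by a smoothed ramp during swing — a velocity plateau bounded
  by Gaussian edges (σ 14 ms) whose acceleration lobes *lead* the
  contact events by 14 ms (ankle pre-swing roll before toe-off;
  deceleration completing just before contact, so the foot lands almost
  stationary). A uniform lead cancels out of every between-event marker.
  `clutter` bystanders appear/disappear with fresh body ids ≥ 0.8 m
  off the walkway;
* a TTL trigger (120 Hz): 5 V idle, 0 V during each task window,
  sample-exact edges.

Two lumbar fidelity parameters emulate trunk transmission: Gaussian
timing jitter of the AP event lobes (cohort default σ = 30 ms) and
attenuation of the embedded vertical excursion (default 0.8, i.e.
≈ 11% step-length underestimation, within the range reported for
uncorrected pendulum estimates). They default to ideal values at the
operation level so the noiseless recovery contracts hold, and to the
realistic values in the cohort configuration — this is what makes the
lumbar modality the least accurate in cohort runs, as trunk-mounted
sensing is in practice.

Not emulated: RGB/depth imagery (joints are generated directly), full
body kinematics beyond the joints the pipelines read, walkway timing
noise (reference events are exact ground truth), inter-device clock
drift (the trigger hardware makes streams synchronous by construction),
and any pathology-specific gait signature. Consequently, passing tests
demonstrate that the *pipelines* are correct and well-conditioned under
realistic noise, turn clutter and multi-person scenes — not that the
detectors would meet the same tolerances on arbitrary clinical data.

## 3. Detection pipelines

**Foot gyro.** 12th-order high-pass Butterworth in second-order
sections (cutoff 0.5 Hz — removes drift, preserves the ~1 Hz stride
fundamental) then a 216-tap Hamming FIR low-pass (10 Hz — gait gyro
energy lies below ~10 Hz), both applied forward–backward because event
*times* are the product and phase lag would bias every marker; then
mean-centering. HS/TO = signed peaks with scale-free default gates:
prominence = 0.5 × robust SD (1.4826·MAD), height = 0.25 × the 99th
percentile of |signal| (rejects inter-stride filter ringing), distance
= half the stride time estimated from the autocorrelation peak.
Alternation repair keeps the more extreme of two same-kind events.

**Lumbar.** Linear detrend, 2nd-order Butterworth low-pass at 10 Hz
(zero-phase), cumulative-trapezoid integration, CWT differentiation
with 'gaus1'. Because ∫ then d/dt cancel, the chain is zero-lag
Gaussian smoothing with std = scale/√2 samples; pywt's 'gaus1'
convolution returns the negative of the smoothed signal, so a sign
factor (default −1) fixes the convention that HS are minima (flip it
for the opposite axis polarity). The scale rule matches the wavelet's
center frequency (0.2 for 'gaus1') to the dominant step frequency in
1.4–2.6 Hz: `scale = 0.2·fs/f_step` ≈ 14 at 128 Hz — chosen so the
smoothing σ (~76 ms) stays below the smallest inter-event gap (~170 ms
between an HS and the following TO); a wider rule proportional to
`fs/(2·f_step)` smooths with σ ≈ 190 ms and merges adjacent lobes.
A single lumbar sensor cannot observe laterality; sides alternate from
the side of the first reference event when available, else right.
Per-step vertical excursion: double cumulative-trapezoid integration
with a linear detrend after each stage (unbounded drift otherwise
dominates h; per-step resets are standard for pendulum models).

**Depth camera.** Participant = the body maximizing coverage ×
fraction-of-frames inside the walkway's lateral gate, ties broken by
depth range traveled (the participant walks the path; bystanders do
not); invariant to clutter id permutation. Joints are linearly
resampled to a uniform 30 Hz grid (frame timing jitters), low-passed
with a 6th-order Butterworth at 3 Hz (zero-phase), and twice
differentiated with the compact central second difference (the wider
double-gradient stencil attenuates ~6% at 2 Hz; the compact one stays
within 5% of the analytic second derivative). Passes are split on the
sign of the 0.4 Hz-smoothed pelvis depth velocity (the step-phasic
velocity dips to zero each double support, so the raw sign fragments).
`direction_sign` is +1 walking toward the camera (depth decreasing):
multiplying the depth acceleration by it makes heel strikes maxima and
toe-offs minima on every pass, because terminal-swing deceleration
makes raw z̈ positive at contact on a toward-camera pass. Event
detection on the depth (progression) signal is the default; the
vertical channel can be selected in code where a deployment's extremum
convention differs. Lengths are ankle-depth differences at heel
strikes, read one frame *after* the event from the raw resampled depth:
at the nearest frame the ankle can still carry most of its swing
momentum, so nearest-frame reads can catch the foot mid-landing
(remaining travel up to swing-speed × half a frame ≈ 5 cm), whereas one
frame later it sits on the stance plateau for the rest of stance.

## 4. Markers

Temporal markers are computed per foot and per stride from the
interleaved event pattern `HS_F, TO_C, HS_C, TO_F, HS_F'`, with step
time taken against the preceding contralateral heel strike. These
definitions satisfy `stance = single_support + double_support` and
`stride = stance + swing` identically. A stride is retained only if
*every* event it uses (including that preceding contralateral HS) lies
inside one walking interval, and the preceding HS must be less than one
stride back (otherwise an event was missed and the step time would be
spurious). Walking intervals run from the first to the last
leading-foot heel strike of each pass, so turn-straddling strides drop
out.

Spatial markers per modality: quarter-power range of the
pitch-projected, gravity-subtracted foot acceleration
(`aZ = aₓ sinθ + a_z cosθ − g`, θ from integrating the medial–lateral
gyro with a per-segment linear drift reset); K is calibrated per
subject on the practice walk so the summed estimated lengths equal the
reference walked distance (zero mean bias on the calibration pass), and
step and stride constants are calibrated separately. Lumbar step length
is the pendulum chord `2√(2lh − h²)` with `l` defaulting to 0.94 m (a
typical adult leg length; the pendulum radius is the COM-to-ground
lever, and a foot-length-scale value would make typical step lengths
geometrically infeasible in the inversion); lumbar stride length is the
sum of the two step lengths inside the stride. Camera lengths come
directly from ankle depths. Cadence uses 2 strides = 2 steps per stride
time (`2n/Σ stride_times × 60`), and average velocity is length-sum
over time-sum — the walkway-style definition on retained footfalls,
which excludes turn intervals by construction.

## 5. Agreement analysis

Pairing is at the subject-trial level: each subject contributes one
mean per marker per trial, the granularity at which such comparisons
are conventionally published; per-stride values remain available in the
stride tables. Statistics: MAE mean ± SD (ddof = 1), MAEP (undefined
and omitted when a reference value is zero), Pearson r with the
two-sided t-transform p (undefined and flagged under zero variance),
and Bland–Altman bias ± 1.96 SD (the 1.96 multiplier is fixed, not
t-based). p-values are uncorrected. Reports include per-task summary
and correlation tables, Bland–Altman plots per marker × modality, and
an r-vs-MAEP scatter with r = 0.6 and MAEP = 10% guide lines.

## 6. Numerical choices and degenerate inputs

* Zero-phase filtering throughout (`sosfiltfilt`/`filtfilt`); FIR
  padlen capped at signal length − 1.
* Peak gates are scale-free (MAD, percentile, autocorrelation) so the
  same defaults serve noiseless and noisy data; all are overridable.
* Ties/duplicates when merging per-pass camera detections: events of
  the same kind within 0.1 s are deduplicated keep-first; alternation
  repair is deterministic.
* Degenerate inputs raise `ValueError` (too-short signals, overlapping
  trigger windows, empty slices, h ≥ 2l, zero-variance correlations)
  or return flagged empty series (no peaks found). Flat Weinberg
  segments yield length 0 rather than an error.
* All randomness flows from integer seeds through
  `numpy.random.default_rng`; a fixed seed reproduces every stream
  bit-identically, including written CSV bytes.

## 7. Validation scale

The standard validation suites (`gaitmark.benchmarks`, driven by the
acceptance tests and `scripts/acceptance.py`) use 20 seeds × 18-subject
cohorts with two passes per task — the cohort size and walkway geometry
of the protocol the simulator emulates. Event recovery is scored inside
walking intervals at ±15 ms (foot), ±30 ms (lumbar) and ±1.5 frames
(camera); marker identities are cross-checked against an independent
pattern-matching interval calculator on 1000 random event trains; the
modality ordering (foot ≤ camera ≤ lumbar in mean temporal MAEP) is
evaluated per cohort at the default noise. The full suite completes in
a few minutes on one CPU.

## 8. Known limitations

* The generator's event lobes are stylized (Gaussian); real IMU
  waveforms have asymmetric multi-lobed shapes, so real-data peak
  parameters will need tuning even though the defaults are scale-free.
* Left/right assignment from the lumbar sensor assumes strict
  alternation; a missed event flips all subsequent labels until the
  next pass.
* The camera pipeline assumes the walkway is roughly aligned with the
  camera axis; oblique setups would need a rotation into path
  coordinates before the depth-based formulas apply.
* Reference events are treated as exact; any timing noise of a real
  reference system adds directly to the reported MAEs.
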