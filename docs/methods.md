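# Methods

This note records the modelling choices behind `ticguard`: what each
stage assumes, which parameters matter, what the synthetic-data generator
does and does not emulate, and the numerical conventions.

## Movement channel

**Features.** Each 1 s window (1 s hop) of accelerometer + gyroscope data
yields six non-negative magnitude features: mean and peak gravity-removed
acceleration magnitude (m/s²), a speed proxy (m/s), mean and peak angular
speed (rad/s), and mean absolute angular acceleration (rad/s²). Windows
are half-open `[start, start+1 s)` so no sample is double-counted at a
boundary.

*Gravity removal* subtracts the per-window **mean** acceleration vector.
Over one second the mean is dominated by the quasi-static gravity
component, and unlike a fixed (0, 0, 9.81) reference it adapts to how the
band sits on the wrist. The mean is exactly rotation-equivariant, so all
magnitude features are invariant under a rigid re-orientation of the
device (verified to 1e-9 in the tests); a component-wise median — the
other natural robust choice — is not, which is why the mean was chosen.

*Speed proxy.* True linear velocity is unobservable from one wrist IMU
(open-loop integration drifts), so "speed" is realised as the trapezoidal
integral of the gravity-removed acceleration magnitude over the window,
reset each window. It is zero for a stationary wrist and grows with
sustained vigorous movement, which is all the outlier model needs.

*Angular acceleration* is the mean absolute first-order finite difference
of the angular-speed magnitude; no estimator smoother than that is
warranted at 50 Hz over 1 s windows.

**LOF model.** Canonical density-ratio LOF (k-distance with tie-inclusive
neighbourhoods, reachability distance, local reachability density) over
feature vectors standardized by the calibration mean and standard
deviation. Only the calibration data — nominally two attack-agnostic days
— define the neighbourhood; later data are scored, never absorbed, so the
model cannot drift toward the anomalies it must flag. Occasional attacks
*inside* the calibration simply score as outliers and inflate the
threshold slightly; fitting tolerates them.

Degenerate geometry is defined, not avoided: coincident duplicate points
give infinite local reachability density, with the conventions
`inf/inf = 1` and `finite/inf = 0` in the score ratio, so a cloud of
duplicates scores exactly 1. Each calibration point is scored leaving
itself out of its own neighbourhood.

Defaults: `k = 20` (clipped to n−1 for small calibrations);
`θ = max(1.5, P99 of calibration scores)`. The percentile adapts the cut
to each wearer's score spread; the 1.5 floor stops a very tight, clean
calibration from producing a hair-trigger cut just above 1. `P_Movement`
is the flagged fraction of a 10-window rolling buffer (~10 s), zero-filled
at start so the probability is defined and low from the first window.

## Vital-sign channel

Each vital is z-scored against its per-user calibration mean and standard
deviation, so one slope threshold — **4/3 z-units per minute**, inclusive
on both signs — applies uniformly to heart rate (bpm), temperature (°C)
and humidity (%RH, the sweat surrogate).

The slope is an OLS fit over the trailing **5-minute trend window** of a
retained 60-minute buffer, refit on every sample. The trend window, not
the full hour, is what approximates the *current* rate of change: a
regression spanning a mostly-flat hour dilutes a several-minute ramp to
well under 0.1 z/min, which would make any fixed threshold inert. Five
minutes is long enough that ordinary fluctuation fits slopes an order of
magnitude below the threshold, and short enough that a physiological ramp
(a few z-units per minute sustained for minutes) dominates the fit.

Flagging additionally requires ≥ 10 points spanning ≥ 3 minutes. The
point floor alone cannot guard fast channels — ten 1 Hz heart-rate samples
span ten seconds, over which per-minute slopes of ordinary noise are
enormous — hence the time-span floor.

A fired flag **latches** `P_Vital = 1`: new samples are buffered but not
analysed until a reset. Resets come from the wearer confirming the attack
is over, or from the controller's quiet-hour timeout; either clears the
latch and refits once over the retained buffer, so a still-rising vital
re-latches immediately.

## Fusion and alerting

`P_Total = 0.7·P_Movement + 0.1·P_HeartRate + 0.1·P_Temperature +
0.1·P_Humidity`. Weights are configurable but validated to be convex.
An alert requires `P_Total` **strictly over** 0.80; the slope threshold is
inclusive ("≥ 4/3"), the alert threshold exclusive ("over 80 %") — both
comparisons are boundary-tested. Note the arithmetic consequence: with
default weights, movement alone yields at most 0.70 and movement plus one
vital exactly 0.80, so an automatic fused alert requires the movement
buffer saturated *and at least two vital channels latched*. Thresholds at
or below 0.70 draw a validation warning because they would let movement
alone alert.

The controller is two-state (`no_issues`/`possible_attack`). Within one
step the order is: quiet-hour timeout, wearer confirmation, alert
decision — so an alert can fire in the same step that cleared the status,
but never while the status still is `possible_attack`. Every alert is
paired with exactly one buzzer event. The one-hour resume clause is read
as: no instant with `P_Total` above threshold within the trailing 60
minutes; the timeout resets only still-latched vitals, a confirmation
resets all latched vitals.

The audio channel bypasses fusion (it alerts on its own evidence) but
shares the suppression state, so one episode produces one notification
regardless of which channel saw it first. Manual button alerts fire at
the hold-completion instant — 5 s into the press, so releasing early
aborts — and the triple-press cancel (first-to-last press within 1 s)
cancels the most recent uncancelled alert of any source.

## Audio channel

Speech-to-text is a pluggable interface and deliberately **not**
implemented; the package consumes time-stamped token streams. "More
repetition than is normal for this user" is operationalised as: the max
single-token count in a 10 s sliding window (1 s hop) exceeds the
calibration mean + 3 sd of that statistic, with a hard floor of two
occurrences (one utterance is never a repetition). The count, rather than
the elapsed time of repeating, was chosen as the statistic; both readings
are defensible and the window already bounds the time scale. Cue-phrase
matching is case-insensitive, in-order, with ≤ 2 s between consecutive
matched tokens; overlapping candidates collapse to the earliest
completion. The high-pass stage is a zero-phase (forward–backward)
4th-order Butterworth, default cutoff 100 Hz.

## Synthetic-data generator

The simulator produces exactly the statistical structure the detectors
assume, with all randomness flowing from one root seed through named
per-channel child seeds (adding a channel never perturbs another; fixed
configs are bit-reproducible).

- **Baseline movement**: per-axis AR(1) noise (coefficient 0.8,
  stationary sd 0.3 m/s² accel / 0.15 rad/s gyro) plus constant gravity —
  low-level everyday wrist motion.
- **Tic bursts**: sinusoids at 3–6 Hz (default 5 Hz) with random-walk
  phase jitter on every axis, amplitude expressed as a multiple of the
  baseline sd (default 8×) — repetitive, high-energy, spectrally distinct.
- **Exercise confounder**: the same construction at 1.5 Hz, available so
  the known failure mode (exercise resembling an attack) can be generated
  and measured rather than hidden.
- **Vitals**: baseline mean ± AR(1) noise (75 ± 3 bpm, 36.6 ± 0.1 °C,
  40 ± 2 %RH) with linear ramps during attacks (defaults 6 bpm/min,
  0.2 °C/min, 5 %RH/min — i.e. z-slopes of roughly 2–2.5 per minute,
  comfortably past the 4/3 threshold, matching the stress response of an
  attack) and exponential relaxation (τ = 120 s) afterwards.
- **Speech**: Poisson background chatter from a small vocabulary with a
  hard cap of 3 occurrences of the same token per 10 s window —
  unconstrained i.i.d. sampling grossly overstates short-range word
  repetition relative to conversation, where repeating one word many
  times in ten seconds is precisely the vocal-tic signature. The tic
  token ignores the cap and repeats at ~1 Hz during attacks.

Ground-truth intervals mirror the configured episodes exactly.

**What the simulator does not emulate:** biomechanically realistic
movement (postures, gestures, transport), heart-rate variability
structure, diurnal vital rhythms, transcription errors, speaker
separation, or sensor artifacts (clipping, dropout, drift). Passing
tests therefore demonstrate that the pipeline implements its stated
contracts and detects the signal structure it was designed for — not
clinical performance on real patients.

**Problem sizes.** The calibration used in tests and in the acceptance
script is the two-day-equivalent recording time-compressed by 288× to
600 s (~600 feature windows); the generator is stationary, so per-window
feature statistics are unchanged by compression (checked against a 4-hour
run at 3-standard-error tolerance). The study scenario is a 15-minute
recording with one 5-minute attack starting at t = 420 s.

## Numerical conventions

- OLS via centred normal equations; degenerate fits (all timestamps
  equal, < 2 points) raise rather than return NaN.
- Zero-variance features/vitals get scale 1 with a warning instead of a
  division by zero.
- Windowing is half-open everywhere (sensor windows, token windows); a
  sample at a window's end time belongs to the next window.
- Event logs are canonical NDJSON; sensor NDJSON written by the package
  round-trips byte-identically.
- Bisection-style threshold recovery in the tests uses 60 halvings
  (≪ 1e-6 resolution).

## Known limitations

- The LOF scorer is exact (O(n·m) distance evaluations); for calibration
  sets far beyond ~10⁵ windows an approximate index would be needed.
- `P_Vital` is binary by design; a graded variant would let fusion
  express partial vital evidence but is deliberately not provided.
- The exercise confounder is generated but not specially handled: a
  wearer exercising hard saturates `P_Movement` at 0.7 and any two
  coincident vital trends would alert. This mirrors the system's known
  weakness rather than hiding it.
- Tic-attack *prediction* (alerting before onset) is out of scope.
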