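# Methods

This note documents the models, algorithms, parameter choices and known
limitations of the toolkit, stage by stage.

## Signals and conventions

All channels in a session share one time base at a default 1000 Hz
(sample *i* at *t = i/fs*, 0-based; all event timestamps in seconds).
sEMG and ECG are in mV; FSR (foot-switch) traces are nominally 0–1.
Trial windows (the ten one-minute treadmill task trials of a session) are
stored in session metadata rather than inferred from the signals. CSV is the
interchange format (one file per session, header row of channel labels), with
a YAML sidecar for the sampling rate, column mapping, trial windows and
participant metadata; values round-trip to better than 1e-9 relative.

## Gait event detection

Heel-strike is the upward crossing of the heel switch through
`rel_threshold` (default 0.5) of the channel's dynamic range; toe-off is the
downward crossing of the toe switch through the same relative level. Because
the threshold is relative, detection is invariant to affine rescaling of the
FSR signal (gain and offset of the sensor chain drop out). Two guards handle
chatter at realistic cadences: a hysteresis band (±0.1 of range) that
requires the signal to retreat beyond the far side of the band before the
detector re-arms, and a refractory `min_gap` (default 0.2 s) between
accepted events of one kind. Crossing times are linearly interpolated
between samples so downstream phase segmentation is sub-sample consistent.

Stance is bound heel-strike → ipsilateral toe-off and swing toe-off → next
ipsilateral heel-strike (the standard gait convention); one complete cycle
requires the full (heel-strike, toe-off, heel-strike) triple, and leading or
trailing fragments are dropped. Flat channels yield an empty event list with
a logged warning rather than an error.

## sEMG preprocessing

The chain is: 2–200 Hz 5th-order Butterworth band-pass (motion artifact and
high-frequency noise), then a 50 Hz 2nd-order IIR notch (mains hum), both
applied forward-backward (`filtfilt`). Zero-phase application keeps burst
timing aligned with the foot-switch events — the delay compensation of the
classic smoothing stage extended to the whole chain — at the cost of
doubling the effective order (the realized magnitude response is the square
of the designed one; the 100 Hz mid-band gain is still 0.9998). The notch
uses Q = 10 (5 Hz −3 dB bandwidth), conventional for mains removal; the
biquad has an exact zero at 50 Hz, and neighbours at 30/80 Hz lose < 0.1 dB.

The linear envelope (full-wave rectification followed by a centered 50 ms
moving average, edge bins normalized by actual window overlap) is provided
for burst-morphology display only. MAV and RMS are computed on the filtered
samples, not the envelope, per their definitions.

## Indices

Per gait phase and cycle: MAV (mean absolute value), RMS, and from a
power spectral density estimate the mean frequency (power-weighted mean,
trapezoidal integration) and median frequency (smallest *f* where the
cumulative power reaches half the total, linearly interpolated on the
cumulative curve — so an exact two-mass tie resolves to the midpoint).

The PSD is a single-taper periodogram with a **symmetric** Kaiser window,
β = 8.6 (Blackman-like sidelobe suppression; the symmetric form keeps MF/MDF
exactly invariant under time reversal). It is normalized as a density: the
integrated PSD matches the mean square of the windowed signal, so for
zero-mean noise it estimates the variance (verified to ~1% in tests).

Indices are computed per cycle-phase segment and averaged across cycles
(`aggregate="per_cycle"`), which tracks cycle-to-cycle physiology; pooling
all samples of a phase first is available via `aggregate="pooled"`. Segments
shorter than 8 samples are skipped for the spectral indices and counted in
the log.

## Cardio

R-peak detection follows the classic QRS energy chain: 5–15 Hz band-pass,
differentiation, squaring, 150 ms moving-window integration, an adaptive
signal/noise threshold (running signal- and noise-level estimators with a
0.25 s refractory period), and refinement of each detection to the local
extremum of the band-passed ECG. R-R intervals outside 0.25–3 s
(240–20 bpm) are treated as detector glitches and dropped — conventional
artifact bounds. Windowed mean HR is `60·(beats − 1)/elapsed` over the beats
inside the window (each trial's HR summary is this windowed mean; an
endpoint-value alternative would be a one-line change but is not exposed).

PCI = (HR_walk − HR_rest)/speed with speed in m/min, so PCI carries its
conventional beats-per-metre unit (a converter from m/s is provided).
HR_rest is the mean HR over the session's resting baseline window. The
exercise zone is [0.5·H, 0.8·H) — lower bound inclusive, upper exclusive,
mirroring the ≥ / > structure of its definition — with H = 220 − age, scaled
by 0.85 for patients on beta-blockers. Note the medicated zone is the
standard zone scaled down by 0.85 (both bounds), not a sub-interval of it.

## Speed-switching controller

A pure state machine over per-trial mean HRs: terminate when a trial HR
exceeds the zone's upper bound; otherwise increase speed by one increment if
the trial HR fell below the preceding trial's (strict comparison; a
configurable deadband exists but defaults to 0), else maintain. The lower
zone bound plays no role in switching and is only logged. "Coping" with an
applied increase is operationalized as the following trial's HR staying at
or below the upper bound, which selects between the two feedback messages.
The default increment is 3 m/min (0.05 m/s) — small enough to be plausible
as a safety-conscious step, large enough to matter over ten one-minute
trials — and sessions cap at 10 trials.

## Synthetic data

The generators define the test conditions and always return their ground
truth (event schedules, R-R times, injected effects):

- **FSR**: square 0/1 traces from a nominal cadence (default 1.2 s cycle,
  60% stance — typical for slowed hemiparetic gait), optional Gaussian
  timing jitter (10 ms in cohort fixtures) and measurement noise.
- **sEMG**: gated band-limited Gaussian noise, the standard surrogate for
  the interference pattern: GL bursts in stance at 60–150 Hz, TA in swing
  (40–120 Hz) plus a short early-stance burst, raised-cosine on/off ramps
  (10% of burst length), and a broadband floor at 2% of the burst
  amplitude. Not modeled: motor-unit structure, electrode artifacts,
  crosstalk, amplitude non-stationarity within a burst.
- **ECG**: a fixed sum-of-Gaussians PQRST template (1 mV R peak) placed at
  cumulative R-R times. No morphology variability or baseline wander.
- **Virtual patient**: first-order HR dynamics toward a linear steady state
  HR_ss(v) = HR_rest + gain·v, relaxed over the 60 s trial with time
  constant τ, plus a within-session adaptation drift: the target for trial
  *t* is HR_ss − t·adaptation, floored at HR_rest. The cumulative-drift form
  is deliberate — it makes trial HR at constant load strictly decreasing
  once the initial transient has died away, which is precisely the
  physiological signature ("spare capacity emerging") the controller's
  increase rule is designed to detect; a one-shot per-trial subtraction
  would instead settle at a fixed point and never exercise that rule.
- **Cohorts**: per participant, lognormal between-subject amplitude factors
  (sd 0.15) and mild band-edge factors (sd 0.05) applied to both sessions
  (the paired structure), independent EMG noise per session, and known
  multiplicative pre→post effects injected on the "post" side. Each session
  runs through the *full* pipeline (FSR generation → event detection →
  filtering → feature extraction), so cohort-level statistics inherit every
  stage's noise.

Because the sEMG surrogate is stationary Gaussian within bursts, passing
tests demonstrate correctness of the computational chain and calibration of
the statistics under known effects — not robustness to the heterogeneity of
real post-stroke recordings (contracture, spasticity, electrode placement
variability), which no synthetic fixture of this kind can establish.

## Statistics

Wilcoxon signed-rank on paired pre/post values, two-sided throughout:
zero differences dropped (count reported), mid-ranks for tied absolute
differences, W = smaller signed-rank sum. For n ≤ 12 the p-value is exact —
the fraction of all 2ⁿ sign assignments whose smaller rank sum is ≤ the
observed W — and beyond that the normal approximation with continuity and
tie corrections. The effect size is r = |z|/√(2n) with z from the
approximation (z over the square root of the total observation count); at
n = 9 this maps two-sided p = 0.01 to r ≈ 0.61 and p = 0.02 to r ≈ 0.55.
Note r is invariant under positive affine rescaling of both arms but not
under arbitrary nonlinear monotone transforms (signed ranks order the
absolute differences).

Index values are peak-dynamic normalized before testing: within each
participant-session, each index is divided by its maximum across
muscle/side/phase entries (sub-maximal normalization, appropriate when
maximal voluntary contraction is not obtainable). A structural consequence:
the peak entry is exactly 1 in both sessions, producing one zero difference
per participant-index, which the zero-drop convention absorbs. Group change
is Δ% = 100·(post mean − pre mean)/pre mean on raw means by default
(normalized means via a switch). No multiple-testing correction by default;
Holm step-down is available. Ambulation categories follow the community
walking speed cut-offs: < 0.6 m/s most limited, < 0.8 m/s least limited,
≥ 0.8 m/s community walker (boundary inclusive).

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen to make the Monte-Carlo
checks statistically meaningful while staying cheap: 10-cycle gait fixtures
over 100 noise seeds for event recovery; 10,000 random HR sequences for
controller conformance; 50 patient parameterizations per closed-loop family;
1000 enumeration cases for the exact test; 100 replicate cohorts of n = 9
participants (10 gait cycles per session) for type-I and power. Degenerate
inputs fail loudly: flat channels and empty cycles warn and return empty
results, zero-power spectra and zero-length segments raise, terminated
controller states refuse further steps.

## Limitations

Clinical cohort outcomes (group Δ% values of clinical mobility scores and
the specific per-muscle index changes reported for real patients) depend on
the original nine participants' recordings and are not reproducible from
synthetic data; the toolkit instead verifies every computational property of
the chain those outcomes rest on. Hardware acquisition (DAQ, treadmill,
instrumented shoes), electrode placement, and administration of clinical
scales are out of scope — clinical scores enter only as numbers.
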