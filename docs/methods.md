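# Methods

## The control problem

People with upper-limb disabilities can express grasp intent with their
feet: a deliberate press of the big toe (hallux) on an instrumented shoe
insole produces a contact-force peak that is far larger than anything
gait or incidental contact generates at that sensor. `halluxgrip`
implements the full decode-and-control chain for a single-degree-of-freedom
three-finger assistive hand driven by two binary lines — (A high, B low)
opens, (A low, B high) closes, (low, low) holds; (high, high) is undefined
and never emitted. The hand has no position feedback, so posture (the
thumb–index interfinger distance, 0–100 mm) is controlled purely by how
long a line is held, via a fitted time–distance calibration.

The pipeline is:

1. **simulate** — synthetic multi-channel insole traces (hallux, little
   toe, forefoot, heel) with gait structure, scheduled presses and sensor
   noise;
2. **filters** — a causal moving average cascaded with a scalar Kalman
   filter on the hallux channel;
3. **press_detect** — per-user threshold calibration and the
   crossing-count press statistic per scan window;
4. **posture** — the polynomial time-ratio model fitted to the packaged
   calibration table, with SSE/R² order selection;
5. **controller** — the five-level press-count→distance code, line-command
   planning, a simulated plant, and the closed loop;
6. **config/cli** — YAML configuration, the `halluxgrip` command and the
   end-to-end runner.

## Signal model and simulator

Forces are dimensionless sensor counts on a nominal 0–2500 scale (the
insole hardware has no published physical calibration). Per channel the
simulated signal is

    y(t) = baseline + gait(t) + presses(t) + noise,   clipped at 0.

* **Gait**: when walking, every channel carries a half-sine stance peak
  each step cycle (default cadence 1.5 steps/s, stance fraction 0.6) —
  large on heel/forefoot (≈2000 counts), small on the toes (≈500). When
  standing, channels sit at baseline.
* **Press**: a raised-cosine bump (smooth, unimodal, default 0.3 s) of the
  channel's press amplitude — 2000 counts on the hallux, deliberately well
  above its gait peak; this amplitude separation is the premise that makes
  the hallux usable as a control site.
* **Noise**: zero-mean Gaussian, default sd 30 counts, clipped with the
  total at zero. The default sampling rate is 100 Hz.

The generator is seeded and bitwise reproducible. What it does **not**
model: biomechanical gait variability, sensor drift and hysteresis,
cross-channel mechanical coupling, or inter-subject differences. Passing
tests therefore demonstrate the decoding logic under the stated signal
structure, not performance on real insole recordings — the human-subject
recognition rates reported for the hardware system are outside what any
simulation can certify.

## Filtering

Stage one is a causal moving average over the last N samples (default
N = 50, i.e. 0.5 s at 100 Hz, the midpoint of the 40–60 range that suits
this signal class); for the first N−1 samples the available prefix is
averaged rather than padding with invented data. Stage two is a scalar
Kalman filter with random-walk state (F = 1, B = 0, H = 1), process
variance Q = 10⁻² and measurement variance R = 1, initialised at the first
averaged sample with P₀ = 1. The cascade reduces white-noise variance by
roughly 60× at these defaults, at the cost of a group delay of about
0.3–0.4 s; delay is harmless here because users pre-trigger the hand
before a grasp. The prefix warm-up produces early estimates with inflated
variance — this matters for calibration, below.

## Press decoding

The threshold t is personal: it is the maximum of the filtered signal
over a press-free segment, times a safety margin (default 1.1). This
shields gait peaks (when calibrated on walking) and weight-shift noise.
Two procedure choices matter:

* **Calibration segment = the first two scan windows (3 s) of the stream
  itself.** Calibrating on a separate recording lets the moving-average
  warm-up transient of a *new* stream cross a threshold derived without
  it; taking the segment from the head of the same stream makes the
  threshold cover the warm-up by construction. Three seconds is long
  enough to observe representative filtered-noise extremes; 1.5 s was
  measurably too short.
* **Counting**: with filtered values a₁..a_N and threshold t, the press
  count is S = ½ · #{i : (a_{i−1}−t)(a_i−t) < 0} — half the number of
  strict threshold crossings. Samples exactly on the threshold do not
  count (the indicator is zero at zero). The stream is tiled into
  consecutive scan windows of b seconds (default b = 1.5 s); a peak that
  straddles a boundary is credited to the window in which it completes,
  by carrying the unpaired crossing forward, so window totals are
  partition-invariant.

A deliberate press is resolvable when presses are ≳1 s apart at the
default filter bandwidth; simulated experiments use a 1.2 s cadence.
Multi-press codes inside a single window need a longer window (the scan
time is explicitly a sensitivity/latency trade-off, configurable); the
closed-loop tests use b = 6 s for three-press codes.

## Posture calibration

The calibration data are N = 23 pairs (lᵢ, dᵢ): interfinger distance in
mm against the time ratio dᵢ = tᵢ/t_A needed to reach it from closed,
where t_A is the full-open time (default 2.0 s — a realistic value for
this class of hand; the calibration is expressed in ratios precisely so
that t_A factors out). A degree-M polynomial d(l) is fit by least squares
on a centered-and-scaled abscissa λ = (l − mean)/sd for conditioning; the
fitted function and its SSE/R² are invariant to that affine substitution,
so the diagnostics do not depend on the scaling convention.

Order selection scans M = 1..6 and stops at the last degree before the
relative SSE improvement first drops below 20%: on the packaged table
the SSE sequence is 0.0207, 0.0041, 0.0029, 0.0018, 0.0017, 0.0017, whose
improvements (80%, 29%, 38%, 5.6%) place the elbow at M = 4.

Two numerical caveats of the quartic fit are deliberate, not bugs: the
table's top rows (100, 1) and (99.8, 0.95) are near-duplicate abscissae
0.05 apart, so the curve passes between them (d(100) ≈ 0.97), and the
flat closed-end rows make the quartic dip by ≈0.002 over l ∈ [0, 3]. The
plant inversion uses a monotone envelope of the curve, so neither affects
control.

## Controller and plant

Press counts map to five coded distances: 1 → 25 mm, 2 → 50 mm,
3 → 75 mm, ≥4 → 100 mm, and a press-free window closes an open hand
(counts above 4 saturate). Moving from distance l₀ to l₁ takes
|d(l₁) − d(l₀)| · t_A on the appropriate line, quantized to a 10 ms
command tick (the quantization contributes <1 mm of posture error at the
defaults). The simulated plant integrates openness along the inverse of
the fitted ratio curve; closing is assumed to traverse the same curve as
opening (only opening was calibrated — a symmetric-plant assumption). In
the noiseless plant the achieved level lands within 2 mm of the command;
the mean absolute error over seeded scenario batches is ≈0.3 mm, which is
a statement about this idealised plant, not about hardware backlash or
motor variability.

Windows are processed sequentially after the trace is recorded, so
"queueing during motion" reduces to ordered processing; no press is
dropped. A mid-motion press cannot preempt a command in this replay model.

## Problem sizes and tolerances

Simulated experiments use: 1000 traces for the press-recognition rate
(12 s standing traces, 0–6 presses), 500 replicates for the noisy-refit
SSE study (σ = 0.005, expected mean SSE (23−5)σ²), 200 traces for the
level-accuracy batch, 10⁴ random sequences for the crossing-statistic
oracle. All random draws derive from a single seed. The whole suite runs
in a few seconds on one CPU.

## Known limitations

* Only the hallux channel is decoded (the little toe is simulated but not
  used, mirroring its lower reliability as a control site).
* The threshold model is a scalar margin; no adaptation to drift.
* One-dimensional Kalman filtering only; no adaptive noise estimation.
* The plant is deterministic and symmetric; real hands show 2–5 mm level
  errors from mechanics that this package does not model.
* No transport layer: traces come from files or the simulator, commands
  go to a simulated plant.
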