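# Methods

## Model

The core estimator treats tremor as a noise-driven harmonic oscillator: the
underlying movement is assumed to be a pure rotating phasor at a reference
frequency `f_c`, and everything else — movement variability, sensor noise,
other oscillatory modes — is treated as observation noise. The state is the
analytic estimate `x_est = (a, b)` in g; the observation is the real part
`a`. Each step subtracts `a` from the input to form the prediction error
`e`, corrects the real part by `G·e`, reports phase and magnitude from the
corrected state, and rotates the phasor by `θ = 2π·f_c/f_s` for the next
sample.

Two choices in that loop were genuinely open and are fixed as follows:

* **Update order: correct, report, then rotate.** The algorithm's
  components (error correction, rotation, readout) do not by themselves
  fix an order. Reporting `(Φ, M)` from the corrected pre-rotation state
  makes the estimate refer to the *current* sample and makes the noiseless
  case exact: a tone at `f_c` is tracked with phase error at machine
  precision after warm-up. Reporting post-rotation instead would shift
  every estimate by one sample (`θ`, up to ~14° at 8 Hz) — within the
  system's own trigger tolerance but needlessly biased.
* **Phase convention.** `Φ = 0°` at the positive peak of the tracked
  oscillation's real component, increasing in the rotation direction,
  degrees in [0, 360). This equals the analytic-signal (Hilbert) phase of
  a cosine, so tracker and oracle use one convention and trigger targets
  are directly comparable across both.

The recursion is linear and time-invariant. Writing it as
`z[n+1] = A·z[n] + B·x[n]` with `A = R(θ)·diag(1−G, 1)` and
`B = R(θ)·(G, 0)ᵀ` gives second-order IIR transfer functions for `a` and
`b` (common denominator `z² − cosθ·(2−G)·z + (1−G)`), which
`tracker.track_batch` evaluates with `scipy.signal.lfilter`. The streaming
loop and this closed form are independent arithmetic paths that agree to
~1e-12 degrees; the pair doubles as the replication check an embedded
implementation would run against its desk-side port, and the batch path
makes long protocol simulations cheap.

With gain `G` the poles sit at radius `sqrt(1−G)`, so the tracker is an
adaptive band-pass around `f_c` whose width grows with `G`. `G = 0.25`
(the empirically chosen default) gives an effective bandwidth of several
hertz: wide enough to follow tremor through frequency drift between
selection instants, wide enough also to admit low-frequency noise — see
"the pre-filtering gap" below.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `f_s` | 208.03 | Hz | device sampling rate; all sample-index arithmetic uses it |
| `G` | 0.25 | – | correction gain; explored grid is 2⁻¹…2⁻⁸ (`gain_sweep`) |
| frequency grid | 2–8 step 1 | Hz | rest-tremor band 3–7 Hz plus 1 Hz margin each side |
| `μ` window | 10 | s | moving-average window for axis amplitude and \|e\| |
| selection interval | 20 | s | one trial period (10 s on + 10 s off) |
| error budget | `f_c/f_s·360` | deg | trigger tolerance = per-sample phase advance (3.46°–13.84° across the grid; note a printed "approximately 5" lower end corresponds to ~3.5° by the formula) |
| refractory | `0.5/f_c` | s | half a tremor period; exceeds the 8-sample burst |
| burst | 5 pulses at `f_s/2` | – | 9.614 ms spacing, ~38.5 ms span |
| high-pass | 0.1 Hz, order 2 | – | Butterworth SOS, causal, streaming |
| oracle band-pass | 1–9 Hz, order 2 | – | Butterworth, forward–backward (zero phase) |

## Synthetic tremor

The generator produces what the adaptive system must survive, with ground
truth attached: per-axis piecewise-constant (or callable) amplitude
envelopes, a piecewise-constant center-frequency trajectory integrated into
a phase-continuous oscillation (frequency steps create no phase jump, as in
physical tremor), cessation intervals that silence the oscillation on all
axes, per-axis DC offsets, and pink (1/f) or brown (1/f²) noise. Pink noise
is white Gaussian noise spectrally shaped by a 1/√f amplitude mask; brown
is a cumulative sum of white noise; both are mean-removed and normalized to
an exact RMS. **SNR is defined as signal RMS / noise RMS** (a unit tone at
SNR 3 carries noise of RMS 0.236).

Ground-truth dominant axis is defined from the instantaneous envelopes
(largest envelope wins), not from moving averages, so the bank's selection
lag is measurable against it; during cessation the pre-gating envelope
keeps dominance defined. The generator does not model limb biomechanics,
gravity-vector rotation during posture changes, gyroscopic cross-talk, or
any physiological response to stimulation — so passing tests demonstrate
correct signal processing under controlled conditions, not clinical
performance.

## Preprocessing

Filter coefficients are designed at construction (bilinear-transform
Butterworth via scipy) for whatever `f_s` is in use rather than hard-coded.
Streaming state starts at zero (the firmware power-on condition); the
sample-by-sample and batch paths share the same second-order-section state
and agree to 1e-12.

Two measured behaviors worth knowing:

* the onset of a signal is a step that excites the 0.1 Hz high-pass's slow
  transient; steady state is reached only ~30 s in, so short analyses
  should discard a generous warm-up;
* the causal high-pass is not phase-neutral in band: its phase lead is
  ~`√2·(0.1/f)` rad — 1.6° at 5 Hz, ~4° at 2 Hz — and the tracker
  faithfully reproduces it (tests assert the tracked shift equals the
  filter's phase response). Offset removal therefore *costs a small,
  frequency-dependent phase bias* relative to a zero-phase reference; any
  claim that it is free is an approximation valid only well above the
  cutoff.

## Adaptive selection

All 21 streams are stepped on every sample; `μ_axis` is computed on the
high-pass-filtered signal's absolute value, `μ_error` on each stream's
`|e|`. Selection fires every `round(interval·f_s)` samples — exact in
sample-index arithmetic; in wall-clock time the instants drift by ~2 ms per
20 s interval because 20 s is not an integer number of samples. Decisions
fixed where the behavior was unspecified:

* **Partial windows**: before 10 s of data exist, the moving average uses
  the samples seen so far.
* **Ties** (exact equality of `μ` values) keep the incumbent selection, to
  avoid phase-reference churn from sub-millig differences; otherwise ties
  fall back to (x, y, z) order / ascending frequency.
* **No reinitialization on switching**: the newly locked stream has been
  running continuously, so its state is taken as-is and switching is
  seamless.
* **Default selection** before any data: y axis (wrist placement biases
  sensed tremor toward sideways motion), 5 Hz (band center).

The batch bank (`run_bank`) replays the identical rules from trailing-mean
evaluations at the selection instants; it matches the streaming bank's
selections and phases on every scenario tested, differing only in
floating-point summation order of the moving averages (relevant exactly at
ties, which the tests avoid constructing accidentally).

## Protocol and triggering

The error budget is interpreted as a **half-width**: trigger when the
circular distance to the target is ≤ `f_c/f_s·360`. Since that equals the
per-sample phase step and the previous sample's estimate may also license a
trigger, the crossing sample is never missed at steady tracking. A
refractory of half a tremor period enforces at most one burst per cycle —
a physical stimulator cannot re-fire mid-burst, and 5 pulses at `f_s/2`
already span a sixth of a 4 Hz cycle.

Protocol structure (defaults): 600 s baseline; 10 blocks × 8 states
(six phasic targets 0–300° in 60° steps, open-loop, sham), each state 10 s
on + 10 s off, order freshly permuted per block; 60 s baseline; 600 s
continuous stimulation at the best state — 2860 s total. All durations are
configurable, and tests run shrunken sessions (2–3 blocks, 40 s baselines).

Decisions where the original behavior was unspecified or out of scope:

* the **on-board severity proxy** is the locked stream's magnitude `M`;
* each trial's **baseline is its immediately preceding 10-s off window**
  (pairing on/off), and the per-trial change is
  `100·(median(M_on) − median(M_off))/median(M_off)` — a zero baseline
  median (absent tremor) makes the trial undefined and it is excluded and
  logged;
* the **best state** minimizes the median change across its trials;
* the **open-loop state** is modeled as continuous pulse markers at the
  burst rate without phase gating (its electrical parameters are
  hardware-side);
* **stimulation does not affect the signal** by default; an optional
  response-model hook scales the recorded amplitude inside a state's
  stimulation windows (used in tests to verify that an imposed 0.61×
  envelope scaling is recovered as a −39% median change). The hook is
  deliberately simple — per-state amplitude gain, not phase-resolved
  feedback — because modeling true physiology is out of scope.

## Offline statistics

* **Wrap-corrected phase error**: circular distance mapped to [0°, 180°];
  mean and SD are arithmetic on those distances.
* **Median instantaneous frequency**: unwrap the oracle phase, first
  difference × `f_s/360`, median over the segment, rounded to 0.1 Hz.
* **State–amplitude profiles**: per-state median change with limits at the
  `α/(2·8)` and `1 − α/(2·8)` quantiles (Bonferroni for eight states,
  `α = 0.05`) of a resampled null. The null **pools trial-change
  magnitudes across all states and randomizes signs**, then takes medians
  of `n` draws. A per-state sign-flip null of the median was evaluated and
  rejected: when all `n` trials change by about −c, the flip-median
  distribution is bimodal at ±c and the observed median always carries
  ≥ ~38% tail mass — such a test can never flag a consistent effect at any
  `n`, which would make the significance flag dead code. The pooled null
  restores power for consistent effects, empirically controls the
  family-wise error rate on simulated nulls (tested), and is the kind of
  global no-modulation reference a sham condition would provide. It
  remains a reconstruction: the original limit construction is not
  published, and the sign-flip variant is kept (`null="sign_flip"`) for
  calibration studies.
* **Envelope comparison**: two-sample Wilcoxon rank-sum via the normal
  approximation with tie correction (`scipy.stats.mannwhitneyu`), two
  sided, on all envelope samples at `f_s`. Envelope samples are strongly
  autocorrelated, so p-values on raw segments are anticonservative; this
  is kept as-is deliberately (it mirrors the offline analysis this layer
  re-creates) and flagged here rather than "fixed".

## The pre-filtering gap

The characterization suite (`tremortrack.characterization`) compares
tracking after offset removal only against tracking after a full 1–9 Hz
band-pass, on 60-s unit tones at 2–8 Hz with pink or brown noise at SNR 3
(ten seeds per condition), scoring both against the band-pass + Hilbert
oracle and excluding a 5-s warm-up. With *full-band* 1/f and 1/f² noise,
the suite-mean gap is about 5°, strongly frequency-dependent (largest at
`f_c = 2` Hz): colored noise concentrates power between the 0.1 Hz cutoff
and the 1 Hz band edge, which the tracker's several-hertz bandwidth admits
but the oracle and the band-passed condition remove. The gap scales
roughly linearly with noise amplitude and is dominated by the noise
spectrum *below* the tremor band, so its value is chiefly a statement
about the assumed noise model, not about the tracker; under noise that is
mild or band-limited below 1 Hz, the high-pass condition's residual cost
approaches the causal filter's phase lead alone (1.6°–4° across the grid).
Both the suite conditions (full-band noise, SNR 3) and the resulting
number are reported as-is by `scripts/acceptance.py` rather than tuned.

## Problem sizes

The default test run uses desk-scale sizes chosen to exercise every code
path with comfortable statistical margins: 20–70 s records for tracking and
selection tests, 210 s for the cessation study, 140 signals × 60 s for the
pre-filtering suite, 70 bank runs for frequency recovery (≥ 200
selections), 30 for axis recovery, shrunken protocol sessions of 2–3
blocks, and 500 replicates × 4000 resamples for the family-wise error
simulation. The full-length 2860-s protocol runs in seconds through the
batch bank and is exercised by the CLI.

## Known limitations

* No biomechanical or physiological model: stimulation effects enter only
  through the optional response hook; closed-loop efficacy questions are
  out of scope.
* The frequency grid is integer-valued; tremor between grid points is
  tracked by the nearest stream (the gain makes this work, at a small
  error cost), and the grid is configurable but defaults to 2–8 Hz.
* Severity statistics treat envelope samples as exchangeable within
  windows; autocorrelation is unmodeled (flagged above).
* The profile-limit construction is a principled reconstruction, not a
  published procedure.
* Streaming-vs-batch agreement is floating-point-tight but not bitwise;
  at exact `μ` ties the two paths could select differently — mirrored in
  the incumbent-keeping tie rule, which exists precisely to make such
  knife-edge decisions rare and inconsequential.
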