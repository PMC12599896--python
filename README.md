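# tremortrack

Adaptive real-time phase tracking of Parkinsonian rest tremor, with
phase-locked peripheral stimulation triggering — a desk-scale software
re-creation of a wrist-worn closed-loop neurotechnology system, for
researchers studying phase-specific tremor interventions and for anyone who
needs a streaming, self-tuning instantaneous-phase estimator for slow
(2–8 Hz) oscillations in noisy triaxial accelerometry.

Rest tremor in Parkinson's disease is a 3–7 Hz limb oscillation whose
dominant movement axis and center frequency drift over time. Stimulating
the wrist at specific tremor phases can suppress (or amplify) the
oscillation, but only if phase is tracked in real time through those
drifts. This package implements the full pipeline: synthetic tremor
generation with ground truth, streaming offset removal, a bank of
phase-tracking streams with self-tuning selection, the trigger/burst logic
and the two-stage in-clinic experimental protocol, and the offline
validation layer (Hilbert oracle, circular error statistics, state–amplitude
profiles, rank tests).

## The estimator

Each stream models the tremor as a noise-driven harmonic oscillator: a
phasor `x_est = (a, b)` (real and imaginary parts of the analytic estimate,
in g) rotating at a fixed reference frequency `f_c`. Per input sample
`x_in` at rate `f_s` (208.03 Hz by default):

```
e   = x_in − a                     prediction error
a*  = a + G·e                      gain-weighted correction   (G = 0.25)
Φ   = atan2(b, a*)                 phase estimate, degrees [0, 360)
M   = sqrt(a*² + b²)               magnitude (envelope proxy)
(a, b) ← R(θ)·(a*, b),  θ = 2π·f_c/f_s      rotate to the next sample
```

`G ∈ (0, 1)` acts like a Kalman gain: it sets how much the measurement
corrects the oscillator model and hence the tracker's effective bandwidth
around `f_c`. The whole tracker is an adaptive band-pass filter, so the
input needs offset removal only (0.1 Hz second-order Butterworth
high-pass), not a band-pass.

Twenty-one such streams run in parallel — 3 axes × 7 center frequencies
(2–8 Hz at 1 Hz spacing). Every 20 s the system locks onto the dominant
axis (largest 10-s moving average `μ_axis` of the offset-removed signal's
absolute amplitude) and, on that axis, the best frequency (smallest 10-s
moving average `μ_error` of `|e|`). Stimulation bursts (5 pulses at
`f_s/2` = 104.015 Hz) are triggered when the locked phase falls within an
error budget of `f_c/f_s·360` degrees around the target phase, at most
once per half tremor period.

## Worked example

Track a synthetic tremor whose dominant axis switches from y to x at 35 s
and whose frequency steps from 4 to 5 Hz at 45 s:

```python
import numpy as np
from tremortrack import (
    TremorScenario, gen_tremor_record, run_bank, BankConfig,
    oracle_phase_envelope, phase_error,
)

scenario = TremorScenario(
    duration_s=70.0,
    envelopes={"y": 0.3, "x": [(0.0, 0.05), (35.0, 0.6)]},  # axis switch at 35 s
    fc=[(0.0, 4.0), (45.0, 5.0)],                           # frequency step at 45 s
    noise_kind="pink", noise_scale=0.02, seed=42,
)
rec = gen_tremor_record(scenario)

run = run_bank(rec, BankConfig(fs=rec.fs))
print(run.selections[["time_s", "axis", "fc_hz"]].round(2).to_string(index=False))

oracle = oracle_phase_envelope(rec.axis("y"), rec.fs)
seg = slice(int(25 * rec.fs), int(34 * rec.fs))  # locked on y / 4 Hz, pre-switch
mean, sd = phase_error(run.locked_phi_deg[seg], oracle.phase_deg[seg])
print(f"phase error vs Hilbert oracle (25-34 s): {mean:.2f} +/- {sd:.2f} deg")
```

prints

```
 time_s axis  fc_hz
  20.00    y    4.0
  40.00    x    4.0
  60.01    x    5.0
phase error vs Hilbert oracle (25-34 s): 3.65 +/- 2.79 deg
```

The selection log shows the bank locking onto (y, 4 Hz), following the
axis switch at the first selection instant whose 10-s window reflects it
(40 s), then the frequency step (60 s). The wrap-corrected phase error of
the locked stream against the offline gold standard (1–9 Hz zero-phase
band-pass + Hilbert transform) stays a few degrees under pink noise.

The same pipeline is scriptable from the shell — `tremortrack simulate`,
`track`, `protocol`, `analyze`, `validate` — e.g.

```
tremortrack simulate --scenario scenario.yaml --seed 7 --out rec.csv
tremortrack track --in rec.csv --g 0.25 --interval 20
tremortrack protocol --in rec.csv --seed 1
```

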