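"""Phase-locked triggering and the two-stage in-clinic protocol.

Triggering: when the locked stream's phase estimate matches the target
phase, a burst of five TTL pulses is emitted at half the sampling rate
(104.015 Hz at the device rate). To avoid missed cycles, a trigger is
permitted if either the current or the previous estimate matches, and
"matches" means falling within an error budget around the target equal to
the theoretical per-sample phase resolution f_c/f_s*360 degrees. A
refractory of half a tremor period prevents re-triggering within the same
cycle (a physical stimulator cannot re-fire during its own burst).

Protocol: a 10-minute baseline; then the random search — ten blocks, each
presenting all eight stimulation states (six phasic targets 0..300 deg in
60-deg steps, one open-loop non-phasic state, and sham) in freshly
shuffled order, each state 10 s on followed by 10 s off; then a 1-minute
baseline and 10 minutes of continuous stimulation at the state the
envelope-based search found most suppressive. Stream selection runs every
20 s, so each stimulation block keeps one locked (axis, f_c) phase
reference throughout.

Stimulation is modeled as event emission only: by default it has no effect
on the input signal (the package cannot know the true physiological
response). An optional response-model hook scales the recorded amplitude
during stimulation windows for closed-loop experimentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .analysis import circular_distance_deg, trial_change
from .bank import BankConfig, BankRun, run_bank
from .record import AXES, DEFAULT_FS, TriaxialRecord

PHASIC_TARGETS = (0, 60, 120, 180, 240, 300)
STATES = tuple(f"phasic_{p}" for p in PHASIC_TARGETS) + ("openloop", "sham")
PULSES_PER_BURST = 5
PULSE_SPACING_SAMPLES = 2  # burst rate = fs / 2


def error_budget(fc: float, fs: float = DEFAULT_FS) -> float:
    """Phase tolerance around the target, in degrees: fc/fs * 360.

    This is the theoretical phase resolution — the phase the oscillation
    advances between two consecutive samples — so the budget guarantees
    the sample crossing the target is caught. At fs = 208.03 Hz it spans
    ~3.5 deg (f_c = 2) to ~13.8 deg (f_c = 8).
    """
    if not 0 < fc < fs / 2:
        raise ValueError(f"fc must lie in (0, fs/2)=(0, {fs / 2}), got fc={fc}")
    return fc / fs * 360.0


def burst_rate_hz(fs: float = DEFAULT_FS) -> float:
    """Intra-burst pulse rate: half the sampling rate."""
    return fs / PULSE_SPACING_SAMPLES


@dataclass(frozen=True)
class TriggerConfig:
    """Trigger settings for one locked stream."""

    target_phase_deg: float
    fc: float
    fs: float = DEFAULT_FS
    refractory_s: float | None = None  # default: half a tremor period
    pulses_per_burst: int = PULSES_PER_BURST

    def __post_init__(self) -> None:
        if not 0 <= self.target_phase_deg < 360:
            raise ValueError(
                f"target phase must lie in [0, 360), got {self.target_phase_deg}"
            )
        if self.refractory_s is None:
            object.__setattr__(self, "refractory_s", 0.5 / self.fc)
        burst_s = (self.pulses_per_burst - 1) * PULSE_SPACING_SAMPLES / self.fs
        if self.refractory_s <= burst_s:
            raise ValueError(
                f"refractory {self.refractory_s} s must exceed the burst "
                f"duration {burst_s} s"
            )

    @property
    def budget_deg(self) -> float:
        return error_budget(self.fc, self.fs)

    @property
    def refractory_samples(self) -> int:
        return int(round(self.refractory_s * self.fs))


def should_trigger(
    phi_now_deg: float,
    phi_prev_deg: float,
    cfg: TriggerConfig,
    samples_since_last_trigger: int,
) -> bool:
    """Trigger decision for one sample.

    Fires iff the refractory has elapsed and either the current or the
    previous phase estimate lies within the error budget of the target
    (circular distance, so the budget wraps across 0/360).
    """
    if samples_since_last_trigger < cfg.refractory_samples:
        return False
    t = cfg.target_phase_deg
    return bool(
        circular_distance_deg(phi_now_deg, t) <= cfg.budget_deg
        or circular_distance_deg(phi_prev_deg, t) <= cfg.budget_deg
    )


def emit_burst(trigger_index: int, fs: float = DEFAULT_FS) -> np.ndarray:
    """Sample indices of the five pulses of one burst.

    Pulses are spaced every 2 samples (rate fs/2), so the burst spans
    8/fs seconds (~38.5 ms at the device rate).
    """
    if trigger_index < 0:
        raise ValueError(f"trigger index must be >= 0, got {trigger_index}")
    return trigger_index + PULSE_SPACING_SAMPLES * np.arange(PULSES_PER_BURST)


@dataclass
class StimEvent:
    """One phase-locked trigger and its burst."""

    sample_index: int
    time_s: float
    block: int
    state: str
    target_phase_deg: float
    est_phase_deg: float
    axis: str
    fc_hz: float
    pulse_indices: np.ndarray


@dataclass
class ProtocolSchedule:
    """Timing and state orders of the two-stage protocol.

    Defaults reproduce the in-clinic session: 600 s baseline, ten blocks of
    eight states at 10 s on + 10 s off (1600 s random search), 60 s
    baseline, 600 s continuous stimulation — 2860 s, about 48 minutes.
    Durations are configurable so desk-scale runs can shrink the session;
    block orders are independent seeded permutations of all eight states
    (shuffled without repetition).
    """

    block_orders: list[list[str]]
    stage1_baseline_s: float = 600.0
    trial_on_s: float = 10.0
    trial_off_s: float = 10.0
    stage2_baseline_s: float = 60.0
    continuous_s: float = 600.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for k, order in enumerate(self.block_orders):
            if sorted(order) != sorted(STATES):
                raise ValueError(
                    f"block {k} is not a permutation of the {len(STATES)} states"
                )

    @property
    def n_blocks(self) -> int:
        return len(self.block_orders)

    @property
    def trial_s(self) -> float:
        return self.trial_on_s + self.trial_off_s

    @property
    def random_search_s(self) -> float:
        return self.n_blocks * len(STATES) * self.trial_s

    @property
    def stage1_s(self) -> float:
        return self.stage1_baseline_s + self.random_search_s

    @property
    def total_s(self) -> float:
        return self.stage1_s + self.stage2_baseline_s + self.continuous_s


def build_schedule(seed: int, n_blocks: int = 10, **durations) -> ProtocolSchedule:
    """Seeded schedule: `n_blocks` independent permutations of the states."""
    rng = np.random.default_rng(seed)
    orders = [list(rng.permutation(STATES)) for _ in range(n_blocks)]
    return ProtocolSchedule(block_orders=orders, seed=seed, **durations)


@dataclass
class ProtocolResult:
    """Event log, per-trial severity changes and the chosen best state."""

    events: pd.DataFrame
    trials: pd.DataFrame
    best_state: str | None
    bank_run: BankRun
    schedule: ProtocolSchedule
    truncated: bool
    continuous_state: str | None = None
    continuous_events: int = 0


# response model: (state_label, target_phase_deg or None) -> amplitude gain
ResponseModel = Callable[[str, float | None], float]


def _target_of(state: str) -> float | None:
    return float(state.split("_")[1]) if state.startswith("phasic_") else None


def run_protocol(
    record: TriaxialRecord,
    schedule: ProtocolSchedule,
    bank_config: BankConfig | None = None,
    response_model: ResponseModel | None = None,
) -> ProtocolResult:
    """Execute the full protocol over a (synthetic or recorded) record.

    Runs the adaptive bank over the whole record (selection every
    `selection_interval_s`, aligned with the trial cadence), then walks the
    schedule: during phasic trials, triggers fire per `should_trigger`
    against the locked stream's phase; the open-loop state stimulates
    continuously without phase gating; sham emits nothing. Each trial's
    severity change is the percentage change of the locked stream's
    magnitude (the on-board envelope proxy) between the 10-s stimulation
    window and the immediately preceding 10-s off window. The best state
    minimizes the median change across its trials and is run continuously
    in stage 2.

    A record shorter than the schedule yields a partial result with
    ``truncated=True``.
    """
    cfg = bank_config or BankConfig(fs=record.fs)
    fs = record.fs
    n = record.n_samples

    def s2i(t_s: float) -> int:
        return int(round(t_s * fs))

    # enumerate trials (block, position, state, window starts)
    trials_spec = []
    for b, order in enumerate(schedule.block_orders):
        for p, state in enumerate(order):
            t_on = (schedule.stage1_baseline_s
                    + (b * len(STATES) + p) * schedule.trial_s)
            trials_spec.append((b, p, state, t_on))

    truncated = n < s2i(schedule.total_s)

    if response_model is not None:
        record = TriaxialRecord(
            samples=record.samples.copy(), fs=fs,
            phase_true_deg=record.phase_true_deg, axis_true=record.axis_true,
            fc_true_hz=record.fc_true_hz, meta=dict(record.meta),
        )
        for _, _, state, t_on in trials_spec:
            gain = response_model(state, _target_of(state))
            lo, hi = s2i(t_on), min(s2i(t_on + schedule.trial_on_s), n)
            record.samples[lo:hi] *= gain

    bank = run_bank(record, cfg)
    phi = bank.locked_phi_deg
    env = bank.locked_M

    events: list[StimEvent] = []
    event_rows = []
    trial_rows = []
    for b, p, state, t_on in trials_spec:
        lo, hi = s2i(t_on), s2i(t_on + schedule.trial_on_s)
        if lo >= n:
            break
        hi = min(hi, n)
        axis_idx = int(bank.locked_axis[lo])
        fc = float(bank.locked_fc[lo])
        target = _target_of(state)
        n_openloop_pulses = 0
        if state == "sham":
            pass
        elif state == "openloop":
            n_openloop_pulses = (hi - lo) // PULSE_SPACING_SAMPLES
        else:
            tcfg = TriggerConfig(target_phase_deg=target, fc=fc, fs=fs)
            since = tcfg.refractory_samples  # armed at trial start
            for k in range(lo, hi):
                prev = phi[k - 1] if k > 0 else phi[k]
                if should_trigger(phi[k], prev, tcfg, since):
                    ev = StimEvent(
                        sample_index=k, time_s=k / fs, block=b, state=state,
                        target_phase_deg=target, est_phase_deg=float(phi[k]),
                        axis=AXES[axis_idx], fc_hz=fc,
                        pulse_indices=emit_burst(k, fs),
                    )
                    events.append(ev)
                    event_rows.append({
                        "sample_index": k, "time_s": k / fs, "block": b,
                        "state": state, "target_phase_deg": target,
                        "est_phase_deg": float(phi[k]), "axis": AXES[axis_idx],
                        "fc_hz": fc,
                    })
                    since = 0
                else:
                    since += 1
        base_lo = s2i(t_on - schedule.trial_off_s)
        change = (
            trial_change(env, slice(lo, hi), slice(base_lo, lo))
            if hi > lo and base_lo >= 0 else float("nan")
        )
        trial_rows.append({
            "block": b, "position": p, "state": state,
            "start_s": t_on, "axis": AXES[axis_idx], "fc_hz": fc,
            "n_triggers": sum(1 for e in events
                              if e.block == b and e.state == state),
            "n_openloop_pulses": n_openloop_pulses,
            "change_percent": change,
        })

    trials = pd.DataFrame(trial_rows)
    best_state = None
    if len(trials):
        medians = (trials.dropna(subset=["change_percent"])
                   .groupby("state")["change_percent"].median())
        if len(medians):
            best_state = str(medians.idxmin())

    continuous_events = 0
    cont_state = None
    cont_lo = s2i(schedule.stage1_s + schedule.stage2_baseline_s)
    if best_state is not None and cont_lo < n and not truncated:
        cont_state = best_state
        cont_hi = min(s2i(schedule.total_s), n)
        if cont_state == "openloop":
            continuous_events = (cont_hi - cont_lo) // PULSE_SPACING_SAMPLES
        elif cont_state.startswith("phasic_"):
            target = _target_of(cont_state)
            fc = float(bank.locked_fc[cont_lo])
            tcfg = TriggerConfig(target_phase_deg=target, fc=fc, fs=fs)
            since = tcfg.refractory_samples
            for k in range(cont_lo, cont_hi):
                fc_k = float(bank.locked_fc[k])
                if fc_k != tcfg.fc:
                    tcfg = TriggerConfig(target_phase_deg=target, fc=fc_k, fs=fs)
                prev = phi[k - 1] if k > 0 else phi[k]
                if should_trigger(phi[k], prev, tcfg, since):
                    continuous_events += 1
                    since = 0
                else:
                    since += 1

    events_df = pd.DataFrame(event_rows, columns=[
        "sample_index", "time_s", "block", "state", "target_phase_deg",
        "est_phase_deg", "axis", "fc_hz",
    ])
    return ProtocolResult(
        events=events_df, trials=trials, best_state=best_state,
        bank_run=bank, schedule=schedule, truncated=truncated,
        continuous_state=cont_state, continuous_events=continuous_events,
    )
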