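"""Built-in self-checks behind ``tremortrack validate``.

Design-constant arithmetic plus a reduced-size tracking suite, each check
returning (pass, detail). These are the tool's own sanity gates — quick to
run on one CPU — not a substitute for the full test suite.
"""

from __future__ import annotations

import numpy as np

from .analysis import oracle_phase_envelope, phase_error
from .bank import BankConfig, DEFAULT_FREQS, grid_design_requirements, run_bank
from .protocol import STATES, build_schedule, burst_rate_hz, error_budget
from .record import DEFAULT_FS
from .signals import gen_pure_sine, gen_tremor_record, TremorScenario
from .tracker import PhaseTracker, TrackerParams, track_batch


def run_selfchecks(seed: int = 0) -> dict[str, tuple[bool, str]]:
    checks: dict[str, tuple[bool, str]] = {}
    fs = DEFAULT_FS

    n_streams = BankConfig().n_streams
    checks["stream_count"] = (n_streams == 21, f"3 axes x 7 freqs = {n_streams}")

    req = grid_design_requirements()
    ok = req["nyquist_hz"] == 16.0 and req["phase_design_min_hz"] == 48.0 \
        and fs > req["phase_design_min_hz"]
    checks["sampling_design"] = (
        ok, f"Nyquist {req['nyquist_hz']:.0f} Hz, six-phase minimum "
            f"{req['phase_design_min_hz']:.0f} Hz, fs {fs} Hz"
    )

    rate = burst_rate_hz(fs)
    checks["burst_rate"] = (abs(rate - 104.015) < 1e-9, f"fs/2 = {rate} Hz")

    budget = error_budget(8.0, fs)
    checks["error_budget_top"] = (budget <= 14.0, f"{budget:.2f} deg at fc=8")

    sched = build_schedule(seed)
    ok = (sched.random_search_s == 1600.0 and sched.total_s == 2860.0
          and all(sorted(o) == sorted(STATES) for o in sched.block_orders))
    checks["schedule_arithmetic"] = (
        ok, f"search {sched.random_search_s / 60:.1f} min, "
            f"total {sched.total_s / 60:.1f} min, "
            f"{sched.n_blocks} permuted blocks"
    )

    # noiseless tones vs the Hilbert oracle, full grid
    worst = 0.0
    skip = int(round(5 * fs))
    for f in DEFAULT_FREQS:
        x, _ = gen_pure_sine(f, fs, duration_s=30.0)
        phi, _, _ = track_batch(x, fs, f)
        oracle = oracle_phase_envelope(x, fs)
        mean, _ = phase_error(phi[skip:-skip], oracle.phase_deg[skip:-skip])
        worst = max(worst, mean)
    checks["tone_vs_hilbert"] = (worst < 1.0, f"worst mean error {worst:.3f} deg")

    # streaming recursion vs closed-form batch replication
    x, _ = gen_pure_sine(5.0, fs, duration_s=20.0)
    rng = np.random.default_rng(seed)
    x = x + 0.1 * rng.standard_normal(len(x))
    phi_b, _, _ = track_batch(x, fs, 5.0)
    phi_s, _, _ = PhaseTracker(TrackerParams(fc=5.0, fs=fs)).process(x)
    mean, _ = phase_error(phi_s, phi_b)
    checks["stream_vs_batch"] = (mean < 0.5, f"mean discrepancy {mean:.2e} deg")

    # adaptive selection on a clean 4 Hz tone
    rec = gen_tremor_record(TremorScenario(
        duration_s=45.0, fs=fs, envelopes={"y": 0.3}, fc=4.0, seed=seed,
    ))
    run = run_bank(rec, BankConfig(fs=fs))
    sel = run.selections
    ok = len(sel) > 0 and (sel["fc_hz"] == 4.0).all() and (sel["axis"] == "y").all()
    checks["tone_selection"] = (
        ok, f"{len(sel)} selections, fc {set(sel['fc_hz'])}, axes {set(sel['axis'])}"
    )
    return checks
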