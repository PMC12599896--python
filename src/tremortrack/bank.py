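"""The adaptive bank: 21 parallel streams with self-tuning selection.

One phase tracker per combination of accelerometer axis (x, y, z) and
center frequency (2-8 Hz at 1 Hz resolution: the 3-7 Hz rest-tremor band
plus a 1 Hz safety margin on each side) — 21 streams stepped on every
sample. Selection of the locked stream happens at a programmable cadence
(default every 20 s, aligned with the stimulation block structure):

  * dominant axis = axis with the largest 10-s moving average (mu_axis) of
    the absolute value of the offset-removed signal;
  * center frequency = on that axis, the stream with the smallest 10-s
    moving average (mu_error) of the absolute prediction error |e| — the
    stream whose reference frequency sits closest to the signal's.

Between selection instants the locked (axis, f_c) never changes, so the
phase reference is stable within a stimulation block. All streams run
continuously, so a newly selected stream is already warmed up and
switching is seamless.

`StreamBank` is the sample-by-sample (firmware-style) implementation;
`run_bank` is an equivalent vectorized batch runner used for long records
and as a replication cross-check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocessing import make_highpass
from .record import AXES, DEFAULT_FS, TriaxialRecord
from .tracker import DEFAULT_GAIN, PhaseTracker, TrackerParams, track_batch

log = logging.getLogger(__name__)

DEFAULT_FREQS = (2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0)
DEFAULT_SELECTION_INTERVAL_S = 20.0
MU_WINDOW_S = 10.0
DEFAULT_AXIS = 1  # y: wrist placement biases sensed tremor sideways
DEFAULT_FC = 5.0


def grid_design_requirements(
    freqs: tuple[float, ...] = DEFAULT_FREQS, phases_per_cycle: int = 6
) -> dict[str, float]:
    """Sampling-rate requirements implied by the frequency grid.

    The Nyquist rate is twice the highest tracked frequency; resolving
    `phases_per_cycle` equally spaced phases per cycle requires
    `phases_per_cycle` times the highest frequency.
    """
    fmax = max(freqs)
    return {
        "nyquist_hz": 2.0 * fmax,
        "phase_design_min_hz": phases_per_cycle * fmax,
    }


class MovingAverage:
    """Exact rectangular-window running mean over the last W samples.

    Backed by a circular buffer and a running sum; before W samples have
    been seen, the mean of the samples available so far is returned.
    """

    def __init__(self, window: int):
        if window < 1:
            raise ValueError(f"window must be >= 1, got {window}")
        self.window = int(window)
        self._buf = np.zeros(self.window)
        self._sum = 0.0
        self._pos = 0
        self.count = 0

    def update(self, v: float) -> float:
        if self.count >= self.window:
            self._sum -= self._buf[self._pos]
        self._buf[self._pos] = v
        self._sum += v
        self._pos = (self._pos + 1) % self.window
        self.count += 1
        return self.value

    @property
    def value(self) -> float:
        n = min(self.count, self.window)
        return self._sum / n if n else 0.0


@dataclass
class BankConfig:
    """Configuration of the adaptive bank."""

    fs: float = DEFAULT_FS
    freqs: tuple[float, ...] = DEFAULT_FREQS
    gain: float = DEFAULT_GAIN
    selection_interval_s: float = DEFAULT_SELECTION_INTERVAL_S
    mu_window_s: float = MU_WINDOW_S

    @property
    def interval_samples(self) -> int:
        return int(round(self.selection_interval_s * self.fs))

    @property
    def mu_window(self) -> int:
        return int(round(self.mu_window_s * self.fs))

    @property
    def n_streams(self) -> int:
        return len(AXES) * len(self.freqs)


@dataclass
class Selection:
    """One selection-log entry."""

    sample_index: int
    time_s: float
    axis: int
    fc: float
    mu_axis: tuple[float, float, float]
    mu_error: tuple[float, ...]  # chosen axis's streams, in freq order


class StreamBank:
    """Sample-by-sample adaptive bank (firmware-style reference path).

    `step` consumes one offset-removed (x, y, z) sample; `process_record`
    feeds a raw record through per-axis high-pass filters first.
    """

    def __init__(self, config: BankConfig | None = None):
        self.config = config or BankConfig()
        cfg = self.config
        self.trackers = [
            [PhaseTracker(TrackerParams(fc=f, fs=cfg.fs, gain=cfg.gain))
             for f in cfg.freqs]
            for _ in AXES
        ]
        self.mu_axis = [MovingAverage(cfg.mu_window) for _ in AXES]
        self.mu_error = [
            [MovingAverage(cfg.mu_window) for _ in cfg.freqs] for _ in AXES
        ]
        self.selection: tuple[int, float] = (DEFAULT_AXIS, DEFAULT_FC)
        self.selection_log: list[Selection] = []
        self.n_seen = 0

    # -- selection ---------------------------------------------------------

    def select_stream(self) -> tuple[int, float]:
        """Re-select the locked (axis, fc) from the current moving averages.

        Ties (exact equality of mu values) keep the incumbent to avoid
        phase-reference churn; otherwise they fall back to fixed order
        (x, y, z) / ascending frequency. Calling before any samples have
        been seen returns the default selection and warns.
        """
        cfg = self.config
        if self.n_seen == 0:
            log.warning(
                "select_stream called before any samples; returning default "
                "(axis=%s, fc=%s)", AXES[DEFAULT_AXIS], DEFAULT_FC
            )
            self.selection = (DEFAULT_AXIS, DEFAULT_FC)
            return self.selection

        inc_axis, inc_fc = self.selection
        mu_ax = [m.value for m in self.mu_axis]
        best = max(mu_ax)
        axis_ties = [i for i, v in enumerate(mu_ax) if v == best]
        axis = inc_axis if inc_axis in axis_ties else axis_ties[0]

        mu_err = [m.value for m in self.mu_error[axis]]
        least = min(mu_err)
        fc_ties = [cfg.freqs[i] for i, v in enumerate(mu_err) if v == least]
        fc = inc_fc if (axis == inc_axis and inc_fc in fc_ties) else fc_ties[0]

        self.selection = (axis, fc)
        self.selection_log.append(Selection(
            sample_index=self.n_seen - 1,
            time_s=self.n_seen / cfg.fs,
            axis=axis, fc=fc,
            mu_axis=tuple(mu_ax), mu_error=tuple(mu_err),
        ))
        return self.selection

    # -- stepping ----------------------------------------------------------

    def step(self, filtered_xyz) -> tuple[float, float]:
        """Step all 21 streams with one offset-removed sample.

        Updates mu_axis with |sample| per axis and mu_error with |e| per
        stream; returns the locked stream's (phi_deg, M). Selection fires
        automatically every `selection_interval_s` (sample-index
        arithmetic).
        """
        xyz = np.asarray(filtered_xyz, dtype=float)
        if xyz.shape != (3,):
            raise ValueError(f"expected one (x, y, z) sample, got shape {xyz.shape}")
        if not np.all(np.isfinite(xyz)):
            raise ValueError(f"non-finite sample {xyz!r}")
        cfg = self.config
        locked_axis, locked_fc = self.selection
        locked_j = cfg.freqs.index(locked_fc)
        out_phi, out_m = 0.0, 0.0
        for i in range(len(AXES)):
            self.mu_axis[i].update(abs(xyz[i]))
            for j, trk in enumerate(self.trackers[i]):
                phi, M, e = trk.step(xyz[i])
                self.mu_error[i][j].update(abs(e))
                if i == locked_axis and j == locked_j:
                    out_phi, out_m = phi, M
        self.n_seen += 1
        if self.n_seen % cfg.interval_samples == 0:
            self.select_stream()
        return out_phi, out_m

    def process_record(self, record: TriaxialRecord) -> "BankRun":
        """High-pass filter a raw record and stream it through the bank."""
        cfg = self.config
        filters = [make_highpass(cfg.fs) for _ in AXES]
        filtered = np.column_stack([
            filters[i].process(record.axis(i)) for i in range(3)
        ])
        n = len(filtered)
        phi = np.empty(n)
        M = np.empty(n)
        axis_track = np.empty(n, dtype=int)
        fc_track = np.empty(n)
        for k in range(n):
            axis_track[k], fc_track[k] = self.selection
            phi[k], M[k] = self.step(filtered[k])
        return BankRun(
            locked_phi_deg=phi, locked_M=M,
            locked_axis=axis_track, locked_fc=fc_track,
            selections=selection_frame(self.selection_log),
            config=cfg,
        )


@dataclass
class BankRun:
    """Output of a bank pass over a record."""

    locked_phi_deg: np.ndarray
    locked_M: np.ndarray
    locked_axis: np.ndarray
    locked_fc: np.ndarray
    selections: pd.DataFrame
    config: BankConfig
    all_phi_deg: np.ndarray | None = None  # (n, 3, n_freqs), batch path only
    all_M: np.ndarray | None = None


def selection_frame(entries: list[Selection]) -> pd.DataFrame:
    """Selection log as a DataFrame (one row per selection instant)."""
    rows = []
    for s in entries:
        row = {
            "sample_index": s.sample_index, "time_s": s.time_s,
            "axis": AXES[s.axis], "fc_hz": s.fc,
        }
        row.update({f"mu_axis_{ax}": v for ax, v in zip(AXES, s.mu_axis)})
        row.update({f"mu_error_{k}": v for k, v in enumerate(s.mu_error)})
        rows.append(row)
    columns = ["sample_index", "time_s", "axis", "fc_hz"]
    columns += [f"mu_axis_{ax}" for ax in AXES]
    columns += [f"mu_error_{k}" for k in range(7)]
    return pd.DataFrame(rows, columns=None if rows else columns)


def _trailing_means(values: np.ndarray, instants: np.ndarray, window: int) -> np.ndarray:
    """Mean of the last min(k+1, window) values at each instant k (cumsum)."""
    csum = np.concatenate([[0.0], np.cumsum(values)])
    lo = np.maximum(instants + 1 - window, 0)
    return (csum[instants + 1] - csum[lo]) / (instants + 1 - lo)


def run_bank(
    record: TriaxialRecord,
    config: BankConfig | None = None,
    highpass: bool = True,
    keep_streams: bool = False,
) -> BankRun:
    """Vectorized batch pass of the adaptive bank over a whole record.

    Tracks all 21 streams with the closed-form batch tracker, evaluates the
    10-s trailing means at every selection instant, and replays the
    selection rules (incumbent-keeping ties included). Produces the same
    locked outputs and selection log as the streaming `StreamBank` path up
    to floating-point rounding of the moving averages.
    """
    cfg = config or BankConfig()
    n = record.n_samples
    if highpass:
        filtered = np.column_stack([
            make_highpass(cfg.fs).process(record.axis(i)) for i in range(3)
        ])
    else:
        filtered = record.samples.astype(float)

    n_f = len(cfg.freqs)
    phi = np.empty((n, 3, n_f))
    M = np.empty((n, 3, n_f))
    abs_e = np.empty((n, 3, n_f))
    for i in range(3):
        for j, f in enumerate(cfg.freqs):
            p, m, e = track_batch(filtered[:, i], cfg.fs, f, gain=cfg.gain)
            phi[:, i, j] = p
            M[:, i, j] = m
            abs_e[:, i, j] = np.abs(e)

    step = cfg.interval_samples
    instants = np.arange(step - 1, n, step)  # streaming fires after these samples
    window = cfg.mu_window
    mu_ax = np.column_stack([
        _trailing_means(np.abs(filtered[:, i]), instants, window) for i in range(3)
    ])
    mu_err = np.stack([
        np.column_stack([
            _trailing_means(abs_e[:, i, j], instants, window) for j in range(n_f)
        ])
        for i in range(3)
    ], axis=1)  # (n_instants, 3, n_f)

    selection = (DEFAULT_AXIS, DEFAULT_FC)
    log_entries: list[Selection] = []
    locked_axis = np.empty(n, dtype=int)
    locked_fc = np.empty(n)
    seg_start = 0
    for k, idx in enumerate(instants):
        locked_axis[seg_start:idx + 1] = selection[0]
        locked_fc[seg_start:idx + 1] = selection[1]
        seg_start = idx + 1
        inc_axis, inc_fc = selection
        row_ax = mu_ax[k]
        best = row_ax.max()
        ties = np.flatnonzero(row_ax == best)
        axis = inc_axis if inc_axis in ties else int(ties[0])
        row_err = mu_err[k, axis]
        least = row_err.min()
        fc_ties = [cfg.freqs[j] for j in np.flatnonzero(row_err == least)]
        fc = inc_fc if (axis == inc_axis and inc_fc in fc_ties) else fc_ties[0]
        selection = (axis, fc)
        log_entries.append(Selection(
            sample_index=int(idx), time_s=(idx + 1) / cfg.fs,
            axis=axis, fc=fc,
            mu_axis=tuple(row_ax), mu_error=tuple(row_err),
        ))
    locked_axis[seg_start:] = selection[0]
    locked_fc[seg_start:] = selection[1]

    j_locked = np.searchsorted(cfg.freqs, locked_fc)
    idx = np.arange(n)
    return BankRun(
        locked_phi_deg=phi[idx, locked_axis, j_locked],
        locked_M=M[idx, locked_axis, j_locked],
        locked_axis=locked_axis, locked_fc=locked_fc,
        selections=selection_frame(log_entries),
        config=cfg,
        all_phi_deg=phi if keep_streams else None,
        all_M=M if keep_streams else None,
    )
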