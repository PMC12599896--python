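"""Offline validation and statistics.

The desk-side counterpart of the streaming system: the band-pass + Hilbert
oracle for phase and envelope, wrap-corrected circular phase error, median
instantaneous frequency, per-trial tremor-severity changes, state-amplitude
profiles with multiplicity-corrected (Bonferroni, eight states) resampling
confidence limits, and the rank-sum envelope comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as _signal
from scipy import stats as _stats

from .preprocessing import offline_bandpass

log = logging.getLogger(__name__)

N_STATES = 8  # six phasic targets + open-loop + sham


def circular_distance_deg(a, b) -> np.ndarray | float:
    """Wrap-corrected absolute phase difference, mapped to [0, 180] degrees."""
    return np.abs(((np.asarray(a) - np.asarray(b) + 180.0) % 360.0) - 180.0)


@dataclass
class OraclePhaseEnvelope:
    """Per-sample oracle phase (deg, [0, 360)) and envelope (g) of one channel."""

    phase_deg: np.ndarray
    envelope: np.ndarray
    fs: float


def oracle_phase_envelope(
    x: np.ndarray, fs: float, low: float = 1.0, high: float = 9.0
) -> OraclePhaseEnvelope:
    """Gold-standard phase and envelope: zero-phase band-pass then Hilbert.

    The channel is band-passed 1-9 Hz with a forward-backward second-order
    Butterworth filter, then the analytic signal is formed; its argument
    (in the same cosine-peak-zero convention as the tracker) is the oracle
    phase and its modulus the tremor envelope.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 10 * fs:
        raise ValueError(
            f"oracle needs at least 10 s of samples ({int(10 * fs)}), got {len(x)}"
        )
    bp = offline_bandpass(x, fs, low=low, high=high)
    analytic = _signal.hilbert(bp)
    return OraclePhaseEnvelope(
        phase_deg=np.degrees(np.angle(analytic)) % 360.0,
        envelope=np.abs(analytic),
        fs=fs,
    )


def phase_error(est_deg: np.ndarray, oracle_deg: np.ndarray) -> tuple[float, float]:
    """Mean and SD of the wrap-corrected phase error, in degrees.

    The per-sample error is the circular distance mapped to [0, 180]; the
    caller is expected to have excluded any warm-up.
    """
    est_deg = np.asarray(est_deg, dtype=float)
    oracle_deg = np.asarray(oracle_deg, dtype=float)
    if est_deg.shape != oracle_deg.shape:
        raise ValueError(
            f"length mismatch: est {est_deg.shape} vs oracle {oracle_deg.shape}"
        )
    err = circular_distance_deg(est_deg, oracle_deg)
    return float(np.mean(err)), float(np.std(err))


def median_instantaneous_frequency(
    oracle: OraclePhaseEnvelope,
    segment: slice | None = None,
    resolution_hz: float = 0.1,
) -> float:
    """Median instantaneous frequency of a segment, at 0.1 Hz resolution.

    Unwraps the oracle phase, converts the first difference to Hz
    (diff * fs / 360) and takes the median over the segment, rounded to the
    nearest `resolution_hz`.
    """
    segment = segment if segment is not None else slice(None)
    phase = np.asarray(oracle.phase_deg, dtype=float)[segment]
    if len(phase) < oracle.fs:
        raise ValueError(
            f"segment must cover at least 1 s ({int(oracle.fs)} samples), "
            f"got {len(phase)}"
        )
    inst_f = np.diff(np.unwrap(phase, period=360.0)) * oracle.fs / 360.0
    return float(np.round(np.median(inst_f) / resolution_hz) * resolution_hz)


def trial_change(
    envelope: np.ndarray,
    stim_window: slice,
    baseline_window: slice,
) -> float:
    """Percentage change in tremor severity of one trial.

    ``100 * (median(env[stim]) - median(env[baseline])) / median(env[baseline])``.
    A zero baseline median means tremor was absent; the trial is undefined
    (NaN, logged) rather than infinite.
    """
    envelope = np.asarray(envelope, dtype=float)
    stim = envelope[stim_window]
    base = envelope[baseline_window]
    if len(stim) == 0 or len(base) == 0:
        raise ValueError("stim and baseline windows must be non-empty")
    base_med = float(np.median(base))
    if base_med == 0.0:
        log.warning("zero baseline envelope median: trial change undefined")
        return float("nan")
    return 100.0 * (float(np.median(stim)) - base_med) / base_med


def profile_significance(
    changes_per_state: dict[str, np.ndarray],
    alpha: float = 0.05,
    n_resamples: int = 10_000,
    seed: int | np.random.Generator | None = 0,
    n_states: int = N_STATES,
    null: str = "pooled",
) -> pd.DataFrame:
    """State-amplitude profile with Bonferroni-corrected resampling limits.

    For each stimulation state, a null distribution of the median trial
    change under "stimulation does nothing" is built by seeded resampling,
    and two-sided limits are taken at the alpha/(2*n_states) and
    1 - alpha/(2*n_states) quantiles — the Bonferroni correction for the
    eight states tested. A state is flagged significant iff its observed
    median falls outside its limits. States with fewer than 3 finite
    trials are untestable.

    Null constructions (`null`):

    * ``"pooled"`` (default) — medians of n draws, with replacement, from
      the pooled trial-change magnitudes of *all* states with random
      signs: a global no-modulation null that shares trial variability
      across states.
    * ``"sign_flip"`` — medians of sign-flipped copies of the state's own
      changes. Note this variant cannot flag a consistent shift: if every
      trial changes by about -c, the flip-median distribution is bimodal
      at +/-c and the observed median is never in its far tail, for any
      number of trials. It is kept for null calibration studies only.

    Returns a DataFrame with one row per state: ``state``, ``n_trials``,
    ``median_change``, ``ci_low``, ``ci_high``, ``significant``,
    ``testable``.
    """
    if null not in ("pooled", "sign_flip"):
        raise ValueError(f"null must be 'pooled' or 'sign_flip', got {null!r}")
    rng = np.random.default_rng(seed)
    lo_q = alpha / (2 * n_states)
    hi_q = 1.0 - lo_q
    finite = {
        state: np.asarray(changes, dtype=float)[
            np.isfinite(np.asarray(changes, dtype=float))
        ]
        for state, changes in changes_per_state.items()
    }
    pooled_mag = np.abs(np.concatenate([v for v in finite.values() if len(v)]))
    rows = []
    for state, changes in finite.items():
        n = len(changes)
        if n < 3:
            rows.append({
                "state": state, "n_trials": n,
                "median_change": float(np.median(changes)) if n else float("nan"),
                "ci_low": float("nan"), "ci_high": float("nan"),
                "significant": False, "testable": False,
            })
            continue
        signs = rng.choice([-1.0, 1.0], size=(n_resamples, n))
        if null == "pooled":
            draws = rng.choice(pooled_mag, size=(n_resamples, n))
        else:
            draws = np.broadcast_to(np.abs(changes), (n_resamples, n))
        null_medians = np.median(signs * draws, axis=1)
        lo, hi = np.quantile(null_medians, [lo_q, hi_q])
        med = float(np.median(changes))
        rows.append({
            "state": state, "n_trials": n, "median_change": med,
            "ci_low": float(lo), "ci_high": float(hi),
            "significant": bool(med < lo or med > hi), "testable": True,
        })
    return pd.DataFrame(rows)


def envelope_rank_compare(
    envelope_a: np.ndarray, envelope_b: np.ndarray
) -> tuple[float, float]:
    """Two-sample Wilcoxon rank-sum comparison of two envelope segments.

    Returns ``(W, p)`` where W is the rank-sum statistic of the first
    sample and p the two-sided p-value from the normal approximation with
    tie correction. Note the test treats samples as independent; envelope
    samples at the device rate are autocorrelated, so p-values on raw
    segments are anticonservative (kept as-is to mirror the offline
    analysis).
    """
    a = np.asarray(envelope_a, dtype=float)
    b = np.asarray(envelope_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both envelope samples must be non-empty")
    res = _stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    w = float(res.statistic) + len(a) * (len(a) + 1) / 2.0  # U1 -> rank sum of a
    return w, float(res.pvalue)
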