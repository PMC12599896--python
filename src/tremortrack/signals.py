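"""Synthetic tremor and test-signal generation.

Everything the offline characterization and the property suites feed the
tracker with is generated here: pure sinusoids with exact phase tracks,
seedable pink (1/f) and brown (1/f^2) noise emulating real-world
accelerometer noise, and full triaxial tremor scenarios with time-varying
per-axis amplitude envelopes, a piecewise-constant center-frequency
trajectory in the Parkinsonian rest-tremor band, cessation intervals, DC
offsets and colored noise — all with ground truth attached.

Conventions: acceleration in g, phases in degrees [0, 360), the oscillation
is a cosine (phase 0 at the positive peak), frequency trajectories are
integrated so frequency steps are phase-continuous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .record import AXES, DEFAULT_FS, TriaxialRecord

NOISE_KINDS = ("none", "pink", "brown")

#: Tremor center-frequency grid bounds in Hz (rest tremor band plus margin).
FC_MIN, FC_MAX = 2.0, 8.0

# A piecewise-constant profile: scalar, breakpoint list [(start_s, value)],
# or an arbitrary callable of time.
Profile = float | Sequence[tuple[float, float]] | Callable[[np.ndarray], np.ndarray]


def _profile_values(profile: Profile, t: np.ndarray) -> np.ndarray:
    """Evaluate a scalar / breakpoint-list / callable profile at times t."""
    if callable(profile):
        return np.broadcast_to(np.asarray(profile(t), dtype=float), t.shape).copy()
    if np.isscalar(profile):
        return np.full_like(t, float(profile))
    pieces = sorted((float(s), float(v)) for s, v in profile)
    starts = np.array([s for s, _ in pieces])
    values = np.array([v for _, v in pieces])
    if starts[0] > 0:
        raise ValueError(
            f"piecewise profile must start at t=0, first breakpoint at {starts[0]} s"
        )
    idx = np.searchsorted(starts, t, side="right") - 1
    return values[idx]


def gen_pure_sine(
    f: float,
    fs: float = DEFAULT_FS,
    duration_s: float = 60.0,
    amplitude: float = 1.0,
    phase0_deg: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Pure cosine test tone with its exact phase track.

    Returns ``(signal, phase_true_deg)`` where
    ``signal[n] = amplitude * cos(2*pi*f*n/fs + phase0)`` and the phase
    track is ``(360*f*n/fs + phase0) mod 360`` degrees.
    """
    if not fs > 0:
        raise ValueError(f"fs must be positive, got fs={fs}")
    if not duration_s > 0:
        raise ValueError(f"duration_s must be positive, got duration_s={duration_s}")
    if not 0 < f < fs / 2:
        raise ValueError(f"f must lie in (0, fs/2)=(0, {fs / 2}), got f={f}")
    n = np.arange(int(round(duration_s * fs)))
    phase_deg = (360.0 * f * n / fs + phase0_deg) % 360.0
    signal = amplitude * np.cos(np.deg2rad(360.0 * f * n / fs + phase0_deg))
    return signal, phase_deg


def gen_colored_noise(
    kind: str,
    n: int,
    scale: float = 1.0,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Zero-mean colored noise of length n, RMS-normalized to `scale` g.

    Pink noise (PSD ~ 1/f) is built by spectrally shaping white Gaussian
    noise with a 1/sqrt(f) amplitude mask; brown noise (PSD ~ 1/f^2) by
    cumulatively summing white noise. Both are mean-removed and scaled to
    the exact requested RMS.
    """
    if kind not in ("pink", "brown"):
        raise ValueError(
            f"unknown noise kind {kind!r}; allowed kinds are 'pink' and 'brown'"
        )
    if not n > 0:
        raise ValueError(f"n must be positive, got n={n}")
    if scale < 0:
        raise ValueError(f"scale must be non-negative, got scale={scale}")
    rng = np.random.default_rng(seed)
    if kind == "pink":
        white = rng.standard_normal(n)
        spectrum = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(n)
        mask = np.zeros_like(freqs)
        mask[1:] = 1.0 / np.sqrt(freqs[1:])
        x = np.fft.irfft(spectrum * mask, n)
    else:
        x = np.cumsum(rng.standard_normal(n))
    x = x - x.mean()
    if scale == 0:
        return np.zeros(n)
    rms = np.sqrt(np.mean(x**2))
    return x * (scale / rms)


@dataclass
class TremorScenario:
    """Parameters of one synthetic triaxial tremor recording.

    Per-axis amplitude envelopes and the center-frequency trajectory are
    piecewise-constant profiles (or callables of time); the oscillation is
    phase-continuous across frequency steps. Cessation intervals zero the
    oscillatory component on all axes, emulating tremor that stops.

    Attributes
    ----------
    duration_s : float
        Record length in seconds.
    fs : float
        Sampling rate in Hz (default 208.03, the device rate).
    envelopes : dict axis-name -> Profile
        Oscillation amplitude in g per axis; missing axes are silent.
    fc : Profile
        Center-frequency trajectory in Hz, within [2, 8].
    cessation : list of (start_s, end_s)
        Intervals where the oscillation amplitude is zero on all axes.
    dc_offset : dict axis-name -> float
        Constant offset in g per axis (gravity / sensor drift).
    noise_kind : {'none', 'pink', 'brown'}
    noise_scale : float
        Noise RMS in g (independent noise per axis).
    phase0_deg : dict axis-name -> float
        Initial oscillation phase per axis in degrees (default 0).
    seed : int
        Seed for the noise generator; regeneration is bit-identical.
    """

    duration_s: float
    fs: float = DEFAULT_FS
    envelopes: dict[str, Profile] = field(default_factory=dict)
    fc: Profile = 5.0
    cessation: list[tuple[float, float]] = field(default_factory=list)
    dc_offset: dict[str, float] = field(default_factory=dict)
    noise_kind: str = "none"
    noise_scale: float = 0.0
    phase0_deg: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if not self.duration_s > 0:
            raise ValueError(f"duration_s must be positive, got {self.duration_s}")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got fs={self.fs}")
        if self.noise_kind not in NOISE_KINDS:
            raise ValueError(
                f"noise_kind {self.noise_kind!r} not in {NOISE_KINDS}"
            )
        if self.noise_scale < 0:
            raise ValueError(f"noise_scale must be >= 0, got {self.noise_scale}")
        for ax in list(self.envelopes) + list(self.dc_offset) + list(self.phase0_deg):
            if ax not in AXES:
                raise ValueError(f"unknown axis {ax!r}; axes are {AXES}")
        for start, end in self.cessation:
            if not (0 <= start < end <= self.duration_s):
                raise ValueError(
                    f"cessation interval ({start}, {end}) outside "
                    f"[0, {self.duration_s}]"
                )
        t = np.arange(int(round(self.duration_s * self.fs))) / self.fs
        fc = _profile_values(self.fc, t)
        if fc.min() < FC_MIN or fc.max() > FC_MAX:
            raise ValueError(
                f"fc trajectory must stay within [{FC_MIN}, {FC_MAX}] Hz, "
                f"got range [{fc.min()}, {fc.max()}]"
            )
        if self.fs <= 2 * fc.max():
            raise ValueError(
                f"fs={self.fs} violates Nyquist for max fc={fc.max()}"
            )
        for ax, env in self.envelopes.items():
            if _profile_values(env, t).min() < 0:
                raise ValueError(f"envelope for axis {ax!r} is negative somewhere")


def gen_tremor_record(scenario: TremorScenario) -> TriaxialRecord:
    """Synthesize a triaxial tremor record with ground truth.

    Each axis is ``envelope(t) * cessation(t) * cos(phi(t) + phase0_axis)
    + dc + noise`` where ``phi(t)`` integrates the frequency trajectory
    (2*pi*cumsum(fc)/fs), so frequency steps create no phase jump. The true
    dominant axis at each sample is the axis with the largest instantaneous
    envelope (before cessation gating, so dominance is defined even while
    tremor is stopped).
    """
    scenario.validate()
    fs = scenario.fs
    n = int(round(scenario.duration_s * fs))
    t = np.arange(n) / fs

    fc = _profile_values(scenario.fc, t)
    # phase-continuous integration; phase at sample k reflects frequencies
    # of samples 0..k-1 so a constant-fc record matches the pure-sine track
    phi_deg = 360.0 * np.concatenate([[0.0], np.cumsum(fc[:-1])]) / fs

    gate = np.ones(n)
    for start, end in scenario.cessation:
        gate[(t >= start) & (t < end)] = 0.0

    envelopes = np.zeros((n, 3))
    for i, ax in enumerate(AXES):
        if ax in scenario.envelopes:
            envelopes[:, i] = _profile_values(scenario.envelopes[ax], t)

    rng = np.random.default_rng(scenario.seed)
    samples = np.zeros((n, 3))
    for i, ax in enumerate(AXES):
        phase0 = scenario.phase0_deg.get(ax, 0.0)
        osc = envelopes[:, i] * gate * np.cos(np.deg2rad(phi_deg + phase0))
        channel = osc + scenario.dc_offset.get(ax, 0.0)
        if scenario.noise_kind != "none" and scenario.noise_scale > 0:
            channel = channel + gen_colored_noise(
                scenario.noise_kind, n, scenario.noise_scale, rng
            )
        samples[:, i] = channel

    axis_true = np.argmax(envelopes, axis=1)
    return TriaxialRecord(
        samples=samples,
        fs=fs,
        phase_true_deg=phi_deg % 360.0,
        axis_true=axis_true,
        fc_true_hz=fc,
        meta={"seed": scenario.seed, "noise_kind": scenario.noise_kind,
              "noise_scale": scenario.noise_scale},
    )


def noisy_sine_record(
    f: float,
    noise_kind: str,
    snr: float = 3.0,
    duration_s: float = 60.0,
    fs: float = DEFAULT_FS,
    axis: str = "y",
    seed: int = 0,
) -> TriaxialRecord:
    """Single-axis unit sinusoid plus colored noise at a given SNR.

    SNR is the ratio of signal RMS to noise RMS, so the noise scale is
    ``(1/sqrt(2)) / snr`` g for a unit-amplitude tone. This is the noisy
    test oscillation used throughout the offline characterization suite.
    """
    if snr <= 0:
        raise ValueError(f"snr must be positive, got {snr}")
    scale = (1.0 / np.sqrt(2.0)) / snr
    scenario = TremorScenario(
        duration_s=duration_s,
        fs=fs,
        envelopes={axis: 1.0},
        fc=f,
        noise_kind=noise_kind,
        noise_scale=scale if noise_kind != "none" else 0.0,
        seed=seed,
    )
    return gen_tremor_record(scenario)
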