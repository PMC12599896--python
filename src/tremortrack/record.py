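"""Triaxial accelerometer records.

The core in-memory container shared by the signal generator, the tracking
bank, the stimulation protocol and the offline analysis: three acceleration
channels in units of g at a common sampling rate, with optional per-sample
ground-truth tracks (true oscillation phase, true dominant axis, true
center frequency) when the record was synthesized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

AXES = ("x", "y", "z")

#: Device sampling rate in Hz (accelerometer driver maximum).
DEFAULT_FS = 208.03


@dataclass
class TriaxialRecord:
    """Triaxial acceleration time series in g.

    Parameters
    ----------
    samples : (n, 3) float array
        Acceleration in g, columns ordered (x, y, z).
    fs : float
        Sampling rate in Hz.
    phase_true_deg : (n,) float array, optional
        True oscillation phase in degrees [0, 360), present for
        synthesized records.
    axis_true : (n,) integer array, optional
        True dominant axis index (0=x, 1=y, 2=z).
    fc_true_hz : (n,) float array, optional
        True instantaneous center frequency in Hz.
    meta : dict
        Free-form provenance (scenario parameters, seed).
    """

    samples: np.ndarray
    fs: float = DEFAULT_FS
    phase_true_deg: np.ndarray | None = None
    axis_true: np.ndarray | None = None
    fc_true_hz: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError(
                f"samples must be (n, 3), got shape {self.samples.shape}"
            )
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        n = len(self.samples)
        for name in ("phase_true_deg", "axis_true", "fc_true_hz"):
            track = getattr(self, name)
            if track is not None:
                track = np.asarray(track)
                if len(track) != n:
                    raise ValueError(
                        f"{name} has length {len(track)}, expected {n}"
                    )
                setattr(self, name, track)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def time_s(self) -> np.ndarray:
        """Sample times in seconds (0-based index / fs)."""
        return np.arange(self.n_samples) / self.fs

    @property
    def has_truth(self) -> bool:
        return self.phase_true_deg is not None

    def axis(self, which: int | str) -> np.ndarray:
        """One channel by index or by name ('x', 'y', 'z')."""
        if isinstance(which, str):
            which = AXES.index(which)
        return self.samples[:, which]
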