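"""Offset removal and the offline band-pass.

The tracker assumes a zero-centered input; accelerometer channels carry a
DC shift from gravity, temperature and mechanical wear. On-device each
channel is run through a causal second-order Butterworth high-pass
(cutoff 0.1 Hz) evaluated in second-order sections, sample by sample. The
1-9 Hz zero-phase (forward-backward) band-pass lives here too but is used
only by the offline oracle, never on the streaming path.

Coefficients are designed at construction (bilinear-transform Butterworth)
for whatever sampling rate is in use, rather than hard-coded for 208.03 Hz.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as _signal


class StreamingFilter:
    """Causal IIR filter in second-order sections with streaming state.

    Processing a signal one sample at a time (`step`) is identical to
    processing it in one call (`process`); both advance the same internal
    per-section delay state, so the filter can be fed from a live sample
    loop or from a batch array interchangeably.
    """

    def __init__(self, sos: np.ndarray, fs: float, design: dict | None = None):
        self.sos = np.atleast_2d(np.asarray(sos, dtype=float))
        if self.sos.shape[1] != 6:
            raise ValueError(f"sos must be (n_sections, 6), got {self.sos.shape}")
        self.fs = float(fs)
        self.design = dict(design or {})
        self.reset()

    def reset(self) -> None:
        """Zero the delay state (firmware power-on condition)."""
        self.zi = np.zeros((self.sos.shape[0], 2))

    def step(self, sample: float) -> float:
        """Filter one sample and advance the state."""
        if not np.isfinite(sample):
            raise ValueError(
                f"non-finite input sample {sample!r} (sensor fault?)"
            )
        out, self.zi = _signal.sosfilt(self.sos, np.array([float(sample)]), zi=self.zi)
        return float(out[0])

    def process(self, x: np.ndarray) -> np.ndarray:
        """Filter a batch of samples, advancing the same state."""
        x = np.asarray(x, dtype=float)
        if not np.all(np.isfinite(x)):
            bad = int(np.flatnonzero(~np.isfinite(x))[0])
            raise ValueError(f"non-finite input at sample {bad} (sensor fault?)")
        out, self.zi = _signal.sosfilt(self.sos, x, zi=self.zi)
        return out

    def copy(self) -> "StreamingFilter":
        new = StreamingFilter(self.sos.copy(), self.fs, self.design)
        new.zi = self.zi.copy()
        return new


def make_highpass(fs: float, cutoff: float = 0.1, order: int = 2) -> StreamingFilter:
    """Streaming Butterworth high-pass for DC/offset removal.

    Default matches the on-device design: order 2, cutoff 0.1 Hz. The
    numerator has its zeros at z=1, so DC is rejected exactly.
    """
    if not 0 < cutoff < fs / 2:
        raise ValueError(
            f"cutoff must lie in (0, fs/2)=(0, {fs / 2}), got cutoff={cutoff}"
        )
    sos = _signal.butter(order, cutoff, btype="highpass", fs=fs, output="sos")
    return StreamingFilter(
        sos, fs, design={"type": "highpass", "order": order, "cutoff_hz": cutoff}
    )


def offline_bandpass(
    x: np.ndarray,
    fs: float,
    low: float = 1.0,
    high: float = 9.0,
    order: int = 2,
) -> np.ndarray:
    """Zero-phase band-pass (forward-backward Butterworth), oracle-only.

    Applies the order-`order` band-pass once forward and once backward
    (zero net phase shift, squared magnitude response). Same length out
    as in.
    """
    x = np.asarray(x, dtype=float)
    if not 0 < low < high < fs / 2:
        raise ValueError(
            f"need 0 < low < high < fs/2, got low={low}, high={high}, fs={fs}"
        )
    sos = _signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    # default filtfilt padding: 3 * (2*order + 1) samples on each side
    padlen = 3 * (2 * sos.shape[0] * 2 + 1)
    if len(x) <= padlen:
        raise ValueError(
            f"signal of {len(x)} samples too short for zero-phase filtering "
            f"(needs > {padlen})"
        )
    return _signal.sosfiltfilt(sos, x)
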