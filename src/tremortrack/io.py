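"""File formats: records, scenario configs and result tables.

Records are plain CSV (the device's flash log stands in as text): a
metadata comment line carrying the sampling rate, then a header and one
row per sample with a strictly increasing 0-based ``sample_index``, the
three acceleration channels in g, and — for synthesized records — the
ground-truth columns. Values are written with Python's shortest exact
decimal representation so a write-read round trip is bit-exact.

Scenario configurations are YAML; every artifact table embeds the
producing configuration and seed as ``# key=value`` comment lines.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .record import AXES, TriaxialRecord
from .signals import TremorScenario

_RECORD_COLUMNS = ["sample_index", "ax_g", "ay_g", "az_g"]
_TRUTH_COLUMNS = ["phase_true_deg", "axis_true", "fc_true_hz"]


def _meta_lines(meta: dict) -> str:
    return "".join(f"# {k}={v}\n" for k, v in meta.items())


def write_record(record: TriaxialRecord, path: str | Path) -> None:
    """Write a record as CSV with an fs metadata line and optional truth."""
    df = pd.DataFrame({
        "sample_index": np.arange(record.n_samples),
        "ax_g": record.samples[:, 0],
        "ay_g": record.samples[:, 1],
        "az_g": record.samples[:, 2],
    })
    if record.has_truth:
        df["phase_true_deg"] = record.phase_true_deg
        df["axis_true"] = [AXES[i] for i in record.axis_true]
        df["fc_true_hz"] = record.fc_true_hz
    meta = {"fs_hz": repr(float(record.fs))}
    meta.update({k: v for k, v in record.meta.items()
                 if isinstance(v, (str, int, float))})
    with open(path, "w") as fh:
        fh.write(_meta_lines(meta))
        df.to_csv(fh, index=False)


def read_record(path: str | Path) -> TriaxialRecord:
    """Read a record CSV; validates the index and sample finiteness."""
    path = Path(path)
    meta: dict = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for line in lines:
        if not line.startswith("#"):
            break
        body_start += 1
        key, _, value = line[1:].strip().partition("=")
        meta[key.strip()] = value.strip()
    if "fs_hz" not in meta:
        raise ValueError(f"{path}: missing '# fs_hz=...' metadata line")
    fs = float(meta.pop("fs_hz"))
    df = pd.read_csv(
        _io.StringIO("".join(lines[body_start:])), float_precision="round_trip"
    )
    missing = [c for c in _RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")

    idx = df["sample_index"].to_numpy()
    expected = np.arange(len(df))
    if len(idx) and not np.array_equal(idx, expected):
        bad = int(np.flatnonzero(idx != expected)[0])
        # +2 for the header line, +1 for 1-based lines, + metadata lines
        raise ValueError(
            f"{path}: sample_index not 0-based contiguous at data row {bad} "
            f"(file line {body_start + 2 + bad})"
        )
    samples = df[["ax_g", "ay_g", "az_g"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(samples)):
        bad = int(np.flatnonzero(~np.all(np.isfinite(samples), axis=1))[0])
        raise ValueError(
            f"{path}: non-finite acceleration at data row {bad} "
            f"(file line {body_start + 2 + bad})"
        )
    kwargs = {}
    if all(c in df.columns for c in _TRUTH_COLUMNS):
        kwargs["phase_true_deg"] = df["phase_true_deg"].to_numpy(dtype=float)
        kwargs["axis_true"] = np.array(
            [AXES.index(a) for a in df["axis_true"]], dtype=int
        )
        kwargs["fc_true_hz"] = df["fc_true_hz"].to_numpy(dtype=float)
    return TriaxialRecord(samples=samples, fs=fs, meta=meta, **kwargs)


def write_table(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    """Write a result table as CSV with provenance comment lines."""
    with open(path, "w") as fh:
        if meta:
            fh.write(_meta_lines(meta))
        df.to_csv(fh, index=False)


def load_scenario(path: str | Path) -> TremorScenario:
    """Load a tremor scenario from a YAML config file.

    Keys mirror :class:`~tremortrack.signals.TremorScenario`; piecewise
    profiles are written as lists of ``[start_s, value]`` pairs, e.g.::

        duration_s: 120
        envelopes:
          y: 0.3
          x: [[0, 0.0], [30, 0.6]]
        fc: 4
        noise_kind: pink
        noise_scale: 0.05
        seed: 7
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: scenario config must be a mapping")

    def profile(v):
        if isinstance(v, list):
            return [tuple(pair) for pair in v]
        return float(v)

    kwargs = dict(raw)
    if "envelopes" in kwargs:
        kwargs["envelopes"] = {ax: profile(v) for ax, v in kwargs["envelopes"].items()}
    if "fc" in kwargs:
        kwargs["fc"] = profile(kwargs["fc"])
    if "cessation" in kwargs:
        kwargs["cessation"] = [tuple(iv) for iv in kwargs["cessation"]]
    scenario = TremorScenario(**kwargs)
    scenario.validate()
    return scenario
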