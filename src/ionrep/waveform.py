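"""Sampled time-series container with a declared interpolation rule.

Waveforms carry V(t), [Ca2+]_i(t), f/f0(t) or [ATP]_o(t) traces: strictly
increasing sample times in ms, values, and a unit tag.  Evaluation between
samples is linear interpolation (constant extrapolation at the ends).  I/O
is two-column delimited text with a one-line ``# unit:`` header.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

VALID_UNITS = ("mV", "nM", "uM", "dimensionless", "pA")


@dataclass
class Waveform:
    times: np.ndarray
    values: np.ndarray
    unit: str = "dimensionless"
    _interp_cache: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.size < 2:
            raise ValueError("waveform needs at least 2 samples")
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same shape")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("sample times must be strictly increasing")
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unit must be one of {VALID_UNITS}")

    @property
    def t0(self) -> float:
        return float(self.times[0])

    @property
    def t1(self) -> float:
        return float(self.times[-1])

    @property
    def duration(self) -> float:
        return self.t1 - self.t0

    def __len__(self) -> int:
        return self.times.size

    def __call__(self, t):
        """Linear interpolation; constant beyond the recorded span."""
        return np.interp(t, self.times, self.values)

    def restricted(self, t0: float, t1: float) -> "Waveform":
        mask = (self.times >= t0) & (self.times <= t1)
        return Waveform(self.times[mask], self.values[mask], self.unit)

    def resampled(self, times: np.ndarray) -> "Waveform":
        times = np.asarray(times, dtype=float)
        return Waveform(times, self(times), self.unit)

    # ------------------------------------------------------------------ I/O

    def to_text(self, path) -> None:
        header = f"# unit: {self.unit}\n# columns: time_ms\tvalue\n"
        body = "\n".join(f"{float(t)!r}\t{float(v)!r}" for t, v in zip(self.times, self.values))
        Path(path).write_text(header + body + "\n")

    @classmethod
    def from_text(cls, path) -> "Waveform":
        unit = "dimensionless"
        times, values = [], []
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "unit:" in line:
                    unit = line.split("unit:")[1].strip()
                continue
            parts = line.replace(",", "\t").split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {line!r}")
            try:
                times.append(float(parts[0]))
                values.append(float(parts[1]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
        return cls(np.array(times), np.array(values), unit)


def common_span(*waveforms: Waveform) -> tuple[float, float]:
    """Overlapping time span of several waveforms; error if disjoint."""
    t0 = max(w.t0 for w in waveforms)
    t1 = min(w.t1 for w in waveforms)
    if t1 <= t0:
        raise ValueError("waveforms have disjoint time spans")
    return t0, t1


def read_recording(path, time_col=0, voltage_col=1, calcium_col=2,
                   time_unit="ms", calcium_unit="nM") -> tuple[Waveform, Waveform]:
    """Import a paired voltage/calcium recording from a delimited table.

    Covers the spreadsheet layout of typical acquisition exports
    (time, voltage, calcium-or-fluorescence columns); the column map is
    configurable.  ``calcium_unit`` of ``dimensionless`` tags the third
    column as an f/f0 fluorescence trace.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#", header=None,
                     skiprows=_count_header_rows(path))
    t = df.iloc[:, time_col].to_numpy(float)
    if time_unit == "s":
        t = t * 1e3
    v = Waveform(t, df.iloc[:, voltage_col].to_numpy(float), "mV")
    ca = Waveform(t, df.iloc[:, calcium_col].to_numpy(float), calcium_unit)
    return v, ca


def _count_header_rows(path) -> int:
    n = 0
    with open(path) as fh:
        for line in fh:
            token = line.split(",")[0].split("\t")[0].strip()
            try:
                float(token)
                return n
            except ValueError:
                n += 1
    return n
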