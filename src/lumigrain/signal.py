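"""Uniformly sampled photon-count time series and its CSV representation."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["DLSignal", "read_signal_csv", "write_signal_csv"]


@dataclass
class DLSignal:
    """A delayed-luminescence trace: photon counts per bin on a uniform time grid.

    Parameters
    ----------
    times
        Bin start times in seconds, strictly increasing with constant step.
    values
        Counts (or counts-equivalent real values) per bin.
    dt
        Sampling interval in seconds.
    meta
        Free-form provenance tags (class label, generator parameters, ...).
    """

    times: np.ndarray
    values: np.ndarray
    dt: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise ValueError("times and values must be 1-D")
        if self.times.size != self.values.size:
            raise ValueError("times and values must have equal length")
        if self.times.size < 1:
            raise ValueError("signal must contain at least one sample")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.times.size > 1:
            steps = np.diff(self.times)
            if np.any(steps <= 0) or not np.allclose(steps, self.dt, rtol=1e-9, atol=1e-12):
                raise ValueError("times must increase with constant step dt")

    def __len__(self) -> int:
        return self.values.size

    def with_values(self, values: np.ndarray, **extra_meta) -> "DLSignal":
        """Return a copy sharing the time grid but holding new values."""
        meta = dict(self.meta)
        meta.update(extra_meta)
        return DLSignal(self.times.copy(), np.asarray(values, dtype=float), self.dt, meta)


def read_signal_csv(path: str | Path) -> DLSignal:
    """Load a two-column ``time_s,counts`` CSV into a :class:`DLSignal`."""
    df = pd.read_csv(path)
    if not {"time_s", "counts"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns 'time_s' and 'counts'")
    times = df["time_s"].to_numpy(dtype=float)
    if times.size < 2:
        raise ValueError(f"{path}: need at least two rows to infer dt")
    dt = float(times[1] - times[0])
    return DLSignal(times, df["counts"].to_numpy(dtype=float), dt, {"source": str(path)})


def write_signal_csv(signal: DLSignal, path: str | Path) -> None:
    """Write a signal as a two-column ``time_s,counts`` CSV with header."""
    pd.DataFrame({"time_s": signal.times, "counts": signal.values}).to_csv(path, index=False)
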