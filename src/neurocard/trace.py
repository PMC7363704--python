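"""One-dimensional time series container shared by all analyzers."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class Trace:
    """A uniformly sampled signal (intensity, correlation, ...).

    values : length-T array; sample_rate in Hz; t0 = time of first sample.
    """

    values: np.ndarray
    sample_rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("a Trace needs at least 2 samples")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.sample_rate

    @property
    def duration(self) -> float:
        return self.values.size / self.sample_rate

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        pd.DataFrame({"time_s": self.times, "value": self.values}).to_csv(
            path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "Trace":
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy()
        if t.size < 2:
            raise ValueError("trace CSV needs at least 2 rows")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("trace CSV must be uniformly sampled")
        return cls(values=df["value"].to_numpy(),
                   sample_rate=1.0 / float(dt[0]), t0=float(t[0]))
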