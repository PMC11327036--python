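"""Core container for a single sampled signal.

Every operation in this package works on a :class:`TimeSeries`: a 1-D float
array of observations taken at a fixed sampling interval (the repetition
time, TR, in seconds).  Short-TR fMRI runs sit around TR = 0.5 s, long-TR
runs around TR = 2.5 s; the TR matters because lag-based settings (maximum
AR order, portmanteau lag range, window widths) are specified in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class TimeSeries:
    """One observed signal ``y(t)`` of length ``T`` with its TR in seconds."""

    values: np.ndarray
    tr: float = 1.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1:
            raise ValueError(f"TimeSeries values must be 1-D, got shape {arr.shape}")
        if arr.size < 1:
            raise ValueError("TimeSeries must contain at least one observation")
        if not np.all(np.isfinite(arr)):
            raise ValueError("TimeSeries values must be finite")
        if not self.tr > 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        object.__setattr__(self, "values", arr)

    @property
    def n(self) -> int:
        """Number of observations ``T``."""
        return self.values.size

    def demeaned(self) -> np.ndarray:
        return self.values - self.values.mean()

    def is_constant(self, rtol: float = 1e-12) -> bool:
        v = self.values
        return bool(np.ptp(v) <= rtol * max(1.0, abs(v[0])))

    def with_values(self, values: np.ndarray) -> "TimeSeries":
        return TimeSeries(np.asarray(values, dtype=float), self.tr)
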