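"""Uniformly sampled signal container and plain-CSV I/O.

A :class:`Trace` holds one device signal — airflow, integrated volume, or
thoraco-abdominal (TA) wall displacement — as a uniformly sampled array with
a sampling rate and a start time.  Traces are written and read as two-column
CSV (``time_s,value``) so recordings round-trip through plain text.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = ["Trace"]

# relative tolerance on sample-interval uniformity when reading CSV
_UNIFORMITY_RTOL = 1e-4


@dataclass
class Trace:
    """One uniformly sampled device signal.

    Parameters
    ----------
    values
        Signal samples (finite floats).
    fs
        Sampling rate in Hz (> 0).
    t0
        Time of the first sample in seconds.
    label
        What the signal is, e.g. ``"pnt_flow"`` or ``"slp_displacement"``.
    units
        Physical units of the samples, e.g. ``"L/s"`` or ``"au"``.
    """

    values: np.ndarray
    fs: float
    t0: float = 0.0
    label: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise DataError("trace values must be one-dimensional")
        if not self.fs > 0:
            raise DataError(f"sampling rate must be positive, got {self.fs}")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise DataError(f"trace {self.label!r} contains non-finite samples")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.values.size) / self.fs

    @property
    def duration(self) -> float:
        """Span from first to last sample in seconds."""
        return max(self.values.size - 1, 0) / self.fs

    def crop(self, t_start: float, t_end: float) -> "Trace":
        """Return the sub-trace with sample times in ``[t_start, t_end]``."""
        if t_end <= t_start:
            raise DataError("crop window is empty")
        t = self.times
        mask = (t >= t_start - 1e-12) & (t <= t_end + 1e-12)
        if not mask.any():
            raise DataError("crop window contains no samples")
        idx = np.nonzero(mask)[0]
        return replace(self, values=self.values[idx[0] : idx[-1] + 1], t0=t[idx[0]])

    def with_values(self, values: np.ndarray) -> "Trace":
        return replace(self, values=np.asarray(values, dtype=float))

    # ------------------------------------------------------------------ I/O

    def to_csv(self, path: str | Path) -> None:
        """Write as two-column CSV ``time_s,value``."""
        pd.DataFrame({"time_s": self.times, "value": self.values}).to_csv(
            path, index=False, float_format="%.9g"
        )

    @classmethod
    def from_csv(
        cls, path: str | Path, label: str = "", units: str = ""
    ) -> "Trace":
        """Read a two-column CSV, validating uniform sampling.

        Raises
        ------
        DataError
            If the file is missing columns, has fewer than two samples, or
            the time stamps are not uniformly spaced (e.g. a gap).
        """
        df = pd.read_csv(path)
        if not {"time_s", "value"}.issubset(df.columns):
            raise DataError(f"{path}: expected columns time_s,value")
        t = df["time_s"].to_numpy(dtype=float)
        v = df["value"].to_numpy(dtype=float)
        if t.size < 2:
            raise DataError(f"{path}: need at least two samples")
        dt = np.diff(t)
        if dt.min() <= 0:
            raise DataError(f"{path}: time stamps not strictly increasing")
        if (dt.max() - dt.min()) > _UNIFORMITY_RTOL * dt.mean():
            raise DataError(f"{path}: non-uniform sampling (gap or jitter in time_s)")
        return cls(values=v, fs=1.0 / dt.mean(), t0=t[0], label=label, units=units)
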