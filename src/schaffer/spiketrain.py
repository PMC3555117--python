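"""Spike-train container and plain-text spike-time file I/O.

Event times are stored internally in milliseconds (the unit of the synapse
and neuron dynamics); spike-time files on disk hold one event time per row
in seconds, which is the convention of the upstream recordings this package
emulates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpikeTrain", "read_spike_file", "write_spike_file"]


@dataclass(frozen=True)
class SpikeTrain:
    """An ordered set of event times with duration metadata.

    Parameters
    ----------
    times_ms : array-like
        Strictly increasing event times in milliseconds, all within
        ``[0, duration_ms)``.
    duration_ms : float
        Length of the observation window in milliseconds.
    """

    times_ms: np.ndarray
    duration_ms: float

    def __post_init__(self) -> None:
        times = np.asarray(self.times_ms, dtype=float)
        object.__setattr__(self, "times_ms", times)
        if self.duration_ms <= 0:
            raise ValueError("duration must be positive")
        if times.size:
            if times[0] < 0:
                raise ValueError("negative event time")
            if np.any(np.diff(times) <= 0):
                raise ValueError("event times must be strictly increasing")
            if times[-1] >= self.duration_ms:
                raise ValueError("event time beyond train duration")

    @classmethod
    def from_seconds(cls, times_s, duration_s: float) -> "SpikeTrain":
        return cls(np.asarray(times_s, dtype=float) * 1000.0, duration_s * 1000.0)

    @property
    def n(self) -> int:
        return int(self.times_ms.size)

    @property
    def times_s(self) -> np.ndarray:
        return self.times_ms / 1000.0

    @property
    def duration_s(self) -> float:
        return self.duration_ms / 1000.0

    def isis_ms(self) -> np.ndarray:
        """Inter-spike intervals in milliseconds (length ``n - 1``)."""
        return np.diff(self.times_ms)


def read_spike_file(path, duration_s: float | None = None, header: bool = False) -> SpikeTrain:
    """Read a plain-text spike-time file (one time per row, seconds).

    Parameters
    ----------
    path : str or Path
        File to read.
    duration_s : float, optional
        Observation window. When omitted, the next whole second after the
        last event is used.
    header : bool
        Skip the first row (tolerate a column header).

    Raises
    ------
    ValueError
        Non-numeric, negative, or non-increasing entries; the error names
        the offending line.
    """
    times = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or (header and lineno == 1):
                continue
            try:
                t = float(line.split(",")[0])
            except ValueError:
                raise ValueError(f"{path}: non-numeric entry on line {lineno}: {line!r}") from None
            if t < 0:
                raise ValueError(f"{path}: negative spike time on line {lineno}")
            if times and t <= times[-1]:
                raise ValueError(f"{path}: spike times not strictly increasing at line {lineno}")
            times.append(t)
    arr = np.asarray(times, dtype=float)
    if duration_s is None:
        duration_s = float(np.floor(arr[-1]) + 1.0) if arr.size else 1.0
    return SpikeTrain.from_seconds(arr, duration_s)


def write_spike_file(train: SpikeTrain, path) -> None:
    """Write a spike train as one time (seconds, microsecond precision) per row."""
    with open(path, "w") as fh:
        for t in train.times_s:
            fh.write(f"{t:.6f}\n")
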