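"""Core time-series containers shared by every stage of the pipeline.

A :class:`Recording` is a uniformly sampled 1-D signal with explicit sampling
rate and unit metadata; a :class:`SubjectDataset` is the time-aligned triplet
of neural / trajectory (/ optional EMG) recordings for one subject.
:class:`IntervalSet` holds movement periods as half-open ``[start, end)``
intervals in seconds, and :class:`WindowSpec` describes the sliding windows
used by the quality metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Recording",
    "SubjectDataset",
    "IntervalSet",
    "WindowSpec",
    "ParameterError",
    "DataError",
]


class ParameterError(ValueError):
    """An argument violates a documented precondition."""


class DataError(ValueError):
    """Input data are structurally unusable (too short, flat, missing)."""


@dataclass
class Recording:
    """Uniformly sampled 1-D signal.

    Parameters
    ----------
    samples : ndarray
        The signal values. Stored as float64.
    fs_hz : float
        Sampling rate in Hz, > 0.
    unit : str
        ``"uV"`` for neural/EMG voltage, ``"mm"`` or ``"normalized"`` for
        whisker trajectories.
    kind : str
        One of ``"neural"``, ``"emg"``, ``"trajectory"``.
    """

    samples: np.ndarray
    fs_hz: float
    unit: str = "uV"
    kind: str = "neural"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ParameterError("Recording samples must be 1-D")
        if self.samples.size < 1:
            raise ParameterError("Recording must contain at least one sample")
        if not np.isfinite(self.samples).all():
            raise DataError("Recording contains non-finite samples")
        if self.fs_hz <= 0:
            raise ParameterError(f"fs_hz must be positive, got {self.fs_hz}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs_hz

    def replace(self, samples: np.ndarray, **meta) -> "Recording":
        """New Recording with the same metadata but different samples."""
        kw = dict(fs_hz=self.fs_hz, unit=self.unit, kind=self.kind)
        kw.update(meta)
        return Recording(np.asarray(samples, dtype=np.float64), **kw)

    def slice_s(self, start_s: float, end_s: float) -> "Recording":
        """Samples in the half-open time interval [start_s, end_s)."""
        i0 = int(np.floor(start_s * self.fs_hz))
        i1 = int(np.floor(end_s * self.fs_hz))
        i0 = max(i0, 0)
        return self.replace(self.samples[i0:i1])


@dataclass
class SubjectDataset:
    """Time-aligned neural + trajectory (+ optional EMG) recordings.

    ``ground_truth_latency_ms`` is only set for synthetic subjects, so that
    alignment operations can be validated against the injected lag.
    """

    subject_id: str
    neural: Recording
    trajectory: Recording
    emg: Optional[Recording] = None
    ground_truth_latency_ms: Optional[float] = None

    def __post_init__(self) -> None:
        ratio = self.neural.fs_hz / self.trajectory.fs_hz
        if abs(ratio - round(ratio)) > 1e-9:
            raise ParameterError(
                "neural fs must be an integer multiple of trajectory fs "
                f"(got {self.neural.fs_hz} / {self.trajectory.fs_hz})"
            )
        # durations must agree to within one trajectory sample
        if abs(self.neural.duration_s - self.trajectory.duration_s) > 1.0 / self.trajectory.fs_hz:
            raise ParameterError("neural and trajectory durations disagree")

    @property
    def stride(self) -> int:
        """Neural samples per trajectory sample (the streaming stride)."""
        return int(round(self.neural.fs_hz / self.trajectory.fs_hz))

    @property
    def duration_s(self) -> float:
        return self.trajectory.duration_s

    def slice_s(self, start_s: float, end_s: float) -> "SubjectDataset":
        return SubjectDataset(
            subject_id=self.subject_id,
            neural=self.neural.slice_s(start_s, end_s),
            trajectory=self.trajectory.slice_s(start_s, end_s),
            emg=self.emg.slice_s(start_s, end_s) if self.emg is not None else None,
            ground_truth_latency_ms=self.ground_truth_latency_ms,
        )


@dataclass
class IntervalSet:
    """Sorted, disjoint, half-open intervals ``[start_s, end_s)`` in seconds."""

    intervals: Sequence[Tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        iv = [(float(a), float(b)) for a, b in self.intervals]
        iv.sort()
        for a, b in iv:
            if not b > a:
                raise ParameterError(f"interval end must exceed start: ({a}, {b})")
        for (a0, b0), (a1, b1) in zip(iv, iv[1:]):
            if a1 < b0:
                raise ParameterError("intervals overlap")
        self.intervals = iv

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[Tuple[float, float]]:
        return iter(self.intervals)

    @property
    def total_s(self) -> float:
        return sum(b - a for a, b in self.intervals)

    def complement(self, duration_s: float) -> "IntervalSet":
        """Intervals covering [0, duration_s) not covered by this set."""
        out = []
        cursor = 0.0
        for a, b in self.intervals:
            if a > cursor:
                out.append((cursor, min(a, duration_s)))
            cursor = max(cursor, b)
        if cursor < duration_s:
            out.append((cursor, duration_s))
        return IntervalSet([(a, b) for a, b in out if b > a])

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.intervals, columns=["start_s", "end_s"]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "IntervalSet":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(list(zip(df["start_s"], df["end_s"])))


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: ``width_s`` wide, ``overlap_s`` shared between
    consecutive windows (so the hop is ``width_s - overlap_s``)."""

    width_s: float
    overlap_s: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.overlap_s < self.width_s):
            raise ParameterError(
                f"need 0 <= overlap < width, got overlap={self.overlap_s}, width={self.width_s}"
            )

    @property
    def hop_s(self) -> float:
        return self.width_s - self.overlap_s

    def n_windows(self, duration_s: float) -> int:
        """Number of full windows that fit in ``duration_s`` seconds."""
        if duration_s < self.width_s:
            return 0
        return int(np.floor((duration_s - self.width_s) / self.hop_s)) + 1

    def starts_s(self, duration_s: float) -> np.ndarray:
        return np.arange(self.n_windows(duration_s)) * self.hop_s

    def centers_s(self, duration_s: float) -> np.ndarray:
        return self.starts_s(duration_s) + self.width_s / 2.0
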