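"""Shared containers and interval utilities.

Conventions used throughout the package (enforced by the validators here):
all times are seconds as floats on one session clock, all intervals are
half-open ``[start, end)``, and bin indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GroomingBouts",
    "SpikeData",
    "BinnedActivity",
    "interval_intersection_length",
    "interval_union_length",
]


@dataclass(frozen=True)
class GroomingBouts:
    """Ordered, non-overlapping half-open grooming intervals in seconds."""

    intervals: np.ndarray  # shape (n, 2): columns start_s, end_s

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "intervals", iv)
        if len(iv):
            if not np.all(iv[:, 1] > iv[:, 0]):
                raise ValueError("every bout must satisfy end > start")
            if not np.all(np.diff(iv[:, 0]) >= 0):
                raise ValueError("bouts must be sorted by start time")
            if np.any(iv[1:, 0] < iv[:-1, 1]):
                raise ValueError("bouts must not overlap")

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(map(tuple, self.intervals))

    @property
    def starts(self) -> np.ndarray:
        return self.intervals[:, 0]

    @property
    def ends(self) -> np.ndarray:
        return self.intervals[:, 1]

    @property
    def durations(self) -> np.ndarray:
        return self.intervals[:, 1] - self.intervals[:, 0]

    def total_time(self) -> float:
        """Summed bout time in seconds."""
        return float(self.durations.sum()) if len(self) else 0.0

    def inter_bout_intervals(self) -> np.ndarray:
        """Gaps (s) between the end of each bout and the start of the next."""
        if len(self) < 2:
            return np.empty(0)
        return self.intervals[1:, 0] - self.intervals[:-1, 1]

    @classmethod
    def from_pairs(cls, pairs) -> "GroomingBouts":
        return cls(np.asarray(list(pairs), dtype=float).reshape(-1, 2))

    @classmethod
    def empty(cls) -> "GroomingBouts":
        return cls(np.empty((0, 2)))


@dataclass
class SpikeData:
    """Per-unit spike timestamps for one session.

    ``times[i]`` is a sorted float array of spike times (s) for ``unit_ids[i]``.
    ``positions`` is an optional (n_units, 2) array of (shank x, depth) in um.
    """

    unit_ids: np.ndarray
    times: list
    duration_s: float
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.unit_ids = np.asarray(self.unit_ids)
        if len(self.unit_ids) != len(self.times):
            raise ValueError("unit_ids and times length mismatch")
        if self.duration_s <= 0:
            raise ValueError("session duration must be positive")
        self.times = [np.asarray(t, dtype=float) for t in self.times]
        for t in self.times:
            if len(t) and (t.min() < 0 or t.max() > self.duration_s):
                raise ValueError("spike times must lie within [0, duration_s]")

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    def mean_rates(self) -> np.ndarray:
        """Mean firing rate per unit over the entire session (Hz)."""
        return np.array([len(t) for t in self.times]) / self.duration_s

    def subset(self, mask_or_idx) -> "SpikeData":
        idx = np.arange(self.n_units)[mask_or_idx]
        pos = self.positions[idx] if self.positions is not None else None
        return SpikeData(
            self.unit_ids[idx], [self.times[i] for i in idx], self.duration_s, pos
        )


@dataclass
class BinnedActivity:
    """Units x time-bins matrix of spike counts with its binning metadata."""

    unit_ids: np.ndarray
    bin_size_s: float
    bin_start_times_s: np.ndarray
    counts: np.ndarray  # units x bins
    normalization: str = "raw_counts"
    bin_widths_s: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.unit_ids), len(self.bin_start_times_s)):
            raise ValueError("counts shape must be (n_units, n_bins)")
        if self.normalization == "raw_counts" and not np.issubdtype(
            self.counts.dtype, np.integer
        ):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("raw counts must be integral")
        if np.any(self.counts < 0) and self.normalization == "raw_counts":
            raise ValueError("raw counts must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]


def _as_interval_array(intervals) -> np.ndarray:
    if isinstance(intervals, GroomingBouts):
        return intervals.intervals
    return np.asarray(intervals, dtype=float).reshape(-1, 2)


def interval_intersection_length(a, b) -> float:
    """Total length of the intersection of two sets of sorted disjoint intervals."""
    a, b = _as_interval_array(a), _as_interval_array(b)
    total, i, j = 0.0, 0, 0
    while i < len(a) and j < len(b):
        lo = max(a[i, 0], b[j, 0])
        hi = min(a[i, 1], b[j, 1])
        if hi > lo:
            total += hi - lo
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    return total


def interval_union_length(a, b) -> float:
    """Total length of the union of two sets of sorted disjoint intervals."""
    a, b = _as_interval_array(a), _as_interval_array(b)
    la = float(np.sum(a[:, 1] - a[:, 0])) if len(a) else 0.0
    lb = float(np.sum(b[:, 1] - b[:, 0])) if len(b) else 0.0
    return la + lb - interval_intersection_length(a, b)
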