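"""Shared in-memory containers for traces, idealized records and assay data.

Units are fixed throughout the package: current in pA, time in s,
substrate in uM, free Mg2+ in mM, rates in s^-1.  Conversions happen at
I/O boundaries only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "Trace",
    "IdealizedRecord",
    "DwellTable",
    "AssaySeries",
]


@dataclass
class Trace:
    """A uniformly sampled current recording.

    Parameters
    ----------
    samples : array of current values, pA.
    sampling_rate : acquisition rate, Hz.
    filter_cutoff : -3 dB frequency of the last low-pass applied, Hz,
        or None for an unfiltered trace.
    metadata : free-form provenance (seed, generating preset, units).
    """

    samples: np.ndarray
    sampling_rate: float
    filter_cutoff: float | None = None
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a nonempty 1-D array")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate


@dataclass
class IdealizedRecord:
    """Event-list representation of a record: runs of constant level.

    ``levels[i]`` counts simultaneously open channels during event *i*
    (nonnegative, regardless of current polarity); ``durations[i]`` is
    its length in seconds.  Adjacent events always differ in level.
    """

    levels: np.ndarray
    durations: np.ndarray
    dead_time: float | None = None

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=int)
        self.durations = np.asarray(self.durations, dtype=float)
        if self.levels.shape != self.durations.shape or self.levels.ndim != 1:
            raise ValueError("levels and durations must be 1-D and equal length")
        if self.levels.size and np.any(self.durations <= 0):
            raise ValueError("event durations must be positive")
        if self.levels.size and np.any(self.levels < 0):
            raise ValueError("levels must be nonnegative")
        if np.any(self.levels[1:] == self.levels[:-1]):
            raise ValueError("adjacent events must have different levels")

    @property
    def n_events(self) -> int:
        return int(self.levels.size)

    @property
    def n_levels_seen(self) -> int:
        return int(np.unique(self.levels).size) if self.levels.size else 0

    @property
    def total_duration(self) -> float:
        return float(self.durations.sum())

    @property
    def start_times(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum(self.durations)[:-1]])


@dataclass
class DwellTable:
    """Per-conductance-level dwell-time collections.

    ``dwells[l]`` holds the uncensored sojourn durations observed at
    level *l* (record-edge events excluded); ``occupancy[l]`` is the
    total time spent at level *l* including censored edge events.
    """

    dwells: dict[int, np.ndarray]
    occupancy: dict[int, float]
    dead_time: float | None = None

    def __post_init__(self) -> None:
        self.dwells = {int(k): np.asarray(v, dtype=float) for k, v in self.dwells.items()}
        self.occupancy = {int(k): float(v) for k, v in self.occupancy.items()}
        for lvl, d in self.dwells.items():
            if d.size and np.any(d <= 0):
                raise ValueError(f"nonpositive dwell at level {lvl}")

    @property
    def levels(self) -> list[int]:
        return sorted(set(self.dwells) | set(self.occupancy))

    @property
    def max_level(self) -> int:
        return max(self.levels)

    @property
    def n_dwells(self) -> int:
        return int(sum(v.size for v in self.dwells.values()))


@dataclass
class AssaySeries:
    """Enzyme-rate (or released-Pi) observations along one varied condition.

    ``x`` is the varied condition (substrate uM, Mg2+ mM, pH, or ADPR uM
    for dose-response work), possibly with repeated entries for
    replicates; ``y`` the per-observation value.
    """

    x: np.ndarray
    y: np.ndarray
    x_label: str = "x"
    y_label: str = "value"
    normalized: bool = False
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D and equal length")
        if self.x.size < 1:
            raise ValueError("series must contain at least one point")

    @property
    def n_points(self) -> int:
        return int(self.x.size)

    def distinct_x(self) -> np.ndarray:
        return np.unique(self.x)
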