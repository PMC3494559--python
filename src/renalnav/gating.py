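"""End-exhale respiratory gating from a tracked-probe distance trace.

The probe is held at a fixed location while slices stream in at a stable
rate; the distance from the centroid of the probe's optical markers to a
fixed cranio-caudal reference axis rises and falls with the breathing cycle.
End-exhale — the longest natural pause of the cycle, where the kidney
reliably returns to the same position — corresponds to the minimum of that
distance, so the slice at the global minimum of the acquired window is
selected.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BreathTrace",
    "ReferenceAxis",
    "distance_to_axis",
    "select_end_exhale",
    "centroid_of_markers",
]


class GatingError(ValueError):
    pass


@dataclass(frozen=True)
class ReferenceAxis:
    """The cranio-caudal reference line l0 (point + unit direction)."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.point, dtype=float).reshape(3)
        d = np.asarray(self.direction, dtype=float).reshape(3)
        n = np.linalg.norm(d)
        if n < 1e-12:
            raise GatingError("zero-norm axis direction")
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "direction", d / n)


@dataclass(frozen=True)
class BreathTrace:
    """Timestamped marker-centroid distances to the reference axis.

    ``rate`` is the slice acquisition rate in samples per second.
    """

    timestamps: np.ndarray
    distances: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        t = np.asarray(self.timestamps, dtype=float).ravel()
        d = np.asarray(self.distances, dtype=float).ravel()
        if len(t) != len(d):
            raise GatingError("timestamps and distances must have equal length")
        if len(t) and np.any(np.diff(t) <= 0):
            raise GatingError("timestamps must be strictly increasing")
        if np.any(~np.isfinite(d)) or np.any(d < 0):
            raise GatingError("distances must be finite and non-negative")
        object.__setattr__(self, "timestamps", t)
        object.__setattr__(self, "distances", d)

    def __len__(self) -> int:
        return len(self.distances)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"t": self.timestamps, "distance": self.distances}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path, rate: float | None = None) -> "BreathTrace":
        df = pd.read_csv(path)
        t = df["t"].to_numpy(float)
        if rate is None:
            rate = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 1.0
        return cls(t, df["distance"].to_numpy(float), rate)


def centroid_of_markers(markers: np.ndarray) -> np.ndarray:
    """Arithmetic mean of the optically-tracked marker positions."""
    m = np.asarray(markers, dtype=float).reshape(-1, 3)
    if len(m) == 0:
        raise GatingError("at least one marker required")
    return m.mean(axis=0)


def distance_to_axis(centroid: np.ndarray, axis: ReferenceAxis) -> float:
    """Perpendicular distance from a point to the reference line."""
    v = np.asarray(centroid, dtype=float).reshape(3) - axis.point
    return float(np.linalg.norm(v - (v @ axis.direction) * axis.direction))


def select_end_exhale(trace: BreathTrace) -> int:
    """Index (0-based) of the maximum-exhalation slice: the global minimum
    distance over the acquired window, earliest index on ties."""
    if len(trace) == 0:
        raise GatingError("empty trace")
    return int(np.argmin(trace.distances))
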