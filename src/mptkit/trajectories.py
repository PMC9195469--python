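"""Core trajectory containers for the particle-tracking pipeline.

All positions are in micrometers and all times in seconds; unit conversion
(e.g. from pixel coordinates) happens once, at parse time, and never inside
the analysis. A :class:`Trajectory` is the time-ordered path of one particle;
a :class:`TrajectorySet` groups the trajectories of one video or simulation
together with the acquisition frame interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np


@dataclass
class Trajectory:
    """One particle's time-ordered 2-D path.

    Parameters
    ----------
    trajectory_id : str
        Unique identifier within a :class:`TrajectorySet`.
    frames : array of int
        Strictly increasing frame indices (0-based).
    t : array of float
        Time of each point in seconds.
    x, y : array of float
        Positions in micrometers.
    """

    trajectory_id: str
    frames: np.ndarray
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.t = np.asarray(self.t, dtype=np.float64)
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        n = len(self.frames)
        if not (len(self.t) == len(self.x) == len(self.y) == n):
            raise ValueError(
                f"trajectory {self.trajectory_id!r}: frames/t/x/y lengths differ"
            )
        if n < 2:
            raise ValueError(
                f"trajectory {self.trajectory_id!r}: needs at least 2 points, got {n}"
            )
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError(
                f"trajectory {self.trajectory_id!r}: frames must be strictly increasing"
            )

    @property
    def n_points(self) -> int:
        return len(self.frames)

    @property
    def positions(self) -> np.ndarray:
        """(N, 2) array of (x, y) positions in μm."""
        return np.column_stack([self.x, self.y])

    def is_uniform(self, rtol: float = 1e-9) -> bool:
        """True when the frame grid has a constant step."""
        steps = np.diff(self.frames)
        return bool(np.all(steps == steps[0]))


@dataclass
class FilterReport:
    """Bookkeeping attached by trajectory quality filtering."""

    n_input: int = 0
    n_removed_short: int = 0
    n_gap_dropped: int = 0
    n_split_segments: int = 0
    n_output: int = 0


@dataclass
class TrajectorySet:
    """A collection of trajectories sharing an acquisition frame interval."""

    trajectories: list[Trajectory]
    frame_interval: float
    source: str = ""
    filter_report: Optional[FilterReport] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        ids = [tr.trajectory_id for tr in self.trajectories]
        if len(ids) != len(set(ids)):
            raise ValueError("trajectory_ids must be unique within a TrajectorySet")

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self) -> Iterator[Trajectory]:
        return iter(self.trajectories)

    def __getitem__(self, i: int) -> Trajectory:
        return self.trajectories[i]

    def ids(self) -> list[str]:
        return [tr.trajectory_id for tr in self.trajectories]
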