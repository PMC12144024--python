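"""Acquisition frame timing for dynamic PET.

A :class:`FrameSchedule` is an ordered list of contiguous, non-overlapping
acquisition frames, each described by its start time and duration in seconds.
The default schedule is the 22-frame, 6-minute protocol used throughout this
package: 1 x 10, 8 x 5, 4 x 10, 2 x 15, 3 x 20, 2 x 30 and 2 x 60 s.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["FrameSchedule", "DEFAULT_FRAME_SPEC"]

#: (count, duration_s) blocks of the default 22-frame / 360 s protocol.
DEFAULT_FRAME_SPEC: tuple[tuple[int, float], ...] = (
    (1, 10.0),
    (8, 5.0),
    (4, 10.0),
    (2, 15.0),
    (3, 20.0),
    (2, 30.0),
    (2, 60.0),
)


@dataclass(frozen=True)
class FrameSchedule:
    """Ordered frame start/duration pairs defining acquisition timing.

    Parameters
    ----------
    starts : array of float
        Frame start times, seconds.
    durations : array of float
        Frame durations, seconds; strictly positive.

    Frames must be contiguous: ``starts[i+1] == starts[i] + durations[i]``.
    """

    starts: np.ndarray
    durations: np.ndarray

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts, dtype=float)
        durations = np.asarray(self.durations, dtype=float)
        if starts.ndim != 1 or starts.shape != durations.shape:
            raise ValueError("starts and durations must be 1-D arrays of equal length")
        if starts.size == 0:
            raise ValueError("schedule must contain at least one frame")
        if np.any(durations <= 0):
            raise ValueError("frame durations must be positive")
        if not np.allclose(starts[1:], starts[:-1] + durations[:-1], atol=1e-9):
            raise ValueError("frames must be contiguous and non-overlapping")
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "durations", durations)

    @classmethod
    def from_blocks(cls, blocks: tuple[tuple[int, float], ...]) -> "FrameSchedule":
        """Build a schedule from (count, duration) blocks starting at t = 0."""
        durations = np.concatenate([np.full(n, d, dtype=float) for n, d in blocks])
        starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
        return cls(starts, durations)

    @classmethod
    def default(cls) -> "FrameSchedule":
        """The 22-frame, 360 s schedule."""
        return cls.from_blocks(DEFAULT_FRAME_SPEC)

    @property
    def n_frames(self) -> int:
        return int(self.starts.size)

    @property
    def ends(self) -> np.ndarray:
        return self.starts + self.durations

    @property
    def midpoints(self) -> np.ndarray:
        return self.starts + 0.5 * self.durations

    @property
    def total_duration(self) -> float:
        return float(self.ends[-1] - self.starts[0])

    # -- sidecar JSON ------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {"starts_s": self.starts.tolist(), "durations_s": self.durations.tolist()}
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "FrameSchedule":
        payload = json.loads(Path(path).read_text())
        return cls(np.asarray(payload["starts_s"]), np.asarray(payload["durations_s"]))
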