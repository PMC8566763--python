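"""Core event containers: fixations, saccades and per-trial bundles."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Fixation", "Saccade", "EventTrial"]


@dataclass(frozen=True)
class Fixation:
    """A single fixation in screen-centered degree coordinates.

    ``onset``/``offset`` in ms; ``x``/``y`` in degrees (right/up positive).
    """

    onset: float
    offset: float
    x: float
    y: float
    participant: str = ""
    clip: str = ""

    def __post_init__(self) -> None:
        if not self.offset > self.onset:
            raise ValueError(
                f"fixation duration must be positive (onset={self.onset}, offset={self.offset})"
            )

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    @property
    def position(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass(frozen=True)
class Saccade:
    """A single saccade; amplitude in deg, direction in [0, 360) deg,
    peak velocity in deg/s."""

    onset: float
    offset: float
    x0: float
    y0: float
    x1: float
    y1: float
    amplitude: float
    direction: float
    peak_velocity: float
    participant: str = ""
    clip: str = ""

    def __post_init__(self) -> None:
        if not self.offset > self.onset:
            raise ValueError("saccade duration must be positive")
        expected = math.hypot(self.x1 - self.x0, self.y1 - self.y0)
        if abs(self.amplitude - expected) > 1e-6:
            raise ValueError(
                f"amplitude {self.amplitude} inconsistent with endpoints (expected {expected})"
            )
        if not (0.0 <= self.direction < 360.0):
            raise ValueError(f"direction {self.direction} outside [0, 360)")

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    @staticmethod
    def from_endpoints(
        onset: float,
        offset: float,
        x0: float,
        y0: float,
        x1: float,
        y1: float,
        peak_velocity: float = float("nan"),
        participant: str = "",
        clip: str = "",
    ) -> "Saccade":
        """Build a saccade with amplitude/direction derived from endpoints."""
        amp = math.hypot(x1 - x0, y1 - y0)
        direction = math.degrees(math.atan2(y1 - y0, x1 - x0)) % 360.0
        return Saccade(
            onset=onset, offset=offset, x0=x0, y0=y0, x1=x1, y1=y1,
            amplitude=amp, direction=direction, peak_velocity=peak_velocity,
            participant=participant, clip=clip,
        )


@dataclass
class EventTrial:
    """Ordered fixations and saccades of one participant watching one clip."""

    participant: str
    clip: str
    fixations: list[Fixation] = field(default_factory=list)
    saccades: list[Saccade] = field(default_factory=list)

    def fixation_positions(self) -> np.ndarray:
        """(n, 2) array of fixation positions in degrees."""
        if not self.fixations:
            return np.empty((0, 2))
        return np.array([[f.x, f.y] for f in self.fixations])

    def span_ms(self) -> tuple[float, float]:
        times = [e.onset for e in self.fixations + self.saccades]
        ends = [e.offset for e in self.fixations + self.saccades]
        if not times:
            return (0.0, 0.0)
        return (min(times), max(ends))
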