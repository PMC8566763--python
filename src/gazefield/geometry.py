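"""Screen geometry and pixel <-> visual-degree conversion.

Gaze positions are analysed in a screen-centered, right-handed degree frame:
x increases rightward, y increases upward, origin at the screen center.
Raw event tables use the tracker convention (pixel origin at the top-left
corner, y increasing downward); the conversion between the two lives here and
nowhere else.

Conversion uses true per-axis tangent geometry rather than a single flat
scale factor: a pixel offset ``d`` cm from the screen center at viewing
distance ``D`` cm subtends ``atan(d / D)`` degrees.  This matches the printed
subtense of wide displays exactly (a 50 x 35 cm screen at 60 cm covers
45.2 x 32.5 deg) and is exact off-axis, where a linear deg-per-pixel
approximation drifts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ScreenGeometry", "MONOCULAR_SCREEN"]


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical display setup: resolution, physical size and viewing distance.

    All lengths strictly positive; ``width_px``/``height_px`` in pixels,
    ``width_cm``/``height_cm``/``distance_cm`` in centimeters.
    """

    width_px: int
    height_px: int
    width_cm: float
    height_cm: float
    distance_cm: float

    def __post_init__(self) -> None:
        for name in ("width_px", "height_px", "width_cm", "height_cm", "distance_cm"):
            if not getattr(self, name) > 0:
                raise ValueError(f"ScreenGeometry.{name} must be strictly positive")

    @property
    def cm_per_px_x(self) -> float:
        return self.width_cm / self.width_px

    @property
    def cm_per_px_y(self) -> float:
        return self.height_cm / self.height_px

    @property
    def subtense_deg(self) -> tuple[float, float]:
        """Full horizontal and vertical visual angle covered by the screen."""
        half_w = np.degrees(np.arctan(self.width_cm / 2 / self.distance_cm))
        half_h = np.degrees(np.arctan(self.height_cm / 2 / self.distance_cm))
        return 2 * half_w, 2 * half_h

    def px_to_deg(self, x_px, y_px) -> tuple[np.ndarray, np.ndarray]:
        """Top-left-origin pixel coordinates -> screen-centered degrees.

        y flips sign: pixel y grows downward, degree y grows upward.
        """
        x_px = np.asarray(x_px, dtype=float)
        y_px = np.asarray(y_px, dtype=float)
        dx_cm = (x_px - self.width_px / 2) * self.cm_per_px_x
        dy_cm = (y_px - self.height_px / 2) * self.cm_per_px_y
        x_deg = np.degrees(np.arctan(dx_cm / self.distance_cm))
        y_deg = -np.degrees(np.arctan(dy_cm / self.distance_cm))
        return x_deg, y_deg

    def deg_to_px(self, x_deg, y_deg) -> tuple[np.ndarray, np.ndarray]:
        """Inverse of :meth:`px_to_deg` (exact; tangent is invertible)."""
        x_deg = np.asarray(x_deg, dtype=float)
        y_deg = np.asarray(y_deg, dtype=float)
        dx_cm = np.tan(np.radians(x_deg)) * self.distance_cm
        dy_cm = -np.tan(np.radians(y_deg)) * self.distance_cm
        x_px = dx_cm / self.cm_per_px_x + self.width_px / 2
        y_px = dy_cm / self.cm_per_px_y + self.height_px / 2
        return x_px, y_px


#: 1,920 x 1,080 px, 50 x 35 cm display viewed from 60 cm (45.2 x 32.5 deg).
MONOCULAR_SCREEN = ScreenGeometry(
    width_px=1920, height_px=1080, width_cm=50.0, height_cm=35.0, distance_cm=60.0
)
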