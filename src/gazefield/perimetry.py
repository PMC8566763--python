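"""Static automated perimetry handling: HFA grids, binocular integration, IVF score.

The Humphrey Field Analyzer (HFA) tests light sensitivity (in dB) on a
6-degree lattice offset 3 deg from the meridians.  The 24-2 pattern has 54
locations (the lattice points with |x|, |y| <= 21 and |x| + |y| <= 30, plus
two nasal points at 27 deg eccentricity); the 30-2 pattern has 76 (lattice
points out to 27 deg with |x| + |y| <= 36).  Two locations fall on the
physiological blind spot — (15, +/-3) deg in right-eye orientation — leaving
52 scored locations on the 24-2 grid.

Binocular (integrated) visual fields merge the two monocular fields by taking
the better (higher-dB) eye at every location; the IVF score then sums a 0/1/2
penalty per location: 0 for >= 20 dB, 1 for [10, 20) dB, 2 for < 10 dB, so
the score ranges from 0 (intact) to 104 (blind at all 52 locations).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Layout",
    "SensitivityField",
    "IVFScoreParams",
    "hfa_locations",
    "merge_ivf",
    "ivf_score",
    "md_summaries",
]

_LATTICE = (-27, -21, -15, -9, -3, 3, 9, 15, 21, 27)

#: blind-spot centers in right-eye orientation, deg
BLIND_SPOT = ((15.0, 3.0), (15.0, -3.0))


def hfa_locations(layout: str) -> np.ndarray:
    """Canonical (x, y) test locations in degrees, right-eye orientation.

    ``hfa24_2`` -> 54 rows, ``hfa30_2`` -> 76 rows.  Rows are sorted
    top-to-bottom, left-to-right (the order printed on HFA charts).
    """
    pts = []
    for y in _LATTICE:
        for x in _LATTICE:
            if layout == "hfa30_2":
                if abs(x) + abs(y) <= 36:
                    pts.append((x, y))
            elif layout == "hfa24_2":
                if abs(x) <= 21 and abs(y) <= 21 and abs(x) + abs(y) <= 30:
                    pts.append((x, y))
                # nasal extension of the right eye (toward the nose = left field)
                elif x == -27 and abs(y) == 3:
                    pts.append((x, y))
            else:
                raise ValueError(f"unknown layout {layout!r}")
    pts.sort(key=lambda p: (-p[1], p[0]))
    return np.array(pts, dtype=float)


class Layout:
    HFA24_2 = "hfa24_2"
    HFA30_2 = "hfa30_2"


@dataclass
class SensitivityField:
    """A perimetry grid: per-location dB sensitivities plus summary MD.

    Coordinates are always stored in right-eye orientation (left-eye fields
    are mirrored about the vertical meridian on read), which makes the
    best-location binocular merge a positionwise maximum.
    """

    layout: str
    locations: np.ndarray            # (n, 2) deg, right-eye orientation
    sensitivity: np.ndarray          # (n,) dB, >= 0
    eye: str = "right"               # left | right | integrated
    md: float = float("nan")         # mean deviation, dB
    blind_spot: np.ndarray = field(default=None)  # (n,) bool

    def __post_init__(self) -> None:
        self.locations = np.asarray(self.locations, dtype=float)
        self.sensitivity = np.asarray(self.sensitivity, dtype=float)
        expected = len(hfa_locations(self.layout))
        if len(self.sensitivity) != expected:
            raise ValueError(
                f"layout {self.layout} expects {expected} locations, "
                f"got {len(self.sensitivity)}"
            )
        if np.any(self.sensitivity < 0):
            raise ValueError("sensitivities must be >= 0 dB")
        if self.blind_spot is None:
            self.blind_spot = np.array(
                [tuple(p) in BLIND_SPOT for p in self.locations], dtype=bool
            )

    @property
    def n_scored(self) -> int:
        return int((~self.blind_spot).sum())

    def sensitivity_at(self, x, y) -> np.ndarray:
        """Nearest-location sensitivity lookup at arbitrary field positions.

        Positions beyond the grid extent take the nearest edge location; this
        is the extrapolation used when relating gaze vectors to the field.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        pts = np.stack([x, y], axis=-1)
        d2 = ((pts[:, None, :] - self.locations[None, :, :]) ** 2).sum(axis=2)
        return self.sensitivity[np.argmin(d2, axis=1)]

    def mirrored(self) -> "SensitivityField":
        """Flip about the vertical meridian (left-eye <-> right-eye chart)."""
        locs = self.locations.copy()
        locs[:, 0] *= -1
        order = np.lexsort((locs[:, 0], -locs[:, 1]))
        return replace(
            self,
            locations=locs[order],
            sensitivity=self.sensitivity[order],
            blind_spot=None,
        )


@dataclass(frozen=True)
class IVFScoreParams:
    """Penalty thresholds for the integrated-visual-field score."""

    mild_db: float = 20.0    # >= mild_db  -> 0 points
    severe_db: float = 10.0  # < severe_db -> 2 points; [severe, mild) -> 1

    def __post_init__(self) -> None:
        if not self.severe_db < self.mild_db:
            raise ValueError("severe threshold must lie below mild threshold")


def merge_ivf(left: SensitivityField, right: SensitivityField) -> SensitivityField:
    """Best-location binocular merge: positionwise maximum sensitivity.

    Both fields must share a layout and be stored in right-eye orientation
    (the reader mirrors left-eye files).  Commutative and idempotent.
    """
    if left.layout != right.layout:
        raise ValueError("cannot merge fields with different layouts")
    if not np.array_equal(left.locations, right.locations):
        raise ValueError("fields must share canonical location ordering")
    merged = np.maximum(left.sensitivity, right.sensitivity)
    md = float(np.nanmean([left.md, right.md]))
    return SensitivityField(
        layout=left.layout,
        locations=left.locations.copy(),
        sensitivity=merged,
        eye="integrated",
        md=md,
    )


def ivf_score(
    fld: SensitivityField, params: IVFScoreParams = IVFScoreParams()
) -> int:
    """Sum of 0/1/2 penalties over the non-blind-spot locations.

    The middle class is the half-open interval [severe, mild) dB so the three
    classes tile the axis; on the 24-2 grid the total lies in [0, 104].
    """
    s = fld.sensitivity[~fld.blind_spot]
    per_loc = np.where(s >= params.mild_db, 0, np.where(s >= params.severe_db, 1, 2))
    return int(per_loc.sum())


def md_summaries(md_left: float, md_right: float, open_eye: str) -> dict:
    """Mean MD and the signed between-eye difference (open − covered eye).

    A positive difference means the clip was watched with the better eye.
    """
    if open_eye not in ("left", "right"):
        raise ValueError("open_eye must be 'left' or 'right'")
    md_open, md_covered = (
        (md_left, md_right) if open_eye == "left" else (md_right, md_left)
    )
    diff = md_open - md_covered
    return {
        "mean_md": (md_left + md_right) / 2.0,
        "md_difference": diff,
        "better_eye_open": diff > 0,
    }
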