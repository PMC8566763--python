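"""Event detection, visual-field vectors, basic features and group statistics.

Saccades are detected with the velocity/acceleration criterion used by
video-based trackers: a sample belongs to a saccade when its instantaneous
velocity exceeds 30 deg/s or its acceleration exceeds 8,000 deg/s^2,
sustained over at least two samples; everything else is aggregated into
fixations.  Velocity is a three-sample central difference with no extra
smoothing.

Group comparisons use the two-sample Mann-Whitney U rank-sum test with
Bonferroni-corrected alpha (0.05 / n_comparisons, rounded to three decimals
for reporting, e.g. 4 comparisons -> 0.013).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .events import EventTrial, Fixation, Saccade

__all__ = [
    "EventDetectionParams",
    "GroupComparison",
    "detect_events",
    "to_vf_vectors",
    "basic_features",
    "compare_groups",
    "pearson_r",
    "UNDEFINED",
]

#: marker for features that cannot be computed (e.g. no saccades)
UNDEFINED = float("nan")


@dataclass(frozen=True)
class EventDetectionParams:
    velocity_threshold: float = 30.0       # deg/s
    acceleration_threshold: float = 8000.0  # deg/s^2
    min_fix_duration: float = 40.0          # ms; absorbs detection jitter

    def __post_init__(self) -> None:
        if self.velocity_threshold <= 0 or self.acceleration_threshold <= 0:
            raise ValueError("detection thresholds must be positive")


@dataclass(frozen=True)
class GroupComparison:
    median_a: float
    median_b: float
    sd_a: float
    sd_b: float
    u_statistic: float
    z: float
    p: float
    n_comparisons: int
    corrected_alpha: float

    @property
    def significant(self) -> bool:
        return self.p < self.corrected_alpha


def _runs(labels: np.ndarray):
    """Yield (value, start, stop) runs over a 1-D label array (stop exclusive)."""
    if len(labels) == 0:
        return
    change = np.flatnonzero(np.diff(labels) != 0)
    starts = np.concatenate([[0], change + 1])
    stops = np.concatenate([change + 1, [len(labels)]])
    for a, b in zip(starts, stops):
        yield labels[a], int(a), int(b)


def detect_events(
    t_ms: np.ndarray,
    x_deg: np.ndarray,
    y_deg: np.ndarray,
    params: EventDetectionParams = EventDetectionParams(),
    participant: str = "",
    clip: str = "",
) -> tuple[list[Fixation], list[Saccade], list[tuple[float, float]]]:
    """Classify uniformly sampled gaze into fixations, saccades and gaps.

    Returns ``(fixations, saccades, gaps)`` where gaps are ``(on, off)`` ms
    intervals of invalid (NaN) gaze.  Events are non-overlapping and tile
    the valid samples: fixation + saccade + gap durations sum exactly to the
    trial span.
    """
    t = np.asarray(t_ms, dtype=float)
    x = np.asarray(x_deg, dtype=float)
    y = np.asarray(y_deg, dtype=float)
    valid = np.isfinite(x) & np.isfinite(y)
    if len(t) < 2 or valid.sum() < 2:
        if valid.sum() == 0 and len(t) > 0:
            raise ValueError("all gaze samples are NaN")
        warnings.warn("fewer than 2 valid samples; no events detected")
        return [], [], []

    dt = np.median(np.diff(t)) / 1000.0  # s
    # 3-sample central difference; one-sided at the edges
    vx = np.gradient(x, t / 1000.0)
    vy = np.gradient(y, t / 1000.0)
    speed = np.hypot(vx, vy)
    accel = np.abs(np.gradient(speed, t / 1000.0))

    is_sac = (speed > params.velocity_threshold) | (
        accel > params.acceleration_threshold
    )
    is_sac &= valid
    # label: 0 fixation, 1 saccade, 2 gap
    labels = np.where(~valid, 2, is_sac.astype(int))

    # saccade bursts must be sustained over >= 2 samples
    labels = labels.copy()
    for val, a, b in list(_runs(labels)):
        if val == 1 and (b - a) < 2:
            labels[a:b] = 0
    # grow saccade runs outward to the surrounding velocity minimum, so the
    # slow tails below threshold still belong to the saccade
    ext_thresh = 0.1 * params.velocity_threshold
    for val, a, b in list(_runs(labels)):
        if val != 1:
            continue
        i = a - 1
        while i >= 0 and labels[i] == 0 and speed[i] > ext_thresh:
            labels[i] = 1
            i -= 1
        i = b
        while i < len(labels) and labels[i] == 0 and speed[i] > ext_thresh:
            labels[i] = 1
            i += 1
    # fixations shorter than min_fix_duration squeezed between saccades are jitter
    runs = list(_runs(labels))
    for i, (val, a, b) in enumerate(runs):
        if val == 0 and (t[b - 1] - t[a]) + dt * 1000 < params.min_fix_duration:
            prev_sac = i > 0 and runs[i - 1][0] == 1
            next_sac = i + 1 < len(runs) and runs[i + 1][0] == 1
            if prev_sac and next_sac:
                labels[a:b] = 1

    fixations: list[Fixation] = []
    saccades: list[Saccade] = []
    gaps: list[tuple[float, float]] = []
    sample_ms = dt * 1000.0
    for val, a, b in _runs(labels):
        on = t[a]
        off = t[b - 1] + sample_ms  # events tile: offset = next sample's onset
        if val == 2:
            gaps.append((on, off))
        elif val == 1:
            pv = float(np.max(speed[a:b]))
            saccades.append(
                Saccade.from_endpoints(on, off, x[a], y[a], x[b - 1], y[b - 1],
                                       peak_velocity=pv,
                                       participant=participant, clip=clip)
            )
        else:
            fixations.append(
                Fixation(on, off, float(np.mean(x[a:b])), float(np.mean(y[a:b])),
                         participant, clip)
            )
    return fixations, saccades, gaps


def to_vf_vectors(fixations: list[Fixation]) -> np.ndarray:
    """Gaze-relative displacement vectors between consecutive fixations.

    Vector i points from fixation i to fixation i+1 in degrees, with the
    origin re-centered on fixation i (leftward/downward negative).  Fewer
    than two fixations give an empty array.
    """
    if len(fixations) < 2:
        return np.empty((0, 2))
    pos = np.array([[f.x, f.y] for f in fixations])
    return np.diff(pos, axis=0)


def basic_features(trials: list[EventTrial], summary: str = "median") -> dict:
    """Per-participant eye-movement features pooled over all trials.

    ``summary`` selects ``median`` (default reporting path) or ``mean``.
    Features: fixation duration (ms), number of fixations, saccade amplitude
    (deg) and saccade peak velocity (deg/s).  With no saccades the amplitude
    and velocity are the undefined marker (NaN), never zero.
    """
    if summary not in ("median", "mean"):
        raise ValueError("summary must be 'median' or 'mean'")
    agg = np.median if summary == "median" else np.mean
    durations = [f.duration for t in trials for f in t.fixations]
    amps = [s.amplitude for t in trials for s in t.saccades]
    pvels = [s.peak_velocity for t in trials for s in t.saccades
             if np.isfinite(s.peak_velocity)]
    if not durations:
        raise ValueError("basic_features needs at least one fixation")
    return {
        "fixation_duration_ms": float(agg(durations)),
        "n_fixations": len(durations),
        "saccade_amplitude_deg": float(agg(amps)) if amps else UNDEFINED,
        "saccade_peak_velocity_deg_s": float(agg(pvels)) if pvels else UNDEFINED,
    }


def compare_groups(values_a, values_b, n_comparisons: int = 1) -> GroupComparison:
    """Two-sided Mann-Whitney U rank-sum comparison of two groups.

    The z statistic comes from the tie-corrected normal approximation of U;
    the p value is exact for small tie-free samples (scipy's policy).  The
    corrected alpha is 0.05 / n_comparisons rounded to three decimals, as
    conventionally reported (4 -> 0.013, 3 -> 0.017).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        u = len(a) * len(b) / 2.0
        z, p = 0.0, 1.0
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        u = float(res.statistic)
        n1, n2 = len(a), len(b)
        # tie-corrected normal approximation for the reported z
        combined = np.concatenate([a, b])
        _, counts = np.unique(combined, return_counts=True)
        n = n1 + n2
        tie_term = (counts**3 - counts).sum() / (n * (n - 1)) if n > 1 else 0.0
        sigma = math.sqrt(n1 * n2 / 12.0 * (n + 1 - tie_term))
        z = (u - n1 * n2 / 2.0) / sigma if sigma > 0 else 0.0
        p = float(res.pvalue)
    alpha = round(0.05 / n_comparisons, 3)
    return GroupComparison(
        median_a=float(np.median(a)), median_b=float(np.median(b)),
        sd_a=float(np.std(a, ddof=1)), sd_b=float(np.std(b, ddof=1)),
        u_statistic=u, z=float(z), p=float(min(p, 1.0)),
        n_comparisons=n_comparisons, corrected_alpha=alpha,
    )


def pearson_r(x, y) -> float:
    """Pearson correlation; NaN (with a warning) when either side is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("pearson_r needs equal-length inputs of size >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero variance: correlation undefined")
        return UNDEFINED
    return float(stats.pearsonr(x, y).statistic)
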