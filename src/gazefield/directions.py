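"""Directional saccade-amplitude profiles and normalized-rank comparison.

Saccade directions are binned into 18 half-open bins of 20 deg covering
[0, 360); per bin the median and the maximum amplitude are kept.  A patient's
profile is compared to a control cohort by the normalized rank of each bin
value among the controls' values (mid-rank for ties, divided by the number of
controls, so ranks lie in [0, 1]); bins where the patient falls in the outer
2.5% tails of the control distribution are flagged.  Controls are always
ranked leave-one-out against the remaining controls to avoid self-ranking
bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .events import Saccade

__all__ = [
    "N_BINS",
    "BIN_WIDTH",
    "DirectionalProfile",
    "RankProfile",
    "directional_profile",
    "normalized_rank_profile",
    "control_extent",
]

N_BINS = 18
BIN_WIDTH = 360.0 / N_BINS  # 20 deg


@dataclass(frozen=True)
class DirectionalProfile:
    """Median/maximum saccade amplitude and count per 20-deg direction bin.

    Empty bins carry NaN (undefined), never zero.
    """

    median: np.ndarray  # (18,) deg
    maximum: np.ndarray  # (18,) deg
    count: np.ndarray    # (18,) int

    def __post_init__(self) -> None:
        for arr in (self.median, self.maximum):
            if arr.shape != (N_BINS,):
                raise ValueError(f"profiles have {N_BINS} bins")


@dataclass(frozen=True)
class RankProfile:
    """Normalized ranks in [0, 1] per bin, with 2.5% tail flags."""

    median_rank: np.ndarray
    max_rank: np.ndarray
    flag_low: np.ndarray   # rank < 0.025
    flag_high: np.ndarray  # rank > 0.975


def direction_bin(direction_deg) -> np.ndarray:
    """Half-open bin index: bin b covers [20b, 20(b+1))."""
    return (np.asarray(direction_deg, dtype=float) % 360.0 // BIN_WIDTH).astype(int)


def directional_profile(saccades: list[Saccade]) -> DirectionalProfile:
    """18-bin amplitude profile of one participant's saccades."""
    med = np.full(N_BINS, np.nan)
    mx = np.full(N_BINS, np.nan)
    cnt = np.zeros(N_BINS, dtype=int)
    if saccades:
        dirs = np.array([s.direction for s in saccades])
        amps = np.array([s.amplitude for s in saccades])
        bins = direction_bin(dirs)
        for b in range(N_BINS):
            sel = amps[bins == b]
            cnt[b] = len(sel)
            if len(sel):
                med[b] = np.median(sel)
                mx[b] = np.max(sel)
    return DirectionalProfile(median=med, maximum=mx, count=cnt)


def _midrank(value: float, pool: np.ndarray) -> float:
    """(# strictly smaller + half the ties) / pool size; NaN pool entries dropped."""
    pool = pool[np.isfinite(pool)]
    if len(pool) == 0 or not np.isfinite(value):
        return np.nan
    smaller = np.sum(pool < value)
    ties = np.sum(pool == value)
    return float((smaller + ties / 2.0) / len(pool))


def normalized_rank_profile(
    patient: DirectionalProfile, controls: list[DirectionalProfile]
) -> RankProfile:
    """Rank each patient bin among the control cohort's bins (mid-rank ties).

    Requires at least five controls.  Bins where the patient value is
    undefined get an undefined rank; control bins with undefined values are
    excluded from the pool bin by bin.
    """
    if len(controls) < 5:
        raise ValueError("normalized_rank_profile needs >= 5 controls")
    med_rank = np.full(N_BINS, np.nan)
    max_rank = np.full(N_BINS, np.nan)
    ctrl_med = np.array([c.median for c in controls])
    ctrl_max = np.array([c.maximum for c in controls])
    for b in range(N_BINS):
        med_rank[b] = _midrank(patient.median[b], ctrl_med[:, b])
        max_rank[b] = _midrank(patient.maximum[b], ctrl_max[:, b])
    ranks = np.stack([med_rank, max_rank])
    with np.errstate(invalid="ignore"):
        low = ranks < 0.025
        high = ranks > 0.975
    return RankProfile(
        median_rank=med_rank, max_rank=max_rank,
        flag_low=low.any(axis=0), flag_high=high.any(axis=0),
    )


def control_extent(
    controls: list[DirectionalProfile], bin_size_deg: float = 2.0
) -> dict:
    """Rectangular grid half-angles covering the controls' typical saccades.

    Per axis, the half-angle is the maximum over the axis-facing bins (bin
    centers within 45 deg of the axis) of the cohort median amplitude plus
    two SDs of the per-control bin medians, rounded up to a whole multiple of
    the map bin size.  The published monocular free-viewing grid of this kind
    spans 21 x 11 deg half-angle; that target shape is kept as provenance
    metadata for comparison.
    """
    if len(controls) < 2:
        raise ValueError("control_extent needs >= 2 controls")
    med = np.array([c.median for c in controls])  # (n, 18)
    centers = (np.arange(N_BINS) + 0.5) * BIN_WIDTH
    horiz = (np.minimum(np.abs(centers - 0), np.abs(centers - 360)) < 45) | (
        np.abs(centers - 180) < 45
    )
    vert = (np.abs(centers - 90) < 45) | (np.abs(centers - 270) < 45)

    def axis_half(mask: np.ndarray) -> float:
        with np.errstate(invalid="ignore"):
            group_med = np.nanmedian(med[:, mask], axis=0)
            group_sd = np.nanstd(med[:, mask], axis=0, ddof=1)
        reach = np.nanmax(group_med + 2 * group_sd)
        return float(np.ceil(reach / bin_size_deg) * bin_size_deg)

    return {
        "half_x": axis_half(horiz),
        "half_y": axis_half(vert),
        "bin_size": bin_size_deg,
        "target_shape": "21 deg half angle",
    }


def rank_profile_table(profile: RankProfile) -> "np.ndarray":
    """Rows of (bin_start_deg, median_rank, max_rank, flag_low, flag_high)."""
    starts = np.arange(N_BINS) * BIN_WIDTH
    return np.column_stack([
        starts, profile.median_rank, profile.max_rank,
        profile.flag_low.astype(float), profile.flag_high.astype(float),
    ])
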