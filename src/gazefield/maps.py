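"""Visual-field map constructions over gaze-relative coordinates.

All maps live on rectangular grids over visual-field (gaze-relative) degree
coordinates, half-open bins, x rightward / y upward.  Map kinds:

``density``
    Sum of unit-mass isotropic Gaussians (default SD 1 deg, reflecting
    tracker accuracy and foveal extent), evaluated pointwise at bin centers;
    total mass = sum(values) * bin area.  Mass outside the grid is lost.
``proportion``
    Bin counts normalized either so the maximum bin is 1 (monocular-study
    style fixation maps) or so included bins sum to 1 (saccade-map style).
``mean_vp``
    VP-weighted density divided by unweighted density; bins with less than
    ``MASK_EPS`` fixation mass are masked as undefined.
``rank``
    Per-bin normalized rank (mid-rank ties, in [0, 1]) of one participant's
    z-normalized map among a control cohort's maps; 0.5 is typical.

The saccade-endpoint grid replicating the earlier binocular free-viewing
study spans 12 x 10 deg half-angle in 2-deg bins with the central four bins
excluded (116 included bins); fixation-distribution variants keep the
central bins.  Discrete perimetry-aligned maps use the true HFA 24-2/30-2
location centers (6-deg lattice) rather than an arbitrary square tiling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .gaze import pearson_r
from .perimetry import SensitivityField, hfa_locations

__all__ = [
    "MapSpec",
    "VFMap",
    "SACCADE_MAP_SPEC",
    "MASK_EPS",
    "fixation_heatmap",
    "fixation_count_map",
    "average_vp_map",
    "z_normalize",
    "relative_rank_map",
    "saccade_map",
    "binned_map_vs_sensitivity",
]

#: minimum fixation mass for a mean-VP bin to be defined
MASK_EPS = 1e-3


@dataclass(frozen=True)
class MapSpec:
    """Grid geometry: half-angles, bin size and Gaussian SD, all in degrees."""

    half_x: float = 21.0
    half_y: float = 11.0
    bin_size: float = 2.0
    sigma: float = 1.0
    central_exclusion: bool = False
    convention: str = "vf-centered-right-up"

    def __post_init__(self) -> None:
        if self.bin_size <= 0 or self.half_x <= 0 or self.half_y <= 0:
            raise ValueError("MapSpec extents and bin size must be positive")

    @property
    def nx(self) -> int:
        return int(round(2 * self.half_x / self.bin_size))

    @property
    def ny(self) -> int:
        return int(round(2 * self.half_y / self.bin_size))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    def edges(self) -> tuple[np.ndarray, np.ndarray]:
        xe = -self.half_x + self.bin_size * np.arange(self.nx + 1)
        ye = -self.half_y + self.bin_size * np.arange(self.ny + 1)
        return xe, ye

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        xe, ye = self.edges()
        return (xe[:-1] + self.bin_size / 2, ye[:-1] + self.bin_size / 2)

    def central_mask(self) -> np.ndarray:
        """True on the four bins adjacent to the origin (rows are y, top row
        = highest y)."""
        mask = np.zeros(self.shape, dtype=bool)
        cx, cy = self.centers()
        xs = np.argsort(np.abs(cx))[:2]
        ys = np.argsort(np.abs(cy))[:2]
        mask[np.ix_(ys, xs)] = True
        return mask


#: 12 x 10 deg half-angle, 2-deg bins, central four bins excluded
SACCADE_MAP_SPEC = MapSpec(half_x=12.0, half_y=10.0, bin_size=2.0, central_exclusion=True)


@dataclass
class VFMap:
    """A rectangular visual-field map with mask and provenance.

    ``values`` is (ny, nx), row 0 = top of the field (highest y); masked
    bins are undefined and excluded from statistics.
    """

    values: np.ndarray
    spec: MapSpec
    kind: str
    mask: np.ndarray = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.spec.shape:
            raise ValueError(
                f"values shape {self.values.shape} != spec shape {self.spec.shape}"
            )
        if self.mask is None:
            self.mask = np.zeros(self.spec.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)

    def unmasked(self) -> np.ndarray:
        return self.values[~self.mask]

    def mass(self) -> float:
        """Total Gaussian mass represented by a density map."""
        return float(self.values[~self.mask].sum() * self.spec.bin_size**2)


def _grid(spec: MapSpec) -> tuple[np.ndarray, np.ndarray]:
    cx, cy = spec.centers()
    gx, gy = np.meshgrid(cx, cy[::-1])  # row 0 = top
    return gx, gy


def fixation_heatmap(
    vectors: np.ndarray, spec: MapSpec = MapSpec(), weights: np.ndarray | None = None
) -> VFMap:
    """Continuous density map: one unit-mass Gaussian (SD ``spec.sigma``)
    per fixation vector, evaluated at bin centers.

    ``weights`` scales each Gaussian's mass (used for VP weighting).  Empty
    input gives the all-zero map.
    """
    vectors = np.asarray(vectors, dtype=float).reshape(-1, 2)
    gx, gy = _grid(spec)
    values = np.zeros(spec.shape)
    if len(vectors):
        w = np.ones(len(vectors)) if weights is None else np.asarray(weights, float)
        s2 = spec.sigma**2
        norm = 1.0 / (2 * np.pi * s2)
        # (n, ny, nx) in chunks to bound memory
        for start in range(0, len(vectors), 512):
            chunk = vectors[start:start + 512]
            cw = w[start:start + 512]
            d2 = (gx[None] - chunk[:, 0, None, None]) ** 2 + (
                gy[None] - chunk[:, 1, None, None]
            ) ** 2
            values += np.tensordot(cw, norm * np.exp(-0.5 * d2 / s2), axes=1)
    return VFMap(values=values, spec=spec, kind="density")


def fixation_count_map(
    vectors: np.ndarray, spec: MapSpec = MapSpec(), normalize: str = "max"
) -> VFMap:
    """Discrete proportion map of fixation vectors per bin.

    ``normalize="max"`` divides by the maximum bin (values in [0, 1], the
    monocular-study convention); ``"sum"`` divides by the total count over
    included bins.  Out-of-grid vectors are dropped; with
    ``spec.central_exclusion`` the central four bins are masked and their
    counts dropped too.
    """
    vectors = np.asarray(vectors, dtype=float).reshape(-1, 2)
    xe, ye = spec.edges()
    counts, _, _ = np.histogram2d(vectors[:, 1], vectors[:, 0], bins=(ye, xe))
    counts = counts[::-1]  # row 0 = top
    mask = spec.central_mask() if spec.central_exclusion else np.zeros(spec.shape, bool)
    counts[mask] = 0.0
    if normalize == "max":
        denom = counts.max()
    elif normalize == "sum":
        denom = counts.sum()
    else:
        raise ValueError("normalize must be 'max' or 'sum'")
    values = counts / denom if denom > 0 else counts
    return VFMap(values=values, spec=spec, kind="proportion", mask=mask,
                 provenance={"normalize": normalize, "n_input": len(vectors)})


def average_vp_map(
    vectors: np.ndarray, vp_values: np.ndarray, spec: MapSpec = MapSpec()
) -> VFMap:
    """Mean-VP map: VP-weighted heat map over unweighted heat map.

    Fixations with undefined VP are skipped; bins whose fixation mass falls
    below ``MASK_EPS`` are masked.
    """
    vectors = np.asarray(vectors, dtype=float).reshape(-1, 2)
    vp_values = np.asarray(vp_values, dtype=float)
    keep = np.isfinite(vp_values)
    num = fixation_heatmap(vectors[keep], spec, weights=vp_values[keep])
    den = fixation_heatmap(vectors[keep], spec)
    mask = den.values < MASK_EPS
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(mask, 0.0, num.values / np.maximum(den.values, 1e-30))
    return VFMap(values=values, spec=spec, kind="mean_vp", mask=mask)


def z_normalize(vfmap: VFMap) -> VFMap:
    """Per-participant z-normalization over unmasked bins (mean 0, SD 1)."""
    vals = vfmap.unmasked()
    mu, sd = vals.mean(), vals.std()
    if sd == 0:
        sd = 1.0
    values = np.where(vfmap.mask, 0.0, (vfmap.values - mu) / sd)
    return replace(vfmap, values=values, kind=vfmap.kind + "_z")


def relative_rank_map(patient: VFMap, controls: list[VFMap],
                      normalize_first: bool = True) -> VFMap:
    """Per-bin normalized rank of the patient among controls (mid-rank ties).

    Maps are z-normalized per participant first (the published procedure);
    rank 0.5 means typical, 1 means more fixation mass at that field
    location than every control.
    """
    if not controls:
        raise ValueError("need at least one control map")
    for c in controls:
        if c.spec != patient.spec:
            raise ValueError("all maps must share a MapSpec")
    if normalize_first:
        patient = z_normalize(patient)
        controls = [z_normalize(c) for c in controls]
    stack = np.stack([c.values for c in controls])  # (n, ny, nx)
    smaller = (stack < patient.values[None]).sum(axis=0)
    ties = (stack == patient.values[None]).sum(axis=0)
    values = (smaller + ties / 2.0) / len(controls)
    mask = patient.mask.copy()
    for c in controls:
        mask |= c.mask
    return VFMap(values=np.where(mask, 0.0, values), spec=patient.spec,
                 kind="rank", mask=mask)


def saccade_map(endpoints: np.ndarray, spec: MapSpec = SACCADE_MAP_SPEC) -> VFMap:
    """Proportion of saccade endpoints per bin, central four bins excluded.

    Included bins sum to 1 whenever at least one endpoint lands on the grid;
    endpoints in excluded or out-of-grid bins are dropped.  Use
    :func:`fixation_count_map` with ``normalize="sum"`` and a
    non-excluding spec for the fixation-distribution variant that keeps the
    central bins.
    """
    if not spec.central_exclusion:
        spec = replace(spec, central_exclusion=True)
    return fixation_count_map(endpoints, spec, normalize="sum")


def binned_map_vs_sensitivity(
    vectors: np.ndarray,
    fld: SensitivityField,
    values: np.ndarray | None = None,
) -> tuple[dict, float]:
    """Per-HFA-location gaze statistic paired with dB sensitivity.

    Each fixation vector is assigned to the 6 x 6 deg cell centered on an
    HFA test location of ``fld``'s layout.  Without ``values`` the statistic
    is the proportion of fixations per location; with ``values`` (e.g. VP
    per fixation) it is their per-location mean.  Blind-spot locations are
    excluded.  Returns ``(per-location table, Pearson r vs sensitivity)``;
    r is NaN when either side has zero variance.
    """
    vectors = np.asarray(vectors, dtype=float).reshape(-1, 2)
    locs = hfa_locations(fld.layout)
    keep_loc = ~fld.blind_spot
    half = 3.0  # 6-deg cells on the HFA lattice
    stat = np.full(len(locs), np.nan)
    counts = np.zeros(len(locs))
    if len(vectors):
        inside = (np.abs(vectors[:, None, 0] - locs[None, :, 0]) < half) & (
            np.abs(vectors[:, None, 1] - locs[None, :, 1]) < half
        )
        counts = inside.sum(axis=0).astype(float)
        if values is None:
            stat = counts / max(len(vectors), 1)
        else:
            values = np.asarray(values, dtype=float)
            with np.errstate(invalid="ignore"):
                for j in range(len(locs)):
                    sel = values[inside[:, j]]
                    sel = sel[np.isfinite(sel)]
                    stat[j] = sel.mean() if len(sel) else np.nan
    table = {
        "x_deg": locs[keep_loc, 0],
        "y_deg": locs[keep_loc, 1],
        "stat": stat[keep_loc],
        "count": counts[keep_loc],
        "sensitivity_db": fld.sensitivity[keep_loc],
    }
    defined = np.isfinite(table["stat"])
    if defined.sum() >= 3:
        r = pearson_r(table["stat"][defined], table["sensitivity_db"][defined])
    else:
        r = float("nan")
    return table, r
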