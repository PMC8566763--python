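"""Viewing priority (VP): gaze-consistency scoring of single fixations.

VP expresses, in [0, 1], how closely one fixation matches where a reference
cohort looked during the same moment of the same clip, discounted by where
that cohort looks regardless of content (center bias, set-up biases).  Two
fixation pools drive the score:

* the *reference set* — cohort fixations made in the same time window while
  watching the **same** clip;
* the *random set* — cohort fixations made in the same time window while
  watching **other** clips.

Fuzzy c-means clustering (C clusters per set) summarizes where each pool
concentrates.  Over the combined cluster list, cluster k receives a priority
weight ``R_k / (R_k + S_k)``, where ``R_k`` and ``S_k`` are the mean mass of
the reference and the random points *near* cluster k: fuzzy membership
weighted by a Gaussian typicality ``exp(-d^2 / (2 s_k^2))`` with ``s_k`` the
cluster's own fuzzy dispersion, so points far from a cluster contribute
nothing to it.  A cluster densely populated by reference fixations but not
by content-independent random fixations has priority near 1; a cluster that
only random fixations populate has priority near 0.  The VP of the scored
fixation is its membership-weighted sum of cluster priorities, so an
all-reference neighborhood gives 1, an all-random neighborhood gives 0, and
two exchangeable pools give 0.5.  The scored observer's own fixations are
always excluded from both pools (leave-one-out for cohort members).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .events import EventTrial, Fixation
from .gaze import pearson_r

__all__ = [
    "VPParams",
    "VPRecord",
    "assemble_sets",
    "compute_vp",
    "score_trial",
    "score_cohort_member",
    "summarize_vp",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class VPParams:
    """Controls for the VP computation.

    ``window_ms`` is the half-width of the time window around fixation onset;
    ``n_clusters`` and ``fuzzifier`` drive the fuzzy c-means fit (fuzzifier
    m > 1; m -> 1 approaches hard k-means).
    """

    window_ms: float = 500.0
    n_clusters: int = 5
    fuzzifier: float = 2.0
    tol: float = 1e-8
    max_iter: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.fuzzifier <= 1:
            raise ValueError("fuzzifier must be > 1")


@dataclass(frozen=True)
class VPRecord:
    fixation_id: int
    onset: float
    clip: str
    participant: str
    vp: float
    n_reference: int
    n_random: int

    def __post_init__(self) -> None:
        if np.isfinite(self.vp) and not (0.0 <= self.vp <= 1.0 + 1e-12):
            raise ValueError(f"VP {self.vp} outside [0, 1]")


def _memberships(points: np.ndarray, centers: np.ndarray, m: float) -> np.ndarray:
    """Fuzzy memberships of ``points`` (n,2) w.r.t. ``centers`` (c,2)."""
    d2 = ((points[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    zero = d2 < 1e-24
    d2 = np.maximum(d2, 1e-24)
    power = 1.0 / (m - 1.0)
    inv = d2 ** (-power)
    u = inv / inv.sum(axis=1, keepdims=True)
    # points coincident with a center get crisp membership there
    hit = zero.any(axis=1)
    if hit.any():
        u[hit] = 0.0
        u[hit, np.argmax(zero[hit], axis=1)] = 1.0
    return u


def _fuzzy_cmeans(
    points: np.ndarray, c: int, m: float, tol: float, max_iter: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Fit fuzzy c-means; returns (centers, memberships, converged).

    Initialization picks ``c`` distinct data points, so the fit (and hence
    VP) is exactly equivariant under rigid transforms of the inputs.
    """
    n = len(points)
    c = min(c, n)
    idx = rng.choice(n, size=c, replace=False)
    centers = points[idx].astype(float).copy()
    u = _memberships(points, centers, m)
    converged = False
    for _ in range(max_iter):
        um = u ** m
        new_centers = (um.T @ points) / np.maximum(um.sum(axis=0)[:, None], 1e-30)
        shift = float(np.abs(new_centers - centers).max())
        centers = new_centers
        u = _memberships(points, centers, m)
        if shift < tol:
            converged = True
            break
    if not converged:
        warnings.warn("fuzzy c-means did not converge; using best iterate")
    return centers, u, converged


def assemble_sets(
    fixation: Fixation,
    cohort_trials: list[EventTrial],
    clip: str,
    params: VPParams = VPParams(),
) -> tuple[np.ndarray, np.ndarray]:
    """Reference and random fixation positions for one scored fixation.

    Reference: cohort fixations on ``clip`` whose [onset, offset] intersects
    the +/- window around the scored fixation's onset.  Random: cohort
    fixations in the same window on any other clip.  The scored observer's
    own fixations are excluded from both.
    """
    lo = fixation.onset - params.window_ms
    hi = fixation.onset + params.window_ms
    ref, rand = [], []
    for trial in cohort_trials:
        if trial.participant == fixation.participant:
            continue
        for f in trial.fixations:
            if f.onset <= hi and f.offset >= lo:
                (ref if trial.clip == clip else rand).append((f.x, f.y))
    return np.array(ref).reshape(-1, 2), np.array(rand).reshape(-1, 2)


def compute_vp(
    position: tuple[float, float],
    reference: np.ndarray,
    random_set: np.ndarray,
    params: VPParams = VPParams(),
) -> float:
    """VP of a fixation at ``position`` given its reference and random sets.

    NaN when the reference set is empty.  With an empty random set a uniform
    baseline is substituted: seeded uniform points over the reference
    bounding box expanded by two reference SDs (logged).
    """
    reference = np.asarray(reference, dtype=float).reshape(-1, 2)
    random_set = np.asarray(random_set, dtype=float).reshape(-1, 2)
    if len(reference) == 0:
        log.warning("empty reference set; VP undefined")
        return float("nan")
    rng = np.random.default_rng(params.seed)
    if len(random_set) == 0:
        log.info("empty random set; substituting uniform baseline")
        margin = 2 * reference.std(axis=0).max() + 1.0
        lo = reference.min(axis=0) - margin
        hi = reference.max(axis=0) + margin
        random_set = rng.uniform(lo, hi, size=(max(len(reference), 50), 2))

    def fit_side(points: np.ndarray):
        """Cluster one pool; returns (centers, dispersions, eval half).

        Clusters are fitted on half the points and masses measured on the
        held-out half: fitting and evaluating on the same points would
        inflate that side's mass (the centers adapt to their own noise) and
        bias VP away from 0.5 under reference/random exchangeability.
        """
        if len(points) >= 10:
            perm = rng.permutation(len(points))
            fit_set, eval_set = points[perm[::2]], points[perm[1::2]]
        else:
            fit_set = eval_set = points
        centers, u_fit, _ = _fuzzy_cmeans(
            fit_set, params.n_clusters, params.fuzzifier,
            params.tol, params.max_iter, rng,
        )
        d2_fit = ((fit_set[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        um = u_fit ** params.fuzzifier
        s2 = (um * d2_fit).sum(axis=0) / np.maximum(um.sum(axis=0), 1e-30)
        # floor: single-point clusters keep a tracker-accuracy-sized footprint
        return centers, np.maximum(s2, 0.25), eval_set

    ref_centers, ref_s2, ref_eval = fit_side(reference)
    rand_centers, rand_s2, rand_eval = fit_side(random_set)
    centers = np.vstack([ref_centers, rand_centers])
    s2 = np.concatenate([ref_s2, rand_s2])

    def near_mass(points: np.ndarray) -> np.ndarray:
        d2 = ((points[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        u = _memberships(points, centers, params.fuzzifier)
        return (u * np.exp(-0.5 * d2 / s2[None, :])).mean(axis=0)

    ref_mass = near_mass(ref_eval)
    rand_mass = near_mass(rand_eval)
    priority = ref_mass / np.maximum(ref_mass + rand_mass, 1e-30)
    u_fix = _memberships(np.asarray(position, dtype=float).reshape(1, 2),
                         centers, params.fuzzifier)[0]
    vp = float(np.clip(u_fix @ priority, 0.0, 1.0))
    return vp


class _CohortIndex:
    """Flat arrays over all cohort fixations for fast windowed set assembly.

    Semantically identical to :func:`assemble_sets`; exists because scoring a
    full cohort probes the pools once per fixation.
    """

    def __init__(self, cohort_trials: list[EventTrial]):
        onset, offset, xy, pid, clip = [], [], [], [], []
        for t in cohort_trials:
            for f in t.fixations:
                onset.append(f.onset)
                offset.append(f.offset)
                xy.append((f.x, f.y))
                pid.append(t.participant)
                clip.append(t.clip)
        self.onset = np.array(onset, dtype=float)
        self.offset = np.array(offset, dtype=float)
        self.xy = np.array(xy, dtype=float).reshape(-1, 2)
        self.pid = np.array(pid, dtype=object)
        self.clip = np.array(clip, dtype=object)

    def sets_for(self, fix: Fixation, clip: str, window_ms: float):
        lo, hi = fix.onset - window_ms, fix.onset + window_ms
        in_window = (self.onset <= hi) & (self.offset >= lo) & (self.pid != fix.participant)
        same = self.clip == clip
        return self.xy[in_window & same], self.xy[in_window & ~same]


def score_trial(
    trial: EventTrial,
    cohort_trials: list[EventTrial] | _CohortIndex,
    params: VPParams = VPParams(),
) -> list[VPRecord]:
    """VP records for every fixation of one trial against a control cohort."""
    index = (cohort_trials if isinstance(cohort_trials, _CohortIndex)
             else _CohortIndex(cohort_trials))
    records = []
    for i, fix in enumerate(trial.fixations):
        ref, rand = index.sets_for(fix, trial.clip, params.window_ms)
        vp = compute_vp(fix.position, ref, rand, params) if len(ref) else float("nan")
        records.append(VPRecord(
            fixation_id=i, onset=fix.onset, clip=trial.clip,
            participant=trial.participant, vp=vp,
            n_reference=len(ref), n_random=len(rand),
        ))
    return records


def score_cohort_member(
    trials: list[EventTrial],
    cohort_trials: list[EventTrial],
    params: VPParams = VPParams(),
) -> list[VPRecord]:
    """Score all of one participant's trials (leave-one-out is automatic:
    their own fixations never enter the pools)."""
    index = _CohortIndex(cohort_trials)
    out: list[VPRecord] = []
    for trial in trials:
        out.extend(score_trial(trial, index, params))
    return out


def summarize_vp(
    records: list[VPRecord],
    severity: dict | None = None,
) -> dict:
    """Per-trial and overall mean VP; optional correlations vs severity.

    ``severity`` maps measure name -> {participant: value}; each measure is
    correlated (Pearson) against the participants' overall mean VP.
    Undefined VP records are excluded from all means.
    """
    by_participant: dict[str, dict[str, list[float]]] = {}
    for r in records:
        if not np.isfinite(r.vp):
            continue
        by_participant.setdefault(r.participant, {}).setdefault(r.clip, []).append(r.vp)
    trial_means = {
        pid: {clip: float(np.mean(v)) for clip, v in clips.items()}
        for pid, clips in by_participant.items()
    }
    overall = {
        pid: float(np.mean(list(clips.values()))) for pid, clips in trial_means.items()
    }
    out = {"trial_means": trial_means, "overall_means": overall}
    if severity:
        correlations = {}
        for name, mapping in severity.items():
            pids = sorted(set(mapping) & set(overall))
            if len(pids) >= 3:
                correlations[name] = pearson_r(
                    [overall[p] for p in pids], [mapping[p] for p in pids]
                )
            else:
                correlations[name] = float("nan")
        out["correlations"] = correlations
    return out
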