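"""Kernel PCA over participant map distances and naive-Bayes classification.

Participants are compared through Euclidean distances between their
flattened visual-field maps, clip by clip.  Two kernel forms are used:

* ``all_clips`` — ``k_ij = exp(-0.5 * (meanDist_ij + maxDist_ij)^2 / sigma^2)``
  where meanDist/maxDist summarize the per-clip distances between
  participants i and j; bandwidth sigma defaults to 2 for fixation and VP
  maps and 0.2 for saccade maps (whose bin values, being proportions over
  116 bins, vary on a much smaller scale).
* ``per_clip`` — ``k_ij = exp(-Dist_ij)`` from the single-clip distance.

These kernels are functions of summed distances and are not guaranteed
positive semidefinite; after double-centering, negative eigenvalues are
dropped and their mass logged, keeping the projections real while staying
faithful to the published formulas.  Classification uses Gaussian naive
Bayes on the first components under stratified 10-fold cross-validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import accuracy_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB

from .maps import VFMap

__all__ = [
    "KernelSpec",
    "EmbeddingResult",
    "ClassifierConfig",
    "map_distances",
    "kernel_matrix",
    "kpca_project",
    "nb_crossval",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class KernelSpec:
    """Kernel form and bandwidth (map-distance units)."""

    form: str = "all_clips"  # all_clips | per_clip
    bandwidth: float = 2.0

    def __post_init__(self) -> None:
        if self.form not in ("all_clips", "per_clip"):
            raise ValueError("form must be 'all_clips' or 'per_clip'")
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")


@dataclass(frozen=True)
class EmbeddingResult:
    kernel: np.ndarray
    eigenvalues: np.ndarray        # retained positive eigenvalues, descending
    projections: np.ndarray        # (n_participants, n_retained)
    explained_variance: np.ndarray  # fractions of positive-eigenvalue mass
    dropped_mass: float            # |sum of negative eigenvalues|


@dataclass(frozen=True)
class ClassifierConfig:
    n_components: int = 5
    n_folds: int = 10
    seed: int = 0


def map_distances(maps_a: list[VFMap], maps_b: list[VFMap]) -> np.ndarray:
    """Per-clip Euclidean distances between two participants' flattened maps."""
    if len(maps_a) != len(maps_b):
        raise ValueError("participants must have maps for the same clips")
    return np.array([
        float(np.linalg.norm(a.values.ravel() - b.values.ravel()))
        for a, b in zip(maps_a, maps_b)
    ])


def kernel_matrix(
    maps_per_participant: dict[str, list[VFMap]],
    spec: KernelSpec = KernelSpec(),
    clip_index: int | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Pairwise participant kernel from per-clip map distances.

    ``maps_per_participant`` maps participant id -> per-clip maps in a
    shared clip order.  For ``per_clip`` form, ``clip_index`` selects the
    clip.  Diagonal entries use zero self-distance (hence 1 exactly).
    Returns ``(kernel, participant order)``.
    """
    pids = sorted(maps_per_participant)
    n = len(pids)
    if n < 2:
        raise ValueError("kernel needs >= 2 participants")
    k = np.ones((n, n))
    for i in range(n):
        for j in range(i, n):
            d = (np.zeros(1) if i == j
                 else map_distances(maps_per_participant[pids[i]],
                                    maps_per_participant[pids[j]]))
            if spec.form == "all_clips":
                s = d.mean() + d.max()
                kij = np.exp(-0.5 * s**2 / spec.bandwidth**2)
            else:
                if clip_index is None:
                    raise ValueError("per_clip kernel needs clip_index")
                kij = np.exp(-d[clip_index] if i != j else 0.0)
            k[i, j] = k[j, i] = kij
    return k, pids


def kpca_project(kernel: np.ndarray) -> EmbeddingResult:
    """Double-center the kernel, eigendecompose, project.

    Components sorted by descending eigenvalue; negative eigenvalues are
    dropped (mass logged); projection of participant i on component k is
    ``sqrt(lambda_k) * v_k[i]`` (standard kernel-PCA scaling).  Signs are
    fixed by making each component's largest-magnitude loading positive.
    """
    kernel = np.asarray(kernel, dtype=float)
    if kernel.ndim != 2 or kernel.shape[0] != kernel.shape[1]:
        raise ValueError("kernel must be square")
    if not np.allclose(kernel, kernel.T, atol=1e-10):
        raise ValueError("kernel must be symmetric")
    n = len(kernel)
    one = np.full((n, n), 1.0 / n)
    centered = kernel - one @ kernel - kernel @ one + one @ kernel @ one
    eigval, eigvec = np.linalg.eigh(centered)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(1e-12, 1e-12 * abs(eigval).max()) if n else 0.0
    pos = eigval > tol
    dropped = float(np.abs(eigval[eigval < -tol]).sum())
    if dropped > 0:
        log.info("kPCA dropped negative eigenvalue mass %.3g", dropped)
    lam = eigval[pos]
    vec = eigvec[:, pos]
    if lam.size == 0:
        log.warning("rank-0 embedding: all maps identical")
        return EmbeddingResult(kernel=kernel, eigenvalues=lam,
                               projections=np.zeros((n, 0)),
                               explained_variance=lam, dropped_mass=dropped)
    # deterministic sign: largest-|loading| entry positive
    for k in range(vec.shape[1]):
        imax = np.argmax(np.abs(vec[:, k]))
        if vec[imax, k] < 0:
            vec[:, k] = -vec[:, k]
    projections = vec * np.sqrt(lam)[None, :]
    return EmbeddingResult(
        kernel=kernel, eigenvalues=lam, projections=projections,
        explained_variance=lam / lam.sum(), dropped_mass=dropped,
    )


def nb_crossval(
    projections: np.ndarray,
    labels: np.ndarray,
    config: ClassifierConfig = ClassifierConfig(),
) -> dict:
    """Gaussian naive Bayes on the first components, stratified K-fold CV.

    Reports per-fold accuracies, their mean and range in the conventional
    "mean% (min - max%)" form.  A fold whose training split degenerates to a
    single class triggers a reseeded refold (logged).
    """
    x = np.asarray(projections, dtype=float)[:, : config.n_components]
    y = np.asarray(labels)
    seed = config.seed
    for attempt in range(20):
        skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True,
                              random_state=seed)
        folds = list(skf.split(x, y))
        if all(len(np.unique(y[tr])) > 1 for tr, _ in folds):
            break
        log.info("single-class training fold; refolding with new seed")
        seed += 1
    accuracies = []
    for train, test in folds:
        clf = GaussianNB().fit(x[train], y[train])
        accuracies.append(accuracy_score(y[test], clf.predict(x[test])))
    accuracies = np.array(accuracies)
    return {
        "fold_accuracies": accuracies,
        "mean": float(accuracies.mean()),
        "min": float(accuracies.min()),
        "max": float(accuracies.max()),
        "report": (f"{accuracies.mean() * 100:.1f}% "
                   f"({accuracies.min() * 100:.1f} - {accuracies.max() * 100:.1f}%)"),
    }
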