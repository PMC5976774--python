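"""Automatic selection of informative contrast strengths.

The only free parameter of cPCA is the contrast strength alpha.  Rather
than guessing a single value, the selection scheme fits cPCA on a
logarithmic alpha grid (40 values between 0.1 and 1000 by default, with
alpha = 0 prepended so the plain-PCA view is always a candidate), measures
how similar the resulting k-dimensional subspaces are via the product of
the cosines of their principal angles, clusters the subspaces with
spectral clustering on that affinity, and reports one *medoid* alpha per
cluster — a handful of genuinely different views the user inspects.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.linalg
from sklearn.cluster import SpectralClustering

from .core import ContrastiveModel, CovariancePair, DataMatrix, fit_cpca, transform

__all__ = [
    "AlphaSpectrum",
    "default_alpha_grid",
    "principal_angle_cosines",
    "max_principal_angle",
    "subspace_affinity",
    "cluster_alphas",
    "auto_cpca",
]


def default_alpha_grid(
    n_points: int = 40,
    low: float = 0.1,
    high: float = 1000.0,
    include_zero: bool = False,
) -> np.ndarray:
    """Log-spaced alpha grid; first = ``low``, last = ``high``.

    With ``include_zero`` the exact PCA limit alpha = 0 is prepended in
    front of the log-spaced part.
    """
    if low <= 0:
        raise ValueError("low must be > 0 (log spacing undefined at 0)")
    if high <= low:
        raise ValueError("need low < high")
    if n_points < 2:
        raise ValueError("need at least 2 grid points")
    grid = np.logspace(np.log10(low), np.log10(high), n_points)
    grid[0], grid[-1] = low, high  # exact endpoints
    if include_zero:
        grid = np.concatenate([[0.0], grid])
    return grid


def _check_orthonormal(b: np.ndarray, name: str) -> np.ndarray:
    b = np.asarray(b, dtype=float)
    if b.ndim != 2:
        raise ValueError(f"{name} must be a d x k matrix")
    gram = b.T @ b
    if not np.allclose(gram, np.eye(b.shape[1]), atol=1e-6):
        raise ValueError(f"{name} does not have orthonormal columns")
    return b


def principal_angle_cosines(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Cosines of the principal angles between span(a) and span(b).

    These are the singular values of ``a' b`` for orthonormal bases,
    sorted descending and clipped into [0, 1].
    """
    a = _check_orthonormal(a, "A")
    b = _check_orthonormal(b, "B")
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    sv = scipy.linalg.svd(a.T @ b, compute_uv=False)
    return np.clip(sv, 0.0, 1.0)


def max_principal_angle(a: np.ndarray, b: np.ndarray) -> float:
    """Largest principal angle (radians) — the natural subspace distance.

    Computed in the sine form ``sin(theta_max) = ||(I - A A') B||_2``,
    which stays accurate for nearly identical subspaces where the cosine
    form loses half the floating-point digits.
    """
    a = _check_orthonormal(a, "A")
    b = _check_orthonormal(b, "B")
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    resid = b - a @ (a.T @ b)
    s = scipy.linalg.svd(resid, compute_uv=False)[0]
    return float(np.arcsin(min(1.0, s)))


def subspace_affinity(a: np.ndarray, b: np.ndarray) -> float:
    """Product of the principal-angle cosines; 1 iff the subspaces coincide."""
    return float(np.prod(principal_angle_cosines(a, b)))


@dataclass
class AlphaSpectrum:
    """The alpha grid with one subspace per alpha and its clustering.

    ``medoid_alphas`` are the representative contrast strengths (ascending);
    ``medoid_indices`` locate them on the grid.
    """

    alphas: np.ndarray
    subspaces: list[np.ndarray]
    affinity: np.ndarray
    cluster_labels: np.ndarray
    medoid_alphas: np.ndarray
    medoid_indices: np.ndarray

    def to_dict(self) -> dict:
        return {
            "alphas": self.alphas.tolist(),
            "affinity": self.affinity.tolist(),
            "cluster_labels": self.cluster_labels.tolist(),
            "medoid_alphas": self.medoid_alphas.tolist(),
            "medoid_indices": self.medoid_indices.tolist(),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def _affinity_matrix(subspaces: list[np.ndarray]) -> np.ndarray:
    n = len(subspaces)
    aff = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aff[i, j] = aff[j, i] = subspace_affinity(subspaces[i], subspaces[j])
    return aff


def _medoid(indices: np.ndarray, affinity: np.ndarray) -> int:
    """Cluster member maximizing within-cluster affinity; ties -> first
    (smallest alpha, since grids are ascending)."""
    sub = affinity[np.ix_(indices, indices)]
    return int(indices[int(np.argmax(sub.sum(axis=1)))])


def cluster_alphas(
    alphas: np.ndarray,
    subspaces: list[np.ndarray],
    n_clusters: int,
    seed: int = 0,
) -> AlphaSpectrum:
    """Cluster the per-alpha subspaces and pick one medoid alpha per cluster.

    Spectral clustering runs on the precomputed cosine-product affinity
    (normalized graph Laplacian, k-means on the leading eigenvectors, seeded).
    Degenerate grids are handled explicitly: an all-identical family of
    subspaces collapses to a single medoid with a warning, and an affinity
    with no off-diagonal mass falls back to evenly spaced medoids.
    """
    alphas = np.asarray(alphas, dtype=float)
    n = len(alphas)
    if len(subspaces) != n:
        raise ValueError("one subspace per alpha required")
    if not 1 <= n_clusters <= n:
        raise ValueError(f"n_clusters must be in [1, {n}], got {n_clusters}")
    affinity = _affinity_matrix(subspaces)

    off = affinity[~np.eye(n, dtype=bool)] if n > 1 else np.array([])
    if n == 1 or off.size == 0 or np.all(off > 1.0 - 1e-10):
        if n_clusters > 1:
            warnings.warn(
                "all subspaces on the alpha grid coincide; returning a "
                "single medoid",
                stacklevel=2,
            )
        labels = np.zeros(n, dtype=int)
        medoids = np.array([0])
    elif np.all(off < 1e-12):
        warnings.warn(
            "affinity has no off-diagonal mass; falling back to evenly "
            "spaced medoid alphas",
            stacklevel=2,
        )
        medoids = np.unique(
            np.round(np.linspace(0, n - 1, n_clusters)).astype(int)
        )
        labels = np.argmin(
            np.abs(np.arange(n)[:, None] - medoids[None, :]), axis=1
        )
    elif n_clusters == 1:
        labels = np.zeros(n, dtype=int)
        medoids = np.array([_medoid(np.arange(n), affinity)])
    else:
        sc = SpectralClustering(
            n_clusters=n_clusters,
            affinity="precomputed",
            assign_labels="kmeans",
            random_state=seed,
        )
        labels = sc.fit_predict(affinity)
        medoids = np.array(
            [
                _medoid(np.flatnonzero(labels == lab), affinity)
                for lab in np.unique(labels)
            ]
        )
        if len(np.unique(labels)) < n_clusters:
            warnings.warn(
                "spectral clustering produced fewer clusters than requested",
                stacklevel=2,
            )
    medoids = np.sort(medoids)
    return AlphaSpectrum(
        alphas=alphas,
        subspaces=list(subspaces),
        affinity=affinity,
        cluster_labels=np.asarray(labels, dtype=int),
        medoid_alphas=alphas[medoids],
        medoid_indices=medoids,
    )


def auto_cpca(
    target: DataMatrix,
    background: DataMatrix,
    k: int = 2,
    n_medoids: int = 4,
    *,
    alphas: np.ndarray | None = None,
    include_zero: bool = True,
    standardize: bool = False,
    seed: int = 0,
    return_spectrum: bool = False,
):
    """Fit cPCA across the alpha grid and return one view per medoid alpha.

    Returns a list of ``(ContrastiveModel, target embedding)`` pairs in
    ascending alpha order — typically four genuinely different projections
    of the target for the user to inspect.  With ``return_spectrum`` the
    full :class:`AlphaSpectrum` is returned as a second value.
    """
    if alphas is None:
        grid = default_alpha_grid(include_zero=include_zero)
    else:
        grid = np.sort(np.asarray(alphas, dtype=float))
    target_orig = target
    if standardize:
        s = target.values.std(axis=0)
        s = np.where(s > 0, s, 1.0)
        target = DataMatrix(target.values / s, target.feature_ids, target.sample_ids)
        background = DataMatrix(
            background.values / s, background.feature_ids, background.sample_ids
        )
    else:
        s = None
    cov = CovariancePair.from_data(target, background)
    x_mean = target.values.mean(axis=0)
    models = [
        fit_cpca(
            cov, a, k, mean=x_mean, scale=s, feature_ids=list(target.feature_ids)
        )
        for a in grid
    ]
    spectrum = cluster_alphas(
        grid, [m.components for m in models], min(n_medoids, len(grid)), seed=seed
    )
    results = [
        (models[i], transform(target_orig, models[i]))
        for i in spectrum.medoid_indices
    ]
    if return_spectrum:
        return results, spectrum
    return results
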