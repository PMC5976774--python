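"""Kernelized contrastive PCA.

Linear cPCA can only expose contrastive structure that lives in a linear
subspace.  The kernel variant maps all points into a reproducing-kernel
feature space and runs the same variance contrast there, which uncovers
nonlinear target-specific structure (e.g. concentric rings the target has
but the background lacks).

Construction.  Let ``z_1..z_N`` be the concatenated target (n) and
background (m) points, ``K`` their Gram matrix and ``H = I - 11'/N`` the
centering projector.  Directions are sought in the span of the jointly
centered mapped points, ``v = sum_j beta_j (phi(z_j) - mu)``, while the
target and background covariance operators center each dataset by its own
feature-space mean (exactly as the linear method does), giving the
generalized symmetric eigenproblem

    maximize  beta' Q beta   s.t.  beta' K~ beta = 1,
    Q  = (1/n) (HK) G_X (KH) - (alpha/m) (HK) G_Y (KH),
    K~ = H K H,

where ``G_X`` (resp. ``G_Y``) is the within-target (within-background)
centering projector embedded in N x N.  Under the linear kernel this
reproduces linear cPCA exactly, which is the module's verifiable anchor.
``K~`` is always singular (centering removes at least one direction), so
the problem is solved on its spectral range: eigenvalues below the
documented cutoff ``1e-10 * trace`` are treated as null and the search is
whitened within the remaining span.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from sklearn.metrics.pairwise import pairwise_kernels

from .core import DataMatrix

__all__ = ["KernelModel", "kernel_matrix", "fit_kernel_cpca", "kernel_transform"]

_KERNELS = ("linear", "rbf")


def kernel_matrix(
    points_a: np.ndarray,
    points_b: np.ndarray,
    kernel: str = "rbf",
    gamma: float | None = None,
) -> np.ndarray:
    """Gram matrix between two point sets.

    ``rbf`` uses ``exp(-gamma * ||a - b||^2)`` with the scikit-learn
    convention ``gamma = 1 / (2 sigma^2)`` for bandwidth sigma; the default
    is ``1 / n_features``.
    """
    a = np.atleast_2d(np.asarray(points_a, dtype=float))
    b = np.atleast_2d(np.asarray(points_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("point sets must share the feature dimension")
    if kernel not in _KERNELS:
        raise ValueError(f"kernel must be one of {_KERNELS}, got {kernel!r}")
    if kernel == "rbf":
        if gamma is not None and gamma <= 0:
            raise ValueError("gamma (inverse squared bandwidth) must be > 0")
        return pairwise_kernels(a, b, metric="rbf", gamma=gamma)
    return pairwise_kernels(a, b, metric="linear")


@dataclass
class KernelModel:
    """Fitted kernel-cPCA model.

    ``dual_coef`` holds one coefficient per training point and component;
    the feature-space direction is the corresponding combination of the
    jointly centered mapped training points, normalized to unit
    feature-space norm (beta' K~ beta = 1).
    """

    kernel: str
    gamma: float | None
    alpha: float
    k: int
    dual_coef: np.ndarray  # (n + m, k)
    eigenvalues: np.ndarray
    train_points: np.ndarray  # (n + m, d), target rows first
    n: int
    m: int
    col_means: np.ndarray  # column means of the training Gram matrix
    grand_mean: float
    target_embedding: np.ndarray  # (n, k), training-target coordinates


def _block_centerer(n_total: int, start: int, count: int) -> np.ndarray:
    g = np.zeros((n_total, n_total))
    block = np.eye(count) - np.ones((count, count)) / count
    g[start : start + count, start : start + count] = block
    return g


def fit_kernel_cpca(
    target: DataMatrix,
    background: DataMatrix,
    alpha: float,
    k: int = 2,
    kernel: str = "rbf",
    gamma: float | None = None,
) -> KernelModel:
    """Solve the contrastive eigenproblem in kernel feature space."""
    if not (np.isfinite(alpha) and alpha >= 0):
        raise ValueError(f"alpha must be finite and >= 0, got {alpha}")
    if target.n_features != background.n_features:
        raise ValueError("target and background must share the feature dimension")
    x, y = target.values, background.values
    n, m = x.shape[0], y.shape[0]
    big_n = n + m
    if not 1 <= k <= big_n:
        raise ValueError(f"k must be in [1, {big_n}]")
    z = np.vstack([x, y])
    k_full = kernel_matrix(z, z, kernel=kernel, gamma=gamma)
    h = np.eye(big_n) - np.ones((big_n, big_n)) / big_n
    k_cent = h @ k_full @ h
    k_cent = (k_cent + k_cent.T) / 2.0

    kh = k_full @ h
    g_x = _block_centerer(big_n, 0, n)
    g_y = _block_centerer(big_n, n, m)
    q = (kh.T @ g_x @ kh) / n - alpha * (kh.T @ g_y @ kh) / m
    q = (q + q.T) / 2.0

    # Solve on the spectral range of K~: directions outside it have zero
    # feature-space norm and would otherwise pollute the top of the
    # spectrum with zero-Rayleigh artefacts.  Eigenvalues below the
    # documented cutoff 1e-10 * trace are treated as null.
    trace = float(np.trace(k_cent))
    cutoff = 1e-10 * (trace if trace > 0 else 1.0)
    s, u = scipy.linalg.eigh(k_cent)
    keep = s > cutoff
    r = int(keep.sum())
    if r < big_n - 1:  # one null direction is structural (centering)
        warnings.warn(
            f"centered kernel matrix is rank-deficient (rank {r} of "
            f"{big_n}); restricting to its span",
            stacklevel=2,
        )
    if k > r:
        raise ValueError(
            f"k={k} exceeds the centered kernel rank {r}"
        )
    whiten = u[:, keep] / np.sqrt(s[keep])  # beta = whiten @ gamma
    q_r = whiten.T @ q @ whiten
    q_r = (q_r + q_r.T) / 2.0
    w, coefs = scipy.linalg.eigh(q_r)
    order = np.argsort(w)[::-1][:k]
    beta = whiten @ coefs[:, order]
    # deterministic sign: largest-magnitude dual coefficient positive
    for j in range(beta.shape[1]):
        i = int(np.argmax(np.abs(beta[:, j])))
        if beta[i, j] < 0:
            beta[:, j] = -beta[:, j]

    return KernelModel(
        kernel=kernel,
        gamma=gamma,
        alpha=float(alpha),
        k=k,
        dual_coef=beta,
        eigenvalues=w[order],
        train_points=z,
        n=n,
        m=m,
        col_means=k_full.mean(axis=0),
        grand_mean=float(k_full.mean()),
        target_embedding=k_cent[:n] @ beta,
    )


def kernel_transform(model: KernelModel, points: np.ndarray | DataMatrix) -> np.ndarray:
    """Project new points: centered kernel row against the dual coefficients."""
    if isinstance(points, DataMatrix):
        points = points.values
    points = np.atleast_2d(np.asarray(points, dtype=float))
    k_new = kernel_matrix(
        points, model.train_points, kernel=model.kernel, gamma=model.gamma
    )
    k_cent = (
        k_new
        - k_new.mean(axis=1, keepdims=True)
        - model.col_means[None, :]
        + model.grand_mean
    )
    return k_cent @ model.dual_coef
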