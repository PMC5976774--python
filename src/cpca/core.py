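"""Linear contrastive PCA: the covariance-difference eigenproblem.

Contrastive PCA (cPCA) compares a *target* dataset ``{x_i}`` against a
*background* dataset ``{y_i}`` defined over the same features.  For a unit
direction ``v`` write

    lambda_X(v) = v' C_X v      (target variance along v)
    lambda_Y(v) = v' C_Y v      (background variance along v)

where ``C_X`` and ``C_Y`` are the empirical covariance matrices.  Given a
contrast strength ``alpha >= 0`` the first contrastive principal component
(cPC) maximizes ``lambda_X(v) - alpha * lambda_Y(v)`` over unit vectors,
which is solved exactly by the leading eigenvector of the (indefinite)
symmetric matrix ``C = C_X - alpha * C_Y``; the top-k cPCs are its leading
eigenvectors sorted by *signed* eigenvalue.

Two limits anchor the interpretation: ``alpha = 0`` is ordinary PCA on the
target, and ``alpha = inf`` projects the target onto the null space of the
background covariance before running PCA there.

Conventions (deliberate, documented so users can reconcile alphas across
implementations):

* covariance divisor ``1/n`` (maximum likelihood), not ``1/(n-1)``;
* each dataset is centered by its **own** mean;
* eigenvalues are sorted by signed value descending (``C`` is indefinite,
  magnitude sorting would promote background-dominated directions);
* each component's largest-magnitude entry is made positive.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.linalg

__all__ = [
    "DataMatrix",
    "CovariancePair",
    "ContrastiveModel",
    "VariancePair",
    "empirical_covariance",
    "contrastive_matrix",
    "fit_cpca",
    "fit_cpca_infinite_alpha",
    "fit",
    "variance_pair",
    "transform",
]

_SYM_TOL = 1e-8


@dataclass
class DataMatrix:
    """A samples-by-features numeric matrix with feature labels.

    Parameters
    ----------
    values : (n, d) array
        One row per sample, one column per feature.  Must be finite.
    feature_ids : sequence of str
        Unique label per feature (gene names, pixel ids, SNP ids, ...).
    sample_ids : sequence of str, optional
        Label per sample.
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.feature_ids = [str(f) for f in self.feature_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-d samples x features matrix")
        n, d = self.values.shape
        if n < 1 or d < 1:
            raise ValueError("need at least one sample and one feature")
        if len(self.feature_ids) != d:
            raise ValueError(
                f"{len(self.feature_ids)} feature_ids for {d} columns"
            )
        if len(set(self.feature_ids)) != d:
            dupes = sorted(
                {f for f in self.feature_ids if self.feature_ids.count(f) > 1}
            )
            raise ValueError(f"feature_ids not unique: {dupes[:5]}")
        bad = ~np.isfinite(self.values)
        if bad.any():
            j = int(np.argwhere(bad.any(axis=0)).ravel()[0])
            raise ValueError(
                f"non-finite values in feature {self.feature_ids[j]!r}"
            )
        if self.sample_ids is not None:
            self.sample_ids = [str(s) for s in self.sample_ids]
            if len(self.sample_ids) != n:
                raise ValueError(
                    f"{len(self.sample_ids)} sample_ids for {n} rows"
                )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_array(
        cls, values: np.ndarray, prefix: str = "f"
    ) -> "DataMatrix":
        """Wrap a bare array, generating feature ids ``f0, f1, ...``."""
        values = np.atleast_2d(np.asarray(values, dtype=float))
        return cls(values, [f"{prefix}{j}" for j in range(values.shape[1])])


def empirical_covariance(data: DataMatrix) -> np.ndarray:
    """Maximum-likelihood covariance ``(1/n) sum (x_i - mean)(x_i - mean)'``.

    The divisor is ``n`` so a single sample yields the zero matrix; the cPCA
    objective is unchanged by a joint rescaling of both covariances and
    alpha, so the choice only matters when comparing alphas across
    conventions.
    """
    x = data.values
    centered = x - x.mean(axis=0)
    cov = centered.T @ centered / x.shape[0]
    return (cov + cov.T) / 2.0


@dataclass
class CovariancePair:
    """The pair ``(C_X, C_Y)`` of target/background covariances.

    Carries the sample counts ``n`` (target) and ``m`` (background) so that
    finite-sample diagnostics can refer to ``min(n, m)``.
    """

    c_x: np.ndarray
    c_y: np.ndarray
    n: int
    m: int

    def __post_init__(self) -> None:
        self.c_x = np.asarray(self.c_x, dtype=float)
        self.c_y = np.asarray(self.c_y, dtype=float)
        for name, c in (("C_X", self.c_x), ("C_Y", self.c_y)):
            if c.ndim != 2 or c.shape[0] != c.shape[1]:
                raise ValueError(f"{name} must be square")
            if not np.allclose(c, c.T, atol=_SYM_TOL * max(1.0, np.abs(c).max())):
                raise ValueError(f"{name} is not symmetric")
            tr = np.trace(c)
            if tr > 0:
                w_min = scipy.linalg.eigvalsh(c, subset_by_index=[0, 0])[0]
                if w_min < -1e-8 * tr:
                    raise ValueError(f"{name} is not positive semidefinite")
        if self.c_x.shape != self.c_y.shape:
            raise ValueError(
                f"dimension mismatch: C_X is {self.c_x.shape}, "
                f"C_Y is {self.c_y.shape}"
            )

    @property
    def dim(self) -> int:
        return self.c_x.shape[0]

    @classmethod
    def from_data(
        cls, target: DataMatrix, background: DataMatrix
    ) -> "CovariancePair":
        if target.n_features != background.n_features:
            raise ValueError(
                "target and background must share the feature dimension "
                f"({target.n_features} vs {background.n_features})"
            )
        return cls(
            empirical_covariance(target),
            empirical_covariance(background),
            n=target.n_samples,
            m=background.n_samples,
        )


@dataclass
class VariancePair:
    """``(lambda_X(v), lambda_Y(v))`` for one unit direction v."""

    lambda_x: float
    lambda_y: float


@dataclass
class ContrastiveModel:
    """Fitted cPCA model for a single contrast strength.

    ``components`` is a d x k matrix with orthonormal columns (the cPCs);
    ``eigenvalues`` the matching eigenvalues of ``C_X - alpha C_Y`` in
    descending order.  ``mean`` (and ``scale`` when standardization was
    requested) are the target-training statistics applied before
    projection.  ``alpha`` may be ``math.inf`` for the null-space limit.
    """

    alpha: float
    components: np.ndarray
    eigenvalues: np.ndarray
    k: int
    mean: np.ndarray
    scale: np.ndarray | None = None
    feature_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        d, k = self.components.shape
        if k != self.k or self.eigenvalues.shape != (k,):
            raise ValueError("inconsistent model dimensions")
        gram = self.components.T @ self.components
        if not np.allclose(gram, np.eye(k), atol=1e-8):
            raise ValueError("components are not orthonormal")
        if np.any(np.diff(self.eigenvalues) > 1e-10):
            raise ValueError("eigenvalues must be sorted descending")

    @property
    def dim(self) -> int:
        return self.components.shape[0]

    def to_dict(self) -> dict:
        return {
            "alpha": "inf" if math.isinf(self.alpha) else float(self.alpha),
            "k": int(self.k),
            "components": self.components.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "mean": self.mean.tolist(),
            "scale": None if self.scale is None else np.asarray(self.scale).tolist(),
            "feature_ids": self.feature_ids,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "ContrastiveModel":
        alpha = math.inf if doc["alpha"] == "inf" else float(doc["alpha"])
        scale = doc.get("scale")
        return cls(
            alpha=alpha,
            components=np.asarray(doc["components"], dtype=float),
            eigenvalues=np.asarray(doc["eigenvalues"], dtype=float),
            k=int(doc["k"]),
            mean=np.asarray(doc["mean"], dtype=float),
            scale=None if scale is None else np.asarray(scale, dtype=float),
            feature_ids=doc.get("feature_ids"),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ContrastiveModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def contrastive_matrix(cov: CovariancePair, alpha: float) -> np.ndarray:
    """``C = C_X - alpha * C_Y``, explicitly symmetrized."""
    if not (np.isfinite(alpha) and alpha >= 0):
        raise ValueError(f"alpha must be finite and >= 0, got {alpha}")
    c = cov.c_x - alpha * cov.c_y
    return (c + c.T) / 2.0


def _fix_signs(components: np.ndarray) -> np.ndarray:
    """Make each column's largest-magnitude entry positive (deterministic)."""
    out = components.copy()
    for j in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, j])))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


def fit_cpca(
    cov: CovariancePair,
    alpha: float,
    k: int,
    *,
    mean: np.ndarray | None = None,
    scale: np.ndarray | None = None,
    feature_ids: list[str] | None = None,
) -> ContrastiveModel:
    """Solve the contrastive eigenproblem for one finite alpha.

    Returns the top-``k`` eigenvectors of ``C_X - alpha C_Y`` sorted by
    signed eigenvalue descending.  ``mean``/``scale`` (the target training
    statistics) are stored for later projection; they default to zero mean
    and unit scale when fitting straight from covariances.
    """
    d = cov.dim
    if not 1 <= k <= d:
        raise ValueError(f"k must be in [1, {d}], got {k}")
    c = contrastive_matrix(cov, alpha)
    w, v = scipy.linalg.eigh(c)
    order = np.argsort(w)[::-1][:k]
    components = _fix_signs(v[:, order])
    return ContrastiveModel(
        alpha=float(alpha),
        components=components,
        eigenvalues=w[order],
        k=k,
        mean=np.zeros(d) if mean is None else np.asarray(mean, dtype=float),
        scale=scale,
        feature_ids=feature_ids,
    )


def fit_cpca_infinite_alpha(
    target: DataMatrix, background: DataMatrix, k: int
) -> ContrastiveModel:
    """The ``alpha = inf`` limit: PCA of the target within null(C_Y).

    Any direction with nonzero background variance receives an infinite
    penalty, so the cPCs must lie in the null space of the background
    covariance; within that subspace the objective is plain target
    variance.  Requires ``rank(C_Y) < d``.
    """
    if target.n_features != background.n_features:
        raise ValueError("target and background must share the feature dimension")
    c_y = empirical_covariance(background)
    d = c_y.shape[0]
    tr = float(np.trace(c_y))
    w, v = scipy.linalg.eigh(c_y)
    if tr > 0:
        null_mask = w < 1e-8 * tr
    else:  # background identically constant: the null space is all of R^d
        null_mask = np.ones(d, dtype=bool)
    r = int(null_mask.sum())
    if r == 0:
        raise ValueError(
            "C_Y has full rank: the infinite-alpha limit is undefined; "
            "use a large finite alpha instead"
        )
    if k > r:
        raise ValueError(
            f"k={k} exceeds the background null-space dimension {r}"
        )
    basis = v[:, null_mask]  # d x r
    x_mean = target.values.mean(axis=0)
    projected = (target.values - x_mean) @ basis  # n x r
    cov_proj = projected.T @ projected / target.n_samples
    cov_proj = (cov_proj + cov_proj.T) / 2.0
    w_p, v_p = scipy.linalg.eigh(cov_proj)
    order = np.argsort(w_p)[::-1][:k]
    components = _fix_signs(basis @ v_p[:, order])
    return ContrastiveModel(
        alpha=math.inf,
        components=components,
        eigenvalues=w_p[order],
        k=k,
        mean=x_mean,
        feature_ids=list(target.feature_ids),
    )


def fit(
    target: DataMatrix,
    background: DataMatrix,
    alpha: float,
    k: int = 2,
    *,
    standardize: bool = False,
) -> ContrastiveModel:
    """Fit cPCA from raw data matrices (the usual entry point).

    Computes both covariances (each dataset centered by its own mean),
    stores the target training mean for projection, and dispatches to the
    null-space construction when ``alpha`` is infinite.  With
    ``standardize=True`` each feature is divided by its target standard
    deviation (the same scaling is applied to the background), off by
    default.
    """
    if target.n_features != background.n_features:
        raise ValueError("target and background must share the feature dimension")
    if standardize:
        s = target.values.std(axis=0)
        s = np.where(s > 0, s, 1.0)
        target_s = DataMatrix(
            target.values / s, target.feature_ids, target.sample_ids
        )
        background_s = DataMatrix(
            background.values / s, background.feature_ids, background.sample_ids
        )
    else:
        s = None
        target_s, background_s = target, background
    if math.isinf(alpha):
        model = fit_cpca_infinite_alpha(target_s, background_s, k)
        model.scale = s  # mean already lives in the scaled space
        return model
    cov = CovariancePair.from_data(target_s, background_s)
    return fit_cpca(
        cov,
        alpha,
        k,
        mean=target_s.values.mean(axis=0),
        scale=s,
        feature_ids=list(target.feature_ids),
    )


def variance_pair(cov: CovariancePair, v: np.ndarray) -> VariancePair:
    """Evaluate ``(v' C_X v, v' C_Y v)`` for a unit direction."""
    v = np.asarray(v, dtype=float).ravel()
    if v.shape[0] != cov.dim:
        raise ValueError(f"direction has dim {v.shape[0]}, expected {cov.dim}")
    nrm = np.linalg.norm(v)
    if abs(nrm - 1.0) > 1e-8:
        raise ValueError(f"v must be a unit vector, ||v|| = {nrm}")
    return VariancePair(float(v @ cov.c_x @ v), float(v @ cov.c_y @ v))


def transform(data: DataMatrix, model: ContrastiveModel) -> np.ndarray:
    """Project data onto the cPCs: ``(values - training mean) @ components``.

    Centering always uses the *target training* mean stored in the model
    (and the training scale when the model was fit with standardization),
    so target and any other dataset land in the same coordinates.
    """
    if data.n_features != model.dim:
        raise ValueError(
            f"data has {data.n_features} features, model expects {model.dim}"
        )
    if model.feature_ids is not None and data.feature_ids != model.feature_ids:
        if set(data.feature_ids) == set(model.feature_ids):
            raise ValueError(
                "feature order differs from the training data; "
                "align features before transforming"
            )
        warnings.warn("feature_ids differ from the training data", stacklevel=2)
    values = data.values
    if model.scale is not None:
        values = values / model.scale
    return (values - model.mean) @ model.components
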