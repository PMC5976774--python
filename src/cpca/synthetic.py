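"""Synthetic target/background scenarios with planted ground truth.

Contrastive analysis is hard to validate on real data because the
"interesting" structure is not annotated.  Each generator here plants the
structure explicitly and returns it alongside the data, emulating the
method's motivating use cases:

* :func:`make_subgroup_scenario` — a diseased-vs-control style design:
  target and background share a dominant low-rank background covariance,
  and only the target carries subgroup mean shifts along a signal subspace
  deliberately placed orthogonal to the top background directions, so
  plain PCA is confounded by construction.
* :func:`make_glyph_scenario` — images of smooth random texture (shared by
  target and background) with one of two sparse glyphs (a ring or a bar)
  superimposed on each target image; the texture variance dominates the
  top principal components while the glyph identity is the planted label.
* :func:`make_ring_scenario` — a nonlinear scenario: the target holds two
  concentric rings, the background a single ring at the intermediate
  radius with the same radial jitter; no linear direction separates the
  target rings.
* :func:`make_population_model` — a population covariance pair with a
  known population first cPC, for finite-sample convergence studies.

All generators are deterministic functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.linalg
from scipy.ndimage import gaussian_filter
from sklearn.cluster import KMeans

from .core import CovariancePair, DataMatrix, fit_cpca

__all__ = [
    "SubgroupScenario",
    "GlyphImageScenario",
    "RingScenario",
    "PopulationModel",
    "make_subgroup_scenario",
    "make_glyph_scenario",
    "make_ring_scenario",
    "make_population_model",
    "make_default_population_model",
    "convergence_error_ratio",
    "kmeans_accuracy",
]


@dataclass
class SubgroupScenario:
    target: DataMatrix
    background: DataMatrix
    true_labels: np.ndarray  # subgroup label per target sample
    signal_basis: np.ndarray  # d x k_s orthonormal planted signal subspace
    params: dict


@dataclass
class GlyphImageScenario:
    target: DataMatrix
    background: DataMatrix
    labels: np.ndarray  # 0 = ring glyph, 1 = bar glyph
    ring_mask: np.ndarray  # flattened boolean masks
    bar_mask: np.ndarray
    side: int
    params: dict


@dataclass
class RingScenario:
    target: DataMatrix
    background: DataMatrix
    labels: np.ndarray  # ring membership (0 inner, 1 outer)
    params: dict


@dataclass
class PopulationModel:
    """Known population covariances with a well-separated first cPC."""

    cov_x: np.ndarray
    cov_y: np.ndarray
    alpha: float
    population_cpc: np.ndarray
    eigengap: float

    def sample_pair(self, n: int, m: int, rng: np.random.Generator) -> CovariancePair:
        """Draw Gaussian samples and return their empirical covariances."""
        lx = np.linalg.cholesky(self.cov_x + 1e-12 * np.eye(self.cov_x.shape[0]))
        ly = np.linalg.cholesky(self.cov_y + 1e-12 * np.eye(self.cov_y.shape[0]))
        x = rng.standard_normal((n, lx.shape[0])) @ lx.T
        y = rng.standard_normal((m, ly.shape[0])) @ ly.T
        return CovariancePair.from_data(
            DataMatrix.from_array(x), DataMatrix.from_array(y)
        )


def _random_orthogonal(d: int, rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((d, d)))
    return q * np.sign(np.diag(r))


def make_subgroup_scenario(
    d: int = 30,
    n: int = 500,
    m: int = 500,
    k_s: int = 1,
    signal_strength: float = 3.5,
    background_spectrum: Sequence[float] = (40.0, 30.0, 20.0),
    noise: float = 1.0,
    seed: int = 0,
) -> SubgroupScenario:
    """Shared background covariance plus target-only subgroup mean shifts.

    Background samples are zero-mean Gaussian with covariance
    ``Q diag(spectrum) Q' + noise^2 I`` (Q random orthogonal, the spectrum
    padded with zeros to length d).  Target samples share that covariance
    and additionally receive a subgroup mean shift of +-``signal_strength``
    along a random unit vector inside the planted signal subspace, which is
    drawn from the orthogonal complement of the top background directions —
    so the leading PCs of the target are background axes, not the signal.
    """
    spectrum = np.asarray(background_spectrum, dtype=float)
    k_b = spectrum.size
    if not 1 <= k_s < d:
        raise ValueError("need 1 <= k_s < d")
    if k_b + k_s > d:
        raise ValueError("background spectrum plus signal exceed the dimension")
    if signal_strength < 0 or noise < 0:
        raise ValueError("signal_strength and noise must be >= 0")
    rng = np.random.default_rng(seed)
    q = _random_orthogonal(d, rng)
    bg_dirs = q[:, :k_b]
    signal_basis = q[:, k_b : k_b + k_s]  # orthogonal to top background axes

    def draw_background_like(count: int) -> np.ndarray:
        loadings = rng.standard_normal((count, k_b)) * np.sqrt(spectrum)
        return loadings @ bg_dirs.T + noise * rng.standard_normal((count, d))

    background = draw_background_like(m)
    target = draw_background_like(n)
    labels = rng.integers(0, 2, size=n)
    # one random unit direction inside the signal subspace per scenario
    u = rng.standard_normal(k_s)
    u /= np.linalg.norm(u)
    shift_dir = signal_basis @ u
    target += np.where(labels[:, None] == 1, 1.0, -1.0) * signal_strength * shift_dir

    features = [f"f{j}" for j in range(d)]
    return SubgroupScenario(
        target=DataMatrix(target, features),
        background=DataMatrix(background, features),
        true_labels=labels,
        signal_basis=signal_basis,
        params=dict(
            d=d, n=n, m=m, k_s=k_s, signal_strength=signal_strength,
            background_spectrum=tuple(spectrum), noise=noise, seed=seed,
        ),
    )


def _texture(rng: np.random.Generator, count: int, side: int,
             sigma: float, std: float) -> np.ndarray:
    """Smooth random fields: white noise blurred then rescaled to ``std``."""
    # periodic smoothing keeps the field stationary: every pixel has the
    # same marginal distribution, edges included
    fields = gaussian_filter(
        rng.standard_normal((count, side, side)), sigma=(0, sigma, sigma),
        mode="wrap",
    )
    fields *= std / fields.std()
    return fields.reshape(count, side * side)


def _glyph_masks(side: int) -> tuple[np.ndarray, np.ndarray]:
    yy, xx = np.mgrid[0:side, 0:side]
    c = (side - 1) / 2.0
    rad = np.hypot(yy - c, xx - c)
    ring = np.abs(rad - side / 4.0) < 0.8
    bar = (np.abs(xx - c) < 1.0) & (np.abs(yy - c) < side / 3.0)
    return ring.ravel(), bar.ravel()


def make_glyph_scenario(
    n_target: int = 500,
    n_background: int = 500,
    side: int = 16,
    texture_std: float = 3.0,
    smoothing: float = 2.5,
    glyph_contrast: tuple[float, float] = (1.0, 2.0),
    pixel_noise: float = 0.5,
    seed: int = 0,
) -> GlyphImageScenario:
    """Texture-background images with one of two sparse glyphs on the target.

    Target and background textures are independent draws from the same
    smoothed-noise process (identical smoothing and amplitude), so their
    covariance structure matches; only the target carries glyphs, each
    drawn with a random contrast in ``glyph_contrast``.
    """
    if side < 8:
        raise ValueError("side must be >= 8")
    rng = np.random.default_rng(seed)
    d = side * side
    ring, bar = _glyph_masks(side)

    background = _texture(rng, n_background, side, smoothing, texture_std)
    background += pixel_noise * rng.standard_normal(background.shape)
    target = _texture(rng, n_target, side, smoothing, texture_std)
    target += pixel_noise * rng.standard_normal(target.shape)
    labels = rng.integers(0, 2, size=n_target)
    contrast = rng.uniform(*glyph_contrast, size=n_target)
    masks = np.where(labels[:, None] == 0, ring[None, :], bar[None, :])
    target += contrast[:, None] * masks

    features = [f"px{j}" for j in range(d)]
    return GlyphImageScenario(
        target=DataMatrix(target, features),
        background=DataMatrix(background, features),
        labels=labels,
        ring_mask=ring,
        bar_mask=bar,
        side=side,
        params=dict(
            n_target=n_target, n_background=n_background, side=side,
            texture_std=texture_std, smoothing=smoothing,
            glyph_contrast=glyph_contrast, pixel_noise=pixel_noise, seed=seed,
        ),
    )


def make_ring_scenario(
    n_per_ring: int = 150,
    n_background: int = 300,
    radii: tuple[float, float] = (1.0, 3.0),
    background_radius: float | None = None,
    radial_noise: float = 0.1,
    seed: int = 0,
) -> RingScenario:
    """Two concentric target rings; background = one intermediate ring.

    Both datasets share the angular uniformity and the radial jitter
    process; only the target is radially bimodal.  By symmetry no linear
    projection separates the two target rings, so this scenario separates
    kernel cPCA from the linear method.
    """
    rng = np.random.default_rng(seed)
    r_in, r_out = radii
    if background_radius is None:
        background_radius = (r_in + r_out) / 2.0

    def ring(count: int, radius: float) -> np.ndarray:
        theta = rng.uniform(0, 2 * np.pi, count)
        r = radius + radial_noise * rng.standard_normal(count)
        return np.column_stack([r * np.cos(theta), r * np.sin(theta)])

    target = np.vstack([ring(n_per_ring, r_in), ring(n_per_ring, r_out)])
    labels = np.repeat([0, 1], n_per_ring)
    background = ring(n_background, background_radius)
    perm = rng.permutation(2 * n_per_ring)
    return RingScenario(
        target=DataMatrix.from_array(target[perm], prefix="x"),
        background=DataMatrix.from_array(background, prefix="x"),
        labels=labels[perm],
        params=dict(
            n_per_ring=n_per_ring, n_background=n_background, radii=radii,
            background_radius=background_radius, radial_noise=radial_noise,
            seed=seed,
        ),
    )


def make_population_model(
    cov_x: np.ndarray,
    cov_y: np.ndarray,
    alpha: float = 1.0,
    min_relative_gap: float = 0.02,
) -> PopulationModel:
    """Wrap a population covariance pair for convergence-rate studies.

    The population first cPC is the leading eigenvector of
    ``cov_x - alpha cov_y``; it must be identifiable, so the relative gap
    between the two largest eigenvalues is enforced.
    """
    cov_x = np.asarray(cov_x, dtype=float)
    cov_y = np.asarray(cov_y, dtype=float)
    c = cov_x - alpha * cov_y
    c = (c + c.T) / 2.0
    w, v = scipy.linalg.eigh(c)
    scale = max(abs(w[-1]), abs(w[0]), 1e-12)
    gap = (w[-1] - w[-2]) / scale
    if gap < min_relative_gap:
        raise ValueError(
            f"population cPC ill-defined: relative eigengap {gap:.3g} below "
            f"{min_relative_gap}"
        )
    cpc = v[:, -1]
    i = int(np.argmax(np.abs(cpc)))
    if cpc[i] < 0:
        cpc = -cpc
    return PopulationModel(cov_x, cov_y, float(alpha), cpc, float(gap))


def make_default_population_model(d: int = 10, alpha: float = 1.0) -> PopulationModel:
    """Diagonal reference model: ``C_X = diag(d..1)``, ``C_Y = diag(1..d)``.

    The population contrastive matrix at alpha = 1 is diagonal with a
    strictly decreasing spectrum, so the population first cPC is exactly
    the first coordinate axis.
    """
    cov_x = np.diag(np.arange(d, 0, -1, dtype=float))
    cov_y = np.diag(np.arange(1, d + 1, dtype=float))
    return make_population_model(cov_x, cov_y, alpha=alpha)


def _sine_angle(u: np.ndarray, v: np.ndarray) -> float:
    c = abs(float(u @ v)) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.sqrt(max(0.0, 1.0 - min(1.0, c) ** 2)))


def convergence_error_ratio(
    model: PopulationModel,
    n_small: int = 100,
    n_large: int = 400,
    n_replicates: int = 200,
    seed: int = 0,
) -> dict:
    """Median sample-cPC error at two sample sizes and their ratio.

    The error of one replicate is the sine of the angle between the sample
    first cPC and the population cPC.  Under the root-(d / min(n, m))
    convergence rate, multiplying both sample sizes by 4 should shrink the
    median error by roughly a factor of 2.
    """
    rng = np.random.default_rng(seed)
    medians = {}
    for size in (n_small, n_large):
        errs = []
        for _ in range(n_replicates):
            pair = model.sample_pair(size, size, rng)
            fitted = fit_cpca(pair, model.alpha, k=1)
            errs.append(_sine_angle(fitted.components[:, 0], model.population_cpc))
        medians[size] = float(np.median(errs))
    return {
        "median_error_small": medians[n_small],
        "median_error_large": medians[n_large],
        "ratio": medians[n_small] / medians[n_large],
        "n_small": n_small,
        "n_large": n_large,
        "n_replicates": n_replicates,
    }


def kmeans_accuracy(
    embedding: np.ndarray,
    labels: np.ndarray,
    n_clusters: int = 2,
    seed: int = 0,
) -> float:
    """Best label-matching accuracy of k-means on an embedding.

    For two clusters the accuracy is maximized over the label swap; used
    to score how well a projection exposes a planted binary structure.
    """
    pred = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed).fit_predict(
        np.asarray(embedding)
    )
    labels = np.asarray(labels)
    if n_clusters != 2:
        raise ValueError("accuracy scoring implemented for 2 clusters")
    acc = np.mean(pred == labels)
    return float(max(acc, 1.0 - acc))
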