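"""Geometric interpretation of cPCA as executable checks.

Every unit direction ``v`` maps to a target-background variance pair
``(lambda_X(v), lambda_Y(v))``.  The image of the unit sphere under this
map is a planar region U; a direction is *most contrastive* when its pair
sits on the lower-right (Pareto) boundary of U — no other direction has
both strictly higher target variance and strictly lower background
variance.  Three characterizations of the first cPC coincide:

1. it maximizes ``lambda_X(v) - alpha * lambda_Y(v)`` (eigen-optimality);
2. its variance pair lies on the lower-right boundary of U;
3. its pair is the tangency point of that boundary with a supporting line
   of slope 1/alpha (plotting lambda_X horizontally).

This module samples U, flags the frontier, and verifies frontier
membership and tangency numerically; these are oracle-style diagnostics
meant for low dimension (an exhaustive angular grid at d = 2, random unit
directions at d = 3).  The tangency check is implemented in the
convention-free support form "no sampled direction beats the cPC's
objective", which is equivalent to the slope-1/alpha tangency statement
and robust to axis conventions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import CovariancePair, fit_cpca

__all__ = [
    "VariancePairCloud",
    "sample_variance_cloud",
    "pareto_flags",
    "check_cpc_on_frontier",
    "check_tangency",
    "plot_variance_cloud",
]


@dataclass
class VariancePairCloud:
    """Sampled unit directions with their variance pairs and frontier flags."""

    directions: np.ndarray  # (n_dirs, d)
    lambda_x: np.ndarray
    lambda_y: np.ndarray
    frontier: np.ndarray  # bool per direction


def _unit_directions(d: int, n_dirs: int, seed: int) -> np.ndarray:
    if d == 2:
        # exhaustive half-circle grid; v and -v give the same pair
        theta = np.linspace(0.0, np.pi, n_dirs, endpoint=False)
        return np.column_stack([np.cos(theta), np.sin(theta)])
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((n_dirs, d))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def pareto_flags(lambda_x: np.ndarray, lambda_y: np.ndarray) -> np.ndarray:
    """Lower-right non-dominated flags: point i is flagged unless some j has
    strictly larger lambda_x AND strictly smaller lambda_y.

    O(n log n) sweep; ties (equal lambda_x) never dominate each other.
    """
    lx = np.asarray(lambda_x, dtype=float)
    ly = np.asarray(lambda_y, dtype=float)
    n = lx.size
    order = np.lexsort((ly, -lx))  # lambda_x descending
    flags = np.ones(n, dtype=bool)
    best_ly = np.inf  # min lambda_y among strictly larger lambda_x
    i = 0
    while i < n:
        j = i
        while j < n and lx[order[j]] == lx[order[i]]:
            j += 1
        group = order[i:j]
        flags[group] = ly[group] <= best_ly
        best_ly = min(best_ly, float(ly[group].min()))
        i = j
    return flags


def sample_variance_cloud(
    cov: CovariancePair, n_dirs: int = 20000, seed: int = 0
) -> VariancePairCloud:
    """Sample U and flag its lower-right boundary.

    At d = 2 the unit directions form an exhaustive angular grid; in
    higher dimension they are drawn uniformly on the sphere.
    """
    if n_dirs < 1:
        raise ValueError("n_dirs must be >= 1")
    dirs = _unit_directions(cov.dim, n_dirs, seed)
    lx = np.einsum("nd,de,ne->n", dirs, cov.c_x, dirs)
    ly = np.einsum("nd,de,ne->n", dirs, cov.c_y, dirs)
    return VariancePairCloud(dirs, lx, ly, pareto_flags(lx, ly))


def _first_cpc_pair(cov: CovariancePair, alpha: float):
    model = fit_cpca(cov, alpha, k=1)
    v = model.components[:, 0]
    return v, float(v @ cov.c_x @ v), float(v @ cov.c_y @ v)


def check_cpc_on_frontier(
    cov: CovariancePair,
    alpha: float,
    tolerance: float = 1e-6,
    n_dirs: int = 100000,
    seed: int = 0,
    direction: np.ndarray | None = None,
) -> tuple[bool, dict]:
    """Is the first cPC's variance pair undominated within the sampled cloud?

    True iff no sampled direction exceeds the cPC's target variance by more
    than ``tolerance`` while undercutting its background variance by more
    than ``tolerance``.  ``direction`` overrides the fitted cPC (useful as a
    negative control).
    """
    if cov.dim > 3:
        raise ValueError("frontier oracle is intended for d <= 3")
    if direction is None:
        v, a_star, b_star = _first_cpc_pair(cov, alpha)
    else:
        v = np.asarray(direction, dtype=float)
        v = v / np.linalg.norm(v)
        a_star, b_star = float(v @ cov.c_x @ v), float(v @ cov.c_y @ v)
    cloud = sample_variance_cloud(cov, n_dirs, seed)
    dominating = (cloud.lambda_x > a_star + tolerance) & (
        cloud.lambda_y < b_star - tolerance
    )
    ok = not bool(dominating.any())
    return ok, {
        "pair": (a_star, b_star),
        "n_dominating": int(dominating.sum()),
        "direction": v,
    }


def check_tangency(
    cov: CovariancePair,
    alpha: float,
    tolerance: float = 1e-6,
    n_dirs: int = 100000,
    seed: int = 0,
    direction: np.ndarray | None = None,
) -> tuple[bool, dict]:
    """Does a slope-1/alpha line through the cPC's pair support the cloud?

    Support form: every sampled pair (a, b) must satisfy
    ``a - alpha*b <= a* - alpha*b* + tolerance`` — i.e. no direction beats
    the cPC's objective.  At alpha = 0 the supporting line is vertical and
    the condition reduces to maximal target variance.
    """
    if cov.dim > 3:
        raise ValueError("tangency oracle is intended for d <= 3")
    if direction is None:
        v, a_star, b_star = _first_cpc_pair(cov, alpha)
    else:
        v = np.asarray(direction, dtype=float)
        v = v / np.linalg.norm(v)
        a_star, b_star = float(v @ cov.c_x @ v), float(v @ cov.c_y @ v)
    cloud = sample_variance_cloud(cov, n_dirs, seed)
    obj_star = a_star - alpha * b_star
    obj = cloud.lambda_x - alpha * cloud.lambda_y
    gap = float(obj.max() - obj_star)
    return gap <= tolerance, {
        "pair": (a_star, b_star),
        "objective": obj_star,
        "max_violation": gap,
        "direction": v,
    }


def plot_variance_cloud(
    cov: CovariancePair,
    alpha: float,
    path,
    n_dirs: int = 20000,
    seed: int = 0,
) -> None:
    """Diagnostic plot: the region U, its lower-right frontier, the first
    cPC's variance pair and the slope-1/alpha tangent line through it."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cloud = sample_variance_cloud(cov, n_dirs, seed)
    _, a_star, b_star = _first_cpc_pair(cov, alpha)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(cloud.lambda_x, cloud.lambda_y, s=2, c="teal", alpha=0.25,
               label="variance pairs")
    f = cloud.frontier
    order = np.argsort(cloud.lambda_x[f])
    ax.plot(cloud.lambda_x[f][order], cloud.lambda_y[f][order], c="goldenrod",
            lw=2, label="most contrastive")
    ax.plot([a_star], [b_star], "b^", ms=9, label=f"cPC (alpha={alpha:g})")
    if alpha > 0:
        xs = np.array(ax.get_xlim())
        ax.plot(xs, b_star + (xs - a_star) / alpha, "k--", lw=1,
                label="slope 1/alpha")
    else:
        ax.axvline(a_star, color="k", ls="--", lw=1, label="vertical support")
    ax.set_xlabel("target variance  lambda_X(v)")
    ax.set_ylabel("background variance  lambda_Y(v)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
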