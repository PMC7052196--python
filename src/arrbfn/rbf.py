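"""Gaussian radial-basis-function primitives.

Centers come from k-means on the library's delay vectors; the kernel width
is the mean distance from each center to its nearest (distinct) neighbour
center; weights are the least-squares solution of the linear read-out, with
an optional small ridge guarding near-singular kernel matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import lstsq
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .embedding import EmbeddingSpec


@dataclass
class RBFLayer:
    """p Gaussian centers and one width for a single manifold."""

    centers: np.ndarray  # (p, E)
    width: float
    spec: EmbeddingSpec | None = None

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if self.centers.shape[0] < 1 or not np.all(np.isfinite(self.centers)):
            raise ValueError("need at least one finite center")
        if not self.width > 0:
            raise ValueError(f"kernel width must be positive, got {self.width}")

    @property
    def p(self) -> int:
        return self.centers.shape[0]


def fit_centers(points: np.ndarray, p: int, seed: int | None = None) -> np.ndarray:
    """k-means centers of the delay vectors; seeded and reproducible."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if p < 1:
        raise ValueError("p must be a positive integer")
    n_unique = np.unique(points, axis=0).shape[0]
    if p > n_unique:
        raise ValueError(
            f"requested {p} centers but only {n_unique} distinct points are "
            "available; use a smaller p or a longer library"
        )
    km = KMeans(n_clusters=p, init="k-means++", n_init=1, max_iter=300,
                random_state=seed)
    km.fit(points)
    return km.cluster_centers_


def compute_width(centers: np.ndarray, fallback_points: np.ndarray | None = None) -> float:
    """Mean nearest-neighbour distance between centers.

    Coincident centers contribute their distance to the nearest *distinct*
    center.  A single center falls back to the spread (SD of norms) of the
    training points, and to 1.0 if even that is degenerate; fully coincident
    center sets are rejected because the Gaussian needs a positive width.
    """
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    p = centers.shape[0]
    if p == 1:
        if fallback_points is not None:
            spread = float(np.std(np.linalg.norm(np.atleast_2d(fallback_points), axis=1)))
            if spread > 0:
                return spread
        return 1.0
    dist = cdist(centers, centers)
    np.fill_diagonal(dist, np.inf)
    dist[dist == 0] = np.inf  # skip coincident duplicates
    nearest = dist.min(axis=1)
    if np.all(np.isinf(nearest)):
        raise ValueError("all centers coincide; cannot define a positive width")
    nearest = nearest[np.isfinite(nearest)]
    # a center whose every distance was 0/inf has no distinct partner; the
    # remaining centers still define the scale
    return float(nearest.mean())


def kernel_row(point: np.ndarray, layer: RBFLayer) -> np.ndarray:
    """Gaussian kernels of one point against each center, entries in (0, 1]."""
    point = np.asarray(point, dtype=float)
    if point.shape != (layer.centers.shape[1],):
        raise ValueError(
            f"point dimension {point.shape} does not match centers "
            f"{layer.centers.shape}"
        )
    sq = np.sum((layer.centers - point) ** 2, axis=1)
    return np.exp(-sq / (2.0 * layer.width**2))


def design_matrix(vectors: np.ndarray, layer: RBFLayer) -> np.ndarray:
    """Kernel design matrix: row g is kernel_row(vectors[g]), shape (G, p)."""
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    if vectors.shape[1] != layer.centers.shape[1]:
        raise ValueError(
            f"delay-vector dimension {vectors.shape[1]} does not match center "
            f"dimension {layer.centers.shape[1]}"
        )
    sq = cdist(vectors, layer.centers, metric="sqeuclidean")
    return np.exp(-sq / (2.0 * layer.width**2))


def fit_weights(design: np.ndarray, targets: np.ndarray, ridge: float = 0.0) -> np.ndarray:
    """Least-squares read-out weights (minimum-norm when rank deficient)."""
    design = np.asarray(design, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if design.ndim != 2 or design.shape[0] != targets.shape[0]:
        raise ValueError("design and targets are misaligned")
    if not (np.all(np.isfinite(design)) and np.all(np.isfinite(targets))):
        raise ValueError("non-finite entries in design matrix or targets")
    if ridge < 0:
        raise ValueError("ridge must be nonnegative")
    if ridge > 0:
        q = design.shape[1]
        aug = np.vstack([design, np.sqrt(ridge) * np.eye(q)])
        rhs = np.concatenate([targets, np.zeros(q)])
        sol, *_ = lstsq(aug, rhs, lapack_driver="gelsd")
    else:
        sol, *_ = lstsq(design, targets, lapack_driver="gelsd")
    return sol
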