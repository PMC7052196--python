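"""One-step-ahead forecasters built on delay embeddings.

``RBFNForecaster``
    A Gaussian radial-basis-function network over one or more fixed
    manifolds: k-means centers per manifold, width from nearest-neighbour
    center distances, and a single joint least-squares read-out over the
    columnwise-concatenated kernel blocks.

``ARRBFNForecaster``
    The attractor-ranked model: enumerate every valid multivariate delay
    embedding, rank each by the forecast skill of its own single-manifold
    RBFN on the in-sample data outside the training library, keep the top
    ``k`` (default: the number of variables), and fuse them in one
    ``RBFNForecaster``.

``MVEForecaster``
    Multiview embedding comparator: rank the same embeddings by their own
    nearest-neighbour forecast skill, keep the top ``ceil(sqrt(m))``, and
    forecast by averaging each view's nearest library neighbour's observed
    next value — a piece-wise constant approximator.

All estimators follow scikit-learn conventions: parameters are set in
``__init__``, ``fit`` consumes a ``(T, N)`` array whose rows are time steps,
and fitted attributes carry a trailing underscore.  Module-level functions
(``rank_embeddings``, ``fit_arrbfn``, ...) are thin wrappers that accept
``TimeSeriesSet`` objects and 1-based time intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, RegressorMixin

from .embedding import (
    EmbeddingSpec,
    as_spec,
    delay_vectors,
    enumerate_embeddings,
    univariate_spec,
)
from .rbf import RBFLayer, compute_width, design_matrix, fit_centers, fit_weights
from .timeseries import Interval, TimeSeriesSet

_EPS_SCALE = 1e-12
_MAX_CENTERS = 50


@dataclass(frozen=True)
class LibrarySpec:
    """A contiguous training window inside the in-sample interval.

    ``start`` is the 1-based time of the first library row, ``length`` the
    number of rows, and ``interval`` the in-sample bounds the library must
    fit within.
    """

    start: int
    length: int
    interval: Interval

    def __post_init__(self) -> None:
        a, b = self.interval
        if self.length < 1:
            raise ValueError("library length must be positive")
        if not (a <= self.start and self.start + self.length - 1 <= b):
            raise ValueError(
                f"library [{self.start}, {self.start + self.length - 1}] does "
                f"not fit inside the in-sample interval {self.interval}"
            )

    @property
    def window(self) -> Interval:
        return (self.start, self.start + self.length - 1)


@dataclass(frozen=True)
class RankedEmbedding:
    """An embedding with its in-sample forecast skill and rank position."""

    spec: EmbeddingSpec
    skill: float
    rank: int


def _layer_seed(random_state: int | None, coords) -> int:
    """Stable k-means seed derived from the manifold itself.

    Seeding by spec content (not layer position) makes a duplicated manifold
    reuse identical centers, which keeps the fused fit invariant to block
    duplication and makes the k=1 fused model coincide exactly with the
    single-manifold fit.
    """
    entropy = [0 if random_state is None else int(random_state)]
    entropy += [d * 8191 + n for d, n in coords]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0])


def _validate_series(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be a (T, N) array with at least two rows")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite entries")
    return X


def _skill(pred: np.ndarray, obs: np.ndarray, metric: str) -> float:
    from .evaluation import mean_absolute_error, pearson_correlation

    if metric == "correlation":
        return pearson_correlation(pred, obs)
    if metric == "mae":
        return mean_absolute_error(pred, obs)
    raise ValueError(f"unknown ranking metric {metric!r}")


def _sort_ranking(entries, metric: str):
    """Total order: best skill first, NaN skill last, ties canonical."""

    def key(item):
        spec, skill = item
        if np.isnan(skill):
            primary = np.inf
        else:
            primary = -skill if metric == "correlation" else skill
        return (primary, spec.canonical_key)

    ordered = sorted(entries, key=key)
    return [RankedEmbedding(spec=s, skill=v, rank=i + 1) for i, (s, v) in enumerate(ordered)]


class _OneStepForecasterMixin:
    """Shared prediction plumbing for anchor-time one-step forecasters."""

    def _usable_anchors(self, T: int) -> np.ndarray:
        lag = self.anchor_lag_ * self.tau
        if T - self.tau <= lag:
            raise ValueError(
                f"window of {T} rows too short: needs at least "
                f"{lag + self.tau + 1} rows for lags and a one-step target"
            )
        return np.arange(lag, T - self.tau)

    def predict(self, X) -> np.ndarray:
        """One-step forecasts for every usable anchor time in the window."""
        X = _validate_series(X)
        return self.predict_at(X, self._usable_anchors(X.shape[0]))

    def forecast(self, X):
        """Aligned (predictions, observations, predicted 0-based times)."""
        X = _validate_series(X)
        anchors = self._usable_anchors(X.shape[0])
        preds = self.predict_at(X, anchors)
        obs = X[anchors + self.tau, self._target_index_]
        return preds, obs, anchors + self.tau


class RBFNForecaster(_OneStepForecasterMixin, RegressorMixin, BaseEstimator):
    """Gaussian RBFN one-step forecaster over fixed delay embeddings.

    Parameters
    ----------
    specs : list of EmbeddingSpec / coordinate tuples / spec strings, or None
        The manifolds whose kernel blocks are concatenated.  ``None`` means
        the classical univariate embedding of the target: lags
        ``0 .. embedding_dim - 1`` of the target variable itself.
    target : int
        Column index of the forecast variable.
    embedding_dim : int
        Dimension of the default univariate embedding (ignored when
        ``specs`` is given).
    n_centers : int or None
        Gaussian centers per manifold.  ``None`` uses
        ``min(50, max(2, G // 3))`` where G is the number of library delay
        vectors, capped at the number of distinct vectors.
    ridge : float
        Tikhonov shrinkage on the read-out weights.  Kernel entries are in
        (0, 1] and targets are z-scored, so the default 0.1 is a modest,
        scale-free shrinkage.  It matters mostly for fused multi-manifold
        designs, whose concatenated blocks are strongly collinear; without
        it the joint solve interpolates observation noise.
    zscore : bool
        Standardize each variable with library mean/SD before embedding;
        forecasts are returned on the original scale.
    random_state : int or None
        Seeds the k-means center placement.
    tau : int
        Time increment between rows.
    """

    def __init__(
        self,
        specs=None,
        target: int = 0,
        embedding_dim: int = 3,
        n_centers: int | None = None,
        ridge: float = 0.1,
        zscore: bool = True,
        random_state: int | None = None,
        tau: int = 1,
    ):
        self.specs = specs
        self.target = target
        self.embedding_dim = embedding_dim
        self.n_centers = n_centers
        self.ridge = ridge
        self.zscore = zscore
        self.random_state = random_state
        self.tau = tau

    # -- fitting -----------------------------------------------------------
    def _resolve_specs(self) -> list[EmbeddingSpec]:
        if self.specs is None:
            return [univariate_spec(self.target, self.embedding_dim)]
        specs = [as_spec(s) for s in self.specs]
        if not specs:
            raise ValueError("specs must be a nonempty list (or None)")
        return specs

    def fit(self, X, y=None):
        """Fit centers, width and read-out weights on a library window."""
        X = _validate_series(X)
        specs = self._resolve_specs()
        T, N = X.shape
        self.n_features_in_ = N
        self._target_index_ = int(self.target)
        if not 0 <= self._target_index_ < N:
            raise ValueError(f"target {self.target} out of range for {N} columns")
        self.specs_ = specs
        self.anchor_lag_ = max(s.max_lag for s in specs)
        anchors = self._usable_anchors(T)
        G = anchors.size

        if self.zscore:
            self.mean_ = X.mean(axis=0)
            scale = X.std(axis=0, ddof=0)
            scale[scale < _EPS_SCALE] = 1.0
            self.scale_ = scale
        else:
            self.mean_ = np.zeros(N)
            self.scale_ = np.ones(N)
        Xs = (X - self.mean_) / self.scale_
        y_lib = Xs[anchors + self.tau, self._target_index_]

        # one center per ~3 library points, per manifold; the same p is used
        # for ranking fits and inside the fused network, so the fused basis
        # strictly contains each component manifold's basis
        auto_p = min(_MAX_CENTERS, max(2, G // 3))
        layers, blocks = [], []
        for spec in specs:
            V = delay_vectors(Xs, spec.coords, anchors, self.tau)
            if self.n_centers is None:
                p = min(auto_p, np.unique(V, axis=0).shape[0])
            else:
                p = int(self.n_centers)
            centers = fit_centers(V, p, seed=_layer_seed(self.random_state, spec.coords))
            width = compute_width(centers, fallback_points=V)
            layer = RBFLayer(centers=centers, width=width, spec=spec)
            layers.append(layer)
            blocks.append(design_matrix(V, layer))
        self.layers_ = layers
        self.weights_ = fit_weights(np.hstack(blocks), y_lib, ridge=self.ridge)
        return self

    # -- prediction --------------------------------------------------------
    def _fused_design(self, Xs: np.ndarray, anchors: np.ndarray) -> np.ndarray:
        blocks = [
            design_matrix(delay_vectors(Xs, layer.spec.coords, anchors, self.tau), layer)
            for layer in self.layers_
        ]
        return np.hstack(blocks)

    def predict_at(self, X, anchors) -> np.ndarray:
        """Forecast ``x_target(t + tau)`` for each 0-based anchor time t."""
        X = _validate_series(X)
        anchors = np.asarray(anchors, dtype=int)
        if anchors.size == 0:
            return np.empty(0)
        lag = self.anchor_lag_ * self.tau
        if anchors.min() < lag or anchors.max() >= X.shape[0]:
            raise ValueError(
                f"anchor times must lie in [{lag}, {X.shape[0] - 1}] so every "
                "lagged coordinate exists"
            )
        Xs = (X - self.mean_) / self.scale_
        pred_scaled = self._fused_design(Xs, anchors) @ self.weights_
        j = self._target_index_
        return self.mean_[j] + self.scale_[j] * pred_scaled


def _ranking_eval_anchors(T, anchor_lag, tau, lib_start0, lib_len):
    """In-sample anchors outside the library window (fit/score separation)."""
    anchors = np.arange(anchor_lag * tau, T - tau)
    inside = (anchors >= lib_start0) & (anchors <= lib_start0 + lib_len - 1)
    outside = anchors[~inside]
    return outside if outside.size else anchors


def _resolve_library(T, library):
    if library is None:
        return 0, T
    start0, length = library
    start0, length = int(start0), int(length)
    if start0 < 0 or length < 1 or start0 + length > T:
        raise ValueError(f"library (start={start0}, length={length}) outside 0..{T - 1}")
    return start0, length


class ARRBFNForecaster(_OneStepForecasterMixin, RegressorMixin, BaseEstimator):
    """Attractor-ranked RBFN: rank all valid embeddings, fuse the top k.

    ``fit(X, library=(start, length))`` takes the in-sample series ``X`` and
    an optional 0-based contiguous library window within it.  Every valid
    embedding of ``embedding_dim`` coordinates over lags ``0 .. n_lags - 1``
    is fitted as a single-manifold RBFN on the library and scored on the
    remaining in-sample rows; the top ``top_k`` (default: one per variable,
    k = N) are refitted jointly as one fused network.

    Attributes
    ----------
    ranking_ : list of RankedEmbedding
        All embeddings in descending skill order.
    top_specs_ : list of EmbeddingSpec
        The fused manifolds.
    model_ : RBFNForecaster
        The fitted fused network.
    """

    def __init__(
        self,
        target: int = 0,
        embedding_dim: int = 3,
        n_lags: int = 3,
        top_k: int | None = None,
        metric: str = "correlation",
        n_centers: int | None = None,
        ridge: float = 0.1,
        zscore: bool = True,
        random_state: int | None = None,
        tau: int = 1,
    ):
        self.target = target
        self.embedding_dim = embedding_dim
        self.n_lags = n_lags
        self.top_k = top_k
        self.metric = metric
        self.n_centers = n_centers
        self.ridge = ridge
        self.zscore = zscore
        self.random_state = random_state
        self.tau = tau

    def _single_manifold_params(self) -> dict:
        return dict(
            target=self.target,
            n_centers=self.n_centers,
            ridge=self.ridge,
            zscore=self.zscore,
            random_state=self.random_state,
            tau=self.tau,
        )

    def fit(self, X, y=None, library: tuple[int, int] | None = None):
        X = _validate_series(X)
        T, N = X.shape
        self.n_features_in_ = N
        self._target_index_ = int(self.target)
        start0, length = _resolve_library(T, library)
        specs = enumerate_embeddings(N, self.n_lags, self.embedding_dim)
        if not specs:
            raise ValueError(
                f"no valid embeddings for N={N}, L={self.n_lags}, E={self.embedding_dim}"
            )
        lib_window = X[start0 : start0 + length]
        anchor_lag = self.n_lags - 1
        eval_anchors = _ranking_eval_anchors(T, anchor_lag, self.tau, start0, length)
        obs = X[eval_anchors + self.tau, self._target_index_]

        entries = []
        for spec in specs:
            est = RBFNForecaster(specs=[spec], **self._single_manifold_params())
            est.fit(lib_window)
            preds = est.predict_at(X, eval_anchors)
            entries.append((spec, _skill(preds, obs, self.metric)))
        self.ranking_ = _sort_ranking(entries, self.metric)

        k = N if self.top_k is None else int(self.top_k)
        if k < 1:
            raise ValueError("top_k must be >= 1")
        k = min(k, len(self.ranking_))
        self.k_ = k
        self.top_specs_ = [r.spec for r in self.ranking_[:k]]
        self.model_ = RBFNForecaster(
            specs=self.top_specs_, **self._single_manifold_params()
        ).fit(lib_window)
        self.anchor_lag_ = self.model_.anchor_lag_
        return self

    def predict_at(self, X, anchors) -> np.ndarray:
        return self.model_.predict_at(X, anchors)


class MVEForecaster(_OneStepForecasterMixin, RegressorMixin, BaseEstimator):
    """Multiview-embedding forecaster (nearest-neighbour ensemble).

    Embeddings are ranked by their own 1-NN in-sample forecast skill with the
    same library/evaluation split as the RBFN ranking; the top
    ``ceil(sqrt(m))`` views are kept.  A forecast is the unweighted mean,
    over views, of the observed next value of each view's nearest library
    delay vector, so predictions are always convex combinations of observed
    library targets.
    """

    def __init__(
        self,
        target: int = 0,
        embedding_dim: int = 3,
        n_lags: int = 3,
        n_views: int | None = None,
        n_neighbors: int = 1,
        metric: str = "correlation",
        zscore: bool = True,
        random_state: int | None = None,
        tau: int = 1,
    ):
        self.target = target
        self.embedding_dim = embedding_dim
        self.n_lags = n_lags
        self.n_views = n_views
        self.n_neighbors = n_neighbors
        self.metric = metric
        self.zscore = zscore
        self.random_state = random_state
        self.tau = tau

    def _nn_predict(self, V_lib: np.ndarray, y_lib: np.ndarray, V_query: np.ndarray) -> np.ndarray:
        d = cdist(V_query, V_lib)
        if self.n_neighbors == 1:
            # argmin returns the earliest library time on ties
            return y_lib[np.argmin(d, axis=1)]
        order = np.argsort(d, axis=1, kind="stable")[:, : self.n_neighbors]
        return y_lib[order].mean(axis=1)

    def fit(self, X, y=None, library: tuple[int, int] | None = None):
        X = _validate_series(X)
        T, N = X.shape
        self.n_features_in_ = N
        self._target_index_ = int(self.target)
        if self.n_neighbors < 1:
            raise ValueError("n_neighbors must be >= 1")
        start0, length = _resolve_library(T, library)
        specs = enumerate_embeddings(N, self.n_lags, self.embedding_dim)
        self.anchor_lag_ = self.n_lags - 1

        lib = X[start0 : start0 + length]
        if self.zscore:
            self.mean_ = lib.mean(axis=0)
            scale = lib.std(axis=0, ddof=0)
            scale[scale < _EPS_SCALE] = 1.0
            self.scale_ = scale
        else:
            self.mean_ = np.zeros(N)
            self.scale_ = np.ones(N)
        lib_s = (lib - self.mean_) / self.scale_

        lag = self.anchor_lag_ * self.tau
        if length - self.tau <= lag:
            raise ValueError(
                f"library of {length} rows too short: needs at least "
                f"{lag + self.tau + 1} rows for one usable delay vector"
            )
        lib_anchors = np.arange(lag, length - self.tau)
        self.library_targets_ = lib[lib_anchors + self.tau, self._target_index_]

        Xs = (X - self.mean_) / self.scale_
        eval_anchors = _ranking_eval_anchors(T, self.anchor_lag_, self.tau, start0, length)
        obs = X[eval_anchors + self.tau, self._target_index_]

        entries, vectors = [], {}
        for spec in specs:
            V = delay_vectors(lib_s, spec.coords, lib_anchors, self.tau)
            vectors[spec] = V
            preds = self._nn_predict(V, self.library_targets_, delay_vectors(Xs, spec.coords, eval_anchors, self.tau))
            entries.append((spec, _skill(preds, obs, self.metric)))
        self.ranking_ = _sort_ranking(entries, self.metric)

        m = len(specs)
        n_views = math.ceil(math.sqrt(m)) if self.n_views is None else int(self.n_views)
        n_views = max(1, min(n_views, m))
        self.views_ = [(r.spec, vectors[r.spec]) for r in self.ranking_[:n_views]]
        return self

    def predict_at(self, X, anchors) -> np.ndarray:
        X = _validate_series(X)
        anchors = np.asarray(anchors, dtype=int)
        if anchors.size == 0:
            return np.empty(0)
        lag = self.anchor_lag_ * self.tau
        if anchors.min() < lag or anchors.max() >= X.shape[0]:
            raise ValueError(f"anchor times must lie in [{lag}, {X.shape[0] - 1}]")
        Xs = (X - self.mean_) / self.scale_
        preds = np.zeros(anchors.size)
        for spec, V_lib in self.views_:
            Q = delay_vectors(Xs, spec.coords, anchors, self.tau)
            preds += self._nn_predict(V_lib, self.library_targets_, Q)
        return preds / len(self.views_)


# ---------------------------------------------------------------------------
# thin TimeSeriesSet/interval wrappers over the estimators
# ---------------------------------------------------------------------------

def _fit_on_library(est, ts: TimeSeriesSet, library: LibrarySpec):
    X_in = ts.window(library.interval)
    rel0 = library.start - library.interval[0]
    return est.fit(X_in, library=(rel0, library.length))


def rank_embeddings(
    ts: TimeSeriesSet,
    specs: list[EmbeddingSpec] | None,
    target_variable: int | str,
    library: LibrarySpec,
    metric: str = "correlation",
    **params,
) -> list[RankedEmbedding]:
    """Rank embeddings by single-manifold RBFN skill on the in-sample data.

    ``specs=None`` enumerates every valid embedding with the default E=3,
    L=3 geometry.
    """
    j = ts.variable_index(target_variable)
    X_in = ts.window(library.interval)
    T = X_in.shape[0]
    rel0 = library.start - library.interval[0]
    if specs is None:
        est = ARRBFNForecaster(target=j, metric=metric, tau=ts.tau, **params)
        est.fit(X_in, library=(rel0, library.length))
        return est.ranking_
    specs = [as_spec(s) for s in specs]
    if not specs:
        raise ValueError("specs must be nonempty")
    anchor_lag = max(s.max_lag for s in specs)
    eval_anchors = _ranking_eval_anchors(T, anchor_lag, ts.tau, rel0, library.length)
    obs = X_in[eval_anchors + ts.tau, j]
    lib_window = X_in[rel0 : rel0 + library.length]
    entries = []
    for spec in specs:
        est = RBFNForecaster(specs=[spec], target=j, tau=ts.tau, **params)
        est.fit(lib_window)
        entries.append((spec, _skill(est.predict_at(X_in, eval_anchors), obs, metric)))
    return _sort_ranking(entries, metric)


def select_top_k(ranked: list[RankedEmbedding], k: int) -> list[EmbeddingSpec]:
    """First k specs in rank order."""
    if not 1 <= k <= len(ranked):
        raise ValueError(f"k must be in 1..{len(ranked)}, got {k}")
    return [r.spec for r in ranked[:k]]


def fit_arrbfn(
    ts: TimeSeriesSet,
    top_specs: list[EmbeddingSpec],
    target_variable: int | str,
    library: LibrarySpec,
    **params,
) -> RBFNForecaster:
    """Fit the fused network on given manifolds over a library window."""
    j = ts.variable_index(target_variable)
    est = RBFNForecaster(specs=list(top_specs), target=j, tau=ts.tau, **params)
    return est.fit(ts.window(library.window))


def forecast(model, ts: TimeSeriesSet, times) -> np.ndarray:
    """One-step forecasts x_j(t + tau) at the given 1-based anchor times t."""
    anchors = np.asarray(list(times), dtype=int) - 1
    return model.predict_at(ts.values, anchors)


def fit_univariate_rbfn(
    ts: TimeSeriesSet,
    target_variable: int | str,
    library: LibrarySpec,
    embedding_dim: int = 3,
    **params,
) -> RBFNForecaster:
    """RBFN on the target's own lag embedding (classical Takens manifold)."""
    j = ts.variable_index(target_variable)
    est = RBFNForecaster(
        specs=[univariate_spec(j, embedding_dim)], target=j, tau=ts.tau, **params
    )
    return est.fit(ts.window(library.window))


def fit_best_multivariate_rbfn(
    ts: TimeSeriesSet,
    target_variable: int | str,
    library: LibrarySpec,
    **params,
) -> RBFNForecaster:
    """Single top-ranked manifold RBFN — identical to the fused model at k=1."""
    ranked = rank_embeddings(ts, None, target_variable, library, **params)
    top = select_top_k(ranked, 1)
    fit_params = {k: v for k, v in params.items() if k not in ("embedding_dim", "n_lags", "metric", "top_k")}
    return fit_arrbfn(ts, top, target_variable, library, **fit_params)


def mve_forecast(
    ts: TimeSeriesSet,
    target_variable: int | str,
    library: LibrarySpec,
    times,
    **params,
) -> np.ndarray:
    """Multiview-embedding forecasts at the given 1-based anchor times."""
    j = ts.variable_index(target_variable)
    est = MVEForecaster(target=j, tau=ts.tau, **params)
    _fit_on_library(est, ts, library)
    return forecast(est, ts, times)
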