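"""Multivariate delay-coordinate embeddings.

A reconstructed manifold is described by an ``EmbeddingSpec``: an ordered
list of E coordinates, each a ``(variable, lag)`` pair meaning
``x_variable(t - lag * tau)``.  A spec is valid only if at least one
coordinate is unlagged (lag 0), i.e. the manifold sees the current state.
With N variables and lags ``0 .. L-1`` the number of valid E-dimensional
manifolds is

    m = C(N*L, E) - C(N*(L-1), E)

where the subtracted term counts the all-lagged (invalid) combinations.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .timeseries import Interval, TimeSeriesSet


@dataclass(frozen=True)
class EmbeddingSpec:
    """An ordered tuple of (variable index, lag multiplier) coordinates."""

    coords: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        coords = tuple((int(d), int(n)) for d, n in self.coords)
        object.__setattr__(self, "coords", coords)
        if not coords:
            raise ValueError("an embedding needs at least one coordinate")
        if len(set(coords)) != len(coords):
            raise ValueError(f"duplicate coordinates in embedding {coords}")
        if any(d < 0 or n < 0 for d, n in coords):
            raise ValueError("variable indices and lags must be nonnegative")
        if not any(n == 0 for _, n in coords):
            raise ValueError(
                "invalid embedding: at least one coordinate must be unlagged "
                f"(lag 0); got {coords}"
            )

    @property
    def E(self) -> int:
        return len(self.coords)

    @property
    def max_lag(self) -> int:
        return max(n for _, n in self.coords)

    @property
    def canonical_key(self) -> tuple[tuple[int, int], ...]:
        return tuple(sorted(self.coords))

    # -- compact text form: "y:0,z:1,x:2" --------------------------------
    def to_string(self, names: tuple[str, ...] | None = None) -> str:
        if names is None:
            return ",".join(f"{d}:{n}" for d, n in self.coords)
        return ",".join(f"{names[d]}:{n}" for d, n in self.coords)

    @classmethod
    def from_string(cls, s: str, names: tuple[str, ...] | None = None) -> "EmbeddingSpec":
        coords = []
        for item in s.split(","):
            var, _, lag = item.strip().partition(":")
            if names is not None and var in names:
                d = names.index(var)
            else:
                d = int(var)
            coords.append((d, int(lag)))
        return cls(tuple(coords))

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


def as_spec(spec) -> EmbeddingSpec:
    if isinstance(spec, EmbeddingSpec):
        return spec
    if isinstance(spec, str):
        return EmbeddingSpec.from_string(spec)
    return EmbeddingSpec(tuple(spec))


def count_embeddings(N: int, L: int, E: int) -> int:
    """Number of valid E-dimensional manifolds for N variables and L lags."""
    if N < 1 or L < 1 or E < 1:
        raise ValueError("N, L and E must be positive integers")
    return math.comb(N * L, E) - math.comb(N * (L - 1), E)


def enumerate_embeddings(N: int, L: int, E: int) -> list[EmbeddingSpec]:
    """All valid specs in canonical (lexicographic in (variable, lag)) order."""
    if N < 1 or L < 1 or E < 1:
        raise ValueError("N, L and E must be positive integers")
    pool = [(d, n) for d in range(N) for n in range(L)]
    return [
        EmbeddingSpec(c)
        for c in itertools.combinations(pool, E)
        if any(n == 0 for _, n in c)
    ]


@dataclass
class DelayMatrix:
    """E x G matrix of delay vectors; column g is the state at time times[g]."""

    points: np.ndarray
    times: np.ndarray
    spec: EmbeddingSpec

    @property
    def vectors(self) -> np.ndarray:
        """The delay vectors as rows, shape (G, E)."""
        return self.points.T


@dataclass
class TargetVector:
    """One-step-ahead targets aligned with a DelayMatrix's columns."""

    values: np.ndarray
    target_variable: int
    times: np.ndarray


def delay_vectors(
    values: np.ndarray, coords, anchors: np.ndarray, tau: int = 1
) -> np.ndarray:
    """Rows ``x_d(t - n*tau)`` for each anchor time t (0-based rows)."""
    return np.column_stack([values[anchors - n * tau, d] for d, n in coords])


def build_delay_matrix(
    ts: TimeSeriesSet,
    spec: EmbeddingSpec,
    target_variable: int | str,
    time_range: Interval | None = None,
    anchor_lag: int | None = None,
) -> tuple[DelayMatrix, TargetVector]:
    """Materialize the delay matrix and aligned one-step targets.

    Anchors are the times t (1-based, inside ``time_range``) for which every
    lagged coordinate ``t - n*tau`` and the target time ``t + tau`` stay
    inside the range.  ``anchor_lag`` can force a deeper common anchor (used
    to align several manifolds on identical columns).
    """
    spec = as_spec(spec)
    j = ts.variable_index(target_variable)
    tau = ts.tau
    if time_range is None:
        time_range = (1, ts.T)
    a, b = time_range
    if not (1 <= a <= b <= ts.T):
        raise ValueError(f"time_range {time_range} outside series times 1..{ts.T}")
    lag = spec.max_lag if anchor_lag is None else max(anchor_lag, spec.max_lag)
    t_lo, t_hi = a + lag * tau, b - tau
    if t_lo > t_hi:
        raise ValueError(
            f"time_range {time_range} too short for embedding {spec}: needs at "
            f"least {lag * tau + tau + 1} points"
        )
    anchors = np.arange(t_lo, t_hi + 1)
    rows = anchors - 1  # 0-based
    points = delay_vectors(ts.values, spec.coords, rows, tau).T
    targets = ts.values[rows + tau, j]
    return (
        DelayMatrix(points=points, times=anchors, spec=spec),
        TargetVector(values=targets, target_variable=j, times=anchors + tau),
    )


def univariate_spec(target: int, E: int = 3) -> EmbeddingSpec:
    """Classical single-variable Takens embedding: lags 0 .. E-1 of the target."""
    return EmbeddingSpec(tuple((target, n) for n in range(E)))
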