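"""Chaotic ecosystem simulators, observational noise, and data partitioning.

Four deterministic model systems are provided, each run in a chaotic regime
and sampled at unit time increments:

* a three-species coupled logistic map (discrete, values in the open unit
  interval),
* the Hastings–Powell three-species food chain (continuous, integrated
  numerically and sampled at ``tau = 1``),
* the LPA larvae–pupae–adult flour-beetle map at its chaotic treatment
  parameters,
* a five-species coupled logistic web.

Noise is purely observational: it is added to the finished trajectory and
never fed back into the dynamics, with per-variable standard deviation equal
to ``level`` times the standard deviation of that variable's noise-free
series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .timeseries import Interval, TimeSeriesSet, interval_length


class SimulationError(RuntimeError):
    """A trajectory left its admissible region or the integrator failed."""


# ---------------------------------------------------------------------------
# parameter containers — every constant is exposed so alternative published
# parameterizations can be swapped in without code changes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoupledLogisticParams:
    """Three logistic maps coupled in a ring, state (x, y, z) in (0, 1)::

        x' = x * (rx - rx*x - cxz*z)
        y' = y * (ry - cyx*x - ry*y)
        z' = z * (rz - czy*y - rz*z)

    Every species is strongly driven by another, so the dynamics are
    genuinely interconnected: no variable is predictable from its own lags
    alone.  The growth rates sit in the chaotic band of the logistic map and
    satisfy ``r * (1 - r/4) > c * max(other)`` so the growth factor stays
    strictly positive and trajectories remain inside (0, 1) for any initial
    state in the open unit cube.
    """

    rx: float = 3.78
    ry: float = 3.71
    rz: float = 3.75
    cxz: float = 0.2
    cyx: float = 0.2
    czy: float = 0.2


@dataclass(frozen=True)
class FoodChainParams:
    """Hastings–Powell tri-trophic chain in its standard chaotic regime."""

    a1: float = 5.0
    b1: float = 3.0
    a2: float = 0.1
    b2: float = 2.0
    d1: float = 0.4
    d2: float = 0.01


@dataclass(frozen=True)
class FlourBeetleParams:
    """LPA stage-structured map, chaotic treatment (cpa manipulated).

    L' = b * A * exp(-cel * L - cea * A)
    P' = (1 - mu_l) * L
    A' = P * exp(-cpa * A) + (1 - mu_a) * A
    """

    b: float = 10.45
    cel: float = 0.01731
    cea: float = 0.01310
    cpa: float = 0.35
    mu_l: float = 0.2
    mu_a: float = 0.96


@dataclass(frozen=True)
class FiveSpeciesParams:
    """Five logistic maps coupled in a ring (species i driven by i-1)."""

    r: tuple[float, ...] = (3.78, 3.71, 3.75, 3.69, 3.77)
    coupling: float = 0.15


@dataclass(frozen=True)
class NoiseSpec:
    """Observational-noise description: fraction of each variable's SD."""

    level: float = 0.1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.level < 0:
            raise ValueError("noise level must be nonnegative")


@dataclass(frozen=True)
class DatasetPartition:
    """Disjoint ordered index intervals covering a generated series."""

    in_sample: Interval
    test: Interval
    burn_in: Interval | None = None
    gap: Interval | None = None

    def intervals(self) -> list[Interval]:
        out = [iv for iv in (self.burn_in, self.in_sample, self.gap, self.test) if iv]
        return sorted(out)


# ---------------------------------------------------------------------------
# simulators
# ---------------------------------------------------------------------------

def _resolve_initial(initial_state, n_vars, seed, low=0.2, high=0.8):
    if initial_state is None:
        rng = np.random.default_rng(seed)
        return rng.uniform(low, high, size=n_vars)
    state = np.asarray(initial_state, dtype=float)
    if state.shape != (n_vars,):
        raise ValueError(f"initial_state must be a length-{n_vars} vector")
    return state


def _iterate_map(step, state, n_steps, check):
    out = np.empty((n_steps, state.size))
    out[0] = state
    for t in range(1, n_steps):
        state = step(state)
        check(state, t)
        out[t] = state
    return out


def simulate_coupled_logistic(
    params: CoupledLogisticParams | None = None,
    n_steps: int = 3000,
    initial_state=None,
    seed: int | None = None,
) -> TimeSeriesSet:
    """Deterministic three-species coupled logistic trajectory in (0, 1).

    ``seed`` is only used to draw an initial state when none is given; the
    map itself is deterministic.
    """
    p = params or CoupledLogisticParams()
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    state = _resolve_initial(initial_state, 3, seed)
    if np.any(state <= 0) or np.any(state >= 1):
        raise ValueError("initial state must lie strictly inside the unit cube")

    def step(s):
        x, y, z = s
        return np.array(
            [
                x * (p.rx - p.rx * x - p.cxz * z),
                y * (p.ry - p.cyx * x - p.ry * y),
                z * (p.rz - p.czy * y - p.rz * z),
            ]
        )

    def check(s, t):
        if np.any(s <= 0) or np.any(s >= 1):
            raise SimulationError(
                f"coupled-logistic trajectory left (0,1) at step {t + 1}: {s}"
            )

    values = _iterate_map(step, state, n_steps, check)
    return TimeSeriesSet(values, ("x", "y", "z"))


def simulate_food_chain(
    params: FoodChainParams | None = None,
    n_steps: int = 3000,
    initial_state=(0.8, 0.2, 8.0),
    dt_internal: float = 0.1,
) -> TimeSeriesSet:
    """Integrate the Hastings–Powell chain and sample it at unit spacing.

    ``dt_internal`` caps the integrator step; the output spacing is always
    ``tau = 1`` regardless.  Tight tolerances keep repeated runs bitwise
    identical.
    """
    p = params or FoodChainParams()
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    y0 = np.asarray(initial_state, dtype=float)
    if y0.shape != (3,) or np.any(y0 <= 0):
        raise ValueError("initial_state must be three positive abundances")

    def rhs(_t, s):
        x, y, z = s
        f1 = p.a1 * x / (1.0 + p.b1 * x)
        f2 = p.a2 * y / (1.0 + p.b2 * y)
        return [x * (1.0 - x) - f1 * y, f1 * y - f2 * z - p.d1 * y, f2 * z - p.d2 * z]

    t_eval = np.arange(n_steps, dtype=float)
    sol = solve_ivp(
        rhs,
        (0.0, float(n_steps - 1)),
        y0,
        t_eval=t_eval,
        method="RK45",
        rtol=1e-9,
        atol=1e-12,
        max_step=dt_internal,
    )
    if not sol.success:
        raise SimulationError(f"food-chain integration failed: {sol.message}")
    values = sol.y.T
    bad = np.argwhere(values <= 0)
    if bad.size:
        t_fail = int(bad[0, 0]) + 1
        raise SimulationError(f"food-chain population non-positive at time {t_fail}")
    return TimeSeriesSet(values, ("x", "y", "z"))


def simulate_flour_beetle(
    params: FlourBeetleParams | None = None,
    n_steps: int = 3000,
    initial_state=(250.0, 5.0, 100.0),
) -> TimeSeriesSet:
    """Deterministic LPA skeleton; stages are larvae, pupae, adults."""
    p = params or FlourBeetleParams()
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    state = np.asarray(initial_state, dtype=float)
    if state.shape != (3,) or np.any(state < 0):
        raise ValueError("initial_state must be three nonnegative stage counts")

    def step(s):
        L, P, A = s
        return np.array(
            [
                p.b * A * np.exp(-p.cel * L - p.cea * A),
                (1.0 - p.mu_l) * L,
                P * np.exp(-p.cpa * A) + (1.0 - p.mu_a) * A,
            ]
        )

    def check(s, t):
        if np.any(s < 0) or not np.all(np.isfinite(s)):
            raise SimulationError(f"flour-beetle stage negative/non-finite at step {t + 1}")

    values = _iterate_map(step, state, n_steps, check)
    return TimeSeriesSet(values, ("larvae", "pupae", "adults"))


def simulate_five_species(
    params: FiveSpeciesParams | None = None,
    n_steps: int = 3000,
    initial_state=None,
    seed: int | None = None,
) -> TimeSeriesSet:
    """Five-species coupled logistic web, values strictly inside (0, 1)."""
    p = params or FiveSpeciesParams()
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    r = np.asarray(p.r, dtype=float)
    n = r.size
    state = _resolve_initial(initial_state, n, seed)
    if np.any(state <= 0) or np.any(state >= 1):
        raise ValueError("initial state must lie strictly inside the unit cube")

    def step(s):
        return s * (r - r * s - p.coupling * np.roll(s, 1))

    def check(s, t):
        if np.any(s <= 0) or np.any(s >= 1):
            raise SimulationError(
                f"five-species trajectory left (0,1) at step {t + 1}: {s}"
            )

    values = _iterate_map(step, state, n_steps, check)
    return TimeSeriesSet(values, tuple(f"y{i + 1}" for i in range(n)))


SIMULATORS = {
    "logistic3": simulate_coupled_logistic,
    "foodchain": simulate_food_chain,
    "beetle": simulate_flour_beetle,
    "five": simulate_five_species,
}


# ---------------------------------------------------------------------------
# observational noise and partitioning
# ---------------------------------------------------------------------------

def add_observational_noise(ts: TimeSeriesSet, noise: NoiseSpec) -> TimeSeriesSet:
    """Add seeded Gaussian measurement noise, SD = level * SD(clean column)."""
    if noise.level == 0:
        return TimeSeriesSet(ts.values.copy(), ts.names, ts.tau)
    rng = np.random.default_rng(noise.seed)
    sd = ts.values.std(axis=0, ddof=0)
    noisy = ts.values + rng.standard_normal(ts.values.shape) * (noise.level * sd)
    return TimeSeriesSet(noisy, ts.names, ts.tau)


def make_partition(
    ts: TimeSeriesSet,
    scheme: str = "holdout",
    burn_in: int = 500,
    gap: int = 500,
    test: int = 500,
    min_in_sample: int = 100,
    split_fraction: float = 0.75,
) -> DatasetPartition:
    """Partition a series for out-of-sample or pseudo-out-of-sample evaluation.

    ``holdout`` (default): discard the first ``burn_in`` rows as transient,
    keep the last ``test`` rows as the test set and leave a ``gap`` of unused
    rows before it; everything between is the in-sample portion.  For a
    3000-row series with the defaults this gives in-sample (501, 2000), gap
    (2001, 2500) and test (2501, 3000).

    ``pseudo``: the first ``split_fraction`` of the series is the training
    (in-sample) set and the remainder the test set.
    """
    T = ts.T
    if scheme == "holdout":
        in_end = T - gap - test
        if in_end - burn_in < min_in_sample:
            raise ValueError(
                f"series of length {T} too short for the holdout scheme: needs "
                f">= {burn_in + gap + test + min_in_sample} rows"
            )
        return DatasetPartition(
            burn_in=(1, burn_in),
            in_sample=(burn_in + 1, in_end),
            gap=(in_end + 1, in_end + gap),
            test=(in_end + gap + 1, T),
        )
    if scheme == "pseudo":
        n_train = int(np.floor(T * split_fraction))
        if n_train < 8 or n_train >= T:
            raise ValueError(f"series of length {T} too short for a {split_fraction} split")
        return DatasetPartition(in_sample=(1, n_train), test=(n_train + 1, T))
    raise ValueError(f"unknown scheme {scheme!r}; expected 'holdout' or 'pseudo'")
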