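"""Forecast-skill evaluation protocols.

Two protocols are provided.  The random-library protocol fits a forecaster
on many short training libraries drawn uniformly from the in-sample
interval and scores each on a held-out test interval, deliberately leaving
an unused gap between training and test data.  The pseudo-out-of-sample
protocol is expanding-window time-series cross-validation for short series:
each test point is forecast one step ahead from a model refitted on all
data up to that point.

Skill is Pearson correlation and mean absolute error between one-step
forecasts and the actual (possibly noisy) future observations.  Zero
variance makes the correlation undefined; such libraries are recorded with
skill 0 and a ``degenerate`` flag so aggregates over libraries stay
well-defined.
"""

from __future__ import annotations

import inspect
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, clone

from .forecasters import ARRBFNForecaster, LibrarySpec, MVEForecaster, RBFNForecaster
from .rbf import fit_weights
from .simulate import DatasetPartition, NoiseSpec, add_observational_noise, make_partition
from .timeseries import Interval, TimeSeriesSet, interval_length

METHODS = ("arrbfn", "univariate", "bestmulti", "mve")


# ---------------------------------------------------------------------------
# skill metrics
# ---------------------------------------------------------------------------

def pearson_correlation(a, b) -> float:
    """Pearson correlation; NaN when either input has zero variance."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("correlation needs two equal-length vectors of size >= 2")
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def mean_absolute_error(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 1:
        raise ValueError("MAE needs two equal-length nonempty vectors")
    return float(np.mean(np.abs(a - b)))


# ---------------------------------------------------------------------------
# library sampling
# ---------------------------------------------------------------------------

def sample_libraries(
    in_sample: Interval, length: int, n_libraries: int, seed: int | None = None
) -> list[LibrarySpec]:
    """Libraries with uniformly random start times inside the interval.

    Starts are drawn uniformly over the positions at which the whole
    library still fits inside ``in_sample``.
    """
    a, b = in_sample
    if length > interval_length(in_sample):
        raise ValueError(
            f"library length {length} exceeds the in-sample width "
            f"{interval_length(in_sample)}"
        )
    rng = np.random.default_rng(seed)
    starts = rng.integers(a, b - length + 2, size=n_libraries)
    return [LibrarySpec(int(s), length, in_sample) for s in starts]


# ---------------------------------------------------------------------------
# evaluation records
# ---------------------------------------------------------------------------

@dataclass
class LibraryRecord:
    library: LibrarySpec | None
    predictions: np.ndarray | None
    observations: np.ndarray | None
    correlation: float = np.nan
    mae: float = np.nan
    degenerate: bool = False
    error: str | None = None

    @property
    def residuals(self) -> np.ndarray | None:
        if self.predictions is None:
            return None
        return self.predictions - self.observations


@dataclass
class ForecastEvaluation:
    """Per-library skill records plus quartile aggregates."""

    records: list[LibraryRecord] = field(default_factory=list)

    @property
    def ok_records(self) -> list[LibraryRecord]:
        return [r for r in self.records if r.error is None]

    @property
    def correlations(self) -> np.ndarray:
        return np.array([r.correlation for r in self.ok_records])

    @property
    def maes(self) -> np.ndarray:
        return np.array([r.mae for r in self.ok_records])

    def aggregate(self) -> dict:
        out = {"n_libraries": len(self.records), "n_failed": len(self.records) - len(self.ok_records)}
        for name, vals in (("correlation", self.correlations), ("mae", self.maes)):
            if vals.size:
                out[f"mean_{name}"] = float(vals.mean())
                out[f"q25_{name}"] = float(np.percentile(vals, 25))
                out[f"q75_{name}"] = float(np.percentile(vals, 75))
            else:
                out[f"mean_{name}"] = out[f"q25_{name}"] = out[f"q75_{name}"] = float("nan")
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, r in enumerate(self.records):
            rows.append(
                {
                    "library": i,
                    "start": r.library.start if r.library else np.nan,
                    "length": r.library.length if r.library else np.nan,
                    "correlation": r.correlation,
                    "mae": r.mae,
                    "degenerate": r.degenerate,
                    "error": r.error,
                }
            )
        return pd.DataFrame(rows)


def _score(preds: np.ndarray, obs: np.ndarray) -> tuple[float, float, bool]:
    corr = pearson_correlation(preds, obs)
    degenerate = bool(np.isnan(corr))
    if degenerate:
        corr = 0.0
    return corr, mean_absolute_error(preds, obs), degenerate


def make_forecaster(method: str, target: int = 0, tau: int = 1, **params):
    """Construct a forecaster by method name (see ``METHODS``)."""
    if method == "arrbfn":
        return ARRBFNForecaster(target=target, tau=tau, **params)
    if method == "bestmulti":
        return ARRBFNForecaster(target=target, tau=tau, top_k=1, **params)
    if method == "univariate":
        return RBFNForecaster(specs=None, target=target, tau=tau, **params)
    if method == "mve":
        return MVEForecaster(target=target, tau=tau, **params)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def _per_library_seed(seed: int | None, index: int) -> int:
    entropy = [0 if seed is None else int(seed), index]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % 2**31)


def _instantiate(method, target: int, tau: int, derived_seed: int, params: dict):
    """Fresh forecaster per library: by name, or a clone of a prototype."""
    if isinstance(method, str):
        est = make_forecaster(method, target=target, tau=tau, **params)
    elif isinstance(method, BaseEstimator):
        est = clone(method)
    else:
        est = method  # duck-typed predictor, used as-is
    if isinstance(est, BaseEstimator) and "random_state" in est.get_params():
        est.set_params(random_state=derived_seed)
    return est


def _fit_for_library(estimator, X_in: np.ndarray, rel0: int, length: int):
    if "library" in inspect.signature(estimator.fit).parameters:
        estimator.fit(X_in, library=(rel0, length))
    else:
        estimator.fit(X_in[rel0 : rel0 + length])
    return estimator


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------

def evaluate_out_of_sample(
    ts: TimeSeriesSet,
    method,
    libraries: list[LibrarySpec],
    test: Interval,
    target: int | str = 0,
    seed: int | None = None,
    **params,
) -> ForecastEvaluation:
    """Random-library out-of-sample evaluation.

    ``method`` is a method name from ``METHODS`` or an unfitted estimator
    prototype (cloned per library).  Each library's forecaster predicts one
    step ahead at every usable time in the test interval; the data between
    the in-sample interval and the test interval is never touched.
    """
    if not libraries:
        raise ValueError("need at least one library")
    j = ts.variable_index(target)
    in_sample = libraries[0].interval
    if not (test[1] < in_sample[0] or test[0] > in_sample[1]):
        raise ValueError(f"test interval {test} overlaps the in-sample interval {in_sample}")
    X_in = ts.window(in_sample)
    X_test = ts.window(test)

    ev = ForecastEvaluation()
    for i, lib in enumerate(libraries):
        est = _instantiate(method, j, ts.tau, _per_library_seed(seed, i), params)
        try:
            _fit_for_library(est, X_in, lib.start - in_sample[0], lib.length)
            preds, obs, _ = est.forecast(X_test)
            corr, mae, degen = _score(preds, obs)
            ev.records.append(
                LibraryRecord(lib, preds, obs, corr, mae, degenerate=degen)
            )
        except Exception as exc:  # recorded, never silently dropped
            ev.records.append(
                LibraryRecord(lib, None, None, error=f"{type(exc).__name__}: {exc}")
            )
    return ev


def pseudo_out_of_sample(
    ts: TimeSeriesSet,
    method,
    split_fraction: float = 0.75,
    target: int | str = 0,
    seed: int | None = None,
    refit: str = "full",
    **params,
) -> ForecastEvaluation:
    """Expanding-window one-step cross-validation for short series.

    The forecast at time t + tau uses a model fitted on all data through
    time t.  ``refit='full'`` re-derives centers, widths and weights each
    step; ``refit='weights'`` fixes the hidden layer after the first fit
    and re-solves only the read-out weights.
    """
    part = make_partition(ts, scheme="pseudo", split_fraction=split_fraction)
    j = ts.variable_index(target)
    n_train = part.in_sample[1]
    X = ts.values
    if refit not in ("full", "weights"):
        raise ValueError("refit must be 'full' or 'weights'")

    preds, obs = [], []
    frozen = None
    for s in range(n_train, ts.T):  # 0-based row s is forecast from rows < s
        window = X[:s]
        if refit == "weights" and frozen is not None:  # reuse hidden layer
            est = frozen
            anchors = est._usable_anchors(window.shape[0])
            Xs = (window - est.mean_) / est.scale_
            design = est._fused_design(Xs, anchors)
            y = Xs[anchors + est.tau, est._target_index_]
            est.weights_ = fit_weights(design, y, ridge=est.ridge)
        else:
            est = _instantiate(method, j, ts.tau, _per_library_seed(seed, s), params)
            _fit_for_library(est, window, 0, window.shape[0])
            if refit == "weights" and isinstance(est, RBFNForecaster):
                frozen = est
        preds.append(float(est.predict_at(window, np.array([s - 1]))[0]))
        obs.append(float(X[s, j]))

    preds_arr, obs_arr = np.array(preds), np.array(obs)
    corr, mae, degen = _score(preds_arr, obs_arr)
    rec = LibraryRecord(None, preds_arr, obs_arr, corr, mae, degenerate=degen)
    return ForecastEvaluation(records=[rec])


def noise_sweep(
    ts_clean: TimeSeriesSet,
    levels,
    lengths,
    methods,
    n_libraries: int = 20,
    target: int | str = 0,
    seed: int | None = 0,
    partition: DatasetPartition | None = None,
    renoise_per_library: bool = False,
    **params,
) -> pd.DataFrame:
    """Full factorial noise level x library length x method skill table.

    Noise is applied once per level to the whole series before
    partitioning (set ``renoise_per_library`` to redraw noise per library
    instead).  Libraries are shared across methods and noise levels within
    a length so comparisons are paired.  Returns one tidy row per
    (method, noise, length, library).
    """
    if any(lv < 0 for lv in levels):
        raise ValueError("noise levels must be nonnegative")
    part = partition or make_partition(ts_clean)
    j = ts_clean.variable_index(target)

    libraries = {
        ln: sample_libraries(part.in_sample, ln, n_libraries, seed=_per_library_seed(seed, 10_000 + ln))
        for ln in lengths
    }
    rows = []
    for li, level in enumerate(levels):
        noise_seed = _per_library_seed(seed, 20_000 + li)
        noisy = add_observational_noise(ts_clean, NoiseSpec(level=level, seed=noise_seed))
        for ln in lengths:
            libs = libraries[ln]
            if renoise_per_library:
                lib_series = [
                    add_observational_noise(
                        ts_clean, NoiseSpec(level=level, seed=_per_library_seed(noise_seed, i))
                    )
                    for i in range(len(libs))
                ]
            for name, method in methods.items():
                if renoise_per_library:
                    ev = ForecastEvaluation()
                    for i, (lib, series) in enumerate(zip(libs, lib_series)):
                        sub = evaluate_out_of_sample(
                            series, method, [lib], part.test, target=j, seed=seed, **params
                        )
                        ev.records.extend(sub.records)
                else:
                    ev = evaluate_out_of_sample(
                        noisy, method, libs, part.test, target=j, seed=seed, **params
                    )
                for i, r in enumerate(ev.records):
                    rows.append(
                        {
                            "method": name,
                            "noise": level,
                            "length": ln,
                            "library": i,
                            "correlation": r.correlation,
                            "mae": r.mae,
                            "degenerate": r.degenerate,
                            "error": r.error,
                        }
                    )
    return pd.DataFrame(rows)


def aggregate_sweep(df: pd.DataFrame) -> pd.DataFrame:
    """Mean and quartiles of each skill metric per (method, noise, length)."""
    ok = df[df["error"].isna()]
    agg = ok.groupby(["method", "noise", "length"]).agg(
        mean_correlation=("correlation", "mean"),
        q25_correlation=("correlation", lambda v: np.percentile(v, 25)),
        q75_correlation=("correlation", lambda v: np.percentile(v, 75)),
        mean_mae=("mae", "mean"),
        q25_mae=("mae", lambda v: np.percentile(v, 25)),
        q75_mae=("mae", lambda v: np.percentile(v, 75)),
        n=("mae", "size"),
    )
    return agg.reset_index()
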