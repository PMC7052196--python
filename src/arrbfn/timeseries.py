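"""Multivariate time-series container and delimited-text I/O.

Time indices are 1-based and intervals are closed, ``(start, end)`` with both
endpoints included, so that a 3000-step series has observation times
``1..3000`` and the default out-of-sample test window is written ``(2501,
3000)``.  Internally rows are ordinary 0-based numpy rows; only the public
interval arithmetic uses the 1-based convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: Closed 1-based time interval (start, end), both included.
Interval = tuple[int, int]


def interval_length(iv: Interval) -> int:
    return iv[1] - iv[0] + 1


def _check_interval(iv: Interval, T: int, what: str = "interval") -> None:
    a, b = iv
    if not (1 <= a <= b <= T):
        raise ValueError(
            f"{what} ({a}, {b}) does not fit a series of length {T}; "
            "intervals are 1-based and closed"
        )


@dataclass
class TimeSeriesSet:
    """A T x N table of observations, one row per time step.

    Parameters
    ----------
    values : ndarray of shape (T, N)
        Observations; no missing entries allowed.
    names : sequence of str
        Unique variable labels, one per column.
    tau : int
        Time increment between consecutive rows (dimensionless steps).
    """

    values: np.ndarray
    names: tuple[str, ...] = field(default=())
    tau: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (T, N) table")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite with no missing entries")
        if not self.names:
            self.names = tuple(f"x{i + 1}" for i in range(self.values.shape[1]))
        self.names = tuple(str(n) for n in self.names)
        if len(self.names) != self.values.shape[1]:
            raise ValueError("need exactly one name per column")
        if len(set(self.names)) != len(self.names):
            raise ValueError("variable names must be unique")
        if self.tau < 1:
            raise ValueError("tau must be a positive integer number of steps")

    # -- basic geometry ----------------------------------------------------
    @property
    def T(self) -> int:
        return self.values.shape[0]

    @property
    def N(self) -> int:
        return self.values.shape[1]

    def variable_index(self, name: int | str) -> int:
        if isinstance(name, str):
            try:
                return self.names.index(name)
            except ValueError:
                raise KeyError(f"unknown variable {name!r}; have {self.names}")
        idx = int(name)
        if not 0 <= idx < self.N:
            raise KeyError(f"variable index {idx} out of range 0..{self.N - 1}")
        return idx

    def window(self, iv: Interval) -> np.ndarray:
        """Rows of the closed 1-based interval ``iv`` as a (len, N) array."""
        _check_interval(iv, self.T)
        return self.values[iv[0] - 1 : iv[1]]

    def subset(self, iv: Interval) -> "TimeSeriesSet":
        return replace(self, values=self.window(iv).copy())

    # -- conversion and I/O ------------------------------------------------
    def to_frame(self, time_column: bool = True) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.names))
        if time_column:
            df.insert(0, "time", np.arange(1, self.T + 1) * self.tau)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, tau: int = 1) -> "TimeSeriesSet":
        cols = list(df.columns)
        if cols and cols[0].lower() == "time":
            df = df.drop(columns=cols[0])
        return cls(df.to_numpy(dtype=float), tuple(df.columns), tau=tau)

    def write_csv(self, path: str | Path, time_column: bool = True) -> None:
        # pandas' default shortest-round-trip float formatting is lossless
        self.to_frame(time_column).to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path, tau: int = 1) -> "TimeSeriesSet":
        # round_trip parsing: the default C float parser can be one ulp off
        return cls.from_frame(pd.read_csv(path, float_precision="round_trip"), tau=tau)
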