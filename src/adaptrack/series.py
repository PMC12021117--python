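"""Hourly time-series containers shared across the package.

All series live on a strictly uniform 1-h (or, for the exact integrator,
arbitrary-step) grid.  Three thin dataclasses cover the domain:

* :class:`OptimalStateSeries` — the environment, i.e. the normalized optimal
  state :math:`y^o_t \\in [0, 1]` (here a normalized solar-irradiance proxy).
* :class:`TargetSeries` — the actionable target :math:`f_t` produced by an
  estimator or a network; unbounded sign, with a validity mask marking
  warm-up samples whose history was unavailable.
* :class:`StateSeries` — the tracked system state :math:`y_t` produced by the
  adaptation dynamics, with a validity mask marking convolution warm-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "HourlySeries",
    "OptimalStateSeries",
    "TargetSeries",
    "StateSeries",
    "AlignmentError",
]

_HOUR = pd.Timedelta(hours=1)


class AlignmentError(ValueError):
    """Two series that must share a time grid do not."""


def _check_hourly(index: pd.DatetimeIndex) -> None:
    if len(index) > 1:
        deltas = np.diff(index.asi8)
        if not np.all(deltas == _HOUR.value):
            raise ValueError("timestamps must be strictly increasing with exact 1-h spacing")


@dataclass
class HourlySeries:
    """A value per hourly timestamp, with an optional validity mask."""

    index: pd.DatetimeIndex
    values: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.index = pd.DatetimeIndex(self.index)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) != len(self.index):
            raise ValueError("values must be 1-D and aligned with the index")
        _check_hourly(self.index)
        if self.valid is None:
            self.valid = np.ones(len(self.values), dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.values.shape:
                raise ValueError("validity mask must align with values")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def hours_since_epoch(self) -> np.ndarray:
        """Hours elapsed since 2000-01-01T00:00 UTC; drives the clock phases."""
        epoch = pd.Timestamp("2000-01-01 00:00:00")
        return (self.index.asi8 - epoch.value) / _HOUR.value

    def slice(self, start: int, length: int) -> "HourlySeries":
        """Positional window ``[start, start+length)`` preserving the mask."""
        if start < 0 or start + length > len(self):
            raise ValueError("window overruns the series")
        return type(self)(
            self.index[start : start + length],
            self.values[start : start + length],
            self.valid[start : start + length],
        )

    def require_same_grid(self, other: "HourlySeries") -> None:
        if len(self) != len(other) or not self.index.equals(other.index):
            raise AlignmentError("series are not on the same time grid")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"value": self.values, "valid": self.valid}, index=self.index)


class OptimalStateSeries(HourlySeries):
    """Normalized optimal-state series: values in [0, 1] with max exactly 1."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
            raise ValueError("optimal-state values must lie in [0, 1]; normalize first")

    def to_csv(self, path) -> None:
        """Persist as two-column CSV (ISO-8601 UTC timestamp, normalized value)."""
        pd.Series(self.values, index=self.index, name="value").rename_axis("timestamp").to_csv(path)

    @classmethod
    def read_csv(cls, path) -> "OptimalStateSeries":
        frame = pd.read_csv(path, index_col=0, parse_dates=True)
        return cls(pd.DatetimeIndex(frame.index), frame.iloc[:, 0].to_numpy())


class TargetSeries(HourlySeries):
    """Actionable-target series :math:`f_t`; unbounded, with warm-up mask."""


class StateSeries(HourlySeries):
    """Tracked state :math:`y_t` from the adaptation dynamics, with warm-up mask."""
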