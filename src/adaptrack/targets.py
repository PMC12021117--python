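"""Actionable-target estimators.

Perfect tracking of a changing optimal state requires adapting toward the
actionable target ``f_t = y^o_t + (1/b0) dy^o_t/dt`` rather than toward the
optimal state itself.  In discrete time the derivative must be estimated
causally; this module implements the exact target (given an analytic
derivative) and the family of causal finite-difference / extrapolation /
recurrent estimators:

===============  =============================================================
method           definition (h = sampling step, b0 = adaptation rate)
===============  =============================================================
naive            f_t = y_t
d1_backward      f_t = y_t + (1/(h b0)) (y_t - y_{t-1})
d2_backward      f_t = y_t + (1/(2 h b0)) (3 y_t - 4 y_{t-1} + y_{t-2})
delayed_naive    f_t = y_{t-d}
delayed_d2       f_t = y_{t-d} + (1/(2 h b0)) (3 y_{t-d} - 4 y_{t-d-1} + y_{t-d-2})
extrapolated     yhat_t = y_{t-d} + (1/2)(3 y_{t-d} - 4 y_{t-d-1} + y_{t-d-2})
                 dyhat_t = (1/(2h))(5 y_{t-d} - 8 y_{t-d-1} + 3 y_{t-d-2})
                 f_t = yhat_t + dyhat_t / b0
recurrent_day    yhat_t = y_{t-1} + y_{t-24} - y_{t-25}
                 dyhat_t = (1/(2h))(y_{t-23} - y_{t-25})
                 f_t = yhat_t + dyhat_t / b0
mean_combination pointwise mean of component targets
===============  =============================================================

(indices in units of h; d = delay / h, default 1).  All estimators are causal
— no formula touches y_t's future — and linear in the input series.  Samples
whose history reaches before the series start are masked invalid, never
zero-filled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import DEFAULT_B0
from .series import AlignmentError, HourlySeries, TargetSeries

__all__ = [
    "EstimatorSpec",
    "ESTIMATOR_METHODS",
    "exact_actionable_target",
    "estimate_target",
    "combine_targets",
]

ESTIMATOR_METHODS = (
    "naive",
    "d1_backward",
    "d2_backward",
    "delayed_naive",
    "delayed_d2",
    "extrapolated",
    "recurrent_day",
    "mean_combination",
)


@dataclass
class EstimatorSpec:
    """Identifies a target estimator and its parameters.

    ``delay`` (hours) only affects the delayed/extrapolated variants and
    defaults to 1 h.  ``components`` holds sub-specs for
    ``mean_combination``.
    """

    method: str
    b0: float = DEFAULT_B0
    h: float = 1.0
    delay: float = 1.0
    components: list["EstimatorSpec"] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.method not in ESTIMATOR_METHODS:
            raise ValueError(f"unknown estimator method {self.method!r}")
        if self.b0 <= 0:
            raise ValueError("b0 must be positive")
        if self.method == "mean_combination" and len(self.components) < 2:
            raise ValueError("mean_combination needs at least two components")

    @property
    def history_depth(self) -> int:
        """Number of leading samples without enough history (masked invalid)."""
        d = int(round(self.delay / self.h))
        depths = {
            "naive": 0,
            "d1_backward": 1,
            "d2_backward": 2,
            "delayed_naive": d,
            "delayed_d2": d + 2,
            "extrapolated": d + 2,
            "recurrent_day": int(round(24 / self.h)) + 1,
        }
        if self.method == "mean_combination":
            return max(c.history_depth for c in self.components)
        return depths[self.method]

    def label(self) -> str:
        if self.method == "mean_combination":
            return "mean(" + "+".join(c.label() for c in self.components) + ")"
        return self.method


def exact_actionable_target(
    y_o: HourlySeries, dy_o: np.ndarray, b0: float = DEFAULT_B0
) -> TargetSeries:
    """f_t = y^o_t + (1/b0) dy^o_t/dt with an analytically known derivative."""
    dy_o = np.asarray(dy_o, dtype=float)
    if dy_o.shape != y_o.values.shape:
        raise AlignmentError("derivative series must align with the optimal state")
    return TargetSeries(y_o.index, y_o.values + dy_o / b0, y_o.valid.copy())


def _lag(values: np.ndarray, k: int) -> np.ndarray:
    """values shifted k steps into the past; the undefined head is 0 (masked)."""
    if k == 0:
        return values
    out = np.zeros_like(values)
    out[k:] = values[:-k]
    return out


def estimate_target(y_o: HourlySeries, spec: EstimatorSpec) -> TargetSeries:
    """Evaluate a causal estimator of the actionable target over a series."""
    if spec.method == "mean_combination":
        return combine_targets([estimate_target(y_o, c) for c in spec.components])

    y = y_o.values
    h, b0 = spec.h, spec.b0
    d = int(round(spec.delay / spec.h))
    if spec.method in ("delayed_naive", "delayed_d2", "extrapolated") and d < 1:
        raise ValueError("delayed estimators need a delay of at least one step")

    if spec.method == "naive":
        f = y.copy()
    elif spec.method == "d1_backward":
        f = y + (y - _lag(y, 1)) / (h * b0)
    elif spec.method == "d2_backward":
        f = y + (3 * y - 4 * _lag(y, 1) + _lag(y, 2)) / (2 * h * b0)
    elif spec.method == "delayed_naive":
        f = _lag(y, d)
    elif spec.method == "delayed_d2":
        yd, yd1, yd2 = _lag(y, d), _lag(y, d + 1), _lag(y, d + 2)
        f = yd + (3 * yd - 4 * yd1 + yd2) / (2 * h * b0)
    elif spec.method == "extrapolated":
        yd, yd1, yd2 = _lag(y, d), _lag(y, d + 1), _lag(y, d + 2)
        y_hat = yd + 0.5 * (3 * yd - 4 * yd1 + yd2)
        dy_hat = (5 * yd - 8 * yd1 + 3 * yd2) / (2 * h)
        f = y_hat + dy_hat / b0
    elif spec.method == "recurrent_day":
        day = int(round(24 / h))
        y_hat = _lag(y, 1) + _lag(y, day) - _lag(y, day + 1)
        dy_hat = (_lag(y, day - 1) - _lag(y, day + 1)) / (2 * h)
        f = y_hat + dy_hat / b0
    else:  # pragma: no cover - guarded by EstimatorSpec
        raise ValueError(spec.method)

    valid = y_o.valid.copy()
    valid[: spec.history_depth] = False
    return TargetSeries(y_o.index, f, valid)


def combine_targets(components: list[TargetSeries]) -> TargetSeries:
    """Pointwise mean of aligned target series; mask = intersection of masks."""
    if len(components) < 2:
        raise ValueError("need at least two target series to combine")
    first = components[0]
    for other in components[1:]:
        first.require_same_grid(other)
    values = np.mean([c.values for c in components], axis=0)
    valid = np.logical_and.reduce([c.valid for c in components])
    return TargetSeries(first.index, values, valid)
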