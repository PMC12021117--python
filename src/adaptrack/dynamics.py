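"""First-order adaptation dynamics dy/dt = b0 (f_t - y_t).

Two numerically distinct routes are provided:

* :func:`integrate_exact` — the closed-form exponential integrator of the
  continuous dynamics for a piecewise-linear target, including the transient
  term ``y0 * exp(-b0 t)``.  Exact for piecewise-linear inputs.
* :func:`apply_dynamics` — the discretized stationary convolution
  ``y_t = sum_i w_i f_{t-i h}`` with the trapezoidal exponential kernel
  ``w_0 = b0 h / 2``, ``w_i = b0 h exp(-b0 i h)``.  This is the form embedded
  as the frozen convolutional layer of the dynamics-informed network.

The kernel is used raw (sum ~ 1.009 for b0 = 1/3 h^-1, M = 25); an optional
renormalization flag gives exact unit DC gain for users who need it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .series import HourlySeries, StateSeries, TargetSeries

__all__ = [
    "AdaptationKernel",
    "build_kernel",
    "apply_dynamics",
    "integrate_exact",
    "delayed_tracking_mse",
    "DEFAULT_B0",
    "DEFAULT_M",
    "DEFAULT_WARMUP_HOURS",
]

DEFAULT_B0 = 1.0 / 3.0  # adaptation rate, h^-1
DEFAULT_M = 25  # highest kernel tap index (kernel spans 24 h of history)
DEFAULT_WARMUP_HOURS = 24  # convolution warm-up discarded per window


@dataclass(frozen=True)
class AdaptationKernel:
    """Discretized exponential kernel of the adaptation convolution."""

    b0: float
    h: float
    M: int
    weights: np.ndarray

    @property
    def neglected_tail(self) -> float:
        """Weight of the first dropped trapezoidal term, (1/2) e^(-b0 (M+1) h)."""
        return 0.5 * np.exp(-self.b0 * (self.M + 1) * self.h)

    @property
    def dc_gain(self) -> float:
        """Sum of the weights: response of the convolution to a constant target."""
        return float(np.sum(self.weights))


def build_kernel(
    b0: float = DEFAULT_B0,
    h: float = 1.0,
    M: int = DEFAULT_M,
    renormalize: bool = False,
) -> AdaptationKernel:
    """Trapezoidal-rule discretization of the exponential convolution kernel.

    ``w_0 = b0 h / 2`` and ``w_i = b0 h exp(-b0 i h)`` for ``i >= 1``; with
    ``h = 1`` this reduces to ``w_0 = b0 / 2``, ``w_i = b0 exp(-b0 i)``.
    With ``renormalize=True`` the weights are scaled to sum to 1 exactly.
    """
    if b0 <= 0 or h <= 0:
        raise ValueError("b0 and h must be positive")
    if M < 1:
        raise ValueError("M must be >= 1")
    i = np.arange(M + 1)
    weights = b0 * h * np.exp(-b0 * i * h)
    weights[0] *= 0.5
    if renormalize:
        weights = weights / weights.sum()
    return AdaptationKernel(b0=b0, h=h, M=M, weights=weights)


def apply_dynamics(
    target: TargetSeries,
    kernel: AdaptationKernel,
    warmup_hours: int = DEFAULT_WARMUP_HOURS,
) -> StateSeries:
    """Run the discretized convolution over an actionable-target series.

    ``y_t = sum_{i=0}^{min(t, M)} w_i f_{t-i}``; taps reaching before the
    start of the series, or landing on masked (warm-up) target samples, are
    dropped — their total weight is negligible past the warm-up.  Outputs at
    indices below ``warmup_hours``, and wherever the current target sample is
    itself invalid, are masked invalid.
    """
    warmup_taps = int(round(warmup_hours / kernel.h))
    f = np.where(target.valid, target.values, 0.0)
    y = np.convolve(f, kernel.weights)[: len(f)]
    valid = target.valid.copy()
    valid[:warmup_taps] = False
    if len(target) <= warmup_taps:
        warnings.warn("target shorter than the warm-up; all outputs masked invalid")
    return StateSeries(target.index, y, valid)


def integrate_exact(
    b0: float,
    f: np.ndarray,
    t_grid: np.ndarray,
    y0: float = 0.0,
) -> np.ndarray:
    """Closed-form solution of dy/dt = b0 (f - y) for piecewise-linear f.

    Over each step the target is taken linear between its grid values, for
    which the exponential integrator is exact: with slope ``s`` on a step of
    length ``dt``, the particular solution is ``f(t) - s/b0`` and the
    residual decays as ``exp(-b0 dt)``.  Returns y on ``t_grid`` with
    ``y[0] = y0`` (the transient term ``y0 exp(-b0 t)`` is carried exactly).
    """
    if b0 <= 0:
        raise ValueError("b0 must be positive")
    f = np.asarray(f, dtype=float)
    t = np.asarray(t_grid, dtype=float)
    if f.shape != t.shape:
        raise ValueError("f and t_grid must be aligned")
    y = np.empty_like(f)
    y[0] = y0
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("t_grid must be strictly increasing")
    slope = np.diff(f) / dt
    decay = np.exp(-b0 * dt)
    for k in range(len(dt)):
        # y_{k+1} = particular(t_{k+1}) + (y_k - particular(t_k)) e^{-b0 dt}
        y[k + 1] = f[k + 1] - slope[k] / b0 + (y[k] - f[k] + slope[k] / b0) * decay[k]
    return y


def delayed_tracking_mse(y_o: HourlySeries, delay_hours: float, h: float = 1.0) -> float:
    """Theoretical MSE floor for tracking a delayed optimum: mean (y^o_t - y^o_{t-dt})^2.

    For small delays this scales as ``dt^2 <(dy^o/dt)^2>`` — quadratically in
    the delay and linearly in the mean squared rate of change.
    """
    lag = int(round(delay_hours / h))
    if lag < 1:
        raise ValueError("delay must be at least one sampling step")
    if lag >= len(y_o):
        raise ValueError("delay exceeds the series length")
    diff = y_o.values[lag:] - y_o.values[:-lag]
    return float(np.mean(diff**2))
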