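"""Dynamics-informed neural network (DINN).

A small trainable dense network maps the ``n`` most recent optimal-state
values (strictly before time t) plus optional daily and annual clock phases
to the actionable target ``f_t``.  The target feeds a *frozen* convolution
layer holding the trapezoidal exponential kernel of the adaptation dynamics,
so the network output is the tracked state ``y_t`` and the training loss is
the tracking MSE against the optimal state itself.  Three variants arise
from the inputs: past values only, past values + daily clock, and past
values + daily + annual clocks.

The network is deliberately tiny — four dense layers of 16 ELU units and a
single linear output neuron — and is trained full-batch with Adamax in
rounds of fixed epoch count and decreasing learning rate, stopping when the
validation loss improves by less than a tolerance between rounds.  The whole
stack (forward, backward, optimizer) is implemented here in NumPy: the
convolution layer and the loss are part of the model's physics, and carrying
them explicitly keeps gradients, masking, and determinism fully auditable.

Clocks are unit-circle phase pairs ``(sin 2*pi*t/tau, cos 2*pi*t/tau)`` with
``tau`` = 24 h (daily) and 365.25 days (annual), evaluated at absolute UTC
time, standing in for endogenous oscillators entrained by the environment.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .dynamics import AdaptationKernel, DEFAULT_WARMUP_HOURS, apply_dynamics, build_kernel
from .series import HourlySeries, StateSeries, TargetSeries

__all__ = [
    "ClockPhase",
    "DINNConfig",
    "TrainConfig",
    "TrainingHistory",
    "TrainingError",
    "DINN",
    "clock_phase",
    "build_dinn",
    "assemble_training_tensors",
    "train_dinn",
    "predict_state",
]

HOURS_PER_DAY = 24.0
DAYS_PER_YEAR = 365.25  # tropical year; exposed via DINNConfig.tau_annual_days


class TrainingError(RuntimeError):
    """Raised when training diverges (NaN/Inf loss)."""


@dataclass(frozen=True)
class ClockPhase:
    """A point on the unit circle encoding the phase of a periodic clock."""

    sin: np.ndarray
    cos: np.ndarray
    period_hours: float


def clock_phase(t_hours, period_hours: float) -> ClockPhase:
    """(sin 2*pi*t/tau, cos 2*pi*t/tau) for time(s) ``t_hours`` since the epoch."""
    if period_hours <= 0:
        raise ValueError("clock period must be positive")
    angle = 2 * np.pi * np.asarray(t_hours, dtype=float) / period_hours
    return ClockPhase(np.sin(angle), np.cos(angle), period_hours)


@dataclass
class DINNConfig:
    """Architecture of the dynamics-informed network.

    ``n_past`` recent optimal-state values (delayed by 1..n_past steps) are
    the sensed inputs; the clock flags append (sin, cos) phase pairs.  The
    annual clock is only meaningful alongside the daily one (the model
    family is: no clocks, daily, daily+annual).
    """

    n_past: int = 2
    use_daily_clock: bool = False
    use_annual_clock: bool = False
    hidden_layers: int = 4
    width: int = 16
    kernel: AdaptationKernel = field(default_factory=build_kernel)
    tau_daily_hours: float = HOURS_PER_DAY
    tau_annual_days: float = DAYS_PER_YEAR
    warmup_hours: int = DEFAULT_WARMUP_HOURS

    def __post_init__(self) -> None:
        if self.n_past < 1:
            raise ValueError("n_past must be >= 1")
        if self.use_annual_clock and not self.use_daily_clock:
            raise ValueError("the annual clock requires the daily clock")
        if self.hidden_layers < 1 or self.width < 1:
            raise ValueError("network must have at least one hidden unit")

    @property
    def input_dim(self) -> int:
        return self.n_past + 2 * self.use_daily_clock + 2 * self.use_annual_clock

    @property
    def variant(self) -> str:
        if self.use_annual_clock:
            return f"dinn_n{self.n_past}_daily_annual"
        if self.use_daily_clock:
            return f"dinn_n{self.n_past}_daily"
        return f"dinn_n{self.n_past}"


@dataclass
class TrainConfig:
    """Full-batch Adamax training protocol.

    Training proceeds in rounds of ``epochs_per_round`` full-batch epochs;
    after each round the validation tracking loss is measured and the
    learning rate is multiplied by ``lr_decay``; training stops when the
    round-to-round validation-loss improvement drops below ``tolerance``
    (or after ``max_rounds`` as a guard).
    """

    epochs_per_round: int = 800
    learning_rate: float = 1e-2
    lr_decay: float = 0.3
    tolerance: float = 1e-5
    max_rounds: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.epochs_per_round < 1:
            raise ValueError("epochs_per_round must be >= 1")


@dataclass
class TrainingHistory:
    val_losses: list[float]
    learning_rates: list[float]
    converged: bool

    @property
    def rounds(self) -> int:
        return len(self.val_losses)


def _elu(z: np.ndarray) -> np.ndarray:
    return np.where(z > 0, z, np.expm1(np.minimum(z, 0.0)))


def _elu_grad(z: np.ndarray, a: np.ndarray) -> np.ndarray:
    # ELU'(z) = 1 for z > 0, ELU(z) + 1 otherwise (alpha = 1)
    return np.where(z > 0, 1.0, a + 1.0)


class DINN:
    """The trainable network; weights live as plain NumPy arrays."""

    def __init__(self, config: DINNConfig, seed: int = 0):
        self.config = config
        self.label = config.variant
        rng = np.random.default_rng(seed)
        dims = [config.input_dim] + [config.width] * config.hidden_layers + [1]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))  # Glorot uniform
            self.weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))
        self.init_seed = seed

    # ---- forward / backward -------------------------------------------------

    @property
    def n_trainable_parameters(self) -> int:
        return sum(w.size + b.size for w, b in zip(self.weights, self.biases))

    def forward(self, X: np.ndarray, cache: list | None = None) -> np.ndarray:
        a = X
        for layer, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ W + b
            if layer < len(self.weights) - 1:
                out = _elu(z)
            else:
                out = z  # linear output neuron: the actionable target
            if cache is not None:
                cache.append((a, z, out))
            a = out
        return a[:, 0]

    def backward(self, cache: list, dL_df: np.ndarray):
        """Gradients of the scalar loss w.r.t. every weight and bias."""
        grads_W = [np.empty_like(W) for W in self.weights]
        grads_b = [np.empty_like(b) for b in self.biases]
        delta = dL_df[:, None]
        for layer in range(len(self.weights) - 1, -1, -1):
            a_in, z, out = cache[layer]
            if layer < len(self.weights) - 1:
                delta = delta * _elu_grad(z, out)
            grads_W[layer] = a_in.T @ delta
            grads_b[layer] = delta.sum(axis=0)
            if layer > 0:
                delta = delta @ self.weights[layer].T
        return grads_W, grads_b

    # ---- feature construction ----------------------------------------------

    def features(self, series: HourlySeries) -> tuple[np.ndarray, np.ndarray]:
        """Input matrix over a series; rows lacking full history are masked.

        Row t holds (y^o_{t-1}, ..., y^o_{t-n}) and the clock phases at the
        absolute time of t.  The current value y^o_t never enters its own
        row (causality), so the first ``n_past`` rows are invalid.
        """
        cfg = self.config
        y = series.values
        n = len(y)
        cols = [np.concatenate([np.zeros(k), y[: n - k]]) for k in range(1, cfg.n_past + 1)]
        X = np.stack(cols, axis=1)
        if cfg.use_daily_clock:
            daily = clock_phase(series.hours_since_epoch, cfg.tau_daily_hours)
            X = np.column_stack([X, daily.sin, daily.cos])
        if cfg.use_annual_clock:
            annual = clock_phase(series.hours_since_epoch, cfg.tau_annual_days * 24.0)
            X = np.column_stack([X, annual.sin, annual.cos])
        valid = series.valid.copy()
        valid[: cfg.n_past] = False
        return X, valid

    def predict_target(self, series: HourlySeries) -> TargetSeries:
        X, valid = self.features(series)
        f = self.forward(X)
        return TargetSeries(series.index, np.where(valid, f, 0.0), valid)

    # ---- persistence --------------------------------------------------------

    def to_json(self) -> str:
        cfg = self.config
        payload = {
            "format": "adaptrack-dinn-1",
            "config": {
                "n_past": cfg.n_past,
                "use_daily_clock": cfg.use_daily_clock,
                "use_annual_clock": cfg.use_annual_clock,
                "hidden_layers": cfg.hidden_layers,
                "width": cfg.width,
                "tau_daily_hours": cfg.tau_daily_hours,
                "tau_annual_days": cfg.tau_annual_days,
                "warmup_hours": cfg.warmup_hours,
                "kernel": {"b0": cfg.kernel.b0, "h": cfg.kernel.h, "M": cfg.kernel.M},
            },
            "init_seed": self.init_seed,
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
        }
        return json.dumps(payload)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            handle.write(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "DINN":
        payload = json.loads(text)
        cfg_d = payload["config"]
        kernel = build_kernel(**cfg_d.pop("kernel"))
        model = cls(DINNConfig(kernel=kernel, **cfg_d), seed=payload.get("init_seed", 0))
        model.weights = [np.asarray(w, dtype=float) for w in payload["weights"]]
        model.biases = [np.asarray(b, dtype=float) for b in payload["biases"]]
        return model

    @classmethod
    def load(cls, path) -> "DINN":
        with open(path, "r", encoding="utf-8") as handle:
            return cls.from_json(handle.read())


def build_dinn(config: DINNConfig, seed: int = 0) -> DINN:
    """Construct an untrained network; the convolution kernel is frozen by
    construction (it lives in the config, outside the trainable parameters)."""
    return DINN(config, seed=seed)


def assemble_training_tensors(y_o: HourlySeries, intervals, config: DINNConfig) -> dict:
    """Stack per-window inputs, labels, and masks for full-batch training.

    Input rows use only values from *within* each window (the first
    ``n_past`` rows of every window are masked rather than reaching before
    the window start); loss terms are the post-warm-up samples whose current
    target is valid, giving ``interval_hours - warmup_hours`` terms per
    window whenever ``n_past <= warmup_hours``.
    """
    model_stub = DINN(config, seed=0)  # features() only; weights unused
    X_parts, fvalid_parts, labels, times = [], [], [], []
    for window in intervals.windows(y_o):
        X, valid = model_stub.features(window)
        X_parts.append(X)
        fvalid_parts.append(valid)
        labels.append(window.values)
        times.append(window.hours_since_epoch)
    L = intervals.length
    warm = int(round(config.warmup_hours / config.kernel.h))
    f_valid = np.stack(fvalid_parts)  # (n_win, L)
    loss_valid = f_valid.copy()
    loss_valid[:, :warm] = False
    return {
        "X": np.concatenate(X_parts, axis=0),  # (n_win * L, d)
        "f_valid": f_valid,
        "labels": np.stack(labels),  # (n_win, L)
        "loss_valid": loss_valid,
        "n_windows": len(intervals),
        "window_length": L,
    }


def _conv_forward(f: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """y[:, t] = sum_i w_i f[:, t-i] per window, taps before the window dropped."""
    n_win, L = f.shape
    y = np.zeros_like(f)
    for i, wi in enumerate(weights):
        if i >= L:
            break
        y[:, i:] += wi * f[:, : L - i]
    return y


def _conv_backward(dL_dy: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Transpose of :func:`_conv_forward`: dL/df[:, t] = sum_i w_i dL/dy[:, t+i]."""
    n_win, L = dL_dy.shape
    g = np.zeros_like(dL_dy)
    for i, wi in enumerate(weights):
        if i >= L:
            break
        g[:, : L - i] += wi * dL_dy[:, i:]
    return g


def _tracking_loss(model: DINN, tensors: dict, cache: list | None = None):
    """MSE between convolution output and optimal state over valid samples."""
    n_win, L = tensors["labels"].shape
    f_flat = model.forward(tensors["X"], cache=cache)
    f = np.where(tensors["f_valid"], f_flat.reshape(n_win, L), 0.0)
    y = _conv_forward(f, model.config.kernel.weights)
    mask = tensors["loss_valid"]
    resid = np.where(mask, y - tensors["labels"], 0.0)
    n_valid = mask.sum()
    loss = float((resid**2).sum() / n_valid)
    return loss, f, resid, n_valid


class _Adamax:
    """Adamax (infinity-norm Adam variant); one slot pair per parameter."""

    def __init__(self, params: list[np.ndarray], beta1=0.9, beta2=0.999, eps=1e-8):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.u = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray], lr: float) -> None:
        self.t += 1
        correction = 1.0 - self.beta1**self.t
        for p, g, m, u in zip(params, grads, self.m, self.u):
            m *= self.beta1
            m += (1 - self.beta1) * g
            np.maximum(self.beta2 * u, np.abs(g), out=u)
            p -= lr / correction * m / (u + self.eps)


def train_dinn(
    model: DINN,
    train_tensors: dict,
    val_tensors: dict,
    train_config: TrainConfig | None = None,
) -> TrainingHistory:
    """Train in rounds of full-batch Adamax epochs until validation converges.

    Mutates ``model`` in place and returns the per-round validation-loss
    history.  Reproducible: the only randomness is the weight initialization
    seed recorded on the model (the optimizer and batching are
    deterministic).
    """
    cfg = train_config or TrainConfig()
    params = model.weights + model.biases
    opt = _Adamax(params)
    lr = cfg.learning_rate
    n_win, L = train_tensors["labels"].shape
    kernel_w = model.config.kernel.weights
    val_losses: list[float] = []
    lrs: list[float] = []
    converged = False
    prev_val = np.inf
    for _round in range(cfg.max_rounds):
        for _epoch in range(cfg.epochs_per_round):
            cache: list = []
            loss, f, resid, n_valid = _tracking_loss(model, train_tensors, cache)
            if not np.isfinite(loss):
                raise TrainingError(
                    f"training diverged (loss={loss}) at round {_round}, lr={lr}"
                )
            dL_dy = 2.0 * resid / n_valid
            dL_df = _conv_backward(dL_dy, kernel_w)
            dL_df = np.where(train_tensors["f_valid"], dL_df, 0.0).reshape(-1)
            grads_W, grads_b = model.backward(cache, dL_df)
            opt.step(params, grads_W + grads_b, lr)
        val_loss, *_ = _tracking_loss(model, val_tensors)
        val_losses.append(val_loss)
        lrs.append(lr)
        if prev_val - val_loss < cfg.tolerance:
            converged = True
            break
        prev_val = val_loss
        lr *= cfg.lr_decay
    return TrainingHistory(val_losses=val_losses, learning_rates=lrs, converged=converged)


def predict_state(model: DINN, series: HourlySeries, warmup_hours: int | None = None) -> StateSeries:
    """Network target followed by the frozen adaptation convolution."""
    warm = model.config.warmup_hours if warmup_hours is None else warmup_hours
    target = model.predict_target(series)
    return apply_dynamics(target, model.config.kernel, warmup_hours=warm)
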