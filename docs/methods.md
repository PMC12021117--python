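# Methods

## The adaptation model

The state of interest is a single cellular variable `y_t` (an ATP level, a
protein copy number, an expression program — any quantity with an
environment-dependent optimum). The environment defines an optimal state
`y^o_t`, here proxied by solar irradiance normalized to [0, 1], and the
system relaxes toward a target `f_t` with first-order kinetics

    dy/dt = b0 (f_t − y_t),

with a constant adaptation rate `b0` (default 1/3 per hour — relaxation time
3 h, a typical scale for regulatory adjustment). The fitness objective near
the optimum is quadratic in the deviation, so the natural score is the mean
square error between `y_t` and `y^o_t`; we report its square root (RMSE),
which has the same units as the normalized state.

The key identity: substituting the solution of the linear ODE shows that the
system tracks `y^o_t` *exactly* after an `exp(−b0 t)` transient when it
adapts toward the **actionable target**

    f_t = y^o_t + (1/b0) · d y^o_t / dt.

No information about the future is required; the fundamental limits on
adaptation are the delay and noise in obtaining `y^o_t` and its rate of
change *now*. All estimators and the neural network below are causal
approximations of this quantity.

## Discretized dynamics

With hourly samples the stationary convolution form of the dynamics is
discretized by the trapezoidal rule into

    y_t = Σ_{i=0..M} w_i f_{t−ih},   w_0 = b0 h / 2,   w_i = b0 h e^(−b0 i h),

with `h = 1` h and `M = 25` taps (the first neglected term,
`(1/2)e^(−b0(M+1)h) ≈ 8.6e−5`, is negligible; the kernel spans 24 h of
history). The raw weights sum to ≈ 1.0090 rather than 1; we keep them raw by
default — the small DC-gain bias is part of the discretization being studied
— and expose `build_kernel(renormalize=True)` for unit gain. The first 24
outputs of every evaluation window lack full kernel history and are
discarded ("warm-up"), so a 744-h window scores 720 samples.

Taps that reach before the start of a series, or that land on masked
(insufficient-history) target samples, are dropped rather than zero-filled
through an imputed value; past the warm-up their total weight is below
2.5e−4, which bounds the deviation this introduces.

`integrate_exact` is the independent continuous-time route: the closed-form
exponential-integrator update, exact for piecewise-linear targets, including
the transient term. It is used to verify the perfect-tracking identity to
1e−6 and to check second-order convergence of the discretized convolution
(halving `h` quarters the deviation).

## Target estimators

All estimators are linear, causal functions of the optimal-state history
(see the table in `adaptrack.targets`). The backward-difference family
(first- and second-order) approximates the derivative term from current and
past values; the delayed variants model a 1-h relay lag (configurable); the
extrapolated variant advances both the state and its derivative one step by
quadratic extrapolation; the day-recurrent variant forecasts today's value
from yesterday's increment at the same clock time plus the latest delayed
observation (a minimal seasonal-recurrence forecast in the Holt–Winters
spirit); and `mean_combination` averages estimators *on the target series,
before the dynamics* — averaging commutes with the linear convolution, but
fixing the order keeps masks and reported targets well defined. Derivative
terms near dawn/dusk push `f_t` outside [0, 1]; values pass through
unclamped, as does the tracked state.

Samples whose history reaches before the series start are masked invalid.
When a series is windowed for evaluation, targets are computed once over the
full series, so window interiors are fully valid and only a window at the
very head of a series loses extra samples (e.g. one extra sample for the
25-h-history recurrent estimator).

## Synthetic environment

The generator emulates the statistical structure of mid-latitude hourly
irradiance:

* **Clear sky** — zero-clipped sine of solar elevation from plain
  zenith-cosine geometry (declination −23.44°·cos(2π(d+10)/365.25), hour
  angle 15°·(hour−12)). This reproduces the daily zero-clipped bell, the
  seasonal amplitude and day-length modulation, and exact 24-h/annual
  recurrence. It is *not* radiometrically accurate (no air mass, no
  atmosphere): peak values, twilight shapes, and absolute irradiance are
  wrong, which is irrelevant here because the series is normalized and only
  its temporal statistics matter.
* **Weather** — a multiplicative attenuation `a_t = expit(2 + x_t)` of a
  stationary AR(1) Gaussian `x_t` (hourly autocorrelation ρ = 0.95,
  innovation scale σ = 0.5). The logistic transform keeps attenuation in
  (0, 1], preserves zero nights, and the AR(1) gives the hour-scale
  persistence of cloud fields. Defaults were fixed once as a realistic
  mid-latitude regime: ρ = 0.95 gives a correlation time of ~20 h, and the
  stationary latent s.d. (≈1.6) spans near-clear to heavily overcast days.
* Normalization divides by the maximum over the *entire* series (never
  per-window or per-year), so values lie in [0, 1] with max exactly 1, and
  normalizing twice equals normalizing once.

What the synthetic weather does **not** reproduce: fronts and diurnally
correlated cloud regimes, multiplicative noise that depends on solar
elevation, interannual climate variation, and instrument artifacts. Passing
tests on synthetic data therefore demonstrate the *relative* behaviour of
the estimators (ordering, delay degradation, averaging gains, clock value) —
which is robust to these differences — rather than the absolute RMSE values
of any particular site record.

Real data enters through the PVGIS v5.2 `seriescalc` reader (CSV or JSON
payloads; timestamps `yyyymmdd:HHMM`, interpreted as UTC and truncated to
the containing hour). Missing or irregular hours are rejected, not imputed.

## Evaluation protocol

Validation uses consecutive 744-h windows spaced 720 h (30 days): each
window discards its 24-h warm-up, so valid samples tile the span contiguously
— 72 windows over six years pool 72 × 720 = 51840 unique hourly residuals.
The 95% CI comes from a block bootstrap: squared residuals are reshaped into
whole 24-h blocks (51840 → 2160), blocks are resampled with replacement
10000 times, and the 2.5/97.5 percentiles of the replicate RMSE distribution
are reported. Blocks are aligned to the pooled-residual order (windows start
on the hour, so blocks are calendar-day-like); the block length, iteration
count, and seed are recorded in every `TrackingResult`. The bootstrap seed
is independent of the data-generation seed.

## Dynamics-informed network

The network replaces the hand-derived estimators with a learned map from
available information to the actionable target: inputs are the `n` most
recent optimal-state values *strictly before* t (never `y^o_t` itself) plus
optional clock phases; the body is 4 dense layers of 16 ELU units and one
linear output neuron (945 trainable parameters at input dimension 6); the
output `f_t` feeds the frozen convolution kernel above, and the loss is the
MSE between the convolution output and `y^o_t` over post-warm-up samples.
Training the target *through* the dynamics is the point: the network learns
whatever derivative/forecast structure minimizes tracking error.

Clocks are unit-circle pairs `(sin 2πt/τ, cos 2πt/τ)` with τ = 24 h and
365.25 days, evaluated at absolute UTC time from a fixed epoch
(2000-01-01T00:00). They model endogenous oscillators entrained by the
environment: the network receives phase, not any sensed quantity. The year
length is a parameter (`tau_annual_days`).

The stack is implemented directly in NumPy — forward pass, transpose-
convolution gradient, manual backpropagation, and Adamax (β1 = 0.9,
β2 = 0.999) — which keeps the frozen-kernel contract, causality masking, and
bit-reproducibility (a single recorded initialization seed; full-batch
steps) explicit and auditable. Training runs in rounds of 800 full-batch
epochs; after each round the validation tracking loss is measured and the
learning rate is scaled by 0.3 (initial 1e−2); training stops when the
improvement between rounds falls below 1e−5, with a cap of 12 rounds as a
divergence guard. Only the round/convergence protocol is canonical; the
initial rate and decay factor are this package's defaults, chosen once so
that the final rounds make sub-tolerance steps. Weight initialization is
Glorot-uniform from the recorded seed; NaN/Inf loss raises a `TrainingError`
rather than returning a silently broken model.

Training windows are drawn uniformly at random (overlap allowed) from the
training period; within each window, input rows do not reach before the
window start — the first `n_past` rows are masked instead — so a 744-h
window contributes 720 loss terms whenever `n_past ≤ 24`. Validation loss
during training uses the same interval construction as the final
evaluation, on a period disjoint from training.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run entirely on synthetic data
generated at run time. The estimator comparisons use six synthetic years
validated over the canonical 72-window layout (51840 residuals); the network
experiments train on 25 random 744-h windows from a multi-year training
slice and validate on the subsequent years, a deliberately compact version
of the full 365-window protocol that preserves every structural element
(window length, warm-up, full-batch rounds, convergence rule). With these
sizes the clock-equipped network at `n_past = 2` lands within a few percent
of `n_past = 30`, reproducing the data-efficiency plateau qualitatively.

## Known limitations

* The adaptation rate is constant (`b_t = b0`); the framework's
  time-varying-rate generality is not implemented.
* The synthetic weather model is phenomenological (see above); absolute
  RMSEs on synthetic data are not comparable to any specific site record.
* The recurrent estimator looks back exactly one day; multi-day seasonal
  smoothing (full Holt–Winters) is out of scope.
* The network family is the fixed 4×16 ELU architecture; no hyperparameter
  search is provided, by design.
* PVGIS ingestion requires a complete uniform hourly grid; records with
  gaps must be repaired upstream.
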