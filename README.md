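# adaptrack

**Actionable-target tracking for continuously adapting biological systems.**

Organisms adapt toward environment-dependent optima — metabolic set points,
expression programs, behavioural states — with first-order kinetics

```
dy/dt = b0 (f_t − y_t),
```

where `y_t` is the adapting state, `b0` the adaptation rate, and `f_t` the
target the system moves toward. Adapting toward the current optimum
`f_t = y_t^o` (naive adaptation) always lags a changing environment. The
central result this package implements is that a first-order system tracks
the optimum *perfectly*, without anticipating the future, when it adapts
toward the **actionable target**

```
f_t = y_t^o + (1/b0) · d y_t^o / dt,
```

the current optimum corrected by its rate of change. What limits real
adaptation is not forecasting the future but obtaining a reliable estimate
of this quantity *now*, under sensing delays and environmental noise — and
that is where predictive machinery such as circadian and circannual clocks
earns its keep.

`adaptrack` is a library (with a thin CLI) for studying these trade-offs on
hourly environmental signals, using normalized solar irradiance as the
canonical optimum:

- **environment** — synthetic hourly irradiance (clear-sky zenith geometry
  at a chosen latitude × autocorrelated multiplicative weather attenuation),
  a PVGIS v5.2 `seriescalc` reader (CSV/JSON) for real field records, global-
  maximum normalization, and training/validation window construction.
- **dynamics** — the exact exponential integrator of the adaptation ODE and
  the trapezoidal exponential-kernel convolution
  (`w_0 = b0h/2`, `w_i = b0h·e^(−b0 i h)`, default `b0 = 1/3 h⁻¹`, `M = 25`)
  that discretizes it.
- **targets** — causal estimators of the actionable target: first/second-
  order backward differences, 1-h-delayed variants, second-order
  extrapolation, a day-recurrent (seasonal-increment) forecast, and target
  averaging.
- **dinn** — a dynamics-informed neural network: a 4×16 ELU dense stack
  producing `f_t` from the `n` most recent optimal-state values plus daily
  (24 h) and annual (365.25 d) unit-circle clock phases, composed with the
  *frozen* adaptation convolution and trained end-to-end on tracking MSE
  (full-batch Adamax in rounds, 1e−5 validation convergence rule), in pure
  NumPy.
- **evaluation** — tracking RMSE over 744-h validation windows with 95%
  confidence intervals from a 24-h block bootstrap (10000 iterations).

## Worked example

```python
from adaptrack import (EstimatorSpec, SyntheticEnvConfig, build_kernel,
                       evaluate_pipeline, make_intervals, synthetic_environment)

B0 = 1/3
env = synthetic_environment(SyntheticEnvConfig(latitude=45.0, n_hours=24*120, seed=3))
kernel = build_kernel(b0=B0, M=25)
windows = make_intervals(env, "validation", interval_hours=744, spacing_hours=720)

for method in ["naive", "d1_backward", "d2_backward", "delayed_naive"]:
    print(evaluate_pipeline(env, EstimatorSpec(method, b0=B0), kernel, windows))
```

prints

```
naive: RMSE = 0.1424 (95% CI [0.1344, 0.1501], n = 2160)
d1_backward: RMSE = 0.0267 (95% CI [0.0257, 0.0277], n = 2160)
d2_backward: RMSE = 0.0123 (95% CI [0.0118, 0.0128], n = 2160)
delayed_naive: RMSE = 0.1895 (95% CI [0.1788, 0.1998], n = 2160)
```

Read: naive adaptation misses the optimum by ~0.14 of the environment's
full range; adding a first-order derivative correction cuts the error ~5×
and a second-order correction ~12×, while a 1-h sensing delay makes
tracking *worse* than naive — the derivative information, not foresight, is
what matters. Each RMSE comes with a block-bootstrap confidence interval
over the pooled validation residuals (720 scored samples per 744-h window
after the 24-h convolution warm-up).

The `examples/` directory holds one narrative script per capability
(perfect tracking, estimator comparison, network training, PVGIS
ingestion); each prints the numbers it computes and a line on what they
mean. The same pipelines are reachable from the shell:

```
adaptrack simulate --n-hours 2880 --seed 3 --out env.csv
adaptrack track --series env.csv --estimator d2_backward --estimator naive
adaptrack train --train-series train.csv --val-series val.csv --n-past 2
```

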