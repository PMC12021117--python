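"""Dynamics-informed network: architecture, causality, training, persistence."""

import numpy as np
import pytest

from adaptrack import (
    DINN,
    DINNConfig,
    EstimatorSpec,
    TrainConfig,
    apply_dynamics,
    assemble_training_tensors,
    build_dinn,
    build_kernel,
    clock_phase,
    estimate_target,
    make_intervals,
    predict_state,
    rmse,
    train_dinn,
)

from conftest import make_series, sinusoid


class TestClockPhase:
    def test_reference_epoch_phase(self):
        phase = clock_phase(0.0, 24.0)
        assert phase.sin == pytest.approx(0.0) and phase.cos == pytest.approx(1.0)

    def test_quarter_cycle(self):
        phase = clock_phase(6.0, 24.0)
        assert phase.sin == pytest.approx(1.0) and phase.cos == pytest.approx(0.0, abs=1e-12)

    def test_unit_circle_and_periodicity(self):
        t = np.linspace(0, 1000, 257)
        phase = clock_phase(t, 24.0)
        assert np.allclose(phase.sin**2 + phase.cos**2, 1.0)
        shifted = clock_phase(t + 24.0, 24.0)
        assert np.allclose(phase.sin, shifted.sin) and np.allclose(phase.cos, shifted.cos)

    def test_invalid_period(self):
        with pytest.raises(ValueError):
            clock_phase(0.0, 0.0)


class TestArchitecture:
    def test_input_dim_and_trainable_parameter_count(self, kernel):
        config = DINNConfig(n_past=2, use_daily_clock=True, use_annual_clock=True, kernel=kernel)
        assert config.input_dim == 6
        model = build_dinn(config)
        # (6*16+16) + 3*(16*16+16) + (16+1) for 4 hidden layers of 16 + linear output
        assert model.n_trainable_parameters == 945

    def test_minimal_input_dim(self, kernel):
        assert DINNConfig(n_past=1, kernel=kernel).input_dim == 1

    def test_annual_clock_requires_daily_clock(self, kernel):
        with pytest.raises(ValueError):
            DINNConfig(n_past=1, use_daily_clock=False, use_annual_clock=True, kernel=kernel)

    def test_convolution_weights_are_the_kernel_and_not_trainable(self, kernel):
        model = build_dinn(DINNConfig(n_past=1, kernel=kernel))
        np.testing.assert_array_equal(model.config.kernel.weights, kernel.weights)
        trainable = sum(w.size for w in model.weights) + sum(b.size for b in model.biases)
        assert model.n_trainable_parameters == trainable  # kernel not counted

    def test_zeroed_network_predicts_bias_times_kernel_sum(self, kernel):
        model = build_dinn(DINNConfig(n_past=1, kernel=kernel))
        for w in model.weights:
            w[:] = 0.0
        for b in model.biases:
            b[:] = 0.0
        model.biases[-1][:] = 0.25
        series = make_series(np.random.default_rng(0).random(100))
        y = predict_state(model, series)
        # earliest valid samples drop sub-warm-up taps of weight < 2.5e-4
        assert np.allclose(y.values[y.valid], 0.25 * kernel.dc_gain, atol=0.25 * 2.5e-4)
        assert np.allclose(y.values[26:], 0.25 * kernel.dc_gain, atol=1e-12)
        assert y.index.equals(series.index)  # no temporal shift


class TestCausality:
    def test_input_rows_are_strictly_delayed(self, kernel):
        model = build_dinn(DINNConfig(n_past=3, kernel=kernel))
        series = make_series(np.arange(50, dtype=float) / 50)
        X, valid = model.features(series)
        t = 30
        assert np.allclose(X[t, :3], series.values[[t - 1, t - 2, t - 3]])
        assert series.values[t] not in X[t, :3]
        assert not valid[:3].any() and valid[3:].all()

    def test_future_perturbation_does_not_change_present_target(self, kernel):
        model = build_dinn(DINNConfig(n_past=2, use_daily_clock=True, kernel=kernel), seed=4)
        rng = np.random.default_rng(5)
        base = rng.random(120)
        bumped = base.copy()
        bumped[100:] += 5.0
        f_base = model.predict_target(make_series(base))
        f_bump = model.predict_target(make_series(bumped))
        np.testing.assert_array_equal(f_base.values[:100], f_bump.values[:100])

    def test_training_window_contributes_720_loss_terms(self, kernel):
        series = make_series(np.random.default_rng(1).random(744 * 2))
        config = DINNConfig(n_past=2, kernel=kernel)
        iv = make_intervals(series, "validation", interval_hours=744, spacing_hours=744)
        tensors = assemble_training_tensors(series, iv, config)
        assert np.all(tensors["loss_valid"].sum(axis=1) == 720)


class TestTraining:
    @pytest.fixture(scope="class")
    def sin_env(self):
        values, _, _ = sinusoid(24 * 40, period=24.0, amplitude=0.5)
        # shift into [0, 1] like a normalized environment
        from adaptrack import OptimalStateSeries
        shifted = 0.5 + values.values
        return make_series(shifted / shifted.max(), cls=OptimalStateSeries)

    def fast_config(self, seed=0):
        return TrainConfig(epochs_per_round=150, learning_rate=1e-2, max_rounds=6, seed=seed)

    def test_training_is_deterministic_given_seed(self, kernel, sin_env):
        iv = make_intervals(sin_env, "validation", interval_hours=240, spacing_hours=240)
        config = DINNConfig(n_past=1, use_daily_clock=True, kernel=kernel)
        tensors = assemble_training_tensors(sin_env, iv, config)
        losses = []
        for _ in range(2):
            model = build_dinn(config, seed=7)
            hist = train_dinn(model, tensors, tensors, self.fast_config(seed=7))
            losses.append(hist.val_losses[-1])
        assert losses[0] == losses[1]

    def test_noiseless_daily_signal_beats_delayed_naive(self, kernel, sin_env):
        config = DINNConfig(n_past=1, use_daily_clock=True, kernel=kernel)
        iv = make_intervals(sin_env, "validation", interval_hours=240, spacing_hours=240)
        tensors = assemble_training_tensors(sin_env, iv, config)
        model = build_dinn(config, seed=0)
        hist = train_dinn(model, tensors, tensors, TrainConfig(epochs_per_round=400, max_rounds=8, seed=0))
        y_model = predict_state(model, sin_env)
        y_naive = apply_dynamics(
            estimate_target(sin_env, EstimatorSpec("delayed_naive")), kernel
        )
        assert rmse(y_model, sin_env) < rmse(y_naive, sin_env)
        # convergence rule: the final round improved by less than the tolerance
        if hist.converged and hist.rounds >= 2:
            assert hist.val_losses[-2] - hist.val_losses[-1] < 1e-5

    def test_clockless_single_value_network_matches_delayed_naive(self, kernel):
        """With one past value and no clock, the network has no phase
        information: its tracking cannot be far better than adapting to the
        last available observation."""
        from adaptrack import SyntheticEnvConfig, evaluate_pipeline, synthetic_environment

        env = synthetic_environment(SyntheticEnvConfig(n_hours=24 * 120, seed=21))
        train_env, val_env = env.slice(0, 24 * 60), env.slice(24 * 60, 24 * 60)
        config = DINNConfig(n_past=1, kernel=kernel)
        train_iv = make_intervals(train_env, "training", n_train=6, seed=2)
        val_iv = make_intervals(val_env, "validation")
        model = build_dinn(config, seed=2)
        train_dinn(
            model,
            assemble_training_tensors(train_env, train_iv, config),
            assemble_training_tensors(val_env, val_iv, config),
            TrainConfig(epochs_per_round=200, max_rounds=5, seed=2),
        )
        dinn_rmse = evaluate_pipeline(val_env, model, kernel, val_iv, iterations=100).rmse
        naive_rmse = evaluate_pipeline(
            val_env, EstimatorSpec("delayed_naive"), kernel, val_iv, iterations=100
        ).rmse
        assert dinn_rmse > 0.7 * naive_rmse

    def test_divergence_raises_training_error(self, kernel, sin_env):
        from adaptrack import TrainingError

        config = DINNConfig(n_past=1, kernel=kernel)
        iv = make_intervals(sin_env, "validation", interval_hours=240, spacing_hours=240)
        tensors = assemble_training_tensors(sin_env, iv, config)
        model = build_dinn(config, seed=0)
        model.weights[0][:] = 1e200  # force overflow
        with pytest.raises(TrainingError):
            train_dinn(model, tensors, tensors, self.fast_config())


class TestPersistence:
    def test_json_roundtrip_preserves_predictions(self, kernel, tmp_path):
        config = DINNConfig(n_past=2, use_daily_clock=True, use_annual_clock=True, kernel=kernel)
        model = build_dinn(config, seed=9)
        path = tmp_path / "model.json"
        model.save(path)
        restored = DINN.load(path)
        series = make_series(np.random.default_rng(2).random(200))
        np.testing.assert_allclose(
            model.predict_target(series).values, restored.predict_target(series).values
        )
        assert restored.config.input_dim == 6
        assert restored.config.kernel.M == kernel.M
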