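"""The NumPy stacked LSTM: gradients, determinism, training behavior."""

import numpy as np
import pytest

from cgmforecast.network import (
    ArchitectureSpec,
    EarlyStopper,
    ForecastModel,
    Normalization,
    TrainConfig,
    last_value_baseline,
    train_on_subset,
)


def _toy_data(rng, n=60, T=24, C=1, h=6):
    X = 100 + 60 * rng.random((n, T, C))
    y = X[:, -1, 0:1] + rng.random((n, h)) * 3
    return X, y


class TestBuild:
    def test_seed_determinism(self):
        spec = ArchitectureSpec(output_units=6)
        a = ForecastModel.build(spec, seed=0)
        b = ForecastModel.build(spec, seed=0)
        assert a.params_equal(b)
        c = ForecastModel.build(spec, seed=1)
        assert not a.params_equal(c)

    def test_dimensions_multivariate_60min(self):
        spec = ArchitectureSpec(input_channels=4, output_units=12)
        m = ForecastModel.build(spec, seed=0)
        assert m.params["W1"].shape[0] == 4
        assert m.params["Wd"].shape[1] == 12

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            ArchitectureSpec(layer1_units=0)
        with pytest.raises(ValueError):
            ArchitectureSpec(dropout_rate=1.0)


class TestGradients:
    def test_backprop_matches_finite_differences(self, rng):
        spec = ArchitectureSpec(
            history_steps=6, input_channels=2, layer1_units=4,
            layer2_units=3, output_units=2, dropout_rate=0.0,
        )
        m = ForecastModel.build(spec, seed=7)
        X = rng.random((5, 6, 2))
        y = rng.random((5, 2))
        _, grads = m._gradients(X, y, rng)
        eps = 1e-6
        for key, P in m.params.items():
            flat = P.reshape(-1)
            for idx in rng.choice(flat.size, size=min(6, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp, _ = m._gradients(X, y, np.random.default_rng(0))
                flat[idx] = orig - eps
                lm, _ = m._gradients(X, y, np.random.default_rng(0))
                flat[idx] = orig
                numeric = (lp - lm) / (2 * eps)
                analytic = grads[key].reshape(-1)[idx]
                assert analytic == pytest.approx(numeric, rel=1e-4, abs=1e-8), key


class TestPredict:
    def test_inference_deterministic(self, rng):
        spec = ArchitectureSpec(dropout_rate=0.2)
        m = ForecastModel.build(spec, seed=0)
        m.norm = Normalization(np.array([40.0]), np.array([400.0]))
        x = 100 + 50 * rng.random((3, 24, 1))
        np.testing.assert_array_equal(m.predict(x), m.predict(x))

    def test_output_length(self):
        spec = ArchitectureSpec(output_units=12)
        m = ForecastModel.build(spec, seed=0)
        m.norm = Normalization(np.array([40.0]), np.array([400.0]))
        assert m.predict(np.full((24, 1), 120.0)).shape == (12,)

    def test_dimension_mismatch(self):
        m = ForecastModel.build(ArchitectureSpec(), seed=0)
        with pytest.raises(ValueError):
            m.predict(np.zeros((2, 10, 1)))

    def test_serialization_roundtrip_exact(self, tmp_path, rng):
        m = ForecastModel.build(ArchitectureSpec(layer1_units=6, layer2_units=4), seed=2)
        m.norm = Normalization(np.array([41.3]), np.array([397.2]))
        m.training_meta = {"epochs_run": 3}
        path = tmp_path / "model.npz"
        m.save(path)
        back = ForecastModel.load(path)
        assert back.params_equal(m)
        assert back.spec == m.spec
        x = 100 + 50 * rng.random((2, 24, 1))
        np.testing.assert_array_equal(back.predict(x), m.predict(x))


class TestEarlyStopping:
    def test_plateau_from_epoch_3_stops_at_8(self):
        stopper = EarlyStopper(patience=5)
        losses = [10.0, 9.0, 8.0, 8.5, 8.4, 8.6, 8.3, 8.7]  # epochs 1..8
        stops = [stopper.update(e, l) for e, l in enumerate(losses, start=1)]
        assert stops == [False] * 7 + [True]
        assert stopper.best_epoch == 3

    def test_improvement_resets_counter(self):
        stopper = EarlyStopper(patience=2)
        assert not stopper.update(1, 5.0)
        assert not stopper.update(2, 6.0)
        assert not stopper.update(3, 4.0)
        assert not stopper.update(4, 4.5)
        assert stopper.update(5, 4.4)

    def test_patience_must_be_below_max_epochs(self):
        with pytest.raises(ValueError):
            TrainConfig(max_epochs=5, patience=5)


class TestTraining:
    def test_overfits_memorizable_set(self, rng):
        """Optimizer sanity: a small net must memorize 10 arbitrary samples.

        Uses the tanh cell variant: the ReLU candidate keeps the cell state
        non-negative, which makes pure memorization needlessly slow.
        """
        spec = ArchitectureSpec(layer1_units=16, layer2_units=8,
                                dropout_rate=0.0, activation="tanh")
        m = ForecastModel.build(spec, seed=0)
        X = 100 + 60 * rng.random((10, 24, 1))
        y = 100 + 60 * rng.random((10, 6))
        cfg = TrainConfig(max_epochs=400, patience=399, learning_rate=2e-2,
                          clip_norm=0.0, seed=0)
        m, _, _ = train_on_subset(m, X, y, X, y, cfg)
        assert m.mse(X, y) < 1.0  # mg^2/dL^2

    def test_empty_validation_rejected(self, rng):
        m = ForecastModel.build(ArchitectureSpec(), seed=0)
        X, y = _toy_data(rng)
        with pytest.raises(ValueError):
            train_on_subset(m, X, y, X[:0], y[:0], TrainConfig(max_epochs=2, patience=1))

    def test_warm_start_not_slower_than_cold(self, rng):
        """Warm start from a converged model needs no more epochs (median of 5)."""
        spec = ArchitectureSpec(layer1_units=8, layer2_units=4, dropout_rate=0.0)
        X, y = _toy_data(rng, n=200)
        cold_eps, warm_eps = [], []
        for seed in range(5):
            cfg = TrainConfig(max_epochs=30, patience=4, seed=seed)
            m0 = ForecastModel.build(spec, seed=seed)
            m1, e_cold, _ = train_on_subset(m0, X, y, X[:50], y[:50], cfg)
            _, e_warm, _ = train_on_subset(m1, X, y, X[:50], y[:50], cfg)
            cold_eps.append(e_cold)
            warm_eps.append(e_warm)
        assert np.median(warm_eps) <= np.median(cold_eps)

    def test_beats_last_value_baseline_on_sinusoid(self, rng):
        """A trained model must beat naive persistence on predictable signal."""
        t = np.arange(288 * 8)
        signal = 140 + 50 * np.sin(2 * np.pi * t / 96) + 2 * rng.standard_normal(t.size)
        n_train, h = 1200, 6
        X = np.stack([signal[s:s + 24, None] for s in range(1800)])
        y = np.stack([signal[s + 24:s + 30] for s in range(1800)])
        spec = ArchitectureSpec(layer1_units=12, layer2_units=6)
        wins = 0
        for seed in range(5):
            m = ForecastModel.build(spec, seed=seed)
            cfg = TrainConfig(max_epochs=15, patience=14, learning_rate=5e-3, seed=seed)
            m, _, _ = train_on_subset(m, X[:n_train], y[:n_train], X[n_train:1400], y[n_train:1400], cfg)
            pred = m.predict(X[1400:])[:, -1]
            base = last_value_baseline(X[1400:], h)[:, -1]
            model_rmse = np.sqrt(np.mean((pred - y[1400:, -1]) ** 2))
            base_rmse = np.sqrt(np.mean((base - y[1400:, -1]) ** 2))
            if model_rmse < base_rmse:
                wins += 1
        assert wins >= 3

    def test_runtime_scales_with_hidden_size(self, rng):
        """Larger hidden layers must not train faster (monotone trend check)."""
        import time

        X, y = _toy_data(rng, n=400)
        times = []
        for H in (4, 32):
            spec = ArchitectureSpec(layer1_units=H, layer2_units=H // 2)
            m = ForecastModel.build(spec, seed=0)
            cfg = TrainConfig(max_epochs=3, patience=2, seed=0)
            t0 = time.time()
            train_on_subset(m, X, y, X[:50], y[:50], cfg)
            times.append(time.time() - t0)
        assert times[-1] > times[0] * 0.8  # generous: trend, not absolute time
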