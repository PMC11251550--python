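"""Forecaster networks: counting, initialization, gradients, training."""

import numpy as np
import pandas as pd
import pytest

from gluconet import (GlucoseMLPRegressor, ModelSpec, Network, SampleConfig,
                      TrainConfig, count_parameters, init_network,
                      linear_weightspace, map_to_weightspace, nearest_state,
                      predict_series, search_learning_rate, sgd_step)
from gluconet.preprocessing import SampleSet


def brute_force_count(spec: ModelSpec) -> int:
    """Oracle: materialize every matrix and vector and count entries."""
    net = init_network(spec, TrainConfig(seed=0))
    return sum(w.size for w in net.weights) + sum(b.size for b in net.biases)


class TestCountParameters:
    @pytest.mark.parametrize("inputs,hidden,expected", [
        (108, (128, 64, 32, 16), 24833),   # full 3-feature 180-min input
        (2, (128, 64, 32, 16), 11265),
        (2, (48, 16), 945),
        (2, (9, 6), 94),
        (2, (6, 3), 43),
        (2, (4, 3), 31),
        (2, (2, 1), 11),
        (1, (), 2),                        # one weight + one bias
    ])
    def test_reference_architectures(self, inputs, hidden, expected):
        assert count_parameters(ModelSpec(inputs, hidden)) == expected

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            depth = rng.integers(0, 4)
            spec = ModelSpec(int(rng.integers(1, 20)),
                             tuple(int(h) for h in rng.integers(1, 30, depth)))
            assert count_parameters(spec) == brute_force_count(spec)


class TestInitNetwork:
    def test_same_seed_identical_networks(self):
        spec = ModelSpec(2, (9, 6))
        a = init_network(spec, TrainConfig(seed=11))
        b = init_network(spec, TrainConfig(seed=11))
        for wa, wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa, wb)

    def test_hardware_init_snaps_all_parameters_to_states(self):
        ws = linear_weightspace(100, -1.5, 1.5)
        spec = ModelSpec(2, (9, 6), activation="ReLU")
        net = init_network(spec, TrainConfig(mode="hardware", weight_space=ws))
        states = ws.all_states
        for p in net.all_parameters():
            assert np.isclose(states, p).any()

    def test_fixed_init_is_architecture_deterministic(self):
        spec = ModelSpec(2, (4, 3), activation="ReLU")
        ws = linear_weightspace(100, -1.7, 1.7)
        a = init_network(spec, TrainConfig(mode="hardware", weight_space=ws,
                                           fixed_init=True, seed=1))
        b = init_network(spec, TrainConfig(mode="hardware", weight_space=ws,
                                           fixed_init=True, seed=999))
        for wa, wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa, wb)

    def test_missing_weight_space_rejected_in_hardware_mode(self):
        with pytest.raises(ValueError, match="weight_space"):
            TrainConfig(mode="hardware")


class TestForward:
    def test_no_hidden_layer_is_affine(self):
        spec = ModelSpec(1, ())
        net = Network([np.array([[2.0]])], [np.array([0.5])], spec)
        assert net.forward(np.array([3.0])) == pytest.approx(6.5)

    def test_zero_weights_output_bias(self):
        spec = ModelSpec(3, (4,), activation="ReLU")
        net = init_network(spec, TrainConfig(seed=0))
        net.weights = [np.zeros_like(w) for w in net.weights]
        net.biases[-1][:] = 7.0
        out = net.forward(np.random.default_rng(0).normal(size=(5, 3)))
        np.testing.assert_allclose(out, 7.0)

    def test_relu_passes_positive_preactivations_unchanged(self):
        spec = ModelSpec(1, (1,), activation="ReLU")
        net = Network([np.array([[1.0]]), np.array([[1.0]])],
                      [np.array([0.0]), np.array([0.0])], spec)
        assert net.forward(np.array([2.5])) == pytest.approx(2.5)
        assert net.forward(np.array([-2.5])) == pytest.approx(0.0)

    def test_dimension_mismatch_rejected(self):
        net = init_network(ModelSpec(4, (3,)), TrainConfig(seed=0))
        with pytest.raises(ValueError):
            net.forward(np.ones(5))


class TestSgdStep:
    def _linear_net(self, w, b):
        return Network([np.array([[w]])], [np.array([b])], ModelSpec(1, ()))

    def test_hand_computed_gradient_step(self):
        # w=1, b=0, sample (x=2, y=1): dL/dw = 2*(2-1)*2 = 4 -> w' = 0.6
        net = self._linear_net(1.0, 0.0)
        out = sgd_step(net, np.array([2.0]), 1.0, learning_rate=0.1)
        assert out.weights[0][0, 0] == pytest.approx(0.6)
        assert out.biases[0][0] == pytest.approx(-0.2)  # dL/db = 2

    def test_hardware_step_snaps_via_nearest_state_oracle(self):
        g = [0.0, 0.5, 1.0]
        ws = map_to_weightspace(g, g, 0.0, 1.0)
        net = self._linear_net(1.0, 0.5)
        out = sgd_step(net, np.array([2.0]), 1.0, learning_rate=0.1,
                       weight_space=ws)
        # ideal w' = 0.6: a decrease from 1.0, so the reset ladder applies
        assert out.weights[0][0, 0] == nearest_state(0.6, "reset", ws) == 0.5

    def test_zero_gradient_is_a_fixed_point(self):
        net = self._linear_net(2.0, 1.0)
        out = sgd_step(net, np.array([3.0]), 7.0, learning_rate=0.1,
                       weight_space=linear_weightspace(10, -3, 3))
        assert out.weights[0][0, 0] == 2.0 and out.biases[0][0] == 1.0

    def test_non_finite_gradient_aborts(self):
        net = self._linear_net(1.0, 0.0)
        with pytest.raises(FloatingPointError):
            sgd_step(net, np.array([1e200]), 0.0, learning_rate=0.1)


class TestFit:
    def test_software_fit_drives_convex_loss_to_zero(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(200, 2))
        y = 0.3 * X[:, 0] - 0.5 * X[:, 1] + 0.1
        m = GlucoseMLPRegressor(hidden_sizes=(), learning_rate=0.05,
                                batch_size=50, max_epochs=200, patience=None,
                                random_state=0)
        m.fit(X, y)
        losses = m.history_.train_loss.to_numpy()
        assert losses[-1] < 1e-4
        assert losses[-1] <= losses[0]

    def test_hardware_fit_keeps_all_parameters_in_states(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(300, 2))
        y = np.tanh(X[:, 0]) - 0.2 * X[:, 1]
        ws = linear_weightspace(100, -1.5, 1.5)
        m = GlucoseMLPRegressor(hidden_sizes=(9, 6), mode="hardware",
                                weight_space=ws, learning_rate=0.05,
                                random_state=0)
        m.fit(X, y)
        states = ws.all_states
        for p in m.network_.all_parameters():
            assert np.isclose(states, p, atol=1e-12).any()

    def test_snapshot_has_lowest_logged_validation_rmse(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(400, 2))
        y = 0.5 * X[:, 0] + rng.normal(0, 0.1, 400)
        m = GlucoseMLPRegressor(hidden_sizes=(4, 3), max_epochs=30,
                                patience=None, batch_size=100, random_state=1)
        m.fit(X[:300], y[:300], X_val=X[300:], y_val=y[300:])
        best = np.sqrt(np.mean((m.predict(X[300:]) - y[300:]) ** 2))
        assert best == pytest.approx(m.history_.val_rmse.min(), abs=1e-9)

    def test_seeded_fit_is_deterministic(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(100, 2))
        y = X[:, 0]
        runs = [GlucoseMLPRegressor(hidden_sizes=(4, 3), max_epochs=5,
                                    batch_size=20, random_state=3).fit(X, y)
                for _ in range(2)]
        for wa, wb in zip(runs[0].network_.weights, runs[1].network_.weights):
            np.testing.assert_array_equal(wa, wb)

    def test_empty_training_set_rejected(self):
        m = GlucoseMLPRegressor(hidden_sizes=())
        with pytest.raises(ValueError):
            m.fit(np.empty((0, 2)), np.empty(0))

    def test_parameter_recovery_within_twice_noise_floor(self):
        # samples from a known 2-input linear rule plus small noise: the
        # smallest architecture should reach the noise-floor RMSE
        rng = np.random.default_rng(10)
        X = rng.normal(size=(2000, 2))
        noise_sd = 0.05
        y = 0.6 * X[:, 0] - 0.3 * X[:, 1] + 0.2 + rng.normal(0, noise_sd, 2000)
        m = GlucoseMLPRegressor(hidden_sizes=(2, 1), learning_rate=3e-3,
                                batch_size=200, max_epochs=400, patience=50,
                                random_state=2)
        m.fit(X[:1600], y[:1600], X_val=X[1600:], y_val=y[1600:])
        val_rmse = np.sqrt(np.mean((m.predict(X[1600:]) - y[1600:]) ** 2))
        assert val_rmse < 2 * noise_sd


class TestLearningRateSearch:
    def _data(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(150, 2))
        y = 0.4 * X[:, 0] + 0.1
        return X, y

    def test_grid_contains_decade_points(self):
        X, y = self._data()
        m = GlucoseMLPRegressor(hidden_sizes=(), max_epochs=3, batch_size=50)
        best, _, table = search_learning_rate(m, X, y, window=(1e-4, 1e-2),
                                              n_points=5)
        for decade in (1e-4, 1e-3, 1e-2):
            assert np.isclose(table.learning_rate, decade).any()
        assert np.isclose(table.learning_rate, best).any()

    def test_degenerate_window_gives_single_candidate(self):
        X, y = self._data()
        m = GlucoseMLPRegressor(hidden_sizes=(), max_epochs=2, batch_size=50)
        best, _, table = search_learning_rate(m, X, y, window=(1e-3, 1e-3))
        assert len(table) == 1 and best == pytest.approx(1e-3)

    def test_returned_rate_minimizes_validation_rmse(self):
        X, y = self._data()
        m = GlucoseMLPRegressor(hidden_sizes=(), max_epochs=10, batch_size=50)
        best, model, table = search_learning_rate(
            m, X[:100], y[:100], X_val=X[100:], y_val=y[100:],
            window=(1e-4, 1e-1), n_points=4)
        assert best == table.loc[table.val_rmse.idxmin(), "learning_rate"]
        assert model.learning_rate == best


class TestPredictSeries:
    def _samples(self, standardized=True):
        from gluconet import ScalingParams
        n = 20
        rng = np.random.default_rng(12)
        inputs = rng.normal(size=(n, 2))
        targets = rng.normal(size=n)
        scaling = ScalingParams(np.zeros(2), np.ones(2), 150.0, 50.0)
        return SampleSet(
            inputs, targets,
            pd.date_range("2022-01-01", periods=n, freq="5min"),
            SampleConfig.two_point(5), np.repeat("P1", n),
            scaling=scaling if standardized else None,
            standardized=standardized)

    def test_oracle_network_gives_zero_error(self):
        samples = self._samples()
        # a network that cannot exist in practice: we substitute predictions
        # by fitting nothing and forcing outputs equal to targets via a stub
        class Stub:
            def forward(self, x):
                return samples.targets
        result = predict_series(Stub(), samples)
        np.testing.assert_allclose(result.predicted_glucose,
                                   result.reference_glucose)

    def test_constant_network_has_zero_predicted_rate(self):
        samples = self._samples()
        net = Network([np.zeros((1, 2))], [np.array([0.3])], ModelSpec(2, ()))
        result = predict_series(net, samples)
        np.testing.assert_allclose(result.predicted_rate[1:], 0.0)
        np.testing.assert_allclose(result.predicted_glucose,
                                   150.0 + 0.3 * 50.0)

    def test_result_length_matches_sample_count(self):
        samples = self._samples()
        net = init_network(ModelSpec(2, (3,)), TrainConfig(seed=0))
        assert len(predict_series(net, samples)) == len(samples)

    def test_unscaled_samples_rejected(self):
        samples = self._samples(standardized=False)
        net = init_network(ModelSpec(2, ()), TrainConfig(seed=0))
        with pytest.raises(ValueError, match="standardized"):
            predict_series(net, samples)
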