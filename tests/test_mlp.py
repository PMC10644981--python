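"""MLP forward pass, training, and input-gradient correctness."""

import numpy as np
import pytest

from connectomlp import (
    MLPParams,
    SimConfig,
    TrainConfig,
    cohort_arrays,
    forward,
    generate_cohort,
    init_params,
    input_gradient,
    load_checkpoint,
    predict_batch,
    save_checkpoint,
    train,
)

from conftest import SMALL_HIDDEN, small_train_config


def random_small_net(seed, input_dim=7, hidden=(6, 5, 4)):
    """Float64 network with non-zero biases for gradient testing."""
    rng = np.random.default_rng(seed)
    p = init_params(input_dim, seed, hidden=hidden, dtype="float64")
    for b in p.biases:
        b += rng.standard_normal(b.size) * 0.3
    return p


class TestInit:
    def test_deterministic_and_seed_sensitive(self):
        a = init_params(20, 3, hidden=SMALL_HIDDEN)
        b = init_params(20, 3, hidden=SMALL_HIDDEN)
        c = init_params(20, 4, hidden=SMALL_HIDDEN)
        for wa, wb, wc in zip(a.weights, b.weights, c.weights):
            assert np.array_equal(wa, wb)
            assert not np.array_equal(wa, wc)
        assert all(np.all(b_ == 0) for b_ in a.biases)

    def test_default_architecture_widths(self):
        p = init_params(3486, 0)
        assert p.layer_widths == (1024, 256, 64, 2)
        assert p.input_dim == 3486

    def test_scaled_init_preserves_activation_magnitude(self):
        """He scaling keeps hidden activations O(1) on standard-normal input."""
        rng = np.random.default_rng(0)
        x = rng.standard_normal((200, 128))
        second_moments = []
        for seed in range(100):
            p = init_params(128, seed, hidden=(64, 48, 32), dtype="float64")
            from connectomlp.mlp import _forward_batch
            _, acts = _forward_batch(p, x)
            second_moments.append(np.mean(acts[3] ** 2))
        m = np.mean(second_moments)
        assert 0.5 < m < 2.0

    def test_invalid_input_dim(self):
        with pytest.raises(ValueError):
            init_params(0, 1)


class TestForward:
    def test_zero_params_give_uniform_probabilities(self):
        p = init_params(5, 0, hidden=(4, 3, 3))
        for w in p.weights:
            w[:] = 0
        pred = forward(p, np.ones(5))
        assert np.allclose(pred.probabilities, [0.5, 0.5])

    def test_probabilities_normalised(self):
        rng = np.random.default_rng(1)
        for seed in range(50):
            p = random_small_net(seed)
            for _ in range(20):
                pred = forward(p, rng.standard_normal(7))
                assert pred.probabilities.min() >= 0
                assert abs(pred.probabilities.sum() - 1.0) < 1e-9
                assert pred.predicted_class == int(np.argmax(pred.logits))

    def test_hand_computed_toy_network(self):
        """2-2-2-2-2 network with hand-worked arithmetic."""
        W = [np.array([[1.0, 0.0], [0.0, 1.0]]),
             np.array([[1.0, -1.0], [2.0, 0.0]]),
             np.array([[1.0, 1.0], [1.0, -1.0]]),
             np.array([[2.0, 0.0], [0.0, 1.0]])]
        b = [np.array([0.5, -1.0]), np.array([0.0, 1.0]),
             np.array([-1.0, 0.0]), np.array([0.5, 0.5])]
        p = MLPParams(W, b)
        pred = forward(p, np.array([1.0, 2.0]))
        # x=(1,2) -> relu(1.5,1) -> relu(3.5,-0.5)=(3.5,0) -> relu(2.5,3.5)
        # -> logits (2*2.5+0.5, 3.5+0.5) = (5.5, 4.0)
        assert np.allclose(pred.logits, [5.5, 4.0])

    def test_nonfinite_input_rejected(self):
        p = init_params(3, 0, hidden=(2, 2, 2))
        with pytest.raises(ValueError):
            forward(p, np.array([1.0, np.nan, 0.0]))


class TestTrain:
    def test_separable_data_fit_perfectly(self, separable_cohort):
        co = separable_cohort
        p = init_params(co.X.shape[1], 0, hidden=SMALL_HIDDEN)
        trained, losses = train(p, co.X, co.y, small_train_config())
        assert np.array_equal(predict_batch(trained, co.X), co.y)
        assert losses[-1] < losses[0]

    def test_zero_learning_rate_is_identity(self, separable_cohort):
        co = separable_cohort
        p = init_params(co.X.shape[1], 1, hidden=SMALL_HIDDEN)
        trained, _ = train(p, co.X, co.y,
                           small_train_config(epochs=5, learning_rate=0.0))
        for w0, w1 in zip(p.weights, trained.weights):
            assert np.array_equal(w0, w1)

    def test_loss_descends_across_seeds(self):
        sim = generate_cohort(SimConfig(n_nodes=12, n_per_group=(8, 8),
                                        effect_size=1.0, n_planted=4,
                                        n_cross_hemisphere_planted=2, seed=19))
        co = cohort_arrays(sim)
        for seed in range(10):
            p = init_params(co.X.shape[1], seed, hidden=SMALL_HIDDEN)
            _, losses = train(p, co.X, co.y, small_train_config())
            assert losses[-1] <= losses[0]

    def test_training_deterministic(self, separable_cohort):
        co = separable_cohort
        cfg = small_train_config(epochs=20)
        a, _ = train(init_params(co.X.shape[1], 2, hidden=SMALL_HIDDEN),
                     co.X, co.y, cfg)
        b, _ = train(init_params(co.X.shape[1], 2, hidden=SMALL_HIDDEN),
                     co.X, co.y, cfg)
        for wa, wb in zip(a.weights, b.weights):
            assert np.array_equal(wa, wb)

    def test_single_class_data_rejected(self):
        p = init_params(4, 0, hidden=(3, 3, 3))
        with pytest.raises(ValueError):
            train(p, np.ones((5, 4)), np.zeros(5, dtype=int), TrainConfig())

    def test_sgd_optimizer_also_descends(self, separable_cohort):
        co = separable_cohort
        p = init_params(co.X.shape[1], 0, hidden=SMALL_HIDDEN)
        _, losses = train(p, co.X, co.y,
                          small_train_config(optimizer_kind="sgd",
                                             learning_rate=0.5))
        assert losses[-1] < losses[0]


class TestInputGradient:
    def test_matches_central_finite_differences(self):
        """Analytic gradients vs the finite-difference oracle on 20 nets."""
        rng = np.random.default_rng(42)
        h = 1e-5
        for seed in range(20):
            p = random_small_net(seed)
            x = rng.standard_normal(7)
            mode = ("probability", "logit", "margin")[seed % 3]
            c = seed % 2

            def f(xx):
                pred = forward(p, xx)
                if mode == "probability":
                    return pred.probabilities[c]
                if mode == "logit":
                    return pred.logits[c]
                return pred.logits[c] - pred.logits[1 - c]

            g = input_gradient(p, x, c, mode=mode)
            fd = np.empty_like(g)
            for k in range(x.size):
                e = np.zeros_like(x)
                e[k] = h
                fd[k] = (f(x + e) - f(x - e)) / (2 * h)
            denom = max(np.abs(fd).max(), 1e-8)
            assert np.abs(g - fd).max() / denom < 1e-4

    def test_probability_mode_antisymmetry_exact(self):
        rng = np.random.default_rng(7)
        for seed in range(20):
            p = random_small_net(seed)
            for _ in range(10):
                x = rng.standard_normal(7)
                g0 = input_gradient(p, x, 0, mode="probability")
                g1 = input_gradient(p, x, 1, mode="probability")
                assert np.array_equal(g0, -g1)

    def test_zero_final_layer_gives_zero_logit_gradient(self):
        p = random_small_net(1)
        p.weights[-1][:] = 0
        g = input_gradient(p, np.ones(7), 0, mode="logit")
        assert np.all(g == 0)

    def test_invalid_class_and_mode_rejected(self):
        p = random_small_net(0)
        with pytest.raises(ValueError):
            input_gradient(p, np.ones(7), 2)
        with pytest.raises(ValueError):
            input_gradient(p, np.ones(7), 0, mode="shapley")


class TestCheckpoint:
    def test_roundtrip(self, tmp_path):
        p = random_small_net(5)
        f = tmp_path / "model.npz"
        save_checkpoint(f, p, {"init_seed": 5})
        q, meta = load_checkpoint(f)
        assert meta == {"init_seed": 5}
        for a, b in zip(p.weights + p.biases, q.weights + q.biases):
            assert np.array_equal(a, b)
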