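"""Auto-encoder core: forward pass, corruption, cost, gradients, training."""

import numpy as np
import pytest

from spliceae import encode_batch, build_scheme, generate_dataset, MotifModel
from spliceae.autoencoder import (
    AELayerParams,
    StackedNetwork,
    TrainConfig,
    ae_cost,
    ae_forward,
    build_network,
    classify,
    corrupt,
    cost_update,
    default_finetune_config,
    finetune,
    init_layer,
    load_model,
    predict_proba,
    pretrain_layer,
    pretrain_stack,
    save_model,
    _cost_and_grads,
    _batch_masks,
    _encode_through,
)


def tiny_layer(S_f="sigmoid", S_g="sigmoid"):
    W = np.array([[0.1, -0.2, 0.3], [0.0, 0.4, -0.1]])
    Wp = np.array([[0.2, -0.3], [0.1, 0.0], [-0.4, 0.5]])
    return AELayerParams(W, Wp, np.array([0.05, -0.05]),
                         np.array([0.0, 0.1, -0.1]), S_f, S_g)


class TestForward:
    def test_zero_weights_sigmoid_gives_half(self):
        p = AELayerParams(np.zeros((4, 3)), np.zeros((3, 4)),
                          np.zeros(4), np.zeros(3))
        h, xs = ae_forward(np.array([1.0, 2.0, 3.0]), p)
        np.testing.assert_allclose(h, 0.5)

    def test_identity_linear_layer_reconstructs(self):
        p = AELayerParams(np.eye(3), np.eye(3), np.zeros(3), np.zeros(3),
                          "linear", "linear")
        x = np.array([0.3, -1.2, 2.0])
        h, xs = ae_forward(x, p)
        np.testing.assert_allclose(xs, x)

    def test_hand_evaluated_matrix_arithmetic(self):
        # frozen from explicit elementwise evaluation of S_f(Wx+b), S_g(W'h+b)
        p = tiny_layer()
        x = np.array([1.0, 0.0, -1.0])
        z1 = p.W @ x + p.b_h
        h_exp = 1 / (1 + np.exp(-z1))
        z2 = p.W_prime @ h_exp + p.b_x
        xs_exp = 1 / (1 + np.exp(-z2))
        h, xs = ae_forward(x, p)
        np.testing.assert_allclose(h, h_exp, rtol=1e-12)
        np.testing.assert_allclose(xs, xs_exp, rtol=1e-12)
        assert xs.shape == x.shape

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            ae_forward(np.zeros(5), tiny_layer())


class TestCorrupt:
    def test_fraction_zero_is_identity(self, rng):
        x = np.arange(10.0)
        np.testing.assert_array_equal(corrupt(x, 0.0, rng), x)

    def test_fraction_one_zeroes_everything(self, rng):
        assert np.all(corrupt(np.arange(1.0, 11.0), 1.0, rng) == 0)

    def test_exact_count_masked(self, rng):
        x = np.ones(10)
        out = corrupt(x, 0.5, rng)
        assert int((out == 0).sum()) == 5

    def test_positions_uniform_monte_carlo(self):
        """Each position zeroed in ~50% of draws at fraction 0.5."""
        x = np.ones(10)
        hits = np.zeros(10)
        n = 10_000
        for seed in range(n):
            hits += corrupt(x, 0.5, np.random.default_rng(seed)) == 0
        freq = hits / n
        assert np.all(np.abs(freq - 0.5) < 0.02)


class TestCost:
    def test_identity_layer_zero_cost(self):
        p = AELayerParams(np.eye(3), np.eye(3), np.zeros(3), np.zeros(3),
                          "linear", "linear")
        cfg = TrainConfig(corruption_fraction=0.0)
        batch = np.random.default_rng(1).normal(size=(5, 3))
        assert ae_cost(batch, p, cfg) == pytest.approx(0.0)

    def test_hand_computed_single_sample_cost(self):
        """Cost of x=(1,0) through a fixed tiny layer equals the explicit
        encode-decode-squared-error composition."""
        W = np.array([[0.5, -0.5]])
        Wp = np.array([[1.0], [-1.0]])
        p = AELayerParams(W, Wp, np.array([0.0]), np.array([0.0, 0.0]))
        cfg = TrainConfig(corruption_fraction=0.0)
        x = np.array([[1.0, 0.0]])
        h = 1 / (1 + np.exp(-0.5))
        xs = np.array([1 / (1 + np.exp(-h)), 1 / (1 + np.exp(h))])
        expected = (1 - xs[0]) ** 2 + (0 - xs[1]) ** 2
        assert ae_cost(x, p, cfg) == pytest.approx(expected, rel=1e-12)

    def test_duplicating_rows_preserves_mean_cost(self):
        p = tiny_layer()
        cfg = TrainConfig(corruption_fraction=0.3, seed=3)
        batch = np.random.default_rng(2).uniform(size=(4, 3))
        doubled = np.vstack([batch, batch])
        assert ae_cost(batch, p, cfg) == pytest.approx(ae_cost(doubled, p, cfg))

    def test_cross_entropy_requires_unit_interval(self):
        cfg = TrainConfig(loss="cross_entropy", corruption_fraction=0.0)
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            ae_cost(np.array([[2.0, -1.0, 0.0]]), tiny_layer(), cfg)

    def test_cost_non_negative(self):
        cfg = TrainConfig(corruption_fraction=0.1, seed=0)
        batch = np.random.default_rng(3).uniform(size=(6, 3))
        assert ae_cost(batch, tiny_layer(), cfg) >= 0


class TestGradients:
    @pytest.mark.parametrize("loss", ["squared_error", "cross_entropy"])
    @pytest.mark.parametrize("trial", range(5))
    def test_analytic_matches_central_finite_differences(self, loss, trial):
        rng = np.random.default_rng(100 + trial)
        d_in, d_h = rng.integers(2, 10, size=2)
        params = init_layer(int(d_in), int(d_h), rng)
        batch = rng.uniform(0.05, 0.95, size=(4, d_in))
        cfg = TrainConfig(corruption_fraction=0.25, seed=trial, loss=loss)
        masks = _batch_masks(batch, cfg, None)
        _, grads = _cost_and_grads(params, batch, masks, loss)

        eps = 1e-6
        for attr in ("W", "W_prime", "b_h", "b_x"):
            arr = getattr(params, attr)
            g = grads[attr]
            idx = tuple(rng.integers(0, s) for s in arr.shape)
            for k in range(min(3, arr.size)):
                flat = rng.integers(0, arr.size)
                ij = np.unravel_index(flat, arr.shape)
                orig = arr[ij]
                arr[ij] = orig + eps
                cp = np.mean(_cost_and_grads(params, batch, masks, loss)[0])
                arr[ij] = orig - eps
                cm = np.mean(_cost_and_grads(params, batch, masks, loss)[0])
                arr[ij] = orig
                fd = (cp - cm) / (2 * eps)
                denom = max(abs(fd), abs(g[ij]), 1e-8)
                assert abs(g[ij] - fd) / denom < 1e-5

    def test_zero_learning_rate_limit_keeps_params(self):
        params = tiny_layer()
        cfg = TrainConfig(learning_rate=1e-12, corruption_fraction=0.0)
        batch = np.random.default_rng(0).uniform(size=(4, 3))
        new = cost_update(params, batch, cfg)
        np.testing.assert_allclose(new.W, params.W, atol=1e-9)

    def test_small_step_strictly_reduces_cost(self):
        params = tiny_layer()
        cfg = TrainConfig(learning_rate=0.05, corruption_fraction=0.0)
        batch = np.random.default_rng(5).uniform(size=(8, 3))
        before = ae_cost(batch, params, cfg)
        after = ae_cost(batch, cost_update(params, batch, cfg), cfg)
        assert after < before

    def test_input_params_not_modified(self):
        params = tiny_layer()
        W0 = params.W.copy()
        cfg = TrainConfig(corruption_fraction=0.0)
        cost_update(params, np.random.default_rng(0).uniform(size=(4, 3)), cfg)
        np.testing.assert_array_equal(params.W, W0)


class TestPretraining:
    def test_epochs_zero_returns_seeded_init(self):
        data = np.random.default_rng(0).uniform(size=(20, 6))
        cfg = TrainConfig(epochs=0, seed=9)
        params, trace = pretrain_layer(data, 4, cfg)
        expected = init_layer(6, 4, np.random.default_rng(9))
        np.testing.assert_array_equal(params.W, expected.W)
        assert trace == []

    def test_descent_on_random_data(self):
        data = np.random.default_rng(1).uniform(size=(50, 10))
        cfg = TrainConfig(epochs=100, seed=1)
        _, trace = pretrain_layer(data, 6, cfg)
        assert trace[-1] < trace[0]

    def test_seeded_determinism_bitwise(self):
        data = np.random.default_rng(2).uniform(size=(30, 8))
        cfg = TrainConfig(epochs=5, seed=7)
        p1, t1 = pretrain_layer(data, 4, cfg)
        p2, t2 = pretrain_layer(data, 4, cfg)
        assert p1.W.tobytes() == p2.W.tobytes()
        assert t1 == t2


class TestStack:
    def test_build_network_shapes(self):
        net = build_network(90, [64, 32])
        assert [l.W.shape for l in net.layers] == [(64, 90), (32, 64)]
        assert net.out_w.shape == (32,)

    def test_single_layer_variant_allowed(self):
        net = build_network(15, [8])
        assert len(net.layers) == 1

    def test_default_depth_is_two_layers(self):
        assert len(build_network(90).layers) == 2
        assert len(build_network(15).layers) == 2

    def test_zero_size_layer_rejected(self):
        with pytest.raises(ValueError):
            build_network(10, [4, 0])

    def test_one_layer_stack_reduces_to_pretrain_layer(self):
        data = np.random.default_rng(3).uniform(size=(40, 12))
        cfg = TrainConfig(epochs=3, seed=11)
        net = pretrain_stack(build_network(12, [5], seed=11), data, cfg)
        params, _ = pretrain_layer(data, 5, cfg)
        np.testing.assert_array_equal(net.layers[0].W, params.W)

    def test_second_layer_trains_on_first_layer_hidden_outputs(self):
        data = np.random.default_rng(4).uniform(size=(30, 10))
        cfg = TrainConfig(epochs=2, seed=13)
        net = pretrain_stack(build_network(10, [6, 3], seed=13), data, cfg)
        H1 = _encode_through(data, net.layers[:1])
        from dataclasses import replace
        params2, _ = pretrain_layer(H1, 3, replace(cfg, seed=cfg.seed + 1))
        np.testing.assert_array_equal(net.layers[1].W, params2.W)

    def test_traces_per_layer_nonempty(self):
        data = np.random.default_rng(5).uniform(size=(30, 10))
        net = pretrain_stack(
            build_network(10, [6, 3]), data, TrainConfig(epochs=2)
        )
        assert len(net.pretrain_traces) == 2
        assert all(len(t) == 2 for t in net.pretrain_traces)


class TestFinetune:
    def test_linearly_separable_toy_reaches_full_accuracy(self):
        rng = np.random.default_rng(0)
        X = np.vstack([
            rng.normal(0.2, 0.05, size=(100, 6)),
            rng.normal(0.8, 0.05, size=(100, 6)),
        ])
        y = np.r_[np.zeros(100), np.ones(100)]
        net = build_network(6, [4], seed=0)
        net = finetune(net, X, y, default_finetune_config(seed=1, epochs=40))
        assert np.mean(classify(net, X) == y) == 1.0

    def test_epochs_zero_leaves_network_unchanged(self):
        net = build_network(6, [4], seed=0)
        X = np.random.default_rng(0).uniform(size=(10, 6))
        y = np.r_[np.zeros(5), np.ones(5)]
        out = finetune(net, X, y, default_finetune_config(epochs=0))
        np.testing.assert_array_equal(out.layers[0].W, net.layers[0].W)

    def test_single_class_labels_rejected(self):
        net = build_network(4, [3])
        X = np.random.default_rng(0).uniform(size=(6, 4))
        with pytest.raises(ValueError, match="each class"):
            finetune(net, X, np.ones(6), default_finetune_config())

    def test_seeded_determinism_of_predictions(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(size=(60, 5))
        y = (X.sum(axis=1) > 2.5).astype(float)
        cfg = default_finetune_config(seed=3, epochs=5)
        p1 = predict_proba(finetune(build_network(5, [3], seed=2), X, y, cfg), X)
        p2 = predict_proba(finetune(build_network(5, [3], seed=2), X, y, cfg), X)
        assert np.asarray(p1).tobytes() == np.asarray(p2).tobytes()


class TestPredict:
    def test_zero_weight_network_is_maximally_uncertain(self):
        net = build_network(4, [3], seed=0)
        for l in net.layers:
            l.W[:] = 0
            l.b_h[:] = 0
        net.out_w[:] = 0
        net.out_b = 0.0
        x = np.ones(4)
        assert predict_proba(net, x) == pytest.approx(0.5)
        assert classify(net, x) == 1  # tie at threshold goes positive

    def test_probability_strictly_inside_unit_interval(self):
        net = build_network(6, [4], seed=1)
        p = predict_proba(net, np.random.default_rng(0).uniform(size=6))
        assert 0.0 < p < 1.0

    def test_batch_predict_equals_per_sample(self):
        net = build_network(5, [4, 2], seed=2)
        X = np.random.default_rng(1).uniform(size=(7, 5))
        batch = predict_proba(net, X)
        singles = [predict_proba(net, x) for x in X]
        np.testing.assert_allclose(batch, singles, rtol=0, atol=0)


class TestSerialization:
    def test_roundtrip_predictions_bitwise_stable(self, tmp_path):
        model = MotifModel(site_type="donor", seed=1)
        data = generate_dataset(30, 30, model)
        scheme = build_scheme("dax")
        X, y = encode_batch(data, scheme)
        net = build_network(X.shape[1], [8, 4], seed=0, scheme_name="dax")
        net = pretrain_stack(net, X, TrainConfig(epochs=2, seed=0))
        net = finetune(net, X, y, default_finetune_config(seed=1, epochs=3))
        path = tmp_path / "model.npz"
        save_model(net, str(path))
        loaded = load_model(str(path))
        assert loaded.scheme_name == "dax"
        assert np.asarray(predict_proba(loaded, X)).tobytes() == \
            np.asarray(predict_proba(net, X)).tobytes()
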