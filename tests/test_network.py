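"""Layer primitives, architecture contracts, training behavior."""

import numpy as np
import pytest

from cdiadem import layers as L
from cdiadem import network as N
from cdiadem.pathways import PathwayMask


def _mask(bits):
    bits = np.asarray(bits)
    return PathwayMask(genes=[f"g{i}" for i in range(bits.shape[0])],
                       pathways=[f"p{j}" for j in range(bits.shape[1])], bits=bits)


class TestMaskedDense:
    def test_all_ones_mask_equals_plain_dense(self):
        rng = np.random.default_rng(0)
        d = L.Dense(5, 3, np.random.default_rng(1), activation="relu")
        md = L.MaskedDense(np.ones((5, 3)), np.random.default_rng(1), activation="relu")
        x = rng.normal(size=(4, 5))
        np.testing.assert_allclose(md.forward(x), d.forward(x))

    def test_all_zero_mask_linear_gives_bias(self):
        md = L.MaskedDense(np.zeros((5, 3)), np.random.default_rng(1), activation="linear")
        md.b[:] = [1.0, -2.0, 3.0]
        x = np.random.default_rng(0).normal(size=(6, 5))
        np.testing.assert_array_equal(md.forward(x), np.tile(md.b, (6, 1)))

    def test_against_loop_oracle(self):
        rng = np.random.default_rng(2)
        mask = (rng.random((7, 3)) < 0.5).astype(float)
        md = L.MaskedDense(mask, np.random.default_rng(3), activation="linear")
        x = rng.normal(size=(2, 7))
        out = md.forward(x)
        for b in range(2):
            for p in range(3):
                expected = md.b[p]
                for g in range(7):
                    expected += x[b, g] * md.W[g, p] * mask[g, p]
                assert out[b, p] == pytest.approx(expected, abs=1e-6)


class TestConv1D:
    def test_against_loop_oracle_same_padding(self):
        rng = np.random.default_rng(4)
        conv = L.Conv1D(1, 2, 3, np.random.default_rng(5), activation="linear")
        x = rng.normal(size=(2, 6, 1))
        out = conv.forward(x)
        xp = np.pad(x, ((0, 0), (1, 1), (0, 0)))
        for b in range(2):
            for t in range(6):
                for f in range(2):
                    expected = conv.b[f]
                    for k in range(3):
                        expected += xp[b, t + k, 0] * conv.W[k, 0, f]
                    assert out[b, t, f] == pytest.approx(expected)


def test_numerical_gradients_through_full_stack():
    """Finite-difference check of backprop through masked dense, conv, BN, dense."""
    rng = np.random.default_rng(6)
    mask = _mask((rng.random((6, 4)) < 0.6).astype(int))
    cfg = N.ModelConfig(conv_filters=2, conv_kernel=3, branch_dense=5,
                        hidden=(4, 3, 2), seed=0)
    model = N.build_constrained_model(cfg, mask, n_expr_genes=3)
    # jitter every parameter (biases start at zero) so no relu pre-activation
    # sits exactly on its kink, where two-sided differences and subgradients
    # legitimately disagree
    for layer in model.layers:
        for p in layer.params:
            p += 0.1 * rng.normal(size=p.shape)
    Xg = rng.normal(size=(8, 6))
    Xe = rng.normal(size=(8, 3))
    Y = np.zeros((8, 2))
    Y[np.arange(8), rng.integers(0, 2, 8)] = 1.0

    def loss():
        logits = model.forward(Xg, Xe, training=True)
        return L.cross_entropy(L.softmax(logits), Y)

    logits = model.forward(Xg, Xe, training=True)
    probs = L.softmax(logits)
    model.backward((probs - Y) / 8)
    eps = 1e-6
    rng_pick = np.random.default_rng(7)
    for layer in model.layers:
        for p, g in zip(layer.params, layer.grads):
            flat = p.reshape(-1)
            for idx in rng_pick.choice(flat.size, size=min(3, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = loss()
                flat[idx] = orig - eps
                down = loss()
                flat[idx] = orig
                numeric = (up - down) / (2 * eps)
                assert g.reshape(-1)[idx] == pytest.approx(numeric, abs=1e-5), layer.name


class TestArchitecture:
    def test_published_configuration_shapes(self):
        """The 5188-gene, 186-pathway configuration reproduces every printed width."""
        rng = np.random.default_rng(0)
        bits = (rng.random((5188, 186)) < 0.02).astype(int)
        model = N.build_constrained_model(N.ModelConfig(seed=0), _mask(bits), 19403)
        shapes = {name: shape for name, shape, _ in model.manifest}
        assert shapes["pathways"] == (186,)
        assert shapes["reshape"] == (186, 1)
        assert shapes["conv1d"] == (186, 12)
        assert shapes["flatten"] == (2232,)
        assert shapes["geno_dense"] == (150,)
        assert shapes["expr_dense"] == (150,)
        assert shapes["concatenate"] == (300,)
        assert shapes["hidden_1"] == (180,)
        assert shapes["hidden_2"] == (30,)
        assert shapes["hidden_3"] == (15,)
        assert shapes["output_softmax"] == (2,)
        assert model.n_layers == 14

    def test_tiny_configuration_flatten_width(self):
        bits = np.ones((10, 4), int)
        model = N.build_constrained_model(N.ModelConfig(seed=0), _mask(bits), 5)
        shapes = {name: shape for name, shape, _ in model.manifest}
        assert shapes["flatten"] == (48,)

    def test_unconstrained_has_nine_layers(self):
        model = N.build_unconstrained_model(N.ModelConfig(seed=0), 50, 40, width=186)
        assert model.n_layers == 9
        shapes = {name: shape for name, shape, _ in model.manifest}
        assert shapes["embedding"] == (186, 3)

    def test_softmax_rows_sum_to_one_both_models(self):
        rng = np.random.default_rng(1)
        bits = (rng.random((12, 5)) < 0.5).astype(int)
        cfg = N.ModelConfig(conv_filters=3, conv_kernel=3, branch_dense=6,
                            hidden=(5, 4, 3), seed=1)
        for model in (N.build_constrained_model(cfg, _mask(bits), 7),
                      N.build_unconstrained_model(cfg, 12, 7, width=5)):
            probs = N.predict(model, rng.normal(size=(9, 12)), rng.normal(size=(9, 7))).probs
            np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)


class TestPredict:
    def test_argmax_and_tie_rule(self):
        pb = N.PredictionBatch(probs=np.array([[0.3, 0.7], [0.5, 0.5], [0.9, 0.1]]))
        assert pb.labels.tolist() == [1, 0, 0]

    def test_duplicate_rows_get_identical_outputs(self):
        rng = np.random.default_rng(3)
        cfg = N.ModelConfig(conv_filters=2, conv_kernel=3, branch_dense=4,
                            hidden=(3, 3, 2), seed=2)
        model = N.build_constrained_model(
            cfg, _mask(np.ones((6, 4), int)), 3)
        xg = rng.normal(size=(1, 6))
        xe = rng.normal(size=(1, 3))
        probs = N.predict(model, np.vstack([xg, xg]), np.vstack([xe, xe])).probs
        np.testing.assert_array_equal(probs[0], probs[1])


def _toy_training_data(rng, n=60, sep=3.0):
    """Linearly separable toy: class decided by the first genotype gene."""
    Xg = rng.normal(size=(n, 6))
    Xe = rng.normal(size=(n, 3))
    y = (Xg[:, 0] > 0).astype(int)
    Xg[:, 0] += sep * (2 * y - 1)
    Y = np.eye(2)[y]
    return Xg, Xe, Y


class TestTraining:
    def _small_model(self, seed=0, epochs=15, patience=15):
        cfg = N.ModelConfig(conv_filters=2, conv_kernel=3, branch_dense=5,
                            hidden=(4, 3, 2), epochs=epochs, patience=patience,
                            batch_size=16, seed=seed)
        return N.build_constrained_model(cfg, _mask(np.ones((6, 4), int)), 3), cfg

    def test_loss_decreases_on_separable_toy(self):
        rng = np.random.default_rng(10)
        model, cfg = self._small_model()
        data = _toy_training_data(rng)
        val = _toy_training_data(rng, n=30)
        trained = N.train(model, data, val, cfg)
        h = trained.history
        assert h["train_loss"].iloc[-1] < h["train_loss"].iloc[0]

    def test_masked_connections_contribute_nothing_after_training(self):
        rng = np.random.default_rng(11)
        bits = (rng.random((6, 4)) < 0.5).astype(int)
        bits[0, :] = 0  # gene 0 fully masked out
        cfg = N.ModelConfig(conv_filters=2, conv_kernel=3, branch_dense=5,
                            hidden=(4, 3, 2), epochs=5, batch_size=16, seed=3)
        model = N.build_constrained_model(cfg, _mask(bits), 3)
        data = _toy_training_data(rng)
        N.train(model, data, (data[0][:20], data[1][:20], data[2][:20]), cfg)
        xg = rng.normal(size=(4, 6))
        xe = rng.normal(size=(4, 3))
        base = model.forward(xg, xe)
        xg2 = xg.copy()
        xg2[:, 0] += 1e6  # masked input may take any value
        np.testing.assert_array_equal(model.forward(xg2, xe), base)

    def test_early_stop_halts_within_patience(self):
        # train and val labels contradict: as the model fits the training
        # side, validation loss worsens monotonically from epoch 1
        rng = np.random.default_rng(12)
        model, _ = self._small_model(epochs=40, patience=3)
        cfg = model.config
        Xg, Xe, Y = _toy_training_data(rng, n=80)
        val = (Xg, Xe, Y[:, ::-1].copy())
        trained = N.train(model, (Xg, Xe, Y), val, cfg)
        assert len(trained.history) <= 1 + cfg.patience + 1

    def test_training_is_bitwise_deterministic(self):
        rng = np.random.default_rng(13)
        data = _toy_training_data(rng)
        val = (data[0][:20], data[1][:20], data[2][:20])
        histories = []
        for _ in range(2):
            model, cfg = self._small_model(seed=7, epochs=6)
            histories.append(N.train(model, data, val, cfg).history)
        assert histories[0].equals(histories[1])

    def test_divergence_raises_named_error(self):
        model, cfg = self._small_model(epochs=3)
        bad = np.full((20, 6), np.nan)
        with pytest.raises(FloatingPointError, match="epoch"):
            N.train(model, (bad, np.zeros((20, 3)), np.eye(2)[np.zeros(20, int)]),
                    (bad[:5], np.zeros((5, 3)), np.eye(2)[np.zeros(5, int)]), cfg)


def test_save_load_roundtrip_preserves_predictions(tmp_path):
    rng = np.random.default_rng(14)
    cfg = N.ModelConfig(conv_filters=2, conv_kernel=3, branch_dense=5,
                        hidden=(4, 3, 2), epochs=3, batch_size=16, seed=5)
    model = N.build_constrained_model(
        cfg, _mask((rng.random((6, 4)) < 0.7).astype(int)), 3)
    data = _toy_training_data(rng)
    trained = N.train(model, data, (data[0][:20], data[1][:20], data[2][:20]), cfg)
    xg, xe = rng.normal(size=(5, 6)), rng.normal(size=(5, 3))
    before = N.predict(model, xg, xe).probs
    N.save_model(trained, tmp_path / "m")
    loaded = N.load_model(tmp_path / "m")
    after = N.predict(loaded.model, xg, xe).probs
    np.testing.assert_array_equal(before, after)
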