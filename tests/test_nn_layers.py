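"""Numpy CNN building blocks: gradient correctness, shapes, losses."""

import numpy as np
import pytest

import tissueseg.nn.layers as layers
from tissueseg.nn import (
    LossConfig,
    NetworkConfig,
    bce_dice_loss,
    build_network,
    load_checkpoint,
    loss_and_grad_from_logits,
    save_checkpoint,
    standardize,
)


@pytest.fixture
def float64_layers():
    """Run layers in float64 so finite differences resolve the gradients."""
    old = layers.DTYPE
    layers.DTYPE = np.float64
    yield
    layers.DTYPE = old


def directional_gradcheck(layer, x, n_checks=25, eps=1e-6, tol=1e-5):
    """Compare backward() against central differences of sum(out·R)."""
    y = layer.forward(x, training=True)
    R = np.random.default_rng(42).normal(size=y.shape)
    dx = layer.backward(R.copy())
    rng = np.random.default_rng(1)
    for _ in range(n_checks):
        idx = tuple(rng.integers(0, s) for s in x.shape)
        xp = x.copy()
        xp[idx] += eps
        xm = x.copy()
        xm[idx] -= eps
        num = (
            (layer.forward(xp, training=True) * R).sum()
            - (layer.forward(xm, training=True) * R).sum()
        ) / (2 * eps)
        assert abs(num - dx[idx]) <= tol * max(1.0, abs(num)), (idx, num, dx[idx])


class TestLayerGradients:
    @pytest.mark.parametrize("ndim,cin,cout,k", [(2, 3, 4, 3), (3, 2, 3, 3), (2, 4, 2, 1)])
    def test_conv_input_gradient(self, float64_layers, ndim, cin, cout, k):
        rng = np.random.default_rng(0)
        conv = layers.Conv(cin, cout, k, ndim, rng)
        x = rng.normal(size=(2, cin) + (6,) * ndim)
        directional_gradcheck(conv, x)

    def test_conv_weight_gradient(self, float64_layers):
        rng = np.random.default_rng(0)
        conv = layers.Conv(2, 3, 3, 2, rng)
        x = rng.normal(size=(2, 2, 6, 6))
        y = conv.forward(x, training=True)
        R = np.random.default_rng(7).normal(size=y.shape)
        conv.backward(R.copy())
        fr = np.random.default_rng(2)
        for _ in range(20):
            idx = tuple(fr.integers(0, s) for s in conv.weight.value.shape)
            eps = 1e-6
            old = conv.weight.value[idx]
            conv.weight.value[idx] = old + eps
            lp = (conv.forward(x) * R).sum()
            conv.weight.value[idx] = old - eps
            lm = (conv.forward(x) * R).sum()
            conv.weight.value[idx] = old
            num = (lp - lm) / (2 * eps)
            assert abs(num - conv.weight.grad[idx]) <= 1e-5 * max(1.0, abs(num))

    @pytest.mark.parametrize("layer_factory", [
        lambda: layers.GroupNorm(4, 2),
        lambda: layers.ReLU(),
        lambda: layers.MaxPool(),
        lambda: layers.Upsample(),
    ])
    def test_parameter_free_and_norm_layers(self, float64_layers, layer_factory):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(2, 4, 6, 6))
        directional_gradcheck(layer_factory(), x)

    def test_batchnorm_training_gradient(self, float64_layers):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(3, 4, 5, 5))
        bn = layers.BatchNorm(4)
        y = bn.forward(x, training=True)
        R = np.random.default_rng(11).normal(size=y.shape)
        dx = bn.backward(R.copy())
        fr = np.random.default_rng(5)
        for _ in range(20):
            idx = tuple(fr.integers(0, s) for s in x.shape)
            eps = 1e-6
            xp = x.copy()
            xp[idx] += eps
            xm = x.copy()
            xm[idx] -= eps
            probe = layers.BatchNorm(4)  # fresh running stats are irrelevant in training mode
            num = (
                (probe.forward(xp, training=True) * R).sum()
                - (probe.forward(xm, training=True) * R).sum()
            ) / (2 * eps)
            assert abs(num - dx[idx]) <= 1e-4 * max(1.0, abs(num))

    def test_full_network_parameter_gradients(self, float64_layers):
        # end-to-end backprop through pooling, skips and concatenation
        m = build_network(
            NetworkConfig(architecture="residual_unet", feature_maps=(4, 8), dims=2),
            rng_seed=1,
        )
        for p in m.params:
            p.value = p.value.astype(np.float64)
            p.grad = np.zeros_like(p.value)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(2, 1, 8, 8))
        t = (rng.random((2, 1, 8, 8)) > 0.7).astype(np.float64)

        def f():
            return loss_and_grad_from_logits(m.forward(x, training=True), t)

        _, g = f()
        m.zero_grad()
        m.backward(g)
        for pi in range(0, len(m.params), 5):
            p = m.params[pi]
            idx = tuple(0 for _ in p.value.shape)
            eps = 1e-6
            old = p.value[idx]
            p.value[idx] = old + eps
            l1, _ = f()
            p.value[idx] = old - eps
            l2, _ = f()
            p.value[idx] = old
            num = (l1 - l2) / (2 * eps)
            # kinks in ReLU/maxpool limit finite-difference accuracy
            assert abs(num - p.grad[idx]) <= 1e-3 * max(0.01, abs(num))


class TestStandardize:
    def test_two_value_closed_form(self):
        vol = np.array([0.0, 2.0] * 8).reshape(4, 4)
        out = standardize(vol)
        assert np.allclose(np.unique(out), [-1.0, 1.0])

    def test_idempotent_on_standardized_input(self):
        rng = np.random.default_rng(0)
        vol = standardize(rng.normal(size=(6, 6, 6)))
        again = standardize(vol)
        assert np.allclose(vol, again, atol=1e-5)

    def test_constant_volume_warns_and_zeroes(self):
        with pytest.warns(UserWarning):
            out = standardize(np.full((4, 4), 3.0))
        assert not out.any()


class TestLosses:
    def test_perfect_binary_like_prediction_near_zero(self):
        t = np.array([0.0, 1.0, 1.0, 0.0])
        p = np.clip(t, 1e-7, 1 - 1e-7)
        assert bce_dice_loss(p, t) == pytest.approx(0.0, abs=1e-5)

    def test_uniform_half_prediction_gives_ln2_bce(self):
        t = (np.random.default_rng(0).random((5, 5)) > 0.5).astype(float)
        p = np.full((5, 5), 0.5)
        cfg = LossConfig(kind="bce_dice", alpha=1.0, beta_loss=0.0)
        assert bce_dice_loss(p, t, cfg) == pytest.approx(np.log(2), abs=1e-12)

    def test_dice_of_identical_masks_near_zero(self):
        t = np.ones((4, 4))
        p = np.full((4, 4), 1 - 1e-7)
        cfg = LossConfig(kind="bce_dice", alpha=0.0, beta_loss=1.0)
        assert bce_dice_loss(p, t, cfg) == pytest.approx(0.0, abs=1e-5)

    def test_loss_nonnegative_random_inputs(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            p = rng.random((3, 3, 3))
            t = (rng.random((3, 3, 3)) > 0.5).astype(float)
            assert bce_dice_loss(p, t) >= 0.0

    def test_logit_form_matches_probability_form(self):
        rng = np.random.default_rng(2)
        z = rng.normal(size=(4, 4))
        t = (rng.random((4, 4)) > 0.5).astype(float)
        from tissueseg.nn.layers import sigmoid

        val, _ = loss_and_grad_from_logits(z, t)
        assert val == pytest.approx(bce_dice_loss(sigmoid(z), t), rel=1e-9)

    def test_shape_mismatch_and_degenerate_config_rejected(self):
        with pytest.raises(ValueError):
            bce_dice_loss(np.ones((2, 2)) * 0.5, np.ones((3, 3)))
        with pytest.raises(ValueError):
            LossConfig(kind="bce_dice", alpha=0.0, beta_loss=0.0)


class TestBuildNetwork:
    def test_same_convolution_contract(self):
        m = build_network(NetworkConfig(feature_maps=(4, 8)))
        x = np.zeros((1, 1, 8, 8, 8), dtype=np.float32)
        assert m.forward(x).shape == (1, 1, 8, 8, 8)

    def test_group_and_batch_norm_same_output_shape(self):
        for norm in ("group", "batch"):
            m = build_network(NetworkConfig(feature_maps=(4, 8), normalization=norm))
            assert m.forward(np.zeros((1, 1, 8, 8, 8))).shape == (1, 1, 8, 8, 8)

    def test_plain_has_fewer_parameters_than_residual(self):
        plain = build_network(NetworkConfig(architecture="unet", feature_maps=(8, 16)))
        res = build_network(NetworkConfig(architecture="residual_unet", feature_maps=(8, 16)))
        assert plain.n_parameters() < res.n_parameters()

    def test_parameter_count_deterministic(self):
        a = build_network(NetworkConfig(feature_maps=(4, 8)), rng_seed=3)
        b = build_network(NetworkConfig(feature_maps=(4, 8)), rng_seed=3)
        assert a.n_parameters() == b.n_parameters()
        assert all(np.array_equal(p.value, q.value) for p, q in zip(a.params, b.params))

    def test_indivisible_shape_raises_clear_error(self):
        m = build_network(NetworkConfig(feature_maps=(4, 8, 16)))  # divisor 4
        with pytest.raises(ValueError, match="divisible"):
            m.forward(np.zeros((1, 1, 6, 8, 8)))

    def test_sigmoid_output_in_unit_interval(self):
        m = build_network(NetworkConfig(feature_maps=(4, 8)))
        p = m.predict(np.random.default_rng(0).normal(size=(1, 1, 8, 8, 8)))
        assert p.min() >= 0.0 and p.max() <= 1.0

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(feature_maps=(8,))
        with pytest.raises(ValueError):
            NetworkConfig(feature_maps=(16, 8))
        with pytest.raises(ValueError):
            NetworkConfig(architecture="vgg")

    def test_checkpoint_round_trip(self, tmp_path):
        m = build_network(NetworkConfig(feature_maps=(4, 8), normalization="batch"), rng_seed=5)
        x = np.random.default_rng(1).normal(size=(1, 1, 8, 8, 8))
        path = tmp_path / "ckpt.npz"
        save_checkpoint(m, path)
        m2 = load_checkpoint(path)
        assert np.allclose(m.predict(x), m2.predict(x))
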