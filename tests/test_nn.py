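"""Convolution primitive, network forward pass, initialisation, training."""

import numpy as np
import pytest

from hicenhance import ContactMatrix, PatchGeometry, extract_patches
from hicenhance.nn import (
    ConvNetParams,
    TrainConfig,
    conv2d_valid,
    forward,
    init_glorot,
    load_params,
    mse_loss,
    receptive_field,
    save_params,
    train,
)
from hicenhance.patches import Patch

from .conftest import random_symmetric_counts


def brute_force_conv(x, w, b):
    """Six-nested-loop reference for valid cross-correlation."""
    k, c, f, _ = w.shape
    hh, ww = x.shape[1] - f + 1, x.shape[2] - f + 1
    out = np.zeros((k, hh, ww))
    for kk in range(k):
        for y in range(hh):
            for z in range(ww):
                out[kk, y, z] = b[kk] + np.sum(w[kk] * x[:, y : y + f, z : z + f])
    return out


class TestConv2dValid:
    def test_identity_kernel(self):
        x = np.array([[[1.0, 2.0], [3.0, 4.0]]])
        out = conv2d_valid(x, np.ones((1, 1, 1, 1)), np.zeros(1))
        np.testing.assert_allclose(out, x)

    def test_sum_kernel(self):
        # an even-sided kernel is rejected by the primitive's odd-side contract,
        # so the full-window sum uses the whole 3x3 input
        x = np.arange(9, dtype=float).reshape(1, 3, 3)
        out = conv2d_valid(x, np.ones((1, 1, 3, 3)), np.zeros(1))
        np.testing.assert_allclose(out, [[[36.0]]])

    def test_matches_brute_force_oracle_100_instances(self, rng):
        for _ in range(100):
            c = int(rng.integers(1, 4))
            k = int(rng.integers(1, 4))
            f = int(rng.choice([1, 3, 5]))
            h = int(rng.integers(f, f + 6))
            x = rng.normal(size=(c, h, h))
            w = rng.normal(size=(k, c, f, f))
            b = rng.normal(size=k)
            ref = brute_force_conv(x, w, b)
            got = conv2d_valid(x, w, b)
            np.testing.assert_allclose(got, ref, rtol=1e-6, atol=1e-9)

    def test_filter_larger_than_input_errors(self):
        with pytest.raises(ValueError, match="exceeds"):
            conv2d_valid(np.zeros((1, 3, 3)), np.zeros((1, 1, 5, 5)), np.zeros(1))


class TestForward:
    def test_default_geometry_40_to_28(self, rng):
        params = init_glorot(seed=0)
        out = forward(params, rng.normal(size=(40, 40)))
        assert out.shape == (28, 28)
        assert out.size == 784

    def test_zero_params_give_zero_output(self, rng):
        p = init_glorot(seed=0)
        for a in p._arrays():
            a[:] = 0.0
        out = forward(p, rng.normal(size=(40, 40)))
        np.testing.assert_array_equal(out, 0.0)

    def test_intermediate_activations_non_negative(self, rng):
        from hicenhance.nn import _forward_batch

        p = init_glorot(seed=1)
        x = rng.normal(size=(2, 1, 40, 40))
        _, (_, _, h1, _, h2) = _forward_batch(p, x, keep=True)
        assert np.all(h1 >= 0)
        assert np.all(h2 >= 0)

    def test_translation_consistency(self, rng):
        """A pure valid convolution commutes with translation: shifting the
        input window shifts the output where they overlap."""
        p = init_glorot(seed=2)
        big = rng.normal(size=(60, 60))
        o1 = forward(p, big[0:40, 0:40])
        o2 = forward(p, big[1:41, 1:41])
        np.testing.assert_allclose(o1[1:, 1:], o2[:-1, :-1], atol=1e-9)

    def test_geometry_mismatch_error(self, rng):
        p = init_glorot(seed=0)
        with pytest.raises(ValueError, match="too small"):
            forward(p, rng.normal(size=(10, 10)))


class TestReceptiveField:
    @pytest.mark.parametrize(
        "f1,f2,f3,expected", [(5, 1, 9, 13), (1, 1, 1, 1), (3, 1, 1, 3)]
    )
    def test_values(self, f1, f2, f3, expected):
        p = init_glorot(n1=2, f1=f1, n2=2, f2=f2, f3=f3, seed=0)
        assert receptive_field(p) == expected


class TestMseLoss:
    def test_examples(self):
        a = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert mse_loss(a, a) == 0.0
        assert mse_loss(a + 2, a) == 4.0
        assert mse_loss(a, np.zeros_like(a)) == pytest.approx(7.5)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            mse_loss(np.zeros((2, 2)), np.zeros((3, 3)))


class TestInitGlorot:
    def test_bounds_layer1(self):
        p = init_glorot(seed=5)
        a = np.sqrt(6.0 / (1 * 25 + 16 * 25))
        assert np.all(np.abs(p.w1) <= a)

    def test_seed_determinism(self):
        p1, p2 = init_glorot(seed=42), init_glorot(seed=42)
        for a, b in zip(p1._arrays(), p2._arrays()):
            np.testing.assert_array_equal(a, b)

    def test_biases_zero(self):
        p = init_glorot(seed=0)
        assert not p.b1.any() and not p.b2.any() and not p.b3.any()

    def test_padding_consumed(self):
        assert init_glorot(seed=0).padding_consumed == 12

    def test_mismatched_channels_rejected(self):
        with pytest.raises(ValueError):
            ConvNetParams(
                w1=np.zeros((4, 1, 3, 3)), b1=np.zeros(4),
                w2=np.zeros((4, 5, 1, 1)), b2=np.zeros(4),
                w3=np.zeros((1, 4, 3, 3)), b3=np.zeros(1),
            )


def _identity_patches(rng, n_patches=40, side=20):
    """Targets are the centre crop of the input: exactly representable."""
    geom = PatchGeometry(N=side, padding=12, max_dist_bins=side)
    patches = []
    for _ in range(n_patches):
        x = rng.poisson(3.0, size=(side, side)).astype(float)
        t = x[6:-6, 6:-6].copy()
        patches.append(Patch(0, 0, x, t))
    return patches, geom


class TestTrain:
    def test_empty_patch_list_errors(self):
        with pytest.raises(ValueError, match="no training patches"):
            train([], TrainConfig())

    def test_divergence_raises_helpful_error(self, rng):
        # targets far beyond float range make the very first loss non-finite
        patches, geom = _identity_patches(rng, n_patches=4)
        for p in patches:
            p.target = p.target + 1e200
        cfg = TrainConfig(learning_rate=1e-4, max_epochs=5, validation_fraction=0.0, seed=0)
        with pytest.raises(FloatingPointError, match="learning rate"):
            train(patches, cfg, geom)

    def test_learns_identity_mapping(self, rng):
        """Loss on the centre-crop task drops below 1% of the epoch-0 loss:
        the architecture can represent the identity."""
        patches, geom = _identity_patches(rng, n_patches=60)
        cfg = TrainConfig(learning_rate=1e-3, batch_size=60, max_epochs=150,
                          validation_fraction=0.0, patience=150, seed=0)
        _, hist = train(patches, cfg, geom)
        assert hist.train[-1] < 0.01 * hist.train[0]

    def test_single_patch_loss_trend_non_increasing(self, rng):
        patches, geom = _identity_patches(rng, n_patches=1)
        cfg = TrainConfig(learning_rate=1e-3, batch_size=1, max_epochs=50,
                          validation_fraction=0.0, patience=50, seed=1)
        _, hist = train(patches, cfg, geom)
        # monotone trend over 5-epoch windows (full-batch on one sample)
        means = [np.mean(hist.train[i : i + 5]) for i in range(0, 50, 5)]
        assert all(a >= b - 1e-9 for a, b in zip(means, means[1:]))

    def test_reproducible_given_seed(self, rng):
        patches, geom = _identity_patches(rng, n_patches=20)
        cfg = TrainConfig(learning_rate=1e-3, max_epochs=5, seed=9, patience=5)
        p1, h1 = train(list(patches), cfg, geom)
        p2, h2 = train(list(patches), cfg, geom)
        for a, b in zip(p1._arrays(), p2._arrays()):
            np.testing.assert_array_equal(a, b)
        assert h1.train == h2.train

    def test_geometry_filter_mismatch_rejected(self, rng):
        patches, _ = _identity_patches(rng, n_patches=4)
        bad_geom = PatchGeometry(N=20, padding=10, max_dist_bins=20)
        with pytest.raises(ValueError, match="padding"):
            train(patches, TrainConfig(max_epochs=1), bad_geom)


class TestLinearKernelRecovery:
    def test_planted_blur_is_recovered(self, rng):
        """Train on targets made by a known 13x13 non-negative kernel; the
        fitted network's linearised impulse responses must match that kernel
        to within 5% of its energy."""
        size = 13
        ax = np.arange(size) - size // 2
        kernel = np.exp(-(np.add.outer(ax**2, ax**2)) / (2 * 3.0**2))
        kernel /= kernel.sum()

        side, border = 26, 6
        geom = PatchGeometry(N=side, padding=12, max_dist_bins=side)
        patches = []
        for _ in range(150):
            x = rng.gamma(2.0, 2.0, size=(side, side))
            t = brute_force_conv(x[None], kernel[None, None], np.zeros(1))[0]
            patches.append(Patch(0, 0, x, t))
        cfg = TrainConfig(learning_rate=1e-3, batch_size=150, max_epochs=400,
                          validation_fraction=0.0, patience=400, seed=0)
        params, hist = train(patches, cfg, geom)

        # linearised response at output cell (y0, x0): the effective kernel is
        # R[u, v] = F(base + impulse at (y0+u, x0+v)) - F(base), read at (y0, x0)
        base = np.full((side, side), 4.0)
        out0 = forward(params, base)
        y0 = x0 = (side - 12) // 2
        resp = np.zeros((size, size))
        for u in range(size):
            for v in range(size):
                probe = base.copy()
                probe[y0 + u, x0 + v] += 1.0
                resp[u, v] = (forward(params, probe) - out0)[y0, x0]
        err = np.sum((resp - kernel) ** 2)
        energy = np.sum(kernel**2)
        assert err < 0.05 * energy


class TestSerialization:
    def test_save_load_round_trip(self, tmp_path, rng):
        params = init_glorot(seed=3)
        geom = PatchGeometry()
        path = tmp_path / "model.npz"
        save_params(params, path, geom, meta={"note": "round trip"})
        loaded, g2, meta = load_params(path)
        for a, b in zip(params._arrays(), loaded._arrays()):
            np.testing.assert_array_equal(a, b)
        assert g2 == geom
        assert meta["note"] == "round trip"
        x = rng.normal(size=(40, 40))
        np.testing.assert_array_equal(forward(params, x), forward(loaded, x))
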