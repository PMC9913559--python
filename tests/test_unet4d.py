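import numpy as np
import pytest

from radscan.unet4d import (
    ConvSpec, Tensor4DSample, UNetConfig,
    assemble_input, build_unet, conv2d_ref, conv4d_ref, identity,
    predict, softmax, softmax_cross_entropy, train,
)
from radscan.preprocess import NoduleBox


def brute_conv2d(inp, w, b, phi, sign):
    c_in, h_in, w_in = inp.shape
    _, kh, kw = w.shape
    out = np.zeros((h_in - kh + 1, w_in - kw + 1))
    for k in range(out.shape[0]):
        for l in range(out.shape[1]):
            acc = 0.0
            for c in range(c_in):
                for i in range(kh):
                    for j in range(kw):
                        acc += w[c, i, j] * inp[c, k + i, l + j]
            out[k, l] = phi(acc + sign * b)
    return out


def brute_conv4d(inp, w, b, phi, sign):
    c_in, R, D, H, W = inp.shape
    _, kr, kd, kh, kw = w.shape
    out = np.zeros((R - kr + 1, D - kd + 1, H - kh + 1, W - kw + 1))
    for k in range(out.shape[0]):
        for l in range(out.shape[1]):
            for m in range(out.shape[2]):
                for n in range(out.shape[3]):
                    acc = 0.0
                    for c in range(c_in):
                        for r in range(kr):
                            for d in range(kd):
                                for i in range(kh):
                                    for j in range(kw):
                                        acc += w[c, r, d, i, j] * \
                                            inp[c, k + r, l + d, m + i, n + j]
                    out[k, l, m, n] = phi(acc + sign * b)
    return out


class TestConv2DRef:
    def test_delta_kernel_identity(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(1, 5, 5))
        w = np.zeros((1, 3, 3))
        w[0, 0, 0] = 1.0
        y = conv2d_ref(x, ConvSpec(weights=w, activation=identity))
        np.testing.assert_allclose(y, x[0, :3, :3])

    def test_all_ones_kernel(self):
        y = conv2d_ref(np.ones((1, 4, 4)),
                       ConvSpec(weights=np.ones((1, 2, 2)),
                                activation=identity))
        np.testing.assert_allclose(y, 4.0)

    def test_bias_subtracted_by_default(self):
        y = conv2d_ref(np.ones((1, 2, 2)),
                       ConvSpec(weights=np.ones((1, 2, 2)), bias=1.5,
                                activation=identity))
        np.testing.assert_allclose(y, 4.0 - 1.5)
        y2 = conv2d_ref(np.ones((1, 2, 2)),
                        ConvSpec(weights=np.ones((1, 2, 2)), bias=1.5,
                                 activation=identity, bias_sign=+1.0))
        np.testing.assert_allclose(y2, 5.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_nested_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        c, h, w = rng.integers(1, 4), rng.integers(2, 5), rng.integers(2, 5)
        kh, kw = rng.integers(1, h + 1), rng.integers(1, w + 1)
        x = rng.normal(size=(c, h, w))
        wt = rng.normal(size=(c, kh, kw))
        b = float(rng.normal())
        for phi in (identity, lambda v: np.maximum(v, 0)):
            got = conv2d_ref(x, ConvSpec(weights=wt, bias=b, activation=phi))
            want = brute_conv2d(x, wt, b, lambda s: phi(np.float64(s)), -1.0)
            np.testing.assert_allclose(got, want, atol=1e-5)

    def test_shape_errors(self):
        with pytest.raises(ValueError, match="channel"):
            conv2d_ref(np.ones((2, 4, 4)), ConvSpec(weights=np.ones((1, 2, 2))))
        with pytest.raises(ValueError, match="extent"):
            conv2d_ref(np.ones((1, 2, 2)), ConvSpec(weights=np.ones((1, 3, 3))))


class TestConv4DRef:
    def test_delta_kernel_identity(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(1, 3, 3, 3, 3))
        w = np.zeros((1, 2, 2, 2, 2))
        w[0, 0, 0, 0, 0] = 1.0
        y = conv4d_ref(x, ConvSpec(weights=w, activation=identity))
        np.testing.assert_allclose(y, x[0, :2, :2, :2, :2])

    def test_all_ones_2222_kernel(self):
        y = conv4d_ref(np.ones((1, 2, 2, 2, 2)),
                       ConvSpec(weights=np.ones((1, 2, 2, 2, 2)),
                                activation=identity))
        np.testing.assert_allclose(y, 16.0)

    def test_bias_added_by_default(self):
        y = conv4d_ref(np.ones((1, 1, 1, 1, 1)),
                       ConvSpec(weights=np.ones((1, 1, 1, 1, 1)), bias=0.25,
                                activation=identity))
        np.testing.assert_allclose(y, 1.25)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_nested_loop_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        c = int(rng.integers(1, 3))
        ext = rng.integers(2, 5, size=4)
        ker = np.array([rng.integers(1, e + 1) for e in ext])
        x = rng.normal(size=(c, *ext))
        wt = rng.normal(size=(c, *ker))
        b = float(rng.normal())
        got = conv4d_ref(x, ConvSpec(weights=wt, bias=b, activation=identity))
        want = brute_conv4d(x, wt, b, lambda s: s, +1.0)
        np.testing.assert_allclose(got, want, atol=1e-5)

    def test_degenerates_to_2d(self):
        # extent-1 plane and slice axes reduce Eq-2 to the Eq-1 sum
        rng = np.random.default_rng(7)
        x = rng.normal(size=(2, 5, 6))
        wt = rng.normal(size=(2, 3, 3))
        y2 = conv2d_ref(x, ConvSpec(weights=wt, activation=identity,
                                    bias_sign=1.0), )
        y4 = conv4d_ref(x[:, None, None], ConvSpec(
            weights=wt[:, None, None], activation=identity))
        np.testing.assert_allclose(y4[0, 0], y2, atol=1e-12)

    def test_linearity(self):
        rng = np.random.default_rng(8)
        x1 = rng.normal(size=(1, 3, 3, 3, 3))
        x2 = rng.normal(size=(1, 3, 3, 3, 3))
        w = rng.normal(size=(1, 2, 2, 2, 2))
        spec = ConvSpec(weights=w, activation=identity)
        np.testing.assert_allclose(
            conv4d_ref(2 * x1 + 3 * x2, spec),
            2 * conv4d_ref(x1, spec) + 3 * conv4d_ref(x2, spec),
            atol=1e-10,
        )


class TestAssembleInput:
    def box(self, gray):
        return NoduleBox(gray=gray, spacing=(1.0, 1.0, 1.0), label="benign",
                         center_voxel=(4, 4, 4),
                         pad=((0, 0), (0, 0), (0, 0)))

    def test_zero_sample_zero_tensor(self):
        s = assemble_input(self.box(np.zeros((8, 8, 8))), np.zeros((8, 8)))
        np.testing.assert_array_equal(s.tensor(), 0.0)
        assert s.tensor().shape == (1, 1, 2, 8, 8, 8)

    def test_impulse_lands_in_plane0(self):
        g = np.zeros((8, 8, 8))
        g[3, 4, 5] = 255.0
        t = assemble_input(self.box(g), np.zeros((8, 8))).tensor()
        assert t[0, 0, 0, 3, 4, 5] == 1.0
        assert t.sum() == 1.0

    def test_plane0_embeds_gray_exactly(self):
        rng = np.random.default_rng(2)
        g = rng.integers(0, 256, size=(8, 8, 8)).astype(float)
        t = assemble_input(self.box(g), np.zeros((8, 8))).tensor()
        np.testing.assert_allclose(t[0, 0, 0], g / 255.0, atol=1e-7)

    def test_plane1_broadcasts_rows(self):
        m = np.linspace(0, 1, 64).reshape(8, 8)
        t = assemble_input(self.box(np.zeros((8, 8, 8))), m).tensor()
        for h in range(8):
            np.testing.assert_allclose(t[0, 0, 1, :, h, :], m, atol=1e-7)

    def test_size_mismatch_errors(self):
        with pytest.raises(ValueError):
            assemble_input(self.box(np.zeros((8, 8, 8))), np.zeros((4, 4)))

    def test_out_of_range_values_rejected(self):
        with pytest.raises(ValueError, match="shape_matrix"):
            Tensor4DSample(volume=np.zeros((4, 4, 4)),
                           shape_matrix=np.full((4, 4), 1.5), label=0)


class TestBuildUNet:
    def test_parameter_counts_scale_with_width(self):
        n4 = build_unet(UNetConfig(depth=2, base_filters=4)).n_parameters
        n8 = build_unet(UNetConfig(depth=2, base_filters=8)).n_parameters
        assert n4 == 22418
        assert n8 == 88898
        # depth 1, base 2 closed form (conv weights + 2 batch-norm affine
        # params per normalized channel + head bias):
        # enc: (108+4) + (108+4); bottleneck: (216+8) + (432+8);
        # dec: (324+4) + (108+4); head: 4+2  ->  1334
        assert build_unet(UNetConfig(depth=1, base_filters=2)).n_parameters \
            == 1334

    def test_divisibility_guard(self):
        with pytest.raises(ValueError, match="divisible"):
            build_unet(UNetConfig(depth=4, base_filters=4),
                       in_extents=(2, 8, 8, 8))

    def test_zeroed_head_gives_uniform_softmax(self):
        model = build_unet(UNetConfig(depth=1, base_filters=2, seed=3),
                           in_extents=(2, 8, 8, 8))
        model.head.w[:] = 0.0
        model.head.b[:] = 0.0
        x = np.random.default_rng(0).random((2, 1, 2, 8, 8, 8))
        p = softmax(model.forward(x))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(p, 0.5, atol=1e-12)

    def test_seeded_construction_deterministic(self):
        cfg = UNetConfig(depth=1, base_filters=2, seed=42)
        a = build_unet(cfg, in_extents=(2, 8, 8, 8))
        b = build_unet(cfg, in_extents=(2, 8, 8, 8))
        x = np.random.default_rng(1).random((1, 1, 2, 8, 8, 8))
        np.testing.assert_array_equal(a.forward(x), b.forward(x))


class TestLossAndTraining:
    def test_uniform_logits_ln2(self):
        assert softmax_cross_entropy(np.array([0.0, 0.0]), 0) == \
            pytest.approx(np.log(2), abs=1e-12)
        assert softmax_cross_entropy(np.array([0.0, 0.0]), 1) == \
            pytest.approx(np.log(2), abs=1e-12)

    def test_large_margin_small_loss(self):
        assert softmax_cross_entropy(np.array([10.0, -10.0]), 0) < 1e-4

    def test_loss_nonnegative(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            logits = rng.normal(size=(4, 2)) * 5
            labels = rng.integers(0, 2, 4)
            assert softmax_cross_entropy(logits, labels) >= 0.0

    def test_bad_label_errors(self):
        with pytest.raises(ValueError):
            softmax_cross_entropy(np.array([0.0, 0.0]), 2)

    @staticmethod
    def toy_samples(n=8, size=8, seed=0):
        """Easily separable: class 1 has a bright central block."""
        rng = np.random.default_rng(seed)
        out = []
        for i in range(n):
            label = i % 2
            vol = rng.random((size, size, size)) * 0.1
            if label:
                vol[2:6, 2:6, 2:6] += 0.8
            mat = rng.random((size, size)) * 0.1 + 0.4 * label
            out.append(Tensor4DSample(volume=np.clip(vol, 0, 1),
                                      shape_matrix=np.clip(mat, 0, 1),
                                      label=label))
        return out

    def test_overfit_tiny_separable_set(self):
        samples = self.toy_samples()
        cfg = UNetConfig(depth=1, base_filters=2, learning_rate=3e-3,
                         epochs=30, batch_size=4, seed=0)
        model = build_unet(cfg, in_extents=(2, 8, 8, 8))
        model, hist = train(model, samples, cfg)
        assert hist[-1]["accuracy"] == 1.0
        assert all(np.isfinite(h["loss"]) for h in hist)
        assert hist[-1]["loss"] < hist[0]["loss"]
        p = predict(model, samples)
        assert (p.argmax(axis=1) == [s.label for s in samples]).all()

    def test_zero_epochs_noop(self):
        samples = self.toy_samples(4)
        cfg = UNetConfig(depth=1, base_filters=2, epochs=0, seed=0)
        model = build_unet(cfg, in_extents=(2, 8, 8, 8))
        w_before = model.head.w.copy()
        model, hist = train(model, samples, cfg)
        assert hist == []
        np.testing.assert_array_equal(model.head.w, w_before)

    def test_single_class_errors(self):
        samples = [s for s in self.toy_samples(6) if s.label == 0]
        cfg = UNetConfig(depth=1, base_filters=2, epochs=1)
        model = build_unet(cfg, in_extents=(2, 8, 8, 8))
        with pytest.raises(ValueError, match="both classes"):
            train(model, samples, cfg)

    def test_training_deterministic(self):
        samples = self.toy_samples(6)
        cfg = UNetConfig(depth=1, base_filters=2, epochs=3, batch_size=2,
                         seed=9)
        _, h1 = train(build_unet(cfg, in_extents=(2, 8, 8, 8)), samples, cfg)
        _, h2 = train(build_unet(cfg, in_extents=(2, 8, 8, 8)), samples, cfg)
        assert h1 == h2

    def test_predict_batching_consistent(self):
        samples = self.toy_samples(5)
        cfg = UNetConfig(depth=1, base_filters=2, seed=1)
        model = build_unet(cfg, in_extents=(2, 8, 8, 8))
        p1 = predict(model, samples, batch_size=2)
        p2 = predict(model, samples, batch_size=5)
        np.testing.assert_allclose(p1, p2, atol=1e-6)
        np.testing.assert_allclose(p1.sum(axis=1), 1.0, atol=1e-9)


class TestGradients:
    @pytest.mark.parametrize("depth", [1, 2])
    def test_model_gradient_matches_finite_differences_f64(self, depth):
        cfg = UNetConfig(depth=depth, base_filters=2, seed=5)
        model = build_unet(cfg, in_extents=(2, 8, 8, 8), dtype=np.float64)
        # zero-initialized biases put dead receptive fields exactly on the
        # ReLU kink (pre-activation == bias == 0), where two-sided finite
        # differences straddle the subgradient; shift away from the kink
        for layer in model._layers():
            layer.b += 0.05
        rng = np.random.default_rng(0)
        x = rng.random((2, 1, 2, 8, 8, 8))
        y = np.array([0, 1])

        def loss_of():
            return softmax_cross_entropy(model.forward(x), y)

        from radscan.unet4d import _loss_and_grad
        logits = model.forward(x)
        _, dlog = _loss_and_grad(logits, y)
        model.backward(dlog)
        checked = 0
        # float64 model: eps can be tiny, so ReLU-kink and max-pool-tie
        # secant errors are O(eps) and the check can be tight
        eps = 1e-6
        for layer in model._layers():
            for p, g in layer.params:
                flat_p = p.ravel()
                flat_g = g.ravel()
                for k in rng.choice(flat_p.size,
                                    size=min(3, flat_p.size), replace=False):
                    orig = flat_p[k]
                    flat_p[k] = orig + eps
                    lp = loss_of()
                    flat_p[k] = orig - eps
                    lm = loss_of()
                    flat_p[k] = orig
                    fd = (lp - lm) / (2 * eps)
                    assert abs(fd - flat_g[k]) < 1e-5 + 1e-4 * abs(fd), \
                        f"grad mismatch {fd} vs {flat_g[k]}"
                    checked += 1
        assert checked >= 20
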