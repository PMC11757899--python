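"""Network contracts: shapes, determinism, attention bounds, gradient flow."""

import numpy as np
import pytest

from skeltube.nn import (
    AttentionGate,
    NetworkSpec,
    ResidualBlock,
    SGCNN,
    SkeletonGuidedBlock,
    Tensor,
    backward,
    build_network,
)
from skeltube.nn import autograd as ag


SMALL = NetworkSpec(base_channels=4, n_levels=2, sg_levels=(1, 2), seed=0)


class TestAutogradOps:
    """Numeric-gradient checks of the convolution kernels (the engine core)."""

    def _numeric_grad(self, f, x, h=1e-3):
        g = np.zeros_like(x)
        it = np.nditer(x, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            x1, x2 = x.copy(), x.copy()
            x1[i] += h
            x2[i] -= h
            g[i] = (f(x1) - f(x2)) / (2 * h)
        return g

    @pytest.mark.parametrize("kernel,pad", [(3, 1), (1, 0)])
    def test_conv3d_gradients(self, rng, kernel, pad):
        x = rng.normal(size=(2, 4, 4, 4)).astype(np.float32)
        w = rng.normal(size=(3, 2, kernel, kernel, kernel)).astype(np.float32)
        b = rng.normal(size=3).astype(np.float32)
        coef = rng.normal(size=(3, 4, 4, 4)).astype(np.float32)

        def value(xa, wa, ba):
            xt, wt, bt = Tensor(xa), Tensor(wa), Tensor(ba)
            return float((ag.conv3d(xt, wt, bt, pad).data * coef).sum())

        xt = Tensor(x, requires_grad=True)
        wt = Tensor(w, requires_grad=True)
        bt = Tensor(b, requires_grad=True)
        y = ag.conv3d(xt, wt, bt, pad)
        backward([(y, coef)])
        assert np.allclose(xt.grad, self._numeric_grad(lambda a: value(a, w, b), x),
                           atol=5e-2)
        assert np.allclose(wt.grad, self._numeric_grad(lambda a: value(x, a, b), w),
                           atol=5e-2)
        assert np.allclose(bt.grad, self._numeric_grad(lambda a: value(x, w, a), b),
                           atol=5e-2)

    def test_conv_transpose_gradients(self, rng):
        x = rng.normal(size=(2, 3, 3, 3)).astype(np.float32)
        w = rng.normal(size=(2, 2, 2, 2, 2)).astype(np.float32)
        coef = rng.normal(size=(2, 6, 6, 6)).astype(np.float32)

        def value(xa, wa):
            return float((ag.conv_transpose3d(Tensor(xa), Tensor(wa), None).data
                          * coef).sum())

        xt = Tensor(x, requires_grad=True)
        wt = Tensor(w, requires_grad=True)
        y = ag.conv_transpose3d(xt, wt, None)
        backward([(y, coef)])
        assert np.allclose(xt.grad, self._numeric_grad(lambda a: value(a, w), x),
                           atol=5e-2)
        assert np.allclose(wt.grad, self._numeric_grad(lambda a: value(x, a), w),
                           atol=5e-2)

    def test_maxpool_routes_gradient_to_argmax(self):
        x = np.zeros((1, 2, 2, 2), dtype=np.float32)
        x[0, 1, 0, 1] = 5.0
        xt = Tensor(x, requires_grad=True)
        y = ag.maxpool2(xt)
        assert y.data.shape == (1, 1, 1, 1) and y.data[0, 0, 0, 0] == 5.0
        backward([(y, np.ones_like(y.data))])
        expected = np.zeros_like(x)
        expected[0, 1, 0, 1] = 1.0
        assert np.array_equal(xt.grad, expected)

    def test_instance_norm_output_standardized(self, rng):
        x = Tensor(rng.normal(3.0, 2.0, size=(3, 4, 4, 4)).astype(np.float32))
        y = ag.instance_norm(x)
        assert np.allclose(y.data.mean(axis=(1, 2, 3)), 0.0, atol=1e-5)
        assert np.allclose(y.data.std(axis=(1, 2, 3)), 1.0, atol=1e-3)


class TestAttentionGate:
    def test_zero_init_gives_exactly_half(self, rng):
        gate = AttentionGate(np.random.default_rng(0), 4)
        gate.zero_()
        t = Tensor(rng.normal(size=(4, 6, 6, 6)).astype(np.float32))
        f = Tensor(rng.normal(size=(4, 6, 6, 6)).astype(np.float32))
        a = gate(t, f)
        assert np.all(a.data == 0.5)

    def test_bounds_half_to_one(self, rng):
        # sigmoid of a ReLU output can never fall below 0.5; the upper
        # bound is strict for inputs that keep float32 sigmoid unsaturated
        gate = AttentionGate(np.random.default_rng(3), 4)
        t = Tensor(rng.normal(scale=2, size=(4, 5, 5, 5)).astype(np.float32))
        f = Tensor(rng.normal(scale=2, size=(4, 5, 5, 5)).astype(np.float32))
        a = gate(t, f).data
        assert a.min() >= 0.5 and a.max() < 1.0
        assert a.shape == t.data.shape

    def test_misaligned_inputs_raise(self, rng):
        gate = AttentionGate(np.random.default_rng(0), 4)
        with pytest.raises(ValueError):
            gate(Tensor(np.zeros((4, 4, 4, 4), np.float32)),
                 Tensor(np.zeros((4, 2, 4, 4), np.float32)))


class TestSkeletonGuidedBlock:
    def test_zero_residual_is_identity(self, rng):
        block = ResidualBlock(np.random.default_rng(0), 4)
        block.zero_()
        x = Tensor(rng.normal(size=(4, 6, 6, 6)).astype(np.float32))
        assert np.allclose(block(x).data, x.data)

    def test_zero_init_block_halves_input(self, rng):
        block = SkeletonGuidedBlock(np.random.default_rng(0), 4)
        block.zero_()
        t = Tensor(rng.normal(size=(4, 6, 6, 6)).astype(np.float32))
        f = Tensor(rng.normal(size=(4, 6, 6, 6)).astype(np.float32))
        assert np.allclose(block(t, f).data, 0.5 * t.data, atol=1e-6)

    def test_gradient_flows_to_both_inputs(self, rng):
        block = SkeletonGuidedBlock(np.random.default_rng(1), 3)
        t = Tensor(rng.normal(size=(3, 4, 4, 4)).astype(np.float32),
                   requires_grad=True)
        f = Tensor(rng.normal(size=(3, 4, 4, 4)).astype(np.float32),
                   requires_grad=True)
        out = block(t, f)
        backward([(out, np.ones_like(out.data))])
        assert t.grad is not None and np.abs(t.grad).max() > 0
        assert f.grad is not None and np.abs(f.grad).max() > 0


class TestSGCNN:
    def test_forward_shape_contract(self):
        model = build_network(NetworkSpec(base_channels=8, n_levels=3,
                                          sg_levels=(2, 3), seed=0))
        x = np.random.default_rng(0).random((32, 32, 32), dtype=np.float32)
        p, ph = model.forward_tensors(x)
        assert p.data.shape == (1, 32, 32, 32)
        assert ph.data.shape == (1, 32, 32, 32)
        assert 0 < p.data.min() and p.data.max() < 1
        assert 0 < ph.data.min() and ph.data.max() < 1

    def test_same_seed_identical_weights(self):
        a = build_network(SMALL)
        b = build_network(SMALL)
        for ka, ta in a.parameters().items():
            assert np.array_equal(ta.data, b.parameters()[ka].data)
        c = build_network(NetworkSpec(base_channels=4, n_levels=2,
                                      sg_levels=(1, 2), seed=99))
        assert any(not np.array_equal(t.data, c.parameters()[k].data)
                   for k, t in a.parameters().items())

    def test_no_sg_ablation_runs_without_skeleton_head(self):
        model = build_network(NetworkSpec(base_channels=4, n_levels=2,
                                          sg_levels=(), seed=0))
        x = np.random.default_rng(1).random((16, 16, 16), dtype=np.float32)
        p, ph = model.forward_tensors(x)
        assert p.data.shape == (1, 16, 16, 16)
        assert ph is None

    def test_bounded_outputs_for_extreme_inputs(self):
        model = build_network(SMALL)
        x = np.full((16, 16, 16), 1e4, dtype=np.float32)
        p, ph = model.forward_tensors(x)
        for out in (p.data, ph.data):
            assert np.isfinite(out).all()
            # float32 sigmoid saturates to exactly 0/1 under extreme inputs;
            # the closure [0, 1] is the representable guarantee
            assert 0.0 <= out.min() and out.max() <= 1.0

    def test_outputs_strictly_inside_unit_interval_for_normal_inputs(self):
        model = build_network(SMALL)
        x = np.random.default_rng(3).random((16, 16, 16), dtype=np.float32)
        p, ph = model.forward_tensors(x)
        for out in (p.data, ph.data):
            assert 0.0 < out.min() and out.max() < 1.0

    def test_invalid_patch_size_raises(self):
        model = build_network(SMALL)
        with pytest.raises(ValueError):
            model.forward_tensors(np.zeros((10, 10, 10), np.float32))

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            NetworkSpec(n_levels=1)
        with pytest.raises(ValueError):
            NetworkSpec(n_levels=2, sg_levels=(3,))
        with pytest.raises(ValueError):
            NetworkSpec(norm="layer")

    def test_state_dict_round_trip(self, tmp_path):
        model = build_network(SMALL)
        path = tmp_path / "model.npz"
        model.save(path)
        back = SGCNN.load(path)
        x = np.random.default_rng(2).random((8, 8, 8), dtype=np.float32)
        p1, _ = model.forward_tensors(x)
        p2, _ = back.forward_tensors(x)
        assert np.array_equal(p1.data, p2.data)

    def test_summary_mentions_parameter_count(self):
        model = build_network(SMALL)
        s = model.summary()
        assert str(model.n_parameters) in s
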