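"""Autodiff engine: finite-difference gradient checks and layer contracts."""

import numpy as np
import pytest

from canalnet import nn
from canalnet.nn import Tensor


def numeric_grad(f, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        xp, xm = x.copy(), x.copy()
        xp[i] += eps
        xm[i] -= eps
        g[i] = (f(xp) - f(xm)) / (2 * eps)
        it.iternext()
    return g


def check_grad(build, x, tol=1e-6):
    """Compare autodiff gradient of sum(build(x)) with central differences."""
    t = Tensor(x, requires_grad=True)
    build(t).sum().backward()
    num = numeric_grad(lambda a: build(Tensor(a)).sum().item(), x)
    np.testing.assert_allclose(t.grad, num, rtol=tol, atol=tol)


class TestElementwiseGrads:
    @pytest.mark.parametrize("op", [nn.relu, nn.sigmoid, nn.tanh, nn.sqrt])
    def test_unary_ops(self, op, rng):
        x = rng.uniform(0.1, 2.0, size=(2, 3, 4))
        check_grad(op, x)

    def test_arithmetic_chain(self, rng):
        x = rng.normal(size=(3, 3))
        y = Tensor(rng.normal(size=(3, 3)))
        check_grad(lambda t: (t * y + 2.0) * t - t / (y * y + 3.0), x)

    def test_broadcast_add(self, rng):
        x = rng.normal(size=(1, 4, 1, 1))
        other = Tensor(rng.normal(size=(2, 4, 3, 3)))
        check_grad(lambda t: t + other, x)

    def test_amax_routes_gradient_to_argmax(self):
        x = np.array([[1.0, 5.0], [7.0, 2.0]])
        t = Tensor(x, requires_grad=True)
        nn.amax(t, 1).sum().backward()
        np.testing.assert_array_equal(t.grad, [[0, 1], [1, 0]])


class TestConvAndPool:
    def test_conv2d_gradients(self, rng):
        x = rng.normal(size=(2, 2, 4, 4))
        w = rng.normal(size=(3, 2, 3, 3)) * 0.3
        b = rng.normal(size=3)
        check_grad(lambda t: nn.conv2d(t, Tensor(w), Tensor(b)), x)
        tw = Tensor(w, requires_grad=True)
        nn.conv2d(Tensor(x), tw, Tensor(b)).sum().backward()
        num = numeric_grad(
            lambda a: nn.conv2d(Tensor(x), Tensor(a), Tensor(b)).sum().item(), w)
        np.testing.assert_allclose(tw.grad, num, rtol=1e-6, atol=1e-6)

    def test_conv3d_matches_scipy_correlate(self, rng):
        from scipy.ndimage import correlate
        x = rng.normal(size=(4, 1, 4, 4))
        w = rng.normal(size=(2, 1, 3, 3, 3))
        out = nn.conv3d(Tensor(x), Tensor(w), Tensor(np.zeros(2))).data
        for c in range(2):
            ref = correlate(x[:, 0], w[c, 0], mode="constant")
            np.testing.assert_allclose(out[:, c], ref, atol=1e-12)

    def test_conv3d_gradients(self, rng):
        x = rng.normal(size=(2, 1, 2, 2))
        w = rng.normal(size=(1, 1, 3, 3, 3)) * 0.3
        check_grad(lambda t: nn.conv3d(t, Tensor(w), Tensor(np.zeros(1))), x)

    def test_pool_shapes_and_grads(self, rng):
        x = rng.normal(size=(4, 2, 4, 4))
        assert nn.maxpool2(Tensor(x)).shape == (2, 2, 2, 2)
        assert nn.avgpool2(Tensor(x)).shape == (2, 2, 2, 2)
        assert nn.upsample2(Tensor(x)).shape == (8, 2, 8, 8)
        check_grad(nn.maxpool2, x)
        check_grad(nn.avgpool2, x)
        check_grad(nn.upsample2, x)

    def test_avgpool_is_block_mean(self):
        x = np.zeros((2, 1, 2, 2))
        x[0, 0, 0, 0] = 1.0
        out = nn.avgpool2(Tensor(x)).data
        np.testing.assert_allclose(out, [[[[1 / 8]]]])

    def test_odd_axis_rejected(self):
        with pytest.raises(ValueError):
            nn.maxpool2(Tensor(np.zeros((3, 1, 4, 4))))


class TestBatchNorm:
    def test_inference_affine_closed_form(self):
        bn = nn.BatchNorm(1)
        bn.training = False
        bn.running_mean[:] = 2.0
        bn.running_var[:] = 4.0
        bn.gamma.data[:] = 3.0
        bn.beta.data[:] = 1.0
        x = np.array([4.0, 0.0]).reshape(2, 1, 1, 1)
        # gamma * (x - mean)/sqrt(var + eps) + beta, evaluated by hand
        expected = 3.0 * (x - 2.0) / np.sqrt(4.0 + bn.eps) + 1.0
        np.testing.assert_allclose(bn(Tensor(x)).data, expected)
        # doubling the input shifts the output per the same affine formula
        np.testing.assert_allclose(
            bn(Tensor(2 * x)).data, 3.0 * (2 * x - 2.0) / np.sqrt(4.0 + bn.eps) + 1.0)

    def test_train_mode_normalises_batch(self, rng):
        bn = nn.BatchNorm(2)
        x = rng.normal(3.0, 2.0, size=(4, 2, 5, 5))
        out = bn(Tensor(x)).data
        np.testing.assert_allclose(out.mean(axis=(0, 2, 3)), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.std(axis=(0, 2, 3)), 1.0, atol=1e-3)

    def test_gradients_through_batch_statistics(self, rng):
        x = rng.normal(size=(2, 1, 2, 2))

        def f(t):
            bn = nn.BatchNorm(1)
            return bn(t)

        check_grad(f, x, tol=1e-5)


class TestConvLSTM:
    def test_saturated_closed_input_gate_keeps_state_at_init(self):
        # gates conv weights zero; biases chosen so i ~ 0, f ~ 1, o ~ 1:
        # the cell state stays at its (zero) init and h = o * tanh(0) = 0
        cell = nn.ConvLSTMCell(1, 1, 3, np.random.default_rng(0))
        cell.gates.weight.data[:] = 0.0
        big = 30.0
        cell.gates.bias.data[:] = [-big, big, big, big]  # i, f, o, g-gate biases
        x = Tensor(np.ones((1, 1, 1, 1)))
        h = Tensor(np.zeros((1, 1, 1, 1)))
        c = Tensor(np.zeros((1, 1, 1, 1)))
        for _ in range(3):
            h, c = cell.step(x, h, c)
        np.testing.assert_allclose(c.data, 0.0, atol=1e-12)
        np.testing.assert_allclose(h.data, 0.0, atol=1e-12)

    def test_bidirectional_output_shape_and_reversal_invariance(self, rng):
        lstm = nn.BiConvLSTM(2, 3, 3, rng)
        x = rng.normal(size=(5, 2, 4, 4))
        out = lstm(Tensor(x)).data
        assert out.shape == (5, 6, 4, 4)
        assert np.isfinite(out).all()
        out_rev = lstm(Tensor(x[::-1].copy())).data
        assert out_rev.shape == (5, 6, 4, 4)
        assert np.isfinite(out_rev).all()

    def test_gradients_flow_through_recurrence(self, rng):
        lstm = nn.BiConvLSTM(1, 1, 3, rng)
        x = rng.normal(size=(3, 1, 2, 2))

        def f(t):
            return lstm(t)

        check_grad(f, x, tol=1e-5)


class TestAdam:
    def test_converges_on_quadratic(self):
        p = Tensor(np.array([5.0, -3.0]), requires_grad=True)
        opt = nn.Adam([p], lr=0.1)
        for _ in range(300):
            opt.zero_grad()
            (p * p).sum().backward()
            opt.step()
        np.testing.assert_allclose(p.data, 0.0, atol=1e-3)
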