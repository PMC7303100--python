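"""Unit and property tests for the numpy autodiff toolkit."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from octmotion.nn import Adam, Conv, Linear, Tensor
from octmotion.nn import core, functional as F


def _rand_case(rng):
    nd = int(rng.integers(3, 5))
    K = tuple(int(rng.integers(1, 4)) for _ in range(nd))
    cin, cout = int(rng.integers(1, 4)), int(rng.integers(1, 4))
    S = tuple(int(rng.integers(k, k + 4)) for k in K)
    x = rng.standard_normal((2, *S, cin))
    w = rng.standard_normal((*K, cin, cout))
    return x, w, K


class TestCorrelateNd:
    def test_matches_direct_summation(self):
        """Windowed-GEMM lowering equals the definition sum, many instances."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            x, w, K = _rand_case(rng)
            nd = len(K)
            pads = tuple((0, 0) for _ in K)
            got = F.correlate_nd(x, w, pads)
            want = np.zeros_like(got)
            for n in range(x.shape[0]):
                import itertools
                out = got.shape[1:-1]
                for p in itertools.product(*map(range, out)):
                    for q in itertools.product(*map(range, K)):
                        idx = tuple(pi + qi for pi, qi in zip(p, q))
                        want[(n, *p)] += x[(n, *idx)] @ w[q]
            np.testing.assert_allclose(got, want, rtol=1e-9, atol=1e-9)

    def test_same_padding_preserves_size(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((1, 6, 7, 8, 2))
        w = rng.standard_normal((3, 3, 3, 2, 4))
        y = F.correlate_nd(x, w, F.same_pads((3, 3, 3)))
        assert y.shape == (1, 6, 7, 8, 4)
        # even kernel: trailing-edge padding keeps the size too
        w2 = rng.standard_normal((2, 3, 3, 3, 2, 4))
        x2 = rng.standard_normal((1, 5, 6, 6, 6, 2))
        y2 = F.correlate_nd(x2, w2, F.same_pads((2, 3, 3, 3)))
        assert y2.shape == (1, 5, 6, 6, 6, 4)

    def test_incompatible_shapes_raise(self):
        x = np.zeros((1, 4, 4, 4, 3))
        w = np.zeros((3, 3, 3, 2, 4))  # c_in mismatch
        with pytest.raises(ValueError):
            F.correlate_nd(x, w, F.same_pads((3, 3, 3)))

    @pytest.mark.parametrize("strides", [(1, 1, 1), (2, 1, 2), (2, 2, 2)])
    def test_strided_equals_subsampled_dense(self, strides):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((2, 8, 8, 8, 2))
        w = rng.standard_normal((3, 3, 3, 2, 3))
        pads = F.same_pads((3, 3, 3))
        dense = F.correlate_nd(x, w, pads)
        sub = dense[:, ::strides[0], ::strides[1], ::strides[2]]
        np.testing.assert_allclose(
            F.correlate_nd(x, w, pads, strides), sub, rtol=1e-6)


class TestGradients:
    """Analytic gradients against central differences."""

    @pytest.mark.parametrize("nd,strides,padding", [
        (3, (1, 1, 1), "same"),
        (3, (2, 1, 2), "same"),
        (4, (1, 1, 1, 1), "same"),
        (4, (1, 2, 2, 1), "valid"),
    ])
    def test_conv_gradcheck(self, nd, strides, padding):
        rng = np.random.default_rng(7 + nd)
        K = (2, 3, 3, 3)[-nd:] if nd == 4 else (3, 2, 3)
        x = rng.standard_normal((2, *(5,) * nd, 2))
        w = rng.standard_normal((*K, 2, 2))
        b = rng.standard_normal(2)
        pads = F.same_pads(K) if padding == "same" else tuple((0, 0) for _ in K)
        xt, wt, bt = Tensor(x, True), Tensor(w, True), Tensor(b, True)
        y = core.conv(xt, wt, bt, pads, strides)
        g = rng.standard_normal(y.shape)
        y.backward(g)
        eps = 1e-6

        def forward(xv, wv, bv):
            return F.correlate_nd(xv, wv, pads, strides) + bv

        for arr, grad in ((x, xt.grad), (w, wt.grad), (b, bt.grad)):
            flat = arr.reshape(-1)
            for i in rng.choice(flat.size, size=min(25, flat.size),
                                replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                fp = (forward(x, w, b) * g).sum()
                flat[i] = orig - eps
                fm = (forward(x, w, b) * g).sum()
                flat[i] = orig
                num = (fp - fm) / (2 * eps)
                assert abs(num - grad.reshape(-1)[i]) < 1e-4 * max(
                    1.0, abs(num))

    def test_pool_gap_norm_linear_gradcheck(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal((3, 5, 6, 6, 6, 2))
        gain = rng.standard_normal(2) + 1.0
        bias = rng.standard_normal(2)
        W = rng.standard_normal((2, 3))

        def forward(xv):
            t = core.avg_pool(Tensor(xv), (1, 2, 3, 4), (2, 2, 2, 2))
            t = core.instance_norm(t, Tensor(gain), Tensor(bias))
            t = core.global_mean(core.relu(t), (1, 2, 3, 4))
            t = core.linear(t, Tensor(W), None)
            return core.mean_squared_norm(t, np.ones((3, 3)))

        xt = Tensor(x, True)
        t = core.avg_pool(xt, (1, 2, 3, 4), (2, 2, 2, 2))
        t = core.instance_norm(t, Tensor(gain), Tensor(bias))
        t = core.global_mean(core.relu(t), (1, 2, 3, 4))
        t = core.linear(t, Tensor(W), None)
        core.mean_squared_norm(t, np.ones((3, 3))).backward()
        eps = 1e-6
        flat = x.reshape(-1)
        for i in rng.choice(flat.size, size=40, replace=False):
            orig = flat[i]
            flat[i] = orig + eps
            fp = forward(x).item()
            flat[i] = orig - eps
            fm = forward(x).item()
            flat[i] = orig
            assert abs((fp - fm) / (2 * eps) - xt.grad.reshape(-1)[i]) < 1e-5

    def test_shared_weight_grads_accumulate(self):
        """Calling the same layer twice accumulates both paths' gradients."""
        rng = np.random.default_rng(0)
        lin = Linear(4, 2, rng, dtype=np.float64)
        xa, xb = rng.standard_normal((3, 4)), rng.standard_normal((3, 4))
        y = core.add(lin(Tensor(xa)), lin(Tensor(xb)))
        core.mean_squared_norm(y, np.zeros((3, 2))).backward()
        shared_grad = lin.weight.grad.copy()
        lin.weight.grad = None
        core.mean_squared_norm(lin(Tensor(xa)), np.zeros((3, 2))).backward()
        # gradient via the sum differs from the single-path gradient
        assert not np.allclose(shared_grad, lin.weight.grad)


class TestPooling:
    def test_ceil_mode_partial_window(self):
        """Odd temporal length 5 pools to 3 with the tail window of size 1."""
        x = np.arange(5, dtype=float).reshape(1, 5, 1)
        y = core.avg_pool(Tensor(x), (1,), (2,)).data
        np.testing.assert_allclose(y[0, :, 0], [0.5, 2.5, 4.0])

    def test_singleton_axis_untouched(self):
        x = np.ones((1, 1, 4, 1))
        y = core.avg_pool(Tensor(x), (1, 2), (2, 2)).data
        assert y.shape == (1, 1, 2, 1)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_adam_decreases_quadratic(seed):
    """Adam makes progress on a random convex quadratic."""
    rng = np.random.default_rng(seed)
    target = rng.standard_normal(6)
    p = Tensor(np.zeros(6), requires_grad=True)
    opt = Adam([p], lr=0.05)
    first = float(((p.data - target) ** 2).sum())
    for _ in range(200):
        opt.zero_grad()
        p.grad = 2 * (p.data - target)
        opt.step()
    assert ((p.data - target) ** 2).sum() < first * 0.05 + 1e-12


def test_conv_layer_shapes_and_bias():
    rng = np.random.default_rng(5)
    conv = Conv(2, 4, (3, 3, 3), rng)
    x = Tensor(rng.standard_normal((2, 8, 8, 8, 2)).astype(np.float32))
    y = conv(x)
    assert y.shape == (2, 8, 8, 8, 4)
    conv.bias.data[:] = 7.0
    y2 = conv(x)
    np.testing.assert_allclose(y2.data, y.data + 7.0, rtol=1e-5)
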