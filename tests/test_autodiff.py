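"""Gradient checks of the autodiff primitives against numerical differences."""

import numpy as np
import pytest

from attnmorph import autodiff as ad


def numerical_grad(fn, arr, idx, eps=1e-3):
    up, dn = arr.copy(), arr.copy()
    up[idx] += eps
    dn[idx] -= eps
    return (fn(up) - fn(dn)) / (2 * eps)


def check_grad(fn_tensor, fn_np, arr, n_checks=5, rtol=2e-3, atol=1e-4, seed=0):
    """Backprop a scalar-valued function and compare at random entries."""
    t = ad.Tensor(arr, requires_grad=True)
    out = fn_tensor(t)
    out.backward()
    rng = np.random.default_rng(seed)
    flat = [tuple(rng.integers(0, s) for s in arr.shape) for _ in range(n_checks)]
    for idx in flat:
        num = numerical_grad(fn_np, arr.astype(np.float64), idx)
        ana = t.grad[idx]
        assert np.isclose(ana, num, rtol=rtol, atol=atol), (idx, ana, num)


class TestElementwise:
    def test_arithmetic_chain_gradient(self, rng):
        x = rng.normal(size=(4, 5)).astype(np.float32)

        def f_t(t):
            return ad.sum_all(ad.div(ad.mul(t, t) + 2.0 * t, ad.add(ad.mul(t, t), 1.5)))

        def f_n(a):
            return float(np.sum((a * a + 2 * a) / (a * a + 1.5)))

        check_grad(f_t, f_n, x)

    @pytest.mark.parametrize("op,npop", [
        (ad.sigmoid, lambda a: 1 / (1 + np.exp(-a))),
        (ad.relu, lambda a: np.maximum(a, 0)),
        (lambda t: ad.leaky_relu(t, 0.2), lambda a: np.where(a > 0, a, 0.2 * a)),
    ])
    def test_nonlinearity_gradients(self, rng, op, npop):
        x = rng.normal(size=(3, 4, 4)).astype(np.float32) + 0.05

        def f_t(t):
            return ad.sum_all(ad.mul(op(t), op(t)))

        def f_n(a):
            y = npop(a)
            return float(np.sum(y * y))

        check_grad(f_t, f_n, x)

    def test_broadcast_mul_unbroadcasts_gradient(self):
        x = ad.Tensor(np.ones((3, 4, 5), dtype=np.float32), requires_grad=True)
        g = ad.Tensor(np.full((3, 1, 1), 2.0, dtype=np.float32), requires_grad=True)
        out = ad.sum_all(ad.mul(x, g))
        out.backward()
        assert g.grad.shape == (3, 1, 1)
        assert np.allclose(g.grad, 20.0)  # 4*5 ones summed per channel
        assert np.allclose(x.grad, 2.0)

    def test_getitem_and_concat_gradients(self, rng):
        x = rng.normal(size=(6, 5)).astype(np.float32)

        def f_t(t):
            parts = ad.concat([t[:3], ad.mul(t[3:], 2.0)], axis=0)
            return ad.sum_all(ad.mul(parts, parts))

        def f_n(a):
            parts = np.concatenate([a[:3], 2.0 * a[3:]])
            return float(np.sum(parts * parts))

        check_grad(f_t, f_n, x)


class TestStructuredOps:
    def test_channel_linear_gradients(self, rng):
        x = rng.normal(size=(4, 3, 3, 3)).astype(np.float32)
        w = rng.normal(size=(2, 4)).astype(np.float32)
        b = rng.normal(size=2).astype(np.float32)

        def f_x(t):
            return ad.sum_all(ad.mul(ad.channel_linear(t, w, b),
                                     ad.channel_linear(t, w, b)))

        def f_xn(a):
            y = np.tensordot(w, a, axes=([1], [0])) + b.reshape(-1, 1, 1, 1)
            return float(np.sum(y * y))

        check_grad(f_x, f_xn, x)
        wt = ad.Tensor(w, requires_grad=True)
        out = ad.sum_all(ad.channel_linear(x, wt, b))
        out.backward()
        num = numerical_grad(
            lambda a: float(np.sum(np.tensordot(a, x, axes=([1], [0]))
                                   + b.reshape(-1, 1, 1, 1))),
            w.astype(np.float64), (1, 2))
        assert np.isclose(wt.grad[1, 2], num, rtol=1e-3)

    @pytest.mark.parametrize("stride", [1, 2])
    def test_conv3d_gradients(self, rng, stride):
        x = rng.normal(size=(2, 4, 4, 4)).astype(np.float32)
        w = rng.normal(size=(3, 2, 3, 3, 3)).astype(np.float32) * 0.3
        b = np.zeros(3, dtype=np.float32)

        def f_t(t):
            y = ad.conv3d(t, w, b, stride=stride)
            return ad.sum_all(ad.mul(y, y))

        def f_n(a):
            y = ad.conv3d(a, w.astype(np.float64), b.astype(np.float64),
                          stride=stride)
            return float(np.sum(y * y))

        check_grad(f_t, f_n, x)

    def test_conv3d_weight_gradient(self, rng):
        x = rng.normal(size=(2, 4, 4, 4)).astype(np.float32)
        w = (rng.normal(size=(3, 2, 3, 3, 3)) * 0.3).astype(np.float32)
        wt = ad.Tensor(w, requires_grad=True)
        out = ad.conv3d(x, wt, None, stride=1)
        ad.sum_all(ad.mul(out, out)).backward()
        idx = (1, 0, 2, 1, 0)
        num = numerical_grad(
            lambda a: float(np.sum(np.square(
                ad.conv3d(x.astype(np.float64), a, None, stride=1)))),
            w.astype(np.float64), idx)
        assert np.isclose(wt.grad[idx], num, rtol=2e-3, atol=1e-4)

    def test_upsample2_gradient_is_block_sum(self):
        x = ad.Tensor(np.arange(8, dtype=np.float32).reshape(1, 2, 2, 2),
                      requires_grad=True)
        y = ad.upsample2(x)
        assert y.shape == (1, 4, 4, 4)
        ad.sum_all(y).backward()
        assert np.allclose(x.grad, 8.0)  # each input voxel feeds 2^3 outputs

    def test_boxsum_matches_loop_and_is_self_adjoint(self, rng):
        x = rng.random((5, 5, 5))
        y = ad.boxsum(x, 3)
        xp = np.pad(x, 1)
        ref = np.zeros_like(x)
        for i in range(5):
            for j in range(5):
                for k in range(5):
                    ref[i, j, k] = xp[i:i + 3, j:j + 3, k:k + 3].sum()
        assert np.allclose(y, ref, rtol=1e-10)
        xt = ad.Tensor(x.astype(np.float32), requires_grad=True)
        ad.sum_all(ad.mul(ad.boxsum(xt, 3), ad.boxsum(xt, 3))).backward()
        num = numerical_grad(
            lambda a: float(np.sum(ad.boxsum(a, 3) ** 2)),
            x.astype(np.float64), (2, 2, 2), eps=1e-4)
        assert np.isclose(xt.grad[2, 2, 2], num, rtol=1e-3)

    def test_warp_gradients_wrt_field_and_image(self, rng):
        m = rng.random((6, 6, 6)).astype(np.float32)
        # keep sampled coordinates away from voxel boundaries: the trilinear
        # derivative has kinks at integer coordinates that break central diffs
        u = (rng.random((3, 6, 6, 6)) * 0.5 + 0.2).astype(np.float32)

        def f_u(t):
            return ad.sum_all(ad.mul(ad.warp3(m, t), ad.warp3(m, t)))

        def f_un(a):
            y = ad.warp3(m.astype(np.float64), a)
            return float(np.sum(y * y))

        # restrict checks to interior voxels where the border clamp is inactive
        t = ad.Tensor(u, requires_grad=True)
        f_u(t).backward()
        for idx in [(0, 3, 3, 3), (1, 2, 4, 2), (2, 4, 1, 3)]:
            num = numerical_grad(f_un, u.astype(np.float64), idx)
            assert np.isclose(t.grad[idx], num, rtol=2e-3, atol=1e-4)

        mt = ad.Tensor(m, requires_grad=True)
        ad.sum_all(ad.warp3(mt, u)).backward()
        num = numerical_grad(
            lambda a: float(np.sum(ad.warp3(a, u.astype(np.float64)))),
            m.astype(np.float64), (3, 3, 3))
        assert np.isclose(mt.grad[3, 3, 3], num, rtol=2e-3, atol=1e-4)


class TestEngine:
    def test_shared_subexpression_accumulates_gradient(self):
        x = ad.Tensor(np.array([3.0]), requires_grad=True)
        y = ad.mul(x, x)  # x appears twice as a parent
        y.backward(np.array([1.0]))
        assert np.allclose(x.grad, 6.0)

    def test_backward_requires_scalar_without_seed_gradient(self):
        x = ad.Tensor(np.ones((2, 2)), requires_grad=True)
        with pytest.raises(ValueError):
            ad.mul(x, 2.0).backward()

    def test_numpy_inputs_stay_numpy(self):
        out = ad.sigmoid(np.zeros(3))
        assert isinstance(out, np.ndarray)
        assert np.allclose(out, 0.5)

    def test_adam_converges_on_quadratic(self):
        x = ad.Tensor(np.array([5.0, -3.0], dtype=np.float32), requires_grad=True)
        opt = ad.Adam([x], lr=0.1)
        for _ in range(500):
            opt.zero_grad()
            ad.sum_all(ad.mul(x, x)).backward()
            opt.step()
        assert np.abs(x.data).max() < 1e-2
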