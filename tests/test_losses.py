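import numpy as np
import pytest

from attnmorph import autodiff as ad
from attnmorph.losses import (
    LossConfig,
    bending_penalty,
    gradient_penalty,
    local_cross_correlation,
    similarity_loss,
    total_loss,
)


def loop_cc(f, w, n, eps):
    """Explicit sliding-window oracle for the local CC.

    Window statistics are taken over the intersection of each n^3 window
    with the grid, so boundary windows use fewer samples."""
    d, h, wd = f.shape
    r = n // 2
    total = 0.0
    for i in range(d):
        for j in range(h):
            for k in range(wd):
                sl = (slice(max(i - r, 0), min(i + r + 1, d)),
                      slice(max(j - r, 0), min(j + r + 1, h)),
                      slice(max(k - r, 0), min(k + r + 1, wd)))
                pf = f.astype(np.float64)[sl].ravel()
                pw = w.astype(np.float64)[sl].ravel()
                fz = pf - pf.mean()
                wz = pw - pw.mean()
                cross = (fz * wz).sum()
                total += cross ** 2 / (((fz ** 2).sum() + eps)
                                       * ((wz ** 2).sum() + eps))
    return total


def loop_bending(u, margin=2):
    """Explicit stencil oracle for the bending energy."""
    d, h, w = u.shape[1:]
    total, count = 0.0, 0
    for i in range(margin, d - margin):
        for j in range(margin, h - margin):
            for k in range(w - 2 * margin):
                kk = k + margin
                for c in range(3):
                    t = u[c]
                    txx = t[i + 1, j, kk] - 2 * t[i, j, kk] + t[i - 1, j, kk]
                    tyy = t[i, j + 1, kk] - 2 * t[i, j, kk] + t[i, j - 1, kk]
                    tzz = t[i, j, kk + 1] - 2 * t[i, j, kk] + t[i, j, kk - 1]
                    txy = 0.25 * (t[i + 1, j + 1, kk] - t[i + 1, j - 1, kk]
                                  - t[i - 1, j + 1, kk] + t[i - 1, j - 1, kk])
                    txz = 0.25 * (t[i + 1, j, kk + 1] - t[i + 1, j, kk - 1]
                                  - t[i - 1, j, kk + 1] + t[i - 1, j, kk - 1])
                    tyz = 0.25 * (t[i, j + 1, kk + 1] - t[i, j + 1, kk - 1]
                                  - t[i, j - 1, kk + 1] + t[i, j - 1, kk - 1])
                    total += (txx ** 2 + tyy ** 2 + tzz ** 2
                              + 2 * (txy ** 2 + txz ** 2 + tyz ** 2))
                count += 1
    return total / count


class TestLocalCrossCorrelation:
    def test_perfect_correlation_scores_volume_size(self, rng):
        f = rng.random((9, 9, 9))
        cfg = LossConfig(window_n=3)
        cc = local_cross_correlation(f, f, cfg)
        assert cc == pytest.approx(9 ** 3, rel=1e-3)

    def test_constant_image_scores_near_zero(self, rng):
        f = rng.random((9, 9, 9))
        w = np.full((9, 9, 9), 0.5)
        cc = local_cross_correlation(f, w, LossConfig(window_n=3))
        assert cc == pytest.approx(0.0, abs=1e-6)

    def test_local_terms_bounded_in_unit_interval(self, rng):
        # bound checked via the total: 0 <= CC <= |Omega| on arbitrary pairs
        f, w = rng.random((8, 8, 8)), rng.random((8, 8, 8))
        cc = local_cross_correlation(f, w, LossConfig(window_n=3))
        assert 0.0 <= cc <= 8 ** 3

    def test_matches_sliding_window_loop_oracle(self):
        rng = np.random.default_rng(6)
        f, w = rng.random((9, 9, 9)), rng.random((9, 9, 9))
        cfg = LossConfig(window_n=3)
        got = local_cross_correlation(f, w, cfg)
        ref = loop_cc(f, w, 3, cfg.eps)
        assert got == pytest.approx(ref, rel=1e-5)

    def test_invariant_to_affine_intensity_rescaling(self, rng):
        f, w = rng.random((9, 9, 9)), rng.random((9, 9, 9))
        cfg = LossConfig(window_n=5)
        base = local_cross_correlation(f, w, cfg)
        scaled = local_cross_correlation(f, 3.0 * w + 0.7, cfg)
        assert scaled == pytest.approx(base, rel=1e-3)

    def test_window_larger_than_volume_raises(self, rng):
        with pytest.raises(ValueError):
            local_cross_correlation(rng.random((5, 5, 5)),
                                    rng.random((5, 5, 5)), LossConfig(window_n=9))

    def test_tensor_path_matches_numpy_path(self, rng):
        f, w = (rng.random((8, 8, 8)).astype(np.float32),
                rng.random((8, 8, 8)).astype(np.float32))
        cfg = LossConfig(window_n=3)
        np_val = local_cross_correlation(f, w, cfg)
        t_val = local_cross_correlation(f, ad.Tensor(w, requires_grad=True), cfg)
        assert float(ad.value_of(t_val)) == pytest.approx(float(np_val), rel=1e-4)


class TestSimilarityLoss:
    def test_perfect_alignment_gives_minus_one(self, rng):
        f = rng.random((9, 9, 9))
        loss = similarity_loss(f, f, np.zeros((3, 9, 9, 9)),
                               LossConfig(window_n=3))
        assert loss == pytest.approx(-1.0, rel=1e-3)

    def test_equals_normalized_negative_cc_identically(self, rng):
        f, m = rng.random((9, 9, 9)), rng.random((9, 9, 9))
        u = (rng.random((3, 9, 9, 9)) - 0.5)
        cfg = LossConfig(window_n=3)
        from attnmorph.transform import WarpSettings, warp_array

        w = warp_array(m, u, WarpSettings("trilinear", "border"))
        expected = -local_cross_correlation(f, w, cfg) / 9 ** 3
        assert similarity_loss(f, m, u, cfg) == pytest.approx(expected, rel=1e-10)

    def test_uncorrelated_noise_scores_near_null_expectation(self):
        # E[sample corr^2] for n iid pairs is ~1/(n-1); with a 9^3 window the
        # per-voxel terms are small, so the loss sits near 0 rather than -1
        losses = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            f, m = rng.random((16, 16, 16)), rng.random((16, 16, 16))
            losses.append(similarity_loss(f, m, np.zeros((3, 16, 16, 16)),
                                          LossConfig(window_n=9)))
        mean = np.mean(losses)
        assert -0.05 < mean < 0.0


class TestBendingPenalty:
    def test_identity_field_has_zero_penalty(self):
        assert bending_penalty(np.zeros((3, 7, 7, 7))) == 0.0

    def test_affine_field_has_zero_penalty(self):
        shape = (8, 7, 9)
        grid = np.indices(shape, dtype=np.float64)
        A = np.array([[0.2, 0.1, 0.0], [0.05, -0.1, 0.3], [0.0, 0.2, 0.1]])
        b = np.array([1.0, -2.0, 0.5])
        u = np.einsum("ij,jdhw->idhw", A, grid) + b.reshape(3, 1, 1, 1)
        assert bending_penalty(u) == pytest.approx(0.0, abs=1e-18)

    def test_quadratic_component_matches_stencil_loop_oracle(self):
        shape = (7, 7, 7)
        grid = np.indices(shape, dtype=np.float64)
        u = np.zeros((3,) + shape)
        u[0] = grid[0] ** 2
        got = bending_penalty(u)
        ref = loop_bending(u)
        assert got == pytest.approx(ref, rel=1e-12)
        assert got == pytest.approx(4.0, rel=1e-12)  # (d2/dx2 x^2)^2 = 4

    def test_random_field_matches_loop_oracle(self):
        rng = np.random.default_rng(8)
        u = rng.normal(size=(3, 7, 8, 9))
        assert bending_penalty(u) == pytest.approx(loop_bending(u), rel=1e-10)

    def test_penalty_is_nonnegative(self, rng):
        u = rng.normal(size=(3, 6, 6, 6))
        assert bending_penalty(u) >= 0

    def test_too_small_grid_raises(self):
        with pytest.raises(ValueError):
            bending_penalty(np.zeros((3, 4, 7, 7)))


class TestTotalLoss:
    def test_alpha_zero_reduces_to_similarity(self, rng):
        f, m = rng.random((9, 9, 9)), rng.random((9, 9, 9))
        u = rng.normal(size=(3, 9, 9, 9)) * 0.5
        cfg = LossConfig(window_n=3, alpha=0.0)
        total, sim, smooth = total_loss(f, m, u, cfg)
        assert smooth == 0.0
        assert total == sim

    def test_decomposition_sums_exactly(self, rng):
        f, m = rng.random((9, 9, 9)), rng.random((9, 9, 9))
        u = rng.normal(size=(3, 9, 9, 9)) * 0.5
        total, sim, smooth = total_loss(f, m, u, LossConfig(window_n=3, alpha=0.05))
        assert total == sim + smooth
        assert smooth == pytest.approx(0.05 * bending_penalty(u), rel=1e-12)

    def test_identity_on_identical_pair(self, rng):
        f = rng.random((9, 9, 9))
        total, sim, smooth = total_loss(f, f, np.zeros((3, 9, 9, 9)),
                                        LossConfig(window_n=3, alpha=0.05))
        assert total == pytest.approx(-1.0, rel=1e-3)
        assert smooth == 0.0

    def test_monotone_in_alpha_for_nonaffine_field(self, rng):
        f, m = rng.random((9, 9, 9)), rng.random((9, 9, 9))
        u = rng.normal(size=(3, 9, 9, 9))
        totals = [float(ad.value_of(total_loss(f, m, u,
                        LossConfig(window_n=3, alpha=a))[0]))
                  for a in (0.0, 0.05, 0.5)]
        assert totals[0] < totals[1] < totals[2]

    def test_gradient_matches_numerical_on_small_toy(self):
        rng = np.random.default_rng(12)
        f = rng.random((7, 7, 7)).astype(np.float32)
        m = rng.random((7, 7, 7)).astype(np.float32)
        u0 = (rng.random((3, 7, 7, 7)).astype(np.float32) * 0.5 + 0.1)
        cfg = LossConfig(window_n=3, alpha=0.05)
        u = ad.Tensor(u0, requires_grad=True)
        total, _, _ = total_loss(f, m, u, cfg)
        total.backward()
        eps = 1e-3
        for idx in [(0, 3, 3, 3), (1, 2, 4, 3), (2, 5, 1, 2)]:
            up, dn = u0.copy(), u0.copy()
            up[idx] += eps
            dn[idx] -= eps
            tp = float(ad.value_of(total_loss(f.astype(np.float64),
                                              m.astype(np.float64),
                                              up.astype(np.float64), cfg)[0]))
            tm = float(ad.value_of(total_loss(f.astype(np.float64),
                                              m.astype(np.float64),
                                              dn.astype(np.float64), cfg)[0]))
            num = (tp - tm) / (2 * eps)
            assert u.grad[idx] == pytest.approx(num, rel=1e-3, abs=1e-6)


class TestGradientPenaltyAblation:
    def test_zero_on_constant_field(self):
        assert gradient_penalty(np.full((3, 5, 5, 5), 2.0)) == 0.0

    def test_positive_on_varying_field(self, rng):
        assert gradient_penalty(rng.normal(size=(3, 5, 5, 5))) > 0
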