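"""Linear CCA and the total-correlation objective against independent oracles."""

import numpy as np
import pytest

from cardicca import linear_cca, total_correlation, total_correlation_with_grad
from cardicca.exceptions import SingularityError, ValidationError

from oracles import brute_force_cca


class TestLinearCCA:
    def test_self_correlation_is_one(self, rng):
        x = rng.normal(size=(40, 3))
        res = linear_cca(x, x, k=3, reg=0.0)
        np.testing.assert_allclose(res.correlations, 1.0, atol=1e-10)

    def test_scalar_cca_equals_absolute_pearson(self, rng):
        x = rng.normal(size=(60, 1))
        y = -0.4 * x + rng.normal(size=(60, 1))
        res = linear_cca(x, y, k=1, reg=0.0)
        expected = abs(np.corrcoef(x[:, 0], y[:, 0])[0, 1])
        assert res.correlations[0] == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_direction_search(self, seed):
        rng = np.random.default_rng(seed)
        n = 50
        z = rng.normal(size=(n, 2))
        x1 = z @ rng.normal(size=(2, 3)) + 0.6 * rng.normal(size=(n, 3))
        x2 = z @ rng.normal(size=(2, 3)) + 0.6 * rng.normal(size=(n, 3))
        res = linear_cca(x1, x2, k=2, reg=0.0)
        oracle = brute_force_cca(x1, x2, k=2, seed=seed)
        np.testing.assert_allclose(res.correlations, oracle, atol=1e-6)

    def test_affine_invariance(self, rng):
        x1 = rng.normal(size=(80, 4))
        x2 = rng.normal(size=(80, 3)) + 0.5 * x1[:, :3]
        base = linear_cca(x1, x2, k=3, reg=0.0).correlations
        a = rng.normal(size=(4, 4)) + 4 * np.eye(4)
        mapped = linear_cca(x1 @ a + rng.normal(size=4), x2, k=3, reg=0.0).correlations
        np.testing.assert_allclose(base, mapped, atol=1e-8)

    def test_projected_training_data_have_unit_variance(self, rng):
        x1 = rng.normal(size=(100, 5))
        x2 = rng.normal(size=(100, 4))
        res = linear_cca(x1, x2, k=3, reg=1e-4)
        v1 = res.project(x1, view=1)
        # variance in the regularized metric: Var(v) + reg * ||w||^2 = 1
        reg_var = v1.var(axis=0, ddof=1) + res.reg * (res.projection_1 ** 2).sum(axis=0)
        np.testing.assert_allclose(reg_var, 1.0, atol=1e-8)

    def test_sign_convention_and_positive_pairing(self, rng):
        x1 = rng.normal(size=(60, 3))
        x2 = x1 @ rng.normal(size=(3, 3)) + 0.1 * rng.normal(size=(60, 3))
        res = linear_cca(x1, x2, k=3, reg=0.0)
        for j in range(3):
            i = np.argmax(np.abs(res.projection_1[:, j]))
            assert res.projection_1[i, j] > 0
            # paired projections correlate positively
            v1 = res.project(x1, 1)[:, j]
            v2 = res.project(x2, 2)[:, j]
            assert np.corrcoef(v1, v2)[0, 1] > 0

    def test_rank_deficiency_raises_naming_block(self, rng):
        x1 = rng.normal(size=(20, 3))
        x1[:, 2] = x1[:, 0]  # collinear
        x2 = rng.normal(size=(20, 2))
        with pytest.raises(SingularityError, match="view1"):
            linear_cca(x1, x2, k=2, reg=0.0)

    @pytest.mark.parametrize("bad", [
        dict(k=5),           # k > min(d1, d2)
        dict(k=0),
        dict(reg=-1.0),
    ])
    def test_invalid_arguments(self, rng, bad):
        x1 = rng.normal(size=(20, 3))
        x2 = rng.normal(size=(20, 3))
        kwargs = dict(k=2, reg=0.0)
        kwargs.update(bad)
        with pytest.raises(ValidationError):
            linear_cca(x1, x2, **kwargs)

    def test_too_few_samples(self, rng):
        with pytest.raises(ValidationError, match="3 samples"):
            linear_cca(rng.normal(size=(2, 2)), rng.normal(size=(2, 2)), k=1)


class TestTotalCorrelation:
    def test_perfect_correlation_reaches_k(self, rng):
        h = rng.normal(size=(30, 4))
        val = total_correlation(h, h.copy(), k_corr=4, reg=0.0)
        assert val == pytest.approx(4.0, abs=1e-10)

    def test_two_point_hand_example(self):
        pts = np.array([[0.0], [1.0]])
        reg = 1e-4
        # centered +-0.5: var = 0.5, cross-cov = 0.5 -> 0.5 / (0.5 + reg)
        expected = 0.5 / (0.5 + reg)
        assert total_correlation(pts, pts, reg=reg) == pytest.approx(expected, rel=1e-12)

    def test_independent_blocks_near_zero(self):
        rng = np.random.default_rng(99)
        h1 = rng.normal(size=(10_000, 2))
        h2 = rng.normal(size=(10_000, 2))
        assert total_correlation(h1, h2, k_corr=2, reg=0.0) < 0.1

    def test_value_bounded_by_k_corr(self, rng):
        h1 = rng.normal(size=(25, 3))
        h2 = 0.5 * h1 + rng.normal(size=(25, 3))
        for k_corr in (1, 2, 3):
            val = total_correlation(h1, h2, k_corr=k_corr, reg=1e-4)
            assert 0.0 <= val <= k_corr + 1e-12

    @pytest.mark.parametrize("seed", [0, 7])
    def test_gradient_matches_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        h1 = rng.normal(size=(12, 3))
        h2 = 0.3 * h1 + rng.normal(size=(12, 3))
        val, g1, g2 = total_correlation_with_grad(h1, h2, k_corr=2, reg=1e-3)
        eps = 1e-6
        for h, g in ((h1, g1), (h2, g2)):
            num = np.zeros_like(h)
            for i in range(h.shape[0]):
                for j in range(h.shape[1]):
                    hp, hm = h.copy(), h.copy()
                    hp[i, j] += eps
                    hm[i, j] -= eps
                    if h is h1:
                        fp = total_correlation(hp, h2, k_corr=2, reg=1e-3)
                        fm = total_correlation(hm, h2, k_corr=2, reg=1e-3)
                    else:
                        fp = total_correlation(h1, hp, k_corr=2, reg=1e-3)
                        fm = total_correlation(h1, hm, k_corr=2, reg=1e-3)
                    num[i, j] = (fp - fm) / (2 * eps)
            rel = np.max(np.abs(num - g)) / np.max(np.abs(num))
            assert rel < 1e-4

    def test_degenerate_zero_variance_raises(self, rng):
        h1 = np.zeros((10, 2))
        h2 = rng.normal(size=(10, 2))
        with pytest.raises(SingularityError):
            total_correlation(h1, h2, reg=0.0)
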