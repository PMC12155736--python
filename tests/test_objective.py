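"""KL fidelity and relative difference prior: values against hand
calculations, analytic derivatives against central finite differences,
convexity, and the total-variation limit."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rdpet.objective import (
    ObjectiveBundle,
    RDPParams,
    kl_bin,
    kl_value,
    prox_nonneg,
)
from rdpet.sampling import partition_views


class TestKL:
    def test_zero_at_perfect_fit(self):
        assert kl_bin(1.0, 1.0) == 0.0
        assert kl_bin(3.7, 3.7) == pytest.approx(0.0, abs=1e-14)

    def test_zero_observed_branch(self):
        for s in (0.0, 0.5, 4.0):
            assert kl_bin(s, 0.0) == s

    def test_hand_value(self):
        assert kl_bin(2.0, 1.0) == pytest.approx(1 - np.log(2), rel=1e-12)

    def test_infinite_branches(self):
        assert kl_bin(0.0, 1.0) == np.inf
        assert kl_bin(-1.0, 0.5) == np.inf

    @given(st.floats(0.01, 100), st.floats(0.01, 100))
    @settings(deadline=None, derandomize=True)
    def test_nonnegative_and_zero_iff_equal(self, s, t):
        d = kl_bin(s, t)
        assert d >= 0
        if abs(s - t) > 1e-6 * max(s, t):
            assert d > 0

    def test_vectorized_sum_matches_scalar(self):
        rng = np.random.default_rng(0)
        s = rng.uniform(0.1, 5, 40)
        t = rng.poisson(s).astype(float)
        assert kl_value(s, t) == pytest.approx(
            sum(kl_bin(si, ti) for si, ti in zip(s, t)), rel=1e-12
        )


class TestProx:
    def test_clamps_negative_entries(self):
        np.testing.assert_array_equal(
            prox_nonneg(np.array([-1.0, 0.0, 2.0])), [0.0, 0.0, 2.0]
        )

    def test_idempotent_and_identity_on_feasible(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(20)
        p = prox_nonneg(x)
        np.testing.assert_array_equal(prox_nonneg(p), p)
        xpos = np.abs(x)
        np.testing.assert_array_equal(prox_nonneg(xpos), xpos)


@pytest.fixture
def rdp():
    return RDPParams(beta=1.0, gamma=2.0, epsilon=0.01, spacing=(2.5, 2.5))


class TestRDPValue:
    def test_constant_image_has_zero_prior(self, rdp):
        assert rdp.value(np.full((6, 6), 3.0)) == 0.0
        assert np.all(rdp.grad(np.full((6, 6), 3.0)) == 0.0)

    def test_two_voxel_hand_value(self):
        # single horizontal pair, unit weight/kappa: S = phi(3, 1)
        rdp = RDPParams(beta=1.0, gamma=1.0, epsilon=0.01, spacing=(1.0, 1.0))
        x = np.array([[2.0, 1.0]])
        expected = 1.0 / (3.0 + 1.0 + 0.01)
        assert rdp.value(x) == pytest.approx(expected, rel=1e-12)

    def test_tv_limit_at_low_activity(self):
        # for a nonnegative pair s >= |d|, so the sharpest case is the pair
        # (t, 0) where phi = t/(1 + gamma): S/t -> 1/(1 + gamma) as t -> 0,
        # which approaches the total-variation slope |d|/gamma for large gamma
        for gamma in (2.0, 100.0):
            rdp = RDPParams(beta=1.0, gamma=gamma, epsilon=1e-12,
                            spacing=(1.0, 1.0))
            for t in (1e-3, 1e-5):
                x = np.array([[t, 0.0]])
                assert rdp.value(x) / t == pytest.approx(1 / (1 + gamma), rel=1e-6)
        # TV-like regime: within 1% of |d|/gamma at gamma = 100
        assert 1 / (1 + 100.0) == pytest.approx(1 / 100.0, rel=1.1e-2)

    def test_negative_voxels_rejected(self, rdp):
        with pytest.raises(ValueError):
            rdp.value(np.array([[-0.1, 1.0]]))

    def test_convexity_on_random_pairs(self, rdp):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = rng.uniform(0, 3, (7, 7))
            z = rng.uniform(0, 3, (7, 7))
            lam = rng.uniform()
            lhs = rdp.value(lam * x + (1 - lam) * z)
            rhs = lam * rdp.value(x) + (1 - lam) * rdp.value(z)
            assert lhs <= rhs + 1e-10


class TestRDPDerivatives:
    @pytest.mark.parametrize("seed", range(5))
    def test_gradient_matches_finite_differences(self, rdp, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0.05, 3, (8, 8))
        g = rdp.grad(x)
        h = 1e-6
        for idx in [(0, 0), (3, 4), (7, 7), (5, 1)]:
            xp, xm = x.copy(), x.copy()
            xp[idx] += h
            xm[idx] -= h
            fd = (rdp.value(xp) - rdp.value(xm)) / (2 * h)
            assert abs(g[idx] - fd) < 1e-6

    @pytest.mark.parametrize("seed", range(5))
    def test_diag_hessian_matches_finite_differences(self, rdp, seed):
        rng = np.random.default_rng(10 + seed)
        x = rng.uniform(0.05, 3, (8, 8))
        hdiag = rdp.diag_hessian(x)
        h = 1e-5
        for idx in [(0, 0), (2, 6), (7, 3)]:
            xp, xm = x.copy(), x.copy()
            xp[idx] += h
            xm[idx] -= h
            fd = (rdp.grad(xp)[idx] - rdp.grad(xm)[idx]) / (2 * h)
            assert abs(hdiag[idx] - fd) < 1e-5

    def test_pair_exchange_symmetry(self):
        # swapping the two voxels swaps their partial derivatives (the prior
        # is symmetric in the pair; note d1 S + d2 S = 2 dphi/ds != 0, so the
        # partials are not antisymmetric: phi also depends on the sum)
        rdp = RDPParams(beta=1.0, gamma=2.0, epsilon=0.01, spacing=(1.0, 1.0))
        g = rdp.grad(np.array([[2.0, 1.0]]))
        gswap = rdp.grad(np.array([[1.0, 2.0]]))
        assert g[0, 0] == pytest.approx(gswap[0, 1], rel=1e-12)
        assert g[0, 1] == pytest.approx(gswap[0, 0], rel=1e-12)

    def test_diag_hessian_strictly_positive(self, rdp):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 2, (6, 6))
        assert np.all(rdp.diag_hessian(x) > 0)

    def test_kappa_scaling_is_quadratic(self):
        # scaling kappa by c multiplies S, its gradient and Hessian by c^2
        x = np.random.default_rng(4).uniform(0, 2, (5, 5))
        base = RDPParams(beta=1.0, gamma=2.0, epsilon=0.01, spacing=(1.0, 1.0))
        scaled = RDPParams(beta=1.0, gamma=2.0, epsilon=0.01,
                           kappa=np.full((5, 5), 3.0), spacing=(1.0, 1.0))
        np.testing.assert_allclose(scaled.value(x), 9.0 * base.value(x), rtol=1e-12)
        np.testing.assert_allclose(
            scaled.diag_hessian(x), 9.0 * base.diag_hessian(x), rtol=1e-12
        )

    def test_background_curvature_decreases_with_activity(self):
        # for a flat pair at level t the diagonal entry behaves as 2/(2t+eps)
        rdp = RDPParams(beta=1.0, gamma=2.0, epsilon=0.01, spacing=(1.0, 1.0))
        vals = [rdp.diag_hessian(np.full((1, 2), t))[0, 0] for t in (0.01, 1.0, 100.0)]
        assert vals[0] > vals[1] > vals[2]


class TestDataFidelity:
    def test_perfect_fit_gives_zero_value_and_gradient(self, tiny_bundle):
        # construct data that the model fits exactly: y = Ax + r, noise-free
        ds_model = tiny_bundle.model
        x = np.abs(np.random.default_rng(5).uniform(0.5, 2, ds_model.grid.shape))
        y = ds_model.forward(x) + tiny_bundle.r
        bundle = ObjectiveBundle(ds_model, y, tiny_bundle.r,
                                 tiny_bundle.scheme, tiny_bundle.rdp)
        val, grad = bundle.data_fidelity(x)
        assert val == pytest.approx(0.0, abs=1e-7)
        assert np.abs(grad).max() < 1e-9

    def test_subset_values_sum_to_full(self, tiny_bundle):
        rng = np.random.default_rng(6)
        x = rng.uniform(0.1, 2, tiny_bundle.model.grid.shape)
        vals = [tiny_bundle.data_fidelity(x, i)[0]
                for i in range(tiny_bundle.n_subsets)]
        full, _ = tiny_bundle.data_fidelity(x)
        assert sum(vals) == pytest.approx(full, rel=1e-10)

    def test_gradient_matches_finite_differences(self, tiny_bundle):
        rng = np.random.default_rng(7)
        x = rng.uniform(0.2, 2, tiny_bundle.model.grid.shape)
        _, g = tiny_bundle.data_fidelity(x)
        h = 1e-4
        for idx in [(2, 3), (8, 8), (12, 5)]:
            xp, xm = x.copy(), x.copy()
            xp[idx] += h
            xm[idx] -= h
            fd = (tiny_bundle.data_fidelity(xp)[0]
                  - tiny_bundle.data_fidelity(xm)[0]) / (2 * h)
            assert abs(g[idx] - fd) < 1e-5


class TestSubsetObjective:
    def test_subset_gradients_sum_to_full_gradient(self, tiny_bundle):
        rng = np.random.default_rng(8)
        x = rng.uniform(0.1, 2, tiny_bundle.model.grid.shape)
        total = sum(tiny_bundle.subset_gradient(x, i)
                    for i in range(tiny_bundle.n_subsets))
        _, full = tiny_bundle.objective(x)
        np.testing.assert_allclose(total, full, rtol=1e-9, atol=1e-12)

    def test_beta_zero_reduces_to_data_fidelity(self, tiny_dataset):
        ds = tiny_dataset
        scheme = partition_views(ds.model.geom.n_views, 3)
        rdp0 = RDPParams(beta=0.0, gamma=2.0, epsilon=0.05,
                         spacing=ds.model.grid.spacing)
        bundle = ObjectiveBundle(ds.model, ds.y, ds.r, scheme, rdp0)
        x = np.random.default_rng(9).uniform(0.1, 1, ds.model.grid.shape)
        v1, g1 = bundle.subset_objective(x, 1)
        v2, g2 = bundle.data_fidelity(x, 1)
        assert v1 == v2
        np.testing.assert_array_equal(g1, g2)

    def test_single_subset_is_full_objective(self, tiny_dataset):
        ds = tiny_dataset
        scheme = partition_views(ds.model.geom.n_views, 1)
        rdp = RDPParams(beta=1e-3, gamma=2.0, epsilon=0.05,
                        spacing=ds.model.grid.spacing)
        bundle = ObjectiveBundle(ds.model, ds.y, ds.r, scheme, rdp)
        x = np.random.default_rng(10).uniform(0.1, 1, ds.model.grid.shape)
        v1, g1 = bundle.subset_objective(x, 0)
        v2, g2 = bundle.objective(x)
        assert v1 == pytest.approx(v2, rel=1e-12)
        np.testing.assert_allclose(g1, g2, rtol=1e-12)

    def test_invalid_subset_index_rejected(self, tiny_bundle):
        with pytest.raises(IndexError):
            tiny_bundle.data_fidelity(
                np.ones(tiny_bundle.model.grid.shape), tiny_bundle.n_subsets
            )
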