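"""Fisher scores, Monte Carlo divergences and kernel-matrix properties."""

import numpy as np
import pytest
from scipy.special import digamma, gammaln

from ssdmix.em import fit_em
from ssdmix.kernels import (
    FisherKernel,
    MixtureDivergenceKernel,
    bhattacharyya_mc,
    bk_kernel_matrix,
    ensure_psd,
    fisher_kernel_matrix,
    fisher_score,
    skk_kernel_matrix,
    skl_divergence_mc,
)
from ssdmix.ssd import (
    FeatureBag,
    SSDMixture,
    SSDParams,
    mixture_log_density_many,
    ssd_sample,
)


def dirichlet_kl(a1, a2):
    """Closed-form KL between Dirichlet densities (oracle)."""
    a1, a2 = np.asarray(a1, float), np.asarray(a2, float)
    s1 = a1.sum()
    return float(
        gammaln(s1) - gammaln(a1).sum() - gammaln(a2.sum()) + gammaln(a2).sum()
        + (a1 - a2) @ (digamma(a1) - digamma(s1))
    )


def dirichlet_bc(a1, a2):
    """Closed-form Bhattacharyya coefficient between Dirichlets (oracle)."""
    a1, a2 = np.asarray(a1, float), np.asarray(a2, float)

    def logmvbeta(a):
        return gammaln(a).sum() - gammaln(a.sum())

    return float(np.exp(logmvbeta((a1 + a2) / 2) - 0.5 * logmvbeta(a1) - 0.5 * logmvbeta(a2)))


def dirichlet_limit_mixture(alpha):
    alpha = np.asarray(alpha, float)
    return SSDMixture([1.0], (SSDParams(alpha, np.ones(alpha.size) / alpha.size, 1.0),))


class TestFisherScore:
    def test_weight_gradient_formula(self, two_component_mixture, rng):
        """grad_pi_j = sum_i (Z_ij/pi_j - Z_i1/pi_1), normalized by bag size."""
        from ssdmix.em import e_step

        mix = two_component_mixture
        bag = FeatureBag("x", rng.dirichlet(np.ones(3), 10))
        z = e_step(bag.vectors, mix)
        manual = (z[:, 1] / mix.weights[1] - z[:, 0] / mix.weights[0]).sum() / bag.size
        fs = fisher_score(bag, mix)
        assert fs.grad_pi[0] == pytest.approx(manual, rel=1e-12)
        # hand arithmetic: responsibility column sums (4, 6) with pi=(0.5, 0.5)
        assert 6 / 0.5 - 4 / 0.5 == pytest.approx(4.0)

    def test_gradient_vanishes_at_single_component_mle(self):
        data = ssd_sample(SSDParams([5, 2, 3], [0.3, 0.3, 0.4], 1.2), 2000, 0)
        model = fit_em(data, 1, seed=0, tol=1e-9, m_step_maxiter=300).model
        fs = fisher_score(FeatureBag("x", data), model)
        assert np.max(np.abs(fs.grad_alpha)) < 1e-4

    def test_alpha_gradient_matches_finite_differences(self, two_component_mixture, rng):
        mix = two_component_mixture
        bag = FeatureBag("y", rng.dirichlet(np.ones(3), 40))
        fs = fisher_score(bag, mix)

        def bag_ll(alphas):
            comps = tuple(
                SSDParams(alphas[j], mix.components[j].beta, mix.components[j].b)
                for j in range(2)
            )
            return mixture_log_density_many(
                bag.vectors, SSDMixture(mix.weights, comps)
            ).sum()

        base = np.stack([c.alpha for c in mix.components])
        for j in range(2):
            for d in range(3):
                up, dn = base.copy(), base.copy()
                up[j, d] += 1e-6
                dn[j, d] -= 1e-6
                num = (bag_ll(up) - bag_ll(dn)) / 2e-6 / bag.size
                assert fs.grad_alpha[j, d] == pytest.approx(num, rel=1e-5, abs=1e-8)

    def test_empty_bag_rejected(self):
        with pytest.raises(ValueError):
            FeatureBag("e", np.empty((0, 3)))

    def test_score_length(self, two_component_mixture, rng):
        bag = FeatureBag("y", rng.dirichlet(np.ones(3), 15))
        fs = fisher_score(bag, two_component_mixture)
        assert fs.concatenated.size == (2 - 1) + 2 * 3


class TestFisherKernelMatrix:
    def test_symmetric_and_identical_bags(self, two_component_mixture, rng):
        v = rng.dirichlet(np.ones(3), 20)
        bags = [FeatureBag("a", v), FeatureBag("b", v), FeatureBag("c", rng.dirichlet(np.ones(3), 20))]
        gram = fisher_kernel_matrix(bags, two_component_mixture)
        np.testing.assert_allclose(gram, gram.T, atol=1e-9)
        np.testing.assert_allclose(gram[0], gram[1], atol=1e-12)
        assert np.all(np.diag(gram) >= 0)

    def test_orthogonal_scores_give_zero(self):
        u = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert u[0] @ u[1] == 0.0  # the Gram entry under identity information

    def test_estimator_fit_transform(self, rng):
        bags = [FeatureBag(f"i{i}", rng.dirichlet(np.ones(3), 25)) for i in range(6)]
        fk = FisherKernel(n_components=2, random_state=0)
        gram = fk.fit_transform(bags[:4])
        assert gram.shape == (4, 4)
        cross = fk.transform(bags[4:])
        assert cross.shape == (2, 4)


class TestDivergences:
    def test_self_divergence_exactly_zero(self, two_component_mixture):
        est, se = skl_divergence_mc(two_component_mixture, two_component_mixture, 200, 0)
        assert est == 0.0

    def test_self_affinity_exactly_one(self, two_component_mixture):
        est, se = bhattacharyya_mc(two_component_mixture, two_component_mixture, 200, 0)
        assert est == 1.0

    def test_skl_matches_dirichlet_closed_form(self):
        p = dirichlet_limit_mixture([3.0, 2.0, 4.0])
        q = dirichlet_limit_mixture([2.0, 5.0, 1.5])
        true = dirichlet_kl([3, 2, 4], [2, 5, 1.5]) + dirichlet_kl([2, 5, 1.5], [3, 2, 4])
        est, se = skl_divergence_mc(p, q, 20_000, 0)
        assert abs(est - true) < 3 * se

    def test_bc_matches_dirichlet_closed_form(self):
        p = dirichlet_limit_mixture([3.0, 2.0, 4.0])
        q = dirichlet_limit_mixture([2.0, 5.0, 1.5])
        true = dirichlet_bc([3, 2, 4], [2, 5, 1.5])
        est, se = bhattacharyya_mc(p, q, 20_000, 0)
        assert abs(est - true) < 3 * se

    def test_skl_nonnegative_over_random_pairs(self, rng):
        for _ in range(10):
            a1 = rng.uniform(0.5, 6, 3)
            a2 = rng.uniform(0.5, 6, 3)
            p, q = dirichlet_limit_mixture(a1), dirichlet_limit_mixture(a2)
            est, se = skl_divergence_mc(p, q, 2000, int(rng.integers(2**31)))
            assert est >= -3 * se

    def test_bc_bounded_by_one(self, rng):
        for _ in range(5):
            a1 = rng.uniform(0.5, 6, 3)
            a2 = rng.uniform(0.5, 6, 3)
            est, se = bhattacharyya_mc(
                dirichlet_limit_mixture(a1), dirichlet_limit_mixture(a2), 2000,
                int(rng.integers(2**31)),
            )
            assert est <= 1 + 3 * se

    def test_mc_error_scales_inverse_sqrt(self):
        """log SE vs log L slope is about -1/2."""
        p = dirichlet_limit_mixture([3.0, 2.0, 4.0])
        q = dirichlet_limit_mixture([2.0, 5.0, 1.5])
        ls = [100, 1000, 10_000]
        ses = [skl_divergence_mc(p, q, L, 0)[1] for L in ls]
        slope = np.polyfit(np.log(ls), np.log(ses), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.1)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            skl_divergence_mc(
                dirichlet_limit_mixture([1, 1]), dirichlet_limit_mixture([1, 1, 1]), 10
            )


@pytest.fixture(scope="module")
def models():
    return [
        dirichlet_limit_mixture([3.0, 2.0, 4.0]),
        dirichlet_limit_mixture([2.0, 5.0, 1.5]),
        dirichlet_limit_mixture([1.0, 1.0, 1.0]),
    ]


class TestKernelMatrices:

    @pytest.mark.parametrize("strategy", ["per_model", "per_pair"])
    def test_skk_matrix_properties(self, models, strategy):
        gram = skk_kernel_matrix(models, n_samples=500, seed=0, strategy=strategy)
        np.testing.assert_allclose(gram, gram.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(gram), 1.0)
        assert np.all(gram > 0) and np.all(gram <= 1 + 1e-12)

    def test_skk_b_factor_squares_entries(self, models):
        g1 = skk_kernel_matrix(models, B=1.0, n_samples=500, seed=0)
        g2 = skk_kernel_matrix(models, B=2.0, n_samples=500, seed=0)
        off = ~np.eye(3, dtype=bool)
        np.testing.assert_allclose(g2[off], g1[off] ** 2, rtol=1e-10)

    @pytest.mark.parametrize("strategy", ["per_model", "per_pair"])
    def test_bk_matrix_properties(self, models, strategy):
        gram = bk_kernel_matrix(models, n_samples=500, seed=0, strategy=strategy)
        np.testing.assert_allclose(gram, gram.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(gram), 1.0)
        assert np.all(gram > 0)

    def test_divergence_kernel_estimator(self, rng):
        bags = [
            FeatureBag(f"i{i}", ssd_sample(SSDParams([3, 2, 2], np.ones(3) / 3, 1.0), 30, i))
            for i in range(5)
        ]
        mk = MixtureDivergenceKernel(kind="skk", n_samples=300, random_state=0)
        gram = mk.fit_transform(bags[:3])
        assert gram.shape == (3, 3)
        assert np.linalg.eigvalsh(gram).min() >= -1e-8
        cross = mk.transform(bags[3:])
        assert cross.shape == (2, 3)


class TestEnsurePsd:
    def test_psd_input_unchanged(self):
        m = np.array([[2.0, 0.5], [0.5, 1.0]])
        np.testing.assert_allclose(ensure_psd(m, jitter=0.0), m, atol=1e-10)

    def test_negative_eigenvalue_clipped(self):
        m = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        out = ensure_psd(m, jitter=0.0)
        np.testing.assert_allclose(out, [[1.5, 1.5], [1.5, 1.5]], atol=1e-12)

    def test_output_symmetric_and_psd(self, rng):
        a = rng.normal(size=(6, 6))
        m = 0.5 * (a + a.T)
        out = ensure_psd(m)
        np.testing.assert_allclose(out, out.T, atol=1e-12)
        assert np.linalg.eigvalsh(out).min() >= -1e-8

    def test_asymmetric_raises(self):
        with pytest.raises(ValueError):
            ensure_psd(np.array([[1.0, 2.0], [0.0, 1.0]]))
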