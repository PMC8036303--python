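"""Density, sampler and simplex-utility tests for the SSD distribution."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import gammaln
from scipy.stats import dirichlet, ks_1samp

from ssdmix.ssd import (
    FeatureBag,
    SSDMixture,
    SSDParams,
    mixture_log_density,
    mixture_log_density_many,
    mixture_sample,
    project_to_simplex,
    ssd_log_density,
    ssd_log_density_many,
    ssd_sample,
)


def scaled_dirichlet_logpdf(y, alpha, beta):
    """Independent closed form of the b=1 (scaled Dirichlet) special case."""
    y, alpha, beta = map(np.asarray, (y, alpha, beta))
    a_plus = alpha.sum()
    return (
        gammaln(a_plus)
        - gammaln(alpha).sum()
        - alpha @ np.log(beta)
        + (alpha - 1) @ np.log(y)
        - a_plus * np.log(np.sum(y / beta))
    )


class TestDensity:
    @pytest.mark.parametrize(
        "y, alpha, beta, b, expected",
        [
            ((0.3, 0.7), (1, 1), (0.5, 0.5), 1.0, 0.0),          # uniform on S_2
            ((0.5, 0.5), (1, 1), (0.5, 0.5), 2.0, np.log(0.5)),  # hand substitution
            ((0.5, 0.5), (2, 1), (0.5, 0.5), 1.0, 0.0),          # Dirichlet(2,1) at 0.5
        ],
    )
    def test_pointwise_values(self, y, alpha, beta, b, expected):
        theta = SSDParams(np.array(alpha, float), np.array(beta, float), b)
        assert ssd_log_density(np.array(y), theta) == pytest.approx(expected, abs=1e-12)

    def test_dimension_mismatch_raises(self):
        theta = SSDParams([1.0, 1.0], [0.5, 0.5], 1.0)
        with pytest.raises(ValueError):
            ssd_log_density(np.array([0.2, 0.3, 0.5]), theta)

    def test_nonpositive_entry_raises(self):
        theta = SSDParams([1.0, 1.0], [0.5, 0.5], 1.0)
        with pytest.raises(ValueError):
            ssd_log_density(np.array([0.0, 1.0]), theta)

    def test_reduces_to_scaled_dirichlet_at_b_one(self, rng):
        """b=1 must match the scaled Dirichlet closed form pointwise."""
        alpha = np.array([2.5, 1.2, 3.7])
        beta = np.array([0.2, 0.45, 0.35])
        theta = SSDParams(alpha, beta, 1.0)
        pts = rng.dirichlet(np.ones(3), 100)
        ours = ssd_log_density_many(pts, theta)
        ref = [scaled_dirichlet_logpdf(p, alpha, beta) for p in pts]
        np.testing.assert_allclose(ours, ref, atol=1e-10)

    def test_reduces_to_dirichlet_with_uniform_beta(self, rng):
        alpha = np.array([2.5, 1.2, 3.7])
        theta = SSDParams(alpha, np.ones(3) / 3, 1.0)
        pts = rng.dirichlet(np.ones(3), 100)
        ours = ssd_log_density_many(pts, theta)
        ref = [dirichlet.logpdf(p, alpha) for p in pts]
        np.testing.assert_allclose(ours, ref, atol=1e-10)

    def test_normalizes_on_s2(self, skewed_params):
        for theta in skewed_params:
            total, _ = quad(
                lambda t: np.exp(ssd_log_density(np.array([t, 1 - t]), theta)),
                1e-9, 1 - 1e-9, limit=200,
            )
            assert total == pytest.approx(1.0, abs=1e-3)


class TestSampler:
    def test_empty_draw(self):
        theta = SSDParams([1.0, 2.0], [0.5, 0.5], 1.0)
        assert ssd_sample(theta, 0, 0).shape == (0, 2)

    def test_dirichlet_moment(self):
        """b=1 with uniform beta is a Dirichlet; check E[y_1] = alpha_1/alpha+."""
        theta = SSDParams([3.0, 2.0], [0.5, 0.5], 1.0)
        y = ssd_sample(theta, 10_000, 0)
        se = y[:, 0].std() / np.sqrt(10_000)
        assert abs(y[:, 0].mean() - 0.6) < 3 * se

    def test_deterministic_under_seed(self):
        theta = SSDParams([2.0, 1.0, 1.5], [0.3, 0.3, 0.4], 0.7)
        np.testing.assert_array_equal(ssd_sample(theta, 50, 9), ssd_sample(theta, 50, 9))

    def test_outputs_on_simplex(self, skewed_params_3d):
        for theta in skewed_params_3d:
            y = ssd_sample(theta, 200, 1)
            assert np.all(y > 0)
            np.testing.assert_allclose(y.sum(axis=1), 1.0, atol=1e-9)

    def test_matches_density_distribution(self):
        """KS test of sampled first coordinates vs the integrated density."""
        theta = SSDParams([3.0, 1.5], [0.2, 0.8], 0.5)
        y = ssd_sample(theta, 5000, 3)
        grid = np.linspace(1e-9, 1 - 1e-9, 20001)
        pdf = np.exp(ssd_log_density_many(np.column_stack([grid, 1 - grid]), theta))
        cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) / 2 * np.diff(grid))])
        cdf /= cdf[-1]
        res = ks_1samp(y[:, 0], lambda q: np.interp(q, grid, cdf))
        assert res.pvalue > 0.01


class TestMixture:
    def test_single_component_equals_component(self, rng):
        theta = SSDParams([2.0, 3.0], [0.4, 0.6], 1.2)
        model = SSDMixture([1.0], (theta,))
        y = rng.dirichlet([2, 2], 10)
        np.testing.assert_allclose(
            mixture_log_density_many(y, model), ssd_log_density_many(y, theta), rtol=1e-12
        )

    def test_duplicate_components_collapse(self):
        theta = SSDParams([2.0, 3.0], [0.4, 0.6], 1.2)
        model = SSDMixture([0.5, 0.5], (theta, theta))
        y = np.array([0.3, 0.7])
        assert mixture_log_density(y, model) == pytest.approx(ssd_log_density(y, theta))

    def test_logsumexp_bounds(self, two_component_mixture, rng):
        model = two_component_mixture
        for y in rng.dirichlet(np.ones(3), 20):
            comp = [
                np.log(w) + ssd_log_density(y, c)
                for w, c in zip(model.weights, model.components)
            ]
            val = mixture_log_density(y, model)
            assert max(comp) <= val <= max(
                ssd_log_density(y, c) for c in model.components
            ) + np.log(2)

    def test_label_switching_invariance(self, two_component_mixture, rng):
        model = two_component_mixture
        flipped = SSDMixture(model.weights[::-1].copy(), model.components[::-1])
        y = rng.dirichlet(np.ones(3), 50)
        np.testing.assert_allclose(
            mixture_log_density_many(y, model),
            mixture_log_density_many(y, flipped),
            atol=1e-12,
        )

    def test_mixture_sampling_deterministic(self, two_component_mixture):
        a = mixture_sample(two_component_mixture, 30, 4)
        b = mixture_sample(two_component_mixture, 30, 4)
        np.testing.assert_array_equal(a, b)


class TestSimplexProjection:
    @pytest.mark.parametrize(
        "v, eps, expected",
        [
            ((1, 1, 2), 0.0, (0.25, 0.25, 0.5)),
            ((0, 1), 0.01, (0.01 / 1.02, 1.01 / 1.02)),
            ((-1, 0, 3), 0.01, (0.01 / 5.03, 1.01 / 5.03, 4.01 / 5.03)),
        ],
    )
    def test_examples(self, v, eps, expected):
        np.testing.assert_allclose(
            project_to_simplex(np.array(v, float), eps), expected, rtol=1e-12
        )

    def test_degenerate_raises(self):
        with pytest.raises(ValueError):
            project_to_simplex(np.array([0.0, 0.0, 0.0]), 0.0)

    def test_output_on_simplex(self, rng):
        v = rng.normal(size=(30, 5))
        out = project_to_simplex(v, 1e-6)
        assert np.all(out > 0)
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-12)


class TestValidation:
    def test_bag_requires_shared_dimension(self):
        with pytest.raises(ValueError):
            FeatureBag("x", np.array([[0.5, 0.5], [0.2, 0.3]]))

    def test_mixture_weights_must_normalize(self):
        theta = SSDParams([1.0, 1.0], [0.5, 0.5], 1.0)
        with pytest.raises(ValueError):
            SSDMixture([0.5, 0.6], (theta, theta))

    def test_params_require_positive_alpha(self):
        with pytest.raises(ValueError):
            SSDParams([1.0, -1.0], [0.5, 0.5], 1.0)
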