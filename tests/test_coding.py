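import numpy as np
import pytest

from fitcode.coding import (FlatObjectiveWarning, escort_response,
                            exponents_from, optimize_escort_exponent,
                            prob_error_loss, quantize, response_density,
                            reward_loss)
from fitcode.domains import RewardMap
from fitcode.errors import ExponentRangeError


class TestEscortResponse:
    def test_uniform_prior_identity_ramp(self, uniform_prior):
        for gamma in (0.5, 1.0, 1.5):
            h = escort_response(uniform_prior, gamma)
            np.testing.assert_allclose(h.values, uniform_prior.grid,
                                       atol=1e-9)

    def test_gamma_one_is_prior_cdf(self, orientation_prior):
        h = escort_response(orientation_prior, 1.0)
        np.testing.assert_allclose(h.values, orientation_prior.cdf_values(),
                                   atol=1e-10)

    def test_piecewise_closed_form(self, piecewise_prior):
        # f^(2/3) integrates to 1.6^(2/3)/2 on the left half, 0.4^(2/3)/2 on
        # the right: h(0.5) = 1.368.../(1.368...+0.543...) ~= 0.716
        h = escort_response(piecewise_prior, 2.0 / 3.0)
        left = 1.6 ** (2 / 3) * 0.5
        right = 0.4 ** (2 / 3) * 0.5
        assert float(h(0.5)) == pytest.approx(left / (left + right), abs=2e-3)

    def test_boundary_values(self, orientation_prior):
        h = escort_response(orientation_prior, 0.7)
        assert h.values[0] == 0.0
        assert h.values[-1] == pytest.approx(1.0)
        assert np.all(np.diff(h.values) >= 0)

    def test_escort_self_consistency(self, orientation_prior):
        """escort(f, gamma) == escort(normalized f^gamma, 1)."""
        from fitcode.domains import Prior
        gamma = 0.6
        raised = orientation_prior.density ** gamma
        raised /= np.trapezoid(raised, orientation_prior.grid)
        prior_raised = Prior(orientation_prior.domain, raised)
        h1 = escort_response(orientation_prior, gamma)
        h2 = escort_response(prior_raised, 1.0)
        assert np.max(np.abs(h1.values - h2.values)) < 1e-10

    def test_invalid_gamma(self, uniform_prior):
        with pytest.raises(ExponentRangeError):
            escort_response(uniform_prior, 0.0)


class TestExponentAlgebra:
    def test_infomax_limit(self):
        es = exponents_from(p=0.0)
        assert es.gamma == 1.0
        assert es.q == pytest.approx(2.0)  # beta_cap = 0.5 default

    def test_reward_code(self):
        es = exponents_from(gamma=2.0 / 3.0)
        assert es.p == pytest.approx(0.5)
        assert es.q == pytest.approx(4.0 / 3.0)

    def test_consistency_relations(self):
        for gamma in (0.4, 2.0 / 3.0, 1.0):
            es = exponents_from(gamma=gamma, beta_cap=0.5)
            assert es.gamma == pytest.approx(1.0 / (1.0 + es.p), abs=1e-12)
            assert es.q == pytest.approx(es.gamma / es.beta_cap, abs=1e-12)
            assert es.gamma == pytest.approx(
                es.beta_cap / (es.beta_cap + es.alpha_obj), abs=1e-12)
            assert es.q == pytest.approx(
                1.0 / (es.beta_cap + es.alpha_obj), abs=1e-12)

    @pytest.mark.parametrize("kwargs", [dict(p=-0.1), dict(gamma=0.0),
                                        dict(gamma=1.2), dict(),
                                        dict(p=1.0, gamma=0.5)])
    def test_range_errors(self, kwargs):
        with pytest.raises(ExponentRangeError):
            exponents_from(**kwargs)


class TestQuantize:
    def test_uniform_quarters(self, uniform_prior):
        code = quantize(escort_response(uniform_prior, 1.0), 4)
        np.testing.assert_allclose(code.boundaries, [0.25, 0.5, 0.75],
                                   atol=1e-9)

    def test_infomax_boundaries_are_deciles(self, orientation_prior):
        code = quantize(escort_response(orientation_prior, 1.0), 10)
        deciles = orientation_prior.ppf(np.arange(1, 10) / 10)
        np.testing.assert_allclose(code.boundaries, deciles, atol=1e-6)

    def test_piecewise_median_boundary(self, piecewise_prior):
        # CDF reaches 0.5 where 1.6 s = 0.5, i.e. s = 0.3125
        code = quantize(escort_response(piecewise_prior, 1.0), 2)
        assert code.boundaries[0] == pytest.approx(0.3125, abs=2e-3)

    def test_too_few_levels(self, uniform_prior):
        with pytest.raises(ValueError):
            quantize(escort_response(uniform_prior, 1.0), 1)


class TestLossFunctionals:
    def test_uniform_error_loss(self, uniform_prior):
        for n in (4, 10):
            code = quantize(escort_response(uniform_prior, 1.0), n)
            assert prob_error_loss(uniform_prior, code) == pytest.approx(
                1.0 / (2 * n), abs=1e-6)

    def test_piecewise_error_loss_masses(self, piecewise_prior):
        from fitcode.coding import QuantizedCode
        code = QuantizedCode(n=2, boundaries=np.array([0.5]))
        # masses (0.8, 0.2) -> (0.64 + 0.04) / 2 = 0.34
        assert prob_error_loss(piecewise_prior, code) == pytest.approx(
            0.34, abs=2e-3)

    def test_error_loss_monotone_in_levels(self, orientation_prior):
        losses = [prob_error_loss(
            orientation_prior,
            quantize(escort_response(orientation_prior, 1.0), n))
            for n in (2, 4, 8, 16, 32)]
        assert np.all(np.diff(losses) < 0)

    def test_uniform_linear_reward_loss(self, uniform_prior):
        reward = RewardMap.linear(uniform_prior.domain, 0.0, 1.0)
        code = quantize(escort_response(uniform_prior, 1.0), 10)
        # E|s1-s2| within a width-w level is w/3: loss = 1/(6 n^2)
        assert reward_loss(uniform_prior, code, reward) == pytest.approx(
            1.0 / 600.0, rel=1e-3)

    def test_constant_reward_gives_zero_loss(self, orientation_prior):
        reward = RewardMap.constant(orientation_prior.domain, 15.0)
        code = quantize(escort_response(orientation_prior, 1.0), 8)
        assert reward_loss(orientation_prior, code, reward) == pytest.approx(
            0.0, abs=1e-12)

    def test_reward_loss_monotone_in_levels(self, piecewise_prior):
        reward = RewardMap.linear(piecewise_prior.domain, 0.0, 1.0)
        losses = [reward_loss(
            piecewise_prior,
            quantize(escort_response(piecewise_prior, 2 / 3), n), reward)
            for n in (2, 4, 8, 16, 32)]
        assert np.all(np.diff(losses) < 0)

    def test_monte_carlo_oracle(self, piecewise_prior, rng):
        """Both loss functionals match pairwise simulation with fair-coin
        tie-breaks within 3 standard errors."""
        reward = RewardMap.linear(piecewise_prior.domain, 0.0, 1.0)
        h = escort_response(piecewise_prior, 2.0 / 3.0)
        code = quantize(h, 2)
        n_pairs = 200_000
        s = piecewise_prior.ppf(rng.random((n_pairs, 2)))
        lev = np.digitize(s, code.boundaries)
        same = lev[:, 0] == lev[:, 1]
        coin = rng.random(n_pairs) < 0.5
        # error: same level and coin picks the lower-valued alternative
        err = same & coin
        p_err = err.mean()
        se_p = np.sqrt(p_err * (1 - p_err) / n_pairs)
        assert prob_error_loss(piecewise_prior, code) == pytest.approx(
            0.5 * same.mean(), abs=3 * 0.5 * np.sqrt(
                same.mean() * (1 - same.mean()) / n_pairs))
        lost = np.where(err, np.abs(reward(s[:, 0]) - reward(s[:, 1])), 0.0)
        se_r = lost.std() / np.sqrt(n_pairs)
        assert reward_loss(piecewise_prior, code, reward) == pytest.approx(
            lost.mean(), abs=3 * se_r)


class TestOptimizeEscortExponent:
    def test_flat_prior_warns(self, uniform_prior):
        with pytest.warns(FlatObjectiveWarning):
            optimize_escort_exponent(uniform_prior, None, "accuracy", 8,
                                     gamma_grid=np.array([0.5, 1.0]),
                                     refine=False)

    def test_refinement_agrees_with_grid(self, orientation_prior):
        reward = RewardMap.linear(orientation_prior.domain, 0.0, 1.0)
        fine = np.arange(0.3, 1.5, 0.01)
        g_grid, _ = optimize_escort_exponent(orientation_prior, reward,
                                             "reward", 16, gamma_grid=fine,
                                             refine=False)
        g_ref, _ = optimize_escort_exponent(orientation_prior, reward,
                                            "reward", 16)
        assert abs(g_grid - g_ref) <= 0.01 + 1e-9


class TestResponseDensity:
    def test_infomax_equalizes(self, orientation_prior):
        h = escort_response(orientation_prior, 1.0)
        r, g = response_density(orientation_prior, h)
        interior = (r > 0.02) & (r < 0.98)
        np.testing.assert_allclose(g[interior], 1.0, rtol=1e-3)

    def test_density_integrates_to_one(self, piecewise_prior):
        h = escort_response(piecewise_prior, 2.0 / 3.0)
        r, g = response_density(piecewise_prior, h)
        assert np.trapezoid(g, r) == pytest.approx(1.0, abs=1e-4)

    def test_sampling_oracle(self, piecewise_prior, rng):
        h = escort_response(piecewise_prior, 2.0 / 3.0)
        r, g = response_density(piecewise_prior, h)
        samples = h(piecewise_prior.ppf(rng.random(200_000)))
        hist, edges = np.histogram(samples, bins=20, range=(0, 1),
                                   density=True)
        # expected bin heights by integrating g over each bin (the
        # push-forward density has a step where the prior density jumps)
        fine = np.linspace(0, 1, 4001)
        gf = np.interp(fine, r, g)
        cum = np.concatenate([[0], np.cumsum(
            0.5 * (gf[1:] + gf[:-1]) * np.diff(fine))])
        expected = np.diff(np.interp(edges, fine, cum)) / np.diff(edges)
        se = np.sqrt(np.maximum(hist, 0.1) / (200_000 * np.diff(edges)))
        assert np.all(np.abs(hist - expected) < 3 * se + 0.05)
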