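import numpy as np
import pytest

from fitcode.observer import (BehaviorParams, ObserverParams,
                              bias_constant_pair, capacity_for_variance,
                              choice_probability, encode, estimate_moments,
                              fisher_information, matched_capacity_params,
                              posterior_mean_estimate,
                              simulate_estimation_report)


class TestFisherInformation:
    def test_flat_allocation_at_q_zero(self, orientation_prior):
        p = ObserverParams(k=3.0, q=0.0)
        J = fisher_information([0.0, 22.5, 45.0], orientation_prior, p)
        np.testing.assert_allclose(J, 3.0)

    def test_cardinal_oblique_ratio(self, orientation_prior):
        # J(0)/J(45) = (f(0)/f(45))^q = ((a+1)/(a-1))^q; a=1.85, q=2
        p = ObserverParams(k=1.0, q=2.0)
        J0 = fisher_information(0.0, orientation_prior, p)
        J45 = fisher_information(45.0, orientation_prior, p)
        assert J0 / J45 == pytest.approx((2.85 / 0.85) ** 2, rel=1e-3)

    def test_linearity_in_k(self, orientation_prior):
        J1 = fisher_information(30.0, orientation_prior,
                                ObserverParams(k=10.0, q=1.5))
        J2 = fisher_information(30.0, orientation_prior,
                                ObserverParams(k=20.0, q=1.5))
        assert J2 == pytest.approx(2 * J1)

    def test_negative_q_rejected(self):
        with pytest.raises(ValueError):
            ObserverParams(k=1.0, q=-0.5)


class TestEncode:
    def test_seed_determinism(self, orientation_prior):
        p = ObserverParams(k=100.0, q=1.0)
        r1 = encode(np.full(10, 30.0), orientation_prior, p,
                    np.random.default_rng(7))
        r2 = encode(np.full(10, 30.0), orientation_prior, p,
                    np.random.default_rng(7))
        np.testing.assert_array_equal(r1, r2)

    def test_empirical_variance(self, orientation_prior, rng):
        p = ObserverParams(k=200.0, q=1.0)
        s0 = 25.0
        r = encode(np.full(50_000, s0), orientation_prior, p, rng)
        expected = 1.0 / fisher_information(s0, orientation_prior, p)
        se = expected * np.sqrt(2.0 / 50_000)
        assert r.var() == pytest.approx(expected, abs=3 * se)

    def test_infinite_capacity_limit(self, orientation_prior, rng):
        p = ObserverParams(k=1e12, q=1.0)
        r = encode(np.full(100, 30.0), orientation_prior, p, rng)
        np.testing.assert_allclose(r, 30.0, atol=1e-3)


class TestPosteriorMean:
    def test_flat_prior_high_snr_tracks_response(self, uniform_prior):
        p = ObserverParams(k=1e6, q=1.0)
        for r in (0.2, 0.5, 0.8):
            assert posterior_mean_estimate(r, uniform_prior, p) == \
                pytest.approx(r, abs=1e-3)

    def test_mc_agrees_with_closed_form(self, orientation_prior, rng):
        q = 4.0 / 3.0
        k = capacity_for_variance(orientation_prior, q, 2.0, 45.0)
        p = ObserverParams(k=k, q=q)
        for s0 in (10.0, 22.5):
            m = estimate_moments(s0, orientation_prior, p)
            shat = posterior_mean_estimate(
                encode(np.full(8000, s0), orientation_prior, p, rng),
                orientation_prior, p)
            se = 3 * shat.std() / np.sqrt(len(shat))
            assert shat.mean() - s0 == pytest.approx(float(m.bias), abs=se)


class TestEstimateMoments:
    def test_zero_bias_at_q_one(self, orientation_prior):
        p = ObserverParams(k=500.0, q=1.0)
        m = estimate_moments(np.linspace(1, 89, 20), orientation_prior, p)
        np.testing.assert_allclose(m.bias, 0.0, atol=1e-12)

    def test_zero_bias_at_cardinal_and_oblique(self, orientation_prior):
        p = ObserverParams(k=500.0, q=2.0)
        m = estimate_moments(np.array([0.0, 45.0, 90.0]),
                             orientation_prior, p)
        np.testing.assert_allclose(m.bias, 0.0, atol=1e-10)

    def test_variance_ratio(self, orientation_prior):
        p = ObserverParams(k=1000.0, q=4.0 / 3.0)
        v0 = float(estimate_moments(0.0, orientation_prior, p).variance)
        v45 = float(estimate_moments(45.0, orientation_prior, p).variance)
        assert v45 / v0 == pytest.approx((2.85 / 0.85) ** (4 / 3), rel=1e-6)

    def test_mean_is_s0_plus_bias(self, orientation_prior):
        p = ObserverParams(k=800.0, q=1.5)
        s0 = np.array([12.0, 57.0])
        m = estimate_moments(s0, orientation_prior, p)
        np.testing.assert_allclose(m.mean, s0 + m.bias)

    def test_q_zero_rejected(self, orientation_prior):
        with pytest.raises(ValueError):
            estimate_moments(10.0, orientation_prior,
                             ObserverParams(k=1.0, q=0.0))

    def test_analytic_matches_grid_derivative(self, orientation_prior):
        """The closed-form bias equals the generic finite-difference form."""
        from fitcode.domains import Prior
        p = ObserverParams(k=2000.0, q=1.7)
        generic = Prior(orientation_prior.domain, orientation_prior.density)
        s0 = np.array([15.0, 30.0, 60.0])
        analytic = estimate_moments(s0, orientation_prior, p).bias
        numeric = estimate_moments(s0, generic, p).bias
        np.testing.assert_allclose(analytic, numeric, rtol=1e-3)


class TestBiasConstants:
    def test_zero_at_q_one(self):
        c1, c2 = bias_constant_pair(1.0, 3.0)
        assert c1 == 0.0 and c2 == 0.0

    @pytest.mark.parametrize("q", [0.5, 0.75, 1.33, 2.0])
    def test_forms_agree_in_working_range(self, q):
        c1, c2 = bias_constant_pair(q, 1.0)
        assert c1 == pytest.approx(c2, abs=0.06)

    def test_k_scaling(self):
        c1a, c2a = bias_constant_pair(2.0, 1.0)
        c1b, c2b = bias_constant_pair(2.0, 2.0)
        assert c1b == pytest.approx(c1a / 2) and c2b == pytest.approx(c2a / 2)


class TestChoiceProbability:
    def test_symmetric_stimuli(self, diagonality_prior):
        p = ObserverParams(k=100.0, q=2.0)
        assert choice_probability(20.0, 20.0, diagonality_prior, p) == \
            pytest.approx(0.5)

    def test_full_lapse_is_coin_flip(self, diagonality_prior):
        p = ObserverParams(k=100.0, q=2.0)
        b = BehaviorParams(lapse=1.0, side_bias=2.0)
        assert choice_probability(40.0, 5.0, diagonality_prior, p, b) == \
            pytest.approx(0.5)

    def test_swap_symmetry(self, diagonality_prior):
        p = ObserverParams(k=100.0, q=2.0)
        p12 = choice_probability(30.0, 10.0, diagonality_prior, p)
        p21 = choice_probability(10.0, 30.0, diagonality_prior, p)
        assert p12 + p21 == pytest.approx(1.0, abs=1e-12)

    def test_matches_monte_carlo(self, diagonality_prior, rng):
        p = ObserverParams(
            k=capacity_for_variance(diagonality_prior, 2.0, 4.0, 45.0),
            q=2.0)
        s1, s2 = 25.0, 20.0
        n = 40_000
        sh1 = posterior_mean_estimate(
            encode(np.full(n, s1), diagonality_prior, p, rng),
            diagonality_prior, p)
        sh2 = posterior_mean_estimate(
            encode(np.full(n, s2), diagonality_prior, p, rng),
            diagonality_prior, p)
        freq = np.mean(sh1 > sh2)
        pred = float(choice_probability(s1, s2, diagonality_prior, p))
        se = np.sqrt(freq * (1 - freq) / n)
        # closed-form moments carry O(1/k) error on top of MC noise
        assert pred == pytest.approx(freq, abs=3 * se + 0.01)


class TestEstimationReport:
    def test_noise_free_report_is_stimulus(self, orientation_prior, rng):
        p = ObserverParams(k=1e10, q=1.0)
        rep = simulate_estimation_report(40.0, orientation_prior, p, 0.0, rng)
        # exact up to the decoding-grid resolution (180/2047 degrees)
        assert rep == pytest.approx(40.0, abs=0.1)

    def test_motor_noise_adds_variance(self, orientation_prior, rng):
        q = 4.0 / 3.0
        k = capacity_for_variance(orientation_prior, q, 2.0, 45.0)
        p = ObserverParams(k=k, q=q)
        s0 = 22.5
        motor_sd = 2.0
        reps = simulate_estimation_report(np.full(8000, s0),
                                          orientation_prior, p, motor_sd,
                                          rng)
        expected = float(estimate_moments(s0, orientation_prior, p).variance
                         ) + motor_sd ** 2
        se = expected * np.sqrt(2.0 / 8000)
        assert reps.var() == pytest.approx(expected, abs=3 * se + 0.05)

    def test_negative_motor_sd_rejected(self, orientation_prior, rng):
        with pytest.raises(ValueError):
            simulate_estimation_report(10.0, orientation_prior,
                                       ObserverParams(k=10.0, q=1.0),
                                       -1.0, rng)


class TestPredictionPatterns:
    """Sign structure of the model predictions for capacity and exponent."""

    def test_lower_q_shifts_precision_to_obliques(self, diagonality_prior):
        base = ObserverParams(
            k=capacity_for_variance(diagonality_prior, 2.0, 4.0, 45.0),
            q=2.0)
        low_q = matched_capacity_params(diagonality_prior, base, 4.0 / 3.0)
        v = lambda pr, s: float(estimate_moments(s, diagonality_prior,
                                                 pr).variance)
        assert v(low_q, 44.0) < v(base, 44.0)   # oblique variance drops
        assert v(low_q, 1.0) > v(base, 1.0)     # cardinal variance rises
        # oblique pair accuracy rises, cardinal pair accuracy falls
        pc = lambda pr, a, b: float(choice_probability(a, b,
                                                       diagonality_prior, pr))
        assert pc(low_q, 42.0, 38.0) > pc(base, 42.0, 38.0)
        assert pc(low_q, 7.0, 3.0) < pc(base, 7.0, 3.0)

    def test_higher_k_helps_everywhere(self, diagonality_prior):
        lo = ObserverParams(k=50.0, q=2.0)
        hi = ObserverParams(k=200.0, q=2.0)
        for s in (2.0, 22.0, 43.0):
            vlo = float(estimate_moments(s, diagonality_prior, lo).variance)
            vhi = float(estimate_moments(s, diagonality_prior, hi).variance)
            assert vhi < vlo
        for a, b in ((42.0, 38.0), (7.0, 3.0)):
            assert choice_probability(a, b, diagonality_prior, hi) > \
                choice_probability(a, b, diagonality_prior, lo)
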