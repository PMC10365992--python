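import numpy as np
import pandas as pd
import pytest

from fitcode.domains import make_orientation_prior
from fitcode.observer import (ObserverParams, capacity_for_variance,
                              matched_capacity_params)
from fitcode.synth import (DIAGONALITY_BIN_EDGES, ERROR_DISCARD_DEG,
                           SessionConfig, StaircaseState, bin_summaries,
                           capacity_for_separation_accuracy,
                           filter_estimation, sample_stimuli,
                           signed_estimation_error,
                           simulate_decision_session,
                           simulate_estimation_session, staircase_update)


class TestStaircase:
    def test_alternating_outcomes_drift_up(self):
        """A correct/incorrect alternation nets +2/3 of an up-step per
        pair (the observer is below the 75% target)."""
        s = StaircaseState(difficulty=10.0, step_up=1.5)
        for _ in range(6):
            s = staircase_update(s, True)
            s = staircase_update(s, False)
        assert s.difficulty == pytest.approx(10.0 + 6 * (2 / 3) * 1.5)

    def test_bounds_respected(self, rng):
        s = StaircaseState(difficulty=10.0)
        for _ in range(10_000):
            s = staircase_update(s, bool(rng.random() < 0.5))
            assert s.floor <= s.difficulty <= s.ceiling

    def test_stationary_at_75_percent(self, rng):
        """Driven by an oracle answering correctly 75% of the time, the
        expected drift is zero (stochastic-approximation fixed point)."""
        s = StaircaseState(difficulty=15.0, step_up=0.9)
        traj = []
        for _ in range(4000):
            s = staircase_update(s, bool(rng.random() < 0.75))
            traj.append(s.difficulty)
        drift = np.mean(traj[2000:]) - np.mean(traj[:2000])
        assert abs(drift) < 2.0


class TestSampleStimuli:
    def test_ks_distance_to_analytic_cdf(self, orientation_prior, rng):
        draws = sample_stimuli(orientation_prior, 100_000, rng)
        ks = np.max(np.abs(np.sort(orientation_prior.cdf(draws))
                           - np.arange(1, 100_001) / 100_000))
        assert ks < 0.01

    def test_flat_prior_draws_uniform(self, rng):
        prior = make_orientation_prior(1e6)
        draws = sample_stimuli(prior, 50_000, rng)
        ks = np.max(np.abs(np.sort(draws) / 180.0
                           - np.arange(1, 50_001) / 50_000))
        assert ks < 0.01

    def test_seed_reproducibility(self, orientation_prior):
        d1 = sample_stimuli(orientation_prior, 100,
                            np.random.default_rng(11))
        d2 = sample_stimuli(orientation_prior, 100,
                            np.random.default_rng(11))
        np.testing.assert_array_equal(d1, d2)


class TestDecisionSession:
    def test_reward_context_payoff_map(self):
        cfg = SessionConfig(context="reward", n_decision_trials=300,
                            observer=ObserverParams(k=105.0, q=2.0), seed=2)
        df = simulate_decision_session(cfg)
        chosen_d = np.where(df["choice"] == 1, df["d1"], df["d2"])
        np.testing.assert_allclose(df["payoff"], 1.0 + chosen_d)
        assert df["payoff"].between(1.0, 46.0).all()

    def test_accuracy_context_payoff(self):
        cfg = SessionConfig(context="accuracy", n_decision_trials=200,
                            observer=ObserverParams(k=105.0, q=2.0), seed=3)
        df = simulate_decision_session(cfg)
        assert set(df["payoff"].unique()) <= {0.0, 15.0}
        assert (df["payoff"].sum()
                == pytest.approx(15.0 * df["correct"].sum()))

    def test_ideal_observer_saturates(self):
        cfg = SessionConfig(context="accuracy", n_decision_trials=120,
                            observer=ObserverParams(k=1e12, q=1.0), seed=4)
        df = simulate_decision_session(cfg)
        assert df["correct"].all()

    def test_phase_labels(self):
        cfg = SessionConfig(context="accuracy", n_decision_trials=250,
                            observer=ObserverParams(k=105.0, q=2.0), seed=5)
        df = simulate_decision_session(cfg)
        assert (df.loc[df["trial"] <= 200, "phase"] == "early").all()
        assert (df.loc[df["trial"] > 200, "phase"] == "late").all()

    def test_determinism(self):
        cfg = SessionConfig(context="reward", n_decision_trials=100,
                            observer=ObserverParams(k=105.0, q=2.0), seed=6)
        df1 = simulate_decision_session(cfg)
        df2 = simulate_decision_session(cfg)
        pd.testing.assert_frame_equal(df1, df2)

    def test_fitter_accepts_generated_table(self):
        """Generator-to-fitter loop closure."""
        import warnings

        from fitcode.fitting import FitConfig, fit_hierarchical
        frames = [simulate_decision_session(
            SessionConfig(context="accuracy", n_decision_trials=120,
                          observer=ObserverParams(k=105.0, q=2.0), seed=s),
            subject=s) for s in (0, 1, 2)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            summary = fit_hierarchical(
                pd.concat(frames, ignore_index=True),
                FitConfig(chains=2, burn_in=100, draws=100, thin=1, seed=0))
        assert summary.n_retained == 200


class TestStaircaseCalibration:
    def test_capacity_solver_hits_target(self):
        k = capacity_for_separation_accuracy(q=2.0, separation=10.0,
                                             target=0.9)
        assert 50 < k < 500  # plausible range for the orientation prior


class TestSignedError:
    @pytest.mark.parametrize("true,rep,expected", [
        (10.0, 15.0, 5.0),     # reported more oblique
        (40.0, 35.0, -5.0),    # reported more cardinal
        (2.0, 178.0, -4.0),    # wraps across 0/180 (equal diagonality:
                               # sign falls back to the wrapped direction)
        (88.0, 95.0, 7.0),     # 95 is farther from the 90-deg cardinal
    ])
    def test_sign_and_magnitude(self, true, rep, expected):
        assert signed_estimation_error(true, rep) == pytest.approx(expected)

    def test_magnitude_bounded_by_90(self, rng):
        t = rng.uniform(0, 180, 1000)
        r = rng.uniform(0, 180, 1000)
        assert np.all(np.abs(signed_estimation_error(t, r)) <= 90.0)


class TestFilter:
    def test_boundary_inclusive(self):
        df = pd.DataFrame({"error_deg": [22.0, 22.5, 23.0, -23.0, 0.0]})
        out = filter_estimation(df)
        assert list(out["kept"]) == [True, True, False, False, True]

    def test_threshold_is_quarter_of_max_error(self):
        assert ERROR_DISCARD_DEG == 0.25 * 90.0


class TestEstimationSession:
    @pytest.fixture(scope="class")
    def base_observer(self, ):
        prior = make_orientation_prior(1.85)
        k = capacity_for_variance(prior, 2.0, 4.0, 45.0)
        return prior, ObserverParams(k=k, q=2.0)

    def test_locations_cycled_evenly(self, base_observer):
        _, obs = base_observer
        cfg = SessionConfig(n_estimation_trials=400,
                            locations=("ul", "ur", "dl", "dr"),
                            trained_locations=("ul", "ur"), observer=obs,
                            seed=1)
        df = simulate_estimation_session(cfg, "before")
        assert df["location"].value_counts().eq(100).all()

    def test_untrained_locations_identical_under_common_noise(
            self, base_observer):
        _, obs = base_observer
        cfg = SessionConfig(n_estimation_trials=160,
                            locations=("ul", "dl"),
                            trained_locations=("ul",), observer=obs, seed=2)
        adapted = matched_capacity_params(make_orientation_prior(1.85), obs,
                                          4.0 / 3.0)
        before = simulate_estimation_session(
            cfg, "before", {"ul": obs, "dl": obs}, 0,
            np.random.default_rng(77))
        after = simulate_estimation_session(
            cfg, "after", {"ul": adapted, "dl": obs}, 0,
            np.random.default_rng(77))
        dl_b = before[before["location"] == "dl"]["reported_deg"]
        dl_a = after[after["location"] == "dl"]["reported_deg"]
        np.testing.assert_array_equal(dl_b.to_numpy(), dl_a.to_numpy())
        ul_b = before[before["location"] == "ul"]["reported_deg"]
        ul_a = after[after["location"] == "ul"]["reported_deg"]
        assert not np.array_equal(ul_b.to_numpy(), ul_a.to_numpy())


class TestBinSummaries:
    def test_bin_edges(self):
        np.testing.assert_array_equal(DIAGONALITY_BIN_EDGES,
                                      [0.0, 9.0, 18.0, 27.0, 36.0, 45.0])

    def test_constant_variance_gives_flat_bins(self, rng):
        n = 4000
        true = rng.uniform(0, 180, n)
        err = rng.normal(0.0, 3.0, n)
        df = pd.DataFrame({
            "subject": 0, "phase": np.where(np.arange(n) % 2 == 0, "before",
                                            "after"),
            "location": "ul", "true_deg": true,
            "reported_deg": true + err, "error_deg": err})
        out = bin_summaries(filter_estimation(df))
        assert np.allclose(out["variance_before"], 9.0, atol=2.5)
        assert np.allclose(out["change_variance"], 0.0, atol=3.0)
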