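"""Seeded generators reproducing the structure of the behavioural experiments.

Two tasks are emulated:

* a *decision* task — two oriented stimuli per trial, the subject chooses
  which is more diagonal; the orientation of the reference follows the
  natural-scene prior, the comparison is offset by an adaptive staircase
  targeting ~75% accuracy; payoffs depend on the context (fixed 15 CHF per
  correct choice in the accuracy context; 1 CHF at 0 degrees diagonality
  rising linearly to 46 CHF at 45 degrees, paid on the *chosen* stimulus,
  in the reward context);
* an *estimation* task — a single stimulus, uniform orientation in
  (0-179 degrees), reproduced by rotating a probe; run before and after
  decision training, with stimuli cycled over screen locations of which
  only a subset is trained.

Choices and reports are produced by the power-law Bayesian observer, so
generated cohorts close the loop with the hierarchical fitter and carry the
theory's signatures (e.g. lowering ``q`` only in trained locations yields
the oblique-vs-cardinal variance-change interaction there and nowhere else).

Trial filtering and summaries follow the behavioural-analysis conventions:
estimation errors larger than 25% of the maximum possible error (22.5 of 90
degrees) are discarded, and bias/variance are summarized in five 9-degree
diagonality bins with before/after change scores.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .domains import (Prior, make_diagonality_prior, make_orientation_prior,
                      orientation_to_diagonality)
from .observer import (BehaviorParams, ObserverParams, choice_probability,
                       simulate_estimation_report)

__all__ = [
    "StaircaseState",
    "SessionConfig",
    "sample_stimuli",
    "capacity_for_separation_accuracy",
    "signed_estimation_error",
    "staircase_update",
    "simulate_decision_session",
    "simulate_estimation_session",
    "simulate_cohort",
    "filter_estimation",
    "bin_summaries",
    "ERROR_DISCARD_DEG",
    "DIAGONALITY_BIN_EDGES",
    "TRIAL_COLUMNS",
]

#: estimation trials with |error| beyond this are discarded (25% of 90 deg)
ERROR_DISCARD_DEG = 22.5

#: five 9-degree diagonality bins, cardinal [0, 9) ... oblique [36, 45]
DIAGONALITY_BIN_EDGES = np.array([0.0, 9.0, 18.0, 27.0, 36.0, 45.0])

TRIAL_COLUMNS = ["subject", "context", "trial", "s1_deg", "s2_deg", "d1",
                 "d2", "choice", "correct", "payoff", "phase", "location"]


@dataclass(frozen=True)
class StaircaseState:
    """Weighted up-down staircase on the diagonality separation (degrees).

    The separation grows by ``step_up`` after an error and shrinks by
    ``step_up / ratio`` after a correct response; with the default 3:1
    ratio the procedure is stationary at 75% accuracy.
    """

    difficulty: float = 10.0
    step_up: float = 1.5
    ratio: float = 3.0
    floor: float = 0.5
    ceiling: float = 30.0
    trial_count: int = 0

    def __post_init__(self):
        if self.difficulty <= 0:
            raise ValueError("difficulty (separation) must be positive")


def staircase_update(state: StaircaseState, correct: bool) -> StaircaseState:
    """One weighted up-down step: easier after errors, harder after successes."""
    delta = -state.step_up / state.ratio if correct else state.step_up
    new = float(np.clip(state.difficulty + delta, state.floor, state.ceiling))
    return replace(state, difficulty=new, trial_count=state.trial_count + 1)


@dataclass(frozen=True)
class SessionConfig:
    """Everything needed to simulate one subject's session."""

    context: str = "accuracy"  # "accuracy" | "reward"
    n_decision_trials: int = 400
    n_estimation_trials: int = 240
    locations: tuple = ("left", "right")
    trained_locations: tuple = ("left", "right")
    observer: ObserverParams = ObserverParams(k=1000.0, q=2.0)
    behavior: BehaviorParams = BehaviorParams()
    q_late: float | None = None  # if set, q after trial 200 (adaptation)
    staircase: StaircaseState = StaircaseState()
    motor_sd: float = 2.0
    prior_steepness: float = 1.85
    seed: int = 0

    def __post_init__(self):
        if self.context not in ("accuracy", "reward"):
            raise ValueError(f"unknown context {self.context!r}")
        if not set(self.trained_locations) <= set(self.locations):
            raise ValueError("trained locations must be a subset of locations")
        if self.n_decision_trials <= 0 or self.n_estimation_trials <= 0:
            raise ValueError("trial counts must be positive")


def capacity_for_separation_accuracy(q: float, separation: float = 10.0,
                                     target: float = 0.9,
                                     prior_steepness: float = 1.85,
                                     n_probe: int = 4000,
                                     probe_seed: int = 7) -> float:
    """Capacity ``k`` at which a fixed separation is discriminated at ``target``.

    Averages the observer's probit accuracy over prior-drawn reference
    diagonalities at the given separation and solves for ``k`` by bisection
    (accuracy is monotone in capacity). Used to place simulated subjects at
    a baseline discrimination level before the staircase takes over.
    """
    from scipy.special import ndtr

    from .observer import estimate_moments
    dprior = make_diagonality_prior(prior_steepness)
    rng = np.random.default_rng(probe_seed)
    d_ref = dprior.ppf(rng.random(n_probe))
    sign = np.where(rng.random(n_probe) < 0.5, 1.0, -1.0)
    d_cmp = np.clip(d_ref + sign * separation, 0.0, 45.0)

    def accuracy(k: float) -> float:
        p = ObserverParams(k=k, q=q)
        m1 = estimate_moments(d_ref, dprior, p)
        m2 = estimate_moments(d_cmp, dprior, p)
        z = (m1.mean - m2.mean) / np.sqrt(m1.variance + m2.variance)
        return float(np.where(d_ref > d_cmp, ndtr(z), 1.0 - ndtr(z)).mean())

    lo, hi = 1e-3, 1e9
    for _ in range(60):
        mid = np.sqrt(lo * hi)
        if accuracy(mid) < target:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def sample_stimuli(prior: Prior, n: int, rng: np.random.Generator) -> np.ndarray:
    """Inverse-CDF draws of stimulus orientations from a prior."""
    return prior.ppf(rng.random(n))


def _comparison_orientation(ref_deg: float, d_cmp: float) -> float:
    """Orientation with diagonality ``d_cmp`` in the reference's quadrant."""
    base = 90.0 * np.floor(ref_deg / 90.0)
    within = ref_deg - base
    if within <= 45.0:
        return base + d_cmp
    return base + 90.0 - d_cmp


def simulate_decision_session(config: SessionConfig,
                              prior: Prior | None = None,
                              subject: int = 0,
                              rng: np.random.Generator | None = None
                              ) -> pd.DataFrame:
    """Simulate one staircase-controlled binary-decision session.

    Per trial, a reference orientation is drawn from the prior and the
    comparison is offset by the current staircase separation in diagonality
    space (random direction, same quadrant); the observer's probit choice
    rule generates the decision, correctness is defined on diagonality, the
    context rule assigns the payoff, and the staircase adapts.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if prior is None:
        prior = make_orientation_prior(config.prior_steepness)
    dprior = make_diagonality_prior(config.prior_steepness)
    state = config.staircase
    obs = config.observer
    rows = []
    for t in range(1, config.n_decision_trials + 1):
        if config.q_late is not None and t > 200:
            obs = ObserverParams(k=config.observer.k, q=config.q_late)
        ref = float(sample_stimuli(prior, 1, rng)[0])
        d_ref = float(orientation_to_diagonality(ref))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        d_cmp = float(np.clip(d_ref + sign * state.difficulty, 0.0, 45.0))
        if d_cmp == d_ref:  # clipped into the reference; flip direction
            d_cmp = float(np.clip(d_ref - sign * state.difficulty, 0.0, 45.0))
        cmp_deg = _comparison_orientation(ref, d_cmp)
        # random side assignment: stimulus 1 is the "left" slot
        if rng.random() < 0.5:
            s1, s2, di1, di2 = ref, cmp_deg, d_ref, d_cmp
        else:
            s1, s2, di1, di2 = cmp_deg, ref, d_cmp, d_ref
        p1 = float(choice_probability(di1, di2, dprior, obs, config.behavior))
        choice = 1 if rng.random() < p1 else 2
        chosen_d, other_d = (di1, di2) if choice == 1 else (di2, di1)
        correct = chosen_d > other_d
        if config.context == "accuracy":
            payoff = 15.0 if correct else 0.0
        else:
            payoff = 1.0 + chosen_d  # 1 CHF at 0 deg ... 46 CHF at 45 deg
        rows.append((subject, config.context, t, s1, s2, di1, di2, choice,
                     bool(correct), payoff,
                     "early" if t <= 200 else "late",
                     config.trained_locations[t % len(config.trained_locations)]))
        state = staircase_update(state, correct)
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def simulate_estimation_session(config: SessionConfig, phase: str,
                                params_by_location: dict | None = None,
                                subject: int = 0,
                                rng: np.random.Generator | None = None
                                ) -> pd.DataFrame:
    """Simulate one estimation session (``phase``: "before" or "after").

    Trials are cycled evenly over the configured locations; true
    orientations are uniform on (0-179 degrees); reports come from the
    observer's encode-decode round trip plus motor noise. Per-location
    observer parameters express location-specific adaptation (trained
    locations may carry a different ``q`` after training).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    if phase not in ("before", "after"):
        raise ValueError(f"phase must be 'before' or 'after', got {phase!r}")
    prior = make_orientation_prior(config.prior_steepness)
    if params_by_location is None:
        params_by_location = {loc: config.observer for loc in config.locations}
    n = config.n_estimation_trials
    locs = np.array([config.locations[i % len(config.locations)]
                     for i in range(n)])
    true = rng.uniform(0.0, 180.0, size=n)
    reported = np.empty(n)
    for loc in config.locations:
        mask = locs == loc
        if not np.any(mask):
            continue
        reported[mask] = np.atleast_1d(simulate_estimation_report(
            true[mask], prior, params_by_location[loc], config.motor_sd, rng))
    err = signed_estimation_error(true, reported)
    df = pd.DataFrame({
        "subject": subject, "phase": phase, "location": locs,
        "true_deg": true, "reported_deg": reported, "error_deg": err,
    })
    return filter_estimation(df)


def signed_estimation_error(true_deg, reported_deg) -> np.ndarray:
    """Signed report error on the circular orientation scale.

    Magnitude is the wrapped orientation difference (period 180 degrees, so
    at most 90); the sign is positive when the report is more oblique than
    the presented orientation.
    """
    true_deg = np.asarray(true_deg, dtype=float)
    reported_deg = np.asarray(reported_deg, dtype=float)
    wrapped = (reported_deg - true_deg + 90.0) % 180.0 - 90.0
    mag = np.abs(wrapped)
    d_true = orientation_to_diagonality(true_deg)
    d_rep = orientation_to_diagonality(reported_deg)
    sign = np.sign(d_rep - d_true)
    # equal diagonality (e.g. a report mirrored about a cardinal axis):
    # fall back to the wrapped-difference direction so the magnitude is kept
    sign = np.where(sign == 0, np.sign(wrapped), sign)
    return sign * mag


def filter_estimation(trials: pd.DataFrame) -> pd.DataFrame:
    """Attach the discard filter: kept iff |error| <= 22.5 deg (inclusive)."""
    out = trials.copy()
    out["kept"] = np.abs(out["error_deg"].to_numpy()) <= ERROR_DISCARD_DEG
    return out


def bin_summaries(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-subject bias/variance in five 9-degree diagonality bins.

    Uses kept trials only. Returns a tidy frame with columns subject,
    location, bin (0 = cardinal ... 4 = oblique), phase, bias, variance,
    n; rows for both phases present per bin when available, plus
    ``change_*`` columns (after - before) merged in. Empty bins propagate
    as missing values.
    """
    kept = trials[trials["kept"]].copy()
    d = orientation_to_diagonality(kept["true_deg"].to_numpy())
    kept["bin"] = np.clip(
        np.digitize(d, DIAGONALITY_BIN_EDGES[1:-1]), 0, 4)
    g = (kept.groupby(["subject", "location", "bin", "phase"])["error_deg"]
         .agg(bias="mean", variance="var", n="count").reset_index())
    wide = g.pivot_table(index=["subject", "location", "bin"],
                         columns="phase", values=["bias", "variance"])
    out = wide.reset_index()
    out.columns = ["_".join([c for c in col if c]) if isinstance(col, tuple)
                   else col for col in out.columns]
    for stat in ("bias", "variance"):
        before = out.get(f"{stat}_before")
        after = out.get(f"{stat}_after")
        if before is not None and after is not None:
            out[f"change_{stat}"] = after - before
    return out


def simulate_cohort(n_subjects: int, context: str, seed: int,
                    group_log_q_mean: float = np.log(2.0),
                    group_log_q_sd: float = 0.08,
                    group_log_k_mean: float | None = None,
                    group_log_k_sd: float = 0.15,
                    lapse: float = 0.0, side_bias: float = 0.0,
                    n_trials: int = 400,
                    q_late_mean: float | None = None,
                    target_var_oblique: float = 2.0) -> pd.DataFrame:
    """A cohort of simulated subjects for parameter-recovery studies.

    Subject-level ``(q, k)`` are drawn log-normally around group means; the
    default group capacity places the oblique-orientation estimator
    variance at ``target_var_oblique`` deg^2 (high-SNR regime). Setting
    ``q_late_mean`` lowers ``q`` after trial 200 to emulate reward-context
    adaptation.
    """
    from .observer import capacity_for_variance
    rng = np.random.default_rng(seed)
    dprior = make_diagonality_prior(1.85)
    if group_log_k_mean is None:
        q0 = float(np.exp(group_log_q_mean))
        group_log_k_mean = float(np.log(capacity_for_variance(
            dprior, q0, target_var_oblique, 45.0)))
    frames = []
    for s in range(n_subjects):
        q = float(np.exp(rng.normal(group_log_q_mean, group_log_q_sd)))
        k = float(np.exp(rng.normal(group_log_k_mean, group_log_k_sd)))
        q_late = None
        if q_late_mean is not None:
            q_late = float(np.exp(rng.normal(np.log(q_late_mean),
                                             group_log_q_sd)))
        cfg = SessionConfig(context=context, n_decision_trials=n_trials,
                            observer=ObserverParams(k=k, q=q),
                            behavior=BehaviorParams(lapse=lapse,
                                                    side_bias=side_bias),
                            q_late=q_late,
                            seed=int(rng.integers(2 ** 31)))
        frames.append(simulate_decision_session(cfg, subject=s,
                                                rng=np.random.default_rng(
                                                    cfg.seed)))
    return pd.concat(frames, ignore_index=True)
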