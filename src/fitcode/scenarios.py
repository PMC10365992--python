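"""Canonical study scenarios tying the modules together.

The resource-allocation studies use a right-skewed prior over a unit
stimulus space (density monotonically decreasing in the stimulus, as for
natural orientation statistics folded to diagonality) and three
stimulus-reward contexts:

* scenario 1 — accuracy maximization (constant payoff per correct choice),
* scenario 2 — reward linear in the stimulus,
* scenario 3 — non-monotonic unimodal reward peaking mid-domain, solved
  jointly with a categorization threshold.

The reaction-time study reuses the same prior with the accuracy and reward
objectives and a grid of RT costs.
"""

from __future__ import annotations

import numpy as np

from .allocation import (DEFAULT_CAPACITY, optimize_allocation,
                         optimize_allocation_rt, power_law_allocation)
from .domains import Prior, RewardMap, StimulusDomain

__all__ = [
    "make_skewed_prior",
    "scenario_reward_map",
    "run_allocation_scenarios",
    "run_rt_study",
    "ORACLE_CAPACITY",
]

#: capacity used for the monotone-scenario oracle comparisons; deep in the
#: low-noise regime where the numerical optimum is capacity-independent
ORACLE_CAPACITY = 400.0

#: decay rate of the right-skewed scenario prior
SKEW_RATE = 2.5


def make_skewed_prior(n_grid: int = 512, rate: float = SKEW_RATE) -> Prior:
    """Right-skewed (monotonically decreasing) prior on the unit domain."""
    domain = StimulusDomain(0.0, 1.0, n_grid=n_grid)
    raw = np.exp(-rate * domain.grid)
    return Prior(domain, raw / np.trapezoid(raw, domain.grid))


def scenario_reward_map(domain: StimulusDomain, scenario: int) -> RewardMap | None:
    """Reward map of scenario 1 (none/constant), 2 (linear) or 3 (unimodal)."""
    if scenario == 1:
        return None
    if scenario == 2:
        return RewardMap.linear(domain, 0.0, 1.0)
    if scenario == 3:
        vals = np.exp(-(domain.grid - 0.5) ** 2 / (2.0 * 0.15 ** 2))
        return RewardMap(domain, vals, kind="tabulated")
    raise ValueError(f"unknown scenario {scenario}")


def run_allocation_scenarios(seed: int = 0, capacity_monotone: float = ORACLE_CAPACITY,
                             capacity_threshold: float = DEFAULT_CAPACITY,
                             n_quad_threshold: int = 65) -> dict:
    """Solve the three allocation scenarios; returns solutions and oracles."""
    prior = make_skewed_prior()
    dom = prior.domain
    out = {}
    out["scenario1"] = optimize_allocation(
        prior, None, "accuracy", capacity=capacity_monotone, seed=seed)
    out["scenario1_oracle"] = power_law_allocation(prior, 2.0,
                                                   capacity=capacity_monotone)
    out["scenario2"] = optimize_allocation(
        prior, scenario_reward_map(dom, 2), "reward",
        capacity=capacity_monotone, seed=seed)
    out["scenario2_oracle"] = power_law_allocation(prior, 4.0 / 3.0,
                                                   capacity=capacity_monotone)
    out["scenario3"] = optimize_allocation(
        prior, scenario_reward_map(dom, 3), "reward",
        capacity=capacity_threshold, tau_search=True, seed=seed,
        n_quad=n_quad_threshold)
    return out


def run_rt_study(etas=(0.002, 0.01, 0.05), seed: int = 0,
                 maxiter: int = 200) -> dict:
    """Joint (allocation, bound) optima over an RT-cost grid, both contexts."""
    prior = make_skewed_prior()
    out = {"prior": prior, "etas": list(etas)}
    for ctx in ("accuracy", "reward"):
        sols = [optimize_allocation_rt(prior, ctx, eta, seed=seed,
                                       maxiter=maxiter) for eta in etas]
        out[ctx] = sols
    out["accuracy_free"] = power_law_allocation(prior, 2.0)
    out["reward_free"] = power_law_allocation(prior, 4.0 / 3.0)
    return out
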