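"""Normative core: escort response functions and quantized-code loss functionals.

A capacity-limited scalar channel maps a stimulus ``s`` with environmental
density ``f(s)`` through a response function ``h(s)`` bounded in [0, 1].
Minimizing the ``L_p`` reconstruction error of the decoded stimulus yields

    h*(s) = int_lower^s f(t)^gamma dt / int_domain f(t)^gamma dt,

the *escort distribution* of ``f`` with exponent ``gamma = 1/(1+p)``.
Infomax coding is the ``p -> 0`` (``gamma = 1``) member, for which ``h`` is
the prior CDF. The same family solves the evolutionary discrete-choice
problem in which ``h`` can take only ``n`` discrete values (a step "utility
function"): minimizing the probability of an erroneous binary choice between
two i.i.d. draws from ``f`` selects ``gamma = 1``, while minimizing the
expected *reward* forgone when reward is linear in the stimulus selects
``gamma = 2/3`` (equivalently ``p = 1/2``).

The exponent algebra connecting the escort family to power-law Fisher
information codes ``J(s) = k f(s)^q`` lives in :class:`ExponentSet`:
``q = gamma / beta_cap`` under a capacity budget ``int J^beta_cap <= c``,
with ``beta_cap = 0.5`` by default, so infomax gives ``q = 2`` and the
reward-maximizing code gives ``q = 4/3``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import minimize_scalar

from .domains import Prior, RewardMap, StimulusDomain
from .errors import DegeneratePlateauError, ExponentRangeError, InvalidPriorError

__all__ = [
    "ExponentSet",
    "EscortResponse",
    "QuantizedCode",
    "escort_response",
    "exponents_from",
    "quantize",
    "prob_error_loss",
    "reward_loss",
    "optimize_escort_exponent",
    "response_density",
    "FlatObjectiveWarning",
]


class FlatObjectiveWarning(UserWarning):
    """The objective does not discriminate between escort exponents."""


@dataclass(frozen=True)
class ExponentSet:
    """Mutually consistent exponents of the escort / power-law code family.

    Attributes
    ----------
    p : float
        L_p reconstruction-error norm exponent, >= 0.
    gamma : float
        Escort exponent in (0, 1]; ``gamma = 1/(1+p)``.
    q : float
        Power-law Fisher-information exponent; ``q = gamma / beta_cap``.
    beta_cap : float
        Capacity-constraint exponent (budget ``int J^beta_cap <= c``).
    alpha_obj : float
        Objective exponent; ``gamma = beta_cap/(beta_cap + alpha_obj)``.
    """

    p: float
    gamma: float
    q: float
    beta_cap: float
    alpha_obj: float


def exponents_from(p: float | None = None, gamma: float | None = None,
                   beta_cap: float = 0.5) -> ExponentSet:
    """Populate the full exponent set from ``p`` or ``gamma``.

    Exactly one of ``p`` or ``gamma`` must be given; ``beta_cap`` defaults
    to 0.5 (the standard infomax capacity convention, under which
    ``gamma = 1`` maps to ``q = 2`` and ``gamma = 2/3`` to ``q = 4/3``).
    """
    if (p is None) == (gamma is None):
        raise ExponentRangeError("specify exactly one of p or gamma")
    if beta_cap <= 0:
        raise ExponentRangeError(f"beta_cap must be positive, got {beta_cap}")
    if p is not None:
        if p < 0:
            raise ExponentRangeError(f"p must be >= 0, got {p}")
        gamma = 1.0 / (1.0 + p)
    else:
        if not 0 < gamma <= 1:
            raise ExponentRangeError(f"gamma must lie in (0, 1], got {gamma}")
        p = 1.0 / gamma - 1.0
    q = gamma / beta_cap
    alpha_obj = beta_cap * (1.0 - gamma) / gamma
    return ExponentSet(p=p, gamma=gamma, q=q, beta_cap=beta_cap,
                       alpha_obj=alpha_obj)


@dataclass(frozen=True)
class EscortResponse:
    """Normalized power-transformed cumulative response ``h(s)`` on a grid."""

    domain: StimulusDomain
    gamma: float
    values: np.ndarray  # h(s) on domain.grid, non-decreasing, h(lower)=0, h(upper)=1

    @property
    def grid(self) -> np.ndarray:
        return self.domain.grid

    def __call__(self, s) -> np.ndarray:
        return np.interp(np.asarray(s, dtype=float), self.grid, self.values)

    def inverse(self, r) -> np.ndarray:
        """Stimulus at which the response reaches ``r`` (monotone interpolation)."""
        return np.interp(np.asarray(r, dtype=float), self.values, self.grid)


def escort_response(prior: Prior, gamma: float) -> EscortResponse:
    """Escort response ``h(s) = int^s f^gamma / int f^gamma`` (cumulative trapezoid).

    ``gamma = 1`` returns the prior CDF (infomax); smaller ``gamma`` flattens
    the response, spreading discriminability into low-density regions.
    """
    if gamma <= 0:
        raise ExponentRangeError(f"gamma must be positive, got {gamma}")
    if not prior.is_normalized(tol=1e-4):
        raise InvalidPriorError("prior must be normalized")
    powered = prior.density ** gamma
    h = cumulative_trapezoid(powered, prior.grid, initial=0.0)
    h /= h[-1]
    return EscortResponse(domain=prior.domain, gamma=gamma, values=h)


@dataclass(frozen=True)
class QuantizedCode:
    """An ``n``-level step code: interior cut points where ``h`` crosses i/n."""

    n: int
    boundaries: np.ndarray  # n-1 interior cut points, strictly increasing


def quantize(response: EscortResponse, n: int) -> QuantizedCode:
    """Cut points of the ``n``-level step code induced by a response function.

    Boundary ``i`` is the stimulus at which ``h(s) = i/n``; a plateau of
    ``h`` containing a needed crossing makes the code degenerate there.
    """
    if n < 2:
        raise ValueError(f"need at least 2 levels, got n={n}")
    h, s = response.values, response.grid
    targets = np.arange(1, n) / n
    # locate plateaus of h that straddle a required crossing
    dh = np.diff(h)
    if np.any(dh <= 0):
        flat = np.where(dh <= 0)[0]
        for i in flat:
            lo, hi = h[i], h[i + 1]
            if np.any((targets >= lo) & (targets <= hi)):
                raise DegeneratePlateauError(
                    f"response is flat on [{s[i]:.4g}, {s[i+1]:.4g}] "
                    "where a level boundary falls",
                    interval=(float(s[i]), float(s[i + 1])),
                )
    boundaries = np.interp(targets, h, s)
    return QuantizedCode(n=n, boundaries=boundaries)


def _level_edges(prior: Prior, code: QuantizedCode) -> np.ndarray:
    return np.concatenate(
        [[prior.domain.lower], code.boundaries, [prior.domain.upper]]
    )


def _level_masses(prior: Prior, code: QuantizedCode) -> np.ndarray:
    edges = _level_edges(prior, code)
    cdf = prior.cdf(edges)
    return np.diff(cdf)


def prob_error_loss(prior: Prior, code: QuantizedCode) -> float:
    """Expected probability of an erroneous binary choice under a step code.

    Two alternatives are drawn i.i.d. from the prior; stimuli falling in the
    same level are indistinguishable and the tie is resolved by a fair coin,
    so the loss is ``(1/2) sum_i m_i^2`` with ``m_i`` the prior mass of
    level ``i``. Stimuli in different levels are always ranked correctly.
    """
    m = _level_masses(prior, code)
    return float(0.5 * np.sum(m ** 2))


def _sub_grid(prior: Prior, reward: RewardMap, lo: float, hi: float):
    """Grid slice of [lo, hi] with exact endpoints; returns (s, f, R)."""
    g = prior.grid
    inner = g[(g > lo) & (g < hi)]
    s = np.concatenate([[lo], inner, [hi]])
    return s, prior.pdf(s), reward(s)


def reward_loss(prior: Prior, code: QuantizedCode, reward: RewardMap) -> float:
    """Expected reward forgone per binary choice under a step code.

    Within a level the fair-coin tie-break loses ``|R(s1) - R(s2)|`` half the
    time; across levels the agent picks the higher level, which loses reward
    only if the map ranks the stimuli the other way (zero for monotone
    increasing maps). Both terms are evaluated by iterated trapezoid
    quadrature on the level sub-grids.
    """
    edges = _level_edges(prior, code)
    n = code.n
    subs = [_sub_grid(prior, reward, edges[i], edges[i + 1]) for i in range(n)]
    # trapezoid weight vectors w_i f_i per level
    wf, R = [], []
    for s, f, r in subs:
        w = np.zeros_like(s)
        ds = np.diff(s)
        w[:-1] += 0.5 * ds
        w[1:] += 0.5 * ds
        wf.append(w * f)
        R.append(r)
    total = 0.0
    for i in range(n):
        dR = np.abs(R[i][:, None] - R[i][None, :])
        total += 0.5 * wf[i] @ dR @ wf[i]
    # cross-level misranking (agent always picks the higher level)
    for i in range(n):
        for j in range(i + 1, n):
            gap = R[i][:, None] - R[j][None, :]  # low-level reward minus chosen
            if np.any(gap > 0):
                total += wf[i] @ np.clip(gap, 0.0, None) @ wf[j]
    return float(total)


def optimize_escort_exponent(prior: Prior, reward: RewardMap | None,
                             objective: str, n: int,
                             gamma_grid: np.ndarray | None = None,
                             refine: bool = True):
    """Escort exponent minimizing a quantized-code loss on a given prior.

    Parameters
    ----------
    prior : Prior
        Environmental stimulus density (must not be flat: for a uniform
        prior every escort code coincides and the optimum is undefined).
    reward : RewardMap or None
        Required for the ``reward`` objective.
    objective : {"accuracy", "reward"}
        Loss functional: probability of error, or expected reward forgone.
    n : int
        Number of code levels (n >= 2).
    gamma_grid : array, optional
        Coarse search grid; defaults to 0.3 .. 1.5 in steps of 0.02.
    refine : bool
        Golden-section refinement around the best grid point.

    Returns
    -------
    (gamma_star, loss_star) : tuple of floats
    """
    if gamma_grid is None:
        gamma_grid = np.arange(0.30, 1.50 + 1e-9, 0.02)
    if np.ptp(prior.density) / np.max(prior.density) < 1e-8:
        warnings.warn(
            "prior is (approximately) uniform: all escort codes coincide and "
            "the optimal exponent is undefined",
            FlatObjectiveWarning,
        )

    def loss_of(gamma: float) -> float:
        code = quantize(escort_response(prior, gamma), n)
        if objective == "accuracy":
            return prob_error_loss(prior, code)
        if objective == "reward":
            if reward is None:
                raise ValueError("reward objective requires a reward map")
            return reward_loss(prior, code, reward)
        raise ValueError(f"unknown objective {objective!r}")

    losses = np.array([loss_of(g) for g in gamma_grid])
    i = int(np.argmin(losses))
    gamma_star, loss_star = float(gamma_grid[i]), float(losses[i])
    if refine:
        lo = gamma_grid[max(i - 1, 0)]
        hi = gamma_grid[min(i + 1, len(gamma_grid) - 1)]
        if hi > lo:
            res = minimize_scalar(loss_of, bounds=(lo, hi), method="bounded",
                                  options={"xatol": 1e-4})
            if res.fun <= loss_star:
                gamma_star, loss_star = float(res.x), float(res.fun)
    return round(gamma_star, 3), loss_star


def response_density(prior: Prior, response: EscortResponse,
                     n_r: int | None = None):
    """Push-forward density of the response ``r = h(s)`` on a uniform [0,1] grid.

    ``g(r) = f(s) / h'(s)`` at ``s = h^{-1}(r)``; for an escort response the
    derivative is exact, ``h'(s) = f(s)^gamma / Z``. Infomax (``gamma = 1``)
    equalizes the response histogram: ``g`` is uniform.
    """
    if n_r is None:
        n_r = prior.domain.n_grid
    powered = prior.density ** response.gamma
    Z = np.trapezoid(powered, prior.grid)
    support = prior.density > 0
    dh = powered / Z
    if np.any(support & (dh <= 0)):
        raise DegeneratePlateauError(
            "response has zero derivative inside the prior support"
        )
    r = np.linspace(0.0, 1.0, n_r)
    s = response.inverse(r)
    f = prior.pdf(s)
    hprime = np.interp(s, prior.grid, dh)
    g = np.where(hprime > 0, f / np.where(hprime > 0, hprime, 1.0), 0.0)
    return r, g
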