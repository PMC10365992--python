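"""Numerical optimization of Fisher-information allocation for arbitrary
priors and stimulus-reward maps.

The allocation is a normalized density ``f~(s)`` over the stimulus domain
with ``J(s) = k f~(s)``; candidate shapes are exponentials of a cubic
interpolant through a small number of knots, which guarantees positivity and
(after renormalization) unit mass. The scale ``k`` is set from a fixed
capacity budget ``int J(s)^beta ds = c`` (``beta = 0.5`` by default, the
standard infomax convention), so the optimizer searches allocation *shapes*
at constant capacity. Under this budget the monotone scenarios recover the
closed-form power laws: accuracy maximization gives ``f~* prop f^2`` and
linear-reward maximization gives ``f~* prop f^{4/3}``.

For non-monotonic reward maps the decision rule uses a categorization
threshold ``tau``: the agent decodes a relative value ``s~ = -|tau - s^|``
and chooses the alternative closer to the threshold. ``tau`` is then a
second latent variable optimized jointly with the allocation.

Reaction-time costs are modelled by a constant-bound drift-diffusion model
with unit diffusion noise: evidence ``z = |E[s^1]-E[s^2]| / sqrt(1/J1+1/J2)``
gives the closed forms ``P(error) = 1/(1+exp(2 b z))`` and
``E[RT] = (b/z) tanh(b z)``; the expected loss adds ``eta`` per unit of
decision time and the decision bound ``b`` is optimized alongside the
allocation shape.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import minimize, minimize_scalar
from scipy.special import ndtr

from .domains import Prior, RewardMap, StimulusDomain
from .errors import InfiniteVarianceError

__all__ = [
    "Allocation",
    "DDMConfig",
    "ScenarioSolution",
    "allocation_from_knots",
    "power_law_allocation",
    "relative_value",
    "scenario_loss",
    "optimize_allocation",
    "ddm_evidence",
    "ddm_error_prob",
    "ddm_mean_rt",
    "rt_loss",
    "optimize_allocation_rt",
    "simulate_ddm_paths",
    "LowSNRWarning",
]

#: default capacity budget: on the unit domain the uniform shape gets k = 500
DEFAULT_CAPACITY = np.sqrt(500.0)
DEFAULT_BETA_CAP = 0.5


class LowSNRWarning(UserWarning):
    """Capacity too small for the high-SNR (low-noise) assumptions."""


@dataclass(frozen=True)
class Allocation:
    """Normalized Fisher-information density with scale: ``J(s) = k f~(s)``."""

    domain: StimulusDomain
    shape: np.ndarray  # f~(s) on the grid; >= 0; trapezoid integral = 1
    k: float

    def __post_init__(self):
        shp = np.asarray(self.shape, dtype=float)
        object.__setattr__(self, "shape", shp)
        total = np.trapezoid(shp, self.domain.grid)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"allocation shape must integrate to 1, got {total:.8g}")
        if np.any(shp < 0):
            raise ValueError("allocation shape must be non-negative")

    @property
    def grid(self) -> np.ndarray:
        return self.domain.grid

    def J(self, s) -> np.ndarray:
        return self.k * np.interp(np.asarray(s, dtype=float), self.grid, self.shape)

    def cdf(self, s) -> np.ndarray:
        from scipy.integrate import cumulative_trapezoid
        F = cumulative_trapezoid(self.shape, self.grid, initial=0.0)
        return np.interp(np.asarray(s, dtype=float), self.grid, F / F[-1])


def _k_from_capacity(domain: StimulusDomain, shape: np.ndarray,
                     capacity: float, beta_cap: float) -> float:
    # int (k f~)^beta = c  =>  k = (c / int f~^beta)^(1/beta)
    budget = np.trapezoid(shape ** beta_cap, domain.grid)
    return float((capacity / budget) ** (1.0 / beta_cap))


def allocation_from_knots(domain: StimulusDomain, knot_values: np.ndarray,
                          capacity: float = DEFAULT_CAPACITY,
                          beta_cap: float = DEFAULT_BETA_CAP) -> Allocation:
    """Allocation whose log-shape is a cubic interpolant through equispaced knots."""
    v = np.asarray(knot_values, dtype=float)
    xk = np.linspace(domain.lower, domain.upper, len(v))
    log_shape = CubicSpline(xk, v - v.mean())(domain.grid)
    shape = np.exp(np.clip(log_shape, -60.0, 60.0))
    shape /= np.trapezoid(shape, domain.grid)
    k = _k_from_capacity(domain, shape, capacity, beta_cap)
    return Allocation(domain=domain, shape=shape, k=k)


def power_law_allocation(prior: Prior, exponent: float,
                         capacity: float = DEFAULT_CAPACITY,
                         beta_cap: float = DEFAULT_BETA_CAP) -> Allocation:
    """Closed-form allocation ``f~ prop f(s)^exponent`` (the analytic oracle)."""
    shape = prior.density ** exponent
    shape = shape / np.trapezoid(shape, prior.grid)
    k = _k_from_capacity(prior.domain, shape, capacity, beta_cap)
    return Allocation(domain=prior.domain, shape=shape, k=k)


@dataclass(frozen=True)
class DDMConfig:
    """Constant-bound DDM: bound ``b > 0``, unit diffusion noise, RT cost ``eta``."""

    bound: float
    rt_cost: float = 0.0
    sigma: float = 1.0

    def __post_init__(self):
        if self.bound <= 0:
            raise ValueError(f"bound must be positive, got {self.bound}")
        if self.rt_cost < 0:
            raise ValueError(f"RT cost must be >= 0, got {self.rt_cost}")
        if self.sigma != 1.0:
            raise ValueError("diffusion noise sigma is fixed to 1")


@dataclass(frozen=True)
class ScenarioSolution:
    """Result record of a numerical resource-allocation optimization."""

    allocation: Allocation
    loss: float
    tau: float | None = None
    bound: float | None = None
    converged: bool = True
    knots: np.ndarray | None = None


def relative_value(s_hat, tau: float) -> np.ndarray:
    """Relative decoded value ``s~ = -|tau - s^|`` (larger is better)."""
    return -np.abs(tau - np.asarray(s_hat, dtype=float))


# -- pair-quadrature losses --------------------------------------------------

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(31)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()


def _pair_grid(prior: Prior, m: int):
    s = np.linspace(prior.domain.lower, prior.domain.upper, m)
    f = prior.pdf(s)
    w = np.zeros(m)
    ds = np.diff(s)
    w[:-1] += 0.5 * ds
    w[1:] += 0.5 * ds
    wf = w * f
    wf = wf / wf.sum()  # normalized prior weights on the quadrature grid
    return s, wf


def _choose1_prob_threshold(mu1, sd1, mu2, sd2, tau):
    """P(|tau - s^1| < |tau - s^2|) for independent Gaussian decodes.

    Gauss-Hermite quadrature over the first decode; vectorized over pair
    grids (arrays broadcast to (m, m))."""
    x = mu1[..., None] + sd1[..., None] * _GH_NODES  # (m, m, H)
    ax = np.abs(tau - x)
    m2 = mu2[..., None]
    s2 = sd2[..., None]
    # P(|tau - s^2| > |x - tau|) = P(s^2 > tau+ax) + P(s^2 < tau-ax)
    p_out = 1.0 - ndtr((tau + ax - m2) / s2) + ndtr((tau - ax - m2) / s2)
    return np.sum(p_out * _GH_WEIGHTS, axis=-1)


def _monotone_loss_local(alloc: Allocation, prior: Prior,
                         reward: RewardMap | None, objective: str,
                         n_quad: int) -> float:
    """Pair loss for the larger-decode rule via a local substitution.

    Errors concentrate where the stimuli are within a few discrimination
    standard deviations of each other, so the inner integral over ``s2`` is
    taken on a grid ``s2 = s1 + scale(s1) u`` with ``u`` spanning [-8, 8];
    remote pairs contribute negligibly (their error probability is
    exponentially small while the cost grows at most linearly). This stays
    accurate at arbitrarily high capacity, where a fixed pair grid cannot
    resolve the error kernel.

    The integrand is extended smoothly past the domain edges (log-linear
    for the prior density and the allocation, linear for the reward map):
    the small-noise regime in which the analytic power-law solutions hold
    is boundary-free, and truncating instead would introduce edge layers of
    width a few standard deviations that the closed forms do not model.
    """
    s1, wf1 = _pair_grid(prior, n_quad)
    J1 = alloc.J(s1)
    if np.any(J1 <= 0):
        raise InfiniteVarianceError("allocation is zero on the prior support")
    u = np.linspace(-8.0, 8.0, 81)
    du = u[1] - u[0]
    scale = np.sqrt(2.0 / J1)
    s2 = s1[:, None] + scale[:, None] * u  # (m, H)
    lo, hi = prior.domain.lower, prior.domain.upper

    def extend_log(values, query):
        """Log-linear extension of a positive tabulated function."""
        g = prior.grid
        logv = np.log(np.maximum(values, 1e-300))
        out = np.interp(query, g, logv)
        slope_lo = (logv[1] - logv[0]) / (g[1] - g[0])
        slope_hi = (logv[-1] - logv[-2]) / (g[-1] - g[-2])
        out = np.where(query < lo, logv[0] + slope_lo * (query - lo), out)
        out = np.where(query > hi, logv[-1] + slope_hi * (query - hi), out)
        return np.exp(out)

    f2 = extend_log(prior.density, s2)
    J2 = alloc.k * extend_log(np.maximum(alloc.shape, 1e-300), s2)
    sd_pair = np.sqrt(1.0 / J1[:, None] + 1.0 / J2)
    dmu = s1[:, None] - s2
    p_wrong = ndtr(-np.abs(dmu) / sd_pair)
    if objective == "reward":
        g = prior.grid
        Rg = reward(g)
        R2 = np.interp(s2, g, Rg)
        slope_lo = (Rg[1] - Rg[0]) / (g[1] - g[0])
        slope_hi = (Rg[-1] - Rg[-2]) / (g[-1] - g[-2])
        R2 = np.where(s2 < lo, Rg[0] + slope_lo * (s2 - lo), R2)
        R2 = np.where(s2 > hi, Rg[-1] + slope_hi * (s2 - hi), R2)
        cost = np.abs(reward(s1)[:, None] - R2)
    else:
        cost = 1.0
    inner = np.sum(f2 * p_wrong * cost, axis=1) * scale * du
    return float(np.sum(wf1 * inner))


def scenario_loss(alloc: Allocation, tau: float | None, prior: Prior,
                  reward: RewardMap | None, objective: str,
                  n_quad: int = 65) -> float:
    """Expected loss of an allocation over i.i.d. stimulus pairs.

    The decoded estimate of stimulus ``s`` is Gaussian with mean ``s`` (the
    low-noise limit; bias is O(1/k)) and variance ``1/J(s)``. Without a
    threshold the agent picks the larger decode (probit choice rule); with
    ``tau`` it picks the decode closer to the threshold. The loss per pair
    is 1 for an error (``accuracy``) or the reward difference forgone
    (``reward``), integrated against the product prior by quadrature.
    """
    if objective not in ("accuracy", "reward"):
        raise ValueError(f"unknown objective {objective!r}")
    if objective == "reward" and reward is None:
        raise ValueError("reward objective requires a reward map")

    s, wf = _pair_grid(prior, n_quad)
    J = alloc.J(s)
    if np.any(J <= 0):
        raise InfiniteVarianceError("allocation is zero on the prior support")
    sd = 1.0 / np.sqrt(J)
    if np.max(sd) > 0.2 * prior.domain.width:
        warnings.warn(
            "discrimination sd exceeds 20% of the domain; the high-SNR "
            "(low-noise) assumptions behind the loss are unreliable",
            LowSNRWarning,
        )

    if tau is None:
        return _monotone_loss_local(alloc, prior, reward, objective, n_quad)

    mu1, mu2 = s[:, None] * np.ones_like(s), np.ones_like(s)[:, None] * s
    sd1, sd2 = sd[:, None] * np.ones_like(s), np.ones_like(s)[:, None] * sd
    if objective == "reward":
        R = reward(s)
    else:
        R = reward(s) if reward is not None else -np.abs(tau - s)
    p1 = _choose1_prob_threshold(mu1, sd1, mu2, sd2, tau)

    dR = R[:, None] - R[None, :]
    # probability the lower-valued alternative is chosen
    p_wrong = np.where(dR > 0, 1.0 - p1, np.where(dR < 0, p1, 0.0))
    cost = np.abs(dR) if objective == "reward" else (np.abs(np.sign(dR)))
    W = wf[:, None] * wf[None, :]
    return float(np.sum(W * p_wrong * cost))


def _optimize_knots(loss_fn, n_knots: int, rng: np.random.Generator,
                    restarts: int, maxiter: int, x0=None):
    """Minimize a smooth loss over knot values; quasi-Newton with restarts."""
    best_x, best_f = None, np.inf
    starts = [np.zeros(n_knots) if x0 is None else np.array(x0, dtype=float)]
    for _ in range(restarts - 1):
        starts.append(starts[0] + rng.normal(0.0, 0.5, size=n_knots))
    success = False
    for s0 in starts:
        res = minimize(loss_fn, s0, method="L-BFGS-B",
                       options={"maxiter": maxiter, "ftol": 1e-12,
                                "gtol": 1e-9})
        if res.fun < best_f:
            best_x, best_f = res.x, float(res.fun)
            success = success or bool(res.success)
    return best_x, best_f, success


def optimize_allocation(prior: Prior, reward: RewardMap | None, objective: str,
                        capacity: float = DEFAULT_CAPACITY,
                        tau_search: bool = False,
                        n_knots: int = 12, n_quad: int = 65,
                        beta_cap: float = DEFAULT_BETA_CAP,
                        seed: int = 0, restarts: int = 3,
                        maxiter: int = 400) -> ScenarioSolution:
    """Numerically optimal allocation shape (and threshold) for a scenario.

    Monotone scenarios recover the analytic power laws (``f^2`` for
    accuracy, ``f^{4/3}`` for linear reward). With ``tau_search`` the
    threshold is optimized by golden-section search alternated with
    allocation updates (two rounds suffice for unimodal reward maps, whose
    loss is smooth and unimodal in ``tau``).
    """
    rng = np.random.default_rng(seed)
    domain = prior.domain
    tau = None

    def make_loss(tau_val):
        def loss_fn(v):
            alloc = allocation_from_knots(domain, v, capacity, beta_cap)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", LowSNRWarning)
                return scenario_loss(alloc, tau_val, prior, reward, objective,
                                     n_quad)
        return loss_fn

    if not tau_search:
        x, fval, ok = _optimize_knots(make_loss(None), n_knots, rng,
                                      restarts, maxiter)
        alloc = allocation_from_knots(domain, x, capacity, beta_cap)
        return ScenarioSolution(allocation=alloc, loss=fval, converged=ok,
                                knots=x)

    # joint (allocation, tau): alternate golden-section on tau with
    # allocation updates, starting from a uniform shape
    x = np.zeros(n_knots)
    ok = True
    for round_ in range(2):
        def tau_loss(t, x=x):
            return make_loss(t)(x)
        res = minimize_scalar(tau_loss, bounds=(domain.lower, domain.upper),
                              method="bounded", options={"xatol": 1e-4})
        tau = float(res.x)
        x, fval, ok_i = _optimize_knots(make_loss(tau), n_knots, rng,
                                        restarts if round_ == 0 else 1,
                                        maxiter, x0=x)
        ok = ok and ok_i
    res = minimize_scalar(lambda t: make_loss(t)(x),
                          bounds=(domain.lower, domain.upper),
                          method="bounded", options={"xatol": 1e-4})
    tau, fval = float(res.x), float(res.fun)
    alloc = allocation_from_knots(domain, x, capacity, beta_cap)
    return ScenarioSolution(allocation=alloc, loss=fval, tau=tau,
                            converged=ok, knots=x)


# -- drift-diffusion closed forms -------------------------------------------

def ddm_evidence(s1, s2, alloc: Allocation, prior: Prior | None = None
                 ) -> np.ndarray:
    """Decision evidence ``z = |E[s^1]-E[s^2]| / sqrt(1/J(s1)+1/J(s2))``.

    In the low-noise limit the decoded means equal the stimuli; this is the
    (unsigned) probit argument of the static choice rule.
    """
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    J1, J2 = alloc.J(s1), alloc.J(s2)
    if np.any(J1 <= 0) or np.any(J2 <= 0):
        raise InfiniteVarianceError("Fisher information is zero at a stimulus")
    return np.abs(s1 - s2) / np.sqrt(1.0 / J1 + 1.0 / J2)


def ddm_error_prob(z, config: DDMConfig) -> np.ndarray:
    """Constant-bound DDM error probability ``1 / (1 + exp(2 b z))``."""
    return 1.0 / (1.0 + np.exp(2.0 * config.bound * np.asarray(z, dtype=float)))


def ddm_mean_rt(z, config: DDMConfig) -> np.ndarray:
    """Mean decision time ``(b/z) tanh(b z)``; the ``z -> 0`` limit is ``b^2``."""
    z = np.asarray(z, dtype=float)
    b = config.bound
    with np.errstate(divide="ignore", invalid="ignore"):
        rt = np.where(z > 0, (b / np.where(z > 0, z, 1.0)) * np.tanh(b * z),
                      b * b)
    return rt if rt.ndim else float(rt)


def rt_loss(alloc: Allocation, config: DDMConfig, prior: Prior,
            objective: str, n_quad: int = 65) -> float:
    """Expected loss with reaction-time cost ``eta`` per unit decision time.

    Pair quadrature of ``P(error) [ * |delta reward| ] + eta E[RT]`` under
    the product prior, with the DDM's logistic psychometric standing in for
    the probit of the static rule (the two agree for the matched bound).
    With ``eta = 0`` the optimal bound diverges.
    """
    if config.rt_cost == 0:
        warnings.warn("with eta = 0 the optimal decision bound diverges",
                      UserWarning)
    s, wf = _pair_grid(prior, n_quad)
    z = ddm_evidence(s[:, None] * np.ones_like(s),
                     np.ones_like(s)[:, None] * s, alloc)
    perr = ddm_error_prob(z, config)
    rt = ddm_mean_rt(z, config)
    if objective == "reward":
        cost = np.abs(s[:, None] - s[None, :])
    elif objective == "accuracy":
        cost = 1.0
    else:
        raise ValueError(f"unknown objective {objective!r}")
    W = wf[:, None] * wf[None, :]
    return float(np.sum(W * (perr * cost + config.rt_cost * rt)))


def optimize_allocation_rt(prior: Prior, objective: str, eta: float,
                           capacity: float = DEFAULT_CAPACITY,
                           n_knots: int = 12, n_quad: int = 65,
                           beta_cap: float = DEFAULT_BETA_CAP,
                           seed: int = 0, restarts: int = 2,
                           maxiter: int = 300,
                           bound_bracket: tuple = (1e-3, 50.0),
                           n_rounds: int = 3) -> ScenarioSolution:
    """Joint optimum of allocation shape and decision bound under RT costs.

    Alternates quasi-Newton allocation updates with a 1-D bounded search
    for ``b``; larger RT costs produce smaller optimal bounds.
    """
    if eta <= 0:
        raise ValueError("RT-cost optimization requires eta > 0")
    rng = np.random.default_rng(seed)
    domain = prior.domain
    x = np.zeros(n_knots)
    b = 1.0
    for round_ in range(n_rounds):
        alloc = allocation_from_knots(domain, x, capacity, beta_cap)

        def bound_loss(bv, alloc=alloc):
            return rt_loss(alloc, DDMConfig(bound=bv, rt_cost=eta), prior,
                           objective, n_quad)
        res = minimize_scalar(bound_loss, bounds=bound_bracket,
                              method="bounded", options={"xatol": 1e-5})
        b = float(res.x)

        def knot_loss(v, b=b):
            a = allocation_from_knots(domain, v, capacity, beta_cap)
            return rt_loss(a, DDMConfig(bound=b, rt_cost=eta), prior,
                           objective, n_quad)
        x, fval, ok = _optimize_knots(knot_loss, n_knots, rng,
                                      restarts if round_ == 0 else 1,
                                      maxiter, x0=x)
    alloc = allocation_from_knots(domain, x, capacity, beta_cap)
    fval = rt_loss(alloc, DDMConfig(bound=b, rt_cost=eta), prior, objective,
                   n_quad)
    return ScenarioSolution(allocation=alloc, loss=fval, bound=b,
                            converged=ok, knots=x)


def simulate_ddm_paths(z: float, config: DDMConfig, n_paths: int,
                       rng: np.random.Generator, dt: float = 1e-3,
                       t_max: float = 200.0):
    """Euler-Maruyama first-passage simulation of the constant-bound DDM.

    Independent oracle for the closed forms: returns (error rate, mean RT,
    RT standard deviation).
    Paths start at 0 with drift ``+z`` toward the correct bound ``+b``.
    A Brownian-bridge correction detects within-step boundary crossings,
    removing the O(sqrt(dt)) first-passage bias of the plain Euler scheme.
    """
    b = config.bound
    n_steps = int(t_max / dt)
    alive = np.arange(n_paths)
    pos = np.zeros(n_paths)
    rt = np.full(n_paths, np.nan)
    err = np.zeros(n_paths, dtype=bool)
    sqdt = np.sqrt(dt)
    for step in range(1, n_steps + 1):
        prev = pos[alive].copy()
        new = prev + z * dt + sqdt * rng.standard_normal(len(alive))
        hit_up = new >= b
        hit_dn = new <= -b
        open_ = ~(hit_up | hit_dn)
        if np.any(open_):
            # within-step crossing probabilities of the Brownian bridge
            p_up = np.exp(-2.0 * (b - prev[open_]) * (b - new[open_]) / dt)
            p_dn = np.exp(-2.0 * (b + prev[open_]) * (b + new[open_]) / dt)
            u = rng.random(open_.sum())
            bridged_up = u < p_up
            bridged_dn = (~bridged_up) & (u < p_up + p_dn)
            hu = hit_up.copy()
            hd = hit_dn.copy()
            hu[open_] = bridged_up
            hd[open_] = bridged_dn
            hit_up, hit_dn = hu, hd
        done = hit_up | hit_dn
        pos[alive] = new
        if np.any(done):
            idx = alive[done]
            rt[idx] = step * dt
            err[idx] = hit_dn[done]
            alive = alive[~done]
        if len(alive) == 0:
            break
    rt[np.isnan(rt)] = t_max
    return float(err.mean()), float(rt.mean()), float(rt.std())
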