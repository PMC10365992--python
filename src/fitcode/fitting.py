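"""Hierarchical Bayesian estimation of observer parameters from choice data.

Each subject's binary "more diagonal" choices are modelled with the
power-law observer's psychometric rule: the probability of choosing
alternative 1 is

    P = lambda/2 + (1 - lambda) Phi( (E[s^1] - E[s^2]) / sqrt(V1 + V2) + beta0 ),

with per-subject capacity ``k``, power-law exponent ``q``, lapse rate
``lambda`` and side bias ``beta0``. Subject parameters are drawn from
group-level normal laws on transformed scales (log k, log q, logit lambda,
identity beta0) with flat (very wide) hyperpriors; positivity of ``k`` and
``q`` and boundedness of ``lambda`` force the transforms.

Posterior inference uses a vectorized Metropolis-within-Gibbs sampler:
subject blocks are updated jointly by adaptive random-walk proposals
(adapted during burn-in only, so the retained chain is a valid MCMC
sample), and the group means/variances have conjugate Gibbs updates.
Convergence is monitored with the Gelman-Rubin potential scale reduction
factor; chains are considered converged below 1.05.

The early/late split of training trials (1-200 vs >200) is fitted with
independent models per phase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .domains import make_diagonality_prior

__all__ = [
    "FitConfig",
    "PosteriorSummary",
    "HierarchicalChoiceModel",
    "split_phases",
    "fit_hierarchical",
    "gelman_rubin",
    "posterior_prob",
    "map_grid_fit",
    "ConvergenceWarning",
]

_DEG = np.pi / 180.0
_PARAM_NAMES = ("log_q", "log_k", "logit_lapse", "side_bias")

# bounds of the flat (very wide, proper) hyperpriors on the group means;
# the logit-lapse bound keeps the latent identified when subjects never
# lapse (the likelihood is flat below logit ~ -5)
_MU_LO = np.array([np.log(0.05), np.log(1e-3), -7.0, -5.0])
_MU_HI = np.array([np.log(20.0), np.log(1e9), 2.0, 5.0])


class ConvergenceWarning(UserWarning):
    pass


@dataclass(frozen=True)
class FitConfig:
    """MCMC schedule. The default mirrors the full analysis schedule
    (20,000 burn-in, 5,000 draws from 3 chains, thinning 5, i.e. 3,000
    retained draws per parameter); tests use a reduced schedule."""

    chains: int = 3
    burn_in: int = 20000
    draws: int = 5000
    thin: int = 5
    seed: int = 0
    sigma_max: float = 5.0  # bound of the flat hyperprior on group sds

    def __post_init__(self):
        if self.chains < 2:
            raise ValueError("need at least 2 chains for convergence checks")
        if self.thin < 1:
            raise ValueError("thinning factor must be >= 1")

    @property
    def retained(self) -> int:
        return self.chains * (self.draws // self.thin)


@dataclass
class PosteriorSummary:
    """Draws, diagnostics and bookkeeping of one hierarchical fit."""

    group_draws: dict            # name -> (chains, kept) array
    subject_draws: np.ndarray    # (chains, kept, S, 4) on transformed scales
    rhat: dict                   # name -> float, every group latent
    n_retained: int
    subjects: list
    converged: bool

    def group_q(self) -> np.ndarray:
        """Pooled draws of the group-level median q (natural scale)."""
        return np.exp(self.group_draws["mu_log_q"].ravel())

    def group_k(self) -> np.ndarray:
        return np.exp(self.group_draws["mu_log_k"].ravel())

    def subject_param(self, name: str) -> np.ndarray:
        """Pooled subject-level draws on the natural scale, (draws, S)."""
        j = _PARAM_NAMES.index(name)
        x = self.subject_draws[..., j].reshape(-1, len(self.subjects))
        if name in ("log_q", "log_k"):
            return np.exp(x)
        if name == "logit_lapse":
            return 1.0 / (1.0 + np.exp(-x))
        return x


def split_phases(trials: pd.DataFrame):
    """Early (trials 1-200) / late (trials > 200) partition of a TrialTable."""
    if "trial" not in trials.columns:
        raise ValueError("TrialTable must carry a 'trial' index column")
    early = trials[trials["trial"] <= 200]
    late = trials[trials["trial"] > 200]
    if len(late) == 0:
        warnings.warn("no trials beyond index 200: late split is empty",
                      UserWarning)
    return early, late


# -- likelihood --------------------------------------------------------------

class _ChoiceData:
    """Per-subject padded trial arrays plus precomputed prior terms."""

    def __init__(self, trials: pd.DataFrame, prior_steepness: float = 1.85):
        dprior = make_diagonality_prior(prior_steepness)
        self.a = dprior.a
        self.omega = dprior.omega
        self.subjects = sorted(trials["subject"].unique())
        S = len(self.subjects)
        counts = trials.groupby("subject").size()
        T = int(counts.max())
        self.d1 = np.zeros((S, T))
        self.d2 = np.zeros((S, T))
        self.y1 = np.zeros((S, T))   # 1 if alternative 1 chosen
        self.mask = np.zeros((S, T), dtype=bool)
        for i, subj in enumerate(self.subjects):
            sub = trials[trials["subject"] == subj]
            n = len(sub)
            self.d1[i, :n] = sub["d1"].to_numpy()
            self.d2[i, :n] = sub["d2"].to_numpy()
            self.y1[i, :n] = (sub["choice"].to_numpy() == 1)
            self.mask[i, :n] = True
        # prior terms reused in the closed-form moments
        self.c1 = self.a - np.cos(4.0 * _DEG * self.d1)
        self.c2 = self.a - np.cos(4.0 * _DEG * self.d2)
        self.sn1 = np.sin(4.0 * _DEG * self.d1)
        self.sn2 = np.sin(4.0 * _DEG * self.d2)

    def loglik(self, x: np.ndarray) -> np.ndarray:
        """Per-subject choice log-likelihood at transformed params x (S, 4)."""
        from scipy.special import ndtr
        q = np.exp(x[:, 0])[:, None]
        k = np.exp(x[:, 1])[:, None]
        lam = 1.0 / (1.0 + np.exp(-x[:, 2]))[:, None]
        b0 = x[:, 3][:, None]
        om = self.omega
        pref = (1.0 - 1.0 / q) / k * 4.0 * _DEG * q / om
        bias1 = pref * self.sn1 * (om / self.c1) ** (1.0 - q)
        bias2 = pref * self.sn2 * (om / self.c2) ** (1.0 - q)
        var1 = (self.c1 / om) ** q / k
        var2 = (self.c2 / om) ** q / k
        z = (self.d1 + bias1 - self.d2 - bias2) / np.sqrt(var1 + var2)
        p1 = lam / 2.0 + (1.0 - lam) * ndtr(z + b0)
        p1 = np.clip(p1, 1e-12, 1.0 - 1e-12)
        ll = np.where(self.y1 > 0.5, np.log(p1), np.log1p(-p1))
        return np.sum(np.where(self.mask, ll, 0.0), axis=1)


def _coarse_init(data: _ChoiceData) -> np.ndarray:
    """Pooled coarse-grid argmax over (log q, log k), polished by a local
    continuous maximization; used to seed the chains."""
    from scipy.optimize import minimize
    qs = np.log(np.array([0.75, 1.0, 1.33, 1.62, 2.0, 2.5]))
    ks = np.log(np.geomspace(5.0, 5e4, 12))
    S = len(data.subjects)
    best, best_ll = (qs[2], ks[5]), -np.inf
    for lq in qs:
        for lk in ks:
            x = np.tile([lq, lk, -4.0, 0.0], (S, 1))
            ll = float(np.sum(data.loglik(x)))
            if ll > best_ll:
                best, best_ll = (lq, lk), ll

    def neg_pooled(v):
        x = np.tile([v[0], v[1], -4.0, 0.0], (S, 1))
        return -float(np.sum(data.loglik(x)))

    res = minimize(neg_pooled, np.array(best), method="Nelder-Mead",
                   options={"maxiter": 200, "xatol": 1e-3, "fatol": 1e-3})
    return np.array([res.x[0], res.x[1], -4.0, 0.0])


# -- sampler ------------------------------------------------------------------

def _run_chain(data: _ChoiceData, config: FitConfig, chain: int,
               x_center: np.ndarray):
    rng = np.random.default_rng(config.seed * 1000 + chain)
    S = len(data.subjects)
    # frozen ridge direction of the q-k likelihood degeneracy: the choice
    # variance is (c/omega)^q / k, so raising log q by d and log k by
    # q * E[log(c/omega)] * d leaves typical variances unchanged -- a slow
    # collective mode that subject-wise updates alone mix poorly
    Lbar = float(np.mean(np.log(np.concatenate(
        [data.c1[data.mask], data.c2[data.mask]]) / data.omega)))
    ridge_slope = float(np.exp(x_center[0]) * Lbar)
    x = x_center + rng.normal(0.0, [0.2, 0.4, 0.5, 0.1], size=(S, 4))
    mu = x.mean(axis=0)
    sigma = np.maximum(x.std(axis=0), 0.05)
    # per-subject proposal Cholesky factors, adapted to the posterior
    # covariance during burn-in only (the q-k ridge needs correlated moves)
    chol = np.tile(np.diag([0.05, 0.1, 0.3, 0.05]), (S, 1, 1))
    step = np.full(S, 1.0)
    ll = data.loglik(x)
    kept_x, kept_group = [], []
    n_total = config.burn_in + config.draws
    accept = np.zeros(S)
    history = []
    for it in range(n_total):
        # subject blocks: joint RW proposal, vectorized across subjects
        eps = rng.standard_normal((S, 4))
        prop = x + step[:, None] * np.einsum("sij,sj->si", chol, eps)
        ll_prop = data.loglik(prop)
        lp = np.sum(-0.5 * ((x - mu) / sigma) ** 2, axis=1)
        lp_prop = np.sum(-0.5 * ((prop - mu) / sigma) ** 2, axis=1)
        log_alpha = (ll_prop + lp_prop) - (ll + lp)
        acc = np.log(rng.random(S)) < log_alpha
        x[acc] = prop[acc]
        ll[acc] = ll_prop[acc]
        accept += acc
        if it < config.burn_in:
            history.append(x.copy())
            if (it + 1) % 50 == 0:
                rate = accept / 50.0
                step *= np.exp(0.7 * (rate - 0.3))
                step = np.clip(step, 1e-3, 10.0)
                accept[:] = 0.0
            if (it + 1) % 200 == 0 and len(history) >= 300:
                recent = np.array(history[-300:])  # (300, S, 4)
                for s in range(S):
                    C = np.cov(recent[:, s, :].T) + 1e-6 * np.eye(4)
                    try:
                        chol[s] = np.linalg.cholesky((2.38 ** 2 / 4.0) * C)
                    except np.linalg.LinAlgError:
                        pass
        # global ridge move: shift every subject and the group mean along
        # the frozen (log q, log k) degeneracy direction (symmetric
        # proposal; the group-prior term is translation invariant)
        d = rng.normal(0.0, 0.03)
        shift = np.array([d, ridge_slope * d, 0.0, 0.0])
        mu_g = mu + shift
        if np.all(mu_g >= _MU_LO) and np.all(mu_g <= _MU_HI):
            x_g = x + shift
            ll_g = data.loglik(x_g)
            if np.log(rng.random()) < np.sum(ll_g - ll):
                x, ll, mu = x_g, ll_g, mu_g
        # group Gibbs: bounded-flat prior on mu (truncated-normal draw),
        # flat bounded prior on sigma
        xbar = x.mean(axis=0)
        sd_mu = sigma / np.sqrt(S)
        lo_u = ndtr((_MU_LO - xbar) / sd_mu)
        hi_u = ndtr((_MU_HI - xbar) / sd_mu)
        u = lo_u + rng.random(4) * (hi_u - lo_u)
        mu = xbar + sd_mu * ndtri(np.clip(u, 1e-12, 1 - 1e-12))
        ss = np.sum((x - mu) ** 2, axis=0)
        sig2 = ss / (2.0 * rng.gamma((S - 1) / 2.0, 1.0, size=4))
        sigma = np.minimum(np.sqrt(sig2), config.sigma_max)
        sigma = np.maximum(sigma, 1e-3)
        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            kept_x.append(x.copy())
            kept_group.append(np.concatenate([mu, sigma]))
    return np.array(kept_x), np.array(kept_group)


def gelman_rubin(chains_draws: np.ndarray) -> float:
    """Gelman-Rubin potential scale reduction factor of one scalar latent.

    ``chains_draws`` has shape (chains, draws). Implemented as
    ``R-hat = sqrt((W + B/N) / W)`` with ``W`` the mean within-chain
    variance and ``B`` the between-chain variance of the means scaled by
    ``N`` — i.e. the classic PSRF without the (N-1)/N finite-sample
    deflation, so identical chains give exactly 1.
    """
    draws = np.asarray(chains_draws, dtype=float)
    if draws.ndim != 2 or draws.shape[0] < 2:
        raise ValueError("need draws from at least 2 chains of equal length")
    n = draws.shape[1]
    W = draws.var(axis=1, ddof=1).mean()
    B = n * draws.mean(axis=1).var(ddof=1)
    if W <= 0:
        return 1.0 if B <= 0 else np.inf
    return float(np.sqrt((W + B / n) / W))


def fit_hierarchical(trials: pd.DataFrame, config: FitConfig | None = None,
                     prior_steepness: float = 1.85) -> PosteriorSummary:
    """Fit the hierarchical observer model to a TrialTable of choices.

    Returns posterior draws for group-level means/sds (transformed scales)
    and subject-level parameters, with a Gelman-Rubin diagnostic for every
    group latent. Any R-hat at or above 1.05 raises a ConvergenceWarning;
    degenerate data (all choices identical) raises an identifiability
    warning.
    """
    if config is None:
        config = FitConfig()
    if trials["subject"].nunique() < 2:
        raise ValueError("hierarchical fit requires at least 2 subjects")
    if trials["choice"].nunique() < 2:
        warnings.warn("all choices identical: parameters are weakly "
                      "identified", UserWarning)
    data = _ChoiceData(trials, prior_steepness)
    center = _coarse_init(data)
    sub_all, grp_all = [], []
    for chain in range(config.chains):
        kx, kg = _run_chain(data, config, chain, center)
        sub_all.append(kx)
        grp_all.append(kg)
    subject_draws = np.array(sub_all)          # (chains, kept, S, 4)
    group = np.array(grp_all)                  # (chains, kept, 8)
    names = ([f"mu_{n}" for n in _PARAM_NAMES]
             + [f"sigma_{n}" for n in _PARAM_NAMES])
    group_draws = {name: group[:, :, j] for j, name in enumerate(names)}
    rhat = {name: gelman_rubin(d) for name, d in group_draws.items()}
    converged = all(r < 1.05 for r in rhat.values())
    if not converged:
        bad = {k: round(v, 3) for k, v in rhat.items() if v >= 1.05}
        warnings.warn(f"chains did not converge (R-hat >= 1.05): {bad}",
                      ConvergenceWarning)
    return PosteriorSummary(
        group_draws=group_draws, subject_draws=subject_draws, rhat=rhat,
        n_retained=int(group.shape[0] * group.shape[1]),
        subjects=list(data.subjects), converged=converged,
    )


def posterior_prob(contrast_draws) -> float:
    """Two-sided MCMC p-value of a scalar contrast.

    ``P_MCMC = 1 - max(P(draws > 0), P(draws < 0))``: zero when all draws
    share a sign, 0.5 for a contrast symmetric about zero.
    """
    d = np.asarray(contrast_draws, dtype=float)
    p_pos = np.mean(d > 0)
    p_neg = np.mean(d < 0)
    return float(1.0 - max(p_pos, p_neg))


def map_grid_fit(trials: pd.DataFrame, q_grid, k_grid, lapse_grid=(0.0,),
                 bias_grid=(0.0,), prior_steepness: float = 1.85):
    """Exhaustive grid maximum-likelihood point estimates (sampler oracle).

    Evaluates the choice log-likelihood on the product grid for every
    subject; returns (per-subject argmax dict, pooled argmax tuple), each
    argmax a (q, k, lapse, side_bias) tuple.
    """
    data = _ChoiceData(trials, prior_steepness)
    S = len(data.subjects)
    best_ll = np.full(S, -np.inf)
    best = [None] * S
    pooled_best, pooled_ll = None, -np.inf
    for q in q_grid:
        for k in k_grid:
            for lam in lapse_grid:
                for b0 in bias_grid:
                    lam_c = float(np.clip(lam, 1e-9, 1 - 1e-9))
                    x = np.tile([np.log(q), np.log(k),
                                 np.log(lam_c / (1 - lam_c)), b0], (S, 1))
                    ll = data.loglik(x)
                    tot = float(ll.sum())
                    upd = ll > best_ll
                    for i in np.where(upd)[0]:
                        best[i] = (q, k, lam, b0)
                    best_ll = np.maximum(best_ll, ll)
                    if tot > pooled_ll:
                        pooled_best, pooled_ll = (q, k, lam, b0), tot
    per_subject = dict(zip(data.subjects, best))
    return per_subject, pooled_best


class HierarchicalChoiceModel:
    """Estimator-style wrapper around :func:`fit_hierarchical`.

    Follows the fit/attributes convention: ``fit(trials)`` runs the MCMC
    and exposes ``summary_``, ``rhat_`` and ``group_q_`` fitted attributes.
    """

    def __init__(self, chains: int = 3, burn_in: int = 20000,
                 draws: int = 5000, thin: int = 5, seed: int = 0,
                 prior_steepness: float = 1.85):
        self.chains = chains
        self.burn_in = burn_in
        self.draws = draws
        self.thin = thin
        self.seed = seed
        self.prior_steepness = prior_steepness

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in
                ("chains", "burn_in", "draws", "thin", "seed",
                 "prior_steepness")}

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, trials: pd.DataFrame):
        cfg = FitConfig(chains=self.chains, burn_in=self.burn_in,
                        draws=self.draws, thin=self.thin, seed=self.seed)
        self.summary_ = fit_hierarchical(trials, cfg, self.prior_steepness)
        self.rhat_ = self.summary_.rhat
        self.group_q_ = float(np.median(self.summary_.group_q()))
        self.group_k_ = float(np.median(self.summary_.group_k()))
        return self


# -- posterior draw export ----------------------------------------------------

def draws_to_frame(summary: PosteriorSummary) -> pd.DataFrame:
    """Long-format export of all posterior draws
    (parameter, level, chain, iteration, value)."""
    recs = []
    for name, arr in summary.group_draws.items():
        C, N = arr.shape
        for c in range(C):
            recs.append(pd.DataFrame({
                "parameter": name, "level": "group", "chain": c,
                "iteration": np.arange(N), "value": arr[c]}))
    C, N, S, P = summary.subject_draws.shape
    for j, pname in enumerate(_PARAM_NAMES):
        for c in range(C):
            for i, subj in enumerate(summary.subjects):
                recs.append(pd.DataFrame({
                    "parameter": pname, "level": f"subject:{subj}",
                    "chain": c, "iteration": np.arange(N),
                    "value": summary.subject_draws[c, :, i, j]}))
    return pd.concat(recs, ignore_index=True)
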