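"""Capacity-constrained network experiment: a stochastic encoder trained
with a variational information-bottleneck (VIB) style objective.

The agent sees two retinal images (oriented Gabor patches), encodes each
through a shared convolutional encoder into a K-dimensional Gaussian latent
code, and a small downstream network decides which input is more diagonal.
The training loss is

    E[reward loss] + beta * I,

where ``I`` is the KL divergence of the encoder posterior from a standard
normal latent prior (summed over both retinal inputs) and the reward loss
is the expected misclassification probability, weighted in the reward
context by the absolute diagonality difference of the pair (so costly
mistakes — confusing a cardinal with an oblique — dominate).

Everything is plain numpy with hand-written backpropagation and Adam; the
network is small (4 conv filters, K = 4 latents, a 20-unit downstream
layer) and trains on CPU in seconds. Encoder precision over the angle
space is read out as Fisher information from the rescaled mean latent
trajectory, J(s) = || d z_bar / d s ||^2, on a 0-45 degree grid in steps
of 0.5 degrees with 500 samples per angle.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .domains import make_orientation_prior, orientation_to_diagonality

#: the network stack runs in single precision: the stochastic objective is
#: noise-dominated far above float32 resolution, and transcendentals and
#: matmuls run about twice as fast
_DT = np.float32

__all__ = [
    "GaborSpec",
    "NetworkSpec",
    "VIBConfig",
    "FisherCurve",
    "render_gabor",
    "init_model",
    "vib_losses",
    "train",
    "fisher_curve",
    "freeze_encoder_retrain",
    "evaluate",
    "run_context_signature",
    "run_freeze_experiment",
]

#: defaults of the desk-scale experiment runs: learning rate raised to 1e-3
#: (step counts are CPU-minutes scale, where 1e-4 has not yet converged),
#: a KL weight that makes the information budget bind, pair separations
#: spanning fine to coarse discriminations, and a shared accuracy target
#: all compared models are calibrated to
EXPERIMENT_LR = 1e-3
EXPERIMENT_BETA = 0.02
EXPERIMENT_OFFSETS = (0.5, 25.0)
EXPERIMENT_TARGET_ACC = 0.85
#: the encoder-transfer comparison runs at a tighter information budget —
#: the frozen-encoder handicap is an information-destruction effect, which
#: only binds when the bottleneck does — with the behavioural calibration
#: level (75% correct, the staircase design target) as the shared accuracy
#: every compared model is trained to
TRANSFER_BETA = 0.1
TRANSFER_TARGET_ACC = 0.75


@dataclass(frozen=True)
class GaborSpec:
    """Pixel recipe for an oriented Gabor patch."""

    size: int = 32
    cycles: float = 3.0          # cycles across the image
    envelope: float = 0.22       # Gaussian envelope width, fraction of image
    phase_policy: str = "random"  # "random" | "fixed"
    contrast: float = 1.0

    def __post_init__(self):
        if self.cycles <= 0:
            raise ValueError("spatial frequency must be positive")
        if not 0 < self.envelope <= 0.5:
            raise ValueError("envelope width must lie within the image")


def render_gabor(spec: GaborSpec, angle_deg: float,
                 rng: np.random.Generator | None = None,
                 phase: float | None = None) -> np.ndarray:
    """Oriented sinusoid under a centred Gaussian envelope, values in [0, 1]."""
    n = spec.size
    ax = (np.arange(n) - (n - 1) / 2.0) / n
    X, Y = np.meshgrid(ax, ax, indexing="xy")
    theta = np.radians(angle_deg)
    if phase is None:
        if spec.phase_policy == "random":
            if rng is None:
                raise ValueError("random phase policy needs an rng")
            phase = float(rng.uniform(0.0, 2.0 * np.pi))
        else:
            phase = 0.0
    u = X * np.cos(theta) + Y * np.sin(theta)
    grating = np.cos(2.0 * np.pi * spec.cycles * u + phase)
    env = np.exp(-(X ** 2 + Y ** 2) / (2.0 * spec.envelope ** 2))
    return 0.5 + 0.5 * spec.contrast * grating * env


def render_batch(spec: GaborSpec, angles_deg: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    """Vectorized rendering of a batch of patches (one phase draw each)."""
    angles_deg = np.asarray(angles_deg, dtype=float)
    B = len(angles_deg)
    phases = (rng.uniform(0.0, 2.0 * np.pi, size=B)
              if spec.phase_policy == "random" else np.zeros(B))
    n = spec.size
    ax = ((np.arange(n) - (n - 1) / 2.0) / n).astype(_DT)
    X, Y = np.meshgrid(ax, ax, indexing="xy")
    theta = np.radians(angles_deg)[:, None, None].astype(_DT)
    u = X * np.cos(theta) + Y * np.sin(theta)
    phase32 = phases[:, None, None].astype(_DT)
    grating = np.cos(_DT(2.0 * np.pi * spec.cycles) * u + phase32)
    env = np.exp(-(X ** 2 + Y ** 2) / _DT(2.0 * spec.envelope ** 2))
    return _DT(0.5) + _DT(0.5 * spec.contrast) * grating * env


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture: conv(4x4, stride 2, 4 filters) -> K-dim stochastic
    latent -> 20-unit ReLU layer -> sigmoid decision unit. The encoder is
    shared across the two retinal inputs."""

    image_size: int = 32
    conv_filters: int = 4
    kernel: int = 4
    stride: int = 2
    latent_dim: int = 4
    hidden: int = 20
    learning_rate: float = 1e-4


@dataclass(frozen=True)
class VIBConfig:
    """Training configuration for one context."""

    beta: float = 1e-3
    context: str = "accuracy"    # "accuracy" | "reward"
    steps: int = 4000
    batch_size: int = 64
    seed: int = 0
    prior_steepness: float = 1.85
    offset_range: tuple = (2.0, 15.0)   # diagonality separation of the pair
    target_accuracy: float | None = None  # early-stop band centre (+-1%)
    eval_every: int = 100
    eval_n: int = 2048  # held-out pairs per evaluation (band is +-1%)

    def __post_init__(self):
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.context not in ("accuracy", "reward"):
            raise ValueError(f"unknown context {self.context!r}")


@dataclass(frozen=True)
class FisherCurve:
    angles: np.ndarray
    J: np.ndarray
    samples_per_angle: int


# -- model -------------------------------------------------------------------

def _conv_dims(spec: NetworkSpec) -> tuple[int, int]:
    out = (spec.image_size - spec.kernel) // spec.stride + 1
    return out, out * out * spec.conv_filters


def init_model(spec: NetworkSpec, rng: np.random.Generator) -> dict:
    """He-initialized parameter dictionary."""
    out, feat = _conv_dims(spec)
    K, H = spec.latent_dim, spec.hidden
    ksz = spec.kernel * spec.kernel

    def he(shape, fan_in):
        return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(_DT)

    return {
        "Wc": he((spec.conv_filters, ksz), ksz),
        "bc": np.zeros(spec.conv_filters, dtype=_DT),
        "Wmu": he((K, feat), feat), "bmu": np.zeros(K, dtype=_DT),
        "Wlv": np.zeros((K, feat), dtype=_DT),
        "blv": np.full(K, -2.0, dtype=_DT),
        "Wh": he((H, 2 * K), 2 * K), "bh": np.zeros(H, dtype=_DT),
        "wo": he((H,), H), "bo": np.zeros(1, dtype=_DT),
        "_spec": spec,
    }


def _im2col(imgs: np.ndarray, spec: NetworkSpec) -> np.ndarray:
    # (B, n, n) -> (B, out*out, kernel*kernel)
    win = sliding_window_view(imgs, (spec.kernel, spec.kernel), axis=(1, 2))
    win = win[:, ::spec.stride, ::spec.stride]
    B, o1, o2, k1, k2 = win.shape
    return win.reshape(B, o1 * o2, k1 * k2)


def _encode_forward(model: dict, imgs: np.ndarray):
    spec = model["_spec"]
    P = _im2col(imgs, spec)                      # (B, O, ksz)
    C = P @ model["Wc"].T + model["bc"]          # (B, O, F)
    A = np.maximum(C, 0.0)
    E = A.reshape(A.shape[0], -1)                # (B, feat)
    mu = E @ model["Wmu"].T + model["bmu"]
    lv = np.clip(E @ model["Wlv"].T + model["blv"], -10.0, 6.0)
    return {"P": P, "C": C, "E": E, "mu": mu, "lv": lv}


def _forward(model: dict, X1, X2, rng: np.random.Generator):
    f1 = _encode_forward(model, X1)
    f2 = _encode_forward(model, X2)
    eps1 = rng.standard_normal(f1["mu"].shape, dtype=_DT)
    eps2 = rng.standard_normal(f2["mu"].shape, dtype=_DT)
    z1 = f1["mu"] + np.exp(0.5 * f1["lv"]) * eps1
    z2 = f2["mu"] + np.exp(0.5 * f2["lv"]) * eps2
    Z = np.concatenate([z1, z2], axis=1)
    Hpre = Z @ model["Wh"].T + model["bh"]
    H = np.maximum(Hpre, 0.0)
    o = H @ model["wo"] + model["bo"][0]
    p = 1.0 / (1.0 + np.exp(-o))
    return {"f1": f1, "f2": f2, "eps1": eps1, "eps2": eps2, "z1": z1,
            "z2": z2, "Z": Z, "Hpre": Hpre, "H": H, "p": p}


def vib_losses(model: dict, X1, X2, y, weights, beta: float,
               rng: np.random.Generator):
    """(reward-loss term, information term, total) for a batch of pairs.

    ``y`` is 1 when input 1 is the more diagonal; ``weights`` is 1 in the
    accuracy context and the normalized diagonality difference in the
    reward context. The reward loss is the weighted expected
    misclassification probability; the information term is the KL of both
    encoder posteriors from the standard-normal latent prior (in nats).
    """
    fw = _forward(model, X1, X2, rng)
    p = fw["p"]
    task = float(np.mean(weights * (y * (1.0 - p) + (1.0 - y) * p)))

    def kl(f):
        return 0.5 * np.sum(f["mu"] ** 2 + np.exp(f["lv"]) - 1.0 - f["lv"],
                            axis=1)
    info = float(np.mean(kl(fw["f1"]) + kl(fw["f2"])))
    return task, info, task + beta * info, fw


def _backward(model: dict, fw: dict, y, weights, beta: float) -> dict:
    B = len(y)
    p = fw["p"]
    do = weights * (1.0 - 2.0 * y) * p * (1.0 - p) / B
    g = {}
    g["wo"] = fw["H"].T @ do
    g["bo"] = np.array([do.sum()])
    dH = np.outer(do, model["wo"])
    dH[fw["Hpre"] <= 0] = 0.0
    g["Wh"] = dH.T @ fw["Z"]
    g["bh"] = dH.sum(axis=0)
    dZ = dH @ model["Wh"]
    K = model["_spec"].latent_dim
    dz = {1: dZ[:, :K], 2: dZ[:, K:]}

    spec = model["_spec"]
    for name in ("Wc", "bc", "Wmu", "bmu", "Wlv", "blv"):
        g[name] = np.zeros_like(model[name])
    for idx in (1, 2):
        f = fw[f"f{idx}"]
        eps = fw[f"eps{idx}"]
        dmu = dz[idx] + beta * f["mu"] / B
        dlv = (dz[idx] * eps * np.exp(0.5 * f["lv"]) * 0.5
               + beta * 0.5 * (np.exp(f["lv"]) - 1.0) / B)
        g["Wmu"] += dmu.T @ f["E"]
        g["bmu"] += dmu.sum(axis=0)
        g["Wlv"] += dlv.T @ f["E"]
        g["blv"] += dlv.sum(axis=0)
        dE = dmu @ model["Wmu"] + dlv @ model["Wlv"]
        dA = dE.reshape(f["C"].shape)
        dC = np.where(f["C"] > 0, dA, 0.0)
        g["Wc"] += np.einsum("bof,boi->fi", dC, f["P"])
        g["bc"] += dC.sum(axis=(0, 1))
    return g


class _Adam:
    def __init__(self, model: dict, lr: float):
        self.lr = lr
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in model.items()
                  if not k.startswith("_")}
        self.v = {k: np.zeros_like(v) for k, v in model.items()
                  if not k.startswith("_")}

    def step(self, model: dict, grads: dict):
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k in self.m:
            self.m[k] = b1 * self.m[k] + (1 - b1) * grads[k]
            self.v[k] = b2 * self.v[k] + (1 - b2) * grads[k] ** 2
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            model[k] = model[k] - self.lr * mhat / (np.sqrt(vhat) + eps)


def _sample_pairs(config: VIBConfig, gabor: GaborSpec, n: int,
                  rng: np.random.Generator, prior):
    """Angle pairs mirroring the behavioural task statistics."""
    ref = prior.ppf(rng.random(n))
    d_ref = orientation_to_diagonality(ref)
    off = rng.uniform(*config.offset_range, size=n)
    sign = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    d_cmp = np.clip(d_ref + sign * off, 0.0, 45.0)
    base = 90.0 * np.floor(ref / 90.0)
    within = ref - base
    cmp_angle = np.where(within <= 45.0, base + d_cmp, base + 90.0 - d_cmp)
    swap = rng.random(n) < 0.5
    a1 = np.where(swap, cmp_angle, ref)
    a2 = np.where(swap, ref, cmp_angle)
    d1 = orientation_to_diagonality(a1)
    d2 = orientation_to_diagonality(a2)
    y = (d1 > d2).astype(_DT)
    # reward-context weights are normalized to unit mean so both contexts
    # face the same effective information pressure beta (only the *shape*
    # of the cost, not its scale, distinguishes the contexts)
    if config.context == "reward":
        w = np.abs(d1 - d2)
        mean_off = 0.5 * (config.offset_range[0] + config.offset_range[1])
        w = w / max(mean_off, 1e-12)
    else:
        w = np.ones(n)
    w = w.astype(_DT)
    X1 = render_batch(gabor, a1, rng)
    X2 = render_batch(gabor, a2, rng)
    return X1, X2, y, w, d1, d2


def evaluate(model: dict, config: VIBConfig, gabor: GaborSpec,
             n: int, rng: np.random.Generator, prior) -> dict:
    """Held-out discrimination accuracy and reward-context loss metric."""
    X1, X2, y, _, d1, d2 = _sample_pairs(config, gabor, n, rng, prior)
    fw = _forward(model, X1, X2, rng)
    p = fw["p"]
    acc = float(np.mean((p > 0.5) == (y > 0.5)))
    wd = np.abs(d1 - d2) / 45.0
    reward_loss = float(np.mean(wd * (y * (1 - p) + (1 - y) * p)))
    return {"accuracy": acc, "reward_loss": reward_loss}


def train(model: dict, config: VIBConfig,
          gabor: GaborSpec | None = None) -> tuple[dict, dict]:
    """Train a model in one context; returns (model, trace).

    The loss trace is recorded every ``eval_every`` steps together with
    held-out accuracy. With a ``target_accuracy``, the parameters whose
    held-out accuracy lies closest to the target are snapshotted at every
    evaluation and restored at the end (and training stops early once the
    accuracy enters a +-1% band around the target) — the calibration device
    used before comparing reward losses across models. Divergence (loss
    above 10x its initial value) aborts with the trace.
    """
    if gabor is None:
        gabor = GaborSpec()
    rng = np.random.default_rng(config.seed)
    prior = make_orientation_prior(config.prior_steepness)
    opt = _Adam(model, model["_spec"].learning_rate)
    trace = {"step": [], "loss": [], "task": [], "info": [], "accuracy": []}
    loss0 = None
    best_gap, best_snap = np.inf, None
    for step in range(1, config.steps + 1):
        X1, X2, y, w, _, _ = _sample_pairs(config, gabor, config.batch_size,
                                           rng, prior)
        task, info, total, fw = vib_losses(model, X1, X2, y, w, config.beta,
                                           rng)
        if loss0 is None:
            loss0 = total
        if total > 10.0 * max(loss0, 1e-6):
            raise RuntimeError(f"training diverged at step {step}: "
                               f"loss {total:.4g} vs initial {loss0:.4g}")
        grads = _backward(model, fw, y, w, config.beta)
        opt.step(model, grads)
        if step % config.eval_every == 0 or step == config.steps:
            ev = evaluate(model, config, gabor, config.eval_n,
                          np.random.default_rng(config.seed + 13), prior)
            trace["step"].append(step)
            trace["loss"].append(total)
            trace["task"].append(task)
            trace["info"].append(info)
            trace["accuracy"].append(ev["accuracy"])
            if config.target_accuracy is not None:
                gap = abs(ev["accuracy"] - config.target_accuracy)
                if gap < best_gap:
                    best_gap = gap
                    best_snap = {k: v.copy() for k, v in model.items()
                                 if isinstance(v, np.ndarray)}
                if gap <= 0.01:
                    break
    if best_snap is not None:
        model.update(best_snap)
    return model, trace


def fisher_curve(model: dict, samples_per_angle: int = 500,
                 gabor: GaborSpec | None = None, seed: int = 0,
                 smooth: int = 5) -> FisherCurve:
    """Fisher information of the encoder over the 0-45 degree angle grid.

    For each angle, ``samples_per_angle`` stochastic latent responses are
    drawn (random Gabor phases and encoder noise); each latent dimension is
    rescaled to unit noise variance, the mean trajectory is smoothed with a
    ``smooth``-point moving average, and J(s) is the squared norm of its
    central-difference derivative. Dimensions with vanishing noise variance
    are rescaled with a small floor.
    """
    if gabor is None:
        gabor = GaborSpec()
    rng = np.random.default_rng(seed)
    angles = np.arange(0.0, 45.0 + 1e-9, 0.5)
    K = model["_spec"].latent_dim
    zbar = np.zeros((len(angles), K))
    noise_var = np.zeros((len(angles), K))
    for i, ang in enumerate(angles):
        imgs = render_batch(gabor, np.full(samples_per_angle, ang), rng)
        f = _encode_forward(model, imgs)
        z = f["mu"] + np.exp(0.5 * f["lv"]) * rng.standard_normal(
            f["mu"].shape, dtype=_DT)
        zbar[i] = z.mean(axis=0)
        noise_var[i] = z.var(axis=0)
    sd = np.sqrt(np.maximum(noise_var.mean(axis=0), 1e-12))
    zs = zbar / sd
    if smooth > 1:
        kern = np.ones(smooth) / smooth
        zs = np.apply_along_axis(
            lambda c: np.convolve(np.pad(c, smooth // 2, mode="edge"), kern,
                                  mode="valid"), 0, zs)
    dz = np.gradient(zs, angles, axis=0)
    J = np.sum(dz ** 2, axis=1)
    return FisherCurve(angles=angles, J=J,
                       samples_per_angle=samples_per_angle)


def freeze_encoder_retrain(source_model: dict, reward_config: VIBConfig,
                           gabor: GaborSpec | None = None,
                           hidden: int | None = None) -> tuple[dict, dict]:
    """Retrain only the downstream circuit of a trained model in a new context.

    The convolutional and latent (encoder) weights are frozen; the
    downstream layer — whose width may be changed via ``hidden`` to probe
    whether extra downstream complexity can compensate — and the decision
    unit are re-initialized and trained under the new context's loss.
    """
    if gabor is None:
        gabor = GaborSpec()
    spec = source_model["_spec"]
    if hidden is not None and hidden != spec.hidden:
        spec = replace(spec, hidden=hidden)
    rng = np.random.default_rng(reward_config.seed + 31)
    model = {k: (v.copy() if isinstance(v, np.ndarray) else v)
             for k, v in source_model.items()}
    model["_spec"] = spec
    K, H = spec.latent_dim, spec.hidden
    model["Wh"] = rng.normal(0.0, np.sqrt(2.0 / (2 * K)), size=(H, 2 * K))
    model["bh"] = np.zeros(H)
    model["wo"] = rng.normal(0.0, np.sqrt(2.0 / H), size=(H,))
    model["bo"] = np.zeros(1)

    frozen = ("Wc", "bc", "Wmu", "bmu", "Wlv", "blv")
    prior = make_orientation_prior(reward_config.prior_steepness)
    opt = _Adam(model, spec.learning_rate)
    best_gap, best_snap = np.inf, None
    rng_t = np.random.default_rng(reward_config.seed)
    trace = {"step": [], "loss": [], "accuracy": []}
    for step in range(1, reward_config.steps + 1):
        X1, X2, y, w, _, _ = _sample_pairs(reward_config, gabor,
                                           reward_config.batch_size, rng_t,
                                           prior)
        task, info, total, fw = vib_losses(model, X1, X2, y, w,
                                           reward_config.beta, rng_t)
        grads = _backward(model, fw, y, w, reward_config.beta)
        for name in frozen:
            grads[name][:] = 0.0
        opt.step(model, grads)
        if step % reward_config.eval_every == 0:
            ev = evaluate(model, reward_config, gabor,
                          reward_config.eval_n,
                          np.random.default_rng(reward_config.seed + 13),
                          prior)
            trace["step"].append(step)
            trace["loss"].append(total)
            trace["accuracy"].append(ev["accuracy"])
            if reward_config.target_accuracy is not None:
                gap = abs(ev["accuracy"] - reward_config.target_accuracy)
                if gap < best_gap:
                    best_gap = gap
                    best_snap = {k: v.copy() for k, v in model.items()
                                 if isinstance(v, np.ndarray)}
                if gap <= 0.01:
                    break
    if best_snap is not None:
        model.update(best_snap)
    return model, trace


def _experiment_config(context: str, seed: int, steps: int, beta: float,
                       target: float | None) -> VIBConfig:
    return VIBConfig(beta=beta, context=context, steps=steps, seed=seed,
                     target_accuracy=target,
                     offset_range=EXPERIMENT_OFFSETS)


def run_context_signature(seeds=(1, 2, 3, 4, 5), steps: int = 8000,
                          beta: float = EXPERIMENT_BETA,
                          target: float | None = None,
                          samples_per_angle: int = 200,
                          return_models: bool = False) -> dict:
    """Train accuracy- and reward-context networks and compare encoders.

    For every seed, one network per context is trained for a fixed number
    of steps (the allocation contrast develops with training; optional
    early stopping at a shared ``target`` accuracy is available but cuts
    training short at seed-dependent points). The Fisher-information curve
    of each encoder is normalized to unit area — the resource
    *allocation*, the quantity the capacity budget constrains — and
    summarized by its mean over the cardinal (0-15 degree) and oblique
    (30-45 degree) thirds of the angle space. The theory predicts accuracy
    training concentrates allocation at the cardinals while reward
    training shifts it toward the obliques.
    """
    spec = NetworkSpec(learning_rate=EXPERIMENT_LR)
    out = {"seeds": list(seeds), "accuracy": [], "reward": []}
    models = {}
    for ctx in ("accuracy", "reward"):
        for seed in seeds:
            model = init_model(spec, np.random.default_rng(seed))
            cfg = _experiment_config(ctx, seed, steps, beta, target)
            model, _ = train(model, cfg)
            fc = fisher_curve(model, samples_per_angle=samples_per_angle,
                              seed=seed + 100)
            Jn = fc.J / np.trapezoid(fc.J, fc.angles)
            out[ctx].append({
                "seed": seed,
                "cardinal": float(Jn[fc.angles <= 15.0].mean()),
                "oblique": float(Jn[fc.angles >= 30.0].mean()),
            })
            models[(ctx, seed)] = model
    if return_models:
        out["models"] = models
    return out


def run_freeze_experiment(seeds=(1, 2, 3), steps: int = 8000,
                          beta: float = TRANSFER_BETA,
                          target: float = TRANSFER_TARGET_ACC,
                          hidden: int | None = None,
                          source_models: dict | None = None,
                          scratch_models: dict | None = None,
                          eval_n: int = 6000, base_seed: int = 0) -> dict:
    """Encoder-transfer experiment: freeze vs retrain vs from-scratch.

    Per seed, four models calibrated to the same discrimination accuracy:
    an accuracy-context source, its frozen-encoder reward retrain, its
    fully retrained (unfrozen) counterpart, and a reward-context model
    trained from scratch. Reward losses are evaluated on a common held-out
    pair stream. The information-theoretic prediction: the frozen encoder
    cannot recover the reward-relevant information it discarded, so its
    reward loss stays above the from-scratch level, while unfrozen
    retraining closes the gap.
    """
    spec = NetworkSpec(learning_rate=EXPERIMENT_LR)
    gabor = GaborSpec()
    prior = make_orientation_prior(1.85)
    rows = []
    for seed in seeds:
        acfg = _experiment_config("accuracy", base_seed + seed, steps, beta,
                                  target)
        if source_models and seed in source_models:
            source = source_models[seed]
        else:
            source = init_model(spec, np.random.default_rng(base_seed + seed))
            source, _ = train(source, acfg)
        rcfg = _experiment_config("reward", base_seed + seed + 500, steps,
                                  beta, target)
        if scratch_models and seed in scratch_models:
            scratch = scratch_models[seed]
        else:
            scratch = init_model(spec,
                                 np.random.default_rng(base_seed + seed + 1000))
            scratch, _ = train(scratch, rcfg)
        frozen, _ = freeze_encoder_retrain(source, rcfg, hidden=hidden)
        unfrozen = {k: (v.copy() if isinstance(v, np.ndarray) else v)
                    for k, v in source.items()}
        unfrozen, _ = train(unfrozen, rcfg)
        row = {"seed": seed}
        for name, model in (("frozen", frozen), ("unfrozen", unfrozen),
                            ("scratch", scratch)):
            ev = evaluate(model, rcfg, gabor, eval_n,
                          np.random.default_rng(base_seed + 999), prior)
            row[f"{name}_reward_loss"] = ev["reward_loss"]
            row[f"{name}_accuracy"] = ev["accuracy"]
        rows.append(row)
    out = {"per_seed": rows}
    for name in ("frozen", "unfrozen", "scratch"):
        out[f"mean_{name}_reward_loss"] = float(np.mean(
            [r[f"{name}_reward_loss"] for r in rows]))
        out[f"mean_{name}_accuracy"] = float(np.mean(
            [r[f"{name}_accuracy"] for r in rows]))
    return out
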