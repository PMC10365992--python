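# Methods notes

This note records the models implemented, the numerical choices behind
them, and what the synthetic data can and cannot show. It states no result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Normative core (`fitcode.coding`, `fitcode.domains`)

Stimulus spaces are bounded 1-D domains with a fixed evaluation grid
(default 1024 points); priors are tabulated densities validated to unit
trapezoid integral. The parametric orientation prior is
`f(s) = ω/(a − cos 4s)` with `s` in degrees and the cosine acting on the
angle in radians — the only reading that gives the 90° period of natural
edge statistics. `a = 1.85` throughout; `a → ∞` tends to uniform.

Escort responses are cumulative trapezoids of `f^γ`. Quantized codes place
the `n − 1` cut points where `h` crosses `i/n` by monotone interpolation;
a plateau of `h` under a required crossing raises a dedicated error rather
than silently producing a degenerate level.

The two loss functionals treat a binary choice between i.i.d. draws from
the prior. Stimuli in the same level are indistinguishable and resolved by
a fair coin (hence the 1/2 factors); any deterministic tie-break would
bias the loss. The reward loss also charges cross-level pairs whose
level ranking disagrees with the reward ranking — zero for monotone maps,
but it keeps the functional meaningful for tabulated non-monotone maps
(which are completed by linear interpolation between given points).
Within-level integrals use iterated trapezoids on the level's sub-grid;
the Monte-Carlo oracle in the tests bounds the quadrature error.

The escort-exponent search is a coarse grid (step 0.02 on [0.3, 1.5])
followed by bounded scalar refinement; the objective was unimodal in γ in
every case tested, and a brute-force fine grid agrees with the refined
minimizer within 0.01.

## Bayesian observer (`fitcode.observer`)

Encoding is Gaussian with variance `1/(k f(s)^q)` — the power-law
efficient code. The likelihood is kept Gaussian (not von Mises) on the
circular orientation space: discrimination thresholds are a few degrees
against a 180° period, so the local-Gaussian approximation is accurate,
and it is what makes the closed-form moments available. Decoding uses the
posterior mean on a 2048-point grid (responses outside the domain decode
against the same grid; posterior-mass underflow returns a flagged NaN).

The closed-form bias and variance are high-SNR approximations. They carry
a `(1 − 1/q)` prefactor, so `q = 0` is rejected rather than silently
extrapolated. For the parametric prior the derivative in the bias is
analytic, including the π/180 factor from degree units; for arbitrary
priors a grid gradient is used, and a test pins the two against each
other. The accuracy of the approximations depends on capacity: the
helpers `capacity_for_variance` and `capacity_for_separation_accuracy`
place observers in regimes where the worst-case estimator standard
deviation is a stated number of degrees, instead of asking callers to
guess `k` (whose scale depends on `q` through `f^q`, with `f` of order
1/180 per degree).

`matched_capacity_params` changes `q` at a fixed capacity budget
`∫ J^β ds` (β = 1/2). This is how adaptation is modelled: a *re-allocation*
of resources, which raises cardinal-orientation variance while lowering
oblique variance, rather than a free increase in precision.

Motor (response-dial) noise is an additive Gaussian term (default sd 2°)
applied to estimation reports only — never to the decision model — so the
encoding parameters stay interpretable when the generator's output is
re-fitted.

## Resource-allocation optimizers (`fitcode.allocation`, `fitcode.scenarios`)

Allocations are `J(s) = k f̃(s)` with `f̃` stored normalized. Candidate
shapes are exponentials of a cubic interpolant through 12 equispaced knots
(positivity and unit mass by construction). Crucially, the scale `k` is
recomputed per shape from a fixed capacity `c` via
`k = (c / ∫ f̃^β ds)^{1/β}` with β = 1/2, so the optimizer searches shapes
at *constant capacity*. Under this budget the monotone scenarios have the
analytic optima `f̃* ∝ f²` (accuracy) and `f̃* ∝ f^{4/3}` (linear reward);
holding `k` fixed instead would implicitly impose a β = 1 budget whose
optima are different power laws.

Two quadratures evaluate the pair loss:

* **Monotone scenarios** use a local substitution around each stimulus
  (`s₂ = s₁ + scale(s₁)·u`, `u ∈ [−8, 8]`), which resolves the error
  kernel at arbitrarily high capacity where a fixed pair grid cannot. The
  integrand is extended smoothly past the domain edges (log-linear density
  and allocation, linear reward): the analytic solutions hold in the
  boundary-free small-noise regime, and truncating instead creates edge
  layers a few discrimination standard deviations wide that the closed
  forms do not model. Decoded means are taken equal to the stimulus (bias
  is O(1/k) and immaterial at the capacities used); variances are `1/J`.
* **Threshold scenarios** (non-monotonic rewards) use a pair grid with
  Gauss–Hermite integration of `P(|τ − ŝ₁| < |τ − ŝ₂|)`, run at the
  moderate default capacity (`k = 500` for a uniform shape on the unit
  domain) where the grid resolves the error kernel.

Knot optimization is quasi-Newton (finite-difference L-BFGS-B) with seeded
random restarts; the loss is smooth in the knots, and a simplex method
proved materially slower and less precise at equal budgets. The oracle
comparisons run at capacity 400 (uniform-shape `k = 160 000`, i.e.
discrimination sd ≈ 0.25% of the domain), deep enough in the low-noise
regime that the numerical optimum is capacity-independent; the threshold
scenario keeps the moderate default, where the "not precisely at 0.5"
caveat (estimator bias and prior skew) applies but stays within ±0.05.

The drift-diffusion machinery uses the constant-bound closed forms
(logistic error probability, `(b/z)·tanh(bz)` mean decision time, `b²` at
`z = 0`). The simulation oracle is Euler–Maruyama with a Brownian-bridge
within-step crossing correction, without which the O(√dt) first-passage
bias exceeds the Monte-Carlo error at the tested path counts. Joint
(allocation, bound) optimization alternates knot updates with a bounded
1-D search for `b`; the time-cost grid is configuration, not hard-coded.

## Hierarchical fitting (`fitcode.fitting`)

Subject parameters live on transformed scales (log q, log k, logit λ,
identity β₀) with group-level normal laws; positivity and boundedness
force the transforms. Hyperpriors are flat but *proper*: bounded-uniform
group means (the logit-λ bound keeps that latent identified when subjects
never lapse — the likelihood is flat below logit ≈ −5) and a bounded-flat
prior on group sds (≤ 5 on the transformed scales, still vastly wider than
any plausible spread).

The sampler is Metropolis-within-Gibbs, vectorized across subjects:

* joint 4-D random-walk subject updates with per-subject proposal
  covariances adapted (during burn-in only) to the empirical posterior
  covariance — the `q`–`k` likelihood ridge (`log Var = q·log c − log k`)
  defeats axis-aligned proposals;
* a global move shifting *all* subjects and the group mean along the
  frozen ridge direction, targeting the slow collective mode;
* conjugate Gibbs draws for group means (truncated normal) and variances
  (inverse gamma from the `p(σ) ∝ 1` posterior).

Chains start from a pooled coarse-grid argmax polished by a local
continuous maximization, with per-chain overdispersed jitter. The
Gelman-Rubin statistic is implemented as `sqrt((W + B/N)/W)` — the classic
PSRF without the (N−1)/N deflation, so identical chains give exactly 1 —
and is reported for every group latent with a 1.05 convergence threshold.
The default schedule retains 3 × 5000/5 = 3000 draws per parameter; tests
and the recovery studies run a reduced schedule (3 × 600 retained after
1500 burn-in sweeps), where the recovery criteria — interval coverage of
the generating group `q`, the sign of a late-phase `q` drop — hold even
though some nuisance latents (lapse, side bias) keep elevated R-hat.
Early and late phases are fitted as independent models.

`map_grid_fit` provides a sampler-independent oracle: exhaustive
log-likelihood evaluation on small parameter grids.

## Synthetic experiments (`fitcode.synth`)

The generator reproduces the *structure* of the two behavioural
experiments: decision sessions (400 trials, or 360 in the four-location
design) with prior-drawn reference orientations, a comparison offset in
diagonality by an adaptive staircase, context payoffs (fixed 15 CHF per
correct choice, or 1–46 CHF linear in the chosen stimulus's diagonality),
and estimation sessions (240 or 400 trials, uniform orientations, evenly
cycled locations) run before and after training. The staircase is a
Kaernbach weighted up-down on the diagonality separation: +step after an
error, −step/3 after a success (stationary at 75% correct), initial
separation 10°, floor 0.5°, ceiling 30°, step 1.5°; the algorithm family
and step sizes are this package's choice — only the 75% target is given by
the task design. Simulated cohorts calibrated so a 10° separation is
discriminated at 90% land at a median staircase accuracy near 76%,
matching the human calibration band.

Estimation errors are signed positive when the report is more oblique than
the stimulus, with magnitude on the wrapped 180° scale; reports mirrored
exactly across a cardinal axis (equal diagonality) fall back to the
wrapped-difference sign so magnitude is never discarded. Trials with
|error| > 22.5° (25% of the maximal 90°) are dropped, boundary inclusive
for determinism. Summaries use five 9° diagonality bins with
after-minus-before change scores.

What the generator does *not* emulate: perceptual learning dynamics
(adaptation is imposed as a parameter change between phases, not learned),
sequential dependencies, attention or fixation lapses beyond the scalar λ,
and payment schemes (per-trial payoffs are recorded; aggregation is the
caller's business). Passing tests therefore show internal consistency of
model, generator and fitter — not that human data would fit this well.
Tests that compare before/after variance changes per location use common
random numbers across phases, so untrained locations change by exactly
zero and the parameter-change effect is isolated from binning noise.

## Capacity-constrained networks (`fitcode.ann`)

A shared convolutional encoder (4×4 kernels, stride 2, 4 filters) maps
each 32×32 Gabor image to a K = 4 Gaussian latent (diagonal covariance —
full covariance is configurable in principle but diagonal is the stable
desk-scale choice); a 20-unit layer and a sigmoid unit decide which input
is more diagonal. The objective is expected misclassification probability
(weighted by the pair's diagonality difference in the reward context)
plus β times the KL of both latent posteriors from a standard normal.
Reward-context weights are normalized to unit mean so both contexts face
the same effective information pressure; only the *shape* of the cost
distinguishes them. Everything is numpy with hand-written backprop and
Adam, in single precision (the stochastic objective sits far above
float32 resolution and the transcendentals and matmuls run about twice
as fast), trained on pair streams whose reference angles follow the
orientation prior with offsets drawn uniformly from a configurable range.

Experiment defaults (`EXPERIMENT_*`): learning rate 1e-3 (the
architecture's 1e-4 default has not converged at CPU-minute step counts),
β = 0.02 (the KL term binds at a few nats per input), offsets 0.5–25°.
Encoder Fisher information is estimated from 0° to 45° in 0.5° steps
(500 latent samples per angle by default) as the squared norm of the
derivative of the noise-rescaled mean latent, after a 5-point moving
average; a constant encoder's measured J is the finite-sample jitter
floor, shrinking as 1/samples.

The two experiments use different controls, each matched to its claim:

* **Context signature** (`run_context_signature`): both contexts train
  for a *fixed* number of steps — the allocation contrast develops with
  training, and early stopping at an accuracy target truncates it at
  seed-dependent points. Comparisons use Fisher curves normalized to unit
  area (the resource *allocation*), because total measured capacity
  varies with training-trajectory luck; the orderings are sign claims
  over seeds, not magnitudes.
* **Encoder transfer** (`run_freeze_experiment`): every compared model —
  frozen-encoder retrain, full retrain, from-scratch reward model — is
  *calibrated to a shared held-out accuracy target* by snapshotting the
  parameters whose evaluation accuracy is closest to it (frequent
  evaluations on a large held-out stream). Without this gate the
  comparison is meaningless: an uncalibrated frozen model inherits a
  longer-trained encoder and wins trivially. The transfer runs use a
  tighter budget (β = 0.1, ~1.5 nats per input): the frozen handicap is
  an information-destruction effect that only binds when the bottleneck
  does. The shared target is 75% correct — the same calibration level the
  behavioural staircase is designed around, and one every compared model
  reaches within the step budget (an unreachable target silently leaves
  models at unmatched accuracy, which dominates the loss comparison).
  The frozen-versus-scratch margin is ~10% of the loss at this scale;
  the full-retrain recovery is the most robust part of the pattern.

## Pipelines (`fitcode.cli`)

Every stochastic operation receives a seed derived from the global seed
and the operation's path string, so any run is reproducible from its
logged resolved configuration; result bundles carry a manifest of all
files written. The library functions are the primary interface; the CLI is
a thin wrapper for shell use.
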