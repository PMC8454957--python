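# Methods

## The problem

Non-invasive brain stimulation (here transcranial alternating current
stimulation, tACS) has two free parameters that matter behaviourally —
frequency and current amplitude — and the best setting appears to depend
on who is being stimulated. Running a full Bayesian-optimization loop
within each person is prohibitively expensive, so this package implements
a *personalized* Bayesian optimization (pBO): a single surrogate model is
learned across subjects, jointly over the stimulation parameters **x** =
(frequency, current) and a per-subject covariate *p* (baseline cognitive
ability), and each new subject receives the recommendation that maximizes
the acquisition function *at their own p*. Formally the target is
x\*(p) = argmax_x f(x, p) rather than a single global x\*.

## Objective: normalized drift rate

Behavioural performance in a 50-trial two-choice block is summarized by
the EZ-diffusion drift rate v, obtained in closed form from proportion
correct, and the mean and variance of correct-response RTs (scaling
constant s = 0.1). The objective is the normalized performance score

    f(x, p) = v_stim / v_base,

where v_stim is the drift rate of the stimulation block and v_base the
drift rate of 25 held-out baseline trials. The 50 baseline trials are
randomly split 25/25: one half yields the personalization covariate
p (the subject's baseline drift), the other half yields v_base, so the
covariate and the normalizer are conditionally independent given the
subject. A score of 1 means no change from baseline.

Conventions and edge handling: RT statistics use correct responses only;
proportion correct 1 (or 0) is replaced by 1 − 1/(2n) (or 1/(2n));
proportion correct exactly ½ raises a degenerate-drift error because the
boundary separation a = s²L/v is then undefined. The scaling constant is
configurable; drift and boundary scale linearly with it while ter and the
implied accuracy are invariant (tested).

The package also contains a Wiener first-passage simulator used as an
independent oracle for the estimator and as the noise engine of the
synthetic cohort. It uses Euler steps (default 1 ms) with the
Brownian-bridge within-step crossing correction, which removes the
leading O(√dt) discretization bias; at n = 10,000 trials the round trip
simulate → estimate recovers (v, a, ter) within a few percent.

## Search space and normalization

The hardware lattice is 5–50 Hz in 1 Hz steps × 0.1–1.6 mA in 0.1 mA
steps (736 points) during burn-in; the 0 mA sham row is added for the
optimization phase (782 points). Model-facing coordinates are min-max
normalized: frequency and current over the fixed physical bounds
(5–50 Hz, 0–1.6 mA in *both* phases, so training points never move in
kernel space when the phase changes), and p over configurable baseline
bounds, default [0, 0.2] drift-rate units — wide enough to bracket
typical baseline drifts around 0.055 with margin; out-of-bounds values
are clipped with a warning. Double blinding is preserved by a seeded
random bijection from grid points to opaque 3-digit codes, persisted to
JSON; the sham row is indistinguishable from active codes.

## Surrogate model

The GP prior uses a product of exponentiated-quadratic kernels,

    k({x_i, p_i}, {x_j, p_j}) = exp(−‖x_i−x_j‖²/(2σ_l²)) · exp(−(p_i−p_j)²/(2σ_p²)),

with observation noise σ_n² added once to the diagonal (index-keyed
Kronecker delta, so repeated measurements at the same grid point carry
independent noise). One length scale σ_l is shared by the two stimulation
coordinates. Outputs are standardized to N(0, 1) over the included
observations at each refit; the transform is stored so raw-scale
predictions can be reported. Hyperparameters are estimated by maximizing
the log marginal likelihood over log-parameters with analytic gradients
(L-BFGS-B, 10 restarts by default, seeded; warm-startable). Box bounds
σ_l, σ_p ∈ [10⁻², 10], σ_n² ∈ [10⁻⁴, 4] comfortably enclose the ranges
such fits occupy on normalized inputs. A jitter of 10⁻⁸ is added before
Cholesky factorization; posterior variances are clipped at 0. A very
large σ_p makes predictions independent of p, numerically reproducing the
standard (non-personalized) two-input GP used as comparator (tested at
σ_p = 10⁶).

## Acquisition

Expected improvement (default) over the best included standardized
observation f⁺, with EI defined as 0 at zero predictive uncertainty; a
GP-UCB alternative with configurable κ (plus a Srinivas-style schedule
helper) is retained. Because the deliverable is a discrete hardware
setting, the acquisition is maximized exhaustively over the ≤782-point
grid at the querying subject's p — exact and cheap — with ties broken by
a seeded uniform draw. Standardization makes the argmax invariant to
affine transforms of the raw scores (tested).

## Sequential protocol

Defaults: 50 subjects × 3 blocks = 150 assignments; the first 60
assignments (20 subjects) are burn-in draws sampled without replacement
from the active grid; thereafter each block's setting is the EI argmax at
the subject's p. The GP (standardization and hyperparameters) is refitted
after every observation to all included data; a configurable refit
schedule (`hyper_refit_every`) trades accuracy for speed on large runs.
Raw scores ≥ 3.6 (configurable, optional) are logged but excluded from
the model — an outlier policy, not part of the mathematics. Each update
records the model's predicted best achievable score at the current
subject's baseline (the per-iteration "predicted best" trace). The whole
loop is replayable: every random draw is derived from the protocol seed
and the assignment index. An optional dropout probability emulates
missing observations (logged as NaN, never modelled); off by default.

Cross-validation splits *participants* 80/20 (all blocks of a subject
stay together), fits the personalized GP on the training subjects'
(frequency, current, p) → raw score and reports test MSE on the raw score
scale. On near-noiseless synthetic cohorts MSE is of the order 10⁻³; with
additive score noise of SD 0.3 it is of the order of the noise variance
(~0.1), as expected for a well-calibrated regressor.

## Synthetic cohorts and ground-truth surfaces

The generator provides the study conditions for every end-to-end test:

* **Surface**: a Gaussian bump in unit coordinates, base 0.85, amplitude
  1.0, width 0.3, whose centre moves linearly from ~(0.8, 0.8) at p = 0
  (high frequency, high current for poor baselines) to ~(0.2, 0.2) at
  p = 1, with small seeded jitter on the endpoints; the optimum path
  x\*(p) is recorded exactly. Expected scores stay within [0.5, 3.8].
* **Cohort**: 50 subjects with latent baseline drifts drawn from
  Beta(2, 5) rescaled to [0, 0.2] (low-ability skew, mean ≈ 0.057); each
  subject carries 50 simulated baseline trials (boundary separation 0.3,
  non-decision time 0.35 s) and the 25/25 split estimates. Subjects whose
  half-blocks yield non-positive drift estimates are regenerated with a
  fresh seed (bounded retries) — the synthetic analogue of screening out
  chance-level participants; this slightly truncates the lowest abilities.
* **Scoring paths**: `diffusion` scores blocks through the full
  trial-simulation + estimation pipeline (realistic, ratio-of-estimates
  noise); `surface` adds Gaussian noise of configurable SD directly to the
  surface value and uses the true p (an idealized fast path for
  protocol-level analyses). Low-noise analyses use SD 0.01.

The end-to-end personalization analysis runs 20 independent replicates
of the full 50-subject protocol on low-noise (SD 0.01) surfaces and asks
whether the posterior-mean argmax lands within one lattice step of the
true optimum path at three probe baselines (cohort mean and ±1 SD), and
whether recommendations at low vs high baseline shift in the built-in
direction.

What passing these tests does *not* show about real data: the surfaces
are smooth and unimodal per baseline slice by construction, baseline
abilities follow an assumed Beta shape, and there is no fatigue,
learning, session, or placebo structure — so recovery rates here are an
upper bound on what a real cohort would give.

## Hartmann-3D benchmark

The negated Hartmann-3 function (global maximum ≈ 3.8628 at ≈ (0.1146,
0.5556, 0.8525)) stands in for the experiment: two controllable
coordinates plus an uncontrollable per-iteration baseline p_t ~ U[0, 1],
shared across algorithms within a repeat for pairing, as are the initial
design and the noise draws. Defaults: 60 iterations, 30 repeats, noise
variances {0, 0.01, 0.1, 0.5, 1, 2} (spanning zero through the magnitude
of the signal), a 10-point random initialization inside the budget, and
hyperparameter refits every iteration. Metrics per iteration: best-found
value (noise-free objective at the best queried point, so the trace
measures true progress and is monotone) and Euclidean distance in the
unit cube between the true optimum and the algorithm's identified
optimum — the posterior-mean argmax over a 50-per-axis lattice ((x, p)
for pBO; x for BO, paired with the true optimum's p since BO cannot infer
it). Random search never narrows its query distribution and therefore
has no estimator; its "identified optimum" is its current query, so its
distance trace measures the accuracy of uninformed sampling itself
(mean ≈ 0.63 in the unit cube, flat in iteration). Selecting random
search's best query by observed value would instead grade a value-based
estimator that, at low noise, is itself a competent optimizer — which
would conflate the sampler with an estimator none of the compared
deliverables use and wash out the accuracy comparison the study makes.
The acceptance-scale run uses 10 repeats and the noise subset {0, 0.1,
2}; the full factorial is available through `pbostim benchmark`.

Observed behaviour at those scales: with little or no noise pBO reaches
higher values sooner and localizes the optimum far better than standard
BO and random search; at noise variance 2 its accuracy band overlaps
random search's — with a SD ~1.4 on a signal of range ~3.9, sixty
evaluations no longer separate the methods.

## Numerical choices

* Jitter 10⁻⁸ on the covariance diagonal; Cholesky with triangular solves.
* Acquisition ties: within 10⁻¹² relative of the maximum, seeded uniform choice.
* Hyperparameter optimization in log-space; first restart warm-started
  from the previous fit during sequential runs.
* Degenerate inputs raise typed errors (`DegenerateDriftError`,
  `DegenerateDataError`, `ProtocolError`, ...) rather than returning NaN.
* All seeds are small integers; derived seeds use `np.random.default_rng`
  sequence seeding and stay below 2³¹.

## Known limitations

* The EZ closed forms assume unbiased starting points and no
  across-trial parameter variability; misfit there propagates into the
  objective.
* The exclusion threshold treats the raw score scale as comparable
  across subjects; with very low baselines the ratio is heavy-tailed.
* The benchmark's identified-optimum definition differs between
  model-based and model-free algorithms by necessity; distances are
  therefore comparable across algorithms only as "what the algorithm
  would deliver", not as a shared estimator.
* Phase, montage, electrode count and stimulation duration are outside
  the search space.
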