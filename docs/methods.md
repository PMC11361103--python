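# Methods

## Model

A subject's binary response on trial *t* is Bernoulli with log-odds
`w·u_t + x_t`. The covariate vector `u_t` carries a constant 1 (intercept)
plus observed regressors, typically signed stimulus evidence and the
previous response. The latent criterion offset `x_t` follows a mean-zero
AR(1) process, `x_t = α x_{t-1} + ε_t`, `ε_t ~ N(0, σ²)`, with
`α ∈ [0, 1]`: α controls the persistence of the drift (α = 0 gives
trial-independent jitter, α near 1 slow coherent drift), σ² its scale.
The latent state enters the log-odds with a fixed unit loading. This is
deliberate: a free loading would trade off against σ², since both scale
the fluctuations; pinning it removes that degeneracy.

Adding `x_t` to the log-odds is equivalent to comparing a decision variable
against a criterion displaced by `-x_t`, so the model separates two sources
of choice variability: the measured covariates and the unmeasured, slowly
varying criterion.

### Hierarchy

Subject-level parameters θᵢ = (wᵢ, αᵢ, σᵢ²) are drawn from group-level
priors — Gaussian for weights, normal truncated to [0, 1] for α (negative α
would make the criterion jump sign from trial to trial; α > 1 is unstable),
inverse-gamma for σ². The group parameters η = (μ_w, σ_w², μ_α, σ_α², a, b)
are themselves inferred, so subjects with few trials borrow strength from
the rest of the sample.

### Weakly informative hyperpriors

The hyperprior constants are this package's own choices (configurable via
`WeakPriors`):

| parameter | prior | rationale |
|---|---|---|
| μ_w (per covariate) | N(0, 10²) | log-odds weights of plausible tasks are well inside ±10 |
| σ_w² (per covariate) | InvGamma(1/2, 1/2) | conjugate, heavy right tail; see below |
| μ_α | N(0.9, 1) on [0, 1] | drift of interest is persistent; essentially flat on [0, 1] |
| σ_α², a, b | log p(v) = −log(1+v²), v > 0 | half-Cauchy-type heavy tails, scale-free |

The σ_w² prior deserves a note. An InvGamma(2, 1) (prior mean 1) is a
common default but is informative enough to pull the group variance of the
intercept down noticeably at N ≈ 10 subjects. The intercept's group
variance is the one dimension that can legitimately be large (it absorbs
the realized mean of each subject's latent trajectory — see
*Identifiability* below), so the default here is the heavier-tailed
InvGamma(1/2, 1/2), under which 95% intervals for σ_w calibrate correctly
in simulation at small N.

## Inference

One blocked Gibbs sweep:

1. **Pólya-gamma auxiliaries.** ω_t ~ PG(1, ψ_t) at the current log-odds
   ψ_t. Conditioned on ω, the Bernoulli likelihood is Gaussian in ψ with
   pseudo-observation κ_t/ω_t (κ_t = y_t − ½) and precision ω_t. Draws use
   the exact Devroye alternating-series rejection sampler (no truncated
   series approximation), JIT-compiled.
2. **Latent chain.** Forward Kalman filter on the pseudo-observations,
   then backward joint sampling from trial T down to 1 — an exact draw of
   x₁..x_T from its Gaussian conditional. The filter's initial prior is the
   stationary distribution N(0, σ²/(1−α²)), with α clipped at 1−10⁻⁶ in
   that expression only.
3. **Mean-centering.** The sampled trajectory is centred to mean zero.
4. **Weights.** Exact Gaussian conditional draw: precision
   Uᵀdiag(ω)U + diag(1/σ_w²), mean solving
   precision·m = Uᵀ(κ − ω∘x) + μ_w/σ_w².
5. **α.** Truncated-normal conjugate draw on [0, 1] from the AR transition
   likelihood (t ≥ 2).
6. **σ².** Inverse-gamma conjugate draw, shape a + (T−1)/2, scale
   b + ½Σ(x_t − αx_{t−1})².
7. **Hyperparameters.** (μ_w, σ_w²): closed-form normal/inverse-gamma
   conditionals per covariate. (μ_α, σ_α²) and (a, b): one random-walk
   Metropolis-Hastings step each with symmetric Gaussian proposals; the
   truncated-normal target includes the [0, 1] normalising constant, which
   depends on both hyperparameters.

**Conditioning convention.** The stationary initial-state term appears in
the filter but is excluded from the α and σ² conditionals (steps 5–6), so
both remain exactly conjugate. This is a deliberate, tiny approximation:
one pseudo-observation out of T.

**Identifiability.** The intercept w₀ and the trajectory mean are not
separately identified by the likelihood — only their sum is. Per-sweep
mean-centering (step 3) resolves this by convention: all trajectories have
mean zero, and the intercept absorbs the realized mean of the true
trajectory. Recovery analyses therefore compare the inferred intercept
against `w₀ + mean(x_true)` (the identified quantity); trajectory recovery
uses Pearson correlation, which is location-invariant. Centering can be
disabled (`FitFlags.mean_center=False`); the sampler-validity (Geweke)
test runs that way, because centering intentionally perturbs the exact
joint the test certifies.

**Initialization.** Weights from a per-subject ridge-regularised logistic
fit; trajectories at 0; α at 0.95; σ² at 0.05; hyperparameters at moment
estimates of the per-subject initial values. Subjects with all-identical
responses are fitted but flagged: their weights are weakly identified and
rely on hierarchical shrinkage.

**MH adaptation.** Proposal scales adapt every 50 sweeps during burn-in
toward a 30–45% acceptance rate and are frozen afterwards, so detailed
balance holds for every retained draw.

**Defaults.** 1000 sweeps, 500 burn-in, no thinning; point estimates are
posterior means throughout (configurable). A fit of 50 subjects × 500
trials takes a few minutes on one CPU; 10 × 500 takes seconds.

**Degenerate settings.** `estimate_fluctuations=False` pins every
trajectory at zero and skips the AR blocks — the model becomes hierarchical
Bayesian logistic regression, used as the "drift-ignored" comparison fit.
Truncated-normal draws use the inverse-CDF method formulated in whichever
Gaussian tail holds the mass, with a bound fallback on complete underflow,
so posteriors pushing against 0 or 1 stay stable.

## Synthetic data

The simulator defines the study conditions and is first-class, tested code.

*Benchmark hierarchical design* (`simulate_hierarchical_dataset`): p = 4
covariates (intercept + three i.i.d. standard-normal columns); group weight
means (0.0, 0.2, −0.3, 0.6) with unit variances; αᵢ ~ TruncNorm(0.99,
0.025², [0, 1]); σᵢ² ~ InvGamma(5.0, 0.45); the initial latent state is
drawn from the stationary distribution. Note this makes the initial-state
variance heavy-tailed: αᵢ drawn very close to 1 occasionally yields a
subject whose criterion starts far from zero and who responds almost
constantly — such subjects are genuinely uninformative about their own
intercept, which is visible as seed-to-seed variation in pooled weight
recovery.

*Confound design* (`simulate_confound_dataset`): log-odds =
β_stim·evidence + β_prev·prev_response + x_t with defaults β_stim = 1.25,
β_prev = 0; evidence either continuous standard normal (history-bias
regression), a 7-level signed grid on [−2, 2] (psychometric slope), or a
single signed intensity, default 1.0 (d′). The previous response is coded
±1 (0 on trial 1), configurable to 0/1. (α, σ²) = (0, 0) is the
static-criterion control; the default fluctuation grid
{(0,0), (.95,.02), (.99,.02), (.99,.05), (.999,.05)} spans static to
strong, persistent drift, ordered by stationary variance σ²/(1−α²).

What the simulator does **not** emulate: reaction times, lapses, learning
or systematic criterion updating, unequal trial counts, non-Gaussian
evidence. Passing recovery tests therefore show that the inference engine
inverts its own generative family at realistic sizes — not that real
observers follow an AR(1) criterion.

## Metrics and conventions

* Recovery is Pearson *r* (the field's convention) between generating
  values and posterior means; pooled across subjects × covariates for
  weights, per subject for trajectories.
* Group-level coverage follows the realized-truth convention: the "true"
  μ_w*, σ_w*, μ_α*, σ_α* of a simulated dataset are the mean/SD of the
  per-subject generating parameters actually drawn for that dataset (with
  the identified-intercept convention above).
* d′ = Φ⁻¹(hit) − Φ⁻¹(false alarm); rates of exactly 0 or 1 are clamped to
  1/(2n) and 1 − 1/(2n) per class.
* History bias: headline metric is the ML logistic coefficient of the
  previous response controlling for the stimulus; P(repeat) − ½ is also
  provided. Under perfect separation the slope fit falls back to a barely
  regularised estimate and warns.
* Convergence hygiene (effective sample size, split-R̂) is provided via
  arviz; it is engineering practice, not a claim of the model.

## Known limitations

* α and σ² recover weakly below ~1000 trials per subject (the trajectory
  itself recovers much better than its dynamics parameters); recovery is
  hardest for low α combined with high σ².
* The stationary-init benchmark design occasionally produces saturated
  subjects (above); downstream pooled metrics inherit that tail.
* Mean-centering is a per-sweep projection, not an exact reparameterisation;
  its effect is negligible in practice but the Geweke certification is run
  without it.
* No missing data, no variational shortcut, single-chain sampler (run
  multiple seeds for between-chain diagnostics).
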