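# critdrift

Hierarchical Bayesian estimation of slow trial-to-trial drift in the
decision criterion from binary choice data.

## The problem

In signal-detection accounts of perceptual decision-making, a binary choice
arises from comparing a noisy decision variable to a criterion. Analyses of
such data almost always assume the criterion is fixed across a session.
When it instead drifts slowly, three standard analyses go wrong in
predictable ways:

* a logistic regression on the previous response shows **apparent choice
  history bias** even when the observer never uses its history;
* the **psychometric slope** is underestimated, because drift adds response
  variability at fixed stimulus intensity;
* **d′** is underestimated for the same reason.

`critdrift` models the drift explicitly and infers it, per trial, from the
choices themselves — pooling statistical strength across subjects so that
ordinary human-sized datasets (hundreds of trials per subject) suffice.

## The model

For subject *i* on trial *t*, with covariates **u**ᵢₜ ∈ ℝᵖ (first entry 1):

```
yᵢₜ ~ Bernoulli( σ(wᵢᵀ uᵢₜ + xᵢₜ) ),      σ(z) = 1/(1+e⁻ᶻ)
xᵢₜ = αᵢ xᵢ,ₜ₋₁ + εᵢₜ,   εᵢₜ ~ N(0, σᵢ²)
```

The latent AR(1) state xᵢₜ is the criterion offset; it enters the log-odds
with fixed unit weight, which removes the scale trade-off between a state
loading and σᵢ². Subject-level parameters share group-level priors:

```
wᵢ  ~ N(μ_w, diag(σ_w²))
αᵢ  ~ TruncNorm(μ_α, σ_α², [0, 1])
σᵢ² ~ InvGamma(a, b)
```

with weakly informative hyperpriors on (μ_w, σ_w², μ_α, σ_α², a, b).
Inference is an augmented blocked Gibbs sampler: Pólya-gamma auxiliaries
make the Bernoulli likelihood conditionally Gaussian, the latent chain is
drawn jointly by forward filtering/backward sampling, the subject-level
parameters by exact conjugate draws, and the hyperparameters by closed-form
draws (weights) or random-walk Metropolis-Hastings (the rest). See
`docs/methods.md` for assumptions, defaults, and numerical choices.

## Worked example

```python
import critdrift

# 10 subjects x 500 trials under the benchmark hierarchical design
ds = critdrift.simulate_hierarchical_dataset(10, 500, rng=42)
draws = critdrift.fit(ds, n_iterations=1000, burn_in=500, seed=1)

rep = critdrift.parameter_recovery(ds, draws)
print(f"weight recovery r = {rep.weight_correlation:.3f}")
print(f"trajectory recovery r = {rep.trajectory_mean_correlation:.3f}")
```

prints

```
weight recovery r = 0.990
trajectory recovery r = 0.850
```

i.e. the posterior-mean weights correlate at r ≈ 0.99 with the generating
weights across subjects and covariates, and the per-trial posterior mean of
the latent criterion tracks the true trajectory at r ≈ 0.85 on average —
with only 500 trials per subject.

The de-confounding result, on data whose log-odds were
`1.25·evidence + 0·previous_response + xₜ` (drifting criterion, no true
history effect):

```python
from critdrift.confounds import deconfound_experiment

ds = critdrift.simulate_confound_dataset(10, 2000, rng=123)
frame = deconfound_experiment(ds, seed=7)
print(frame.round(3).to_string(index=False))
```

```
    covariate  fluctuations_estimated  posterior_mean  ci_low  ci_high
    intercept                    True           0.133  -0.298    0.596
     stimulus                    True           1.269   1.025    1.489
prev_response                    True           0.019  -0.216    0.242
    intercept                   False           0.082  -0.237    0.373
     stimulus                   False           0.949   0.716    1.163
prev_response                   False           0.569   0.348    0.782
```

With drift estimated, the previous-response weight centres on its true
value 0 and the stimulus weight on 1.25; with drift ignored, a spurious
history bias (0.57) appears and the stimulus weight is underestimated.

There is also a sklearn-style front end (`CriterionDriftModel`) and a CLI:

```bash
critdrift simulate --design benchmark --subjects 10 --trials 500 --seed 1 --out trials.csv
critdrift recover trials.csv --truth trials.truth.json --out-dir posterior/
critdrift demo-confounds --agents 50 --trials 5000 --seed 1 --out confounds.csv
```

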