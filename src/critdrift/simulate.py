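"""Generative model: latent AR(1) criterion drift and Bernoulli responses.

Two ready-made designs are provided.  ``simulate_hierarchical_dataset``
draws subject parameters from the benchmark hierarchical design used for
the recovery studies (p = 4: intercept plus three standard-normal
covariates, group weight means (0.0, 0.2, -0.3, 0.6) with unit variances,
alpha ~ TruncNorm(0.99, 0.025^2, [0, 1]), sigma2 ~ IGa(5.0, 0.45)).
``simulate_confound_dataset`` generates agents whose log-odds combine a
stimulus weight, a previous-response weight, and the drifting criterion —
the design behind the apparent-history-bias / sensitivity-shrinkage
demonstrations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ConfigurationError, InvalidArgumentError
from .types import Dataset, GroundTruth, HyperParams, LatentTrajectory, SubjectData, SubjectParams

__all__ = [
    "sigmoid",
    "simulate_latent",
    "simulate_responses",
    "sample_subject_params",
    "simulate_hierarchical_dataset",
    "simulate_confound_dataset",
    "EvidenceSpec",
    "BENCHMARK_HYPER",
    "DEFAULT_FLUCTUATION_GRID",
]

# Upper clip on alpha when evaluating the stationary variance sigma2/(1-alpha^2):
# keeps the initial-state draw proper for alpha at (or numerically above) 1.
_ALPHA_CLIP = 1.0 - 1e-6


def _benchmark_hyper() -> HyperParams:
    return HyperParams(
        weight_mean=np.array([0.0, 0.2, -0.3, 0.6]),
        weight_var=np.ones(4),
        ar_mean=0.99,
        ar_var=0.025**2,
        iga_shape=5.0,
        iga_scale=0.45,
    )


#: Group-level parameters of the benchmark recovery design.
BENCHMARK_HYPER = _benchmark_hyper()

#: Default (alpha, sigma2) grid for the criterion-fluctuation demonstrations,
#: spanning from a static criterion to strong, persistent drift.
DEFAULT_FLUCTUATION_GRID: tuple[tuple[float, float], ...] = (
    (0.0, 0.0),
    (0.95, 0.02),
    (0.99, 0.02),
    (0.99, 0.05),
    (0.999, 0.05),
)


def sigmoid(z):
    """Logistic function f(z) = 1 / (1 + exp(-z)), stable for large |z|."""
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise InvalidArgumentError("sigmoid requires finite input")
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out if out.ndim else float(out)


def stationary_variance(ar_coef: float, innov_var: float) -> float:
    """Long-run variance sigma2 / (1 - alpha^2) of the AR(1) chain."""
    a = min(float(ar_coef), _ALPHA_CLIP)
    return float(innov_var) / (1.0 - a * a)


def simulate_latent(
    ar_coef: float, innov_var: float, n_trials: int, rng: np.random.Generator
) -> LatentTrajectory:
    """Simulate x_t = alpha * x_{t-1} + eps_t, eps_t ~ N(0, sigma2).

    The initial state is drawn from the stationary distribution
    N(0, sigma2 / (1 - alpha^2)) (with alpha clipped just below 1 for that
    draw) so short chains start in equilibrium rather than at an arbitrary
    transient.  ``innov_var = 0`` is allowed and yields the identically-zero
    trajectory (the static-criterion control).
    """
    ar_coef = float(ar_coef)
    innov_var = float(innov_var)
    if not 0.0 <= ar_coef <= 1.0:
        raise InvalidArgumentError(f"ar_coef must lie in [0, 1], got {ar_coef}")
    if innov_var < 0.0:
        raise InvalidArgumentError(f"innov_var must be non-negative, got {innov_var}")
    n_trials = int(n_trials)
    if n_trials < 1:
        raise InvalidArgumentError("n_trials must be >= 1")
    x = np.empty(n_trials)
    x[0] = rng.normal(0.0, np.sqrt(stationary_variance(ar_coef, innov_var)))
    if n_trials > 1:
        eps = rng.normal(0.0, np.sqrt(innov_var), size=n_trials - 1)
        for t in range(1, n_trials):
            x[t] = ar_coef * x[t - 1] + eps[t - 1]
    return LatentTrajectory(states=x)


def simulate_responses(
    params: SubjectParams,
    covariates: np.ndarray,
    trajectory: LatentTrajectory,
    rng: np.random.Generator,
    prev_response_col: int | None = None,
    prev_coding: str = "pm1",
) -> np.ndarray:
    """Draw y_t ~ Bernoulli(sigmoid(w @ u_t + x_t)).

    If ``prev_response_col`` is given, that covariate column is filled in
    sequentially during generation with the previous trial's response
    (coded -1/+1 under ``prev_coding='pm1'`` or 0/1 under ``'01'``; trial 1
    gets 0 either way), so history-dependent designs can be simulated
    without knowing the responses in advance.
    """
    covariates = np.array(covariates, dtype=float)
    t, p = covariates.shape
    if trajectory.n_trials != t:
        raise InvalidArgumentError("trajectory length must match the number of trials")
    if params.weights.size != p:
        raise InvalidArgumentError("weights length must match the covariate count")
    if prev_coding not in ("pm1", "01"):
        raise InvalidArgumentError("prev_coding must be 'pm1' or '01'")
    x = trajectory.states
    w = params.weights
    u = rng.random(t)
    y = np.empty(t, dtype=np.int8)
    if prev_response_col is None:
        prob = sigmoid(covariates @ w + x)
        return (u < prob).astype(np.int8)
    if not 0 < prev_response_col < p:
        raise InvalidArgumentError("prev_response_col must index a non-intercept column")
    covariates[0, prev_response_col] = 0.0
    for i in range(t):
        if i > 0:
            prev = float(y[i - 1])
            if prev_coding == "pm1":
                prev = 2.0 * prev - 1.0
            covariates[i, prev_response_col] = prev
        prob = sigmoid(float(covariates[i] @ w + x[i]))
        y[i] = 1 if u[i] < prob else 0
    return y


def sample_subject_params(
    hyper: HyperParams, n_covariates: int, rng: np.random.Generator
) -> SubjectParams:
    """Draw theta_i from the hierarchical prior.

    weights ~ N(mu_w, diag(sigma_w^2)); alpha ~ TruncNorm(mu_a, sigma_a^2)
    on [0, 1]; sigma2 ~ IGa(shape, scale).
    """
    if n_covariates != hyper.n_covariates:
        raise InvalidArgumentError("n_covariates must match the hyperparameter dimension")
    w = rng.normal(hyper.weight_mean, np.sqrt(hyper.weight_var))
    sd = np.sqrt(hyper.ar_var)
    a_lo, a_hi = (0.0 - hyper.ar_mean) / sd, (1.0 - hyper.ar_mean) / sd
    ar = float(stats.truncnorm.ppf(rng.random(), a_lo, a_hi, loc=hyper.ar_mean, scale=sd))
    ar = min(max(ar, 0.0), 1.0)
    innov = float(hyper.iga_scale / rng.standard_gamma(hyper.iga_shape))
    return SubjectParams(weights=w, ar_coef=ar, innov_var=innov)


def simulate_hierarchical_dataset(
    n_subjects: int,
    n_trials: int,
    rng: np.random.Generator | int | None = None,
    hyper: HyperParams | None = None,
) -> Dataset:
    """Simulate the benchmark hierarchical design (ground truth attached).

    Covariate column 0 is the constant 1; the remaining p-1 columns are
    i.i.d. standard normal.  Subject parameters come from
    ``sample_subject_params`` under ``hyper`` (default ``BENCHMARK_HYPER``).
    """
    rng = np.random.default_rng(rng)
    if hyper is None:
        hyper = _benchmark_hyper()
    n_subjects = int(n_subjects)
    n_trials = int(n_trials)
    if n_subjects < 1:
        raise InvalidArgumentError("n_subjects must be >= 1")
    if n_trials < 2:
        raise InvalidArgumentError("n_trials must be >= 2")
    p = hyper.n_covariates
    names = ["intercept"] + [f"cov{j}" for j in range(1, p)]
    subjects, params_list, traj_list = [], [], []
    for i in range(n_subjects):
        params = sample_subject_params(hyper, p, rng)
        u = np.column_stack([np.ones(n_trials), rng.standard_normal((n_trials, p - 1))])
        traj = simulate_latent(params.ar_coef, params.innov_var, n_trials, rng)
        y = simulate_responses(params, u, traj, rng)
        subjects.append(
            SubjectData(subject_id=f"s{i:03d}", responses=y, covariates=u, covariate_names=names)
        )
        params_list.append(params)
        traj_list.append(traj)
    return Dataset(
        subjects=subjects,
        ground_truth=GroundTruth(params=params_list, trajectories=traj_list, hyper=hyper),
    )


@dataclass
class EvidenceSpec:
    """How stimulus evidence is generated in the confound designs.

    kind='gaussian': continuous standard-normal evidence.
    kind='levels':   evidence drawn uniformly from a signed grid
                     (default 7 equally spaced levels on [-2, 2]) for
                     psychometric-curve fitting.
    kind='single':   evidence is +/-``level`` with equal probability (one
                     signed intensity, the d-prime design; default 1.0).
    """

    kind: str = "gaussian"
    levels: np.ndarray | None = None
    level: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "levels", "single"):
            raise ConfigurationError(f"unknown evidence kind {self.kind!r}")
        if self.kind == "levels":
            if self.levels is None:
                self.levels = np.linspace(-2.0, 2.0, 7)
            self.levels = np.asarray(self.levels, dtype=float)
            if self.levels.size < 3 or self.levels.min() >= 0 or self.levels.max() <= 0:
                raise ConfigurationError(
                    "levels must contain >= 3 values spanning negative and positive evidence"
                )
        if self.kind == "single" and not self.level > 0:
            raise ConfigurationError("level must be positive")

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "gaussian":
            return rng.standard_normal(n)
        if self.kind == "levels":
            return rng.choice(self.levels, size=n)
        return self.level * np.where(rng.random(n) < 0.5, -1.0, 1.0)


def simulate_confound_dataset(
    n_agents: int,
    n_trials: int,
    beta_stimulus: float = 1.25,
    beta_prev: float = 0.0,
    ar_coef: float = 0.99,
    innov_var: float = 0.05,
    evidence_spec: EvidenceSpec | None = None,
    rng: np.random.Generator | int | None = None,
    prev_coding: str = "pm1",
) -> Dataset:
    """Simulate agents with log-odds = b_stim*evidence + b_prev*prev + x_t.

    Covariates are [intercept, stimulus, prev_response] with the intercept
    weight fixed at 0 in generation; ``ar_coef = innov_var = 0`` gives the
    static-criterion control.  Ground truth is attached.
    """
    rng = np.random.default_rng(rng)
    if evidence_spec is None:
        evidence_spec = EvidenceSpec()
    n_agents = int(n_agents)
    n_trials = int(n_trials)
    if n_agents < 1 or n_trials < 2:
        raise InvalidArgumentError("need n_agents >= 1 and n_trials >= 2")
    names = ["intercept", "stimulus", "prev_response"]
    subjects, params_list, traj_list = [], [], []
    for i in range(n_agents):
        evidence = evidence_spec.draw(n_trials, rng)
        u = np.column_stack([np.ones(n_trials), evidence, np.zeros(n_trials)])
        traj = simulate_latent(ar_coef, innov_var, n_trials, rng)
        params = SubjectParams(
            weights=np.array([0.0, beta_stimulus, beta_prev]),
            ar_coef=ar_coef,
            # SubjectParams requires a positive variance; record a token
            # epsilon for the static control whose trajectory is exactly 0.
            innov_var=max(innov_var, 1e-300),
        )
        y = simulate_responses(
            params, u, traj, rng, prev_response_col=2, prev_coding=prev_coding
        )
        prev = np.zeros(n_trials)
        coded = y[:-1].astype(float) if prev_coding == "01" else 2.0 * y[:-1] - 1.0
        prev[1:] = coded
        u[:, 2] = prev
        subjects.append(
            SubjectData(subject_id=f"a{i:03d}", responses=y, covariates=u, covariate_names=names)
        )
        params_list.append(params)
        traj_list.append(traj)
    return Dataset(
        subjects=subjects,
        ground_truth=GroundTruth(params=params_list, trajectories=traj_list, hyper=None),
    )
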