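"""Blocked Gibbs sampler for the hierarchical criterion-drift model.

One sweep cycles through exact conditional draws:

* per subject — Pólya-gamma auxiliaries at the current log-odds; a joint
  forward-filter/backward-sample draw of the latent AR(1) trajectory;
  mean-centering of the trajectory (identifiability of the intercept);
  a Gaussian draw of the covariate weights; a truncated-normal draw of the
  AR coefficient; an inverse-gamma draw of the innovation variance;
* group level — closed-form normal/inverse-gamma draws for the weight
  hyperprior, and random-walk Metropolis-Hastings steps for the
  truncated-normal and inverse-gamma hyperprior parameters.

The truncated-normal and inverse-gamma subject-level conditionals condition
on transitions t = 2..T only (the stationary initial-state term is used in
the filter but excluded from these two updates so both stay exactly
conjugate).

Weakly informative hyperpriors (configurable via ``WeakPriors``):
mu_w ~ N(0, 10^2) and sigma_w^2 ~ IGa(1/2, 1/2) per covariate (a
heavy-tailed conjugate choice so the prior does not dominate group
variances at small N); mu_alpha ~ N(0.9, 1) restricted to [0, 1];
sigma_alpha^2, and the inverse-gamma shape and scale, get heavy-tailed
log-densities -log(1 + v^2) on v > 0.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, ndtr, ndtri

from ._ffbs import backward_core, filter_core
from ._pg import pg_draw, pg_draws
from .errors import InvalidArgumentError
from .types import Dataset, HyperParams, LatentTrajectory, PosteriorDraws

__all__ = [
    "PGAuxiliaries",
    "FilterState",
    "FitFlags",
    "WeakPriors",
    "GibbsState",
    "sample_pg",
    "forward_filter",
    "backward_sample",
    "mean_center",
    "update_weights",
    "update_ar_coef",
    "update_innov_var",
    "update_weight_hyperprior",
    "update_ar_hyperprior_mh",
    "update_iga_hyperprior_mh",
    "truncnorm_draw",
    "initialize_state",
    "gibbs_sweep",
    "fit",
]

logger = logging.getLogger("critdrift")

_MH_NAMES = ("ar_mean", "ar_var", "iga_shape", "iga_scale")


@dataclass
class PGAuxiliaries:
    """Per-trial Pólya-gamma auxiliary variables for one subject."""

    omega: np.ndarray

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        if np.any(self.omega <= 0) or not np.all(np.isfinite(self.omega)):
            raise InvalidArgumentError("omega entries must be positive and finite")


@dataclass
class FilterState:
    """Filtering distributions N(means[t], variances[t]) of the latent state."""

    means: np.ndarray
    variances: np.ndarray

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        if self.means.shape != self.variances.shape:
            raise InvalidArgumentError("means and variances must have equal length")
        if np.any(self.variances <= 0):
            raise InvalidArgumentError("filtering variances must be positive")


@dataclass
class FitFlags:
    """Model flags for a fit.

    estimate_fluctuations=False pins every trajectory at zero and skips the
    AR blocks, reducing the model to hierarchical Bayesian logistic
    regression.  mean_center=False disables the per-sweep centering (used
    by the sampler-validity tests, where the exact joint must be left
    untouched).
    """

    estimate_fluctuations: bool = True
    update_hyperpriors: bool = True
    mean_center: bool = True


@dataclass
class WeakPriors:
    """Weakly informative hyperprior constants (see module docstring)."""

    weight_mean_loc: float = 0.0
    weight_mean_var: float = 100.0
    weight_var_shape: float = 0.5
    weight_var_scale: float = 0.5
    ar_mean_loc: float = 0.9
    ar_mean_var: float = 1.0

    def log_prior_ar(self, ar_mean: float, ar_var: float) -> float:
        if not 0.0 <= ar_mean <= 1.0 or ar_var <= 0.0:
            return -np.inf
        lp = -0.5 * (ar_mean - self.ar_mean_loc) ** 2 / self.ar_mean_var
        lp -= np.log1p(ar_var**2)
        return lp

    def log_prior_iga(self, shape: float, scale: float) -> float:
        if shape <= 0.0 or scale <= 0.0:
            return -np.inf
        return -np.log1p(shape**2) - np.log1p(scale**2)


# ---------------------------------------------------------------------------
# elementary draws


def sample_pg(c: float, rng: np.random.Generator) -> float:
    """One exact draw from the Pólya-gamma distribution PG(1, c)."""
    c = float(c)
    if not np.isfinite(c):
        raise InvalidArgumentError("PG tilt parameter must be finite")
    return float(pg_draw(c, rng))


def truncnorm_draw(
    mean: float, var: float, lo: float, hi: float, rng: np.random.Generator
) -> float:
    """Inverse-CDF draw from N(mean, var) truncated to [lo, hi].

    The CDF interval is formed in whichever tail carries the mass so the
    draw stays accurate when [lo, hi] sits many standard deviations from
    the mean; on complete underflow the nearer bound is returned.
    """
    sd = np.sqrt(var)
    a = (lo - mean) / sd
    b = (hi - mean) / sd
    u = rng.random()
    if a > 0.0:  # interval in the upper tail: work with survival functions
        sa, sb = ndtr(-a), ndtr(-b)
        s = sa - u * (sa - sb)
        z = -ndtri(s) if s > 0.0 else b
    elif b < 0.0:  # lower tail
        fa, fb = ndtr(a), ndtr(b)
        f = fa + u * (fb - fa)
        z = ndtri(f) if f > 0.0 else a
    else:
        fa, fb = ndtr(a), ndtr(b)
        z = ndtri(fa + u * (fb - fa))
    if not np.isfinite(z):
        z = a if abs(a) < abs(b) else b
    z = min(max(z, a), b)
    return float(mean + sd * z)


def _invgamma_draw(shape: float, scale: float, rng: np.random.Generator) -> float:
    return float(scale / rng.standard_gamma(shape))


# ---------------------------------------------------------------------------
# latent-state blocks


def forward_filter(
    responses: np.ndarray,
    offsets: np.ndarray,
    omega: PGAuxiliaries,
    ar_coef: float,
    innov_var: float,
) -> FilterState:
    """Kalman forward pass on the PG pseudo-observations.

    Pseudo-observation at trial t: z_t = kappa_t / omega_t - offset_t with
    kappa_t = y_t - 1/2 and observation variance 1 / omega_t; prior
    x_1 ~ N(0, innov_var / (1 - ar_coef^2)) and transition
    x_t | x_{t-1} ~ N(ar_coef * x_{t-1}, innov_var).
    """
    responses = np.asarray(responses, dtype=float)
    offsets = np.asarray(offsets, dtype=float)
    if not (responses.shape == offsets.shape == omega.omega.shape):
        raise InvalidArgumentError("responses, offsets and omega must share a length")
    if innov_var <= 0:
        raise InvalidArgumentError("innov_var must be positive")
    kappa = responses - 0.5
    means, variances = filter_core(kappa, omega.omega, offsets, float(ar_coef), float(innov_var))
    return FilterState(means=means, variances=variances)


def backward_sample(
    filter_state: FilterState, ar_coef: float, innov_var: float, rng: np.random.Generator
) -> LatentTrajectory:
    """Joint draw of the trajectory from its exact Gaussian conditional."""
    if innov_var <= 0:
        raise InvalidArgumentError("innov_var must be positive")
    x = backward_core(filter_state.means, filter_state.variances, float(ar_coef), float(innov_var), rng)
    return LatentTrajectory(states=x)


def mean_center(trajectory: LatentTrajectory) -> LatentTrajectory:
    """Subtract the trajectory mean (keeps the intercept weight identifiable)."""
    states = trajectory.states - trajectory.states.mean()
    return LatentTrajectory(states=states, centered=True)


# ---------------------------------------------------------------------------
# subject-level conjugate blocks


def update_weights(
    covariates: np.ndarray,
    responses: np.ndarray,
    trajectory: LatentTrajectory,
    omega: PGAuxiliaries,
    weight_mean: np.ndarray,
    weight_var: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw w from its Gaussian conditional given (omega, x) and the prior.

    Precision = U' diag(omega) U + diag(1/sigma_w^2); the mean solves
    precision @ m = U' (kappa - omega * x) + mu_w / sigma_w^2.
    """
    u = np.asarray(covariates, dtype=float)
    kappa = np.asarray(responses, dtype=float) - 0.5
    om = omega.omega
    prec = (u.T * om) @ u + np.diag(1.0 / weight_var)
    rhs = u.T @ (kappa - om * trajectory.states) + weight_mean / weight_var
    chol = np.linalg.cholesky(prec)
    m = np.linalg.solve(chol.T, np.linalg.solve(chol, rhs))
    z = rng.standard_normal(m.size)
    return m + np.linalg.solve(chol.T, z)


def update_ar_coef(
    trajectory: LatentTrajectory,
    innov_var: float,
    ar_mean: float,
    ar_var: float,
    rng: np.random.Generator,
) -> float:
    """Truncated-normal conjugate draw of alpha on [0, 1] (transitions t >= 2)."""
    x = trajectory.states
    if x.size < 2:
        raise InvalidArgumentError("need at least 2 trials to update ar_coef")
    sxx = float(x[:-1] @ x[:-1])
    sxy = float(x[1:] @ x[:-1])
    v = 1.0 / (sxx / innov_var + 1.0 / ar_var)
    m = v * (sxy / innov_var + ar_mean / ar_var)
    return truncnorm_draw(m, v, 0.0, 1.0, rng)


def update_innov_var(
    trajectory: LatentTrajectory,
    ar_coef: float,
    iga_shape: float,
    iga_scale: float,
    rng: np.random.Generator,
) -> float:
    """Inverse-gamma conjugate draw of sigma2 (transitions t >= 2)."""
    x = trajectory.states
    if x.size < 2:
        raise InvalidArgumentError("need at least 2 trials to update innov_var")
    resid = x[1:] - ar_coef * x[:-1]
    shape = iga_shape + (x.size - 1) / 2.0
    scale = iga_scale + 0.5 * float(resid @ resid)
    return _invgamma_draw(shape, scale, rng)


# ---------------------------------------------------------------------------
# group-level blocks


def update_weight_hyperprior(
    all_weights: np.ndarray,
    current_weight_mean: np.ndarray,
    rng: np.random.Generator,
    priors: WeakPriors | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Conjugate draws of (mu_w, sigma_w^2) per covariate dimension.

    sigma_w^2 is drawn from its inverse-gamma conditional given the current
    mu_w, then mu_w from its normal conditional given the new sigma_w^2.
    """
    w = np.asarray(all_weights, dtype=float)
    if w.ndim != 2 or w.shape[0] < 2:
        raise InvalidArgumentError("need an N x p weight matrix with N >= 2")
    if priors is None:
        priors = WeakPriors()
    n = w.shape[0]
    sse = ((w - current_weight_mean) ** 2).sum(axis=0)
    shape = priors.weight_var_shape + n / 2.0
    scale = priors.weight_var_scale + 0.5 * sse
    weight_var = scale / rng.standard_gamma(shape, size=w.shape[1])
    prec = n / weight_var + 1.0 / priors.weight_mean_var
    mean = (w.sum(axis=0) / weight_var + priors.weight_mean_loc / priors.weight_mean_var) / prec
    weight_mean = mean + rng.standard_normal(w.shape[1]) / np.sqrt(prec)
    return weight_mean, weight_var


def _log_trunc_normal_lik(alphas: np.ndarray, mean: float, var: float) -> float:
    sd = np.sqrt(var)
    z = ndtr((1.0 - mean) / sd) - ndtr((0.0 - mean) / sd)
    if z <= 0.0:
        return -np.inf
    n = alphas.size
    return float(
        -n * np.log(sd) - ((alphas - mean) ** 2).sum() / (2.0 * var) - n * np.log(z)
    )


def _log_invgamma_lik(variances: np.ndarray, shape: float, scale: float) -> float:
    n = variances.size
    return float(
        n * (shape * np.log(scale) - gammaln(shape))
        - (shape + 1.0) * np.log(variances).sum()
        - scale * (1.0 / variances).sum()
    )


def _mh_step(current, log_target, scale, rng):
    proposal = current + scale * rng.standard_normal()
    lp_new = log_target(proposal)
    if lp_new == -np.inf:
        return current, False
    lp_old = log_target(current)
    if np.log(rng.random()) < lp_new - lp_old:
        return proposal, True
    return current, False


def update_ar_hyperprior_mh(
    all_ar_coefs: np.ndarray,
    current: tuple[float, float],
    proposal_scales: tuple[float, float],
    rng: np.random.Generator,
    priors: WeakPriors | None = None,
) -> tuple[float, float, tuple[bool, bool]]:
    """One random-walk MH step each for (mu_alpha, sigma_alpha^2).

    The target includes the [0, 1] truncation normaliser of the subject-level
    prior, which depends on both hyperparameters.
    """
    alphas = np.asarray(all_ar_coefs, dtype=float)
    if alphas.size < 2:
        raise InvalidArgumentError("need at least 2 subjects")
    if priors is None:
        priors = WeakPriors()
    mean, var = current

    def target_mean(m):
        lp = priors.log_prior_ar(m, var)
        return lp if lp == -np.inf else lp + _log_trunc_normal_lik(alphas, m, var)

    mean, acc_mean = _mh_step(mean, target_mean, proposal_scales[0], rng)

    def target_var(v):
        lp = priors.log_prior_ar(mean, v)
        return lp if lp == -np.inf else lp + _log_trunc_normal_lik(alphas, mean, v)

    var, acc_var = _mh_step(var, target_var, proposal_scales[1], rng)
    return mean, var, (acc_mean, acc_var)


def update_iga_hyperprior_mh(
    all_innov_vars: np.ndarray,
    current: tuple[float, float],
    proposal_scales: tuple[float, float],
    rng: np.random.Generator,
    priors: WeakPriors | None = None,
) -> tuple[float, float, tuple[bool, bool]]:
    """One random-walk MH step each for the inverse-gamma (shape, scale)."""
    variances = np.asarray(all_innov_vars, dtype=float)
    if variances.size < 2:
        raise InvalidArgumentError("need at least 2 subjects")
    if priors is None:
        priors = WeakPriors()
    shape, scale = current

    def target_shape(a):
        lp = priors.log_prior_iga(a, scale)
        return lp if lp == -np.inf else lp + _log_invgamma_lik(variances, a, scale)

    shape, acc_shape = _mh_step(shape, target_shape, proposal_scales[0], rng)

    def target_scale(b):
        lp = priors.log_prior_iga(shape, b)
        return lp if lp == -np.inf else lp + _log_invgamma_lik(variances, shape, b)

    scale, acc_scale = _mh_step(scale, target_scale, proposal_scales[1], rng)
    return shape, scale, (acc_shape, acc_scale)


# ---------------------------------------------------------------------------
# sweep driver


@dataclass
class GibbsState:
    """Mutable sampler state: one value of every unknown plus MH bookkeeping."""

    weights: np.ndarray                 # (N, p)
    ar_coef: np.ndarray                 # (N,)
    innov_var: np.ndarray               # (N,)
    trajectories: list[np.ndarray]      # N arrays (T_i,)
    hyper: HyperParams
    iteration: int = 0
    proposal_scales: dict = field(
        default_factory=lambda: {n: 0.05 for n in _MH_NAMES}
    )
    accept_counts: dict = field(default_factory=lambda: {n: 0 for n in _MH_NAMES})
    proposal_counts: dict = field(default_factory=lambda: {n: 0 for n in _MH_NAMES})
    flagged_subjects: list[int] = field(default_factory=list)

    def acceptance_rates(self) -> dict[str, float]:
        return {
            n: self.accept_counts[n] / max(self.proposal_counts[n], 1) for n in _MH_NAMES
        }


def initialize_state(
    data: Dataset,
    rng: np.random.Generator,
    hyper_init: HyperParams | None = None,
) -> GibbsState:
    """Build the initial GibbsState.

    Weights come from a per-subject ridge-regularised logistic fit;
    trajectories start at 0; alpha at 0.95 and sigma2 at 0.05; the
    hyperparameters at moment estimates of the per-subject initial values
    (unless an explicit ``hyper_init`` is given).  Subjects whose responses
    are all identical are fitted anyway but flagged: their weights are only
    weakly identified and rely on hierarchical shrinkage.
    """
    from sklearn.linear_model import LogisticRegression

    n = data.n_subjects
    p = data.n_covariates
    weights = np.zeros((n, p))
    flagged: list[int] = []
    for i, subj in enumerate(data.subjects):
        y = subj.responses
        if y.min() == y.max():
            flagged.append(i)
            rate = np.clip(y.mean(), 1.0 / (2 * y.size), 1.0 - 1.0 / (2 * y.size))
            weights[i, 0] = np.log(rate / (1.0 - rate))
            continue
        clf = LogisticRegression(C=1.0, fit_intercept=False, max_iter=200)
        clf.fit(subj.covariates, y)
        weights[i] = clf.coef_[0]
    ar = np.full(n, 0.95)
    innov = np.full(n, 0.05)
    trajectories = [np.zeros(s.n_trials) for s in data.subjects]
    if hyper_init is None:
        wv = weights.var(axis=0, ddof=1) if n > 1 else np.ones(p)
        hyper_init = HyperParams(
            weight_mean=weights.mean(axis=0),
            weight_var=np.clip(wv, 0.1, None),
            ar_mean=0.95,
            ar_var=0.01,
            iga_shape=3.0,
            iga_scale=0.1,
        )
    return GibbsState(
        weights=weights,
        ar_coef=ar,
        innov_var=innov,
        trajectories=trajectories,
        hyper=hyper_init,
        flagged_subjects=flagged,
    )


def gibbs_sweep(
    state: GibbsState,
    data: Dataset,
    rng: np.random.Generator,
    flags: FitFlags | None = None,
    priors: WeakPriors | None = None,
) -> GibbsState:
    """One full sweep over all blocks (mutates and returns ``state``)."""
    if flags is None:
        flags = FitFlags()
    if priors is None:
        priors = WeakPriors()
    hyper = state.hyper
    for i, subj in enumerate(data.subjects):
        u = subj.covariates
        y = subj.responses.astype(float)
        kappa = y - 0.5
        offset = u @ state.weights[i]
        if flags.estimate_fluctuations:
            psi = offset + state.trajectories[i]
            omega = pg_draws(psi, rng)
            means, variances = filter_core(
                kappa, omega, offset, state.ar_coef[i], state.innov_var[i]
            )
            x = backward_core(means, variances, state.ar_coef[i], state.innov_var[i], rng)
            if flags.mean_center:
                x = x - x.mean()
            state.trajectories[i] = x
            traj = LatentTrajectory(states=x)
            state.weights[i] = update_weights(
                u, y, traj, PGAuxiliaries(omega),
                hyper.weight_mean, hyper.weight_var, rng,
            )
            state.ar_coef[i] = update_ar_coef(
                traj, state.innov_var[i], hyper.ar_mean, hyper.ar_var, rng
            )
            state.innov_var[i] = update_innov_var(
                traj, state.ar_coef[i], hyper.iga_shape, hyper.iga_scale, rng
            )
        else:
            omega = pg_draws(offset, rng)
            state.trajectories[i][:] = 0.0
            traj = LatentTrajectory(states=state.trajectories[i])
            state.weights[i] = update_weights(
                u, y, traj, PGAuxiliaries(omega),
                hyper.weight_mean, hyper.weight_var, rng,
            )
    if flags.update_hyperpriors and data.n_subjects >= 2:
        weight_mean, weight_var = update_weight_hyperprior(
            state.weights, hyper.weight_mean, rng, priors
        )
        ar_mean, ar_var = hyper.ar_mean, hyper.ar_var
        iga_shape, iga_scale = hyper.iga_shape, hyper.iga_scale
        if flags.estimate_fluctuations:
            ar_mean, ar_var, acc_ar = update_ar_hyperprior_mh(
                state.ar_coef,
                (ar_mean, ar_var),
                (state.proposal_scales["ar_mean"], state.proposal_scales["ar_var"]),
                rng,
                priors,
            )
            iga_shape, iga_scale, acc_iga = update_iga_hyperprior_mh(
                state.innov_var,
                (iga_shape, iga_scale),
                (state.proposal_scales["iga_shape"], state.proposal_scales["iga_scale"]),
                rng,
                priors,
            )
            for name, acc in zip(_MH_NAMES, (*acc_ar, *acc_iga)):
                state.proposal_counts[name] += 1
                state.accept_counts[name] += bool(acc)
        state.hyper = HyperParams(
            weight_mean=weight_mean,
            weight_var=weight_var,
            ar_mean=ar_mean,
            ar_var=ar_var,
            iga_shape=iga_shape,
            iga_scale=iga_scale,
        )
    state.iteration += 1
    return state


_ADAPT_WINDOW = 50
_ADAPT_LO, _ADAPT_HI = 0.30, 0.45


def _adapt_proposals(state: GibbsState) -> None:
    # Proposal scales chase a 30-45% acceptance rate during burn-in only.
    for name in _MH_NAMES:
        count = state.proposal_counts[name]
        if count < _ADAPT_WINDOW:
            return
        rate = state.accept_counts[name] / count
        if rate > _ADAPT_HI:
            state.proposal_scales[name] *= 1.25
        elif rate < _ADAPT_LO:
            state.proposal_scales[name] *= 0.8
        state.accept_counts[name] = 0
        state.proposal_counts[name] = 0


def fit(
    data: Dataset,
    n_iterations: int = 1000,
    burn_in: int = 500,
    thin: int = 1,
    seed: int | np.random.Generator | None = None,
    flags: FitFlags | None = None,
    priors: WeakPriors | None = None,
    hyper_init: HyperParams | None = None,
) -> PosteriorDraws:
    """Run the blocked Gibbs sampler and collect retained draws.

    Retains ``floor((n_iterations - burn_in) / thin)`` post-burn-in draws.
    MH proposal scales adapt during burn-in and are frozen afterwards
    (detailed balance holds for every retained draw).  Fully reproducible
    for a fixed integer ``seed``.
    """
    if flags is None:
        flags = FitFlags()
    if priors is None:
        priors = WeakPriors()
    n_iterations = int(n_iterations)
    burn_in = int(burn_in)
    thin = int(thin)
    if not (n_iterations > burn_in >= 0):
        raise InvalidArgumentError("need n_iterations > burn_in >= 0")
    if thin < 1:
        raise InvalidArgumentError("thin must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    state = initialize_state(data, rng, hyper_init=hyper_init)
    n, p = state.weights.shape
    n_keep = (n_iterations - burn_in) // thin
    weights = np.empty((n_keep, n, p))
    ar = np.empty((n_keep, n))
    innov = np.empty((n_keep, n))
    trajs = [np.empty((n_keep, s.n_trials)) for s in data.subjects]
    weight_mean = np.empty((n_keep, p))
    weight_var = np.empty((n_keep, p))
    ar_mean = np.empty(n_keep)
    ar_var = np.empty(n_keep)
    iga_shape = np.empty(n_keep)
    iga_scale = np.empty(n_keep)
    kept = 0
    t_start = time.perf_counter()
    for it in range(n_iterations):
        gibbs_sweep(state, data, rng, flags=flags, priors=priors)
        if it < burn_in:
            _adapt_proposals(state)
            if it == burn_in - 1:
                # freeze scales; reset counters so reported rates are post-burn-in
                for name in _MH_NAMES:
                    state.accept_counts[name] = 0
                    state.proposal_counts[name] = 0
        elif (it - burn_in) % thin == 0 and kept < n_keep:
            weights[kept] = state.weights
            ar[kept] = state.ar_coef
            innov[kept] = state.innov_var
            for i in range(n):
                trajs[i][kept] = state.trajectories[i]
            weight_mean[kept] = state.hyper.weight_mean
            weight_var[kept] = state.hyper.weight_var
            ar_mean[kept] = state.hyper.ar_mean
            ar_var[kept] = state.hyper.ar_var
            iga_shape[kept] = state.hyper.iga_shape
            iga_scale[kept] = state.hyper.iga_scale
            kept += 1
        if (it + 1) % 100 == 0:
            logger.info(
                "sweep %d/%d (%.1fs) MH acceptance %s",
                it + 1,
                n_iterations,
                time.perf_counter() - t_start,
                {k: round(v, 3) for k, v in state.acceptance_rates().items()},
            )
    metadata = {
        "n_iterations": n_iterations,
        "burn_in": burn_in,
        "thin": thin,
        "seed": seed if isinstance(seed, int) else None,
        "estimate_fluctuations": flags.estimate_fluctuations,
        "update_hyperpriors": flags.update_hyperpriors,
        "mean_center": flags.mean_center,
        "subject_ids": [s.subject_id for s in data.subjects],
        "covariate_names": data.covariate_names,
        "flagged_subjects": state.flagged_subjects,
        "mh_acceptance": state.acceptance_rates(),
        "mh_proposal_scales": dict(state.proposal_scales),
        "runtime_s": time.perf_counter() - t_start,
    }
    return PosteriorDraws(
        weights=weights,
        ar_coef=ar,
        innov_var=innov,
        trajectories=trajs,
        weight_mean=weight_mean,
        weight_var=weight_var,
        ar_mean=ar_mean,
        ar_var=ar_var,
        iga_shape=iga_shape,
        iga_scale=iga_scale,
        metadata=metadata,
    )
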