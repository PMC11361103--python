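"""Recovery metrics, posterior summaries, and convergence checks.

Identifiability convention: the sampler mean-centers each latent trajectory
every sweep, so the model's intercept absorbs the realized mean of the true
(uncentered) trajectory.  The identified intercept for subject i is
therefore ``w_i0 + mean(x_i)``, and all recovery and coverage comparisons
use that as the generating truth for the intercept.  Pearson correlation is
location-invariant, so trajectory recovery is unaffected by centering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidArgumentError, UndefinedMetricError
from .types import Dataset, PosteriorDraws

__all__ = [
    "recovery_correlation",
    "identified_true_weights",
    "RecoveryReport",
    "parameter_recovery",
    "trajectory_recovery",
    "credible_interval",
    "coverage_report",
    "effective_sample_size",
    "split_rhat",
]


def recovery_correlation(truth, estimates) -> float:
    """Pearson correlation between generating values and estimates."""
    truth = np.asarray(truth, dtype=float)
    estimates = np.asarray(estimates, dtype=float)
    if truth.shape != estimates.shape or truth.ndim != 1:
        raise InvalidArgumentError("truth and estimates must be equal-length 1-D sequences")
    if truth.size < 3:
        raise InvalidArgumentError("need at least 3 points for a correlation")
    if truth.std() == 0 or estimates.std() == 0:
        raise UndefinedMetricError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(truth, estimates).statistic)


def identified_true_weights(dataset: Dataset) -> np.ndarray:
    """Generating weights with the intercept shifted by the trajectory mean.

    Shape (N, p).  Requires ground truth.
    """
    gt = _require_truth(dataset)
    w = np.array([p.weights for p in gt.params])
    w[:, 0] += np.array([t.states.mean() for t in gt.trajectories])
    return w


def _require_truth(dataset: Dataset):
    if dataset.ground_truth is None:
        raise InvalidArgumentError("dataset carries no ground truth")
    return dataset.ground_truth


@dataclass
class RecoveryReport:
    """True-vs-estimate recovery summaries for one fitted simulation."""

    weight_correlation: float                  # pooled over subjects x dimensions
    per_weight_correlations: np.ndarray        # (p,)
    ar_correlation: float | None
    innov_correlation: float | None
    trajectory_correlations: np.ndarray        # (N,) NaN when undefined
    trajectory_mean_correlation: float
    covariate_names: list[str] = field(default_factory=list)
    flagged: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [("weights_pooled", self.weight_correlation)]
        for name, r in zip(self.covariate_names, self.per_weight_correlations):
            rows.append((f"weight_{name}", r))
        if self.ar_correlation is not None:
            rows.append(("ar_coef", self.ar_correlation))
        if self.innov_correlation is not None:
            rows.append(("innov_var", self.innov_correlation))
        rows.append(("trajectory_mean", self.trajectory_mean_correlation))
        return pd.DataFrame(rows, columns=["quantity", "correlation"])


def parameter_recovery(dataset: Dataset, draws: PosteriorDraws) -> RecoveryReport:
    """Correlate generating subject-level parameters with posterior means.

    Per-weight correlations need >= 3 subjects; with fewer, only the pooled
    weight correlation is reported (per-weight entries are NaN).  The AR
    correlations are NaN-guarded the same way and omitted entirely for
    fluctuations-off fits.
    """
    gt = _require_truth(dataset)
    w_true = identified_true_weights(dataset)
    w_est = draws.weight_estimates()
    n, p = w_true.shape
    pooled = recovery_correlation(w_true.ravel(), w_est.ravel())
    per_weight = np.full(p, np.nan)
    if n >= 3:
        for j in range(p):
            try:
                per_weight[j] = recovery_correlation(w_true[:, j], w_est[:, j])
            except UndefinedMetricError:
                pass
    ar_r = innov_r = None
    if draws.metadata.get("estimate_fluctuations", True) and n >= 3:
        a_true = np.array([prm.ar_coef for prm in gt.params])
        s_true = np.array([prm.innov_var for prm in gt.params])
        try:
            ar_r = recovery_correlation(a_true, draws.ar_estimates())
            innov_r = recovery_correlation(s_true, draws.innov_estimates())
        except UndefinedMetricError:
            ar_r = innov_r = None
    traj = trajectory_recovery(dataset, draws)
    return RecoveryReport(
        weight_correlation=pooled,
        per_weight_correlations=per_weight,
        ar_correlation=ar_r,
        innov_correlation=innov_r,
        trajectory_correlations=traj.trajectory_correlations,
        trajectory_mean_correlation=traj.trajectory_mean_correlation,
        covariate_names=dataset.covariate_names,
        flagged=traj.flagged,
    )


def trajectory_recovery(dataset: Dataset, draws: PosteriorDraws) -> RecoveryReport:
    """Per-subject correlation between true trajectory and posterior mean.

    Subjects whose posterior-mean trajectory has (numerically) zero variance
    — e.g. from a fluctuations-off fit, where states are pinned at 0 — get
    NaN and are flagged rather than failing.
    """
    gt = _require_truth(dataset)
    n = dataset.n_subjects
    corrs = np.full(n, np.nan)
    flagged: list[str] = []
    for i in range(n):
        truth = gt.trajectories[i].states
        est = draws.trajectory_estimate(i)
        if truth.std() == 0 or est.std() < 1e-12:
            flagged.append(dataset.subjects[i].subject_id)
            continue
        corrs[i] = recovery_correlation(truth, est)
    if flagged:
        warnings.warn(
            f"trajectory correlation undefined for subjects {flagged} "
            "(zero-variance trajectory)",
            stacklevel=2,
        )
    mean_r = float(np.nanmean(corrs)) if np.any(np.isfinite(corrs)) else float("nan")
    return RecoveryReport(
        weight_correlation=float("nan"),
        per_weight_correlations=np.full(dataset.n_covariates, np.nan),
        ar_correlation=None,
        innov_correlation=None,
        trajectory_correlations=corrs,
        trajectory_mean_correlation=mean_r,
        covariate_names=dataset.covariate_names,
        flagged=flagged,
    )


def credible_interval(samples, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed posterior interval from MCMC samples."""
    samples = np.asarray(samples, dtype=float)
    if samples.size < 100:
        raise InvalidArgumentError("need at least 100 samples for a credible interval")
    if not 0.0 < level < 1.0:
        raise InvalidArgumentError("level must lie strictly between 0 and 1")
    tail = (1.0 - level) / 2.0
    return float(np.quantile(samples, tail)), float(np.quantile(samples, 1.0 - tail))


def _group_truth(dataset: Dataset) -> dict[str, float]:
    """Realized group-level truth: mean/SD of per-subject generating values.

    The intercept uses the identified convention (see module docstring);
    group-level SDs use the population (ddof=1) standard deviation.
    """
    gt = _require_truth(dataset)
    w = identified_true_weights(dataset)
    alphas = np.array([p.ar_coef for p in gt.params])
    out: dict[str, float] = {}
    names = dataset.covariate_names
    for j, name in enumerate(names):
        out[f"weight_mean[{name}]"] = float(w[:, j].mean())
        out[f"weight_sd[{name}]"] = float(w[:, j].std(ddof=1))
    out["ar_mean"] = float(alphas.mean())
    out["ar_sd"] = float(alphas.std(ddof=1))
    return out


def _group_interval(draws: PosteriorDraws, key: str, level: float) -> tuple[float, float]:
    names = draws.metadata.get("covariate_names")
    if key.startswith("weight_mean["):
        j = names.index(key[len("weight_mean["):-1])
        return credible_interval(draws.weight_mean[:, j], level)
    if key.startswith("weight_sd["):
        j = names.index(key[len("weight_sd["):-1])
        return credible_interval(np.sqrt(draws.weight_var[:, j]), level)
    if key == "ar_mean":
        return credible_interval(draws.ar_mean, level)
    if key == "ar_sd":
        return credible_interval(np.sqrt(draws.ar_var), level)
    raise KeyError(key)


def coverage_report(
    fitted: list[tuple[Dataset, PosteriorDraws]], level: float = 0.95
) -> pd.DataFrame:
    """Fraction of simulated datasets whose credible interval covers truth.

    One row per group-level parameter (per-covariate weight means and SDs,
    plus the mean and SD of the AR coefficients); ``covered`` counts
    datasets whose equal-tailed ``level`` interval contains the realized
    group-level truth of that dataset.
    """
    if not fitted:
        raise InvalidArgumentError("need at least one fitted dataset")
    keys = list(_group_truth(fitted[0][0]).keys())
    counts = {k: 0 for k in keys}
    for dataset, draws in fitted:
        truths = _group_truth(dataset)
        for k in keys:
            lo, hi = _group_interval(draws, k, level)
            if lo <= truths[k] <= hi:
                counts[k] += 1
    n = len(fitted)
    return pd.DataFrame(
        {
            "parameter": keys,
            "covered": [counts[k] for k in keys],
            "n_datasets": n,
            "coverage": [counts[k] / n for k in keys],
        }
    )


# -- convergence hygiene ----------------------------------------------------


def effective_sample_size(chain) -> float:
    """Bulk effective sample size of a single chain (via arviz)."""
    import arviz as az

    return float(az.ess(np.asarray(chain, dtype=float)[None, :]))


def split_rhat(chain) -> float:
    """Split-chain potential-scale-reduction factor of a single chain."""
    import arviz as az

    chain = np.asarray(chain, dtype=float)
    half = chain.size // 2
    return float(az.rhat(np.stack([chain[:half], chain[half : 2 * half]])))
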