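"""Core data containers.

The model describes a subject making T binary decisions.  On trial t the
response is Bernoulli with log-odds ``w @ u_t + x_t``: ``u_t`` are observed
covariates (column 0 is the constant 1 so ``w[0]`` is the intercept), ``w``
are per-subject weights, and ``x_t`` is a latent decision-criterion offset
following a mean-zero AR(1) process ``x_t = alpha * x_{t-1} + eps_t`` with
``eps_t ~ N(0, sigma2)``.  The latent state enters the log-odds with fixed
unit weight, which removes the scale trade-off between a state loading and
the innovation variance.

Per-subject parameters ``theta_i = (w_i, alpha_i, sigma2_i)`` are tied
together by group-level priors: Gaussian on the weights, normal truncated
to [0, 1] on the autoregressive coefficient, and inverse-gamma on the
innovation variance.  ``HyperParams`` carries the group-level parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import InvalidArgumentError

__all__ = [
    "SubjectData",
    "SubjectParams",
    "LatentTrajectory",
    "HyperParams",
    "GroundTruth",
    "Dataset",
    "PosteriorDraws",
]


def _as_float_vector(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise InvalidArgumentError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise InvalidArgumentError(f"{name} contains non-finite entries")
    return arr


@dataclass
class SubjectData:
    """One subject's trial table: binary responses plus covariates.

    ``covariates`` is a ``T x p`` matrix whose first column is identically 1
    (the intercept); ``responses`` is a length-``T`` 0/1 vector.
    """

    subject_id: str
    responses: np.ndarray
    covariates: np.ndarray
    covariate_names: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses)
        self.covariates = np.asarray(self.covariates, dtype=float)
        if self.covariates.ndim != 2:
            raise InvalidArgumentError("covariates must be a T x p matrix")
        t, p = self.covariates.shape
        if self.responses.shape != (t,):
            raise InvalidArgumentError(
                f"responses (len {self.responses.shape}) and covariates (T={t}) disagree"
            )
        if t < 2:
            raise InvalidArgumentError("a subject needs at least 2 trials")
        if not np.all(np.isin(self.responses, (0, 1))):
            raise InvalidArgumentError("responses must be 0/1")
        self.responses = self.responses.astype(np.int8)
        if not np.all(np.isfinite(self.covariates)):
            raise InvalidArgumentError("covariates contain non-finite entries")
        if not np.allclose(self.covariates[:, 0], 1.0):
            raise InvalidArgumentError("covariate column 0 must be identically 1 (intercept)")
        if self.covariate_names is None:
            self.covariate_names = ["intercept"] + [f"cov{j}" for j in range(1, p)]
        elif len(self.covariate_names) != p:
            raise InvalidArgumentError("covariate_names length must equal p")
        self.covariate_names = list(self.covariate_names)

    @property
    def n_trials(self) -> int:
        return self.covariates.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.covariates.shape[1]


@dataclass
class SubjectParams:
    """Per-subject parameters theta = (weights, ar_coef, innov_var)."""

    weights: np.ndarray
    ar_coef: float
    innov_var: float

    def __post_init__(self) -> None:
        self.weights = _as_float_vector(self.weights, "weights")
        self.ar_coef = float(self.ar_coef)
        self.innov_var = float(self.innov_var)
        if not 0.0 <= self.ar_coef <= 1.0:
            raise InvalidArgumentError(f"ar_coef must lie in [0, 1], got {self.ar_coef}")
        if not self.innov_var > 0.0:
            raise InvalidArgumentError(f"innov_var must be positive, got {self.innov_var}")


@dataclass
class LatentTrajectory:
    """A realisation x_1..x_T of the latent criterion offset (log-odds units)."""

    states: np.ndarray
    centered: bool = False

    def __post_init__(self) -> None:
        self.states = _as_float_vector(self.states, "states")
        if self.centered and self.states.size and abs(float(self.states.mean())) > 1e-8:
            raise InvalidArgumentError("centered trajectory must have mean 0")

    @property
    def n_trials(self) -> int:
        return self.states.size


@dataclass
class HyperParams:
    """Group-level prior parameters eta shared across subjects.

    ``iga_shape``/``iga_scale`` parameterise the inverse-gamma prior on the
    per-subject innovation variance (mean = scale / (shape - 1) for
    shape > 1).
    """

    weight_mean: np.ndarray
    weight_var: np.ndarray
    ar_mean: float
    ar_var: float
    iga_shape: float
    iga_scale: float

    def __post_init__(self) -> None:
        self.weight_mean = _as_float_vector(self.weight_mean, "weight_mean")
        self.weight_var = _as_float_vector(self.weight_var, "weight_var")
        if self.weight_mean.shape != self.weight_var.shape:
            raise InvalidArgumentError("weight_mean and weight_var must have equal length")
        self.ar_mean = float(self.ar_mean)
        self.ar_var = float(self.ar_var)
        self.iga_shape = float(self.iga_shape)
        self.iga_scale = float(self.iga_scale)
        for name in ("ar_var", "iga_shape", "iga_scale"):
            if not getattr(self, name) > 0:
                raise InvalidArgumentError(f"{name} must be positive")
        if np.any(self.weight_var <= 0):
            raise InvalidArgumentError("weight_var entries must be positive")

    @property
    def n_covariates(self) -> int:
        return self.weight_mean.size


@dataclass
class GroundTruth:
    """Generating quantities attached to a simulated dataset."""

    params: list[SubjectParams]
    trajectories: list[LatentTrajectory]
    hyper: HyperParams | None = None


@dataclass
class Dataset:
    """A collection of subjects sharing a covariate layout."""

    subjects: list[SubjectData]
    ground_truth: GroundTruth | None = None

    def __post_init__(self) -> None:
        if not self.subjects:
            raise InvalidArgumentError("Dataset needs at least one subject")
        p = self.subjects[0].n_covariates
        for s in self.subjects:
            if s.n_covariates != p:
                raise InvalidArgumentError("all subjects must share the same covariate count")
        if self.ground_truth is not None:
            gt = self.ground_truth
            if len(gt.params) != len(self.subjects) or len(gt.trajectories) != len(self.subjects):
                raise InvalidArgumentError("ground truth must cover every subject")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_covariates(self) -> int:
        return self.subjects[0].n_covariates

    @property
    def covariate_names(self) -> list[str]:
        return list(self.subjects[0].covariate_names)


@dataclass
class PosteriorDraws:
    """Retained Gibbs samples (post burn-in, thinned) for all unknowns.

    Array layout: leading axis indexes retained draws (S of them).
    ``trajectories`` is a per-subject list because trial counts may differ
    across subjects; each entry has shape ``(S, T_i)``.
    """

    weights: np.ndarray                     # (S, N, p)
    ar_coef: np.ndarray                     # (S, N)
    innov_var: np.ndarray                   # (S, N)
    trajectories: list[np.ndarray]          # N arrays of shape (S, T_i)
    weight_mean: np.ndarray                 # (S, p)
    weight_var: np.ndarray                  # (S, p)
    ar_mean: np.ndarray                     # (S,)
    ar_var: np.ndarray                      # (S,)
    iga_shape: np.ndarray                   # (S,)
    iga_scale: np.ndarray                   # (S,)
    metadata: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.weights.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.weights.shape[1]

    @property
    def n_covariates(self) -> int:
        return self.weights.shape[2]

    # -- point estimates (posterior means) --------------------------------

    def weight_estimates(self) -> np.ndarray:
        """Posterior-mean weights, shape (N, p)."""
        return self.weights.mean(axis=0)

    def ar_estimates(self) -> np.ndarray:
        return self.ar_coef.mean(axis=0)

    def innov_estimates(self) -> np.ndarray:
        return self.innov_var.mean(axis=0)

    def trajectory_estimate(self, i: int) -> np.ndarray:
        """Per-trial posterior mean of subject ``i``'s latent trajectory."""
        return self.trajectories[i].mean(axis=0)

    def trajectory_band(self, i: int, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
        """Equal-tailed per-trial credible band for subject ``i``."""
        tail = (1.0 - level) / 2.0
        draws = self.trajectories[i]
        return (
            np.quantile(draws, tail, axis=0),
            np.quantile(draws, 1.0 - tail, axis=0),
        )

    def hyper_draws(self) -> dict[str, np.ndarray]:
        return {
            "weight_mean": self.weight_mean,
            "weight_var": self.weight_var,
            "ar_mean": self.ar_mean,
            "ar_var": self.ar_var,
            "iga_shape": self.iga_shape,
            "iga_scale": self.iga_scale,
        }
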