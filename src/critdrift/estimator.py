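"""scikit-learn style front end for the hierarchical criterion-drift model.

``CriterionDriftModel`` wraps the blocked Gibbs sampler behind the familiar
``fit`` / ``predict_proba`` / ``get_params`` surface so it composes with
sklearn pipelines and model selection.  ``fit`` accepts long-format arrays
(one row per trial, subjects identified via ``groups``); library code that
already holds a :class:`~critdrift.types.Dataset` can call ``fit_dataset``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .errors import InvalidArgumentError
from .sampler import FitFlags, WeakPriors, fit as _fit
from .simulate import sigmoid
from .types import Dataset, SubjectData

__all__ = ["CriterionDriftModel"]


class CriterionDriftModel(BaseEstimator):
    """Hierarchical Bayesian logistic model with a latent AR(1) criterion.

    Parameters
    ----------
    n_iterations, burn_in, thin : int
        Gibbs schedule; ``floor((n_iterations - burn_in) / thin)`` draws
        are retained.
    estimate_fluctuations : bool
        If False, latent trajectories are pinned at zero and the model
        reduces to hierarchical Bayesian logistic regression.
    update_hyperpriors : bool
        If False, group-level parameters stay at their initial values
        (useful for fixed-prior analyses and validation against oracles).
    mean_center : bool
        Per-sweep mean-centering of the latent trajectories (keeps the
        intercept identifiable); disable only for sampler diagnostics.
    add_intercept : bool
        Prepend a constant-1 column to ``X`` (set False if ``X`` already
        carries one as its first column).
    random_state : int or None
        Seed for the single RNG stream driving the whole fit.

    Attributes
    ----------
    draws_ : PosteriorDraws
        All retained posterior draws.
    coef_ : ndarray of shape (n_subjects, n_features)
        Posterior-mean per-subject weights (intercept included).
    trajectories_ : list of ndarray
        Per-subject per-trial posterior-mean latent criterion.
    group_weight_mean_ : ndarray of shape (n_features,)
        Posterior mean of the group-level weight means.
    classes_ : ndarray
        Always ``[0, 1]``.
    """

    def __init__(
        self,
        n_iterations: int = 1000,
        burn_in: int = 500,
        thin: int = 1,
        estimate_fluctuations: bool = True,
        update_hyperpriors: bool = True,
        mean_center: bool = True,
        add_intercept: bool = True,
        random_state: int | None = None,
    ):
        self.n_iterations = n_iterations
        self.burn_in = burn_in
        self.thin = thin
        self.estimate_fluctuations = estimate_fluctuations
        self.update_hyperpriors = update_hyperpriors
        self.mean_center = mean_center
        self.add_intercept = add_intercept
        self.random_state = random_state

    # -- fitting -----------------------------------------------------------

    def _build_dataset(self, X, y, groups) -> Dataset:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.shape[0]:
            raise InvalidArgumentError("X must be (n_trials, n_features) aligned with y")
        if groups is None:
            groups = np.zeros(y.shape[0], dtype=int)
        groups = np.asarray(groups)
        if self.add_intercept:
            X = np.column_stack([np.ones(X.shape[0]), X])
            names = ["intercept"] + [f"x{j}" for j in range(X.shape[1] - 1)]
        else:
            names = [f"x{j}" for j in range(X.shape[1])]
            names[0] = "intercept"
        subjects = []
        for g in _unique_stable(groups):
            mask = groups == g
            subjects.append(
                SubjectData(
                    subject_id=str(g),
                    responses=y[mask],
                    covariates=X[mask],
                    covariate_names=names,
                )
            )
        return Dataset(subjects=subjects)

    def fit(self, X, y, groups=None):
        """Run the Gibbs sampler on long-format trial data."""
        dataset = self._build_dataset(X, y, groups)
        return self.fit_dataset(dataset)

    def fit_dataset(self, dataset: Dataset):
        """Run the Gibbs sampler on an assembled Dataset."""
        flags = FitFlags(
            estimate_fluctuations=self.estimate_fluctuations,
            update_hyperpriors=self.update_hyperpriors,
            mean_center=self.mean_center,
        )
        self.draws_ = _fit(
            dataset,
            n_iterations=self.n_iterations,
            burn_in=self.burn_in,
            thin=self.thin,
            seed=self.random_state,
            flags=flags,
            priors=WeakPriors(),
        )
        self.dataset_ = dataset
        self.coef_ = self.draws_.weight_estimates()
        self.trajectories_ = [
            self.draws_.trajectory_estimate(i) for i in range(dataset.n_subjects)
        ]
        self.group_weight_mean_ = self.draws_.weight_mean.mean(axis=0)
        self.subject_ids_ = [s.subject_id for s in dataset.subjects]
        self.n_features_in_ = dataset.n_covariates - (1 if self.add_intercept else 0)
        self.classes_ = np.array([0, 1])
        return self

    # -- prediction --------------------------------------------------------

    def _weights_for(self, group) -> np.ndarray:
        if group is not None and str(group) in self.subject_ids_:
            return self.coef_[self.subject_ids_.index(str(group))]
        # unseen subject: fall back to the group-level weight means
        return self.group_weight_mean_

    def predict_proba(self, X, groups=None):
        """P(response = 1) per trial from posterior-mean weights.

        The latent criterion of out-of-sample trials is unknown and enters
        at its stationary mean of zero.
        """
        check_is_fitted(self, "draws_")
        X = np.asarray(X, dtype=float)
        if self.add_intercept:
            X = np.column_stack([np.ones(X.shape[0]), X])
        if groups is None:
            groups = np.full(X.shape[0], None)
        groups = np.asarray(groups, dtype=object)
        p1 = np.empty(X.shape[0])
        for g in set(groups.tolist()):
            mask = np.array([x == g for x in groups])
            p1[mask] = sigmoid(X[mask] @ self._weights_for(g))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X, groups=None):
        return (self.predict_proba(X, groups)[:, 1] >= 0.5).astype(int)

    def score(self, X, y, groups=None):
        """Mean accuracy of the posterior-mean predictor."""
        return float(np.mean(self.predict(X, groups) == np.asarray(y)))


def _unique_stable(values) -> list:
    seen: dict = {}
    for v in np.asarray(values).tolist():
        seen.setdefault(v, None)
    return list(seen)
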