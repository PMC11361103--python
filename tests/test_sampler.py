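"""Whole-sampler validity: invariants, limits, and the Geweke joint test."""

import numpy as np
import pytest
from scipy import stats

from critdrift.errors import InvalidArgumentError
from critdrift.sampler import FitFlags, GibbsState, fit, gibbs_sweep, initialize_state
from critdrift.simulate import (
    sample_subject_params,
    sigmoid,
    simulate_hierarchical_dataset,
    simulate_latent,
)
from critdrift.types import Dataset, HyperParams, SubjectData

from conftest import quadrature_logistic_posterior_mean


def small_dataset(seed=0, n=4, t=60):
    return simulate_hierarchical_dataset(n, t, rng=seed)


class TestSweepInvariants:
    def test_contract_preserved_across_sweeps(self):
        ds = small_dataset()
        rng = np.random.default_rng(1)
        state = initialize_state(ds, rng)
        for _ in range(20):
            gibbs_sweep(state, ds, rng)
            for i in range(ds.n_subjects):
                assert abs(state.trajectories[i].mean()) < 1e-9
                assert 0.0 <= state.ar_coef[i] <= 1.0
                assert state.innov_var[i] > 0
            assert np.all(np.isfinite(state.weights))
            assert np.all(state.hyper.weight_var > 0)

    def test_fluctuations_off_pins_trajectories(self):
        ds = small_dataset()
        draws = fit(ds, n_iterations=30, burn_in=10, seed=2,
                    flags=FitFlags(estimate_fluctuations=False))
        for traj in draws.trajectories:
            assert np.all(traj == 0.0)
        assert draws.metadata["estimate_fluctuations"] is False

    def test_degenerate_subject_is_flagged_but_fitted(self):
        ds = small_dataset(n=3, t=40)
        const = SubjectData(
            subject_id="const",
            responses=np.ones(40, dtype=int),
            covariates=ds.subjects[0].covariates,
            covariate_names=ds.subjects[0].covariate_names,
        )
        ds2 = Dataset(subjects=ds.subjects[:3] + [const])
        draws = fit(ds2, n_iterations=30, burn_in=10, seed=3)
        assert draws.metadata["flagged_subjects"] == [3]
        assert np.all(np.isfinite(draws.weights))


class TestFitContract:
    def test_retained_draw_count_and_thinning(self):
        ds = small_dataset(n=2, t=30)
        draws = fit(ds, n_iterations=57, burn_in=20, thin=3, seed=4)
        assert draws.n_draws == (57 - 20) // 3
        assert draws.weights.shape == (12, 2, 4)

    def test_reproducible_under_seed(self):
        ds = small_dataset(n=2, t=40)
        a = fit(ds, n_iterations=40, burn_in=20, seed=11)
        b = fit(ds, n_iterations=40, burn_in=20, seed=11)
        np.testing.assert_array_equal(a.weights, b.weights)
        np.testing.assert_array_equal(a.trajectories[0], b.trajectories[0])
        np.testing.assert_array_equal(a.ar_mean, b.ar_mean)

    def test_schedule_validation(self):
        ds = small_dataset(n=2, t=30)
        with pytest.raises(InvalidArgumentError):
            fit(ds, n_iterations=10, burn_in=10)
        with pytest.raises(InvalidArgumentError):
            fit(ds, n_iterations=10, burn_in=2, thin=0)


class TestHierarchicalLogisticLimit:
    def test_single_weight_posterior_matches_quadrature(self):
        # one subject, T=4, p=1, fluctuations off, fixed prior on the weight:
        # the exact posterior is a 1-D logistic regression posterior
        y = np.array([1, 1, 0, 1])
        u = np.ones((4, 1))
        subj = SubjectData("s0", y, u, ["intercept"])
        ds = Dataset(subjects=[subj])
        prior_mean, prior_var = 0.5, 4.0
        hyper = HyperParams(
            weight_mean=np.array([prior_mean]),
            weight_var=np.array([prior_var]),
            ar_mean=0.9, ar_var=0.01, iga_shape=3.0, iga_scale=0.1,
        )
        draws = fit(
            ds, n_iterations=60_000, burn_in=2_000, seed=5,
            flags=FitFlags(estimate_fluctuations=False, update_hyperpriors=False),
            hyper_init=hyper,
        )
        oracle = quadrature_logistic_posterior_mean(y, u[:, 0], prior_mean, prior_var)
        assert draws.weights[:, 0, 0].mean() == pytest.approx(oracle, abs=0.03)

    def test_multisubject_posterior_matches_emcee(self):
        # fluctuations off, fixed hyper: per-subject weights have independent
        # logistic-regression posteriors; emcee samples them without any
        # Pólya-gamma augmentation
        emcee = pytest.importorskip("emcee")
        rng = np.random.default_rng(6)
        n_subj, t = 3, 40
        hyper = HyperParams(
            weight_mean=np.array([0.0, 0.5]), weight_var=np.array([1.0, 1.0]),
            ar_mean=0.9, ar_var=0.01, iga_shape=3.0, iga_scale=0.1,
        )
        subjects, truths = [], []
        for i in range(n_subj):
            u = np.column_stack([np.ones(t), rng.standard_normal(t)])
            p = sample_subject_params(hyper, 2, rng)
            x = simulate_latent(0.0, 0.0, t, rng)
            y = (rng.random(t) < sigmoid(u @ p.weights)).astype(int)
            subjects.append(SubjectData(f"s{i}", y, u, ["intercept", "ev"]))
        ds = Dataset(subjects=subjects)

        def log_prob(theta):
            lp = 0.0
            for i, s in enumerate(ds.subjects):
                w = theta[2 * i : 2 * i + 2]
                psi = s.covariates @ w
                lp += float(psi @ s.responses - np.logaddexp(0.0, psi).sum())
                lp += float(
                    -0.5 * ((w - hyper.weight_mean) ** 2 / hyper.weight_var).sum()
                )
            return lp

        ndim = 2 * n_subj
        sampler = emcee.EnsembleSampler(24, ndim, log_prob)
        p0 = 0.1 * np.random.default_rng(7).standard_normal((24, ndim))
        sampler.run_mcmc(p0, 3000, progress=False)
        ref = sampler.get_chain(discard=1000, flat=True).mean(axis=0).reshape(n_subj, 2)

        draws = fit(
            ds, n_iterations=8_000, burn_in=1_000, seed=8,
            flags=FitFlags(estimate_fluctuations=False, update_hyperpriors=False),
            hyper_init=hyper,
        )
        np.testing.assert_allclose(draws.weight_estimates(), ref, atol=0.06)


def test_group_posteriors_narrow_with_more_subjects():
    """Hierarchical pooling: group-level posterior width shrinks with N."""
    widths = {}
    for n in (4, 16):
        ds = simulate_hierarchical_dataset(n, 200, rng=50)
        draws = fit(ds, n_iterations=400, burn_in=200, seed=51)
        widths[n] = draws.weight_mean.std(axis=0).mean()
    assert widths[16] < widths[4]


def _regenerate_responses(state: GibbsState, data: Dataset, rng) -> None:
    for i, subj in enumerate(data.subjects):
        psi = subj.covariates @ state.weights[i] + state.trajectories[i]
        subj.responses = (rng.random(psi.size) < sigmoid(psi)).astype(np.int8)


class TestGewekeJointDistribution:
    """Successive-conditional simulator vs. direct prior simulation.

    Alternating one Gibbs sweep with regeneration of the responses leaves
    the prior marginals of the subject-level unknowns invariant if and only
    if every conditional draw targets the right distribution.  Run with
    fixed hyperparameters and per-sweep centering disabled (the centering
    is an intentional identifiability device that perturbs the exact joint;
    the exact blocks are what this test certifies).
    """

    def test_prior_marginals_invariant(self):
        n_subj, t, p = 3, 20, 2
        hyper = HyperParams(
            weight_mean=np.array([0.0, 0.3]), weight_var=np.array([0.5, 0.5]),
            ar_mean=0.8, ar_var=0.04, iga_shape=5.0, iga_scale=0.45,
        )
        rng = np.random.default_rng(9)
        flags = FitFlags(update_hyperpriors=False, mean_center=False)

        # direct prior simulation
        prior_ar, prior_innov, prior_w, prior_x1 = [], [], [], []
        for _ in range(4000):
            prm = sample_subject_params(hyper, p, rng)
            prior_ar.append(prm.ar_coef)
            prior_innov.append(prm.innov_var)
            prior_w.append(prm.weights[1])
            prior_x1.append(
                simulate_latent(prm.ar_coef, prm.innov_var, 1, rng).states[0]
            )

        # successive-conditional chain
        subjects = []
        params, trajs = [], []
        for i in range(n_subj):
            u = np.column_stack([np.ones(t), rng.standard_normal(t)])
            prm = sample_subject_params(hyper, p, rng)
            x = simulate_latent(prm.ar_coef, prm.innov_var, t, rng)
            y = (rng.random(t) < sigmoid(u @ prm.weights + x.states)).astype(int)
            subjects.append(SubjectData(f"s{i}", y, u, ["intercept", "ev"]))
            params.append(prm)
            trajs.append(x)
        data = Dataset(subjects=subjects)
        state = initialize_state(data, rng, hyper_init=hyper)
        state.weights = np.array([prm.weights for prm in params])
        state.ar_coef = np.array([prm.ar_coef for prm in params])
        state.innov_var = np.array([prm.innov_var for prm in params])
        state.trajectories = [x.states.copy() for x in trajs]

        succ_ar, succ_innov, succ_w, succ_x1 = [], [], [], []
        n_iter, keep_every = 6000, 3
        for it in range(n_iter):
            gibbs_sweep(state, data, rng, flags=flags)
            _regenerate_responses(state, data, rng)
            if it % keep_every == 0:
                for i in range(n_subj):
                    succ_ar.append(state.ar_coef[i])
                    succ_innov.append(state.innov_var[i])
                    succ_w.append(state.weights[i, 1])
                    succ_x1.append(state.trajectories[i][0])

        for prior, succ, label in [
            (prior_ar, succ_ar, "ar_coef"),
            (np.log(prior_innov), np.log(succ_innov), "log innov_var"),
            (prior_w, succ_w, "weight"),
            (prior_x1, succ_x1, "x_1"),
        ]:
            stat = stats.ks_2samp(prior, succ).statistic
            assert stat < 0.06, f"{label}: KS={stat:.3f}"
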