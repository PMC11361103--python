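"""Conjugate and Metropolis-Hastings parameter blocks against oracles."""

import numpy as np
import pytest
from scipy import stats

from critdrift.errors import InvalidArgumentError
from critdrift.sampler import (
    PGAuxiliaries,
    WeakPriors,
    truncnorm_draw,
    update_ar_coef,
    update_ar_hyperprior_mh,
    update_iga_hyperprior_mh,
    update_innov_var,
    update_weight_hyperprior,
    update_weights,
)
from critdrift.simulate import simulate_latent
from critdrift.types import LatentTrajectory

from conftest import grid_posterior_ar, grid_posterior_innov, ks_against_grid


class TestTruncNormDraw:
    @pytest.mark.parametrize(
        "mean,var", [(0.5, 0.04), (0.99, 0.025**2), (-0.3, 0.1), (1.4, 0.01)]
    )
    def test_matches_scipy_truncnorm(self, mean, var):
        rng = np.random.default_rng(5)
        draws = np.array([truncnorm_draw(mean, var, 0.0, 1.0, rng) for _ in range(20_000)])
        sd = np.sqrt(var)
        a, b = (0 - mean) / sd, (1 - mean) / sd
        stat = stats.kstest(draws, stats.truncnorm(a, b, loc=mean, scale=sd).cdf).statistic
        assert stat < 0.015
        assert np.all((draws >= 0) & (draws <= 1))

    def test_extreme_tail_stays_in_support(self):
        rng = np.random.default_rng(6)
        for mean, var in [(25.0, 0.01), (-25.0, 0.01), (1e4, 1.0)]:
            d = truncnorm_draw(mean, var, 0.0, 1.0, rng)
            assert 0.0 <= d <= 1.0 and np.isfinite(d)


class TestUpdateWeights:
    def _toy(self, seed=0, t=3):
        rng = np.random.default_rng(seed)
        u = np.column_stack([np.ones(t)])
        y = rng.integers(0, 2, t).astype(float)
        omega = rng.gamma(2.0, 0.3, t) + 0.1
        x = rng.normal(0, 0.5, t)
        return u, y, omega, x

    def test_strong_prior_limit(self):
        u, y, omega, x = self._toy()
        rng = np.random.default_rng(1)
        prior_mean = np.array([1.7])
        draws = [
            update_weights(
                u, y, LatentTrajectory(states=x), PGAuxiliaries(omega),
                prior_mean, np.array([1e-12]), rng,
            )[0]
            for _ in range(200)
        ]
        np.testing.assert_allclose(draws, 1.7, atol=1e-4)

    def test_toy_conjugate_moments(self):
        # T=3, p=1: hand-computed Gaussian conditional
        u, y, omega, x = self._toy(seed=3)
        kappa = y - 0.5
        prior_mean, prior_var = 0.4, 2.0
        prec = float((u[:, 0] ** 2 * omega).sum() + 1.0 / prior_var)
        mean = (float(u[:, 0] @ (kappa - omega * x)) + prior_mean / prior_var) / prec
        rng = np.random.default_rng(4)
        draws = np.array(
            [
                update_weights(
                    u, y, LatentTrajectory(states=x), PGAuxiliaries(omega),
                    np.array([prior_mean]), np.array([prior_var]), rng,
                )[0]
                for _ in range(100_000)
            ]
        )
        assert draws.mean() == pytest.approx(mean, abs=4.5 / np.sqrt(prec * draws.size))
        assert draws.var() == pytest.approx(1.0 / prec, rel=0.03)

    def test_uninformative_column_follows_prior(self):
        # an all-zero covariate column contributes no likelihood information
        t = 50
        rng = np.random.default_rng(9)
        u = np.column_stack([np.ones(t), np.zeros(t)])
        y = rng.integers(0, 2, t).astype(float)
        omega = rng.gamma(2.0, 0.3, t) + 0.1
        x = np.zeros(t)
        pm = np.array([0.0, -1.2])
        pv = np.array([4.0, 0.5])
        draws = np.array(
            [
                update_weights(
                    u, y, LatentTrajectory(states=x), PGAuxiliaries(omega), pm, pv,
                    rng,
                )
                for _ in range(30_000)
            ]
        )
        assert draws[:, 1].mean() == pytest.approx(-1.2, abs=0.02)
        assert draws[:, 1].var() == pytest.approx(0.5, rel=0.04)


class TestARCoefUpdate:
    def test_zero_trajectory_reduces_to_prior(self):
        rng = np.random.default_rng(10)
        traj = LatentTrajectory(states=np.zeros(30))
        draws = np.array(
            [update_ar_coef(traj, 0.1, 0.9, 0.02, rng) for _ in range(20_000)]
        )
        sd = np.sqrt(0.02)
        a, b = (0 - 0.9) / sd, (1 - 0.9) / sd
        stat = stats.kstest(draws, stats.truncnorm(a, b, loc=0.9, scale=sd).cdf).statistic
        assert stat < 0.015

    def test_support(self, rng):
        traj = LatentTrajectory(states=rng.normal(0, 2, 100))
        for _ in range(200):
            assert 0.0 <= update_ar_coef(traj, 0.5, 0.5, 10.0, rng) <= 1.0

    def test_grid_oracle(self):
        rng = np.random.default_rng(12)
        x = simulate_latent(0.9, 0.3, 50, rng).states
        draws = np.array(
            [update_ar_coef(LatentTrajectory(states=x), 0.3, 0.8, 0.1, rng)
             for _ in range(30_000)]
        )
        grid, cdf = grid_posterior_ar(x, 0.3, 0.8, 0.1)
        assert ks_against_grid(draws, grid, cdf) < 0.015

    def test_too_short(self, rng):
        with pytest.raises(InvalidArgumentError):
            update_ar_coef(LatentTrajectory(states=np.array([1.0])), 0.1, 0.9, 0.1, rng)


class TestInnovVarUpdate:
    def test_closed_form_example(self):
        # x = (0, 1, 0), alpha = 0: residuals (1, 0), SSE = 1 -> IGa(6, 0.95)
        rng = np.random.default_rng(13)
        traj = LatentTrajectory(states=np.array([0.0, 1.0, 0.0]))
        draws = np.array(
            [update_innov_var(traj, 0.0, 5.0, 0.45, rng) for _ in range(30_000)]
        )
        stat = stats.kstest(draws, stats.invgamma(6.0, scale=0.95).cdf).statistic
        assert stat < 0.015

    def test_zero_residuals(self):
        # perfectly autoregressive chain: posterior scale = prior scale
        rng = np.random.default_rng(14)
        x = 2.0 * 0.5 ** np.arange(10)
        traj = LatentTrajectory(states=x)
        draws = np.array(
            [update_innov_var(traj, 0.5, 3.0, 0.2, rng) for _ in range(30_000)]
        )
        stat = stats.kstest(draws, stats.invgamma(3.0 + 4.5, scale=0.2).cdf).statistic
        assert stat < 0.015

    def test_grid_oracle(self):
        rng = np.random.default_rng(15)
        x = simulate_latent(0.95, 0.2, 50, rng).states
        draws = np.array(
            [update_innov_var(LatentTrajectory(states=x), 0.95, 2.0, 0.3, rng)
             for _ in range(30_000)]
        )
        grid, cdf = grid_posterior_innov(x, 0.95, 2.0, 0.3)
        assert ks_against_grid(draws, grid, cdf) < 0.015


class TestWeightHyperUpdate:
    def test_zero_dispersion_concentrates(self):
        rng = np.random.default_rng(16)
        w = np.tile([1.3, -0.7], (40, 1))
        means, variances = [], []
        cur_mean = np.zeros(2)
        for _ in range(2000):
            m, v = update_weight_hyperprior(w, cur_mean, rng)
            cur_mean = m
            means.append(m)
            variances.append(v)
        means = np.array(means)[500:]
        variances = np.array(variances)[500:]
        np.testing.assert_allclose(means.mean(axis=0), [1.3, -0.7], atol=0.05)
        assert variances.mean() < 0.15  # shrinks toward the prior's low range

    def test_conditional_moments_against_closed_form(self):
        # N=5 toy: scipy-based independent implementation of both conditionals
        rng = np.random.default_rng(17)
        w = np.array([[0.2], [1.1], [-0.4], [0.8], [0.3]])
        priors = WeakPriors()
        cur_mean = np.array([0.5])
        draws_v, draws_m = [], []
        for _ in range(40_000):
            m, v = update_weight_hyperprior(w, cur_mean, rng, priors)
            draws_v.append(v[0])
            draws_m.append(m[0])
        # sigma_w^2 | mu: IGa(a0 + N/2, b0 + SSE/2) at the held mu
        sse = float(((w[:, 0] - 0.5) ** 2).sum())
        expect_v = stats.invgamma(priors.weight_var_shape + 2.5,
                                  scale=priors.weight_var_scale + sse / 2.0)
        assert np.mean(draws_v) == pytest.approx(expect_v.mean(), rel=0.03)
        # mu | sigma_w^2 integrates to a mean near the sample mean under weak prior
        assert np.mean(draws_m) == pytest.approx(w.mean(), abs=0.03)

    def test_weak_prior_large_n_matches_sample_mean(self):
        rng = np.random.default_rng(18)
        w = rng.normal(0.7, 1.0, size=(200, 1))
        cur_mean = np.zeros(1)
        ms = []
        for _ in range(3000):
            m, _ = update_weight_hyperprior(w, cur_mean, rng)
            cur_mean = m
            ms.append(m[0])
        assert np.mean(ms[500:]) == pytest.approx(w.mean(), abs=0.03)

    def test_needs_two_subjects(self, rng):
        with pytest.raises(InvalidArgumentError):
            update_weight_hyperprior(np.ones((1, 2)), np.zeros(2), rng)


def _grid_ar_hyper_posterior(alphas, priors, n=400):
    """2-D grid posterior of (mu_alpha, sigma_alpha^2) given alpha_i."""
    mus = np.linspace(0.0, 1.0, n)
    vs = np.linspace(1e-4, 0.2, n)
    mm, vv = np.meshgrid(mus, vs, indexing="ij")
    sd = np.sqrt(vv)
    z = stats.norm.cdf((1 - mm) / sd) - stats.norm.cdf((0 - mm) / sd)
    logp = -0.5 * (mm - priors.ar_mean_loc) ** 2 / priors.ar_mean_var
    logp += -np.log1p(vv**2)
    for a in alphas:
        logp += stats.norm.logpdf(a, mm, sd)
    logp -= len(alphas) * np.log(z)
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    return mus, vs, p


class TestARHyperMH:
    def test_null_proposal_keeps_state(self, rng):
        alphas = np.array([0.9, 0.95, 0.85, 0.92])
        m, v, acc = update_ar_hyperprior_mh(alphas, (0.9, 0.01), (0.0, 0.0), rng)
        assert (m, v) == (0.9, 0.01)
        assert acc == (True, True)

    def test_negative_variance_proposals_rejected(self):
        rng = np.random.default_rng(19)
        alphas = np.array([0.9, 0.95, 0.85, 0.92])
        m, v = 0.9, 1e-4
        for _ in range(500):
            m, v, _ = update_ar_hyperprior_mh(alphas, (m, v), (0.02, 0.5), rng)
            assert v > 0 and 0 <= m <= 1

    def test_long_chain_matches_grid_marginal(self):
        rng = np.random.default_rng(20)
        alphas = np.array([0.93, 0.97, 0.91, 0.99, 0.95, 0.96, 0.9, 0.94, 0.98, 0.92])
        priors = WeakPriors()
        m, v = 0.9, 0.01
        chain = []
        for _ in range(40_000):
            m, v, _ = update_ar_hyperprior_mh(alphas, (m, v), (0.03, 0.01), rng, priors)
            chain.append(m)
        chain = np.array(chain)[5000:]
        mus, vs, p = _grid_ar_hyper_posterior(alphas, priors)
        marg_mean = float((mus * p.sum(axis=1)).sum())
        assert chain.mean() == pytest.approx(marg_mean, abs=0.01)

    def test_needs_two_subjects(self, rng):
        with pytest.raises(InvalidArgumentError):
            update_ar_hyperprior_mh(np.array([0.9]), (0.9, 0.01), (0.1, 0.1), rng)


class TestIGaHyperMH:
    def test_null_proposal_keeps_state(self, rng):
        s2 = np.array([0.1, 0.2, 0.08, 0.15])
        a, b, acc = update_iga_hyperprior_mh(s2, (3.0, 0.3), (0.0, 0.0), rng)
        assert (a, b) == (3.0, 0.3)

    def test_nonpositive_shape_proposals_rejected(self):
        rng = np.random.default_rng(21)
        s2 = np.array([0.1, 0.2, 0.08, 0.15])
        a, b = 0.05, 0.3
        for _ in range(500):
            a, b, _ = update_iga_hyperprior_mh(s2, (a, b), (1.0, 0.1), rng)
            assert a > 0 and b > 0

    def test_scale_marginal_matches_grid_oracle(self):
        # hold the shape fixed via a zero proposal scale; compare the scale's
        # long-run marginal against 1-D grid integration of its conditional
        rng = np.random.default_rng(22)
        s2 = np.array([0.1, 0.15, 0.08, 0.2, 0.12, 0.09, 0.11, 0.14, 0.13, 0.1])
        shape = 4.0
        b = 0.3
        chain = []
        for _ in range(60_000):
            _, b, _ = update_iga_hyperprior_mh(s2, (shape, b), (0.0, 0.08), rng)
            chain.append(b)
        chain = np.array(chain)[5000:]
        grid = np.linspace(1e-4, 3.0, 30_000)
        logp = s2.size * shape * np.log(grid) - grid * (1.0 / s2).sum() - np.log1p(grid**2)
        logp -= logp.max()
        p = np.exp(logp)
        p /= p.sum()
        assert chain.mean() == pytest.approx(float((grid * p).sum()), rel=0.02)
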