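"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the code paths they check: the latent
chain's conditional is rebuilt by dense multivariate-normal linear algebra,
the scalar conditionals by 1-D grid integration, and the fluctuations-off
posterior by quadrature.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from critdrift.simulate import sigmoid


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


# ---------------------------------------------------------------------------
# dense Gaussian oracle for the latent-chain conditional


def dense_latent_posterior(kappa, omega, offset, ar_coef, innov_var):
    """Exact joint Gaussian posterior of x_{1:T} by dense matrix inversion.

    Prior: x_1 ~ N(0, innov_var / (1 - ar_coef^2)), x_t | x_{t-1} ~
    N(ar_coef x_{t-1}, innov_var).  Pseudo-observations z_t =
    kappa_t / omega_t - offset_t with precision omega_t.  Returns
    (mean vector, covariance matrix).
    """
    t = len(kappa)
    a, s2 = ar_coef, innov_var
    v0 = s2 / (1.0 - min(a, 1 - 1e-6) ** 2)
    q = np.zeros((t, t))
    q[0, 0] = 1.0 / v0
    for i in range(1, t):
        q[i, i] += 1.0 / s2
        q[i - 1, i - 1] += a * a / s2
        q[i, i - 1] -= a / s2
        q[i - 1, i] -= a / s2
    z = np.asarray(kappa) / np.asarray(omega) - np.asarray(offset)
    q += np.diag(omega)
    cov = np.linalg.inv(q)
    mean = cov @ (np.asarray(omega) * z)
    return mean, cov


# ---------------------------------------------------------------------------
# 1-D grid oracles for the scalar conjugate conditionals


def grid_posterior_ar(x, innov_var, ar_mean, ar_var, n_grid=20001):
    """Grid CDF of p(alpha | x) on [0, 1]: TruncNorm prior x AR likelihood."""
    grid = np.linspace(0.0, 1.0, n_grid)
    logp = stats.norm.logpdf(grid, ar_mean, np.sqrt(ar_var))
    resid2 = np.array([((x[1:] - a * x[:-1]) ** 2).sum() for a in grid])
    logp -= resid2 / (2.0 * innov_var)
    logp -= logp.max()
    pdf = np.exp(logp)
    cdf = np.cumsum(pdf)
    cdf /= cdf[-1]
    return grid, cdf


def grid_posterior_innov(x, ar_coef, iga_shape, iga_scale, n_grid=20001, hi=None):
    """Grid CDF of p(sigma2 | x): IGa prior x AR likelihood."""
    resid2 = ((x[1:] - ar_coef * x[:-1]) ** 2).sum()
    shape = iga_shape + (len(x) - 1) / 2.0
    scale = iga_scale + resid2 / 2.0
    if hi is None:
        hi = stats.invgamma.ppf(1 - 1e-10, shape, scale=scale)
    lo = stats.invgamma.ppf(1e-12, shape, scale=scale)
    grid = np.linspace(lo, hi, n_grid)
    logp = -(iga_shape + 1) * np.log(grid) - iga_scale / grid
    logp += -((len(x) - 1) / 2.0) * np.log(grid) - resid2 / (2.0 * grid)
    logp -= logp.max()
    pdf = np.exp(logp)
    cdf = np.cumsum(pdf)
    cdf /= cdf[-1]
    return grid, cdf


def ks_against_grid(draws, grid, cdf):
    """Kolmogorov-Smirnov distance of samples against a grid CDF."""
    draws = np.sort(np.asarray(draws))
    emp = np.arange(1, draws.size + 1) / draws.size
    theo = np.interp(draws, grid, cdf)
    return float(np.max(np.abs(emp - theo)))


# ---------------------------------------------------------------------------
# quadrature oracle for the fluctuations-off (logistic) limit


def quadrature_logistic_posterior_mean(y, u_col, prior_mean, prior_var, lim=12.0):
    """Posterior mean of a 1-D logistic-regression weight by dense quadrature."""
    w = np.linspace(prior_mean - lim, prior_mean + lim, 40001)
    logp = -0.5 * (w - prior_mean) ** 2 / prior_var
    for yt, ut in zip(y, u_col):
        psi = w * ut
        logp += psi * yt - np.logaddexp(0.0, psi)
    logp -= logp.max()
    p = np.exp(logp)
    return float(np.trapezoid(p * w) / np.trapezoid(p))


def mc_halfnormal_sigmoid(beta, n=400000, seed=7):
    """Monte-Carlo E[sigmoid(beta * |U|)], U standard normal."""
    g = np.random.default_rng(seed)
    return float(np.mean(sigmoid(beta * np.abs(g.standard_normal(n)))))
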