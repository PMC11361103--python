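"""Exact Pólya-gamma PG(1, c) sampling.

Implements the Devroye alternating-series rejection sampler for the
Jacobi-type distribution J*(1, z), of which PG(1, c) is a scaled tilt:
if X ~ J*(1, |c|/2) then X/4 ~ PG(1, c).  The sampler is exact (no
truncated-sum approximation) and JIT-compiled; the per-trial draws in the
Gibbs sweep dominate runtime, so this is the hot path of the package.

Moment identity used throughout the tests: E[PG(1, c)] = tanh(c/2) / (2c),
with the limit 1/4 at c = 0.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["pg_draw", "pg_draws"]

# Devroye's truncation point separating the inverse-Gaussian and
# exponential envelope regions of J*(1, z).
_TRUNC = 0.64


@njit(cache=True, inline="always")
def _norm_cdf(x):
    return 0.5 * math.erfc(-x / math.sqrt(2.0))


@njit(cache=True)
def _coef(n, x):
    # n-th coefficient a_n(x) of the alternating series for the J*(1,.) density.
    if x > _TRUNC:
        return math.pi * (n + 0.5) * math.exp(-((n + 0.5) ** 2) * math.pi**2 * x / 2.0)
    if x > 0.0:
        return (
            math.pi
            * (n + 0.5)
            * (2.0 / (math.pi * x)) ** 1.5
            * math.exp(-2.0 * (n + 0.5) ** 2 / x)
        )
    return 0.0


@njit(cache=True)
def _mass_texpon(z):
    # Probability that the proposal falls in the exponential (x > t) region.
    t = _TRUNC
    k = math.pi**2 / 8.0 + z**2 / 2.0
    b = math.sqrt(1.0 / t) * (t * z - 1.0)
    a = -math.sqrt(1.0 / t) * (t * z + 1.0)
    x0 = math.log(k) + k * t
    xb = x0 - z + math.log(_norm_cdf(b))
    xa = x0 + z + math.log(_norm_cdf(a))
    qdivp = 4.0 / math.pi * (math.exp(xb) + math.exp(xa))
    return 1.0 / (1.0 + qdivp)


@njit(cache=True)
def _rtigauss(z, rng):
    # Inverse-Gaussian IG(mu=1/z, lambda=1) truncated to (0, _TRUNC].
    t = _TRUNC
    if z < 1.0 / t:
        # Large-mean regime: rejection from a scaled chi-square envelope.
        while True:
            e1 = rng.exponential(1.0)
            e2 = rng.exponential(1.0)
            while e1 * e1 > 2.0 * e2 / t:
                e1 = rng.exponential(1.0)
                e2 = rng.exponential(1.0)
            x = t / (1.0 + t * e1) ** 2
            if rng.random() <= math.exp(-(z**2) * x / 2.0):
                return x
    else:
        mu = 1.0 / z
        while True:
            y = rng.standard_normal() ** 2
            x = mu + 0.5 * mu * mu * y - 0.5 * mu * math.sqrt(4.0 * mu * y + (mu * y) ** 2)
            if rng.random() > mu / (mu + x):
                x = mu * mu / x
            if x <= t:
                return x


@njit(cache=True)
def _jstar(z, rng):
    # One draw from J*(1, z), z >= 0, by alternating-series rejection.
    k = math.pi**2 / 8.0 + z**2 / 2.0
    p_expon = _mass_texpon(z)
    while True:
        if rng.random() < p_expon:
            x = _TRUNC + rng.exponential(1.0) / k
        else:
            x = _rtigauss(z, rng)
        s = _coef(0, x)
        y = rng.random() * s
        n = 0
        while True:
            n += 1
            if n % 2 == 1:
                s -= _coef(n, x)
                if y <= s:
                    return x
            else:
                s += _coef(n, x)
                if y > s:
                    break


@njit(cache=True)
def pg_draw(c, rng):
    """One draw from PG(1, c)."""
    return 0.25 * _jstar(abs(c) * 0.5, rng)


@njit(cache=True)
def pg_draws(c, rng):
    """Element-wise draws from PG(1, c_i) for a 1-D array of tilts."""
    out = np.empty(c.shape[0])
    for i in range(c.shape[0]):
        out[i] = 0.25 * _jstar(abs(c[i]) * 0.5, rng)
    return out
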