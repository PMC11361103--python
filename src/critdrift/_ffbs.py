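"""JIT-compiled Kalman forward filter and backward sampler.

After Pólya-gamma augmentation the latent AR(1) chain is conditionally a
linear-Gaussian state-space model with pseudo-observations
``z_t = kappa_t / omega_t - offset_t`` (kappa_t = y_t - 1/2) observed with
variance ``1 / omega_t``.  These kernels run once per subject per sweep and
are scalar-state, so everything is O(T).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["filter_core", "backward_core"]

_ALPHA_CLIP = 1.0 - 1e-6


@njit(cache=True)
def filter_core(kappa, omega, offset, ar_coef, innov_var):
    """Forward filtering pass; returns per-trial filtered means and variances."""
    n = kappa.shape[0]
    means = np.empty(n)
    variances = np.empty(n)
    a = ar_coef if ar_coef < _ALPHA_CLIP else _ALPHA_CLIP
    v0 = innov_var / (1.0 - a * a)
    m_pred = 0.0
    v_pred = v0
    for t in range(n):
        z = kappa[t] / omega[t] - offset[t]
        r = 1.0 / omega[t]
        gain = v_pred / (v_pred + r)
        m = m_pred + gain * (z - m_pred)
        v = v_pred * r / (v_pred + r)
        means[t] = m
        variances[t] = v
        m_pred = ar_coef * m
        v_pred = ar_coef * ar_coef * v + innov_var
    return means, variances


@njit(cache=True)
def backward_core(means, variances, ar_coef, innov_var, rng):
    """Joint draw of x_1..x_T given the filtering pass (sampled T -> 1)."""
    n = means.shape[0]
    x = np.empty(n)
    x[n - 1] = means[n - 1] + np.sqrt(variances[n - 1]) * rng.standard_normal()
    for t in range(n - 2, -1, -1):
        prec = 1.0 / variances[t] + ar_coef * ar_coef / innov_var
        v = 1.0 / prec
        m = v * (means[t] / variances[t] + ar_coef * x[t + 1] / innov_var)
        x[t] = m + np.sqrt(v) * rng.standard_normal()
    return x
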