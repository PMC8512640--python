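"""Jit-compiled inner loops: conditional-mean recursion, likelihoods, simulators.

The ARMAX conditional-mean recursion is inherently sequential (the MA part
feeds back the innovation g(y_t) - alpha_t), so the Monte Carlo harness --
thousands of quasi-Newton fits, each needing hundreds of likelihood
evaluations -- lives or dies by the speed of this loop.  Everything here is
numba ``njit`` with plain float64 arrays; the user-facing wrappers in
``model.py`` and ``simulate.py`` handle validation and parameter packing.

Conventions (identity link unless ``log_link``):

    alpha_t = eta + x_t'beta
              + sum_i phi_i [g(y_{t-i}) - x_{t-i}'beta]
              + sum_j theta_j [g(y_{t-j}) - alpha_{t-j}]

for t = m..n-1 (0-based), m = max(p, q); MA innovations with index < m are
taken as 0, AR terms always use observed values.  mu_t = g^{-1}(alpha_t).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

PENALTY = 1e10  # returned (plus squared violation) when some mu_t <= 0


@njit(cache=True)
def alpha_err(gy, xb, eta, phi, theta, m):
    """Linear predictor series and innovations.

    Returns (alpha, err); alpha[t] = nan for t < m, err[t] = 0 for t < m.
    """
    n = gy.shape[0]
    p = phi.shape[0]
    q = theta.shape[0]
    alpha = np.empty(n)
    err = np.zeros(n)
    for t in range(m):
        alpha[t] = np.nan
    for t in range(m, n):
        a = eta + xb[t]
        for i in range(p):
            a += phi[i] * (gy[t - 1 - i] - xb[t - 1 - i])
        for j in range(q):
            a += theta[j] * err[t - 1 - j]
        alpha[t] = a
        err[t] = gy[t] - a
    return alpha, err


@njit(cache=True)
def rbs_negloglik(y, gy, xb, eta, phi, theta, m, delta, log_link):
    """Negative conditional log-likelihood of the RBS-ARMAX model.

    Infeasible conditional means (mu_t <= 0 under the identity link) return
    a large finite penalty plus the squared total violation, so that
    quasi-Newton line searches retreat smoothly.
    """
    n = y.shape[0]
    alpha, _ = alpha_err(gy, xb, eta, phi, theta, m)
    pen = 0.0
    bad = False
    for t in range(m, n):
        mu = math.exp(alpha[t]) if log_link else alpha[t]
        if mu <= 0.0 or not math.isfinite(mu):
            bad = True
            v = min(1.0 - mu, 1e6) if math.isfinite(mu) else 1e6
            pen += v * v
    if bad:
        return PENALTY + pen
    c0 = 0.5 * delta + 0.5 * math.log(delta + 1.0) - math.log(4.0)
    ll = 0.0
    for t in range(m, n):
        mu = math.exp(alpha[t]) if log_link else alpha[t]
        lam = delta * mu / (delta + 1.0)
        ll += (
            c0
            - 0.5 * math.log(math.pi * mu)
            - 1.5 * math.log(y[t])
            + math.log(y[t] + lam)
            - 0.25 * delta * ((delta + 1.0) * y[t] / (delta * mu) + lam / y[t])
        )
    if not math.isfinite(ll):
        return PENALTY
    return -ll


@njit(cache=True)
def gaussian_negloglik_profiled(y, gy, xb, eta, phi, theta, m, log_link):
    """Profiled (over sigma^2) Gaussian conditional-sum-of-squares likelihood.

    Same mean recursion and conditioning as the RBS model so that model
    comparisons run on an identical index set.  Returns the negative
    log-likelihood at sigma2_hat = RSS/(n-m).
    """
    n = y.shape[0]
    alpha, _ = alpha_err(gy, xb, eta, phi, theta, m)
    rss = 0.0
    for t in range(m, n):
        mu = math.exp(alpha[t]) if log_link else alpha[t]
        if not math.isfinite(mu):
            return PENALTY
        d = y[t] - mu
        rss += d * d
    nu = n - m
    if rss <= 0.0 or not math.isfinite(rss):
        return PENALTY
    s2 = rss / nu
    return 0.5 * nu * (math.log(2.0 * math.pi * s2) + 1.0)


@njit(cache=True)
def gaussian_negloglik(y, gy, xb, eta, phi, theta, m, sigma2, log_link):
    """Full Gaussian conditional log-likelihood (sigma^2 free, for Hessians)."""
    n = y.shape[0]
    if sigma2 <= 0.0:
        return PENALTY
    alpha, _ = alpha_err(gy, xb, eta, phi, theta, m)
    ll = 0.0
    c = -0.5 * math.log(2.0 * math.pi * sigma2)
    for t in range(m, n):
        mu = math.exp(alpha[t]) if log_link else alpha[t]
        d = y[t] - mu
        ll += c - 0.5 * d * d / sigma2
    if not math.isfinite(ll):
        return PENALTY
    return -ll


@njit(cache=True)
def simulate_rbs(z, xb, eta, phi, theta, delta, log_link):
    """Generate an RBS-ARMAX path from pre-drawn N(0,1) innovations ``z``.

    Returns (y, alpha, bad_t): bad_t >= 0 flags the first step whose
    conditional mean was non-positive (identity link), in which case the
    caller must raise.
    """
    n = z.shape[0]
    p = phi.shape[0]
    q = theta.shape[0]
    y = np.empty(n)
    gy = np.empty(n)
    alpha = np.empty(n)
    err = np.zeros(n)
    sq2d = math.sqrt(2.0 * delta)
    for t in range(n):
        a = eta + xb[t]
        for i in range(p):
            s = t - 1 - i
            if s >= 0:
                a += phi[i] * (gy[s] - xb[s])
        for j in range(q):
            s = t - 1 - j
            if s >= 0:
                a += theta[j] * err[s]
        mu = math.exp(a) if log_link else a
        if mu <= 0.0 or not math.isfinite(mu):
            return y, alpha, t
        w = z[t] / sq2d + math.sqrt(z[t] * z[t] / (2.0 * delta) + 1.0)
        y[t] = (delta * mu / (delta + 1.0)) * w * w
        gy[t] = math.log(y[t]) if log_link else y[t]
        alpha[t] = a
        err[t] = gy[t] - a
    return y, alpha, -1


@njit(cache=True)
def simulate_weibull(e, xb, eta, phi, theta, shape, inv_gamma1p, log_link):
    """Generate a Weibull-ARMAX path from pre-drawn unit-exponential ``e``.

    The Weibull scale at each step is mu_t / Gamma(1 + 1/shape)
    (``inv_gamma1p`` is its reciprocal factor 1/Gamma(1+1/shape)), so the
    conditional mean equals the same recursion's mu_t: the generator is a
    pure distributional misspecification of the RBS-ARMAX mean structure.
    """
    n = e.shape[0]
    p = phi.shape[0]
    q = theta.shape[0]
    y = np.empty(n)
    gy = np.empty(n)
    alpha = np.empty(n)
    err = np.zeros(n)
    for t in range(n):
        a = eta + xb[t]
        for i in range(p):
            s = t - 1 - i
            if s >= 0:
                a += phi[i] * (gy[s] - xb[s])
        for j in range(q):
            s = t - 1 - j
            if s >= 0:
                a += theta[j] * err[s]
        mu = math.exp(a) if log_link else a
        if mu <= 0.0 or not math.isfinite(mu):
            return y, alpha, t
        y[t] = mu * inv_gamma1p * e[t] ** (1.0 / shape)
        gy[t] = math.log(y[t]) if log_link else y[t]
        alpha[t] = a
        err[t] = gy[t] - a
    return y, alpha, -1
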