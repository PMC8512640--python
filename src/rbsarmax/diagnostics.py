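"""Residual diagnostics: GCS and RQ residuals, simulated envelopes, ACF/PACF.

Under a correctly specified model the generalized Cox-Snell residual
-log S_hat(y_t | F_{t-1}) is unit exponential and the randomized-quantile
residual Phi^{-1}[S_hat(y_t | F_{t-1})] is standard normal, so QQ plots of
either (with Monte Carlo envelopes) assess fit adequacy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.tsa import stattools

from . import distribution
from .simulate import SimScenario

__all__ = [
    "gcs_residuals",
    "rq_residuals",
    "EnvelopeBands",
    "envelope",
    "acf",
    "pacf",
]

_TINY = np.finfo(float).tiny


def _survival(results) -> np.ndarray:
    model = results.model
    sl = slice(model.m, None)
    y, mu = model.y[sl], results.mu[sl]
    delta = float(results._params[0])
    s = np.array(
        [distribution.sf(yi, mi, delta) for yi, mi in zip(y, mu)]
    )
    if np.any(s < _TINY):
        warnings.warn("survival underflow in residuals; clipping at machine tiny")
        s = np.maximum(s, _TINY)
    s = np.minimum(s, 1.0 - 1e-16)
    return s

def gcs_residuals(results) -> np.ndarray:
    """Generalized Cox-Snell residuals -log S_hat(y_t | F_{t-1})."""
    return -np.log(_survival(results))


def rq_residuals(results, convention: str = "survival") -> np.ndarray:
    """Randomized-quantile residuals.

    ``convention='survival'`` follows Phi^{-1}(S_hat); the usual CDF form
    Phi^{-1}(F_hat) is its negation and is available as
    ``convention='cdf'``.  Either is N(0,1) under correct specification.
    """
    s = _survival(results)
    if convention == "survival":
        return stats.norm.ppf(s)
    if convention == "cdf":
        return stats.norm.ppf(1.0 - s)
    raise ValueError("convention must be 'survival' or 'cdf'")


@dataclass
class EnvelopeBands:
    """Order-statistic envelope for a residual QQ assessment."""

    observed: np.ndarray  # sorted observed residuals
    lower: np.ndarray
    median: np.ndarray
    upper: np.ndarray
    level: float
    n_sim: int
    n_failed: int

    @property
    def coverage(self) -> float:
        """Fraction of observed order statistics inside the band."""
        inside = (self.observed >= self.lower) & (self.observed <= self.upper)
        return float(np.mean(inside))


def envelope(results, kind="gcs", n_sim=100, level=0.95, seed=0) -> EnvelopeBands:
    """Simulated envelope: parametric-bootstrap bands for sorted residuals.

    Simulates ``n_sim`` series from the fitted model (same regressors, no
    burn-in, conditioning handled by the refit), refits each with the
    original estimates as warm start, and takes per-order-statistic
    quantiles of the sorted residuals.  Replicates whose refit fails are
    dropped; more than 20% failures is an error.
    """
    if kind not in ("gcs", "rq"):
        raise ValueError("kind must be 'gcs' or 'rq'")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    model = results.model
    from .model import Gamma  # local import to avoid cycle at module load

    gamma = Gamma.from_array(results._params, model.order)
    observed = np.sort(gcs_residuals(results) if kind == "gcs" else rq_residuals(results))
    ss = np.random.SeedSequence(seed)
    sims = []
    n_failed = 0
    from .simulate import simulate_rbsarmax

    for child in ss.spawn(n_sim):
        scen = SimScenario(
            gamma=gamma,
            n=model.nobs,
            seed=child,
            burn_in=0,
            regressor_law="fixed",
            X=model.X,
            link=model.link,
        )
        try:
            sim = simulate_rbsarmax(scen)
            refit = type(model)(
                sim.y, exog=sim.X if model.order.r else None,
                order=(model.order.p, model.order.q), link=model.link,
            ).fit(start_params=results._params)
            resid = gcs_residuals(refit) if kind == "gcs" else rq_residuals(refit)
            sims.append(np.sort(resid))
        except (RuntimeError, ValueError):
            n_failed += 1
    if n_failed > 0.2 * n_sim:
        raise RuntimeError(f"{n_failed}/{n_sim} envelope refits failed")
    sims = np.asarray(sims)
    lo = (1.0 - level) / 2.0
    return EnvelopeBands(
        observed=observed,
        lower=np.quantile(sims, lo, axis=0),
        median=np.quantile(sims, 0.5, axis=0),
        upper=np.quantile(sims, 1.0 - lo, axis=0),
        level=level,
        n_sim=n_sim,
        n_failed=n_failed,
    )


def _check_series(x, max_lag):
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.shape[0] <= max_lag:
        raise ValueError("series must be 1-d and longer than max_lag")
    if np.ptp(x) == 0:
        raise ValueError("autocorrelation is undefined for a constant series")
    return x


def acf(x, max_lag: int) -> np.ndarray:
    """Sample autocorrelations, lags 0..max_lag (denominator n, ACF(0)=1)."""
    x = _check_series(x, max_lag)
    return stattools.acf(x, nlags=max_lag, adjusted=False, fft=True)


def pacf(x, max_lag: int) -> np.ndarray:
    """Partial autocorrelations via Durbin-Levinson on the biased ACF."""
    x = _check_series(x, max_lag)
    return stattools.pacf(x, nlags=max_lag, method="ldb")


def whitenoise_bound(n: int, level: float = 0.95) -> float:
    """White-noise confidence bound z_{(1+level)/2} / sqrt(n)."""
    return float(stats.norm.ppf(0.5 + level / 2.0) / np.sqrt(n))


def plot_qq_envelope(bands: EnvelopeBands, kind: str = "gcs", ax=None):
    """QQ plot of residuals against their reference law with envelope bands."""
    import matplotlib.pyplot as plt

    n = len(bands.observed)
    probs = (np.arange(1, n + 1) - 0.5) / n
    if kind == "gcs":
        theo = stats.expon.ppf(probs)
        label = "EXP(1) quantiles"
    else:
        theo = stats.norm.ppf(probs)
        label = "N(0,1) quantiles"
    if ax is None:
        _, ax = plt.subplots()
    ax.fill_between(theo, bands.lower, bands.upper, alpha=0.3, label=f"{bands.level:.0%} envelope")
    ax.plot(theo, bands.median, "--", lw=1, label="envelope median")
    ax.plot(theo, bands.observed, "o", ms=3, label="observed")
    ax.set_xlabel(label)
    ax.set_ylabel("ordered residuals")
    ax.legend()
    return ax


def plot_acf_pacf(x, max_lag: int = 36, axes=None):
    """Stem plots of the sample ACF and PACF with white-noise bounds."""
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(1, 2, figsize=(9, 3.2))
    bound = whitenoise_bound(len(x))
    for ax, vals, title in (
        (axes[0], acf(x, max_lag)[1:], "ACF"),
        (axes[1], pacf(x, max_lag)[1:], "PACF"),
    ):
        lags = np.arange(1, max_lag + 1)
        ax.stem(lags, vals)
        ax.axhline(bound, ls="--", color="gray")
        ax.axhline(-bound, ls="--", color="gray")
        ax.set_title(title)
        ax.set_xlabel("lag")
    return axes
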