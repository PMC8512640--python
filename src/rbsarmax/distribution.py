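"""The mean-parameterized (reparameterized) Birnbaum-Saunders distribution.

The classical Birnbaum-Saunders (BS) fatigue-life law on (0, inf) has shape
``alpha`` and scale/median ``lam``, with CDF

    F(t) = Phi( (sqrt(t/lam) - sqrt(lam/t)) / alpha ).

The RBS parameterization indexes the same family by its mean ``mu`` and a
precision/shape parameter ``delta``::

    mu = lam * (1 + alpha**2 / 2),      delta = 2 / alpha**2,

so that E(Y) = mu, Var(Y) = mu**2 (2 delta + 5) / (delta + 1)**2 and the
median is delta*mu/(delta+1).  This makes GLM-style direct modelling of the
mean possible on the original data scale.  All functions here are
vectorized over ``y``/``q`` and validate their domains strictly (no silent
clipping).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RBSParams",
    "BSParams",
    "bs_to_rbs",
    "rbs_to_bs",
    "logpdf",
    "pdf",
    "cdf",
    "sf",
    "ppf",
    "rvs",
    "moments",
    "RBSMoments",
]

_LOG4 = math.log(4.0)


def _check_positive(name: str, value: float) -> None:
    if not value > 0:
        raise ValueError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class RBSParams:
    """Mean/precision pair (mu, delta) of the RBS law."""

    mu: float
    delta: float

    def __post_init__(self) -> None:
        _check_positive("mu", self.mu)
        _check_positive("delta", self.delta)


@dataclass(frozen=True)
class BSParams:
    """Classical Birnbaum-Saunders shape/scale pair (alpha, lam)."""

    alpha: float
    lam: float

    def __post_init__(self) -> None:
        _check_positive("alpha", self.alpha)
        _check_positive("lam", self.lam)


def bs_to_rbs(bs: BSParams) -> RBSParams:
    """Convert BS(alpha, lam) to the mean/precision parameterization."""
    return RBSParams(mu=bs.lam * (1.0 + bs.alpha**2 / 2.0), delta=2.0 / bs.alpha**2)


def rbs_to_bs(rbs: RBSParams) -> BSParams:
    """Convert RBS(mu, delta) back to the shape/scale parameterization."""
    return BSParams(
        alpha=math.sqrt(2.0 / rbs.delta),
        lam=rbs.delta * rbs.mu / (rbs.delta + 1.0),
    )


def _validate(y, mu: float, delta: float):
    _check_positive("mu", mu)
    _check_positive("delta", delta)
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0) or not np.all(np.isfinite(y)):
        raise ValueError("y must be strictly positive and finite")
    return y


def logpdf(y, mu: float, delta: float):
    """Log-density of RBS(mu, delta), computed directly in log space.

    Stable for large ``delta`` (precision up to ~1e4 and beyond): the
    exp(delta/2) factor of the closed form never leaves log scale.
    """
    y = _validate(y, mu, delta)
    lam = delta * mu / (delta + 1.0)  # BS scale = median
    out = (
        0.5 * delta
        + 0.5 * math.log(delta + 1.0)
        - _LOG4
        - 0.5 * math.log(math.pi * mu)
        - 1.5 * np.log(y)
        + np.log(y + lam)
        - 0.25 * delta * ((delta + 1.0) * y / (delta * mu) + lam / y)
    )
    return out if out.shape else float(out)


def pdf(y, mu: float, delta: float):
    """Density of RBS(mu, delta)."""
    return np.exp(logpdf(y, mu, delta))


def _normal_arg(y, mu: float, delta: float):
    ratio = (delta + 1.0) * y / (mu * delta)
    return math.sqrt(delta / 2.0) * (np.sqrt(ratio) - 1.0 / np.sqrt(ratio))


def cdf(y, mu: float, delta: float):
    """Distribution function: Phi of the BS normalizing transform."""
    y = _validate(y, mu, delta)
    out = stats.norm.cdf(_normal_arg(y, mu, delta))
    return out if np.ndim(out) else float(out)


def sf(y, mu: float, delta: float):
    """Survival function 1 - F(y), via Phi of the negated argument."""
    y = _validate(y, mu, delta)
    out = stats.norm.sf(_normal_arg(y, mu, delta))
    return out if np.ndim(out) else float(out)


def ppf(q, mu: float, delta: float):
    """Quantile function (closed form through the normal transform)."""
    _check_positive("mu", mu)
    _check_positive("delta", delta)
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0) or np.any(q >= 1):
        raise ValueError("q must lie strictly inside (0, 1)")
    z = stats.norm.ppf(q)
    w = z / math.sqrt(2.0 * delta) + np.sqrt(z * z / (2.0 * delta) + 1.0)
    out = (delta * mu / (delta + 1.0)) * w**2
    return out if out.shape else float(out)


def rvs(mu: float, delta: float, size: int, rng) -> np.ndarray:
    """Draw ``size`` independent RBS(mu, delta) variates.

    Uses the exact normal-transform representation: with Z ~ N(0,1),
    Y = [delta mu/(delta+1)] * (Z/sqrt(2 delta) + sqrt(Z^2/(2 delta)+1))^2.

    ``rng`` is a `numpy.random.Generator` or an integer seed.
    """
    _check_positive("mu", mu)
    _check_positive("delta", delta)
    if size < 1:
        raise ValueError("size must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    z = rng.standard_normal(size)
    w = z / math.sqrt(2.0 * delta) + np.sqrt(z * z / (2.0 * delta) + 1.0)
    return (delta * mu / (delta + 1.0)) * w**2


@dataclass(frozen=True)
class RBSMoments:
    mean: float
    variance: float
    cv: float
    median: float


def moments(mu: float, delta: float) -> RBSMoments:
    """Mean, variance, coefficient of variation and median of RBS(mu, delta)."""
    _check_positive("mu", mu)
    _check_positive("delta", delta)
    cv = math.sqrt(2.0 * delta + 5.0) / (delta + 1.0)
    return RBSMoments(
        mean=mu,
        variance=(mu * cv) ** 2,
        cv=cv,
        median=delta * mu / (delta + 1.0),
    )
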