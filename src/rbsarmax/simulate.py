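"""Synthetic series generators: RBS-ARMAX paths, the Weibull-ARMAX
misspecification model, and regressor paths.

These generators define the package's study conditions.  The Weibull
generator shares the exact conditional-mean recursion with the RBS one
(its scale is mu_t / Gamma(1 + 1/shape)), so fitting RBS-ARMAX to Weibull
data isolates a pure distributional misspecification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .data import SeriesData
from .model import Gamma, ModelOrder

__all__ = ["SimScenario", "make_regressors", "simulate_rbsarmax", "simulate_weibull_armax"]

_LAWS = ("uniform01", "standard_normal", "fixed")


@dataclass
class SimScenario:
    """A simulation configuration.

    ``gamma`` carries the generating parameters; for the Weibull generator
    ``gamma.delta`` plays the Weibull shape role.  ``regressor_law`` is one
    of 'uniform01', 'standard_normal' or 'fixed' (supply ``X`` then).
    """

    gamma: Gamma
    n: int
    seed: int
    burn_in: int = 50
    regressor_law: str = "uniform01"
    X: np.ndarray | None = None
    link: str = "identity"
    regressor_seed: int | None = None  # defaults to seed: X fixed per scenario

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        if self.regressor_law not in _LAWS:
            raise ValueError(f"unknown regressor law {self.regressor_law!r}")

    @property
    def order(self) -> ModelOrder:
        return self.gamma.order


def make_regressors(law: str, n: int, r: int, seed, fixed=None) -> np.ndarray:
    """Draw an (n, r) regressor matrix by the named law, reproducibly."""
    if n < 0 or r < 0:
        raise ValueError("n and r must be non-negative")
    if law == "fixed":
        if fixed is None:
            raise ValueError("law 'fixed' requires the matrix to pass through")
        X = np.asarray(fixed, dtype=float).reshape(n, r)
        return X
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if law == "uniform01":
        return rng.random((n, r))
    if law == "standard_normal":
        return rng.standard_normal((n, r))
    raise ValueError(f"unknown regressor law {law!r}")


def _prepare(scenario: SimScenario):
    g = scenario.gamma
    r = g.order.r
    total = scenario.n + scenario.burn_in
    rng = np.random.default_rng(scenario.seed)
    xseed = (
        scenario.seed if scenario.regressor_seed is None else scenario.regressor_seed
    )
    if scenario.regressor_law == "fixed":
        X = make_regressors("fixed", total, r, None, fixed=scenario.X)
    else:
        X = make_regressors(scenario.regressor_law, total, r, np.random.default_rng(xseed))
    xb = X @ g.beta if r else np.zeros(total)
    return g, total, rng, X, xb


def _finalize(scenario, X, y, alpha, bad_t, label):
    if bad_t >= 0:
        g = scenario.gamma
        raise RuntimeError(
            f"{label} generator produced a non-positive conditional mean at "
            f"step {bad_t} (delta={g.delta}, eta={g.eta}, phi={g.phi}, theta={g.theta})"
        )
    keep = slice(scenario.burn_in, None)
    return SeriesData(y=y[keep], X=X[keep])


def simulate_rbsarmax(scenario: SimScenario) -> SeriesData:
    """Simulate y_t | F_{t-1} ~ RBS(mu_t, delta) along the mean recursion.

    Draws use the exact normal-transform representation of the RBS law.
    ``burn_in`` initial points are generated and discarded; the returned
    SeriesData has length ``scenario.n`` with the aligned regressors.
    """
    g, total, rng, X, xb = _prepare(scenario)
    z = rng.standard_normal(total)
    y, alpha, bad_t = _kernels.simulate_rbs(
        z, xb, g.eta, g.phi, g.theta, g.delta, scenario.link == "log"
    )
    return _finalize(scenario, X, y, alpha, bad_t, "RBS-ARMAX")


def simulate_weibull_armax(scenario: SimScenario) -> SeriesData:
    """Simulate a Weibull-ARMAX path: y_t | F_{t-1} ~ Weibull with shape
    ``gamma.delta`` and scale mu_t / Gamma(1 + 1/shape), so that the
    conditional mean equals the same recursion's mu_t."""
    g, total, rng, X, xb = _prepare(scenario)
    shape = g.delta
    e = rng.standard_exponential(total)
    inv_g = 1.0 / math.gamma(1.0 + 1.0 / shape)
    y, alpha, bad_t = _kernels.simulate_weibull(
        e, xb, g.eta, g.phi, g.theta, shape, inv_g, scenario.link == "log"
    )
    return _finalize(scenario, X, y, alpha, bad_t, "Weibull-ARMAX")
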