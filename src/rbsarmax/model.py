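"""RBS-ARMAX models: conditional-mean ARMA with regressors and an RBS response.

The model for a strictly positive series {y_t} with regressors x_t is

    y_t | F_{t-1}  ~  RBS(mu_t, delta),
    g(mu_t) = alpha_t = eta + x_t'beta
              + sum_{i=1}^p phi_i [g(y_{t-i}) - x_{t-i}'beta]
              + sum_{j=1}^q theta_j [g(y_{t-j}) - alpha_{t-j}],

with g the identity by default (a log link is available).  Estimation is
by conditional maximum likelihood: the likelihood conditions on the first
m = max(p, q) observations and is maximized by BFGS with delta handled on
the log scale.  A Gaussian counterpart with the same mean recursion and
conditioning (`GaussianARMAX`) is provided as the comparison baseline.

Usage follows the statsmodels pattern::

    res = RBSARMAX(y, exog=X, order=(1, 1)).fit()
    res.params, res.bse, res.llf, res.fittedvalues, res.summary()
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.tools import numdiff

from . import _kernels
from .data import SeriesData

__all__ = ["ModelOrder", "Gamma", "RBSARMAX", "GaussianARMAX", "RBSARMAXResults"]


@dataclass(frozen=True)
class ModelOrder:
    """AR order p, MA order q, and regressor count r."""

    p: int
    q: int
    r: int = 0

    def __post_init__(self) -> None:
        if self.p < 0 or self.q < 0 or self.r < 0:
            raise ValueError("orders must be non-negative")

    @property
    def m(self) -> int:
        return max(self.p, self.q)


@dataclass
class Gamma:
    """Full RBS-ARMAX parameter vector (delta, eta, beta, phi, theta)."""

    delta: float
    eta: float
    beta: np.ndarray = field(default_factory=lambda: np.empty(0))
    phi: np.ndarray = field(default_factory=lambda: np.empty(0))
    theta: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if not self.delta > 0:
            raise ValueError("delta must be strictly positive")
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.phi = np.atleast_1d(np.asarray(self.phi, dtype=float))
        self.theta = np.atleast_1d(np.asarray(self.theta, dtype=float))

    @property
    def order(self) -> ModelOrder:
        return ModelOrder(p=len(self.phi), q=len(self.theta), r=len(self.beta))

    def to_array(self) -> np.ndarray:
        return np.concatenate(([self.delta, self.eta], self.beta, self.phi, self.theta))

    @classmethod
    def from_array(cls, arr, order: ModelOrder) -> "Gamma":
        arr = np.asarray(arr, dtype=float)
        r, p, q = order.r, order.p, order.q
        if arr.shape[0] != 2 + r + p + q:
            raise ValueError("parameter vector length does not match the order")
        return cls(
            delta=float(arr[0]),
            eta=float(arr[1]),
            beta=arr[2 : 2 + r],
            phi=arr[2 + r : 2 + r + p],
            theta=arr[2 + r + p :],
        )


def _as_endog_exog(endog, exog):
    names = None
    if isinstance(endog, SeriesData):
        return endog.y, endog.X, list(endog.names)
    if isinstance(endog, pd.Series):
        endog = endog.to_numpy()
    if exog is None:
        exog = np.empty((len(endog), 0))
    elif isinstance(exog, pd.DataFrame):
        names = [str(c) for c in exog.columns]
        exog = exog.to_numpy(float)
    data = SeriesData(np.asarray(endog, float), np.asarray(exog, float), names or [])
    return data.y, data.X, data.names


class _ARMAXBase:
    """Shared plumbing for the RBS and Gaussian ARMAX models."""

    _scale_name = "delta"

    def __init__(self, endog, exog=None, order=(0, 0), link="identity"):
        self.y, self.X, self.exog_names = _as_endog_exog(endog, exog)
        p, q = int(order[0]), int(order[1])
        self.order = ModelOrder(p=p, q=q, r=self.X.shape[1])
        self.m = self.order.m
        if link not in ("identity", "log"):
            raise ValueError("link must be 'identity' or 'log'")
        self.link = link
        self._log_link = link == "log"
        self.gy = np.log(self.y) if self._log_link else self.y
        self.nobs = self.y.shape[0]
        if self.nobs <= self.m:
            raise ValueError(f"need more than m={self.m} observations, got {self.nobs}")
        self.k_params = 2 + self.order.r + p + q

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, response: str, regressors=(), **kw):
        return cls(df[response], exog=df[list(regressors)] if regressors else None, **kw)

    @property
    def param_names(self):
        p, q = self.order.p, self.order.q
        return (
            [self._scale_name, "const"]
            + list(self.exog_names)
            + [f"ar.L{i + 1}" for i in range(p)]
            + [f"ma.L{j + 1}" for j in range(q)]
        )

    def _split(self, params):
        """(scale, eta, beta, phi, theta) from a reported-scale vector."""
        params = np.asarray(params, dtype=float)
        r, p = self.order.r, self.order.p
        return (
            float(params[0]),
            float(params[1]),
            np.ascontiguousarray(params[2 : 2 + r]),
            np.ascontiguousarray(params[2 + r : 2 + r + p]),
            np.ascontiguousarray(params[2 + r + p :]),
        )

    def _coerce(self, params):
        if isinstance(params, Gamma):
            params = params.to_array()
        params = np.asarray(params, dtype=float)
        if params.shape[0] != self.k_params:
            raise ValueError(
                f"expected {self.k_params} parameters, got {params.shape[0]}"
            )
        return params

    def linear_predictor(self, params):
        """Return (alpha, mu) series; entries before t = m are NaN."""
        _, eta, beta, phi, theta = self._split(self._coerce(params))
        xb = self.X @ beta if self.order.r else np.zeros(self.nobs)
        alpha, _ = _kernels.alpha_err(self.gy, xb, eta, phi, theta, self.m)
        mu = np.exp(alpha) if self._log_link else alpha.copy()
        return alpha, mu

    # -- initialization ----------------------------------------------------
    def start_params(self) -> np.ndarray:
        """OLS-based starting values: eta/beta from a static regression of
        g(y) on the regressors, phi = theta = 0, and the scale from the
        method of moments on the OLS residual variance."""
        Z = np.column_stack([np.ones(self.nobs), self.X])
        if np.linalg.matrix_rank(Z) < Z.shape[1]:
            warnings.warn("rank-deficient regressor matrix; using pseudo-inverse")
        coef, *_ = np.linalg.lstsq(Z, self.gy, rcond=None)
        resid = self.gy - Z @ coef
        var = float(np.var(resid)) if self.nobs > 1 else 1.0
        scale0 = self._start_scale(var)
        return np.concatenate(
            ([scale0], coef, np.zeros(self.order.p), np.zeros(self.order.q))
        )

    def _neg_loglik(self, params) -> float:
        raise NotImplementedError

    def loglike(self, params) -> float:
        """Conditional log-likelihood at a reported-scale parameter vector."""
        return -self._neg_loglik(self._coerce(params))

    def fit(self, start_params=None, maxiter=500, gtol=1e-6):
        if start_params is None:
            start = self.start_params()
        else:
            start = self._coerce(start_params)
        z0 = self._to_opt(start)
        if self._opt_objective(z0) >= _kernels.PENALTY:
            # infeasible start: retreat to a flat conditional mean
            fallback = start.copy()
            fallback[1] = float(np.mean(self.gy))
            fallback[2:] = 0.0
            z0 = self._to_opt(fallback)
            if self._opt_objective(z0) >= _kernels.PENALTY:
                raise RuntimeError("no feasible starting point found")
        res = optimize.minimize(
            self._opt_objective,
            z0,
            method="BFGS",
            options={"gtol": gtol, "maxiter": maxiter},
        )
        params = self._from_opt(res.x)
        # BFGS often ends with "precision loss" when finite-difference
        # gradient noise dominates near the optimum; accept the point if
        # the gradient is small on the likelihood's scale.
        converged = bool(res.success) or (
            res.status == 2
            and np.all(np.isfinite(res.jac))
            and float(np.max(np.abs(res.jac))) < 1.0
            and res.fun < _kernels.PENALTY
        )
        ar = params[2 + self.order.r : 2 + self.order.r + self.order.p]
        if converged and self.order.p and np.sum(np.abs(ar)) >= 1.0:
            warnings.warn("AR coefficients at or beyond the unit circle")
        return RBSARMAXResults(
            model=self,
            params=params,
            llf=-float(res.fun),
            converged=converged,
            n_iter=int(res.nit),
        )


class RBSARMAX(_ARMAXBase):
    """ARMAX model with a mean-parameterized Birnbaum-Saunders response.

    Parameters
    ----------
    endog : array-like or SeriesData
        Strictly positive response series.
    exog : array-like, optional
        Regressor matrix, one row per time point.
    order : tuple (p, q)
        AR and MA orders of the conditional-mean recursion.
    link : {"identity", "log"}
        Link for the conditional mean; the identity is the default and
        infeasible mu_t <= 0 values are penalized during optimization.
    """

    _scale_name = "delta"

    def _start_scale(self, var: float) -> float:
        # Var(Y) = mu^2 (2 delta + 5)/(delta + 1)^2, solved at mu = mean(y)
        mu_bar = float(np.mean(self.y))
        v = max(var / mu_bar**2, 1e-8) if not self._log_link else max(var, 1e-8)
        delta0 = (1.0 - v + np.sqrt(3.0 * v + 1.0)) / v
        return max(delta0, 0.5)

    def _neg_loglik(self, params) -> float:
        delta, eta, beta, phi, theta = self._split(params)
        if delta <= 0:
            return _kernels.PENALTY
        xb = self.X @ beta if self.order.r else np.zeros(self.nobs)
        return _kernels.rbs_negloglik(
            self.y, self.gy, xb, eta, phi, theta, self.m, delta, self._log_link
        )

    # optimizer works on [log delta, eta, beta, phi, theta]
    def _to_opt(self, params):
        z = np.asarray(params, dtype=float).copy()
        z[0] = np.log(z[0])
        return z

    def _from_opt(self, z):
        params = np.asarray(z, dtype=float).copy()
        params[0] = np.exp(params[0])
        return params

    def _opt_objective(self, z) -> float:
        z = np.asarray(z, dtype=float)
        if not np.all(np.isfinite(z)) or z[0] > 50.0:
            return _kernels.PENALTY
        return self._neg_loglik(self._from_opt(z))


class GaussianARMAX(_ARMAXBase):
    """Gaussian ARMAX baseline with the identical mean recursion.

    The likelihood is the conditional (CSS-style) Gaussian likelihood on
    t = m+1..n with sigma^2 profiled out, so AIC/BIC/MAPE comparisons with
    `RBSARMAX` run on the same index set.  Reported parameters put sigma2
    in the scale slot.
    """

    _scale_name = "sigma2"

    def _start_scale(self, var: float) -> float:
        return max(var, 1e-12)

    def _mean_negloglik(self, mean_params) -> float:
        eta = float(mean_params[0])
        r, p = self.order.r, self.order.p
        beta = np.ascontiguousarray(mean_params[1 : 1 + r])
        phi = np.ascontiguousarray(mean_params[1 + r : 1 + r + p])
        theta = np.ascontiguousarray(mean_params[1 + r + p :])
        xb = self.X @ beta if r else np.zeros(self.nobs)
        return _kernels.gaussian_negloglik_profiled(
            self.y, self.gy, xb, eta, phi, theta, self.m, self._log_link
        )

    def _neg_loglik(self, params) -> float:
        sigma2, eta, beta, phi, theta = self._split(params)
        xb = self.X @ beta if self.order.r else np.zeros(self.nobs)
        return _kernels.gaussian_negloglik(
            self.y, self.gy, xb, eta, phi, theta, self.m, sigma2, self._log_link
        )

    def _to_opt(self, params):
        return np.asarray(params, dtype=float)[1:].copy()

    def _from_opt(self, z):
        # recover the profiled sigma2 from the residual sum of squares
        mean_params = np.asarray(z, dtype=float)
        nu = self.nobs - self.m
        nll = self._mean_negloglik(mean_params)
        if nll >= _kernels.PENALTY:
            sigma2 = np.nan
        else:
            sigma2 = np.exp(2.0 * nll / nu - np.log(2.0 * np.pi) - 1.0)
        return np.concatenate(([sigma2], mean_params))

    def _opt_objective(self, z) -> float:
        z = np.asarray(z, dtype=float)
        if not np.all(np.isfinite(z)):
            return _kernels.PENALTY
        return self._mean_negloglik(z)


class RBSARMAXResults:
    """Fit results: estimates, uncertainty, fitted means, diagnostics."""

    def __init__(self, model, params, llf, converged, n_iter):
        self.model = model
        self._params = np.asarray(params, dtype=float)
        self.llf = llf
        self.converged = converged
        self.n_iter = n_iter
        self.alpha, self.mu = model.linear_predictor(self._params)
        self._vcov = None

    # -- basic accessors ---------------------------------------------------
    @property
    def params(self) -> pd.Series:
        return pd.Series(self._params, index=self.model.param_names)

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def nobs_effective(self) -> int:
        return self.model.nobs - self.model.m

    @property
    def k_params(self) -> int:
        return self.model.k_params

    @property
    def fittedvalues(self) -> np.ndarray:
        """One-step conditional means mu_t (NaN for the conditioned head)."""
        return self.mu

    @property
    def resid_response(self) -> np.ndarray:
        return self.model.y - self.mu

    # -- uncertainty -------------------------------------------------------
    def cov_params(self) -> np.ndarray:
        """Covariance of the estimates from the inverse numerical Hessian
        of the negative conditional log-likelihood (central differences)."""
        if self._vcov is None:
            vcov = None
            # near-collinear designs can leave an almost flat curvature
            # direction; retry with a larger step before giving up
            for rel_step in (1e-5, 1e-4, 1e-3):
                eps = rel_step * np.maximum(1.0, np.abs(self._params))
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    hess = numdiff.approx_hess3(
                        self._params, self.model._neg_loglik, epsilon=eps
                    )
                try:
                    cand = np.linalg.inv(hess)
                except np.linalg.LinAlgError:
                    continue
                if np.all(np.diag(cand) > 0):
                    vcov = cand
                    break
            if vcov is None:
                warnings.warn("singular/indefinite Hessian: standard errors unavailable")
                vcov = np.full((len(self._params),) * 2, np.nan)
            self._vcov = vcov
        return self._vcov

    @property
    def bse(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.diag(self.cov_params())), index=self.model.param_names
        )

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(
            2 * stats.norm.sf(np.abs(self.tvalues)), index=self.model.param_names
        )

    # -- information criteria and in-sample accuracy -----------------------
    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.k_params

    @property
    def bic(self) -> float:
        # full-sample n in the penalty (the convention the tables follow)
        return -2.0 * self.llf + self.k_params * np.log(self.nobs)

    def mape(self) -> float:
        """In-sample one-step mean absolute percentage error, in percent."""
        sl = slice(self.model.m, None)
        y, yhat = self.model.y[sl], self.mu[sl]
        return float(np.mean(np.abs((y - yhat) / y)) * 100.0)

    def rmse(self) -> float:
        sl = slice(self.model.m, None)
        return float(np.sqrt(np.mean((self.model.y[sl] - self.mu[sl]) ** 2)))

    # -- prediction --------------------------------------------------------
    def predict(self) -> np.ndarray:
        return self.fittedvalues

    def forecast(self, steps: int, exog_future=None) -> np.ndarray:
        """Iterate the mean recursion ``steps`` ahead.

        Unobserved responses are replaced by their forecasts and future MA
        innovations by 0 (their conditional expectation).
        """
        model = self.model
        r = model.order.r
        if r:
            if exog_future is None:
                raise ValueError("exog_future is required when the model has regressors")
            Xf = np.asarray(exog_future, dtype=float).reshape(steps, r)
        else:
            Xf = np.empty((steps, 0))
        _, eta, beta, phi, theta = model._split(self._params)
        xb = list(model.X @ beta if r else np.zeros(model.nobs))
        gy = list(model.gy)
        _, err_arr = _kernels.alpha_err(
            model.gy, np.asarray(xb), eta, phi, theta, model.m
        )
        err = list(err_arr)
        out = np.empty(steps)
        for h in range(steps):
            xb_h = float(Xf[h] @ beta) if r else 0.0
            a = eta + xb_h
            for i, ph in enumerate(phi):
                a += ph * (gy[-1 - i] - xb[-1 - i])
            for j, th in enumerate(theta):
                a += th * err[-1 - j]
            mu_h = float(np.exp(a)) if model._log_link else a
            if mu_h <= 0:
                raise ValueError(f"forecast step {h + 1} produced a non-positive mean")
            out[h] = mu_h
            xb.append(xb_h)
            gy.append(np.log(mu_h) if model._log_link else mu_h)
            err.append(0.0)
        return out

    # -- residual diagnostics ----------------------------------------------
    def resid_gcs(self) -> np.ndarray:
        from .diagnostics import gcs_residuals

        return gcs_residuals(self)

    def resid_rq(self, convention: str = "survival") -> np.ndarray:
        from .diagnostics import rq_residuals

        return rq_residuals(self, convention=convention)

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        model = self.model
        name = type(model).__name__
        o = model.order
        lines = [
            f"{name}({o.p},{o.q}) with {o.r} regressor(s), link={model.link}",
            f"nobs: {self.nobs} (conditioning on first {model.m}); "
            f"converged: {self.converged} in {self.n_iter} iterations",
            f"log-likelihood: {self.llf:.4f}   AIC: {self.aic:.4f}   BIC: {self.bic:.4f}",
            "-" * 64,
            f"{'parameter':<12}{'estimate':>12}{'std err':>12}{'z':>10}{'P>|z|':>10}",
        ]
        bse, tv, pv = self.bse, self.tvalues, self.pvalues
        for nm in model.param_names:
            lines.append(
                f"{nm:<12}{self.params[nm]:>12.4f}{bse[nm]:>12.4f}"
                f"{tv[nm]:>10.3f}{pv[nm]:>10.3f}"
            )
        lines.append("-" * 64)
        return "\n".join(lines)

    def to_report(self) -> dict:
        """Flat key/value record of the fit (for text serialization)."""
        rec = {
            "model": type(self.model).__name__,
            "p": self.model.order.p,
            "q": self.model.order.q,
            "r": self.model.order.r,
            "link": self.model.link,
            "nobs": self.nobs,
            "loglik": self.llf,
            "aic": self.aic,
            "bic": self.bic,
            "mape": self.mape(),
            "rmse": self.rmse(),
            "converged": self.converged,
        }
        for nm, val in self.params.items():
            rec[f"coef.{nm}"] = float(val)
        return rec
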