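# Methods

## Model and likelihood

The RBSARMAX(p, q, r) model couples a conditional reparameterized
Birnbaum–Saunders (RBS) distribution with a GARMA-style linear predictor.
Writing g for the link (identity by default) and m = max(p, q):

    y_t | F_{t-1} ~ RBS(μ_t, δ),
    g(μ_t) = α_t = η + x_t'β + Σ_i φ_i [g(y_{t-i}) − x_{t-i}'β]
                       + Σ_j θ_j [g(y_{t-j}) − α_{t-j}],   t = m+1..n.

MA innovations g(y_{t-j}) − α_{t-j} with index inside the conditioning
head (t − j ≤ m) are set to 0; AR terms always use observed values. The
conditional log-likelihood Σ_{t>m} log f(y_t; μ_t, δ) is maximized by BFGS
with δ on the log scale; η, β, φ, θ are unconstrained (no stationarity
constraint is imposed; estimates with Σ|φ̂_i| ≥ 1 trigger a warning).
Standard errors come from the inverse numerical Hessian of the negative
log-likelihood (central differences, relative step 1e-5 escalating to
1e-3 if the smallest step leaves the matrix numerically indefinite —
needed when a calendar-scale trend regressor makes the intercept direction
almost flat).

The RBS density is defined through the classical BS form with shape
α = √(2/δ) and scale λ = δμ/(δ+1); the log-density is evaluated directly
in log space so precisions of order 10³–10⁴ (the mortality application
fits δ̂ ≈ 600) never overflow. Correctness of the kernel is anchored on
the closed-form CDF and checked in the tests against an independent BS
implementation (`scipy.stats.fatiguelife`) and adaptive quadrature.

**Intercept convention.** η sits outside the AR deflation: the AR terms
subtract only x'β. GARMA-style software often reports the equivalent
"inside" intercept η_in = η/(1 − Σφ); the application workflow reports
both, since published mortality fits use the inside convention with a
calendar-year trend.

**Information criteria.** AIC = −2ℓ + 2k and BIC = −2ℓ + k·log n with
k = p + q + r + 2 (intercept and δ, or σ² for the Gaussian baseline,
included) and n the full series length. MAPE/RMSE are in-sample one-step
quantities over t = m+1..n with ŷ_t = μ̂_t.

## Identity link and feasibility

The identity link keeps coefficients on the data scale but does not
enforce μ_t > 0. Two guards apply:

- during **fitting**, parameter values producing any μ_t ≤ 0 receive a
  large finite penalty (10¹⁰ plus the squared violation), so quasi-Newton
  line searches retreat smoothly; a log link is available as an option;
- during **simulation**, a path reaching μ_t ≤ 0 raises an error naming
  the step, and the Monte Carlo harness excludes that replicate, reporting
  the exclusion rate per cell.

This matters for the strongest-dependence study design (φ = 0.7, θ = 0.5,
δ = 8): there the MA feedback compounds (ψ₁ = φ + θ = 1.2) and a single
sharp drop in y drives the next conditional mean negative with per-step
probability ≈ 0.3%, so most length-500 paths are infeasible and the
retained sample is conditioned on feasibility. The Monte Carlo summaries
for the AR/MA coefficients are essentially unaffected (they reproduce the
published values to three decimals), but the precision estimator δ̂ picks
up two small positive bias components at these settings: conditioning on
feasible (hence less dispersed) paths, and the usual dispersion-estimator
bias that grows with the number of fitted mean parameters. Both are
quantified in the acceptance outputs rather than removed: no bias
correction is applied because the estimator under study is the plain CML
estimator. At moderate dependence (φ, θ ≤ 0.5 with φ + θ ≤ 0.8)
exclusions are rare (< 2%) and all summaries are clean.

## Simulators

`simulate_rbsarmax` draws y_t through the exact normal-transform
representation of the RBS law along the recursion;
`simulate_weibull_armax` replaces the conditional law by a Weibull with
shape δ and scale μ_t/Γ(1 + 1/δ), so its conditional mean equals the same
recursion's μ_t — fitting RBSARMAX to it isolates a pure distributional
misspecification. Defaults that define the study conditions:

- one regressor, i.i.d. uniform(0, 1), drawn once per scenario and held
  fixed across replicates (a per-replicate redraw is a switch); uniform
  regressors keep x'β positive, which helps identity-link feasibility;
- burn-in of 50 points generated and discarded;
- one master seed spawns independent substreams per cell and replicate
  (`numpy.random.SeedSequence`), so any cell reproduces in isolation.

What the generators do **not** emulate: real series' seasonality,
outliers, measurement error, or lack of fit. Passing tests on simulated
data therefore demonstrate estimator and diagnostic calibration under the
model, not real-data adequacy. In particular, the synthetic stand-in for
the mortality dataset (`synthetic_la_series`, labelled synthetic) carries
the published point estimates and seasonal regressor scales but not the
real series' excess variation: its in-sample MAPE sits at the
model-implied level (≈ 4.5% at δ ≈ 623) rather than the published
real-data 4.81%.

## Residual diagnostics

The generalized Cox–Snell residual −log Ŝ(y_t | F_{t-1}) is unit
exponential and the randomized-quantile residual Φ⁻¹[Ŝ(y_t | F_{t-1})]
standard normal under correct specification. The survival-based RQ sign
convention is kept as the default (it is the negation of the usual CDF
form; both are N(0,1), and the convention is switchable). Envelopes are
parametric bootstrap: simulate from the fitted model over the observed
regressors, refit each replicate warm-started at the original estimates,
and take per-order-statistic quantiles (defaults: 100 replicates, 95%
band); more than 20% refit failures is an error. ACF uses the biased
(denominator n) convention and PACF the Durbin–Levinson recursion, via
statsmodels.

## Numerical choices

- Optimizer: scipy BFGS, gradient tolerance 1e-6, max 500 iterations;
  "precision loss" terminations are accepted as converged when the final
  gradient is small (< 1 in max-norm on a log-likelihood of order 10²–10³),
  since finite-difference noise dominates near the optimum.
- Starting values: η, β by OLS of g(y) on the regressors; φ = θ = 0; δ by
  method of moments on the OLS residual variance, floored at 0.5; an
  infeasible start retreats to a flat mean at the sample average.
- Gaussian baseline: identical mean recursion and conditioning with σ²
  profiled out (CSS), so model comparisons share the index set; with
  p = q = 0 it reduces exactly to OLS.
- Monte Carlo summaries use 1/N_r denominators, so MSE = Var + Bias²
  holds exactly.
- Degenerate inputs raise: non-positive responses, constant series in
  ACF/PACF, q outside (0,1), unknown regressor laws.

## Problem sizes

The default test and acceptance runs use the study's sample sizes
(n ∈ {100, 200, 500}, n = 1000 for residual calibration, n = 508 for the
application stand-in) with replicate counts of 100–1000 per cell — chosen
as the smallest counts whose Monte Carlo standard errors keep the
published values' 3-SE bands meaningful; every cell reports its own MC
standard error so reduced-replicate comparisons stay principled.

## Known limitations

- Exact (unconditional) likelihood, seasonal operators, missing data, and
  analytic score/information are out of scope; standard errors are purely
  numerical.
- Under strong positive dependence the identity link's feasibility
  conditioning is part of the estimand (see above); a log link avoids it
  at the cost of coefficient interpretability.
- The Weibull misspecification generator is the mean-parameterized
  reading; with both models correctly estimating the conditional mean,
  their in-sample RMSE is near-identical (the Gaussian baseline, being
  the efficient quasi-ML mean estimator, wins by a hair), and model
  choice there rests on AIC/BIC and MAPE.
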