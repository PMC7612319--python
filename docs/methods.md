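# Methods

## Problem and model classes

`voikit` computes the expected value of information for simulation models
in which uncertain inputs θ carry a joint probability distribution and
the model is a deterministic map Y = f(θ). Two problem classes are
supported throughout:

* **Decision problems.** An action a ∈ {1, …, A} is chosen to maximise
  the expected net benefit E[NB_a(θ)], where NB_a = λY_a − C_a (net
  monetary benefit), Y_a − C_a/λ (net health benefit), or, for the
  common "implement if the benefit clears a threshold k" setting,
  NB_2 = f(θ) − k against a status quo NB_1 ≡ 0. Information is valued
  in net-benefit units.
* **Estimation problems.** The "action" is the reported point estimate
  of Y under squared-error loss; the optimal report is E(Y), the
  expected loss is var(Y), and information is valued as a reduction in
  variance.

All measures are computed from a single Monte Carlo sample: an R×P table
of input draws and the aligned output draws. EVPI is exact given the
sample (mean opportunity benefit for decisions; the empirical variance,
divisor R−1, for estimation). EVPPI and EVSI are estimated by
nonparametric regression, following the generalized-additive-model
approach of Strong & Oakley and its extension to summary-statistic
regression for sample information.

## Regression emulators

The conditional mean h(x) = E(Y | x) is fitted by one of three backends:

* `spline_gam` — additive penalized cubic regression splines. The
  B-spline basis (default dimension min(10, ⌊R/50⌋) per predictor) and
  its second-derivative penalty are built by statsmodels; the Gaussian
  penalized least-squares system is solved directly and the smoothing
  parameter chosen by generalized cross-validation over a 31-point
  log-spaced grid scaled to tr(XᵀX)/tr(S). A predictor with ≤ 25 unique
  values (a discrete study summary, say a binomial count at small n) is
  fitted saturated — per-level means — which is the exact flexible
  conditional mean and avoids a rank-deficient spline basis.
* `adaptive_splines` — multivariate adaptive regression splines:
  forward selection of hinge-pair terms (max 21 terms, interaction
  degree ≤ 2, knots at 15 marginal quantiles) scored by incremental
  Gram-matrix updates, then backward pruning against GCV with the
  conventional penalty of 3 per knot.
* `gaussian_process` — squared-exponential kernel with per-dimension
  lengthscales plus a nugget, hyperparameters by marginal-likelihood
  maximization (scikit-learn), trained on a random subset of
  min(R, 1000) draws and evaluated at all R. The subset keeps a fit to
  seconds on one core; on smooth test functions the explained variance
  at subset 1000 is indistinguishable from subset 2000.
* `auto` — fits all three on a seeded 80/20 split and keeps the backend
  with the lowest held-out mean squared error.

Predictors are standardized internally. Each fit reports the fitted
values, the residual variance, and diagnostics; by the law of total
variance var(fitted) + resid_var ≈ var(y), and the discrepancy is a
misfit diagnostic (tested to be < 2% on smooth problems at R = 5000).
Defaults for EVPPI follow dimension: splines for |φ| ≤ 4, adaptive
splines for 5–15; joint EVPPI beyond 15 parameters is refused, since
nonparametric regression is unreliable there. No backend is universally
reliable, so cross-backend sensitivity analysis is recommended and the
suite asserts 1-D agreement within 5%.

Estimation EVPPI is reported as estimator (a), var(fitted); estimator
(b), var(y) − resid_var, travels in the metadata. Decision EVPPI fits
one surface per action and evaluates mean_r[max_a ĥ_a(φ^(r))] −
max_a[mean_r NB_a]. Monte Carlo noise can make small true values come
out negative; estimates are clipped to zero (and to var(y) above) with
the raw value retained. The reported `mc_se` is approximate: it is the
sampling SE of the variance of the fitted values (estimation) or of the
mean regression-based opportunity benefit (decision), and ignores
emulator uncertainty; a draw-level bootstrap is the honest but costly
alternative.

## EVSI and study designs

For a proposed study with sampling model Z | θ and summary statistic
T(Z), one dataset Z^(r) is simulated per input draw and the outputs are
regressed on T(Z^(r)); var(fitted) (or the decision form above) is the
EVSI. The binary design observes Z ~ Binomial(n, p^(r)) with T = Z.
Custom designs supply a pure simulate-and-summarise function, validated
on probe draws for determinism given the rng and for a constant summary
dimension. Per-size simulation seeds derive from one user seed. The
suite checks the Beta-binomial closed form EVSI(n) = V₀·n/(a+b+n), the
n → ∞ limit (EVPPI of the informed parameter), and monotonicity in n.

The expected value of *imperfect published information* uses the
effective-sample-size conversion n = m(1−m)/σ² − 1 (the Beta posterior
from a vague Beta(0,0) prior whose mean m and SD σ match the published
estimate), rounding half-to-even and flooring at zero; σ ≥ √(m(1−m)) is
rejected as inconsistent with any Beta posterior. ENBS is EVSI minus
the study cost and may be negative; an optimiser over an n-grid is
provided.

## The PM2.5–stroke fixture

The worked example estimates stroke cases averted when transport PM2.5
emissions are scaled by D = 0.5: Y = I₀ − I₀·g2(g1(μ,π,D), d)/g2(μ, d)
with g1 = μ(πD + 1 − π) and g2(x, d) = 1 + α(1 − exp(−β(x−τ)^γ)) for
x ≥ τ, 1 below. Defaults: μ ~ log-normal(2.7, 0.3) μg/m³ (95% limits ≈ 8
and 27), π ~ Beta(5.7, 8.9) (mean 0.4, SD 0.12, 95% limits ≈ 17–64%),
I₀ = 18,530 cases/year, decision threshold k = 500 cases/year. μ and π
are sampled independently; the four dose-response parameters are
mutually correlated by construction.

**What is synthetic.** The published analysis this fixture emulates drew
its dose-response parameter sample from an unpublished posterior (a
Burnett-style curve refitted to perturbed literature relative risks) and
its multi-area illustration from an unprinted dataset. Those inputs are
not available, so the printed downstream numbers of that analysis — the
118–806 credible interval, expected values 375 vs 329, EVPI of 31
cases, per-parameter EVPPIs of 14/5/<1 cases, the remaining-SD figures,
and the n = 42 second-source conversion — are **not reproducible** here
and are nowhere asserted. The fixture instead generates a synthetic
relative-risk table (seven exposures 5–35 μg/m³ from a reference curve
d* = (0.6, 0.06, 1.2, 4) with SE 0.05 on log RR) and the suite checks
the *qualitative* findings that survive the substitution: the
transport-share EVPPI exceeds the dose-response group's, which exceeds
the background concentration's; the Monte Carlo mean differs from the
all-medians plug-in by more than 5% (nonlinearity bias); tornado rows
for π span more than those for μ. Passing these says the machinery
reproduces the analysis's structure, not its data.

The dose-response uncertainty sampler perturbs log RR by its SE and
refits d by bounded least squares (trust-region reflective) with
log(α), log(β) ∈ [−7, 3], log(γ) ∈ [−2, 2], and τ ∈ [0, min(x)) via a
logit map. The box is part of the generator's design: the asymptote α is
unidentified beyond the observed exposure range, and unbounded fits
produce physically meaningless α in the thousands. Starts are the
unperturbed-table fit plus two fixed jitters, used only when the first
start does not already fit to the noise level; fits failing to converge
are dropped, and a convergence rate below 90% is an error. Curve
strength for joint sensitivity analysis is ρ = g2(10)/g2(15) (scenario
vs base-case mean exposures), with extreme curves at the nearest-rank
2.5%/97.5% order statistics of ρ.

## Evidence models

*Bias.* A possibly non-transportable estimate π_a is mapped to the
context-specific π₀ = expit(logit(π_a) + δ), δ ~ N(shift, σ²), keeping
(0,1) support for any σ. σ is elicited from "with probability p, π₀ is
no more than 100(r−1)% larger than π_a" and solved by bisection
(tolerance 10⁻⁴) on the empirical nearest-rank p-quantile of π₀/π_a
over a fixed 10⁵-draw common-random-numbers sample, making the
objective monotone and deterministic. The fixture check: increasing
probable bias from 20% to 50% raises the variance share explained by π₀
and lowers that of π_a.

*Hierarchy.* With logit-normal sampling and exchangeable logit-normal
area effects, the area effects integrate out analytically —
logit(x_i) ~ N(μ, σ² + s_i²) — so only the hyperparameters are sampled:
hyperpriors μ ~ N(0, 10²), σ ~ half-Normal(1) (configurable), 32
ensemble-sampler walkers × 4000 steps with the first half discarded,
and a split-R-hat convergence contract of 1.05 (an error, not a
warning, when exceeded). Target-area draws are the posterior predictive
logit(π₀) ~ N(μ, σ²) over retained hyperparameter draws. The six-area
demonstration table is synthetic, generated with documented seeds at
configurable heterogeneity.

## Numerical conventions

* Variance divisor R−1 throughout (results at R ≥ 5000 are insensitive
  to the choice).
* Ties in expected net benefit resolve to the lowest action index with
  a warning.
* Tornado credible limits default to the 2.5%/97.5% quantiles
  (closed-form for μ and π, empirical for the curve draws); rows are
  ordered by descending output span; the probabilistic version refuses
  to clamp a column correlated (|r| > 0.9) with columns outside its
  group, since substituting a clamp into a dependent joint sample does
  not estimate E(f | clamp).
* All stochastic entry points take an explicit integer seed;
  reproducibility is bit-for-bit under a fixed seed and is tested.
* Problem sizes in the test suite — R = 5000 for the fixture and
  emulator checks, R = 10⁴–10⁵ for closed-form checks, 500 × 500 for
  the nested-Monte-Carlo oracle — were chosen as the smallest sizes at
  which the regression emulators are reliably identified, matching the
  guidance that upwards of 5000 draws are needed with several
  predictors.

## Limitations

* The `mc_se` of regression-based EVPPI/EVSI understates total
  uncertainty (no emulator-uncertainty term).
* Additive spline surfaces ignore interactions between the parameters
  in φ; the adaptive-splines and GP backends capture degree-2 and
  general interactions respectively, which is one reason cross-backend
  checks matter.
* Net benefits are per-population-as-modelled; scaling to other
  populations, QALY valuation, microsimulation uncertainty, and
  EVSI algorithms other than summary-statistic regression
  (moment matching, importance sampling) are out of scope.
* The synthetic fixture emulates input *distributions*, not real
  exposure or outcome data: passing its tests demonstrates correctness
  of the VoI machinery, not calibration of any real-world estimate.
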