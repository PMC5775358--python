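# Methods

This note documents the statistical model behind `laborcast`, the choices
made where the design was genuinely open, and what the synthetic test bed
does and does not establish.

## Rate surfaces and principal components

Each demographic component is a years × ages panel of rates for one
sex × nationality stratum. Transforms map rates into an unbounded domain
where a linear factor model is sensible: `ln r` for fertility (keeps
forecast rates positive), `ln(1 − q)` for mortality (the log survival
probability; its inverse keeps death rates below 1), `logit r` for
emigration, naturalization and immigration shares (keeps rates in (0,1)).
Ages with structurally zero rates (fertility outside 15–49) are excluded
rather than imputed, because the log transform is undefined there.

PCA is computed by singular value decomposition of the centered panel.
**Columns are standardized by default** (correlation-metric PCA): the
Kaiser-Guttmann retention rule — keep components with eigenvalue ≥ 1, with
a floor of one so there is always a forecastable component — is stated in
that metric, where the eigenvalues sum to the number of age columns. An
unstandardized (covariance) option is available. Eigenvalues are
`s_i²/(n−1)`; each loading vector is sign-normalized so its
largest-magnitude entry is positive, which removes the SVD sign
indeterminacy that would otherwise make coefficient tests ambiguous.

Reconstruction inverts the transform of `means + scales ⊙ (scores · loadingsᵀ)`.
Two reconstruction-specific rules:

* immigration-share surfaces are renormalized to unit row sums (a truncated
  reconstruction does not preserve them exactly);
* for mortality, forecast scores can push the log survival probability of a
  near-zero-mortality age a few parts in 10⁷ above 0. Mortality improvement
  saturates at q = 0, so crossings up to 10⁻³ are capped at q = 0; larger
  crossings abort, because they indicate real model breakdown rather than
  rounding.

## Forecasting the components

Score series are fitted over the grid AR(1)/MA(1) … ARMA(2,2). **Pure AR
orders use conditional least squares** — the lagged regression on an
adjusted sample of n − p observations, with the concentrated Gaussian
log-likelihood `−m/2·(ln 2π + ln(SSR/m) + 1)`. This is the estimator whose
log-likelihood, regression standard error and information criteria
reproduce standard least-squares time-series regression output exactly,
and it makes bootstrap refits cheap (a closed-form OLS solve). Orders with
an MA part use exact maximum likelihood (statsmodels). Scores are centered by
construction, but a *trending* score still has drift in its differences:
by default an intercept (drift) term is included exactly when the score's
fitted linear trend is significant at the 5% level — a trending first
component is then a random walk with drift, Lee-Carter style, while
stationary components are modeled without a constant. (Fitting a drifting
component without drift turns it into a near-unit-root model whose
bootstrap paths wander symmetrically instead of continuing the trend,
which both biases the forecast and drives mortality across the q = 0
boundary.) Either choice can be forced globally. Criteria are
per-observation,

    aic = (−2ℓ + 2k)/n,  sc = (−2ℓ + k ln n)/n,  hq = (−2ℓ + 2k ln ln n)/n,

with k the mean-parameter count and n the model's own effective sample;
the Schwarz criterion selects by default (Hannan-Quinn optional), ties
going to fewer parameters, then to the lower AR order.

A first component with a significant linear trend (5% level) whose
extrapolation would leave a plausibility interval — the data range widened
by a configurable factor, default 100% on each side — within the forecast
horizon is instead given a **logistic saturation trend**

    pc_t = SN′ / (1 + exp(c1 + c2·t)) − d,   0 < pc_t + d < SN′.

The four parameters are estimated by least squares in pc-space under the
reparameterization `d = −min(pc) + e^α`, `SN′ = max(pc) + d + e^β`, which
enforces the constraint for every observed point, from five documented
starting margins (0.05/0.25/1.0 × range, plus two asymmetric pairs), each
start solving (c1, c2) by a linearized regression first. A fitted
saturation margin exceeding 100× the data range is flagged as a boundary
fit (a strictly linear series has no curvature to pin SN′ down) and raises
rather than returning a spurious asymptote. Residuals on the *transformed*
scale `ln(SN′/(pc+d) − 1) − (c1 + c2 t)` are stored for simulation: adding
innovations there keeps every stochastic path strictly inside
(−d, SN′ − d). Note on conditioning: the pair (c1, c2) is identified by
the curvature location, and its sampling error grows linearly with the
residual noise (about 4% relative error at a noise sd of 0.5% of the
series range at n = 100); SN′ and d are better determined.

Aggregate immigration counts are forecast as ARMA on log totals, keeping
forecast counts positive.

## Cohort-component engine

Within a projection year the event order is survival + aging → births →
immigration → emigration → naturalization. The order is a convention; it
places emigration after immigration so emigration applies to the grown
stock, consistent with rates-times-population emigration that can never
exceed any cell. Further conventions, all configurable: birth exposure is
the start-of-year female count; newborns take the mother's nationality;
sex ratio at birth 105 males per 100 females; immigrants neither give
birth nor die in their arrival year (no partial-year exposure); counts stay
real-valued (integerization would add unmodeled noise). The immigration
add-on schedule defaults to 340,000 persons in 2016 declining linearly to
0 in 2025. Mortality does not distinguish nationalities. The 90+ group is
absorbing. The per-nationality accounting identity holds to float exactness
and is asserted per simulated year in the test suite.

## Labor supply

Per demographic group (default 40 = 2 sexes × 2 nationalities × 10
quinquennial bands 15–19 … 60–64; 65–69/70–74 extension bands available),
`logit(a_t)` is regressed on covariates and a labor-market indicator by
weighted least squares. The default weight `a(1−a)` is the inverse of the
approximate variance of the logit of a proportion up to the unknown
sample-size factor; uniform weights reproduce OLS. The full-employment
value `U^v` is configuration input (a very low benchmark unemployment
rate, default 2), never estimated. Exogenous covariates are extrapolated by
a linear time trend; proportion-type covariates are clamped to declared
bounds with the clamping flagged. All fitted, potential and forecast rates
lie strictly in (0,1) by the logit codomain (kept open at float precision).

## Bootstrap simulation

Each draw re-fits every model on a residual-bootstrap replicate of its own
series (coefficient uncertainty), then draws forecast innovations by
i.i.d. residual resampling — plain residual-by-residual resampling, the
resampling unit being a choice documented here. The model *order* selected
on the observed data is held fixed across refits. A failed refit is redrawn
up to 10 times before erroring, and so is a strongly explosive one: refits
whose largest AR inverse root exceeds max(1.05, the point fit's root plus
0.02) are rejected, the standard guard in bootstrap AR forecasting. Mildly
super-unit roots are deliberately kept — they encode the drift of a random
walk fitted without an intercept — while the rejected draws would otherwise
blow up a trajectory geometrically. Draws are independent across models: the
cross-age dependence of rates lives inside each surface's components.
An asymptotic-normal coefficient option is not implemented beyond the
refit route; refits are cheap because AR fits are closed-form.

Bands are empirical quantiles with linear interpolation of order statistics
(type 7); level 66 reads the 17th/50th/83rd percentiles. The median is
preferred over the mean for robustness to outlying trajectories. The
default draw count is 5000; the test suite and the acceptance script use
200, which stabilizes the 17th/83rd percentiles to within a few percent of
the band width while keeping a full run in minutes on one CPU.

## Indicators

TFR sums single-year fertility rates over ages 15–49. Life expectancy comes
from a radix-1 period table with mid-interval deaths (a = 0.5) below the
open age and the constant-hazard closure `m = q/(1 − q/2)`,
`L_open = l_open/m`; a zero death probability at the open age cannot close
the table and raises. Median age interpolates linearly within the
single-year class containing the half-total (a point mass at age x yields
x + 0.5). Life expectancy is always computed from the model's own mortality
surface for the year in question.

## Synthetic data: what it emulates, what it does not

The generator produces every input from stated distributions: rate panels
as `inverse-transform(mean profile + loadings · factor paths + noise)`,
with smooth demographic mean profiles (a log-quadratic fertility schedule
peaking near age 29 with TFR ≈ 1.6; Gompertz-like mortality with infant
bump, e0 ≈ 79; young-adult-humped emigration/naturalization/immigration
profiles, foreign emigration roughly an order of magnitude above nationals
on the logit scale), factor paths with a 50-step burn-in where stationary
(unit-root factors start at zero — burn-in would only accumulate drift),
and Gaussian noise small enough that the leading sample eigenvalues
dominate, as they do in strongly collinear real age profiles. Default
sample lengths are the study conditions of annual official series: 23
years for vital rates, participation and migration, 54 for mortality; base
population 80.2 million, 90/10 national/foreign, in an aged pyramid.
Participation series come from known logit coefficients (indicator
coefficient −0.1138, full-employment value 2). A master seed spawns child
seeds per surface through `SeedSequence([seed, component, sex, nationality])`,
so adding a surface never shifts the randomness of others. Rates that would
leave their transform's domain abort generation naming the offending cell —
silent clipping would corrupt recovery tests.

Not emulated: calendar-specific level shifts (census-style breaks), cohort
(age-period-cohort) structure, cross-component correlation beyond what the
shared pipeline induces, non-Gaussian shocks, and any attempt to match a
specific country's observed levels. Passing recovery and coverage tests
therefore demonstrates internal statistical correctness of the estimators
and the engine — not that real vital statistics follow a low-rank factor
model with i.i.d. Gaussian noise.

## Problem sizes used in tests and the acceptance script

Simulations in the test suite and `scripts/acceptance.py` use 200 bootstrap
draws, horizons of 12–22 years and, in integration fixtures, two broad
participation bands instead of ten; these sizes stabilize every asserted
statistic while keeping a full run in minutes on a single CPU. The band
coverage experiment fits on the 1991–2013 prefix of a generated
1991–2035 world with the ARMA route only (`logistic_first_pc="never"`),
so the model family matches the stationary generating dynamics and the
nominal 66% band can be compared to the realized coverage of the world's
own continuation.

## Known limitations

* **Bootstrap bands undercover at the study sample lengths.** Two effects
  stack. First, the small-sample downward bias of AR persistence estimates
  (which residual bootstrap propagates rather than corrects) makes bands
  mean-revert too fast: for an AR(1) with phi = 0.95 fitted on 23
  observations, a calibration experiment with 200 outer replications puts
  pooled 22-year coverage of the nominal 66% band at about 61% (72% at
  horizon one, decaying to ~58%). Second, the draw design perturbs only the
  fitted time-series and regression models; the PCA layer (loadings, means,
  scales estimated from the same short panel) is held fixed, so quantities
  that aggregate several surfaces — total population above all — lose
  another ~10 points of coverage in full-system experiments (~51% pooled
  over ten generated worlds). Resampled residuals are df-rescaled by
  sqrt(n/(n−k)) and trending scores carry drift terms, which together
  recover several points; the remainder is intrinsic to the method at
  n ≈ 23 with forecast horizons of the same order. Users should read the
  66% label as a lower bound on band width, not an exact frequency.
* The logistic trend's (c1, c2) are weakly identified when the observed
  window misses the curvature; the boundary-fit guard converts the worst
  cases into errors instead of silent garbage.
* Migration totals and shares are modeled independently per nationality;
  no behavioral linkage between immigration and labor-market conditions.
* The potential labor force has no hours dimension; participation is heads.
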