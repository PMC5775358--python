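# laborcast

Stochastic, integrated forecasting of a national population **and** its
potential labor supply, disaggregated by single year of age, sex and
nationality (nationals vs. non-nationals).

`laborcast` is written for demographers and labor-market researchers who
want probabilistic long-run forecasts instead of scenario bundles: every
output comes as a median path with bootstrap confidence bands, so the
uncertainty of, say, the 2035 working-age population is a computed quantity,
not an assumption.

## The model

**Rates, not counts, are forecast.** For each demographic component
(age-specific fertility, mortality, emigration and naturalization rates, and
the age × sex distribution of immigrants) the historical years × ages panel
is mapped into an unbounded domain — `ln(rate)` for fertility,
`ln(1 − q)` (log survival) for mortality, `logit(rate)` otherwise — and
decomposed by singular values into principal components, Lee-Carter style
but keeping every component whose eigenvalue reaches 1 in the correlation
metric (Kaiser-Guttmann), so less collinear surfaces keep more than one
component:

    z_{t,a} = mean_a + Σ_k  loading_{a,k} · pc_{k,t} + ε_{t,a}

**Components are forecast as time series.** Each retained score series is
fitted over the ARMA grid AR(1)/MA(1) … ARMA(2,2); pure AR orders use
conditional least squares, MA orders exact maximum likelihood, and the
per-observation Schwarz criterion (Hannan-Quinn as alternative) selects the
order. A strongly trending first component can instead receive a logistic
saturation trend

    pc_t = SN′ / (1 + exp(c1 + c2·t)) − d ,     0 < pc_t + d < SN′,

whose four parameters are estimated by multi-start least squares, keeping
long-horizon forecasts inside plausible limits.

**Population accounting is cohort-component.** Starting from a base-year
pyramid, each year applies survival and aging, births (mothers'
nationality, configurable sex ratio), *top-down* immigration (an aggregate
count distributed over age × sex shares, plus an additive add-on schedule,
by default 340,000 in 2016 declining linearly to 0 in 2025), *bottom-up*
emigration (per-cell rates, so emigration grows with the population and can
never exceed it) and naturalization. Every flow is ledgered and the identity
`P(t+1) = P(t) − D + B + I − E ± N` holds per nationality to machine
precision.

**Labor supply is a logit regression per demographic group.** For each of
40 groups (sex × nationality × age band) the participation rate is modeled as

    logit(a_jt) = b0 + b1'Z_t + c·U_t ,

estimated by weighted least squares (weights `a(1−a)`), and the *potential*
rate — participation under full employment, including the hidden labor
force — substitutes a very low benchmark value `U^v` for the labor-market
indicator. Combined with the projected population this yields the potential
labor force.

**Uncertainty is bootstrapped.** Each of the (by default 5000) draws
resamples every model's residuals through its recursion, *re-fits* the model
(coefficient uncertainty), draws forecast innovations by residual
resampling, and runs a complete projection. Bands are empirical quantiles;
the conventional level is 66% (17th–83rd percentile) around the median.

No official statistics ship with the package: a synthetic-data module
generates rate panels with known low-rank factor structure, base pyramids,
immigration counts and participation series from known coefficients, so the
whole pipeline is testable end to end by parameter recovery.

## Worked example

```python
from laborcast import SyntheticConfig, PipelineOptions
from laborcast.stochastic_simulation import (
    synthetic_scenario, fit_pipeline, run_simulation, quantile_bands)

config = SyntheticConfig(seed=3)            # 1991-2013 synthetic histories
scenario = synthetic_scenario(config)
pipeline = fit_pipeline(scenario, PipelineOptions(end_year=2035))
result = run_simulation(pipeline, n_draws=200, seed=3)
bands = quantile_bands(result, level=66)

pop = bands["total_population"]
lf = bands["potential_labor_force"]
print(f"2035 population: {pop['median'].iloc[-1]/1e6:.1f}m "
      f"[{pop['lower'].iloc[-1]/1e6:.1f}, {pop['upper'].iloc[-1]/1e6:.1f}]")
print(f"2035 potential labor force: {lf['median'].iloc[-1]/1e6:.1f}m "
      f"[{lf['lower'].iloc[-1]/1e6:.1f}, {lf['upper'].iloc[-1]/1e6:.1f}]")
```

prints (seed 3):

```
2035 population: 84.3m [83.1, 85.4]
2035 potential labor force: 46.8m [45.9, 47.4]
```

i.e. from a base population of 80.2 million, the median trajectory reaches
84.3 million in 2035 and the 66% band spans about 2.3 million persons —
the width is the uncertainty accumulated from fertility, mortality,
migration and participation shocks plus coefficient uncertainty.

The same pipeline is scriptable from a shell:

```
laborcast --config run.yaml synth     # write synthetic input panels
laborcast --config run.yaml fit       # estimate all models
laborcast --config run.yaml simulate  # bootstrap bands -> outputs/results.csv
laborcast --config run.yaml report    # per-quantity band CSVs
```

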