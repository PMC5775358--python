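"""Bootstrap simulation engine for the integrated forecast.

The pipeline is: decompose each historical rate surface into principal
components (``rate_surfaces``), fit a forecasting model per retained
component (``pc_forecasting``), fit per-group participation equations
(``labor_supply``), then run many complete projection trajectories.  Each
bootstrap draw

1. rebuilds a replicate of every fitted series by resampling its residuals
   with replacement through the model recursion and *re-fits* the model on
   the replicate — so the draws carry coefficient uncertainty, not only
   residual variability;
2. draws forecast innovations by residual resampling;
3. forecasts the components, reconstructs rate surfaces, projects the
   population year by year through the cohort engine, and records the
   tracked indicators (total and working-age population, TFR by nationality,
   life expectancy by sex, net migration, the potential labor force and the
   per-group participation rates).

Quantile bands use linearly interpolated order statistics (the type-7
convention); the 66% level reads off the 17th/50th/83rd percentiles.  Draws
are independent across models: the cross-age correlation of rates is already
captured inside each surface's principal components.

The default draw count is 5000; everything is reproducible from one seed,
with per-draw child seeds spawned as ``SeedSequence([seed, draw_index])``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import indicators as ind
from .cohort_engine import (
    FlowLedger,
    MigrationSpec,
    N_AGES,
    NAT_INDEX,
    NATIONALITIES,
    PopulationState,
    SEXES,
    default_addon_schedule,
    project_year,
)
from .labor_supply import (
    AgeBand,
    LFPRModel,
    default_age_bands,
    extrapolate_covariates,
    fit_lfpr_model,
    labor_force,
)
from .pc_forecasting import (
    DEFAULT_GRID,
    FitError,
    PCModel,
    fit_arma,
    fit_logistic_trend,
    forecast_pc,
    select_model,
)
from .rate_surfaces import PCDecomposition, RateSurface, fit_pca, reconstruct_rates, transform
from .synthetic_data import (
    SyntheticConfig,
    generate_base_population,
    generate_immigration_totals,
    generate_lfpr_history,
    generate_rate_history,
)

__all__ = [
    "ScenarioData",
    "PipelineOptions",
    "FittedPipeline",
    "SimulationResult",
    "synthetic_scenario",
    "truncate_scenario",
    "fit_pipeline",
    "bootstrap_draw",
    "project_deterministic",
    "run_simulation",
    "quantile_bands",
]

MAX_REDRAWS = 10


@dataclass
class ScenarioData:
    """Raw inputs of one forecasting run (synthetic or user-supplied)."""

    surfaces: dict[tuple, RateSurface]
    immigration_totals: dict[str, pd.Series]
    lfpr: dict[tuple, tuple[pd.Series, pd.DataFrame]]
    base: PopulationState
    u_full: dict[tuple, float]


def synthetic_scenario(config: SyntheticConfig) -> ScenarioData:
    """Generate the complete input set from a synthetic configuration.

    Surface keys: ``("fertility", nat)``, ``("mortality", sex)``,
    ``("emigration", sex, nat)``, ``("naturalization", sex)`` (foreign
    population only) and ``("immigration_shares", sex, nat)``.
    """
    surfaces: dict[tuple, RateSurface] = {}
    for nat in NATIONALITIES:
        surfaces[("fertility", nat)] = generate_rate_history(
            config, "fertility", stratum=("f", nat)
        )
    for sex in SEXES:
        surfaces[("mortality", sex)] = generate_rate_history(
            config, "mortality", stratum=(sex, "german")
        )
        surfaces[("naturalization", sex)] = generate_rate_history(
            config, "naturalization", stratum=(sex, "foreign")
        )
        for nat in NATIONALITIES:
            surfaces[("emigration", sex, nat)] = generate_rate_history(
                config, "emigration", stratum=(sex, nat)
            )
            surfaces[("immigration_shares", sex, nat)] = generate_rate_history(
                config, "immigration_shares", stratum=(sex, nat)
            )
    totals = {
        nat: generate_immigration_totals(config, nat) for nat in NATIONALITIES
    }
    lfpr = {g: generate_lfpr_history(config, g) for g in config.lfpr_truth}
    u_full = {g: t.u_full for g, t in config.lfpr_truth.items()}
    return ScenarioData(
        surfaces=surfaces,
        immigration_totals=totals,
        lfpr=lfpr,
        base=generate_base_population(config),
        u_full=u_full,
    )


def truncate_scenario(scenario: ScenarioData, end_year: int) -> ScenarioData:
    """Restrict every input series to years <= end_year (for truth-holdout
    experiments where models are fitted on a prefix of the generated world)."""
    surfaces = {}
    for key, s in scenario.surfaces.items():
        keep = s.years <= end_year
        surfaces[key] = RateSurface(
            years=s.years[keep],
            ages=s.ages,
            values=s.values[keep],
            component_label=s.component_label,
            stratum=s.stratum,
            transform_kind=s.transform_kind,
        )
    totals = {
        nat: ser[ser.index <= end_year] for nat, ser in scenario.immigration_totals.items()
    }
    lfpr = {
        g: (ser[ser.index <= end_year], panel[panel.index <= end_year])
        for g, (ser, panel) in scenario.lfpr.items()
    }
    base = scenario.base
    if base.year > end_year:
        base = PopulationState(end_year, base.counts)
    return ScenarioData(surfaces, totals, lfpr, base, dict(scenario.u_full))


@dataclass
class PipelineOptions:
    """Knobs of the fitting and projection stage."""

    end_year: int = 2060
    criterion: str = "sc"
    standardize: bool = True
    # "auto": include a drift/intercept term exactly for score series whose
    # linear trend is significant at 5% (a trending component is a random
    # walk with drift, Lee-Carter style); True/False force it globally
    arma_intercept: bool | str = "auto"
    grid: tuple = DEFAULT_GRID
    logistic_first_pc: str = "auto"  # "auto" | "never" | "always"
    plausibility_expand: float = 1.0  # widen the data range by this factor
    addon_schedule: Mapping[int, float] = field(default_factory=default_addon_schedule)
    sex_ratio: float = 105.0
    working_age_bounds: tuple[int, int] = (15, 66)
    immigrant_sex_split: float = 0.5  # female share of each immigrant cohort
    weights_kind: str = "inverse_logit_variance"
    age_bands: tuple[AgeBand, ...] = field(default_factory=default_age_bands)
    covariate_bounds: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"parttime_rate": (0.0, 100.0)}
    )


@dataclass
class FittedPipeline:
    scenario: ScenarioData
    options: PipelineOptions
    decomps: dict[tuple, PCDecomposition]
    pc_models: dict[tuple, list[PCModel]]
    totals_models: dict[str, PCModel]
    lfpr_models: dict[tuple, LFPRModel]

    @property
    def horizon_years(self) -> np.ndarray:
        return np.arange(self.scenario.base.year + 1, self.options.end_year + 1)


def _wants_logistic(score: np.ndarray, horizon: int, expand: float) -> bool:
    """First-component logistic rule: significant linear trend whose
    extrapolation exits the plausibility interval within the horizon."""
    n = score.size
    t = np.arange(1, n + 1, dtype=float)
    res = sps.linregress(t, score)
    if res.pvalue >= 0.05:
        return False
    endpoint = res.intercept + res.slope * (n + horizon)
    lo, hi = float(np.min(score)), float(np.max(score))
    rng = hi - lo
    return bool(endpoint < lo - expand * rng or endpoint > hi + expand * rng)


def _trend_significant(score: np.ndarray) -> bool:
    t = np.arange(1, score.size + 1, dtype=float)
    return bool(sps.linregress(t, score).pvalue < 0.05)


def _fit_score_model(
    score: np.ndarray, first: bool, horizon: int, options: PipelineOptions
) -> PCModel:
    if first and options.logistic_first_pc != "never":
        wanted = options.logistic_first_pc == "always" or _wants_logistic(
            score, horizon, options.plausibility_expand
        )
        if wanted:
            try:
                return fit_logistic_trend(score)
            except FitError:
                pass  # fall back to the ARMA grid
    if options.arma_intercept == "auto":
        intercept = _trend_significant(score)
    else:
        intercept = bool(options.arma_intercept)
    return select_model(
        score, grid=options.grid, criterion=options.criterion,
        intercept=intercept,
    )


def fit_pipeline(
    scenario: ScenarioData, options: PipelineOptions | None = None
) -> FittedPipeline:
    """Fit every model of the system on the scenario's historical inputs."""
    options = options or PipelineOptions()
    horizon = options.end_year - scenario.base.year
    if horizon <= 0:
        raise ValueError("end_year must lie beyond the base year")

    decomps: dict[tuple, PCDecomposition] = {}
    pc_models: dict[tuple, list[PCModel]] = {}
    for key, surface in scenario.surfaces.items():
        decomp = fit_pca(transform(surface), standardize=options.standardize, surface=surface)
        decomps[key] = decomp
        models = []
        for j in range(decomp.n_retained):
            score = decomp.scores[:, j]
            models.append(_fit_score_model(score, j == 0, horizon, options))
        pc_models[key] = models

    totals_models = {
        nat: select_model(
            np.log(ser.to_numpy(dtype=float)),
            grid=options.grid,
            criterion=options.criterion,
            intercept=True,
        )
        for nat, ser in scenario.immigration_totals.items()
    }

    lfpr_models = {}
    for group, (ser, panel) in scenario.lfpr.items():
        covs = panel.drop(columns=["indicator"])
        lfpr_models[group] = fit_lfpr_model(
            ser.to_numpy(dtype=float),
            covs,
            panel["indicator"].to_numpy(dtype=float),
            weights_kind=options.weights_kind,
            group=group,
            u_full=scenario.u_full.get(group, 2.0),
        )
    return FittedPipeline(scenario, options, decomps, pc_models, totals_models, lfpr_models)


# ---------------------------------------------------------------------------
# bootstrap draws
# ---------------------------------------------------------------------------


def _rescaled_residuals(model) -> np.ndarray:
    """Residuals inflated by sqrt(n/(n-k)): fitted residuals underdisperse by
    the degrees of freedom lost to estimation, and resampling them raw makes
    bootstrap bands too narrow in short samples (standard correction)."""
    resid = model.residuals
    n = resid.size
    k = model.n_params if hasattr(model, "n_params") else len(model.coef)
    if n > k:
        return resid * math.sqrt(n / (n - k))
    return resid


def _replicate_arma(model: PCModel, rng: np.random.Generator) -> np.ndarray:
    """Residual-bootstrap replicate of the series behind an ARMA fit."""
    x = model.series
    n = x.size
    p, q = model.order
    resid = _rescaled_residuals(model)
    if np.all(resid == 0.0):
        return x.copy()
    if q == 0:
        eps = rng.choice(resid, size=n - p, replace=True)
        out = np.empty(n)
        out[:p] = x[:p]
        for i in range(p, n):
            acc = model.intercept + eps[i - p]
            for j, ph in enumerate(model.ar, start=1):
                acc += ph * out[i - j]
            out[i] = acc
        return out
    eps = rng.choice(resid, size=n, replace=True)
    out = np.empty(n)
    mu = model.intercept / (1.0 - np.sum(model.ar)) if p else model.intercept
    for i in range(n):
        acc = model.intercept + eps[i]
        for j, ph in enumerate(model.ar, start=1):
            acc += ph * (out[i - j] if i - j >= 0 else mu)
        for j, th in enumerate(model.ma, start=1):
            acc += th * (eps[i - j] if i - j >= 0 else 0.0)
        out[i] = acc
    return out


#: Refits whose largest AR inverse root exceeds this modulus are rejected.
#: Mildly super-unit roots are intrinsic (a drifting random-walk score fitted
#: without intercept estimates phi slightly above 1) and harmless over the
#: horizon; strongly explosive draws would blow up the trajectory.
MAX_AR_ROOT = 1.05


def _max_ar_root(ar: np.ndarray) -> float:
    if ar.size == 0:
        return 0.0
    companion = np.diag(np.ones(ar.size - 1), k=-1)
    companion[0, :] = ar
    return float(np.max(np.abs(np.linalg.eigvals(companion))))


def _redraw_model(model: PCModel, rng: np.random.Generator) -> PCModel:
    """One coefficient draw: refit the model on a residual-bootstrap replicate."""
    last_err: Exception | None = None
    # never stricter than the point fit itself plus a small margin
    root_cap = max(MAX_AR_ROOT, _max_ar_root(model.ar) + 0.02)
    for _ in range(MAX_REDRAWS):
        try:
            if model.kind == "logistic_trend":
                t = np.arange(1, model.n_obs + 1, dtype=float)
                pool = _rescaled_residuals(model)
                rho = rng.choice(pool, size=model.n_obs, replace=True)
                if np.all(pool == 0.0):
                    rho = np.zeros(model.n_obs)
                z = model.c1 + model.c2 * t + rho
                series = model.sn / (1.0 + np.exp(z)) - model.d
                return fit_logistic_trend(series)
            series = _replicate_arma(model, rng)
            refit = fit_arma(series, *model.order, intercept=model.has_intercept)
            if _max_ar_root(refit.ar) > root_cap:
                last_err = FitError(
                    f"explosive refit (max AR root {_max_ar_root(refit.ar):.3f})"
                )
                continue
            return refit
        except FitError as exc:
            last_err = exc
            continue
    raise FitError(f"bootstrap refit failed after {MAX_REDRAWS} attempts: {last_err}")


def _redraw_lfpr(model: LFPRModel, data, rng: np.random.Generator) -> LFPRModel:
    ser, panel = data
    resid = _rescaled_residuals(model)
    e = rng.choice(resid, size=resid.size, replace=True)
    if np.all(resid == 0.0):
        e = np.zeros(resid.size)
    logits = model.fitted_logits + e
    a = 1.0 / (1.0 + np.exp(-logits))
    covs = panel.drop(columns=["indicator"])
    return fit_lfpr_model(
        a,
        covs,
        panel["indicator"].to_numpy(dtype=float),
        weights_kind=model.weights_kind,
        group=model.group,
        u_full=model.u_full,
    )


@dataclass
class DrawModels:
    """A perturbed model set plus forecast innovation streams for one draw."""

    pc_models: dict[tuple, list[PCModel]]
    totals_models: dict[str, PCModel]
    lfpr_models: dict[tuple, LFPRModel]
    pc_innovations: dict[tuple, list[np.ndarray]]
    totals_innovations: dict[str, np.ndarray]
    lfpr_innovations: dict[tuple, np.ndarray]


def bootstrap_draw(pipeline: FittedPipeline, seed) -> DrawModels:
    """Build one draw: coefficient draws by residual-bootstrap refitting and
    forecast innovations by residual resampling, all from one seed."""
    rng = np.random.default_rng(seed)
    h = pipeline.horizon_years.size

    def innov(model) -> np.ndarray:
        resid = _rescaled_residuals(model)
        if resid.size == 0 or np.all(resid == 0.0):
            return np.zeros(h)
        return rng.choice(resid, size=h, replace=True)

    pc_models, pc_inn = {}, {}
    for key, models in pipeline.pc_models.items():
        pc_models[key] = [_redraw_model(m, rng) for m in models]
        pc_inn[key] = [innov(m) for m in models]
    totals_models = {
        nat: _redraw_model(m, rng) for nat, m in pipeline.totals_models.items()
    }
    totals_inn = {nat: innov(m) for nat, m in pipeline.totals_models.items()}
    lfpr_models = {
        g: _redraw_lfpr(m, pipeline.scenario.lfpr[g], rng)
        for g, m in pipeline.lfpr_models.items()
    }
    lfpr_inn = {g: innov(m) for g, m in pipeline.lfpr_models.items()}
    return DrawModels(pc_models, totals_models, lfpr_models, pc_inn, totals_inn, lfpr_inn)


# ---------------------------------------------------------------------------
# trajectory simulation
# ---------------------------------------------------------------------------


def _forecast_surfaces(
    pipeline: FittedPipeline, draw: DrawModels | None
) -> dict[tuple, RateSurface]:
    years = pipeline.horizon_years
    h = years.size
    out = {}
    for key, decomp in pipeline.decomps.items():
        models = draw.pc_models[key] if draw else pipeline.pc_models[key]
        inns = draw.pc_innovations[key] if draw else [None] * len(models)
        paths = np.column_stack(
            [forecast_pc(m, h, innovations=e) for m, e in zip(models, inns)]
        )
        out[key] = reconstruct_rates(decomp, paths, years=years)
    return out


def _forecast_totals(
    pipeline: FittedPipeline, draw: DrawModels | None
) -> dict[str, np.ndarray]:
    h = pipeline.horizon_years.size
    out = {}
    for nat, model in pipeline.totals_models.items():
        m = draw.totals_models[nat] if draw else model
        e = draw.totals_innovations[nat] if draw else None
        out[nat] = np.exp(forecast_pc(m, h, innovations=e))
    return out


def _forecast_lfpr(
    pipeline: FittedPipeline, draw: DrawModels | None
) -> dict[tuple, np.ndarray]:
    """Potential participation paths per group over the horizon."""
    h = pipeline.horizon_years.size
    out = {}
    for group, model in pipeline.lfpr_models.items():
        m = draw.lfpr_models[group] if draw else model
        _, panel = pipeline.scenario.lfpr[group]
        future = {}
        for name in m.covariate_names:
            bounds = pipeline.options.covariate_bounds.get(name)
            ext, _ = extrapolate_covariates(
                panel[name].to_numpy(dtype=float), h, bounds=bounds
            )
            future[name] = ext[-h:]
        Z = np.column_stack([future[name] for name in m.covariate_names])
        z = m.b0 + Z @ m.b1 + m.c * m.u_full
        if draw is not None:
            z = z + draw.lfpr_innovations[group]
        out[group] = 1.0 / (1.0 + np.exp(-z))
    return out


def _simulate_trajectory(
    pipeline: FittedPipeline, draw: DrawModels | None
) -> dict[str, np.ndarray]:
    """One full projection: rates -> population -> indicators per year."""
    opts = pipeline.options
    years = pipeline.horizon_years
    h = years.size
    surfaces = _forecast_surfaces(pipeline, draw)
    totals = _forecast_totals(pipeline, draw)
    lfpr_paths = _forecast_lfpr(pipeline, draw)
    split = opts.immigrant_sex_split

    migration = MigrationSpec(
        immigration_totals={
            nat: dict(zip(years, totals[nat])) for nat in NATIONALITIES
        },
        immigration_shares={
            nat: {
                int(y): np.column_stack(
                    [
                        (1.0 - split) * surfaces[("immigration_shares", "m", nat)].row(y),
                        split * surfaces[("immigration_shares", "f", nat)].row(y),
                    ]
                )
                for y in years
            }
            for nat in NATIONALITIES
        },
        emigration_rates={
            int(y): np.stack(
                [
                    np.column_stack(
                        [
                            surfaces[("emigration", "m", nat)].row(y)
                            for nat in NATIONALITIES
                        ]
                    ),
                    np.column_stack(
                        [
                            surfaces[("emigration", "f", nat)].row(y)
                            for nat in NATIONALITIES
                        ]
                    ),
                ],
                axis=1,
            )
            for y in years
        },
        addon_schedule=dict(opts.addon_schedule),
    )

    tracked = {
        name: np.empty(h)
        for name in (
            "total_population",
            "working_age_population",
            "tfr_german",
            "tfr_foreign",
            "e0_m",
            "e0_f",
            "net_migration_foreign",
            "potential_labor_force",
        )
    }
    for group in lfpr_paths:
        tracked[f"lfpr_{group[0]}_{group[1]}_{group[2]}"] = np.empty(h)

    state = pipeline.scenario.base
    ledger = FlowLedger()
    lo, hi = opts.working_age_bounds
    for i, year in enumerate(years):
        flow_year = int(year) - 1  # rates of the year leading into `year`
        death = np.column_stack(
            [surfaces[("mortality", "m")].row(year), surfaces[("mortality", "f")].row(year)]
        )
        fertility = {
            nat: surfaces[("fertility", nat)].row(year) for nat in NATIONALITIES
        }
        naturalization = np.column_stack(
            [
                surfaces[("naturalization", "m")].row(year),
                surfaces[("naturalization", "f")].row(year),
            ]
        )
        # migration schedules are keyed by the origin year of the step
        mig = MigrationSpec(
            immigration_totals={
                nat: {flow_year: migration.immigration_totals[nat][year]}
                for nat in NATIONALITIES
            },
            immigration_shares={
                nat: {flow_year: migration.immigration_shares[nat][int(year)]}
                for nat in NATIONALITIES
            },
            emigration_rates={flow_year: migration.emigration_rates[int(year)]},
            addon_schedule=migration.addon_schedule,
        )
        state, entry = project_year(
            state, death, fertility, mig,
            naturalization_rates=naturalization, sex_ratio=opts.sex_ratio,
        )
        ledger.add(entry)

        tracked["total_population"][i] = state.total()
        tracked["working_age_population"][i] = ind.working_age(state, lo, hi)
        for nat in NATIONALITIES:
            tracked[f"tfr_{nat}"][i] = ind.total_fertility_rate(fertility[nat])
        tracked["e0_m"][i] = ind.life_expectancy(death[:, 0])
        tracked["e0_f"][i] = ind.life_expectancy(death[:, 1])
        tracked["net_migration_foreign"][i] = ind.net_migration(
            ledger, flow_year, "foreign"
        )
        rates_now = {g: lfpr_paths[g][i] for g in lfpr_paths}
        lf_total, _, _ = labor_force(rates_now, state, group_map=opts.age_bands)
        tracked["potential_labor_force"][i] = lf_total
        for g in lfpr_paths:
            tracked[f"lfpr_{g[0]}_{g[1]}_{g[2]}"][i] = lfpr_paths[g][i]
    return tracked


def project_deterministic(pipeline: FittedPipeline) -> dict[str, np.ndarray]:
    """Point projection: conditional-mean forecasts, no perturbation."""
    return _simulate_trajectory(pipeline, None)


@dataclass
class SimulationResult:
    """Stacked trajectories: one (n_draws, n_years) array per tracked quantity."""

    quantities: dict[str, np.ndarray]
    years: np.ndarray
    seed: int
    n_draws: int

    def __post_init__(self) -> None:
        for name, arr in self.quantities.items():
            if arr.shape != (self.n_draws, self.years.size):
                raise ValueError(f"{name}: shape {arr.shape} inconsistent")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name}: missing or non-finite values")


def run_simulation(
    pipeline: FittedPipeline, n_draws: int = 5000, seed: int = 0
) -> SimulationResult:
    """Run ``n_draws`` complete bootstrap trajectories.

    Each draw perturbs every model (coefficients and innovations), forecasts
    the components, reconstructs the rates, projects the population and
    records the tracked indicators.  Reproducible: draw i uses the child
    seed ``SeedSequence([seed, i])``.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    stacks: dict[str, list[np.ndarray]] = {}
    for i in range(n_draws):
        draw = bootstrap_draw(pipeline, np.random.SeedSequence([int(seed), i]))
        traj = _simulate_trajectory(pipeline, draw)
        for name, path in traj.items():
            stacks.setdefault(name, []).append(path)
    quantities = {name: np.vstack(paths) for name, paths in stacks.items()}
    return SimulationResult(
        quantities=quantities,
        years=pipeline.horizon_years.copy(),
        seed=int(seed),
        n_draws=n_draws,
    )


def quantile_bands(result: SimulationResult, level: float = 66.0) -> dict[str, pd.DataFrame]:
    """Per-year empirical (lower, median, upper) bands per tracked quantity.

    ``level`` is the central coverage in percent: level 66 reads the 17th and
    83rd percentiles around the median.  Quantiles interpolate order
    statistics linearly (type 7).
    """
    if not (0.0 < level < 100.0):
        raise ValueError(f"level must lie in (0, 100), got {level}")
    if result.n_draws < 2:
        raise ValueError("need at least 2 draws for quantile bands")
    lo_q = (100.0 - level) / 200.0
    out = {}
    for name, arr in result.quantities.items():
        lower, median, upper = np.quantile(
            arr, [lo_q, 0.5, 1.0 - lo_q], axis=0, method="linear"
        )
        out[name] = pd.DataFrame(
            {
                "year": result.years,
                "median": median,
                "lower": lower,
                "upper": upper,
                "level": level,
                "n_draws": result.n_draws,
                "seed": result.seed,
            }
        )
    return out
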