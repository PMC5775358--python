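"""Synthetic demographic inputs with known generating structure.

Every input the forecasting pipeline needs can be generated here from stated
distributions: rate panels with low-rank latent factor structure plus noise
(the assumption under the principal-component models), aggregate immigration
count series, a base-year population pyramid, and participation-rate series
produced from known logit coefficients.  Because the generating parameters
are known, every downstream estimator can be validated by parameter
recovery.

Defaults emulate the study conditions of an integrated German-style
population and labor-supply forecast: 23 annual observations (vital-rate and
participation panels of 1991-2013 length; mortality runs longer, 54 years),
single-year ages with a 90+ open group, two sexes and two nationality
groups, a base population of 80.2 million with a roughly 90/10
German/foreign split, trending first factors with an AR(2) second factor
(coefficients 1.2322, -0.3825), and logit participation equations whose
unemployment-indicator coefficient is -0.1138 with a full-employment value
of 2 (a very low unemployment rate).

Reproducibility: one master seed derives per-surface child seeds through
``numpy.random.SeedSequence([seed, component_code, sex_code, nat_code])``,
a fixed documented rule, so adding one surface never shifts the randomness
of any other.  Rates that would leave the domain of their transform abort
generation with an error naming the offending cell — silent clipping would
break recovery tests.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort_engine import N_AGES, PopulationState
from .labor_supply import AgeBand, default_age_bands
from .rate_surfaces import DomainError, RateSurface

__all__ = [
    "FactorSpec",
    "ComponentSpec",
    "PyramidParams",
    "CovariateProcess",
    "LFPRTruth",
    "SyntheticConfig",
    "generate_rate_history",
    "generate_base_population",
    "generate_lfpr_history",
    "generate_immigration_totals",
    "child_rng",
]

# fixed child-seed codes; the spawn rule is SeedSequence([seed, component,
# sex_code, nat_code]) with 2 = "both"/"not applicable"
COMPONENT_CODES = {
    "fertility": 1,
    "mortality": 2,
    "emigration": 3,
    "naturalization": 4,
    "immigration_shares": 5,
    "immigration_totals": 6,
    "lfpr": 7,
    "base_population": 8,
}
SEX_CODES = {"m": 0, "f": 1, None: 2}
NAT_CODES = {"german": 0, "foreign": 1, None: 2}

BURN_IN = 50  # factor-path burn-in steps before the retained window


def child_rng(
    seed: int, component: str, sex: str | None = None, nat: str | None = None, extra: int = 0
) -> np.random.Generator:
    """Deterministic per-surface generator derived from the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(
            [int(seed), COMPONENT_CODES[component], SEX_CODES[sex], NAT_CODES[nat], extra]
        )
    )


@dataclass
class FactorSpec:
    """One latent factor process.

    ``kind="ar"``: x_t = drift + sum(phi_i x_{t-i}) + sigma e_t, simulated
    with a 50-step burn-in when the AR polynomial is stationary (burn-in on a
    unit-root process would only accumulate drift, so nonstationary factors
    start at zero).

    ``kind="logistic_trend"``: x_t = sn/(1 + exp(c1 + c2 t)) - d + sigma e_t,
    a saturating trend path.
    """

    kind: str = "ar"
    phi: tuple[float, ...] = (0.8,)
    drift: float = 0.0
    sigma: float = 0.3
    sn: float = float("nan")
    c1: float = float("nan")
    c2: float = float("nan")
    d: float = float("nan")

    def is_stationary(self) -> bool:
        if self.kind != "ar" or not self.phi:
            return True
        poly = np.r_[1.0, -np.asarray(self.phi)]
        roots = np.roots(poly[::-1])  # roots of phi(B) in B
        return bool(np.all(np.abs(roots) > 1.0 + 1e-10)) if roots.size else True

    def simulate(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "logistic_trend":
            t = np.arange(1, n + 1, dtype=float)
            path = self.sn / (1.0 + np.exp(self.c1 + self.c2 * t)) - self.d
            if self.sigma > 0.0:
                path = path + self.sigma * rng.standard_normal(n)
            return path
        if self.kind != "ar":
            raise ValueError(f"unknown factor kind {self.kind!r}")
        p = len(self.phi)
        burn = BURN_IN if self.is_stationary() else 0
        total = burn + n
        x = np.zeros(total + p)
        eps = self.sigma * rng.standard_normal(total) if self.sigma > 0 else np.zeros(total)
        for i in range(total):
            acc = self.drift + eps[i]
            for j, ph in enumerate(self.phi, start=1):
                acc += ph * x[p + i - j]
            x[p + i] = acc
        return x[p + burn :]


@dataclass
class ComponentSpec:
    """Generating structure of one rate surface."""

    ages: np.ndarray
    transform_kind: str
    mean_profile: np.ndarray  # transformed-space column means
    loadings: np.ndarray  # ages x n_factors, full column rank
    factors: tuple[FactorSpec, ...]
    noise_sd: float = 0.02
    noise_relative: bool = False  # scale noise by |mean_profile| per age
    n_years: int | None = None  # override config.n_years (e.g. mortality)
    normalize_rows: bool = False  # shares surfaces: softmax over ages
    stratum_mean_shift: dict = field(default_factory=dict)  # nationality -> shift

    def validate(self) -> None:
        A, k = self.loadings.shape
        if A != self.ages.size:
            raise ValueError("loading rows must match ages")
        if k != len(self.factors):
            raise ValueError("loading columns must match factor count")
        if np.linalg.matrix_rank(self.loadings) < k:
            raise ValueError("loading matrix must have full column rank")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class PyramidParams:
    total: float = 80_200_000.0
    shape: str = "aged"  # "uniform" | "aged"
    german_share: float = 0.9
    female_share: float = 0.5


@dataclass
class CovariateProcess:
    """Linear trend plus stationary AR(1) noise around it."""

    start: float = 25.0
    slope: float = 0.5
    phi: float = 0.6
    sigma: float = 0.5

    def simulate(self, n: int, rng: np.random.Generator) -> np.ndarray:
        trend = self.start + self.slope * np.arange(n, dtype=float)
        noise = np.zeros(n)
        eps = self.sigma * rng.standard_normal(BURN_IN + n) if self.sigma > 0 else np.zeros(BURN_IN + n)
        x = 0.0
        path = np.empty(BURN_IN + n)
        for i in range(BURN_IN + n):
            x = self.phi * x + eps[i]
            path[i] = x
        noise = path[BURN_IN:]
        return trend + noise


@dataclass
class LFPRTruth:
    """Known logit coefficients generating one group's participation series."""

    b0: float
    b1: tuple[float, ...] = (0.01,)
    c: float = -0.1138
    u_full: float = 2.0


def _gauss_bump(ages: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-(((ages - center) / width) ** 2))


def _fertility_spec() -> ComponentSpec:
    ages = np.arange(15, 50)
    mean = -2.4 - 0.01 * (ages - 29.0) ** 2  # log rates, TFR ~ 1.5
    # every age column carries factor signal (real age profiles co-move
    # strongly), so the spectrum concentrates on the leading components
    load = np.column_stack(
        [
            0.06 * (0.5 + _gauss_bump(ages, 29.0, 8.0)),
            0.04 * np.linspace(0.2, 1.0, ages.size),  # age-shift gradient
        ]
    )
    factors = (
        FactorSpec(kind="ar", phi=(0.95,), drift=0.02, sigma=0.25),
        FactorSpec(kind="ar", phi=(1.2322, -0.3825), drift=0.0, sigma=0.25),
    )
    return ComponentSpec(ages, "log", mean, load, factors, noise_sd=0.008)


def _mortality_spec() -> ComponentSpec:
    ages = np.arange(N_AGES)
    q = 3e-5 + 8e-5 * np.exp(0.085 * ages) + 0.003 * np.exp(-ages)
    mean = np.log1p(-q)  # log survival probabilities, all < 0
    # multiplicative factor structure keeps log survival negative
    load = (0.04 * mean)[:, None]
    factors = (FactorSpec(kind="ar", phi=(1.0,), drift=-0.12, sigma=0.10),)
    return ComponentSpec(
        ages, "log_survival", mean, load, factors,
        noise_sd=0.004, noise_relative=True, n_years=54,
    )


def _emigration_spec() -> ComponentSpec:
    ages = np.arange(N_AGES)
    r = 0.0015 + 0.004 * _gauss_bump(ages, 25.0, 12.0)
    mean = np.log(r / (1.0 - r))
    load = np.column_stack(
        [
            0.2 * (0.4 + _gauss_bump(ages, 25.0, 15.0)),
            0.1 * np.linspace(0.2, 1.0, ages.size),
        ]
    )
    factors = (
        FactorSpec(kind="ar", phi=(0.8,), drift=0.0, sigma=0.3),
        FactorSpec(kind="ar", phi=(0.5,), drift=0.0, sigma=0.25),
    )
    return ComponentSpec(
        ages, "logit", mean, load, factors, noise_sd=0.01,
        # foreign nationals emigrate at roughly an order of magnitude higher
        # rates than nationals; shift on the logit scale per stratum
        stratum_mean_shift={"foreign": 3.2},
    )


def _naturalization_spec() -> ComponentSpec:
    ages = np.arange(N_AGES)
    r = 0.003 + 0.015 * _gauss_bump(ages, 30.0, 15.0)
    mean = np.log(r / (1.0 - r))
    load = np.column_stack(
        [
            0.2 * (0.4 + _gauss_bump(ages, 30.0, 18.0)),
            0.1 * np.linspace(0.2, 1.0, ages.size),
        ]
    )
    factors = (
        FactorSpec(kind="ar", phi=(0.85,), drift=0.0, sigma=0.3),
        FactorSpec(kind="ar", phi=(0.4,), drift=0.0, sigma=0.25),
    )
    return ComponentSpec(ages, "logit", mean, load, factors, noise_sd=0.01)


def _immigration_shares_spec() -> ComponentSpec:
    ages = np.arange(N_AGES)
    w = _gauss_bump(ages, 27.0, 11.0) + 0.02  # young-adult concentration
    mean = np.log(w)
    load = np.column_stack(
        [
            0.15 * (0.6 + _gauss_bump(ages, 27.0, 14.0)),
            0.08 * np.linspace(0.2, 1.0, ages.size),
        ]
    )
    factors = (
        FactorSpec(kind="ar", phi=(0.8,), drift=0.0, sigma=0.25),
        FactorSpec(kind="ar", phi=(0.5,), drift=0.0, sigma=0.2),
    )
    return ComponentSpec(
        ages, "logit", mean, load, factors, noise_sd=0.003, normalize_rows=True
    )


def default_components() -> dict[str, ComponentSpec]:
    return {
        "fertility": _fertility_spec(),
        "mortality": _mortality_spec(),
        "emigration": _emigration_spec(),
        "naturalization": _naturalization_spec(),
        "immigration_shares": _immigration_shares_spec(),
    }


_BAND_TARGET_RATES = {
    # participation-rate levels by quinquennial band 15-19 .. 60-64
    "m": (0.35, 0.75, 0.92, 0.96, 0.97, 0.96, 0.95, 0.93, 0.85, 0.55),
    "f": (0.30, 0.68, 0.78, 0.80, 0.82, 0.84, 0.85, 0.84, 0.75, 0.40),
}
_FOREIGN_LOGIT_SHIFT = {"m": -0.25, "f": -0.6}


def default_lfpr_truth(
    bands: Sequence[AgeBand] | None = None,
) -> dict[tuple, LFPRTruth]:
    """Known coefficients for the 40 default groups (2 sexes x 2 nationalities
    x 10 quinquennial bands), at plausible participation levels."""
    bands = tuple(bands) if bands is not None else default_age_bands()
    truth: dict[tuple, LFPRTruth] = {}
    for sex in ("m", "f"):
        targets = _BAND_TARGET_RATES[sex]
        for nat in ("german", "foreign"):
            for i, band in enumerate(bands):
                target = targets[min(i, len(targets) - 1)]
                logit = math.log(target / (1.0 - target))
                if nat == "foreign":
                    logit += _FOREIGN_LOGIT_SHIFT[sex]
                b1 = (0.01,)
                c = -0.1138
                # anchor the intercept so the mid-sample rate sits at the target
                z_mid, u_mid = 30.0, 8.0
                b0 = logit - b1[0] * z_mid - c * u_mid
                truth[(sex, nat, band.label)] = LFPRTruth(b0=b0, b1=b1, c=c)
    return truth


@dataclass
class SyntheticConfig:
    """Master configuration of the synthetic world."""

    n_years: int = 23
    start_year: int = 1991
    seed: int = 0
    components: dict[str, ComponentSpec] = field(default_factory=default_components)
    pyramid: PyramidParams = field(default_factory=PyramidParams)
    lfpr_truth: dict[tuple, LFPRTruth] = field(default_factory=default_lfpr_truth)
    lfpr_covariates: dict[str, CovariateProcess] = field(
        default_factory=lambda: {"parttime_rate": CovariateProcess()}
    )
    indicator_process: CovariateProcess = field(
        default_factory=lambda: CovariateProcess(start=8.0, slope=0.0, phi=0.7, sigma=0.8)
    )
    lfpr_noise_sd: float = 0.03
    # aggregate immigration counts: stationary AR(1) on log totals
    immigration_levels: dict[str, float] = field(
        default_factory=lambda: {"german": 120_000.0, "foreign": 800_000.0}
    )
    immigration_phi: float = 0.8
    immigration_sigma: float = 0.08

    def __post_init__(self) -> None:
        if self.n_years < 10:
            raise ValueError(f"n_years must be >= 10, got {self.n_years}")
        for name, spec in self.components.items():
            spec.validate()
            if spec.n_years is not None and spec.n_years < 10:
                raise ValueError(f"{name}: n_years override must be >= 10")

    @property
    def end_year(self) -> int:
        return self.start_year + self.n_years - 1

    def years_for(self, spec: ComponentSpec) -> np.ndarray:
        n = spec.n_years or self.n_years
        return np.arange(self.end_year - n + 1, self.end_year + 1)


def generate_rate_history(
    config: SyntheticConfig,
    component: str,
    stratum: tuple = ("f", "german"),
) -> RateSurface:
    """Simulate one rate surface: inverse-transform(mean + loadings @ factors
    + noise), with factor paths from the configured dynamics.

    Deterministic given the master seed; each (component, stratum) surface
    has its own child seed.  A rate outside the transform's domain aborts
    with an error naming the year and age.
    """
    if component not in config.components:
        raise ValueError(f"unknown component {component!r}")
    spec = config.components[component]
    sex, nat = stratum
    rng = child_rng(config.seed, component, sex, nat)
    years = config.years_for(spec)
    n = years.size

    factors = np.column_stack([f.simulate(n, rng) for f in spec.factors])
    mean = spec.mean_profile + spec.stratum_mean_shift.get(nat, 0.0)
    Z = mean + factors @ spec.loadings.T
    if spec.noise_sd > 0:
        noise = rng.standard_normal((n, spec.ages.size)) * spec.noise_sd
        if spec.noise_relative:
            noise = noise * np.abs(spec.mean_profile)
        Z = Z + noise

    if spec.normalize_rows:
        expz = np.exp(Z)
        values = expz / expz.sum(axis=1, keepdims=True)
    elif spec.transform_kind == "log":
        values = np.exp(Z)
    elif spec.transform_kind == "logit":
        values = 1.0 / (1.0 + np.exp(-Z))
    elif spec.transform_kind == "log_survival":
        if np.any(Z > 0):
            i, j = np.argwhere(Z > 0)[0]
            raise DomainError(
                f"simulated log survival probability {Z[i, j]:.6g} > 0 "
                f"(death rate would be negative) at year={years[i]}, "
                f"age={spec.ages[j]}"
            )
        values = -np.expm1(Z)
    else:
        raise ValueError(f"unknown transform {spec.transform_kind!r}")

    return RateSurface(
        years=years,
        ages=spec.ages,
        values=values,
        component_label=component,
        stratum=stratum,
        transform_kind=spec.transform_kind,
    )


def generate_base_population(config: SyntheticConfig) -> PopulationState:
    """Deterministic base-year pyramid: total x age shares x stratum shares."""
    p = config.pyramid
    if p.total < 0:
        raise ValueError("total population must be non-negative")
    ages = np.arange(N_AGES, dtype=float)
    if p.shape == "uniform":
        w = np.ones(N_AGES)
    elif p.shape == "aged":
        # flat to age 50, declining linearly to 5% of that level at 90+
        w = np.where(ages <= 50, 1.0, 1.0 - 0.95 * (ages - 50) / 40.0)
    else:
        raise ValueError(f"unknown pyramid shape {p.shape!r}")
    age_share = w / w.sum()
    sex_share = np.array([1.0 - p.female_share, p.female_share])
    nat_share = np.array([p.german_share, 1.0 - p.german_share])
    counts = p.total * age_share[:, None, None] * sex_share[None, :, None] * nat_share[None, None, :]
    return PopulationState(config.end_year, counts)


def generate_lfpr_history(
    config: SyntheticConfig, group: tuple
) -> tuple[pd.Series, pd.DataFrame]:
    """Simulate one group's participation series with its covariate panel.

    Returns ``(lfpr, panel)`` where the panel holds the covariate columns
    plus the labor-market ``indicator``; the observed LFPR is
    inverse-logit(b0 + b1'Z + c U + noise) and always lies in (0, 1).
    """
    if group not in config.lfpr_truth:
        raise ValueError(f"no generating coefficients for group {group!r}")
    truth = config.lfpr_truth[group]
    sex, nat, band = group
    # stable across processes (unlike hash()) so runs are reproducible
    band_code = zlib.crc32(str(band).encode("utf-8"))
    rng = child_rng(config.seed, "lfpr", sex, nat, extra=band_code)
    n = config.n_years
    years = np.arange(config.start_year, config.start_year + n)

    panel = {}
    for name, proc in config.lfpr_covariates.items():
        panel[name] = proc.simulate(n, rng)
    u = config.indicator_process.simulate(n, rng)
    Z = np.column_stack([panel[name] for name in config.lfpr_covariates])
    logits = truth.b0 + Z @ np.asarray(truth.b1) + truth.c * u
    if config.lfpr_noise_sd > 0:
        logits = logits + config.lfpr_noise_sd * rng.standard_normal(n)
    lfpr = 1.0 / (1.0 + np.exp(-logits))

    frame = pd.DataFrame(panel, index=years)
    frame["indicator"] = u
    return pd.Series(lfpr, index=years, name="lfpr"), frame


def generate_immigration_totals(
    config: SyntheticConfig, nationality: str
) -> pd.Series:
    """Aggregate annual immigration counts: AR(1) on the log scale around a
    configured level, so counts stay positive."""
    if nationality not in config.immigration_levels:
        raise ValueError(f"no immigration level for {nationality!r}")
    level = config.immigration_levels[nationality]
    rng = child_rng(config.seed, "immigration_totals", None, nationality)
    n = config.n_years
    phi, sigma = config.immigration_phi, config.immigration_sigma
    eps = sigma * rng.standard_normal(BURN_IN + n)
    x = 0.0
    path = np.empty(BURN_IN + n)
    for i in range(BURN_IN + n):
        x = phi * x + eps[i]
        path[i] = x
    logs = math.log(level) + path[BURN_IN:]
    years = np.arange(config.start_year, config.start_year + n)
    return pd.Series(np.exp(logs), index=years, name=f"immigration_{nationality}")
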