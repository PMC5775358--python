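"""Cohort-component projection engine.

A :class:`PopulationState` holds real-valued counts indexed by single-year
age 0..89 plus an open 90+ group, sex (m/f) and nationality (German/foreign).
One projection year applies, in this fixed order:

1. survival and aging (deaths; survivors shift one age up, 89 and 90+ pool),
2. births from start-of-year female counts and age-specific fertility
   (newborns enter age 0 with the mother's nationality, split by the sex
   ratio at birth),
3. immigration, top-down: an aggregate count per nationality distributed
   over age x sex by a share schedule, plus an additive add-on,
4. emigration, bottom-up: per-cell rates applied to the post-immigration
   stock (so emigration grows with the population and can never exceed it),
5. naturalization: per-cell rates move foreign nationals into the German
   group at the same age and sex.

Every flow is recorded in a :class:`FlowLedger`, and the per-nationality
accounting identity P(t+1) = P(t) - deaths + births + immigrants - emigrants
+/- naturalizations holds to floating-point exactness by construction.

Counts stay real-valued throughout: the projection is rate-based and
integerization would only add unmodeled noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "AGES",
    "N_AGES",
    "OPEN_AGE",
    "SEXES",
    "NATIONALITIES",
    "PopulationState",
    "FlowLedger",
    "MigrationSpec",
    "default_addon_schedule",
    "apply_survival_and_age",
    "compute_births",
    "distribute_immigration",
    "compute_emigration",
    "apply_naturalization",
    "project_year",
]

OPEN_AGE = 90
AGES = np.arange(OPEN_AGE + 1)
N_AGES = AGES.size  # 91: single years 0..89 plus open group 90+
SEXES = ("m", "f")
NATIONALITIES = ("german", "foreign")
SEX_INDEX = {s: i for i, s in enumerate(SEXES)}
NAT_INDEX = {n: i for i, n in enumerate(NATIONALITIES)}

SHARE_TOL = 1e-9


@dataclass
class PopulationState:
    """Counts by age x sex x nationality for one calendar year."""

    year: int
    counts: np.ndarray  # shape (N_AGES, 2 sexes, 2 nationalities)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (N_AGES, 2, 2):
            raise ValueError(
                f"counts must have shape ({N_AGES}, 2, 2), got {self.counts.shape}"
            )
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("counts must be finite")
        if np.any(self.counts < 0):
            a, s, n = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative count at age={a}, sex={SEXES[s]}, nationality={NATIONALITIES[n]}"
            )

    def total(self, nationality: str | None = None) -> float:
        if nationality is None:
            return float(self.counts.sum())
        return float(self.counts[:, :, NAT_INDEX[nationality]].sum())

    def copy(self) -> "PopulationState":
        return PopulationState(self.year, self.counts.copy())


@dataclass
class LedgerEntry:
    """All demographic flows of one projection year."""

    year: int
    births: np.ndarray  # (2 sexes, 2 nationalities)
    deaths: np.ndarray  # (N_AGES, 2, 2)
    immigrants: np.ndarray  # (N_AGES, 2, 2)
    emigrants: np.ndarray  # (N_AGES, 2, 2)
    naturalizations: np.ndarray  # (N_AGES, 2) foreign -> German


class FlowLedger:
    """Per-year record of births, deaths and migratory flows."""

    def __init__(self) -> None:
        self.entries: dict[int, LedgerEntry] = {}

    def add(self, entry: LedgerEntry) -> None:
        self.entries[entry.year] = entry

    def __contains__(self, year: int) -> bool:
        return year in self.entries

    def __getitem__(self, year: int) -> LedgerEntry:
        if year not in self.entries:
            raise KeyError(f"no ledger entry for year {year}")
        return self.entries[year]

    def to_frame(self):
        """Long-format DataFrame: one row per (year, flow, age, sex, nationality)."""
        import pandas as pd

        rows = []
        for year, e in sorted(self.entries.items()):
            for flow, arr in (
                ("deaths", e.deaths),
                ("immigrants", e.immigrants),
                ("emigrants", e.emigrants),
            ):
                for a in range(N_AGES):
                    for si, s in enumerate(SEXES):
                        for ni, nat in enumerate(NATIONALITIES):
                            v = arr[a, si, ni]
                            if v != 0.0:
                                rows.append((year, flow, a, s, nat, v))
            for a in range(N_AGES):
                for si, s in enumerate(SEXES):
                    v = e.naturalizations[a, si]
                    if v != 0.0:
                        rows.append((year, "naturalizations", a, s, "foreign", v))
            for si, s in enumerate(SEXES):
                for ni, nat in enumerate(NATIONALITIES):
                    v = e.births[si, ni]
                    if v != 0.0:
                        rows.append((year, "births", 0, s, nat, v))
        return pd.DataFrame(
            rows, columns=["year", "flow", "age", "sex", "nationality", "count"]
        )


def default_addon_schedule(
    start_year: int = 2016,
    end_year: int = 2025,
    start_value: float = 340_000.0,
) -> dict[int, float]:
    """Additive immigration markup declining linearly to zero.

    The default starts at 340,000 persons in 2016 and reaches zero in 2025.
    """
    span = end_year - start_year
    return {
        y: start_value * (end_year - y) / span for y in range(start_year, end_year + 1)
    }


@dataclass
class MigrationSpec:
    """Migration inputs for a run of projection years.

    immigration_totals : {nationality: {year: count}}
    immigration_shares : {nationality: {year: (N_AGES, 2) age x sex shares}}
        Shares sum to 1 (tolerance 1e-9) per year.
    emigration_rates : {year: (N_AGES, 2, 2) per-cell rates in [0, 1]}
    addon_schedule : {year: additive immigrant count} applied to the foreign
        aggregate; defaults to the linear 340k(2016) -> 0(2025) ramp.
    """

    immigration_totals: Mapping[str, Mapping[int, float]]
    immigration_shares: Mapping[str, Mapping[int, np.ndarray]]
    emigration_rates: Mapping[int, np.ndarray]
    addon_schedule: Mapping[int, float] = field(default_factory=default_addon_schedule)


def _check_rates(rates: np.ndarray, name: str) -> np.ndarray:
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0.0) or np.any(rates > 1.0):
        bad = rates[(rates < 0.0) | (rates > 1.0)].flat[0]
        raise ValueError(f"{name} rate {bad!r} outside [0, 1]")
    return rates


def apply_survival_and_age(
    state: PopulationState, death_rates: np.ndarray
) -> tuple[PopulationState, np.ndarray]:
    """Apply mortality and shift everyone one year of age.

    ``death_rates`` has shape (N_AGES,) or (N_AGES, 2) (per sex); the same
    rates apply to both nationalities, mirroring mortality data that do not
    distinguish Germans from non-Germans.  Survivors of ages 89 and 90+ pool
    in the open group.  Returns the aged state (age 0 empty) and the deaths
    array.
    """
    q = _check_rates(death_rates, "death")
    if q.ndim == 1:
        q = np.repeat(q[:, None], 2, axis=1)
    if q.shape != (N_AGES, 2):
        raise ValueError(f"death rates must have shape ({N_AGES},) or ({N_AGES}, 2)")
    deaths = state.counts * q[:, :, None]
    survivors = state.counts - deaths
    aged = np.zeros_like(state.counts)
    aged[1:OPEN_AGE] = survivors[: OPEN_AGE - 1]
    aged[OPEN_AGE] = survivors[OPEN_AGE - 1] + survivors[OPEN_AGE]
    return PopulationState(state.year + 1, aged), deaths


FERTILE_AGES = np.arange(15, 50)


def compute_births(
    state: PopulationState,
    fertility: Mapping[str, np.ndarray],
    sex_ratio: float = 105.0,
) -> np.ndarray:
    """Births by sex x nationality from start-of-year female exposure.

    ``fertility`` maps nationality to a length-35 rate vector over ages
    15..49 (the mother's nationality determines the newborn's).  The sex
    ratio is male births per 100 female births.
    """
    births = np.zeros((2, 2))
    male_share = sex_ratio / (100.0 + sex_ratio)
    fi = SEX_INDEX["f"]
    for nat, rates in fertility.items():
        rates = np.asarray(rates, dtype=float)
        if rates.shape != (FERTILE_AGES.size,):
            raise ValueError(
                f"fertility for {nat!r} must cover ages 15..49 "
                f"({FERTILE_AGES.size} values), got shape {rates.shape}"
            )
        if np.any(rates < 0.0):
            raise ValueError(f"negative fertility rate for {nat!r}")
        women = state.counts[FERTILE_AGES, fi, NAT_INDEX[nat]]
        total = float(women @ rates)
        births[SEX_INDEX["m"], NAT_INDEX[nat]] = total * male_share
        births[fi, NAT_INDEX[nat]] = total * (1.0 - male_share)
    return births


def distribute_immigration(
    total: float, shares: np.ndarray, addon: float = 0.0
) -> np.ndarray:
    """Distribute an aggregate immigration count over age x sex (top-down).

    ``shares`` has shape (N_AGES, 2) and must sum to 1 within 1e-9; the
    output sums to ``total + addon`` exactly (shares are renormalized by
    their float sum before multiplying).
    """
    if total < 0.0 or addon < 0.0:
        raise ValueError("immigration total and add-on must be non-negative")
    shares = np.asarray(shares, dtype=float)
    if shares.shape != (N_AGES, 2):
        raise ValueError(f"shares must have shape ({N_AGES}, 2)")
    if np.any(shares < 0.0):
        raise ValueError("immigration shares must be non-negative")
    s = shares.sum()
    if abs(s - 1.0) > SHARE_TOL:
        raise ValueError(f"immigration shares sum to {s!r}, expected 1")
    return (total + addon) * (shares / s)


def compute_emigration(
    state: PopulationState, emigration_rates: np.ndarray
) -> np.ndarray:
    """Emigrants per cell: counts times rates (bottom-up).

    Rates outside [0, 1] raise; emigrants can therefore never exceed the
    population in any cell.
    """
    rates = _check_rates(emigration_rates, "emigration")
    if rates.shape != state.counts.shape:
        raise ValueError(
            f"emigration rates must have shape {state.counts.shape}, got {rates.shape}"
        )
    return state.counts * rates


def apply_naturalization(
    state: PopulationState, naturalization_rates: np.ndarray
) -> tuple[PopulationState, np.ndarray]:
    """Move foreign nationals into the German group at the same age and sex.

    ``naturalization_rates`` has shape (N_AGES, 2) and applies to the foreign
    population only; the total population is unchanged.
    """
    rates = _check_rates(naturalization_rates, "naturalization")
    if rates.shape != (N_AGES, 2):
        raise ValueError(f"naturalization rates must have shape ({N_AGES}, 2)")
    gi, fi = NAT_INDEX["german"], NAT_INDEX["foreign"]
    moved = state.counts[:, :, fi] * rates
    counts = state.counts.copy()
    counts[:, :, fi] -= moved
    counts[:, :, gi] += moved
    return PopulationState(state.year, counts), moved


def project_year(
    state: PopulationState,
    death_rates: np.ndarray,
    fertility: Mapping[str, np.ndarray],
    migration: MigrationSpec,
    naturalization_rates: np.ndarray | None = None,
    sex_ratio: float = 105.0,
) -> tuple[PopulationState, LedgerEntry]:
    """Advance the population one calendar year and ledger every flow.

    Event order: survival + aging, births, immigration, emigration,
    naturalization.  Newborns and arrival-year immigrants face no mortality
    in their first partial year; emigration applies to the post-immigration
    stock.
    """
    year = state.year
    next_state, deaths = apply_survival_and_age(state, death_rates)
    births = compute_births(state, fertility, sex_ratio=sex_ratio)
    counts = next_state.counts
    counts[0] += births

    immigrants = np.zeros_like(counts)
    addon = float(migration.addon_schedule.get(year, 0.0))
    for nat in NATIONALITIES:
        totals = migration.immigration_totals.get(nat, {})
        if year not in totals:
            continue
        shares = migration.immigration_shares[nat][year]
        cell = distribute_immigration(
            float(totals[year]), shares, addon=addon if nat == "foreign" else 0.0
        )
        immigrants[:, :, NAT_INDEX[nat]] = cell
    counts += immigrants

    interim = PopulationState(year + 1, counts)
    emi_rates = migration.emigration_rates.get(year)
    if emi_rates is None:
        emigrants = np.zeros_like(counts)
    else:
        emigrants = compute_emigration(interim, emi_rates)
    counts = interim.counts - emigrants

    interim = PopulationState(year + 1, counts)
    if naturalization_rates is None:
        final, naturalizations = interim, np.zeros((N_AGES, 2))
    else:
        final, naturalizations = apply_naturalization(interim, naturalization_rates)
    entry = LedgerEntry(
        year=year,
        births=births,
        deaths=deaths,
        immigrants=immigrants,
        emigrants=emigrants,
        naturalizations=naturalizations,
    )
    return final, entry
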