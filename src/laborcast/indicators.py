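"""Summary indicators: TFR, period life expectancy, median age, working-age
population, net migration.

The life table is a standard period table with radix 1 and mid-interval
deaths (a = 0.5) below the open age.  The open interval is closed with the
constant-hazard conversion m = q / (1 - q/2) and L_open = l_open / m, so a
zero death probability at the open age makes the table impossible to close
and raises an error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort_engine import (
    FlowLedger,
    NAT_INDEX,
    OPEN_AGE,
    PopulationState,
    SEX_INDEX,
)

__all__ = [
    "LifeTable",
    "total_fertility_rate",
    "life_expectancy",
    "build_life_table",
    "median_age",
    "working_age",
    "net_migration",
]

N_FERTILE = 35  # single-year ages 15..49


def total_fertility_rate(fertility_row: np.ndarray) -> float:
    """TFR: sum of single-year age-specific fertility rates over ages 15-49."""
    rates = np.asarray(fertility_row, dtype=float)
    if rates.shape != (N_FERTILE,):
        raise ValueError(
            f"fertility row must cover the {N_FERTILE} single-year ages 15..49, "
            f"got shape {rates.shape}"
        )
    if np.any(rates < 0.0):
        raise ValueError("negative fertility rate")
    return float(rates.sum())


@dataclass
class LifeTable:
    q: np.ndarray  # death probabilities, ages 0..open_age
    l: np.ndarray  # survivors, radix 1
    L: np.ndarray  # person-years lived per age interval
    e0: float
    open_age: int


def build_life_table(q: np.ndarray, open_age: int = OPEN_AGE) -> LifeTable:
    q = np.asarray(q, dtype=float)
    if q.shape != (open_age + 1,):
        raise ValueError(f"need {open_age + 1} death probabilities, got {q.shape}")
    if np.any(q < 0.0) or np.any(q > 1.0):
        raise ValueError("death probabilities must lie in [0, 1]")
    if q[-1] == 0.0:
        raise ValueError("death probability at the open age is 0; table cannot close")
    l = np.empty(open_age + 1)
    l[0] = 1.0
    for a in range(open_age):
        l[a + 1] = l[a] * (1.0 - q[a])
    d = l * q
    L = np.empty_like(l)
    L[:-1] = l[:-1] - 0.5 * d[:-1]
    m_open = q[-1] / (1.0 - q[-1] / 2.0)
    L[-1] = l[-1] / m_open
    return LifeTable(q=q, l=l, L=L, e0=float(L.sum()), open_age=open_age)


def life_expectancy(q: np.ndarray, open_age: int = OPEN_AGE) -> float:
    """Period life expectancy at birth from per-age death probabilities."""
    return build_life_table(q, open_age=open_age).e0


def median_age(
    state: PopulationState,
    sex: str | None = None,
    nationality: str | None = None,
) -> float:
    """Age at which the cumulative count reaches half the total.

    Counts are assumed uniform within each single-year age class, so the
    median interpolates linearly inside the class in which the half-total
    falls.  If the half-total is reached exactly at a class boundary the
    upper boundary of that class is returned.
    """
    counts = state.counts
    if sex is not None:
        counts = counts[:, [SEX_INDEX[sex]], :]
    if nationality is not None:
        counts = counts[:, :, [NAT_INDEX[nationality]]]
    by_age = counts.sum(axis=(1, 2))
    total = by_age.sum()
    if total <= 0.0:
        raise ValueError("empty population has no median age")
    half = total / 2.0
    cum = np.cumsum(by_age)
    a = int(np.searchsorted(cum, half))
    below = cum[a - 1] if a > 0 else 0.0
    return a + (half - below) / by_age[a]


def working_age(state: PopulationState, lower: int, upper: int) -> float:
    """Population with lower <= age <= upper (upper may be the open group)."""
    if not (0 <= lower <= upper <= OPEN_AGE):
        raise ValueError(f"age bounds ({lower}, {upper}) outside 0..{OPEN_AGE}")
    return float(state.counts[lower : upper + 1].sum())


def net_migration(ledger: FlowLedger, year: int, nationality: str) -> float:
    """Immigrants minus emigrants for one nationality in one ledgered year."""
    entry = ledger[year]
    ni = NAT_INDEX[nationality]
    return float(entry.immigrants[:, :, ni].sum() - entry.emigrants[:, :, ni].sum())
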