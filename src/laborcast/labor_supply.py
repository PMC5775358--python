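"""Labor force participation: logit regressions and the potential labor force.

For each demographic group j (sex x nationality x age band) the observed
participation rate a_jt in (0, 1) is transformed to its logit and regressed
on covariates Z_t and a labor-market indicator U_t:

    logit(a_jt) = b0 + b1' Z_t + c U_t + error.

Estimation is by weighted least squares because proportions (and their
logits) are heteroscedastic; the default weight a_t (1 - a_t) is the inverse
of the approximate variance of the logit of a proportion up to the unknown
sample-size factor.  Uniform weights reproduce OLS.

Substituting a full-employment value U^v for the actual indicator yields the
*potential* participation rate — participation under boom labor-market
conditions, which implicitly includes the hidden labor force.  The logit
codomain keeps every fitted, potential and forecast rate strictly inside
(0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort_engine import NAT_INDEX, PopulationState, SEX_INDEX

__all__ = [
    "LFPRModel",
    "AgeBand",
    "fit_lfpr_model",
    "potential_lfpr",
    "extrapolate_covariates",
    "labor_force",
    "default_age_bands",
]


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def _expit(z: np.ndarray) -> np.ndarray:
    out = 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=float)))
    # the logit codomain is the open unit interval; keep it open even where
    # the float saturates
    return np.clip(out, np.nextafter(0.0, 1.0), np.nextafter(1.0, 0.0))


@dataclass
class LFPRModel:
    """Fitted logit participation equation for one demographic group."""

    group: tuple  # (sex, nationality, band-label)
    b0: float
    b1: np.ndarray
    c: float
    covariate_names: tuple[str, ...]
    indicator_name: str
    weights_kind: str
    u_full: float
    resid_var: float
    residuals: np.ndarray
    fitted_logits: np.ndarray
    se: np.ndarray = field(default_factory=lambda: np.zeros(0))  # (b0, b1..., c)

    @property
    def coef(self) -> np.ndarray:
        return np.concatenate([[self.b0], self.b1, [self.c]])


def fit_lfpr_model(
    lfpr: Sequence[float],
    covariates: pd.DataFrame,
    indicator: Sequence[float],
    weights_kind: str = "inverse_logit_variance",
    group: tuple = ("f", "german", "unspecified"),
    u_full: float = 2.0,
) -> LFPRModel:
    """Weighted least squares of logit(LFPR) on (1, Z, U).

    ``weights_kind`` is ``"uniform"`` (OLS) or ``"inverse_logit_variance"``
    (weight a(1-a)).  Perfectly collinear regressors raise ``ValueError``
    naming the offending columns.
    """
    a = np.asarray(lfpr, dtype=float)
    if np.any(a <= 0.0) or np.any(a >= 1.0):
        raise ValueError("participation rates must lie strictly in (0, 1)")
    covariates = pd.DataFrame(covariates)
    u = np.asarray(indicator, dtype=float)
    if not (len(a) == len(covariates) == len(u)):
        raise ValueError("lfpr, covariates and indicator must be aligned")
    if weights_kind not in ("uniform", "inverse_logit_variance"):
        raise ValueError(f"unknown weights kind {weights_kind!r}")

    y = _logit(a)
    names = tuple(covariates.columns)
    X = np.column_stack([np.ones(len(a)), covariates.to_numpy(dtype=float), u])
    col_labels = ["const", *names, "indicator"]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name a minimal culprit: find a column dependent on the preceding ones
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) <= np.linalg.matrix_rank(X[:, :j]):
                raise ValueError(
                    f"perfect collinearity: column {col_labels[j]!r} is a linear "
                    f"combination of {col_labels[:j]}"
                )
        raise ValueError("perfect collinearity among regressors")

    w = np.ones(len(a)) if weights_kind == "uniform" else a * (1.0 - a)
    res = sm.WLS(y, X, weights=w).fit()
    params = np.asarray(res.params, dtype=float)
    return LFPRModel(
        group=group,
        b0=float(params[0]),
        b1=params[1:-1].copy(),
        c=float(params[-1]),
        covariate_names=names,
        indicator_name="indicator",
        weights_kind=weights_kind,
        u_full=float(u_full),
        resid_var=float(res.mse_resid),
        residuals=np.asarray(res.resid, dtype=float),
        fitted_logits=np.asarray(res.fittedvalues, dtype=float),
        se=np.asarray(res.bse, dtype=float),
    )


def potential_lfpr(
    model: LFPRModel,
    covariates: pd.DataFrame,
    indicator: Sequence[float] | float | None = None,
) -> np.ndarray:
    """Participation under full employment: U is replaced by the model's U^v.

    ``indicator`` is accepted for signature symmetry but ignored in favor of
    ``model.u_full`` (a scalar or per-year sequence set on the model); the
    potential rate is inverse-logit(b0 + b1'Z_t + c U^v).
    """
    covariates = pd.DataFrame(covariates)
    missing = [c for c in model.covariate_names if c not in covariates.columns]
    if missing:
        raise ValueError(f"missing covariates: {missing}")
    Z = covariates[list(model.covariate_names)].to_numpy(dtype=float)
    u_full = np.broadcast_to(
        np.asarray(model.u_full, dtype=float), (len(covariates),)
    )
    z = model.b0 + Z @ model.b1 + model.c * u_full
    return _expit(z)


def extrapolate_covariates(
    series: Sequence[float],
    horizon: int,
    bounds: tuple[float, float] | None = None,
) -> tuple[np.ndarray, bool]:
    """Extend an exogenous covariate by a linear time trend.

    Returns ``(extended, clamped)`` where ``extended`` contains the observed
    values followed by ``horizon`` trend continuations, and ``clamped`` flags
    whether any continuation hit the declared bounds (e.g. (0, 100) for a
    percentage) and was clipped there.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 5:
        raise ValueError(f"need at least 5 observations to fit a trend, got {n}")
    t = np.arange(n, dtype=float)
    slope, intercept = np.polyfit(t, x, 1)
    future = intercept + slope * np.arange(n, n + horizon, dtype=float)
    clamped = False
    if bounds is not None:
        lo, hi = bounds
        out_of_bounds = (future < lo) | (future > hi)
        if np.any(out_of_bounds):
            clamped = True
            future = np.clip(future, lo, hi)
    return np.concatenate([x, future]), clamped


@dataclass(frozen=True)
class AgeBand:
    lower: int
    upper: int  # inclusive

    @property
    def label(self) -> str:
        return f"{self.lower}-{self.upper}"

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.lower, self.upper + 1)


def default_age_bands(extended: bool = False) -> tuple[AgeBand, ...]:
    """Quinquennial bands 15-19 .. 60-64; optionally 65-69 and 70-74."""
    bands = [AgeBand(lo, lo + 4) for lo in range(15, 65, 5)]
    if extended:
        bands += [AgeBand(65, 69), AgeBand(70, 74)]
    return tuple(bands)


def labor_force(
    potential_rates: Mapping[tuple, float],
    population: PopulationState,
    group_map: Sequence[AgeBand] | None = None,
) -> tuple[float, dict[tuple, float], dict[tuple, float]]:
    """Combine per-group potential rates with the population.

    ``potential_rates`` maps (sex, nationality, band-label) to a rate for the
    state's year.  Every population cell within the covered age range must
    map to exactly one group.  Returns (total labor force, per-group labor
    force, per-group shares of the total).
    """
    bands = tuple(group_map) if group_map is not None else default_age_bands()
    seen: set[int] = set()
    for b in bands:
        overlap = seen.intersection(b.ages.tolist())
        if overlap:
            raise ValueError(f"age {min(overlap)} mapped to more than one band")
        seen.update(b.ages.tolist())

    by_group: dict[tuple, float] = {}
    for band in bands:
        for sex, si in SEX_INDEX.items():
            for nat, ni in NAT_INDEX.items():
                key = (sex, nat, band.label)
                if key not in potential_rates:
                    raise ValueError(f"no participation rate for group {key}")
                pop = float(population.counts[band.ages, si, ni].sum())
                by_group[key] = float(potential_rates[key]) * pop
    total = sum(by_group.values())
    shares = {
        k: (v / total if total > 0.0 else 0.0) for k, v in by_group.items()
    }
    return total, by_group, shares
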