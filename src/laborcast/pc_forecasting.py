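"""Forecasting models for principal-component score series.

Two model families are supported:

* ARMA(p, q) with p, q <= 2.  Scores are centered by construction, so the
  default has no intercept (an intercept is available by option).  Pure AR
  orders are estimated by conditional least squares on the lagged regression
  — the estimator whose log-likelihood and information criteria reproduce
  standard least-squares regression output on an adjusted sample — while
  orders with an MA part use exact Gaussian maximum likelihood via
  statsmodels.

* A logistic saturation trend for strongly trending components whose linear
  extrapolation would leave a plausible range.  The fitted path is

      pc_t = SN' / (1 + exp(c1 + c2 * t)) - d,

  so that pc_t + d lies strictly inside (0, SN'): the component saturates at
  ``SN' - d`` (or ``-d``) instead of trending without bound.  SN', d, c1 and
  c2 are estimated jointly by least squares with a documented multi-start
  scheme.  Residuals on the transformed scale
  ``rho_t = ln(SN'/(pc_t + d) - 1) - (c1 + c2 t)`` are stored for stochastic
  simulation, which keeps every simulated path inside the saturation bounds.

Candidate ARMA orders are compared on per-observation information criteria

    aic = (-2 loglik + 2k) / n
    sc  = (-2 loglik + k ln n) / n
    hq  = (-2 loglik + 2k ln ln n) / n

with k the number of estimated mean parameters and n the model's effective
sample, and the Schwarz criterion decides by default (ties go to the more
parsimonious model, then to the lower AR order).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "PCModel",
    "CriterionTriple",
    "FitError",
    "BoundaryFitError",
    "DEFAULT_GRID",
    "fit_arma",
    "information_criteria",
    "select_model",
    "fit_logistic_trend",
    "forecast_pc",
    "save_models",
    "load_models",
]

#: All orders from AR(1) / MA(1) up to ARMA(2,2).
DEFAULT_GRID: tuple[tuple[int, int], ...] = tuple(
    (p, q) for p in range(3) for q in range(3) if (p, q) != (0, 0)
)

_LN_2PI = math.log(2.0 * math.pi)


class FitError(RuntimeError):
    """Estimation failed (non-convergence, degenerate input)."""


class BoundaryFitError(FitError):
    """The logistic saturation level ran to its boundary (no curvature)."""


@dataclass
class CriterionTriple:
    aic: float
    sc: float
    hq: float


@dataclass
class PCModel:
    """A fitted forecasting model for one component score series."""

    kind: str  # "arma" | "logistic_trend"
    n_obs: int
    loglik: float
    resid_var: float
    residuals: np.ndarray
    # --- arma fields ---
    order: tuple[int, int] = (0, 0)
    intercept: float = 0.0
    has_intercept: bool = False
    ar: np.ndarray = field(default_factory=lambda: np.zeros(0))
    ma: np.ndarray = field(default_factory=lambda: np.zeros(0))
    last_values: np.ndarray = field(default_factory=lambda: np.zeros(0))
    last_resids: np.ndarray = field(default_factory=lambda: np.zeros(0))
    se: np.ndarray = field(default_factory=lambda: np.zeros(0))  # coefficient SEs
    # --- logistic fields ---
    sn: float = float("nan")
    d: float = float("nan")
    c1: float = float("nan")
    c2: float = float("nan")
    t_last: int = 0
    # series kept for residual-bootstrap replication
    series: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def n_params(self) -> int:
        if self.kind == "logistic_trend":
            return 4
        p, q = self.order
        return p + q + (1 if self.has_intercept else 0)

    def criteria(self) -> CriterionTriple:
        return information_criteria(self.loglik, self.n_params, self.n_obs)

    def to_dict(self) -> dict:
        out = asdict(self)
        for key, val in out.items():
            if isinstance(val, np.ndarray):
                out[key] = val.tolist()
            elif isinstance(val, np.generic):
                out[key] = val.item()
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "PCModel":
        d = dict(d)
        for key in ("residuals", "ar", "ma", "last_values", "last_resids", "se", "series"):
            d[key] = np.asarray(d[key], dtype=float)
        d["order"] = tuple(d["order"])
        return cls(**d)


def _gaussian_loglik(ssr: float, n: int) -> float:
    """Concentrated Gaussian log-likelihood with sigma^2 = SSR / n."""
    if ssr <= 0.0:
        # perfect fit: likelihood unbounded; report +inf consistently
        return float("inf")
    return -0.5 * n * (_LN_2PI + math.log(ssr / n) + 1.0)


def fit_arma(
    series: Sequence[float],
    p: int,
    q: int,
    intercept: bool = False,
) -> PCModel:
    """Fit an ARMA(p, q) model with p, q in {0, 1, 2}.

    Pure AR orders use conditional least squares (effective sample n - p);
    orders with q > 0 use exact Gaussian ML via statsmodels.  A constant
    series or too-short sample raises :class:`FitError`.
    """
    x = np.asarray(series, dtype=float)
    if not (0 <= p <= 2 and 0 <= q <= 2):
        raise ValueError(f"orders must lie in 0..2, got ({p}, {q})")
    if p == 0 and q == 0 and not intercept:
        raise ValueError("ARMA(0,0) without intercept has nothing to estimate")
    n = x.size
    if n < p + q + 5:
        raise FitError(f"series length {n} below minimum {p + q + 5} for ARMA({p},{q})")
    if np.std(x) == 0.0:
        raise FitError("constant series has zero variance")

    if q == 0:
        # conditional least squares: regress x_t on its p lags
        y = x[p:]
        cols = [x[p - i : n - i] for i in range(1, p + 1)]
        if intercept:
            cols.append(np.ones(n - p))
        if cols:
            X = np.column_stack(cols)
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
        else:  # intercept-only
            beta = np.array([y.mean()])
            resid = y - beta[0]
        ar = beta[:p]
        const = float(beta[p]) if intercept else 0.0
        m = n - p
        ssr = float(resid @ resid)
        loglik = _gaussian_loglik(ssr, m)
        k_mean = p + (1 if intercept else 0)
        if k_mean and m > k_mean:
            sigma2_ols = ssr / (m - k_mean)
            se = np.sqrt(sigma2_ols * np.diag(np.linalg.inv(X.T @ X)))
        else:
            se = np.zeros(k_mean)
        return PCModel(
            kind="arma",
            n_obs=m,
            loglik=loglik,
            resid_var=ssr / m,
            residuals=resid,
            order=(p, q),
            intercept=const,
            has_intercept=intercept,
            ar=np.asarray(ar, dtype=float),
            ma=np.zeros(0),
            last_values=x[n - max(p, 1) :].copy() if p else np.zeros(0),
            last_resids=np.zeros(0),
            se=se,
            series=x.copy(),
        )

    import warnings

    from statsmodels.tsa.arima.model import ARIMA

    try:
        with warnings.catch_warnings():
            # convergence problems surface as FitError below, not as warnings
            warnings.simplefilter("ignore")
            res = ARIMA(
                x, order=(p, 0, q), trend="c" if intercept else "n"
            ).fit(method_kwargs={"disp": 0})
    except Exception as exc:  # statsmodels raises a zoo of error types
        raise FitError(f"ARMA({p},{q}) estimation failed: {exc}") from exc
    retvals = getattr(res, "mle_retvals", None) or {}
    if retvals.get("converged") is False:
        raise FitError(
            f"ARMA({p},{q}) optimizer did not converge: {retvals}"
        )
    resid = np.asarray(res.resid, dtype=float)
    const = 0.0
    if intercept:
        # statsmodels parameterizes trend="c" as the process mean times (1 - sum(ar))
        mu = float(res.params[0])
        const = mu * (1.0 - float(np.sum(res.arparams)))
    return PCModel(
        kind="arma",
        n_obs=n,
        loglik=float(res.llf),
        resid_var=float(res.params[-1]),
        residuals=resid,
        order=(p, q),
        intercept=const,
        has_intercept=intercept,
        ar=np.asarray(res.arparams, dtype=float),
        ma=np.asarray(res.maparams, dtype=float),
        last_values=x[n - p :].copy() if p else np.zeros(0),
        last_resids=resid[n - q :].copy(),
        se=np.asarray(res.bse[: p + q + (1 if intercept else 0)], dtype=float),
        series=x.copy(),
    )


def information_criteria(loglik: float, k: int, n: int) -> CriterionTriple:
    """Per-observation Akaike, Schwarz and Hannan-Quinn criteria.

    Requires n >= 3 so that ln(ln n) is positive.
    """
    if n < 3:
        raise ValueError(f"sample size {n} too small for information criteria")
    aic = (-2.0 * loglik + 2.0 * k) / n
    sc = (-2.0 * loglik + k * math.log(n)) / n
    hq = (-2.0 * loglik + 2.0 * k * math.log(math.log(n))) / n
    return CriterionTriple(aic=aic, sc=sc, hq=hq)


def select_model(
    series: Sequence[float],
    grid: Iterable[tuple[int, int]] = DEFAULT_GRID,
    criterion: str = "sc",
    intercept: bool = False,
) -> PCModel:
    """Fit every order in the grid and return the criterion-minimal model.

    Ties break toward fewer parameters, then toward the lower AR order.
    Individual fit failures are tolerated; if every fit fails, the collected
    errors are raised.
    """
    if criterion not in ("sc", "hq"):
        raise ValueError("criterion must be 'sc' or 'hq'")
    grid = list(grid)
    if not grid:
        raise ValueError("empty model grid")
    fits: list[tuple[float, int, int, PCModel]] = []
    errors: list[str] = []
    for p, q in grid:
        try:
            model = fit_arma(series, p, q, intercept=intercept)
        except (FitError, ValueError) as exc:
            errors.append(f"ARMA({p},{q}): {exc}")
            continue
        crit = getattr(model.criteria(), criterion)
        fits.append((crit, model.n_params, p, model))
    if not fits:
        raise FitError("all grid fits failed: " + "; ".join(errors))
    fits.sort(key=lambda t: (t[0], t[1], t[2]))
    return fits[0][3]


def _logistic_path(sn: float, d: float, c1: float, c2: float, t: np.ndarray) -> np.ndarray:
    return sn / (1.0 + np.exp(c1 + c2 * t)) - d


def fit_logistic_trend(series: Sequence[float]) -> PCModel:
    """Fit the four-parameter logistic saturation trend by least squares.

    The observed series must be non-constant and at least 8 points long.  The
    parameterization d = -min(pc) + exp(alpha), SN' = max(pc) + d + exp(beta)
    keeps 0 < pc_t + d < SN' for every observed t during optimization.  Five
    documented starting points (margin fractions of the data range) guard
    against the multimodality of the fit; the lowest-SSR solution wins.

    A fit whose saturation margin runs to a value far beyond the data range
    (a strictly linear series has no curvature to pin SN' down) raises
    :class:`BoundaryFitError`.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 8:
        raise FitError(f"series length {n} below minimum 8 for the logistic trend")
    mn, mx = float(np.min(x)), float(np.max(x))
    rng = mx - mn
    if rng == 0.0:
        raise FitError("constant series has zero variance")
    t = np.arange(1, n + 1, dtype=float)

    def unpack(theta):
        alpha, beta, c1, c2 = theta
        d = -mn + math.exp(alpha)
        sn = mx + d + math.exp(beta)
        return sn, d, c1, c2

    def resid_fn(theta):
        sn, d, c1, c2 = unpack(theta)
        return _logistic_path(sn, d, c1, c2, t) - x

    # documented margin-fraction starting points (lower margin, upper margin)
    start_fracs = [(0.05, 0.05), (0.25, 0.25), (1.0, 1.0), (0.05, 1.0), (1.0, 0.05)]
    best = None
    for lo_f, hi_f in start_fracs:
        alpha0 = math.log(lo_f * rng)
        beta0 = math.log(hi_f * rng)
        d0 = -mn + lo_f * rng
        sn0 = mx + d0 + hi_f * rng
        # linearize: z = ln(SN'/(pc+d) - 1) = c1 + c2 t
        z = np.log(sn0 / (x + d0) - 1.0)
        A = np.column_stack([np.ones(n), t])
        (c10, c20), *_ = np.linalg.lstsq(A, z, rcond=None)
        try:
            sol = least_squares(
                resid_fn,
                x0=np.array([alpha0, beta0, c10, c20]),
                method="lm",
                max_nfev=20000,
            )
        except Exception:
            continue
        ssr = float(sol.fun @ sol.fun)
        if best is None or ssr < best[0]:
            best = (ssr, sol)
    if best is None:
        raise FitError("logistic trend estimation failed from every starting point")
    ssr, sol = best
    sn, d, c1, c2 = unpack(sol.x)
    # boundary diagnosis: saturation margin vastly exceeding the data range
    # means the curvature is unidentified (e.g. a strictly linear series)
    if sn - rng - (d - (-mn)) > 100.0 * rng or not np.all(np.isfinite([sn, d, c1, c2])):
        raise BoundaryFitError(
            f"saturation level SN'={sn:.6g} ran to its boundary relative to the "
            f"data range {rng:.6g}; the series shows no saturation curvature"
        )
    fitted = _logistic_path(sn, d, c1, c2, t)
    resid_pc = x - fitted
    # delta-method standard errors for (SN', c1, c2, d) from the Jacobian
    ey = np.exp(c1 + c2 * t)
    J = np.column_stack([1.0 / (1.0 + ey), -sn * ey / (1.0 + ey) ** 2,
                         -sn * t * ey / (1.0 + ey) ** 2, -np.ones(n)])
    se = np.zeros(4)
    if n > 4:
        try:
            cov = float(resid_pc @ resid_pc) / (n - 4) * np.linalg.inv(J.T @ J)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:
            pass
    # transformed-scale residuals drive bootstrap innovations (bounded paths);
    # points numerically on either bound get floored arguments so the
    # residual stays finite
    arg = np.maximum(sn / np.maximum(x + d, 1e-300) - 1.0, 1e-300)
    rho = np.log(arg) - (c1 + c2 * t)
    return PCModel(
        kind="logistic_trend",
        n_obs=n,
        loglik=_gaussian_loglik(float(resid_pc @ resid_pc), n),
        resid_var=float(resid_pc @ resid_pc) / n,
        residuals=rho,
        sn=sn,
        d=d,
        c1=c1,
        c2=c2,
        t_last=n,
        se=se,
        series=x.copy(),
    )


def forecast_pc(
    model: PCModel,
    horizon: int,
    innovations: Sequence[float] | None = None,
) -> np.ndarray:
    """Forecast a component series.

    Without innovations, the deterministic conditional-mean path.  With an
    innovation sequence of length ``horizon``, the stochastic path obtained by
    feeding the innovations through the model recursion — for the logistic
    trend they enter on the transformed scale, so every stochastic path stays
    strictly inside (-d, SN' - d).
    """
    if horizon <= 0:
        raise ValueError(f"horizon must be positive, got {horizon}")
    eps = np.zeros(horizon)
    if innovations is not None:
        eps = np.asarray(innovations, dtype=float)
        if eps.size != horizon:
            raise ValueError("innovations length must equal horizon")

    if model.kind == "logistic_trend":
        t = model.t_last + np.arange(1, horizon + 1, dtype=float)
        y = model.c1 + model.c2 * t
        if innovations is not None:
            y = y + eps
        path = model.sn / (1.0 + np.exp(y)) - model.d
        # keep the open bounds strict even where exp(y) under/overflows
        lo = np.nextafter(-model.d, np.inf)
        hi = np.nextafter(model.sn - model.d, -np.inf)
        return np.clip(path, lo, hi)

    p, q = model.order
    hist = list(model.last_values[-p:]) if p else []
    eps_hist = list(model.last_resids[-q:]) if q else []
    out = np.empty(horizon)
    for h in range(horizon):
        val = model.intercept + eps[h]
        for i in range(1, p + 1):
            val += model.ar[i - 1] * hist[-i]
        for j in range(1, q + 1):
            past = eps_hist[-j] if j <= len(eps_hist) else 0.0
            val += model.ma[j - 1] * past
        out[h] = val
        if p:
            hist.append(val)
        eps_hist.append(eps[h])
    return out


def save_models(models: dict[str, PCModel], path) -> None:
    """Serialize fitted models to a plain-text JSON file for exact reload."""
    payload = {name: m.to_dict() for name, m in models.items()}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)


def load_models(path) -> dict[str, PCModel]:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return {name: PCModel.from_dict(d) for name, d in payload.items()}
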