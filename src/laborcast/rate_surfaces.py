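"""Age-specific rate surfaces and their principal-component decomposition.

A *rate surface* is a years x ages panel of one demographic rate (age-specific
fertility, death, emigration or naturalization rates, or immigration
distribution shares) for one sex x nationality stratum.  Each surface carries
a transform that maps rates into an unbounded modeling domain:

``log``
    ``z = ln(r)`` for fertility rates, which must stay positive.
``log_survival``
    ``z = ln(1 - q)`` for death rates: the log survival probability.
``logit``
    ``z = ln(r / (1 - r))`` for rates bounded in (0, 1).

In the transformed domain the panel is decomposed by singular values into
orthogonal principal components, Lee-Carter style but retaining more than one
component where the age profiles are less collinear.  The number of retained
components follows the Kaiser-Guttmann rule (eigenvalue >= 1 in the
standardized metric), with a floor of one so the pipeline always has a
forecastable component.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "COMPONENT_LABELS",
    "TRANSFORM_KINDS",
    "DomainError",
    "RateSurface",
    "PCDecomposition",
    "transform",
    "inverse_transform",
    "fit_pca",
    "select_components",
    "reconstruct_rates",
]

COMPONENT_LABELS = (
    "fertility",
    "mortality",
    "emigration",
    "naturalization",
    "immigration_shares",
)

TRANSFORM_KINDS = ("log", "log_survival", "logit")

#: Tolerance for the row-sum invariant of immigration-share surfaces.
SHARE_SUM_TOL = 1e-9


class DomainError(ValueError):
    """A rate lies outside the domain of its declared transform."""


@dataclass
class RateSurface:
    """One demographic rate panel for one stratum.

    Parameters
    ----------
    years : sequence of int
        Strictly increasing, consecutive calendar years (rows).
    ages : sequence of int
        Integer single-year ages (columns); the last may represent an open
        interval such as 90+.
    values : ndarray, shape (n_years, n_ages)
        Non-negative rates.
    component_label : str
        One of :data:`COMPONENT_LABELS`.
    stratum : tuple
        ``(sex, nationality)`` labels, e.g. ``("f", "german")``.
    transform_kind : str
        One of :data:`TRANSFORM_KINDS`.
    """

    years: np.ndarray
    ages: np.ndarray
    values: np.ndarray
    component_label: str
    stratum: tuple = ("f", "german")
    transform_kind: str = "log"

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.ages = np.asarray(self.ages, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.component_label not in COMPONENT_LABELS:
            raise ValueError(f"unknown component label {self.component_label!r}")
        if self.transform_kind not in TRANSFORM_KINDS:
            raise ValueError(f"unknown transform {self.transform_kind!r}")
        if self.values.shape != (self.years.size, self.ages.size):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{self.years.size} years x {self.ages.size} ages"
            )
        if self.years.size and not np.all(np.diff(self.years) == 1):
            raise ValueError("years must be strictly increasing and consecutive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if np.any(self.values < 0):
            bad = np.argwhere(self.values < 0)[0]
            raise DomainError(
                f"negative rate at year={self.years[bad[0]]}, age={self.ages[bad[1]]}"
            )
        if self.component_label == "immigration_shares":
            row_sums = self.values.sum(axis=1)
            if np.any(np.abs(row_sums - 1.0) > SHARE_SUM_TOL):
                bad = int(np.argmax(np.abs(row_sums - 1.0)))
                raise ValueError(
                    f"immigration shares for year {self.years[bad]} sum to "
                    f"{row_sums[bad]:.12f}, expected 1"
                )

    @property
    def n_years(self) -> int:
        return int(self.years.size)

    def row(self, year: int) -> np.ndarray:
        """Return the rate vector for one calendar year."""
        idx = np.flatnonzero(self.years == year)
        if idx.size == 0:
            raise KeyError(f"year {year} not on surface")
        return self.values[idx[0]]


@dataclass
class PCDecomposition:
    """SVD decomposition of one transformed rate surface.

    ``means + scales * (scores @ loadings.T)`` reproduces the transformed
    surface exactly when all components are kept.  ``loadings`` is
    column-orthonormal; ``eigenvalues[i] = s_i**2 / (n_years - 1)`` with
    ``s_i`` the singular values of the centered (optionally standardized)
    matrix.  Each loading vector is sign-flipped so its largest-magnitude
    entry is positive.
    """

    means: np.ndarray
    scales: np.ndarray
    loadings: np.ndarray
    scores: np.ndarray
    eigenvalues: np.ndarray
    n_retained: int
    # surface metadata carried through so rate surfaces can be rebuilt
    ages: np.ndarray = field(default=None)
    component_label: str = "fertility"
    stratum: tuple = ("f", "german")
    transform_kind: str = "log"

    @property
    def n_components(self) -> int:
        return int(self.loadings.shape[1])

    def retained_scores(self) -> np.ndarray:
        return self.scores[:, : self.n_retained]


def _domain_check(values: np.ndarray, kind: str, years, ages) -> None:
    if kind == "log":
        bad = values <= 0.0
        msg = "rate must be > 0 under log transform"
    elif kind == "log_survival":
        bad = (values < 0.0) | (values >= 1.0)
        msg = "death rate must lie in [0, 1) under log-survival transform"
    else:  # logit
        bad = (values <= 0.0) | (values >= 1.0)
        msg = "rate must lie strictly in (0, 1) under logit transform"
    if np.any(bad):
        i, j = np.argwhere(bad)[0]
        raise DomainError(
            f"{msg}: value {values[i, j]!r} at year={np.asarray(years)[i]}, "
            f"age={np.asarray(ages)[j]}"
        )


def transform(surface: RateSurface) -> np.ndarray:
    """Map a rate surface into its unbounded modeling domain.

    Raises :class:`DomainError` naming the offending cell if any rate lies
    outside the declared transform's domain.
    """
    v = surface.values
    _domain_check(v, surface.transform_kind, surface.years, surface.ages)
    if surface.transform_kind == "log":
        return np.log(v)
    if surface.transform_kind == "log_survival":
        return np.log1p(-v)
    return np.log(v / (1.0 - v))


def inverse_transform(z: np.ndarray, kind: str) -> np.ndarray:
    """Map transformed values back to rates.

    ``log`` maps onto (0, inf) and ``logit`` onto (0, 1) for any finite input.
    ``log_survival`` requires z <= 0 (a positive log survival probability
    would be a negative death rate) and raises :class:`DomainError` otherwise.
    """
    z = np.asarray(z, dtype=float)
    if kind == "log":
        return np.exp(z)
    if kind == "logit":
        # expit, stable for large |z|
        out = np.empty_like(z)
        pos = z >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
        ez = np.exp(z[~pos])
        out[~pos] = ez / (1.0 + ez)
        return out
    if kind == "log_survival":
        if np.any(z > 0):
            idx = np.argwhere(z > 0)[0]
            raise DomainError(
                f"log survival probability {z[tuple(idx)]!r} > 0 at index "
                f"{tuple(int(i) for i in idx)}: death rate would be negative"
            )
        return -np.expm1(z)
    raise ValueError(f"unknown transform {kind!r}")


def fit_pca(
    transformed: np.ndarray,
    standardize: bool = True,
    surface: RateSurface | None = None,
) -> PCDecomposition:
    """Principal-component decomposition of a transformed surface.

    Columns are centered and, by default, standardized (the Kaiser-Guttmann
    eigenvalue >= 1 rule is stated in the correlation metric, under which the
    eigenvalues sum to the number of age columns).  Scores are projections of
    the standardized matrix on the loadings; ``eigenvalue_i = s_i**2/(n-1)``.

    Parameters
    ----------
    transformed : ndarray, shape (n_years, n_ages)
        Output of :func:`transform`; no missing cells, at least 3 rows.
    standardize : bool
        Divide each centered column by its sample standard deviation
        (ddof=1).  A constant column then raises ``ValueError``.
    surface : RateSurface, optional
        If given, its metadata (ages, labels, transform) is carried into the
        decomposition so surfaces can be reconstructed later.
    """
    X = np.asarray(transformed, dtype=float)
    if X.ndim != 2:
        raise ValueError("transformed surface must be 2-D")
    n, k = X.shape
    if n < 3:
        raise ValueError(f"need at least 3 years, got {n}")
    if not np.all(np.isfinite(X)):
        raise ValueError("transformed surface has non-finite cells")

    means = X.mean(axis=0)
    if standardize:
        scales = X.std(axis=0, ddof=1)
        if np.any(scales == 0.0):
            j = int(np.argmax(scales == 0.0))
            raise ValueError(f"column {j} is constant; cannot standardize")
    else:
        scales = np.ones(k)
    Z = (X - means) / scales

    _, s, vt = np.linalg.svd(Z, full_matrices=False)
    loadings = vt.T
    eigenvalues = s**2 / (n - 1)

    # sign convention: largest-magnitude entry of each loading vector positive
    flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = Z @ loadings

    meta = {}
    if surface is not None:
        meta = dict(
            ages=surface.ages,
            component_label=surface.component_label,
            stratum=surface.stratum,
            transform_kind=surface.transform_kind,
        )
    return PCDecomposition(
        means=means,
        scales=scales,
        loadings=loadings,
        scores=scores,
        eigenvalues=eigenvalues,
        n_retained=select_components(eigenvalues),
        **meta,
    )


def select_components(eigenvalues: Sequence[float]) -> int:
    """Kaiser-Guttmann retention: count of eigenvalues >= 1, floor of 1.

    Eigenvalues must be sorted in non-increasing order.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    if ev.size == 0:
        raise ValueError("empty eigenvalue sequence")
    if np.any(np.diff(ev) > 1e-10):
        raise ValueError("eigenvalues must be sorted in descending order")
    return max(1, int(np.sum(ev >= 1.0)))


def reconstruct_rates(
    decomp: PCDecomposition,
    score_paths: np.ndarray,
    years: Sequence[int] | None = None,
) -> RateSurface:
    """Rebuild a rate surface from component trajectories.

    ``score_paths`` has one column per retained component, aligned with the
    leading retained loadings.  The inverse transform guarantees valid rates
    for ``log`` and ``logit`` surfaces; a ``log_survival`` surface whose
    reconstruction leaves the negative half-line raises :class:`DomainError`.
    """
    paths = np.atleast_2d(np.asarray(score_paths, dtype=float))
    j = decomp.n_retained
    if paths.shape[1] != j:
        raise ValueError(
            f"score paths have {paths.shape[1]} columns, expected n_retained={j}"
        )
    Z = paths @ decomp.loadings[:, :j].T
    X = decomp.means + decomp.scales * Z
    if decomp.transform_kind == "log_survival":
        # the log-survival transform bounds death rates below 1 but nothing
        # bounds them above 0: stochastic score paths can push the log
        # survival probability of a low-mortality age past 0.  Mortality
        # improvement saturates there, so such cells cap at q = 0; a gross
        # crossing (survival probability beyond e^0.5) signals model
        # breakdown and still aborts.
        overshoot = float(np.max(X, initial=0.0))
        if overshoot > 0.5:
            raise DomainError(
                f"reconstructed log survival probability {overshoot:.6g} > 0: "
                "death rates left their domain by far more than boundary noise"
            )
        X = np.minimum(X, 0.0)
    rates = inverse_transform(X, decomp.transform_kind)
    if decomp.component_label == "immigration_shares":
        # a truncated reconstruction does not preserve the unit row sum of a
        # share surface exactly; renormalize so the distribution invariant holds
        rates = rates / rates.sum(axis=1, keepdims=True)
    if years is None:
        years = np.arange(paths.shape[0])
    return RateSurface(
        years=np.asarray(years, dtype=int),
        ages=decomp.ages if decomp.ages is not None else np.arange(X.shape[1]),
        values=rates,
        component_label=decomp.component_label,
        stratum=decomp.stratum,
        transform_kind=decomp.transform_kind,
    )
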