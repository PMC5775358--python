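"""File formats and run configuration.

The panel dialect is one UTF-8 CSV per (component, sex, nationality): a
``year`` column followed by one column per single-year age, the open group
labelled ``90plus``; comma separated, decimal point, no thousands
separators.  Reads are validated (consecutive years, numeric cells, no
missing ages) with parse errors naming the offending line, and a
write-then-read round trip is value-identical because floats are written in
shortest-repr form.

A run configuration is a hierarchical YAML file; :func:`load_config`
validates the schema before any computation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .cohort_engine import (
    N_AGES,
    NAT_INDEX,
    NATIONALITIES,
    PopulationState,
    SEX_INDEX,
    SEXES,
    default_addon_schedule,
)
from .rate_surfaces import RateSurface

__all__ = [
    "DEFAULT_TRANSFORMS",
    "PanelParseError",
    "RunConfig",
    "read_panel",
    "write_panel",
    "write_population",
    "read_population",
    "scenario_to_dir",
    "scenario_from_dir",
    "load_config",
]

DEFAULT_TRANSFORMS = {
    "fertility": "log",
    "mortality": "log_survival",
    "emigration": "logit",
    "naturalization": "logit",
    "immigration_shares": "logit",
}

OPEN_LABEL = "90plus"


class PanelParseError(ValueError):
    """A panel file violates the dialect; the message names the line."""


def _age_label(age: int) -> str:
    return OPEN_LABEL if age == 90 else str(age)


def _parse_age(label: str, path, lineno: int) -> int:
    if label == OPEN_LABEL:
        return 90
    try:
        return int(label)
    except ValueError:
        raise PanelParseError(
            f"{path}, line {lineno}: age column label {label!r} is not an integer"
        ) from None


def write_panel(surface: RateSurface, path) -> None:
    """Write a rate surface in the panel dialect."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["year", *(_age_label(int(a)) for a in surface.ages)])
        for year, row in zip(surface.years, surface.values):
            writer.writerow([int(year), *(repr(float(v)) for v in row)])


def read_panel(
    path,
    component_label: str,
    stratum: tuple = ("f", "german"),
    transform_kind: str | None = None,
) -> RateSurface:
    """Parse a panel file into a validated :class:`RateSurface`.

    Non-consecutive years, non-numeric cells and malformed headers raise
    :class:`PanelParseError` naming the offending line.
    """
    path = Path(path)
    if transform_kind is None:
        transform_kind = DEFAULT_TRANSFORMS[component_label]
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise PanelParseError(f"{path}, line 1: empty file") from None
        if not header or header[0] != "year":
            raise PanelParseError(f"{path}, line 1: first column must be 'year'")
        ages = [_parse_age(lbl, path, 1) for lbl in header[1:]]
        if not ages:
            raise PanelParseError(f"{path}, line 1: no age columns")
        years, rows = [], []
        for lineno, rec in enumerate(reader, start=2):
            if not rec:
                continue
            if len(rec) != len(header):
                raise PanelParseError(
                    f"{path}, line {lineno}: expected {len(header)} fields, got {len(rec)}"
                )
            try:
                years.append(int(rec[0]))
            except ValueError:
                raise PanelParseError(
                    f"{path}, line {lineno}: year {rec[0]!r} is not an integer"
                ) from None
            try:
                rows.append([float(v) for v in rec[1:]])
            except ValueError:
                bad = next(v for v in rec[1:] if not _is_float(v))
                raise PanelParseError(
                    f"{path}, line {lineno}: non-numeric cell {bad!r}"
                ) from None
    years_arr = np.asarray(years)
    if years_arr.size > 1 and np.any(np.diff(years_arr) != 1):
        gap = int(years_arr[np.argmax(np.diff(years_arr) != 1)])
        raise PanelParseError(
            f"{path}: years are not consecutive (gap after {gap})"
        )
    try:
        return RateSurface(
            years=years_arr,
            ages=np.asarray(ages),
            values=np.asarray(rows, dtype=float),
            component_label=component_label,
            stratum=stratum,
            transform_kind=transform_kind,
        )
    except ValueError as exc:
        raise PanelParseError(f"{path}: {exc}") from exc


def _is_float(v: str) -> bool:
    try:
        float(v)
        return True
    except ValueError:
        return False


def write_population(state: PopulationState, path) -> None:
    rows = []
    for a in range(N_AGES):
        for s in SEXES:
            for nat in NATIONALITIES:
                rows.append((a, s, nat, state.counts[a, SEX_INDEX[s], NAT_INDEX[nat]]))
    frame = pd.DataFrame(rows, columns=["age", "sex", "nationality", "count"])
    frame.insert(0, "year", state.year)
    frame.to_csv(path, index=False)


def read_population(path) -> PopulationState:
    frame = pd.read_csv(path)
    counts = np.zeros((N_AGES, 2, 2))
    for _, row in frame.iterrows():
        counts[int(row["age"]), SEX_INDEX[row["sex"]], NAT_INDEX[row["nationality"]]] = row[
            "count"
        ]
    return PopulationState(int(frame["year"].iloc[0]), counts)


def _surface_filename(key: tuple) -> str:
    comp = key[0]
    if comp == "fertility":
        return f"fertility_f_{key[1]}.csv"
    if comp == "mortality":
        return f"mortality_{key[1]}_all.csv"
    if comp == "naturalization":
        return f"naturalization_{key[1]}_foreign.csv"
    return f"{comp}_{key[1]}_{key[2]}.csv"


def scenario_to_dir(scenario, directory) -> None:
    """Write a full scenario (panels, base population, totals, LFPR) to a
    directory in the panel dialect, byte-compatible with real-data runs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for key, surface in scenario.surfaces.items():
        write_panel(surface, directory / _surface_filename(key))
    write_population(scenario.base, directory / "base_population.csv")
    totals = pd.DataFrame(
        {nat: ser for nat, ser in scenario.immigration_totals.items()}
    )
    totals.index.name = "year"
    totals.to_csv(directory / "immigration_totals.csv")
    for group, (ser, panel) in scenario.lfpr.items():
        frame = panel.copy()
        frame.insert(0, "lfpr", ser)
        frame.index.name = "year"
        frame.to_csv(directory / f"lfpr_{group[0]}_{group[1]}_{group[2]}.csv")
    pd.Series({f"{g[0]}_{g[1]}_{g[2]}": v for g, v in scenario.u_full.items()}).to_csv(
        directory / "u_full.csv", header=["u_full"]
    )


def scenario_from_dir(directory):
    """Load a scenario previously written by :func:`scenario_to_dir`."""
    from .stochastic_simulation import ScenarioData

    directory = Path(directory)
    surfaces = {}
    for nat in NATIONALITIES:
        key = ("fertility", nat)
        surfaces[key] = read_panel(
            directory / _surface_filename(key), "fertility", stratum=("f", nat)
        )
    for sex in SEXES:
        key = ("mortality", sex)
        surfaces[key] = read_panel(
            directory / _surface_filename(key), "mortality", stratum=(sex, "german")
        )
        key = ("naturalization", sex)
        surfaces[key] = read_panel(
            directory / _surface_filename(key), "naturalization", stratum=(sex, "foreign")
        )
        for nat in NATIONALITIES:
            for comp in ("emigration", "immigration_shares"):
                key = (comp, sex, nat)
                surfaces[key] = read_panel(
                    directory / _surface_filename(key), comp, stratum=(sex, nat)
                )
    totals_frame = pd.read_csv(directory / "immigration_totals.csv", index_col="year")
    totals = {nat: totals_frame[nat] for nat in NATIONALITIES}
    lfpr = {}
    u_full = {}
    u_frame = pd.read_csv(directory / "u_full.csv", index_col=0)
    for path in sorted(directory.glob("lfpr_*.csv")):
        parts = path.stem[len("lfpr_") :].split("_", 2)
        group = (parts[0], parts[1], parts[2])
        frame = pd.read_csv(path, index_col="year")
        ser = frame.pop("lfpr")
        lfpr[group] = (ser, frame)
        u_full[group] = float(u_frame.loc[f"{parts[0]}_{parts[1]}_{parts[2]}", "u_full"])
    base = read_population(directory / "base_population.csv")
    return ScenarioData(surfaces, totals, lfpr, base, u_full)


@dataclass
class RunConfig:
    """Validated run configuration."""

    workdir: Path
    base_year: int = 2013
    horizon_end: int = 2035
    n_draws: int = 200
    seed: int = 0
    level: float = 66.0
    sex_ratio: float = 105.0
    working_age: tuple[int, int] = (15, 66)
    synthetic: dict = field(default_factory=dict)
    addon_schedule: Mapping[int, float] = field(default_factory=default_addon_schedule)

    def __post_init__(self) -> None:
        if self.horizon_end <= self.base_year:
            raise ValueError("horizon_end must lie beyond base_year")
        if not (0.0 < self.level < 100.0):
            raise ValueError("level must lie in (0, 100)")
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        lo, hi = self.working_age
        if not (0 <= lo <= hi <= 90):
            raise ValueError("working_age bounds must satisfy 0 <= lo <= hi <= 90")

    @property
    def inputs_dir(self) -> Path:
        return self.workdir / "inputs"

    @property
    def outputs_dir(self) -> Path:
        return self.workdir / "outputs"

    @property
    def models_path(self) -> Path:
        return self.workdir / "models.json"


def load_config(path) -> RunConfig:
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {
        "workdir", "base_year", "horizon_end", "n_draws", "seed", "level",
        "sex_ratio", "working_age", "synthetic", "addon_schedule",
    }
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    workdir = Path(raw.get("workdir", path.parent / "run"))
    kwargs = {k: raw[k] for k in raw if k != "workdir"}
    if "working_age" in kwargs:
        kwargs["working_age"] = tuple(kwargs["working_age"])
    if "addon_schedule" in kwargs:
        kwargs["addon_schedule"] = {int(k): float(v) for k, v in kwargs["addon_schedule"].items()}
    return RunConfig(workdir=workdir, **kwargs)
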