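"""File formats: Tucson RWL ring widths, climate/harvest CSV, run config.

The RWL reader/writer handles the two dominant decadal Tucson dialects,
auto-detected from the stopper value: units of 0.01 mm with stopper 999
(the dialect written here) and 0.001 mm with stopper -9999.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml


class FormatError(ValueError):
    """Raised when a file cannot be parsed or fails a validity check."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class RingSeries:
    """Raw ring widths of one core over consecutive calendar years.

    A width of 0 mm encodes a missing (locally absent) ring.  ``age_at_first``
    is the estimated cambial age of the innermost measured ring at coring
    height; per-ring age is ``age_at_first + (year - first_year)``.
    """

    core_id: str
    tree_id: str
    first_year: int
    widths: np.ndarray  # mm
    age_at_first: int = 1

    def __post_init__(self) -> None:
        self.widths = np.asarray(self.widths, dtype=float)
        if self.widths.ndim != 1 or self.widths.size == 0:
            raise ValueError("widths must be a non-empty 1-d array")
        if np.any(self.widths < 0):
            raise ValueError(f"{self.core_id}: negative ring width")
        if self.age_at_first < 1:
            raise ValueError(f"{self.core_id}: age_at_first must be >= 1")

    @property
    def years(self) -> np.ndarray:
        return self.first_year + np.arange(self.widths.size)

    @property
    def last_year(self) -> int:
        return self.first_year + self.widths.size - 1

    def width_in(self, year: int) -> float | None:
        """Width in ``year`` (mm), or None if outside the measured span."""
        if self.first_year <= year <= self.last_year:
            return float(self.widths[year - self.first_year])
        return None


@dataclass
class ClimateTable:
    """Site-level monthly mean temperature (degC) and total precipitation (mm)."""

    site_id: str
    data: pd.DataFrame  # MultiIndex (year, month), columns temperature, precipitation

    def __post_init__(self) -> None:
        df = self.data
        for col in ("temperature", "precipitation"):
            if col not in df.columns:
                raise FormatError(f"climate table missing column {col!r}")
        years = df.index.get_level_values("year")
        self.start_year = int(years.min())
        self.end_year = int(years.max())
        expected = pd.MultiIndex.from_product(
            [range(self.start_year, self.end_year + 1), range(1, 13)],
            names=["year", "month"],
        )
        missing = expected.difference(df.index)
        if len(missing):
            y, m = missing[0]
            raise FormatError(f"climate table missing cell {y}-{m:02d}")
        if df.isna().any().any():
            raise FormatError("climate table contains missing values")
        if (df["precipitation"] < 0).any():
            bad = df.index[df["precipitation"] < 0][0]
            raise FormatError(
                f"negative precipitation at {bad[0]}-{bad[1]:02d}"
            )
        self.data = df.sort_index()

    def value(self, variable: str, year: int, month: int) -> float:
        return float(self.data.loc[(year, month), variable])

    def covers(self, year: int) -> bool:
        return self.start_year <= year <= self.end_year


@dataclass
class HarvestSeries:
    """Annual harvesting intensity for one species at one site.

    ``hi`` is dimensionless: trees removed / stand density (or volume
    removed / stand volume, depending on the configured definition).  Years
    with no recorded intervention are implicitly zero.
    """

    site_id: str
    species_id: str
    years: np.ndarray
    hi: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.hi = np.asarray(self.hi, dtype=float)
        if self.years.shape != self.hi.shape:
            raise ValueError("years and hi must have equal length")
        if np.any(self.hi < 0):
            raise ValueError("harvesting intensity must be >= 0")
        if len(np.unique(self.years)) != len(self.years):
            raise ValueError("duplicate harvest years")

    def intensity(self, year: int) -> float:
        """HI in ``year``; 0 if the archives record no intervention."""
        hit = np.nonzero(self.years == year)[0]
        return float(self.hi[hit[0]]) if hit.size else 0.0

    def intensities(self, years: np.ndarray) -> np.ndarray:
        return np.array([self.intensity(int(y)) for y in np.asarray(years)])


# ---------------------------------------------------------------------------
# Tucson RWL
# ---------------------------------------------------------------------------

_STOPPERS = {999: 0.01, -9999: 0.001}  # stopper value -> mm per unit


def read_rwl(path: str | Path, ages: dict[str, int] | None = None) -> list[RingSeries]:
    """Read a decadal Tucson RWL file into a list of :class:`RingSeries`.

    ``ages`` optionally maps core id to the estimated cambial age of the
    innermost ring (the format itself does not carry ages; default 1).
    The measurement unit (0.01 or 0.001 mm) is auto-detected per series from
    the stopper value (999 or -9999).
    """
    path = Path(path)
    raw: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            sid = line[:8].strip()
            rest = line[8:].split()
            if not sid or len(rest) < 2:
                raise FormatError(f"{path.name}:{lineno}: malformed decade line")
            try:
                year = int(rest[0])
                values = [int(v) for v in rest[1:]]
            except ValueError as exc:
                raise FormatError(
                    f"{path.name}:{lineno}: malformed decade line ({exc})"
                ) from None
            if sid not in raw:
                raw[sid] = {"first_year": year, "next_year": year, "values": [],
                            "done": False}
                order.append(sid)
            rec = raw[sid]
            if rec["done"]:
                raise FormatError(
                    f"{path.name}:{lineno}: data after stopper for series {sid}"
                )
            if year != rec["next_year"]:
                raise FormatError(
                    f"{path.name}:{lineno}: series {sid} expected decade line "
                    f"starting {rec['next_year']}, got {year} (non-consecutive years)"
                )
            for v in values:
                if v in _STOPPERS:
                    rec["done"] = True
                    rec["unit"] = _STOPPERS[v]
                    break
                rec["values"].append(v)
                rec["next_year"] += 1
            else:
                # decade lines run to the end of the decade
                rec["next_year"] = rec["first_year"] + len(rec["values"])

    series = []
    ages = ages or {}
    for sid in order:
        rec = raw[sid]
        if not rec["done"]:
            raise FormatError(f"{path.name}: series {sid} has no stopper value")
        if not rec["values"]:
            raise FormatError(f"{path.name}: series {sid} has no measurements")
        unit = rec["unit"]
        widths = np.array(rec["values"], dtype=float) * unit
        series.append(
            RingSeries(
                core_id=sid,
                tree_id=sid,
                first_year=rec["first_year"],
                widths=widths,
                age_at_first=ages.get(sid, 1),
            )
        )
    return series


def write_rwl(series: list[RingSeries], path: str | Path) -> None:
    """Write series as decadal Tucson RWL (units 0.01 mm, stopper 999)."""
    path = Path(path)
    lines = []
    for s in series:
        if len(s.core_id) > 8:
            raise FormatError(
                f"core id {s.core_id!r} exceeds the 8-character RWL field"
            )
        values = [int(round(w * 100)) for w in s.widths] + [999]
        year = s.first_year
        pos = 0
        while pos < len(values):
            # a decade row runs to the year ending in 9
            row_len = min(10 - (year % 10), len(values) - pos)
            row = values[pos : pos + row_len]
            lines.append(
                f"{s.core_id:<8}{year:>4}" + "".join(f"{v:>6d}" for v in row)
            )
            pos += row_len
            year += row_len
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# climate / harvest CSV
# ---------------------------------------------------------------------------


def read_climate(path: str | Path, site_id: str | None = None) -> ClimateTable:
    """Read a CSV with columns year, month, temperature, precipitation."""
    path = Path(path)
    df = pd.read_csv(path)
    required = {"year", "month", "temperature", "precipitation"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path.name}: climate CSV needs columns {sorted(required)}"
        )
    df = df.set_index(["year", "month"])[["temperature", "precipitation"]]
    return ClimateTable(site_id=site_id or path.stem, data=df)


def write_climate(table: ClimateTable, path: str | Path) -> None:
    table.data.reset_index().to_csv(path, index=False)


def read_harvest(
    path: str | Path, site_id: str = "site", species_id: str = "species"
) -> HarvestSeries:
    """Read harvesting intensity from CSV.

    Accepts columns ``year, hi``; or ``year, removed, density`` (count-based
    definition: trees removed / stand density); or ``year, volume_removed,
    stand_volume`` (volume-based definition) -- the ratio computation is the
    same either way.  Years absent from the file are treated as hi = 0 by
    :meth:`HarvestSeries.intensity`.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if {"volume_removed", "stand_volume"}.issubset(df.columns):
        df = df.rename(columns={"volume_removed": "removed",
                                "stand_volume": "density"})
    if "hi" in df.columns:
        hi = df["hi"].to_numpy(dtype=float)
    elif {"removed", "density"}.issubset(df.columns):
        removed = df["removed"].to_numpy(dtype=float)
        density = df["density"].to_numpy(dtype=float)
        if np.any(removed < 0):
            raise FormatError(f"{path.name}: negative removals")
        if np.any(density <= 0):
            raise FormatError(f"{path.name}: stand density must be > 0")
        hi = removed / density
    else:
        raise FormatError(
            f"{path.name}: harvest CSV needs columns (year, hi) or "
            "(year, removed, density)"
        )
    if "year" not in df.columns:
        raise FormatError(f"{path.name}: harvest CSV needs a year column")
    if np.any(hi < 0):
        raise FormatError(f"{path.name}: negative harvesting intensity")
    return HarvestSeries(
        site_id=site_id,
        species_id=species_id,
        years=df["year"].to_numpy(dtype=int),
        hi=hi,
    )


def write_harvest(series: HarvestSeries, path: str | Path) -> None:
    pd.DataFrame({"year": series.years, "hi": series.hi}).to_csv(path, index=False)


def read_ages(path: str | Path) -> dict[str, int]:
    """Read a core_id -> age_at_first CSV sidecar."""
    df = pd.read_csv(path)
    if not {"core_id", "age_at_first"}.issubset(df.columns):
        raise FormatError("ages CSV needs columns core_id, age_at_first")
    return {str(r.core_id): int(r.age_at_first) for r in df.itertuples()}


def write_ages(series: list[RingSeries], path: str | Path) -> None:
    pd.DataFrame(
        {"core_id": [s.core_id for s in series],
         "age_at_first": [s.age_at_first for s in series]}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "species": "abies_alba",
    "site": "stressed",
    "modeled_range": [1967, 2016],
    "hi_definition": "count",  # or "volume"
    "weight_scheme": "default",
    "seed": 0,
    "mcmc": {"chains": 3, "iters": 40_000, "burnin": 10_000, "thin": 10},
}


def load_config(path: str | Path | None = None, **overrides) -> dict:
    """Load YAML run configuration, merged over defaults, then overrides."""
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise FormatError("config file must be a YAML mapping")
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    for key, val in overrides.items():
        if val is None:
            continue
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update({k: v for k, v in val.items() if v is not None})
        else:
            cfg[key] = val
    return cfg


def series_equal(a: RingSeries, b: RingSeries, tol: float = 0.0) -> bool:
    """Equality of the measured content of two series (ids, span, widths)."""
    return (
        a.core_id == b.core_id
        and a.first_year == b.first_year
        and a.widths.size == b.widths.size
        and np.allclose(a.widths, b.widths, atol=tol, rtol=0)
    )

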