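"""Assemble the aligned, centered regression design from raw inputs.

Growth is modelled on the log scale, G = log(r + 1) with r the raw ring
width in mm (the +1 keeps missing rings, r = 0, in the sample).  A year t is
modelled for core c when the core has a measured ring in t and in t-1 (the
autoregressive covariate) and the climate table covers the full 60-month
window ending in December of year t.  Age, prior-year growth and harvesting
intensity are centered once, by their sample means over all modelled
records; the antecedent climate covariates are centered per MCMC iteration
(their values change with the weights), so the design carries the raw
60-month windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .antecedent import N_MONTHS, lag_to_year_month
from .io_formats import ClimateTable, HarvestSeries, RingSeries

YEARS_BACK = 4  # antecedent window spans the current year plus 4 prior years


def log_growth(width_mm: float | np.ndarray) -> float | np.ndarray:
    """Log-scale growth G = log(width + 1); width 0 (missing ring) maps to 0."""
    width = np.asarray(width_mm, dtype=float)
    if np.any(width < 0):
        raise ValueError("ring width must be >= 0")
    out = np.log1p(width)
    return float(out) if np.isscalar(width_mm) else out


def climate_window(climate: ClimateTable, year: int, variable: str) -> np.ndarray:
    """The 60 monthly values ending in December of ``year``, lag 1 first."""
    if not (climate.covers(year) and climate.covers(year - YEARS_BACK)):
        first_missing = year - YEARS_BACK if not climate.covers(year - YEARS_BACK) else year
        raise ValueError(
            f"climate does not cover the window for {year} "
            f"(first uncovered year: {first_missing})"
        )
    sub = climate.data[variable]
    window = np.empty(N_MONTHS)
    for lag in range(1, N_MONTHS + 1):
        y_back, month = lag_to_year_month(lag)
        window[lag - 1] = sub.loc[(year - y_back, month)]
    return window


@dataclass
class ModelDesign:
    """Aligned records of one species-site dataset, ready for the model.

    Records are flat over (year, core): ``core_index[i]`` indexes ``cores``.
    ``temp_windows`` / ``precip_windows`` hold one 60-month window per
    distinct modelled year (rows of ``window_years``); ``year_of_record``
    maps records to those rows.
    """

    cores: list[str]
    core_index: np.ndarray
    years: np.ndarray
    G: np.ndarray
    G_prev_centered: np.ndarray
    age_centered: np.ndarray
    hi_centered: np.ndarray
    window_years: np.ndarray
    temp_windows: np.ndarray
    precip_windows: np.ndarray
    year_of_record: np.ndarray
    centering: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.G.size
        for name in ("core_index", "years", "G_prev_centered", "age_centered",
                     "hi_centered", "year_of_record"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} must have one entry per record")
        if self.temp_windows.shape != (self.window_years.size, N_MONTHS):
            raise ValueError("temp_windows must be (n_window_years, 60)")
        if self.precip_windows.shape != (self.window_years.size, N_MONTHS):
            raise ValueError("precip_windows must be (n_window_years, 60)")
        for name in ("G_prev_centered", "age_centered", "hi_centered"):
            m = float(np.mean(getattr(self, name)))
            if abs(m) > 1e-10:
                raise ValueError(f"{name} is not centered (mean {m:.3e})")

    @property
    def n_records(self) -> int:
        return self.G.size

    @property
    def n_cores(self) -> int:
        return len(self.cores)

    def record(self, year: int, core_id: str) -> int:
        """Flat index of record (year, core); raises KeyError if unmodelled."""
        c = self.cores.index(core_id) if core_id in self.cores else -1
        hit = np.nonzero((self.core_index == c) & (self.years == year))[0]
        if c < 0 or hit.size == 0:
            raise KeyError(f"(year={year}, core={core_id}) is not a modelled record")
        return int(hit[0])

    def uncenter(self) -> dict[str, np.ndarray]:
        """Recover raw covariates from the stored centering constants."""
        return {
            "G_prev": self.G_prev_centered + self.centering["G_prev"],
            "age": self.age_centered + self.centering["age"],
            "hi": self.hi_centered + self.centering["hi"],
        }


def build_design(
    series: list[RingSeries],
    climate: ClimateTable,
    harvest: HarvestSeries,
    modeled_range: tuple[int, int],
) -> ModelDesign:
    """Build the centered model design for one species-site dataset."""
    lo, hi_year = int(modeled_range[0]), int(modeled_range[1])
    if lo > hi_year:
        raise ValueError("modeled_range must be (first, last) with first <= last")

    rec_core, rec_year, rec_G, rec_Gprev, rec_age = [], [], [], [], []
    cores: list[str] = []
    for s in series:
        c = len(cores)
        added = False
        for t in range(max(lo, s.first_year + 1), min(hi_year, s.last_year) + 1):
            if not (climate.covers(t) and climate.covers(t - YEARS_BACK)):
                continue
            w = s.width_in(t)
            w_prev = s.width_in(t - 1)
            if w is None or w_prev is None:
                continue
            rec_core.append(c)
            rec_year.append(t)
            rec_G.append(log_growth(w))
            rec_Gprev.append(log_growth(w_prev))
            rec_age.append(s.age_at_first + (t - s.first_year))
            added = True
        if added:
            cores.append(s.core_id)
    if not rec_G:
        raise ValueError("no eligible (year, core) records in the modelled range")

    years = np.array(rec_year)
    window_years = np.unique(years)
    temp_w = np.stack([climate_window(climate, int(t), "temperature")
                       for t in window_years])
    precip_w = np.stack([climate_window(climate, int(t), "precipitation")
                         for t in window_years])
    year_of_record = np.searchsorted(window_years, years)

    g_prev = np.array(rec_Gprev)
    age = np.array(rec_age, dtype=float)
    hi_rec = harvest.intensities(years)
    centering = {
        "G_prev": float(g_prev.mean()),
        "age": float(age.mean()),
        "hi": float(hi_rec.mean()),
    }
    return ModelDesign(
        cores=cores,
        core_index=np.array(rec_core),
        years=years,
        G=np.array(rec_G),
        G_prev_centered=g_prev - centering["G_prev"],
        age_centered=age - centering["age"],
        hi_centered=hi_rec - centering["hi"],
        window_years=window_years,
        temp_windows=temp_w,
        precip_windows=precip_w,
        year_of_record=year_of_record,
        centering=centering,
    )
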