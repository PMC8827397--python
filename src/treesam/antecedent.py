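"""Block-structured antecedent importance weights on the 60-month simplex.

Antecedent climate covariates are weighted averages of the past 60 months
(current year plus four prior years) of a monthly climate variable.  The
weights live on a simplex with two structural constraints:

* October--December of the current year carry weight exactly zero, because
  climate after the cessation of radial growth cannot affect the ring formed
  that year;
* the temporal resolution of the weights declines with time into the past --
  single months for the current and prior year, then blocks of 2, 3 and 4
  calendar months for years 2, 3 and 4 back.  Within a block, mass is split
  equally across months.

Months are indexed by "months into the past": lag 1 is December of the
current year, lag 4 is September of the current year, lag 60 is January four
years before ring formation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_MONTHS = 60
#: lags fixed to zero weight (Oct, Nov, Dec of the current year)
FIXED_ZERO_LAGS = (1, 2, 3)


def months_into_past(year_back: int, month: int) -> int:
    """Map (years into past, calendar month) to a 1-based lag index.

    ``(0, 12)`` (December of the current year) maps to 1 and ``(4, 1)``
    (January four years back) maps to 60.
    """
    if not (0 <= year_back <= 4):
        raise ValueError(f"year_back must be in 0..4, got {year_back}")
    if not (1 <= month <= 12):
        raise ValueError(f"month must be in 1..12, got {month}")
    return 12 * year_back + (12 - month) + 1


def lag_to_year_month(lag: int) -> tuple[int, int]:
    """Inverse of :func:`months_into_past`."""
    if not (1 <= lag <= N_MONTHS):
        raise ValueError(f"lag must be in 1..{N_MONTHS}, got {lag}")
    year_back, rem = divmod(lag - 1, 12)
    return year_back, 12 - rem


@dataclass(frozen=True)
class WeightScheme:
    """Partition of the 57 free lags into blocks of 1-4 months.

    ``blocks`` lists, per block, the tuple of 1-based lag indices it covers.
    Blocks are ordered by increasing lag (most recent first).
    """

    blocks: tuple[tuple[int, ...], ...]
    fixed_zero: tuple[int, ...] = FIXED_ZERO_LAGS

    def __post_init__(self) -> None:
        covered = [lag for block in self.blocks for lag in block]
        if sorted(covered) != sorted(set(covered)):
            raise ValueError("blocks overlap")
        free = set(range(1, N_MONTHS + 1)) - set(self.fixed_zero)
        if set(covered) != free:
            raise ValueError("blocks must partition the free (non-zero) lags")
        sizes = [len(b) for b in self.blocks]
        if any(s not in (1, 2, 3, 4) for s in sizes):
            raise ValueError("block sizes must be 1, 2, 3 or 4 months")
        # resolution must not become finer with increasing time into the past
        order = np.argsort([min(b) for b in self.blocks])
        if np.any(np.diff(np.asarray(sizes)[order]) < 0):
            raise ValueError("block size must be non-decreasing with lag")

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def block_sizes(self) -> np.ndarray:
        return np.array([len(b) for b in self.blocks])

    @property
    def monthly_map(self) -> np.ndarray:
        """(60, n_blocks) matrix spreading block mass equally over months."""
        m = np.zeros((N_MONTHS, self.n_blocks))
        for j, block in enumerate(self.blocks):
            for lag in block:
                m[lag - 1, j] = 1.0 / len(block)
        return m


def default_scheme() -> WeightScheme:
    """The standard declining-resolution scheme: 34 blocks over 57 lags.

    Current year: Jan--Sep as 9 single months (Oct--Dec are fixed zeros);
    one year back: 12 single months; two years back: six 2-month blocks;
    three years back: four 3-month blocks; four years back: three 4-month
    blocks.  Calendar blocks are aligned from January, which makes them
    contiguous in lag space.
    """
    blocks: list[tuple[int, ...]] = []
    lag = 4  # lags 1..3 are the fixed zeros
    for size, count in ((1, 9), (1, 12), (2, 6), (3, 4), (4, 3)):
        for _ in range(count):
            blocks.append(tuple(range(lag, lag + size)))
            lag += size
    assert lag == N_MONTHS + 1
    return WeightScheme(blocks=tuple(blocks))


@dataclass(frozen=True)
class WeightVector:
    """A point on the block-weight simplex plus its induced monthly vector."""

    variable: str
    block_weights: np.ndarray
    scheme: WeightScheme
    monthly: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        bw = np.asarray(self.block_weights, dtype=float)
        if bw.shape != (self.scheme.n_blocks,):
            raise ValueError(
                f"expected {self.scheme.n_blocks} block weights, got shape {bw.shape}"
            )
        if np.any(bw < 0):
            raise ValueError("block weights must be non-negative")
        if abs(bw.sum() - 1.0) > 1e-9:
            raise ValueError(f"block weights must sum to 1, got {bw.sum():.12f}")
        object.__setattr__(self, "block_weights", bw)
        object.__setattr__(self, "monthly", self.scheme.monthly_map @ bw)


def to_monthly(
    block_weights: np.ndarray,
    scheme: WeightScheme,
    variable: str = "precipitation",
) -> WeightVector:
    """Expand block weights to the 60-month vector (validates the simplex)."""
    return WeightVector(variable=variable, block_weights=block_weights, scheme=scheme)


def antecedent_value(window: np.ndarray, weights: WeightVector) -> float:
    """Weighted average of a 60-month climate window (most recent lag first)."""
    window = np.asarray(window, dtype=float)
    if window.shape != (N_MONTHS,):
        raise ValueError(f"window must have {N_MONTHS} values, got {window.shape}")
    return float(window @ weights.monthly)


def annual_weights(weights: WeightVector) -> np.ndarray:
    """Total weight per year into the past (y = 0..4)."""
    return weights.monthly.reshape(5, 12).sum(axis=1)


def cumulative_weights(weights: WeightVector) -> np.ndarray:
    """Running total of monthly weight by months into the past."""
    return np.cumsum(weights.monthly)


@dataclass(frozen=True)
class MemoryLengths:
    """Months into the past at which cumulative weight reaches 50% / 90%."""

    m50: int
    m90: int

    def __post_init__(self) -> None:
        if not (1 <= self.m50 <= self.m90 <= N_MONTHS):
            raise ValueError(f"require 1 <= M50 <= M90 <= {N_MONTHS}")


_TIE_TOL = 1e-12


def memory_lengths(weights: WeightVector) -> MemoryLengths:
    """First lags at which the cumulative weights cross 0.5 and 0.9."""
    cum = cumulative_weights(weights)
    m50 = int(np.argmax(cum >= 0.5 - _TIE_TOL)) + 1
    m90 = int(np.argmax(cum >= 0.9 - _TIE_TOL)) + 1
    return MemoryLengths(m50=m50, m90=m90)
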