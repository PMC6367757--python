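"""Age-specific hazard schedules and attributable-risk calibration.

Rates are piecewise-constant over 5-year age bands (the Gail-model
convention). The baseline breast-cancer hazard — the hazard for a woman at
the reference level of every risk factor — is obtained by multiplying the
population age-specific incidence rate by (1 − AR), where AR is the
population attributable risk of the modelled factors estimated by Bruzzi's
case-distribution method: AR = 1 − Σ_j ρ_j / r_j with ρ_j the proportion of
cases in risk stratum j and r_j the stratum's composite relative risk.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .profiles import RiskFactorScheme, RiskProfile, composite_rr

logger = logging.getLogger(__name__)

__all__ = [
    "AgeBandGrid",
    "HazardSchedule",
    "CaseStratumDistribution",
    "DEFAULT_GRID",
    "bruzzi_ar",
    "calibrate_baseline",
    "read_rate_table",
    "write_rate_table",
]

PER_100K = 1e5


@dataclass(frozen=True)
class AgeBandGrid:
    """Contiguous, non-overlapping age bands [start, start+width)."""

    band_starts: tuple[int, ...]
    band_width: int = 5

    def __post_init__(self) -> None:
        starts = self.band_starts
        if not starts:
            raise ValueError("empty age grid")
        for a, b in zip(starts, starts[1:]):
            if b != a + self.band_width:
                raise ValueError(
                    f"age bands must be contiguous: band at {a} (width {self.band_width}) "
                    f"followed by band at {b}"
                )

    @property
    def start(self) -> int:
        return self.band_starts[0]

    @property
    def end(self) -> int:
        return self.band_starts[-1] + self.band_width

    @property
    def n_bands(self) -> int:
        return len(self.band_starts)

    @property
    def edges(self) -> np.ndarray:
        """Band edges, length n_bands + 1."""
        return np.asarray(self.band_starts + (self.end,), dtype=float)


#: Default grid: twelve 5-year bands, 25–29 through 80–84.
DEFAULT_GRID = AgeBandGrid(band_starts=tuple(range(25, 85, 5)))


@dataclass(frozen=True)
class HazardSchedule:
    """Per-band rates (events per person-year) of a given kind.

    ``kind`` is one of ``incidence`` (population breast-cancer incidence),
    ``competing_mortality`` (non-breast-cancer death) or ``baseline``
    (AR-calibrated reference-level breast-cancer hazard).
    """

    grid: AgeBandGrid
    rates: tuple[float, ...]
    kind: str

    _KINDS = ("incidence", "competing_mortality", "baseline")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown schedule kind {self.kind!r}; expected one of {self._KINDS}")
        if len(self.rates) != self.grid.n_bands:
            raise ValueError(
                f"{len(self.rates)} rates for {self.grid.n_bands} age bands"
            )
        for start, r in zip(self.grid.band_starts, self.rates):
            if not (math.isfinite(r) and r >= 0):
                raise ValueError(f"band {start}-{start + self.grid.band_width - 1}: invalid rate {r}")

    @property
    def rates_array(self) -> np.ndarray:
        return np.asarray(self.rates, dtype=float)

    def rate_at(self, age: float) -> float:
        """Rate of the band containing ``age`` (bands are half-open)."""
        if not (self.grid.start <= age < self.grid.end):
            raise ValueError(f"age {age} outside hazard grid [{self.grid.start}, {self.grid.end})")
        idx = int((age - self.grid.start) // self.grid.band_width)
        return self.rates[idx]


@dataclass(frozen=True)
class CaseStratumDistribution:
    """Distribution of cases over risk strata: (composite RR, case proportion)."""

    strata: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.strata:
            raise ValueError("empty case distribution")
        total = 0.0
        for rr, rho in self.strata:
            if not (math.isfinite(rr) and rr > 0):
                raise ValueError(f"stratum relative risk {rr} must be positive and finite")
            if rho < 0:
                raise ValueError(f"negative case proportion {rho}")
            total += rho
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"case proportions sum to {total}, expected 1")

    @classmethod
    def from_profiles(
        cls,
        profiles: Iterable[RiskProfile],
        scheme: RiskFactorScheme,
    ) -> "CaseStratumDistribution":
        """Aggregate individual case profiles into RR strata."""
        counts: dict[float, int] = {}
        n = 0
        for p in profiles:
            r = composite_rr(p, scheme)
            counts[r] = counts.get(r, 0) + 1
            n += 1
        if n == 0:
            raise ValueError("no case profiles supplied")
        return cls(strata=tuple((r, c / n) for r, c in sorted(counts.items())))


def bruzzi_ar(dist: CaseStratumDistribution, scheme: RiskFactorScheme | None = None) -> float:
    """Population attributable risk from the case distribution over strata.

    AR = 1 − Σ_j ρ_j / r_j. Invariant to stratum order and to merging
    strata with equal r_j; 0 when every stratum has r_j = 1.
    The ``scheme`` argument is accepted for symmetry with profile-level
    construction but unused once strata carry composite RRs.
    """
    return 1.0 - sum(rho / rr for rr, rho in dist.strata)


def calibrate_baseline(incidence: HazardSchedule, ar: float) -> HazardSchedule:
    """Baseline hazard = age-specific incidence × (1 − AR)."""
    if incidence.kind != "incidence":
        raise ValueError(f"expected an incidence schedule, got kind {incidence.kind!r}")
    if not (0.0 <= ar < 1.0):
        raise ValueError(f"attributable risk {ar} outside [0, 1)")
    return HazardSchedule(
        grid=incidence.grid,
        rates=tuple(r * (1.0 - ar) for r in incidence.rates),
        kind="baseline",
    )


def read_rate_table(path, kind: str = "incidence") -> HazardSchedule:
    """Read a CSV rate table with columns ``age_start,age_end,rate_per_100k``.

    Rows may arrive out of order (sorted, with a log note); bands must tile
    an interval with no gaps or overlaps. Rates are stored internally per
    person-year.
    """
    df = pd.read_csv(path)
    required = {"age_start", "age_end", "rate_per_100k"}
    if missing := required - set(df.columns):
        raise ValueError(f"rate table {path}: missing columns {sorted(missing)}")
    if not df["age_start"].is_monotonic_increasing:
        logger.info("rate table %s: bands out of order, sorting by age_start", path)
        df = df.sort_values("age_start")
    starts = df["age_start"].astype(int).tolist()
    ends = df["age_end"].astype(int).tolist()
    widths = {e - s + 1 for s, e in zip(starts, ends)}
    if len(widths) != 1:
        raise ValueError(f"rate table {path}: mixed band widths {sorted(widths)}")
    width = widths.pop()
    for (s1, e1), s2 in zip(zip(starts, ends), starts[1:]):
        if s2 != e1 + 1:
            raise ValueError(
                f"rate table {path}: band {s1}-{e1} not followed contiguously "
                f"(next band starts at {s2})"
            )
    rates = df["rate_per_100k"].astype(float)
    if (rates < 0).any():
        bad = df.loc[rates < 0].iloc[0]
        raise ValueError(
            f"rate table {path}: negative rate {bad['rate_per_100k']} in band "
            f"{int(bad['age_start'])}-{int(bad['age_end'])}"
        )
    grid = AgeBandGrid(band_starts=tuple(starts), band_width=width)
    return HazardSchedule(grid=grid, rates=tuple(rates / PER_100K), kind=kind)


def write_rate_table(schedule: HazardSchedule, path) -> None:
    """Write a schedule back to the ``age_start,age_end,rate_per_100k`` dialect."""
    w = schedule.grid.band_width
    pd.DataFrame(
        {
            "age_start": schedule.grid.band_starts,
            "age_end": [s + w - 1 for s in schedule.grid.band_starts],
            "rate_per_100k": [r * PER_100K for r in schedule.rates],
        }
    ).to_csv(path, index=False)
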