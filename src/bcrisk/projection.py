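"""Absolute-risk projection under the cause-specific competing-risk model.

The probability that a woman of age ``a`` with composite relative risk ``r``
develops breast cancer within ``tau`` years, allowing for the competing
risk of death from other causes, is

    P(a, tau, r) = ∫_a^{a+tau} r h1*(t) exp(−∫_a^t [r h1*(u) + h2(u)] du) dt

with h1* the calibrated baseline breast-cancer hazard and h2 the
non-breast-cancer mortality hazard, both piecewise-constant on 5-year age
bands. The integral is evaluated in closed form band by band: on a
sub-interval of length D with total hazard lam = r h1* + h2, the
contribution is (r h1*/lam) · S · (1 − e^{−lam D}), where S is the survival
probability accumulated from a to the sub-interval start (lam = 0
contributes nothing). Probabilities are carried as proportions; rendering
as percent happens only at output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .hazards import HazardSchedule

__all__ = [
    "AbsoluteRiskQuery",
    "RiskTable",
    "absolute_risk",
    "competing_outcome_probabilities",
    "absolute_risk_vector",
    "build_risk_table",
    "interpolate_risk",
    "project_profile",
    "percent_str",
]


def percent_str(p: float, decimals: int = 2) -> str:
    """Render a proportion as percent, rounded half-up."""
    q = Decimal(1).scaleb(-decimals)
    return str(Decimal(p * 100).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class AbsoluteRiskQuery:
    """Projection request: initial age, horizon in years, composite RR."""

    initial_age: float
    duration: float
    rr: float

    def validate(self, grid_start: float, grid_end: float) -> None:
        if self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        if self.rr <= 0 or not math.isfinite(self.rr):
            raise ValueError(f"relative risk must be positive and finite, got {self.rr}")
        if self.initial_age < grid_start:
            raise ValueError(
                f"initial age {self.initial_age} below hazard grid start {grid_start}"
            )
        if self.initial_age + self.duration > grid_end:
            raise ValueError(
                f"projection to age {self.initial_age + self.duration} extends beyond the "
                f"hazard grid end {grid_end}; shorten the horizon or supply rates for "
                f"older ages"
            )


def _check_schedules(baseline: HazardSchedule, mortality: HazardSchedule) -> None:
    if baseline.kind != "baseline":
        raise ValueError(f"expected a baseline schedule, got kind {baseline.kind!r}")
    if mortality.kind != "competing_mortality":
        raise ValueError(
            f"expected a competing-mortality schedule, got kind {mortality.kind!r}"
        )
    if baseline.grid != mortality.grid:
        raise ValueError("baseline and mortality schedules must share one age grid")


def competing_outcome_probabilities(
    query: AbsoluteRiskQuery,
    baseline: HazardSchedule,
    mortality: HazardSchedule,
) -> tuple[float, float, float]:
    """(P[breast cancer first], P[competing death first], P[event-free at a+tau]).

    The three sum to 1 exactly (up to float rounding): each sub-interval's
    total event mass S·(1 − e^{−lam D}) is split between the two causes in
    proportion r·h1* : h2.
    """
    grid = baseline.grid
    query.validate(grid.start, grid.end)
    a, tau, r = query.initial_age, query.duration, query.rr
    edges = grid.edges
    h1 = baseline.rates_array
    h2 = mortality.rates_array

    p_event = 0.0
    p_death = 0.0
    surv = 1.0
    for k in range(grid.n_bands):
        lo = max(a, edges[k])
        hi = min(a + tau, edges[k + 1])
        if hi <= lo:
            continue
        lam = r * h1[k] + h2[k]
        if lam <= 0.0:
            continue
        mass = surv * (1.0 - math.exp(-lam * (hi - lo)))
        p_event += (r * h1[k] / lam) * mass
        p_death += (h2[k] / lam) * mass
        surv *= math.exp(-lam * (hi - lo))
    return p_event, p_death, surv


def absolute_risk(
    query: AbsoluteRiskQuery,
    baseline: HazardSchedule,
    mortality: HazardSchedule,
) -> float:
    """Absolute risk P(a, tau, r) as a proportion in [0, 1]."""
    _check_schedules(baseline, mortality)
    return competing_outcome_probabilities(query, baseline, mortality)[0]


def absolute_risk_vector(
    ages: np.ndarray,
    durations: np.ndarray,
    rrs: np.ndarray,
    baseline: HazardSchedule,
    mortality: HazardSchedule,
) -> np.ndarray:
    """Vectorised absolute risk over parallel arrays of (age, duration, RR).

    Same closed form as :func:`absolute_risk`, computed band-sweep style:
    bands are visited in ascending age order and each woman's survival is
    accumulated through the slice of the band her horizon overlaps.
    """
    _check_schedules(baseline, mortality)
    grid = baseline.grid
    a = np.asarray(ages, dtype=float)
    tau = np.asarray(durations, dtype=float)
    r = np.asarray(rrs, dtype=float)
    a, tau, r = np.broadcast_arrays(a, tau, r)
    if np.any(tau <= 0):
        raise ValueError("durations must be positive")
    if np.any(r <= 0):
        raise ValueError("relative risks must be positive")
    if np.any(a < grid.start) or np.any(a + tau > grid.end + 1e-9):
        raise ValueError("some projections extend beyond the hazard grid")

    edges = grid.edges
    h1 = baseline.rates_array
    h2 = mortality.rates_array
    p = np.zeros_like(a, dtype=float)
    surv = np.ones_like(a, dtype=float)
    end = a + tau
    for k in range(grid.n_bands):
        width = np.clip(np.minimum(end, edges[k + 1]) - np.maximum(a, edges[k]), 0.0, None)
        lam = r * h1[k] + h2[k]
        active = (width > 0) & (lam > 0)
        if not np.any(active):
            continue
        decay = np.exp(-lam * width, where=active, out=np.ones_like(p))
        frac = np.divide(r * h1[k], lam, where=active, out=np.zeros_like(p))
        p = np.where(active, p + frac * surv * (1.0 - decay), p)
        surv = np.where(active, surv * decay, surv)
    return p


@dataclass(frozen=True)
class RiskTable:
    """Grid of projected risks indexed by initial age × duration × RR.

    ``risks`` holds proportions; absent age/duration combinations (a ragged
    published grid) are NaN. Entries are non-decreasing along the duration
    and RR axes wherever defined.
    """

    ages: tuple[float, ...]
    durations: tuple[float, ...]
    rr_grid: tuple[float, ...]
    risks: np.ndarray  # shape (len(ages), len(durations), len(rr_grid))

    def __post_init__(self) -> None:
        expected = (len(self.ages), len(self.durations), len(self.rr_grid))
        if self.risks.shape != expected:
            raise ValueError(f"risk array shape {self.risks.shape} != {expected}")
        with np.errstate(invalid="ignore"):
            if np.any((self.risks < 0) | (self.risks > 1)):
                raise ValueError("risk entries must lie in [0, 1] (proportion scale)")
        if list(self.ages) != sorted(self.ages) or list(self.durations) != sorted(
            self.durations
        ) or list(self.rr_grid) != sorted(self.rr_grid):
            raise ValueError("table axes must be sorted ascending")

    def cell(self, age: float, duration: float, rr: float) -> float:
        i = self.ages.index(age)
        j = self.durations.index(duration)
        k = self.rr_grid.index(rr)
        v = self.risks[i, j, k]
        if np.isnan(v):
            raise ValueError(f"no table entry for age {age}, duration {duration}, RR {rr}")
        return float(v)

    def to_frame(self, percent: bool = True) -> pd.DataFrame:
        """Long-format frame with columns age,duration,rr,risk(_pct)."""
        rows = []
        for i, age in enumerate(self.ages):
            for j, dur in enumerate(self.durations):
                for k, rr in enumerate(self.rr_grid):
                    v = self.risks[i, j, k]
                    if np.isnan(v):
                        continue
                    rows.append((age, dur, rr, v * 100 if percent else v))
        col = "risk_pct" if percent else "risk"
        return pd.DataFrame(rows, columns=["age", "duration", "rr", col])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RiskTable":
        """Build from a long-format frame (``risk_pct`` or ``risk`` column)."""
        if "risk_pct" in df.columns:
            vals = df["risk_pct"].astype(float) / 100.0
        elif "risk" in df.columns:
            vals = df["risk"].astype(float)
        else:
            raise ValueError("risk table frame needs a 'risk' or 'risk_pct' column")
        ages = tuple(sorted(df["age"].astype(float).unique()))
        durations = tuple(sorted(df["duration"].astype(float).unique()))
        rr_grid = tuple(sorted(df["rr"].astype(float).unique()))
        risks = np.full((len(ages), len(durations), len(rr_grid)), np.nan)
        for (age, dur, rr), v in zip(
            df[["age", "duration", "rr"]].astype(float).itertuples(index=False), vals
        ):
            risks[ages.index(age), durations.index(dur), rr_grid.index(rr)] = v
        return cls(ages=ages, durations=durations, rr_grid=rr_grid, risks=risks)


def build_risk_table(
    ages,
    durations,
    rr_grid,
    baseline: HazardSchedule,
    mortality: HazardSchedule,
) -> RiskTable:
    """Project every (age, duration, RR) grid cell; raise naming the cell on error."""
    ages = tuple(float(x) for x in ages)
    durations = tuple(float(x) for x in durations)
    rr_grid = tuple(float(x) for x in rr_grid)
    if not (ages and durations and rr_grid):
        raise ValueError("table axes must be non-empty")
    risks = np.empty((len(ages), len(durations), len(rr_grid)))
    for i, age in enumerate(ages):
        for j, dur in enumerate(durations):
            for k, rr in enumerate(rr_grid):
                try:
                    risks[i, j, k] = absolute_risk(
                        AbsoluteRiskQuery(age, dur, rr), baseline, mortality
                    )
                except ValueError as exc:
                    raise ValueError(
                        f"risk-table cell (age {age}, duration {dur}, RR {rr}): {exc}"
                    ) from exc
    return RiskTable(ages=ages, durations=durations, rr_grid=rr_grid, risks=risks)


def interpolate_risk(
    table: RiskTable,
    age: float,
    duration: float,
    rr: float,
    *,
    extrapolate: bool = False,
) -> float:
    """Table lookup with linear interpolation along the RR axis only.

    ``age`` and ``duration`` must match grid values exactly (off-grid
    queries belong to the exact engine); ``rr`` is interpolated between the
    two bracketing grid RRs, or linearly extrapolated from the nearest
    segment when ``extrapolate`` is set.
    """
    if age not in table.ages:
        raise ValueError(f"age {age} not on the table grid {table.ages}; use the exact engine")
    if duration not in table.durations:
        raise ValueError(
            f"duration {duration} not on the table grid {table.durations}; use the exact engine"
        )
    grid = table.rr_grid
    if rr in grid:
        return table.cell(age, duration, rr)
    if not extrapolate and not (grid[0] <= rr <= grid[-1]):
        raise ValueError(
            f"RR {rr} outside the table grid [{grid[0]}, {grid[-1]}]; pass extrapolate=True"
        )
    idx = int(np.clip(np.searchsorted(grid, rr), 1, len(grid) - 1))
    r0, r1 = grid[idx - 1], grid[idx]
    v0 = table.cell(age, duration, r0)
    v1 = table.cell(age, duration, r1)
    return v0 + (v1 - v0) * (rr - r0) / (r1 - r0)


def project_profile(
    profile,
    initial_age: float,
    duration: float,
    region,
    *,
    scheme=None,
) -> dict:
    """Full pipeline for one woman: composite RR, exact and table risks.

    ``profile`` is a RiskProfile or RawMeasurements; ``region`` a
    RegionConfig supplying hazards, AR and (optionally) a published risk
    table for interpolation. ``interpolated_risk`` is None when the region
    bundles no table or the query is off its age/duration grid.
    """
    from .profiles import RawMeasurements, composite_rr, default_scheme, encode_profile

    if scheme is None:
        scheme = default_scheme()
    if isinstance(profile, RawMeasurements):
        profile = encode_profile(profile, scheme)
    rr = composite_rr(profile, scheme)
    exact = absolute_risk(
        AbsoluteRiskQuery(initial_age, duration, rr),
        region.baseline(),
        region.mortality(),
    )
    interpolated = None
    table = region.risk_table()
    if table is not None:
        try:
            interpolated = interpolate_risk(table, initial_age, duration, rr)
        except ValueError:
            interpolated = None
    return {
        "composite_rr": rr,
        "exact_risk": exact,
        "interpolated_risk": interpolated,
    }
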