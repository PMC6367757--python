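"""Cohort validation: calibration (E/O) and discrimination (C-statistic).

Expected events E sum each woman's model probability over her own observed
follow-up; the E/O ratio carries a 95% CI from a log-normal Poisson
approximation on the observed count, ratio × exp(∓1.96/√O). The
C-statistic is the probability that a randomly chosen case is assigned a
higher predicted risk than a randomly chosen non-case, computed by a rank
(Mann–Whitney) method with ties counted half, with a Hanley–McNeil
standard error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .profiles import RiskFactorScheme, RiskProfile, composite_rr, default_scheme
from .projection import absolute_risk_vector

__all__ = [
    "CohortRecord",
    "ValidationResult",
    "expected_events",
    "eo_ratio",
    "c_statistic",
    "crude_incidence_rate",
    "validate_cohort",
    "read_cohort_csv",
    "write_cohort_csv",
]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class CohortRecord:
    """One woman's follow-up: entry age, observed years, outcome, profile."""

    entry_age: float
    follow_up: float
    event: bool
    competing_death: bool
    profile: RiskProfile

    def __post_init__(self) -> None:
        if self.follow_up <= 0:
            raise ValueError(f"follow-up must be positive, got {self.follow_up}")
        if self.event and self.competing_death:
            raise ValueError("a record cannot have both the event and a competing death")


@dataclass(frozen=True)
class ValidationResult:
    expected: float
    observed: int
    eo: float | None
    eo_ci: tuple[float, float] | None
    c: float
    c_se: float
    c_ci: tuple[float, float]

    def as_dict(self) -> dict:
        return {
            "E": self.expected,
            "O": self.observed,
            "eo_ratio": self.eo,
            "eo_ci": list(self.eo_ci) if self.eo_ci else None,
            "c": self.c,
            "c_se": self.c_se,
            "c_ci": list(self.c_ci),
        }


def _cohort_risks(
    cohort: Sequence[CohortRecord],
    region,
    scheme: RiskFactorScheme,
    horizon: float | None,
) -> np.ndarray:
    """Per-woman model probabilities over realized follow-up (or a fixed horizon)."""
    if not cohort:
        return np.zeros(0)
    ages = np.array([r.entry_age for r in cohort])
    taus = (
        np.full(len(cohort), float(horizon))
        if horizon is not None
        else np.array([r.follow_up for r in cohort])
    )
    rrs = np.array([composite_rr(r.profile, scheme) for r in cohort])
    try:
        return absolute_risk_vector(ages, taus, rrs, region.baseline(), region.mortality())
    except ValueError:
        # recompute one-by-one to name the offending record
        out = np.empty(len(cohort))
        from .projection import AbsoluteRiskQuery, absolute_risk

        for i, (a, t, r) in enumerate(zip(ages, taus, rrs)):
            try:
                out[i] = absolute_risk(
                    AbsoluteRiskQuery(a, t, r), region.baseline(), region.mortality()
                )
            except ValueError as exc:
                raise ValueError(f"cohort record {i} (entry age {a}, follow-up {t}): {exc}")
        return out


def expected_events(
    cohort: Sequence[CohortRecord],
    region,
    scheme: RiskFactorScheme | None = None,
    *,
    horizon: float | None = None,
) -> float:
    """E = Σ_i P(entry_age_i, follow_up_i, r_i).

    Each woman contributes her model probability over her own realized
    follow-up; pass ``horizon`` to use a fixed projection window instead.
    """
    if scheme is None:
        scheme = default_scheme()
    return float(np.sum(_cohort_risks(cohort, region, scheme, horizon)))


def eo_ratio(expected: float, observed: int) -> tuple[float | None, tuple[float, float] | None]:
    """E/O ratio with 95% CI ratio × exp(∓1.96/√O); undefined when O = 0."""
    if expected < 0:
        raise ValueError(f"expected count must be non-negative, got {expected}")
    if observed < 0:
        raise ValueError(f"observed count must be non-negative, got {observed}")
    if observed == 0:
        return None, None
    ratio = expected / observed
    half = Z_95 / math.sqrt(observed)
    return ratio, (ratio * math.exp(-half), ratio * math.exp(half))


def c_statistic(
    risks: Sequence[float], outcomes: Sequence[bool]
) -> tuple[float, float, tuple[float, float]]:
    """Concordance of predicted risks with binary outcomes.

    c = (concordant + ½·tied) / (n_pos · n_neg) via midranks (O(n log n));
    SE by Hanley–McNeil; 95% CI c ∓ 1.96·SE truncated to [0, 1].
    """
    risks = np.asarray(risks, dtype=float)
    outcomes = np.asarray(outcomes, dtype=bool)
    if risks.shape != outcomes.shape or risks.ndim != 1:
        raise ValueError("risks and outcomes must be parallel 1-D sequences")
    n_pos = int(outcomes.sum())
    n_neg = int((~outcomes).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            "concordance needs at least one case and one non-case "
            f"(got {n_pos} cases, {n_neg} non-cases)"
        )
    ranks = rankdata(risks)  # midranks handle ties
    u = float(ranks[outcomes].sum()) - n_pos * (n_pos + 1) / 2.0
    c = u / (n_pos * n_neg)
    q1 = c / (2.0 - c)
    q2 = 2.0 * c * c / (1.0 + c)
    var = (
        c * (1.0 - c) + (n_pos - 1) * (q1 - c * c) + (n_neg - 1) * (q2 - c * c)
    ) / (n_pos * n_neg)
    se = math.sqrt(max(var, 0.0))
    ci = (max(0.0, c - Z_95 * se), min(1.0, c + Z_95 * se))
    return c, se, ci


def crude_incidence_rate(n_cases: int, n_persons: int, years: float) -> float:
    """Cases per 100,000 person-years under a shared follow-up window."""
    if n_cases < 0:
        raise ValueError(f"negative case count {n_cases}")
    if n_persons <= 0 or years <= 0:
        raise ValueError("person-time must be positive")
    return n_cases / (n_persons * years) * 1e5


def validate_cohort(
    cohort: Sequence[CohortRecord],
    region,
    scheme: RiskFactorScheme | None = None,
    *,
    horizon: float | None = None,
) -> ValidationResult:
    """E, O, E/O with CI, and C-statistic for one cohort against one region."""
    if scheme is None:
        scheme = default_scheme()
    risks = _cohort_risks(cohort, region, scheme, horizon)
    expected = float(risks.sum())
    observed = sum(r.event for r in cohort)
    ratio, ci = eo_ratio(expected, observed)
    outcomes = [r.event for r in cohort]
    c, se, c_ci = c_statistic(risks, outcomes)
    return ValidationResult(
        expected=expected,
        observed=observed,
        eo=ratio,
        eo_ci=ci,
        c=c,
        c_se=se,
        c_ci=c_ci,
    )


def read_cohort_csv(path, scheme: RiskFactorScheme | None = None) -> list[CohortRecord]:
    """Cohort CSV: entry_age, follow_up_years, event[, competing_death] + coded factors."""
    if scheme is None:
        scheme = default_scheme()
    df = pd.read_csv(path)
    required = {"entry_age", "follow_up_years", "event"}
    if missing := required - set(df.columns):
        raise ValueError(f"cohort file {path}: missing columns {sorted(missing)}")
    if missing := set(scheme.factor_names) - set(df.columns):
        raise ValueError(f"cohort file {path}: missing factor columns {sorted(missing)}")
    has_cd = "competing_death" in df.columns
    records = []
    for _, row in df.iterrows():
        profile = RiskProfile(codes={n: int(row[n]) for n in scheme.factor_names})
        profile.validate(scheme)
        records.append(
            CohortRecord(
                entry_age=float(row["entry_age"]),
                follow_up=float(row["follow_up_years"]),
                event=bool(row["event"]),
                competing_death=bool(row["competing_death"]) if has_cd else False,
                profile=profile,
            )
        )
    return records


def write_cohort_csv(cohort: Sequence[CohortRecord], path, scheme=None) -> None:
    if scheme is None:
        scheme = default_scheme()
    rows = []
    for r in cohort:
        row = {
            "entry_age": r.entry_age,
            "follow_up_years": r.follow_up,
            "event": int(r.event),
            "competing_death": int(r.competing_death),
        }
        row.update({n: int(r.profile.codes[n]) for n in scheme.factor_names})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
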