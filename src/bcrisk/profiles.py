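"""Risk-factor coding and composite relative risks.

The model scores six questionnaire-derived risk factors — number of
abortions, age at first live birth, history of benign breast disease,
body-mass index, family history of breast cancer, and life-satisfaction
score — each coded into ordered categories with a published relative risk
(RR) per category. A woman's composite RR is the product of her six
category RRs (multiplicative model, reference level RR = 1 for every
factor).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FactorSpec",
    "RiskFactorScheme",
    "RawMeasurements",
    "RiskProfile",
    "default_scheme",
    "read_scheme_csv",
    "write_scheme_csv",
    "encode_profile",
    "composite_rr",
    "read_profiles_csv",
]

# BMI (kg/m^2) category cut points: <24 normal, [24, 28) overweight, >=28 obese.
BMI_CUTS = (24.0, 28.0)
# Life-satisfaction: six items each scored 1 (very satisfied) .. 5 (very
# unsatisfied); a total >= 13 codes as "unsatisfied".
SATISFACTION_THRESHOLD = 13
N_SATISFACTION_ITEMS = 6


@dataclass(frozen=True)
class FactorSpec:
    """One coded risk factor: ordered category labels and their RRs.

    Code 0 is always the reference level and must carry RR exactly 1.0.
    """

    name: str
    level_labels: tuple[str, ...]
    rr_per_code: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.level_labels) != len(self.rr_per_code):
            raise ValueError(
                f"factor {self.name!r}: {len(self.level_labels)} labels but "
                f"{len(self.rr_per_code)} relative risks"
            )
        if not self.rr_per_code:
            raise ValueError(f"factor {self.name!r} has no categories")
        if self.rr_per_code[0] != 1.0:
            raise ValueError(
                f"factor {self.name!r}: reference category must have RR 1.0, "
                f"got {self.rr_per_code[0]}"
            )
        for rr in self.rr_per_code:
            if not (math.isfinite(rr) and rr > 0):
                raise ValueError(f"factor {self.name!r}: RR {rr} not a positive finite number")

    @property
    def n_levels(self) -> int:
        return len(self.rr_per_code)


@dataclass(frozen=True)
class RiskFactorScheme:
    """Ordered collection of :class:`FactorSpec` defining the coding scheme."""

    factors: tuple[FactorSpec, ...]

    def __post_init__(self) -> None:
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise ValueError("duplicate factor names in scheme")

    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors)

    def __getitem__(self, name: str) -> FactorSpec:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(name)


@dataclass(frozen=True)
class RiskProfile:
    """A woman's coded risk factors: factor name -> integer category code."""

    codes: Mapping[str, int]

    def validate(self, scheme: RiskFactorScheme) -> None:
        for spec in scheme.factors:
            if spec.name not in self.codes:
                raise ValueError(f"profile missing factor {spec.name!r}")
            code = self.codes[spec.name]
            if not (0 <= int(code) < spec.n_levels) or int(code) != code:
                raise ValueError(
                    f"factor {spec.name!r}: code {code} outside 0..{spec.n_levels - 1}"
                )


@dataclass(frozen=True)
class RawMeasurements:
    """Raw questionnaire measurements prior to category coding.

    ``age_first_live_birth`` is ``None`` for nulliparous women; their code is
    configurable at encoding time (default: reference level, logged).
    """

    n_abortions: int
    age_first_live_birth: float | None
    benign_breast_disease: bool
    height_m: float
    weight_kg: float
    family_history: bool
    satisfaction_items: Sequence[int] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.n_abortions < 0:
            raise ValueError(f"negative abortion count: {self.n_abortions}")
        if self.height_m <= 0:
            raise ValueError(f"non-positive height: {self.height_m} m")
        if self.weight_kg <= 0:
            raise ValueError(f"non-positive weight: {self.weight_kg} kg")
        items = tuple(self.satisfaction_items)
        if len(items) != N_SATISFACTION_ITEMS:
            raise ValueError(
                f"expected {N_SATISFACTION_ITEMS} life-satisfaction items, got {len(items)}"
            )
        for v in items:
            if v not in (1, 2, 3, 4, 5):
                raise ValueError(f"life-satisfaction item {v} outside 1..5")

    @property
    def bmi(self) -> float:
        """Body-mass index: weight in kilograms over height in metres squared."""
        return self.weight_kg / self.height_m**2

    @property
    def satisfaction_total(self) -> int:
        return int(sum(self.satisfaction_items))


# Default scheme: the six factors, Table-1-style codings with the published
# category relative risks from the multivariate conditional logistic fit.
_DEFAULT_SCHEME_ROWS = [
    ("abortions", 0, "0", 1.0),
    ("abortions", 1, "1-2", 2.512),
    ("abortions", 2, ">=3", 6.313),
    ("age_first_live_birth", 0, "<25", 1.0),
    ("age_first_live_birth", 1, "25-29", 1.895),
    ("age_first_live_birth", 2, ">=30", 3.589),
    ("benign_breast_disease", 0, "no", 1.0),
    ("benign_breast_disease", 1, "yes", 4.255),
    ("bmi", 0, "<24", 1.0),
    ("bmi", 1, "24-27.9", 1.372),
    ("bmi", 2, ">=28", 1.882),
    ("family_history", 0, "no", 1.0),
    ("family_history", 1, "yes", 3.250),
    ("life_satisfaction", 0, "<13", 1.0),
    ("life_satisfaction", 1, ">=13", 2.424),
]


def _scheme_from_rows(rows: pd.DataFrame) -> RiskFactorScheme:
    factors = []
    for name in rows["factor"].drop_duplicates():
        sub = rows[rows["factor"] == name].sort_values("code")
        codes = sub["code"].tolist()
        if codes != list(range(len(codes))):
            raise ValueError(f"factor {name!r}: codes {codes} are not contiguous from 0")
        factors.append(
            FactorSpec(
                name=str(name),
                level_labels=tuple(str(x) for x in sub["label"]),
                rr_per_code=tuple(float(x) for x in sub["rr"]),
            )
        )
    return RiskFactorScheme(factors=tuple(factors))


def default_scheme() -> RiskFactorScheme:
    """The bundled six-factor scheme with the published category RRs."""
    return _scheme_from_rows(
        pd.DataFrame(_DEFAULT_SCHEME_ROWS, columns=["factor", "code", "label", "rr"])
    )


def read_scheme_csv(path) -> RiskFactorScheme:
    """Read a scheme CSV with columns ``factor,code,label,rr``."""
    df = pd.read_csv(path)
    required = {"factor", "code", "label", "rr"}
    if missing := required - set(df.columns):
        raise ValueError(f"scheme file {path}: missing columns {sorted(missing)}")
    return _scheme_from_rows(df)


def write_scheme_csv(scheme: RiskFactorScheme, path) -> None:
    rows = [
        (f.name, code, f.level_labels[code], f.rr_per_code[code])
        for f in scheme.factors
        for code in range(f.n_levels)
    ]
    pd.DataFrame(rows, columns=["factor", "code", "label", "rr"]).to_csv(path, index=False)


def bundled_scheme_path():
    """Path of the packaged scheme CSV (context-manager friendly Traversable)."""
    return resources.files("bcrisk.data") / "risk_factor_scheme.csv"


def _code_from_cuts(value: float, cuts: Sequence[float]) -> int:
    code = 0
    for cut in cuts:
        if value >= cut:
            code += 1
    return code


def encode_profile(
    raw: RawMeasurements,
    scheme: RiskFactorScheme | None = None,
    *,
    nulliparous_code: int = 0,
) -> RiskProfile:
    """Code raw measurements into the six-factor :class:`RiskProfile`.

    Codings: abortions 0 / 1–2 / ≥3 → 0/1/2; age at first live birth
    <25 / 25–29 / ≥30 → 0/1/2; BMI <24 / [24,28) / ≥28 → 0/1/2; benign
    breast disease and family history booleans → 0/1; life-satisfaction
    total (six items, range 6–30) ≥ 13 → 1 else 0. Nulliparous women have
    no stated coding; the default assigns the reference level
    (``nulliparous_code=0``) and logs a warning.
    """
    if scheme is None:
        scheme = default_scheme()
    if raw.age_first_live_birth is None:
        logger.warning(
            "nulliparous woman: age at first live birth coded %d (no published coding)",
            nulliparous_code,
        )
        birth_code = nulliparous_code
    else:
        birth_code = _code_from_cuts(float(raw.age_first_live_birth), (25.0, 30.0))
    codes = {
        "abortions": _code_from_cuts(raw.n_abortions, (1, 3)),
        "age_first_live_birth": birth_code,
        "benign_breast_disease": int(bool(raw.benign_breast_disease)),
        "bmi": _code_from_cuts(raw.bmi, BMI_CUTS),
        "family_history": int(bool(raw.family_history)),
        "life_satisfaction": int(raw.satisfaction_total >= SATISFACTION_THRESHOLD),
    }
    profile = RiskProfile(codes=codes)
    profile.validate(scheme)
    return profile


def composite_rr(profile: RiskProfile, scheme: RiskFactorScheme | None = None) -> float:
    """Composite relative risk: product of the per-factor category RRs.

    Order-invariant; 1.0 for the all-reference profile.
    """
    if scheme is None:
        scheme = default_scheme()
    profile.validate(scheme)
    rr = 1.0
    for spec in scheme.factors:
        rr *= spec.rr_per_code[int(profile.codes[spec.name])]
    return rr


_RAW_COLUMNS = {
    "n_abortions",
    "age_first_live_birth",
    "benign_breast_disease",
    "height_m",
    "weight_kg",
    "family_history",
}


def read_profiles_csv(
    path, scheme: RiskFactorScheme | None = None, *, coded: bool | None = None
) -> list[RiskProfile]:
    """Read one profile per row; pre-coded or raw-measurement columns.

    ``coded=None`` auto-detects: a file whose columns include every factor
    name of the scheme is treated as pre-coded. Raw files need the
    measurement columns plus ``satisfaction_1``..``satisfaction_6``.
    """
    if scheme is None:
        scheme = default_scheme()
    df = pd.read_csv(path)
    if coded is None:
        coded = set(scheme.factor_names) <= set(df.columns)
    profiles: list[RiskProfile] = []
    if coded:
        if missing := set(scheme.factor_names) - set(df.columns):
            raise ValueError(f"coded profile file {path}: missing columns {sorted(missing)}")
        for _, row in df.iterrows():
            p = RiskProfile(codes={n: int(row[n]) for n in scheme.factor_names})
            p.validate(scheme)
            profiles.append(p)
        return profiles
    if missing := _RAW_COLUMNS - set(df.columns):
        raise ValueError(f"raw profile file {path}: missing columns {sorted(missing)}")
    item_cols = [f"satisfaction_{i}" for i in range(1, N_SATISFACTION_ITEMS + 1)]
    if missing := set(item_cols) - set(df.columns):
        raise ValueError(f"raw profile file {path}: missing columns {sorted(missing)}")
    for _, row in df.iterrows():
        age_flb = row["age_first_live_birth"]
        raw = RawMeasurements(
            n_abortions=int(row["n_abortions"]),
            age_first_live_birth=None if pd.isna(age_flb) else float(age_flb),
            benign_breast_disease=bool(row["benign_breast_disease"]),
            height_m=float(row["height_m"]),
            weight_kg=float(row["weight_kg"]),
            family_history=bool(row["family_history"]),
            satisfaction_items=tuple(int(row[c]) for c in item_cols),
        )
        profiles.append(encode_profile(raw, scheme))
    return profiles
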