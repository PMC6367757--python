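"""Region configuration: rate tables, attributable risk, risk-table grids.

A "region" bundles everything location-specific: the age-specific
breast-cancer incidence and non-breast-cancer mortality tables, the
population attributable risk used to calibrate the baseline hazard (an AR
estimated in one population applies to that population only — none is ever
applied silently), and optionally a pre-computed risk table for the
interpolation lookup.

The packaged region ``synthetic_taixing`` carries a plausible but
synthetic rural-China rate table (the official registry tables are not
redistributed here) together with the published reference risk-table grid.
"""

from __future__ import annotations

import functools
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .hazards import HazardSchedule, calibrate_baseline, read_rate_table
from .projection import RiskTable

__all__ = ["RegionConfig", "load_region", "bundled_region", "data_dir"]

DEFAULT_TABLE_AGES = (25.0, 30.0, 40.0, 50.0, 60.0, 70.0)
DEFAULT_TABLE_DURATIONS = (5.0, 10.0, 20.0, 30.0)
DEFAULT_TABLE_RR_GRID = (1.0, 5.0, 10.0, 15.0, 20.0, 25.0)


def data_dir() -> Path:
    """Directory of the packaged data files."""
    return Path(str(resources.files("bcrisk.data")))


@dataclass(frozen=True)
class RegionConfig:
    name: str
    incidence: HazardSchedule
    competing_mortality: HazardSchedule
    attributable_risk: float
    table_ages: tuple[float, ...] = DEFAULT_TABLE_AGES
    table_durations: tuple[float, ...] = DEFAULT_TABLE_DURATIONS
    table_rr_grid: tuple[float, ...] = DEFAULT_TABLE_RR_GRID
    reference_table: RiskTable | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.attributable_risk < 1.0):
            raise ValueError(
                f"region {self.name!r}: attributable risk {self.attributable_risk} "
                "outside [0, 1)"
            )
        if self.incidence.grid != self.competing_mortality.grid:
            raise ValueError(
                f"region {self.name!r}: incidence and mortality tables on different age grids"
            )

    @functools.cached_property
    def _baseline(self) -> HazardSchedule:
        return calibrate_baseline(self.incidence, self.attributable_risk)

    def baseline(self) -> HazardSchedule:
        """AR-calibrated baseline breast-cancer hazard."""
        return self._baseline

    def mortality(self) -> HazardSchedule:
        return self.competing_mortality

    def risk_table(self) -> RiskTable | None:
        """The region's bundled (published) risk table, if any."""
        return self.reference_table


def load_region(path) -> RegionConfig:
    """Load a region config from YAML (JSON parses too).

    Keys: ``name``, ``incidence_table``, ``mortality_table``,
    ``attributable_risk``; optional ``risk_table`` (long-format CSV with a
    ``risk_pct`` column) and ``risk_grid`` ({ages, durations, rr}).
    File paths are resolved relative to the config file.
    """
    path = Path(path)
    try:
        cfg = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ValueError(f"region file {path}: not valid YAML/JSON: {exc}") from exc
    if not isinstance(cfg, dict):
        raise ValueError(f"region file {path}: expected a mapping, got {type(cfg).__name__}")
    for key in ("name", "incidence_table", "mortality_table", "attributable_risk"):
        if key not in cfg:
            raise ValueError(f"region file {path}: missing key {key!r}")
    base = path.parent
    incidence = read_rate_table(base / cfg["incidence_table"], kind="incidence")
    mortality = read_rate_table(base / cfg["mortality_table"], kind="competing_mortality")
    table = None
    if cfg.get("risk_table"):
        table = RiskTable.from_frame(pd.read_csv(base / cfg["risk_table"]))
    grids = cfg.get("risk_grid", {})
    return RegionConfig(
        name=str(cfg["name"]),
        incidence=incidence,
        competing_mortality=mortality,
        attributable_risk=float(cfg["attributable_risk"]),
        table_ages=tuple(float(x) for x in grids.get("ages", DEFAULT_TABLE_AGES)),
        table_durations=tuple(
            float(x) for x in grids.get("durations", DEFAULT_TABLE_DURATIONS)
        ),
        table_rr_grid=tuple(float(x) for x in grids.get("rr", DEFAULT_TABLE_RR_GRID)),
        reference_table=table,
    )


def bundled_region() -> RegionConfig:
    """The packaged synthetic Taixing-like region."""
    return load_region(data_dir() / "synthetic_taixing.yaml")


def region_to_json(region: RegionConfig) -> str:
    """Small JSON summary of a region (name, AR, grids) for reports."""
    return json.dumps(
        {
            "name": region.name,
            "attributable_risk": region.attributable_risk,
            "age_grid": [region.incidence.grid.start, region.incidence.grid.end],
            "has_reference_table": region.reference_table is not None,
        }
    )
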