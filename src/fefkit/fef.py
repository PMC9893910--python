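"""Nutrition index, food environmental footprint and scenario comparison.

The nutrition index S normalizes a basin's total caloric production against
a global reference: ``S = T_cal / (B x P)`` where T_cal is total daily
caloric output (cal/day), B the malnutrition baseline (default 2,000
cal/day/person) and P the global population (default 7.75e9).  The food
environmental footprint is ``FEF = C / S`` — cumulative per-person
environmental damage per unit of normalized nutrition production.  FEF near
zero marks a clean production pattern; values above one mark a destructive
one (interpretive guide, not an assertion).

Scenario comparison tabulates C, S, FEF, loads and water footprints per
best-management-practice scenario with percent reductions versus the base
scenario, plus per-area nutrient export coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .basin_data import LandUseRecord, Pollutant
from .errors import DataValidationError, DomainError
from .weighting import CumulativeImpact

__all__ = [
    "NutritionAccount",
    "FefResult",
    "ScenarioResult",
    "ComparisonReport",
    "nutrition_total",
    "s_index",
    "fef",
    "percent_reduction",
    "export_coefficient",
    "compare_scenarios",
    "DEFAULT_BASELINE_CAL_DAY",
    "DEFAULT_POPULATION",
    "DAYS_PER_YEAR",
]

#: malnutrition baseline, cal/day/person
DEFAULT_BASELINE_CAL_DAY = 2000.0
#: global population used to normalize S per person
DEFAULT_POPULATION = 7.75e9
#: calendar convention for MCal/yr -> cal/day
DAYS_PER_YEAR = 365.0
_CAL_PER_MCAL = 1e6


@dataclass(frozen=True)
class NutritionAccount:
    """Total nutrition production and its normalized per-person index S."""

    t_cal_day: float  # cal/day
    baseline: float = DEFAULT_BASELINE_CAL_DAY
    population: float = DEFAULT_POPULATION

    def __post_init__(self) -> None:
        if self.baseline <= 0 or self.population <= 0:
            raise DomainError("baseline and population must be > 0")
        if self.t_cal_day < 0:
            raise DomainError("total nutrition must be >= 0")

    @property
    def s_index(self) -> float:
        return self.t_cal_day / (self.baseline * self.population)


@dataclass(frozen=True)
class FefResult:
    """FEF with the provenance of both operands."""

    fef: float
    cumulative_impact: CumulativeImpact
    nutrition: NutritionAccount
    scenario: str = ""

    @property
    def method(self) -> str:
        return self.cumulative_impact.method


@dataclass
class ScenarioResult:
    """Pipeline outputs for one scenario: midpoints, normalized endpoints,
    cumulative impacts per weighting method, nutrition index and FEF."""

    scenario_id: str
    r_health: float
    r_ecosystem: float
    c_by_method: dict[str, float]
    s: float | None
    fef_by_method: dict[str, float] = field(default_factory=dict)
    midpoints: dict[str, float] = field(default_factory=dict)
    loads_kg_yr: dict[Pollutant, float] = field(default_factory=dict)
    wf_total_m3: float | None = None
    nutrition_mcal_yr: float | None = None


def nutrition_total(records: Iterable[LandUseRecord]) -> tuple[float, float]:
    """Total nutrition over land uses: (MCal/yr, cal/day).

    Each record either carries nutrition directly or provides yield, area
    and caloric value from which it is computed; a 365-day year converts the
    annual total to a daily rate.
    """
    total_mcal = 0.0
    for rec in records:
        total_mcal += rec.nutrition_mcal  # raises if not computable
    cal_day = total_mcal * _CAL_PER_MCAL / DAYS_PER_YEAR
    return total_mcal, cal_day


def s_index(
    t_cal_per_day: float,
    baseline: float = DEFAULT_BASELINE_CAL_DAY,
    population: float = DEFAULT_POPULATION,
) -> float:
    """Nutrition index ``S = T_cal / (B x P)``, dimensionless per person."""
    return NutritionAccount(t_cal_day=t_cal_per_day, baseline=baseline, population=population).s_index


def fef(c: CumulativeImpact, s: float, nutrition: NutritionAccount | None = None) -> FefResult:
    """Food environmental footprint ``FEF = C / S``."""
    if s <= 0:
        raise DomainError(f"nutrition index S must be > 0 to form a footprint, got {s}")
    if nutrition is None:
        # reconstruct an account consistent with s under the default constants
        nutrition = NutritionAccount(t_cal_day=s * DEFAULT_BASELINE_CAL_DAY * DEFAULT_POPULATION)
    return FefResult(fef=c.value / s, cumulative_impact=c, nutrition=nutrition, scenario=c.scenario)


def percent_reduction(base_value: float, scenario_value: float) -> float:
    """Percent reduction vs base, ``100 x (base - scenario) / base``.

    Negative results indicate an increase.
    """
    if base_value <= 0:
        raise DomainError(f"base value must be > 0, got {base_value}")
    return 100.0 * (base_value - scenario_value) / base_value


def export_coefficient(load: float, area: float) -> float:
    """Annual pollutant export per farmed hectare (kg/ha/yr)."""
    if area <= 0:
        raise DomainError(f"area must be > 0, got {area}")
    if load < 0:
        raise DomainError(f"load must be >= 0, got {load}")
    return load / area


@dataclass
class ComparisonReport:
    """Per-scenario absolute values with reductions versus the base scenario."""

    base_id: str
    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self) -> list[dict]:
        return self.table.to_dict(orient="records")


def compare_scenarios(
    results: Mapping[str, ScenarioResult],
    base_id: str = "base",
    farm_area_ha: float | None = None,
) -> ComparisonReport:
    """Tabulate C, S, FEF, loads and reductions vs the base scenario.

    Every reduction column equals ``percent_reduction`` applied to the
    report's own absolute columns.  Export coefficients (kg/ha/yr) are
    included when a farmed area is supplied.
    """
    if base_id not in results:
        raise KeyError(f"base scenario {base_id!r} not among results {sorted(results)}")
    base = results[base_id]
    if base.s is None:
        raise DataValidationError(f"scenario {base_id!r} lacks a nutrition index S")
    rows = []
    for sid, res in results.items():
        if res.s is None:
            raise DataValidationError(f"scenario {sid!r} lacks a nutrition index S")
        row: dict[str, object] = {
            "scenario": sid,
            "r_health": res.r_health,
            "r_ecosystem": res.r_ecosystem,
            "s": res.s,
            "wf_total_m3": res.wf_total_m3,
            "nutrition_mcal_yr": res.nutrition_mcal_yr,
        }
        for method, c in res.c_by_method.items():
            row[f"c_{method}"] = c
        for method, f in res.fef_by_method.items():
            row[f"fef_{method}"] = f
        for pollutant, load in res.loads_kg_yr.items():
            row[f"load_{pollutant.value}_kg_yr"] = load
            if farm_area_ha:
                row[f"export_{pollutant.value}_kg_ha_yr"] = export_coefficient(load, farm_area_ha)
        rows.append(row)
    table = pd.DataFrame(rows)
    # reductions vs base for every numeric absolute column
    base_row = table[table["scenario"] == base_id].iloc[0]
    for col in [c for c in table.columns if c != "scenario" and not c.startswith("export_")]:
        base_val = base_row[col]
        if pd.notna(base_val) and float(base_val) > 0:
            table[f"{col}_reduction_pct"] = [
                percent_reduction(float(base_val), float(v)) if pd.notna(v) else float("nan")
                for v in table[col]
            ]
    return ComparisonReport(base_id=base_id, table=table)
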