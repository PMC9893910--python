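"""Green, blue, grey and total water footprints per land use, scenario and year.

The three components follow the standard crop water-footprint accounting:

* green water — rain-fed evapotranspiration, ``GnWF = 10 * ETa`` (m3/ha, with
  ET in mm; the factor 10 converts mm over one hectare to m3/ha);
* blue water — irrigation consumption, ``BWF = 10 * (ETb - ETa)`` (m3/ha);
* grey water — the dilution volume needed to assimilate the exported
  pollutant loads to the receiving-water standard,
  ``GWF = max_i ( L_i / (Cmax_i - Cnat_i) )`` taken over pollutants i.

Green and blue footprints are per-hectare quantities; the grey footprint is
per land use and year (loads are annual masses).  The basis is always an
explicit field — mixing bases silently would corrupt totals.

Grey-water units: loads are kg/yr and concentrations mg/L = g/m3, so
``L * 1000 / (Cmax - Cnat)`` yields m3/yr.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .basin_data import (
    EvapotranspirationRecord,
    Pollutant,
    PollutantLoadSeries,
    ScenarioDataset,
    WaterQualityStandard,
)
from .errors import ConfigurationError, DomainError

__all__ = [
    "Basis",
    "WaterFootprint",
    "green_wf",
    "blue_wf",
    "grey_wf",
    "wf_per_ton",
    "compute_water_footprints",
]

#: m3/ha per mm of ET depth over one hectare
_M3_PER_HA_MM = 10.0
#: g per kg, for kg/yr loads against g/m3 concentrations
_G_PER_KG = 1e3


class Basis(str, enum.Enum):
    PER_HECTARE = "per_hectare"
    PER_LANDUSE = "per_landuse"
    PER_TON = "per_ton"


@dataclass(frozen=True)
class WaterFootprint:
    """Water footprint components (m3 on the stated basis)."""

    green: float
    blue: float
    grey: float
    basis: Basis

    def __post_init__(self) -> None:
        for name in ("green", "blue", "grey"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} water footprint must be >= 0")

    @property
    def total(self) -> float:
        return self.green + self.blue + self.grey


def green_wf(et_a: float) -> float:
    """Green water footprint (m3/ha) from rain-fed ET depth (mm)."""
    if et_a < 0:
        raise DomainError(f"et_a must be >= 0, got {et_a}")
    return _M3_PER_HA_MM * et_a


def blue_wf(et_b: float, et_a: float) -> float:
    """Blue water footprint (m3/ha) from the irrigation ET increment (mm).

    ``et_b`` is total ET under irrigation, ``et_a`` ET without irrigation;
    rain-fed records have ``et_b == et_a`` and a zero blue footprint.
    """
    if et_a < 0:
        raise DomainError(f"et_a must be >= 0, got {et_a}")
    if et_b < et_a:
        raise DomainError(f"inconsistent ET inputs: et_b ({et_b}) < et_a ({et_a})")
    return _M3_PER_HA_MM * (et_b - et_a)


def grey_wf(
    loads: Mapping[Pollutant, float] | Iterable[PollutantLoadSeries],
    standards: Mapping[Pollutant, WaterQualityStandard],
) -> float:
    """Grey water footprint (m3/yr) for one land-use-year's pollutant loads.

    The grey footprint is governed by the pollutant demanding the largest
    dilution volume (max rule), not by the sum over pollutants.
    """
    if not isinstance(loads, Mapping):
        acc: dict[Pollutant, float] = {}
        for rec in loads:
            acc[rec.pollutant] = acc.get(rec.pollutant, 0.0) + rec.load
        loads = acc
    best = 0.0
    for pollutant, load in loads.items():
        if load < 0:
            raise DomainError(f"{pollutant.value}: load must be >= 0, got {load}")
        std = standards.get(pollutant)
        if std is None:
            raise ConfigurationError(
                f"no water-quality standard configured for pollutant {pollutant.value}"
            )
        dilution = load * _G_PER_KG / (std.c_max - std.c_nat)
        best = max(best, dilution)
    return best


def wf_per_ton(wf_total: float, production: float) -> float:
    """Total water footprint per ton of production (m3/ton)."""
    if wf_total < 0:
        raise DomainError(f"wf_total must be >= 0, got {wf_total}")
    if production <= 0 or not math.isfinite(production):
        raise DomainError(f"production must be > 0 to form a per-ton rate, got {production}")
    return wf_total / production


def compute_water_footprints(
    dataset: ScenarioDataset,
    standards: Mapping[Pollutant, WaterQualityStandard],
    pollutants: Iterable[Pollutant] = (Pollutant.TN, Pollutant.TP),
) -> pd.DataFrame:
    """Per-(land use, year) water footprint components for one scenario.

    Green and blue components are scaled from per-hectare to per-land-use by
    area; the grey component comes from that land use's annual loads for the
    selected pollutants (TN and TP aggregates by default).  Requires areas on
    the land-use records.

    Returns a frame with columns scenario, lu_name, year, green_m3, blue_m3,
    grey_m3, total_m3.
    """
    pollutants = set(pollutants)
    areas: dict[str, float] = {}
    for lu in dataset.land_uses:
        if lu.area is None:
            raise ConfigurationError(
                f"{dataset.scenario_id}/{lu.lu_name}: area required to compute land-use water footprints"
            )
        areas[lu.lu_name] = lu.area
    et_by_key: dict[tuple[str, int], EvapotranspirationRecord] = {
        (r.lu_name, r.year): r for r in dataset.et
    }
    loads_by_key: dict[tuple[str, int], dict[Pollutant, float]] = {}
    for rec in dataset.loads:
        if rec.pollutant in pollutants:
            loads_by_key.setdefault((rec.lu_name, rec.year), {})
            loads_by_key[(rec.lu_name, rec.year)][rec.pollutant] = (
                loads_by_key[(rec.lu_name, rec.year)].get(rec.pollutant, 0.0) + rec.load
            )
    rows = []
    for (lu_name, year) in sorted(set(et_by_key) | set(loads_by_key)):
        area = areas.get(lu_name)
        if area is None:
            raise ConfigurationError(
                f"{dataset.scenario_id}: land use {lu_name!r} appears in loads/ET but has no record"
            )
        et = et_by_key.get((lu_name, year))
        green = green_wf(et.et_a) * area if et is not None else 0.0
        blue = blue_wf(et.et_b, et.et_a) * area if et is not None else 0.0
        grey = grey_wf(loads_by_key.get((lu_name, year), {}), standards)
        rows.append(
            {
                "scenario": dataset.scenario_id,
                "lu_name": lu_name,
                "year": year,
                "green_m3": green,
                "blue_m3": blue,
                "grey_m3": grey,
                "total_m3": green + blue + grey,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["scenario", "lu_name", "year", "green_m3", "blue_m3", "grey_m3", "total_m3"],
    )
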