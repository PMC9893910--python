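"""Data model and I/O for basin-model outputs, coefficient tables and bundled fixtures.

The basin model (a SWAT-type watershed simulator) exports, per land use and
year: pollutant mass loads delivered to the receiving water (kg/yr),
evapotranspiration with and without irrigation (mm), crop yields (ton/ha) and
areas (ha).  This module defines the validated in-memory representation of
those exports, a delimited-file reader driven by an explicit column map, and
the bundled transcriptions of the published coefficient tables and scenario
outputs that the rest of the pipeline consumes.

Native fixed-width basin-model output is deliberately not parsed: dialects
vary by model version, so the reader takes delimited tables plus a
user-supplied column map with declared units.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import ConfigurationError, DataValidationError

__all__ = [
    "Pollutant",
    "FilterStrip",
    "LandUseRecord",
    "PollutantLoadSeries",
    "EvapotranspirationRecord",
    "WaterQualityStandard",
    "ScenarioDefinition",
    "ScenarioDataset",
    "Fixtures",
    "read_scenario_tables",
    "write_scenario_tables",
    "load_fixtures",
]


class Pollutant(str, enum.Enum):
    """Nutrient species and aggregates tracked by the pipeline."""

    NO3 = "NO3"
    NO2 = "NO2"
    NH3 = "NH3"
    PO4 = "PO4"
    TN = "TN"
    TP = "TP"


class FilterStrip(str, enum.Enum):
    NONE = "none"
    SLIM = "slim"  # 10-12 m vegetated strip
    MODERATE = "moderate"  # 20-25 m vegetated strip


#: cal per MCal
CAL_PER_MCAL = 1e6
#: kg per ton
KG_PER_TON = 1e3


@dataclass(frozen=True)
class LandUseRecord:
    """One land use's production accounting for a scenario.

    ``nutrition`` (MCal/yr) may be given directly, as published scenario
    tables do; otherwise it is computed as yield x area x caloric value.
    ``area`` is optional when nutrition is given directly.
    """

    lu_name: str
    irrigated: bool
    crop_yield: float  # ton/ha/yr
    caloric_value: float  # cal/kg fresh mass
    area: float | None = None  # ha
    nutrition: float | None = None  # MCal/yr
    wf_per_ton: float | None = None  # m3/ton

    def __post_init__(self) -> None:
        if self.area is not None and self.area < 0:
            raise DataValidationError(f"{self.lu_name}: area must be >= 0, got {self.area}")
        if self.crop_yield < 0:
            raise DataValidationError(f"{self.lu_name}: crop_yield must be >= 0, got {self.crop_yield}")
        if self.caloric_value < 0:
            raise DataValidationError(f"{self.lu_name}: caloric_value must be >= 0, got {self.caloric_value}")
        if self.nutrition is None and self.area is None:
            raise DataValidationError(
                f"{self.lu_name}: nutrition not given and not computable (area missing)"
            )

    @property
    def nutrition_mcal(self) -> float:
        """Nutrition output in MCal/yr, computed from production if not given."""
        if self.nutrition is not None:
            return self.nutrition
        # ton/ha * ha * kg/ton * cal/kg -> cal/yr -> MCal/yr
        return self.crop_yield * self.area * KG_PER_TON * self.caloric_value / CAL_PER_MCAL


@dataclass(frozen=True)
class PollutantLoadSeries:
    """Annual pollutant mass delivered from one land use to the receiving water."""

    lu_name: str
    pollutant: Pollutant
    year: int
    load: float  # kg/yr

    def __post_init__(self) -> None:
        if self.load < 0:
            raise DataValidationError(
                f"{self.lu_name}/{self.pollutant.value}/{self.year}: load must be >= 0, got {self.load}"
            )


@dataclass(frozen=True)
class EvapotranspirationRecord:
    """Annual ET depths for one land use, with (et_b) and without (et_a) irrigation."""

    lu_name: str
    year: int
    et_a: float  # mm
    et_b: float  # mm

    def __post_init__(self) -> None:
        if self.et_a < 0:
            raise DataValidationError(f"{self.lu_name}/{self.year}: et_a must be >= 0, got {self.et_a}")
        if self.et_b < self.et_a:
            raise DataValidationError(
                f"{self.lu_name}/{self.year}: et_b ({self.et_b}) < et_a ({self.et_a})"
            )


@dataclass(frozen=True)
class WaterQualityStandard:
    """Receiving-water concentration standard used by the grey water footprint.

    c_max is the maximum allowable concentration, c_nat the natural
    background concentration, both in mg/L.
    """

    pollutant: Pollutant
    c_max: float
    c_nat: float

    def __post_init__(self) -> None:
        if self.c_nat < 0:
            raise DataValidationError(f"{self.pollutant.value}: c_nat must be >= 0")
        if self.c_max <= self.c_nat:
            raise DataValidationError(
                f"{self.pollutant.value}: c_max ({self.c_max}) must exceed c_nat ({self.c_nat})"
            )


@dataclass(frozen=True)
class ScenarioDefinition:
    """Metadata describing a farm best-management-practice scenario."""

    scenario_id: str
    fertilizer_reduction: float = 0.0
    irrigation_reduction: float = 0.0
    filter_strip: FilterStrip = FilterStrip.NONE
    description: str = ""

    def __post_init__(self) -> None:
        for name in ("fertilizer_reduction", "irrigation_reduction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DataValidationError(f"{self.scenario_id}: {name} must be in [0,1], got {v}")


@dataclass
class ScenarioDataset:
    """Validated basin-model outputs for one scenario."""

    scenario_id: str
    land_uses: list[LandUseRecord] = field(default_factory=list)
    loads: list[PollutantLoadSeries] = field(default_factory=list)
    et: list[EvapotranspirationRecord] = field(default_factory=list)

    def validate(self) -> "ScenarioDataset":
        """Check cross-record invariants (key uniqueness); return self."""
        seen: set[tuple[str, Pollutant, int]] = set()
        for rec in self.loads:
            key = (rec.lu_name, rec.pollutant, rec.year)
            if key in seen:
                raise DataValidationError(
                    f"{self.scenario_id}: duplicate load key (lu={rec.lu_name}, "
                    f"pollutant={rec.pollutant.value}, year={rec.year})"
                )
            seen.add(key)
        seen_et: set[tuple[str, int]] = set()
        for et in self.et:
            key_et = (et.lu_name, et.year)
            if key_et in seen_et:
                raise DataValidationError(
                    f"{self.scenario_id}: duplicate ET key (lu={et.lu_name}, year={et.year})"
                )
            seen_et.add(key_et)
        seen_lu: set[str] = set()
        for lu in self.land_uses:
            if lu.lu_name in seen_lu:
                raise DataValidationError(f"{self.scenario_id}: duplicate land use {lu.lu_name}")
            seen_lu.add(lu.lu_name)
        return self

    @property
    def years(self) -> list[int]:
        return sorted({rec.year for rec in self.loads} | {rec.year for rec in self.et})

    def total_load(self, pollutant: Pollutant, year: int | None = None) -> float:
        """Summed load (kg/yr) over land uses, for one year or averaged over all years."""
        sel = [r for r in self.loads if r.pollutant == pollutant]
        if year is not None:
            return sum(r.load for r in sel if r.year == year)
        years = sorted({r.year for r in sel})
        if not years:
            return 0.0
        return sum(r.load for r in sel) / len(years)

    def loads_by_year(self) -> dict[int, dict[Pollutant, float]]:
        """Scenario-level loads summed over land uses, keyed by year then pollutant."""
        out: dict[int, dict[Pollutant, float]] = {}
        for rec in self.loads:
            out.setdefault(rec.year, {}).setdefault(rec.pollutant, 0.0)
            out[rec.year][rec.pollutant] += rec.load
        return out

    def to_frames(self) -> dict[str, pd.DataFrame]:
        lu = pd.DataFrame(
            [
                {
                    "scenario": self.scenario_id,
                    "lu_name": r.lu_name,
                    "irrigated": r.irrigated,
                    "area_ha": r.area,
                    "yield_ton_ha": r.crop_yield,
                    "caloric_value_cal_kg": r.caloric_value,
                    "nutrition_mcal_yr": r.nutrition,
                    "wf_m3_ton": r.wf_per_ton,
                }
                for r in self.land_uses
            ]
        )
        loads = pd.DataFrame(
            [
                {
                    "scenario": self.scenario_id,
                    "lu_name": r.lu_name,
                    "pollutant": r.pollutant.value,
                    "year": r.year,
                    "load_kg_yr": r.load,
                }
                for r in self.loads
            ]
        )
        et = pd.DataFrame(
            [
                {
                    "scenario": self.scenario_id,
                    "lu_name": r.lu_name,
                    "year": r.year,
                    "et_a_mm": r.et_a,
                    "et_b_mm": r.et_b,
                }
                for r in self.et
            ]
        )
        return {"land_use": lu, "loads": loads, "et": et}


# ---------------------------------------------------------------------------
# Delimited-table reader / writer

#: canonical column names required per table
_REQUIRED_COLUMNS = {
    "land_use": ["scenario", "lu_name", "irrigated", "yield_ton_ha", "caloric_value_cal_kg"],
    "loads": ["scenario", "lu_name", "pollutant", "year", "load_kg_yr"],
    "et": ["scenario", "lu_name", "year", "et_a_mm", "et_b_mm"],
}
_OPTIONAL_COLUMNS = {
    "land_use": ["area_ha", "nutrition_mcal_yr", "wf_m3_ton"],
    "loads": [],
    "et": [],
}

#: multiplicative conversions to canonical units
_LOAD_UNIT_TO_KG = {"kg": 1.0, "kg/yr": 1.0, "ton": 1e3, "ton/yr": 1e3, "g": 1e-3}


def _resolve_columns(df: pd.DataFrame, table: str, column_map: Mapping[str, str] | None) -> pd.DataFrame:
    """Rename file columns to canonical names; fail naming any missing column."""
    cmap = dict(column_map or {})
    rename = {src: canon for canon, src in cmap.items() if src in df.columns}
    df = df.rename(columns=rename)
    missing = [c for c in _REQUIRED_COLUMNS[table] if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"table '{table}': missing required column(s) {missing}; "
            f"available columns: {list(df.columns)}"
        )
    return df


def read_scenario_tables(
    paths: Mapping[str, str | Path],
    column_map: Mapping[str, Mapping[str, str]] | None = None,
    units: Mapping[str, str] | None = None,
) -> dict[str, ScenarioDataset]:
    """Read land-use, load and ET tables into validated scenario datasets.

    Parameters
    ----------
    paths
        Mapping with keys among ``{"land_use", "loads", "et"}`` pointing to
        CSV files.  Each file carries a scenario column; rows are grouped by
        scenario on ingest.
    column_map
        Optional per-table mapping ``{canonical_name: file_column_name}``
        resolving non-canonical headers.
    units
        Unit declarations, e.g. ``{"load": "ton/yr"}``.  Loads are converted
        to kg/yr on ingest; ET is always mm, areas ha, yields ton/ha.

    Duplicate (land use, pollutant, year) rows within a scenario are an
    error: upstream HRU-level exports must be aggregated to land-use level
    before ingest (or via a groupby-sum, which keeps keys unique).
    """
    column_map = column_map or {}
    units = units or {}
    load_factor = _LOAD_UNIT_TO_KG.get(units.get("load", "kg"))
    if load_factor is None:
        raise ConfigurationError(f"unknown load unit {units.get('load')!r}; expected one of {sorted(_LOAD_UNIT_TO_KG)}")

    frames: dict[str, pd.DataFrame] = {}
    for table in ("land_use", "loads", "et"):
        if table not in paths:
            continue
        path = Path(paths[table])
        if not path.exists():
            raise ConfigurationError(f"input file for table '{table}' not found: {path}")
        frames[table] = _resolve_columns(pd.read_csv(path), table, column_map.get(table))

    scenario_ids: list[str] = []
    for df in frames.values():
        for sid in df["scenario"].astype(str):
            if sid not in scenario_ids:
                scenario_ids.append(sid)

    datasets: dict[str, ScenarioDataset] = {}
    for sid in scenario_ids:
        ds = ScenarioDataset(scenario_id=sid)
        if "land_use" in frames:
            sub = frames["land_use"]
            sub = sub[sub["scenario"].astype(str) == sid]
            for idx, row in sub.iterrows():
                try:
                    ds.land_uses.append(
                        LandUseRecord(
                            lu_name=str(row["lu_name"]),
                            irrigated=bool(row["irrigated"]),
                            crop_yield=float(row["yield_ton_ha"]),
                            caloric_value=float(row["caloric_value_cal_kg"]),
                            area=_opt_float(row.get("area_ha")),
                            nutrition=_opt_float(row.get("nutrition_mcal_yr")),
                            wf_per_ton=_opt_float(row.get("wf_m3_ton")),
                        )
                    )
                except DataValidationError as exc:
                    raise DataValidationError(f"land_use row {idx}: {exc}") from exc
        if "loads" in frames:
            sub = frames["loads"]
            sub = sub[sub["scenario"].astype(str) == sid]
            for idx, row in sub.iterrows():
                try:
                    ds.loads.append(
                        PollutantLoadSeries(
                            lu_name=str(row["lu_name"]),
                            pollutant=Pollutant(str(row["pollutant"])),
                            year=int(row["year"]),
                            load=float(row["load_kg_yr"]) * load_factor,
                        )
                    )
                except DataValidationError as exc:
                    raise DataValidationError(f"loads row {idx}: {exc}") from exc
                except ValueError as exc:
                    raise DataValidationError(f"loads row {idx}: {exc}") from exc
        if "et" in frames:
            sub = frames["et"]
            sub = sub[sub["scenario"].astype(str) == sid]
            for idx, row in sub.iterrows():
                try:
                    ds.et.append(
                        EvapotranspirationRecord(
                            lu_name=str(row["lu_name"]),
                            year=int(row["year"]),
                            et_a=float(row["et_a_mm"]),
                            et_b=float(row["et_b_mm"]),
                        )
                    )
                except DataValidationError as exc:
                    raise DataValidationError(f"et row {idx}: {exc}") from exc
        datasets[sid] = ds.validate()
    return datasets


def _opt_float(v) -> float | None:
    if v is None or (isinstance(v, float) and pd.isna(v)) or (isinstance(v, str) and not v.strip()):
        return None
    return float(v)


def write_scenario_tables(datasets: Mapping[str, ScenarioDataset], out_dir: str | Path) -> dict[str, Path]:
    """Write scenario datasets to the canonical CSV dialect (round-trips with the reader)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    merged: dict[str, list[pd.DataFrame]] = {"land_use": [], "loads": [], "et": []}
    for ds in datasets.values():
        for name, frame in ds.to_frames().items():
            if not frame.empty:
                merged[name].append(frame)
    paths: dict[str, Path] = {}
    for name, parts in merged.items():
        path = out_dir / f"{name}.csv"
        frame = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(
            columns=_REQUIRED_COLUMNS[name] + _OPTIONAL_COLUMNS[name]
        )
        frame.to_csv(path, index=False)
        paths[name] = path
    return paths


# ---------------------------------------------------------------------------
# Bundled fixtures

#: fixed endpoint-group weights of the environmental performance index
EPI_WEIGHTS = {"human_health": 0.4, "ecosystem": 0.6}
#: entropy-method endpoint-group weights as published for the study basin
PUBLISHED_ENTROPY_WEIGHTS = {"human_health": 0.56, "ecosystem": 0.44}
#: published bounds on average annual nutrient export from the study farmlands (kg/yr)
N_LOAD_RANGE_KG_YR = (1176.0, 3985.0)
P_LOAD_RANGE_KG_YR = (20.0, 82.0)
#: total farmed area of the study basin (20 km2)
FARM_AREA_HA = 2000.0
#: published average load reductions vs base, as fractions, per scenario and pollutant
PUBLISHED_LOAD_REDUCTIONS = {
    "BMP1": {Pollutant.TN: 0.338, Pollutant.TP: 0.077},
    "BMP2": {Pollutant.TN: 0.599, Pollutant.TP: 0.209},
}


@dataclass(frozen=True)
class Fixtures:
    """Bundled coefficient tables and published scenario outputs.

    All tables are cell-for-cell transcriptions of the published study; they
    load from package resources without network or filesystem configuration.
    """

    scenario_outputs: pd.DataFrame
    midpoint_factors: dict[tuple[str, str, str], float]
    endpoint_factors: pd.DataFrame
    standards: dict[Pollutant, WaterQualityStandard]
    endpoint_averages: pd.DataFrame
    scenarios: dict[str, ScenarioDefinition]

    def scenario_output_records(self, scenario: str) -> list[LandUseRecord]:
        """LandUseRecords for one scenario column of the published output table."""
        sub = self.scenario_outputs[self.scenario_outputs["scenario"] == scenario]
        if sub.empty:
            raise ConfigurationError(f"unknown scenario {scenario!r} in bundled output table")
        return [
            LandUseRecord(
                lu_name=row.lu_name,
                irrigated=bool(row.irrigated),
                crop_yield=float(row.yield_ton_ha),
                caloric_value=float(row.caloric_value_cal_kg),
                nutrition=float(row.nutrition_mcal_yr),
                wf_per_ton=float(row.wf_m3_ton),
            )
            for row in sub.itertuples()
        ]

    def endpoint_average(self, scenario: str, group: str) -> float:
        sub = self.endpoint_averages
        sel = sub[(sub["scenario"] == scenario) & (sub["group"] == group)]
        if sel.empty:
            raise ConfigurationError(f"no published endpoint average for ({scenario}, {group})")
        return float(sel["value"].iloc[0])


def _data_path(name: str):
    return resources.files("fefkit.data").joinpath(name)


def load_fixtures() -> Fixtures:
    """Load the bundled coefficient tables and published scenario outputs."""
    with resources.as_file(_data_path("bmp_scenario_outputs.csv")) as p:
        scenario_outputs = pd.read_csv(p)
    with resources.as_file(_data_path("midpoint_factors.csv")) as p:
        mf = pd.read_csv(p)
    midpoint_factors = {
        (r.species, r.emission_compartment, r.category): float(r.factor) for r in mf.itertuples()
    }
    with resources.as_file(_data_path("endpoint_factors.csv")) as p:
        endpoint_factors = pd.read_csv(p)
    with resources.as_file(_data_path("water_quality_standards.csv")) as p:
        st = pd.read_csv(p)
    standards = {
        Pollutant(r.pollutant): WaterQualityStandard(
            pollutant=Pollutant(r.pollutant), c_max=float(r.c_max_mg_l), c_nat=float(r.c_nat_mg_l)
        )
        for r in st.itertuples()
    }
    with resources.as_file(_data_path("endpoint_averages.csv")) as p:
        endpoint_averages = pd.read_csv(p)
    with resources.as_file(_data_path("scenarios.csv")) as p:
        sc = pd.read_csv(p)
    scenarios = {
        str(r.scenario_id): ScenarioDefinition(
            scenario_id=str(r.scenario_id),
            fertilizer_reduction=float(r.fertilizer_reduction),
            irrigation_reduction=float(r.irrigation_reduction),
            filter_strip=FilterStrip(str(r.filter_strip)),
            description=str(r.description),
        )
        for r in sc.itertuples()
    }
    return Fixtures(
        scenario_outputs=scenario_outputs,
        midpoint_factors=midpoint_factors,
        endpoint_factors=endpoint_factors,
        standards=standards,
        endpoint_averages=endpoint_averages,
        scenarios=scenarios,
    )
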