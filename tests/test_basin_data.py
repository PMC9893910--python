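"""Data model, delimited-table I/O and bundled fixtures."""

import pandas as pd
import pytest

from fefkit import (
    EvapotranspirationRecord,
    LandUseRecord,
    Pollutant,
    PollutantLoadSeries,
    ScenarioDataset,
    WaterQualityStandard,
    read_scenario_tables,
    write_scenario_tables,
)
from fefkit.errors import ConfigurationError, DataValidationError


def _tiny_dataset(scenario="base"):
    ds = ScenarioDataset(scenario_id=scenario)
    ds.land_uses = [
        LandUseRecord("wheat", True, 2.8, 3640.0, area=128.0),
        LandUseRecord("rf_wheat", False, 1.1, 3640.0, area=1000.0),
    ]
    ds.loads = [
        PollutantLoadSeries("wheat", Pollutant.TN, 2007, 100.0),
        PollutantLoadSeries("wheat", Pollutant.TP, 2007, 2.0),
        PollutantLoadSeries("rf_wheat", Pollutant.TN, 2007, 400.0),
    ]
    ds.et = [
        EvapotranspirationRecord("wheat", 2007, 450.0, 620.0),
        EvapotranspirationRecord("rf_wheat", 2007, 450.0, 450.0),
    ]
    return ds.validate()


class TestRecordInvariants:
    def test_negative_load_rejected(self):
        with pytest.raises(DataValidationError, match="load"):
            PollutantLoadSeries("wheat", Pollutant.TN, 2007, -1.0)

    def test_et_b_below_et_a_rejected(self):
        with pytest.raises(DataValidationError, match="et_b"):
            EvapotranspirationRecord("wheat", 2007, et_a=500.0, et_b=400.0)

    def test_standard_requires_cmax_above_cnat(self):
        with pytest.raises(DataValidationError):
            WaterQualityStandard(Pollutant.TN, c_max=0.4, c_nat=0.4)

    def test_nutrition_computed_from_production(self):
        # 2 ton/ha * 100 ha * 1000 kg/ton * 3640 cal/kg = 7.28e8 cal = 728 MCal
        rec = LandUseRecord("wheat", True, 2.0, 3640.0, area=100.0)
        assert rec.nutrition_mcal == pytest.approx(728.0)

    def test_record_needs_nutrition_or_area(self):
        with pytest.raises(DataValidationError, match="not computable"):
            LandUseRecord("wheat", True, 2.0, 3640.0)

    def test_duplicate_load_keys_rejected(self):
        ds = _tiny_dataset()
        ds.loads.append(PollutantLoadSeries("wheat", Pollutant.TN, 2007, 5.0))
        with pytest.raises(DataValidationError, match="duplicate"):
            ds.validate()


class TestTabularIO:
    def test_round_trip(self, tmp_path):
        datasets = {"base": _tiny_dataset("base"), "BMP1": _tiny_dataset("BMP1")}
        paths = write_scenario_tables(datasets, tmp_path)
        back = read_scenario_tables(paths)
        assert set(back) == {"base", "BMP1"}
        for sid in datasets:
            assert back[sid].land_uses == datasets[sid].land_uses
            assert back[sid].loads == datasets[sid].loads
            assert back[sid].et == datasets[sid].et

    def test_empty_load_table_gives_zero_series(self, tmp_path):
        p = tmp_path / "loads.csv"
        p.write_text("scenario,lu_name,pollutant,year,load_kg_yr\n")
        datasets = read_scenario_tables({"loads": p})
        assert datasets == {}

    def test_negative_load_row_names_index(self, tmp_path):
        p = tmp_path / "loads.csv"
        p.write_text(
            "scenario,lu_name,pollutant,year,load_kg_yr\n"
            "base,wheat,TN,2007,10\nbase,wheat,TN,2008,-1\n"
        )
        with pytest.raises(DataValidationError, match="row 1"):
            read_scenario_tables({"loads": p})

    def test_missing_column_named_in_error(self, tmp_path):
        p = tmp_path / "loads.csv"
        p.write_text("scenario,lu_name,pollutant,year\nbase,wheat,TN,2007\n")
        with pytest.raises(ConfigurationError, match="load_kg_yr"):
            read_scenario_tables({"loads": p})

    def test_column_map_and_unit_conversion(self, tmp_path):
        p = tmp_path / "loads.csv"
        p.write_text("SCEN,LU,POLL,YR,LOAD\nbase,wheat,TN,2007,1.5\n")
        datasets = read_scenario_tables(
            {"loads": p},
            column_map={
                "loads": {
                    "scenario": "SCEN",
                    "lu_name": "LU",
                    "pollutant": "POLL",
                    "year": "YR",
                    "load_kg_yr": "LOAD",
                }
            },
            units={"load": "ton/yr"},
        )
        assert datasets["base"].loads[0].load == pytest.approx(1500.0)

    def test_missing_file_is_configuration_error(self, tmp_path):
        with pytest.raises(ConfigurationError, match="not found"):
            read_scenario_tables({"loads": tmp_path / "nope.csv"})


class TestFixtures:
    def test_scenario_output_table_matches_printed_values(self, fx):
        assert len(fx.scenario_outputs) == 30
        records = {r.lu_name: r for r in fx.scenario_output_records("base")}
        assert records["alfalfa"].crop_yield == pytest.approx(4.5)
        assert records["alfalfa"].wf_per_ton == pytest.approx(2699.7)
        assert records["rf_wheat"].nutrition == pytest.approx(4004.0)
        sums = fx.scenario_outputs.groupby("scenario")["nutrition_mcal_yr"].sum()
        # hand sums of the printed per-land-use nutrition columns
        assert sums["base"] == pytest.approx(7117.0)
        assert sums["BMP1"] == pytest.approx(6998.0)
        assert sums["BMP2"] == pytest.approx(6850.0)

    def test_coefficient_tables_spot_values(self, fx):
        assert fx.midpoint_factors[("nitrate", "freshwater", "marine_eutrophication")] == 0.07
        assert fx.midpoint_factors[("phosphate", "freshwater", "freshwater_eutrophication")] == 33
        assert fx.midpoint_factors[("nitrate", "marine", "marine_eutrophication")] == 0.23
        ef = fx.endpoint_factors.set_index("endpoint_row")
        assert ef.loc["health_water", "factor"] == pytest.approx(2.22e-6)
        assert ef.loc["health_water", "normalization"] == pytest.approx(1.96e-4)
        assert ef.loc["freshwater_eutro", "factor"] == pytest.approx(6.71e-7)
        assert fx.standards[Pollutant.TN].c_max == 1.5
        assert fx.standards[Pollutant.TN].c_nat == 0.4
        assert fx.standards[Pollutant.TP].c_max == 0.035
        assert fx.standards[Pollutant.TP].c_nat == 0.01

    def test_scenario_definitions(self, fx):
        assert fx.scenarios["BMP1"].fertilizer_reduction == 0.25
        assert fx.scenarios["BMP2"].filter_strip.value == "moderate"
        assert fx.scenarios["base"].fertilizer_reduction == 0.0

    def test_published_endpoint_averages(self, fx):
        assert fx.endpoint_average("base", "ecosystem") == pytest.approx(1.41e-6)
        assert fx.endpoint_average("BMP2", "human_health") == pytest.approx(2.22e-7)
        with pytest.raises(ConfigurationError):
            fx.endpoint_average("base", "unknown_group")
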