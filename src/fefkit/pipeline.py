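"""End-to-end pipeline: basin outputs -> water footprints -> midpoints ->
endpoints -> normalization -> weighting -> nutrition -> FEF -> comparison.

Two entry points:

* :func:`run_pipeline` runs the full per-year computation on scenario
  datasets (model exports or synthetic data).  Entropy weights are derived
  from the per-year normalized endpoint series, pooled across scenarios by
  default (per-scenario mode via ``entropy_pooled=False``, which then uses
  each scenario's own series).
* :func:`results_from_published` builds scenario results directly from the
  bundled published endpoint averages and scenario output table, using the
  published entropy weights — a desk-scale reproduction of the study's
  summary numbers.
"""

from __future__ import annotations

from typing import Mapping

from .basin_data import (
    EPI_WEIGHTS,
    FARM_AREA_HA,
    Fixtures,
    Pollutant,
    PUBLISHED_ENTROPY_WEIGHTS,
    ScenarioDataset,
    load_fixtures,
)
from .errors import DomainError
from .fef import (
    ComparisonReport,
    DEFAULT_BASELINE_CAL_DAY,
    DEFAULT_POPULATION,
    ScenarioResult,
    compare_scenarios,
    fef,
    nutrition_total,
    s_index,
)
from .lcia import characterize, endpoint_factors_from_frame, normalize, to_endpoints
from .water_footprint import compute_water_footprints
from .weighting import ImpactWeights, aggregate, entropy_weights_health_eco

__all__ = ["PipelineResult", "run_pipeline", "results_from_published"]


class PipelineResult:
    """Scenario results, the weights used per method, and the comparison table."""

    def __init__(
        self,
        results: dict[str, ScenarioResult],
        weights: dict[str, ImpactWeights],
        report: ComparisonReport,
    ):
        self.results = results
        self.weights = weights
        self.report = report


def _epi_weights() -> ImpactWeights:
    return ImpactWeights(
        w_health=EPI_WEIGHTS["human_health"], w_ecosystem=EPI_WEIGHTS["ecosystem"], method="EPI"
    )


def run_pipeline(
    datasets: Mapping[str, ScenarioDataset],
    fixtures: Fixtures | None = None,
    base_id: str = "base",
    baseline_cal_day: float = DEFAULT_BASELINE_CAL_DAY,
    population: float = DEFAULT_POPULATION,
    entropy_pooled: bool = True,
    farm_area_ha: float | None = None,
) -> PipelineResult:
    """Run the full accounting pipeline on per-scenario basin datasets.

    Per scenario and year: total water footprint, midpoint characterization
    of the year's loads, endpoint damages and per-group normalized scores.
    Multi-year averages of the normalized scores feed the weighted
    cumulative impact C under both EPI and entropy weights; the scenario's
    nutrition production gives S and then FEF = C/S per weighting method.
    """
    fx = fixtures or load_fixtures()
    endpoint_factors = endpoint_factors_from_frame(fx.endpoint_factors)
    if farm_area_ha is None:
        farm_area_ha = FARM_AREA_HA

    per_year: dict[str, tuple[list[float], list[float]]] = {}
    interim: dict[str, dict] = {}
    for sid, ds in datasets.items():
        wf_table = compute_water_footprints(ds, fx.standards)
        wf_by_year = wf_table.groupby("year")["total_m3"].sum()
        loads_by_year = ds.loads_by_year()
        years = sorted(set(wf_by_year.index) | set(loads_by_year))
        if not years:
            raise DomainError(f"scenario {sid!r} has no yearly data")
        r_h_series: list[float] = []
        r_e_series: list[float] = []
        mid_acc: dict[str, float] = {}
        for year in years:
            mids = characterize(
                loads_by_year.get(year, {}),
                float(wf_by_year.get(year, 0.0)),
                fx.midpoint_factors,
            )
            damages = to_endpoints(mids, endpoint_factors)
            _, r_h, r_e = normalize(damages)
            r_h_series.append(r_h)
            r_e_series.append(r_e)
            for cat, q in mids.items():
                mid_acc[cat.value] = mid_acc.get(cat.value, 0.0) + q / len(years)
        per_year[sid] = (r_h_series, r_e_series)
        mcal, cal_day = nutrition_total(ds.land_uses)
        interim[sid] = {
            "midpoints": mid_acc,
            "mcal": mcal,
            "s": s_index(cal_day, baseline_cal_day, population),
            "wf_avg": float(wf_by_year.mean()),
            "loads_avg": {p: ds.total_load(p) for p in {r.pollutant for r in ds.loads}},
        }

    if entropy_pooled:
        pooled_h = [v for sid in datasets for v in per_year[sid][0]]
        pooled_e = [v for sid in datasets for v in per_year[sid][1]]
        entropy_w = {sid: entropy_weights_health_eco(pooled_h, pooled_e) for sid in datasets}
    else:
        entropy_w = {
            sid: entropy_weights_health_eco(*per_year[sid]) for sid in datasets
        }
    epi_w = _epi_weights()

    results: dict[str, ScenarioResult] = {}
    for sid in datasets:
        r_h_series, r_e_series = per_year[sid]
        r_h = sum(r_h_series) / len(r_h_series)
        r_e = sum(r_e_series) / len(r_e_series)
        c_by_method = {
            "EPI": aggregate(r_h, r_e, epi_w, scenario=sid).value,
            "entropy": aggregate(r_h, r_e, entropy_w[sid], scenario=sid).value,
        }
        s = interim[sid]["s"]
        fef_by_method = {
            m: fef(aggregate(r_h, r_e, w, scenario=sid), s).fef
            for m, w in (("EPI", epi_w), ("entropy", entropy_w[sid]))
        }
        results[sid] = ScenarioResult(
            scenario_id=sid,
            r_health=r_h,
            r_ecosystem=r_e,
            c_by_method=c_by_method,
            s=s,
            fef_by_method=fef_by_method,
            midpoints=interim[sid]["midpoints"],
            loads_kg_yr=interim[sid]["loads_avg"],
            wf_total_m3=interim[sid]["wf_avg"],
            nutrition_mcal_yr=interim[sid]["mcal"],
        )
    report = compare_scenarios(results, base_id=base_id, farm_area_ha=farm_area_ha)
    weights = {"EPI": epi_w}
    # pooled mode yields one entropy weight pair; per-scenario mode reports the base pair
    weights["entropy"] = entropy_w[base_id] if base_id in entropy_w else next(iter(entropy_w.values()))
    return PipelineResult(results=results, weights=weights, report=report)


def results_from_published(
    fixtures: Fixtures | None = None,
    baseline_cal_day: float = DEFAULT_BASELINE_CAL_DAY,
    population: float = DEFAULT_POPULATION,
) -> PipelineResult:
    """Scenario results from the bundled published summary numbers.

    Uses the published multi-year average normalized endpoint scores per
    scenario, the published entropy weights, and the published per-land-use
    nutrition outputs; recomputes C, S and FEF from them.
    """
    fx = fixtures or load_fixtures()
    entropy_w = ImpactWeights(
        w_health=PUBLISHED_ENTROPY_WEIGHTS["human_health"],
        w_ecosystem=PUBLISHED_ENTROPY_WEIGHTS["ecosystem"],
        method="entropy",
    )
    epi_w = _epi_weights()
    results: dict[str, ScenarioResult] = {}
    for sid in fx.endpoint_averages["scenario"].unique():
        r_h = fx.endpoint_average(sid, "human_health")
        r_e = fx.endpoint_average(sid, "ecosystem")
        records = fx.scenario_output_records(sid)
        mcal, cal_day = nutrition_total(records)
        s = s_index(cal_day, baseline_cal_day, population)
        c_by_method = {
            "EPI": aggregate(r_h, r_e, epi_w, scenario=sid).value,
            "entropy": aggregate(r_h, r_e, entropy_w, scenario=sid).value,
        }
        fef_by_method = {
            m: fef(aggregate(r_h, r_e, w, scenario=sid), s).fef
            for m, w in (("EPI", epi_w), ("entropy", entropy_w))
        }
        results[sid] = ScenarioResult(
            scenario_id=sid,
            r_health=r_h,
            r_ecosystem=r_e,
            c_by_method=c_by_method,
            s=s,
            fef_by_method=fef_by_method,
            nutrition_mcal_yr=mcal,
        )
    report = compare_scenarios(results, base_id="base", farm_area_ha=FARM_AREA_HA)
    return PipelineResult(
        results=results, weights={"EPI": epi_w, "entropy": entropy_w}, report=report
    )
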