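# Methods

## Scope and model

`fefkit` turns per-land-use, per-year watershed exports into a single
damage-per-food index. The chain is deliberately linear and auditable:
every stage is a small set of multiplications by editable coefficient
tables, so scenario differences propagate transparently from loads and ET
to the final FEF. The package does not simulate the watershed itself —
loads, ET and yields are inputs, produced upstream by a calibrated
basin model or by the bundled synthetic generator.

## Water footprints

Green and blue components are per-hectare quantities (`10·ETa`,
`10·(ETb − ETa)` m³/ha with ET in mm); the grey component is per land use
and year. The three bases (`per_hectare`, `per_landuse`, `per_ton`) are
explicit fields and never inferred, because silently mixing a per-hectare
green value with a per-land-use grey value corrupts totals.

The grey footprint uses the max rule — the dilution volume of the single
most demanding pollutant — rather than a sum, matching the standard grey-WF
definition: dilution water for the binding pollutant also dilutes the rest.
Loads are fixed as kg/yr per land use and concentrations converted
mg/L → g/m³, so the footprint comes out in m³/yr; this keeps the equation
dimensionally consistent for annual mass exports. Default standards are
the global lake-trophic-control limits (TN: C_max 1.5, C_nat 0.4 mg/L;
TP: 0.035, 0.01 mg/L), overridable per pollutant.

Grey water is computed from TN and TP aggregates by default; species-level
grey footprints work by passing species loads and standards instead.
When a land-use-level WF table reports per-ton values, grey water is
implicitly apportioned to crops by area share; this is a reporting default,
not a physical claim.

## Characterization, damages, normalization

Midpoint and endpoint factors are bundled CSV transcriptions of the
published coefficient tables and can be replaced wholesale. Three points
deserve flagging:

* The bundled phosphate → P-eq factor is 33, as printed in the source
  table. The plausible mass-fraction value is ≈ 0.33 (P is ~33% of PO₄ by
  mass), so this cell may carry a misplaced decimal point. The default
  follows the printed table; the factor is config-overridable and never
  silently "fixed".
* Emissions are assumed discharged to freshwater (the receiving lake).
  Marine eutrophication is still assessed — through the
  freshwater-emission marine factors — because nutrients reaching
  freshwater propagate to marine systems in the long run.
* TN is characterized with the nitrate factors and TP with the elemental
  phosphorus factor (1 kg P-eq/kg). This alias is a documented default in
  `SPECIES_ALIASES`; pass species-resolved loads (NO₃, NO₂, PO₄) when the
  upstream model provides them. Ammonia has no factor column in the
  bundled table and is logged and skipped, not zeroed silently.

Normalization divides each endpoint damage by the per-person reference on
its factor row (`R = D / N`) and sums rows into two group scores. The
published summary averages for the emulated basin (e.g. ecosystem
1.41 × 10⁻⁶ per person) are treated as given normalized group scores: the
intermediate normalization workbook behind them is not public, and their
absolute scale is not recoverable from the printed coefficient chain
applied to basin-scale inventories. Consequently the synthetic pipeline's
absolute R, C and FEF values live on a different (much larger) scale than
the published per-person averages. This does not affect the quantities the
method is for — percent reductions, weight derivation, and scenario
ranking are scale-invariant — and matches the method's own framing as a
comparative tool rather than a source of absolute damage values.

Multi-year aggregation happens after per-year normalization, preserving
the yearly series that entropy weighting needs.

## Weighting

EPI weights are fixed at health 0.4 / ecosystem 0.6. Entropy weights
implement the standard procedure — per-group proportions, entropy
`e = −(1/ln t)·Σ p ln p` with `0·ln 0 := 0`, divergence `d = 1 − e`,
weights `d / Σd` — because the bare entropy statistic alone cannot produce
a weight pair summing to one; the bare statistic is still exposed as
`entropy_statistic` for diagnostics. Edge cases: a constant series has
zero divergence and zero weight; if *every* group is constant the weights
fall back to uniform (documented tie-break); an all-zero group is rejected
as degenerate rather than assigned a weight.

Entropy weights are computed from the pooled multi-scenario yearly series
by default, which yields a single weight pair for the whole comparison;
`entropy_pooled=False` derives weights per scenario. Both modes are
provided because the published 0.44/0.56 pair could have been derived
either way; neither is asserted as "the" original computation, and the
published pair itself is bundled for desk-scale reproduction.

## Nutrition and FEF

`S = T_cal / (B × P)` with B = 2,000 cal/day/person and P = 7.75 × 10⁹,
both config-overridable; MCal/yr converts to cal/day over a 365-day year.
`FEF = C / S` with `S = 0` rejected as undefined. Report display rounds
FEF to 2 decimals and percentages to 1 decimal; full precision is kept
internally. The EPI-weighted base FEF computed from the bundled (rounded)
summary inputs is 0.75; the entropy-weighted value, 0.61, is the
reproduction target asserted in tests, since the EPI figure is sensitive
to rounding of its inputs.

## Synthetic generator

The generator emulates the study basin's structure: ten land uses over
2,000 ha (areas back-calculated from the published nutrition, yield and
caloric-value columns, since areas themselves are not printed), seven
years, and three scenarios. Its statistical assumptions:

* **Interannual variability** is a single multiplicative lognormal shock
  per year (mean 1, default CV 0.45), shared across pollutants and land
  uses — precipitation acts as a common driver, and the default CV
  reproduces the ~3–4× wet/dry swing of the emulated basin's annual loads.
* **Scenarios are counterfactuals over the same climate period**: by
  default the same year shocks apply to every scenario, so configured
  load multipliers (TN 0.662/0.401, TP 0.923/0.791 for the two BMP
  levels, i.e. one minus the published average reductions) are recovered
  exactly, noise or no noise. `shared_year_shocks=False` draws
  independent shocks per scenario, emulating comparisons across different
  periods; recovery then holds only in expectation.
* **ET series** come from a Hargreaves–Samani reference-ET model
  (`0.0023·0.408·Ra·(T̄+17.8)·√(Tmax−Tmin)`) driven by a sinusoidal annual
  temperature/radiation cycle for a semi-arid highland climate (mean 13 °C,
  amplitude 12 °C, diurnal range 14 °C, Ra 30 ± 10 MJ/m²/day), scaled per
  land use by crop coefficients with and without irrigation. Irrigation
  reduction shrinks the ETb − ETa increment proportionally.
* **Yield responses** default to the published per-land-use yield ratios.

What the generator does **not** emulate: physical rainfall–runoff and
filter-strip trapping (BMP effects are folded into the calibrated
multipliers), nutrient speciation (TN/TP only by default), within-year
dynamics, spatial HRU structure, and any correlation between yield and
weather. Passing tests on synthetic data therefore demonstrate the
accounting chain's correctness and the comparison machinery's statistical
behaviour — not predictive skill on a real basin.

All randomness flows from one integer seed through a single PCG64
generator; a fixed seed reproduces identical CSV bytes.

## Numerical choices and problem sizes

* Weights must sum to 1 within 1e−9; WF component sums are exact float
  sums checked at 1e−9 relative in tests.
* The LCIA stage is checked against an explicit cell-by-cell oracle at
  1e−12 relative.
* Degenerate inputs fail loudly: zero production (per-ton WF), zero
  nutrition (FEF), single-year series (entropy), missing standards or
  factor rows (configuration errors naming the item).
* Test and demonstration runs use the study-scale problem: 10 land uses,
  3 scenarios, 7 years, and a 200-seed Monte-Carlo sweep for parameter
  recovery; the whole suite runs in seconds on one CPU.

## Limitations

* Only eutrophication and water-consumption midpoints are implemented;
  toxicity, land-use-change and climate categories would need additional
  factor tables and inventory flows.
* Coefficient uncertainty is not propagated; results are point values.
* The grey-WF max rule and the freshwater-discharge assumption are fixed
  modelling choices, not sensitivity-analyzed.
* Absolute normalized damages depend on a normalization chain that the
  source material does not fully specify (see above); use the outputs
  comparatively.
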