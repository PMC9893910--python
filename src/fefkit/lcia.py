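"""Midpoint characterization, endpoint damages and normalization.

Life-cycle impact assessment stage, following the ReCiPe midpoint/endpoint
scheme.  Nutrient emissions (kg/yr to the receiving freshwater) are
characterized into eutrophication midpoints in equivalent units (kg P-eq to
freshwater, kg N-eq to marine water); the crops' total water footprint (m3)
passes through unchanged as the water-consumption midpoint.  Midpoints are
converted to damage-based endpoints — human health in DALY, ecosystem loss
in species.yr — and each endpoint is divided by a global per-person
normalization constant, yielding dimensionless per-person scores R.

The characterization and endpoint factors are data, not code: the bundled
defaults transcribe the published coefficient tables and can be overridden
wholesale.  Emissions are assumed discharged to freshwater (the lake);
indirect marine eutrophication uses the freshwater-emission marine factors,
since nutrient pollution reaches marine systems in the long run even when
not discharged to the sea directly.  Factor-table cells that the published
table leaves blank are "no pathway": the flow simply does not contribute to
that category.

Both stages are linear maps of the inventory, so per-year results can be
summed or averaged freely; here multi-year averaging happens after per-year
normalization, preserving the per-year series needed by entropy weighting.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Mapping

from .basin_data import Pollutant
from .errors import ConfigurationError

import pandas as pd

__all__ = [
    "MidpointCategory",
    "EndpointRow",
    "EndpointGroup",
    "EndpointFactor",
    "EndpointDamage",
    "SPECIES_ALIASES",
    "characterize",
    "to_endpoints",
    "normalize",
    "endpoint_factors_from_frame",
]

logger = logging.getLogger(__name__)


class MidpointCategory(str, enum.Enum):
    FRESHWATER_EUTROPHICATION = "freshwater_eutrophication"  # kg P-eq to freshwater
    MARINE_EUTROPHICATION = "marine_eutrophication"  # kg N-eq to marine water
    WATER_CONSUMPTION = "water_consumption"  # m3


class EndpointRow(str, enum.Enum):
    HEALTH_WATER = "health_water"
    TERRESTRIAL_WATER = "terrestrial_water"
    FRESHWATER_EUTRO = "freshwater_eutro"
    FRESHWATER_WATER = "freshwater_water"
    MARINE_EUTRO = "marine_eutro"


class EndpointGroup(str, enum.Enum):
    HUMAN_HEALTH = "human_health"
    ECOSYSTEM = "ecosystem"


@dataclass(frozen=True)
class EndpointFactor:
    """Damage factor and normalization constant for one endpoint row."""

    endpoint_row: EndpointRow
    group: EndpointGroup
    midpoint_category: MidpointCategory
    factor: float  # DALY or species.yr per midpoint unit
    unit: str
    normalization: float  # per-person divisor

    def __post_init__(self) -> None:
        if self.factor < 0:
            raise ConfigurationError(f"{self.endpoint_row.value}: factor must be >= 0")
        if self.normalization <= 0:
            raise ConfigurationError(f"{self.endpoint_row.value}: normalization must be > 0")


@dataclass(frozen=True)
class EndpointDamage:
    """Damage and normalized per-person score for one endpoint row."""

    endpoint_row: EndpointRow
    group: EndpointGroup
    damage: float  # DALY or species.yr
    normalized: float  # dimensionless per person


#: map from pollutant identifiers to the species names of the factor table.
#: TN and TP aggregates are characterized with the nitrate and elemental-
#: phosphorus factors respectively (documented, overridable alias).
SPECIES_ALIASES: dict[Pollutant, str] = {
    Pollutant.NO3: "nitrate",
    Pollutant.NO2: "nitrite",
    Pollutant.PO4: "phosphate",
    Pollutant.TN: "nitrate",
    Pollutant.TP: "phosphorus",
}


def characterize(
    loads: Mapping[Pollutant, float],
    water_consumption_m3: float,
    midpoint_factors: Mapping[tuple[str, str, str], float],
    emission_compartment: str = "freshwater",
    species_aliases: Mapping[Pollutant, str] | None = None,
    strict: bool = True,
) -> dict[MidpointCategory, float]:
    """Convert an inventory into midpoint scores, ``Q = T x M``.

    ``loads`` are annual emissions (kg) keyed by pollutant;
    ``water_consumption_m3`` is the total water footprint, passed through
    with an implicit factor of 1.  ``midpoint_factors`` is keyed by
    (species, emission compartment, category).  A pollutant with no factor
    row in any category is an error in strict mode, otherwise logged and
    skipped; a pollutant with no alias at all (no characterization pathway,
    e.g. ammonia in the bundled table) is always logged and skipped.
    """
    aliases = dict(SPECIES_ALIASES if species_aliases is None else species_aliases)
    out = {cat: 0.0 for cat in MidpointCategory}
    out[MidpointCategory.WATER_CONSUMPTION] = float(water_consumption_m3)
    species_in_table = {k[0] for k in midpoint_factors}
    for pollutant, load in loads.items():
        species = aliases.get(pollutant)
        if species is None:
            logger.info("pollutant %s has no characterization pathway; skipped", pollutant.value)
            continue
        if species not in species_in_table:
            msg = f"no midpoint factor for species {species!r} (pollutant {pollutant.value})"
            if strict:
                raise ConfigurationError(msg)
            logger.warning("%s; skipped", msg)
            continue
        for cat in (MidpointCategory.FRESHWATER_EUTROPHICATION, MidpointCategory.MARINE_EUTROPHICATION):
            factor = midpoint_factors.get((species, emission_compartment, cat.value))
            if factor is not None:
                out[cat] += load * factor
    return out


def endpoint_factors_from_frame(frame: pd.DataFrame) -> dict[EndpointRow, EndpointFactor]:
    """Build typed endpoint factors from a coefficient table frame."""
    factors: dict[EndpointRow, EndpointFactor] = {}
    for row in frame.itertuples():
        er = EndpointRow(row.endpoint_row)
        factors[er] = EndpointFactor(
            endpoint_row=er,
            group=EndpointGroup(row.group),
            midpoint_category=MidpointCategory(row.midpoint_category),
            factor=float(row.factor),
            unit=str(row.unit),
            normalization=float(row.normalization),
        )
    return factors


def to_endpoints(
    midpoints: Mapping[MidpointCategory, float],
    endpoint_factors: Mapping[EndpointRow, EndpointFactor],
) -> dict[EndpointRow, EndpointDamage]:
    """Convert midpoints into damage-based endpoints, ``D = Q x E``.

    Every endpoint row of the factor table is produced; normalized scores
    (``R = D / N``) are filled in at the same time since the normalization
    constant lives on the factor row.
    """
    for er in EndpointRow:
        if er not in endpoint_factors:
            raise ConfigurationError(f"missing endpoint factor for row {er.value}")
    out: dict[EndpointRow, EndpointDamage] = {}
    for er, fac in endpoint_factors.items():
        q = midpoints.get(fac.midpoint_category)
        if q is None:
            raise ConfigurationError(
                f"endpoint row {er.value} needs midpoint {fac.midpoint_category.value}, absent from input"
            )
        damage = q * fac.factor
        out[er] = EndpointDamage(
            endpoint_row=er, group=fac.group, damage=damage, normalized=damage / fac.normalization
        )
    return out


def normalize(
    damages: Mapping[EndpointRow, EndpointDamage],
) -> tuple[dict[EndpointRow, EndpointDamage], float, float]:
    """Per-group sums of normalized endpoints.

    Returns ``(damages, R_health, R_ecosystem)`` where R_health sums the
    normalized human-health rows and R_ecosystem the normalized terrestrial,
    freshwater and marine rows.
    """
    r_health = sum(d.normalized for d in damages.values() if d.group is EndpointGroup.HUMAN_HEALTH)
    r_eco = sum(d.normalized for d in damages.values() if d.group is EndpointGroup.ECOSYSTEM)
    return dict(damages), r_health, r_eco
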