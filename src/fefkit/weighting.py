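"""Aggregation of normalized endpoint groups into a single cumulative impact.

The cumulative impact is a weighted sum ``C = w_health * R_health +
w_ecosystem * R_ecosystem`` (dimensionless per person per year).  Two
weighting schemes are supported:

* EPI — the environmental performance index's fixed weights, 0.4 for human
  health and 0.6 for ecosystem;
* entropy — data-driven weights from the interannual dispersion of each
  group's normalized series: groups whose yearly scores vary more carry
  more information and receive larger weights.

The entropy procedure is the standard one: for each group z with yearly
values R_1..R_t, form proportions p_i = R_i / sum(R), compute the entropy
``e = -(1/ln t) * sum_i p_i ln p_i`` (with 0 ln 0 := 0), the divergence
``d = 1 - e``, and weights ``w_z = d_z / sum_z d_z``.  A constant series has
e = 1 and receives zero weight.  The bare entropy statistic (without the
proportion and divergence normalizations, which on its own cannot yield a
weight set summing to one) is exposed separately as a diagnostic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .errors import DataValidationError, DegenerateInputError, DomainError

__all__ = [
    "ImpactWeights",
    "CumulativeImpact",
    "aggregate",
    "entropy_weights",
    "entropy_statistic",
]

_WEIGHT_SUM_TOL = 1e-9


@dataclass(frozen=True)
class ImpactWeights:
    """Endpoint-group weights; must be convex (sum to 1)."""

    w_health: float
    w_ecosystem: float
    method: str = "user"  # "EPI", "entropy" or "user"

    def __post_init__(self) -> None:
        for name in ("w_health", "w_ecosystem"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DataValidationError(f"{name} must be in [0,1], got {v}")
        if abs(self.w_health + self.w_ecosystem - 1.0) > _WEIGHT_SUM_TOL:
            raise DataValidationError(
                f"weights must sum to 1, got {self.w_health} + {self.w_ecosystem}"
            )


#: fixed EPI weights (health 0.4, ecosystem 0.6)
EPI = ImpactWeights(w_health=0.4, w_ecosystem=0.6, method="EPI")


@dataclass(frozen=True)
class CumulativeImpact:
    """Annual environmental damage per person: weighted sum of group scores."""

    value: float
    scenario: str
    method: str


def aggregate(r_health: float, r_ecosystem: float, weights: ImpactWeights, scenario: str = "") -> CumulativeImpact:
    """Cumulative impact ``C = w_h * R_health + w_e * R_ecosystem``."""
    value = weights.w_health * r_health + weights.w_ecosystem * r_ecosystem
    return CumulativeImpact(value=value, scenario=scenario, method=weights.method)


def entropy_statistic(series: Sequence[float]) -> float:
    """Bare entropy statistic ``-(1/ln t) * sum(R ln R)`` over raw values.

    Diagnostic only: raw values are used without proportion normalization,
    so the result is not a weight.  Zero values contribute 0 (0 ln 0 := 0).
    """
    t = len(series)
    if t < 2:
        raise DomainError(f"need at least 2 observations, got {t}")
    return -sum(r * math.log(r) for r in series if r > 0) / math.log(t)


def entropy_weights(series: Mapping[str, Sequence[float]]) -> dict[str, float]:
    """Entropy weights from per-year normalized series, one per group.

    All series must have the same length t >= 2 and non-negative values;
    an all-zero series carries no information to apportion and is rejected.
    When every group is perfectly constant (all divergences zero) the
    groups are indistinguishable and weights fall back to uniform.
    """
    if not series:
        raise DomainError("at least one group series is required")
    lengths = {len(v) for v in series.values()}
    if len(lengths) != 1:
        raise DataValidationError(f"group series have unequal lengths: { {k: len(v) for k, v in series.items()} }")
    t = lengths.pop()
    if t < 2:
        raise DomainError(f"entropy weighting needs at least 2 years of data, got {t}")
    divergence: dict[str, float] = {}
    for name, values in series.items():
        if any(v < 0 for v in values):
            raise DataValidationError(f"group {name!r}: negative values not allowed")
        total = sum(values)
        if total == 0:
            raise DegenerateInputError(f"group {name!r} is all-zero; entropy weight undefined")
        p = [v / total for v in values]
        e = -sum(pi * math.log(pi) for pi in p if pi > 0) / math.log(t)
        divergence[name] = 1.0 - e
    d_sum = sum(divergence.values())
    if d_sum <= 0:
        # all groups constant over years: no dispersion signal, uniform tie-break
        n = len(series)
        return {name: 1.0 / n for name in series}
    return {name: d / d_sum for name, d in divergence.items()}


def entropy_weights_health_eco(
    health_series: Sequence[float], eco_series: Sequence[float]
) -> ImpactWeights:
    """Entropy weights for the two endpoint groups, as an ImpactWeights."""
    w = entropy_weights({"human_health": list(health_series), "ecosystem": list(eco_series)})
    return ImpactWeights(w_health=w["human_health"], w_ecosystem=w["ecosystem"], method="entropy")
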