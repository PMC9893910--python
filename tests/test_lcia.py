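"""Midpoint characterization, endpoint conversion and normalization."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fefkit import Pollutant, characterize, normalize, to_endpoints
from fefkit.errors import ConfigurationError
from fefkit.lcia import (
    EndpointGroup,
    EndpointRow,
    MidpointCategory,
    endpoint_factors_from_frame,
)


@pytest.fixture(scope="module")
def efac(fx):
    return endpoint_factors_from_frame(fx.endpoint_factors)


class TestCharacterize:
    def test_nitrate_to_marine_n_eq(self, fx):
        mids = characterize({Pollutant.NO3: 100.0}, 0.0, fx.midpoint_factors)
        assert mids[MidpointCategory.MARINE_EUTROPHICATION] == pytest.approx(7.0)
        assert mids[MidpointCategory.FRESHWATER_EUTROPHICATION] == 0.0

    def test_phosphate_to_freshwater_p_eq(self, fx):
        mids = characterize({Pollutant.PO4: 10.0}, 0.0, fx.midpoint_factors)
        assert mids[MidpointCategory.FRESHWATER_EUTROPHICATION] == pytest.approx(330.0)

    def test_zero_inventory_all_zero(self, fx):
        mids = characterize({}, 0.0, fx.midpoint_factors)
        assert all(v == 0.0 for v in mids.values())

    def test_water_consumption_passes_through(self, fx):
        mids = characterize({}, 12345.0, fx.midpoint_factors)
        assert mids[MidpointCategory.WATER_CONSUMPTION] == 12345.0

    def test_ammonia_has_no_pathway_and_is_skipped(self, fx):
        # the bundled table prints no factor column for ammonia
        mids = characterize({Pollutant.NH3: 50.0}, 0.0, fx.midpoint_factors)
        assert mids[MidpointCategory.MARINE_EUTROPHICATION] == 0.0
        assert mids[MidpointCategory.FRESHWATER_EUTROPHICATION] == 0.0

    def test_unknown_species_strict_mode_errors(self, fx):
        aliases = {Pollutant.NH3: "ammonia"}  # no such row in the table
        with pytest.raises(ConfigurationError, match="ammonia"):
            characterize({Pollutant.NH3: 1.0}, 0.0, fx.midpoint_factors, species_aliases=aliases)

    def test_tn_tp_aggregate_aliases(self, fx):
        mids = characterize({Pollutant.TN: 100.0, Pollutant.TP: 10.0}, 0.0, fx.midpoint_factors)
        assert mids[MidpointCategory.MARINE_EUTROPHICATION] == pytest.approx(7.0)  # nitrate factor
        assert mids[MidpointCategory.FRESHWATER_EUTROPHICATION] == pytest.approx(10.0)  # elemental P


class TestEndpoints:
    def test_water_consumption_health_damage(self, efac):
        mids = {
            MidpointCategory.WATER_CONSUMPTION: 1e6,
            MidpointCategory.FRESHWATER_EUTROPHICATION: 0.0,
            MidpointCategory.MARINE_EUTROPHICATION: 0.0,
        }
        d = to_endpoints(mids, efac)
        assert d[EndpointRow.HEALTH_WATER].damage == pytest.approx(2.22)  # DALY
        assert d[EndpointRow.TERRESTRIAL_WATER].damage == pytest.approx(0.0135)  # species.yr

    def test_p_eq_freshwater_damage(self, efac):
        mids = {
            MidpointCategory.WATER_CONSUMPTION: 0.0,
            MidpointCategory.FRESHWATER_EUTROPHICATION: 1.0,
            MidpointCategory.MARINE_EUTROPHICATION: 0.0,
        }
        d = to_endpoints(mids, efac)
        assert d[EndpointRow.FRESHWATER_EUTRO].damage == pytest.approx(6.71e-7)

    def test_missing_factor_is_configuration_error(self, efac):
        partial = {k: v for k, v in efac.items() if k is not EndpointRow.MARINE_EUTRO}
        with pytest.raises(ConfigurationError, match="marine_eutro"):
            to_endpoints({c: 0.0 for c in MidpointCategory}, partial)

    def test_normalized_identity_and_group_sums(self, efac):
        mids = {
            MidpointCategory.WATER_CONSUMPTION: 1.96e-4 / 2.22e-6,  # health damage == its N
            MidpointCategory.FRESHWATER_EUTROPHICATION: 0.0,
            MidpointCategory.MARINE_EUTROPHICATION: 0.0,
        }
        damages = to_endpoints(mids, efac)
        assert damages[EndpointRow.HEALTH_WATER].normalized == pytest.approx(1.0)
        _, r_h, r_e = normalize(damages)
        eco_rows = [d.normalized for d in damages.values() if d.group is EndpointGroup.ECOSYSTEM]
        assert r_e == sum(eco_rows)  # exact decomposition
        assert r_h == damages[EndpointRow.HEALTH_WATER].normalized

    def test_zero_damages_zero_scores(self, efac):
        damages = to_endpoints({c: 0.0 for c in MidpointCategory}, efac)
        _, r_h, r_e = normalize(damages)
        assert r_h == 0.0 and r_e == 0.0


# --- independent brute-force oracle -----------------------------------------
# Frozen transcription of the published coefficient tables, evaluated by
# explicit scalar arithmetic, independent of the package's data files.

_ORACLE_MID = {"NO3": ("marine", 0.07), "NO2": ("marine", 0.09), "PO4": ("fresh", 33.0), "TP": ("fresh", 1.0), "TN": ("marine", 0.07)}
_ORACLE_END = [
    # (group, driver, factor, normalization)
    ("health", "water", 2.22e-6, 1.96e-4),
    ("eco", "water", 1.35e-8, 3.48e-6),
    ("eco", "fresh", 6.71e-7, 4.90e-7),
    ("eco", "water", 6.04e-13, 6.16e-10),
    ("eco", "marine", 1.70e-9, 6.12e-9),
]


def _oracle(loads: dict[str, float], wf: float) -> tuple[float, float]:
    q = {"fresh": 0.0, "marine": 0.0, "water": wf}
    for species, mass in loads.items():
        cat, m = _ORACLE_MID[species]
        q[cat] += mass * m
    r_h = r_e = 0.0
    for group, driver, e, n in _ORACLE_END:
        r = q[driver] * e / n
        if group == "health":
            r_h += r
        else:
            r_e += r
    return r_h, r_e


@given(
    no3=st.floats(0, 1e4),
    no2=st.floats(0, 1e3),
    po4=st.floats(0, 1e3),
    wf=st.floats(0, 1e8),
)
@settings(max_examples=100, deadline=None)
def test_pipeline_matches_bruteforce_oracle(fx, no3, no2, po4, wf):
    loads = {Pollutant.NO3: no3, Pollutant.NO2: no2, Pollutant.PO4: po4}
    mids = characterize(loads, wf, fx.midpoint_factors)
    damages = to_endpoints(mids, endpoint_factors_from_frame(fx.endpoint_factors))
    _, r_h, r_e = normalize(damages)
    oh, oe = _oracle({"NO3": no3, "NO2": no2, "PO4": po4}, wf)
    assert r_h == pytest.approx(oh, rel=1e-12, abs=1e-300)
    assert r_e == pytest.approx(oe, rel=1e-12, abs=1e-300)


@given(
    a=st.tuples(st.floats(0, 1e4), st.floats(0, 1e4), st.floats(0, 1e6)),
    b=st.tuples(st.floats(0, 1e4), st.floats(0, 1e4), st.floats(0, 1e6)),
    k=st.floats(0, 100),
)
@settings(max_examples=100, deadline=None)
def test_lcia_is_linear_in_inventory(fx, a, b, k):
    efac = endpoint_factors_from_frame(fx.endpoint_factors)

    def score(no3, po4, wf):
        mids = characterize({Pollutant.NO3: no3, Pollutant.PO4: po4}, wf, fx.midpoint_factors)
        _, r_h, r_e = normalize(to_endpoints(mids, efac))
        return r_h, r_e

    sa, se = score(*a)
    sb, sbe = score(*b)
    sh_sum, se_sum = score(a[0] + b[0], a[1] + b[1], a[2] + b[2])
    assert sh_sum == pytest.approx(sa + sb, rel=1e-9, abs=1e-300)
    assert se_sum == pytest.approx(se + sbe, rel=1e-9, abs=1e-300)
    sh_k, se_k = score(k * a[0], k * a[1], k * a[2])
    assert sh_k == pytest.approx(k * sa, rel=1e-9, abs=1e-300)
    assert se_k == pytest.approx(k * se, rel=1e-9, abs=1e-300)
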