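"""Heat-balance solver: geometry, resistances, convection, thermoregulation."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermorange import endotherm as en
from tests.conftest import make_hour


class TestGeometryFromMass:
    def test_total_volume_and_sphere_equivalent_radius(self):
        parts = en.geometry_from_mass(0.00875, 875.0)
        volume = sum(p.volume_m3 for p in parts)
        assert volume == pytest.approx(1.0e-5, rel=1e-9)
        r = (3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0)
        assert r == pytest.approx(0.01337, abs=5e-5)

    def test_measured_dims_within_density_band_kept(self):
        parts = en.geometry_from_mass(0.1, 875.0)
        mass_at_880 = 880.0 * sum(p.volume_m3 for p in parts)
        kept = en.geometry_from_mass(mass_at_880, 875.0, measured_parts=parts)
        assert all(k.dims_m == p.dims_m for k, p in zip(kept, parts))

    def test_measured_dims_outside_band_rescaled(self):
        parts = en.geometry_from_mass(0.1, 875.0)
        mass_at_1000 = 1000.0 * sum(p.volume_m3 for p in parts)
        scaled = en.geometry_from_mass(mass_at_1000, 875.0, measured_parts=parts)
        implied = mass_at_1000 / sum(p.volume_m3 for p in scaled)
        assert implied == pytest.approx(875.0, rel=1e-9)

    def test_isometric_doubling(self):
        p1 = en.geometry_from_mass(0.1, 875.0)
        p2 = en.geometry_from_mass(0.2, 875.0)
        for a, b in zip(p1, p2):
            for d1, d2 in zip(a.dims_m, b.dims_m):
                assert d2 / d1 == pytest.approx(2.0 ** (1.0 / 3.0), rel=1e-9)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            en.geometry_from_mass(0.0, 875.0)


class TestInsulationResistance:
    def _feathered(self):
        return en.BodyPart(
            "torso", "ellipsoid", (0.04, 0.02, 0.02),
            feather_depth_dorsal_m=0.01, feather_depth_ventral_m=0.008,
            feather_length_dorsal_m=0.025, feather_length_ventral_m=0.02,
        )

    def test_ptiloerection_increases_resistance(self):
        part = self._feathered()
        r1 = en.insulation_resistance(part, en.ThermoState(0.41, 1.0))
        r15 = en.insulation_resistance(part, en.ThermoState(0.41, 1.5))
        assert r15 > r1

    def test_flesh_term_scales_inversely_with_conductivity(self):
        part = self._feathered()
        lo = en.insulation_resistance(part, en.ThermoState(0.41, 1.0))
        hi = en.insulation_resistance(part, en.ThermoState(2.80, 1.0))
        flesh_lo = 0.5 * part.flesh_radius_m / 0.41
        flesh_hi = 0.5 * part.flesh_radius_m / 2.80
        assert lo - hi == pytest.approx(flesh_lo - flesh_hi, rel=1e-12)
        assert flesh_hi / flesh_lo == pytest.approx(0.41 / 2.80, rel=1e-12)

    def test_bare_part_has_no_plumage_term(self):
        leg = en.BodyPart("leg", "cylinder", (0.05, 0.005), bare=True)
        state_flat = en.ThermoState(0.41, 1.0)
        state_fluffed = en.ThermoState(0.41, 1.5)
        assert en.insulation_resistance(leg, state_flat) == en.insulation_resistance(leg, state_fluffed)


class TestConvectiveCoefficient:
    def test_free_convection_floor_at_zero_wind(self):
        assert en.convective_coefficient(0.0, 0.03) == en.FREE_CONVECTION_H

    def test_square_root_wind_dependence(self):
        h1 = en.convective_coefficient(1.0, 0.01)
        h4 = en.convective_coefficient(4.0, 0.01)
        assert h4 / h1 == pytest.approx(2.0, rel=1e-12)

    def test_larger_bodies_shed_less_per_area(self):
        assert en.convective_coefficient(3.0, 0.10) < en.convective_coefficient(3.0, 0.02)

    def test_negative_wind_rejected(self):
        with pytest.raises(ValueError):
            en.convective_coefficient(-0.1, 0.03)


def closed_form_m(traits, state, air, wind, tr=None):
    """Independent series-resistance conductance oracle (no solar/evaporation)."""
    tr = air if tr is None else tr
    hr = 4.0 * en.SURFACE_EMISSIVITY * en.STEFAN_BOLTZMANN * (
        0.5 * (air + traits.core_temp_c) + 273.15
    ) ** 3
    tb = traits.core_temp_c - traits.core_skin_delta_c
    total = 0.0
    for part in traits.parts:
        h = en.convective_coefficient(wind, part.characteristic_dimension_m)
        r = en.insulation_resistance(
            part, state, fat_fraction=traits.fat_fraction, feather_diameter_m=traits.feather_diameter_m
        )
        # mixed-sink equivalent air temperature for conduction to (air, radiant)
        t_env = (h * air + hr * tr) / (h + hr)
        total += part.area_m2 * (tb - t_env) / (r + 1.0 / (h + hr))
    return total


class TestSolveHeatBalance:
    def test_zero_gradient_zero_metabolism(self, finch):
        mc = make_hour(air=finch.core_temp_c, wind=1.0, solar=0.0)
        res = en.solve_heat_balance(finch, en.neutral_state(finch), mc, disable_evaporation=True)
        assert res.m_required_w == pytest.approx(0.0, abs=1e-9)

    def test_matches_series_resistance_oracle(self, finch):
        state = en.neutral_state(finch)
        mc = make_hour(air=0.0, wind=3.0, solar=0.0)
        res = en.solve_heat_balance(finch, state, mc, disable_evaporation=True)
        assert res.m_required_w == pytest.approx(closed_form_m(finch, state, 0.0, 3.0), rel=1e-9)

    def test_requirement_falls_with_air_temperature(self, finch):
        state = en.neutral_state(finch)
        m = [
            en.solve_heat_balance(finch, state, make_hour(air=t, wind=2.0), disable_evaporation=True).m_required_w
            for t in (-20.0, 0.0, 20.0, 40.0)
        ]
        assert all(a > b for a, b in zip(m, m[1:]))

    def test_requirement_rises_with_wind(self, finch):
        state = en.neutral_state(finch)
        m = [
            en.solve_heat_balance(finch, state, make_hour(air=0.0, wind=w), disable_evaporation=True).m_required_w
            for w in (0.5, 2.0, 8.0)
        ]
        assert m[0] <= m[1] <= m[2]

    def test_energy_conservation(self, finch):
        mc = make_hour(air=-5.0, wind=4.0, rh=70.0, solar=300.0, sky=-20.0, ground=2.0)
        res = en.solve_heat_balance(finch, en.neutral_state(finch), mc, work_fraction=0.25)
        fluxes = [
            res.m_required_w, res.solar_absorbed_w, res.convection_w, res.net_longwave_w,
            res.cutaneous_evap_w, res.respiratory_evap_w, res.work_export_w,
        ]
        assert abs(res.flux_residual_w()) <= 1e-6 * max(abs(f) for f in fluxes)

    def test_shade_removes_solar_only(self, finch):
        mc = make_hour(air=30.0, wind=1.0, solar=600.0)
        lit = en.solve_heat_balance(finch, en.neutral_state(finch), mc)
        shaded_state = dataclasses.replace(en.neutral_state(finch), in_shade=True)
        shaded = en.solve_heat_balance(finch, shaded_state, mc)
        assert shaded.solar_absorbed_w == 0.0
        assert lit.solar_absorbed_w > 0.0
        assert shaded.m_required_w > lit.m_required_w


class TestThermoregulate:
    def test_state_unchanged_when_already_in_band(self, finch):
        state = en.neutral_state(finch)
        # find an air temperature whose neutral requirement is the target
        mc0 = make_hour(air=25.0, wind=2.0)
        target = en.solve_heat_balance(finch, state, mc0).m_required_w
        res = en.thermoregulate(finch, mc0, target)
        assert res.state == state
        assert res.status == "balanced"

    def test_vasoconstriction_precedes_ptiloerection(self, finch):
        state = en.neutral_state(finch)
        target = finch.activity_multiplier * finch.bmr_w
        for air in np.arange(35.0, -40.0, -0.25):
            mc = make_hour(air=float(air), wind=2.0)
            if en.solve_heat_balance(finch, state, mc).m_required_w > 1.05 * target:
                res = en.thermoregulate(finch, mc, target)
                assert res.state.k_flesh == finch.k_flesh_min
                # first cold response: conductivity drop, plumage untouched
                first = en.solve_heat_balance(
                    finch, en.ThermoState(finch.k_flesh_min, 1.0, finch.wet_skin_min), mc
                )
                if first.m_required_w <= 1.05 * target:
                    assert res.state.plumage_depth_multiplier == 1.0
                return
        pytest.fail("no cold-stressed condition found")

    def test_deep_cold_returns_extreme_state(self, finch):
        res = en.thermoregulate(finch, make_hour(air=-35.0, wind=6.0), finch.bmr_w)
        assert res.state.k_flesh == finch.k_flesh_min
        assert res.state.plumage_depth_multiplier == pytest.approx(finch.ptiloerection_max)
        assert res.m_required_w > 1.05 * finch.bmr_w

    def test_heat_stress_ends_wet_and_shaded(self, finch):
        mc = make_hour(air=finch.core_temp_c + 6.0, wind=0.5, rh=30.0, solar=900.0)
        res = en.thermoregulate(finch, mc, finch.activity_multiplier * finch.bmr_w)
        if res.m_required_w < 0.95 * finch.activity_multiplier * finch.bmr_w:
            assert res.state.in_shade
            assert res.state.wet_skin_fraction == pytest.approx(finch.wet_skin_max)
            assert res.status == "heat_death" or res.m_required_w >= finch.bmr_w

    def test_cascade_deterministic_and_idempotent(self, finch):
        mc = make_hour(air=-10.0, wind=3.0)
        r1 = en.thermoregulate(finch, mc, finch.bmr_w)
        r2 = en.thermoregulate(finch, mc, finch.bmr_w)
        assert r1.m_required_w == r2.m_required_w
        assert r1.state == r2.state
        again = en.solve_heat_balance(finch, r1.state, mc)
        assert again.m_required_w == pytest.approx(r1.m_required_w, rel=1e-12)


class TestClosedFormEquivalence:
    @given(
        mass=st.floats(0.008, 1.0),
        air=st.floats(-35.0, 35.0),
        wind=st.floats(0.0, 10.0),
        k_idx=st.floats(0.0, 1.0),
        mult=st.floats(1.0, 1.5),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_solver_equals_conductance_formula_without_solar_evap(self, mass, air, wind, k_idx, mult):
        from thermorange import synthetic_data as sd

        traits = sd.generate_species("medium_parakeet", seed=3)
        traits = dataclasses.replace(
            traits, mass_kg=mass, parts=en.geometry_from_mass(mass, 875.0), muscle_efficiency=0.0
        )
        # re-dress the generated (bare-geometry) parts with plumage
        traits = dataclasses.replace(
            traits,
            parts=[
                dataclasses.replace(
                    p,
                    feather_depth_dorsal_m=0.0 if p.bare else 0.01,
                    feather_depth_ventral_m=0.0 if p.bare else 0.008,
                    feather_length_dorsal_m=0.0 if p.bare else 0.02,
                    feather_length_ventral_m=0.0 if p.bare else 0.018,
                )
                for p in traits.parts
            ],
        )
        k = traits.k_flesh_min + k_idx * (traits.k_flesh_max - traits.k_flesh_min)
        state = en.ThermoState(k, mult, traits.wet_skin_min)
        mc = make_hour(air=air, wind=wind, solar=0.0)
        res = en.solve_heat_balance(traits, state, mc, disable_evaporation=True)
        assert res.m_required_w == pytest.approx(closed_form_m(traits, state, air, wind), rel=1e-9, abs=1e-12)
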