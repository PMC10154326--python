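"""Suitability rules, the at-risk classification and the compiled map engine."""

import dataclasses

import numpy as np
import pytest

from thermorange import suitability as su
from thermorange import synthetic_data as sd
from thermorange.suitability import MonthEnergetics


def _stub_month(month, survival=None, breeding=None):
    return MonthEnergetics(
        month=month,
        hourly_m_required_w=np.zeros(24),
        daily_mean_multiple_of_bmr=2.0,
        survival_ok=bool(survival) if survival is not None else False,
        breeding_ok=bool(breeding) if breeding is not None else False,
    )


def oracle_at_risk(surv_flags, breed_flags, duration):
    """Independent rule oracle: year-round survival + circular breeding run."""
    if not all(surv_flags):
        return False
    if all(not b for b in breed_flags):
        return False
    doubled = list(breed_flags) + list(breed_flags)
    run = best = 0
    for f in doubled:
        run = run + 1 if f else 0
        best = max(best, run)
    return best >= min(duration, 12)


class TestCircularRun:
    def test_wraparound(self):
        flags = [True, False, False, False, False, False, False, False, False, False, True, True]
        assert su.has_circular_run(flags, 3)

    def test_summer_run(self):
        flags = [False] * 4 + [True] * 4 + [False] * 4
        assert su.has_circular_run(flags, 3)
        assert not su.has_circular_run(flags, 5)

    def test_no_breeding_months(self):
        assert not su.has_circular_run([False] * 12, 1)


class TestPixelAtRisk:
    def test_matches_rule_oracle_on_sampled_patterns(self, finch):
        rng = np.random.default_rng(0)
        traits = dataclasses.replace(finch, breeding_duration_months=3)
        for _ in range(300):
            surv = rng.random(12) < 0.8
            breed = rng.random(12) < 0.5
            months = [
                (_stub_month(m + 1, survival=surv[m]), _stub_month(m + 1, breeding=breed[m]))
                for m in range(12)
            ]
            assert su.pixel_at_risk(traits, months) == oracle_at_risk(surv, breed, 3)

    def test_one_failed_survival_month_fails_pixel(self, finch):
        surv = [True] * 12
        surv[7] = False
        months = [
            (_stub_month(m + 1, survival=surv[m]), _stub_month(m + 1, breeding=True)) for m in range(12)
        ]
        assert not su.pixel_at_risk(finch, months)

    def test_wrong_month_count_rejected(self, finch):
        with pytest.raises(ValueError):
            su.pixel_at_risk(finch, [])


class TestMonthEnergetics:
    def test_thermoneutral_month_tracks_target_schedule(self, parakeet, small_landscape):
        # a mild cell: southern edge, July
        clim = small_landscape.climate.cell(24, 12)
        terr = small_landscape.terrain.cell(24, 12)
        res = su.month_energetics(parakeet, clim, terr, 7)
        assert res.survival_ok
        day = __import__("thermorange").microclimate.build_day(clim, terr, 7, parakeet.animal_height_m)
        n_active = sum(h.is_active_window for h in day)
        expected = (n_active * parakeet.activity_multiplier + (24 - n_active)) / 24.0
        assert res.daily_mean_multiple_of_bmr == pytest.approx(expected, rel=0.25)

    def test_extreme_cold_exceeds_intake(self, finch, small_landscape):
        clim = small_landscape.climate.cell(0, 0)
        cold = dataclasses.replace(
            clim, tmin_c=clim.tmin_c - 40.0, tmax_c=clim.tmax_c - 40.0, snow=np.ones(12, dtype=bool)
        )
        res = su.month_energetics(finch, cold, small_landscape.terrain.cell(0, 0), 1)
        assert not res.survival_ok
        assert res.failure_reason == "exceeds_intake"

    def test_extreme_heat_kills_by_overheating(self, finch, small_landscape):
        clim = small_landscape.climate.cell(24, 0)
        hot = dataclasses.replace(
            clim, tmin_c=clim.tmin_c + 45.0, tmax_c=clim.tmax_c + 45.0, snow=np.zeros(12, dtype=bool)
        )
        res = su.month_energetics(finch, hot, small_landscape.terrain.cell(24, 0), 7)
        assert not res.survival_ok
        assert res.failure_reason == "below_bmr"


class TestKernelAgainstScalarPath:
    def test_monthly_energetics_match(self, finch, small_landscape):
        env = su.precompute_environment(small_landscape, finch.animal_height_m)
        surv, breed, maxmult = su.evaluate_cells(env, [finch], require_breeding=True)
        rng = np.random.default_rng(1)
        rows, cols = small_landscape.shape
        for _ in range(6):
            r, c = rng.integers(rows), rng.integers(cols)
            month = int(rng.integers(1, 13))
            cell = r * cols + c
            scalar = su.month_energetics(
                finch, small_landscape.climate.cell(r, c), small_landscape.terrain.cell(r, c), month
            )
            assert surv[0, cell, month - 1] == scalar.survival_ok
            scalar_b = su.month_energetics(
                finch, small_landscape.climate.cell(r, c), small_landscape.terrain.cell(r, c),
                month, breeding=True,
            )
            assert breed[0, cell, month - 1] == scalar_b.breeding_ok

    def test_environment_precompute_matches_build_day(self, finch, small_landscape):
        from thermorange import microclimate as mi

        env = su.precompute_environment(small_landscape, finch.animal_height_m)
        rng = np.random.default_rng(2)
        rows, cols = small_landscape.shape
        for _ in range(4):
            r, c = rng.integers(rows), rng.integers(cols)
            month = int(rng.integers(1, 13))
            cell = r * cols + c
            day = mi.build_day(
                small_landscape.climate.cell(r, c), small_landscape.terrain.cell(r, c),
                month, finch.animal_height_m,
            )
            np.testing.assert_allclose(
                env.ta[cell, month - 1], [h.air_temp_c for h in day], rtol=1e-9, atol=1e-9
            )
            np.testing.assert_allclose(
                env.sol[cell, month - 1], [h.solar_wm2 for h in day], rtol=1e-7, atol=1e-7
            )
            np.testing.assert_allclose(
                env.tr[cell, month - 1],
                [0.5 * (h.sky_temp_c + h.ground_temp_c) for h in day],
                rtol=1e-7, atol=1e-7,
            )
            np.testing.assert_allclose(
                env.wsqrt[cell, month - 1] ** 2, day[0].wind_ms, rtol=1e-9
            )
            assert np.array_equal(env.active[cell, month - 1].astype(bool),
                                  [h.is_active_window for h in day])


class TestMapSpecies:
    def test_monomorphic_equals_single_sex(self, finch, controlled_landscape):
        a = su.map_species(finch, controlled_landscape)
        b = su.map_species([finch], controlled_landscape)
        assert np.array_equal(a.at_risk, b.at_risk)

    def test_dimorphic_and_rule(self, finch, controlled_landscape):
        # a sex that fails everywhere: tiny bird, enormous metabolic ceiling demand
        doomed = dataclasses.replace(finch, bmr_w=finch.bmr_w * 1e-3)
        combined = su.map_species([finch, doomed], controlled_landscape)
        assert not combined.at_risk.any()

    def test_breeding_area_within_survival_area(self, finch, controlled_landscape):
        full = su.map_species(finch, controlled_landscape, require_breeding=True)
        surv_only = su.map_species(finch, controlled_landscape, require_breeding=False)
        assert not (full.at_risk & ~surv_only.at_risk).any()

    def test_cold_limited_range_is_contiguous_southern_block(self, controlled_finch, controlled_landscape):
        smap = su.map_species(
            controlled_finch, controlled_landscape, disable_solar=True, disable_evaporation=True
        )
        at_risk = smap.at_risk
        assert at_risk.any() and not at_risk.all()
        for col in range(at_risk.shape[1]):
            column = at_risk[:, col]
            if column.any():
                first = np.argmax(column)
                assert column[first:].all()  # contiguous down to the southern edge

    def test_cold_edge_within_one_cell_of_truth(self, controlled_finch, controlled_landscape):
        truth = sd.truth_suitability(controlled_finch, controlled_landscape.climate)
        smap = su.map_species(
            controlled_finch, controlled_landscape, disable_solar=True, disable_evaporation=True
        )
        for col in range(truth.at_risk.shape[1]):
            t_edge = np.argmax(truth.at_risk[:, col]) if truth.at_risk[:, col].any() else -1
            m_edge = np.argmax(smap.at_risk[:, col]) if smap.at_risk[:, col].any() else -1
            assert abs(t_edge - m_edge) <= 1


class TestMonotonicity:
    @pytest.mark.parametrize(
        "field,factor,direction",
        [
            ("mass", 1.3, "up"),
            ("bmr_w", 1.3, "up"),
            ("feather_depth", 1.3, "up"),
            ("core_temp_c", -1.5, "up_when_lower"),
        ],
    )
    def test_area_monotone_in_key_traits(self, finch, controlled_landscape, field, factor, direction):
        from thermorange.sensitivity import apply_variant

        base_map = su.map_species(finch, controlled_landscape)
        base_area = base_map.at_risk.sum()
        if field == "mass":
            # a heavier species carries its allometric BMR along
            varied = apply_variant(
                finch,
                ["mass_kg", "bmr_w"],
                [finch.mass_kg * factor, finch.bmr_w * factor**sd.BMR_ALLOMETRIC_EXPONENT],
            )
        elif field == "feather_depth":
            varied = apply_variant(finch, ["feather_depth_scale"], [factor])
        elif field == "core_temp_c":
            varied = dataclasses.replace(finch, core_temp_c=finch.core_temp_c + factor)
        else:
            varied = dataclasses.replace(finch, **{field: getattr(finch, field) * factor})
        new_area = su.map_species(varied, controlled_landscape).at_risk.sum()
        assert new_area >= base_area
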