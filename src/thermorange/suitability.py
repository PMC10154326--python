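"""Monthly/annual energetic suitability and the per-pixel at-risk rule.

A pixel is at risk of invasion only when (a) survival energetics succeed in
all twelve months — the daily-mean requirement never exceeds the digestible
intake ceiling (4.6 x BMR) and no hour forces the allowable rate below BMR —
and (b) a circular run of at least ``breeding_duration_months`` consecutive
months also succeeds under the 1.5 x breeding multiplier.  For dimorphic
species both sexes must pass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernel, microclimate
from .endotherm import (
    AIR_KINEMATIC_VISCOSITY,
    GROUND_REFLECTANCE,
    K_STILL_AIR,
    NUSSELT_COEFF,
    BirdTraits,
    cascade_states,
    flesh_resistance,
    insulation_resistance,
    neutral_state,
    thermoregulate,
)
from .landscape import Landscape
from .microclimate import (
    ATM_TRANSMITTANCE,
    CIVIL_TWILIGHT_DEG,
    CLEAR_SKY_EMISSIVITY_0C,
    CLEAR_SKY_EMISSIVITY_SLOPE,
    DIFFUSE_FRACTION,
    GROUND_ALBEDO,
    GROUND_SOLAR_OFFSET_C_PER_WM2,
    OVERCAST_FLOOR,
    SOLAR_CONSTANT_WM2,
    TMAX_LAG_H,
    ClimateNormals,
    TerrainCell,
    mid_month_doy,
    solar_declination_deg,
    wind_log_profile_factor,
)

__all__ = [
    "MonthEnergetics",
    "SuitabilityMap",
    "EnvArrays",
    "precompute_environment",
    "month_energetics",
    "pixel_at_risk",
    "has_circular_run",
    "map_species",
    "evaluate_cells",
    "pack_variants",
]


@dataclass
class MonthEnergetics:
    month: int
    hourly_m_required_w: np.ndarray
    daily_mean_multiple_of_bmr: float
    survival_ok: bool
    breeding_ok: bool
    failure_reason: str = "none"  # none | exceeds_intake | below_bmr


@dataclass
class SuitabilityMap:
    survival_ok: np.ndarray  # (12, rows, cols) bool
    breeding_ok: np.ndarray  # (12, rows, cols) bool
    at_risk: np.ndarray  # (rows, cols) bool
    max_monthly_multiple: np.ndarray  # (rows, cols)
    species: str = "bird"


# ---------------------------------------------------------------------------
# vectorized hourly environment (mirrors microclimate.build_day)


@dataclass
class EnvArrays:
    """Hourly environment of every cell: arrays (n_cells, 12, 24)."""

    ta: np.ndarray
    sol: np.ndarray
    tr: np.ndarray  # mean radiant temperature, 0.5*(sky+ground)
    eair_kpa: np.ndarray
    wsqrt: np.ndarray  # (n_cells, 12) sqrt of wind at animal height
    active: np.ndarray  # (n_cells, 12, 24) uint8
    cells: np.ndarray  # flat cell indices into the source grid
    grid_shape: tuple

    def without_solar(self) -> "EnvArrays":
        env = EnvArrays(
            ta=self.ta, sol=np.zeros_like(self.sol), tr=self.tr, eair_kpa=self.eair_kpa,
            wsqrt=self.wsqrt, active=self.active, cells=self.cells, grid_shape=self.grid_shape,
        )
        return env


def _esat(t):
    return 0.61078 * np.exp(17.27 * t / (t + 237.3))


def precompute_environment(
    landscape: Landscape, animal_height_m: float, cells: np.ndarray | None = None
) -> EnvArrays:
    """Vectorized 12-model-day hourly environment for all (or selected) cells."""
    climate, terrain = landscape.climate, landscape.terrain
    if cells is None:
        cells = np.arange(landscape.n_cells)
    cells = np.asarray(cells, dtype=np.int64)
    lat = climate.lat.ravel()[cells]
    n = cells.size

    months = np.arange(1, 13)
    doy = np.array([mid_month_doy(m) for m in months])
    dec = np.radians(np.array([solar_declination_deg(d) for d in doy]))  # (12,)
    phi = np.radians(lat)[:, None]  # (n, 1)

    cos_h0 = np.clip(-np.tan(phi) * np.tan(dec[None, :]), -1.0, 1.0)
    h0 = np.degrees(np.arccos(cos_h0)) / 15.0
    sunrise = 12.0 - h0  # (n, 12)

    hours = np.arange(24.0)
    tmin = climate.tmin_c.reshape(12, -1)[:, cells].T  # (n, 12)
    tmax = climate.tmax_c.reshape(12, -1)[:, cells].T
    amp = tmax - tmin
    peak = 12.0 + TMAX_LAG_H
    sr = sunrise[:, :, None]
    h = hours[None, None, :]
    day = (h >= sr) & (h <= peak)
    phase_day = (h - sr) / (peak - sr)
    night_len = 24.0 - (peak - sr)
    phase_night = 1.0 + ((h - peak) % 24.0) / night_len
    phase = np.where(day, phase_day, phase_night)
    ta = tmin[:, :, None] + amp[:, :, None] * 0.5 * (1.0 - np.cos(np.pi * phase))

    # solar position
    ha = np.radians(15.0 * (hours - 12.0))[None, None, :]
    cos_z = np.clip(
        np.sin(phi[:, :, None]) * np.sin(dec[None, :, None])
        + np.cos(phi[:, :, None]) * np.cos(dec[None, :, None]) * np.cos(ha),
        -1.0,
        1.0,
    )
    zen = np.degrees(np.arccos(cos_z))
    sin_z = np.sin(np.arccos(cos_z))
    with np.errstate(divide="ignore", invalid="ignore"):
        cos_az = (np.sin(dec[None, :, None]) - np.sin(phi[:, :, None]) * cos_z) / (
            np.cos(phi[:, :, None]) * sin_z + 1e-300
        )
    cos_az = np.clip(cos_az, -1.0, 1.0)
    az = np.degrees(np.arccos(cos_az))
    azimuth = np.where(hours[None, None, :] <= 12.0, az, 360.0 - az)
    azimuth = np.where(sin_z < 1e-12, 180.0, azimuth)

    cloud = climate.cloud_frac.reshape(12, -1)[:, cells].T  # (n, 12)
    slope = terrain.slope_deg.ravel()[cells][:, None, None]
    aspect = terrain.aspect_deg.ravel()[cells][:, None, None]
    up = zen < 90.0
    zsafe = np.where(up, zen, 0.0)
    m_air = 1.0 / (np.cos(np.radians(zsafe)) + 0.50572 * (96.07995 - zsafe) ** -1.6364)
    tau_m = ATM_TRANSMITTANCE**m_air
    beam_normal = SOLAR_CONSTANT_WM2 * tau_m
    diffuse = DIFFUSE_FRACTION * (1.0 - tau_m) * SOLAR_CONSTANT_WM2 * np.cos(np.radians(zsafe))
    sl = np.radians(slope)
    cos_inc = np.cos(np.radians(zsafe)) * np.cos(sl) + np.sin(np.radians(zsafe)) * np.sin(sl) * np.cos(
        np.radians(azimuth - aspect)
    )
    cloud_factor = (1.0 - (1.0 - OVERCAST_FLOOR) * np.clip(cloud, 0.0, 1.0))[:, :, None]
    sol = np.where(up, np.maximum(0.0, (beam_normal * np.maximum(0.0, cos_inc) + diffuse) * cloud_factor), 0.0)

    # humidity -> ambient vapor pressure (constant absolute water content)
    eair = np.minimum(_esat(tmin)[:, :, None], _esat(ta))

    # sky and ground temperatures
    eps_clear = np.minimum(1.0, CLEAR_SKY_EMISSIVITY_0C + CLEAR_SKY_EMISSIVITY_SLOPE * ta)
    eps = (1.0 - cloud[:, :, None]) * eps_clear + cloud[:, :, None]
    tsky = eps**0.25 * (ta + 273.15) - 273.15
    tgnd = ta + GROUND_SOLAR_OFFSET_C_PER_WM2 * (1.0 - GROUND_ALBEDO) * sol
    snow = climate.snow.reshape(12, -1)[:, cells].T[:, :, None]
    tgnd = np.where(snow, np.minimum(tgnd, 0.0), tgnd)
    tr = 0.5 * (tsky + tgnd)

    factors = np.array([microclimate.WIND_LANDCOVER_FACTOR[str(c)] for c in terrain.landcover.ravel()[cells]])
    wind = climate.wind_ms.reshape(12, -1)[:, cells].T * factors[:, None]
    wind = wind * wind_log_profile_factor(animal_height_m)
    wsqrt = np.sqrt(wind)

    active = (zen < 90.0 + CIVIL_TWILIGHT_DEG).astype(np.uint8)

    return EnvArrays(
        ta=np.ascontiguousarray(ta),
        sol=np.ascontiguousarray(sol),
        tr=np.ascontiguousarray(tr),
        eair_kpa=np.ascontiguousarray(eair),
        wsqrt=np.ascontiguousarray(wsqrt),
        active=np.ascontiguousarray(active),
        cells=cells,
        grid_shape=landscape.shape,
    )


# ---------------------------------------------------------------------------
# variant packing for the compiled kernel


def pack_variants(traits_list: list[BirdTraits], disable_evaporation: bool = False) -> dict:
    """Flatten variant trait sets into the kernel's parameter arrays."""
    nv = len(traits_list)
    n_parts = len(traits_list[0].parts)
    base = traits_list[0]
    cold = cascade_states(base, "cold")
    hot = cascade_states(base, "hot")
    n_states = 1 + len(cold) + len(hot)
    n_cold_end = len(cold)

    gc = np.zeros((nv, n_parts, n_states))
    area = np.zeros((nv, n_parts))
    hcoef = np.zeros((nv, n_parts))
    qabs = np.zeros((nv, n_parts))
    rflt = np.zeros((nv, n_states))
    wet = np.zeros((nv, n_states))
    shade = np.zeros(n_states, dtype=np.bool_)
    scalars = {k: np.zeros(nv) for k in (
        "tb", "tcore", "bmr", "fresp", "weff", "act_mult", "breed_mult", "ceil_mult"
    )}

    for v, tr in enumerate(traits_list):
        if len(tr.parts) != n_parts:
            raise ValueError("all variants must share the body-part structure")
        states = [neutral_state(tr)] + cascade_states(tr, "cold") + cascade_states(tr, "hot")
        if len(states) != n_states:
            raise ValueError("all variants must share the cascade-state count")
        torso = tr.parts[0]
        if torso.name != "torso":
            raise ValueError("first part must be the torso")
        for s, st in enumerate(states):
            rflt[v, s] = flesh_resistance(torso, st.k_flesh)
            wet[v, s] = 0.0 if disable_evaporation else st.wet_skin_fraction
            shade[s] = st.in_shade
        for p, part in enumerate(tr.parts):
            area[v, p] = part.area_m2
            hcoef[v, p] = NUSSELT_COEFF * K_STILL_AIR / math.sqrt(
                AIR_KINEMATIC_VISCOSITY * part.characteristic_dimension_m
            )
            if part.bare:
                rho_d = rho_v = tr.bare_part_reflectivity
            else:
                rho_d, rho_v = part.reflect_dorsal, part.reflect_ventral
            qabs[v, p] = 0.5 * (1.0 - rho_d) + GROUND_REFLECTANCE * 0.5 * (1.0 - rho_v)
            for s, st in enumerate(states):
                gc[v, p, s] = 1.0 / insulation_resistance(
                    part, st, fat_fraction=tr.fat_fraction, feather_diameter_m=tr.feather_diameter_m
                )
        scalars["tb"][v] = tr.core_temp_c - tr.core_skin_delta_c
        scalars["tcore"][v] = tr.core_temp_c
        scalars["bmr"][v] = tr.bmr_w
        scalars["fresp"][v] = 0.0 if disable_evaporation else tr.resp_fraction_effective
        scalars["weff"][v] = tr.muscle_efficiency
        scalars["act_mult"][v] = tr.activity_multiplier
        scalars["breed_mult"][v] = tr.breeding_multiplier
        scalars["ceil_mult"][v] = tr.intake_ceiling_multiplier
    return dict(
        gc=gc, area=area, hcoef=hcoef, qabs=qabs, rflt=rflt, wet=wet, shade=shade,
        n_cold_end=n_cold_end, **scalars,
    )


def evaluate_cells(
    env: EnvArrays,
    traits_list: list[BirdTraits],
    require_breeding: bool = True,
    early_exit: bool = False,
    disable_evaporation: bool = False,
):
    """Run the compiled engine; returns (surv, breed, maxmult) arrays.

    ``surv``/``breed`` are (nv, n_cells, 12) booleans, ``maxmult`` the largest
    monthly daily-mean multiple of BMR per variant and cell.
    """
    pk = pack_variants(traits_list, disable_evaporation=disable_evaporation)
    nv, n = len(traits_list), env.cells.size
    surv = np.zeros((nv, n, 12), dtype=np.uint8)
    breed = np.zeros((nv, n, 12), dtype=np.uint8)
    maxmult = np.zeros((nv, n))
    _kernel.run_maps(
        env.ta, env.sol, env.tr, env.eair_kpa, env.wsqrt, env.active,
        pk["gc"], pk["area"], pk["hcoef"], pk["qabs"], pk["rflt"], pk["wet"], pk["shade"],
        pk["tb"], pk["tcore"], pk["bmr"], pk["fresp"], pk["weff"],
        pk["act_mult"], pk["breed_mult"], pk["ceil_mult"],
        pk["n_cold_end"], require_breeding, early_exit,
        surv, breed, maxmult,
    )
    return surv.astype(bool), breed.astype(bool), maxmult


# ---------------------------------------------------------------------------
# scalar reference path


def month_energetics(
    traits: BirdTraits,
    climate_cell: ClimateNormals,
    terrain_cell: TerrainCell,
    month: int,
    breeding: bool = False,
    disable_evaporation: bool = False,
) -> MonthEnergetics:
    """Hour-by-hour thermoregulation for one cell and model day.

    The hourly target is BMR at rest and ``activity_multiplier x BMR`` during
    daylight and civil twilight; breeding multiplies the target by the
    breeding multiplier.  Hours when the allowable rate is negative
    contribute zero to the daily mean.
    """
    day = microclimate.build_day(climate_cell, terrain_cell, month, traits.animal_height_m)
    m_hours = np.zeros(24)
    died_heat = False
    for mc in day:
        mult = traits.activity_multiplier if mc.is_active_window else 1.0
        if breeding:
            mult *= traits.breeding_multiplier
        work = traits.muscle_efficiency if mc.is_active_window else 0.0
        res = thermoregulate(
            traits, mc, mult * traits.bmr_w, work_fraction=work, disable_evaporation=disable_evaporation
        )
        m_hours[mc.hour] = res.m_required_w
        if res.status == "heat_death":
            died_heat = True
    mean_mult = float(np.maximum(m_hours, 0.0).mean() / traits.bmr_w)
    ok = mean_mult <= traits.intake_ceiling_multiplier and not died_heat
    if died_heat:
        reason = "below_bmr"
    elif mean_mult > traits.intake_ceiling_multiplier:
        reason = "exceeds_intake"
    else:
        reason = "none"
    return MonthEnergetics(
        month=month,
        hourly_m_required_w=m_hours,
        daily_mean_multiple_of_bmr=mean_mult,
        survival_ok=ok and not breeding,
        breeding_ok=ok and breeding,
        failure_reason=reason,
    )


def has_circular_run(flags, duration: int) -> bool:
    """True when >= ``duration`` consecutive true months exist, wrapping Dec->Jan."""
    flags = np.asarray(flags, dtype=bool)
    if flags.size != 12:
        raise ValueError("12 monthly flags required")
    if duration <= 0:
        return True
    if flags.all():
        return True
    doubled = np.concatenate([flags, flags])
    run = best = 0
    for f in doubled:
        run = run + 1 if f else 0
        best = max(best, run)
    return best >= min(duration, 12)


def pixel_at_risk(traits: BirdTraits, months: list) -> bool:
    """At-risk rule from 12 (survival, breeding) MonthEnergetics pairs."""
    if len(months) != 12:
        raise ValueError("exactly 12 monthly pairs required")
    surv = [s.survival_ok for s, _ in months]
    breed = [b.breeding_ok for _, b in months]
    return all(surv) and has_circular_run(breed, traits.breeding_duration_months)


def map_species(
    traits,
    landscape: Landscape,
    require_breeding: bool = True,
    disable_solar: bool = False,
    disable_evaporation: bool = False,
    env: EnvArrays | None = None,
) -> SuitabilityMap:
    """Per-pixel at-risk classification over a landscape.

    ``traits`` may be a single ``BirdTraits`` or a per-sex list (dimorphic
    species): the at-risk map is then the AND over sexes, and
    ``max_monthly_multiple`` the per-cell maximum across sexes.
    """
    traits_list = traits if isinstance(traits, (list, tuple)) else [traits]
    rows, cols = landscape.shape
    at_risk = np.ones((rows, cols), dtype=bool)
    maxmult_all = np.zeros((rows, cols))
    surv_keep = None
    breed_keep = None
    for tr in traits_list:
        e = env if env is not None else precompute_environment(landscape, tr.animal_height_m)
        if disable_solar:
            e = e.without_solar()
        surv, breed, maxmult = evaluate_cells(
            e, [tr], require_breeding=require_breeding, disable_evaporation=disable_evaporation
        )
        surv, breed, maxmult = surv[0], breed[0], maxmult[0]
        ok = surv.all(axis=1)
        if require_breeding:
            runs = np.array([has_circular_run(b, tr.breeding_duration_months) for b in breed])
            ok = ok & runs
        at_risk &= ok.reshape(rows, cols)
        maxmult_all = np.maximum(maxmult_all, maxmult.reshape(rows, cols))
        surv_keep = surv.T.reshape(12, rows, cols)
        breed_keep = breed.T.reshape(12, rows, cols)
    return SuitabilityMap(
        survival_ok=surv_keep,
        breeding_ok=breed_keep,
        at_risk=at_risk,
        max_monthly_multiple=maxmult_all,
        species=traits_list[0].name,
    )
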