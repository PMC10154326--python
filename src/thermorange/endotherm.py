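"""Steady-state heat balance of a feathered endotherm.

The bird is modelled as a small set of body parts (torso, neck, head, legs,
beak) sharing one core temperature.  For each part, heat conducts from the
core through flesh, optional subcutaneous fat and the plumage (a series of
thermal resistances) to the outer surface, which exchanges energy with the
environment by convection, long-wave radiation and absorbed solar radiation.
The long-wave exchange is linearized through a radiative conductance
``h_r = 4 eps sigma T_film^3`` (film temperature midway between air and core),
so each part's surface temperature has a closed form and every returned
solution conserves energy exactly.

The required metabolic rate follows from

    M (1 - f_resp) (1 - f_work) = sum_parts Q_cond + E_cut

where ``f_resp`` is the respiratory evaporative fraction, ``f_work`` the
mechanical-work fraction during activity (muscle efficiency; that heat is
exported as work, not available for thermoregulation), and ``E_cut`` the
cutaneous evaporative loss from the wetted skin fraction.

Thermoregulation follows the cascade: physiological responses first
(vasoconstriction/vasodilation of flesh conductivity, ptiloerection, skin
wetting), then behaviour (shade seeking), stopping at the first state whose
required rate is within +-5 % of the hourly target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .microclimate import MicroclimateHour, saturation_vapor_pressure_kpa

__all__ = [
    "BodyPart",
    "BirdTraits",
    "ThermoState",
    "HeatBalanceResult",
    "geometry_from_mass",
    "insulation_resistance",
    "convective_coefficient",
    "solve_heat_balance",
    "thermoregulate",
    "cascade_states",
    "DEFAULT_PART_PROPORTIONS",
]

STEFAN_BOLTZMANN = 5.670374419e-8
#: still-air thermal conductivity within the plumage [W/m.K]
K_STILL_AIR = 0.0255
#: feather keratin thermal conductivity [W/m.K]
K_KERATIN = 0.20
#: subcutaneous fat thermal conductivity [W/m.K]
K_FAT = 0.20
#: kinematic viscosity of air [m2/s]
AIR_KINEMATIC_VISCOSITY = 1.45e-5
#: forced-convection power law Nu = C Re^n for cylinders/ellipsoids
NUSSELT_COEFF = 0.62
NUSSELT_EXPONENT = 0.5
#: free-convection floor on the convective coefficient [W/m2.K]
FREE_CONVECTION_H = 4.0
#: feather/plumage surface long-wave emissivity
SURFACE_EMISSIVITY = 0.95
#: latent-heat mass-transfer coefficient via the Lewis analogy:
#: E [W/m2] = LATENT_COEFF * h_conv * (e_skin - e_air) with e in kPa
LATENT_COEFF = 0.622 * 2.43e6 / (1006.0 * 101.325)
#: short-wave albedo of the ground for the reflected beam
GROUND_REFLECTANCE = 0.2
#: reference barb diameter for the plumage packing fraction [m]
FEATHER_DIAMETER_REF_M = 3.0e-5
PACKING_COEFF = 0.02
#: ptiloerection: maximal plumage-depth multiplier and step size
PTILOERECTION_MAX = 1.5
PTILOERECTION_STEP = 0.1
#: adjust measured geometry only when implied density is off by more than this
DENSITY_TOLERANCE = 0.05
#: bare appendages (legs, beak) conduct over an extended path representing
#: counter-current heat exchange and regional heterothermy: their flesh
#: conduction depth is this multiple of the feathered-part depth (half radius)
APPENDAGE_PATH_FACTOR = 30.0

#: body-part mass fractions used when building a bird from mass alone; the
#: leg entry is the exposed tarsus only (the feathered thigh sits in the torso)
DEFAULT_PART_PROPORTIONS = {
    "torso": 0.75,
    "neck": 0.07,
    "head": 0.14,
    "leg": 0.03,
    "beak": 0.01,
}

#: cylinder length-to-diameter ratios per part
PART_ASPECT = {"neck": 4.0, "leg": 12.0, "beak": 3.0}


@dataclass
class BodyPart:
    """Geometry and plumage of one body part.

    ``shape`` is ``"cylinder"`` (length_m, diameter_m) or ``"ellipsoid"``
    (semi-axes a >= b >= c, metres).  ``count`` duplicates the part (two legs).
    Feather depth/length are means of dorsal and ventral measurements unless
    given separately.
    """

    name: str
    shape: str
    dims_m: tuple
    feather_depth_dorsal_m: float = 0.0
    feather_depth_ventral_m: float = 0.0
    feather_length_dorsal_m: float = 0.0
    feather_length_ventral_m: float = 0.0
    reflect_dorsal: float = 0.5
    reflect_ventral: float = 0.5
    bare: bool = False
    has_subcutaneous_fat: bool = False
    count: int = 1

    def __post_init__(self) -> None:
        if self.shape not in ("cylinder", "ellipsoid"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if any(d <= 0 for d in self.dims_m):
            raise ValueError("part dimensions must be positive")
        if self.bare and (self.feather_depth_dorsal_m or self.feather_depth_ventral_m):
            raise ValueError("bare parts must have zero feather depth")
        for r in (self.reflect_dorsal, self.reflect_ventral):
            if not 0.0 <= r <= 1.0:
                raise ValueError("reflectivity must lie in [0, 1]")

    @property
    def volume_m3(self) -> float:
        if self.shape == "cylinder":
            length, diam = self.dims_m
            v = math.pi * (diam / 2.0) ** 2 * length
        else:
            a, b, c = self.dims_m
            v = 4.0 / 3.0 * math.pi * a * b * c
        return v * self.count

    @property
    def area_m2(self) -> float:
        """Outer surface area (Thomsen approximation for ellipsoids)."""
        if self.shape == "cylinder":
            length, diam = self.dims_m
            a = math.pi * diam * length + 2.0 * math.pi * (diam / 2.0) ** 2
        else:
            p = 1.6075
            ax, bx, cx = self.dims_m
            a = 4.0 * math.pi * (((ax * bx) ** p + (ax * cx) ** p + (bx * cx) ** p) / 3.0) ** (1.0 / p)
        return a * self.count

    @property
    def characteristic_dimension_m(self) -> float:
        """Flow-facing dimension for convection (cylinder diameter analogue)."""
        if self.shape == "cylinder":
            return self.dims_m[1]
        return 2.0 * self.dims_m[1]

    @property
    def flesh_radius_m(self) -> float:
        if self.shape == "cylinder":
            return self.dims_m[1] / 2.0
        return self.dims_m[2]

    @property
    def feather_depth_m(self) -> float:
        return 0.5 * (self.feather_depth_dorsal_m + self.feather_depth_ventral_m)

    @property
    def feather_length_m(self) -> float:
        return 0.5 * (self.feather_length_dorsal_m + self.feather_length_ventral_m)


@dataclass
class BirdTraits:
    """Morphology, physiology and behaviour of one modelled bird (or sex)."""

    mass_kg: float
    core_temp_c: float
    bmr_w: float
    parts: list = field(default_factory=list)
    body_density_kg_m3: float = 875.0
    fat_fraction: float = 0.05
    k_flesh_min: float = 0.41
    k_flesh_max: float = 2.80
    flesh_specific_heat_j_kgc: float = 4185.0
    muscle_efficiency: float = 0.25
    wet_skin_min: float = 0.01
    wet_skin_max: float = 0.05
    activity_multiplier: float = 2.5
    breeding_multiplier: float = 1.5
    intake_ceiling_multiplier: float = 4.6
    bare_part_reflectivity: float = 0.33
    breeding_duration_months: int = 3
    animal_height_m: float = 1.2
    ptiloerection_max: float = PTILOERECTION_MAX
    #: respiratory evaporative + sensible loss as a fraction of M at the
    #: default exhaled-air warming; scales linearly with the actual warming
    resp_evap_fraction: float = 0.05
    exhaled_air_offset_c: float = 2.0
    exhaled_air_offset_ref_c: float = 2.0
    #: empirical core-to-skin temperature depression (skin-node offset) [C]
    core_skin_delta_c: float = 0.0
    feather_diameter_m: float = FEATHER_DIAMETER_REF_M
    name: str = "bird"
    sex: str = "mono"

    def __post_init__(self) -> None:
        if self.mass_kg <= 0 or self.bmr_w <= 0:
            raise ValueError("mass and BMR must be positive")
        if self.k_flesh_min > self.k_flesh_max:
            raise ValueError("k_flesh_min must not exceed k_flesh_max")
        if not 0.0 <= self.fat_fraction < 1.0:
            raise ValueError("fat fraction must lie in [0, 1)")
        for m in (self.activity_multiplier, self.breeding_multiplier, self.intake_ceiling_multiplier):
            if m <= 0:
                raise ValueError("multipliers must be positive")
        self.breeding_duration_months = int(math.ceil(self.breeding_duration_months))
        if self.breeding_duration_months < 1:
            raise ValueError("breeding duration must be >= 1 month")

    @property
    def k_flesh_neutral(self) -> float:
        return 0.5 * (self.k_flesh_min + self.k_flesh_max)

    @property
    def resp_fraction_effective(self) -> float:
        return self.resp_evap_fraction * (self.exhaled_air_offset_c / self.exhaled_air_offset_ref_c)

    @property
    def total_area_m2(self) -> float:
        return sum(p.area_m2 for p in self.parts)


@dataclass
class ThermoState:
    """Current thermoregulatory configuration."""

    k_flesh: float
    plumage_depth_multiplier: float = 1.0
    wet_skin_fraction: float = 0.01
    in_shade: bool = False

    def validate(self, traits: BirdTraits) -> None:
        if not traits.k_flesh_min <= self.k_flesh <= traits.k_flesh_max:
            raise ValueError("k_flesh outside physiological bounds")
        if not 1.0 <= self.plumage_depth_multiplier <= traits.ptiloerection_max + 1e-12:
            raise ValueError("plumage multiplier outside [1, ptiloerection_max]")
        if not traits.wet_skin_min <= self.wet_skin_fraction <= traits.wet_skin_max + 1e-12:
            raise ValueError("wet skin fraction outside bounds")


@dataclass
class HeatBalanceResult:
    m_required_w: float
    solar_absorbed_w: float
    convection_w: float
    net_longwave_w: float
    cutaneous_evap_w: float
    respiratory_evap_w: float
    work_export_w: float
    surface_temps_c: dict
    skin_temps_c: dict
    state: ThermoState
    status: str = "balanced"

    def flux_residual_w(self) -> float:
        """Energy-closure residual: production + gains minus all losses."""
        return (
            self.m_required_w
            + self.solar_absorbed_w
            - self.convection_w
            - self.net_longwave_w
            - self.cutaneous_evap_w
            - self.respiratory_evap_w
            - self.work_export_w
        )


def neutral_state(traits: BirdTraits) -> ThermoState:
    return ThermoState(
        k_flesh=traits.k_flesh_neutral,
        plumage_depth_multiplier=1.0,
        wet_skin_fraction=traits.wet_skin_min,
        in_shade=False,
    )


# ---------------------------------------------------------------------------
# geometry


def geometry_from_mass(
    mass_kg: float,
    density_kg_m3: float = 875.0,
    part_proportions: dict | None = None,
    measured_parts: list | None = None,
) -> list:
    """Build (or density-check) body-part geometry from total mass.

    Without measured parts, each part's volume is its mass fraction times
    ``mass / density``; the torso is a 2:1:1 ellipsoid, neck/legs/beak are
    cylinders, the head a sphere.  With measured parts, dimensions are kept
    when the implied whole-bird density is within +-5 % of the target and
    rescaled isometrically otherwise.
    """
    if mass_kg <= 0 or density_kg_m3 <= 0:
        raise ValueError("mass and density must be positive")
    if measured_parts is not None:
        vol = sum(p.volume_m3 for p in measured_parts)
        implied = mass_kg / vol
        if abs(implied - density_kg_m3) / density_kg_m3 <= DENSITY_TOLERANCE:
            return list(measured_parts)
        scale = (implied / density_kg_m3) ** (1.0 / 3.0)
        return [replace(p, dims_m=tuple(d * scale for d in p.dims_m)) for p in measured_parts]

    props = dict(DEFAULT_PART_PROPORTIONS if part_proportions is None else part_proportions)
    if abs(sum(props.values()) - 1.0) > 1e-9:
        raise ValueError("part mass fractions must sum to 1")
    total_volume = mass_kg / density_kg_m3
    parts = []
    for name, frac in props.items():
        v = frac * total_volume
        if name == "torso":
            # ellipsoid with semi-axes a = 2b = 2c: V = (4/3) pi (2c) c c
            c = (3.0 * v / (8.0 * math.pi)) ** (1.0 / 3.0)
            part = BodyPart(name, "ellipsoid", (2.0 * c, c, c))
        elif name == "head":
            r = (3.0 * v / (4.0 * math.pi)) ** (1.0 / 3.0)
            part = BodyPart(name, "ellipsoid", (r, r, r))
        else:
            count = 2 if name == "leg" else 1
            aspect = PART_ASPECT.get(name, 5.0)
            d = (4.0 * v / count / (math.pi * aspect)) ** (1.0 / 3.0)
            part = BodyPart(name, "cylinder", (aspect * d, d), bare=name in ("leg", "beak"), count=count)
        parts.append(part)
    return parts


# ---------------------------------------------------------------------------
# resistances and exchange coefficients


def plumage_conductivity(part: BodyPart, feather_diameter_m: float = FEATHER_DIAMETER_REF_M) -> float:
    """Effective plumage conductivity: still air / keratin interpolation.

    The keratin weight (packing fraction) grows with barb diameter and with
    feather length relative to plumage depth:
    ``phi = clip(PACKING_COEFF * (d/d_ref) * L/D, 0.002, 0.5)``.
    """
    if part.feather_depth_m <= 0:
        return K_STILL_AIR
    phi = PACKING_COEFF * (feather_diameter_m / FEATHER_DIAMETER_REF_M) * (
        part.feather_length_m / part.feather_depth_m
    )
    phi = min(0.5, max(0.002, phi))
    return K_STILL_AIR + phi * (K_KERATIN - K_STILL_AIR)


def insulation_resistance(
    part: BodyPart,
    state: ThermoState,
    k_flesh: float | None = None,
    fat_fraction: float = 0.0,
    feather_diameter_m: float = FEATHER_DIAMETER_REF_M,
) -> float:
    """Series core-to-surface resistance per unit area [K.m2/W].

    Flesh conducts over half the part's flesh radius; subcutaneous fat (torso
    and neck) adds ``fat_fraction * flesh_radius / K_FAT``; the plumage adds
    ``depth * multiplier / k_plumage``.  Bare appendages carry flesh only,
    over a path lengthened by ``APPENDAGE_PATH_FACTOR`` (counter-current
    exchange keeps leg and beak skin far below core temperature).
    """
    kf = state.k_flesh if k_flesh is None else k_flesh
    flesh_depth = 0.5 * part.flesh_radius_m
    if part.bare:
        flesh_depth *= APPENDAGE_PATH_FACTOR
    if flesh_depth <= 0:
        raise ValueError("zero-depth flesh layer")
    r = flesh_depth / kf
    if part.has_subcutaneous_fat and fat_fraction > 0:
        r += fat_fraction * part.flesh_radius_m / K_FAT
    if not part.bare and part.feather_depth_m > 0:
        depth = part.feather_depth_m * state.plumage_depth_multiplier
        r += depth / plumage_conductivity(part, feather_diameter_m)
    return r


def flesh_resistance(part: BodyPart, k_flesh: float) -> float:
    """Core-to-skin (flesh-only) resistance per unit area [K.m2/W]."""
    return 0.5 * part.flesh_radius_m / k_flesh


def convective_coefficient(wind_ms: float, characteristic_dimension_m: float, air_temp_c: float = 15.0) -> float:
    """Convective heat-transfer coefficient [W/m2.K].

    Forced convection from ``Nu = 0.62 Re^0.5`` for a cylinder in cross-flow,
    floored by a fixed free-convection minimum of 4 W/m2.K.
    """
    if wind_ms < 0:
        raise ValueError("wind must be non-negative")
    if characteristic_dimension_m <= 0:
        raise ValueError("characteristic dimension must be positive")
    re = wind_ms * characteristic_dimension_m / AIR_KINEMATIC_VISCOSITY
    nu = NUSSELT_COEFF * re**NUSSELT_EXPONENT
    h_forced = nu * K_STILL_AIR / characteristic_dimension_m
    return max(h_forced, FREE_CONVECTION_H)


def radiative_conductance(air_temp_c: float, core_temp_c: float) -> float:
    """Linearized long-wave exchange coefficient h_r = 4 eps sigma T_film^3."""
    t_film = 0.5 * (air_temp_c + core_temp_c) + 273.15
    return 4.0 * SURFACE_EMISSIVITY * STEFAN_BOLTZMANN * t_film**3


# ---------------------------------------------------------------------------
# heat balance


def solve_heat_balance(
    traits: BirdTraits,
    state: ThermoState,
    mc: MicroclimateHour,
    target_m_w: float | None = None,
    work_fraction: float = 0.0,
    disable_evaporation: bool = False,
) -> HeatBalanceResult:
    """Metabolic rate required to hold core temperature in this microclimate.

    Solves, per part, the linear surface balance
    ``(T_core' - Ts)/r = h (Ts - Ta) + h_r (Ts - Tr) - q_sol`` and sums the
    conductive losses; cutaneous evaporation is charged to the metabolic
    budget at the torso skin temperature.  Negative values mean the bird must
    dissipate heat it cannot avoid producing.
    """
    state.validate(traits)
    tb = traits.core_temp_c - traits.core_skin_delta_c
    ta = mc.air_temp_c
    tr = 0.5 * (mc.sky_temp_c + mc.ground_temp_c)
    hr = radiative_conductance(ta, traits.core_temp_c)
    e_air = mc.rh_pct / 100.0 * saturation_vapor_pressure_kpa(ta)

    cond_total = 0.0
    conv_total = 0.0
    lw_total = 0.0
    sol_total = 0.0
    surface_temps: dict = {}
    skin_temps: dict = {}
    torso_skin = tb
    torso_h = FREE_CONVECTION_H

    for part in traits.parts:
        h = convective_coefficient(mc.wind_ms, part.characteristic_dimension_m, ta)
        r = insulation_resistance(
            part, state, fat_fraction=traits.fat_fraction, feather_diameter_m=traits.feather_diameter_m
        )
        if part.bare:
            rho_d = rho_v = traits.bare_part_reflectivity
        else:
            rho_d, rho_v = part.reflect_dorsal, part.reflect_ventral
        if mc.solar_wm2 > 0 and not state.in_shade:
            # direct beam on the dorsal silhouette (half the area), ground-
            # reflected beam on the ventral half
            q_sol = mc.solar_wm2 * (0.5 * (1.0 - rho_d) + GROUND_REFLECTANCE * 0.5 * (1.0 - rho_v))
        else:
            q_sol = 0.0
        gc = 1.0 / r
        ts = (gc * tb + h * ta + hr * tr + q_sol) / (gc + h + hr)
        area = part.area_m2
        cond = area * gc * (tb - ts)
        cond_total += cond
        conv_total += area * h * (ts - ta)
        lw_total += area * hr * (ts - tr)
        sol_total += area * q_sol
        surface_temps[part.name] = ts
        skin_temps[part.name] = tb - gc * (tb - ts) * flesh_resistance(part, state.k_flesh)
        if part.name == "torso":
            torso_skin = skin_temps[part.name]
            torso_h = h

    if disable_evaporation:
        e_cut = 0.0
        f_resp = 0.0
    else:
        deficit = max(0.0, saturation_vapor_pressure_kpa(torso_skin) - e_air)
        e_cut = state.wet_skin_fraction * traits.total_area_m2 * LATENT_COEFF * torso_h * deficit
        f_resp = traits.resp_fraction_effective

    m = (cond_total + e_cut) / ((1.0 - f_resp) * (1.0 - work_fraction))
    e_resp = f_resp * m
    work = (1.0 - f_resp) * work_fraction * m

    return HeatBalanceResult(
        m_required_w=m,
        solar_absorbed_w=sol_total,
        convection_w=conv_total,
        net_longwave_w=lw_total,
        cutaneous_evap_w=e_cut,
        respiratory_evap_w=e_resp,
        work_export_w=work,
        surface_temps_c=surface_temps,
        skin_temps_c=skin_temps,
        state=state,
    )


def cascade_states(traits: BirdTraits, direction: str) -> list[ThermoState]:
    """Ordered thermoregulatory states beyond neutral, coldest/hottest last."""
    wmin, wmax = traits.wet_skin_min, traits.wet_skin_max
    if direction == "cold":
        states = [ThermoState(traits.k_flesh_min, 1.0, wmin, False)]
        mult = 1.0
        while mult < traits.ptiloerection_max - 1e-9:
            mult = min(traits.ptiloerection_max, round(mult + PTILOERECTION_STEP, 10))
            states.append(ThermoState(traits.k_flesh_min, mult, wmin, False))
        return states
    if direction == "hot":
        return [
            ThermoState(traits.k_flesh_max, 1.0, wmin, False),
            ThermoState(traits.k_flesh_max, 1.0, wmax, False),
            ThermoState(traits.k_flesh_max, 1.0, wmax, True),
        ]
    raise ValueError(direction)


def thermoregulate(
    traits: BirdTraits,
    mc: MicroclimateHour,
    target_m_w: float,
    work_fraction: float = 0.0,
    disable_evaporation: bool = False,
    tolerance: float = 0.05,
) -> HeatBalanceResult:
    """Run the thermoregulatory cascade against an hourly metabolic target.

    Starts neutral; under cold stress (required rate > 1.05 x target)
    vasoconstricts, then ptiloerects stepwise; under heat stress (< 0.95 x
    target) vasodilates, wets the skin, then seeks shade.  Stops at the first
    state within the +-5 % band, else returns the extreme state.  The status
    is ``heat_death`` when even the extreme hot state leaves the allowable
    rate below BMR; cold failure is judged against the intake ceiling by the
    suitability layer.
    """
    solve = lambda st: solve_heat_balance(  # noqa: E731
        traits, st, mc, target_m_w, work_fraction, disable_evaporation
    )
    res = solve(neutral_state(traits))
    lo, hi = (1.0 - tolerance) * target_m_w, (1.0 + tolerance) * target_m_w
    if lo <= res.m_required_w <= hi:
        return res
    if res.m_required_w > hi:
        for st in cascade_states(traits, "cold"):
            res = solve(st)
            if res.m_required_w <= hi:
                break
        return res
    for st in cascade_states(traits, "hot"):
        res = solve(st)
        if res.m_required_w >= lo:
            break
    if res.m_required_w < lo and res.m_required_w < traits.bmr_w:
        res.status = "heat_death"
    return res
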