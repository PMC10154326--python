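"""Hourly microclimate reconstruction from monthly climate normals.

Monthly normals (tmin/tmax, wind, cloud, snow) are expanded into 24 hourly
conditions for one representative mid-month day per month (12 model days per
year), at the height the animal experiences.  The reference day course is:

* air temperature: piecewise sinusoid with the minimum at sunrise and the
  maximum at solar noon + 2 h, a symmetric cosine night branch returning to
  tmin at the next sunrise;
* relative humidity: constant absolute water content over the day, i.e. vapor
  pressure fixed at saturation at tmin, RH capped at 100 %;
* solar: clear-sky beam/diffuse from a transmittance^airmass model, projected
  on the local slope and attenuated linearly by cloud fraction;
* wind: the 2 m reference scaled by a land-cover factor (forest 0.50,
  shrub/herb 0.90, urban 0.75, other 1.00) and then by a neutral log profile
  (roughness length 0.01 m) to the animal's height;
* sky temperature: clear/overcast emissivity blend; ground temperature: air
  temperature plus a solar-driven daytime offset, clamped to <= 0 C when snow
  is present.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ClimateNormals",
    "TerrainCell",
    "MicroclimateHour",
    "SOIL_PROPERTIES",
    "WIND_LANDCOVER_FACTOR",
    "solar_geometry",
    "solar_declination_deg",
    "daylength_hours",
    "hourly_air_temperature",
    "incident_solar",
    "wind_at_height",
    "hourly_humidity",
    "saturation_vapor_pressure_kpa",
    "sky_temperature",
    "ground_temperature",
    "build_day",
    "mid_month_doy",
]

SOLAR_CONSTANT_WM2 = 1361.0
#: broadband clear-sky atmospheric transmittance (zenith path)
ATM_TRANSMITTANCE = 0.70
#: fraction of intercepted-but-scattered radiation reaching the ground as diffuse
DIFFUSE_FRACTION = 0.30
#: solar flux multiplier under full overcast
OVERCAST_FLOOR = 0.25
#: aerodynamic roughness length for the neutral log wind profile [m]
ROUGHNESS_LENGTH_M = 0.01
WIND_REFERENCE_HEIGHT_M = 2.0
#: clock hours after solar noon at which air temperature peaks
TMAX_LAG_H = 2.0
#: sky long-wave emissivity under clear sky at 0 C and its temperature slope
CLEAR_SKY_EMISSIVITY_0C = 0.72
CLEAR_SKY_EMISSIVITY_SLOPE = 0.005
#: ground warming per unit absorbed solar flux [C per W m-2]
GROUND_SOLAR_OFFSET_C_PER_WM2 = 0.010
GROUND_ALBEDO = 0.2
#: sun elevation (deg below horizon) bounding civil twilight
CIVIL_TWILIGHT_DEG = 6.0

WIND_LANDCOVER_FACTOR = {
    "forest": 0.50,
    "shrub_herb": 0.90,
    "urban": 0.75,
    "other": 1.00,
}

#: thermal conductivity [W/m.K], density [kg/m3], specific heat [J/kg.K], reflectivity
SOIL_PROPERTIES = {
    "sand": {"conductivity": 0.30, "density": 1500.0, "specific_heat": 800.0, "reflectivity": 0.30},
    "rock": {"conductivity": 2.50, "density": 2600.0, "specific_heat": 790.0, "reflectivity": 0.20},
    "soil": {"conductivity": 1.00, "density": 1300.0, "specific_heat": 1000.0, "reflectivity": 0.15},
    "concrete": {"conductivity": 1.70, "density": 2300.0, "specific_heat": 880.0, "reflectivity": 0.35},
}


@dataclass
class ClimateNormals:
    """Monthly weather normals for one cell; arrays indexed by month 0..11."""

    tmin_c: np.ndarray
    tmax_c: np.ndarray
    wind_ms: np.ndarray
    cloud_frac: np.ndarray
    snow: np.ndarray

    def __post_init__(self) -> None:
        for name in ("tmin_c", "tmax_c", "wind_ms", "cloud_frac"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (12,):
                raise ValueError(f"{name} must have 12 monthly values")
            setattr(self, name, arr)
        self.snow = np.asarray(self.snow, dtype=bool)
        if np.any(self.tmin_c > self.tmax_c):
            raise ValueError("tmin_c must not exceed tmax_c")
        if np.any(self.wind_ms < 0):
            raise ValueError("wind must be non-negative")
        if np.any((self.cloud_frac < 0) | (self.cloud_frac > 1)):
            raise ValueError("cloud fraction must lie in [0, 1]")


@dataclass
class TerrainCell:
    """Static terrain attributes of one landscape cell."""

    lat: float
    lon: float
    elevation_m: float = 0.0
    slope_deg: float = 0.0
    aspect_deg: float = 0.0
    landcover: str = "other"
    soil: str = "soil"
    soil_properties: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.landcover not in WIND_LANDCOVER_FACTOR:
            raise ValueError(f"unknown landcover {self.landcover!r}")
        if self.landcover == "urban":
            self.soil = "concrete"
        if self.soil not in SOIL_PROPERTIES:
            raise ValueError(f"unknown soil class {self.soil!r}")
        if not 0.0 <= self.slope_deg < 90.0:
            raise ValueError("slope must lie in [0, 90)")
        if not self.soil_properties:
            self.soil_properties = dict(SOIL_PROPERTIES[self.soil])


@dataclass
class MicroclimateHour:
    """The hourly thermal environment at animal height."""

    hour: int
    air_temp_c: float
    wind_ms: float
    rh_pct: float
    solar_wm2: float
    sky_temp_c: float
    ground_temp_c: float
    is_daylight: bool
    is_active_window: bool = False


def solar_declination_deg(day_of_year: int) -> float:
    """Solar declination (Cooper's formula)."""
    return 23.45 * math.sin(math.radians(360.0 * (284 + day_of_year) / 365.0))


def solar_geometry(lat: float, lon: float, day_of_year: int, hour: float):
    """Solar zenith/azimuth plus sunrise and sunset hours (local solar time).

    Hours are local solar time: solar noon is at hour 12.  Polar day and night
    are signalled with the sentinel sunrise == sunset (12.0 for polar night,
    sunrise 0.0 == sunset 24.0 treated as polar day).

    Returns (zenith_deg, azimuth_deg, sunrise_h, sunset_h).
    """
    if abs(lat) > 90.0:
        raise ValueError("latitude must lie in [-90, 90]")
    dec = math.radians(solar_declination_deg(day_of_year))
    phi = math.radians(lat)
    hour_angle = math.radians(15.0 * (hour - 12.0))
    cos_z = math.sin(phi) * math.sin(dec) + math.cos(phi) * math.cos(dec) * math.cos(hour_angle)
    cos_z = min(1.0, max(-1.0, cos_z))
    zenith = math.degrees(math.acos(cos_z))
    sin_z = math.sin(math.acos(cos_z))
    if sin_z < 1e-12:
        azimuth = 180.0
    else:
        cos_az = (math.sin(dec) - math.sin(phi) * cos_z) / (math.cos(phi) * sin_z + 1e-300)
        cos_az = min(1.0, max(-1.0, cos_az))
        az = math.degrees(math.acos(cos_az))
        azimuth = az if hour <= 12.0 else 360.0 - az
    cos_h0 = -math.tan(phi) * math.tan(dec)
    if cos_h0 >= 1.0:  # polar night
        sunrise = sunset = 12.0
    elif cos_h0 <= -1.0:  # polar day
        sunrise, sunset = 0.0, 24.0
    else:
        h0 = math.degrees(math.acos(cos_h0)) / 15.0
        sunrise, sunset = 12.0 - h0, 12.0 + h0
    return zenith, azimuth, sunrise, sunset


def daylength_hours(lat: float, day_of_year: int) -> float:
    _, _, sunrise, sunset = solar_geometry(lat, 0.0, day_of_year, 12.0)
    return sunset - sunrise


def hourly_air_temperature(tmin_c: float, tmax_c: float, hour: float, sunrise_h: float) -> float:
    """Sinusoidal day course: tmin at sunrise, tmax at solar noon + 2 h.

    A rising half-cosine runs from sunrise to the afternoon peak; a symmetric
    falling branch spans the remainder of the 24 h cycle back to tmin at the
    next sunrise.  Values never leave [tmin, tmax].
    """
    if tmin_c > tmax_c:
        raise ValueError("tmin must not exceed tmax")
    if tmax_c == tmin_c:
        return tmin_c
    peak = 12.0 + TMAX_LAG_H
    if sunrise_h >= peak:  # degenerate polar geometry; fall back to daily mean
        return 0.5 * (tmin_c + tmax_c)
    amp = tmax_c - tmin_c
    h = hour % 24.0
    if sunrise_h <= h <= peak:
        phase = (h - sunrise_h) / (peak - sunrise_h)
    else:
        elapsed = (h - peak) % 24.0
        night_len = 24.0 - (peak - sunrise_h)
        phase = 1.0 + elapsed / night_len
    return tmin_c + amp * 0.5 * (1.0 - math.cos(math.pi * phase))


def _optical_air_mass(zenith_deg: float) -> float:
    # Kasten & Young style correction keeps the mass finite near the horizon.
    z = math.radians(zenith_deg)
    return 1.0 / (math.cos(z) + 0.50572 * (96.07995 - zenith_deg) ** -1.6364)


def incident_solar(
    zenith_deg: float,
    slope_deg: float,
    aspect_deg: float,
    azimuth_deg: float,
    cloud_frac: float,
) -> float:
    """Global solar flux on an inclined surface, cloud-attenuated [W/m2].

    Clear-sky beam at normal incidence is S0 * tau^m (tau the broadband
    transmittance, m the optical air mass); the diffuse part is a fixed
    fraction of the scattered flux on the horizontal.  The beam is projected
    on the slope/aspect plane.  Cloud multiplies the total by
    ``1 - (1 - OVERCAST_FLOOR) * cloud_frac``.
    """
    if not 0.0 <= zenith_deg <= 180.0:
        raise ValueError("zenith must lie in [0, 180]")
    if zenith_deg >= 90.0:
        return 0.0
    m = _optical_air_mass(zenith_deg)
    beam_normal = SOLAR_CONSTANT_WM2 * ATM_TRANSMITTANCE**m
    cos_z = math.cos(math.radians(zenith_deg))
    diffuse = DIFFUSE_FRACTION * (1.0 - ATM_TRANSMITTANCE**m) * SOLAR_CONSTANT_WM2 * cos_z
    # angle of incidence on the tilted plane
    sl = math.radians(slope_deg)
    cos_inc = cos_z * math.cos(sl) + math.sin(math.radians(zenith_deg)) * math.sin(sl) * math.cos(
        math.radians(azimuth_deg - aspect_deg)
    )
    beam = beam_normal * max(0.0, cos_inc)
    cloud_factor = 1.0 - (1.0 - OVERCAST_FLOOR) * min(1.0, max(0.0, cloud_frac))
    return max(0.0, (beam + diffuse) * cloud_factor)


def wind_log_profile_factor(animal_height_m: float) -> float:
    """Neutral log-profile scaling from the 2 m reference to animal height."""
    z = max(animal_height_m, ROUGHNESS_LENGTH_M * math.e)
    return math.log(z / ROUGHNESS_LENGTH_M) / math.log(WIND_REFERENCE_HEIGHT_M / ROUGHNESS_LENGTH_M)


def wind_at_height(ref_wind_ms: float, landcover: str, animal_height_m: float) -> float:
    """Reference wind x land-cover factor, log-profile scaled to animal height."""
    if ref_wind_ms < 0:
        raise ValueError("wind must be non-negative")
    try:
        factor = WIND_LANDCOVER_FACTOR[landcover]
    except KeyError:
        raise ValueError(f"unknown landcover {landcover!r}") from None
    return ref_wind_ms * factor * wind_log_profile_factor(animal_height_m)


def saturation_vapor_pressure_kpa(temp_c: float) -> float:
    """Saturation vapor pressure over water (Tetens) [kPa]."""
    return 0.61078 * math.exp(17.27 * temp_c / (temp_c + 237.3))


def hourly_humidity(hourly_temps_c, tmin_c: float) -> np.ndarray:
    """RH profile with constant water mass: saturation at tmin, capped at 100 %."""
    temps = np.asarray(hourly_temps_c, dtype=float)
    if not np.all(np.isfinite(temps)):
        raise ValueError("temperatures must be finite")
    e_fixed = saturation_vapor_pressure_kpa(tmin_c)
    e_sat = 0.61078 * np.exp(17.27 * temps / (temps + 237.3))
    return np.minimum(100.0, 100.0 * e_fixed / e_sat)


def sky_temperature(air_temp_c: float, cloud_frac: float) -> float:
    """Effective radiant sky temperature from a clear/overcast emissivity blend.

    Clear-sky emissivity is ``0.72 + 0.005 * T_air``; overcast emissivity is
    1 (cloud base radiating at air temperature); the blend is linear in cloud
    fraction.  T_sky = eps^(1/4) * T_air (Kelvin).
    """
    eps_clear = min(1.0, CLEAR_SKY_EMISSIVITY_0C + CLEAR_SKY_EMISSIVITY_SLOPE * air_temp_c)
    eps = (1.0 - cloud_frac) * eps_clear + cloud_frac * 1.0
    t_k = air_temp_c + 273.15
    return eps**0.25 * t_k - 273.15


def ground_temperature(air_temp_c: float, solar_wm2: float, snow: bool) -> float:
    """Surface temperature: air + solar-driven daytime offset; <= 0 C on snow."""
    t = air_temp_c + GROUND_SOLAR_OFFSET_C_PER_WM2 * (1.0 - GROUND_ALBEDO) * solar_wm2
    if snow:
        t = min(t, 0.0)
    return t


def mid_month_doy(month: int) -> int:
    """Day of year of the representative mid-month model day (month in 1..12)."""
    if not 1 <= month <= 12:
        raise ValueError("month must lie in 1..12")
    days = [31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31]
    return sum(days[: month - 1]) + 15


def build_day(
    climate: ClimateNormals,
    terrain: TerrainCell,
    month: int,
    animal_height_m: float,
) -> list[MicroclimateHour]:
    """Compose the 24 hourly microclimates of the mid-month model day."""
    doy = mid_month_doy(month)
    mi = month - 1
    tmin, tmax = climate.tmin_c[mi], climate.tmax_c[mi]
    cloud = float(climate.cloud_frac[mi])
    snow = bool(climate.snow[mi])
    wind = wind_at_height(float(climate.wind_ms[mi]), terrain.landcover, animal_height_m)

    _, _, sunrise, sunset = solar_geometry(terrain.lat, terrain.lon, doy, 12.0)
    temps = [hourly_air_temperature(tmin, tmax, h, sunrise) for h in range(24)]
    rh = hourly_humidity(temps, tmin)

    hours: list[MicroclimateHour] = []
    for h in range(24):
        zen, azi, _, _ = solar_geometry(terrain.lat, terrain.lon, doy, float(h))
        solar = incident_solar(zen, terrain.slope_deg, terrain.aspect_deg, azi, cloud)
        hours.append(
            MicroclimateHour(
                hour=h,
                air_temp_c=temps[h],
                wind_ms=wind,
                rh_pct=float(rh[h]),
                solar_wm2=solar,
                sky_temp_c=sky_temperature(temps[h], cloud),
                ground_temp_c=ground_temperature(temps[h], solar, snow),
                is_daylight=zen < 90.0,
                is_active_window=zen < 90.0 + CIVIL_TWILIGHT_DEG,
            )
        )
    return hours
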