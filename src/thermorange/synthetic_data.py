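"""Seeded generators for synthetic landscapes, climates, species and samples.

The generators emulate the statistical structure of the real inputs of a
continental invasion-risk analysis — latitudinal and seasonal temperature
gradients, spatially autocorrelated terrain, bird trait sets with analytically
known thermal limits, and presence-only occurrence samples drawn from a known
truth map with optional accessibility bias — so every downstream stage can be
exercised without downloading anything.

Grids are northern-hemisphere by convention (month 1 = January = winter);
row 0 is the northern edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import endotherm, microclimate
from .endotherm import BirdTraits, BodyPart, ThermoState, geometry_from_mass
from .landscape import ClimateGrid, Landscape, TerrainGrid

__all__ = [
    "SyntheticConfig",
    "TruthMap",
    "generate_climate_normals",
    "generate_terrain",
    "generate_landscape",
    "generate_species",
    "truth_suitability",
    "sample_occurrences",
    "ARCHETYPES",
]


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic world.

    Temperatures describe the annual-mean air temperature at the southern,
    sea-level edge of the grid, the cooling rate with latitude and elevation,
    the seasonal (annual sinusoid) amplitude and the diurnal range.
    """

    grid_rows: int = 50
    grid_cols: int = 50
    lat_range: tuple = (30.0, 65.0)
    lon_range: tuple = (0.0, 25.0)
    sea_level_temp_c: float = 19.0
    lapse_rate_c_per_km: float = 6.5
    latitudinal_gradient_c_per_deg: float = 0.8
    seasonal_amplitude_c: float = 6.0
    diurnal_range_c: float = 8.0
    mean_wind_ms: float = 3.0
    wind_noise_ms: float = 0.3
    cloud_mean_frac: float = 0.5
    cloud_noise_frac: float = 0.15
    relief_amplitude_m: float = 400.0
    smoothing_cells: float = 3.0
    landcover_mix: dict = field(
        default_factory=lambda: {"forest": 0.35, "shrub_herb": 0.45, "urban": 0.05, "other": 0.15}
    )
    flat_terrain: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows < 2 or self.grid_cols < 2:
            raise ValueError("grid dimensions must be >= 2")
        if self.diurnal_range_c < 0:
            raise ValueError("diurnal range must be >= 0")
        if not 0.0 <= self.cloud_mean_frac <= 1.0:
            raise ValueError("cloud fraction must lie in [0, 1]")
        numeric = [
            self.sea_level_temp_c,
            self.lapse_rate_c_per_km,
            self.latitudinal_gradient_c_per_deg,
            self.seasonal_amplitude_c,
            self.diurnal_range_c,
            self.mean_wind_ms,
            self.wind_noise_ms,
            self.cloud_mean_frac,
            self.cloud_noise_frac,
            *self.lat_range,
            *self.lon_range,
        ]
        if not np.all(np.isfinite(numeric)):
            raise ValueError("configuration values must be finite")
        if abs(sum(self.landcover_mix.values()) - 1.0) > 1e-9:
            raise ValueError("land-cover mixture must sum to 1")


@dataclass
class TruthMap:
    """Analytic ground-truth suitability used as an oracle in tests.

    ``at_risk`` is true exactly where the coldest-month minimum temperature
    lies on the warm side of ``critical_isotherm_c``; the isotherm comes from
    the documented no-solar/no-evaporation conductance closed form (see
    :func:`truth_suitability`).
    """

    at_risk: np.ndarray
    critical_isotherm_c: float
    conductance_w_per_k: float
    lat: np.ndarray
    lon: np.ndarray
    coldest_tmin_c: np.ndarray
    provenance: str = ""


def _coords(cfg: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    lats = np.linspace(cfg.lat_range[1], cfg.lat_range[0], cfg.grid_rows)
    lons = np.linspace(cfg.lon_range[0], cfg.lon_range[1], cfg.grid_cols)
    lon, lat = np.meshgrid(lons, lats)
    return lat, lon


def _smooth_noise(rng: np.random.Generator, shape: tuple, sigma: float) -> np.ndarray:
    """Seeded Gaussian noise smoothed to a documented kernel width, unit std."""
    field_ = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    sd = field_.std()
    return field_ / sd if sd > 0 else field_


def generate_climate_normals(cfg: SyntheticConfig, terrain: TerrainGrid | None = None) -> ClimateGrid:
    """Monthly tmin/tmax/wind/cloud/snow grids from the configured gradients.

    The monthly mean is linear in latitude (cooling northwards) plus an
    annual sinusoid with its minimum in January; ``tmax = tmin +
    diurnal_range_c``.  When a terrain grid is supplied the lapse rate is
    applied to its elevations.  Snow is flagged where monthly tmax < 0 C.
    """
    lat, lon = _coords(cfg)
    rng = np.random.default_rng(cfg.seed)
    months = np.arange(1, 13)
    seasonal = -cfg.seasonal_amplitude_c * np.cos(2.0 * np.pi * (months - 1) / 12.0)
    tmean = (
        cfg.sea_level_temp_c
        - cfg.latitudinal_gradient_c_per_deg * (lat[None, :, :] - cfg.lat_range[0])
        + seasonal[:, None, None]
    )
    if terrain is not None:
        tmean = tmean - cfg.lapse_rate_c_per_km * terrain.elevation_m[None, :, :] / 1000.0
    tmin = tmean - cfg.diurnal_range_c / 2.0
    tmax = tmin + cfg.diurnal_range_c

    wind_field = cfg.mean_wind_ms + cfg.wind_noise_ms * _smooth_noise(rng, lat.shape, cfg.smoothing_cells)
    wind = np.clip(np.broadcast_to(wind_field, (12, *lat.shape)).copy(), 0.05, None)
    cloud_field = cfg.cloud_mean_frac + cfg.cloud_noise_frac * _smooth_noise(rng, lat.shape, cfg.smoothing_cells)
    cloud = np.clip(np.broadcast_to(cloud_field, (12, *lat.shape)).copy(), 0.0, 1.0)
    snow = tmax < 0.0
    return ClimateGrid(lat=lat, lon=lon, tmin_c=tmin, tmax_c=tmax, wind_ms=wind, cloud_frac=cloud, snow=snow)


def generate_terrain(cfg: SyntheticConfig) -> TerrainGrid:
    """Spatially autocorrelated elevation/slope/aspect plus categorical covers."""
    lat, lon = _coords(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    shape = lat.shape
    if cfg.flat_terrain or cfg.relief_amplitude_m == 0:
        elev = np.zeros(shape)
        slope = np.zeros(shape)
        aspect = np.zeros(shape)
    else:
        noise = _smooth_noise(rng, shape, cfg.smoothing_cells)
        elev = cfg.relief_amplitude_m * (noise - noise.min()) / max(np.ptp(noise), 1e-12)
        cell_m = 111_000.0 * abs(cfg.lat_range[1] - cfg.lat_range[0]) / max(cfg.grid_rows - 1, 1)
        dy, dx = np.gradient(elev, cell_m)
        slope = np.clip(np.degrees(np.arctan(np.hypot(dx, dy))), 0.0, 60.0)
        aspect = np.degrees(np.arctan2(dx, dy)) % 360.0
        aspect[np.hypot(dx, dy) == 0] = 0.0
    covers = list(cfg.landcover_mix)
    landcover = rng.choice(covers, size=shape, p=[cfg.landcover_mix[c] for c in covers]).astype(object)
    soil = rng.choice(["sand", "rock", "soil"], size=shape).astype(object)
    soil[landcover == "urban"] = "concrete"
    return TerrainGrid(
        lat=lat, lon=lon, elevation_m=elev, slope_deg=slope, aspect_deg=aspect, landcover=landcover, soil=soil
    )


def generate_landscape(cfg: SyntheticConfig, apply_lapse: bool = False) -> Landscape:
    terrain = generate_terrain(cfg)
    climate = generate_climate_normals(cfg, terrain=terrain if apply_lapse else None)
    return Landscape(climate=climate, terrain=terrain)


#: archetype trait anchors: mass, physiology, behaviour and measured-style
#: torso plumage depth (small birds carry relatively deeper plumage than an
#: isometric rescaling of a 170 g reference would give them)
ARCHETYPES = {
    "small_finch": dict(
        mass_kg=0.009, core_temp_c=41.0, animal_height_m=1.20,
        breeding_duration_months=2, feather_depth_torso_m=0.009,
    ),
    "medium_parakeet": dict(
        mass_kg=0.170, core_temp_c=41.0, animal_height_m=1.50,
        breeding_duration_months=3, feather_depth_torso_m=0.012,
    ),
    "large_pheasant": dict(
        mass_kg=1.0, core_temp_c=41.3, animal_height_m=0.20,
        breeding_duration_months=4, feather_depth_torso_m=0.020,
    ),
}

#: allometric BMR for birds: BMR [W] = 6.25 * mass[kg]^0.724
BMR_ALLOMETRIC_COEFF = 6.25
BMR_ALLOMETRIC_EXPONENT = 0.724
#: feather length relative to plumage depth
FEATHER_LENGTH_TO_DEPTH = 2.33
#: per-part plumage depth relative to torso
PART_FEATHER_FACTOR = {"torso": 1.0, "neck": 0.7, "head": 0.5}


def allometric_bmr_w(mass_kg: float) -> float:
    return BMR_ALLOMETRIC_COEFF * mass_kg**BMR_ALLOMETRIC_EXPONENT


def generate_species(archetype: str, seed: int = 0) -> BirdTraits:
    """A full trait set for one of the named archetypes.

    Geometry comes from mass at the default 875 kg/m3 density; plumage depth
    and length scale isometrically with mass from a 170 g reference; BMR
    follows the allometric power law.  The seed jitters reflectivities and
    BMR by a few percent within plausible ranges.
    """
    if archetype not in ARCHETYPES:
        raise ValueError(f"unknown archetype {archetype!r}")
    spec = ARCHETYPES[archetype]
    rng = np.random.default_rng(seed)
    mass = spec["mass_kg"]
    depth0 = spec["feather_depth_torso_m"]
    parts = geometry_from_mass(mass, 875.0)
    dressed = []
    for p in parts:
        if p.bare:
            dressed.append(p)
            continue
        f = PART_FEATHER_FACTOR.get(p.name, 0.7)
        refl_d = float(np.clip(0.25 + rng.normal(0.0, 0.02), 0.05, 0.6))
        refl_v = float(np.clip(0.35 + rng.normal(0.0, 0.02), 0.05, 0.7))
        dressed.append(
            BodyPart(
                name=p.name,
                shape=p.shape,
                dims_m=p.dims_m,
                feather_depth_dorsal_m=f * depth0,
                feather_depth_ventral_m=0.8 * f * depth0,
                feather_length_dorsal_m=f * depth0 * FEATHER_LENGTH_TO_DEPTH,
                feather_length_ventral_m=0.8 * f * depth0 * FEATHER_LENGTH_TO_DEPTH,
                reflect_dorsal=refl_d,
                reflect_ventral=refl_v,
                has_subcutaneous_fat=p.name in ("torso", "neck"),
                count=p.count,
            )
        )
    bmr = allometric_bmr_w(mass) * float(1.0 + 0.03 * rng.standard_normal())
    return BirdTraits(
        mass_kg=mass,
        core_temp_c=spec["core_temp_c"],
        bmr_w=bmr,
        parts=dressed,
        animal_height_m=spec["animal_height_m"],
        breeding_duration_months=spec["breeding_duration_months"],
        name=archetype,
    )


def truth_conductance_w_per_k(
    traits: BirdTraits, wind_ms: float, reference_air_temp_c: float
) -> float:
    """Whole-bird cold-limit conductance G [W/K] of the closed-form oracle.

    Maximal cold defence (vasoconstriction, full ptiloerection), no solar, no
    evaporation: ``G = sum_p A_p / (r_p + 1/(h_p + h_r))`` with the radiative
    conductance evaluated at the reference air temperature.
    """
    state = ThermoState(traits.k_flesh_min, traits.ptiloerection_max, traits.wet_skin_min, False)
    wind = microclimate.wind_at_height(wind_ms, "other", traits.animal_height_m)
    hr = endotherm.radiative_conductance(reference_air_temp_c, traits.core_temp_c)
    g = 0.0
    for part in traits.parts:
        h = endotherm.convective_coefficient(wind, part.characteristic_dimension_m)
        r = endotherm.insulation_resistance(
            part, state, fat_fraction=traits.fat_fraction, feather_diameter_m=traits.feather_diameter_m
        )
        g += part.area_m2 / (r + 1.0 / (h + hr))
    return g


def truth_suitability(traits: BirdTraits, climate: ClimateGrid, wind_ms: float | None = None) -> TruthMap:
    """Analytic at-risk map from the conductance closed form.

    A cell is at risk iff the coldest-month requirement
    ``M = G (T_b - T_a,min)`` stays within the intake ceiling
    (``M <= 4.6 x BMR``), i.e. iff the coldest-month tmin is on the warm side
    of the critical isotherm ``T_b - 4.6 BMR / G``.
    """
    coldest = climate.tmin_c.min(axis=0)
    if wind_ms is None:
        wind_ms = float(climate.wind_ms.mean())
    ref_ta = float(coldest.mean())
    g = truth_conductance_w_per_k(traits, wind_ms, ref_ta)
    tb = traits.core_temp_c - traits.core_skin_delta_c
    isotherm = tb - traits.intake_ceiling_multiplier * traits.bmr_w / g
    at_risk = coldest >= isotherm
    return TruthMap(
        at_risk=at_risk,
        critical_isotherm_c=isotherm,
        conductance_w_per_k=g,
        lat=climate.lat,
        lon=climate.lon,
        coldest_tmin_c=coldest,
        provenance=(
            "at_risk <=> coldest-month tmin >= Tb - ceiling*BMR/G; "
            f"G={g:.6g} W/K at wind {wind_ms:.3g} m/s, h_r at {ref_ta:.3g} C"
        ),
    )


def sample_occurrences(
    truth: TruthMap,
    n: int,
    bias_strength: float = 0.0,
    seed: int = 0,
    terrain: TerrainGrid | None = None,
    species: str = "synthetic_bird",
    range_label: str = "invasive",
    bias_scale_cells: float = 10.0,
) -> pd.DataFrame:
    """Presence-only points from at-risk cells, optionally accessibility-biased.

    Cells are drawn with replacement; with ``bias_strength`` > 0 the sampling
    weight decays as ``exp(-bias * d_urban / bias_scale_cells)`` with the
    cell-distance to the nearest urban cell.  Points are jittered uniformly
    within their cell.  Returns a DataFrame ``species,lon,lat,range``.
    """
    if not 0.0 <= bias_strength <= 1.0:
        raise ValueError("bias_strength must lie in [0, 1]")
    rows, cols = np.nonzero(truth.at_risk)
    if n > 0 and rows.size == 0:
        raise ValueError("no at-risk cells to sample from")
    rng = np.random.default_rng(seed)
    if n == 0:
        return pd.DataFrame(columns=["species", "lon", "lat", "range"])
    if bias_strength > 0:
        if terrain is None:
            raise ValueError("accessibility bias requires a terrain grid (urban cells)")
        urban = terrain.landcover == "urban"
        if not urban.any():
            dist = np.zeros(truth.at_risk.shape)
        else:
            dist = ndimage.distance_transform_edt(~urban)
        w = np.exp(-bias_strength * dist[rows, cols] / bias_scale_cells)
    else:
        w = np.ones(rows.size)
    w = w / w.sum()
    idx = rng.choice(rows.size, size=n, replace=True, p=w)
    # cell-centre coordinates plus within-cell jitter
    dlat = abs(truth.lat[1, 0] - truth.lat[0, 0]) if truth.lat.shape[0] > 1 else 0.0
    dlon = abs(truth.lon[0, 1] - truth.lon[0, 0]) if truth.lat.shape[1] > 1 else 0.0
    lat = truth.lat[rows[idx], cols[idx]] + rng.uniform(-0.5, 0.5, n) * dlat
    lon = truth.lon[rows[idx], cols[idx]] + rng.uniform(-0.5, 0.5, n) * dlon
    return pd.DataFrame({"species": species, "lon": lon, "lat": lat, "range": range_label})


def occurrence_cells(points: pd.DataFrame, grid_lat: np.ndarray, grid_lon: np.ndarray) -> np.ndarray:
    """Map occurrence points to flat cell indices of the (row-major) grid."""
    lat_axis = grid_lat[:, 0]
    lon_axis = grid_lon[0, :]
    # latitude axis decreases with row index
    r = np.abs(points["lat"].to_numpy()[:, None] - lat_axis[None, :]).argmin(axis=1)
    c = np.abs(points["lon"].to_numpy()[:, None] - lon_axis[None, :]).argmin(axis=1)
    return r * grid_lon.shape[1] + c
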