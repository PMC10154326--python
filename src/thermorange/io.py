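"""Plain-text I/O: ESRI ASCII grid rasters, trait tables and point sets.

Rasters are written as single-band ESRI ASCII grids (``.asc``), one file per
variable and month for climate normals (``tmin_01.asc`` ... ``snow_12.asc``),
plus a ``grid.json`` sidecar holding the geographic extent.  Occurrences
travel as ``species,lon,lat,range`` CSV; traits as a CSV with one species
row and one row per body part.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .endotherm import BirdTraits, BodyPart
from .landscape import ClimateGrid, Landscape, TerrainGrid

__all__ = [
    "write_ascii_grid",
    "read_ascii_grid",
    "write_landscape",
    "read_landscape",
    "write_occurrences",
    "read_occurrences",
    "write_traits",
    "read_traits",
    "write_microclimate_csv",
]

_CLIMATE_VARS = ("tmin", "tmax", "wind", "cloud", "snow")
_TERRAIN_VARS = ("elevation", "slope", "aspect")


def write_ascii_grid(path, array, xll: float, yll: float, cellsize: float, nodata: float = -9999.0) -> None:
    arr = np.asarray(array, dtype=float)
    rows, cols = arr.shape
    header = (
        f"ncols {cols}\nnrows {rows}\nxllcorner {xll}\nyllcorner {yll}\n"
        f"cellsize {cellsize}\nNODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, arr, fmt="%.6g")


def read_ascii_grid(path) -> tuple[np.ndarray, dict]:
    meta = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            meta[key.lower()] = float(val)
        arr = np.loadtxt(fh)
    return arr.reshape(int(meta["nrows"]), int(meta["ncols"])), meta


def _grid_geometry(lat: np.ndarray, lon: np.ndarray) -> tuple[float, float, float]:
    cellsize = abs(lon[0, 1] - lon[0, 0]) if lon.shape[1] > 1 else 1.0
    xll = lon.min() - cellsize / 2.0
    yll = lat.min() - cellsize / 2.0
    return xll, yll, cellsize


def write_landscape(directory, landscape: Landscape) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    clim, terr = landscape.climate, landscape.terrain
    xll, yll, cs = _grid_geometry(clim.lat, clim.lon)
    meta = {
        "lat_min": float(clim.lat.min()), "lat_max": float(clim.lat.max()),
        "lon_min": float(clim.lon.min()), "lon_max": float(clim.lon.max()),
        "rows": clim.shape[0], "cols": clim.shape[1],
    }
    (d / "grid.json").write_text(json.dumps(meta, indent=1))
    arrays = {"tmin": clim.tmin_c, "tmax": clim.tmax_c, "wind": clim.wind_ms,
              "cloud": clim.cloud_frac, "snow": clim.snow.astype(float)}
    for var, arr in arrays.items():
        for m in range(12):
            write_ascii_grid(d / f"{var}_{m + 1:02d}.asc", arr[m], xll, yll, cs)
    for var, arr in (("elevation", terr.elevation_m), ("slope", terr.slope_deg), ("aspect", terr.aspect_deg)):
        write_ascii_grid(d / f"{var}.asc", arr, xll, yll, cs)
    pd.DataFrame({
        "landcover": terr.landcover.ravel(),
        "soil": terr.soil.ravel(),
    }).to_csv(d / "categorical.csv", index=False)


def read_landscape(directory) -> Landscape:
    d = Path(directory)
    meta = json.loads((d / "grid.json").read_text())
    rows, cols = meta["rows"], meta["cols"]
    lats = np.linspace(meta["lat_max"], meta["lat_min"], rows)
    lons = np.linspace(meta["lon_min"], meta["lon_max"], cols)
    lon, lat = np.meshgrid(lons, lats)
    stacks = {}
    for var in _CLIMATE_VARS:
        stacks[var] = np.stack([read_ascii_grid(d / f"{var}_{m + 1:02d}.asc")[0] for m in range(12)])
    climate = ClimateGrid(
        lat=lat, lon=lon, tmin_c=stacks["tmin"], tmax_c=stacks["tmax"],
        wind_ms=stacks["wind"], cloud_frac=stacks["cloud"], snow=stacks["snow"] > 0.5,
    )
    cat = pd.read_csv(d / "categorical.csv")
    terrain = TerrainGrid(
        lat=lat, lon=lon,
        elevation_m=read_ascii_grid(d / "elevation.asc")[0],
        slope_deg=read_ascii_grid(d / "slope.asc")[0],
        aspect_deg=read_ascii_grid(d / "aspect.asc")[0],
        landcover=cat["landcover"].to_numpy().reshape(rows, cols).astype(object),
        soil=cat["soil"].to_numpy().reshape(rows, cols).astype(object),
    )
    return Landscape(climate=climate, terrain=terrain)


def write_occurrences(path, points: pd.DataFrame) -> None:
    points[["species", "lon", "lat", "range"]].to_csv(path, index=False)


def read_occurrences(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"species", "lon", "lat", "range"} - set(df.columns)
    if missing:
        raise ValueError(f"occurrence CSV lacks columns: {sorted(missing)}")
    return df


_SPECIES_FIELDS = [
    "mass_kg", "core_temp_c", "bmr_w", "body_density_kg_m3", "fat_fraction",
    "k_flesh_min", "k_flesh_max", "muscle_efficiency", "wet_skin_min", "wet_skin_max",
    "activity_multiplier", "breeding_multiplier", "intake_ceiling_multiplier",
    "bare_part_reflectivity", "breeding_duration_months", "animal_height_m",
    "ptiloerection_max", "resp_evap_fraction", "exhaled_air_offset_c",
    "core_skin_delta_c", "feather_diameter_m",
]
_PART_FIELDS = [
    "shape", "dim1", "dim2", "dim3",
    "feather_depth_dorsal_m", "feather_depth_ventral_m",
    "feather_length_dorsal_m", "feather_length_ventral_m",
    "reflect_dorsal", "reflect_ventral", "bare", "has_subcutaneous_fat", "count",
]


def write_traits(path, traits: BirdTraits) -> None:
    rows = [{"record": "species", "name": traits.name,
             **{f: getattr(traits, f) for f in _SPECIES_FIELDS}}]
    for p in traits.parts:
        dims = list(p.dims_m) + [np.nan] * (3 - len(p.dims_m))
        rows.append({
            "record": "part", "name": p.name, "shape": p.shape,
            "dim1": dims[0], "dim2": dims[1], "dim3": dims[2],
            "feather_depth_dorsal_m": p.feather_depth_dorsal_m,
            "feather_depth_ventral_m": p.feather_depth_ventral_m,
            "feather_length_dorsal_m": p.feather_length_dorsal_m,
            "feather_length_ventral_m": p.feather_length_ventral_m,
            "reflect_dorsal": p.reflect_dorsal, "reflect_ventral": p.reflect_ventral,
            "bare": p.bare, "has_subcutaneous_fat": p.has_subcutaneous_fat, "count": p.count,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_traits(path) -> BirdTraits:
    df = pd.read_csv(path)
    sp = df[df["record"] == "species"].iloc[0]
    parts = []
    for _, r in df[df["record"] == "part"].iterrows():
        dims = tuple(float(r[f"dim{i}"]) for i in (1, 2, 3) if np.isfinite(r[f"dim{i}"]))
        parts.append(BodyPart(
            name=r["name"], shape=r["shape"], dims_m=dims,
            feather_depth_dorsal_m=float(r["feather_depth_dorsal_m"]),
            feather_depth_ventral_m=float(r["feather_depth_ventral_m"]),
            feather_length_dorsal_m=float(r["feather_length_dorsal_m"]),
            feather_length_ventral_m=float(r["feather_length_ventral_m"]),
            reflect_dorsal=float(r["reflect_dorsal"]), reflect_ventral=float(r["reflect_ventral"]),
            bare=bool(r["bare"]), has_subcutaneous_fat=bool(r["has_subcutaneous_fat"]),
            count=int(r["count"]),
        ))
    kwargs = {f: sp[f] for f in _SPECIES_FIELDS}
    kwargs["breeding_duration_months"] = int(kwargs["breeding_duration_months"])
    return BirdTraits(parts=parts, name=sp["name"], **kwargs)


def write_microclimate_csv(path, rows: list[dict]) -> None:
    cols = ["cell_id", "month", "hour", "air_temp_c", "wind_ms", "rh_pct",
            "solar_wm2", "sky_temp_c", "ground_temp_c"]
    pd.DataFrame(rows)[cols].to_csv(path, index=False)
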