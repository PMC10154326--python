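"""Gridded landscape containers: monthly climate normals plus static terrain."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .microclimate import SOIL_PROPERTIES, ClimateNormals, TerrainCell

__all__ = ["ClimateGrid", "TerrainGrid", "Landscape"]


@dataclass
class ClimateGrid:
    """Monthly normals on a (rows, cols) grid; weather arrays are (12, rows, cols)."""

    lat: np.ndarray
    lon: np.ndarray
    tmin_c: np.ndarray
    tmax_c: np.ndarray
    wind_ms: np.ndarray
    cloud_frac: np.ndarray
    snow: np.ndarray

    def __post_init__(self) -> None:
        rc = self.lat.shape
        for name in ("tmin_c", "tmax_c", "wind_ms", "cloud_frac", "snow"):
            if getattr(self, name).shape != (12, *rc):
                raise ValueError(f"{name} must have shape (12, rows, cols)")
        if np.any(self.tmin_c > self.tmax_c):
            raise ValueError("tmin exceeds tmax")

    @property
    def shape(self) -> tuple[int, int]:
        return self.lat.shape

    @property
    def n_cells(self) -> int:
        return self.lat.size

    def cell(self, row: int, col: int) -> ClimateNormals:
        return ClimateNormals(
            tmin_c=self.tmin_c[:, row, col],
            tmax_c=self.tmax_c[:, row, col],
            wind_ms=self.wind_ms[:, row, col],
            cloud_frac=self.cloud_frac[:, row, col],
            snow=self.snow[:, row, col],
        )


@dataclass
class TerrainGrid:
    """Static terrain attributes on the same (rows, cols) grid."""

    lat: np.ndarray
    lon: np.ndarray
    elevation_m: np.ndarray
    slope_deg: np.ndarray
    aspect_deg: np.ndarray
    landcover: np.ndarray  # str array
    soil: np.ndarray  # str array

    def __post_init__(self) -> None:
        rc = self.lat.shape
        for name in ("elevation_m", "slope_deg", "aspect_deg", "landcover", "soil"):
            if getattr(self, name).shape != rc:
                raise ValueError(f"{name} shape mismatch")
        urban = self.landcover == "urban"
        if np.any(urban & (self.soil != "concrete")):
            raise ValueError("urban cells must carry concrete soil")
        if not set(np.unique(self.soil)) <= set(SOIL_PROPERTIES):
            raise ValueError("unknown soil class present")

    @property
    def shape(self) -> tuple[int, int]:
        return self.lat.shape

    def cell(self, row: int, col: int) -> TerrainCell:
        return TerrainCell(
            lat=float(self.lat[row, col]),
            lon=float(self.lon[row, col]),
            elevation_m=float(self.elevation_m[row, col]),
            slope_deg=float(self.slope_deg[row, col]),
            aspect_deg=float(self.aspect_deg[row, col]),
            landcover=str(self.landcover[row, col]),
            soil=str(self.soil[row, col]),
        )


@dataclass
class Landscape:
    """Climate + terrain bundle consumed by the mapping stages."""

    climate: ClimateGrid
    terrain: TerrainGrid

    def __post_init__(self) -> None:
        if self.climate.shape != self.terrain.shape:
            raise ValueError("climate and terrain grids must share a shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.climate.shape

    @property
    def n_cells(self) -> int:
        return self.climate.n_cells
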