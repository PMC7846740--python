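"""Regional upscaling of stand water use over a fractional-cover raster.

Each pixel contributes Fc_i * W_i * S litres per day, with Fc_i the fractional
canopy cover (0-1), W_i the stand water-use rate at 100% cover (mm/day) and S
the pixel area (m^2; 1 mm over 1 m^2 is 1 L).  Regional totals sum valid
pixels; the invaded area is the footprint of pixels with any cover.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CoverRaster",
    "WaterUseRate",
    "RegionalEstimate",
    "pixel_water_use",
    "per_pixel_map",
    "regional_totals",
    "depth_vs_precipitation",
]

DAYS_PER_YEAR = 365.0  # fixed annualization constant, no leap handling


@dataclass
class CoverRaster:
    """Georeferenced grid of fractional cover values in [0, 1].

    ``values`` may contain ``nodata`` entries; every other value must lie in
    [0, 1].  ``pixel_area_m2`` defaults to a 15 m x 15 m cell.
    """

    values: np.ndarray
    pixel_area_m2: float = 225.0
    nodata: float = -9999.0
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    cellsize: float = 15.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 2:
            raise ValueError("cover raster must be 2-D")
        if self.pixel_area_m2 <= 0:
            raise ValueError("pixel area must be > 0")
        v = self.valid_values()
        if v.size and (np.nanmin(v) < 0 or np.nanmax(v) > 1):
            raise ValueError("fractional cover values must lie in [0, 1]")

    def valid_mask(self) -> np.ndarray:
        return (self.values != self.nodata) & np.isfinite(self.values)

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask()]


@dataclass(frozen=True)
class WaterUseRate:
    """Stand water-use rate at 100% canopy cover, mm/day."""

    mm_per_day: float
    source: str  # "sapflow" | "et"

    def __post_init__(self) -> None:
        if self.mm_per_day < 0:
            raise ValueError("water-use rate must be >= 0")
        if self.source not in ("sapflow", "et"):
            raise ValueError("source must be 'sapflow' or 'et'")


@dataclass(frozen=True)
class RegionalEstimate:
    """Regional water-use totals derived from a cover raster and a rate."""

    source: str
    daily_volume_m3: float
    annual_volume_m3: float
    invaded_area_ha: float          # footprint of pixels with cover > 0
    cover_weighted_area_ha: float   # sum(Fc_i) * S, for transparency
    mean_annual_depth_mm: float     # annual volume over the invaded footprint
    n_pixels: int


def pixel_water_use(fci, rate: WaterUseRate, pixel_area_m2: float = 225.0):
    """Water use of one pixel, L/day: Fc_i * W_i * S.

    W_i in mm/day over S m^2 gives Fc_i * W_i * S litres (1 mm * 1 m^2 = 1 L).
    """
    fci = np.asarray(fci, dtype=float)
    if np.any((fci < 0) | (fci > 1)):
        raise ValueError("fractional cover must lie in [0, 1]")
    return fci * rate.mm_per_day * pixel_area_m2


def per_pixel_map(raster: CoverRaster, rate: WaterUseRate) -> np.ndarray:
    """Per-pixel water use map, L/day, with nodata propagated as NaN."""
    mask = raster.valid_mask()
    out = np.full(raster.values.shape, np.nan, dtype=np.float64)
    out[mask] = pixel_water_use(raster.values[mask], rate, raster.pixel_area_m2)
    return out


def regional_totals(raster: CoverRaster, rate: WaterUseRate) -> RegionalEstimate:
    """Sum pixel water use over the valid raster into regional totals."""
    mask = raster.valid_mask()
    if not mask.any():
        raise ValueError("all-nodata raster")
    cover = raster.values[mask].astype(np.float64)
    s = raster.pixel_area_m2
    daily_l = float(cover.sum()) * rate.mm_per_day * s
    daily_m3 = daily_l / 1000.0
    annual_m3 = daily_m3 * DAYS_PER_YEAR
    invaded_px = int(np.count_nonzero(cover > 0))
    invaded_ha = invaded_px * s / 1e4
    cover_ha = float(cover.sum()) * s / 1e4
    if invaded_ha > 0:
        depth_mm = annual_m3 / (invaded_ha * 1e4) * 1000.0
    else:
        depth_mm = 0.0
    return RegionalEstimate(
        source=rate.source,
        daily_volume_m3=daily_m3,
        annual_volume_m3=annual_m3,
        invaded_area_ha=invaded_ha,
        cover_weighted_area_ha=cover_ha,
        mean_annual_depth_mm=depth_mm,
        n_pixels=int(mask.sum()),
    )


def depth_vs_precipitation(estimate: RegionalEstimate, annual_precip_mm: float) -> float:
    """Mean annual water-use depth as a percentage of annual precipitation."""
    if annual_precip_mm <= 0:
        raise ValueError("annual precipitation must be > 0")
    return 100.0 * estimate.mean_annual_depth_mm / annual_precip_mm
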