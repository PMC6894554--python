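"""Pack-year bookkeeping and regional wolf-density surfaces.

The longitudinal pack-by-year matrix (rows = packs, columns = years) holds
observed pack sizes, 0 for absent, NaN for not-surveyed.  Panel gaps are
filled by midpoint extrapolation, pack sizes are converted to territory
densities (wolves per 1000 km²), and a circular moving window with radius
equal to the median dispersal distance turns the territory mosaic into a
regional density surface.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .covariates import circular_mean_filter
from .grids import GridSpec
from .records import TerritoryRecord

DEFAULT_DISPERSAL_MEAN_KM = 55.0


class InvalidTerritoryError(ValueError):
    pass


@dataclass(frozen=True)
class DispersalKernel:
    """Exponential dispersal-distance model with rate ``rate_per_km`` (km^-1).

    The regional smoothing radius is the median (ln 2 / rate); the
    availability buffer is the 0.95 quantile (-ln 0.05 / rate), which is
    just under 165 km for the default mean of 55 km.
    """

    rate_per_km: float = 1.0 / DEFAULT_DISPERSAL_MEAN_KM

    def __post_init__(self) -> None:
        if self.rate_per_km <= 0:
            raise ValueError("dispersal rate must be positive")

    @property
    def mean_km(self) -> float:
        return 1.0 / self.rate_per_km

    @property
    def median_km(self) -> float:
        return math.log(2.0) / self.rate_per_km

    @property
    def q95_km(self) -> float:
        return -math.log(0.05) / self.rate_per_km


@dataclass
class DensityRaster:
    grid: GridSpec
    year: int
    values: np.ndarray  # wolves per 1000 km^2
    window_radius_km: float | None = None

    def __post_init__(self) -> None:
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("density values must be finite and nonnegative")


# ---------------------------------------------------------------------------
# longitudinal matrix


def fill_midpoint(matrix: pd.DataFrame) -> pd.DataFrame:
    """Fill not-surveyed (NaN) cells by midpoint/linear extrapolation.

    A pack not surveyed at t but detected at the nearest surveyed years on
    both sides is assumed present with the (linearly interpolated) midpoint
    size, rounded half-up to an integer.  If the nearest surveyed year on
    either side records the pack absent — or no surveyed year exists on that
    side — the gap resolves to absent.
    """
    filled = matrix.copy()
    years = list(matrix.columns)
    for pack_id, row in matrix.iterrows():
        vals = row.to_numpy(float)
        isna = np.isnan(vals)
        if not isna.any():
            continue
        surveyed = np.where(~isna)[0]
        for j in np.where(isna)[0]:
            left = surveyed[surveyed < j]
            right = surveyed[surveyed > j]
            if len(left) == 0 or len(right) == 0:
                filled.loc[pack_id, years[j]] = 0.0
                continue
            jl, jr = left[-1], right[0]
            if vals[jl] < 2 or vals[jr] < 2:
                filled.loc[pack_id, years[j]] = 0.0
                continue
            frac = (j - jl) / (jr - jl)
            size = vals[jl] + frac * (vals[jr] - vals[jl])
            filled.loc[pack_id, years[j]] = math.floor(size + 0.5)  # round half-up
    return filled


def abundance_check(matrix: pd.DataFrame) -> pd.Series:
    """Per-year total wolves: row sums of the filled matrix over present packs."""
    if matrix.isna().any().any():
        raise ValueError("matrix contains not-surveyed cells; fill gaps first")
    sizes = matrix.where(matrix >= 2, 0.0)
    return sizes.sum(axis=0)


# ---------------------------------------------------------------------------
# density rasters


def territory_density(records: list[TerritoryRecord], grid: GridSpec, year: int,
                      background_per_1000km2: float = 0.0) -> DensityRaster:
    """Burn per-territory densities (1000 * size / area) into a raster.

    Overlapping territories contribute additively — summing conserves total
    wolves.  Space outside every territory gets the lone-wolf background
    density (default 0).
    """
    values = np.full(grid.shape, float(background_per_1000km2))
    for rec in records:
        if rec.area_km2 <= 0:
            raise InvalidTerritoryError(f"{rec.pack_id}/{rec.year}: non-positive area")
        if rec.size is None:
            raise InvalidTerritoryError(f"{rec.pack_id}/{rec.year}: missing pack size")
        mask = grid.rasterize(rec.polygon)
        values[mask] += 1000.0 * rec.size / rec.area_km2
    return DensityRaster(grid=grid, year=year, values=values)


def smooth_density(raster: DensityRaster, kernel: DispersalKernel | None = None,
                   radius_km: float | None = None) -> DensityRaster:
    """Circular moving-window mean with radius = median dispersal distance.

    Edge cells average over the truncated window.  The result is the
    regional (rather than local) density used to condition habitat effects.
    """
    if radius_km is None:
        radius_km = (kernel or DispersalKernel()).median_km
    if radius_km < raster.grid.cell_size:
        warnings.warn("smoothing radius below one cell; returning input unchanged")
        return DensityRaster(grid=raster.grid, year=raster.year,
                             values=raster.values.copy(), window_radius_km=radius_km)
    smoothed = circular_mean_filter(raster.values, radius_km, raster.grid.cell_size)
    return DensityRaster(grid=raster.grid, year=raster.year,
                         values=np.clip(smoothed, 0.0, None),
                         window_radius_km=radius_km)


def annual_density_surfaces(records_by_year: dict[int, list[TerritoryRecord]],
                            grid: GridSpec,
                            kernel: DispersalKernel | None = None,
                            background_per_1000km2: float = 0.0,
                            ) -> dict[int, DensityRaster]:
    """Territory densities burned and smoothed for every year."""
    kernel = kernel or DispersalKernel()
    out = {}
    for year, recs in records_by_year.items():
        raw = territory_density(recs, grid, year, background_per_1000km2)
        out[year] = smooth_density(raw, kernel)
    return out
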