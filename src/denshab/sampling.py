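"""Pack-year used/unused sampling domains and the RSPF design table.

For each pack-year the used domain is the territory polygon itself; the
available, unoccupied domain is a disc of radius equal to the 95% dispersal
quantile (164.79 km for a 55 km mean) centred on the territory centroid,
clipped to the study area, with the pack's own territory removed.  Other
occupied space is admissible only through the overlap allowance, and
otherwise down-weighted by 1 − P(occupied) from the Monte-Carlo occupancy
rasters.  Used points are drawn at one per 50 km², unused at one per
1000 km² — so an average 283 km² territory contributes about five used
points, and the used:unused ratio tracks territory size against the area
actually available to that pack.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point

from .covariates import ScalerRecord, fit_scaler
from .density import DensityRaster, DispersalKernel
from .occupancy import OccupancyRaster
from .records import TerritoryRecord
from .synthetic_world import CovariateStack

USED_RATE_KM2 = 50.0
UNUSED_RATE_KM2 = 1000.0


class InvalidRecordError(ValueError):
    pass


class NoPointsError(RuntimeError):
    pass


@dataclass
class AvailabilityDomain:
    """The unoccupied sampling domain of one pack-year."""

    pack_id: str
    year: int
    center: tuple[float, float]
    radius_km: float
    domain: shapely.Geometry              # disc ∩ study area, own territory removed
    other_territories: list               # other packs' polygons (allowance sampling)
    occupancy: OccupancyRaster | None
    overlap_allowance: float

    @property
    def effective_area_km2(self) -> float:
        return float(self.domain.area)


def overlap_proportion(year_records: list[TerritoryRecord]) -> float:
    """Sum of pairwise territory intersections over the sum of territory areas."""
    if not year_records:
        raise ValueError("need at least one territory")
    total = sum(r.polygon.area for r in year_records)
    inter = sum(a.polygon.intersection(b.polygon).area
                for a, b in combinations(year_records, 2))
    return inter / total


def build_available_domain(record: TerritoryRecord, occupancy: OccupancyRaster,
                           kernel: DispersalKernel | None = None,
                           overlap_allowance: float = 0.0,
                           year_records: list[TerritoryRecord] | None = None,
                           ) -> AvailabilityDomain:
    """Disc of radius q95(dispersal) about the territory centroid, minus self."""
    kernel = kernel or DispersalKernel()
    grid = occupancy.grid
    c = record.polygon.centroid
    if not (grid.x_min <= c.x <= grid.x_max and grid.y_min <= c.y <= grid.y_max):
        raise InvalidRecordError(
            f"{record.pack_id}/{record.year}: centroid outside study area")
    radius = kernel.q95_km
    disc = Point(c.x, c.y).buffer(radius, quad_segs=32)
    domain = disc.intersection(grid.extent_polygon).difference(record.polygon)
    shapely.prepare(domain)
    others = [r.polygon for r in (year_records or [])
              if r.pack_id != record.pack_id and r.polygon.distance(disc) == 0]
    return AvailabilityDomain(
        pack_id=record.pack_id, year=record.year, center=(c.x, c.y),
        radius_km=radius, domain=domain, other_territories=others,
        occupancy=occupancy, overlap_allowance=float(overlap_allowance),
    )


def _uniform_in_polygon(polygon, n: int, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample n points uniformly inside a polygon."""
    if polygon.is_empty or polygon.area == 0:
        raise NoPointsError("cannot sample from an empty region")
    shapely.prepare(polygon)
    minx, miny, maxx, maxy = polygon.bounds
    out = np.empty((n, 2))
    got = 0
    while got < n:
        m = (n - got) * max(4, int(2 * (maxx - minx) * (maxy - miny) / max(polygon.area, 1e-9)))
        m = min(m, 200_000)
        px = rng.uniform(minx, maxx, m)
        py = rng.uniform(miny, maxy, m)
        ok = shapely.contains_xy(polygon, px, py)
        px, py = px[ok], py[ok]
        take = min(px.size, n - got)
        out[got:got + take, 0] = px[:take]
        out[got:got + take, 1] = py[:take]
        got += take
    return out


def draw_used(record: TerritoryRecord, rate_km2: float = USED_RATE_KM2,
              rng: np.random.Generator | None = None) -> pd.DataFrame:
    """One uniform point per ``rate_km2`` of territory (minimum one)."""
    if record.polygon.area <= 0:
        raise InvalidRecordError("territory has zero area")
    rng = rng or np.random.default_rng()
    n = n_points_for_area(record.polygon.area, rate_km2)
    pts = _uniform_in_polygon(record.polygon, n, rng)
    return pd.DataFrame({"pack_id": record.pack_id, "year": record.year,
                         "x_km": pts[:, 0], "y_km": pts[:, 1], "y": 1})


def n_points_for_area(area_km2: float, rate_km2: float) -> int:
    return max(1, int(math.floor(area_km2 / rate_km2)))


def _stratified_weighted(domain: AvailabilityDomain, n: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Spatially balanced weighted sample: one candidate per grid stratum,
    accepted with probability proportional to 1 − P(occupied).

    Occupied space is excluded through the occupancy weight itself (cells
    certainly inside a territory have P = 1 and are never accepted), which is
    exactly the inverse-probability-of-occupancy design.
    """
    region = domain.domain
    if region.is_empty or region.area == 0:
        raise NoPointsError(f"{domain.pack_id}/{domain.year}: empty unoccupied domain")
    occ = domain.occupancy
    minx, miny, maxx, maxy = region.bounds
    out: list[tuple[float, float]] = []
    # stratum edge sized so a few candidates per requested point exist
    n_strata_target = max(4 * n, 16)
    edge = math.sqrt(region.area / n_strata_target)
    for _ in range(12):  # refine strata until enough accepted points
        nx = max(1, int(math.ceil((maxx - minx) / edge)))
        ny = max(1, int(math.ceil((maxy - miny) / edge)))
        sx = rng.permutation(nx * ny)
        out.clear()
        gx = minx + (sx % nx) * edge
        gy = miny + (sx // nx) * edge
        px = gx + rng.uniform(0, edge, sx.size)
        py = gy + rng.uniform(0, edge, sx.size)
        ok = shapely.contains_xy(region, px, py)
        px, py = px[ok], py[ok]
        if occ is not None:
            r_i, c_i = occ.grid.index_of(px, py)
            w = 1.0 - occ.values[r_i, c_i]
        else:
            w = np.ones(px.size)
        accept = rng.random(px.size) < w
        px, py = px[accept], py[accept]
        if px.size >= n:
            return np.column_stack([px[:n], py[:n]])
        out = list(zip(px, py))
        edge *= 0.7
    if not out:
        raise NoPointsError(f"{domain.pack_id}/{domain.year}: weight surface excludes all points")
    arr = np.array(out)
    reps = int(math.ceil(n / len(arr)))
    return np.tile(arr, (reps, 1))[:n]


def draw_unused(domain: AvailabilityDomain, rate_km2: float = UNUSED_RATE_KM2,
                rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Unused points: allowance fraction inside other territories, the rest
    spatially balanced over unoccupied space weighted by 1 − P(occupied)."""
    rng = rng or np.random.default_rng()
    if domain.domain.is_empty or domain.domain.area == 0:
        raise NoPointsError(f"{domain.pack_id}/{domain.year}: empty domain")
    n = n_points_for_area(domain.effective_area_km2, rate_km2)
    n_overlap = int(round(domain.overlap_allowance * n))
    if not domain.other_territories:
        n_overlap = 0
    pts = []
    if n_overlap > 0:
        # pick other territories area-proportionally, then a uniform point in
        # each, kept only if it falls inside the availability disc
        areas = np.array([p.area for p in domain.other_territories])
        got = []
        for _ in range(20 * n_overlap):
            poly = domain.other_territories[rng.choice(len(areas), p=areas / areas.sum())]
            p = _uniform_in_polygon(poly, 1, rng)[0]
            if shapely.contains_xy(domain.domain, p[0], p[1]):
                got.append(p)
            if len(got) == n_overlap:
                break
        if got:
            pts.append(np.array(got))
        n_overlap = len(got)
    n_rest = n - n_overlap
    if n_rest > 0:
        pts.append(_stratified_weighted(domain, n_rest, rng))
    pts = np.vstack(pts)
    return pd.DataFrame({"pack_id": domain.pack_id, "year": domain.year,
                         "x_km": pts[:, 0], "y_km": pts[:, 1], "y": 0})


# ---------------------------------------------------------------------------
# design-table assembly


def assemble_sample_table(points: pd.DataFrame, stack: CovariateStack,
                          density_by_year: dict[int, DensityRaster],
                          covariate_scaler: ScalerRecord | None = None,
                          density_scaler: ScalerRecord | None = None,
                          ) -> tuple[pd.DataFrame, ScalerRecord, ScalerRecord]:
    """Attach standardized covariates and regional density to sampled points.

    Covariates and wolf density are centred and scaled over the assembled
    table itself (all fixed effects are centred at fitting time), so z = 0
    is the mean condition of the design — "conditional on mean wolf
    density".  Pass pre-fitted scalers to standardize new points on the same
    basis.  Points falling off the raster are dropped (count recorded in the
    returned table's attrs).
    """
    grid = stack.grid
    pts = points.copy()
    inside = grid.contains(pts["x_km"].to_numpy(), pts["y_km"].to_numpy())
    n_dropped = int((~inside).sum())
    pts = pts.loc[inside].reset_index(drop=True)
    row, col = grid.index_of(pts["x_km"].to_numpy(), pts["y_km"].to_numpy())
    raw_cov = {name: layer[row, col] for name, layer in stack.layers.items()}
    dens = np.empty(len(pts))
    for year, sub in pts.groupby("year"):
        raster = density_by_year[year]
        r_i, c_i = raster.grid.index_of(sub["x_km"].to_numpy(), sub["y_km"].to_numpy())
        dens[sub.index.to_numpy()] = raster.values[r_i, c_i]
    if covariate_scaler is None:
        covariate_scaler = fit_scaler(raw_cov)
    if density_scaler is None:
        density_scaler = fit_scaler({"wolf_density": dens})
    for name in stack.layers:
        pts[name] = covariate_scaler.transform(name, raw_cov[name])
    pts["wolf_density"] = density_scaler.transform("wolf_density", dens)
    if pts.isna().any().any():
        raise ValueError("sample table contains missing covariates")
    pts.attrs["n_dropped_off_raster"] = n_dropped
    return pts, covariate_scaler, density_scaler


def design_table(records_by_year: dict[int, list[TerritoryRecord]],
                 stack: CovariateStack,
                 density_by_year: dict[int, DensityRaster],
                 occupancy_by_year: dict[int, OccupancyRaster],
                 kernel: DispersalKernel | None = None,
                 overlap_allowance: str | float = "measured",
                 used_rate_km2: float = USED_RATE_KM2,
                 unused_rate_km2: float = UNUSED_RATE_KM2,
                 seed: int = 0):
    """Full pack-year sampling design over all years.

    ``overlap_allowance='measured'`` uses each year's measured overlap
    proportion as the fraction of unused points allowed inside other
    occupied territories, mirroring the observed rise in territory overlap.
    """
    kernel = kernel or DispersalKernel()
    rng = np.random.default_rng(seed)
    frames = []
    for year in sorted(records_by_year):
        recs = records_by_year[year]
        if not recs:
            continue
        allowance = (overlap_proportion(recs) if overlap_allowance == "measured"
                     else float(overlap_allowance))
        occ = occupancy_by_year[year]
        for rec in recs:
            frames.append(draw_used(rec, used_rate_km2, rng))
            dom = build_available_domain(rec, occ, kernel, allowance, recs)
            frames.append(draw_unused(dom, unused_rate_km2, rng))
    points = pd.concat(frames, ignore_index=True)
    return assemble_sample_table(points, stack, density_by_year)
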