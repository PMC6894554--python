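"""Monte-Carlo territory-boundary uncertainty → occupancy-probability rasters.

Observed territory boundaries are imperfect, so for each year we build
``n_sim`` plausible versions of every pack's territory by resampling its
area from a normal distribution (pack-specific when telemetry supports it,
population-level otherwise) and rescaling the baseline polygon to the
sampled area by signed buffering.  Rasterizing each replicate's union and
averaging yields P(cell occupied) per year — the probabilistic resistance
surface used when drawing available points.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from shapely.geometry import MultiPolygon, Polygon
from shapely.ops import unary_union

from .grids import GridSpec
from .records import TerritoryRecord

TELEMETRY_TAGS = ("A-yearly", "A-window", "A", "B", "truth")


@dataclass
class OccupancyRaster:
    grid: GridSpec
    year: int
    values: np.ndarray  # P(cell occupied), multiples of 1/n_sim
    n_sim: int

    def __post_init__(self) -> None:
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("occupancy probabilities must lie in [0, 1]")


@dataclass
class AreaStats:
    """Territory-area means/sds: per pack (telemetry-based) and population-wide."""

    pack_mean: dict[str, float]
    pack_sd: dict[str, float]
    population_mean: float
    population_sd: float


def compute_area_stats(all_records: list[TerritoryRecord]) -> AreaStats:
    """Summarize UD-based areas per pack and across the population.

    Only telemetry-based estimates (kernel methods) inform the statistics;
    method-C (track-only MCP) packs fall back to the population numbers.
    """
    by_pack: dict[str, list[float]] = {}
    ud_areas = []
    for rec in all_records:
        if rec.method_tag in TELEMETRY_TAGS:
            by_pack.setdefault(rec.pack_id, []).append(rec.area_km2)
            ud_areas.append(rec.area_km2)
    if not ud_areas:
        ud_areas = [rec.area_km2 for rec in all_records]
    pack_mean = {p: float(np.mean(a)) for p, a in by_pack.items() if len(a) >= 2}
    pack_sd = {p: float(np.std(by_pack[p], ddof=1)) for p in pack_mean}
    return AreaStats(
        pack_mean=pack_mean, pack_sd=pack_sd,
        population_mean=float(np.mean(ud_areas)),
        population_sd=float(np.std(ud_areas, ddof=1)) if len(ud_areas) > 1 else 0.0,
    )


def sample_territory_area(record: TerritoryRecord, stats: AreaStats,
                          rng: np.random.Generator) -> float:
    """Draw a plausible area for one pack-year, truncated below at 10% of mean.

    Packs with >= 2 telemetry pack-years use their own sd around the
    current-year area (method A / yearly) or the long-term pack mean
    (method B); otherwise the population mean/sd applies.
    """
    pid = record.pack_id
    if record.method_tag in TELEMETRY_TAGS and pid in stats.pack_sd:
        mean = record.area_km2 if record.method_tag.startswith("A") else stats.pack_mean[pid]
        sd = stats.pack_sd[pid]
    else:
        mean, sd = stats.population_mean, stats.population_sd
    floor = 0.1 * mean
    for _ in range(200):
        a = rng.normal(mean, sd) if sd > 0 else mean
        if a >= floor:
            return float(a)
    return float(floor)


def rescale_polygon(polygon: Polygon, target_area_km2: float,
                    rel_tol: float = 0.01) -> Polygon:
    """Dilate/erode a polygon to a target area via 1-D root-finding on offset.

    The signed buffer distance is bracketed and solved with Brent's method
    until |area - target| / target <= rel_tol.  If erosion splits the
    polygon the largest component is kept; if the target is unreachable
    (polygon vanishes first) the smallest non-vanishing shape near 10% of
    the baseline area is returned with a warning.
    """
    if target_area_km2 <= 0:
        raise ValueError("target area must be positive")
    base = polygon.area
    if abs(base - target_area_km2) / target_area_km2 <= rel_tol:
        return polygon

    def buffered(d: float):
        # keep every part while solving: total area is continuous and
        # monotone in the offset, so the bracket is always valid
        return polygon.buffer(d, quad_segs=8)

    def f(d: float) -> float:
        return buffered(d).area - target_area_km2

    scale = np.sqrt(base)
    if target_area_km2 > base:
        lo, hi = 0.0, scale
        while f(hi) < 0:
            hi *= 2.0
    else:
        hi = 0.0
        lo = -0.05 * scale
        while f(lo) > 0:
            lo *= 2.0
            if buffered(lo).area <= 0:
                warnings.warn("target area unreachable by erosion; returning minimal polygon")
                # walk back up to the smallest surviving shape (~10% of baseline)
                d = lo
                while buffered(d).area < 0.1 * base:
                    d *= 0.9
                return buffered(d)
    d_star = brentq(f, lo, hi, xtol=1e-6 * max(scale, 1.0))
    result = buffered(d_star)
    if isinstance(result, MultiPolygon) and isinstance(polygon, Polygon):
        # erosion split a contiguous territory: keep the main body when it
        # still carries essentially all of the target area
        largest = max(result.geoms, key=lambda g: g.area)
        if largest.area >= (1.0 - rel_tol) * target_area_km2:
            result = largest
    return result


class _OffsetAreaCurve:
    """Tabulated signed-offset → area curve for fast repeated rescaling.

    The Monte-Carlo loop rescales the same baseline polygon hundreds of
    times; interpolating the (monotone) offset-area relation replaces a full
    root-find per draw with a single buffer call, falling back to
    :func:`rescale_polygon` when the interpolated offset misses tolerance.
    """

    def __init__(self, polygon, simplify_tol: float = 0.25, rel_tol: float = 0.01):
        self.polygon = polygon.simplify(simplify_tol) if simplify_tol else polygon
        self.rel_tol = rel_tol
        scale = np.sqrt(self.polygon.area)
        deltas = np.concatenate([
            -np.geomspace(0.005, 0.6, 10)[::-1], [0.0], np.geomspace(0.005, 1.2, 10),
        ]) * scale
        offs, areas = [], []
        for d in deltas:
            a = self.polygon.buffer(d, quad_segs=4).area
            if a > 0:
                offs.append(d)
                areas.append(a)
        self.offsets = np.asarray(offs)
        self.areas = np.asarray(areas)

    def __call__(self, target_area_km2: float):
        if target_area_km2 <= self.areas[0] or target_area_km2 >= self.areas[-1]:
            return rescale_polygon(self.polygon, target_area_km2, self.rel_tol)
        d = float(np.interp(target_area_km2, self.areas, self.offsets))
        p = self.polygon.buffer(d, quad_segs=4)
        if isinstance(p, MultiPolygon):
            largest = max(p.geoms, key=lambda g: g.area)
            if largest.area >= (1.0 - self.rel_tol) * target_area_km2:
                p = largest
        if p.area <= 0 or abs(p.area - target_area_km2) / target_area_km2 > self.rel_tol:
            return rescale_polygon(self.polygon, target_area_km2, self.rel_tol)
        return p


def occupancy_probability(year_records: list[TerritoryRecord], grid: GridSpec,
                          year: int, stats: AreaStats | None = None,
                          n_sim: int = 100, seed: int = 0) -> OccupancyRaster:
    """Mean of ``n_sim`` rasterized replicate territory mosaics.

    Each pack gets an independent substream spawned from the seed and the
    pack id, so adding or removing one pack leaves the other packs' draws
    unchanged (common random numbers across scenarios).
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    if not year_records:
        return OccupancyRaster(grid=grid, year=year,
                               values=np.zeros(grid.shape), n_sim=n_sim)
    if stats is None:
        stats = compute_area_stats(year_records)
    counts = np.zeros(grid.shape)
    # per-pack substreams keyed by a stable digest of the pack id, so one
    # pack's draws are independent of which other packs are present
    streams = {
        rec.pack_id: np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(
                zlib.crc32(rec.pack_id.encode()) & 0x7FFFFFFF,)))
        for rec in year_records
    }
    curves = {rec.pack_id: _OffsetAreaCurve(rec.polygon) for rec in year_records}
    for _ in range(n_sim):
        polys = []
        for rec in year_records:
            area = sample_territory_area(rec, stats, streams[rec.pack_id])
            polys.append(curves[rec.pack_id](area))
        union = unary_union(polys)
        counts += grid.rasterize(union)
    return OccupancyRaster(grid=grid, year=year, values=counts / n_sim, n_sim=n_sim)
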